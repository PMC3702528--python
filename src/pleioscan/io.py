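"""Tab-separated file I/O and flat key:value configuration.

All tabular files are TSV with a header row, UTF-8, ``NA`` for missing
values; positions are 1-based and chromosomes are strings.  The summary
format mirrors GWAS meta-analysis release tables:

    snp_id  chrom  pos  maf  n  z_<trait1> ... z_<traitd>

Raw mode uses a phenotype TSV (header = trait names, one row per
individual) plus a genotype TSV (one SNP per row: ``snp_id`` then one
column per individual).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .eb import EBWeights
from .summary import RawDataset, SnpSummaryRecord

__all__ = [
    "ScanConfig",
    "read_summary_tsv",
    "write_summary_tsv",
    "read_phenotypes_tsv",
    "write_phenotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "write_weights_tsv",
    "read_weights_tsv",
    "read_config",
]

NA = "NA"


@dataclass
class ScanConfig:
    """Configuration of a scan run; file values are overridden by CLI flags."""

    mode: str = "summary"  # raw | summary
    sigma_grid: Tuple[float, ...] = (0.05, 0.1, 0.2, 0.4, 0.8)
    sigma_weights: Optional[Tuple[float, ...]] = None
    pi0: float = 0.5
    stage1_p: float = 1e-4
    null_z_threshold: float = 2.0
    min_n: Optional[int] = None
    prune_window: int = 500_000
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("raw", "summary"):
            raise ValueError("mode must be 'raw' or 'summary'")
        if not (0.0 <= self.pi0 <= 1.0):
            raise ValueError("pi0 must lie in [0, 1]")
        if not (0.0 < self.stage1_p <= 1.0):
            raise ValueError("stage1_p must lie in (0, 1]")
        g = np.asarray(self.sigma_grid, dtype=float)
        if np.any(g <= 0):
            raise ValueError("sigma grid values must be positive")
        if self.sigma_weights is not None:
            w = np.asarray(self.sigma_weights, dtype=float)
            if w.size != g.size or np.any(w < 0) or abs(w.sum() - 1.0) > 1e-8:
                raise ValueError("sigma weights must be a probability vector "
                                 "matching the grid")

    def config_hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_config(path: Union[str, Path]) -> Dict[str, str]:
    """Flat ``key: value`` text config; '#' starts a comment."""
    out: Dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, _, value = line.partition(":")
        out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# summary-statistic tables


def read_summary_tsv(path: Union[str, Path]) -> Tuple[List[SnpSummaryRecord], List[str]]:
    """Read summary records; returns (records, trait names).  Raises with the
    offending line number on malformed rows."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=[NA])
    required = ["snp_id", "chrom", "pos", "maf", "n"]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    zcols = [c for c in df.columns if c.startswith("z_")]
    if not zcols:
        raise ValueError(f"{path}: no z_<trait> columns found")
    traits = [c[2:] for c in zcols]
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                SnpSummaryRecord(
                    snp_id=str(row["snp_id"]),
                    chrom=str(row["chrom"]),
                    pos=int(row["pos"]),
                    maf=float(row["maf"]),
                    n=int(row["n"]),
                    z=np.array([float(row[c]) for c in zcols]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return records, traits


def write_summary_tsv(path: Union[str, Path], records: Sequence[SnpSummaryRecord],
                      trait_names: Sequence[str]) -> None:
    rows = []
    for r in records:
        row = {"snp_id": r.snp_id, "chrom": r.chrom, "pos": r.pos,
               "maf": r.maf, "n": r.n}
        for name, z in zip(trait_names, r.z):
            row[f"z_{name}"] = z
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep=NA)


# ---------------------------------------------------------------------------
# raw mode


def read_phenotypes_tsv(path: Union[str, Path]) -> Tuple[np.ndarray, List[str]]:
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    return df.to_numpy(dtype=float), list(df.columns)


def write_phenotypes_tsv(path: Union[str, Path], Y: np.ndarray,
                         trait_names: Sequence[str]) -> None:
    pd.DataFrame(np.atleast_2d(Y), columns=list(trait_names)).to_csv(
        path, sep="\t", index=False, na_rep=NA
    )


def read_genotypes_tsv(path: Union[str, Path]) -> Tuple[List[str], np.ndarray]:
    """Returns (snp ids, genotype matrix with one row per SNP)."""
    df = pd.read_csv(path, sep="\t", na_values=[NA])
    if df.columns[0] != "snp_id":
        raise ValueError(f"{path}: first column must be 'snp_id'")
    ids = df["snp_id"].astype(str).tolist()
    G = df.drop(columns=["snp_id"]).to_numpy(dtype=float)
    return ids, G


def write_genotypes_tsv(path: Union[str, Path], snp_ids: Sequence[str],
                        G: np.ndarray) -> None:
    G = np.atleast_2d(G)
    cols = [f"ind{i+1}" for i in range(G.shape[1])]
    df = pd.DataFrame(G, columns=cols)
    df.insert(0, "snp_id", list(snp_ids))
    df.to_csv(path, sep="\t", index=False, na_rep=NA)


def raw_dataset_from_files(pheno_path: Union[str, Path],
                           geno_path: Union[str, Path],
                           snp_index: int = 0) -> Tuple[RawDataset, str]:
    Y, traits = read_phenotypes_tsv(pheno_path)
    ids, G = read_genotypes_tsv(geno_path)
    if G.shape[1] != Y.shape[0]:
        raise ValueError("genotype individual count does not match phenotype rows")
    return RawDataset(Y=Y, g=G[snp_index], trait_names=traits), ids[snp_index]


# ---------------------------------------------------------------------------
# EM weights


def write_weights_tsv(path: Union[str, Path], eb: EBWeights) -> None:
    if eb.labels is None:
        raise ValueError("weights carry no (partition, sigma) labels")
    df = pd.DataFrame(
        {"partition": [p for p, _ in eb.labels],
         "sigma_a": [s for _, s in eb.labels],
         "weight": eb.weights}
    )
    df.to_csv(path, sep="\t", index=False)


def read_weights_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("partition", "sigma_a", "weight"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return df
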