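"""Single-SNP analysis: which of two correlated traits does a variant affect?

Simulates one bivariate dataset in which the genotype directly affects
trait 1 only (trait 2 is merely correlated with trait 1), computes Bayes
factors for all six partitions of the two traits into
unassociated/direct/indirect, and prints the posterior.
"""

import numpy as np

from pleioscan import (
    ScenarioSpec,
    compute_bf_table,
    default_partition_prior,
    posterior_partitions,
    simulate_bivariate,
    sufficient_from_raw,
)

spec = ScenarioSpec(name="bivariate-U", n=1000, maf=0.2, effects=(0.25,),
                    rho=0.6, seed=3)
sim = simulate_bivariate(spec)
stats = sufficient_from_raw(sim.data)

prior = default_partition_prior(d=2, pi0=0.5)
sigma_grid = [0.05, 0.1, 0.2, 0.4, 0.8]
tab = compute_bf_table(stats, sigma_grid, prior)
post = posterior_partitions(tab.partitions, tab.log10_bf, prior,
                            np.full(5, 0.2))

print(f"true partition        : {sim.truth}")
print(f"log10 BF_av           : {tab.log10_bf_av:.2f}")
print(f"log10 BF_all          : {tab.log10_bf_all:.2f}   (standard multivariate test)")
print(f"log10 BF_uni          : {tab.log10_bf_uni:.2f}   (best-univariate-style test)")
print(f"P(global null | data) : {post.p_null:.4f}")
print("\nper-trait category probabilities:")
for j, name in enumerate(stats.trait_names):
    u, d, i = post.trait_category_probs[j]
    print(f"  {name}: P(U)={u:.3f}  P(D)={d:.3f}  P(I)={i:.3f}")
print("\ntop partitions:")
for gamma, p in post.top_partitions(3):
    print(f"  {gamma.to_string():<16} {p:.3f}")

# A large BF_av and a dominant partition with trait 1 direct / trait 2
# unassociated mean the variant's effect is specific to trait 1, despite
# the 0.6 trait correlation.
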