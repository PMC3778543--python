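"""Group samples into viral-enterotypes and validate the grouping.

Generates a 40-sample cohort with four planted abundance-profile groups,
runs the two-pass heuristic grouping (Spearman profile similarity, 40%
incidence noise rule), and validates with Bray-Curtis + non-metric MDS +
ANOSIM.
"""

from sklearn.metrics import adjusted_rand_score

from pgsr.enterotypes import anosim, bray_curtis, heuristic_group, nmds
from pgsr.simulate import make_enterotype_cohort

matrix, truth = make_enterotype_cohort(seed=11)
assign = heuristic_group(matrix, noise_incidence=40.0, tau=0.6, seed=5)

ari = adjusted_rand_score(
    [truth[s] for s in matrix.sample_ids],
    [assign.assignments[s] for s in matrix.sample_ids],
)
bc = bray_curtis(matrix)
ordination = nmds(bc, seed=7)
result = anosim(bc, assign.assignments, n_permutations=999, seed=9)

sizes = {
    g: sum(v == g for v in assign.assignments.values())
    for g in sorted(set(assign.assignments.values()))
}
print(f"group sizes: {sizes}")
print(f"adjusted Rand index vs planted truth: {ari:.3f}")
print(f"ANOSIM R = {result.R:.3f}, p = {result.p_value:.4g} "
      f"({result.n_permutations} permutations)")
print(f"NMDS Kruskal stress-1 = {ordination.stress:.3f}")
print(
    "ARI 1.0 means the heuristic recovered the planted groups exactly;\n"
    "R near 1 with small p confirms between-group separation exceeds\n"
    "within-group spread; stress <= 0.15 means the 2-D ordination is a\n"
    "faithful summary of the Bray-Curtis geometry."
)
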