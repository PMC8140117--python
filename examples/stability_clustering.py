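"""mRNA stability time course: differential decay and profile clustering.

Simulates a transcription-shutoff experiment (0/8/12/24 h, two genotypes,
six replicates each) in which 10% of genes are stabilized in the mutant
with one of three temporal archetypes.  Tests each time point with the
two-group NB likelihood-ratio test at FDR 0.05, clusters the logFC
profiles of the stabilized genes with average linkage on the distance
(1 - Pearson R)/2, and tests the increased set for enrichment of a
"target" gene list with the one-sided hypergeometric test.
"""

import pandas as pd
from sklearn.metrics import adjusted_rand_score

import syncliptic as sc

sim = sc.simulate_stability_timecourse(1500, frac_stabilized=0.1, seed=4)
groups = ["wt"] * 6 + ["mut"] * 6

de = {}
for t, cm in sim.counts.items():
    de[t] = sc.nb_de_two_group(cm, groups)
    up, down = sc.split_by_direction(de[t], fdr=0.05)
    print(
        f"t={t:>4.0f} h: {len(up):4d} increased, {len(down):3d} decreased "
        f"(FDR 0.05), dispersion {de[t]['dispersion'].iloc[0]:.3f}"
    )

profiles = pd.DataFrame({t: d["logFC"] for t, d in de.items()})
truth = sim.truth.set_index("gene_id")
stabilized = truth.index[truth["stabilized"]]
D, _ = sc.correlation_distance(profiles.loc[stabilized])
labels = sc.average_linkage_cut(D, k=3)
ari = adjusted_rand_score(
    truth.loc[stabilized, "archetype"].astype("category").cat.codes, labels
)
print(f"decay archetypes recovered from logFC profiles: ARI = {ari:.2f}")

# enrichment of a target list among the increased genes at 24 h
up24, _ = sc.split_by_direction(de[24.0], fdr=0.05)
targets = set(stabilized)  # pretend the binding assay flagged these genes
k = len(set(up24) & targets)
p = sc.fisher_one_sided(k, len(targets), len(up24), profiles.shape[0])
print(
    f"targets among 24 h increased genes: {k}/{len(up24)} "
    f"(one-sided hypergeometric p = {p:.2e})"
)

# Per-time-point counts of significant genes rise with chase time as decay
# differences accumulate; ARI near 1 means the three stabilization behaviours
# separate cleanly in correlation distance; the tiny enrichment p reflects
# that increased RNAs are overwhelmingly the stabilized targets.
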