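"""Neural maturity index per child, validated against generative maturity.

Builds the adult reference map (group t, FDR q=0.01 mask), scores each
child's Fisher-z similarity to it, applies the 3-SD outlier screen, and
checks that the index tracks the latent maturity the generator assigned.
"""

from scipy.stats import spearmanr

from common import RESULTS, get_study_and_bundle

study, bundle = get_study_and_bundle(["glm", "nmi"])

table = bundle["nmi"]["table"].merge(
    study.child_truth.table[["subject", "maturity", "true_ssrt"]],
    on="subject")
table.to_csv(RESULTS / "nmi_children.csv", index=False)

ref = bundle["nmi"]["reference"]
print(f"adult reference mask: {ref.mask.sum()} voxels at FDR q={ref.q}")
print(f"children scored: {len(table)}, excluded as 3-SD outliers: "
      f"{table.excluded.sum()}")
kept = table[~table.excluded]
rho = spearmanr(kept.nmi, kept.maturity).statistic
print(f"Spearman(NMI, generative maturity) = {rho:.3f}")
print(kept[["subject", "r", "nmi"]].round(3).head(8).to_string(index=False))
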