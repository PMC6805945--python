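"""Brain-behavior statistics: do the neural measures predict SSRT?

Correlates NMI, STN stop activation and rAI->rSTN coupling with each
child's estimated SSRT, converts each correlation to Cohen's d, fits the
confound-adjusted regression (age, gender, max framewise displacement) and
applies FDR across the connectivity family. The generator couples every
neural latent negatively to SSRT, so all three correlations should come out
negative — the recovery the whole pipeline exists to demonstrate.
"""

from common import RESULTS, get_study_and_bundle

study, bundle = get_study_and_bundle(
    ["behavior", "glm", "nmi", "roi", "ppi", "brain_behavior"])

bb = bundle["brain_behavior"]
bb["correlations"].to_csv(RESULTS / "brain_behavior_correlations.csv",
                          index=False)
bb["regression"].to_csv(RESULTS / "brain_behavior_regression.csv", index=False)
bb["fdr"].to_csv(RESULTS / "brain_behavior_fdr.csv", index=False)

print("neural measure vs SSRT (Pearson r, two-sided p, Cohen's d):")
print(bb["correlations"].round(3).to_string(index=False))
print("\nconfound-adjusted regression (SSRT ~ NMI + age + gender + max FD):")
print(bb["regression"].round(3).to_string(index=False))
print("\nFDR across measures:")
print(bb["fdr"].round(3).to_string(index=False))
signs = (bb["correlations"]["r"] < 0).all()
print(f"\nall brain-behavior correlations negative as generated: {signs}")
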