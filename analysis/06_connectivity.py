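"""Stop-specific rAI->rSTN effective connectivity (gPPI) per child.

Fits the generalized psychophysiological interaction regression at the
right-STN target with the right anterior insula as seed and contrasts the
successful-stop against the unsuccessful-stop interaction terms; the
generator couples this gain to the latent factor, so the table should
correlate with the subjects' assigned coupling strengths.
"""

import numpy as np

from common import RESULTS, get_study_and_bundle

study, bundle = get_study_and_bundle(["glm", "ppi"])

table = bundle["ppi"]["table"].merge(
    study.child_truth.table[["subject", "ppi_gain"]], on="subject")
table.to_csv(RESULTS / "ppi_children.csv", index=False)

r = np.corrcoef(table.ppi_effect, table.ppi_gain)[0, 1]
print(f"gPPI effects for {len(table)} children "
      f"(seed {table.seed.iloc[0]}, target {table.target.iloc[0]})")
print(f"mean ppi_effect = {table.ppi_effect.mean():.3f}")
print(f"correlation with generative coupling gain: r = {r:.3f}")
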