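"""ROI activation analysis and STN multivoxel decoding.

Extracts condition betas from the sphere ROI set, runs paired stop-vs-go
tests over the cortical nodes (Bonferroni-corrected), and asks whether the
voxel pattern inside the right STN separates successful stops from go
trials under leave-one-subject-out SVM classification (C = 1).
"""

from common import RESULTS, get_study_and_bundle

study, bundle = get_study_and_bundle(["glm", "roi", "mvpa"])

paired = bundle["roi"]["paired_tests"]
paired.to_csv(RESULTS / "roi_paired_tests.csv", index=False)
print("paired SuccStop vs Go tests over cortical ROIs "
      f"(alpha {paired.attrs['corrected_alpha']:.5f} Bonferroni):")
print(paired.round(4).to_string(index=False))

bundle["roi"]["betas"].to_csv(RESULTS / "roi_betas.csv", index=False)
stn = bundle["roi"]["stn_stop"]
print(f"\nrSTN stop activation (SuccStop/UnsuccStop average): "
      f"mean {stn.mean():.3f} across {len(stn)} children")

mvpa = bundle["mvpa"]
print(f"STN decoding (LOSO linear SVM): accuracy {mvpa.accuracy:.3f}, "
      f"permutation p = {mvpa.p:.4f} ({mvpa.n_perm} label shuffles)")
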