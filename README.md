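# stopdev

Inhibitory action control in the developing brain, rebuilt as a tested,
end-to-end analysis pipeline on synthetic cohorts. The package is aimed at
developmental-neuroimaging researchers who want the full chain — stop-signal
behavior, event-related fMRI GLM, child–adult activation similarity, the
neural maturity index, subthalamic-nucleus decoding, cortico-subthalamic
effective connectivity, and brain–behavior regression — with every step
validated against a generative model whose latent structure is known.

## The science in brief

**Race model and SSRT.** In the stop-signal task (SST) a go process and a
stop process race independently; a response escapes on a stop trial iff the
go process finishes before `SSD + SSRT`, where SSD is the stop-signal delay
and SSRT the latent stopping latency. An adaptive staircase (±33 ms in the
child design, ±50 ms in the adult/ABCD-style designs) drives the inhibition
rate toward 50%, and SSRT is estimated by the integration method,

```
SSRT = Q_p(go RT) − mean(SSD),   p = P(respond | stop trial)
```

**Neural maturity index (NMI).** An adult cohort's group *t*-map for the
SuccStop−Go contrast, masked at FDR *q* = 0.01 (activations and
deactivations), serves as a reference; a child's NMI is the Fisher-z
transformed spatial correlation between the child's *t*-map and the
reference inside that mask. The hypothesis: more adult-like activation
(higher NMI) predicts faster stopping (lower SSRT).

**Hyperdirect pathway.** The subthalamic nucleus (STN) receives direct
cortical input that bypasses the striatum, enabling rapid action
cancellation. The pipeline tests its signatures: STN stop-activation vs
SSRT, Go/SuccStop decoding from STN voxel patterns (linear SVM, *C* = 1,
leave-one-subject-out), and stop-specific rAI→rSTN coupling from a
generalized psychophysiological interaction (gPPI) — the difference between
the SuccStop and UnsuccStop seed×task interaction betas.

**Synthetic cohorts.** `stopdev.simulate`/`stopdev.study` generate both
behavior and 4-D BOLD with known ground truth: one latent factor per child
drives maturity (template-likeness of the activation map), STN amplitude and
rAI→rSTN coupling gain, and loads negatively (−0.8) on true SSRT — so every
downstream brain-behavior correlation has a known sign and size to recover.

## Worked example

```python
from stopdev.study import StudyConfig, simulate_study
from stopdev.pipeline import run_pipeline

study = simulate_study(StudyConfig(), seed=11)   # 20 children, 12 adults
bundle = run_pipeline(study, seed=11)
print(bundle["brain_behavior"]["correlations"].round(3))
```

prints

```
       measure      r     p      d  n
           nmi -0.562 0.010 -1.360 20
stn_activation -0.586 0.007 -1.448 20
  ppi_rAI_rSTN -0.387 0.092 -0.839 20
```

— the three neural measures all correlate negatively with estimated SSRT,
recovering the generative couplings; `d` is the Cohen's-d equivalent
`2r/√(1−r²)`. The numbered drivers under `analysis/` walk the same study
through each stage (`python analysis/01_simulate_behavior.py`, …) and write
their tables under `results/`. For the 38-subject behavioral cohort the
staircase yields mean stop accuracy 51.3%, go accuracy 93.8%, and
integration-method SSRT within −7 ms of the generative truth on average.

A CLI mirrors the pipeline for on-disk studies:

```
stopdev simulate --out study/ --seed 11
stopdev report --study study/ --out report/ --seed 11
```

## Layout

- `src/stopdev/` — the library: `designs`, `simulate`, `bold`, `study`
  (generators); `behavior`, `glm`, `similarity`, `nmi`, `roi`, `ppi`,
  `brain_behavior` (analyses); `io`, `pipeline`, `cli` (orchestration).
- `analysis/` — numbered narrative drivers over the library.
- `tests/` — unit, property and acceptance suites.
- `docs/methods.md` — model, assumptions, parameter choices, limitations.
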