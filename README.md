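# ktrcycle

Analysis of simultaneous **CDK4/6 and CDK2 kinase-translocation-reporter
(KTR) traces** from single-cell live imaging, for cell-cycle biologists
quantifying when and how cells commit to — or revert from — cell-cycle
entry.

A KTR reads kinase activity as the cytoplasmic:nuclear fluorescence ratio
of an engineered substrate. A dual-reporter system measures CDK4/6 and
CDK2 activity in the same cell, alongside an APC/C<sup>Cdh1</sup>-degron
reporter whose nuclear intensity starts accumulating at the G1/S
transition. Three analysis problems arise, and this package implements all
of them, driven by a synthetic trace generator with per-cell ground truth
so every stage is testable without imaging data:

1. **Reporter correction.** The raw CDK4/6 reporter ratio contains an
   additive CDK2 contribution. The corrected activity is

   > corrected CDK4/6 = raw CDK4/6 − *f* · CDK2,  *f* ≈ 0.35,

   with *f* estimated by linear regression of the post-CDK4/6-inhibition
   raw signal on simultaneous CDK2 activity across pooled S/G2 frames
   (after acute inhibition, whatever raw signal tracks CDK2 *is* the
   contamination).
2. **Event detection and fate classification.** Per-cell landmarks
   (CDK4/6-on at activity > 0.7 with 2 h persistence, CDK2-on at > 0.76,
   APC/C-off at degron rise onset) and the categorical fates:
   CDK4/6<sup>high/low</sup> at quiescence release,
   CDK4/6<sup>high/low/delay</sup> at mitotic exit, and
   CDK2<sup>inc/low</sup> after a stress, scored at 15 h.
3. **Population statistics.** Event-aligned activity matrices, cumulative
   activation curves, bootstrap median bands, bimodality tests
   (2-component Gaussian mixture + Ashman's D), the binned stress
   dose-response in CDK2 activity, phase-plane trajectories, and
   live-fixed Rb pS807/811 fraction matching.

## Layout

- `src/ktrcycle/` — the library: `trace_model` (containers + CSV I/O),
  `synth_cohort` (generator + perturbations), `correction`, `events`,
  `classify`, `cohort_stats`, `cli`, `plots`.
- `analysis/` — numbered driver scripts, each a thin narrative over the
  library that prints what it finds and writes tables under `results/`.
- `scripts/acceptance.py` — recomputes the headline correction numbers.

## Worked example

```sh
python analysis/02_reporter_correction.py
```

prints

```
contamination fraction: f_hat = 0.3471 +- 0.0012 (3800 pooled frames); corrected-signal trend 4.34e-05 activity/h post-inhibition
unsuppressible raw signal: 35.1% of the pre-inhibition plateau
```

meaning: on a 200-cell synthetic S/G2 cohort acutely treated with a
CDK4/6 inhibitor, the regression recovers the generating contamination
fraction (0.35), the corrected signal is flat (no residual CDK2 trend)
after inhibition, and with CDK2 activity at 1.0 about 35% of the raw
CDK4/6 reporter signal cannot be suppressed — the part contributed by
CDK2. The remaining drivers reproduce the rest of the analysis:

```
$ python analysis/03_quiescence_release.py
1000 cells: 55.2% classified CDK4/6-high (generator truth 56.6%)
cumulative-curve ordering CDK4/6-on >= CDK2-on >= APC/C-off: True

$ python analysis/04_mitotic_exit.py
post-mitotic fates: {'high': '61.3%', 'delay': '19.5%', 'low': '19.2%'}
2 h after anaphase: corrected CDK4/6 bimodal = True, CDK2 bimodal = False
Rb-phospho vs cumulative CDK4/6-on: max |diff| = 0.045 over 11 bins (Rb threshold 3.31)

$ python analysis/05_stress_response.py
569 eligible G1 cells at 11 h (of 4000 tracked)
exit fraction by CDK2 at stress addition:
  CDK2 [0.76, 0.86): 68% exit (n=251)
  CDK2 [0.86, 0.96): 52% exit (n=233)
  CDK2 [0.96, 1.06): 35% exit (n=85)
S-phase cells (degron rising, CDK2 > 1.0): 0.0% exit (n=101)
h2o2_like_lag1h: median CDK4/6 off at 11.2 h, CDK2 off at 12.2 h (+5 frames, n=320 exiting cells)
nacl_like_lag0: median CDK4/6 off at 11.2 h, CDK2 off at 11.2 h (+0 frames, n=224 exiting cells)
```

A `ktrcycle` command-line interface wraps the same pipeline
(`ktrcycle simulate --config cfg.yaml --out dir/`, then
`ktrcycle analyze --cohort dir/cohort.csv --out report/`); every run
writes a resolved-config copy next to its outputs.

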