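# neurotact

Neuromorphic tactile encoding, temporal-code analysis, psychophysics and
peripheral-nerve recruitment modelling for texture discrimination with
sensory neuroprostheses.

## The problem

A prosthetic fingertip sliding over a grating produces a periodic shear
signal whose temporal structure carries the grating's geometry. If that
signal is converted into spike trains and injected into the median
nerve, can a human user discriminate surface coarseness — and which
neural code (burst timing vs mean rate) makes the discrimination
possible? This package implements that whole processing chain on
synthetic data, for computational neuroscientists and neuroprosthetics
engineers who want to study temporal coding of texture without the
bench hardware:

1. **`synthetic_touch`** — a generative model of a MEMS fingertip with
   two opposing piezoresistive channels (S_x+, S_x−) sampled at 380 Hz
   while gratings (spatial period SP = 0.5–3.0 mm, ridge width 0.25 mm)
   slide at 10 mm/s under 400 mN for 2 s.
2. **`mnt_encoder`** — the mechano-neuro-transduction chain:
   S_x = S_x+ − S_x−, then I_x = K·max(S_x, 0) with K = 15 000, driving
   an Izhikevich neuron (mV/ms convention)

       dv/dt = 0.04 v² + 5 v + 140 − u + I_x
       du/dt = a (b v − u)
       if v ≥ 30 mV:  v ← c,  u ← u + d

   with the regular-spiking set a = 0.02, b = 0.2, c = −65 mV, d = 8 mV.
3. **`spike_coding`** — inter-burst interval (IBI = SP/velocity for
   periodic sliding), average firing rate (AFR = spikes / 2 s slide),
   instantaneous rate, spatial modulation index, ΔIBI/ΔAFR regressions
   on ΔSP, and ANOVA/Tukey–Kramer specificity tests.
4. **`psychophysics`** — the three-alternative forced-choice protocol
   (16-trial sessions, 4 surface pairs × 2 orders × 2 repeats), an
   ideal-observer decoder reading ΔIBI, confusion matrices, exact
   Clopper–Pearson intervals against the 1/3 chance level, and logistic
   psychometric fits.
5. **`nerve_recruitment`** — an analytic stand-in for a hybrid
   FEM/biophysical nerve model: point-source potentials in an
   anisotropic medium (endoneurium σ = [0.0826, 0.0826, 0.571] S/m)
   with perineurium attenuation, 21-node myelinated axons with
   MRG-style nodal channels, 100-fiber populations, recruitment curves,
   and a Kruskal–Wallis comparison of needle microstimulation vs an
   implanted intrafascicular (TIME) electrode.
6. **`io` / `cli`** — raster and trace round-trips, YAML configs,
   deterministic seed fan-out, and `neurotact` CLI subcommands
   (`simulate`, `encode`, `analyze`, `session`, `recruit`, `pipeline`).

## Worked example

```python
from neurotact.io import RunConfig, run_pipeline

report = run_pipeline(RunConfig(n_sessions=5), seed=11)
print(report["n_correct"], "/", report["n_trials"])          # 80 / 80
print(report["clopper_pearson_95"])                           # [0.955, 1.0]
print(report["delta_ibi_regression"]["r_squared"])            # 0.9999991
print(report["delta_afr_regression"]["r_squared"])            # 0.059
```

Five 16-trial sessions are simulated, encoded and decoded by the
noise-free ideal observer: all 80 responses are correct, the exact 95%
binomial interval (lower bound 0.955) clears the 1/3 chance level, and
the signed ΔIBI between the two halves of each surface tracks ΔSP
almost perfectly (R² ≈ 1.0, slope ≈ 100 ms/mm at 10 mm/s) while ΔAFR
carries almost no information (R² ≈ 0.06) — the temporal code, not the
rate code, supports the discrimination.

Per-grating statistics from noise-free encodings:

| SP (mm) | median IBI (ms) | AFR (spikes/s) | modal spikes/burst |
|--------:|----------------:|---------------:|-------------------:|
|     0.5 |              50 |             20 |                  1 |
|     1.0 |             100 |             20 |                  2 |
|     1.5 |             150 |             21 |                  3 |
|     2.0 |             200 |             20 |                  4 |
|     3.0 |             300 |             21 |                  6 |

IBI equals SP/velocity at every spatial period; AFR is nearly constant
because coarser gratings emit fewer but denser bursts.

From a shell:

```bash
neurotact simulate --pair D1.0+ --seed 7 --out trace.csv
neurotact encode --trace trace.csv --out raster.json
neurotact analyze --raster raster.json
neurotact session --n-sessions 5 --observer-noise 0 --seed 11
neurotact recruit --plan reduced --seed 3
```

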