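# Methods

## Synthetic sensor model

The generator emulates the two opposing piezoresistive channels of a
MEMS fingertip during a passive-touch trial: indent the surface at
400 mN for 4 s, slide it at 10 mm/s for 2 s, hold for 2 s, detach, wait
3 s, repeat with the second half-surface; both channels are sampled at
380 Hz. Three ingredients make up each channel:

- **Indentation settle** — a step plus exponential approach
  (τ = 0.5 s) applied equally to both channels. It is common-mode by
  construction and cancels in the differential S_x = S_x+ − S_x−,
  reflecting that only the sliding-correlated shear component is
  encoded.
- **Ridge-crossing pulses** — during sliding, each ridge produces one
  transient on the differential channel. The pulse is an asymmetric
  raised cosine: a fixed 4 ms attack (so spikes lock to ridge onsets
  with a short, SP-independent latency) and a groove-dependent decay
  d(g) = 10 ms · (g / 0.25 mm)^0.90. The amplitude scales as
  a(g) = 0.74 mV · (g / 0.25 mm)^0.54. Wider grooves let the fingertip
  sink deeper, so coarser gratings drive larger and longer transients;
  both exponents are part of the sensor calibration.
- **Noise** — additive Gaussian noise per channel (σ = 5·10⁻⁵,
  arbitrary units), a 3% s.d. multiplicative gain on each ridge pulse,
  and a random slide-onset phase uniform over one spatial period. The
  phase term models the arbitrary registration between the first ridge
  and the moment sliding starts when a surface is mounted; it matters
  statistically because it makes the expected spike count per slide
  exactly (slide length / SP) × (spikes per burst), independent of how
  20 mm divides by SP.

### How the calibration was fixed

The target spike statistics the generator must reproduce (one burst per
ridge; 1 spike per burst at SP 0.5 mm through ~6 at 3.0 mm; median IBI
= SP/velocity; near-constant AFR across SPs) pin the calibration. The
encoder's spikes-per-burst response to a pulse train is a staircase in
pulse amplitude whose plateau edges depend on SP (through the pulse
decay and the inter-ridge interval, which sets how much spike-frequency
adaptation persists between bursts). We mapped these staircases
numerically — including the 1:1 burst-locking requirement at SP
0.5 mm, where subthreshold adaptation otherwise causes every-other-
ridge firing — and chose the amplitude power law that places every SP
mid-plateau of its target count. Mid-plateau placement makes the counts
robust to the declared noise sources rather than biased upward by them
(a perturbation near a plateau edge adds spikes far more easily than it
removes them).

### What the generator does *not* model

No continuum skin mechanics, no stick–slip friction, no force-servo
dynamics, and — importantly for interpretation — no mechanical
low-pass blur. Real SA1 responses lose spatial modulation at fine
gratings because skin mechanics filter the stimulus; our synthetic
traces resolve every grating perfectly, so the spatial modulation index
saturates near its theoretical maximum (≈2) at *all* spatial periods
instead of rising with SP. Passing tests therefore demonstrate the
temporal-coding logic (IBI vs AFR) on idealized transduction, not the
spatial-resolution limits of real touch.

## Encoder

Canonical Izhikevich regular-spiking neuron in the mV/ms convention
(A = 0.04, B = 5, C = 140, a = 0.02, b = 0.2, c = −65, d = 8,
v_th = 30, K = 15 000, R·C_m = 1). The printed unit annotations of the
source parameter set (e.g. "0.04/sV") are typesetting artifacts of the
canonical dimensionless form; the numbers themselves are the standard
regular-spiking values and are implemented as such. Integration is
explicit Euler with dt = 0.1 ms sub-steps under a zero-order hold of
the 380 Hz drive (26 sub-steps per sample; the remainder is absorbed
into the last sub-step). Accuracy is guarded by convergence tests
(halving dt changes slide-window spike counts by ≤2%; a 10× finer
reference changes constant-drive counts by ≤1 spike over 2 s) rather
than by a higher-order scheme, matching common practice for this
model. Initial state v₀ = −70 mV, u₀ = b·v₀ — the closed-form resting
fixed point of 0.04v² + 5v + 140 − u = 0 with u = 0.2v — so contact
onset produces no artifactual transient. Non-finite state aborts with
the failing sample index.

## Temporal-coding analysis

- **Burst segmentation**: a new burst opens at any spike whose
  preceding ISI exceeds 25 ms. The threshold sits between the largest
  intra-burst ISI the encoder produces under default calibration
  (≤ ~15 ms, at SP 3.0 mm) and the smallest inter-burst interval in the
  stimulus set (50 ms at SP 0.5 mm); it is exposed in the config.
- **IBI**: median over consecutive burst-onset differences; the median
  is robust to edge bursts truncated at slide onset/offset. Fewer than
  two bursts → flagged undefined, and the flag propagates to pair
  features and forces the ideal observer to guess.
- **AFR**: spike count divided by the fixed 2 s slide duration.
- **Instantaneous rate**: inverse ISI assigned to the right edge of
  each interval.
- **Spatial modulation index**: spikes are binned at 5 ms; the index is
  the magnitude of the Fourier component of the binned rate at the
  ridge frequency v/SP, normalized by the mean (DC) component — 2 for a
  perfect Dirac comb, ~0 for a rate-matched Poisson train. See the
  generator caveat above for why it does not increase with SP here.
- **Statistics**: ΔIBI and ΔAFR are ordinary least squares on signed
  ΔSP with R² the squared Pearson correlation; SP-specificity uses
  one-way ANOVA with Tukey–Kramer pairwise comparisons (delegated to
  scipy/statsmodels; inputs and outputs fixed by this package).

## Psychophysics

Sessions are uniform random permutations of the fixed 16-trial multiset
(4 surfaces × 2 orders × 2 repeats). The ideal observer adds Gaussian
decision noise to ΔIBI and answers "same" when |noisy ΔIBI| < τ with
τ = 50 ms — half the smallest nonzero |ΔIBI| in the stimulus set
(100 ms at ΔSP = 1 mm, v = 10 mm/s), i.e. the maximal-margin threshold.
Confidence intervals are exact Clopper–Pearson (beta quantiles;
validated against direct inversion of the binomial tail equations to
1e−9) against the 1/3 chance level. Psychometric fits are binomial
GLMs with a logit link on |ΔSP| (or |ΔIBI|); R² is the squared Pearson
correlation between observed and fitted fractions; perfect separation
returns a capped-coefficient result with a convergence flag instead of
raising.

## Nerve recruitment

The volume conductor is the closed-form potential of a point source in
an unbounded anisotropic medium,
V = I / (4π √(σ_y σ_z Δx² + σ_x σ_z Δy² + σ_x σ_y Δz²)), with
endoneurial σ = (0.0826, 0.0826, 0.571) S/m and a scalar attenuation of
0.3 per perineurium sheath crossed by the straight source-to-fiber
path (crossings counted geometrically on the fascicle cross-section).
This replaces a finite-element solve; it preserves the *relative*
quantities the analysis needs (threshold orderings, device comparison)
and makes no claim about absolute voltages near boundaries. The
closed form is verified against a source-free anisotropic
finite-difference solve (≤2%) and a discrete Gauss flux integral
(≤2%).

Axons are 21-node myelinated fibers: nodal length 1 μm, node diameter
D/3, internodal spacing 100·D, passive internodes reduced to axial
resistances (ρ = 70 Ω·cm, axial diameter 0.65·D). Nodes carry fast Na,
persistent Na, slow K and leak currents with MRG-style rate kinetics
(g_Naf = 3.0, g_Nap = 0.01, g_Ks = 0.08, g_L = 0.007 S/cm²,
E_Na = 50 mV, E_K = E_L = −90 mV, c_m = 2 μF/cm², rest −80 mV; all
configurable). Integration uses exponential-Euler gates and a
semi-implicit membrane update at 1 μs during the biphasic pulse and
5 μs after, over a 3 ms horizon; rate functions are evaluated with
removable-singularity-safe forms and voltages clamped to
[−150, 100] mV inside the rate evaluation only. A fiber is recruited
when the last node crosses 0 mV; thresholds are found by bisection on
amplitude (1% tolerance) at 100 μs phase width, and charge = amplitude
× width.

Fiber diameters follow the touch/pressure population Gaussian
(mean 9 μm, s.d. 2 μm, truncated below 3 μm — declared defaults, since
only the distribution's existence is documented upstream). Populations
1..9 (large fascicle; 5 medium, 1 small) shrink monotonically from the
full fascicle disc to a tight off-center cluster, all nested inside
the full disc. The simulation plan crosses 3 device placements
(within / close to / shielded by another fascicle) with the 15
populations: 45 needle cases and 90 TIME cases (mirrored left/right
sites 50 μm either side of the substrate). Device equivalence is a
Kruskal–Wallis test on the charge at 10% recruitment (linear
interpolation on each curve; curves never reaching 10% — typical for
shielded placements at desk scale — are excluded and counted).

Problem sizes: the default plan uses 100 fibers per fascicle; tests
and the acceptance script use 20 fibers per fascicle and a 0.25–60 nC
charge grid, which preserves every ordering and the device comparison.

## Reproducibility

Every stochastic quantity derives from a master seed through a
counter-based fan-out (`derive_seed(master, *stage_keys)`, CRC-32 of
the key tuple, < 2³¹), so adding a pipeline stage never perturbs the
random stream of earlier stages, and identical configurations produce
byte-identical reports. File writes are atomic (temp file + rename).

## Known limitations

- The sensor calibration is an idealization fixed by downstream spike
  statistics, not by fitting recorded sensor data; absolute sensor
  amplitudes are arbitrary units.
- No mechanical low-pass: spatial modulation saturates at all SPs (see
  above).
- The volume conductor ignores the nerve boundary and saline return
  path; absolute recruitment charges are not comparable to published
  figures, only orderings and device contrasts are.
- The ideal observer reads ΔIBI only; it is a decoder of the injected
  code, not a model of human perception, learning, or the
  needle-vs-implant performance gap.
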