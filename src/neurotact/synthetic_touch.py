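"""Synthetic two-channel tactile sensor traces.

Emulates a MEMS fingertip with two opposing piezoresistive channels
(``s_plus``, ``s_minus``) sampled at 380 Hz while grating surfaces slide
under the finger at constant velocity and regulated load force.  Each
trial presents two half-gratings in sequence:

    indent (4 s) -> slide (2 s) -> hold (2 s) -> gap (3 s) -> second half

During sliding, every ridge crossing produces one transient shear pulse
on the differential channel; pulse amplitude and decay time grow with
groove width, so coarser gratings drive larger and longer transients.
Static phases carry only baseline, a common-mode indentation settle and
additive Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GratingSpec",
    "StimulusPair",
    "SlidingProtocol",
    "SensorCalibration",
    "SensorTrace",
    "PAIR_SP_MAP",
    "STANDARD_SPS",
    "make_stimulus_pair",
    "ridge_crossing_times",
    "synth_sensor_trace",
]

#: spatial periods (mm) of the four paired surfaces, keyed by label
PAIR_SP_MAP: dict[str, tuple[float, float]] = {
    "D0.0": (1.5, 1.5),
    "D1.0": (2.0, 1.0),
    "D2.0": (3.0, 1.0),
    "D2.5": (3.0, 0.5),
}

#: every spatial period (mm) appearing in the stimulus set
STANDARD_SPS: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 3.0)

_LABEL_ALIASES = {
    "Δ0.0": "D0.0",
    "Δ1.0": "D1.0",
    "Δ2.0": "D2.0",
    "Δ2.5": "D2.5",
}


@dataclass(frozen=True)
class GratingSpec:
    """Geometry of one grating half: ridges of fixed width alternating
    with grooves, repeating with spatial period ``spatial_period`` (mm)."""

    spatial_period: float
    ridge_width: float = 0.25
    length: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.ridge_width < self.spatial_period:
            raise ValueError(
                f"ridge_width must satisfy 0 < ridge_width < spatial_period, "
                f"got ridge_width={self.ridge_width}, spatial_period={self.spatial_period}"
            )
        if self.length <= 0:
            raise ValueError("grating length must be positive")

    @property
    def groove_width(self) -> float:
        """Groove width (mm): spatial period minus ridge width."""
        return self.spatial_period - self.ridge_width


@dataclass(frozen=True)
class StimulusPair:
    """One paired surface: two half-gratings presented in sequence.

    ``label`` is one of D0.0/D1.0/D2.0/D2.5 (the nominal difference in
    spatial period, mm); ``order`` '+' presents the coarser half first,
    '-' the reverse.
    """

    label: str
    order: str
    first_sp: float
    second_sp: float

    @property
    def delta_sp(self) -> float:
        """Signed spatial-period difference first - second (mm)."""
        return self.first_sp - self.second_sp


@dataclass(frozen=True)
class SlidingProtocol:
    """Timing and kinematics of one half-surface presentation."""

    indent_force: float = 400.0  # mN
    pre_slide_dwell: float = 4.0  # s
    velocity: float = 10.0  # mm/s
    slide_duration: float = 2.0  # s
    post_slide_dwell: float = 2.0  # s
    inter_half_gap: float = 3.0  # s
    sample_rate: float = 380.0  # Hz

    def __post_init__(self) -> None:
        for name in (
            "indent_force",
            "pre_slide_dwell",
            "velocity",
            "slide_duration",
            "post_slide_dwell",
            "inter_half_gap",
            "sample_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def slide_length(self) -> float:
        """Distance (mm) the surface travels during one slide."""
        return self.velocity * self.slide_duration

    @property
    def half_duration(self) -> float:
        return self.pre_slide_dwell + self.slide_duration + self.post_slide_dwell

    @property
    def total_duration(self) -> float:
        return 2 * self.half_duration + self.inter_half_gap


@dataclass(frozen=True)
class SensorCalibration:
    """Generative parameters of the synthetic sensor.

    Each ridge crossing produces an asymmetric raised-cosine pulse with a
    fixed fast attack and a groove-dependent decay; amplitude and decay
    both scale as (groove / 0.25 mm) ** groove_scaling_exponent, so wider
    grooves (the fingertip sinking deeper) yield larger, longer pulses.
    """

    ridge_pulse_amplitude: float = 0.74e-3
    groove_scaling_exponent: float = 0.54
    decay_scaling_exponent: float = 0.90
    pulse_attack: float = 0.004  # s, groove-independent rise
    pulse_decay_base: float = 0.010  # s, decay at the 0.25 mm reference groove
    pulse_gain_jitter: float = 0.03  # relative sd of per-ridge amplitude
    onset_phase_jitter: float = 1.0  # slide onset phase, fraction of one SP
    noise_sd: float = 5e-5  # per channel, arb. units
    baseline: float = 0.0
    indent_step: float = 5e-3  # common-mode indentation amplitude
    indent_tau: float = 0.5  # s, settle time constant
    reference_groove: float = 0.25  # mm

    def __post_init__(self) -> None:
        if self.ridge_pulse_amplitude <= 0:
            raise ValueError("ridge_pulse_amplitude must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def groove_gain(self, groove_width: float) -> float:
        return (groove_width / self.reference_groove) ** self.groove_scaling_exponent

    def pulse_amplitude(self, groove_width: float) -> float:
        return self.ridge_pulse_amplitude * self.groove_gain(groove_width)

    def pulse_decay(self, groove_width: float) -> float:
        ratio = groove_width / self.reference_groove
        return self.pulse_decay_base * ratio**self.decay_scaling_exponent


@dataclass
class SensorTrace:
    """Two-channel piezoresistive time series with protocol phase markers.

    ``event_markers`` maps phase names (``indent1``, ``slide1``, ``hold1``,
    ``gap``, ``indent2``, ``slide2``, ``hold2``) to (onset, offset) in
    seconds from trial start.
    """

    s_plus: np.ndarray
    s_minus: np.ndarray
    sample_rate: float
    event_markers: dict[str, tuple[float, float]] = field(default_factory=dict)
    pair: StimulusPair | None = None

    def __post_init__(self) -> None:
        if len(self.s_plus) != len(self.s_minus):
            raise ValueError("s_plus and s_minus must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.s_plus)

    @property
    def duration(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


def make_stimulus_pair(label: str, order: str) -> StimulusPair:
    """Resolve a surface label and presentation order to its two spatial
    periods.  '+' presents (SP1, SP2) as printed; '-' swaps the halves."""
    label = _LABEL_ALIASES.get(label, label)
    if label not in PAIR_SP_MAP:
        raise ValueError(
            f"unknown stimulus label {label!r}; valid labels: {sorted(PAIR_SP_MAP)}"
        )
    if order not in ("+", "-"):
        raise ValueError(f"order must be '+' or '-', got {order!r}")
    sp1, sp2 = PAIR_SP_MAP[label]
    if order == "-":
        sp1, sp2 = sp2, sp1
    return StimulusPair(label=label, order=order, first_sp=sp1, second_sp=sp2)


def ridge_crossing_times(
    grating: GratingSpec, velocity: float, duration: float
) -> np.ndarray:
    """Times (s) at which successive ridges reach the sensor while the
    grating slides at constant ``velocity`` (mm/s), starting on a ridge at
    t = 0 and truncated at ``duration``."""
    if velocity <= 0:
        raise ValueError("velocity must be positive")
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    spacing = grating.spatial_period / velocity
    n = int(np.floor(duration / spacing))
    times = np.arange(n + 1) * spacing
    return times[times < duration]


def _pulse_kernel(t: np.ndarray, onset: float, attack: float, decay: float) -> np.ndarray:
    """Asymmetric raised-cosine: half-cosine rise over ``attack`` seconds,
    half-cosine fall over ``decay`` seconds, zero elsewhere."""
    u = t - onset
    out = np.zeros_like(t)
    rising = (u >= 0) & (u < attack)
    falling = (u >= attack) & (u < attack + decay)
    out[rising] = 0.5 * (1.0 - np.cos(np.pi * u[rising] / attack))
    out[falling] = 0.5 * (1.0 + np.cos(np.pi * (u[falling] - attack) / decay))
    return out


def _slide_pulses(
    t_rel: np.ndarray,
    grating: GratingSpec,
    protocol: SlidingProtocol,
    calib: SensorCalibration,
    rng: np.random.Generator,
) -> np.ndarray:
    groove = grating.groove_width
    amp = calib.pulse_amplitude(groove)
    decay = calib.pulse_decay(groove)
    crossings = ridge_crossing_times(grating, protocol.velocity, protocol.slide_duration)
    if calib.onset_phase_jitter > 0:
        # where the first ridge sits relative to slide onset is arbitrary
        # for each mounting of the surface
        period = grating.spatial_period / protocol.velocity
        phase = rng.uniform(0.0, calib.onset_phase_jitter) * period
        crossings = crossings + phase
        crossings = crossings[crossings < protocol.slide_duration]
    signal = np.zeros_like(t_rel)
    for t_k in crossings:
        gain = 1.0 + calib.pulse_gain_jitter * rng.standard_normal()
        gain = max(gain, 0.0)
        signal += amp * gain * _pulse_kernel(t_rel, t_k, calib.pulse_attack, decay)
    return signal


def synth_sensor_trace(
    pair: StimulusPair,
    protocol: SlidingProtocol | None = None,
    calib: SensorCalibration | None = None,
    seed: int = 0,
) -> SensorTrace:
    """Generate one synthetic trial trace for a paired surface.

    The full protocol sequence (indent, slide, hold, gap, second half) is
    reproduced with phase markers.  Ridge-crossing pulses appear on the
    ``s_plus`` channel only, so the differential signal isolates them;
    the indentation settle is common-mode and cancels in the differential.
    A given ``(pair, protocol, calib, seed)`` always yields the same trace.
    """
    protocol = protocol or SlidingProtocol()
    calib = calib or SensorCalibration()
    rng = np.random.default_rng(seed)

    fs = protocol.sample_rate
    n = int(round(protocol.total_duration * fs))
    t = np.arange(n) / fs

    half = protocol.half_duration
    markers = {
        "indent1": (0.0, protocol.pre_slide_dwell),
        "slide1": (protocol.pre_slide_dwell, protocol.pre_slide_dwell + protocol.slide_duration),
        "hold1": (protocol.pre_slide_dwell + protocol.slide_duration, half),
        "gap": (half, half + protocol.inter_half_gap),
        "indent2": (
            half + protocol.inter_half_gap,
            half + protocol.inter_half_gap + protocol.pre_slide_dwell,
        ),
        "slide2": (
            half + protocol.inter_half_gap + protocol.pre_slide_dwell,
            half + protocol.inter_half_gap + protocol.pre_slide_dwell + protocol.slide_duration,
        ),
        "hold2": (half + protocol.inter_half_gap + protocol.half_duration - protocol.post_slide_dwell,
                  2 * half + protocol.inter_half_gap),
    }

    common = np.full(n, calib.baseline)
    # indentation settle: step + exponential approach on both channels
    for indent_key, contact_end in (("indent1", markers["hold1"][1]),
                                    ("indent2", markers["hold2"][1])):
        onset = markers[indent_key][0]
        in_contact = (t >= onset) & (t < contact_end)
        common[in_contact] += calib.indent_step * (
            1.0 - np.exp(-(t[in_contact] - onset) / calib.indent_tau)
        )

    pulses = np.zeros(n)
    for slide_key, sp in (("slide1", pair.first_sp), ("slide2", pair.second_sp)):
        onset, offset = markers[slide_key]
        window = (t >= onset) & (t < offset)
        grating = GratingSpec(spatial_period=sp)
        pulses[window] += _slide_pulses(t[window] - onset, grating, protocol, calib, rng)

    noise_plus = calib.noise_sd * rng.standard_normal(n) if calib.noise_sd else 0.0
    noise_minus = calib.noise_sd * rng.standard_normal(n) if calib.noise_sd else 0.0

    s_plus = common + pulses + noise_plus
    s_minus = common + noise_minus
    return SensorTrace(
        s_plus=s_plus,
        s_minus=s_minus,
        sample_rate=fs,
        event_markers=markers,
        pair=pair,
    )


def noise_free(calib: SensorCalibration | None = None) -> SensorCalibration:
    """Copy of ``calib`` with all stochastic components disabled."""
    calib = calib or SensorCalibration()
    return replace(
        calib, noise_sd=0.0, pulse_gain_jitter=0.0, onset_phase_jitter=0.0
    )
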