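"""Mechano-neuro-transduction: sensor trace -> artificial spike train.

The encoder chains three stages:

1. ``differential`` — subtract the two opposing piezoresistive channels,
   S_x = S_x+ - S_x-, isolating the shear component along the sliding
   direction.
2. ``drive_current`` — half-rectify and amplify, I_x = K * max(S_x, 0).
3. ``izhikevich_encode`` — integrate the Izhikevich neuron

       dv/dt = A v^2 + B v + C - u + I
       du/dt = a (b v - u)
       if v >= v_th:  v <- c,  u <- u + d     (spike emitted)

   in the canonical millisecond/millivolt convention, with the 380 Hz
   drive held constant within each sensor sample (zero-order hold) and
   explicit-Euler sub-stepping at dt = 0.1 ms.

Default parameters are the regular-spiking set (a=0.02, b=0.2, c=-65,
d=8) with gain K=15000 and threshold 30 mV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a declared dependency
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

from .synthetic_touch import SensorTrace

__all__ = [
    "EncoderParams",
    "NeuronState",
    "SpikeTrain",
    "differential",
    "drive_current",
    "izhikevich_encode",
    "encode_trial",
]


@dataclass(frozen=True)
class EncoderParams:
    """Gain and Izhikevich neuron constants (mV / ms convention)."""

    K: float = 15000.0
    A: float = 0.04
    B: float = 5.0
    C: float = 140.0
    a: float = 0.02
    b: float = 0.2
    c: float = -65.0  # mV, reset
    d: float = 8.0  # mV, recovery increment
    v_th: float = 30.0  # mV
    R: float = 1.0
    C_m: float = 1.0
    dt: float = 0.1  # ms, Euler sub-step

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.v_th <= self.c:
            raise ValueError("v_th must exceed the reset value c")


@dataclass
class NeuronState:
    """Membrane potential v (mV) and recovery variable u."""

    v: float = -70.0
    u: float = -14.0  # b * v at the resting fixed point

    @classmethod
    def resting(cls, params: EncoderParams) -> "NeuronState":
        v0 = -70.0
        return cls(v=v0, u=params.b * v0)


@dataclass
class SpikeTrain:
    """Ordered spike times in seconds from trial start."""

    spike_times: np.ndarray
    duration: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.size:
            if np.any(np.diff(self.spike_times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.spike_times[0] < 0 or self.spike_times[-1] > self.duration:
                raise ValueError("spike times must lie within [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size

    def windowed(self, start: float, stop: float, rezero: bool = True) -> "SpikeTrain":
        """Spikes in [start, stop), optionally re-referenced to ``start``."""
        mask = (self.spike_times >= start) & (self.spike_times < stop)
        times = self.spike_times[mask]
        if rezero:
            times = times - start
        return SpikeTrain(
            spike_times=times,
            duration=stop - start,
            provenance=dict(self.provenance, window=(start, stop)),
        )


def differential(trace: SensorTrace) -> np.ndarray:
    """Differential shear signal S_x = s_plus - s_minus."""
    if len(trace.s_plus) != len(trace.s_minus):
        raise ValueError("sensor channels have mismatched lengths")
    return np.asarray(trace.s_plus) - np.asarray(trace.s_minus)


def drive_current(sx: np.ndarray, K: float = 15000.0) -> np.ndarray:
    """Half-rectified amplified drive: I_x = K * S_x where S_x >= 0, else 0."""
    sx = np.asarray(sx, dtype=float)
    return K * np.maximum(sx, 0.0)


@njit(cache=False)
def _integrate(
    current: np.ndarray,
    sample_interval_ms: float,
    dt: float,
    A: float,
    B: float,
    C: float,
    a: float,
    b: float,
    c: float,
    d: float,
    v_th: float,
    input_gain: float,
    v0: float,
    u0: float,
):  # pragma: no cover - exercised through izhikevich_encode
    n_sub = int(sample_interval_ms / dt)
    remainder = sample_interval_ms - n_sub * dt
    if remainder > 1e-12:
        last_dt = dt + remainder
    else:
        last_dt = dt
    v = v0
    u = u0
    spike_times = []
    for i in range(current.shape[0]):
        I = current[i] * input_gain
        t_base = i * sample_interval_ms
        t_local = 0.0
        for k in range(n_sub):
            h = last_dt if k == n_sub - 1 else dt
            dv = A * v * v + B * v + C - u + I
            du = a * (b * v - u)
            v = v + h * dv
            u = u + h * du
            t_local += h
            if v >= v_th:
                spike_times.append(t_base + t_local)
                v = c
                u = u + d
            if not (np.isfinite(v) and np.isfinite(u)):
                return spike_times, v, u, i
    return spike_times, v, u, -1


def izhikevich_encode(
    current: np.ndarray,
    params: EncoderParams | None = None,
    initial: NeuronState | None = None,
    sample_rate: float = 380.0,
) -> SpikeTrain:
    """Integrate the Izhikevich neuron driven by ``current`` (one value per
    sensor sample, zero-order hold) and return the emitted spike train.

    Raises ``FloatingPointError`` naming the failing sample if the state
    diverges.
    """
    params = params or EncoderParams()
    initial = initial or NeuronState.resting(params)
    current = np.ascontiguousarray(current, dtype=np.float64)
    sample_interval_ms = 1000.0 / sample_rate
    input_gain = params.R * params.C_m
    spike_ms, v, u, bad = _integrate(
        current,
        sample_interval_ms,
        params.dt,
        params.A,
        params.B,
        params.C,
        params.a,
        params.b,
        params.c,
        params.d,
        params.v_th,
        input_gain,
        initial.v,
        initial.u,
    )
    if bad >= 0:
        raise FloatingPointError(
            f"neuron state diverged at sample {bad} "
            f"(t = {bad / sample_rate:.4f} s): v={v}, u={u}"
        )
    times_s = np.asarray(spike_ms, dtype=float) / 1000.0
    duration = current.shape[0] / sample_rate
    # guard against float round-off pushing the last spike past the end
    if times_s.size and times_s[-1] > duration:
        times_s[-1] = duration
    return SpikeTrain(
        spike_times=times_s,
        duration=duration,
        provenance={"n_samples": int(current.shape[0]), "sample_rate": sample_rate},
    )


def encode_trial(
    trace: SensorTrace,
    params: EncoderParams | None = None,
) -> tuple[SpikeTrain, SpikeTrain, SpikeTrain]:
    """Encode a full trial trace and window the result to the two slides.

    Returns ``(first_half, second_half, full_trial)`` where the half
    trains are re-referenced to their slide onsets.  Requires the trace to
    carry ``slide1``/``slide2`` phase markers.
    """
    params = params or EncoderParams()
    for key in ("slide1", "slide2"):
        if key not in trace.event_markers:
            raise ValueError(f"trace is missing required phase marker {key!r}")
    sx = differential(trace)
    ix = drive_current(sx, params.K)
    full = izhikevich_encode(ix, params, sample_rate=trace.sample_rate)
    if trace.pair is not None:
        full.provenance.update(label=trace.pair.label, order=trace.pair.order)
    first = full.windowed(*trace.event_markers["slide1"])
    second = full.windowed(*trace.event_markers["slide2"])
    if trace.pair is not None:
        first.provenance.update(sp=trace.pair.first_sp, half=1)
        second.provenance.update(sp=trace.pair.second_sp, half=2)
    return first, second, full
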