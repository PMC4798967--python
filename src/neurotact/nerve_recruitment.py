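"""Peripheral-nerve recruitment: needle microstimulation vs an implanted
intrafascicular (TIME) electrode.

Desk-scale hybrid model.  The extracellular field of each stimulating
site is the closed-form potential of a point current source in an
unbounded anisotropic medium,

    V = I / (4 pi sqrt(sy*sz*dx^2 + sx*sz*dy^2 + sx*sy*dz^2)),

attenuated by a scalar factor for every perineurium sheath the straight
source-to-fiber path crosses.  Sensory axons are myelinated fibers with
21 excitable nodes of Ranvier (internodal spacing 100 times the fiber
diameter) carrying fast/persistent sodium, slow potassium and leak
currents with rate kinetics in the style of the double-cable myelinated
axon literature; internodes act as passive axial resistances.  A fiber
counts as recruited when the action potential evoked by a cathodic-first
biphasic balanced pulse propagates to the last node.

Population recruitment curves (fraction of fibers whose threshold charge
falls below the injected charge) are computed for 100-fiber populations
placed in fascicles of three sizes, at three device placements (within /
close to / shielded from the target fascicle), and compared between the
needle and the TIME sites with a Kruskal-Wallis rank test on the charge
needed for 10% recruitment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from ._util import derive_seed

try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f


@njit(cache=False)
def _vexp(x: float, k: float) -> float:  # pragma: no cover
    """x / (1 - exp(-x/k)) with the removable singularity at x = 0."""
    r = x / k
    if -1e-6 < r < 1e-6:
        return k * (1.0 + r / 2.0)
    return x / (1.0 - np.exp(-r))


@njit(cache=False)
def _gate_rates(V: float):  # pragma: no cover
    """MRG-style nodal gate rates (1/ms) at a clamped membrane voltage."""
    if V > 100.0:
        V = 100.0
    elif V < -150.0:
        V = -150.0
    am = 6.57 * _vexp(V + 20.4, 10.3)
    bm = 0.304 * _vexp(-(V + 25.7), 9.16)
    ah = 0.34 * _vexp(-(V + 114.0), 11.0)
    bh = 12.6 / (1.0 + np.exp(-(V + 31.8) / 13.4))
    ap = 0.0353 * _vexp(V + 27.0, 10.2)
    bp = 0.000883 * _vexp(-(V + 34.0), 10.0)
    asv = 0.3 / (1.0 + np.exp(-(V + 53.0) / 5.0))
    bsv = 0.03 / (1.0 + np.exp(-(V + 90.0) / 1.0))
    return am, bm, ah, bh, ap, bp, asv, bsv

__all__ = [
    "TissueConductivities",
    "Fascicle",
    "NerveModel",
    "ElectrodeModel",
    "StimPulse",
    "FiberPopulation",
    "AxonParams",
    "RecruitmentCurve",
    "SimulationCase",
    "extracellular_potential",
    "perineurium_crossings",
    "axon_response",
    "fiber_threshold",
    "sample_population",
    "recruitment_curve",
    "enumerate_simulation_plan",
    "compare_devices",
    "run_plan",
]

PERINEURIUM_ATTENUATION = 0.3
N_POPULATIONS = {"large": 9, "medium": 5, "small": 1}
PLACEMENTS = ("within", "close", "shielded")


@dataclass(frozen=True)
class TissueConductivities:
    """Tissue conductivities (S/m); endoneurium is anisotropic with the
    high-conductivity axis along the fibers (z)."""

    endoneurium: tuple[float, float, float] = (0.0826, 0.0826, 0.571)
    perineurium: float = 880e-6
    epineurium: float = 0.0826
    saline: float = 2.0

    def __post_init__(self) -> None:
        sx, sy, sz = self.endoneurium
        if min(sx, sy, sz, self.perineurium, self.epineurium, self.saline) <= 0:
            raise ValueError("all conductivities must be positive")
        if sz <= sx:
            raise ValueError("longitudinal endoneurial conductivity must exceed transverse")


@dataclass(frozen=True)
class Fascicle:
    center: tuple[float, float]  # mm, cross-section
    diameter: float  # mm
    size_class: str  # small / medium / large

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("fascicle diameter must be positive")
        if self.size_class not in N_POPULATIONS:
            raise ValueError(f"size_class must be one of {sorted(N_POPULATIONS)}")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    @property
    def perineurium_thickness(self) -> float:
        """3% of the fascicle diameter (mm)."""
        return 0.03 * self.diameter

    def contains(self, x: float, y: float) -> bool:
        return math.hypot(x - self.center[0], y - self.center[1]) <= self.radius


@dataclass
class NerveModel:
    """Cross-section of the nerve trunk: disjoint cylindrical fascicles."""

    fascicles: list[Fascicle]
    nerve_diameter: float = 3.0  # mm, within the anatomical 2.3-4.6 range

    def __post_init__(self) -> None:
        if not 2.3 <= self.nerve_diameter <= 4.6:
            raise ValueError("nerve diameter must lie in the anatomical 2.3-4.6 mm range")
        for i, f1 in enumerate(self.fascicles):
            for f2 in self.fascicles[i + 1:]:
                d = math.hypot(
                    f1.center[0] - f2.center[0], f1.center[1] - f2.center[1]
                )
                if d < f1.radius + f2.radius:
                    raise ValueError("fascicles must be disjoint")


@dataclass(frozen=True)
class ElectrodeModel:
    """Point-source reduction of the stimulating interfaces.

    The needle contributes its conical tip apex (shank 250 um, cone
    semi-angle 12.78 deg, tip insulation variant recorded as metadata);
    the TIME contributes two mirrored active sites (radius 40 um) on the
    faces of a 4 mm x 0.35 mm x 20 um substrate, offset laterally from
    the needle-tip reference position.
    """

    kind: str  # "needle" | "TIME"
    position: tuple[float, float]  # mm, reference (tip / substrate center)
    tip_variant: str = "insulated"  # needle tip exposure variant
    shank_diameter_um: float = 250.0
    cone_semi_angle_deg: float = 12.78
    site_radius_um: float = 40.0
    body_mm: tuple[float, float, float] = (4.0, 0.35, 0.020)
    site_offset_mm: float = 0.05  # lateral offset of the two TIME faces

    def __post_init__(self) -> None:
        if self.kind not in ("needle", "TIME"):
            raise ValueError("kind must be 'needle' or 'TIME'")

    def sites(self) -> list[tuple[str, tuple[float, float]]]:
        """Active-site labels and cross-section positions (mm)."""
        x, y = self.position
        if self.kind == "needle":
            return [("tip", (x, y))]
        return [
            ("L", (x, y - self.site_offset_mm)),
            ("R", (x, y + self.site_offset_mm)),
        ]


@dataclass(frozen=True)
class StimPulse:
    """Cathodic-first biphasic charge-balanced square pulse."""

    amplitude: float = 160.0  # uA per phase
    width: float = 100.0  # us per phase
    shape: str = "cathodic_biphasic_balanced"

    def __post_init__(self) -> None:
        if self.amplitude * self.width <= 0:
            raise ValueError("pulse charge must be positive")

    @property
    def charge_nC(self) -> float:
        return self.amplitude * self.width * 1e-3


@dataclass
class FiberPopulation:
    """Sampled sensory axons of one fascicle population."""

    positions: np.ndarray  # (n, 2) mm in the cross-section
    diameters: np.ndarray  # (n,) um
    z_offsets: np.ndarray  # (n,) mm, shift of the node ladder along z
    population_id: int
    fascicle: Fascicle

    @property
    def n_fibers(self) -> int:
        return self.positions.shape[0]


@dataclass(frozen=True)
class AxonParams:
    """Nodal membrane and cable constants (mV, ms, S/cm2, uF/cm2)."""

    n_nodes: int = 21
    nodal_length_um: float = 1.0
    node_diameter_ratio: float = 1.0 / 3.0  # node diameter / fiber diameter
    axon_diameter_ratio: float = 0.65  # internodal axon diameter / fiber D
    rho_axial_ohm_cm: float = 70.0
    cm_uF_cm2: float = 2.0
    g_naf: float = 3.0
    g_nap: float = 0.01
    g_ks: float = 0.08
    g_leak: float = 0.007
    e_na: float = 50.0
    e_k: float = -90.0
    e_leak: float = -90.0
    v_rest: float = -80.0
    dt_pulse_us: float = 1.0
    dt_post_us: float = 5.0
    horizon_ms: float = 3.0
    spike_threshold_mV: float = 0.0


@dataclass
class RecruitmentCurve:
    charges: np.ndarray  # nC
    fraction_recruited: np.ndarray
    thresholds_nC: np.ndarray  # per fiber, inf when never recruited
    case_key: tuple = ()

    def charge_at(self, fraction: float) -> float:
        """Charge (nC) at a recruitment fraction via linear interpolation;
        NaN when the curve never reaches it."""
        f = self.fraction_recruited
        if f[-1] < fraction:
            return float("nan")
        idx = int(np.argmax(f >= fraction))
        if idx == 0:
            return float(self.charges[0])
        c0, c1 = self.charges[idx - 1], self.charges[idx]
        f0, f1 = f[idx - 1], f[idx]
        if f1 == f0:
            return float(c1)
        return float(c0 + (fraction - f0) * (c1 - c0) / (f1 - f0))


@dataclass(frozen=True)
class SimulationCase:
    device: str  # "needle" | "TIME"
    placement: str  # within / close / shielded
    fascicle_class: str
    population_id: int
    site: str  # "tip" | "L" | "R"

    @property
    def key(self) -> tuple:
        return (self.device, self.placement, self.fascicle_class, self.population_id, self.site)


# ---------------------------------------------------------------------------
# fields


def extracellular_potential(
    source: Sequence[float],
    current: float,
    point: Sequence[float],
    conductivities: TissueConductivities | None = None,
    n_crossings: int = 0,
    attenuation: float = PERINEURIUM_ATTENUATION,
) -> float:
    """Potential (mV) at ``point`` of a point source of ``current`` (uA)
    at ``source`` (both mm, 3-vectors) in an unbounded anisotropic medium,
    attenuated by ``attenuation`` per perineurium crossing."""
    cond = conductivities or TissueConductivities()
    sx, sy, sz = cond.endoneurium
    dx = (point[0] - source[0]) * 1e-3
    dy = (point[1] - source[1]) * 1e-3
    dz = (point[2] - source[2]) * 1e-3
    denom = math.sqrt(sy * sz * dx * dx + sx * sz * dy * dy + sx * sy * dz * dz)
    if denom == 0.0:
        raise ValueError("field point coincides with the source")
    v_volts = current * 1e-6 / (4.0 * math.pi * denom)
    return v_volts * 1e3 * attenuation**n_crossings


def perineurium_crossings(
    source_xy: Sequence[float],
    point_xy: Sequence[float],
    nerve: NerveModel,
) -> int:
    """Number of perineurium sheaths the straight segment from source to
    point crosses in the nerve cross-section (fascicles as circles)."""
    x0, y0 = source_xy
    x1, y1 = point_xy
    dx, dy = x1 - x0, y1 - y0
    total = 0
    for f in nerve.fascicles:
        cx, cy = f.center
        # |(p0 + t d) - c|^2 = r^2, t in (0, 1)
        fx, fy = x0 - cx, y0 - cy
        a = dx * dx + dy * dy
        b = 2.0 * (fx * dx + fy * dy)
        c = fx * fx + fy * fy - f.radius**2
        if a == 0.0:
            continue
        disc = b * b - 4.0 * a * c
        if disc <= 0.0:
            continue
        sq = math.sqrt(disc)
        for t in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
            if 0.0 < t < 1.0:
                total += 1
    return total


# ---------------------------------------------------------------------------
# axon dynamics


@njit(cache=False)
def _axon_sim(
    phi_mV: np.ndarray,  # (n_nodes,) potential per uA at each node
    amplitude_uA: float,
    width_ms: float,
    g_axial_S: float,
    area_cm2: float,
    cm: float,
    g_naf: float,
    g_nap: float,
    g_ks: float,
    g_leak: float,
    e_na: float,
    e_k: float,
    e_leak: float,
    v_rest: float,
    dt_pulse_ms: float,
    dt_post_ms: float,
    horizon_ms: float,
    v_spike: float,
):  # pragma: no cover - exercised through axon_response
    n = phi_mV.shape[0]
    v = np.full(n, v_rest)
    # steady-state gates at rest
    m = np.zeros(n)
    h = np.zeros(n)
    p = np.zeros(n)
    s = np.zeros(n)
    for i in range(n):
        am, bm, ah, bh, ap, bp, asv, bsv = _gate_rates(v[i])
        m[i] = am / (am + bm)
        h[i] = ah / (ah + bh)
        p[i] = ap / (ap + bp)
        s[i] = asv / (asv + bsv)

    g_ax = g_axial_S / area_cm2  # S/cm2 equivalent coupling
    last_node_fired = False
    t = 0.0
    while t < horizon_ms:
        if t < width_ms:
            stim = -1.0  # cathodic phase
            dt = dt_pulse_ms
            if t + dt > width_ms:
                dt = width_ms - t
        elif t < 2.0 * width_ms:
            stim = 1.0  # anodic (balancing) phase
            dt = dt_pulse_ms
            if t + dt > 2.0 * width_ms:
                dt = 2.0 * width_ms - t
        else:
            stim = 0.0
            dt = dt_post_ms
        v_new = np.empty(n)
        for i in range(n):
            V = v[i]
            ve_i = phi_mV[i] * amplitude_uA * stim
            if i == 0:
                ax = (v[1] - V) + (phi_mV[1] - phi_mV[0]) * amplitude_uA * stim
            elif i == n - 1:
                ax = (v[n - 2] - V) + (phi_mV[n - 2] - phi_mV[n - 1]) * amplitude_uA * stim
            else:
                ax = (v[i - 1] - 2.0 * V + v[i + 1]) + (
                    phi_mV[i - 1] - 2.0 * phi_mV[i] + phi_mV[i + 1]
                ) * amplitude_uA * stim
            # gate updates (exponential Euler, unconditionally stable)
            am, bm, ah, bh, ap, bp, asv, bsv = _gate_rates(V)
            tm = 1.0 / (am + bm)
            th = 1.0 / (ah + bh)
            tp = 1.0 / (ap + bp)
            ts = 1.0 / (asv + bsv)
            m[i] = am * tm + (m[i] - am * tm) * np.exp(-dt / tm)
            h[i] = ah * th + (h[i] - ah * th) * np.exp(-dt / th)
            p[i] = ap * tp + (p[i] - ap * tp) * np.exp(-dt / tp)
            s[i] = asv * ts + (s[i] - asv * ts) * np.exp(-dt / ts)
            gna = g_naf * m[i] ** 3 * h[i]
            gnap = g_nap * p[i] ** 3
            gks = g_ks * s[i]
            g_tot = gna + gnap + gks + g_leak + 2.0 * g_ax
            drive = (
                gna * e_na
                + gnap * e_na
                + gks * e_k
                + g_leak * e_leak
                + g_ax * (ax + 2.0 * V)  # ax holds the explicit neighbor terms
            )
            # semi-implicit: membrane conductances implicit in V
            v_new[i] = (V + dt / cm * drive) / (1.0 + dt / cm * g_tot)
            if not np.isfinite(v_new[i]):
                return False, True
        v = v_new
        if v[n - 1] >= v_spike:
            last_node_fired = True
            break
        t += dt
    return last_node_fired, False


def _node_phi(
    fiber_xy: tuple[float, float],
    diameter_um: float,
    z_offset_mm: float,
    site_xy: tuple[float, float],
    nerve: NerveModel,
    cond: TissueConductivities,
    params: AxonParams,
    attenuation: float,
) -> np.ndarray:
    """Extracellular potential per uA of source current at the fiber's
    node positions (mV/uA)."""
    n = params.n_nodes
    spacing_mm = 100.0 * diameter_um * 1e-3
    z = (np.arange(n) - (n - 1) / 2.0) * spacing_mm + z_offset_mm
    crossings = perineurium_crossings(site_xy, fiber_xy, nerve)
    phi = np.empty(n)
    for i in range(n):
        phi[i] = extracellular_potential(
            (site_xy[0], site_xy[1], 0.0),
            1.0,
            (fiber_xy[0], fiber_xy[1], z[i]),
            cond,
            n_crossings=crossings,
            attenuation=attenuation,
        )
    return phi


def axon_response(
    phi_mV_per_uA: np.ndarray,
    diameter_um: float,
    pulse: StimPulse,
    params: AxonParams | None = None,
) -> bool:
    """Whether the fiber fires a propagating action potential reaching the
    last node under the given extracellular potential profile and pulse."""
    params = params or AxonParams()
    d_node_cm = params.node_diameter_ratio * diameter_um * 1e-4
    l_node_cm = params.nodal_length_um * 1e-4
    area = math.pi * d_node_cm * l_node_cm
    d_ax_cm = params.axon_diameter_ratio * diameter_um * 1e-4
    l_inter_cm = 100.0 * diameter_um * 1e-4
    g_axial = math.pi * d_ax_cm**2 / (4.0 * params.rho_axial_ohm_cm * l_inter_cm)
    recruited, diverged = _axon_sim(
        np.ascontiguousarray(phi_mV_per_uA, dtype=np.float64),
        pulse.amplitude,
        pulse.width * 1e-3,
        g_axial,
        area,
        params.cm_uF_cm2 * 1e-6 * 1e3,  # uF/cm2 -> mF/cm2 so that ms*S/cm2 matches
        params.g_naf,
        params.g_nap,
        params.g_ks,
        params.g_leak,
        params.e_na,
        params.e_k,
        params.e_leak,
        params.v_rest,
        params.dt_pulse_us * 1e-3,
        params.dt_post_us * 1e-3,
        params.horizon_ms,
        params.spike_threshold_mV,
    )
    if diverged:
        raise FloatingPointError(
            f"axon integration diverged (D={diameter_um} um, "
            f"amplitude={pulse.amplitude} uA)"
        )
    return bool(recruited)


def fiber_threshold(
    phi_mV_per_uA: np.ndarray,
    diameter_um: float,
    width_us: float = 100.0,
    params: AxonParams | None = None,
    max_amplitude: float = 3200.0,
    rel_tol: float = 0.01,
) -> float:
    """Threshold charge (nC) by bisection on pulse amplitude at fixed
    width; inf when the fiber is not recruited even at ``max_amplitude``."""
    params = params or AxonParams()

    def recruited(amp: float) -> bool:
        return axon_response(
            phi_mV_per_uA, diameter_um, StimPulse(amplitude=amp, width=width_us), params
        )

    lo, hi = 0.0, 25.0
    while not recruited(hi):
        lo = hi
        hi *= 2.0
        if hi > max_amplitude:
            return float("inf")
    while hi - lo > rel_tol * hi:
        mid = 0.5 * (lo + hi)
        if recruited(mid):
            hi = mid
        else:
            lo = mid
    return hi * width_us * 1e-3


# ---------------------------------------------------------------------------
# populations and plans


def default_nerve() -> NerveModel:
    """Three-fascicle cross-section: a large target fascicle at the
    origin, a medium and a small fascicle beside it."""
    return NerveModel(
        fascicles=[
            Fascicle(center=(0.0, 0.0), diameter=1.2, size_class="large"),
            Fascicle(center=(1.15, 0.0), diameter=0.7, size_class="medium"),
            Fascicle(center=(0.0, 1.0), diameter=0.35, size_class="small"),
        ],
        nerve_diameter=3.0,
    )


def sample_population(
    fascicle: Fascicle,
    population_id: int,
    seed: int,
    n_fibers: int = 100,
    diameter_mean_um: float = 9.0,
    diameter_sd_um: float = 2.0,
    diameter_min_um: float = 3.0,
) -> FiberPopulation:
    """Sample one fiber population of a fascicle.

    Populations index decreasing spatial extent: id 1 fills the whole
    fascicle uniformly; the highest id is a tight cluster.  Centroids of
    the clustered populations are displaced inside the fascicle so every
    population disc stays within the id-1 disc.  Fiber diameters follow
    the touch/pressure Gaussian truncated below ``diameter_min_um``.
    """
    n_pops = N_POPULATIONS[fascicle.size_class]
    if not 1 <= population_id <= n_pops:
        raise ValueError(
            f"population_id must be in 1..{n_pops} for a {fascicle.size_class} fascicle"
        )
    rng = np.random.default_rng(seed)
    r_full = 0.95 * fascicle.radius
    if n_pops == 1:
        extent = r_full
        centroid = np.array(fascicle.center)
    else:
        frac = (population_id - 1) / (n_pops - 1)
        extent = r_full * (1.0 - 0.85 * frac)
        shift = 0.8 * (r_full - extent)
        angle = 2.0 * math.pi * (population_id - 1) / n_pops
        centroid = np.array(fascicle.center) + shift * np.array(
            [math.cos(angle), math.sin(angle)]
        )
    rr = extent * np.sqrt(rng.uniform(size=n_fibers))
    th = rng.uniform(0.0, 2.0 * math.pi, size=n_fibers)
    positions = centroid + np.column_stack([rr * np.cos(th), rr * np.sin(th)])
    diameters = np.empty(n_fibers)
    filled = 0
    while filled < n_fibers:
        draw = rng.normal(diameter_mean_um, diameter_sd_um, size=n_fibers)
        ok = draw[draw > diameter_min_um]
        take = min(ok.size, n_fibers - filled)
        diameters[filled : filled + take] = ok[:take]
        filled += take
    z_span = 100.0 * diameters * 1e-3 / 2.0  # half the internodal spacing, mm
    z_offsets = rng.uniform(-z_span, z_span)
    return FiberPopulation(
        positions=positions,
        diameters=diameters,
        z_offsets=z_offsets,
        population_id=population_id,
        fascicle=fascicle,
    )


def placement_position(
    placement: str, nerve: NerveModel, target: Fascicle
) -> tuple[float, float]:
    """Cross-section position of the needle tip / TIME center for a
    device placement relative to the target fascicle."""
    cx, cy = target.center
    r = target.radius
    if placement == "within":
        return (cx + 0.25 * r, cy)
    if placement == "close":
        return (cx - (r + 0.15), cy)
    if placement == "shielded":
        # behind the largest neighboring fascicle, so its perineurium screens the target
        shield = max(
            (f for f in nerve.fascicles if f is not target),
            key=lambda f: f.radius,
        )
        sx, sy = shield.center
        direction = np.array([sx - cx, sy - cy])
        direction = direction / np.linalg.norm(direction)
        far = np.array([sx, sy]) + direction * (shield.radius + 0.15)
        return (float(far[0]), float(far[1]))
    raise ValueError(f"unknown placement {placement!r}; valid: {PLACEMENTS}")


def enumerate_simulation_plan(nerve: NerveModel | None = None) -> list[SimulationCase]:
    """Cross product of 3 placements x population ensembles (9 large + 5
    medium + 1 small): one case per cell for the needle, two (mirrored
    L/R sites) for the TIME — 45 and 90 cases respectively."""
    nerve = nerve or default_nerve()
    cases = []
    for placement in PLACEMENTS:
        for fasc in nerve.fascicles:
            for pop_id in range(1, N_POPULATIONS[fasc.size_class] + 1):
                cases.append(
                    SimulationCase("needle", placement, fasc.size_class, pop_id, "tip")
                )
                for site in ("L", "R"):
                    cases.append(
                        SimulationCase("TIME", placement, fasc.size_class, pop_id, site)
                    )
    return cases


def recruitment_curve(
    population: FiberPopulation,
    electrode: ElectrodeModel,
    site: str,
    nerve: NerveModel,
    charge_grid: np.ndarray,
    conductivities: TissueConductivities | None = None,
    params: AxonParams | None = None,
    width_us: float = 100.0,
    attenuation: float = PERINEURIUM_ATTENUATION,
    case_key: tuple = (),
) -> RecruitmentCurve:
    """Fraction of the population recruited at each injected charge."""
    charge_grid = np.asarray(charge_grid, dtype=float)
    if charge_grid.size and np.any(np.diff(charge_grid) <= 0):
        raise ValueError("charge grid must be strictly increasing")
    cond = conductivities or TissueConductivities()
    params = params or AxonParams()
    site_xy = dict(electrode.sites())[site]
    thresholds = np.empty(population.n_fibers)
    for i in range(population.n_fibers):
        phi = _node_phi(
            tuple(population.positions[i]),
            population.diameters[i],
            population.z_offsets[i],
            site_xy,
            nerve,
            cond,
            params,
            attenuation,
        )
        thresholds[i] = fiber_threshold(
            phi, population.diameters[i], width_us, params
        )
    fractions = np.array(
        [np.mean(thresholds <= c) for c in charge_grid]
    )
    return RecruitmentCurve(
        charges=charge_grid,
        fraction_recruited=fractions,
        thresholds_nC=thresholds,
        case_key=case_key,
    )


def run_plan(
    seed: int,
    nerve: NerveModel | None = None,
    n_fibers: int = 100,
    charge_grid: np.ndarray | None = None,
    cases: Sequence[SimulationCase] | None = None,
    conductivities: TissueConductivities | None = None,
    params: AxonParams | None = None,
) -> dict[tuple, RecruitmentCurve]:
    """Run every case of the simulation plan and return its curves.

    Population sampling is seeded per (placement-independent) population,
    so the same fibers are stimulated by every device and placement —
    matching the paired structure of the device comparison.
    """
    nerve = nerve or default_nerve()
    if charge_grid is None:
        charge_grid = np.linspace(0.25, 60.0, 120)
    cases = list(cases) if cases is not None else enumerate_simulation_plan(nerve)
    fasc_by_class = {f.size_class: f for f in nerve.fascicles}
    pop_cache: dict[tuple, FiberPopulation] = {}
    results: dict[tuple, RecruitmentCurve] = {}
    for case in cases:
        fasc = fasc_by_class[case.fascicle_class]
        pkey = (case.fascicle_class, case.population_id)
        if pkey not in pop_cache:
            pop_cache[pkey] = sample_population(
                fasc, case.population_id, derive_seed(seed, "population", *pkey),
                n_fibers=n_fibers,
            )
        pop = pop_cache[pkey]
        position = placement_position(case.placement, nerve, fasc)
        electrode = ElectrodeModel(kind=case.device, position=position)
        results[case.key] = recruitment_curve(
            pop,
            electrode,
            case.site,
            nerve,
            charge_grid,
            conductivities,
            params,
            case_key=case.key,
        )
    return results


@dataclass
class DeviceComparison:
    statistic: float
    p_value: float
    needle_charges: np.ndarray
    time_charges: np.ndarray
    n_excluded: int
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def compare_devices(
    results: dict[tuple, RecruitmentCurve],
    fraction: float = 0.10,
    alpha: float = 0.05,
) -> DeviceComparison:
    """Kruskal-Wallis comparison of the charges needed for ``fraction``
    recruitment between needle and TIME cases.  Curves never reaching the
    level are excluded and counted."""
    needle, time_, excluded = [], [], 0
    for key, curve in results.items():
        q = curve.charge_at(fraction)
        if not np.isfinite(q):
            excluded += 1
            continue
        (needle if key[0] == "needle" else time_).append(q)
    if not needle or not time_:
        raise ValueError("both device groups must be nonempty")
    needle = np.asarray(needle)
    time_ = np.asarray(time_)
    if np.array_equal(np.sort(needle), np.sort(time_)) and np.ptp(
        np.concatenate([needle, time_])
    ) == 0:
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.kruskal(needle, time_)
    return DeviceComparison(
        statistic=float(stat),
        p_value=float(p),
        needle_charges=needle,
        time_charges=time_,
        n_excluded=excluded,
        alpha=alpha,
    )
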