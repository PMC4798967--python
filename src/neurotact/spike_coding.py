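"""Temporal-coding analysis of encoder spike trains.

Under constant sliding velocity the encoder responds with one burst per
ridge, so the inter-burst interval (IBI) — the distance between onsets
of consecutive bursts — equals spatial_period / velocity and carries the
grating geometry.  The average firing rate (AFR, spikes during the 2 s
slide divided by the slide duration) does not: coarser gratings fire
fewer but denser bursts, leaving the total count nearly constant.  This
module computes both codes, the instantaneous rate, a spatial modulation
index, the per-pair signed feature differences, and the statistics that
contrast them (OLS regressions of features on delta-SP; one-way ANOVA
with Tukey-Kramer pairwise comparisons across spatial periods).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .mnt_encoder import SpikeTrain
from .synthetic_touch import GratingSpec, StimulusPair

__all__ = [
    "BurstSegmentation",
    "CodingMetrics",
    "PairFeatures",
    "RegressionResult",
    "GroupingReport",
    "segment_bursts",
    "compute_metrics",
    "spatial_modulation_index",
    "pair_features",
    "feature_vs_dsp_regression",
    "ibi_specificity_test",
]

DEFAULT_ISI_GAP_MS = 25.0
SMI_BIN_S = 0.005


@dataclass
class BurstSegmentation:
    burst_onsets: np.ndarray  # s
    spikes_per_burst: np.ndarray  # counts
    isi_gap_threshold: float  # ms

    @property
    def n_bursts(self) -> int:
        return self.burst_onsets.size

    @property
    def ibis(self) -> np.ndarray:
        """Inter-burst intervals (ms) between consecutive burst onsets."""
        return np.diff(self.burst_onsets) * 1000.0

    @property
    def modal_spikes_per_burst(self) -> int:
        if self.spikes_per_burst.size == 0:
            return 0
        vals, counts = np.unique(self.spikes_per_burst, return_counts=True)
        return int(vals[np.argmax(counts)])


@dataclass
class CodingMetrics:
    """Per-trial-half temporal-coding summary."""

    ibi_median: float  # ms, NaN when undefined
    ibis: np.ndarray  # ms
    afr: float  # spikes/s
    inst_rate_times: np.ndarray  # s, right edge of each ISI
    inst_rate: np.ndarray  # spikes/s
    smi: float  # dimensionless, NaN when undefined
    n_spikes: int
    ibi_defined: bool
    provenance: dict = field(default_factory=dict)


@dataclass
class PairFeatures:
    """Signed first-minus-second differences for one presented pair."""

    delta_sp: float  # mm
    delta_ibi: float  # ms, NaN if either half undefined
    delta_afr: float  # spikes/s
    defined: bool
    label: str = ""
    order: str = "+"


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


@dataclass
class GroupingReport:
    f_statistic: float
    p_value: float
    separated_pairs: list[tuple[float, float]]
    unseparated_pairs: list[tuple[float, float]]
    alpha: float

    @property
    def all_separated(self) -> bool:
        return not self.unseparated_pairs


def segment_bursts(
    train: SpikeTrain, isi_gap_threshold: float = DEFAULT_ISI_GAP_MS
) -> BurstSegmentation:
    """Split a spike train into bursts.

    A new burst starts at any spike whose preceding inter-spike interval
    exceeds ``isi_gap_threshold`` (ms); the first spike always opens a
    burst.  An empty train yields an empty segmentation.
    """
    if isi_gap_threshold <= 0:
        raise ValueError("isi_gap_threshold must be positive")
    t = train.spike_times
    if t.size == 0:
        return BurstSegmentation(
            burst_onsets=np.empty(0),
            spikes_per_burst=np.empty(0, dtype=int),
            isi_gap_threshold=isi_gap_threshold,
        )
    isi_ms = np.diff(t) * 1000.0
    onset_idx = np.concatenate([[0], np.where(isi_ms > isi_gap_threshold)[0] + 1])
    sizes = np.diff(np.concatenate([onset_idx, [t.size]]))
    return BurstSegmentation(
        burst_onsets=t[onset_idx],
        spikes_per_burst=sizes.astype(int),
        isi_gap_threshold=isi_gap_threshold,
    )


def spatial_modulation_index(
    train: SpikeTrain,
    grating: GratingSpec | float,
    velocity: float = 10.0,
    bin_width: float = SMI_BIN_S,
) -> float:
    """Modulation of the binned spike rate at the ridge-passage frequency.

    The spike train is binned at ``bin_width`` over its duration and the
    index is the magnitude of the Fourier component of the binned rate at
    f = velocity / spatial_period, normalized by the mean rate (the DC
    component).  A perfectly periodic train at the ridge frequency scores
    near the theoretical maximum of 2; a homogeneous Poisson train scores
    near 0 in expectation.  Returns NaN for an empty train.
    """
    sp = grating.spatial_period if isinstance(grating, GratingSpec) else float(grating)
    t = train.spike_times
    if t.size == 0:
        return float("nan")
    duration = train.duration
    n_bins = max(int(round(duration / bin_width)), 1)
    counts, _ = np.histogram(t, bins=n_bins, range=(0.0, duration))
    f_ridge = velocity / sp
    # direct Fourier projection at the (generally off-grid) ridge frequency
    centers = (np.arange(n_bins) + 0.5) * (duration / n_bins)
    z = np.sum(counts * np.exp(-2j * np.pi * f_ridge * centers))
    mean = np.sum(counts)
    return float(2.0 * np.abs(z) / mean)


def compute_metrics(
    train: SpikeTrain,
    slide_duration: float = 2.0,
    grating: GratingSpec | float | None = None,
    velocity: float = 10.0,
    isi_gap_threshold: float = DEFAULT_ISI_GAP_MS,
) -> CodingMetrics:
    """Temporal-coding metrics for a spike train windowed to one slide.

    AFR is total spikes / ``slide_duration``; the IBI median is taken
    over consecutive burst onsets and flagged undefined (NaN) with fewer
    than two bursts; the instantaneous rate is the inverse inter-spike
    interval assigned to the right edge of each ISI.
    """
    seg = segment_bursts(train, isi_gap_threshold)
    ibis = seg.ibis
    ibi_defined = seg.n_bursts >= 2
    ibi_median = float(np.median(ibis)) if ibi_defined else float("nan")
    afr = train.n_spikes / slide_duration
    t = train.spike_times
    if t.size >= 2:
        isis = np.diff(t)
        inst_rate_times = t[1:]
        inst_rate = 1.0 / isis
    else:
        inst_rate_times = np.empty(0)
        inst_rate = np.empty(0)
    smi = (
        spatial_modulation_index(train, grating, velocity)
        if grating is not None and t.size
        else float("nan")
    )
    return CodingMetrics(
        ibi_median=ibi_median,
        ibis=ibis,
        afr=afr,
        inst_rate_times=inst_rate_times,
        inst_rate=inst_rate,
        smi=smi,
        n_spikes=train.n_spikes,
        ibi_defined=ibi_defined,
        provenance=dict(train.provenance),
    )


def pair_features(
    first: CodingMetrics, second: CodingMetrics, pair: StimulusPair
) -> PairFeatures:
    """Signed first-minus-second differences in IBI and AFR for one pair."""
    defined = first.ibi_defined and second.ibi_defined
    delta_ibi = first.ibi_median - second.ibi_median if defined else float("nan")
    return PairFeatures(
        delta_sp=pair.delta_sp,
        delta_ibi=delta_ibi,
        delta_afr=first.afr - second.afr,
        defined=defined,
        label=pair.label,
        order=pair.order,
    )


def feature_vs_dsp_regression(
    features: Sequence[PairFeatures], which: str = "delta_ibi"
) -> RegressionResult:
    """OLS of a signed pair feature on signed delta-SP; R^2 is the squared
    Pearson correlation.  Requires at least three distinct delta-SP values."""
    if which not in ("delta_ibi", "delta_afr"):
        raise ValueError("which must be 'delta_ibi' or 'delta_afr'")
    x = np.array([f.delta_sp for f in features], dtype=float)
    y = np.array([getattr(f, which) for f in features], dtype=float)
    keep = np.isfinite(y)
    x, y = x[keep], y[keep]
    if np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct delta-SP values")
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: delta-SP has no variance")
    if np.ptp(y) == 0:
        # constant response carries no information about delta-SP
        return RegressionResult(
            slope=0.0, intercept=float(y[0]), r_squared=0.0, p_value=1.0, n=int(x.size)
        )
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=int(x.size),
    )


def ibi_specificity_test(
    groups: Mapping[float, Iterable[float]], alpha: float = 0.05
) -> GroupingReport:
    """One-way ANOVA across spatial-period groups with Tukey-Kramer
    pairwise comparisons; reports which SP pairs separate at ``alpha``.

    ``groups`` maps spatial period -> per-trial metric values (e.g. the
    median IBI of each repetition).  Rejects fewer than two groups or any
    singleton group.
    """
    keys = sorted(groups)
    data = {k: np.asarray(list(groups[k]), dtype=float) for k in keys}
    if len(keys) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in data.items():
        if v.size < 2:
            raise ValueError(f"group {k} has fewer than 2 observations")
    f_stat, p_val = stats.f_oneway(*(data[k] for k in keys))
    values = np.concatenate([data[k] for k in keys])
    labels = np.concatenate([np.full(data[k].size, k) for k in keys])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    separated, unseparated = [], []
    for (g1, g2), reject in zip(
        [(a, b) for i, a in enumerate(tukey.groupsunique) for b in tukey.groupsunique[i + 1:]],
        tukey.reject,
    ):
        (separated if reject else unseparated).append((float(g1), float(g2)))
    return GroupingReport(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        separated_pairs=separated,
        unseparated_pairs=unseparated,
        alpha=alpha,
    )
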