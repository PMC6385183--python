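"""Alternation ratios and circular statistics.

Left-right coordination is summarised by ratios on the circle [0, 1), where
0 and 1 are identical events:

- *spatial alternation ratio*: step length divided by the opposing limb's
  spanning stride length — 0.5 means each foot lands exactly halfway along
  the other side's stride;
- *temporal alternation ratio*: the time offset of the opposing footfall
  within a limb's cycle, divided by cycle duration — 0.5 is strict
  alternation.

Ratios are treated as circular data (angle = 2*pi*ratio): summarised by the
mean direction and resultant length r (1 = perfect clustering, 0 = uniform
dispersion), plotted on polar axes, and compared between conditions with
the Watson–Williams test at alpha = 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AlternationSeries",
    "CircularSummary",
    "WatsonWilliamsResult",
    "spatial_ratios",
    "temporal_ratios",
    "circ_summary",
    "circ_kappa",
    "watson_williams",
    "bin_by_speed",
    "polar_export",
    "plot_polar",
    "DEFAULT_SPEED_BINS",
]

#: mouse walking-range speed bins (cm/s); boundary speed goes to the upper bin
DEFAULT_SPEED_BINS = ((3.0, 10.0), (10.0, 16.0))


@dataclass
class AlternationSeries:
    """Ratios on [0,1) with the stride velocities they are attached to.

    The attached speed is that of the opposing (denominator / cycle-defining)
    limb's stride, since the ratio is defined on that limb's stride or cycle.
    """

    kind: str  # "spatial" | "temporal"
    limb_pair: str  # "hind" | "fore" | "legs"
    ratios: np.ndarray
    speeds: np.ndarray
    condition: str = ""
    n_skipped: int = 0

    def __post_init__(self):
        self.ratios = np.mod(np.asarray(self.ratios, float), 1.0)
        self.speeds = np.asarray(self.speeds, float)
        if self.ratios.shape != self.speeds.shape:
            raise ValueError("ratios and speeds must have equal length")

    def __len__(self):
        return len(self.ratios)


@dataclass
class CircularSummary:
    """Circular mean direction and resultant length of one ratio series."""

    mean_direction: float  # radians in [0, 2*pi)
    r: float
    n: int
    undefined: bool = False  # resultant vanishes; mean direction meaningless

    @property
    def mean_ratio(self) -> float:
        return (self.mean_direction / (2.0 * math.pi)) % 1.0


@dataclass
class WatsonWilliamsResult:
    """Two-sample Watson–Williams test for equal circular mean directions."""

    F: float
    df_num: int
    df_den: int
    p: float
    correction: float
    rbar: float
    warnings: list = field(default_factory=list)

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


# ---------------------------------------------------------------------------
# ratio construction
# ---------------------------------------------------------------------------


def _pair_name(limb_a: str, limb_b: str) -> str:
    from .core import HOMOLOGOUS_PAIRS

    for name, pair in HOMOLOGOUS_PAIRS.items():
        if {limb_a, limb_b} == set(pair):
            return name
    raise ValueError(f"{limb_a}/{limb_b} is not a homologous pair")


def spatial_ratios(
    strides_a: pd.DataFrame, strides_b: pd.DataFrame, condition: str = ""
) -> AlternationSeries:
    """Step length of limb A over the spanning stride length of limb B.

    The spanning stride of B is the one whose cycle contains A's placement
    time.  Ratios are wrapped mod 1 (a negative step length wraps toward 1);
    strides without a step length, without a spanning stride, or with a zero
    opposing stride length are skipped and counted.
    """
    if len(strides_a) == 0 or len(strides_b) == 0:
        return AlternationSeries("spatial", "hind", np.array([]), np.array([]), condition)
    pair = _pair_name(strides_a["limb"].iloc[0], strides_b["limb"].iloc[0])
    key = ["subject_id", "condition", "trial_id"]
    ratios, speeds = [], []
    skipped = 0
    for trial, ga in strides_a.groupby(key):
        gb = strides_b.merge(
            pd.DataFrame([trial], columns=key), on=key
        ).sort_values("t_start")
        if len(gb) == 0:
            skipped += len(ga)
            continue
        tb = gb["t_start"].to_numpy(float)
        end_b = tb + gb["cycle_duration"].to_numpy(float)
        lb = gb["stride_length"].to_numpy(float)
        vb = gb["stride_velocity"].to_numpy(float)
        for _, row in ga.iterrows():
            if not np.isfinite(row["step_length"]):
                skipped += 1
                continue
            idx = np.searchsorted(tb, row["t_start"], side="right") - 1
            if idx < 0 or row["t_start"] >= end_b[idx]:
                skipped += 1
                continue
            if lb[idx] == 0:
                skipped += 1
                continue
            ratios.append(row["step_length"] / lb[idx])
            speeds.append(vb[idx])
    if skipped:
        logger.info("spatial_ratios: skipped %d strides", skipped)
    return AlternationSeries(
        "spatial", pair, np.asarray(ratios), np.asarray(speeds), condition, skipped
    )


def temporal_ratios(
    events_a: pd.DataFrame, events_b: pd.DataFrame, condition: str = ""
) -> AlternationSeries:
    """Phase of limb A's footfalls within limb B's cycles.

    For each cycle [t_i, t_{i+1}) of limb B containing exactly one footfall
    of limb A at t_A, the ratio is (t_A - t_i)/(t_{i+1} - t_i).  Cycles with
    zero or multiple opposing footfalls (arrhythmic stepping) are skipped
    and counted.  The attached speed is that cycle's stride velocity.
    """
    if len(events_a) == 0 or len(events_b) == 0:
        return AlternationSeries("temporal", "hind", np.array([]), np.array([]), condition)
    pair = _pair_name(events_a["limb"].iloc[0], events_b["limb"].iloc[0])
    key = ["subject_id", "condition", "trial_id"]
    ratios, speeds = [], []
    skipped = 0
    for trial, gb in events_b.groupby(key):
        ga = events_a.merge(
            pd.DataFrame([trial], columns=key), on=key
        ).sort_values("stance_onset")
        gb = gb.sort_values("stance_onset")
        if len(gb) < 2:
            continue
        tb = gb["stance_onset"].to_numpy(float)
        xb = gb["position"].to_numpy(float)
        ta = ga["stance_onset"].to_numpy(float)
        counts, _ = np.histogram(ta, bins=tb)
        pos_in_cycle = np.searchsorted(tb, ta, side="right") - 1
        for i in range(len(tb) - 1):
            if counts[i] != 1:
                skipped += 1
                continue
            t_a = ta[pos_in_cycle == i][0]
            cyc = tb[i + 1] - tb[i]
            ratios.append((t_a - tb[i]) / cyc)
            speeds.append((xb[i + 1] - xb[i]) / cyc)
    if skipped:
        logger.info("temporal_ratios: skipped %d cycles", skipped)
    return AlternationSeries(
        "temporal", pair, np.asarray(ratios), np.asarray(speeds), condition, skipped
    )


# ---------------------------------------------------------------------------
# circular summaries and tests
# ---------------------------------------------------------------------------


def circ_summary(series) -> CircularSummary:
    """Mean direction and resultant length of ratios on [0,1).

    theta_j = 2*pi*ratio_j; C = sum cos, S = sum sin;
    mean direction = atan2(S, C) wrapped to [0, 2*pi); r = |(C,S)|/n.
    An (anti)podal cancellation (r ~ 0) flags the mean as undefined.
    """
    ratios = series.ratios if isinstance(series, AlternationSeries) else np.mod(
        np.asarray(series, float), 1.0
    )
    n = len(ratios)
    if n == 0:
        raise ValueError("empty ratio series")
    theta = 2.0 * math.pi * ratios
    C = float(np.cos(theta).sum())
    S = float(np.sin(theta).sum())
    r = math.hypot(C, S) / n
    mean_dir = math.atan2(S, C) % (2.0 * math.pi)
    return CircularSummary(mean_dir, r, n, undefined=r < 1e-12)


def circ_kappa(rbar: float) -> float:
    """Maximum-likelihood-style estimate of the von Mises concentration
    parameter from a mean resultant length (Fisher's approximation)."""
    if rbar < 0.53:
        return 2.0 * rbar + rbar**3 + 5.0 * rbar**5 / 6.0
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1.0 - rbar)
    return 1.0 / (rbar**3 - 4.0 * rbar**2 + 3.0 * rbar)


def watson_williams(series1, series2) -> WatsonWilliamsResult:
    """Two-sample Watson–Williams test for equal mean directions.

    F = (N-2) * (R1 + R2 - R) / (N - R1 - R2), multiplied by the standard
    correction 1 + 3/(8*kappa) with kappa estimated from the pooled
    within-sample mean resultant length; p from F(1, N-2).  The test assumes
    von Mises samples with common, reasonably high concentration; warnings
    are attached for small samples (n < 5) and low concentration
    (pooled rbar < 0.45).
    """
    s1 = circ_summary(series1)
    s2 = circ_summary(series2)
    if s1.undefined or s2.undefined:
        raise ValueError("mean direction undefined in one of the samples")
    r1 = series1.ratios if isinstance(series1, AlternationSeries) else np.asarray(series1, float)
    r2 = series2.ratios if isinstance(series2, AlternationSeries) else np.asarray(series2, float)
    th1 = 2.0 * math.pi * np.mod(r1, 1.0)
    th2 = 2.0 * math.pi * np.mod(r2, 1.0)
    n1, n2 = len(th1), len(th2)
    N = n1 + n2
    warnings = []
    if min(n1, n2) < 5:
        warnings.append("sample size < 5; test unreliable")
    R1 = s1.r * n1
    R2 = s2.r * n2
    pooled = np.concatenate([th1, th2])
    Rp = math.hypot(float(np.cos(pooled).sum()), float(np.sin(pooled).sum()))
    rbar = (R1 + R2) / N
    if rbar < 0.45:
        warnings.append(f"pooled mean resultant length {rbar:.2f} < 0.45; "
                        "Watson-Williams assumptions doubtful")
    kappa = circ_kappa(rbar)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    denom = N - (R1 + R2)
    if denom <= 0:
        F = math.inf
        p = 0.0
    else:
        F = correction * (N - 2) * max(R1 + R2 - Rp, 0.0) / denom
        p = float(stats.f.sf(F, 1, N - 2)) if F > 0 else 1.0
    return WatsonWilliamsResult(float(F), 1, N - 2, p, correction, rbar, warnings)


def bin_by_speed(series: AlternationSeries, bins=DEFAULT_SPEED_BINS):
    """Partition a ratio series into speed bins.

    Bins are half-open [lo, hi) except the last, which is closed at its
    upper edge, so the boundary between adjacent bins goes to the upper bin.
    Empty bins are reported (returned with n = 0), not fatal.
    """
    out = []
    bins = list(bins)
    for i, (lo, hi) in enumerate(bins):
        last = i == len(bins) - 1
        mask = (series.speeds >= lo) & (
            (series.speeds <= hi) if last else (series.speeds < hi)
        )
        if not mask.any():
            logger.warning("speed bin [%g, %g%s empty", lo, hi, "]" if last else ")")
        out.append(
            (
                (lo, hi),
                replace(series, ratios=series.ratios[mask], speeds=series.speeds[mask]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# polar export
# ---------------------------------------------------------------------------


def polar_export(summaries: dict, raw: dict | None = None) -> pd.DataFrame:
    """Plot-ready table of resultant vectors and raw circular points.

    ``summaries`` maps a label to a :class:`CircularSummary` (rendered as a
    radial line at the mean direction with length r); ``raw`` maps a label
    to a ratio array (points on the unit circle).
    """
    rows = []
    for label, s in summaries.items():
        rows.append(
            {
                "label": label,
                "type": "summary",
                "angle_rad": s.mean_direction,
                "radius": s.r,
                "ratio": s.mean_ratio,
                "n": s.n,
            }
        )
    if raw:
        for label, ratios in raw.items():
            for rt in np.mod(np.asarray(ratios, float), 1.0):
                rows.append(
                    {
                        "label": label,
                        "type": "raw",
                        "angle_rad": 2.0 * math.pi * rt,
                        "radius": 1.0,
                        "ratio": rt,
                        "n": 1,
                    }
                )
    return pd.DataFrame(rows, columns=["label", "type", "angle_rad", "radius", "ratio", "n"])


def plot_polar(table: pd.DataFrame, ax=None):
    """Render a :func:`polar_export` table on a polar axis (cosmetic)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for label, grp in table.groupby("label"):
        raw = grp[grp["type"] == "raw"]
        if len(raw):
            ax.scatter(raw["angle_rad"], raw["radius"], s=8, alpha=0.5, label=label)
        for _, row in grp[grp["type"] == "summary"].iterrows():
            ax.plot([row["angle_rad"]] * 2, [0, row["radius"]], lw=2, label=f"{label} mean")
    ax.set_rmax(1.05)
    return ax
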