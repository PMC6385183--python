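"""Human-cohort utilities.

Asymmetries in a patient cohort fall on either body side at random, which
would wash out at the group level.  Subjects with a clinically obvious
asymmetry are therefore re-oriented before group analysis so the shorter
step is uniformly on the right (:func:`assign_sides`).  The module also
provides Welch's unequal-variance t test from published (n, mean, SD)
summaries, subgroup splits on supplied clinical labels, and Pearson
correlation of left/right asymmetry ratios between gait and clinical
measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import MIRROR_LIMB, GaitDataset

logger = logging.getLogger(__name__)

__all__ = [
    "GroupSummary",
    "WelchResult",
    "SubjectAssignment",
    "welch_t",
    "assign_sides",
    "split_cohort",
    "asymmetry_ratio",
    "asymmetry_corr",
    "CorrelationResult",
]


@dataclass(frozen=True)
class GroupSummary:
    """(n, mean, SD) of one variable in one group."""

    n: int
    mean: float
    sd: float
    label: str = ""

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass
class WelchResult:
    """Welch's two-sample t test with Satterthwaite degrees of freedom."""

    t: float
    df: float
    p: float
    infinite: bool = False  # both SDs zero with unequal means

    @property
    def df_rounded(self) -> int:
        return int(round(self.df))

    @property
    def abs_t(self) -> float:
        return abs(self.t)


def welch_t(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's t from group summaries.

    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); df via Welch–Satterthwaite;
    two-tailed p.  Degenerate zero-variance groups: equal means give t = 0,
    unequal means are flagged infinite.
    """
    if g1.sd == 0 and g2.sd == 0:
        if g1.mean == g2.mean:
            return WelchResult(0.0, float(g1.n + g2.n - 2), 1.0)
        return WelchResult(float("inf"), float(g1.n + g2.n - 2), 0.0, infinite=True)
    res = stats.ttest_ind_from_stats(
        g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n, equal_var=False
    )
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n  # Welch-Satterthwaite df
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    return WelchResult(float(res.statistic), float(df), float(res.pvalue))


@dataclass(frozen=True)
class SubjectAssignment:
    """Clinical orientation label for one subject.

    ``shorter_side`` is the side with visibly shorter steps ("left",
    "right", or "none" for symmetric subjects and controls).  Only subjects
    with the shorter step on the LEFT are remapped, making the shorter-step
    side uniformly "right" in group analyses.
    """

    subject_id: str
    asymmetric: bool
    shorter_side: str = "none"

    def __post_init__(self):
        if self.shorter_side not in ("left", "right", "none"):
            raise ValueError(f"bad shorter_side {self.shorter_side!r}")
        if self.asymmetric and self.shorter_side == "none":
            raise ValueError("asymmetric subject needs a shorter_side")

    @property
    def remap(self) -> bool:
        return self.shorter_side == "left"


def assign_sides(dataset: GaitDataset, assignments) -> tuple[GaitDataset, list]:
    """Swap left/right limb labels for subjects whose shorter side is left.

    ``assignments`` is an iterable of :class:`SubjectAssignment` covering
    every subject in the dataset (missing labels raise).  Applying the
    remap twice restores the original labels (involution).  Returns the
    remapped dataset and an audit list of swapped subject ids.
    """
    amap = {a.subject_id: a for a in assignments}
    df = dataset.records.copy()
    missing = set(df["subject_id"]) - set(amap)
    if missing:
        raise ValueError(f"no side assignment for subjects: {sorted(missing)}")
    swapped = sorted({s for s in df["subject_id"].unique() if amap[s].remap})
    mask = df["subject_id"].isin(swapped)
    df.loc[mask, "limb"] = df.loc[mask, "limb"].map(MIRROR_LIMB)
    for s in swapped:
        logger.info("subject %s: left/right metrics swapped", s)
    out = GaitDataset(
        df, dataset.species, dataset.length_unit, dataset.time_unit,
        dict(dataset.metadata, remapped_subjects=swapped),
    )
    return out, swapped


def split_cohort(df: pd.DataFrame, labels: dict, scheme: str = "PIGD_TD"):
    """Partition subject-level data by clinical subgroup labels.

    ``labels`` maps subject_id → subgroup.  For ``scheme="PIGD_TD"`` valid
    labels are PIGD/TD/indeterminate (indeterminate subjects are excluded
    and counted); for ``scheme="asym_symm"`` they are asym/symm.  Unknown
    labels raise; an empty subgroup raises.
    Returns ``(dict of subgroup → DataFrame, excluded subject ids)``.
    """
    schemes = {
        "PIGD_TD": (("PIGD", "TD"), ("indeterminate",)),
        "asym_symm": (("asym", "symm"), ()),
    }
    if scheme not in schemes:
        raise ValueError(f"unknown scheme {scheme!r}")
    keep, drop = schemes[scheme]
    subjects = df["subject_id"].unique()
    missing = [s for s in subjects if s not in labels]
    if missing:
        raise ValueError(f"no label for subjects: {missing}")
    bad = {labels[s] for s in subjects} - set(keep) - set(drop)
    if bad:
        raise ValueError(f"unknown labels {bad} for scheme {scheme}")
    excluded = [s for s in subjects if labels[s] in drop]
    out = {}
    for g in keep:
        members = [s for s in subjects if labels[s] == g]
        if not members:
            raise ValueError(f"subgroup {g!r} is empty")
        out[g] = df[df["subject_id"].isin(members)].reset_index(drop=True)
    if excluded:
        logger.info("excluded %d indeterminate subjects: %s", len(excluded), excluded)
    return out, excluded


def asymmetry_ratio(left, right, method: str = "smaller_larger"):
    """Per-subject left/right asymmetry ratio.

    ``smaller_larger``: min/max of the side means, bounded (0, 1] with 1 =
    perfect symmetry.  ``signed``: (L - R)/(L + R), signed and centred at 0.
    """
    left = np.asarray(left, float)
    right = np.asarray(right, float)
    if method == "smaller_larger":
        hi = np.maximum(np.abs(left), np.abs(right))
        lo = np.minimum(np.abs(left), np.abs(right))
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(hi > 0, lo / hi, np.nan)
    if method == "signed":
        s = left + right
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(s != 0, (left - right) / s, np.nan)
    raise ValueError(f"unknown asymmetry ratio method {method!r}")


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    undefined: bool = False
    ratios: pd.DataFrame | None = field(default=None, repr=False)


def asymmetry_corr(
    gait_left,
    gait_right,
    clinical_left,
    clinical_right,
    method: str = "smaller_larger",
) -> CorrelationResult:
    """Pearson correlation between gait and clinical asymmetry ratios.

    Each input is a per-subject vector of side means (gait metric) or side
    sub-scores (clinical measure).  Ratios are formed per
    :func:`asymmetry_ratio` and correlated across subjects (two-tailed p).
    Fewer than 3 complete subjects raise; zero variance in either ratio
    flags the correlation undefined.
    """
    g = asymmetry_ratio(gait_left, gait_right, method)
    c = asymmetry_ratio(clinical_left, clinical_right, method)
    ok = np.isfinite(g) & np.isfinite(c)
    g, c = g[ok], c[ok]
    n = len(g)
    if n < 3:
        raise ValueError(f"need >= 3 complete subjects, got {n}")
    ratios = pd.DataFrame({"gait_ratio": g, "clinical_ratio": c})
    if np.std(g) == 0 or np.std(c) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, method, True, ratios)
    r, p = stats.pearsonr(g, c)
    return CorrelationResult(float(r), float(p), n, method, False, ratios)
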