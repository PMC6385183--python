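"""Footfall events and stride-level gait metrics.

The fundamental observation is a *footfall event*: one paw or foot contact,
described by its position along the travel axis, the time the stance phase
begins (touch-down) and the time the swing phase begins (lift-off).  From an
ordered train of events for one limb we derive per-cycle stride metrics:

- stride length: distance between consecutive placements of the same limb;
- cycle duration: stance-onset to the next stance-onset of the same limb;
- stance time: stance onset to swing onset within a cycle;
- swing time: swing onset to the next stance onset (so that
  ``stance + swing == cycle`` exactly, by construction);
- stride velocity: stride length / cycle duration;
- step length: distance by which a limb lands in front of (positive) or
  behind (negative) the most recent placement of the opposing homologous
  limb.

Quadrupeds carry four limbs (LH/RH hind, LF/RF fore); bipeds two (L/R).
Positions are 1-D along the direction of travel, in cm (mouse) or m (human);
times in seconds.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class Species(str, enum.Enum):
    MOUSE = "mouse"
    HUMAN = "human"


#: limbs valid per species
SPECIES_LIMBS = {
    Species.MOUSE: ("LH", "RH", "LF", "RF"),
    Species.HUMAN: ("L", "R"),
}

#: homologous left/right pairs, keyed by the names used throughout
HOMOLOGOUS_PAIRS = {
    "hind": ("LH", "RH"),
    "fore": ("LF", "RF"),
    "legs": ("L", "R"),
}

#: mapping used when left/right labels are swapped (see cohort.assign_sides)
MIRROR_LIMB = {"LH": "RH", "RH": "LH", "LF": "RF", "RF": "LF", "L": "R", "R": "L"}

EVENT_COLUMNS = [
    "subject_id",
    "condition",
    "trial_id",
    "limb",
    "position",
    "stance_onset",
    "swing_onset",
]

STRIDE_COLUMNS = [
    "subject_id",
    "condition",
    "trial_id",
    "limb",
    "stride_velocity",
    "stride_length",
    "step_length",
    "swing_time",
    "stance_time",
    "cycle_duration",
    "t_start",
    "position",
]

#: numerical tolerance for exact-arithmetic invariants, in input units
INVARIANT_TOL = 1e-9


@dataclass(frozen=True)
class FootfallEvent:
    """One paw/foot contact."""

    limb: str
    position: float
    stance_onset: float
    swing_onset: float
    trial_id: str = "0"
    subject_id: str = "0"
    condition: str = "baseline"

    def __post_init__(self):
        if not self.swing_onset > self.stance_onset:
            raise ValueError(
                f"swing_onset ({self.swing_onset}) must exceed stance_onset "
                f"({self.stance_onset})"
            )


def events_to_frame(events) -> pd.DataFrame:
    """Assemble FootfallEvent records into the canonical events table."""
    return pd.DataFrame([vars(e) if not isinstance(e, dict) else e for e in events])[
        EVENT_COLUMNS
    ]


def validate_events(events: pd.DataFrame) -> None:
    """Check the footfall-event invariants, raising ``ValueError`` on the
    first violation (with the offending row index in the message).

    Invariants: swing follows stance; events of one limb within a trial are
    strictly ordered by stance onset; positions are non-decreasing along the
    travel direction per limb per trial.
    """
    missing = [c for c in EVENT_COLUMNS if c not in events.columns]
    if missing:
        raise ValueError(f"events table missing columns: {missing}")
    bad = events.index[~(events["swing_onset"] > events["stance_onset"])]
    if len(bad):
        raise ValueError(f"swing_onset <= stance_onset at row {bad[0]}")
    for key, grp in events.groupby(["subject_id", "condition", "trial_id", "limb"]):
        t = grp["stance_onset"].to_numpy()
        x = grp["position"].to_numpy()
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"stance onsets not strictly increasing for {key}")
        if np.any(np.diff(x) < -INVARIANT_TOL):
            raise ValueError(f"positions decrease along travel axis for {key}")


@dataclass
class GaitDataset:
    """Stride records plus species/unit metadata.

    ``records`` is a tidy table with :data:`STRIDE_COLUMNS`; ``step_length``
    is NaN where no opposing placement preceded the stride.
    """

    records: pd.DataFrame
    species: Species = Species.MOUSE
    length_unit: str = "cm"
    time_unit: str = "s"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.species = Species(self.species)
        if len(self.records):
            valid = set(SPECIES_LIMBS[self.species])
            bad = set(self.records["limb"]) - valid
            if bad:
                raise ValueError(f"limbs {bad} invalid for species {self.species.value}")

    def __len__(self):
        return len(self.records)

    def select(self, **conditions) -> "GaitDataset":
        """Subset by equality on columns, e.g. ``select(limb="LH")``."""
        df = self.records
        for col, val in conditions.items():
            df = df[df[col] == val]
        return replace(self, records=df.reset_index(drop=True))

    def side_pair(self, pair: str):
        """Return (left_df, right_df) stride tables for a homologous pair."""
        left, right = HOMOLOGOUS_PAIRS[pair]
        df = self.records
        return (
            df[df["limb"] == left].reset_index(drop=True),
            df[df["limb"] == right].reset_index(drop=True),
        )


def extract_strides(events: pd.DataFrame) -> pd.DataFrame:
    """Derive stride metrics from the ordered events of ONE limb in ONE trial.

    Each consecutive pair of events yields one stride anchored at the first
    event.  Fewer than two events yield an empty table.  Strides with a
    non-positive cycle duration are rejected with a logged warning.
    """
    if len(events) < 2:
        return pd.DataFrame(columns=STRIDE_COLUMNS)
    ev = events.sort_values("stance_onset")
    x = ev["position"].to_numpy(float)
    t_st = ev["stance_onset"].to_numpy(float)
    t_sw = ev["swing_onset"].to_numpy(float)

    stride_length = np.diff(x)
    cycle = np.diff(t_st)
    stance = t_sw[:-1] - t_st[:-1]
    swing = t_st[1:] - t_sw[:-1]

    ok = cycle > 0
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("rejected %d strides with non-positive cycle duration", n_bad)

    first = ev.iloc[0]
    out = pd.DataFrame(
        {
            "subject_id": first["subject_id"],
            "condition": first["condition"],
            "trial_id": first["trial_id"],
            "limb": first["limb"],
            "stride_velocity": stride_length[ok] / cycle[ok],
            "stride_length": stride_length[ok],
            "step_length": np.nan,
            "swing_time": swing[ok],
            "stance_time": stance[ok],
            "cycle_duration": cycle[ok],
            "t_start": t_st[:-1][ok],
            "position": x[:-1][ok],
        }
    )
    return out[STRIDE_COLUMNS]


def pair_step_lengths(
    strides_self: pd.DataFrame, events_opposite: pd.DataFrame
) -> pd.DataFrame:
    """Fill ``step_length`` for limb A's strides against limb B's placements.

    For the placement anchoring each stride of limb A at position ``x_A``
    and time ``t_A``, the step length is ``x_A - x_B`` where ``x_B`` is the
    most recent opposing placement with ``stance_onset <= t_A``.  Strides
    with no preceding opposing placement keep NaN.  Negative values mean the
    limb landed behind the opposing limb.
    """
    if len(strides_self) == 0:
        return strides_self.copy()
    own_limb = strides_self["limb"].iloc[0]
    opp_limb = events_opposite["limb"].iloc[0] if len(events_opposite) else None
    pair_ok = any(
        {own_limb, opp_limb} == set(pair) for pair in HOMOLOGOUS_PAIRS.values()
    )
    if opp_limb is not None and not pair_ok:
        raise ValueError(f"limbs {own_limb}/{opp_limb} are not a homologous pair")
    trials_self = set(strides_self["trial_id"])
    trials_opp = set(events_opposite["trial_id"]) if len(events_opposite) else set()
    if len(events_opposite) and not trials_self <= trials_opp:
        raise ValueError(
            f"trial ids {trials_self - trials_opp} missing from opposing events"
        )

    out = strides_self.copy()
    key = ["subject_id", "condition", "trial_id"]
    for keyvals, grp in strides_self.groupby(key):
        opp = events_opposite.merge(
            pd.DataFrame([keyvals], columns=key), on=key
        ).sort_values("stance_onset")
        if len(opp) == 0:
            continue
        t_opp = opp["stance_onset"].to_numpy(float)
        x_opp = opp["position"].to_numpy(float)
        idx = np.searchsorted(t_opp, grp["t_start"].to_numpy(float), side="right") - 1
        step = np.where(idx >= 0, grp["position"].to_numpy(float) - x_opp[idx.clip(0)], np.nan)
        out.loc[grp.index, "step_length"] = step
    return out


def build_dataset(
    events: pd.DataFrame,
    species: Species | str = Species.MOUSE,
    length_unit: str | None = None,
    validate: bool = True,
) -> GaitDataset:
    """Events table → :class:`GaitDataset` with step lengths for every limb.

    Strides are extracted per (subject, condition, trial, limb); step lengths
    are paired within each homologous pair in both directions.  Trials are
    independent: no stride spans a trial boundary.
    """
    species = Species(species)
    if validate:
        validate_events(events)
    parts = []
    for _, grp in events.groupby(["subject_id", "condition", "trial_id", "limb"]):
        parts.append(extract_strides(grp))
    strides = (
        pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(columns=STRIDE_COLUMNS)
    )

    paired = []
    for key, grp in strides.groupby(["subject_id", "condition", "trial_id"]):
        ev_trial = events[
            (events["subject_id"] == key[0])
            & (events["condition"] == key[1])
            & (events["trial_id"] == key[2])
        ]
        for pair in HOMOLOGOUS_PAIRS.values():
            for own, opp in (pair, pair[::-1]):
                own_strides = grp[grp["limb"] == own]
                opp_events = ev_trial[ev_trial["limb"] == opp]
                if len(own_strides) and len(opp_events):
                    paired.append(pair_step_lengths(own_strides, opp_events))
                elif len(own_strides):
                    paired.append(own_strides)
    out = (
        pd.concat(paired, ignore_index=True) if paired else strides
    )
    if length_unit is None:
        length_unit = "cm" if species is Species.MOUSE else "m"
    return GaitDataset(out, species=species, length_unit=length_unit)


def filter_speed_range(dataset: GaitDataset, lo: float, hi: float) -> GaitDataset:
    """Keep strides with ``lo <= stride_velocity <= hi``.

    The retained/total counts are logged; an empty result is permitted but
    flagged in the returned dataset's metadata.
    """
    if not lo < hi:
        raise ValueError(f"speed window requires lo < hi, got [{lo}, {hi}]")
    v = dataset.records["stride_velocity"]
    kept = dataset.records[(v >= lo) & (v <= hi)].reset_index(drop=True)
    logger.info("speed window [%g, %g]: kept %d of %d strides", lo, hi, len(kept), len(v))
    out = replace(dataset, records=kept, metadata=dict(dataset.metadata))
    out.metadata["speed_window"] = (lo, hi)
    if len(kept) == 0:
        out.metadata["empty_after_filter"] = True
        logger.warning("speed window [%g, %g] removed every stride", lo, hi)
    return out
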