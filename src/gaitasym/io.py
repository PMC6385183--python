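"""Readers and writers for the plain-text interchange formats.

Footfall CSV (input): subject_id, condition, trial_id, limb, position,
stance_onset, swing_onset — header required, UTF-8, decimal point.  Times
may be given in frames and converted at a stated frame rate (120 fps is the
usual high-speed-video rate for mouse runways).

Stride CSV (output/input): subject_id, condition, trial_id, limb,
stride_velocity, stride_length, step_length, swing_time, stance_time
(+ cycle_duration, t_start, position when written by this package).
"""

from __future__ import annotations

import pandas as pd
import yaml

from .core import EVENT_COLUMNS, STRIDE_COLUMNS, GaitDataset, Species, validate_events
from .simulate import Asymmetry, CurveSpec, GaitProfile, NoiseSpec
from .speedfit import Family


class ParseError(ValueError):
    """Input-file validation failure with row/column context."""


_NUMERIC_EVENT_COLS = ["position", "stance_onset", "swing_onset"]


def read_footfalls(path, frame_rate: float | None = None) -> pd.DataFrame:
    """Read and validate a footfall-event CSV.

    ``frame_rate`` (Hz) converts stance/swing onsets from frames to seconds.
    Raises :class:`ParseError` naming the offending row/column for missing
    columns, non-numeric fields, swing-before-stance rows, and duplicate
    (subject, condition, trial, limb, stance_onset) events.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str, "condition": str})
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in _NUMERIC_EVENT_COLS:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {bad[0]}")
        if coerced.isna().any():
            raise ParseError(
                f"{path}: empty value in column {col!r} at row {coerced.index[coerced.isna()][0]}"
            )
        df[col] = coerced
    if frame_rate is not None:
        df["stance_onset"] = df["stance_onset"] / frame_rate
        df["swing_onset"] = df["swing_onset"] / frame_rate
    bad = df.index[df["swing_onset"] <= df["stance_onset"]]
    if len(bad):
        raise ParseError(f"{path}: swing_onset <= stance_onset at row {bad[0]}")
    key = ["subject_id", "condition", "trial_id", "limb", "stance_onset"]
    dup = df.index[df.duplicated(key)]
    if len(dup):
        raise ParseError(f"{path}: duplicate event at row {dup[0]}")
    df = df.sort_values(["subject_id", "condition", "trial_id", "limb", "stance_onset"])
    df = df.reset_index(drop=True)
    validate_events(df)
    return df[EVENT_COLUMNS]


def write_events(events: pd.DataFrame, path) -> None:
    events[EVENT_COLUMNS].to_csv(path, index=False)


def write_strides(dataset: GaitDataset, path) -> None:
    dataset.records[STRIDE_COLUMNS].to_csv(path, index=False)


def read_strides(path, species: Species | str = Species.MOUSE) -> GaitDataset:
    """Read a stride-metric CSV into a :class:`GaitDataset`."""
    df = pd.read_csv(path, dtype={"subject_id": str, "trial_id": str, "condition": str})
    required = [c for c in STRIDE_COLUMNS if c not in ("cycle_duration", "t_start", "position")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("cycle_duration", "t_start", "position"):
        if col not in df.columns:
            df[col] = float("nan")
    return GaitDataset(df[STRIDE_COLUMNS], species=Species(species))


# ---------------------------------------------------------------------------
# simulator profile config
# ---------------------------------------------------------------------------


def profile_from_dict(cfg: dict) -> GaitProfile:
    """Build a :class:`~gaitasym.simulate.GaitProfile` from a config dict."""
    species = Species(cfg.get("species", "mouse"))
    base = GaitProfile.mouse() if species is Species.MOUSE else GaitProfile.human()
    kw: dict = {}
    for name in ("stride_length", "swing_time"):
        if name in cfg:
            spec = cfg[name]
            kw[name] = CurveSpec(Family(spec["family"]), tuple(spec["params"]))
    for name in ("speed_range", "phase_offset", "step_fraction", "fore_offset",
                 "speed_sampler", "seed"):
        if name in cfg:
            kw[name] = tuple(cfg[name]) if name == "speed_range" else cfg[name]
    if "noise" in cfg:
        kw["noise"] = NoiseSpec(**cfg["noise"])
    if "asymmetry" in cfg:
        a = dict(cfg["asymmetry"])
        if a.get("speed_gate") is not None:
            a["speed_gate"] = tuple(a["speed_gate"])
        kw["asymmetry"] = Asymmetry(**a)
    import dataclasses

    return dataclasses.replace(base, **kw)


def load_profile(path) -> GaitProfile:
    """Load a simulator profile from a YAML file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return profile_from_dict(cfg or {})
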