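"""End-to-end analysis pipeline and its configuration.

``run_pipeline`` mirrors the full workflow: speed-window filtering, per
metric model choice, left-vs-right curve-sharing F tests within each
condition, per-limb between-condition comparisons, alternation ratios with
circular summaries and Watson–Williams tests (whole window and per speed
bin).  Every verdict in the report is reproducible by calling the module
operation it names with the logged arguments.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alternation as alt
from .core import HOMOLOGOUS_PAIRS, GaitDataset, Species, build_dataset, filter_speed_range
from .speedfit import CurveShareTest, Family, ModelSpec

logger = logging.getLogger(__name__)

METRICS = ("step_length", "stride_length", "swing_time", "stance_time")

#: default model per metric; "stance_log" = log transform + linear family
DEFAULT_MODELS = {
    "step_length": "linear",
    "stride_length": "linear",
    "swing_time": "linear",
    "stance_time": "stance_log",
}


@dataclass
class AnalysisConfig:
    """Pipeline configuration; defaults mirror the validated workflow
    (alpha 0.001 for curve comparisons, 0.05 for circular tests)."""

    species: str = "mouse"
    speed_window: tuple = (3.0, 16.0)
    alpha_compare: float = 0.001
    alpha_circular: float = 0.05
    models: dict = field(default_factory=lambda: dict(DEFAULT_MODELS))
    bins: tuple = alt.DEFAULT_SPEED_BINS
    outlier_elimination: str = "off"
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        lo, hi = self.speed_window
        if not lo < hi:
            raise ValueError("speed window requires lo < hi")
        for a in (self.alpha_compare, self.alpha_circular):
            if not 0 < a < 1:
                raise ValueError("alpha must lie in (0, 1)")
        if self.outlier_elimination != "off":
            raise ValueError("automatic outlier elimination is not a validated path")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        if "speed_window" in cfg:
            cfg["speed_window"] = tuple(cfg["speed_window"])
        if "bins" in cfg:
            cfg["bins"] = tuple(tuple(b) for b in cfg["bins"])
        return cls(**cfg)


def _model_for(config: AnalysisConfig, metric: str):
    """Return (family-or-'auto', stance_log flag) for a metric."""
    m = config.models.get(metric, "linear")
    if m == "stance_log":
        return Family.LINEAR, True
    if m == "auto":
        return "auto", False
    return Family(m), False


def _comparison_row(res, **context):
    return dict(
        context,
        family=Family(res.shared_fit.model.family).value,
        F=res.F,
        df_num=res.df_num,
        df_den=res.df_den,
        p=res.p,
        verdict=res.verdict,
        n_a=res.separate_fits[0].n,
        n_b=res.separate_fits[1].n,
    )


def run_pipeline(events: pd.DataFrame, config: AnalysisConfig) -> dict:
    """Execute the full asymmetry analysis on a footfall-event table.

    Returns a JSON-serialisable report; if ``config.out_dir`` is set, the
    report (JSON) and tidy comparison tables (CSV) are written there.
    Stage failures are collected into an ``errors`` section rather than
    aborting the whole run.
    """
    species = Species(config.species)
    report: dict = {
        "config": dataclasses.asdict(config),
        "comparisons": [],
        "alternation": [],
        "errors": [],
    }
    dataset = build_dataset(events, species=species)
    lo, hi = config.speed_window
    dataset = filter_speed_range(dataset, lo, hi)
    report["n_strides"] = int(len(dataset))
    conditions = list(dict.fromkeys(dataset.records["condition"]))
    pairs = ["hind", "fore"] if species is Species.MOUSE else ["legs"]

    # left vs right within each condition
    for cond in conditions:
        sub = dataset.select(condition=cond)
        for pair in pairs:
            for metric in METRICS:
                family, stance_log = _model_for(config, metric)
                try:
                    res = CurveShareTest.from_dataset(
                        sub, metric, pair=pair, family=family,
                        alpha=config.alpha_compare, stance_log=stance_log,
                    ).fit(seed=config.seed)
                    report["comparisons"].append(_comparison_row(
                        res, comparison="left_vs_right", condition=cond,
                        pair=pair, metric=metric,
                    ))
                except Exception as exc:
                    report["errors"].append(
                        f"left_vs_right {cond}/{pair}/{metric}: {exc}")

    # each limb between the first two conditions
    if len(conditions) >= 2:
        c1, c2 = conditions[:2]
        for pair in pairs:
            for limb in HOMOLOGOUS_PAIRS[pair]:
                sub = dataset.select(limb=limb)
                for metric in METRICS:
                    family, stance_log = _model_for(config, metric)
                    try:
                        res = CurveShareTest.from_dataset(
                            sub, metric, by="condition", groups=(c1, c2),
                            family=family, alpha=config.alpha_compare,
                            stance_log=stance_log,
                        ).fit(seed=config.seed)
                        report["comparisons"].append(_comparison_row(
                            res, comparison="between_conditions", limb=limb,
                            pair=pair, metric=metric,
                        ))
                    except Exception as exc:
                        report["errors"].append(
                            f"between_conditions {limb}/{metric}: {exc}")

    # alternation ratios + circular tests
    ev_window = events  # ratios are speed-gated via the attached speed
    series: dict = {}
    for cond in conditions:
        sub = dataset.select(condition=cond)
        ev_c = ev_window[ev_window["condition"] == cond]
        for pair in pairs:
            left, right = HOMOLOGOUS_PAIRS[pair]
            try:
                ldf, rdf = sub.side_pair(pair)
                sp = alt.spatial_ratios(rdf, ldf, condition=cond)
                tp = alt.temporal_ratios(
                    ev_c[ev_c["limb"] == right], ev_c[ev_c["limb"] == left],
                    condition=cond,
                )
                for s in (sp, tp):
                    mask = (s.speeds >= lo) & (s.speeds <= hi)
                    s.ratios, s.speeds = s.ratios[mask], s.speeds[mask]
                series[(cond, pair, "spatial")] = sp
                series[(cond, pair, "temporal")] = tp
                for s in (sp, tp):
                    if len(s):
                        summ = alt.circ_summary(s)
                        report["alternation"].append({
                            "condition": cond, "pair": pair, "kind": s.kind,
                            "n": summ.n, "mean_ratio": summ.mean_ratio,
                            "r": summ.r,
                        })
            except Exception as exc:
                report["errors"].append(f"alternation {cond}/{pair}: {exc}")

    if len(conditions) >= 2:
        c1, c2 = conditions[:2]
        report["watson_williams"] = []
        for pair in pairs:
            for kind in ("spatial", "temporal"):
                s1 = series.get((c1, pair, kind))
                s2 = series.get((c2, pair, kind))
                if s1 is None or s2 is None or not len(s1) or not len(s2):
                    continue
                windows = [("full", s1, s2)]
                if config.bins:
                    b1 = dict(alt.bin_by_speed(s1, config.bins))
                    b2 = dict(alt.bin_by_speed(s2, config.bins))
                    for b in b1:
                        windows.append((f"{b[0]:g}-{b[1]:g}", b1[b], b2[b]))
                for label, w1, w2 in windows:
                    if len(w1) < 2 or len(w2) < 2:
                        continue
                    try:
                        ww = alt.watson_williams(w1, w2)
                        report["watson_williams"].append({
                            "pair": pair, "kind": kind, "window": label,
                            "F": ww.F, "df_den": ww.df_den, "p": ww.p,
                            "significant": ww.significant(config.alpha_circular),
                            "n1": len(w1), "n2": len(w2),
                            "correction": ww.correction,
                            "warnings": ww.warnings,
                        })
                    except Exception as exc:
                        report["errors"].append(
                            f"watson_williams {pair}/{kind}/{label}: {exc}")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        if report["comparisons"]:
            pd.DataFrame(report["comparisons"]).to_csv(out / "comparisons.csv", index=False)
        if report["alternation"]:
            pd.DataFrame(report["alternation"]).to_csv(out / "alternation.csv", index=False)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
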