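"""Synthetic footfall-event generator.

Emulates stride-level gait data for a quadruped (mouse) or biped (human)
walker whose metrics follow configurable speed-dependent curve families,
with stride-to-stride noise and injectable left-right asymmetries:

- a *spatial* asymmetry shifts where the opposing limb is placed within the
  reference limb's stride (shortening one side's step length), emulating a
  unilateral dopaminergic lesion;
- a *temporal* asymmetry shifts the opposing limb's phase within the cycle;
- either can be gated to a speed window, emulating divergence that appears
  only at the faster end of the walking range;
- a *bilateral* condition is emulated by scaling the stride-length and
  swing-time curves identically on both sides (no asymmetry).

Construction guarantees the stride-metric invariants: stance time is derived
as cycle minus swing, so stance + swing = cycle exactly and the stance curve
emerges hyperbolically with speed.  All randomness flows from one seed via
per-subject/condition/trial stream splitting; identical seed and profile
give bit-identical event tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import EVENT_COLUMNS, Species
from .speedfit import Family, eval_model

__all__ = [
    "CurveSpec",
    "NoiseSpec",
    "Asymmetry",
    "GaitProfile",
    "generate_trial",
    "make_cohort",
    "scenario",
    "bilateral_modifier",
]


@dataclass(frozen=True)
class CurveSpec:
    """A metric's nominal speed dependence: curve family + parameters."""

    family: Family
    params: tuple

    def __call__(self, v):
        return eval_model(self.family, self.params, v)

    def scaled(self, factor: float) -> "CurveSpec":
        """Scale the level parameters (not rate constants) by ``factor``."""
        fam = Family(self.family)
        p = list(self.params)
        if fam is Family.LINEAR:
            p = [q * factor for q in p]
        elif fam is Family.ONE_PHASE:
            p[0] *= factor
            p[1] *= factor
        else:
            p[0] *= factor
            p[1] *= factor
            p[3] *= factor
        return CurveSpec(fam, tuple(p))


@dataclass(frozen=True)
class NoiseSpec:
    """Stride-to-stride SDs (input units; fractions for placement/phase)."""

    stride_length_sd: float = 0.0
    swing_sd: float = 0.0
    spatial_sd: float = 0.0
    temporal_sd: float = 0.0

    @classmethod
    def none(cls) -> "NoiseSpec":
        return cls()


@dataclass(frozen=True)
class Asymmetry:
    """Injectable left-right asymmetry.

    ``step_delta`` changes the opposing (right) limb's step length —
    multiplicative mode scales the placement fraction by (1 + delta) so a
    negative delta shortens the right step and lengthens the left; additive
    mode adds ``step_delta`` length units.  ``phase_delta`` shifts the
    opposing limb's temporal phase.  ``speed_gate = (lo, hi)`` restricts the
    asymmetry to strides in that speed window.
    """

    step_delta: float = 0.0
    phase_delta: float = 0.0
    mode: str = "multiplicative"
    speed_gate: tuple | None = None

    def applies(self, v: np.ndarray) -> np.ndarray:
        if self.speed_gate is None:
            return np.ones_like(v, dtype=bool)
        lo, hi = self.speed_gate
        return (v > lo) & (v <= hi)


@dataclass(frozen=True)
class GaitProfile:
    """Full parameterisation of a synthetic walker."""

    species: Species = Species.MOUSE
    stride_length: CurveSpec = CurveSpec(Family.ONE_PHASE, (3.0, 8.0, 0.15))
    swing_time: CurveSpec = CurveSpec(Family.ONE_PHASE, (0.20, 0.08, 0.2))
    speed_range: tuple = (3.0, 16.0)
    #: "trial_target": each trial walks near a target speed drawn uniformly
    #: over the range (how runway/gait-mat passes actually sample speed);
    #: "uniform": iid per-stride draws (no within-trial speed continuity).
    speed_sampler: str = "trial_target"
    speed_jitter: float = 0.04  # within-trial stride speed SD, fraction of range
    phase_offset: float = 0.5
    step_fraction: float = 0.5
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    asymmetry: Asymmetry = field(default_factory=Asymmetry)
    fore_offset: float = 3.5  # cm ahead of the hind pair (quadruped only)
    seed: int = 0

    @classmethod
    def mouse(cls, **overrides) -> "GaitProfile":
        """Walking/trotting mouse, 3-16 cm/s, realistic stride-level noise."""
        base = dict(
            species=Species.MOUSE,
            stride_length=CurveSpec(Family.ONE_PHASE, (3.0, 8.0, 0.15)),
            swing_time=CurveSpec(Family.ONE_PHASE, (0.20, 0.08, 0.2)),
            speed_range=(3.0, 16.0),
            noise=NoiseSpec(0.45, 0.012, 0.03, 0.03),
            fore_offset=3.5,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def human(cls, **overrides) -> "GaitProfile":
        """Overground human walking, 0.3-1.5 m/s."""
        base = dict(
            species=Species.HUMAN,
            stride_length=CurveSpec(Family.LINEAR, (0.40, 0.70)),
            swing_time=CurveSpec(Family.ONE_PHASE, (0.30, 0.42, 2.0)),
            speed_range=(0.3, 1.5),
            noise=NoiseSpec(0.05, 0.015, 0.02, 0.02),
        )
        base.update(overrides)
        return cls(**base)

    def noiseless(self) -> "GaitProfile":
        return dataclasses.replace(self, noise=NoiseSpec.none())

    def with_asymmetry(self, **kw) -> "GaitProfile":
        return dataclasses.replace(self, asymmetry=Asymmetry(**kw))

    def validate(self) -> None:
        lo, hi = self.speed_range
        if not 0 < lo < hi:
            raise ValueError("speed range must satisfy 0 < lo < hi")
        v = np.linspace(lo, hi, 64)
        L = self.stride_length(v)
        sw = self.swing_time(v)
        if np.any(L <= 0):
            raise ValueError("stride-length curve non-positive in speed range")
        if np.any(sw <= 0):
            raise ValueError("swing-time curve non-positive in speed range")
        if np.any(sw >= L / v):
            raise ValueError("swing time exceeds cycle duration in speed range")


def _draw_speeds(profile: GaitProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    lo, hi = profile.speed_range
    if profile.speed_sampler == "trial_target":
        target = rng.uniform(lo, hi)
        sd = profile.speed_jitter * (hi - lo)
        return np.clip(rng.normal(target, sd, n), lo, hi)
    if profile.speed_sampler == "uniform":
        return rng.uniform(lo, hi, n)
    raise ValueError(f"unknown speed sampler {profile.speed_sampler!r}")


def _generate_pair(
    profile: GaitProfile,
    n_strides: int,
    rng: np.random.Generator,
    limbs: tuple,
    x0: float,
    t0: float,
    subject_id: str,
    condition: str,
    trial_id: str,
) -> pd.DataFrame:
    ref_limb, opp_limb = limbs
    noise = profile.noise
    asym = profile.asymmetry
    n = n_strides

    v = _draw_speeds(profile, n, rng)
    L = profile.stride_length(v) + rng.normal(0.0, noise.stride_length_sd or 0.0, n) * (
        noise.stride_length_sd > 0
    )
    if np.any(L <= 0):
        raise ValueError("noise produced a non-positive stride length")
    T = L / v
    swing = profile.swing_time(v) + rng.normal(0.0, noise.swing_sd or 1e-12, n) * (
        noise.swing_sd > 0
    )
    swing = np.clip(swing, 1e-6, T - 1e-6)
    stance = T - swing

    # reference limb: cumulative placements
    t_ref = t0 + np.concatenate([[0.0], np.cumsum(T)])
    x_ref = x0 + np.concatenate([[0.0], np.cumsum(L)])
    stance_ref = np.append(stance, stance[-1])
    swing_on_ref = t_ref + stance_ref

    # opposing limb: fractional placement within each reference stride
    f = profile.step_fraction + (
        rng.normal(0.0, noise.spatial_sd, n) if noise.spatial_sd > 0 else 0.0
    )
    phi = profile.phase_offset + (
        rng.normal(0.0, noise.temporal_sd, n) if noise.temporal_sd > 0 else 0.0
    )
    gate = asym.applies(v)
    if asym.step_delta:
        if asym.mode == "multiplicative":
            f = np.where(gate, f * (1.0 + asym.step_delta), f)
        elif asym.mode == "additive":
            f = np.where(gate, f + asym.step_delta / L, f)
        else:
            raise ValueError(f"unknown asymmetry mode {asym.mode!r}")
    if asym.phase_delta:
        phi = np.where(gate, phi + asym.phase_delta, phi)

    t_opp = t_ref[:-1] + phi * T
    x_opp = x_ref[:-1] + f * L
    if np.any(np.diff(t_opp) <= 0):
        raise ValueError("opposing-limb times not strictly increasing; "
                         "reduce temporal noise or phase_delta")
    if np.any(np.diff(x_opp) < 0):
        raise ValueError("opposing-limb positions decreasing; "
                         "reduce spatial noise or step_delta")
    cycle_opp = np.append(np.diff(t_opp), T[-1])
    swing_opp = np.clip(
        profile.swing_time(v)
        + (rng.normal(0.0, noise.swing_sd, n) if noise.swing_sd > 0 else 0.0),
        1e-6,
        cycle_opp - 1e-6,
    )
    swing_on_opp = t_opp + (cycle_opp - swing_opp)

    def frame(limb, x, t_st, t_sw):
        return pd.DataFrame(
            {
                "subject_id": subject_id,
                "condition": condition,
                "trial_id": trial_id,
                "limb": limb,
                "position": x,
                "stance_onset": t_st,
                "swing_onset": t_sw,
            }
        )

    return pd.concat(
        [frame(ref_limb, x_ref, t_ref, swing_on_ref),
         frame(opp_limb, x_opp, t_opp, swing_on_opp)],
        ignore_index=True,
    )[EVENT_COLUMNS]


def generate_trial(
    profile: GaitProfile,
    n_strides: int = 12,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "s1",
    condition: str = "baseline",
    trial_id: str = "t1",
) -> pd.DataFrame:
    """Generate one trial's footfall events for all limbs.

    Quadrupeds get hind (LH/RH) and fore (LF/RF) pairs — the fore pair is
    generated with the same curves, offset ``fore_offset`` ahead; bipeds get
    L/R.  Deterministic under a fixed seed.
    """
    profile.validate()
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(profile.seed if seed is None else seed)
    if profile.species is Species.MOUSE:
        hind = _generate_pair(profile, n_strides, rng, ("LH", "RH"), 0.0, 0.0,
                              subject_id, condition, trial_id)
        fore = _generate_pair(profile, n_strides, rng, ("LF", "RF"),
                              profile.fore_offset, 0.0,
                              subject_id, condition, trial_id)
        return pd.concat([hind, fore], ignore_index=True)
    return _generate_pair(profile, n_strides, rng, ("L", "R"), 0.0, 0.0,
                          subject_id, condition, trial_id)


def bilateral_modifier(stride_scale: float = 0.8, swing_scale: float = 0.85):
    """Condition modifier scaling both sides' stride length and swing time
    equally — a symmetric (bilateral-lesion-like) gait change."""

    def modify(profile: GaitProfile) -> GaitProfile:
        return dataclasses.replace(
            profile,
            stride_length=profile.stride_length.scaled(stride_scale),
            swing_time=profile.swing_time.scaled(swing_scale),
        )

    return modify


def _apply_condition(profile: GaitProfile, modifier) -> GaitProfile:
    if modifier is None:
        return profile
    if isinstance(modifier, Asymmetry):
        return dataclasses.replace(profile, asymmetry=modifier)
    return modifier(profile)


def make_cohort(
    profile: GaitProfile,
    n_subjects: int = 12,
    conditions: dict | None = None,
    n_trials: int = 4,
    strides_per_trial: int = 12,
    subject_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate a cohort's footfall events across conditions.

    ``conditions`` maps condition name to a modifier (None, an
    :class:`Asymmetry`, or a callable profile → profile).  Each subject
    receives a lognormal random effect (SD ``subject_sd`` on the log scale)
    on its stride-length and swing-time curve levels, shared across
    conditions so each subject is its own control.
    """
    if conditions is None:
        conditions = {"baseline": None}
    ss = np.random.SeedSequence(seed)
    subj_seeds = ss.spawn(n_subjects)
    frames = []
    for i in range(n_subjects):
        subj_rng = np.random.default_rng(subj_seeds[i])
        stride_factor = float(np.exp(subj_rng.normal(0.0, subject_sd)))
        swing_factor = float(np.exp(subj_rng.normal(0.0, subject_sd)))
        subj_profile = dataclasses.replace(
            profile,
            stride_length=profile.stride_length.scaled(stride_factor),
            swing_time=profile.swing_time.scaled(swing_factor),
        )
        for cond, modifier in conditions.items():
            cond_profile = _apply_condition(subj_profile, modifier)
            for j in range(n_trials):
                frames.append(
                    generate_trial(
                        cond_profile,
                        strides_per_trial,
                        seed=np.random.default_rng(subj_rng.integers(2**31)),
                        subject_id=f"s{i+1:02d}",
                        condition=cond,
                        trial_id=f"t{j+1}",
                    )
                )
    return pd.concat(frames, ignore_index=True)


def scenario(name: str, species: str | Species = Species.MOUSE):
    """Preset study conditions: (baseline profile, condition modifiers).

    - ``"control"``: two identical assessments, no change;
    - ``"unilateral"``: one-sided multiplicative step shortening of 10%
      gated to the 10-16 cm/s window (spatial asymmetry at higher walking
      speeds, timing untouched);
    - ``"bilateral"``: stride length x0.8 and swing time x0.85 on both
      sides (global slowing, no asymmetry).
    """
    species = Species(species)
    profile = GaitProfile.mouse() if species is Species.MOUSE else GaitProfile.human()
    if name == "control":
        return profile, {"test1": None, "test2": None}
    if name == "unilateral":
        gate = (10.0, 16.0) if species is Species.MOUSE else (0.9, 1.5)
        return profile, {
            "baseline": None,
            "lesioned": Asymmetry(step_delta=-0.10, speed_gate=gate),
        }
    if name == "bilateral":
        return profile, {"baseline": None, "lesioned": bilateral_modifier()}
    raise ValueError(f"unknown scenario {name!r}")
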