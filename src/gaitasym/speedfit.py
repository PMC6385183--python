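"""Speed-dependent regression and curve-sharing F tests.

Gait metrics are strongly speed dependent, so left and right limbs are
compared as *curves over stride velocity*, never as raw means.  Each metric
is fitted with the simplest adequate member of a nested model ladder

- linear:            y = b0 + b1 * v                           (2 params)
- one-phase assoc.:  y = Y0 + (Plateau - Y0) * (1 - exp(-K v)) (3 params)
- two-phase assoc.:  y = Y0 + SpanFast * (1 - exp(-KFast v))
                          + SpanSlow * (1 - exp(-KSlow v))     (5 params)

(the exponential-association forms follow the GraphPad convention), and two
datasets are declared asymmetric when an extra-sum-of-squares F test rejects
a single shared parameter set in favour of independent fits — for linear
models this captures both slope and intercept at once.  Stance time behaves
hyperbolically with speed and is analysed after a log transform
(Y = 1 - log10(stance), X = log10(speed) + 1) paired with the linear family.

The module exposes a statsmodels-flavoured object layer
(:class:`SpeedCurveModel` → :class:`SpeedCurveResults`,
:class:`CurveShareTest` → :class:`CurveComparisonResult`) and plain
functions (:func:`fit_model`, :func:`compare_curves`, ...) over the same
machinery.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .core import HOMOLOGOUS_PAIRS, GaitDataset, Species

logger = logging.getLogger(__name__)

__all__ = [
    "Family",
    "ModelSpec",
    "FitResult",
    "FTestResult",
    "CurveComparisonResult",
    "RunsResult",
    "SpeedCurveModel",
    "SpeedCurveResults",
    "CurveShareTest",
    "eval_model",
    "fit_model",
    "extra_ss_ftest",
    "select_model",
    "sweep_speed_ranges",
    "compare_curves",
    "stance_transform",
    "inverse_stance_transform",
    "runs_test",
    "averaged_analysis",
    "DEFAULT_LADDER",
]


class Family(str, enum.Enum):
    LINEAR = "linear"
    ONE_PHASE = "one_phase_assoc"
    TWO_PHASE = "two_phase_assoc"


N_PARAMS = {Family.LINEAR: 2, Family.ONE_PHASE: 3, Family.TWO_PHASE: 5}

PARAM_NAMES = {
    Family.LINEAR: ("intercept", "slope"),
    Family.ONE_PHASE: ("Y0", "Plateau", "K"),
    Family.TWO_PHASE: ("Y0", "SpanFast", "KFast", "SpanSlow", "KSlow"),
}


@dataclass(frozen=True)
class ModelSpec:
    """A curve family plus optional metric transform."""

    family: Family = Family.LINEAR
    transform: str | None = None  # None | "stance_log"

    @property
    def n_params(self) -> int:
        return N_PARAMS[Family(self.family)]

    @property
    def param_names(self):
        return PARAM_NAMES[Family(self.family)]


DEFAULT_LADDER = (
    ModelSpec(Family.LINEAR),
    ModelSpec(Family.ONE_PHASE),
    ModelSpec(Family.TWO_PHASE),
)


def eval_model(model: ModelSpec | Family | str, params, x):
    """Evaluate a curve family at speeds ``x``."""
    fam = model.family if isinstance(model, ModelSpec) else model
    fam = Family(fam)
    x = np.asarray(x, float)
    p = np.asarray(params, float)
    if len(p) != N_PARAMS[fam]:
        raise ValueError(f"{fam.value} needs {N_PARAMS[fam]} params, got {len(p)}")
    if fam is Family.LINEAR:
        return p[0] + p[1] * x
    if fam is Family.ONE_PHASE:
        y0, plateau, k = p
        return y0 + (plateau - y0) * (1.0 - np.exp(-k * x))
    y0, span_f, k_f, span_s, k_s = p
    return (
        y0
        + span_f * (1.0 - np.exp(-k_f * x))
        + span_s * (1.0 - np.exp(-k_s * x))
    )


# ---------------------------------------------------------------------------
# runs test (Wald–Wolfowitz, one sample about a reference value)
# ---------------------------------------------------------------------------


@dataclass
class RunsResult:
    """Runs test for non-random deviation about a reference value.

    ``z`` and the normal two-sided ``p_normal`` use
    mu_R = 2 n+ n- / n + 1 and
    sigma_R^2 = 2 n+ n- (2 n+ n- - n) / (n^2 (n-1)).
    ``p_exact`` (closed-form runs distribution, doubled smaller tail) is
    reported for n <= 50 and used as ``p`` there; values equal to the
    reference are dropped before counting.
    """

    n_runs: int
    z: float
    p: float
    n_above: int
    n_below: int
    method: str = "normal"
    p_normal: float = float("nan")
    p_exact: float | None = None
    message: str = ""

    @property
    def valid(self) -> bool:
        return self.message == ""


def _runs_pmf(n_above: int, n_below: int) -> np.ndarray:
    """Exact distribution of the number of runs; index r = 0..n (pmf[r])."""
    n = n_above + n_below
    pmf = np.zeros(n + 1)
    logC = lambda a, b: gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1) if 0 <= b <= a else -np.inf
    log_total = logC(n, n_above)
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            lg = math.log(2) + logC(n_above - 1, k - 1) + logC(n_below - 1, k - 1)
            pmf[r] = math.exp(lg - log_total) if np.isfinite(lg) else 0.0
        else:
            k = (r - 1) // 2
            terms = []
            a = logC(n_above - 1, k - 1) + logC(n_below - 1, k)
            b = logC(n_above - 1, k) + logC(n_below - 1, k - 1)
            for lg in (a, b):
                if np.isfinite(lg):
                    terms.append(math.exp(lg - log_total))
            pmf[r] = sum(terms)
    return pmf


def runs_test(values, reference: float | None = None, exact_max_n: int = 50) -> RunsResult:
    """Wald–Wolfowitz runs test of ``values`` about ``reference``.

    ``reference`` defaults to the sample mean.  Values exactly equal to the
    reference are dropped.  If every remaining value falls on one side the
    statistic is undefined and an error result is returned.
    """
    v = np.asarray(values, float)
    if reference is None:
        reference = float(np.mean(v))
    signs = np.sign(v - reference)
    signs = signs[signs != 0]
    n_above = int((signs > 0).sum())
    n_below = int((signs < 0).sum())
    n = n_above + n_below
    if n < 2 or n_above == 0 or n_below == 0:
        return RunsResult(0, float("nan"), float("nan"), n_above, n_below,
                          method="undefined", message="all values on one side of reference")
    r = int(1 + (np.diff(signs) != 0).sum())
    mu = 2.0 * n_above * n_below / n + 1.0
    var = 2.0 * n_above * n_below * (2.0 * n_above * n_below - n) / (n * n * (n - 1.0))
    z = (r - mu) / math.sqrt(var)
    p_normal = float(2.0 * stats.norm.sf(abs(z)))
    res = RunsResult(r, float(z), p_normal, n_above, n_below, p_normal=p_normal)
    if n <= exact_max_n:
        pmf = _runs_pmf(n_above, n_below)
        lower = float(pmf[: r + 1].sum())
        upper = float(pmf[r:].sum())
        p_exact = min(1.0, 2.0 * min(lower, upper))
        res.p_exact = p_exact
        res.p = p_exact
        res.method = "exact"
    return res


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Least-squares fit of one curve family to one dataset."""

    model: ModelSpec
    params: np.ndarray
    ss_resid: float
    n: int
    converged: bool
    bse: np.ndarray | None = None
    runs: RunsResult | None = None

    @property
    def df(self) -> int:
        return self.n - self.model.n_params

    def predict(self, x):
        return eval_model(self.model, self.params, x)


def _starts_one_phase(x, y, rng):
    y0 = float(y[np.argmin(x)])
    plateau = float(y[np.argmax(x)])
    span = plateau - y0
    xr = float(np.ptp(x)) or 1.0
    mid = y0 + span / 2.0
    # half-rise heuristic for K
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    crossing = np.nonzero(np.diff(np.sign(ys - mid)))[0]
    x_half = float(xs[crossing[0]]) if len(crossing) and xs[crossing[0]] > 0 else xr / 3.0
    k0 = math.log(2.0) / max(x_half, 1e-6)
    starts = [(y0, plateau, k0)]
    for _ in range(2):
        starts.append(
            (
                y0 + 0.2 * span * rng.standard_normal(),
                plateau + 0.2 * span * rng.standard_normal(),
                k0 * math.exp(rng.standard_normal()),
            )
        )
    return starts


def _starts_two_phase(x, y, rng):
    out = []
    for y0, plateau, k in _starts_one_phase(x, y, rng):
        span = plateau - y0
        out.append((y0, 0.6 * span, 3.0 * k, 0.4 * span, k / 3.0))
    return out


def fit_model(
    x,
    y,
    model: ModelSpec | Family | str = Family.LINEAR,
    n_starts: int = 3,
    seed: int = 0,
    runs: bool = False,
) -> FitResult:
    """Least-squares fit of one family; honest ``converged`` flag.

    Linear fits are solved exactly; exponential families use bounded
    Levenberg–Marquardt (trust region) with multi-start from data-driven
    heuristics.  Rate constants are constrained positive and, for the
    two-phase family, relabelled post-fit so KFast >= KSlow.  If ``runs`` is
    true a runs test of the residuals (about their mean) is attached.
    """
    spec = model if isinstance(model, ModelSpec) else ModelSpec(Family(model))
    fam = Family(spec.family)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n <= spec.n_params:
        raise ValueError(f"need n > {spec.n_params} points for {fam.value}, got {n}")

    if fam is Family.LINEAR:
        X = np.column_stack([np.ones(n), x])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ssr = float(resid @ resid)
        dof = n - 2
        s2 = ssr / dof if dof > 0 else np.nan
        try:
            cov = s2 * np.linalg.inv(X.T @ X)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:
            bse = None
        result = FitResult(spec, np.asarray(beta), ssr, n, True, bse=bse)
    else:
        rng = np.random.default_rng(seed)
        if fam is Family.ONE_PHASE:
            starts = _starts_one_phase(x, y, rng)[:n_starts]
            lb = [-np.inf, -np.inf, 1e-8]
            ub = [np.inf, np.inf, np.inf]
        else:
            starts = _starts_two_phase(x, y, rng)[:n_starts]
            lb = [-np.inf, -np.inf, 1e-8, -np.inf, 1e-8]
            ub = [np.inf, np.inf, np.inf, np.inf, np.inf]

        def residfun(p):
            return eval_model(fam, p, x) - y

        best = None
        ok = False
        for p0 in starts:
            p0 = np.clip(p0, lb, ub)
            try:
                sol = optimize.least_squares(residfun, p0, bounds=(lb, ub), method="trf")
            except Exception:  # pragma: no cover - optimizer pathologies
                continue
            ssr = 2.0 * sol.cost
            if best is None or ssr < best[0]:
                best = (ssr, sol)
                ok = ok or sol.success
        if best is None:
            return FitResult(spec, np.full(spec.n_params, np.nan), np.nan, n, False)
        ssr, sol = best
        params = sol.x.copy()
        if fam is Family.TWO_PHASE and params[4] > params[2]:
            params = params[[0, 3, 4, 1, 2]]  # relabel so KFast >= KSlow
        bse = None
        dof = n - spec.n_params
        if dof > 0:
            J = sol.jac
            try:
                cov = (ssr / dof) * np.linalg.inv(J.T @ J)
                bse = np.sqrt(np.clip(np.diag(cov), 0, None))
                if fam is Family.TWO_PHASE and not np.array_equal(params, sol.x):
                    bse = bse[[0, 3, 4, 1, 2]]
            except np.linalg.LinAlgError:
                bse = None
        result = FitResult(spec, params, float(ssr), n, bool(sol.success or ok), bse=bse)

    if runs and result.converged:
        resid = y - result.predict(x)
        order = np.argsort(x)
        result.runs = runs_test(resid[order], reference=float(np.mean(resid)))
    return result


# ---------------------------------------------------------------------------
# F tests
# ---------------------------------------------------------------------------


@dataclass
class FTestResult:
    F: float
    df_num: int
    df_den: int
    p: float


def extra_ss_ftest(simple: FitResult, complex_: FitResult) -> FTestResult:
    """Extra-sum-of-squares F test between nested fits on the same data.

    F = ((SS_s - SS_c)/(df_s - df_c)) / (SS_c/df_c); when the simpler model
    fits numerically better (optimizer noise) F is clamped to 0.
    """
    if complex_.model.n_params <= simple.model.n_params:
        raise ValueError("complex model must have more parameters")
    if simple.n != complex_.n:
        raise ValueError("fits must be on the same data")
    if not (simple.converged and complex_.converged):
        raise ValueError("both fits must have converged")
    df_s, df_c = simple.df, complex_.df
    if df_c <= 0:
        raise ValueError("complex fit has no residual degrees of freedom")
    num = (simple.ss_resid - complex_.ss_resid) / (df_s - df_c)
    den = complex_.ss_resid / df_c
    if num <= 0 or den == 0:
        F = 0.0
    else:
        F = num / den
    p = float(stats.f.sf(F, df_s - df_c, df_c)) if F > 0 else 1.0
    return FTestResult(float(F), df_s - df_c, df_c, p)


@dataclass
class SelectionResult:
    model: ModelSpec
    fits: dict
    tests: list

    @property
    def family(self) -> Family:
        return Family(self.model.family)


def select_model(
    x,
    y,
    ladder=DEFAULT_LADDER,
    alpha_select: float = 0.05,
    seed: int = 0,
) -> SelectionResult:
    """Walk a nested ladder, promoting only when the extra-SS F test rejects.

    Returns the simplest non-rejected model; models with insufficient
    degrees of freedom (n <= n_params + 1) are never attempted.  Raises if
    no model on the ladder converges.
    """
    x = np.asarray(x, float)
    ladder = sorted(ladder, key=lambda m: m.n_params)
    fits: dict = {}
    tests: list = []
    current = None
    for spec in ladder:
        if len(x) <= spec.n_params + 1:
            continue
        fit = fit_model(x, y, spec, seed=seed)
        if not fit.converged:
            continue
        fits[Family(spec.family)] = fit
        if current is None:
            current = fit
            continue
        test = extra_ss_ftest(current, fit)
        tests.append((Family(current.model.family), Family(spec.family), test))
        if test.p < alpha_select:
            current = fit
        else:
            break
    if current is None:
        raise RuntimeError("no model on the ladder could be fitted")
    return SelectionResult(current.model, fits, tests)


@dataclass
class SweepReport:
    """Model selection across a grid of speed windows."""

    table: pd.DataFrame
    skipped: list

    def widest_window(self, family: Family | None = None):
        """Widest window whose every nested grid window selects ``family``
        (default: the family selected most often across the grid)."""
        tab = self.table
        if len(tab) == 0:
            return None
        if family is None:
            family = Family(tab["family"].mode().iloc[0])
        cand = tab[tab["family"] == family.value].copy()
        cand["width"] = cand["hi"] - cand["lo"]
        for _, row in cand.sort_values("width", ascending=False).iterrows():
            inside = tab[(tab["lo"] >= row["lo"]) & (tab["hi"] <= row["hi"])]
            if (inside["family"] == family.value).all():
                return (row["lo"], row["hi"], family)
        return None


def sweep_speed_ranges(
    x,
    y,
    ladder=DEFAULT_LADDER,
    lo_start: float = 0.0,
    hi_start: float = 25.0,
    step: float = 1.0,
    alpha_select: float = 0.05,
    seed: int = 0,
) -> SweepReport:
    """Re-select the model while trimming the slowest and fastest speeds.

    Windows start from the full (lo_start, hi_start) range; the lower edge
    increases and the upper edge decreases in ``step`` increments.  Windows
    with too few points are skipped and recorded.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    min_params = min(m.n_params for m in ladder)
    rows, skipped = [], []
    lo = lo_start
    los = []
    while lo < hi_start:
        los.append(lo)
        lo += step
    his = []
    hi = hi_start
    while hi > lo_start:
        his.append(hi)
        hi -= step
    for lo in los:
        for hi in his:
            if hi <= lo:
                continue
            mask = (x >= lo) & (x <= hi)
            n = int(mask.sum())
            if n <= min_params + 1:
                skipped.append((lo, hi, n))
                continue
            try:
                sel = select_model(x[mask], y[mask], ladder, alpha_select, seed=seed)
            except RuntimeError:
                skipped.append((lo, hi, n))
                continue
            rows.append(
                {
                    "lo": lo,
                    "hi": hi,
                    "n": n,
                    "family": sel.family.value,
                    "ss_resid": sel.fits[sel.family].ss_resid,
                }
            )
    return SweepReport(pd.DataFrame(rows), skipped)


# ---------------------------------------------------------------------------
# curve sharing
# ---------------------------------------------------------------------------


@dataclass
class CurveComparisonResult:
    """Shared-vs-separate curve comparison between two datasets.

    ``shared`` is True when a single parameter set is adequate for both
    (p >= alpha); a significant F means the curves — slope and intercept
    jointly, for the linear family — differ between the datasets.
    """

    F: float
    df_num: int
    df_den: int
    p: float
    shared_fit: FitResult
    separate_fits: tuple
    alpha: float
    labels: tuple = ("A", "B")

    @property
    def shared(self) -> bool:
        return self.p >= self.alpha

    @property
    def verdict(self) -> str:
        return "shared" if self.shared else "different"

    def summary(self) -> str:
        fam = Family(self.shared_fit.model.family).value
        lines = [
            "Curve-sharing F test",
            "=" * 52,
            f"model family:   {fam}",
            f"datasets:       {self.labels[0]} (n={self.separate_fits[0].n}), "
            f"{self.labels[1]} (n={self.separate_fits[1].n})",
            f"F({self.df_num}, {self.df_den}) = {self.F:.4g}",
            f"p = {self.p:.4g}   (alpha = {self.alpha:g})",
            f"verdict:        {self.verdict}",
        ]
        names = self.shared_fit.model.param_names
        lines.append("shared params:  " + ", ".join(
            f"{k}={v:.4g}" for k, v in zip(names, self.shared_fit.params)))
        for lab, fit in zip(self.labels, self.separate_fits):
            lines.append(f"{lab} params:       " + ", ".join(
                f"{k}={v:.4g}" for k, v in zip(names, fit.params)))
        return "\n".join(lines)


def compare_curves(
    xa,
    ya,
    xb,
    yb,
    model: ModelSpec | Family | str = Family.LINEAR,
    alpha: float = 0.001,
    seed: int = 0,
    labels=("A", "B"),
) -> CurveComparisonResult:
    """F test of one shared curve (pooled fit) vs independent curves.

    SS_sep = SS_A + SS_B with df_sep = n_A + n_B - 2p; the pooled fit has
    df_shared = n_A + n_B - p, so the test has p numerator degrees of
    freedom: *all* parameters are shared or none.
    """
    spec = model if isinstance(model, ModelSpec) else ModelSpec(Family(model))
    xa, ya, xb, yb = (np.asarray(a, float) for a in (xa, ya, xb, yb))
    if len(xa) == 0 or len(xb) == 0:
        raise ValueError("both datasets must be non-empty")
    p_n = spec.n_params
    n_tot = len(xa) + len(xb)
    df_sep = n_tot - 2 * p_n
    if df_sep <= 0:
        raise ValueError("not enough points for separate fits")
    fit_a = fit_model(xa, ya, spec, seed=seed)
    fit_b = fit_model(xb, yb, spec, seed=seed + 1)
    if not (fit_a.converged and fit_b.converged):
        raise RuntimeError("separate fit failed to converge")
    shared = fit_model(np.concatenate([xa, xb]), np.concatenate([ya, yb]), spec, seed=seed + 2)
    if not shared.converged:
        raise RuntimeError("shared fit failed to converge")
    ss_sep = fit_a.ss_resid + fit_b.ss_resid
    df_shared = n_tot - p_n
    extra = shared.ss_resid - ss_sep
    den = ss_sep / df_sep
    y_pool = np.concatenate([ya, yb])
    tss = float(np.sum((y_pool - y_pool.mean()) ** 2))
    if shared.ss_resid <= 1e-12 * max(tss, np.finfo(float).tiny):
        extra = 0.0  # pooled fit is exact: one curve describes both datasets
    # relative guard: optimizer noise and exact (zero-residual) fits
    if extra <= 1e-9 * max(shared.ss_resid, np.finfo(float).tiny):
        if extra < 0:
            logger.warning("SS_shared < SS_separate by %g; F clamped to 0", -extra)
        F, pval = 0.0, 1.0
    elif den == 0.0:
        F, pval = math.inf, 0.0  # separate fits are exact, pooling is not
    else:
        F = (extra / (df_shared - df_sep)) / den
        pval = float(stats.f.sf(F, p_n, df_sep))
    return CurveComparisonResult(
        float(F), p_n, df_sep, pval, shared, (fit_a, fit_b), alpha, tuple(labels)
    )


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------


def stance_transform(stance_time, speed, species: Species | str = Species.HUMAN):
    """Log transform pairing stance time with the linear family.

    Y = 1 - log10(stance time), X = log10(speed) + 1 for both species (any
    fixed log base yields identical linear-family F tests).  Non-positive
    inputs are excluded and counted.

    Returns ``(X, Y, n_excluded)``.
    """
    st = np.asarray(stance_time, float)
    v = np.asarray(speed, float)
    ok = (st > 0) & (v > 0)
    n_excl = int((~ok).sum())
    if n_excl:
        logger.warning("stance transform excluded %d non-positive records", n_excl)
    return np.log10(v[ok]) + 1.0, 1.0 - np.log10(st[ok]), n_excl


def inverse_stance_transform(X, Y):
    """Invert :func:`stance_transform`: returns (speed, stance_time)."""
    return 10.0 ** (np.asarray(X, float) - 1.0), 10.0 ** (1.0 - np.asarray(Y, float))


# ---------------------------------------------------------------------------
# statsmodels-style object layer
# ---------------------------------------------------------------------------


class SpeedCurveResults:
    """Results wrapper with named parameters, uncertainties and summary."""

    def __init__(self, model: "SpeedCurveModel", fit: FitResult):
        self.model = model
        self._fit = fit

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._fit.params, index=self._fit.model.param_names)

    @property
    def bse(self) -> pd.Series:
        b = self._fit.bse
        vals = b if b is not None else np.full(self._fit.model.n_params, np.nan)
        return pd.Series(vals, index=self._fit.model.param_names)

    @property
    def ssr(self) -> float:
        return self._fit.ss_resid

    @property
    def df_resid(self) -> int:
        return self._fit.df

    @property
    def nobs(self) -> int:
        return self._fit.n

    @property
    def converged(self) -> bool:
        return self._fit.converged

    @property
    def runs(self) -> RunsResult | None:
        return self._fit.runs

    @property
    def fitresult(self) -> FitResult:
        return self._fit

    def predict(self, x=None):
        x = self.model.x if x is None else x
        return self._fit.predict(x)

    @property
    def resid(self):
        return self.model.y - self.predict()

    def summary(self) -> str:
        fam = Family(self._fit.model.family).value
        lines = [
            "Speed-curve regression",
            "=" * 46,
            f"family: {fam}    n = {self.nobs}    df_resid = {self.df_resid}",
            f"SSR = {self.ssr:.6g}    converged = {self.converged}",
            "-" * 46,
            f"{'param':<10}{'estimate':>14}{'std err':>14}",
        ]
        for name, est, se in zip(self.params.index, self.params, self.bse):
            lines.append(f"{name:<10}{est:>14.6g}{se:>14.6g}")
        if self.runs is not None and self.runs.valid:
            lines.append("-" * 46)
            lines.append(
                f"runs test: R = {self.runs.n_runs}, Z = {self.runs.z:.3f}, "
                f"p = {self.runs.p:.3f}"
            )
        return "\n".join(lines)

    def plot(self, ax=None, **scatter_kw):
        """Scatter of the data with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.model.x, self.model.y, s=8, alpha=0.5, **scatter_kw)
        grid = np.linspace(self.model.x.min(), self.model.x.max(), 200)
        ax.plot(grid, self.predict(grid), color="k")
        ax.set_xlabel("stride velocity")
        return ax


class SpeedCurveModel:
    """A gait metric as a curve over stride velocity.

    Parameters
    ----------
    x, y : array-like
        Stride velocities and metric values.
    family : Family or str
        Curve family; ``"auto"`` selects via the nested ladder at ``fit``.
    """

    def __init__(self, x, y, family: Family | str = Family.LINEAR):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        self.family = family

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        metric: str,
        family: Family | str = Family.LINEAR,
        xname: str = "stride_velocity",
    ) -> "SpeedCurveModel":
        df = data.dropna(subset=[metric, xname])
        return cls(df[xname].to_numpy(), df[metric].to_numpy(), family)

    def fit(self, runs: bool = False, n_starts: int = 3, seed: int = 0,
            alpha_select: float = 0.05) -> SpeedCurveResults:
        if isinstance(self.family, str) and self.family == "auto":
            sel = select_model(self.x, self.y, alpha_select=alpha_select, seed=seed)
            fit = fit_model(self.x, self.y, sel.model, n_starts=n_starts, seed=seed, runs=runs)
        else:
            fit = fit_model(self.x, self.y, Family(self.family), n_starts=n_starts,
                            seed=seed, runs=runs)
        return SpeedCurveResults(self, fit)


class CurveShareTest:
    """Shared-vs-separate curve model for two datasets of one metric.

    Built either from raw arrays or from a :class:`~gaitasym.core.GaitDataset`
    (``from_dataset``), e.g. left vs right step length.  ``fit()`` returns a
    :class:`CurveComparisonResult`.
    """

    def __init__(self, xa, ya, xb, yb, family: Family | str = Family.LINEAR,
                 alpha: float = 0.001, labels=("A", "B")):
        self.xa, self.ya = np.asarray(xa, float), np.asarray(ya, float)
        self.xb, self.yb = np.asarray(xb, float), np.asarray(yb, float)
        self.family = family
        self.alpha = alpha
        self.labels = tuple(labels)

    @classmethod
    def from_dataset(
        cls,
        dataset: GaitDataset,
        metric: str,
        pair: str = "hind",
        by: str = "limb",
        groups: tuple | None = None,
        family: Family | str = Family.LINEAR,
        alpha: float = 0.001,
        stance_log: bool = False,
    ) -> "CurveShareTest":
        """Left-vs-right (``by="limb"``) or condition-vs-condition
        (``by="condition"``) comparison of one metric."""
        df = dataset.records
        if by == "limb" and groups is None:
            groups = HOMOLOGOUS_PAIRS[pair]
        if groups is None:
            raise ValueError("groups required when by != 'limb'")
        sides = []
        for g in groups:
            sub = df[df[by] == g].dropna(subset=[metric, "stride_velocity"])
            if stance_log:
                x, y, _ = stance_transform(sub[metric], sub["stride_velocity"],
                                           dataset.species)
            else:
                x, y = sub["stride_velocity"].to_numpy(), sub[metric].to_numpy()
            sides.append((x, y))
        (xa, ya), (xb, yb) = sides
        return cls(xa, ya, xb, yb, family=family, alpha=alpha, labels=groups)

    def fit(self, seed: int = 0) -> CurveComparisonResult:
        fam = self.family
        if isinstance(fam, str) and fam == "auto":
            sel = select_model(
                np.concatenate([self.xa, self.xb]),
                np.concatenate([self.ya, self.yb]),
                seed=seed,
            )
            fam = sel.model
        return compare_curves(self.xa, self.ya, self.xb, self.yb, fam,
                              alpha=self.alpha, seed=seed, labels=self.labels)


# ---------------------------------------------------------------------------
# per-subject averaged analysis
# ---------------------------------------------------------------------------


@dataclass
class AveragedAnalysis:
    """Per-subject mean metric vs mean speed, plus a paired side test."""

    means: pd.DataFrame
    comparison: CurveComparisonResult | None
    t: float
    df: int
    p: float
    excluded_subjects: list = field(default_factory=list)


def averaged_analysis(
    dataset: GaitDataset,
    metric: str,
    pair: str = "hind",
    family: Family | str = Family.LINEAR,
    alpha: float = 0.001,
    seed: int = 0,
) -> AveragedAnalysis:
    """Collapse each subject to one (mean speed, mean metric) point per side.

    Guards against pseudo-replication: the curve comparison is repeated on
    the averaged points and a two-tailed paired t test compares left vs
    right subject means.  Subjects missing a side are excluded and logged.
    """
    left, right = HOMOLOGOUS_PAIRS[pair]
    df = dataset.records.dropna(subset=[metric, "stride_velocity"])
    rows, excluded = [], []
    for subj, grp in df.groupby("subject_id"):
        sides = {}
        for limb in (left, right):
            sub = grp[grp["limb"] == limb]
            if len(sub):
                sides[limb] = (sub["stride_velocity"].mean(), sub[metric].mean())
        if len(sides) < 2:
            excluded.append(subj)
            logger.warning("subject %s missing a side for %s; excluded", subj, metric)
            continue
        for limb, (v, m) in sides.items():
            rows.append({"subject_id": subj, "limb": limb,
                         "mean_speed": v, f"mean_{metric}": m})
    means = pd.DataFrame(rows)
    if len(means) == 0:
        raise ValueError("no subject contributed both sides")
    lvals = means[means["limb"] == left].set_index("subject_id")[f"mean_{metric}"]
    rvals = means[means["limb"] == right].set_index("subject_id")[f"mean_{metric}"]
    common = lvals.index.intersection(rvals.index)
    d = lvals[common].to_numpy() - rvals[common].to_numpy()
    nsub = len(d)
    if np.allclose(d, 0):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(lvals[common], rvals[common])
    comparison = None
    ml = means[means["limb"] == left]
    mr = means[means["limb"] == right]
    spec = family if isinstance(family, ModelSpec) else ModelSpec(Family(family))
    if len(ml) + len(mr) > 2 * spec.n_params:
        comparison = compare_curves(
            ml["mean_speed"], ml[f"mean_{metric}"],
            mr["mean_speed"], mr[f"mean_{metric}"],
            spec, alpha=alpha, seed=seed, labels=(left, right),
        )
    return AveragedAnalysis(means, comparison, float(t), nsub - 1, float(p), excluded)
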