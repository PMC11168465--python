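"""Dwell-time survival analysis.

Empirical 1-CDF construction, constrained two-phase exponential fitting
(plateau fixed at 0, K_slow > 0, K_fast ≥ K_slow, amplitudes ≥ 0, 1/Y²
weighting), residence-time/half-life derivation, Kaplan-Meier cumulative
dwell curves and the two-group log-rank test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "SurvivalCurve",
    "BiExpFit",
    "KMCurve",
    "LogRankResult",
    "FitError",
    "survival_from_dwells",
    "fit_biexponential",
    "derive_half_life",
    "km_cumulative_dwell",
    "log_rank",
]

LN2 = math.log(2.0)


class FitError(RuntimeError):
    """Raised when no fitting start converges."""


@dataclass
class SurvivalCurve:
    """Empirical survival (1-CDF) of dwell durations.

    ``S[i]`` is the fraction of events with duration strictly greater than
    ``t[i]``; the grid starts at t=0 with S=1.
    """

    t: np.ndarray
    S: np.ndarray
    n_events: int
    censored: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if np.any(np.diff(self.S) > 1e-12):
            raise ValueError("survival must be non-increasing")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("survival values must lie in [0, 1]")


@dataclass
class BiExpFit:
    """Constrained two-phase exponential decay parameters."""

    A_fast: float
    A_slow: float
    K_fast: float  # per s, >= K_slow
    K_slow: float  # per s, > 0
    r_squared: float
    plateau: float = 0.0
    single_phase: bool = False

    @property
    def tau_fast(self) -> float:
        return 1.0 / self.K_fast

    @property
    def tau_slow(self) -> float:
        return 1.0 / self.K_slow

    @property
    def halflife_fast(self) -> float:
        return LN2 / self.K_fast

    @property
    def halflife_slow(self) -> float:
        return LN2 / self.K_slow

    @property
    def fast_fraction(self) -> float:
        tot = self.A_fast + self.A_slow
        return self.A_fast / tot if tot > 0 else float("nan")

    def predict(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.A_fast * np.exp(-self.K_fast * t) + self.A_slow * np.exp(-self.K_slow * t)


@dataclass
class KMCurve:
    """Product-limit survival over (cumulative) dwell durations."""

    t: np.ndarray
    S: np.ndarray
    at_risk: np.ndarray
    median: float  # nan when undefined under censoring
    n: int

    @property
    def median_defined(self) -> bool:
        return not math.isnan(self.median)


@dataclass
class LogRankResult:
    chi_square: float
    p_value: float
    n_a: int
    n_b: int


# ---------------------------------------------------------------------------


def survival_from_dwells(
    durations, censored=None
) -> SurvivalCurve:
    """Empirical 1-CDF of dwell durations on the sorted unique-time grid.

    Censored flags are carried through but — matching the per-event
    analysis convention — censored durations are treated as observed event
    ends here; use :func:`km_cumulative_dwell` for censoring-aware
    estimation.
    """
    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no durations supplied")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    cens = None if censored is None else np.asarray(censored, dtype=bool)
    uniq = np.unique(d)
    t = np.concatenate([[0.0], uniq])
    S = np.array([(d > ti).mean() for ti in t])
    return SurvivalCurve(t, S, n_events=d.size, censored=cens)


def _fit_once(t, S, x0, bounds, model_of) -> tuple[np.ndarray, float]:
    def residuals(params):
        m = np.maximum(model_of(params, t), 1e-12)
        return (S - m) / m  # relative (1/Y²) weighting against the fitted value

    sol = least_squares(residuals, x0, bounds=bounds, max_nfev=10000)
    return sol.x, float(np.sum(sol.fun**2))


def fit_biexponential(
    curve: SurvivalCurve,
    n_restarts: int = 5,
    seed: int = 0,
    identifiability_ratio: float = 0.8,
    free_amplitudes: bool = False,
    min_tail_events: int = 5,
) -> BiExpFit:
    """Relative-weighted constrained bi-exponential fit of a survival curve.

    Minimizes Σ wᵢ(Sᵢ − A_f e^(−K_f tᵢ) − A_s e^(−K_s tᵢ))² with 1/Y²
    weighting taken against the fitted value (wᵢ = 1/m(tᵢ)², the relative
    least-squares convention of common fitting tools), under plateau = 0,
    K_slow > 0, K_fast ≥ K_slow and amplitudes ≥ 0. Points with S = 0 are
    excluded (their relative weight is undefined), as are deep-tail points
    supported by fewer than ``min_tail_events`` remaining events, whose
    empirical survival is order-statistic noise (the floor is relaxed if it
    would leave fewer than 6 points).

    By default the amplitudes are constrained to sum to S(0) — an empirical
    survival curve passes through (0, 1) by construction — which markedly
    stabilizes tau recovery; set ``free_amplitudes=True`` for free spans.
    Initialization is a log-linear fit of the tail for K_slow and of the
    early residual for K_fast, plus jittered restarts. If the fitted
    tau_fast/tau_slow ratio exceeds ``identifiability_ratio`` the result is
    flagged single-phase.
    """
    keep = curve.S > 0
    floor = min_tail_events / curve.n_events if curve.n_events else 0.0
    if np.count_nonzero(curve.S >= floor) >= 6:
        keep &= curve.S >= floor
    t = curve.t[keep]
    S = curve.S[keep]
    if len(np.unique(t)) < 6:
        raise ValueError("need at least 6 distinct time points with S > 0")
    s0 = float(S[t == t.min()][0])

    # --- initialization ----------------------------------------------------
    n_tail = max(3, len(t) // 3)
    slope_tail, icpt_tail = np.polyfit(t[-n_tail:], np.log(S[-n_tail:]), 1)
    k_slow0 = max(1e-4, -slope_tail)
    a_slow0 = min(s0, math.exp(icpt_tail))
    resid = S - a_slow0 * np.exp(-k_slow0 * t)
    n_early = max(3, len(t) // 3)
    early, early_t = resid[:n_early], t[:n_early]
    pos = early > 1e-6
    if pos.sum() >= 2:
        slope_e, icpt_e = np.polyfit(early_t[pos], np.log(early[pos]), 1)
        k_fast0 = max(k_slow0 * 2, -slope_e)
        a_fast0 = max(0.0, min(s0, math.exp(icpt_e)))
    else:
        k_fast0, a_fast0 = k_slow0 * 5, 0.1 * s0

    if free_amplitudes:
        bounds = ([0.0, 0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf, np.inf])
        x0 = np.array([a_fast0, a_slow0, k_slow0, max(k_fast0 - k_slow0, 1e-6)])

        def model_of(p, tt):
            a_f, a_s, k_s, dk = p
            return a_f * np.exp(-(k_s + dk) * tt) + a_s * np.exp(-k_s * tt)

        def unpack(p):
            return p[0], p[1], p[2] + p[3], p[2]
    else:
        bounds = ([0.0, 1e-9, 0.0], [1.0, np.inf, np.inf])
        f0 = min(1.0, max(0.0, a_fast0 / s0))
        x0 = np.array([f0, k_slow0, max(k_fast0 - k_slow0, 1e-6)])

        def model_of(p, tt):
            f, k_s, dk = p
            return s0 * (f * np.exp(-(k_s + dk) * tt) + (1 - f) * np.exp(-k_s * tt))

        def unpack(p):
            return s0 * p[0], s0 * (1 - p[0]), p[1] + p[2], p[1]

    starts = [x0]
    rng = np.random.default_rng(seed)
    for _ in range(n_restarts):
        jitter = rng.lognormal(0.0, 0.5, size=len(x0))
        starts.append(np.clip(x0 * jitter, bounds[0], bounds[1]))

    best = None
    for start in starts:
        try:
            params, cost = _fit_once(t, S, start, bounds, model_of)
        except Exception:
            continue
        if best is None or cost < best[1]:
            best = (params, cost)
    if best is None:
        raise FitError(
            f"bi-exponential fit failed to converge from {len(starts)} starts "
            f"(n={len(t)} points, S range [{S.min():.3g}, {S.max():.3g}])"
        )

    a_f, a_s, k_f, k_s = unpack(best[0])
    model = a_f * np.exp(-k_f * t) + a_s * np.exp(-k_s * t)
    ss_res = float(np.sum((S - model) ** 2))
    ss_tot = float(np.sum((S - S.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    single = (k_s / k_f > identifiability_ratio) if k_f > 0 else True
    return BiExpFit(float(a_f), float(a_s), float(k_f), float(k_s), r2,
                    single_phase=bool(single))


def derive_half_life(fit: BiExpFit) -> tuple[float, float]:
    """(half-life fast, half-life slow) = ln2/K per phase."""
    if fit.K_fast <= 0 or fit.K_slow <= 0:
        raise ValueError("rates must be positive")
    return LN2 / fit.K_fast, LN2 / fit.K_slow


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank (backed by lifelines)
# ---------------------------------------------------------------------------

def km_cumulative_dwell(durations, censored=None) -> KMCurve:
    """Product-limit estimator of per-telomere cumulative dwell durations.

    Right-censoring (e.g., movies ending while a particle is still bound)
    is honored. The median is the smallest time at which survival drops to
    ≤ 0.5; undefined (NaN) when censoring keeps survival above 0.5.
    """
    from lifelines import KaplanMeierFitter

    d = np.asarray(durations, dtype=float)
    if d.size == 0:
        raise ValueError("no telomeres supplied")
    cens = np.zeros(d.size, dtype=bool) if censored is None else np.asarray(censored, bool)
    kmf = KaplanMeierFitter()
    kmf.fit(d, event_observed=~cens)
    t = kmf.survival_function_.index.to_numpy(dtype=float)
    S = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array(
        [int((d >= ti).sum()) for ti in t]
    )
    med = float(kmf.median_survival_time_)
    if math.isinf(med):
        med = float("nan")
    return KMCurve(t, S, at_risk, med, int(d.size))


def log_rank(
    durations_a, durations_b, censored_a=None, censored_b=None
) -> LogRankResult:
    """Standard two-group log-rank test (1 degree of freedom)."""
    from lifelines.statistics import logrank_test

    da = np.asarray(durations_a, dtype=float)
    db = np.asarray(durations_b, dtype=float)
    if da.size == 0 or db.size == 0:
        raise ValueError("both groups must be non-empty")
    ca = np.zeros(da.size, bool) if censored_a is None else np.asarray(censored_a, bool)
    cb = np.zeros(db.size, bool) if censored_b is None else np.asarray(censored_b, bool)
    res = logrank_test(da, db, event_observed_A=~ca, event_observed_B=~cb)
    chi2 = float(res.test_statistic)
    p = float(res.p_value)
    if not math.isfinite(chi2):  # degenerate: no variance in pooled risk sets
        chi2, p = 0.0, 1.0
    return LogRankResult(chi2, p, int(da.size), int(db.size))
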