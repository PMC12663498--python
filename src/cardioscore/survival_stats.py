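"""From-scratch survival estimators and regressions.

Everything the validation reports is computed here without delegating to an
external survival library: the product-limit (Kaplan-Meier) estimator with
Greenwood variance, the Nelson-Aalen cumulative hazard, the Aalen-Johansen
cumulative incidence functions for two competing causes, Harrell's
concordance index with a Noether-type normal-approximation CI, Cox
proportional-hazards regression (Breslow ties, Newton-Raphson with
step-halving), and Fine-Gray subdistribution-hazard regression via the IPCW
weighted partial likelihood — subjects failing from the competing cause
remain in later risk sets with weight ``G(t)/G(min(T_i, t))`` where ``G`` is
the pooled Kaplan-Meier estimate of the censoring survivor function.

Cox and Fine-Gray share one weighted Newton-Raphson core; the Cox weights
are plain risk-set indicators, so Fine-Gray reduces exactly to Cox when no
competing events are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cohort_model import RiskCategory

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


# --------------------------------------------------------------------------
# Nonparametric estimators
# --------------------------------------------------------------------------

@dataclass
class SurvivalCurve:
    """Step function S(t): value ``survival[i]`` holds on [times[i], times[i+1])."""

    times: np.ndarray  # distinct event times, ascending
    survival: np.ndarray  # S(t) at each step, in [0, 1]
    variance: np.ndarray  # Greenwood variance of S(t)
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t); 1 before the first event time."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def at_minus(self, t: float) -> float:
        """Left limit S(t-)."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        se = np.sqrt(self.variance)
        return (np.clip(self.survival - _Z95 * se, 0, 1),
                np.clip(self.survival + _Z95 * se, 0, 1))


def _check_input(times, indicator):
    times = np.asarray(times, dtype=float)
    indicator = np.asarray(indicator)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != indicator.shape:
        raise ValueError("times and indicator must have equal length")
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    return times, indicator


def _risk_table(times: np.ndarray, flags: np.ndarray):
    """Distinct times with any flagged occurrence, at-risk and event counts."""
    order = np.argsort(times, kind="stable")
    t, f = times[order], flags[order]
    uniq, first_idx = np.unique(t, return_index=True)
    n = t.size
    at_risk = n - first_idx  # count with time >= uniq[k]
    events = np.add.reduceat(f.astype(float), first_idx)
    keep = events > 0
    return uniq[keep], at_risk[keep], events[keep]


def kaplan_meier(times, event_indicator) -> SurvivalCurve:
    """Product-limit survival estimate with Greenwood variance.

    ``event_indicator`` is 1 for an observed event, 0 for censoring.  For the
    composite display under competing risks, pass competing deaths as
    censorings (the naive KM complement; the Aalen-Johansen CIF is the
    adjusted alternative).
    """
    times, events = _check_input(times, event_indicator)
    t, n_at_risk, d = _risk_table(times, np.asarray(events, dtype=bool))
    frac = d / n_at_risk
    survival = np.cumprod(1.0 - frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        greenwood = np.cumsum(d / (n_at_risk * (n_at_risk - d)))
        variance = np.where(survival > 0, survival**2 * greenwood, 0.0)
    return SurvivalCurve(t, survival, variance, n_at_risk, d)


@dataclass
class CumulativeHazard:
    times: np.ndarray
    cumhaz: np.ndarray  # nondecreasing
    variance: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.cumhaz[idx])


def nelson_aalen(times, event_indicator) -> CumulativeHazard:
    """Nelson-Aalen cumulative hazard H(t) = sum d_i / n_i over event times <= t."""
    times, events = _check_input(times, event_indicator)
    t, n_at_risk, d = _risk_table(times, np.asarray(events, dtype=bool))
    return CumulativeHazard(t, np.cumsum(d / n_at_risk), np.cumsum(d / n_at_risk**2))


@dataclass
class CIFSet:
    """Aalen-Johansen cumulative incidence for causes 1 and 2.

    At every step ``cif1 + cif2 + overall_survival == 1`` (to numerical
    precision); each CIF is nondecreasing.
    """

    times: np.ndarray
    cif1: np.ndarray
    cif2: np.ndarray
    overall_survival: np.ndarray

    def cif_at(self, cause: int, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        if idx < 0:
            return 0.0
        return float((self.cif1 if cause == 1 else self.cif2)[idx])


def aalen_johansen_cif(times, status) -> CIFSet:
    """Cumulative incidence functions under two competing causes.

    ``status``: 0 censored, 1 cause of interest, 2 competing cause, as in
    :class:`~cardioscore.cohort_model.OutcomeRecord`.
    """
    times, status = _check_input(times, status)
    status = status.astype(int)
    if not np.all(np.isin(status, (0, 1, 2))):
        raise ValueError("status must be coded 0/1/2")
    any_event = status > 0
    t, n_at_risk, d_any = _risk_table(times, any_event)
    d1 = np.array([np.sum((times == tk) & (status == 1)) for tk in t], dtype=float)
    d2 = np.array([np.sum((times == tk) & (status == 2)) for tk in t], dtype=float)
    surv = np.cumprod(1.0 - d_any / n_at_risk)
    s_minus = np.concatenate([[1.0], surv[:-1]])
    cif1 = np.cumsum(s_minus * d1 / n_at_risk)
    cif2 = np.cumsum(s_minus * d2 / n_at_risk)
    return CIFSet(t, cif1, cif2, surv)


# --------------------------------------------------------------------------
# Concordance
# --------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    c: float
    comparable_pairs: int
    concordant: int
    tied_score: int
    ci_lower: float
    ci_upper: float


def harrell_c(risk_scores, times, event_indicator) -> ConcordanceResult:
    """Harrell's concordance index for right-censored data.

    Higher score must mean higher predicted risk.  A pair (i, j) is
    comparable iff subject i had the event and ``t_i < t_j`` (time-tied event
    pairs are excluded); it is concordant when ``score_i > score_j``; tied
    scores count 1/2.  The 95% CI is a normal approximation on the
    concordance variance estimated by the U-statistic linearisation
    (per-subject influence terms).

    Competing deaths should be passed as censorings for the composite.
    """
    scores = np.asarray(risk_scores, dtype=float)
    times, events = _check_input(times, event_indicator)
    events = np.asarray(events, dtype=bool)
    if scores.shape != times.shape:
        raise ValueError("scores and times must have equal length")
    n = times.size
    ev = np.where(events)[0]
    # comparable: i in ev, t_i < t_j  (vectorised over the event rows)
    W = times[ev][:, None] < times[None, :]
    ds = scores[ev][:, None]
    concordant = W & (ds > scores[None, :])
    tied = W & (ds == scores[None, :])
    m = int(W.sum())
    if m == 0:
        raise ValueError("no comparable pairs")
    nc, nt = int(concordant.sum()), int(tied.sum())
    c = (nc + 0.5 * nt) / m
    # influence of each subject: residual kernel mass over its pairs
    K = concordant.astype(float) + 0.5 * tied.astype(float)
    resid = K - c * W  # rows: event subjects, cols: all subjects
    psi = np.zeros(n)
    np.add.at(psi, ev, resid.sum(axis=1))
    psi += resid.sum(axis=0)
    se = float(np.sqrt(np.sum(psi**2)) / m)
    return ConcordanceResult(c, m, nc, nt,
                             max(0.0, c - _Z95 * se), min(1.0, c + _Z95 * se))


# --------------------------------------------------------------------------
# Cox / Fine-Gray regression (shared weighted Newton-Raphson core)
# --------------------------------------------------------------------------

@dataclass
class RegressionFit:
    names: list[str]
    coef: np.ndarray  # log hazard ratios
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    separation: bool = False  # |beta| diverged

    @property
    def hr(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        return (np.exp(self.coef - _Z95 * self.se),
                np.exp(self.coef + _Z95 * self.se))

    def summary(self) -> list[dict]:
        lo, hi = self.ci
        return [{"covariate": n, "coef": float(b), "se": float(s),
                 "hr": float(np.exp(b)), "hr_ci_lower": float(l),
                 "hr_ci_upper": float(h)}
                for n, b, s, l, h in zip(self.names, self.coef, self.se, lo, hi)]


def _validate_design(X: np.ndarray) -> None:
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than covariates")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant covariate column")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient covariate matrix (duplicated column?)")


def _newton_raphson(X: np.ndarray, event_groups: list[np.ndarray],
                    W: np.ndarray, names: list[str],
                    tol: float = 1e-8, max_iter: int = 100) -> RegressionFit:
    """Maximise a Breslow-tie weighted Cox partial likelihood.

    ``W`` is (n_event_times, n): the weight of each subject in the risk set
    of each event time (0 when out of the risk set).  ``event_groups[k]``
    holds the row indices failing at event time k.
    """
    n, p = X.shape
    d_counts = np.array([len(g) for g in event_groups], dtype=float)
    x_event_sum = np.vstack([X[g].sum(axis=0) for g in event_groups])

    def evaluate(beta):
        eta = X @ beta
        eta = np.clip(eta, -500, 500)
        r = np.exp(eta)
        wr = W * r[None, :]
        denom = wr.sum(axis=1)
        s1 = wr @ X
        s2 = np.einsum("ti,ip,iq->tpq", wr, X, X)
        loglik = float(np.sum([eta[g].sum() for g in event_groups])
                       - np.sum(d_counts * np.log(denom)))
        mean = s1 / denom[:, None]
        score = (x_event_sum - d_counts[:, None] * mean).sum(axis=0)
        info = np.einsum("t,tpq->pq", d_counts, s2 / denom[:, None, None]) \
            - np.einsum("t,tp,tq->pq", d_counts, mean, mean)
        return loglik, score, info

    beta = np.zeros(p)
    loglik, score, info = evaluate(beta)
    converged, separation, it = False, False, 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            break
        new_beta = beta + step
        new_ll, new_score, new_info = evaluate(new_beta)
        halves = 0
        while new_ll < loglik - 1e-12 and halves < 30:  # step-halving
            step *= 0.5
            new_beta = beta + step
            new_ll, new_score, new_info = evaluate(new_beta)
            halves += 1
        beta, loglik, score, info = new_beta, new_ll, new_score, new_info
        if np.max(np.abs(beta)) > 10:
            separation = True
        if np.max(np.abs(score)) < tol:
            converged = True
            break
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    return RegressionFit(list(names), beta, se, loglik, converged, it,
                         separation=separation)


def _event_structure(times: np.ndarray, fail: np.ndarray):
    """Distinct failure times (ascending) and the row indices failing at each."""
    uniq = np.unique(times[fail])
    groups = [np.where(fail & (times == t))[0] for t in uniq]
    return uniq, groups


def cox_ph_fit(covariates, times, event_indicator,
               names: list[str] | None = None) -> RegressionFit:
    """Cox proportional-hazards fit (Breslow ties, Newton-Raphson).

    Convergence: max |score| < 1e-8, at most 100 iterations with
    step-halving; SEs from the inverse observed information.  Diverging
    coefficients (|beta| > 10) set the ``separation`` flag.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    times, events = _check_input(times, event_indicator)
    events = np.asarray(events, dtype=bool)
    _validate_design(X)
    names = names or [f"x{i}" for i in range(X.shape[1])]
    uniq, groups = _event_structure(times, events)
    if uniq.size == 0:
        raise ValueError("no events")
    W = (times[None, :] >= uniq[:, None]).astype(float)
    return _newton_raphson(X, groups, W, names)


def censoring_survival(times, status) -> SurvivalCurve:
    """Kaplan-Meier estimate of the censoring survivor function G(t).

    Censorings (status 0) are the 'events'; failures of any cause are
    censored.  Pooled (covariate-free), per the original Fine-Gray
    formulation.
    """
    status = np.asarray(status, dtype=int)
    return kaplan_meier(times, (status == 0).astype(int))


def fine_gray_fit(covariates, times, status,
                  names: list[str] | None = None) -> RegressionFit:
    """Fine-Gray subdistribution-hazard regression for cause 1.

    Subjects failing from the competing cause (status 2) remain in risk sets
    after their event time with IPCW weight ``G(t-)/G(T_i-)``; ``G`` is the
    pooled censoring-distribution KM.  Same Newton-Raphson contract as
    :func:`cox_ph_fit`; with zero competing events the weights collapse to
    risk-set indicators and the fit equals the Cox fit exactly.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    if X.shape[0] != len(times):
        X = X.T
    times, status = _check_input(times, status)
    status = status.astype(int)
    if not np.all(np.isin(status, (0, 1, 2))):
        raise ValueError("status must be coded 0/1/2")
    _validate_design(X)
    names = names or [f"x{i}" for i in range(X.shape[1])]
    fail1 = status == 1
    uniq, groups = _event_structure(times, fail1)
    if uniq.size == 0:
        raise ValueError("no cause-1 events")

    G = censoring_survival(times, status)
    g_at_t = np.array([G.at_minus(t) for t in uniq])  # G(t-) per event time
    g_at_T = np.array([G.at_minus(t) for t in times])  # G(T_i-)

    in_risk = times[None, :] >= uniq[:, None]
    W = in_risk.astype(float)
    competing = status == 2
    past_competing = competing[None, :] & (times[None, :] < uniq[:, None])
    with np.errstate(divide="ignore", invalid="ignore"):
        ipcw = g_at_t[:, None] / g_at_T[None, :]
    ipcw = np.where(np.isfinite(ipcw), ipcw, 0.0)
    W = np.where(past_competing, ipcw, W)
    return _newton_raphson(X, groups, W, names)


# --------------------------------------------------------------------------
# Classification of the dichotomised score
# --------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("cell counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


@dataclass
class ClassificationMetrics:
    """Sensitivity, specificity, PPV, NPV, accuracy — raw % floats and
    report-style integers (half away from zero); ``None`` marks an undefined
    (zero-denominator) metric."""

    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    accuracy: float | None

    def rounded(self) -> dict[str, int | None]:
        return {k: (None if v is None else _round_half_away(v))
                for k, v in self.__dict__.items()}


def classification_metrics(cm: ConfusionMatrix) -> ClassificationMetrics:
    """Standard 2x2 metrics as percentages (0-100)."""
    def pct(num, den):
        return None if den == 0 else 100.0 * num / den

    return ClassificationMetrics(
        sensitivity=pct(cm.tp, cm.tp + cm.fn),
        specificity=pct(cm.tn, cm.tn + cm.fp),
        ppv=pct(cm.tp, cm.tp + cm.fp),
        npv=pct(cm.tn, cm.tn + cm.fn),
        accuracy=pct(cm.tp + cm.tn, cm.n) if cm.n else None,
    )


def dichotomize_and_tabulate(categories, outcomes) -> ConfusionMatrix:
    """2x2 table for low-moderate vs high-very-high prediction of the event.

    Test-positive = category HIGH or VERY_HIGH; condition-positive = a
    composite event (status 1) over full follow-up.
    """
    cats = list(categories)
    outs = list(outcomes)
    if len(cats) != len(outs):
        raise ValueError("categories and outcomes length mismatch")
    tp = fp = fn = tn = 0
    for cat, out in zip(cats, outs):
        positive = RiskCategory(cat) >= RiskCategory.HIGH
        event = (out.status if hasattr(out, "status") else int(out)) == 1
        if positive and event:
            tp += 1
        elif positive:
            fp += 1
        elif event:
            fn += 1
        else:
            tn += 1
    return ConfusionMatrix(tp, fp, fn, tn)
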