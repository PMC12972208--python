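"""Survival machinery: Kaplan–Meier, log-rank, Cox PH, min-p cutoff scan, FDR.

The Cox partial likelihood is maximized by Newton–Raphson with Efron tie
handling (Breslow available), fully vectorized over tied event-time blocks
so that the thousands of single-covariate fits performed during weight
derivation and simulation studies stay cheap.  The log-rank machinery is
likewise vectorized over many candidate cutoffs at once, which is what
makes the minimum-p cutoff scan and its permutation correction tractable.

These estimators are implemented here rather than delegated because the
cutoff-optimization procedure needs batched access to their internals;
independent implementations (lifelines) are used as cross-check oracles in
the test-suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "km_estimate",
    "logrank_test",
    "LogrankResult",
    "fit_cox",
    "cox_score_test",
    "SurvivalFit",
    "ConvergenceError",
    "scan_cutoffs",
    "CutoffScanResult",
    "bh_adjust",
    "BHResult",
    "two_variable_cox",
]

Z_95 = 1.959964  # normal quantile for the fixed 95% Wald intervals


# ----------------------------------------------------------------------
# Kaplan–Meier
# ----------------------------------------------------------------------
def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns a step-function table with one row per distinct event time
    (plus the S(0)=1 anchor): columns ``time``, ``survival``,
    ``n_at_risk``, ``events``.  Censored-only times affect risk sets but
    add no step.  S is right-continuous.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("km_estimate needs at least one subject")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    order = np.argsort(times, kind="stable")
    t, e = times[order], events[order]
    uniq, start = np.unique(t, return_index=True)
    n_total = len(t)
    n_at_risk = n_total - start
    d = np.add.reduceat(e, start)
    mask = d > 0
    surv = np.cumprod(1.0 - d[mask] / n_at_risk[mask])
    rows = pd.DataFrame(
        {
            "time": np.concatenate([[0.0], uniq[mask]]),
            "survival": np.concatenate([[1.0], surv]),
            "n_at_risk": np.concatenate([[n_total], n_at_risk[mask]]),
            "events": np.concatenate([[0], d[mask]]),
        }
    )
    return rows


def km_median(km: pd.DataFrame) -> float:
    """Median survival time from a km_estimate table (inf if S stays > 0.5)."""
    below = km[km["survival"] <= 0.5]
    return float(below["time"].iloc[0]) if len(below) else float("inf")


# ----------------------------------------------------------------------
# Log-rank (vectorized over membership rows)
# ----------------------------------------------------------------------
def _sorted_event_blocks(times, events):
    """Sort descending by time; return order, block ends, per-block info."""
    order = np.argsort(-times, kind="stable")
    t, e = times[order], events[order]
    # block boundaries of tied times in descending order
    change = np.flatnonzero(np.diff(t) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(t) - 1]])
    n_at_risk = ends + 1  # at-risk = all with time >= block time (prefix)
    d = np.add.reduceat(e, starts)
    return order, e, starts, ends, n_at_risk, d


def _logrank_membership(times, events, membership):
    """1-df log-rank for each row of boolean ``membership`` (group 1 flags).

    Returns (chi2, p, O, E, V) arrays, one entry per membership row.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    order, e_s, starts, ends, n_risk, d = _sorted_event_blocks(times, events)
    M = np.ascontiguousarray(membership[:, order], dtype=float)

    n1 = np.cumsum(M, axis=1)[:, ends]  # group-1 at risk at each block
    d1c = np.cumsum(M * e_s[None, :], axis=1)[:, ends]
    d1 = np.diff(d1c, axis=1, prepend=0.0)  # group-1 events per block

    mask = d > 0
    n_b = n_risk[mask].astype(float)
    d_b = d[mask].astype(float)
    n1_b = n1[:, mask]
    d1_b = d1[:, mask]

    frac = n1_b / n_b
    O = d1_b.sum(axis=1)
    E = (d_b * frac).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_terms = d_b * frac * (1.0 - frac) * np.where(n_b > 1, (n_b - d_b) / (n_b - 1), 0.0)
    V = var_terms.sum(axis=1)
    chi2 = np.where(V > 0, (O - E) ** 2 / np.where(V > 0, V, 1.0), 0.0)
    p = np.where(V > 0, stats.chi2.sf(chi2, 1), 1.0)
    return chi2, p, O, E, V


@dataclass(frozen=True)
class LogrankResult:
    chi2: float
    p: float
    observed: float  # group-1 events
    expected: float  # group-1 expected events
    variance: float


def logrank_test(times, events, group) -> LogrankResult:
    """Two-group 1-df log-rank test; ``group`` is a binary indicator."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group).astype(bool)
    if times.shape != group.shape:
        raise ValueError("times and group must have equal length")
    if group.all() or (~group).all():
        raise ValueError("log-rank test needs two non-empty groups")
    if events.sum() < 1:
        raise ValueError("log-rank test needs at least one event")
    chi2, p, O, E, V = _logrank_membership(times, events, group[None, :])
    return LogrankResult(float(chi2[0]), float(p[0]), float(O[0]), float(E[0]), float(V[0]))


# ----------------------------------------------------------------------
# Cox proportional hazards (Efron / Breslow, Newton–Raphson)
# ----------------------------------------------------------------------
class ConvergenceError(RuntimeError):
    pass


@dataclass
class SurvivalFit:
    """Result of a Cox PH fit.

    ``table`` has one row per covariate: coef, se, hr, ci_low, ci_high, p.
    """

    table: pd.DataFrame
    loglik: float
    n: int
    n_events: int
    converged: bool
    n_iter: int
    ties: str
    flags: dict = field(default_factory=dict)

    @property
    def params(self) -> pd.Series:
        return self.table["coef"]

    @property
    def hazard_ratios(self) -> pd.Series:
        return self.table["hr"]

    def summary(self) -> pd.DataFrame:
        return self.table.copy()


def _cox_blocks(X, times, events):
    """Pre-sort data descending by time and expose tied-event blocks."""
    order = np.argsort(-times, kind="stable")
    Xs = np.ascontiguousarray(X[order])
    e_s = events[order].astype(float)
    t_s = times[order]
    change = np.flatnonzero(np.diff(t_s) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(t_s) - 1]])
    d = np.add.reduceat(e_s, starts)
    ev_mask = d > 0
    return Xs, e_s, starts[ev_mask], ends[ev_mask], d[ev_mask]


def _cox_derivs(beta, Xs, e_s, starts, ends, d, ties):
    """Log partial likelihood, gradient and Hessian at ``beta``.

    Data come pre-sorted descending in time (``_cox_blocks``); ``starts``,
    ``ends`` and ``d`` describe the tied blocks that contain events.
    Vectorized over the Efron within-block expansion.
    """
    n, p = Xs.shape
    eta = Xs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wx = w[:, None] * Xs
    wxx = wx[:, :, None] * Xs[:, None, :]

    c0 = np.cumsum(w)
    c1 = np.cumsum(wx, axis=0)
    c2 = np.cumsum(wxx.reshape(n, p * p), axis=0)

    S0 = c0[ends]
    S1 = c1[ends]
    S2 = c2[ends].reshape(-1, p, p)

    ew = e_s[:, None] * wx
    eww = e_s[:, None] * wxx.reshape(n, p * p)
    S0D = np.add.reduceat(e_s * w, starts)
    S1D = np.add.reduceat(ew, starts)
    S2D = np.add.reduceat(eww, starts).reshape(-1, p, p)

    d_int = d.astype(int)
    m = int(d_int.sum())
    rep = np.repeat(np.arange(len(d_int)), d_int)
    l = np.arange(m) - np.repeat(np.cumsum(d_int) - d_int, d_int)
    if ties == "efron":
        frac = l / np.repeat(d_int, d_int)
    elif ties == "breslow":
        frac = np.zeros(m)
    else:
        raise ValueError(f"unknown ties method {ties!r}")

    phi = S0[rep] - frac * S0D[rep]  # > 0 since frac < 1 and S0 >= S0D
    num1 = S1[rep] - frac[:, None] * S1D[rep]
    num2 = S2[rep] - frac[:, None, None] * S2D[rep]

    event_eta = float(eta @ e_s)
    loglik = event_eta - float(np.log(phi).sum())
    xbar = num1 / phi[:, None]
    grad = (e_s[:, None] * Xs).sum(axis=0) - xbar.sum(axis=0)
    hess = -(num2 / phi[:, None, None]).sum(axis=0) + np.einsum("ki,kj->ij", xbar, xbar)
    return loglik, grad, hess


def _prepare_design(design) -> tuple[np.ndarray, list[str]]:
    if isinstance(design, pd.DataFrame):
        names = [str(c) for c in design.columns]
        X = design.to_numpy(dtype=float)
    elif isinstance(design, pd.Series):
        names = [str(design.name) if design.name is not None else "x"]
        X = design.to_numpy(dtype=float)[:, None]
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"x{i}" for i in range(X.shape[1])]
    return X, names


def fit_cox(
    design,
    times,
    events,
    ties: str = "efron",
    max_iter: int = 100,
    tol: float = 1e-8,
) -> SurvivalFit:
    """Fit a Cox proportional-hazards model.

    Newton–Raphson on the partial likelihood (Efron ties by default) until
    the gradient norm drops below ``tol``.  Wald 95% CIs use the fixed
    normal quantile 1.959964.  A constant covariate raises (naming it);
    monotone likelihood (perfect separation) yields a flagged — never
    silent — result.
    """
    X, names = _prepare_design(design)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if not np.isfinite(X).all():
        raise ValueError("design matrix contains non-finite values")
    if len(times) != X.shape[0]:
        raise ValueError("design and times must have equal length")
    n_events = int(events.sum())
    if n_events < 1:
        raise ValueError("Cox fit needs at least one event")
    sds = X.std(axis=0)
    for j, sd in enumerate(sds):
        if sd == 0:
            raise ValueError(f"covariate {names[j]!r} is constant across subjects")

    Xs, e_s, starts, ends, d = _cox_blocks(X, times, events)
    beta = np.zeros(X.shape[1])
    loglik, grad, hess = _cox_derivs(beta, Xs, e_s, starts, ends, d, ties)
    flags: dict = {}
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if np.linalg.norm(grad) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:  # singular information
            raise ConvergenceError(f"singular information matrix at iteration {it}: {exc}")
        # step-halving to guarantee ascent
        for _ in range(40):
            cand = beta + step
            new_ll, new_grad, new_hess = _cox_derivs(cand, Xs, e_s, starts, ends, d, ties)
            if new_ll >= loglik - 1e-12:
                break
            step /= 2.0
        beta, loglik, grad, hess = cand, new_ll, new_grad, new_hess
        if np.abs(beta).max() > 12.0:
            flags["monotone_likelihood"] = True
            warnings.warn(
                "possible monotone partial likelihood (perfect separation); "
                "coefficients are unreliable",
                stacklevel=2,
            )
            break
    else:
        it = max_iter
    if not converged and np.linalg.norm(grad) < tol:
        converged = True
    if not converged and "monotone_likelihood" not in flags:
        raise ConvergenceError(
            f"Cox Newton–Raphson did not converge in {max_iter} iterations "
            f"(gradient norm {np.linalg.norm(grad):.3g}, beta {beta})"
        )

    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "hr": np.exp(beta),
            "ci_low": np.exp(beta - Z_95 * se),
            "ci_high": np.exp(beta + Z_95 * se),
            "p": pvals,
        },
        index=pd.Index(names, name="covariate"),
    )
    return SurvivalFit(
        table=table,
        loglik=float(loglik),
        n=int(len(times)),
        n_events=n_events,
        converged=converged,
        n_iter=it,
        ties=ties,
        flags=flags,
    )


def cox_score_test(design, times, events, ties: str = "efron") -> tuple[float, float]:
    """Score (Rao) test of beta = 0; equals the log-rank test for a binary
    covariate with untied event times."""
    X, _ = _prepare_design(design)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    Xs, e_s, starts, ends, d = _cox_blocks(X, times, events)
    _, grad, hess = _cox_derivs(np.zeros(X.shape[1]), Xs, e_s, starts, ends, d, ties)
    stat = float(grad @ np.linalg.solve(-hess, grad))
    return stat, float(stats.chi2.sf(stat, X.shape[1]))


# ----------------------------------------------------------------------
# IQR-restricted minimum-p cutoff scan
# ----------------------------------------------------------------------
@dataclass
class CutoffScanResult:
    """Outcome of the minimum-p dichotomization scan.

    ``p_selected`` is the *unadjusted* minimum log-rank p over the
    candidate cutoffs — the quantity cutoff-optimizing survival platforms
    display.  Because it is a minimum over ``n_candidates`` correlated
    tests it overstates significance under the null; ``p_permutation``
    (when requested) is a permutation-based selection-adjusted p.
    """

    candidates: np.ndarray
    pvalues: np.ndarray
    chi2: np.ndarray
    cutoff: float
    p_selected: float
    chi2_selected: float
    high_group: pd.Series  # sample -> bool (score > cutoff)
    n_high: int
    n_low: int
    cox: SurvivalFit
    km_high: pd.DataFrame
    km_low: pd.DataFrame
    n_candidates: int
    p_permutation: float | None = None
    multiplicity_note: str = ""

    @property
    def hazard_ratio(self) -> float:
        return float(self.cox.table["hr"].iloc[0])

    @property
    def conf_int(self) -> tuple[float, float]:
        row = self.cox.table.iloc[0]
        return float(row["ci_low"]), float(row["ci_high"])


def _candidate_cutoffs(score: np.ndarray, window: tuple[float, float], min_group: int):
    n = len(score)
    values = np.unique(score)
    q_lo, q_hi = np.quantile(score, window)  # candidates restricted to the IQR
    n_le = np.searchsorted(np.sort(score), values, side="right")
    n_high = n - n_le
    ok = (values >= q_lo) & (values <= q_hi) & (n_le >= min_group) & (n_high >= min_group)
    return values[ok]


def _min_p_scan(times, events, score, candidates):
    membership = score[None, :] > candidates[:, None]
    chi2, p, *_ = _logrank_membership(times, events, membership)
    i = int(np.argmin(p))  # ties -> first = smallest cutoff
    return chi2, p, i


def scan_cutoffs(
    score,
    times,
    events,
    window: tuple[float, float] = (0.25, 0.75),
    min_group: int = 5,
    n_permutations: int = 0,
    seed: int | None = None,
) -> CutoffScanResult:
    """Scan all distinct score values inside the IQR window and select the
    cutoff with the smallest log-rank p (ties break to the smallest
    cutoff).  Samples with score strictly greater than the cutoff form the
    "high" group.

    ``n_permutations > 0`` additionally computes a selection-adjusted p by
    re-running the scan on score permutations.
    """
    if isinstance(score, pd.Series):
        sample_index = score.index
        score_arr = score.to_numpy(dtype=float)
    else:
        score_arr = np.asarray(score, dtype=float)
        sample_index = pd.RangeIndex(len(score_arr))
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    n = len(score_arr)
    if n < 2 * min_group:
        raise ValueError(f"need at least {2 * min_group} samples, got {n}")

    candidates = _candidate_cutoffs(score_arr, window, min_group)
    if len(candidates) < 2:
        raise ValueError(
            f"fewer than 2 candidate cutoffs inside the {window} quantile window"
        )

    chi2, p, i = _min_p_scan(times, events, score_arr, candidates)
    cutoff = float(candidates[i])
    high = score_arr > cutoff

    cox = fit_cox(
        pd.DataFrame({"high": high.astype(float)}), times, events
    )
    km_high = km_estimate(times[high], events[high])
    km_low = km_estimate(times[~high], events[~high])

    p_perm = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(score_arr)
            _, pp, j = _min_p_scan(times, events, perm, _candidate_cutoffs(perm, window, min_group))
            if pp[j] <= p[i]:
                count += 1
        p_perm = (1 + count) / (n_permutations + 1)

    note = (
        f"selected p is the minimum over {len(candidates)} correlated log-rank "
        "tests and overstates significance under the null; see p_permutation "
        "for a selection-adjusted value"
    )
    return CutoffScanResult(
        candidates=candidates,
        pvalues=p,
        chi2=chi2,
        cutoff=cutoff,
        p_selected=float(p[i]),
        chi2_selected=float(chi2[i]),
        high_group=pd.Series(high, index=sample_index, name="high"),
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
        cox=cox,
        km_high=km_high,
        km_low=km_low,
        n_candidates=int(len(candidates)),
        p_permutation=p_perm,
        multiplicity_note=note,
    )


# ----------------------------------------------------------------------
# Benjamini–Hochberg
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class BHResult:
    qvalues: np.ndarray
    significant: np.ndarray
    fdr: float


def bh_adjust(pvals, fdr: float = 0.10) -> BHResult:
    """Benjamini–Hochberg step-up adjustment (q-values in input order).

    Significance is flagged at q < ``fdr`` (default 10%, the screening
    threshold used throughout this analysis).
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return BHResult(p.copy(), np.zeros(0, dtype=bool), fdr)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    _, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return BHResult(q, q < fdr, fdr)


# ----------------------------------------------------------------------
# Two-variable adjusted models
# ----------------------------------------------------------------------
_MISSING_TOKENS = {"missing", "na", "nan", ""}


def two_variable_cox(
    score,
    covariate,
    times,
    events,
    score_name: str = "signature",
    covariate_name: str | None = None,
) -> SurvivalFit:
    """Cox model of the signature term plus one clinical covariate.

    The fit uses exactly the samples with a non-missing covariate value
    (complete cases per model, maximizing n for each comparison).
    Categorical covariates enter as reference-coded indicators (reference
    = first category in sorted order); numeric covariates enter as-is.
    The signature term (first row of the result table) may be a continuous
    score or a high/low indicator.
    """
    score = pd.Series(np.asarray(score, dtype=float))
    covariate = pd.Series(covariate).reset_index(drop=True)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    name = covariate_name or (str(covariate.name) if covariate.name else "covariate")

    if covariate.dtype == object or isinstance(covariate.dtype, pd.CategoricalDtype):
        cov_str = covariate.astype(str)
        miss = covariate.isna() | cov_str.str.lower().isin(_MISSING_TOKENS)
    else:
        miss = covariate.isna()
    keep = (~miss) & score.notna() & np.isfinite(times) & np.isfinite(events)
    if not keep.any():
        raise ValueError(f"covariate {name!r} has no non-missing values")
    cov_kept = covariate[keep]
    if cov_kept.nunique() < 2:
        raise ValueError(f"covariate {name!r} has fewer than 2 levels among complete cases")
    if events[keep.to_numpy()].sum() < 1:
        raise ValueError(f"no events among complete cases for covariate {name!r}")

    if cov_kept.dtype == object or isinstance(cov_kept.dtype, pd.CategoricalDtype):
        levels = sorted(cov_kept.astype(str).unique())
        dummies = pd.get_dummies(
            pd.Categorical(cov_kept.astype(str), categories=levels), drop_first=True
        ).astype(float)
        dummies.columns = [f"{name}[{lvl}]" for lvl in levels[1:]]
        dummies.index = cov_kept.index
        design = pd.concat([score[keep].rename(score_name), dummies], axis=1)
    else:
        design = pd.DataFrame(
            {score_name: score[keep], name: cov_kept.astype(float)}
        )
    return fit_cox(design, times[keep.to_numpy()], events[keep.to_numpy()])
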