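"""Proportional-hazards partial-likelihood solvers.

A single Newton-Raphson engine backs every model fit in the updating ladder:

* cause-specific Cox regression (Efron or Breslow tie handling), with
  optional offset — needed for offset-style predictor addition and for
  linear-predictor slope recalibration;
* the Fine-Gray subdistribution-hazard model, in which subjects failing from
  the competing cause remain in the risk set with time-decaying
  inverse-probability-of-censoring weights G(t-)/G(T_i-).

Newton-Raphson uses step-halving and declares convergence when the largest
score component falls below ``tol`` (default 1e-7); non-convergence raises
with the achieved gradient norm.  The engine is deliberately independent of
lifelines so that lifelines can act as a cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimators import censoring_survival

__all__ = ["CoxFit", "ConvergenceError", "cox_newton_raphson", "fine_gray_newton_raphson"]


class ConvergenceError(RuntimeError):
    pass


@dataclass
class CoxFit:
    """Converged partial-likelihood fit."""

    beta: np.ndarray
    loglik: float
    score: np.ndarray
    information: np.ndarray
    n_iter: int
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray

    def baseline_survival(self, t: float) -> float:
        idx = np.searchsorted(self.baseline_times, t, side="right")
        cum = 0.0 if idx == 0 else self.baseline_cumhaz[idx - 1]
        return float(np.exp(-cum))

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(np.linalg.inv(self.information)))


def _group_event_times(times_sorted, flags_sorted):
    """Indices of tied event groups and risk-set start indices (sorted data)."""
    event_idx = np.flatnonzero(flags_sorted > 0)
    etimes, first = np.unique(times_sorted[event_idx], return_index=True)
    groups = np.split(event_idx, np.searchsorted(times_sorted[event_idx], etimes[1:]))
    starts = np.searchsorted(times_sorted, etimes, side="left")
    return etimes, groups, starts


def _cox_quantities(X, times, flags, beta, offset, ties):
    n, p = X.shape
    eta = X @ beta + offset
    shift = eta.mean()  # partial likelihood invariant to constant shifts
    eta = eta - shift
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]

    etimes, groups, starts = _group_event_times(times, flags)
    event_rows = np.flatnonzero(flags > 0)
    d_k = np.array([g.size for g in groups], dtype=float)
    R0 = S0[starts]
    R1 = S1[starts]
    R2 = S2[starts]
    loglik = float(eta[event_rows].sum())
    score = X[event_rows].sum(axis=0)
    info = np.zeros((p, p))
    # vectorised Breslow-type contributions for untied times (d == 1)
    simple = d_k == 1.0 if ties == "efron" else np.ones_like(d_k, dtype=bool)
    if simple.any():
        r0 = R0[simple]
        r1 = R1[simple]
        r2 = R2[simple]
        dd = d_k[simple]
        loglik -= float(np.sum(dd * np.log(r0)))
        score -= (dd[:, None] * r1 / r0[:, None]).sum(axis=0)
        u = r1 / r0[:, None]
        info += np.einsum("k,kij->ij", dd, r2 / r0[:, None, None])
        info -= np.einsum("k,ki,kj->ij", dd, u, u)
    if ties == "efron":
        for k in np.flatnonzero(~simple):
            grp, d = groups[k], int(d_k[k])
            D0 = w[grp].sum()
            D1 = wx[grp].sum(axis=0)
            D2 = wxx[grp].sum(axis=0)
            for ell in range(d):
                phi = ell / d
                r0 = R0[k] - phi * D0
                r1 = R1[k] - phi * D1
                r2 = R2[k] - phi * D2
                loglik -= np.log(r0)
                score -= r1 / r0
                info += r2 / r0 - np.outer(r1, r1) / r0**2
    cumhaz = d_k / R0  # Breslow baseline irrespective of tie method
    # undo the stabilising shift so the baseline matches the raw LP scale
    return loglik, score, info, etimes, np.cumsum(cumhaz) * np.exp(-shift)


def cox_newton_raphson(
    X,
    times,
    event_flags,
    offset=None,
    ties: str = "efron",
    tol: float = 1e-7,
    max_iter: int = 50,
    init=None,
):
    """Maximise the Cox partial likelihood by Newton-Raphson with step-halving.

    ``event_flags`` is 1 for the primary event, 0 otherwise (competing deaths
    must already be coded 0 for a cause-specific fit).  The returned baseline
    cumulative hazard is the Breslow estimator at ``beta``; the offset is
    treated as part of the linear predictor (its exp() enters the risk sets)
    but the baseline is reported on the offset-included scale.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(times).size > 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags).astype(int)
    n, p = X.shape
    if flags.sum() == 0:
        raise ValueError("no events of the primary cause; cannot fit")
    if offset is None:
        offset = np.zeros(n)
    offset = np.asarray(offset, dtype=float)
    order = np.argsort(times, kind="mergesort")
    Xs, ts, fs, offs = X[order], times[order], flags[order], offset[order]

    const = [j for j in range(p) if np.ptp(Xs[:, j]) == 0]
    if const:
        raise ValueError(f"constant predictor column(s) {const}; unidentifiable")

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    loglik, score, info, bt, bh = _cox_quantities(Xs, ts, fs, beta, offs, ties)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            return CoxFit(beta, loglik, score, info, it - 1, bt, bh)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(
                f"singular information matrix (possible separation); "
                f"gradient norm {np.max(np.abs(score)):.3g}"
            ) from exc
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll, sc, inf, bt, bh = _cox_quantities(Xs, ts, fs, cand, offs, ties)
            if ll >= loglik - 1e-12 or not np.isfinite(loglik):
                break
            step /= 2.0
        if np.max(np.abs(cand)) > 50:
            raise ConvergenceError(
                "coefficients diverging (|beta| > 50); likely separation"
            )
        beta, loglik, score, info = cand, ll, sc, inf
    if np.max(np.abs(score)) < tol * 100:
        return CoxFit(beta, loglik, score, info, max_iter, bt, bh)
    raise ConvergenceError(
        f"Newton-Raphson did not converge in {max_iter} iterations; "
        f"max |score| = {np.max(np.abs(score)):.3g}"
    )


# -- Fine-Gray ---------------------------------------------------------------


def _fg_quantities(X, times, codes, beta, g_at_comp, G):
    """Weighted partial-likelihood quantities for the subdistribution model.

    Risk set at a primary-event time t: subjects still under observation
    (T_j >= t) with weight 1, plus subjects who failed from the competing
    cause at T_j < t with weight G(t-)/G(T_j-).
    """
    n, p = X.shape
    eta = X @ beta
    shift = eta.mean()
    eta = eta - shift
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = wx[:, :, None] * X[:, None, :]
    # natural (still-observed) part: suffix sums over all subjects
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wx[::-1], axis=0)[::-1]
    S2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    # competing part: prefix sums of w/G(T-) over competing-event subjects
    comp = codes == 2
    u = np.zeros(n)
    u[comp] = w[comp] / g_at_comp[comp]
    ux = u[:, None] * X
    uxx = ux[:, :, None] * X[:, None, :]
    P0 = np.concatenate(([0.0], np.cumsum(u)))
    P1 = np.concatenate((np.zeros((1, p)), np.cumsum(ux, axis=0)))
    P2 = np.concatenate((np.zeros((1, p, p)), np.cumsum(uxx, axis=0)))

    flags = (codes == 1).astype(int)
    etimes, groups, starts = _group_event_times(times, flags)
    g_minus = G.left_limit(etimes)
    # competing subjects with T_j < t_k: prefix index
    before = np.searchsorted(times, etimes, side="left")
    event_rows = np.flatnonzero(flags > 0)
    d_k = np.array([g.size for g in groups], dtype=float)
    R0 = S0[starts] + g_minus * P0[before]
    R1 = S1[starts] + g_minus[:, None] * P1[before]
    R2 = S2[starts] + g_minus[:, None, None] * P2[before]
    loglik = float(eta[event_rows].sum() - np.sum(d_k * np.log(R0)))
    score = X[event_rows].sum(axis=0) - (d_k[:, None] * R1 / R0[:, None]).sum(axis=0)
    u = R1 / R0[:, None]
    info = np.einsum("k,kij->ij", d_k, R2 / R0[:, None, None])
    info -= np.einsum("k,ki,kj->ij", d_k, u, u)
    cumhaz = d_k / R0
    return loglik, score, info, etimes, np.cumsum(cumhaz) * np.exp(-shift)


def fine_gray_newton_raphson(
    X,
    times,
    event_codes,
    tol: float = 1e-7,
    max_iter: int = 50,
    init=None,
):
    """Maximise the Fine-Gray weighted partial likelihood (Breslow ties).

    ``event_codes``: 0 censored, 1 primary event, 2 competing event.  The
    censoring distribution G is the overall Kaplan-Meier of censoring,
    evaluated with left limits.  With no competing events and no censoring
    this reduces exactly to the Cox partial likelihood.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(times).size > 1:
        X = X.T
    times = np.asarray(times, dtype=float)
    codes = np.asarray(event_codes).astype(int)
    n, p = X.shape
    if (codes == 1).sum() == 0:
        raise ValueError("no primary-cause events; cannot fit")
    order = np.argsort(times, kind="mergesort")
    Xs, ts, cs = X[order], times[order], codes[order]
    G = censoring_survival(ts, (cs > 0).astype(int))
    g_at_comp = G.left_limit(ts)
    if np.any((cs == 2) & (g_at_comp <= 0)):
        raise ValueError("censoring survival G reaches 0 before a competing event")

    beta = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    loglik, score, info, bt, bh = _fg_quantities(Xs, ts, cs, beta, g_at_comp, G)
    for it in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol:
            return CoxFit(beta, loglik, score, info, it - 1, bt, bh)
        try:
            delta = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError("singular information matrix") from exc
        step = 1.0
        for _ in range(30):
            cand = beta + step * delta
            ll, sc, inf, bt, bh = _fg_quantities(Xs, ts, cs, cand, g_at_comp, G)
            if ll >= loglik - 1e-12 or not np.isfinite(loglik):
                break
            step /= 2.0
        if np.max(np.abs(cand)) > 50:
            raise ConvergenceError("coefficients diverging; likely separation")
        beta, loglik, score, info = cand, ll, sc, inf
    if np.max(np.abs(score)) < tol * 100:
        return CoxFit(beta, loglik, score, info, max_iter, bt, bh)
    raise ConvergenceError(
        f"Fine-Gray Newton-Raphson did not converge; "
        f"max |score| = {np.max(np.abs(score)):.3g}"
    )
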