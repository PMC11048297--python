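"""Beta-binomial likelihood, maximum-likelihood fitting, and the two-group
likelihood-ratio test for differential RNA editing.

Model
-----
At one site, the edited-read count ``k`` of a sample with coverage ``n`` is
beta-binomial: ``p ~ Beta(alpha, beta)``, ``k | p ~ Binomial(n, p)``.  The
editing level of the population is the beta mean ``mu = alpha/(alpha+beta)``;
the concentration ``phi = alpha + beta`` controls overdispersion (the
equivalent overdispersion parameter is ``rho = 1/(1+phi)``).  Coverage varies
freely across samples — nothing assumes equal totals.

The differential test compares a null with one shared (alpha, beta) across
both sample groups against an alternative with independent per-group pairs;
``2 * (loglik_alt - loglik_null)`` is referred to a chi-square with 2 degrees
of freedom (two extra free parameters under the alternative).

With the small group sizes typical of cell-line panels (5-10 samples per
arm) the raw statistic is stochastically larger than its chi-square limit —
the per-group concentration parameters are weakly identified and the
alternative chases noise in them.  The default test therefore calibrates
the p-value by parametric bootstrap: the fitted null model is simulated at
the observed coverages, and the observed statistic is referred to the
bootstrap LLR distribution through a linearly interpolated empirical
survival function, extended beyond the bootstrap maximum by a
moment-matched gamma tail so that extreme statistics still map to
arbitrarily small p-values.  The bootstrap seed is derived from the data,
so results are deterministic and invariant to sample order and group
relabeling.  ``correction="bartlett"`` rescales the statistic by
``df / E0[LLR]`` and uses the chi-square tail; ``correction="none"`` is the
plain asymptotic test.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, digamma, gammaln
from scipy.stats import chi2


def _trigamma(x: np.ndarray) -> np.ndarray:
    """Vectorized trigamma via upward recurrence + asymptotic series.

    Accurate to ~1e-9 for x > 0; much faster than scipy's polygamma, which
    dominates the batched Newton iterations otherwise.
    """
    x = np.array(x, dtype=float, copy=True)
    out = np.zeros_like(x)
    for _ in range(6):  # shift to x >= 6 where the series converges fast
        m = x < 6.0
        if not m.any():
            break
        out[m] += 1.0 / (x[m] * x[m])
        x[m] += 1.0
    z = 1.0 / x
    z2 = z * z
    out += z + 0.5 * z2 + z * z2 * (1.0 / 6.0 - z2 * (1.0 / 30.0 - z2 * (1.0 / 42.0 - z2 / 30.0)))
    return out

__all__ = ["BetaBinFit", "LLRResult", "bb_loglik", "fit_beta_binomial", "redit_llr_test"]

_LOGIT_BOUND = 15.0
_LOGPHI_BOUNDS = (-6.0, math.log(1e4))
#: bootstrap Bartlett factors are clipped to this range for robustness
_SCALE_CLIP = (1.0 / 3.0, 3.0)


@dataclass(frozen=True)
class BetaBinFit:
    """A fitted beta-binomial: shapes, mean alpha/(alpha+beta), and the
    log-likelihood attained on the fitting data."""

    alpha: float
    beta: float
    loglik: float
    converged: bool = True
    boundary: bool = False

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def concentration(self) -> float:
        return self.alpha + self.beta


@dataclass(frozen=True)
class LLRResult:
    llr: float
    pvalue: float
    fit_g1: BetaBinFit
    fit_g2: BetaBinFit
    fit_null: BetaBinFit
    df: int = 2
    bartlett_scale: float = 1.0


def _as_counts(cells) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(cells, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("cells must be a sequence of (alt, total) pairs")
    k, n = arr[:, 0], arr[:, 1]
    if np.any(n < k) or np.any(k < 0):
        raise ValueError("cells require total >= alt >= 0")
    return k, n


def bb_loglik(alpha: float, beta: float, cells) -> float:
    """Log-likelihood (nats) of (alt, total) cells under BetaBin(alpha, beta).

    Computed with log-gamma throughout:
    ``sum_i logC(n_i, k_i) + betaln(k_i+alpha, n_i-k_i+beta) - betaln(alpha, beta)``.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("shape parameters must be positive")
    k, n = _as_counts(cells)
    log_choose = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    return float(
        np.sum(log_choose + betaln(k + alpha, n - k + beta) - betaln(alpha, beta))
    )


def _nll_grad(theta: np.ndarray, k: np.ndarray, n: np.ndarray) -> tuple[float, np.ndarray]:
    """Negative log-likelihood and gradient in (logit mu, log phi) coordinates.

    The log-choose term is constant in the parameters and omitted here; the
    public ``bb_loglik`` includes it.
    """
    mu = 1.0 / (1.0 + math.exp(-theta[0]))
    phi = math.exp(theta[1])
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = float(np.sum(betaln(k + a, n - k + b)) - k.size * betaln(a, b))
    # d(ll)/d(a), d(ll)/d(b) via digamma, then chain rule to theta
    dpsi_sum = digamma(n + phi)
    dll_da = float(np.sum(digamma(k + a) - dpsi_sum) - k.size * (digamma(a) - digamma(phi)))
    dll_db = float(np.sum(digamma(n - k + b) - dpsi_sum) - k.size * (digamma(b) - digamma(phi)))
    g_logit = mu * (1.0 - mu) * phi * (dll_da - dll_db)
    g_logphi = a * dll_da + b * dll_db
    return -ll, np.array([-g_logit, -g_logphi])


def _moment_init(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Method-of-moments starting point in (logit mu, log phi)."""
    mu = float(np.sum(k) / np.sum(n))
    mu = min(max(mu, 1e-4), 1 - 1e-4)
    p = k / n
    s2 = float(np.var(p, ddof=1)) if p.size > 1 else 0.0
    inv_n = float(np.mean(1.0 / n))
    denom = mu * (1.0 - mu)
    rho = 0.0
    if denom > 0 and s2 > 0:
        rho = (s2 / denom - inv_n) / (1.0 - inv_n) if inv_n < 1 else 0.0
    rho = min(max(rho, 1e-3), 0.9)
    phi = (1.0 - rho) / rho
    return np.array([math.log(mu / (1.0 - mu)), math.log(phi)])


def fit_beta_binomial(cells, max_restarts: int = 3) -> BetaBinFit:
    """Maximum-likelihood beta-binomial fit to (alt, total) cells.

    Optimizes in unconstrained (logit mu, log phi) coordinates with an
    analytic gradient (L-BFGS-B, projected-gradient tolerance 1e-6),
    initialized from method-of-moments estimates with jittered restarts on
    non-convergence.  Cells with zero total must be excluded by the caller.

    Data entirely at a boundary (all alt 0, or all alt == total) have their
    likelihood supremum at mu -> 0 (resp. 1); a boundary fit is returned with
    loglik 0 and a representative near-boundary mean.
    """
    k, n = _as_counts(cells)
    if k.size == 0 or np.all(n == 0):
        raise ValueError("need at least one cell with positive total")
    keep = n > 0
    k, n = k[keep], n[keep]

    if np.all(k == 0) or np.all(k == n):
        # supremum at the boundary: P -> 1 for every cell, loglik -> 0
        frac = 0.5 / (float(np.sum(n)) + 1.0)
        mean = frac if np.all(k == 0) else 1.0 - frac
        return BetaBinFit(alpha=mean, beta=1.0 - mean, loglik=0.0, boundary=True)

    x0 = _moment_init(k, n)
    bounds = [(-_LOGIT_BOUND, _LOGIT_BOUND), _LOGPHI_BOUNDS]
    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(0.0, 0.5 * attempt, size=2)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            _nll_grad,
            start,
            args=(k, n),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun:
            best = res
        if res.success:
            break

    mu = 1.0 / (1.0 + math.exp(-best.x[0]))
    phi = math.exp(best.x[1])
    ll = bb_loglik(mu * phi, (1.0 - mu) * phi, np.column_stack([k, n]))
    at_bound = bool(
        abs(best.x[0]) >= _LOGIT_BOUND - 1e-6
        or best.x[1] <= _LOGPHI_BOUNDS[0] + 1e-6
        or best.x[1] >= _LOGPHI_BOUNDS[1] - 1e-6
    )
    return BetaBinFit(
        alpha=mu * phi,
        beta=(1.0 - mu) * phi,
        loglik=ll,
        converged=bool(best.success),
        boundary=at_bound,
    )


def _raw_llr(k1, n1, k2, n2) -> tuple[float, BetaBinFit, BetaBinFit, BetaBinFit]:
    fit1 = fit_beta_binomial(np.column_stack([k1, n1]))
    fit2 = fit_beta_binomial(np.column_stack([k2, n2]))
    pooled = np.column_stack([np.concatenate([k1, k2]), np.concatenate([n1, n2])])
    fit0 = fit_beta_binomial(pooled)
    return max(0.0, 2.0 * (fit1.loglik + fit2.loglik - fit0.loglik)), fit1, fit2, fit0


def _data_seed(k1, n1, k2, n2) -> int:
    """Deterministic bootstrap seed, invariant to group order and sample order."""
    blocks = sorted(
        np.ascontiguousarray(np.sort(np.column_stack([k, n]), axis=0), dtype=np.int64).tobytes()
        for k, n in ((k1, n1), (k2, n2))
    )
    return zlib.crc32(b"".join(blocks)) % 2**31


def _stacked_nll_grad(theta_flat: np.ndarray, K: np.ndarray, n: np.ndarray):
    """Summed NLL and gradient for B independent fits sharing coverages ``n``.

    ``theta_flat`` is (B, 2) flattened; ``K`` is (B, m) counts.  Because the
    objective is separable across rows, minimizing the sum fits every row at
    once with fully vectorized numpy ops.
    """
    theta = theta_flat.reshape(-1, 2)
    mu = 1.0 / (1.0 + np.exp(-theta[:, 0]))
    phi = np.exp(theta[:, 1])
    a = (mu * phi)[:, None]
    b = ((1.0 - mu) * phi)[:, None]
    m = K.shape[1]
    ll_rows = np.sum(betaln(K + a, n[None, :] - K + b), axis=1) - m * betaln(a[:, 0], b[:, 0])
    dpsi_sum = digamma(n[None, :] + phi[:, None])
    dll_da = np.sum(digamma(K + a) - dpsi_sum, axis=1) - m * (digamma(a[:, 0]) - digamma(phi))
    dll_db = np.sum(digamma(n[None, :] - K + b) - dpsi_sum, axis=1) - m * (
        digamma(b[:, 0]) - digamma(phi)
    )
    g1 = mu * (1.0 - mu) * phi * (dll_da - dll_db)
    g2 = a[:, 0] * dll_da + b[:, 0] * dll_db
    grad = np.column_stack([-g1, -g2]).ravel()
    return -float(np.sum(ll_rows)), grad


def _rows_ll(theta: np.ndarray, K: np.ndarray, n: np.ndarray) -> np.ndarray:
    mu = 1.0 / (1.0 + np.exp(-theta[:, 0]))
    phi = np.exp(theta[:, 1])
    a = (mu * phi)[:, None]
    b = ((1.0 - mu) * phi)[:, None]
    return np.sum(betaln(K + a, n[None, :] - K + b), axis=1) - K.shape[1] * betaln(
        a[:, 0], b[:, 0]
    )


def _rows_grad_hess(theta: np.ndarray, K: np.ndarray, n: np.ndarray):
    """Row-wise gradient and Hessian of the log-likelihood in theta space."""
    mu = 1.0 / (1.0 + np.exp(-theta[:, 0]))
    phi = np.exp(theta[:, 1])
    a, b = mu * phi, (1.0 - mu) * phi
    m = K.shape[1]
    ac, bc, nn = a[:, None], b[:, None], n[None, :]
    psi_sum = digamma(nn + phi[:, None])
    tri_sum = _trigamma(nn + phi[:, None])
    ll_a = np.sum(digamma(K + ac) - psi_sum, axis=1) - m * (digamma(a) - digamma(phi))
    ll_b = np.sum(digamma(nn - K + bc) - psi_sum, axis=1) - m * (digamma(b) - digamma(phi))
    tri_phi = _trigamma(phi)
    ll_aa = np.sum(_trigamma(K + ac) - tri_sum, axis=1) - m * (_trigamma(a) - tri_phi)
    ll_bb = np.sum(_trigamma(nn - K + bc) - tri_sum, axis=1) - m * (_trigamma(b) - tri_phi)
    ll_ab = -np.sum(tri_sum, axis=1) + m * tri_phi
    w = mu * (1.0 - mu) * phi
    g1 = w * (ll_a - ll_b)
    g2 = a * ll_a + b * ll_b
    h11 = w * w * (ll_aa - 2 * ll_ab + ll_bb) + phi * mu * (1 - mu) * (1 - 2 * mu) * (
        ll_a - ll_b
    )
    h12 = g1 + w * (a * ll_aa - b * ll_bb + (b - a) * ll_ab)
    h22 = g2 + a * a * ll_aa + 2 * a * b * ll_ab + b * b * ll_bb
    return np.column_stack([g1, g2]), h11, h12, h22


_THETA_LO = np.array([-_LOGIT_BOUND, _LOGPHI_BOUNDS[0]])
_THETA_HI = np.array([_LOGIT_BOUND, _LOGPHI_BOUNDS[1]])


def _batched_max_ll(
    K: np.ndarray, n: np.ndarray, max_iter: int = 40, tol: float = 1e-4
) -> np.ndarray:
    """Row-wise maximized beta-binomial log-likelihood (log-choose omitted).

    Damped projected Newton, fully vectorized across rows: each iteration
    solves every row's 2x2 Newton system, falls back to a capped gradient
    step where the Hessian is not negative definite, and backtracks rows
    whose likelihood did not improve.  Accuracy here only needs to resolve a
    Monte-Carlo mean, so the tolerance is loose.
    """
    B = K.shape[0]
    ksum = K.sum(axis=1)
    # rows with every count at a boundary have their supremum at mu -> 0/1
    # with loglik exactly 0 (all-zero or all-total data); solved directly
    degenerate = (ksum == 0) | (ksum == float(n.sum()))
    mu0 = np.clip(ksum / float(n.sum()), 1e-4, 1 - 1e-4)
    theta = np.column_stack([np.log(mu0 / (1 - mu0)), np.full(B, math.log(10.0))])
    ll = _rows_ll(theta, K, n)
    ll[degenerate] = 0.0
    converged = degenerate.copy()
    for _ in range(max_iter):
        g, h11, h12, h22 = _rows_grad_hess(theta, K, n)
        at_lo = theta <= _THETA_LO + 1e-9
        at_hi = theta >= _THETA_HI - 1e-9
        # coordinates pinned at a bound with the gradient pointing outward
        pinned = (at_lo & (g < 0)) | (at_hi & (g > 0))
        pg = np.where(pinned, 0.0, g)
        active = ~converged & (np.max(np.abs(pg), axis=1) > tol)
        if not active.any():
            break
        det = h11 * h22 - h12 * h12
        newton_ok = (h11 < 0) & (det > 0)  # negative definite => interior max
        with np.errstate(divide="ignore", invalid="ignore"):
            d1 = -(h22 * g[:, 0] - h12 * g[:, 1]) / det
            d2 = -(-h12 * g[:, 0] + h11 * g[:, 1]) / det
            # 1-D Newton along each coordinate (used when the other is pinned)
            d1_only = np.where(h11 < 0, -g[:, 0] / h11, np.clip(g[:, 0], -1.0, 1.0))
            d2_only = np.where(h22 < 0, -g[:, 1] / h22, np.clip(g[:, 1], -1.0, 1.0))
        step = np.column_stack([d1, d2])
        gnorm = np.linalg.norm(g, axis=1, keepdims=True)
        step = np.where(newton_ok[:, None], step, g / np.maximum(gnorm, 1.0))
        # active-set override: zero the pinned coordinate, 1-D Newton the other
        step[:, 0] = np.where(pinned[:, 1], d1_only, step[:, 0])
        step[:, 1] = np.where(pinned[:, 0], d2_only, step[:, 1])
        step = np.where(pinned, 0.0, step)
        t = np.where(active, 1.0, 0.0)
        for _bt in range(12):
            trial = np.clip(theta + t[:, None] * step, _THETA_LO, _THETA_HI)
            ll_new = _rows_ll(trial, K, n)
            improved = ll_new >= ll - 1e-12
            accept = active & improved
            theta[accept] = trial[accept]
            ll[accept] = ll_new[accept]
            active = active & ~improved
            if not active.any():
                break
            t = np.where(active, t * 0.5, t)
    ll[degenerate] = 0.0
    return ll


def _bootstrap_null_llrs(fit0: BetaBinFit, n1, n2, n_boot: int, seed: int) -> np.ndarray:
    """Raw LLRs of ``n_boot`` datasets simulated from the fitted null at the
    observed coverages (all refits batched into vectorized optimizations)."""
    rng = np.random.default_rng(seed)
    a, b = fit0.alpha, fit0.beta
    # canonical coverage order => the sample is invariant to sample order
    # and to group relabeling (the LLR itself is symmetric in the groups)
    n1, n2 = np.sort(n1), np.sort(n2)
    if (n1.size, float(n1.sum())) > (n2.size, float(n2.sum())):
        n1, n2 = n2, n1
    p1 = rng.beta(a, b, size=(n_boot, n1.size))
    p2 = rng.beta(a, b, size=(n_boot, n2.size))
    K1 = rng.binomial(n1.astype(int)[None, :], p1)
    K2 = rng.binomial(n2.astype(int)[None, :], p2)
    ll1 = _batched_max_ll(K1, n1.astype(float))
    ll2 = _batched_max_ll(K2, n2.astype(float))
    ll0 = _batched_max_ll(np.concatenate([K1, K2], axis=1), np.concatenate([n1, n2]).astype(float))
    return np.maximum(0.0, 2.0 * (ll1 + ll2 - ll0))


def _bootstrap_pvalue(llr: float, null_llrs: np.ndarray) -> float:
    """Smoothed parametric-bootstrap p-value.

    Within the bootstrap range: linear interpolation through the points
    ``(L_(j), (B+1-j)/(B+1))`` of the sorted null sample (and ``(0, 1)``),
    i.e. a continuous version of the usual ``(1 + #{L >= llr})/(B+1)`` rank
    p-value.  Beyond the bootstrap maximum: the empirical minimum
    ``1/(B+1)`` is extended by the tail ratio of a gamma distribution
    moment-matched to the null sample, so that very large statistics keep
    shrinking the p-value instead of saturating.
    """
    B = null_llrs.size
    ls = np.sort(null_llrs)
    if llr <= ls[-1]:
        xs = np.concatenate([[0.0], ls])
        ps = np.concatenate([[1.0], (B - np.arange(B)) / (B + 1.0)])
        return float(np.interp(llr, xs, ps))
    mean = float(np.mean(null_llrs))
    var = float(np.var(null_llrs, ddof=1))
    if mean <= 0 or var <= 0:
        return 1.0 / (B + 1.0)
    shape = np.clip(mean * mean / var, 0.1, 10.0)
    scale = mean / shape
    tail_at_max = float(chi2.sf(2 * ls[-1] / scale, 2 * shape))  # gamma via chi2 form
    tail_at_llr = float(chi2.sf(2 * llr / scale, 2 * shape))
    ratio = tail_at_llr / tail_at_max if tail_at_max > 0 else 0.0
    return max(float(np.clip(ratio, 0.0, 1.0)) / (B + 1.0), 1e-300)


def _bartlett_scale(null_llrs: np.ndarray, df: int) -> float:
    """Bartlett factor ``df / E0[LLR]`` from a bootstrap null sample, clipped
    for robustness against degenerate draws."""
    mean_llr = float(np.mean(null_llrs))
    if mean_llr <= 0:
        return 1.0
    return float(np.clip(df / mean_llr, *_SCALE_CLIP))


def redit_llr_test(
    cells_g1,
    cells_g2,
    df: int = 2,
    correction: str = "bootstrap",
    n_boot: int = 100,
) -> LLRResult:
    """Two-group beta-binomial likelihood-ratio test of differential editing.

    Null: one BetaBin(alpha, beta) fit on the pooled cells (2 parameters).
    Alternative: independent fits per group (4 parameters).
    ``llr = 2 * (ll_g1 + ll_g2 - ll_null)`` clamped at zero.

    The p-value is calibrated per ``correction`` (see module docstring):
    ``"bootstrap"`` (default) refers the statistic to a smoothed parametric
    bootstrap of the fitted null with a gamma tail; ``"bartlett"`` rescales
    by the bootstrap Bartlett factor and uses the chi-square(``df``) tail;
    ``"none"`` is the plain chi-square(``df``) asymptotic test.  The
    reported ``llr`` is always the raw statistic.
    """
    if correction not in ("bootstrap", "bartlett", "none"):
        raise ValueError(
            f"correction must be 'bootstrap', 'bartlett' or 'none', got {correction!r}"
        )
    k1, n1 = _as_counts(cells_g1)
    k2, n2 = _as_counts(cells_g2)
    if np.count_nonzero(n1 > 0) < 2 or np.count_nonzero(n2 > 0) < 2:
        raise ValueError("each group needs at least two cells with coverage")
    llr, fit1, fit2, fit0 = _raw_llr(k1, n1, k2, n2)
    scale = 1.0
    if llr <= 0:
        pvalue = 1.0
    elif correction == "none" or fit0.boundary:
        pvalue = float(chi2.sf(llr, df))
    else:
        null_llrs = _bootstrap_null_llrs(fit0, n1, n2, n_boot, _data_seed(k1, n1, k2, n2))
        if correction == "bootstrap":
            pvalue = _bootstrap_pvalue(llr, null_llrs)
        else:
            scale = _bartlett_scale(null_llrs, df)
            pvalue = float(chi2.sf(llr * scale, df))
    return LLRResult(
        llr=llr, pvalue=pvalue, fit_g1=fit1, fit_g2=fit2, fit_null=fit0,
        df=df, bartlett_scale=scale,
    )
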