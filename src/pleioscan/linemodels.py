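"""Two-group Bayesian line-model classification of bivariate effect sizes.

Given per-variant effect estimates on two traits, (beta_1, se_1) and
(beta_2, se_2) on the sqrt-heritability scale, each mixture component
("line group") places a bivariate normal prior on the TRUE effects that
concentrates around a line through the origin:

* slope s   — the multiplicative relation between the two effects;
* scale tau — prior standard deviation of effect magnitude along the line;
* correlation rho — tightness around the line (rho -> 1 pins effects to it).

With unit vectors u = (1, s)/sqrt(1+s^2) along the line and
v = (-s, 1)/sqrt(1+s^2) across it, the prior covariance is

    Sigma_g = tau^2 [ (1+rho) u u^T + (1-rho) v v^T ],

so that at slope 1 the coordinate correlation of the prior equals rho.
The observed pair is the true pair plus independent Gaussian noise with
the reported standard errors, giving the marginal likelihood
N(b_hat; 0, Sigma_g + diag(se_1^2, se_2^2)) per component.

Mixture proportions and any free slopes are fitted by EM (slopes via
bounded 1-D maximisation on the angle scale); group memberships are then
sampled with a Gibbs sampler alternating variant assignments and a
Dirichlet draw of the proportions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

logger = logging.getLogger(__name__)

_MAX_ANGLE = math.radians(89.9)


@dataclass(frozen=True)
class LineGroup:
    """Prior component: a line through the origin in effect-size space."""

    slope: float
    scale: float
    correlation: float = 0.99
    slope_free: bool = False
    label: str = ""

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError(f"scale must be > 0, got {self.scale}")
        if not 0 <= self.correlation < 1:
            raise ValueError(f"correlation must be in [0, 1), got {self.correlation}")


def group_covariance(group: LineGroup) -> np.ndarray:
    """2x2 prior covariance of true effects under a line group."""
    s, tau, rho = group.slope, group.scale, group.correlation
    norm = math.sqrt(1.0 + s * s)
    u = np.array([1.0, s]) / norm
    v = np.array([-s, 1.0]) / norm
    sigma = tau * tau * ((1.0 + rho) * np.outer(u, u) + (1.0 - rho) * np.outer(v, v))
    return sigma


def scale_init(betas: np.ndarray) -> float:
    """Initial scale: 95% of pooled |effects| fall within twice the scale."""
    betas = np.asarray(betas, dtype=float)
    return float(np.percentile(np.abs(betas).ravel(), 95.0) / 2.0)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _component_logpdf(B: np.ndarray, S2: np.ndarray, sigma: np.ndarray,
                      err_corr: float = 0.0) -> np.ndarray:
    """log N(B_i; 0, sigma + S_i) for all variants, vectorised over i.

    B is (n, 2) observed effects, S2 is (n, 2) squared standard errors.
    ``err_corr`` adds off-diagonal se1*se2*err_corr observation covariance
    for overlapping-sample trait pairs.
    """
    a = sigma[0, 0] + S2[:, 0]
    d = sigma[1, 1] + S2[:, 1]
    b = sigma[0, 1] + err_corr * np.sqrt(S2[:, 0] * S2[:, 1])
    det = a * d - b * b
    if np.any(det <= 0):
        raise FloatingPointError("singular total covariance in mixture likelihood")
    x, y = B[:, 0], B[:, 1]
    quad = (d * x * x - 2.0 * b * x * y + a * y * y) / det
    return -0.5 * (quad + np.log(det)) - math.log(2.0 * math.pi)


def _log_component_matrix(B, S2, groups, err_corr=0.0) -> np.ndarray:
    return np.column_stack([
        _component_logpdf(B, S2, group_covariance(g), err_corr) for g in groups
    ])


def mixture_loglik(B: np.ndarray, S: np.ndarray, groups: list[LineGroup],
                   pi: np.ndarray, err_corr: float = 0.0) -> float:
    """Total log marginal likelihood of the line-model mixture.

    Parameters
    ----------
    B, S:
        (n, 2) arrays of effects and standard errors on the
        sqrt-heritability scale.
    pi:
        Mixture proportions on the simplex, one per group.
    """
    B = np.asarray(B, float)
    S = np.asarray(S, float)
    pi = np.asarray(pi, float)
    if not math.isclose(pi.sum(), 1.0, abs_tol=1e-8) or np.any(pi < 0):
        raise ValueError("pi must be a probability vector")
    logm = _log_component_matrix(B, S ** 2, groups, err_corr)
    with np.errstate(divide="ignore"):
        logpi = np.where(pi > 0, np.log(np.maximum(pi, 1e-300)), -np.inf)
    m = logm + logpi
    mmax = m.max(axis=1, keepdims=True)
    ll = mmax[:, 0] + np.log(np.exp(m - mmax).sum(axis=1))
    return float(ll.sum())


def responsibilities(B, S, groups, pi, err_corr=0.0) -> np.ndarray:
    """Closed-form posterior membership probabilities given pi."""
    logm = _log_component_matrix(np.asarray(B, float),
                                 np.asarray(S, float) ** 2, groups, err_corr)
    with np.errstate(divide="ignore"):
        m = logm + np.log(np.maximum(np.asarray(pi, float), 1e-300))
    m -= m.max(axis=1, keepdims=True)
    r = np.exp(m)
    return r / r.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

@dataclass
class EMConfig:
    tol: float = 1e-6
    max_iter: int = 1000
    n_starts: int = 5
    err_corr: float = 0.0
    seed: int | None = None


@dataclass
class LineModelFit:
    """A fitted line-model mixture."""

    groups: list[LineGroup]
    pi: np.ndarray
    loglik: float
    posteriors: np.ndarray  # (n, k) membership responsibilities
    n_iter: int
    converged: bool
    loglik_trace: list[float] = field(default_factory=list)
    err_corr: float = 0.0
    gibbs_summary: "GibbsSummary | None" = None

    @property
    def slopes(self) -> list[float]:
        return [g.slope for g in self.groups]


def _expected_loglik_for_slope(angle, g_idx, groups, resp, B, S2, err_corr):
    g = replace(groups[g_idx], slope=math.tan(angle))
    logpdf = _component_logpdf(B, S2, group_covariance(g), err_corr)
    return float(np.sum(resp[:, g_idx] * logpdf))


def _em_once(B, S2, groups, pi0, config: EMConfig):
    groups = list(groups)
    pi = np.asarray(pi0, float).copy()
    trace: list[float] = []
    n = B.shape[0]
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        logm = _log_component_matrix(B, S2, groups, config.err_corr)
        with np.errstate(divide="ignore"):
            m = logm + np.log(np.maximum(pi, 1e-300))
        mmax = m.max(axis=1, keepdims=True)
        lse = mmax[:, 0] + np.log(np.exp(m - mmax).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(m - lse[:, None])

        if ll - prev < config.tol and it > 1:
            converged = ll >= prev - 1e-9
            break
        prev = ll

        # M-step: proportions, then each free slope by 1-D search on angle
        pi = resp.sum(axis=0) / n
        for gi, g in enumerate(groups):
            if not g.slope_free:
                continue
            cur_angle = math.atan(g.slope)
            q_cur = _expected_loglik_for_slope(cur_angle, gi, groups, resp,
                                               B, S2, config.err_corr)
            res = optimize.minimize_scalar(
                lambda a: -_expected_loglik_for_slope(a, gi, groups, resp,
                                                      B, S2, config.err_corr),
                bounds=(-_MAX_ANGLE, _MAX_ANGLE), method="bounded",
                options={"xatol": 1e-8})
            # generalised EM: only accept a slope that does not decrease Q
            if -res.fun >= q_cur:
                groups[gi] = replace(g, slope=math.tan(float(res.x)))
    return groups, pi, trace, converged, it


def fit_em(B: np.ndarray, S: np.ndarray, groups_init: list[LineGroup],
           config: EMConfig | None = None,
           pi_init: np.ndarray | None = None) -> LineModelFit:
    """Fit mixture proportions and free slopes by EM.

    Scales and correlations stay fixed at their initial values, mirroring
    the standard usage in which only the slope(s) and the proportions are
    optimised.  Free slopes are re-estimated each M-step by bounded
    maximisation of the expected complete-data log-likelihood over the
    line angle (handles near-vertical lines smoothly); the update is only
    accepted when it does not decrease the objective, so the observed
    log-likelihood is non-decreasing across iterations.

    To guard against local optima, each free slope is restarted from
    ``config.n_starts`` angles evenly spread over (-90, 90) degrees; ties
    between starts are broken by highest log-likelihood, then smallest
    |slope|.
    """
    config = config or EMConfig()
    B = np.asarray(B, float)
    S = np.asarray(S, float)
    if B.ndim != 2 or B.shape[1] != 2 or B.shape != S.shape:
        raise ValueError("B and S must both have shape (n, 2)")
    if B.shape[0] < 2:
        raise ValueError("need at least 2 effect pairs")
    S2 = S ** 2
    k = len(groups_init)
    pi0 = np.full(k, 1.0 / k) if pi_init is None else np.asarray(pi_init, float)

    free_idx = [i for i, g in enumerate(groups_init) if g.slope_free]
    if free_idx:
        start_angles = np.linspace(-_MAX_ANGLE, _MAX_ANGLE, config.n_starts + 2)[1:-1]
        starts = []
        for a in start_angles:
            gs = list(groups_init)
            for gi in free_idx:
                gs[gi] = replace(gs[gi], slope=math.tan(float(a)))
            starts.append(gs)
        # include the user-provided initial slopes as one start
        starts.append(list(groups_init))
    else:
        starts = [list(groups_init)]

    best = None
    for gs in starts:
        groups, pi, trace, converged, it = _em_once(B, S2, gs, pi0, config)
        ll = trace[-1]
        key = (round(ll, 9), -max(abs(g.slope) for g in groups))
        if best is None or key > best[0]:
            best = (key, groups, pi, trace, converged, it)
    _, groups, pi, trace, converged, it = best
    if not converged:
        logger.warning("EM did not converge in %d iterations (dll=%.3g)",
                       it, trace[-1] - trace[-2] if len(trace) > 1 else float("nan"))
    post = responsibilities(B, S, groups, pi, config.err_corr)
    return LineModelFit(groups=groups, pi=pi, loglik=trace[-1], posteriors=post,
                        n_iter=it, converged=converged, loglik_trace=trace,
                        err_corr=config.err_corr)


def compare_one_vs_two(B: np.ndarray, S: np.ndarray, *,
                       scale: float | None = None, correlation: float = 0.99,
                       fixed_slope: float | None = 0.0,
                       config: EMConfig | None = None) -> dict:
    """Likelihood comparison of a one-line model against a two-line mixture.

    The one-group model has a single free slope.  The two-group model
    fixes one slope (default 0, capturing "trait-1 only" variants) and
    frees the other; with ``fixed_slope=None`` both slopes are free.
    Scales are equal across groups (the pooled-percentile initial value
    unless given).  Returns the raw statistic 2*(ll2 - ll1); no p-value
    is attached because the mixture null sits on the parameter-space
    boundary, but ``strong_evidence`` flags statistics above 20.
    """
    config = config or EMConfig()
    tau = scale_init(B) if scale is None else scale

    one = [LineGroup(slope=1.0, scale=tau, correlation=correlation,
                     slope_free=True, label="single")]
    fit1 = fit_em(B, S, one, config)

    if fixed_slope is None:
        g1 = LineGroup(slope=0.2, scale=tau, correlation=correlation,
                       slope_free=True, label="group1")
    else:
        g1 = LineGroup(slope=fixed_slope, scale=tau, correlation=correlation,
                       slope_free=False, label="trait1_only")
    g2 = LineGroup(slope=1.0, scale=tau, correlation=correlation,
                   slope_free=True, label="shared")
    fit2 = fit_em(B, S, [g1, g2], config)

    stat = 2.0 * (fit2.loglik - fit1.loglik)
    return {"loglik_one": fit1.loglik, "loglik_two": fit2.loglik,
            "stat": stat, "strong_evidence": stat > 20.0,
            "fit_one": fit1, "fit_two": fit2}


# ---------------------------------------------------------------------------
# Gibbs membership sampling
# ---------------------------------------------------------------------------

@dataclass
class GibbsSummary:
    membership: np.ndarray  # (n, k) posterior mean membership
    mc_se: np.ndarray       # (n, k) batch-means Monte-Carlo standard error
    pi_mean: np.ndarray
    n_iter: int
    burn_in: int
    seed: int | None


def gibbs_membership(B: np.ndarray, S: np.ndarray, fit: LineModelFit,
                     n_iter: int = 10_000, burn_in: int = 1_000,
                     seed: int | None = 0,
                     pi_fixed: np.ndarray | None = None,
                     n_batches: int = 20) -> GibbsSummary:
    """Sample per-variant group memberships by Gibbs.

    Each sweep (a) samples every variant's group label from its
    conditional categorical given the current proportions and (b) samples
    the proportions from Dirichlet(1 + counts).  With ``pi_fixed`` the
    Dirichlet step is skipped and the chain's marginal assignment
    frequencies converge to the closed-form responsibilities — the
    analytic check used in the tests.

    Monte-Carlo standard errors come from batch means over
    ``n_batches`` post-burn-in segments (assignments are autocorrelated
    through the shared proportions).
    """
    if n_iter <= burn_in:
        raise ValueError("n_iter must exceed burn_in")
    rng = np.random.default_rng(seed)
    B = np.asarray(B, float)
    S2 = np.asarray(S, float) ** 2
    logm = _log_component_matrix(B, S2, fit.groups, fit.err_corr)
    n, k = logm.shape

    pi = np.asarray(pi_fixed, float) if pi_fixed is not None else fit.pi.copy()
    kept = n_iter - burn_in
    batch_len = max(1, kept // n_batches)
    batch_sums = np.zeros((n_batches, n, k))
    pi_sum = np.zeros(k)
    kept_count = 0

    for t in range(n_iter):
        with np.errstate(divide="ignore"):
            m = logm + np.log(np.maximum(pi, 1e-300))
        m -= m.max(axis=1, keepdims=True)
        p = np.exp(m)
        p /= p.sum(axis=1, keepdims=True)
        u = rng.random((n, 1))
        labels = (u > np.cumsum(p, axis=1)).sum(axis=1)
        if pi_fixed is None:
            counts = np.bincount(labels, minlength=k)
            pi = rng.dirichlet(1.0 + counts)
        if t >= burn_in:
            b = min(kept_count // batch_len, n_batches - 1)
            batch_sums[b, np.arange(n), labels] += 1.0
            pi_sum += pi
            kept_count += 1

    batch_means = batch_sums / np.maximum(
        1, np.array([batch_len] * (n_batches - 1) + [kept - batch_len * (n_batches - 1)])
    )[:, None, None]
    membership = batch_sums.sum(axis=0) / kept
    mc_se = batch_means.std(axis=0, ddof=1) / math.sqrt(n_batches)
    return GibbsSummary(membership=membership, mc_se=mc_se,
                        pi_mean=pi_sum / kept, n_iter=n_iter,
                        burn_in=burn_in, seed=seed)


# ---------------------------------------------------------------------------
# Sharing proportion
# ---------------------------------------------------------------------------

def sharing_proportion(shared_posterior: np.ndarray, p1: np.ndarray,
                       p_cutoff: float = 1e-11,
                       prob_cutoff: float = 0.8) -> dict:
    """Fraction of strong discovery-trait associations assigned shared.

    Restricts to variants with discovery p-value below ``p_cutoff``
    (confident effect estimates) and reports the fraction whose
    shared-group posterior exceeds ``prob_cutoff``, plus counts at the
    0.95 and 0.99 high-confidence tiers.

    Only the ordering of ``p1`` against ``p_cutoff`` matters, so
    log-scale p-values (with a log-scale cutoff) are equally valid
    inputs when raw p-values would underflow.
    """
    shared_posterior = np.asarray(shared_posterior, float)
    p1 = np.asarray(p1, float)
    if shared_posterior.shape != p1.shape:
        raise ValueError("posterior and p-value vectors must align")
    mask = p1 < p_cutoff
    n_top = int(mask.sum())
    if n_top == 0:
        raise ValueError("no variants pass the discovery p-value filter")
    top = shared_posterior[mask]
    return {
        "n_top": n_top,
        "fraction_shared": float(np.mean(top > prob_cutoff)),
        "n_shared": int(np.sum(top > prob_cutoff)),
        "n_95": int(np.sum(shared_posterior >= 0.95)),
        "n_99": int(np.sum(shared_posterior >= 0.99)),
    }
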