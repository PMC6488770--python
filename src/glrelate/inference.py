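"""Maximum-likelihood estimation of the Jacquard vector by accelerated EM.

The likelihood is a finite mixture over the nine condensed IBD states with
site-specific component densities (the emissions).  The EM update is the
posterior-mean update on the probability simplex; acceleration uses the
squared-extrapolation scheme S3 of Varadhan & Roland, falling back to the
plain double EM step whenever the extrapolated point leaves the simplex
or fails to improve on it, which preserves EM's monotone ascent.

Because biallelic markers do not identify all nine coefficients separately
in every pedigree, the optimizer is restarted from several random points on
the simplex; linear combinations such as relatedness and the inbreeding
coefficients agree across equally likely optima even when the individual
coefficients do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DegenerateSiteError, N_STATES, pair_loglikelihood, site_emissions

__all__ = [
    "EmOptions",
    "EstimateResult",
    "BootstrapResult",
    "em_step",
    "squarem_update",
    "estimate_pair",
    "bootstrap_ci",
    "simplex_em",
]

#: coefficients closer to zero than this are examined as boundary solutions
BOUNDARY_TOL = 1e-5

#: floor used when projecting extrapolated points back onto the simplex
_SIMPLEX_EPS = 1e-12


@dataclass
class EmOptions:
    """Optimizer settings.

    tol
        Convergence threshold on the absolute change in log-likelihood
        between successive accepted iterates.
    max_iter
        Cap on EM-step evaluations per start point.
    n_restarts
        Independent random start points (uniform on the simplex); the
        highest-likelihood solution is kept.
    seed
        Seeds every random draw; identical options give identical results.
    use_acceleration
        Apply SQUAREM extrapolation (S3) on top of plain EM.
    """

    tol: float = 1e-9
    max_iter: int = 5_000
    n_restarts: int = 5
    seed: int = 1
    use_acceleration: bool = True

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1 or self.n_restarts < 1:
            raise ValueError("max_iter and n_restarts must be >= 1")


@dataclass
class EstimateResult:
    j_hat: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    n_sites_used: int
    seed_used: int
    boundary_flags: np.ndarray = field(default_factory=lambda: np.zeros(N_STATES, bool))


@dataclass
class BootstrapResult:
    """Percentile bootstrap intervals for the summary statistics.

    ``point``, ``lower`` and ``upper`` map statistic name to value; the
    percentile method can in principle place the point estimate outside the
    interval for skewed statistics, but ``lower <= upper`` always holds.
    """

    point: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    n_boot: int
    level: float
    seed: int


def _loglik(j: np.ndarray, e: np.ndarray) -> float:
    per_site = e @ j
    if np.any(per_site <= 0.0):
        raise DegenerateSiteError(int(np.argmax(per_site <= 0.0)))
    return float(np.log(per_site).sum())


def em_step(j: np.ndarray, e: np.ndarray) -> np.ndarray:
    """One plain EM update: the mean posterior state distribution.

    ``j'_m = (1/L) sum_l j_m e[l,m] / sum_m' j_m' e[l,m']``.  Works for any
    mixture dimension (the 2D-SFS estimator reuses it with 9 genotype-pair
    classes).  The log-likelihood never decreases under this map.
    """
    j = np.asarray(j, dtype=float)
    e = np.atleast_2d(np.asarray(e, dtype=float))
    totals = e @ j
    if np.any(totals <= 0.0):
        raise DegenerateSiteError(int(np.argmax(totals <= 0.0)))
    return j * (e.T @ (1.0 / totals)) / e.shape[0]


def _project_simplex(j: np.ndarray) -> np.ndarray:
    j = np.clip(j, _SIMPLEX_EPS, None)
    return j / j.sum()


def squarem_update(j: np.ndarray, e: np.ndarray) -> np.ndarray:
    """One SQUAREM (scheme S3) cycle: two EM steps plus squared extrapolation.

    With ``r = EM(j) - j`` and ``v = EM(EM(j)) - 2 EM(j) + j`` the step
    length is ``alpha = -||r|| / ||v||`` and the proposal
    ``j - 2 alpha r + alpha^2 v`` (``alpha = -1`` recovers the plain double
    step).  The proposal is projected onto the simplex and discarded in
    favour of the plain double step whenever it fails to improve on it, so
    every accepted cycle makes at least EM's own progress.
    """
    j = np.asarray(j, dtype=float)
    j1 = em_step(j, e)
    j2 = em_step(j1, e)
    r = j1 - j
    v = (j2 - j1) - r
    v_norm = float(np.sqrt(v @ v))
    if v_norm < 1e-14:  # at or next to a fixed point
        return j2
    alpha = -float(np.sqrt(r @ r)) / v_norm
    proposal = j - 2.0 * alpha * r + alpha * alpha * v
    if proposal.min() < 0.0 or proposal.max() > 1.0:
        return j2
    proposal = proposal / proposal.sum()
    try:
        if _loglik(proposal, e) >= _loglik(j2, e):
            return proposal
    except DegenerateSiteError:
        pass
    return j2


def _em_step_with_ll(j: np.ndarray, e: np.ndarray) -> tuple[np.ndarray, float]:
    """EM update plus the log-likelihood at the *input* point (free byproduct)."""
    totals = e @ j
    if np.any(totals <= 0.0):
        raise DegenerateSiteError(int(np.argmax(totals <= 0.0)))
    return j * (e.T @ (1.0 / totals)) / e.shape[0], float(np.log(totals).sum())


def simplex_em(
    j0: np.ndarray,
    e: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 5_000,
    use_acceleration: bool = True,
) -> tuple[np.ndarray, float, int, bool]:
    """Run (accelerated) EM from ``j0`` until the log-likelihood stabilizes.

    Returns ``(j, loglik, n_em_steps, converged)`` where ``n_em_steps``
    counts plain-EM-update evaluations (an accelerated cycle costs two).
    """
    e = np.atleast_2d(np.asarray(e, dtype=float))
    j = _project_simplex(np.asarray(j0, dtype=float))
    ll = _loglik(j, e)
    n_steps = 0
    while n_steps < max_iter:
        if use_acceleration:
            j1, _ = _em_step_with_ll(j, e)
            j2, _ = _em_step_with_ll(j1, e)
            n_steps += 2
            r = j1 - j
            v = (j2 - j1) - r
            v_norm = float(np.sqrt(v @ v))
            ll_j2 = _loglik(j2, e)
            j_new, ll_new = j2, ll_j2
            if v_norm >= 1e-14:
                alpha = -float(np.sqrt(r @ r)) / v_norm
                proposal = j - 2.0 * alpha * r + alpha * alpha * v
                if proposal.min() >= 0.0 and proposal.max() <= 1.0:
                    proposal = proposal / proposal.sum()
                    try:
                        ll_prop = _loglik(proposal, e)
                    except DegenerateSiteError:
                        ll_prop = -np.inf
                    if ll_prop >= ll_j2:
                        j_new, ll_new = proposal, ll_prop
        else:
            j_new = em_step(j, e)
            n_steps += 1
            ll_new = _loglik(j_new, e)
        j = j_new
        if abs(ll_new - ll) < tol:
            return j, ll_new, n_steps, True
        ll = ll_new
    return j, ll, n_steps, False


def _clamp_boundary(j: np.ndarray, e: np.ndarray, ll: float, tol: float) -> tuple[np.ndarray, float]:
    """Examine the simplex boundary: snap near-zero coefficients to 0.

    The clamped-and-renormalized vector replaces the interior solution when
    its log-likelihood is not worse by more than ``tol``.
    """
    near_zero = j < BOUNDARY_TOL
    if not near_zero.any() or near_zero.all():
        return j, ll
    clamped = np.where(near_zero, 0.0, j)
    clamped /= clamped.sum()
    try:
        ll_clamped = _loglik(clamped, e)
    except DegenerateSiteError:
        return j, ll
    if ll_clamped >= ll - tol:
        return clamped, ll_clamped
    return j, ll


def estimate_pair(emissions: np.ndarray, opts: EmOptions | None = None) -> EstimateResult:
    """Maximum-likelihood Jacquard vector for one pair from its emissions.

    Runs ``opts.n_restarts`` accelerated-EM optimizations from independent
    uniform (Dirichlet(1,..,1)) start points on the simplex, keeps the best,
    and then examines the boundary of the parameter space by clamping
    near-zero coefficients to exactly zero.  Deterministic given
    ``opts.seed``.
    """
    opts = opts or EmOptions()
    e = np.atleast_2d(np.asarray(emissions, dtype=float))
    n_sites = e.shape[0]
    if n_sites < 1:
        raise ValueError("no sites available for estimation")
    rng = np.random.default_rng(opts.seed)
    best: tuple[np.ndarray, float, int, bool] | None = None
    for _ in range(opts.n_restarts):
        j0 = rng.dirichlet(np.ones(N_STATES))
        j, ll, n_steps, converged = simplex_em(
            j0, e, tol=opts.tol, max_iter=opts.max_iter,
            use_acceleration=opts.use_acceleration,
        )
        if best is None or ll > best[1]:
            best = (j, ll, n_steps, converged)
    j, ll, n_steps, converged = best
    j, ll = _clamp_boundary(j, e, ll, opts.tol)
    return EstimateResult(
        j_hat=j,
        loglik=ll,
        n_iter=n_steps,
        converged=converged,
        n_sites_used=n_sites,
        seed_used=opts.seed,
        boundary_flags=j < BOUNDARY_TOL,
    )


def bootstrap_ci(
    gl_a: np.ndarray,
    gl_b: np.ndarray,
    freqs: np.ndarray,
    n_boot: int = 200,
    level: float = 0.95,
    opts: EmOptions | None = None,
    include_ibs: bool = True,
) -> BootstrapResult:
    """Site-level percentile bootstrap for all pairwise summary statistics.

    Sites are resampled with replacement (L draws per replicate, consistent
    with the unlinked-sites assumption); the Jacquard vector, its IBD-based
    summaries and, optionally, the 2D-SFS IBS statistics are re-estimated on
    each replicate.  Deterministic given ``opts.seed``.
    """
    from .sfs2d import estimate_2dsfs
    from .summaries import ibd_summaries, ibs_summaries

    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    opts = opts or EmOptions()

    def _stats(gl_a_r, gl_b_r, e_r) -> dict[str, float]:
        est = estimate_pair(e_r, opts)
        row = {f"J{m + 1}": est.j_hat[m] for m in range(N_STATES)}
        row.update(ibd_summaries(est.j_hat).as_dict())
        if include_ibs:
            sfs = estimate_2dsfs(gl_a_r, gl_b_r, tol=opts.tol, max_iter=opts.max_iter)
            row.update(ibs_summaries(sfs.s).as_dict())
        return row

    e = site_emissions(gl_a, gl_b, freqs)
    n_sites = e.shape[0]
    point = _stats(gl_a, gl_b, e)
    rng = np.random.default_rng(opts.seed)
    replicates: dict[str, list[float]] = {k: [] for k in point}
    for _ in range(n_boot):
        idx = rng.integers(0, n_sites, size=n_sites)
        for key, value in _stats(gl_a[idx], gl_b[idx], e[idx]).items():
            replicates[key].append(value)
    tail = (1.0 - level) / 2.0
    lower = {k: float(np.quantile(v, tail)) for k, v in replicates.items()}
    upper = {k: float(np.quantile(v, 1.0 - tail)) for k, v in replicates.items()}
    return BootstrapResult(point=point, lower=lower, upper=upper,
                           n_boot=n_boot, level=level, seed=opts.seed)
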