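"""Expected improvement and seeded acquisition optimization.

Because duplicate proposals return cached scores, the fitted GP learns
long lengthscales and most of the hypercube is effectively stationary:
purely random multistart ascent of the acquisition surface rarely finds
its optima.  The acquisition optima, however, must lie close to already
known good points, so each proposal round mixes uniform random seeds with
seeds perturbed around history points whose observed score exceeded the
seeding threshold (0.4 by default).  The best seeds are refined by
bounded L-BFGS-B ascent of the expected improvement, and the best refined
point across all rounds is proposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.optimize import minimize
from scipy.stats import norm

from .gp import GPModel, SQRT5, gp_posterior, matern52_gram
from .latent import EPS

__all__ = ["AcquisitionConfig", "expected_improvement", "propose_candidate"]


@dataclass(frozen=True)
class AcquisitionConfig:
    """Knobs of the seeded acquisition search.

    Defaults follow the original scheme: per proposal, 10 rounds of
    (1024 uniform + 1024 perturbed) seeds, perturbation sd 0.1 per
    dimension in hypercube units, L-BFGS-B refinement of the best seeds.
    """

    n_random_seeds: int = 1024
    n_perturbed_seeds: int = 1024
    perturb_sd: float = 0.1
    n_rounds: int = 10
    seed_threshold: float = 0.4
    n_local_starts: int = 64
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_random_seeds, self.n_perturbed_seeds, self.n_rounds, self.n_local_starts) < 1:
            raise ValueError("counts must be >= 1")
        if not (0 < self.perturb_sd < 1):
            raise ValueError("perturb_sd must be in (0, 1)")
        if not (0 < self.seed_threshold < 1):
            raise ValueError("seed_threshold must be in (0, 1)")


def expected_improvement(
    mean: np.ndarray, sd: np.ndarray, best_observed: float
) -> np.ndarray:
    """Closed-form EI for maximization.

    ``EI = (mu - best) * Phi(z) + sd * phi(z)`` with ``z = (mu - best)/sd``;
    degenerates to ``max(mu - best, 0)`` at zero predictive sd.
    Vectorized over mean/sd.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    scalar = mean.ndim == 0
    mean, sd = np.atleast_1d(mean), np.atleast_1d(sd)
    imp = mean - best_observed
    ei = np.maximum(imp, 0.0)
    pos = sd > 0
    z = imp[pos] / sd[pos]
    ei_pos = imp[pos] * norm.cdf(z) + sd[pos] * norm.pdf(z)
    out = ei.copy()
    out[pos] = ei_pos
    out = np.maximum(out, 0.0)
    return float(out[0]) if scalar else out


def _neg_ei_and_grad(
    u: np.ndarray, model: GPModel, best: float
) -> tuple[float, np.ndarray]:
    """-EI and its gradient at a single hypercube point.

    dEI/dx = Phi(z) dmu/dx + phi(z) dsd/dx (the z cross-terms cancel).
    Kernel gradient: dk/dx_i = -sv*(5/3)*(1+sqrt5 d)*exp(-sqrt5 d)
    * (x_i - xj_i)/l_i^2, smooth through d=0.
    """
    L, alpha = model.factorize()
    ls = model.params.lengthscales
    sv = model.params.signal_variance
    diff = (u[None, :] - model.X) / ls  # (n, dim)
    d = np.sqrt(np.einsum("ij,ij->i", diff, diff))
    e = np.exp(-SQRT5 * d)
    k = sv * (1.0 + SQRT5 * d + (5.0 / 3.0) * d * d) * e
    # dk/du: (n, dim)
    dk = -(sv * (5.0 / 3.0) * (1.0 + SQRT5 * d) * e)[:, None] * (diff / ls)
    mu = model.mean_const + k @ alpha
    Kinv_k = linalg.cho_solve((L, True), k)
    var = max(sv - k @ Kinv_k, 1e-14)
    sdv = np.sqrt(var)
    dmu = dk.T @ alpha
    dsd = -(dk.T @ Kinv_k) / sdv
    z = (mu - best) / sdv
    ei = (mu - best) * norm.cdf(z) + sdv * norm.pdf(z)
    grad = norm.cdf(z) * dmu + norm.pdf(z) * dsd
    return -float(ei), -grad


def propose_candidate(
    model: GPModel,
    history,
    cfg: AcquisitionConfig,
    rng: np.random.Generator | None = None,
    return_diagnostics: bool = False,
) -> np.ndarray | tuple[np.ndarray, dict]:
    """Select the next hypercube point to evaluate by seeded EI ascent.

    ``history`` is any iterable of records carrying ``hypercube`` and
    ``score`` attributes; records with score above ``cfg.seed_threshold``
    anchor the perturbed seeds.  With no above-threshold anchors all seeds
    are uniform.  Deterministic for a fixed ``cfg.rng_seed`` (or supplied
    generator).

    With ``return_diagnostics=True`` also returns a dict with the proposal
    EI, the best raw-seed EI, and per-round median seed EIs split by seed
    type (used to verify the ascent contract and the seeding rationale).
    """
    if model.n == 0:
        raise ValueError("model must be fitted before proposing")
    records = list(history)
    if not records:
        raise ValueError("history must be non-empty")
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    dim = model.X.shape[1]
    lo, hi = EPS, 1.0 - EPS
    best_observed = float(max(r.score for r in records))
    anchors = np.array(
        [np.asarray(r.hypercube, dtype=float) for r in records if r.score > cfg.seed_threshold]
    )
    bounds = [(lo, hi)] * dim

    best_point, best_ei = None, -np.inf
    max_seed_ei = -np.inf
    median_uniform_ei: list[float] = []
    median_perturbed_ei: list[float] = []
    for _ in range(cfg.n_rounds):
        uniform = rng.uniform(lo, hi, size=(cfg.n_random_seeds, dim))
        if anchors.size:
            idx = rng.integers(0, len(anchors), size=cfg.n_perturbed_seeds)
            perturbed = anchors[idx] + rng.normal(
                0.0, cfg.perturb_sd, size=(cfg.n_perturbed_seeds, dim)
            )
            perturbed = np.clip(perturbed, lo, hi)
        else:
            perturbed = rng.uniform(lo, hi, size=(cfg.n_perturbed_seeds, dim))
        seeds = np.vstack([uniform, perturbed])
        mean, var = gp_posterior(model, seeds)
        ei = expected_improvement(mean, np.sqrt(var), best_observed)
        max_seed_ei = max(max_seed_ei, float(ei.max()))
        median_uniform_ei.append(float(np.median(ei[: cfg.n_random_seeds])))
        median_perturbed_ei.append(float(np.median(ei[cfg.n_random_seeds :])))
        top = np.argsort(ei)[::-1][: cfg.n_local_starts]
        for i in top:
            x0 = seeds[i]
            res = minimize(
                _neg_ei_and_grad,
                x0,
                args=(model, best_observed),
                method="L-BFGS-B",
                jac=True,
                bounds=bounds,
                options={"maxiter": 60},
            )
            # ascent contract: never return less than the seed's own EI
            cand, cand_ei = (res.x, -res.fun) if -res.fun >= ei[i] else (x0, ei[i])
            if cand_ei > best_ei:
                best_ei, best_point = cand_ei, np.clip(cand, lo, hi)
    if return_diagnostics:
        return best_point, {
            "proposal_ei": best_ei,
            "max_seed_ei": max_seed_ei,
            "median_uniform_ei": median_uniform_ei,
            "median_perturbed_ei": median_perturbed_ei,
            "n_anchors": int(len(anchors)) if anchors.size else 0,
        }
    return best_point
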