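"""Likelihood of the irreversible-editing model and Bayesian estimation of
(mu, alpha) under uniform priors.

Marginally, a unit observed after d divisions is still in the ground state
with probability (1 - mu)**d, and in edit state s with probability

    P_s(d) = sum_{k=1..d} (1 - mu)**(k - 1) * mu * alpha_s
           = alpha_s * (1 - (1 - mu)**d),

summing the unknown division k at which the edit happened.  Units and cells
are conditionally independent given their division counts, so the total
likelihood is the product of these marginals over colonies, cells and units —
it depends on the data only through the count of each (depth, state) pair.

Posterior estimation uses adaptive multiple importance sampling: rounds of
draws from a defensive mixture of the uniform prior and an iteratively
refitted Gaussian proposal in transformed space (logit for mu, additive
log-ratio for alpha), with final weights computed against the pooled mixture
of all round proposals.  A random-walk Metropolis sampler is provided as an
independent cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit, logit
from scipy.stats import multivariate_normal

from .matrix import BarcodeMatrix
from .simulate import Colony, EditModel


class UnderflowError(RuntimeError):
    pass


@dataclass
class ObservationSet:
    """Sufficient statistics: count of units observed in each state code
    (0 = ground, 1..K = edit states) at each division depth."""

    counts: dict[tuple[int, int], int]
    n_edit_states: int

    def __post_init__(self):
        for (d, code), cnt in self.counts.items():
            if d < 1:
                raise ValueError("depths must be >= 1")
            if not 0 <= code <= self.n_edit_states:
                raise ValueError(f"state code {code} outside alphabet")
            if cnt < 0:
                raise ValueError("negative count")

    @property
    def n_observations(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_matrix(cls, matrix: BarcodeMatrix, depths: dict[str, int]) -> "ObservationSet":
        missing = [c for c in matrix.cell_ids if c not in depths]
        if missing:
            raise ValueError(f"depth missing for cells {missing[:3]}")
        counts: dict[tuple[int, int], int] = {}
        for cid in matrix.cell_ids:
            d = depths[cid]
            codes, n = np.unique(matrix.row(cid), return_counts=True)
            for code, cnt in zip(codes, n):
                key = (d, int(code))
                counts[key] = counts.get(key, 0) + int(cnt)
        return cls(counts, matrix.alphabet.n_states - 1)

    @classmethod
    def from_colonies(cls, colonies: list[Colony]) -> "ObservationSet":
        merged: dict[tuple[int, int], int] = {}
        k = None
        for col in colonies:
            sub = cls.from_matrix(col.barcodes, col.depths)
            k = sub.n_edit_states
            for key, cnt in sub.counts.items():
                merged[key] = merged.get(key, 0) + cnt
        if k is None:
            raise ValueError("no colonies")
        return cls(merged, k)


def edit_probabilities(d: int, model: EditModel) -> np.ndarray:
    """Per-unit state distribution after d divisions.

    Returns ``[P(ground), P(s_1), ..., P(s_K)]`` with P(ground) = (1-mu)**d
    and P(s) = alpha_s * (1 - (1-mu)**d); entries sum to 1.
    """
    if d < 1:
        raise ValueError("d must be >= 1")
    p_ground = (1.0 - model.mu) ** d
    alpha = np.asarray(model.alpha)
    return np.concatenate([[p_ground], alpha * (1.0 - p_ground)])


def log_likelihood(obs: ObservationSet, model: EditModel) -> float:
    """Log of the product of per-unit marginals over all observations; -inf
    when an observed state has probability exactly 0."""
    if obs.n_edit_states != len(model.alpha):
        raise ValueError("observation alphabet does not match model")
    total = 0.0
    by_depth: dict[int, np.ndarray] = {}
    for (d, code), cnt in obs.counts.items():
        if d not in by_depth:
            by_depth[d] = edit_probabilities(d, model)
        p = by_depth[d][code]
        if p <= 0.0:
            if cnt > 0:
                return -np.inf
            continue
        total += cnt * np.log(p)
    return total


# -- posterior sampling ----------------------------------------------------


@dataclass
class PosteriorSample:
    """Weighted draws of (mu, alpha) with normalized importance weights."""

    mu: np.ndarray            # (n,)
    alpha: np.ndarray         # (n, K)
    weights: np.ndarray       # (n,), nonnegative, sums to 1
    ess: float

    @property
    def mean_mu(self) -> float:
        return float(np.sum(self.weights * self.mu))

    @property
    def mean_alpha(self) -> np.ndarray:
        return self.weights @ self.alpha

    def quantile_mu(self, q) -> np.ndarray:
        order = np.argsort(self.mu)
        cdf = np.cumsum(self.weights[order])
        return np.interp(np.atleast_1d(q), cdf, self.mu[order])

    def credible_interval_mu(self, level: float = 0.95) -> tuple[float, float]:
        lo, hi = self.quantile_mu([(1 - level) / 2, 1 - (1 - level) / 2])
        return float(lo), float(hi)


def _transform(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """(mu, alpha) -> unconstrained (logit mu, additive log-ratios of alpha)."""
    cols = [logit(mu)]
    k = alpha.shape[1]
    for i in range(k - 1):
        cols.append(np.log(alpha[:, i]) - np.log(alpha[:, -1]))
    return np.column_stack(cols)


def _untransform(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    mu = expit(theta[:, 0])
    if k == 1:
        return mu, np.ones((len(mu), 1))
    z = np.column_stack([theta[:, 1:], np.zeros(len(theta))])
    z -= z.max(axis=1, keepdims=True)
    alpha = np.exp(z)
    alpha /= alpha.sum(axis=1, keepdims=True)
    return mu, alpha


def _log_prior_transformed(mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Uniform on mu, flat Dirichlet on alpha, expressed in the transformed
    coordinates (log-Jacobian of the logit/ALR maps)."""
    lp = np.log(mu) + np.log1p(-mu)
    if alpha.shape[1] > 1:
        lp = lp + np.log(alpha).sum(axis=1)
    return lp


def _sample_prior(n: int, k: int, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    mu = rng.uniform(0.0, 1.0, size=n)
    alpha = rng.dirichlet(np.ones(k), size=n) if k > 1 else np.ones((n, 1))
    return mu, alpha


def fit_parameters(
    obs: ObservationSet,
    n_draws: int = 4000,
    rng: np.random.Generator | None = None,
    n_rounds: int = 4,
    defensive_weight: float = 0.2,
) -> PosteriorSample:
    """Adaptive multiple importance sampling for (mu, alpha).

    ``n_draws`` draws are spread over ``n_rounds`` rounds; the first round
    samples the prior, later rounds a defensive mixture of the prior and a
    Gaussian fitted (in transformed space) to the weighted draws so far.
    Final weights use the pooled mixture of all proposals, so no round's
    draws are wasted.  All weight arithmetic is in log space.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if rng is None:
        rng = np.random.default_rng()
    k = max(obs.n_edit_states, 1)
    dim = 1 + (k - 1)
    per_round = n_draws // n_rounds

    all_theta: list[np.ndarray] = []
    proposals: list[tuple[np.ndarray, np.ndarray] | None] = []  # (mean, cov) or None=prior

    def propose(round_idx: int, n: int) -> np.ndarray:
        if proposals[round_idx] is None:
            mu, alpha = _sample_prior(n, k, rng)
            mu = np.clip(mu, 1e-12, 1 - 1e-12)
            alpha = np.clip(alpha, 1e-12, None)
            alpha /= alpha.sum(axis=1, keepdims=True)
            return _transform(mu, alpha)
        mean, cov = proposals[round_idx]
        n_gauss = int(round(n * (1 - defensive_weight)))
        gauss = rng.multivariate_normal(mean, cov, size=n_gauss)
        mu, alpha = _sample_prior(n - n_gauss, k, rng)
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        alpha = np.clip(alpha, 1e-12, None)
        alpha /= alpha.sum(axis=1, keepdims=True)
        return np.vstack([gauss, _transform(mu, alpha)])

    def log_q(round_idx: int, theta: np.ndarray) -> np.ndarray:
        mu, alpha = _untransform(theta, k)
        mu = np.clip(mu, 1e-300, 1 - 1e-16)
        lp_prior = _log_prior_transformed(mu, np.clip(alpha, 1e-300, None))
        if proposals[round_idx] is None:
            return lp_prior
        mean, cov = proposals[round_idx]
        lg = multivariate_normal(mean=mean, cov=cov, allow_singular=True).logpdf(theta)
        lg = np.atleast_1d(lg)
        return np.logaddexp(
            np.log(1 - defensive_weight) + lg, np.log(defensive_weight) + lp_prior
        )

    def log_target(theta: np.ndarray) -> np.ndarray:
        mu, alpha = _untransform(theta, k)
        out = np.empty(len(theta))
        for i in range(len(theta)):
            model = EditModel.__new__(EditModel)  # skip sum check for tiny fp drift
            object.__setattr__(model, "mu", float(mu[i]))
            object.__setattr__(model, "alpha", tuple(alpha[i]))
            object.__setattr__(model, "alphabet", None)
            out[i] = log_likelihood(obs, model)
        return out + _log_prior_transformed(
            np.clip(mu, 1e-300, 1 - 1e-16), np.clip(alpha, 1e-300, None)
        )

    log_pi_all: list[np.ndarray] = []
    for r in range(n_rounds):
        proposals.append(None if r == 0 else (fit_mean, fit_cov))
        theta = propose(r, per_round)
        all_theta.append(theta)
        log_pi_all.append(log_target(theta))
        # refit proposal on pooled draws weighted by current-round densities
        pooled = np.vstack(all_theta)
        log_pi = np.concatenate(log_pi_all)
        log_qs = np.column_stack(
            [log_q(j, pooled) for j in range(len(proposals))]
        )
        counts = np.array([len(t) for t in all_theta], dtype=float)
        log_mix = _logmeanexp_weighted(log_qs, counts)
        lw = log_pi - log_mix
        if not np.isfinite(lw).any():
            raise UnderflowError(
                "all importance weights underflowed; weights must be computed "
                "in log space and the proposal adapted"
            )
        w = _normalize_log_weights(lw)
        fit_mean = w @ pooled
        centered = pooled - fit_mean
        fit_cov = (centered * w[:, None]).T @ centered
        fit_cov += np.eye(dim) * max(1e-6, 1e-3 * np.trace(fit_cov) / dim)
        fit_cov *= 1.5  # overdispersed proposal

    weights = _normalize_log_weights(lw)
    ess = float(1.0 / np.sum(weights**2))
    mu, alpha = _untransform(pooled, k)
    return PosteriorSample(mu=mu, alpha=alpha, weights=weights, ess=ess)


def _logmeanexp_weighted(log_qs: np.ndarray, counts: np.ndarray) -> np.ndarray:
    logw = np.log(counts / counts.sum())
    return np.logaddexp.reduce(log_qs + logw[None, :], axis=1)


def _normalize_log_weights(lw: np.ndarray) -> np.ndarray:
    lw = np.where(np.isfinite(lw), lw, -np.inf)
    m = lw.max()
    if not np.isfinite(m):
        raise UnderflowError("all importance weights are zero")
    w = np.exp(lw - m)
    return w / w.sum()


def metropolis_fit(
    obs: ObservationSet,
    n_steps: int = 20000,
    rng: np.random.Generator | None = None,
    step: float = 0.25,
    burn_frac: float = 0.3,
) -> PosteriorSample:
    """Random-walk Metropolis in transformed space; independent cross-check
    for :func:`fit_parameters`."""
    if rng is None:
        rng = np.random.default_rng()
    k = max(obs.n_edit_states, 1)
    dim = 1 + (k - 1)

    def log_post(theta_row: np.ndarray) -> float:
        theta = theta_row[None, :]
        mu, alpha = _untransform(theta, k)
        model = EditModel.__new__(EditModel)
        object.__setattr__(model, "mu", float(mu[0]))
        object.__setattr__(model, "alpha", tuple(alpha[0]))
        object.__setattr__(model, "alphabet", None)
        ll = log_likelihood(obs, model)
        return ll + float(_log_prior_transformed(mu, np.clip(alpha, 1e-300, None))[0])

    theta = np.zeros(dim)
    lp = log_post(theta)
    draws = np.empty((n_steps, dim))
    for i in range(n_steps):
        prop = theta + step * rng.standard_normal(dim)
        lp_prop = log_post(prop)
        if np.log(rng.random()) < lp_prop - lp:
            theta, lp = prop, lp_prop
        draws[i] = theta
    keep = draws[int(burn_frac * n_steps):]
    mu, alpha = _untransform(keep, k)
    w = np.full(len(keep), 1.0 / len(keep))
    ess = float(len(keep))
    return PosteriorSample(mu=mu, alpha=alpha, weights=w, ess=ess)
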