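"""Likelihoods and priors for the three fruit-production analyses.

Three regressions share one linear predictor. For tree i of species j,

    eta_ij = x_i' beta_j + beta_j,crowd * (NCI_i(alpha_j, nu_j) / scale) + eps_i

with species coefficients pooled hierarchically,

    beta_j ~ MVNormal(mu, Sigma),

individual random effects eps_i ~ Normal(0, precision tau), and crowding
shape parameters alpha_j, nu_j ~ Gamma(1, 1) estimated inside the
likelihood (present only when the covariate set includes NCI/ANCI).

Binomial analysis: reproductive status R_i ~ Bernoulli(logit^-1(eta)).

Ordinal analyses: the K-category response follows a cumulative-logit
(proportional-odds) model with cut points gamma,

    logit(Q_k) = gamma_k - eta,      pi_k = Q_k - Q_{k-1},

Q_0 = 0, Q_K = 1, and identification gamma_1 = 0 < gamma_2 < ... The
all-individual analysis uses K = 4; the reproductive-only analysis drops
the zero-fruit category and uses K = 3 (codes relabeled 1..3).

Hyperpriors (vague, WinBUGS-style precision parameterization): mu elements
Normal(0, SD 100); Sigma ~ inverse-Wishart(identity, dim + 2); tau ~
Gamma(0.001, 0.001); free cut points flat subject to ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from scipy.special import expit, logsumexp  # noqa: F401  (expit used widely)

from fruitprod.covariates import DesignMatrix

__all__ = [
    "PriorConfig",
    "ModelParams",
    "BinomialModel",
    "OrdinalModel",
    "cumulative_category_probs",
    "linear_predictor",
    "binomial_loglik",
    "ordinal_loglik",
    "log_prior",
]


@dataclass(frozen=True)
class PriorConfig:
    """Hyperprior settings; defaults are the vague choices described above."""

    mu_sd: float = 100.0
    sigma_scale: float = 1.0          # inverse-Wishart scale matrix = c*I
    sigma_df_extra: float = 2.0       # df = dim + extra
    tau_shape: float = 0.001
    tau_rate: float = 0.001
    alpha_shape: float = 1.0
    alpha_rate: float = 1.0
    nu_shape: float = 1.0
    nu_rate: float = 1.0
    beta_sd_flat: float = 100.0       # used when hierarchy is off


@dataclass
class ModelParams:
    """One point in parameter space.

    ``beta`` is (n_species, n_coef); the last coefficient is the crowding
    slope when the design includes NCI/ANCI. ``gamma`` is the full cut-point
    vector of length K-1 with gamma[0] fixed at 0 (``None`` for binomial
    models). ``alpha``/``nu`` are per-species crowding shape parameters
    (``None`` without a crowding term). ``tau`` is a precision.
    """

    beta: np.ndarray
    mu: np.ndarray
    Sigma: np.ndarray
    eps: np.ndarray
    tau: float = 1.0
    alpha: np.ndarray | None = None
    nu: np.ndarray | None = None
    gamma: np.ndarray | None = None

    def copy(self) -> "ModelParams":
        return replace(
            self,
            beta=self.beta.copy(),
            mu=self.mu.copy(),
            Sigma=self.Sigma.copy(),
            eps=self.eps.copy(),
            alpha=None if self.alpha is None else self.alpha.copy(),
            nu=None if self.nu is None else self.nu.copy(),
            gamma=None if self.gamma is None else self.gamma.copy(),
        )


def cumulative_category_probs(eta, gamma, K: int | None = None) -> np.ndarray:
    """Category probabilities pi_1..pi_K of the cumulative-logit model.

    ``gamma`` is the full cut-point vector (length K-1, first element 0,
    strictly increasing). ``eta`` may be scalar or an array; the returned
    array has a trailing axis of length K. Increasing eta moves probability
    mass toward higher categories.
    """
    gamma = np.asarray(gamma, dtype=float)
    if K is None:
        K = len(gamma) + 1
    if len(gamma) != K - 1:
        raise ValueError(f"need {K - 1} cut points for K={K}, got {len(gamma)}")
    if gamma[0] != 0.0 or np.any(np.diff(gamma) <= 0):
        raise ValueError("cut points must satisfy 0 = gamma_1 < gamma_2 < ...")
    eta_arr = np.asarray(eta, dtype=float)
    q = expit(gamma - eta_arr[..., None])          # (..., K-1)
    shape = eta_arr.shape + (1,)
    q_full = np.concatenate(
        [np.zeros(shape), q, np.ones(shape)], axis=-1
    )
    return np.diff(q_full, axis=-1)


def bernoulli_loglik_terms(eta: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Stable per-unit Bernoulli log-likelihood at p = logit^-1(eta)."""
    sign = 1.0 - 2.0 * y  # y=1 -> -1, y=0 -> +1
    return -np.logaddexp(0.0, sign * eta)


def ordinal_loglik_terms(
    eta: np.ndarray, y: np.ndarray, gamma: np.ndarray, K: int
) -> np.ndarray:
    """Stable per-observation log pi_y for the cumulative-logit model.

    ``y`` holds 1-based category codes. Internal cells use
    log(expit(a) - expit(b)) = b + log(expm1(a-b)) - log1pexp(a) - log1pexp(b)
    with a, b the upper/lower cut points shifted by eta.
    """
    y = np.asarray(y)
    if np.any((y < 1) | (y > K)):
        raise ValueError(f"categories must lie in 1..{K}")
    out = np.empty(len(y))
    lo = y == 1
    hi = y == K
    mid = ~(lo | hi)
    if lo.any():
        out[lo] = -np.logaddexp(0.0, eta[lo] - gamma[0])
    if hi.any():
        out[hi] = -np.logaddexp(0.0, gamma[K - 2] - eta[hi])
    if mid.any():
        a = gamma[y[mid] - 1] - eta[mid]
        b = gamma[y[mid] - 2] - eta[mid]
        out[mid] = (
            b
            + np.log(np.expm1(a - b))
            - np.logaddexp(0.0, a)
            - np.logaddexp(0.0, b)
        )
    return out


class _BaseModel:
    """Shared structure for the binomial and ordinal regressions."""

    is_ordinal: bool

    def __init__(
        self,
        design: DesignMatrix,
        y: np.ndarray,
        obs_tree_index: np.ndarray | None = None,
        hierarchical: bool = True,
        random_effects: bool = True,
        prior: PriorConfig | None = None,
        crowding_shapes: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> None:
        self.design = design
        self.y = np.asarray(y, dtype=int)
        if obs_tree_index is None:
            obs_tree_index = np.arange(design.n_trees)
        self.obs_tree_index = np.asarray(obs_tree_index, dtype=np.int64)
        if len(self.y) != len(self.obs_tree_index):
            raise ValueError("y and obs_tree_index must align")
        if self.obs_tree_index.max(initial=-1) >= design.n_trees:
            raise ValueError("obs_tree_index out of range")
        self.hierarchical = hierarchical
        self.random_effects = random_effects
        self.prior = prior or PriorConfig()
        # Optionally condition on known crowding shapes (alpha_j, nu_j).
        # The index scale DBH^alpha is only weakly identified from a single
        # stem map (every neighborhood shares nearly the same size
        # composition), so recovery experiments may fix the shapes.
        self.fixed_shapes = None
        if crowding_shapes is not None:
            if design.crowding is None:
                raise ValueError("crowding_shapes given but the covariate "
                                 "set has no crowding term")
            a, v = (np.asarray(x, dtype=float) for x in crowding_shapes)
            if (a <= 0).any() or (v <= 0).any():
                raise ValueError("crowding shapes must be positive")
            if len(a) != design.n_species or len(v) != design.n_species:
                raise ValueError("need one (alpha, nu) pair per species")
            self.fixed_shapes = (a, v)

    # -- structure ---------------------------------------------------------
    @property
    def n_trees(self) -> int:
        return self.design.n_trees

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def n_species(self) -> int:
        return self.design.n_species

    @property
    def n_coef(self) -> int:
        return self.design.n_coef

    @property
    def has_crowding(self) -> bool:
        return self.design.crowding is not None

    # -- likelihood --------------------------------------------------------
    def loglik_terms(self, eta_tree: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def systematic_eta(self, params: ModelParams) -> np.ndarray:
        """Fixed-effects part of eta (no eps): X beta + crowding term."""
        d = self.design
        beta = np.asarray(params.beta, dtype=float)
        p_fixed = d.X.shape[1]
        eta = np.einsum("np,np->n", d.X, beta[d.species_index, :p_fixed])
        if self.has_crowding:
            if params.alpha is None or params.nu is None:
                raise ValueError("crowding model needs alpha and nu")
            for j in range(d.n_species):
                rows = d.species_rows(j)
                nci = d.nci_values(j, float(params.alpha[j]),
                                   float(params.nu[j]))
                eta[rows] += beta[j, -1] * nci
        return eta

    def eta(self, params: ModelParams) -> np.ndarray:
        eta = self.systematic_eta(params)
        if self.random_effects:
            eta = eta + params.eps
        return eta

    def loglik(self, params: ModelParams) -> float:
        return float(self.loglik_terms(self.eta(params)).sum())

    def deviance(self, params: ModelParams) -> float:
        return -2.0 * self.loglik(params)

    # -- prior -------------------------------------------------------------
    def log_prior(self, params: ModelParams) -> float:
        pr = self.prior
        beta = params.beta
        p = beta.shape[1]
        total = 0.0
        if self.hierarchical:
            try:
                total += float(
                    stats.multivariate_normal.logpdf(
                        beta, mean=params.mu, cov=params.Sigma
                    ).sum()
                )
            except (np.linalg.LinAlgError, ValueError):
                return -np.inf
            total += float(
                stats.norm.logpdf(params.mu, 0.0, pr.mu_sd).sum()
            )
            try:
                total += float(
                    stats.invwishart.logpdf(
                        params.Sigma,
                        df=p + pr.sigma_df_extra,
                        scale=pr.sigma_scale * np.eye(p),
                    )
                )
            except (np.linalg.LinAlgError, ValueError):
                return -np.inf
        else:
            total += float(
                stats.norm.logpdf(beta, 0.0, pr.beta_sd_flat).sum()
            )
        if self.random_effects:
            if params.tau <= 0:
                return -np.inf
            sd = 1.0 / np.sqrt(params.tau)
            total += float(stats.norm.logpdf(params.eps, 0.0, sd).sum())
            total += float(
                stats.gamma.logpdf(params.tau, pr.tau_shape,
                                   scale=1.0 / pr.tau_rate)
            )
        if self.has_crowding:
            a, v = params.alpha, params.nu
            if a is None or v is None or (a <= 0).any() or (v <= 0).any():
                return -np.inf
            total += float(
                stats.gamma.logpdf(a, pr.alpha_shape,
                                   scale=1.0 / pr.alpha_rate).sum()
            )
            total += float(
                stats.gamma.logpdf(v, pr.nu_shape,
                                   scale=1.0 / pr.nu_rate).sum()
            )
        if self.is_ordinal:
            g = params.gamma
            if g is None or g[0] != 0.0 or np.any(np.diff(g) <= 0):
                return -np.inf
            # flat improper prior on free cut points given the ordering
        return total

    def log_posterior(self, params: ModelParams) -> float:
        lp = self.log_prior(params)
        if not np.isfinite(lp):
            return -np.inf
        return lp + self.loglik(params)

    # -- initialization ----------------------------------------------------
    def init_params(self, rng: np.random.Generator,
                    jitter: float = 0.1) -> ModelParams:
        """Overdispersed starting point.

        Intercepts start at empirical logits of species response rates,
        other coefficients at 0 (plus chain-specific jitter); eps = 0,
        alpha = nu = 1, cut points from pooled empirical cumulative logits.
        """
        d = self.design
        p = self.n_coef
        beta = np.zeros((d.n_species, p))
        obs_sp = d.species_index[self.obs_tree_index]
        for j in range(d.n_species):
            yj = self.y[obs_sp == j]
            if len(yj) == 0:
                continue
            if self.is_ordinal:
                frac = np.clip(np.mean(yj > 1), 0.02, 0.98)
            else:
                frac = np.clip(np.mean(yj), 0.02, 0.98)
            beta[j, 0] = np.log(frac / (1 - frac))
        beta += jitter * rng.standard_normal(beta.shape)
        gamma = None
        if self.is_ordinal:
            K = self.K
            cum = np.array([np.mean(self.y <= k) for k in range(1, K)])
            cum = np.clip(cum, 0.02, 0.98)
            raw = np.log(cum / (1 - cum))
            raw = raw - raw[0]
            raw[1:] += jitter * np.abs(rng.standard_normal(K - 2))
            gamma = np.maximum.accumulate(raw)
            for k in range(1, K - 1):  # enforce strict ordering
                if gamma[k] <= gamma[k - 1]:
                    gamma[k] = gamma[k - 1] + 0.1
        if self.fixed_shapes is not None:
            alpha0, nu0 = (x.copy() for x in self.fixed_shapes)
        elif self.has_crowding:
            alpha0, nu0 = np.ones(d.n_species), np.ones(d.n_species)
        else:
            alpha0 = nu0 = None
        return ModelParams(
            beta=beta,
            mu=beta.mean(axis=0),
            Sigma=np.eye(p),
            eps=np.zeros(self.n_trees),
            tau=1.0,
            alpha=alpha0,
            nu=nu0,
            gamma=gamma,
        )


class BinomialModel(_BaseModel):
    """Bernoulli regression of binary reproductive status on the design."""

    is_ordinal = False
    K = 2

    def __init__(self, design, status, **kwargs) -> None:
        status = np.asarray(status, dtype=int)
        if not np.isin(status, (0, 1)).all():
            raise ValueError("statuses must be 0/1")
        super().__init__(design, status, **kwargs)

    def loglik_terms(self, eta_tree: np.ndarray) -> np.ndarray:
        return bernoulli_loglik_terms(eta_tree[self.obs_tree_index], self.y)


class OrdinalModel(_BaseModel):
    """Cumulative-logit regression of ordinal fruit categories.

    ``K=4`` for the all-individual analysis; ``K=3`` for the
    reproductive-only analysis, whose responses must be relabeled 1..3
    (original categories 2..4) before fitting — the zero-fruit category
    receives no probability there. ``obs_tree_index`` permits several
    observations per tree (repeated periods sharing one eps_i); by default
    each tree contributes a single response (e.g. the max-category
    reduction).
    """

    is_ordinal = True

    def __init__(self, design, categories, K: int = 4, **kwargs) -> None:
        self.K = int(K)
        categories = np.asarray(categories, dtype=int)
        if len(categories) and (categories.min() < 1
                                or categories.max() > self.K):
            raise ValueError(f"categories must lie in 1..{self.K}")
        super().__init__(design, categories, **kwargs)

    def loglik_terms(self, eta_tree: np.ndarray) -> np.ndarray:
        return ordinal_loglik_terms(
            eta_tree[self.obs_tree_index], self.y, self._gamma, self.K
        )

    # gamma is not part of eta, so thread it through a slot the sampler and
    # loglik() can set; public API passes params explicitly.
    _gamma: np.ndarray | None = None

    def loglik(self, params: ModelParams) -> float:
        self._gamma = np.asarray(params.gamma, dtype=float)
        try:
            return float(self.loglik_terms(self.eta(params)).sum())
        finally:
            self._gamma = None


# ---------------------------------------------------------------------------
# Functional wrappers matching the operation contracts


def linear_predictor(params: ModelParams, design: DesignMatrix,
                     random_effects: bool = True) -> np.ndarray:
    """eta for every tree in the design at the given parameters."""
    model = BinomialModel(design, np.zeros(design.n_trees, dtype=int),
                          random_effects=random_effects)
    return model.eta(params) if random_effects else model.systematic_eta(params)


def binomial_loglik(params: ModelParams, statuses, design: DesignMatrix,
                    **kwargs) -> float:
    return BinomialModel(design, statuses, **kwargs).loglik(params)


def ordinal_loglik(params: ModelParams, categories, design: DesignMatrix,
                   K: int = 4, **kwargs) -> float:
    return OrdinalModel(design, categories, K=K, **kwargs).loglik(params)


def log_prior(params: ModelParams, model: _BaseModel) -> float:
    return model.log_prior(params)
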