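"""MCMC fitting of the fruit-production models, diagnostics, and summaries.

The sampler is a blocked adaptive random-walk Metropolis-within-Gibbs:

* each species gets one random-walk block holding its coefficient vector
  beta_j together with (log alpha_j, log nu_j) when the crowding shapes
  are estimated — the crowding slope and log alpha share an exponential
  posterior ridge (DBH^alpha rescales the whole index), so they must move
  with an adaptively-learned correlated proposal; the species' crowding
  indices are recomputed at each proposed shape pair;
* all individual random effects eps_i update in parallel single-site moves
  (the likelihood factorizes over trees, so the vector of independent
  proposals is accepted/rejected elementwise in one pass);
* the free cut points update jointly, with out-of-order proposals rejected;
* the hyperparameters mu, Sigma and the random-effect precision tau have
  conjugate full-conditional draws (normal, inverse-Wishart, gamma).

Step sizes adapt by Robbins-Monro toward standard acceptance targets during
burn-in only, so the retained chain is a valid Markov chain. The deviance
-2 log L is recorded at every retained draw for DIC. Runs are reproducible:
a single integer seed spawns independent per-chain generators.

Two named protocols are shipped: ``TEST_SCALE`` (3 chains x 5,000, burn-in
1,000) for desk-scale experiments, and the full field protocols
``FIELD_SCALE_BINOMIAL`` (3 x 50,000 retained after 10,000 burn-in) and
``FIELD_SCALE_MULTINOMIAL`` (3 x 100,000, thin 10).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import linalg, stats

from fruitprod.model_core import (
    ModelParams,
    _BaseModel,
    bernoulli_loglik_terms,
    ordinal_loglik_terms,
)

__all__ = [
    "McmcConfig",
    "PosteriorSamples",
    "TEST_SCALE",
    "FIELD_SCALE_BINOMIAL",
    "FIELD_SCALE_MULTINOMIAL",
    "run_mcmc",
    "gelman_rubin",
    "summarize_posterior",
    "adaptive_metropolis",
]


@dataclass(frozen=True)
class McmcConfig:
    """Chain protocol: lengths, thinning, seed, adaptation targets."""

    n_chains: int = 3
    n_iterations: int = 5_000
    n_burnin: int = 1_000
    thin: int = 1
    seed: int = 0
    target_accept_block: float = 0.234
    target_accept_scalar: float = 0.44
    adapt_decay: float = 0.6

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iterations:
            raise ValueError("n_burnin must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.n_burnin) // self.thin

    def with_seed(self, seed: int) -> "McmcConfig":
        from dataclasses import replace

        return replace(self, seed=seed)


TEST_SCALE = McmcConfig(n_chains=3, n_iterations=5_000, n_burnin=1_000)
FIELD_SCALE_BINOMIAL = McmcConfig(
    n_chains=3, n_iterations=60_000, n_burnin=10_000, thin=1
)
FIELD_SCALE_MULTINOMIAL = McmcConfig(
    n_chains=3, n_iterations=110_000, n_burnin=10_000, thin=10
)


@dataclass
class PosteriorSamples:
    """Retained draws for every sampled block, plus the deviance trace.

    ``arrays`` maps parameter names to arrays of shape (chains, draws, ...).
    Individual random effects are summarized (pooled mean/SD per tree)
    rather than stored draw-by-draw; their posterior means enter DIC.
    """

    arrays: dict[str, np.ndarray]
    deviance: np.ndarray
    eps_mean: np.ndarray
    eps_sd: np.ndarray
    config: McmcConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.deviance.shape[0]

    @property
    def n_draws(self) -> int:
        return self.deviance.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """Draws pooled across chains: shape (chains*draws, ...)."""
        a = self.arrays[name]
        return a.reshape(-1, *a.shape[2:])

    def posterior_mean_params(self) -> ModelParams:
        """theta-bar: posterior means of all sampled quantities.

        Cut points are averaged directly (they live on an unconstrained
        scale up to the ordering) and re-sorted for safety.
        """
        beta = self.flat("beta").mean(axis=0)
        mu = self.flat("mu").mean(axis=0) if "mu" in self.arrays else (
            beta.mean(axis=0) if beta.ndim == 2 else beta
        )
        Sigma = (
            self.flat("Sigma").mean(axis=0)
            if "Sigma" in self.arrays else np.eye(beta.shape[-1])
        )
        tau = (
            float(self.flat("tau").mean()) if "tau" in self.arrays else 1.0
        )
        gamma = None
        if "gamma" in self.arrays:
            gamma = np.sort(self.flat("gamma").mean(axis=0))
            gamma[0] = 0.0
        return ModelParams(
            beta=beta,
            mu=mu,
            Sigma=Sigma,
            eps=self.eps_mean.copy(),
            tau=tau,
            alpha=(self.flat("alpha").mean(axis=0)
                   if "alpha" in self.arrays else None),
            nu=(self.flat("nu").mean(axis=0)
                if "nu" in self.arrays else None),
            gamma=gamma,
        )

    def scalar_elements(self):
        """Yield (label, (chains, draws) array) for every scalar element."""
        species = self.meta.get("species", None)
        coef = self.meta.get("coef_names", None)
        for name, a in self.arrays.items():
            if a.ndim == 2:
                yield name, a
            elif a.ndim == 3:
                if name == "gamma":
                    continue  # labeled 1-based below
                for k in range(a.shape[2]):
                    lab = None
                    if name in ("alpha", "nu") and species:
                        lab = f"{name}[{species[k]}]"
                    elif name == "mu" and coef:
                        lab = f"mu[{coef[k]}]"
                    yield lab or f"{name}[{k}]", a[:, :, k]
            elif a.ndim == 4 and name == "Sigma":
                for r in range(a.shape[2]):
                    for c in range(r, a.shape[3]):
                        yield f"Sigma[{r},{c}]", a[:, :, r, c]
        if "beta" in self.arrays:
            b = self.arrays["beta"]
            for j in range(b.shape[2]):
                for c in range(b.shape[3]):
                    sp = species[j] if species else str(j)
                    cf = coef[c] if coef else str(c)
                    yield f"beta[{sp},{cf}]", b[:, :, j, c]
        if "gamma" in self.arrays and self.arrays["gamma"].ndim == 3:
            g = self.arrays["gamma"]
            for k in range(g.shape[2]):
                yield f"gamma[{k + 1}]", g[:, :, k]

    def save(self, path) -> None:
        """Columnar text: '#' JSON metadata header then CSV of draws."""
        labels, cols = [], []
        for lab, a in self.scalar_elements():
            labels.append(lab)
            cols.append(a.reshape(-1))
        dev = self.deviance.reshape(-1)
        c, d = self.deviance.shape
        df = pd.DataFrame(dict(zip(labels, cols)))
        df.insert(0, "chain", np.repeat(np.arange(c), d))
        df.insert(1, "draw", np.tile(np.arange(d), c))
        df["deviance"] = dev
        header = {
            "config": asdict(self.config),
            "meta": {k: v for k, v in self.meta.items()
                     if isinstance(v, (str, int, float, list))},
            "eps_mean": self.eps_mean.tolist(),
            "eps_sd": self.eps_sd.tolist(),
        }
        with open(path, "w") as fh:
            fh.write("# " + json.dumps(header) + "\n")
            df.to_csv(fh, index=False, lineterminator="\n")

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        """Rebuild samples from the columnar text format written by save."""
        with open(path) as fh:
            first = fh.readline()
            if not first.startswith("#"):
                raise ValueError("missing metadata header line")
            header = json.loads(first[1:].strip())
            df = pd.read_csv(fh)
        config = McmcConfig(**header["config"])
        meta = header["meta"]
        c = int(df["chain"].max()) + 1
        d = int(df["draw"].max()) + 1
        species = meta.get("species", [])
        coef = meta.get("coef_names", [])
        J, P = len(species), len(coef)

        def grab(col):
            return df[col].to_numpy().reshape(c, d)

        arrays: dict[str, np.ndarray] = {}
        if "tau" in df.columns:
            arrays["tau"] = grab("tau")
        if all(f"mu[{cf}]" in df.columns for cf in coef) and P:
            arrays["mu"] = np.stack(
                [grab(f"mu[{cf}]") for cf in coef], axis=-1
            )
        if P and f"Sigma[0,0]" in df.columns:
            sig = np.empty((c, d, P, P))
            for r in range(P):
                for s in range(r, P):
                    block = grab(f"Sigma[{r},{s}]")
                    sig[:, :, r, s] = block
                    sig[:, :, s, r] = block
            arrays["Sigma"] = sig
        if J and P and f"beta[{species[0]},{coef[0]}]" in df.columns:
            beta = np.empty((c, d, J, P))
            for j, sp in enumerate(species):
                for k, cf in enumerate(coef):
                    beta[:, :, j, k] = grab(f"beta[{sp},{cf}]")
            arrays["beta"] = beta
        for name in ("alpha", "nu"):
            cols = [f"{name}[{sp}]" for sp in species]
            if cols and all(col in df.columns for col in cols):
                arrays[name] = np.stack([grab(col) for col in cols], axis=-1)
        gcols = sorted(
            (col for col in df.columns if col.startswith("gamma[")),
            key=lambda s: int(s[6:-1]),
        )
        if gcols:
            arrays["gamma"] = np.stack([grab(col) for col in gcols], axis=-1)
        return cls(
            arrays=arrays,
            deviance=grab("deviance"),
            eps_mean=np.asarray(header["eps_mean"], dtype=float),
            eps_sd=np.asarray(header["eps_sd"], dtype=float),
            config=config,
            meta=meta,
        )


def data_fingerprint(model: _BaseModel) -> str:
    """Hash of the response and tree identities defining a data subset."""
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(model.y).tobytes())
    h.update(np.ascontiguousarray(model.obs_tree_index).tobytes())
    h.update(",".join(map(str, model.design.tree_id)).encode())
    h.update(str(getattr(model, "K", 2)).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Sampler internals


def _acc_prob(log_r: float) -> float:
    """min(1, exp(log_r)) with non-finite ratios treated as rejection."""
    if not np.isfinite(log_r):
        return 0.0
    return float(np.exp(min(log_r, 0.0)))


class _Adapt:
    """Robbins-Monro log-step adaptation toward a target acceptance rate."""

    def __init__(self, step: float, target: float, decay: float) -> None:
        self.log_step = np.log(step)
        self.target = target
        self.decay = decay

    @property
    def step(self) -> float:
        return float(np.exp(self.log_step))

    def update(self, t: int, acc_prob: float) -> None:
        self.log_step += (t + 1.0) ** (-self.decay) * (acc_prob - self.target)


class _AdaptCov:
    """Adaptive-covariance random-walk proposal for one parameter block.

    Combines a Haario-style empirical proposal covariance (learned from the
    chain during burn-in, refreshed periodically) with Robbins-Monro global
    scale adaptation toward the multivariate acceptance target. Posterior
    ridges — e.g. intercept vs crowding slope, or the two crowding shape
    parameters — need correlated proposals to mix. Frozen after burn-in.
    """

    def __init__(self, dim: int, step: float, target: float, decay: float,
                 start: int = 300, refresh: int = 50) -> None:
        self.dim = dim
        self.log_scale = np.log(step)
        self.target = target
        self.decay = decay
        self.start = start
        self.refresh = refresh
        self.mean = np.zeros(dim)
        self.m2 = np.zeros((dim, dim))
        self.count = 0
        self.chol = np.eye(dim)

    def record(self, x: np.ndarray) -> None:
        """Accumulate the current state into the running covariance."""
        self.count += 1
        d = x - self.mean
        self.mean += d / self.count
        self.m2 += np.outer(d, x - self.mean)
        if self.count >= self.start and self.count % self.refresh == 0:
            cov = self.m2 / (self.count - 1) + 1e-6 * np.eye(self.dim)
            try:
                self.chol = np.linalg.cholesky(cov)
            except np.linalg.LinAlgError:
                pass

    def propose(self, x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        scale = np.exp(self.log_scale) * 2.38 / np.sqrt(self.dim)
        return x + scale * (self.chol @ rng.standard_normal(self.dim))

    def update(self, t: int, acc_prob: float) -> None:
        self.log_scale += (t + 1.0) ** (-self.decay) * (acc_prob - self.target)


def _make_ll(y: np.ndarray, ordinal: bool, K: int):
    """Loglik-term evaluator specialized to a fixed response vector.

    Category masks are precomputed once so each call is a handful of
    vector operations; non-finite eta yields -inf terms (proposals that
    blow up are rejected, never propagated as NaN).
    """
    if not ordinal:
        sign = 1.0 - 2.0 * y

        def f(eta, gamma=None):
            out = -np.logaddexp(0.0, sign * eta)
            return np.where(np.isfinite(out), out, -np.inf)

        return f
    lo = np.flatnonzero(y == 1)
    hi = np.flatnonzero(y == K)
    mid = np.flatnonzero((y > 1) & (y < K))
    y_mid = y[mid]

    def f(eta, gamma):
        out = np.empty(len(y))
        out[lo] = -np.logaddexp(0.0, eta[lo] - gamma[0])
        out[hi] = -np.logaddexp(0.0, gamma[K - 2] - eta[hi])
        if len(mid):
            a = gamma[y_mid - 1] - eta[mid]
            b = gamma[y_mid - 2] - eta[mid]
            with np.errstate(over="ignore", invalid="ignore",
                             divide="ignore"):
                out[mid] = (
                    b + np.log(np.expm1(a - b))
                    - np.logaddexp(0.0, a) - np.logaddexp(0.0, b)
                )
        return np.where(np.isfinite(out), out, -np.inf)

    return f


def _chain(model: _BaseModel, config: McmcConfig, rng: np.random.Generator):
    d = model.design
    pr = model.prior
    J = d.n_species
    pc = model.n_coef
    p_fixed = d.X.shape[1]
    n = d.n_trees
    y = model.y
    oti = model.obs_tree_index
    ordinal = model.is_ordinal
    K = model.K
    crowding = model.has_crowding

    sp_rows = [d.species_rows(j) for j in range(J)]
    X_sp = [d.X[r] for r in sp_rows]
    obs_sp = d.species_index[oti]
    sp_obs = [np.flatnonzero(obs_sp == j) for j in range(J)]
    loc = []
    for j in range(J):
        pos = np.full(n, -1, dtype=np.int64)
        pos[sp_rows[j]] = np.arange(len(sp_rows[j]))
        loc.append(pos[oti[sp_obs[j]]])
    y_sp = [y[o] for o in sp_obs]
    ll_full = _make_ll(y, ordinal, K)
    ll_sp = [_make_ll(yj, ordinal, K) for yj in y_sp]

    # --- initialization, with re-tries on a non-finite posterior ----------
    params = None
    for attempt in range(5):
        cand = model.init_params(rng, jitter=0.1 * (attempt + 1))
        if np.isfinite(model.log_posterior(cand)):
            params = cand
            break
    if params is None:
        raise RuntimeError("could not find a finite starting point")

    beta = params.beta.copy()
    eps = params.eps.copy()
    tau = params.tau
    alpha = params.alpha.copy() if crowding else None
    nu = params.nu.copy() if crowding else None
    gamma = params.gamma.copy() if ordinal else None
    mu = params.mu.copy()
    Sigma = params.Sigma.copy()
    Sigma_inv = np.linalg.inv(Sigma)

    nci = [
        d.nci_values(j, float(alpha[j]), float(nu[j])) if crowding else None
        for j in range(J)
    ]

    def species_eta_sys(j, b):
        e = X_sp[j] @ b[:p_fixed]
        if crowding:
            e = e + b[-1] * nci[j]
        return e

    eta_sys = np.empty(n)
    for j in range(J):
        eta_sys[sp_rows[j]] = species_eta_sys(j, beta[j])
    cur_terms = ll_full(eta_sys[oti] + eps[oti], gamma)

    est_shapes = crowding and model.fixed_shapes is None
    block_dim = pc + (2 if est_shapes else 0)
    steps_beta = [_AdaptCov(block_dim, 0.1, config.target_accept_block,
                            config.adapt_decay) for _ in range(J)]
    step_eps = _Adapt(0.5, config.target_accept_scalar, config.adapt_decay)
    step_scale = _Adapt(0.2, config.target_accept_scalar,
                        config.adapt_decay)
    step_gam = _Adapt(0.1, config.target_accept_block, config.adapt_decay)

    n_ret = config.n_retained_per_chain
    out = {
        "beta": np.empty((n_ret, J, pc)),
        "mu": np.empty((n_ret, pc)),
        "Sigma": np.empty((n_ret, pc, pc)),
        "tau": np.empty(n_ret),
    }
    if crowding:
        out["alpha"] = np.empty((n_ret, J))
        out["nu"] = np.empty((n_ret, J))
    if ordinal:
        out["gamma"] = np.empty((n_ret, K - 1))
    if not model.hierarchical:
        out.pop("mu")
        out.pop("Sigma")
    if not model.random_effects:
        out.pop("tau", None)
    deviance = np.empty(n_ret)
    eps_sum = np.zeros(n)
    eps_sq = np.zeros(n)

    mu_prec_prior = 1.0 / pr.mu_sd**2
    flat_prec = 1.0 / pr.beta_sd_flat**2

    ret = 0
    for t in range(config.n_iterations):
        adapt = t < config.n_burnin

        # ----- species blocks: beta and crowding shapes jointly -----------
        # The crowding slope rides an exponential ridge with log(alpha)
        # (DBH^alpha rescales the whole index), so beta_j and the two
        # shape parameters must move as one adaptively-correlated block.
        for j in range(J):
            r = sp_rows[j]
            o = sp_obs[j]
            b = beta[j]
            if est_shapes:
                la0, ln0 = np.log(alpha[j]), np.log(nu[j])
                prop = steps_beta[j].propose(
                    np.concatenate([b, [la0, ln0]]), rng
                )
                b_new = prop[:pc]
                la, ln = prop[pc], prop[pc + 1]
                a_new, v_new = np.exp(la), np.exp(ln)
                nci_new = d.nci_values(j, a_new, v_new)
                eta_new = X_sp[j] @ b_new[:p_fixed] + b_new[-1] * nci_new
            else:
                b_new = steps_beta[j].propose(b, rng)
                eta_new = species_eta_sys(j, b_new)
            new_terms = ll_sp[j]((eta_new + eps[r])[loc[j]], gamma)
            dll = new_terms.sum() - cur_terms[o].sum()
            if model.hierarchical:
                rc, rp = b - mu, b_new - mu
                dlp = -0.5 * (rp @ Sigma_inv @ rp - rc @ Sigma_inv @ rc)
            else:
                dlp = -0.5 * flat_prec * (b_new @ b_new - b @ b)
            if est_shapes:
                # Gamma priors on alpha, nu plus the log-scale Jacobian
                dlp += (
                    pr.alpha_shape * (la - la0)
                    - pr.alpha_rate * (a_new - alpha[j])
                    + pr.nu_shape * (ln - ln0)
                    - pr.nu_rate * (v_new - nu[j])
                )
            log_r = dll + dlp
            if np.isfinite(log_r) and np.log(rng.uniform()) < log_r:
                beta[j] = b_new
                eta_sys[r] = eta_new
                cur_terms[o] = new_terms
                if est_shapes:
                    alpha[j], nu[j] = a_new, v_new
                    nci[j] = nci_new
            if adapt:
                steps_beta[j].update(t, _acc_prob(log_r))
                rec = (np.concatenate(
                    [beta[j], [np.log(alpha[j]), np.log(nu[j])]]
                ) if est_shapes else beta[j])
                steps_beta[j].record(rec)

        # ----- individual random effects (parallel single-site) ----------
        if model.random_effects:
            prop = eps + step_eps.step * rng.standard_normal(n)
            new_terms = ll_full(eta_sys[oti] + prop[oti], gamma)
            dll_tree = np.bincount(oti, weights=new_terms - cur_terms,
                                   minlength=n)
            log_r = dll_tree - 0.5 * tau * (prop**2 - eps**2)
            log_r = np.where(np.isnan(log_r), -np.inf, log_r)
            acc = np.log(rng.uniform(size=n)) < log_r
            eps[acc] = prop[acc]
            acc_obs = acc[oti]
            cur_terms[acc_obs] = new_terms[acc_obs]
            if adapt:
                with np.errstate(over="ignore"):
                    step_eps.update(
                        t,
                        float(np.minimum(
                            1.0, np.exp(np.minimum(log_r, 0.0))).mean()),
                    )

            # joint rescale of (eps, tau) along the prior-preserving ridge
            # (interweaving move): eps' = c*eps, tau' = tau/c^2. The eps
            # prior and the Jacobian cancel to -2a*log c - b*(tau'-tau),
            # so the move slides the weakly identified scale of the random
            # effects at essentially the likelihood ratio — without it,
            # tau (and hence pD/DIC) mixes far too slowly.
            lc = step_scale.step * rng.standard_normal()
            c = np.exp(lc)
            eps_p = c * eps
            new_terms = ll_full(eta_sys[oti] + eps_p[oti], gamma)
            tau_p = tau / c**2
            dll = new_terms.sum() - cur_terms.sum()
            dlp = -2.0 * pr.tau_shape * lc - pr.tau_rate * (tau_p - tau)
            log_r2 = dll + dlp
            if np.isfinite(log_r2) and np.log(rng.uniform()) < log_r2:
                eps = eps_p
                tau = tau_p
                cur_terms = new_terms
            if adapt:
                step_scale.update(t, _acc_prob(log_r2))

        # ----- cut points -------------------------------------------------
        if ordinal and K > 2:
            free = gamma[1:] + step_gam.step * rng.standard_normal(K - 2)
            cand = np.concatenate([[0.0], free])
            if np.all(np.diff(cand) > 0):
                new_terms = ll_full(eta_sys[oti] + eps[oti], cand)
                dll = new_terms.sum() - cur_terms.sum()
                if np.isfinite(dll) and np.log(rng.uniform()) < dll:
                    gamma = cand
                    cur_terms = new_terms
                if adapt:
                    step_gam.update(t, _acc_prob(dll))
            elif adapt:
                step_gam.update(t, 0.0)

        # ----- conjugate hyper draws --------------------------------------
        if model.hierarchical:
            prec = J * Sigma_inv + mu_prec_prior * np.eye(pc)
            L = np.linalg.cholesky(prec)
            m = np.linalg.solve(prec, Sigma_inv @ beta.sum(axis=0))
            mu = m + linalg.solve_triangular(
                L.T, rng.standard_normal(pc), lower=False
            )
            dev = beta - mu
            S = dev.T @ dev
            Sigma = stats.invwishart.rvs(
                df=pc + pr.sigma_df_extra + J,
                scale=pr.sigma_scale * np.eye(pc) + S,
                random_state=rng,
            )
            Sigma = np.atleast_2d(Sigma)
            Sigma_inv = np.linalg.inv(Sigma)
        if model.random_effects:
            tau = rng.gamma(
                pr.tau_shape + 0.5 * n,
                1.0 / (pr.tau_rate + 0.5 * float(eps @ eps)),
            )

        # tau moved, so the eps prior used by the next iteration's
        # acceptance ratios changes; cur_terms (likelihood only) is intact.

        # ----- record -----------------------------------------------------
        if t >= config.n_burnin and (t - config.n_burnin) % config.thin == 0:
            out["beta"][ret] = beta
            if model.hierarchical:
                out["mu"][ret] = mu
                out["Sigma"][ret] = Sigma
            if model.random_effects:
                out["tau"][ret] = tau
            if crowding:
                out["alpha"][ret] = alpha
                out["nu"][ret] = nu
            if ordinal:
                out["gamma"][ret] = gamma
            deviance[ret] = -2.0 * cur_terms.sum()
            eps_sum += eps
            eps_sq += eps**2
            ret += 1

    return out, deviance, eps_sum, eps_sq, ret


def run_mcmc(model: _BaseModel, config: McmcConfig = TEST_SCALE
             ) -> PosteriorSamples:
    """Fit a model by MCMC under the given chain protocol.

    Chains run sequentially with independent generators spawned from
    ``config.seed``; identical (model, config) reproduces identical draws.
    """
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains, devs = [], []
    eps_sum = np.zeros(model.n_trees)
    eps_sq = np.zeros(model.n_trees)
    total = 0
    for ss in seeds:
        rng = np.random.default_rng(ss)
        out, dev, es, eq, ret = _chain(model, config, rng)
        chains.append(out)
        devs.append(dev)
        eps_sum += es
        eps_sq += eq
        total += ret
    arrays = {
        k: np.stack([c[k] for c in chains]) for k in chains[0]
    }
    eps_mean = eps_sum / max(total, 1)
    eps_var = np.maximum(eps_sq / max(total, 1) - eps_mean**2, 0.0)
    meta = {
        "model_type": "ordinal" if model.is_ordinal else "binomial",
        "K": int(model.K),
        "covariate_set": model.design.covariate_set,
        "kernel": model.design.kernel,
        "species": list(model.design.species_names),
        "coef_names": list(model.design.coef_names),
        "n_trees": int(model.n_trees),
        "n_obs": int(model.n_obs),
        "fingerprint": data_fingerprint(model),
        "hierarchical": model.hierarchical,
        "random_effects": model.random_effects,
    }
    return PosteriorSamples(
        arrays=arrays,
        deviance=np.stack(devs),
        eps_mean=eps_mean,
        eps_sd=np.sqrt(eps_var),
        config=config,
        meta=meta,
    )


# ---------------------------------------------------------------------------
# Diagnostics and summaries


def gelman_rubin(samples: PosteriorSamples | np.ndarray,
                 min_draws: int = 10) -> dict[str, float] | float:
    """Potential scale reduction factor from between/within chain variances.

    Accepts a (chains, draws) array (returns a float) or PosteriorSamples
    (returns {parameter label: R-hat}). Requires >= 2 chains.
    """
    if isinstance(samples, np.ndarray):
        return _psrf(samples, min_draws)
    if samples.n_chains < 2:
        raise ValueError(
            "R-hat needs >= 2 chains; rerun with a multi-chain config"
        )
    return {lab: _psrf(a, min_draws) for lab, a in samples.scalar_elements()}


def _psrf(a: np.ndarray, min_draws: int = 10) -> float:
    m, nn = a.shape
    if m < 2:
        raise ValueError("R-hat needs >= 2 chains")
    if nn < min_draws:
        raise ValueError(f"R-hat needs >= {min_draws} draws per chain")
    chain_means = a.mean(axis=1)
    w = a.var(axis=1, ddof=1).mean()
    b_over_n = chain_means.var(ddof=1)
    if w == 0:
        return 1.0 if b_over_n == 0 else np.inf
    var_hat = (nn - 1) / nn * w + b_over_n
    # values below 1 are finite-sample artifacts; floor at the ideal
    return float(max(1.0, np.sqrt(var_hat / w)))


def summarize_posterior(samples: PosteriorSamples,
                        rhat_warn: float = 1.1) -> pd.DataFrame:
    """Per-parameter posterior summary table.

    Reports the mean, SD, both interval conventions — SD-based bands
    (mean +/- 2 SD for 95%, +/- 1.5 SD for 87%, the convention used for
    effect classification) and central quantile intervals — plus classic
    R-hat and an effective sample size. Warns when any R-hat >= 1.1.
    """
    import warnings

    rows = []
    for lab, a in samples.scalar_elements():
        flat = a.reshape(-1)
        mean = float(flat.mean())
        sd = float(flat.std(ddof=1)) if len(flat) > 1 else 0.0
        try:
            rhat = _psrf(a) if a.shape[0] >= 2 else np.nan
        except ValueError:
            rhat = np.nan
        rows.append({
            "parameter": lab,
            "mean": mean,
            "sd": sd,
            "sd95_lo": mean - 2 * sd,
            "sd95_hi": mean + 2 * sd,
            "sd87_lo": mean - 1.5 * sd,
            "sd87_hi": mean + 1.5 * sd,
            "q2.5": float(np.quantile(flat, 0.025)),
            "q97.5": float(np.quantile(flat, 0.975)),
            "q6.5": float(np.quantile(flat, 0.065)),
            "q93.5": float(np.quantile(flat, 0.935)),
            "rhat": rhat,
            "ess": _ess(a),
        })
    if not rows:
        raise ValueError("no retained samples to summarize")
    df = pd.DataFrame(rows).set_index("parameter")
    bad = df["rhat"].dropna()
    if (bad >= rhat_warn).any():
        worst = bad.idxmax()
        warnings.warn(
            f"convergence warning: R-hat >= {rhat_warn} "
            f"(worst {bad.max():.3f} at {worst})",
            stacklevel=2,
        )
    return df


def _ess(a: np.ndarray) -> float:
    """Effective sample size of a (chains, draws) array, via arviz."""
    try:
        import arviz as az

        return float(az.ess(np.asarray(a)))
    except Exception:
        return float("nan")


# ---------------------------------------------------------------------------
# Small generic kernel (used for oracle checks and quick 1-d problems)


def adaptive_metropolis(
    logpost,
    x0: float,
    n_iterations: int,
    n_burnin: int,
    rng: np.random.Generator,
    step: float = 1.0,
    target: float = 0.44,
    decay: float = 0.6,
) -> np.ndarray:
    """1-d random-walk Metropolis with burn-in-only step adaptation."""
    x = float(x0)
    lp = logpost(x)
    ad = _Adapt(step, target, decay)
    out = np.empty(n_iterations - n_burnin)
    for t in range(n_iterations):
        prop = x + ad.step * rng.standard_normal()
        lp_new = logpost(prop)
        log_r = lp_new - lp
        if np.log(rng.uniform()) < log_r:
            x, lp = prop, lp_new
        if t < n_burnin:
            ad.update(t, min(1.0, np.exp(min(log_r, 0.0))))
        else:
            out[t - n_burnin] = x
    return out
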