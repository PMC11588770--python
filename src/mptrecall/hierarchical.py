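"""Bayesian-hierarchical latent-trait estimation for MPT models.

The latent-trait approach places each participant's MPT parameters on
the probit scale: person i's parameter vector is eta_i ~ MVN(mu, Sigma),
and theta_ip = Phi(eta_ip) enters the product-multinomial likelihood of
that person's category counts.  Group means mu_p get standard-normal
priors on the probit scale; Sigma gets a scaled inverse-Wishart prior
(identity scale, df P+1) implemented by parameter expansion with
per-parameter scaling factors xi_p ~ Uniform(0, 10):

    eta_i = mu + xi * delta_i,   delta_i ~ MVN(0, Q),   Q ~ InvWishart(I, P+1)
    Sigma = diag(xi) Q diag(xi)

Posterior sampling is Metropolis-within-Gibbs: adaptive random-walk
Metropolis for delta_i (blocked per person), mu_p and xi_p (per
coordinate), and a conjugate Wishart draw for Q.  Proposal scales adapt
toward standard target acceptance rates during burn-in/adaptation phases
only, so the retained chains are draws from a fixed Markov kernel.

Sampling follows a configurable plan (defaults: 20,000 samples per chain
of which 2,000 are burn-in/adaptation, every fifth retained, then blocks
of 10,000 samples with 1,000 adaptation samples appended until every
monitored quantity reaches R-hat < 1.05 and effective sample size >
2,000, or the extension budget is exhausted).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import wishart

from .models import MPTModel, PersonCounts

logger = logging.getLogger(__name__)

__all__ = [
    "LatentTraitConfig",
    "PosteriorFit",
    "PPCResult",
    "fit_latent_trait",
    "summarize_parameters",
    "posterior_covariate_correlation",
    "bayesian_p",
    "compare_groups",
    "ppc_t1_t2",
    "check_convergence",
]


@dataclass(frozen=True)
class LatentTraitConfig:
    """Sampling plan and priors for the latent-trait fit.

    ``initial_samples`` is the total per-chain length of the first run,
    including ``burn_in`` burn-in/adaptation samples; every ``thin``-th
    post-burn-in sample is retained.  When convergence thresholds are not
    met, blocks of ``extension_samples`` (preceded by
    ``extension_adapt`` discarded adaptation samples) are appended, at
    most ``max_extensions`` times.
    """

    n_chains: int = 3
    initial_samples: int = 20_000
    burn_in: int = 2_000
    thin: int = 5
    extension_samples: int = 10_000
    extension_adapt: int = 1_000
    rhat_threshold: float = 1.05
    ess_threshold: float = 2_000.0
    max_extensions: int = 3
    mu_prior_mean: float = 0.0
    mu_prior_sd: float = 1.0
    wishart_df_extra: int = 1  # prior df = P + this
    xi_upper: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.burn_in >= self.initial_samples:
            raise ValueError("burn_in must be smaller than initial_samples")
        for name in ("rhat_threshold", "ess_threshold", "xi_upper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def reduced(cls, seed: int = 0, **overrides) -> "LatentTraitConfig":
        """A short plan for simulation studies: 3 chains x 2,000 retained draws."""
        defaults = dict(
            n_chains=3, initial_samples=2_500, burn_in=500, thin=1,
            extension_samples=1_000, extension_adapt=200, max_extensions=0,
            ess_threshold=200.0, seed=seed,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class PosteriorFit:
    """Retained MCMC draws plus diagnostics for a latent-trait fit.

    Draw arrays are indexed (chain, draw, ...): ``mu`` (probit group
    means, shape C x D x P), ``sigma`` (C x D x P x P), ``eta`` (person
    probit values, C x D x n x P).  Probability-scale group means are
    ``Phi(mu)``; person parameters are ``Phi(eta)``.
    """

    model: MPTModel
    counts: PersonCounts
    config: LatentTraitConfig
    mu: np.ndarray
    sigma: np.ndarray
    eta: np.ndarray
    diagnostics: pd.DataFrame
    converged: bool
    n_extensions: int
    covariates: pd.DataFrame | None = None

    @property
    def parameters(self) -> tuple[str, ...]:
        return self.model.parameters

    @property
    def n_draws(self) -> int:
        return self.mu.shape[0] * self.mu.shape[1]

    def group_theta_draws(self) -> np.ndarray:
        """Probability-scale group means, flattened over chains: (draws, P)."""
        return ndtr(self.mu.reshape(-1, self.mu.shape[-1]))

    def eta_draws(self) -> np.ndarray:
        """Person probit values, flattened over chains: (draws, n, P)."""
        return self.eta.reshape(-1, *self.eta.shape[2:])


@dataclass(frozen=True)
class PPCResult:
    """Posterior-predictive check of mean frequencies (T1) and covariances (T2)."""

    t1_observed: np.ndarray
    t1_replicated: np.ndarray
    t1_p: float
    t2_observed: np.ndarray
    t2_replicated: np.ndarray
    t2_p: float


# ---------------------------------------------------------------------------
# likelihood machinery


class _CompiledModel:
    """Branch structure flattened for vectorized likelihood evaluation."""

    def __init__(self, model: MPTModel, counts: PersonCounts):
        counts.validate_for(model)
        self.model = model
        self.P = len(model.parameters)
        pidx = {p: j for j, p in enumerate(model.parameters)}
        self.trees = []
        self.param_trees: list[list[int]] = [[] for _ in range(self.P)]
        for ti, tree in enumerate(model.trees):
            x = np.asarray(counts.tables[tree.name], dtype=float)
            branches = []
            cidx = {c: i for i, c in enumerate(tree.categories)}
            for b in tree.branches:
                branches.append(
                    (cidx[b.category], float(b.multiplicity),
                     [(pidx[n], pol == "direct") for n, pol in b.factors])
                )
                for n_, _ in b.factors:
                    if ti not in self.param_trees[pidx[n_]]:
                        self.param_trees[pidx[n_]].append(ti)
            self.trees.append((x, len(tree.categories), branches))
        self.n_trees = len(self.trees)

    def probs(self, theta: np.ndarray, tree_idx: Sequence[int] | None = None):
        out = {}
        for ti in range(self.n_trees) if tree_idx is None else tree_idx:
            _, K, branches = self.trees[ti]
            p = np.zeros((theta.shape[0], K))
            for cat, mult, factors in branches:
                term = np.full(theta.shape[0], mult)
                for j, direct in factors:
                    term = term * (theta[:, j] if direct else 1.0 - theta[:, j])
                p[:, cat] += term
            out[ti] = p
        return out

    def loglik_by_tree(
        self, theta: np.ndarray, tree_idx: Sequence[int] | None = None
    ) -> dict[int, np.ndarray]:
        """Per-person log likelihood contribution of each requested tree."""
        out = {}
        for ti, p in self.probs(theta, tree_idx).items():
            x = self.trees[ti][0]
            out[ti] = np.einsum("nk,nk->n", x, np.log(np.clip(p, 1e-300, None)))
        return out

    def loglik(self, theta: np.ndarray) -> np.ndarray:
        """Per-person product-multinomial log likelihood (kernel only)."""
        return sum(self.loglik_by_tree(theta).values())


# ---------------------------------------------------------------------------
# sampler


class _ChainState:
    def __init__(self, comp: _CompiledModel, n: int, rng: np.random.Generator,
                 cfg: LatentTraitConfig):
        P = comp.P
        self.rng = rng
        self.mu = rng.normal(0.0, 0.5, size=P)
        self.xi = np.full(P, 1.0)
        self.delta = rng.normal(0.0, 0.1, size=(n, P))
        self.Qinv = np.eye(P)
        self.Q = np.eye(P)
        self.ls_delta = np.full(n, np.log(0.3))
        self.ls_mu = np.full(P, np.log(0.1))
        self.ls_xi = np.full(P, np.log(0.1))
        self.eta = self.mu + self.xi * self.delta
        self.llmat = np.zeros((n, comp.n_trees))
        for ti, v in comp.loglik_by_tree(ndtr(self.eta)).items():
            self.llmat[:, ti] = v

    @property
    def ll(self) -> np.ndarray:
        return self.llmat.sum(axis=1)


def _sweep(comp: _CompiledModel, st: _ChainState, cfg: LatentTraitConfig,
           adapt: bool, t: int) -> None:
    rng = st.rng
    n, P = st.delta.shape
    gamma = min(0.05, 2.0 / np.sqrt(t + 20.0)) if adapt else 0.0

    # --- person effects delta_i, blocked random walk per person
    prop = st.delta + np.exp(st.ls_delta)[:, None] * rng.standard_normal((n, P))
    eta_prop = st.mu + st.xi * prop
    llmat_prop = np.zeros_like(st.llmat)
    for ti, v in comp.loglik_by_tree(ndtr(eta_prop)).items():
        llmat_prop[:, ti] = v
    quad_cur = np.einsum("np,pq,nq->n", st.delta, st.Qinv, st.delta)
    quad_prop = np.einsum("np,pq,nq->n", prop, st.Qinv, prop)
    log_acc = (llmat_prop.sum(axis=1) - st.llmat.sum(axis=1)) - 0.5 * (
        quad_prop - quad_cur
    )
    accept = np.log(rng.uniform(size=n)) < log_acc
    st.delta[accept] = prop[accept]
    st.eta[accept] = eta_prop[accept]
    st.llmat[accept] = llmat_prop[accept]
    if adapt:
        st.ls_delta += gamma * (accept.astype(float) - 0.234)

    # --- group means mu_p, scalar random walk; only trees containing p change
    for p in range(P):
        trees_p = comp.param_trees[p]
        cand = st.mu[p] + np.exp(st.ls_mu[p]) * rng.standard_normal()
        eta_col = cand + st.xi[p] * st.delta[:, p]
        theta_prop = ndtr(np.where(np.arange(P) == p, eta_col[:, None], st.eta))
        part = comp.loglik_by_tree(theta_prop, trees_p)
        d_ll = sum(part[ti].sum() - st.llmat[:, ti].sum() for ti in trees_p)
        dprior = (
            -0.5 * ((cand - cfg.mu_prior_mean) / cfg.mu_prior_sd) ** 2
            + 0.5 * ((st.mu[p] - cfg.mu_prior_mean) / cfg.mu_prior_sd) ** 2
        )
        acc = np.log(rng.uniform()) < d_ll + dprior
        if acc:
            st.mu[p] = cand
            st.eta[:, p] = eta_col
            for ti in trees_p:
                st.llmat[:, ti] = part[ti]
        if adapt:
            st.ls_mu[p] += gamma * (float(acc) - 0.44)

    # --- scaling factors xi_p, scalar random walk with Uniform(0, upper) prior
    for p in range(P):
        trees_p = comp.param_trees[p]
        cand = st.xi[p] + np.exp(st.ls_xi[p]) * rng.standard_normal()
        if 0.0 < cand < cfg.xi_upper:
            eta_col = st.mu[p] + cand * st.delta[:, p]
            theta_prop = ndtr(
                np.where(np.arange(P) == p, eta_col[:, None], st.eta)
            )
            part = comp.loglik_by_tree(theta_prop, trees_p)
            d_ll = sum(part[ti].sum() - st.llmat[:, ti].sum() for ti in trees_p)
            acc = np.log(rng.uniform()) < d_ll
            if acc:
                st.xi[p] = cand
                st.eta[:, p] = eta_col
                for ti in trees_p:
                    st.llmat[:, ti] = part[ti]
        else:
            acc = False
        if adapt:
            st.ls_xi[p] += gamma * (float(acc) - 0.44)

    # --- Q, conjugate Wishart draw for the precision of delta
    nu = P + cfg.wishart_df_extra + n
    scale = np.linalg.inv(np.eye(P) + st.delta.T @ st.delta)
    st.Qinv = wishart.rvs(df=nu, scale=scale, random_state=rng)
    if P == 1:
        st.Qinv = np.atleast_2d(st.Qinv)
    st.Q = np.linalg.inv(st.Qinv)


def _run_chain(comp: _CompiledModel, cfg: LatentTraitConfig, n: int,
               seed_seq: np.random.SeedSequence,
               n_adapt: int, n_keep: int,
               state: _ChainState | None = None):
    rng = np.random.default_rng(seed_seq)
    st = state if state is not None else _ChainState(comp, n, rng, cfg)
    st.rng = rng
    P = comp.P
    for t in range(n_adapt):
        _sweep(comp, st, cfg, adapt=True, t=t)
    n_ret = n_keep // cfg.thin
    mu = np.empty((n_ret, P))
    sigma = np.empty((n_ret, P, P))
    eta = np.empty((n_ret, n, P))
    j = 0
    for t in range(n_keep):
        _sweep(comp, st, cfg, adapt=False, t=t)
        if (t + 1) % cfg.thin == 0 and j < n_ret:
            mu[j] = st.mu
            sigma[j] = (st.xi[:, None] * st.Q) * st.xi[None, :]
            eta[j] = st.eta
            j += 1
    return st, mu[:j], sigma[:j], eta[:j]


def _monitored(mu: np.ndarray, sigma: np.ndarray, params: Sequence[str]):
    """Quantities whose convergence is monitored: mu_p and Sigma entries."""
    out = {}
    P = len(params)
    for p in range(P):
        out[f"mu_{params[p]}"] = mu[:, :, p]
    for p in range(P):
        for q in range(p, P):
            out[f"sigma_{params[p]}_{params[q]}"] = sigma[:, :, p, q]
    return out


def _diagnose(quantities: Mapping[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, arr in quantities.items():
        if np.allclose(arr.var(), 0.0):
            # constant chains: R-hat is undefined; by convention report 1
            rhat, ess = 1.0, float(arr.size)
        else:
            ds = az.convert_to_dataset(arr)
            rhat = float(np.asarray(az.rhat(ds).to_array()).squeeze())
            ess = float(np.asarray(az.ess(ds).to_array()).squeeze())
            if not np.isfinite(rhat):
                rhat = 1.0
        rows.append(dict(quantity=name, rhat=rhat, ess=ess))
    return pd.DataFrame(rows).set_index("quantity")


def check_convergence(
    fit_or_draws, config: LatentTraitConfig
) -> tuple[pd.DataFrame, str]:
    """R-hat / ESS diagnostics and the extend-or-stop decision.

    Accepts a :class:`PosteriorFit` or a mapping quantity -> (chain, draw)
    array.  R-hat is arviz's rank-normalized split R-hat; for constant
    chains it is undefined and reported as 1 by convention.  Returns the
    diagnostics table and ``"extend"`` iff any monitored quantity fails
    either threshold, else ``"stop"``.  At least two chains are required.
    """
    if isinstance(fit_or_draws, PosteriorFit):
        quantities = _monitored(fit_or_draws.mu, fit_or_draws.sigma,
                                fit_or_draws.parameters)
    else:
        quantities = dict(fit_or_draws)
    any_arr = next(iter(quantities.values()))
    if any_arr.shape[0] < 2:
        raise ValueError("R-hat requires at least two chains")
    diag = _diagnose(quantities)
    ok = (diag["rhat"] < config.rhat_threshold) & (diag["ess"] > config.ess_threshold)
    return diag, ("stop" if bool(ok.all()) else "extend")


def fit_latent_trait(
    model: MPTModel,
    counts: PersonCounts,
    config: LatentTraitConfig | None = None,
    covariates: pd.DataFrame | None = None,
) -> PosteriorFit:
    """Fit the hierarchical latent-trait MPT model by MCMC.

    Runs ``config.n_chains`` independent chains under the configured
    plan, extending them until the convergence thresholds are met or
    ``max_extensions`` is exhausted (the returned fit then carries
    ``converged=False``).  Identical config and seed reproduce identical
    draws.  ``covariates`` (indexed by person_id) are stored for
    downstream correlation analyses; persons without covariates still
    contribute to the hierarchy.
    """
    config = config or LatentTraitConfig()
    comp = _CompiledModel(model, counts)
    n = counts.n_persons
    if n < 2:
        warnings.warn(
            "fewer than 2 persons: the person-level covariance is weakly "
            "identified; estimates rely on the prior"
        )
    root = np.random.SeedSequence(config.seed)
    chain_seeds = root.spawn(config.n_chains * (config.max_extensions + 1))

    states, mus, sigmas, etas = [], [], [], []
    for c in range(config.n_chains):
        st, mu, sg, et = _run_chain(
            comp, config, n, chain_seeds[c],
            n_adapt=config.burn_in,
            n_keep=config.initial_samples - config.burn_in,
        )
        states.append(st)
        mus.append(mu)
        sigmas.append(sg)
        etas.append(et)

    n_ext = 0
    while True:
        mu = np.stack(mus)
        sigma = np.stack(sigmas)
        eta = np.stack(etas)
        diag, decision = check_convergence(
            _monitored(mu, sigma, model.parameters), config
        )
        if decision == "stop":
            converged = True
            break
        if n_ext >= config.max_extensions:
            converged = False
            logger.warning(
                "convergence thresholds not met after %d extensions; "
                "returning fit flagged as non-converged", n_ext
            )
            break
        n_ext += 1
        for c in range(config.n_chains):
            st, mu_c, sg_c, et_c = _run_chain(
                comp, config, n,
                chain_seeds[config.n_chains * n_ext + c],
                n_adapt=config.extension_adapt,
                n_keep=config.extension_samples,
                state=states[c],
            )
            states[c] = st
            mus[c] = np.concatenate([mus[c], mu_c])
            sigmas[c] = np.concatenate([sigmas[c], sg_c])
            etas[c] = np.concatenate([etas[c], et_c])

    return PosteriorFit(
        model=model, counts=counts, config=config,
        mu=mu, sigma=sigma, eta=eta,
        diagnostics=diag, converged=converged, n_extensions=n_ext,
        covariates=covariates,
    )


# ---------------------------------------------------------------------------
# posterior summaries


def summarize_parameters(fit: PosteriorFit) -> pd.DataFrame:
    """Posterior mean and central 95% credibility interval of Phi(mu_p)."""
    theta = fit.group_theta_draws()
    lo, hi = np.percentile(theta, [2.5, 97.5], axis=0)
    diag = fit.diagnostics
    rows = []
    for j, p in enumerate(fit.parameters):
        d = diag.loc[f"mu_{p}"] if f"mu_{p}" in diag.index else None
        rows.append(dict(
            parameter=p, mean=float(theta[:, j].mean()),
            ci_low=float(lo[j]), ci_high=float(hi[j]),
            rhat=float(d["rhat"]) if d is not None else np.nan,
            ess=float(d["ess"]) if d is not None else np.nan,
        ))
    return pd.DataFrame(rows).set_index("parameter")


def bayesian_p(samples: np.ndarray, direction: str = "le_zero") -> float:
    """Proportion of posterior samples at or below zero (or at/above).

    This is the one-sided posterior probability used to test directional
    effects: small values indicate that nearly all posterior mass is on
    the positive (resp. negative) side.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("empty sample vector")
    if direction == "le_zero":
        return float(np.mean(samples <= 0))
    if direction == "ge_zero":
        return float(np.mean(samples >= 0))
    raise ValueError(f"unknown direction {direction!r}")


def posterior_covariate_correlation(
    fit: PosteriorFit,
    covariate: np.ndarray | pd.Series,
    direction: str = "le_zero",
) -> pd.DataFrame:
    """Draw-wise Pearson correlations between a covariate and person probits.

    For every retained draw, correlates the covariate with the
    person-level probit values eta_.p of each parameter; missing
    covariate entries are excluded pairwise.  Returns per parameter the
    correlation draws' mean, central 95% interval, and Bayesian p
    (posterior mass at or below zero).  The draws themselves are attached
    as a ``samples`` column of arrays.
    """
    z = np.asarray(covariate, dtype=float)
    if z.shape[0] != fit.counts.n_persons:
        raise ValueError("covariate must align with persons")
    mask = np.isfinite(z)
    if mask.sum() < 3:
        raise ValueError("need at least 3 non-missing covariate values")
    zz = z[mask]
    if np.std(zz) == 0:
        raise ValueError("covariate has zero variance; correlation undefined")
    zz = (zz - zz.mean()) / zz.std()
    eta = fit.eta_draws()[:, mask, :]  # (D, n_obs, P)
    ec = eta - eta.mean(axis=1, keepdims=True)
    sd = eta.std(axis=1)
    r = np.einsum("dnp,n->dp", ec, zz) / (mask.sum() * np.where(sd > 0, sd, np.inf))
    rows = []
    for j, p in enumerate(fit.parameters):
        lo, hi = np.percentile(r[:, j], [2.5, 97.5])
        rows.append(dict(
            parameter=p, r_mean=float(r[:, j].mean()),
            ci_low=float(lo), ci_high=float(hi),
            bayes_p=bayesian_p(r[:, j], direction),
            samples=r[:, j],
        ))
    return pd.DataFrame(rows).set_index("parameter")


def compare_groups(fit_a: PosteriorFit, fit_b: PosteriorFit) -> pd.DataFrame:
    """Posterior of probability-scale group-mean differences, b minus a.

    Draws are paired by index across the two independent fits (the
    longer draw sequence is deterministically subsampled at evenly spaced
    indices to match the shorter).  Reports mean difference, central 95%
    interval, and Bayesian p per parameter.
    """
    if fit_a.parameters != fit_b.parameters:
        raise ValueError("fits must share the same model parameters")
    ta, tb = fit_a.group_theta_draws(), fit_b.group_theta_draws()
    na, nb = ta.shape[0], tb.shape[0]
    m = min(na, nb)
    if na != nb:
        logger.info("subsampling %d of %d draws for pairing", m, max(na, nb))
    ia = np.linspace(0, na - 1, m).round().astype(int)
    ib = np.linspace(0, nb - 1, m).round().astype(int)
    diff = tb[ib] - ta[ia]
    rows = []
    for j, p in enumerate(fit_a.parameters):
        lo, hi = np.percentile(diff[:, j], [2.5, 97.5])
        rows.append(dict(
            parameter=p, diff_mean=float(diff[:, j].mean()),
            ci_low=float(lo), ci_high=float(hi),
            bayes_p=bayesian_p(diff[:, j]),
            samples=diff[:, j],
        ))
    return pd.DataFrame(rows).set_index("parameter")


# ---------------------------------------------------------------------------
# posterior predictive checks


def _t1(xbar: np.ndarray, ebar: np.ndarray) -> float:
    return float(np.sum((xbar - ebar) ** 2 / np.clip(ebar, 1e-9, None)))


def _t2(cov_obs: np.ndarray, cov_exp: np.ndarray) -> float:
    d = np.clip(np.sqrt(np.abs(np.outer(np.diag(cov_exp), np.diag(cov_exp)))), 1e-9, None)
    stat = (cov_obs - cov_exp) ** 2 / d
    iu = np.triu_indices_from(stat)
    return float(stat[iu].sum())


def ppc_t1_t2(
    fit: PosteriorFit,
    observed: PersonCounts | None = None,
    max_draws: int = 400,
) -> PPCResult:
    """Posterior-predictive checks of mean frequencies (T1) and covariances (T2).

    Per posterior draw, a fresh sample of n persons is drawn from the
    draw's group-level probit-normal distribution (so the checks are
    sensitive to violations of the population assumption, e.g. latent
    subgroups).  T1 is the chi-square-type distance between the observed
    mean category frequencies (averaged over persons, all trees
    concatenated) and their expectation under those group-level
    parameters; the same statistic on data replicated from them gives the
    reference distribution, and p = P(T1_rep >= T1_obs).  T2 does the
    analogous comparison for the covariance matrix of individual category
    frequencies, against the expected covariance (between-person spread
    of expected counts plus average within-person multinomial
    covariance), standardized by expected variances.  Ties count as
    exceedances (the ``>=`` convention), so a replicated statistic that
    always equals the observed one yields p = 1.
    """
    observed = observed or fit.counts
    comp = _CompiledModel(fit.model, observed)
    n = observed.n_persons
    mu_d = fit.mu.reshape(-1, fit.mu.shape[-1])
    sigma_d = fit.sigma.reshape(-1, *fit.sigma.shape[-2:])
    D = mu_d.shape[0]
    take = np.linspace(0, D - 1, min(max_draws, D)).round().astype(int)
    totals = [int(np.asarray(observed.tables[t.name]).sum(axis=1)[0])
              for t in fit.model.trees]
    x_all = np.concatenate(
        [np.asarray(observed.tables[t.name], dtype=float) for t in fit.model.trees],
        axis=1,
    )
    xbar_obs = x_all.mean(axis=0)
    cov_obs = np.cov(x_all, rowvar=False, ddof=1)

    rng = np.random.default_rng(np.random.SeedSequence([fit.config.seed, 7_654_321]))
    t1o, t1r, t2o, t2r = [], [], [], []
    for d in take:
        # replicate a fresh sample of n persons from the group-level
        # distribution of this draw, so the checks are sensitive to
        # violations of the probit-normal population assumption
        L = np.linalg.cholesky(
            sigma_d[d] + 1e-10 * np.eye(sigma_d[d].shape[0])
        )
        eta_rep = mu_d[d] + rng.standard_normal((n, mu_d[d].shape[0])) @ L.T
        theta = ndtr(eta_rep)
        plist = [comp.probs(theta)[ti] for ti in range(comp.n_trees)]
        e_blocks, cov_within = [], []
        rep_blocks = []
        for (pmat, N) in zip(plist, totals):
            e_blocks.append(N * pmat)
            # mean within-person multinomial covariance N(diag(p) - p p^T)
            cw = N * (
                np.einsum("nk,kl->kl", pmat, np.eye(pmat.shape[1])) / n
                - pmat.T @ pmat / n
            )
            cov_within.append(cw)
            rep = np.stack([rng.multinomial(N, np.clip(p, 0, None) / p.sum())
                            for p in pmat])
            rep_blocks.append(rep.astype(float))
        e_all = np.concatenate(e_blocks, axis=1)
        rep_all = np.concatenate(rep_blocks, axis=1)
        ebar = e_all.mean(axis=0)
        cov_exp = np.cov(e_all, rowvar=False, ddof=1)
        k0 = 0
        for cw in cov_within:  # trees are independent: block-diagonal within part
            k = cw.shape[0]
            cov_exp[k0:k0 + k, k0:k0 + k] += cw
            k0 += k
        t1o.append(_t1(xbar_obs, ebar))
        t1r.append(_t1(rep_all.mean(axis=0), ebar))
        t2o.append(_t2(cov_obs, cov_exp))
        t2r.append(_t2(np.cov(rep_all, rowvar=False, ddof=1), cov_exp))

    t1o, t1r = np.array(t1o), np.array(t1r)
    t2o, t2r = np.array(t2o), np.array(t2r)
    return PPCResult(
        t1_observed=t1o, t1_replicated=t1r, t1_p=float(np.mean(t1r >= t1o)),
        t2_observed=t2o, t2_replicated=t2r, t2_p=float(np.mean(t2r >= t2o)),
    )
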