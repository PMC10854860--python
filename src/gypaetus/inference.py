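"""Model fitting: maximum likelihood and Bayesian MCMC, with diagnostics.

The Bayesian fit is an adaptive Metropolis-within-Gibbs sampler on the
marginal likelihood (latent alive/dead states are integrated out by the
forward recursion, so no data augmentation is needed). Priors are
weakly informative: Normal(0, 10^2) on each logit-scale effect,
Uniform(0, 10) on the year-effect scale sigma, and eps_t | sigma ~
Normal(0, sigma^2). Each scalar parameter gets its own random-walk
proposal whose scale adapts toward a 44% acceptance rate during
burn-in and is frozen afterwards; sigma moves by a random walk on
log(sigma).

The frequentist cross-check (:func:`fit_mle`) maximises the same
likelihood with the year effects fixed at zero and reports delta-method
standard errors from a finite-difference Hessian.

Convergence is judged by the classic multi-chain Gelman–Rubin potential
scale reduction factor (values below 1.1 conventionally indicate
convergence) alongside an autocorrelation-based effective sample size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import optimize

from .encounter import AgeClass, EncounterDataset, StudyDesign
from .model import ModelSpec, _dataset_loglik_kernel, invlogit

__all__ = [
    "McmcConfig",
    "McmcChains",
    "MleResult",
    "PosteriorSummary",
    "fit_mle",
    "run_mcmc",
    "gelman_rubin",
    "effective_sample_size",
    "summarize_posterior",
    "NonIdentifiableError",
]


class NonIdentifiableError(ValueError):
    """The data carry no information on the requested parameters."""


# ---------------------------------------------------------------------------
# Maximum likelihood

@dataclass(frozen=True)
class MleResult:
    """Fixed-effects MLE on the logit scale with delta-method SEs."""

    beta: np.ndarray                 # (3,) logit-scale survival effects
    logit_p: np.ndarray              # (1,) or (3,)
    survival: np.ndarray             # (3,) probability scale
    p: np.ndarray                    # per class, probability scale
    se_survival: np.ndarray
    se_p: np.ndarray
    loglik: float
    converged: bool
    boundary: bool                   # any |logit estimate| > 10
    message: str = ""

    def to_frame(self) -> pd.DataFrame:
        names = [f"survival_{c.name.lower()}" for c in AgeClass]
        rows = list(zip(names, self.survival, self.se_survival))
        pnames = (
            ["p"] if len(self.logit_p) == 1
            else [f"p_{c.name.lower()}" for c in AgeClass]
        )
        pvals = self.p if len(self.p) == len(pnames) else self.p[: len(pnames)]
        rows += list(zip(pnames, pvals, self.se_p))
        return pd.DataFrame(rows, columns=["parameter", "estimate", "se"]).set_index(
            "parameter"
        )


def _expand_logit_p(logit_p: np.ndarray) -> np.ndarray:
    return np.repeat(logit_p, 3) if logit_p.shape[0] == 1 else logit_p


_MLE_STARTS = ((0.0, 0.0), (2.0, 2.0), (-1.0, 1.0), (3.0, 0.5))


def fit_mle(dataset: EncounterDataset, spec: ModelSpec) -> MleResult:
    """Maximise the fixed-effects CJS likelihood (year effects at zero).

    Runs from several fixed starting points and keeps the best; flags
    non-convergence and boundary estimates (|logit| > 10) instead of
    failing silently.
    """
    if spec.random_year_effect:
        raise ValueError("fit_mle handles the fixed-effects model only")
    det, frst, ac = dataset.to_arrays()
    if det.shape[0] == 0:
        raise NonIdentifiableError("empty dataset")
    post_entry = det.copy()
    for i, f in enumerate(frst):
        post_entry[i, : f + 1] = 0
    if not post_entry.any():
        raise NonIdentifiableError(
            "no individual was ever detected after first capture; survival "
            "and detection are confounded"
        )
    P = spec.n_p_params
    K = dataset.design.n_intervals
    eps = np.zeros(K)

    def nll(x: np.ndarray) -> float:
        beta = x[:3]
        lp = _expand_logit_p(x[3:])
        return -_dataset_loglik_kernel(det, frst, ac, beta, lp, eps)

    best = None
    best_ok = False
    for b0, p0 in _MLE_STARTS:
        x0 = np.concatenate([np.full(3, b0), np.full(P, p0)])
        nm = optimize.minimize(nll, x0, method="Nelder-Mead",
                               options={"xatol": 1e-8, "fatol": 1e-10,
                                        "maxiter": 20000})
        res = optimize.minimize(nll, nm.x, method="BFGS",
                                options={"gtol": 1e-8, "maxiter": 2000})
        if res.fun > nm.fun:  # polish made it worse; keep the simplex result
            res = nm
        if best is None or res.fun < best.fun:
            best = res
            # BFGS often reports precision loss at a genuine optimum the
            # simplex already found; either flag counts as converged
            best_ok = bool(nm.success or res.success)
    x = best.x
    beta, lp = x[:3], x[3:]
    se_logit = _fd_hessian_se(nll, x)
    surv = invlogit(beta)
    pfull = invlogit(_expand_logit_p(lp))
    se_surv = se_logit[:3] * surv * (1 - surv)
    p_se_raw = se_logit[3:]
    pvals = invlogit(lp)
    se_p = p_se_raw * pvals * (1 - pvals)
    boundary = bool(np.any(np.abs(x) > 10))
    return MleResult(
        beta=beta,
        logit_p=lp,
        survival=surv,
        p=pfull,
        se_survival=se_surv,
        se_p=se_p,
        loglik=-best.fun,
        converged=best_ok,
        boundary=boundary,
        message=str(best.message),
    )


def _fd_hessian_se(f, x: np.ndarray, h: float = 1e-4) -> np.ndarray:
    """Standard errors from a central finite-difference Hessian of -loglik."""
    d = len(x)
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = h
            ej = np.zeros(d); ej[j] = h
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * h * h)
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    var = np.diag(cov).copy()
    var[var < 0] = np.nan
    return np.sqrt(var)


# ---------------------------------------------------------------------------
# MCMC

@dataclass(frozen=True)
class McmcConfig:
    """Sampler settings; defaults follow the study protocol.

    ``burn_in`` counts discarded pre-thinning iterations; retained draws
    are every ``thin``-th iteration afterwards.
    """

    n_iterations: int = 150_000
    burn_in: int = 5_000
    thin: int = 3
    n_chains: int = 3
    seed: int | None = None
    prior_sd: float = 10.0
    sigma_upper: float = 10.0
    target_accept: float = 0.44

    def __post_init__(self) -> None:
        if not self.burn_in < self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence checks")

    @property
    def n_retained(self) -> int:
        return -(-(self.n_iterations - self.burn_in) // self.thin)


@dataclass(frozen=True)
class McmcChains:
    """Retained draws: (n_chains, n_draws, n_params), plus log posterior."""

    draws: np.ndarray
    log_posterior: np.ndarray
    param_names: tuple[str, ...]
    design: StudyDesign
    spec: ModelSpec
    config: McmcConfig

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def index_of(self, parameter: str) -> int:
        return self.param_names.index(parameter)

    def pooled(self, parameter: str) -> np.ndarray:
        return self.draws[:, :, self.index_of(parameter)].ravel()

    def to_dataframe(self) -> pd.DataFrame:
        n_chains, n_draws, _ = self.draws.shape
        df = pd.DataFrame(
            self.draws.reshape(n_chains * n_draws, -1), columns=list(self.param_names)
        )
        df.insert(0, "chain", np.repeat(np.arange(n_chains), n_draws))
        df.insert(1, "draw", np.tile(np.arange(n_draws), n_chains))
        df["log_posterior"] = self.log_posterior.ravel()
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


@njit(cache=True)
def _chain_kernel(det, first, ac, n_iter, burn_in, thin, seed,
                  beta0, logitp0, eps0, sigma0, random_effect,
                  prior_sd, sigma_upper, target_accept):  # pragma: no cover
    np.random.seed(seed)
    P = logitp0.shape[0]
    K = eps0.shape[0]
    beta = beta0.copy()
    logitp = logitp0.copy()
    eps = eps0.copy()
    sigma = sigma0

    lp3 = np.empty(3)
    for c in range(3):
        lp3[c] = logitp[c % P] if P == 3 else logitp[0]
    ll = _dataset_loglik_kernel(det, first, ac, beta, lp3, eps)

    n_extra = (1 + K) if random_effect else 0
    n_par = 3 + P + n_extra
    scales = np.full(n_par, 0.25)
    n_kept = (n_iter - burn_in + thin - 1) // thin
    out = np.empty((n_kept, n_par))
    out_lp = np.empty(n_kept)
    kept = 0
    two_ps2 = 2.0 * prior_sd * prior_sd

    for it in range(n_iter):
        gamma = min(0.1, (it + 1.0) ** -0.6) if it < burn_in else 0.0

        # survival effects
        for c in range(3):
            prop = beta[c] + scales[c] * np.random.normal()
            old = beta[c]
            beta[c] = prop
            if P == 3:
                for q in range(3):
                    lp3[q] = logitp[q]
            else:
                for q in range(3):
                    lp3[q] = logitp[0]
            ll_new = _dataset_loglik_kernel(det, first, ac, beta, lp3, eps)
            logr = ll_new - ll + (old * old - prop * prop) / two_ps2
            if np.log(np.random.random()) < logr:
                ll = ll_new
                acc = 1.0
            else:
                beta[c] = old
                acc = 0.0
            if gamma > 0.0:
                scales[c] *= np.exp(gamma * (acc - target_accept))

        # detection effects
        for j in range(P):
            prop = logitp[j] + scales[3 + j] * np.random.normal()
            old = logitp[j]
            logitp[j] = prop
            if P == 3:
                for q in range(3):
                    lp3[q] = logitp[q]
            else:
                for q in range(3):
                    lp3[q] = logitp[0]
            ll_new = _dataset_loglik_kernel(det, first, ac, beta, lp3, eps)
            logr = ll_new - ll + (old * old - prop * prop) / two_ps2
            if np.log(np.random.random()) < logr:
                ll = ll_new
                acc = 1.0
            else:
                logitp[j] = old
                for q in range(3):
                    lp3[q] = logitp[q] if P == 3 else logitp[0]
                acc = 0.0
            if gamma > 0.0:
                scales[3 + j] *= np.exp(gamma * (acc - target_accept))

        if random_effect:
            # year effects, one site at a time
            s2 = sigma * sigma
            for k in range(K):
                prop = eps[k] + scales[3 + P + 1 + k] * np.random.normal()
                old = eps[k]
                eps[k] = prop
                ll_new = _dataset_loglik_kernel(det, first, ac, beta, lp3, eps)
                logr = ll_new - ll + (old * old - prop * prop) / (2.0 * s2)
                if np.log(np.random.random()) < logr:
                    ll = ll_new
                    acc = 1.0
                else:
                    eps[k] = old
                    acc = 0.0
                if gamma > 0.0:
                    scales[3 + P + 1 + k] *= np.exp(gamma * (acc - target_accept))

            # sigma: random walk on log(sigma), Uniform(0, sigma_upper) prior
            S = 0.0
            for k in range(K):
                S += eps[k] * eps[k]
            prop = sigma * np.exp(scales[3 + P] * np.random.normal())
            acc = 0.0
            if prop < sigma_upper:
                logr = (-K * np.log(prop) - S / (2.0 * prop * prop)
                        + K * np.log(sigma) + S / (2.0 * sigma * sigma)
                        + np.log(prop) - np.log(sigma))
                if np.log(np.random.random()) < logr:
                    sigma = prop
                    acc = 1.0
            if gamma > 0.0:
                scales[3 + P] *= np.exp(gamma * (acc - target_accept))

        if it >= burn_in and (it - burn_in) % thin == 0:
            for c in range(3):
                out[kept, c] = beta[c]
            for j in range(P):
                out[kept, 3 + j] = logitp[j]
            lpost = ll
            for c in range(3):
                lpost -= beta[c] * beta[c] / two_ps2
            for j in range(P):
                lpost -= logitp[j] * logitp[j] / two_ps2
            if random_effect:
                out[kept, 3 + P] = sigma
                for k in range(K):
                    out[kept, 3 + P + 1 + k] = eps[k]
                    lpost -= (eps[k] * eps[k] / (2.0 * sigma * sigma)
                              + np.log(sigma))
            out_lp[kept] = lpost
            kept += 1
    return out, out_lp


def _param_names(spec: ModelSpec, design: StudyDesign) -> tuple[str, ...]:
    names = [f"beta_{c.name.lower()}" for c in AgeClass]
    if spec.p_structure == "constant":
        names.append("logit_p")
    else:
        names += [f"logit_p_{c.name.lower()}" for c in AgeClass]
    if spec.random_year_effect:
        names.append("sigma")
        names += [f"eps_{y}" for y in design.occasion_years[:-1]]
    return tuple(names)


def run_mcmc(
    dataset: EncounterDataset, spec: ModelSpec, config: McmcConfig
) -> McmcChains:
    """Sample the posterior of the age-dependent CJS model.

    Chains start from overdispersed seeded draws; each chain uses an
    independent RNG stream derived from ``config.seed``. Identical
    inputs give identical chains.
    """
    det, frst, ac = dataset.to_arrays()
    if det.shape[0] == 0:
        raise ValueError("cannot fit an empty dataset")
    K = dataset.design.n_intervals
    P = spec.n_p_params
    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.generate_state(config.n_chains, dtype=np.uint32)
    names = _param_names(spec, dataset.design)

    all_draws = []
    all_lp = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(chain_seeds[c])
        kernel_seed = int(rng.integers(0, 2**31 - 1))
        for attempt in range(100):
            beta0 = rng.normal(1.5, 1.0, size=3)
            logitp0 = rng.normal(1.0, 1.0, size=P)
            if spec.random_year_effect:
                sigma0 = float(rng.uniform(0.1, 1.0))
                eps0 = rng.normal(0.0, 0.3, size=K)
            else:
                sigma0, eps0 = 0.0, np.zeros(K)
            ll0 = _dataset_loglik_kernel(
                det, frst, ac, beta0, _expand_logit_p(logitp0),
                eps0 if spec.random_year_effect else np.zeros(K),
            )
            if np.isfinite(ll0):
                break
        else:
            raise RuntimeError("no finite starting point found in 100 draws")
        draws, lp = _chain_kernel(
            det, frst, ac,
            config.n_iterations, config.burn_in, config.thin, kernel_seed,
            beta0, logitp0, eps0, sigma0, spec.random_year_effect,
            config.prior_sd, config.sigma_upper, config.target_accept,
        )
        all_draws.append(draws)
        all_lp.append(lp)
    return McmcChains(
        draws=np.stack(all_draws),
        log_posterior=np.stack(all_lp),
        param_names=names,
        design=dataset.design,
        spec=spec,
        config=config,
    )


# ---------------------------------------------------------------------------
# Diagnostics

def _chains_matrix(chains, parameter) -> np.ndarray:
    if isinstance(chains, McmcChains):
        if parameter is None:
            raise ValueError("parameter name required")
        return chains.draws[:, :, chains.index_of(parameter)]
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected an (n_chains, n_draws) array")
    return x


def gelman_rubin(chains, parameter: str | None = None) -> float:
    """Classic multi-chain potential scale reduction factor.

    With m chains of length n: W is the mean within-chain sample
    variance, B/n the variance of the chain means, var+ =
    ((n-1)/n) W + B/n and Rhat = sqrt(var+ / W). Values near 1 indicate
    the chains have mixed; below 1.1 is the conventional criterion.
    """
    x = _chains_matrix(chains, parameter)
    m, n = x.shape
    if m < 2:
        raise ValueError("Rhat needs at least 2 chains")
    if n < 4:
        raise ValueError("Rhat needs at least 4 draws per chain")
    W = float(np.mean(np.var(x, axis=1, ddof=1)))
    if W == 0.0:
        raise ValueError("within-chain variance is zero; Rhat undefined")
    B_over_n = float(np.var(np.mean(x, axis=1), ddof=1))
    var_plus = (n - 1) / n * W + B_over_n
    return math.sqrt(var_plus / W)


def effective_sample_size(chains, parameter: str | None = None) -> float:
    """Autocorrelation-based multi-chain effective sample size.

    Averages per-chain autocorrelations, sums them in adjacent pairs
    and truncates at the first negative pair (initial positive-sequence
    rule); the result never exceeds the pooled number of draws.
    """
    x = _chains_matrix(chains, parameter)
    m, n = x.shape
    if n < 4:
        raise ValueError("ESS needs at least 4 draws per chain")
    variances = np.var(x, axis=1, ddof=0)
    if np.all(variances == 0.0):
        raise ValueError("constant chain; ESS undefined")
    acov = np.zeros(n)
    for c in range(m):
        xc = x[c] - x[c].mean()
        f = np.fft.rfft(np.concatenate([xc, np.zeros(n)]))
        ac = np.fft.irfft(f * np.conj(f))[:n] / n
        acov += ac
    acov /= m
    rho = acov / acov[0]
    s = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair < 0.0:
            break
        s += pair
        t += 2
    ess = m * n / (1.0 + 2.0 * s)
    return float(min(ess, m * n))


# ---------------------------------------------------------------------------
# Posterior summaries

@dataclass(frozen=True)
class PosteriorSummary:
    """Posterior table: mean, sd, 95% interval, Rhat, ESS per quantity."""

    table: pd.DataFrame

    def __getitem__(self, name: str) -> pd.Series:
        return self.table.loc[name]

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    @property
    def max_rhat(self) -> float:
        return float(self.table["rhat"].max())


def _summary_row(sample: np.ndarray, per_chain: np.ndarray) -> dict:
    row = {
        "mean": float(np.mean(sample)),
        "sd": float(np.std(sample, ddof=1)),
        # order-statistic quantiles: exactly equivariant under monotone
        # transforms (invlogit), unlike interpolated ones
        "q2.5": float(np.quantile(sample, 0.025, method="inverted_cdf")),
        "q97.5": float(np.quantile(sample, 0.975, method="inverted_cdf")),
    }
    try:
        row["rhat"] = gelman_rubin(per_chain)
    except ValueError:
        row["rhat"] = float("nan")
    try:
        row["ess"] = effective_sample_size(per_chain)
    except ValueError:
        row["ess"] = float("nan")
    return row


def summarize_posterior(
    chains: McmcChains, design: StudyDesign | None = None
) -> PosteriorSummary:
    """Summaries for every sampled parameter and the derived survivals.

    Derived quantities are computed draw-by-draw (not from plug-in
    means): class survival invlogit(beta_x), class resighting
    probability invlogit(logit_p_x), and — when year effects are
    sampled — the annual survival series invlogit(beta_x + eps_t).
    """
    if chains.draws.shape[1] == 0:
        raise ValueError("no retained draws")
    design = design or chains.design
    rows = {}
    for j, name in enumerate(chains.param_names):
        per_chain = chains.draws[:, :, j]
        rows[name] = _summary_row(per_chain.ravel(), per_chain)

    class_names = [c.name.lower() for c in AgeClass]
    for c, cname in enumerate(class_names):
        per_chain = invlogit(chains.draws[:, :, c])
        rows[f"survival_{cname}"] = _summary_row(per_chain.ravel(), per_chain)
    if chains.spec.p_structure == "constant":
        per_chain = invlogit(chains.draws[:, :, chains.index_of("logit_p")])
        rows["p"] = _summary_row(per_chain.ravel(), per_chain)
    else:
        for cname in class_names:
            j = chains.index_of(f"logit_p_{cname}")
            per_chain = invlogit(chains.draws[:, :, j])
            rows[f"p_{cname}"] = _summary_row(per_chain.ravel(), per_chain)
    if chains.spec.random_year_effect:
        for c, cname in enumerate(class_names):
            for y in design.occasion_years[:-1]:
                j = chains.index_of(f"eps_{y}")
                per_chain = invlogit(chains.draws[:, :, c] + chains.draws[:, :, j])
                rows[f"survival_{cname}_{y}"] = _summary_row(
                    per_chain.ravel(), per_chain
                )
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "quantity"
    return PosteriorSummary(table)
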