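"""Age-dependent Cormack–Jolly–Seber likelihood.

The model: conditional on its first capture, an animal survives each
annual interval with probability

    phi[i, t] = invlogit(beta[x(i, t)] + eps[t]),

where ``x(i, t)`` is its age class (juvenile / subadult / adult) at the
start of interval ``t`` and ``eps[t]`` is a year effect shared by all
individuals, Normal(0, sigma^2) under the hierarchical model. An animal
alive at occasion ``t`` is detected with probability ``p[x(i, t)]``;
a dead animal is never detected, and death is absorbing (apparent
survival: permanent emigration is indistinguishable from death).

Because ages are known, the only latent structure is alive/dead, which
is marginalised exactly by a two-state forward recursion. A brute-force
enumeration over death intervals (:func:`enumerate_history_probs`) and a
multinomial m-array likelihood (:func:`marray_loglik`) provide
independent cross-checks.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass

import numpy as np
from numba import njit

from .encounter import (
    AgeClass,
    EncounterDataset,
    EncounterHistory,
    MArray,
    StudyDesign,
)

__all__ = [
    "CJSParameters",
    "ModelSpec",
    "survival_of",
    "history_loglik",
    "dataset_loglik",
    "enumerate_history_probs",
    "marray_loglik",
    "invlogit",
    "logit",
]


def invlogit(x):
    """Numerically safe inverse logit."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


def logit(p):
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore"):
        out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ModelSpec:
    """Structural choices for the fit.

    Survival is always age-class dependent (the model the study design
    calls for); resighting probability is either one shared value or one
    per age class. A fully time-varying p is deliberately not offered:
    it would confound the final survival and detection parameters.
    """

    p_structure: str = "by_age_class"  # "constant" | "by_age_class"
    random_year_effect: bool = True

    def __post_init__(self) -> None:
        if self.p_structure not in ("constant", "by_age_class"):
            raise ValueError(f"unknown p_structure {self.p_structure!r}")

    @property
    def n_p_params(self) -> int:
        return 1 if self.p_structure == "constant" else 3


@dataclass(frozen=True)
class CJSParameters:
    """A full parameter point.

    beta : logit-scale survival effect per age class (juv, sub, ad)
    eps  : one year effect per interval (occasions - 1 values)
    sigma: scale of the year effects (0 fixes them off)
    p    : resighting probability per age class, in (0, 1); components
           may be tied.
    """

    beta: tuple[float, float, float]
    eps: tuple[float, ...]
    sigma: float
    p: tuple[float, float, float]

    def __post_init__(self) -> None:
        beta = tuple(float(b) for b in self.beta)
        eps = tuple(float(e) for e in self.eps)
        p = tuple(float(q) for q in self.p)
        if len(beta) != 3 or len(p) != 3:
            raise ValueError("beta and p must have one entry per age class")
        if not all(0.0 < q <= 1.0 for q in p):
            raise ValueError("p components must lie in (0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "eps", eps)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "sigma", float(self.sigma))

    @classmethod
    def from_survival(
        cls,
        survival: tuple[float, float, float] | float,
        p: tuple[float, float, float] | float,
        n_intervals: int,
        eps: tuple[float, ...] | None = None,
        sigma: float = 0.0,
    ) -> "CJSParameters":
        """Build parameters from probability-scale survival and p."""
        if np.isscalar(survival):
            survival = (survival,) * 3
        if np.isscalar(p):
            p = (p,) * 3
        beta = tuple(logit(s) for s in survival)
        if eps is None:
            eps = (0.0,) * n_intervals
        return cls(beta=beta, eps=tuple(eps), sigma=sigma, p=tuple(p))

    def survival(self, age: AgeClass | int, interval_index: int) -> float:
        """Interval survival probability for one age class and year."""
        if not 0 <= interval_index < len(self.eps):
            raise IndexError(f"interval_index {interval_index} out of range")
        return invlogit(self.beta[int(age)] + self.eps[interval_index])

    # -- serialisation ----------------------------------------------------
    def to_dict(self, design: StudyDesign | None = None) -> dict:
        eps = list(self.eps)
        if design is not None:
            if design.n_intervals != len(eps):
                raise ValueError("design does not match eps length")
            eps = {str(y): e for y, e in zip(design.occasion_years, eps)}
        return {
            "beta": {c.name.lower(): b for c, b in zip(AgeClass, self.beta)},
            "p": {c.name.lower(): q for c, q in zip(AgeClass, self.p)},
            "sigma": self.sigma,
            "eps": eps,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CJSParameters":
        eps = d["eps"]
        if isinstance(eps, dict):
            eps = [eps[k] for k in sorted(eps, key=int)]
        return cls(
            beta=tuple(d["beta"][c.name.lower()] for c in AgeClass),
            p=tuple(d["p"][c.name.lower()] for c in AgeClass),
            sigma=d["sigma"],
            eps=tuple(eps),
        )

    def save(self, path, design: StudyDesign | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(design), fh, indent=2)

    @classmethod
    def load(cls, path) -> "CJSParameters":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def survival_of(params: CJSParameters, age: AgeClass | int, interval_index: int) -> float:
    """invlogit(beta[age] + eps[interval]); see :meth:`CJSParameters.survival`."""
    return params.survival(age, interval_index)


def _check_dims(params: CJSParameters, design: StudyDesign) -> None:
    if len(params.eps) != design.n_intervals:
        raise ValueError(
            f"params have {len(params.eps)} year effects but the design has "
            f"{design.n_intervals} intervals"
        )


# ---------------------------------------------------------------------------
# Reference forward recursion (pure Python, one history at a time)

def history_loglik(
    history: EncounterHistory, params: CJSParameters, design: StudyDesign
) -> float:
    """Log-probability of the detections after first capture.

    Two-state (alive/dead) forward recursion conditional on being alive
    at the first capture, which itself contributes no factor. Impossible
    histories (e.g. a detection after an interval with phi = 0) return
    ``-inf`` rather than raising, so optimisers and samplers can reject.
    """
    _check_dims(params, design)
    det = history.detections
    if len(det) != design.n_occasions:
        raise ValueError("history length does not match design")
    f = history.first_capture
    classes = design.age_classes_for(history.birth_year)
    alive, dead = 1.0, 0.0
    for t in range(f + 1, design.n_occasions):
        phi = params.survival(int(classes[t - 1]), t - 1)
        p = params.p[int(classes[t])]
        if det[t]:
            alive, dead = alive * phi * p, 0.0
        else:
            alive, dead = alive * phi * (1.0 - p), alive * (1.0 - phi) + dead
    total = alive + dead
    return float(np.log(total)) if total > 0.0 else -np.inf


# ---------------------------------------------------------------------------
# Fast kernel (whole dataset at once); used by dataset_loglik and the fitters

@njit(cache=True)
def _dataset_loglik_kernel(det, first, ac, beta, logit_p, eps):  # pragma: no cover
    n, T = det.shape
    total = 0.0
    for i in range(n):
        alive = 1.0
        dead = 0.0
        for t in range(first[i] + 1, T):
            z = beta[ac[i, t - 1]] + eps[t - 1]
            if z >= 0.0:
                phi = 1.0 / (1.0 + np.exp(-z))
            else:
                e = np.exp(z)
                phi = e / (1.0 + e)
            zp = logit_p[ac[i, t]]
            if zp >= 0.0:
                p = 1.0 / (1.0 + np.exp(-zp))
            else:
                e = np.exp(zp)
                p = e / (1.0 + e)
            if det[i, t] == 1:
                alive = alive * phi * p
                dead = 0.0
            else:
                new_alive = alive * phi * (1.0 - p)
                dead = alive * (1.0 - phi) + dead
                alive = new_alive
        tot = alive + dead
        if tot <= 0.0:
            return -np.inf
        total += np.log(tot)
    return total


def dataset_loglik(dataset: EncounterDataset, params: CJSParameters) -> float:
    """Log-likelihood of the whole dataset (sum over histories).

    Individuals are independent, so this is the sum of
    :func:`history_loglik` over histories; computed by a compiled kernel
    over the packed arrays.
    """
    _check_dims(params, dataset.design)
    det, frst, ac = dataset.to_arrays()
    beta = np.asarray(params.beta, dtype=float)
    logit_p = logit(np.asarray(params.p))
    eps = np.asarray(params.eps, dtype=float)
    return float(_dataset_loglik_kernel(det, frst, ac, beta, logit_p, eps))


# ---------------------------------------------------------------------------
# Brute-force oracle

_MAX_ENUM_SPAN = 12


def enumerate_history_probs(
    params: CJSParameters,
    entry_occasion: int,
    design: StudyDesign,
    birth_year: int | None = None,
) -> dict[tuple[int, ...], float]:
    """Probability of every possible post-entry detection vector.

    Sums explicitly over each possible death interval (and survival to
    the study end) the product of survival, death and detection terms —
    no recursion, no marginalisation tricks. Intended as an oracle for
    :func:`history_loglik`; refuses spans over 12 occasions.

    ``birth_year`` defaults to the entry occasion's calendar year
    (animals ringed in the nest enter at age 0).
    """
    _check_dims(params, design)
    T = design.n_occasions
    if not 0 <= entry_occasion < T:
        raise ValueError("entry_occasion out of range")
    span = T - entry_occasion
    if span > _MAX_ENUM_SPAN:
        raise ValueError(
            f"refusing to enumerate 2^{span - 1} histories; span must be "
            f"<= {_MAX_ENUM_SPAN}"
        )
    if birth_year is None:
        birth_year = design.occasion_years[entry_occasion]
    classes = design.age_classes_for(birth_year)
    phi = [params.survival(int(classes[t]), t) for t in range(T - 1)]
    pdet = [params.p[int(classes[t])] for t in range(T)]

    out: dict[tuple[int, ...], float] = {}
    f = entry_occasion
    for tail in itertools.product((0, 1), repeat=T - f - 1):
        det = (0,) * f + (1,) + tail
        prob = 0.0
        # death during interval d (alive at occasions f..d, dead at d+1..),
        # plus d = T-1 meaning survival through the final occasion
        for d in range(f, T):
            term = 1.0
            for t in range(f + 1, T):
                if t <= d:
                    term *= phi[t - 1]
                    term *= pdet[t] if det[t] else 1.0 - pdet[t]
                elif t == d + 1:
                    term *= (1.0 - phi[t - 1]) * (0.0 if det[t] else 1.0)
                else:
                    term *= 0.0 if det[t] else 1.0
            prob += term
        out[det] = prob
    return out


# ---------------------------------------------------------------------------
# m-array multinomial likelihood

def _tied_params(params: CJSParameters) -> tuple[np.ndarray, float]:
    beta = np.asarray(params.beta)
    p = np.asarray(params.p)
    if not (np.all(beta == beta[0]) and np.all(p == p[0])):
        raise ValueError(
            "marray_loglik requires parameters tied across age classes: the "
            "m-array is not a sufficient statistic when survival or "
            "detection varies within a release row"
        )
    phi = invlogit(beta[0] + np.asarray(params.eps, dtype=float))
    return phi, float(p[0])


def marray_loglik(marray: MArray, params: CJSParameters) -> float:
    """Multinomial log-likelihood of an m-array (class-tied parameters).

    Each release row is a multinomial over the first-recapture occasion
    with cell probabilities built from interval survivals and the shared
    detection probability; the residual cell is never-seen-again. Valid
    only when phi and p do not vary between individuals of a row, hence
    the tied-parameter requirement (time variation through eps is fine).
    Drops the multinomial coefficient, which is parameter-free.
    """
    R = marray.n_release_occasions
    if len(params.eps) != R:
        raise ValueError("m-array and params imply different interval counts")
    phi, p = _tied_params(params)
    T = R + 1
    # cell[i, j-1]: released at i, next seen at j
    cell = np.zeros((R, R))
    for i in range(R):
        for j in range(i + 1, T):
            prob = p
            for k in range(i, j):
                prob *= phi[k]
            for k in range(i + 1, j):
                prob *= 1.0 - p
            cell[i, j - 1] = prob
    chi = 1.0 - cell.sum(axis=1)  # never seen again
    chi = np.clip(chi, 0.0, 1.0)

    rec = marray.recaptures.reshape(-1, R, R).sum(axis=0)
    nsa = marray.never_seen_again.reshape(-1, R).sum(axis=0)
    ll = 0.0
    for counts, probs in ((rec, cell), (nsa[None, :].T, chi[None, :].T)):
        pos = counts > 0
        if np.any(probs[pos] == 0.0):
            return -np.inf
        ll += float(np.sum(counts[pos] * np.log(probs[pos])))
    return ll
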