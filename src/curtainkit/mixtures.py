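"""Population models for velocity and distance samples.

Single-molecule velocity and travel-distance samples are summarized by
fitting single-Gaussian, lognormal, and sum-of-two/three-Gaussian models;
the best model is chosen by BIC (ties toward fewer parameters). Gaussian
mixtures are fit by EM with a quantile-split initialization plus seeded
random restarts; a small variance floor prevents component collapse.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import InvalidParameterError

MODEL_NAMES = ("gaussian", "lognormal", "gauss2", "gauss3")


@dataclass(frozen=True)
class MixtureFit:
    """A fitted population model, components sorted by increasing mean."""

    model_name: str
    means: Tuple[float, ...]
    sds: Tuple[float, ...]
    weights: Tuple[float, ...]
    log_likelihood: float
    bic: float
    n_samples: int
    n_params: int
    converged: bool

    @property
    def n_components(self) -> int:
        return len(self.means)

    def component(self, which: str) -> Tuple[float, float, float]:
        """(mean, sd, weight) of the 'slowest' or 'fastest' component."""
        idx = {"slowest": 0, "fastest": -1}[which]
        return self.means[idx], self.sds[idx], self.weights[idx]


def _validate_samples(samples) -> np.ndarray:
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise InvalidParameterError("samples must be non-empty and finite")
    return x


def _gaussian_fit(x: np.ndarray) -> MixtureFit:
    mu = float(np.mean(x))
    sd = float(np.std(x))
    sd_floor = max(sd, 1e-12)
    ll = float(np.sum(stats.norm.logpdf(x, mu, sd_floor)))
    n_params = 2
    bic = n_params * np.log(x.size) - 2 * ll
    return MixtureFit("gaussian", (mu,), (sd,), (1.0,), ll, bic, x.size, n_params, True)


def _lognormal_fit(x: np.ndarray) -> MixtureFit:
    if np.any(x <= 0):
        raise InvalidParameterError("lognormal model requires strictly positive samples")
    shape, _, scale = stats.lognorm.fit(x, floc=0)
    ll = float(np.sum(stats.lognorm.logpdf(x, shape, 0, scale)))
    mean = float(scale * np.exp(shape**2 / 2))
    sd = float(mean * np.sqrt(np.exp(shape**2) - 1.0))
    n_params = 2
    bic = n_params * np.log(x.size) - 2 * ll
    return MixtureFit("lognormal", (mean,), (sd,), (1.0,), ll, bic, x.size, n_params, True)


def fit_mixture(samples, k: int, seed: int = 0, n_init: int = 10) -> MixtureFit:
    """Maximum-likelihood k-component Gaussian mixture via EM.

    One run is initialized from a quantile split of the sorted sample;
    the remaining ``n_init - 1`` runs use seeded random responsibilities.
    Deterministic for a fixed seed. Requires at least 5k samples.
    """
    x = _validate_samples(samples)
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    if x.size < 5 * k:
        raise InvalidParameterError(f"need at least {5 * k} samples for k={k}")
    if k == 1:
        return _gaussian_fit(x)

    X = np.sort(x)[:, None]  # canonical order: the fit is order-invariant
    sample_sd = float(np.std(x))
    reg = max((1e-6 * sample_sd) ** 2, 1e-12)

    # quantile-split initialization: component j starts at the midpoint
    # quantile of its share of the sorted sample
    qs = (2 * np.arange(k) + 1) / (2 * k)
    means_init = np.quantile(x, qs)[:, None]

    best: Optional[GaussianMixture] = None
    gm = GaussianMixture(
        n_components=k, covariance_type="full", reg_covar=reg,
        means_init=means_init, n_init=1, random_state=seed, max_iter=500,
    ).fit(X)
    best = gm
    for i in range(1, n_init):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", reg_covar=reg,
            init_params="random_from_data", n_init=1,
            random_state=seed + i, max_iter=500,
        ).fit(X)
        if gm.score(X) > best.score(X):
            best = gm

    means = best.means_.ravel()
    sds = np.sqrt(best.covariances_.ravel())
    weights = best.weights_.ravel()
    order = np.argsort(means)
    ll = float(best.score(X) * x.size)
    n_params = 3 * k - 1
    bic = n_params * np.log(x.size) - 2 * ll
    return MixtureFit(
        f"gauss{k}",
        tuple(float(m) for m in means[order]),
        tuple(float(s) for s in sds[order]),
        tuple(float(w) for w in weights[order]),
        ll, bic, x.size, n_params, bool(best.converged_),
    )


def select_model(
    samples,
    candidates: Sequence[str] = MODEL_NAMES,
    seed: int = 0,
) -> MixtureFit:
    """Fit each candidate model and return the one minimizing BIC.

    Ties are broken toward the model with fewer parameters. Candidate
    names: gaussian, lognormal, gauss2, gauss3.
    """
    if not candidates:
        raise InvalidParameterError("candidates must be non-empty")
    x = _validate_samples(samples)
    fits = []
    for name in candidates:
        if name == "gaussian":
            fits.append(_gaussian_fit(x))
        elif name == "lognormal":
            fits.append(_lognormal_fit(x))
        elif name in ("gauss2", "gauss3"):
            fits.append(fit_mixture(x, int(name[-1]), seed=seed))
        else:
            raise InvalidParameterError(f"unknown model {name!r}")
    fits.sort(key=lambda f: (round(f.bic, 9), f.n_params))
    return fits[0]


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: Optional[float]  # None when n = 1 (unbiased SD undefined)
    se: Optional[float]
    median: float
    n: int


def summarize(samples) -> SummaryStats:
    """Mean, unbiased SD, SE, median and n of a sample."""
    x = _validate_samples(samples)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else None
    return SummaryStats(
        mean=float(np.mean(x)),
        sd=sd,
        se=None if sd is None else sd / np.sqrt(n),
        median=float(np.median(x)),
        n=n,
    )
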