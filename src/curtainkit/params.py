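"""Parameter containers and sampling-distribution helpers.

Defaults describe the reference experiment the package models: doubly
tethered lambda DNA (48,502 bp) imaged as a 1-pixel-wide line at
~1 kb/pixel, three-color alternating acquisition with 200 ms integration
(0.4 s effective per-channel interval), and Rad51/Rad54 presynaptic
complexes translocating with mixture-distributed velocities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .errors import InvalidParameterError

LAMBDA_DNA_BP = 48_502


# ---------------------------------------------------------------------------
# Sampling distributions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Distribution:
    """A small family of 1-D sampling distributions.

    kind:
        ``point``        -- degenerate at ``value``
        ``exponential``  -- exponential with mean ``value``
        ``discrete``     -- pmf over integer ``support`` with ``probs``
    """

    kind: str
    value: float = 0.0
    support: Tuple[int, ...] = ()
    probs: Tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("point", "exponential", "discrete"):
            raise InvalidParameterError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "exponential" and self.value < 0:
            raise InvalidParameterError("exponential mean must be >= 0")
        if self.kind == "discrete":
            p = np.asarray(self.probs, dtype=float)
            if len(self.support) != p.size or p.size == 0:
                raise InvalidParameterError("discrete support/probs mismatch")
            if np.any(p < 0) or not np.isclose(p.sum(), 1.0, atol=1e-8):
                raise InvalidParameterError("discrete probs must be >= 0 and sum to 1")

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        if self.kind == "point":
            return self.value if size is None else np.full(size, self.value)
        if self.kind == "exponential":
            return rng.exponential(self.value, size=size)
        idx = rng.choice(len(self.support), size=size, p=np.asarray(self.probs))
        support = np.asarray(self.support)
        return support[idx]

    def mean(self) -> float:
        if self.kind in ("point", "exponential"):
            return self.value
        return float(np.dot(self.support, self.probs))

    @staticmethod
    def point(value: float) -> "Distribution":
        return Distribution("point", value=value)

    @staticmethod
    def exponential(mean: float) -> "Distribution":
        return Distribution("exponential", value=mean)

    @staticmethod
    def exponential_from_median(median: float) -> "Distribution":
        return Distribution("exponential", value=median / np.log(2.0))

    @staticmethod
    def discrete(support: Sequence[int], probs: Sequence[float]) -> "Distribution":
        return Distribution("discrete", support=tuple(support), probs=tuple(probs))


def discrete_two_moment_pmf(
    support: Sequence[int], mean: float, sd: float
) -> Tuple[float, ...]:
    """Maximum-entropy pmf on ``support`` with the requested mean and SD.

    Solves for p(k) proportional to exp(a*k + b*k^2) subject to the two
    moment constraints; this is the least-committal discrete law matching
    a reported "mean +/- SD" for a count variable (e.g. fluorophores per
    binding event).
    """
    k = np.asarray(support, dtype=float)
    target = np.array([mean, sd**2 + mean**2])

    def residual(theta):
        logits = theta[0] * k + theta[1] * k**2
        logits -= logits.max()
        p = np.exp(logits)
        p /= p.sum()
        return np.array([np.dot(p, k), np.dot(p, k**2)]) - target

    sol = optimize.least_squares(residual, x0=np.zeros(2), xtol=1e-14, ftol=1e-14)
    logits = sol.x[0] * k + sol.x[1] * k**2
    logits -= logits.max()
    p = np.exp(logits)
    p /= p.sum()
    if not np.allclose([np.dot(p, k), np.sqrt(np.dot(p, k**2) - np.dot(p, k) ** 2)],
                       [mean, sd], rtol=1e-3):
        raise InvalidParameterError(
            f"moments (mean={mean}, sd={sd}) not attainable on support {tuple(support)}"
        )
    return tuple(p)


def zero_truncated_normal_params(mean: float, sd: float) -> Tuple[float, float]:
    """Underlying (mu, sigma) whose zero-truncated normal matches (mean, sd).

    Velocities and distances are non-negative, so component draws come from
    normals truncated at zero; the printed population moments refer to the
    observed (truncated) distribution. A zero-truncated normal cannot have
    a coefficient of variation above 1, so when sd >= mean the closest
    attainable law is returned (the mean is matched with priority).
    """
    if mean <= 0 or sd < 0:
        raise InvalidParameterError("mean must be > 0 and sd >= 0")
    if sd == 0:
        return mean, 0.0
    if mean / sd >= 6.0:  # truncation negligible
        return mean, sd

    def trunc_moments(alpha, sigma):
        lam = stats.norm.pdf(alpha) / stats.norm.sf(alpha)
        m = sigma * (lam - alpha)
        v = sigma**2 * (1.0 + alpha * lam - lam**2)
        return m, np.sqrt(max(v, 0.0))

    def residual(theta):
        alpha, log_sigma = theta
        m, s = trunc_moments(alpha, np.exp(log_sigma))
        # weight the mean residual more: it is the quantity analyses report
        return np.array([3.0 * (m - mean) / mean, (s - sd) / sd])

    # alpha = -mu/sigma is capped at 2: beyond that the truncated normal
    # degenerates toward an exponential and sampling becomes ill-conditioned
    sol = optimize.least_squares(
        residual,
        x0=np.array([0.0, np.log(sd)]),
        bounds=(np.array([-np.inf, np.log(sd) - 4]), np.array([2.0, np.log(sd) + 4])),
        xtol=1e-13,
        ftol=1e-13,
    )
    alpha, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return float(-alpha * sigma), sigma


def sample_zero_truncated_normal(
    rng: np.random.Generator, mu: float, sigma: float, size: Optional[int] = None
) -> np.ndarray:
    """Draw from N(mu, sigma^2) conditioned on being > 0."""
    if sigma == 0:
        return mu if size is None else np.full(size, mu)
    a = (0.0 - mu) / sigma
    u = rng.uniform(stats.norm.cdf(a), 1.0, size=size)
    return mu + sigma * stats.norm.ppf(u)


# ---------------------------------------------------------------------------
# Acquisition optics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticsParams:
    """Geometry and camera model of the 1-pixel kymograph line.

    bp_per_pixel: physical scale of the DNA axis (default 1000 bp/px).
    frame_interval_s: effective time between consecutive frames of the
        same channel under shuttered alternating acquisition (default
        0.4 s = 200 ms integration + 200 ms shutter delay).
    psf_sigma_px: SD of the 1-D Gaussian point-spread function.
    unit_intensity: mean integrated intensity of one fluorophore.
    bleach_rate_per_frame: per-fluorophore photobleaching probability per
        frame; 0 by default because shuttered illumination is used
        precisely to suppress bleaching over the observation window.
    """

    bp_per_pixel: float = 1000.0
    frame_interval_s: float = 0.4
    n_pixels: int = 49
    n_frames: int = 400
    psf_sigma_px: float = 1.0
    background_mean: float = 100.0
    background_sd: float = 5.0
    unit_intensity: float = 200.0
    bleach_rate_per_frame: float = 0.0

    def __post_init__(self) -> None:
        if self.bp_per_pixel <= 0:
            raise InvalidParameterError("bp_per_pixel must be > 0")
        if self.frame_interval_s <= 0:
            raise InvalidParameterError("frame_interval_s must be > 0")
        if self.n_pixels <= 0 or self.n_frames <= 0:
            raise InvalidParameterError("n_pixels and n_frames must be > 0")
        if self.unit_intensity <= 0:
            raise InvalidParameterError("unit_intensity must be > 0")
        if not 0.0 <= self.bleach_rate_per_frame < 1.0:
            raise InvalidParameterError("bleach_rate_per_frame must be in [0, 1)")

    @property
    def fov_length_bp(self) -> float:
        return self.n_pixels * self.bp_per_pixel


# ---------------------------------------------------------------------------
# Motor (PSC translocation) model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotorParams:
    """Generative model of PSC translocation on one DNA molecule.

    Velocity and track-length mixtures default to the wild-type Rad51/54
    presynaptic-complex populations: velocities 114.3 +/- 73 and
    394 +/- 183 bp/s, travel distances 4.1 +/- 0.9 and 6.2 +/- 1.9 kb,
    equal weights. Component draws are zero-truncated normals whose
    post-truncation moments match the configured values.
    """

    mixture_weights: Tuple[float, ...] = (0.5, 0.5)
    mixture_means_bp_s: Tuple[float, ...] = (114.3, 394.0)
    mixture_sds_bp_s: Tuple[float, ...] = (73.0, 183.0)
    track_len_weights: Tuple[float, ...] = (0.5, 0.5)
    track_len_means_kb: Tuple[float, ...] = (4.1, 6.2)
    track_len_sds_kb: Tuple[float, ...] = (0.9, 1.9)
    pause_prob_per_frame: float = 0.005
    pause_len_frames_range: Tuple[int, int] = (2, 4)
    binding_rate: float = 0.01
    target_pos_bp: Optional[float] = None
    p_capture_1d: float = 0.3
    p_capture_3d: float = 0.02
    p_transient_release: float = 0.2
    dwell_release_s: float = 30.0
    stop_dwell_mean_frames: float = 25.0
    end_behavior: str = "terminate"  # motor hitting a tether point: "terminate" | "reflect"

    def __post_init__(self) -> None:
        w = np.asarray(self.mixture_weights, dtype=float)
        if not np.isclose(w.sum(), 1.0, atol=1e-8) or np.any(w <= 0):
            raise InvalidParameterError("mixture_weights must be positive and sum to 1")
        if len(self.mixture_means_bp_s) != w.size or len(self.mixture_sds_bp_s) != w.size:
            raise InvalidParameterError("velocity mixture component count mismatch")
        lw = np.asarray(self.track_len_weights, dtype=float)
        if not np.isclose(lw.sum(), 1.0, atol=1e-8) or np.any(lw <= 0):
            raise InvalidParameterError("track_len_weights must be positive and sum to 1")
        if any(m < 0 for m in self.mixture_means_bp_s) or any(
            s < 0 for s in self.mixture_sds_bp_s
        ):
            raise InvalidParameterError("velocity means and SDs must be >= 0")
        if not 0.0 <= self.pause_prob_per_frame <= 1.0:
            raise InvalidParameterError("pause_prob_per_frame must be in [0, 1]")
        lo, hi = self.pause_len_frames_range
        if lo < 1 or hi < lo:
            raise InvalidParameterError("pause_len_frames_range must satisfy 1 <= lo <= hi")
        for p in (self.p_capture_1d, self.p_capture_3d, self.p_transient_release):
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterError("capture/release probabilities must be in [0, 1]")
        if self.end_behavior not in ("terminate", "reflect"):
            raise InvalidParameterError("end_behavior must be 'terminate' or 'reflect'")


# ---------------------------------------------------------------------------
# RPA recruitment model
# ---------------------------------------------------------------------------


def default_stoichiometry_distribution() -> Distribution:
    """Molecule-count law over 1..6 matching the wild-type 2.5 +/- 1.5."""
    support = tuple(range(1, 7))
    return Distribution.discrete(support, discrete_two_moment_pmf(support, 2.5, 1.5))


@dataclass(frozen=True)
class RPAGenParams:
    """Generative model of RPA recruitment behind a translocating PSC.

    association_delay defaults to an exponential with median 0.14 min
    (8.4 s), the wild-type association time; lifetimes default to an
    exponential with mean 150 s, which leaves roughly half of the events
    still bound at the end of a ~160 s observation window. footprint_nt
    is the ssDNA occluded per RPA heterotrimer (30 nt).
    """

    stoich_distribution: Distribution = field(
        default_factory=default_stoichiometry_distribution
    )
    association_delay_s_distribution: Distribution = field(
        default_factory=lambda: Distribution.exponential_from_median(8.4)
    )
    lifetime_s_distribution: Distribution = field(
        default_factory=lambda: Distribution.exponential(150.0)
    )
    footprint_nt: float = 30.0
    episode_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.footprint_nt <= 0:
            raise InvalidParameterError("footprint_nt must be > 0")
        if not 0.0 <= self.episode_prob <= 1.0:
            raise InvalidParameterError("episode_prob must be in [0, 1]")
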