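"""Ideal-observer core: likelihoods, Kalman filter, recursive posterior.

The observer holds a discrete posterior over candidate source directions on
the template grid.  At each look it:

1. updates its belief about the head yaw with a one-dimensional Kalman
   filter driven by the motor command and a noisy orientation reading,
2. evaluates the acoustic likelihood of the look for every candidate source
   direction, marginalising over a small set of candidate head orientations
   spanning +/- ``k_sigma`` posterior SDs of the head belief (about 95% of
   the belief mass at the default ``k_sigma = 2``),
3. multiplies the posterior by the marginal likelihood and renormalises.

The first look of a trial carries the full 65-dimensional feature vector
(ITD + both ear spectra); every later look carries the ITD alone.  All
likelihood arithmetic runs in log space; Gaussian normalisation constants
that cancel in the posterior normalisation are dropped, but the
head-orientation weights are kept proper so the candidates weight
correctly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

from .frontend import AcousticObservation, AcousticTemplate, observe_features
from .geometry import DirectionGrid, HeadOrientation
from .synth import HeadTrajectory, SourcePrior

__all__ = [
    "NoiseConfig",
    "AcousticCovariance",
    "HeadEstimate",
    "Posterior",
    "build_sigma_A",
    "spatial_prior",
    "acoustic_loglik",
    "kalman_step",
    "motor_loglik",
    "candidate_orientations",
    "posterior_update",
    "decide",
    "run_observer",
    "ObserverResult",
]


@dataclass(frozen=True)
class NoiseConfig:
    """Sensory-noise and prior parameters of the observer.

    Defaults follow the a-priori values used for the headline simulations:
    0.6 JND of ITD noise, 3.5 dB of spectral noise per channel, perfect
    head-orientation sensing and control, a 30-degree elevation prior and a
    100-ms look interval.
    """

    sigma_itd: float = 0.6  # JND
    sigma_I: float = 3.5  # dB
    sigma_H: float = 0.0  # deg, head-orientation sensor noise
    sigma_u: float = 0.0  # deg, motor-command noise
    sigma_p: float = 30.0  # deg, SD of the elevation prior (inf = uniform)
    dt: float = 0.1  # s, posterior update interval
    itd_floor: float = 0.05  # JND; variance floor keeping Sigma_A invertible
    k_sigma: float = 2.0  # half-width of the head-candidate window, in SDs
    n_candidates: int = 9  # head-orientation candidates per look

    def __post_init__(self) -> None:
        for name in ("sigma_itd", "sigma_I", "sigma_H", "sigma_u"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_candidates < 1:
            raise ValueError("need at least one head-orientation candidate")


class AcousticCovariance:
    """Full 65x65 covariance of the acoustic features.

    Block layout (ITD; left spectrum; right spectrum):

    =========  ===============  ===============
    sigma_itd^2        0                0
        0        Sig_L + Sig_S       Sig_S
        0           Sig_S        Sig_R + Sig_S
    =========  ===============  ===============

    with ``Sig_L = Sig_R = sigma_I^2 I`` and ``Sig_S`` the source-spectrum
    prior covariance, which couples the two ears because the source is
    common to both.  The ITD variance is floored at ``itd_floor^2`` so the
    matrix stays invertible when the configured ITD noise is zero.
    """

    def __init__(self, noise: NoiseConfig, prior: SourcePrior):
        k = prior.n_channels
        sig_itd2 = max(noise.sigma_itd, noise.itd_floor) ** 2
        full = np.zeros((1 + 2 * k, 1 + 2 * k))
        full[0, 0] = sig_itd2
        ear = noise.sigma_I**2 * np.eye(k) + prior.cov
        full[1 : 1 + k, 1 : 1 + k] = ear
        full[1 + k :, 1 + k :] = ear
        full[1 : 1 + k, 1 + k :] = prior.cov
        full[1 + k :, 1 : 1 + k] = prior.cov
        eig_min = float(np.linalg.eigvalsh(full).min())
        if eig_min < -1e-9:
            raise np.linalg.LinAlgError(f"assembled covariance is not PSD (min eigenvalue {eig_min})")
        self.full = full
        self.itd_var = sig_itd2
        self.n_channels = k
        try:
            self._cho = cho_factor(full, lower=True)
        except np.linalg.LinAlgError as err:  # pragma: no cover - guarded above
            cond = np.linalg.cond(full)
            raise np.linalg.LinAlgError(f"acoustic covariance not factorisable (cond={cond:.3g})") from err
        self._solved_templates: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def solve(self, r: np.ndarray) -> np.ndarray:
        """``Sigma_A^{-1} r`` for r of shape (65,) or (m, 65)."""
        return cho_solve(self._cho, np.atleast_2d(r).T).T.reshape(np.shape(r))

    def mahalanobis_sq(self, residuals: np.ndarray) -> np.ndarray:
        """Quadratic form ``r^T Sigma_A^{-1} r`` along the last axis."""
        sol = cho_solve(self._cho, np.atleast_2d(residuals).T).T
        out = np.einsum("...i,...i->...", np.atleast_2d(residuals), sol)
        return out.reshape(np.shape(residuals)[:-1])

    def _template_terms(self, template: AcousticTemplate) -> tuple[np.ndarray, np.ndarray]:
        """Cache ``Sigma^{-1} T^T`` and ``diag(T Sigma^{-1} T^T)`` per template."""
        key = id(template)
        cached = self._solved_templates.get(key)
        if cached is None:
            sol = cho_solve(self._cho, template.features.T)  # (65, n)
            quad = np.einsum("ij,ji->i", template.features, sol)
            cached = (sol, quad)
            self._solved_templates[key] = cached
        return cached


def build_sigma_A(noise: NoiseConfig, prior: SourcePrior) -> AcousticCovariance:
    """Assemble the acoustic-feature covariance from the noise config."""
    if prior.n_channels != 32:
        raise ValueError("source prior must cover the 32 ERB channels")
    return AcousticCovariance(noise, prior)


@dataclass(frozen=True)
class HeadEstimate:
    """Gaussian belief over the head yaw angle (degrees)."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("head-estimate SD must be non-negative")


class Posterior:
    """Discrete posterior density over a direction grid.

    ``log_density`` holds log densities per steradian; the per-point
    probability masses are ``density * weight`` and sum to one.
    """

    def __init__(self, grid: DirectionGrid, log_density: np.ndarray, time_index: int = 0):
        log_density = np.asarray(log_density, dtype=float)
        if log_density.shape != (grid.n,):
            raise ValueError("log density must have one entry per grid point")
        self.grid = grid
        self.log_density = log_density
        self.time_index = time_index
        self.normalize()

    def normalize(self) -> None:
        log_mass = logsumexp(self.log_density + np.log(self.grid.weights))
        if not np.isfinite(log_mass):
            raise FloatingPointError("posterior has no finite mass")
        self.log_density = self.log_density - log_mass

    @property
    def density(self) -> np.ndarray:
        return np.exp(self.log_density)

    @property
    def probabilities(self) -> np.ndarray:
        """Per-point probability mass (sums to one)."""
        p = np.exp(self.log_density + np.log(self.grid.weights))
        return p / p.sum()

    def copy(self) -> "Posterior":
        return Posterior(self.grid, self.log_density.copy(), self.time_index)


def spatial_prior(grid: DirectionGrid, sigma_p: float, over: str = "elevation") -> Posterior:
    """Gaussian prior around the horizontal plane.

    ``p(psi) ~ exp(-angle^2 / (2 sigma_p^2))`` with ``angle`` the elevation
    (default) or the polar angle of the grid point; ``sigma_p = inf`` gives
    the uniform prior.
    """
    if not sigma_p > 0:
        raise ValueError("sigma_p must be positive (use inf for uniform)")
    if over == "elevation":
        ang = grid.elevation
    elif over == "polar":
        ang = grid.lateral_polar()[:, 1]
    else:
        raise ValueError("prior must be over 'elevation' or 'polar'")
    if np.isinf(sigma_p):
        log_density = np.zeros(grid.n)
    else:
        log_density = -(ang**2) / (2.0 * sigma_p**2)
    return Posterior(grid, log_density)


def acoustic_loglik(
    obs: AcousticObservation,
    template: AcousticTemplate,
    sigma_A: AcousticCovariance,
    head: HeadOrientation,
    prior: SourcePrior,
) -> np.ndarray:
    """Log-likelihood of one look for every candidate source direction.

    For each grid direction the template row of its head-relative direction
    is looked up and the residual ``[y_itd - T_itd, y_L - T_L - S_hat,
    y_R - T_R - S_hat]`` scored as ``-0.5 * Mahalanobis^2`` under the full
    covariance (constant terms dropped).  ITD-only looks use the scalar ITD
    marginal.
    """
    idx = template.indices_for_orientation(head)
    if obs.mask == "itd":
        r = obs.y_itd - template.itd[idx]
        return -0.5 * r * r / sigma_A.itd_var
    y = np.concatenate([[obs.y_itd], obs.y_left - prior.mean, obs.y_right - prior.mean])
    residuals = y[None, :] - template.features[idx]
    return -0.5 * sigma_A.mahalanobis_sq(residuals)


def _full_look_loglik_fast(
    obs: AcousticObservation,
    template: AcousticTemplate,
    sigma_A: AcousticCovariance,
    yaw_candidates: np.ndarray,
    prior: SourcePrior,
    pitch: float = 0.0,
    roll: float = 0.0,
) -> np.ndarray:
    """Full-look log-likelihoods for many yaw candidates at once.

    Expands the Mahalanobis form ``(y-t)' S^-1 (y-t) = y'S^-1 y - 2 t'S^-1 y
    + t'S^-1 t`` so the expensive solves happen once per look instead of
    once per candidate.  Agrees with :func:`acoustic_loglik` to rounding.
    """
    sol_T, quad_T = sigma_A._template_terms(template)
    y = np.concatenate([[obs.y_itd], obs.y_left - prior.mean, obs.y_right - prior.mean])
    cross_all = y @ sol_T  # (n,): y' Sigma^-1 t_j
    y_quad = float(y @ sigma_A.solve(y))
    idx = template.indices_batch(yaw_candidates, pitch, roll)
    return -0.5 * (y_quad - 2.0 * cross_all[idx] + quad_T[idx])


def _itd_look_loglik_fast(
    obs: AcousticObservation,
    template: AcousticTemplate,
    sigma_A: AcousticCovariance,
    yaw_candidates: np.ndarray,
    pitch: float = 0.0,
    roll: float = 0.0,
) -> np.ndarray:
    idx = template.indices_batch(yaw_candidates, pitch, roll)
    r = obs.y_itd - template.itd[idx]
    return -0.5 * r * r / sigma_A.itd_var


def kalman_step(est: HeadEstimate, u: float, dt: float, y_H: float, noise: NoiseConfig) -> HeadEstimate:
    """One predict-update cycle of the head-yaw Kalman filter.

    ``K = (sd^2 + sigma_u^2) / (sd^2 + sigma_u^2 + sigma_H^2)``;
    ``mean <- (1-K) (mean + u dt) + K y_H``;
    ``sd^2 <- (1-K) (sd^2 + sigma_u^2)``.  When every variance is zero the
    filter degenerates to exact dead reckoning.
    """
    pred_var = est.sd**2 + noise.sigma_u**2
    denom = pred_var + noise.sigma_H**2
    gain = pred_var / denom if denom > 0 else 0.0
    mean = (1.0 - gain) * (est.mean + u * dt) + gain * y_H
    var = (1.0 - gain) * pred_var
    return HeadEstimate(mean=mean, sd=float(np.sqrt(max(var, 0.0))))


def motor_loglik(est: HeadEstimate, theta_candidates: np.ndarray) -> np.ndarray:
    """Gaussian log-density of candidate yaws under the head belief."""
    theta = np.asarray(theta_candidates, dtype=float)
    if est.sd == 0.0:
        return np.where(theta == est.mean, 0.0, -np.inf)
    z = (theta - est.mean) / est.sd
    return -0.5 * z * z - np.log(est.sd) - 0.5 * np.log(2.0 * np.pi)


def candidate_orientations(est: HeadEstimate, k_sigma: float = 2.0, n_points: int = 9) -> np.ndarray:
    """Evenly spaced yaw candidates over ``mean +/- k_sigma * sd``."""
    if n_points < 1:
        raise ValueError("need at least one candidate")
    if est.sd == 0.0:
        return np.array([est.mean])
    return np.linspace(est.mean - k_sigma * est.sd, est.mean + k_sigma * est.sd, n_points)


def _candidate_weights(est: HeadEstimate, candidates: np.ndarray) -> np.ndarray:
    """Proper (normalised) log weights of the head candidates."""
    logw = motor_loglik(est, candidates)
    return logw - logsumexp(logw)


def posterior_update(
    prev: Posterior,
    obs: AcousticObservation,
    est: HeadEstimate,
    template: AcousticTemplate,
    sigma_A: AcousticCovariance,
    prior: SourcePrior,
    cfg: NoiseConfig,
    pitch: float = 0.0,
    roll: float = 0.0,
) -> Posterior:
    """Recursive Bayesian update of the direction posterior for one look.

    ``p_t(psi) = C * p_{t-1}(psi) * sum_c w_c L_A(y | theta_c, psi)`` where
    the candidates ``theta_c`` discretise the head-orientation integral over
    the +/- ``k_sigma`` belief window.  ``pitch``/``roll`` are the observer's
    readings of the non-rotated axes, applied to every candidate.
    """
    cands = candidate_orientations(est, cfg.k_sigma, cfg.n_candidates)
    logw = _candidate_weights(est, cands)
    if obs.mask == "full":
        ll = _full_look_loglik_fast(obs, template, sigma_A, cands, prior, pitch, roll)
    else:
        ll = _itd_look_loglik_fast(obs, template, sigma_A, cands, pitch, roll)
    marg = logsumexp(ll + logw[:, None], axis=0)
    return Posterior(prev.grid, prev.log_density + marg, time_index=obs.time_index)


def decide(post: Posterior, rule: str, rng: np.random.Generator | None = None) -> int:
    """Point estimate from the posterior: grid index of the response.

    ``"PM"`` (posterior matching) draws a weighted random sample from the
    posterior; ``"MAP"`` takes the maximum, breaking ties toward the lowest
    index.
    """
    if rule == "MAP":
        return int(np.argmax(post.probabilities))
    if rule == "PM":
        if rng is None:
            raise ValueError("posterior-matching needs a random generator")
        return int(rng.choice(post.grid.n, p=post.probabilities))
    raise ValueError(f"unknown decision rule {rule!r}")


@dataclass
class ObserverResult:
    response_index: int
    response_dir: np.ndarray
    posterior: Posterior
    n_looks: int
    trace: list = field(default_factory=list)


def look_schedule(traj: HeadTrajectory) -> list[int]:
    """Trajectory sample indices at which the observer takes a look.

    Active trials look at every trajectory sample, so the final look
    coincides with the end of the rotation gate.  Passive trials look every
    ``dt`` while the stimulus is on (a 500-ms stimulus at dt = 100 ms gives
    five looks); a trial always contains at least two looks when the
    trajectory allows it.
    """
    n = len(traj)
    if n == 1:
        return [0]
    if traj.condition == "passive":
        idx = [i for i in range(n) if traj.t[i] < traj.t[-1] - 1e-9]
        if len(idx) < 2:
            idx = [0, n - 1]
        return idx
    return list(range(n))


def run_observer(
    true_dir: np.ndarray,
    traj: HeadTrajectory,
    template: AcousticTemplate,
    sigma_A: AcousticCovariance,
    source_prior: SourcePrior,
    prior: Posterior,
    noise: NoiseConfig,
    rule: str,
    rng: np.random.Generator,
    stimulus_spectrum: np.ndarray,
    gain_db: float = 0.0,
    store_trace: bool = False,
) -> ObserverResult:
    """Simulate one localisation trial.

    The world draws noisy observations from the template at the source's
    true head-relative direction; the observer runs the Kalman filter and
    recursive posterior update, then answers with the configured decision
    rule.  The first look is full; later looks are ITD-only.
    """
    looks = look_schedule(traj)
    post = prior.copy()
    # the motor command fed to the Kalman filter is the executed rotation
    # (as a head tracker would log it), so with sigma_H = sigma_u = 0 the
    # observer knows the true orientation exactly
    cmd_yaw = traj.yaw
    est: HeadEstimate | None = None
    trace: list = []
    prev_i = looks[0]
    # the observer reads the (per-trial constant) pitch and roll with the
    # same sensor quality as the yaw
    if noise.sigma_H > 0:
        pitch_read = float(traj.pitch[looks[0]] + rng.normal(0.0, noise.sigma_H))
        roll_read = float(traj.roll[looks[0]] + rng.normal(0.0, noise.sigma_H))
    else:
        pitch_read = float(traj.pitch[looks[0]])
        roll_read = float(traj.roll[looks[0]])
    for k, i in enumerate(looks):
        head_true = traj.orientation(i)
        y_H = head_true.yaw + (rng.normal(0.0, noise.sigma_H) if noise.sigma_H > 0 else 0.0)
        if k == 0:
            est = HeadEstimate(mean=float(y_H), sd=noise.sigma_H)
        else:
            interval = float(traj.t[i] - traj.t[prev_i])
            u_eff = float(cmd_yaw[i] - cmd_yaw[prev_i]) / interval
            est = kalman_step(est, u_eff, interval, float(y_H), noise)
        mask = "full" if k == 0 else "itd"
        obs = observe_features(
            true_dir, head_true, template, stimulus_spectrum, noise, mask, rng, time_index=k, gain_db=gain_db
        )
        post = posterior_update(
            post, obs, est, template, sigma_A, source_prior, noise, pitch=pitch_read, roll=roll_read
        )
        if store_trace:
            trace.append(post.copy())
        prev_i = i
    idx = decide(post, rule, rng)
    return ObserverResult(
        response_index=idx,
        response_dir=post.grid.points[idx].copy(),
        posterior=post,
        n_looks=len(looks),
        trace=trace,
    )


def posterior_trace_to_csv(trace: list, path) -> None:
    """Export a posterior trace as tidy CSV (time, grid index, probability)."""
    import pandas as pd

    rows = []
    for post in trace:
        p = post.probabilities
        rows.append(
            pd.DataFrame({"time_index": post.time_index, "grid_index": np.arange(post.grid.n), "probability": p})
        )
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)
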