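"""Synthetic acoustic world: HRIRs, source spectra and head trajectories.

The package needs three things that would normally come from measurements:

* listener HRIRs — generated by a rigid spherical-head model (Woodworth
  interaural delays, head-shadow low-pass on the far ear) augmented with a
  parametric pinna notch whose frequency rises with source elevation and a
  rear high-frequency tilt.  The static spectral cues therefore disambiguate
  elevation and front/back *imperfectly*, leaving room for the dynamic-ITD
  benefit of head rotation.
* a corpus of natural-source log-magnitude spectra — smooth, broadband,
  with strong correlation (rho ~ 0.8) between adjacent 100-ms segments of a
  clip, from which the observer's source-spectrum prior is estimated.
* head trajectories — still (passive) or single-sided 10-degree yaw ramps
  at a variable speed (active), contaminated with small yaw/pitch/roll
  jitter like a real head tracker would record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frontend import HRIRSet
from .geometry import DirectionGrid, HeadOrientation

__all__ = [
    "SphericalHeadParams",
    "SourceCorpus",
    "SourcePrior",
    "HeadTrajectory",
    "TrajectoryJitter",
    "ear_delay",
    "interaural_delay",
    "synth_hrir",
    "synth_hrir_set",
    "synth_source_corpus",
    "segment_correlation",
    "fit_source_prior",
    "synth_head_trajectory",
    "draw_rotation_speed",
]


@dataclass(frozen=True)
class SphericalHeadParams:
    """Parameters of the spherical-head + parametric-pinna HRIR generator.

    ``notch_f0`` is the pinna-notch centre frequency at zero elevation; the
    notch moves by ``notch_octaves_per_90deg`` octaves over 90 degrees of
    elevation (rising with elevation), which is the main monaural elevation
    cue.  It is deep but broad and slow-moving, so elevation is read out
    gradually rather than snapping, leaving a measurable benefit for the
    dynamic (rotation) cue.  Front/back is cued by a second, fixed-frequency
    notch that deepens with rearness plus a rear high-frequency tilt; the
    localized notch matters because a broad tilt alone is confounded with
    the observer's uncertainty about the source spectrum.
    """

    radius: float = 0.0875  # m
    ear_azimuth_deg: float = 100.0  # ears slightly behind the interaural axis
    ear_elevation_deg: float = -10.0  # and slightly below the equator
    speed_of_sound: float = 343.0  # m/s
    notch_f0: float = 6000.0  # Hz at elevation 0
    notch_octaves_per_90deg: float = 0.75
    notch_depth_db: float = 18.0
    notch_width_oct: float = 0.3
    notch2_ratio: float = 1.4  # second pinna notch at ratio * f_notch
    notch2_depth_db: float = 12.0
    notch2_width_oct: float = 0.25
    rear_notch_f0: float = 10500.0  # Hz, fixed; depth scales with rearness
    rear_notch_depth_db: float = 12.0
    rear_notch_width_oct: float = 0.2
    rear_tilt_db: float = 8.0
    shadow_fc_lo: float = 1500.0  # far-ear low-pass corner at full shadow

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("head radius must be positive")
        lo = self.notch_f0 * 2.0 ** (-self.notch_octaves_per_90deg)
        hi = self.notch_f0 * 2.0 ** (self.notch_octaves_per_90deg)
        if lo < 300.0 or hi > 15000.0:
            raise ValueError("notch frequency range must stay within 300 Hz - 15 kHz")

    def ear_vector(self, side: str) -> np.ndarray:
        az = np.radians(self.ear_azimuth_deg if side == "left" else -self.ear_azimuth_deg)
        el = np.radians(self.ear_elevation_deg)
        return np.array([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


def ear_delay(d: np.ndarray, p: SphericalHeadParams, side: str) -> float:
    """Propagation delay (s) to one ear, relative to the head centre.

    Woodworth model: for a visible ear the wavefront arrives ``r*cos(gamma)``
    early; for a shadowed ear it travels the extra arc ``r*(gamma - pi/2)``,
    where ``gamma`` is the angle between the source and the ear's radial
    direction.
    """
    d = np.asarray(d, dtype=float)
    gamma = float(np.arccos(np.clip(d @ p.ear_vector(side), -1.0, 1.0)))
    r_c = p.radius / p.speed_of_sound
    if gamma <= np.pi / 2:
        return -r_c * np.cos(gamma)
    return r_c * (gamma - np.pi / 2)


def interaural_delay(d: np.ndarray, p: SphericalHeadParams) -> float:
    """Closed-form ITD in seconds, ``delay(left) - delay(right)``.

    With ears on the interaural axis (``ear_azimuth_deg = 90``) this reduces
    to the classic Woodworth formula ``(r/c) * (theta + sin(theta))`` for a
    horizontal source at azimuth ``theta``.
    """
    return ear_delay(d, p, "left") - ear_delay(d, p, "right")


def _ear_magnitude(freqs: np.ndarray, d: np.ndarray, p: SphericalHeadParams, side: str) -> np.ndarray:
    """Smooth magnitude response (linear) of one ear for direction ``d``."""
    gamma = float(np.arccos(np.clip(np.asarray(d, float) @ p.ear_vector(side), -1.0, 1.0)))
    shadow = max(0.0, gamma - np.pi / 2) / (np.pi / 2)  # 0 (visible) .. 1 (antipodal)
    gain_db = np.zeros_like(freqs)
    if shadow > 0:
        fc = (1.0 - shadow) * 16000.0 + shadow * p.shadow_fc_lo
        gain_db -= 10.0 * np.log10(1.0 + (freqs / fc) ** 2)
    # pinna notch pair sweeping up with elevation; two notches give the
    # localized multi-channel structure that a smooth source spectrum
    # cannot mimic, which is what vetoes up/down cone mirrors
    elev = np.degrees(np.arcsin(np.clip(d[2], -1.0, 1.0)))
    f_notch = p.notch_f0 * 2.0 ** (p.notch_octaves_per_90deg * elev / 90.0)
    lf = np.log2(np.maximum(freqs, 1e-3))
    gain_db -= p.notch_depth_db * np.exp(-0.5 * ((lf - np.log2(f_notch)) / p.notch_width_oct) ** 2)
    gain_db -= p.notch2_depth_db * np.exp(
        -0.5 * ((lf - np.log2(p.notch2_ratio * f_notch)) / p.notch2_width_oct) ** 2
    )
    # fixed-frequency rear notch plus high-frequency tilt
    rearness = max(0.0, -float(d[0]))
    if rearness > 0:
        loct_r = np.where(freqs > 0, np.log2(np.maximum(freqs, 1e-3) / p.rear_notch_f0), -10.0)
        gain_db -= p.rear_notch_depth_db * rearness * np.exp(-0.5 * (loct_r / p.rear_notch_width_oct) ** 2)
        hf = np.clip(np.log2(np.maximum(freqs, 1e-3) / 2000.0), 0.0, None)
        gain_db -= p.rear_tilt_db * rearness * hf / np.log2(16000.0 / 2000.0)
    return 10.0 ** (gain_db / 20.0)


def synth_hrir(d: np.ndarray, p: SphericalHeadParams, fs: float = 48000.0, length: int = 256) -> np.ndarray:
    """Impulse-response pair (2, length) for one direction."""
    return _synth_hrir_block(np.asarray(d, float)[None, :], p, fs, length)[0]


def _minimum_phase_spectrum(mag: np.ndarray, length: int) -> np.ndarray:
    """Minimum-phase complex spectrum with the given rfft magnitude.

    Built via the real cepstrum so the impulse response stays causal;
    a zero-phase construction would smear energy ahead of the onset and
    bias the threshold-based time-of-arrival estimate.
    """
    log_mag = np.log(np.maximum(mag, 1e-10))
    cep = np.fft.irfft(log_mag, n=length)
    half = length // 2
    cep[1:half] *= 2.0
    cep[half + 1 :] = 0.0
    return np.exp(np.fft.rfft(cep, n=length))


def _synth_hrir_block(dirs: np.ndarray, p: SphericalHeadParams, fs: float, length: int) -> np.ndarray:
    """Vectorised HRIR synthesis for an (n, 3) block of directions."""
    n = dirs.shape[0]
    freqs = np.fft.rfftfreq(length, 1.0 / fs)
    base_delay = 1.0e-3  # keeps negative interaural leads causal
    irs = np.empty((n, 2, length))
    for i, d in enumerate(dirs):
        for e, side in enumerate(("left", "right")):
            tau = base_delay + ear_delay(d, p, side)
            mag = _ear_magnitude(freqs, d, p, side)
            spec = _minimum_phase_spectrum(mag, length) * np.exp(-2j * np.pi * freqs * tau)
            irs[i, e] = np.fft.irfft(spec, n=length)
    return irs


def synth_hrir_set(grid: DirectionGrid, p: SphericalHeadParams, fs: float = 48000.0, length: int = 256) -> HRIRSet:
    """Synthesize HRIRs for every direction of a grid."""
    return HRIRSet(fs=fs, irs=_synth_hrir_block(grid.points, p, fs, length), grid=grid)


@dataclass
class SourceCorpus:
    """Synthetic stand-in for a natural-sound corpus.

    ``spectra`` has shape (n_clips, n_segments, n_channels): per clip, the
    log-magnitude spectra (dB, on the ERB channel centres) of consecutive
    100-ms segments.
    """

    spectra: np.ndarray
    cfs: np.ndarray

    @property
    def pooled(self) -> np.ndarray:
        return self.spectra.reshape(-1, self.spectra.shape[-1])


def synth_source_corpus(
    n_clips: int = 200,
    n_segments: int = 10,
    seed: int | np.random.Generator = 0,
    n_channels: int = 32,
    cfs: np.ndarray | None = None,
    tilt_sd_db_per_oct: float = 2.0,
    shape_sd_db: float = 6.0,
    shape_smoothness: float = 4.0,
    segment_sd_db: float = 3.8,
    segment_ar: float = 0.3,
    gain_sd_db: float = 5.0,
) -> SourceCorpus:
    """Generate clip spectra with natural-like statistical structure.

    Each clip is a random broad spectral tilt plus a smooth correlated
    deviation across ERB channels plus a clip-level gain; consecutive
    segments share the clip spectrum and add an AR(1) deviation.  With the
    defaults the spectral correlation between adjacent segments is ~0.8,
    matching what natural recordings show.
    """
    if n_clips < 100:
        raise ValueError("need at least 100 clips for a stable corpus")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cfs is None:
        from .frontend import erb_space

        cfs = erb_space(300.0, 15000.0, n_channels)
    loct = np.log2(cfs / 1000.0)
    # smooth channel-correlation kernel for the clip shapes
    ch = np.arange(n_channels)
    K = np.exp(-0.5 * ((ch[:, None] - ch[None, :]) / shape_smoothness) ** 2)
    L = np.linalg.cholesky(K + 1e-9 * np.eye(n_channels))
    Ks = np.exp(-0.5 * ((ch[:, None] - ch[None, :]) / (shape_smoothness / 2.0)) ** 2)
    Ls = np.linalg.cholesky(Ks + 1e-9 * np.eye(n_channels))

    tilt = rng.normal(0.0, tilt_sd_db_per_oct, n_clips)
    shape = shape_sd_db * (rng.standard_normal((n_clips, n_channels)) @ L.T)
    gain = rng.normal(0.0, gain_sd_db, n_clips)
    base = tilt[:, None] * loct[None, :] + shape + gain[:, None]

    spectra = np.empty((n_clips, n_segments, n_channels))
    e = segment_sd_db * (rng.standard_normal((n_clips, n_channels)) @ Ls.T)
    innov_scale = segment_sd_db * np.sqrt(1.0 - segment_ar**2)
    for t in range(n_segments):
        if t > 0:
            e = segment_ar * e + innov_scale * (rng.standard_normal((n_clips, n_channels)) @ Ls.T)
        spectra[:, t, :] = base + e
    return SourceCorpus(spectra=spectra, cfs=np.asarray(cfs, float))


def segment_correlation(corpus: SourceCorpus) -> float:
    """Mean Pearson correlation between consecutive segment spectra."""
    s = corpus.spectra
    a = s[:, :-1, :]
    b = s[:, 1:, :]
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    num = (a * b).sum(axis=-1)
    den = np.sqrt((a * a).sum(axis=-1) * (b * b).sum(axis=-1))
    return float(np.mean(num / den))


@dataclass
class SourcePrior:
    """Observer's prior on the source log-magnitude spectrum."""

    mean: np.ndarray  # S_hat, (n_channels,) dB
    cov: np.ndarray  # Sigma_S, (n_channels, n_channels) dB^2

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, float)
        self.cov = np.asarray(self.cov, float)
        n = self.mean.shape[0]
        if self.cov.shape != (n, n):
            raise ValueError("covariance shape does not match the mean")
        if not np.allclose(self.cov, self.cov.T, atol=1e-10):
            raise ValueError("covariance must be symmetric")

    @property
    def n_channels(self) -> int:
        return self.mean.shape[0]


def fit_source_prior(corpus, ridge: float = 1e-6) -> SourcePrior:
    """Pooled mean and (ridge-regularised) covariance of corpus spectra."""
    if isinstance(corpus, SourceCorpus):
        pooled = corpus.pooled
    else:
        pooled = np.asarray(corpus, dtype=float)
    if pooled.ndim != 2:
        raise ValueError("corpus must be a 2-D array of spectra")
    n, k = pooled.shape
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} spectra for a {k}x{k} covariance")
    mean = pooled.mean(axis=0)
    cov = np.cov(pooled, rowvar=False) + ridge * np.eye(k)
    return SourcePrior(mean=mean, cov=cov)


@dataclass(frozen=True)
class TrajectoryJitter:
    """Tracker-style contamination SDs in degrees.

    Yaw jitter is drawn per sample; pitch and roll are per-trial constant
    offsets (slow postural drift rather than frame-to-frame noise), matching
    how small their variation is within a sub-second trial.
    """

    yaw_sd: float = 0.3
    pitch_sd: float = 0.8
    roll_sd: float = 0.5


@dataclass
class HeadTrajectory:
    """Sampled head orientation and motor command over one trial."""

    t: np.ndarray  # seconds, constant step
    yaw: np.ndarray
    pitch: np.ndarray
    roll: np.ndarray
    u: np.ndarray  # commanded yaw speed (deg/s) over [t_i, t_i+1)
    condition: str

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("yaw", "pitch", "roll", "u"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must match the time axis")
            setattr(self, name, arr)
        self.t = np.asarray(self.t, float)
        dt = np.diff(self.t)
        if n > 1 and (np.any(dt <= 0) or np.ptp(dt) > 1e-9):
            raise ValueError("time stamps must increase with a constant step")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def orientation(self, i: int) -> HeadOrientation:
        return HeadOrientation(yaw=float(self.yaw[i]), pitch=float(self.pitch[i]), roll=float(self.roll[i]))

    @property
    def commanded_yaw(self) -> np.ndarray:
        """Noiseless yaw implied by the motor commands (starts at 0)."""
        dt = self.dt
        return np.concatenate([[0.0], np.cumsum(self.u[:-1] * dt)])

    def summary(self) -> dict:
        return {
            "total_yaw": float(abs(self.yaw[-1] - self.yaw[0])),
            "max_abs_pitch": float(np.max(np.abs(self.pitch))),
            "max_any_axis": float(
                max(np.max(np.abs(self.yaw - self.yaw[0])), np.max(np.abs(self.pitch)), np.max(np.abs(self.roll)))
            ),
            "duration": self.duration,
        }

    def to_csv(self, path) -> None:
        pd.DataFrame({"t": self.t, "yaw": self.yaw, "pitch": self.pitch, "roll": self.roll, "u": self.u}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, condition: str) -> "HeadTrajectory":
        df = pd.read_csv(path)
        return cls(
            t=df["t"].to_numpy(),
            yaw=df["yaw"].to_numpy(),
            pitch=df["pitch"].to_numpy(),
            roll=df["roll"].to_numpy(),
            u=df["u"].to_numpy(),
            condition=condition,
        )


def draw_rotation_speed(rng: np.random.Generator, median: float = 15.75, sigma_log: float = 0.5) -> float:
    """Log-normal rotation speed in deg/s.

    The default median makes a 10-degree rotation last ~635 ms, bracketing
    the durations humans produce for unrestricted small rotations.
    """
    return float(median * np.exp(sigma_log * rng.standard_normal()))


def synth_head_trajectory(
    condition: str,
    target_yaw: float = 10.0,
    speed: float = 15.75,
    jitter: TrajectoryJitter | None = None,
    dt: float = 0.1,
    seed: int | np.random.Generator = 0,
    passive_duration: float = 0.5,
) -> HeadTrajectory:
    """Generate one head trajectory.

    Passive trials hold the head at the reference orientation up to jitter.
    Active trials ramp the yaw at ``speed`` toward the signed target
    (positive = leftward) and stop at the first sample at or beyond it, with
    the realised yaw capped at the target (the rotation gate).  Left and
    right rotations with the same seed are exact mirror images.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if condition not in ("passive", "active-left", "active-right"):
        raise ValueError(f"unknown condition {condition!r}")
    jitter = jitter or TrajectoryJitter()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if condition == "passive":
        steps = int(round(passive_duration / dt))
        if steps < 1:
            # update interval longer than the stimulus: sample start and end
            n = 2
            t = np.array([0.0, passive_duration])
        else:
            n = steps + 1
            t = np.arange(n) * dt
        yaw = rng.normal(0.0, jitter.yaw_sd, n)
        u = np.zeros(n)
    else:
        sign = 1.0 if condition == "active-left" else -1.0
        if speed <= 0:
            raise ValueError("active rotation speed must be positive")
        n_steps = int(np.ceil(target_yaw / (speed * dt)))
        n = n_steps + 1
        t = np.arange(n) * dt
        mag = np.minimum(speed * t, target_yaw)
        yaw = sign * (mag + rng.normal(0.0, jitter.yaw_sd, n))
        u = np.zeros(n)
        u[:-1] = sign * np.diff(mag) / dt
    pitch = np.full(n, rng.normal(0.0, jitter.pitch_sd))
    roll = np.full(n, rng.normal(0.0, jitter.roll_sd))
    return HeadTrajectory(t=t, yaw=yaw, pitch=pitch, roll=roll, u=u, condition=condition)
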