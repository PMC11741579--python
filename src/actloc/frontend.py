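"""Auditory front end: impulse responses -> acoustic feature vectors.

Each direction is summarised by 65 features: one interaural time difference
(ITD) expressed in just-noticeable-difference (JND) units, plus a 32-channel
log-magnitude excitation spectrum per ear.  The spectral pipeline is a
gammatone filterbank on the ERB scale (300 Hz - 15 kHz) followed by a
simplified inner-hair-cell stage: half-wave rectification and five cascaded
first-order low-pass filters at 2 kHz.  Channel magnitudes are reported in
dB of the RMS of that envelope (see :func:`gammatone_spectrum` for the
alternative dB-domain average).

The ITD is the difference between the two ears' times of arrival (TOA),
where the TOA is the first time the 3-kHz-low-passed impulse response rises
to within 10 dB of its maximum.  Sign convention: ``TOA(left) - TOA(right)``
is positive when the sound reaches the left ear later, i.e. for sources on
the right.
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.spatial.transform import Rotation

from .geometry import DirectionGrid, HeadOrientation

__all__ = [
    "ErbBank",
    "JndMap",
    "HRIRSet",
    "AcousticTemplate",
    "AcousticObservation",
    "erb_number",
    "erb_space",
    "compute_toa",
    "compute_itd",
    "itd_to_jnd",
    "gammatone_spectrum",
    "build_template",
    "observe_features",
]

SILENCE_FLOOR_DB = -120.0


def erb_number(f_hz):
    """Glasberg & Moore ERB-number (Cam) scale."""
    return 21.4 * np.log10(1.0 + 0.00437 * np.asarray(f_hz, dtype=float))


def erb_space(f_lo: float, f_hi: float, n: int) -> np.ndarray:
    """``n`` frequencies equally spaced on the ERB-number scale, inclusive."""
    e = np.linspace(erb_number(f_lo), erb_number(f_hi), n)
    return (10.0 ** (e / 21.4) - 1.0) / 0.00437


@dataclass
class ErbBank:
    """32-channel gammatone filterbank on the ERB scale."""

    fs: float
    n_channels: int = 32
    f_lo: float = 300.0
    f_hi: float = 15000.0
    cfs: np.ndarray = field(init=False)
    _gt: list = field(init=False, repr=False)
    _lp: tuple = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.f_hi:
            raise ValueError("sample rate must exceed twice the top channel frequency")
        self.cfs = erb_space(self.f_lo, self.f_hi, self.n_channels)
        self._gt = [signal.gammatone(cf, "iir", fs=self.fs) for cf in self.cfs]
        self._lp = signal.butter(1, 2000.0, fs=self.fs)

    def channel_envelope(self, x: np.ndarray, ch: int) -> np.ndarray:
        """Rectified, low-passed output of one gammatone channel.

        ``x`` may be 1-D or (batch, samples); filtering runs along the last
        axis.
        """
        b, a = self._gt[ch]
        y = signal.lfilter(b, a, x, axis=-1)
        y = np.maximum(y, 0.0)
        bl, al = self._lp
        for _ in range(5):
            y = signal.lfilter(bl, al, y, axis=-1)
        return y


@dataclass
class JndMap:
    """Odd, strictly monotone map from ITD (seconds) to JND units.

    Modelled as a signed cumulative JND count: the local JND width grows
    linearly with the ITD magnitude, ``w(t) = w0 + growth * t``, so the count
    is ``f(t) = log(1 + growth * t / w0) / growth``.  The default width at
    zero is 20 us (one JND near the midline) and the growth rate makes the
    local JND roughly 100 us near the 700-us physiological limit.  The map is
    tabulated at configurable knots and interpolated piecewise-linearly.
    """

    w0: float = 20e-6
    growth: float = 0.114  # d(width)/d(ITD); 20 us at midline -> ~100 us at 700 us
    max_itd: float = 1e-3
    n_knots: int = 64
    knots_s: np.ndarray = field(init=False)
    knots_jnd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.growth = float(self.growth)
        t = np.linspace(0.0, self.max_itd, self.n_knots)
        if self.growth > 0:
            j = np.log1p(self.growth * t / self.w0) / self.growth
        else:
            j = t / self.w0
        self.knots_s = t
        self.knots_jnd = j

    def __call__(self, itd_s):
        itd = np.asarray(itd_s, dtype=float)
        if np.any(np.abs(itd) > self.max_itd):
            warnings.warn("ITD outside the mapped range; clamping", stacklevel=2)
            itd = np.clip(itd, -self.max_itd, self.max_itd)
        out = np.sign(itd) * np.interp(np.abs(itd), self.knots_s, self.knots_jnd)
        return float(out) if np.isscalar(itd_s) else out


@dataclass
class HRIRSet:
    """Pairs of head-related impulse responses on a direction grid."""

    fs: float
    irs: np.ndarray  # (n_directions, 2, n_samples); ear order (left, right)
    grid: DirectionGrid

    def __post_init__(self) -> None:
        self.irs = np.asarray(self.irs, dtype=float)
        if self.irs.ndim != 3 or self.irs.shape[1] != 2:
            raise ValueError("irs must have shape (n, 2, samples)")
        if self.irs.shape[0] != self.grid.n:
            raise ValueError("one impulse-response pair per grid direction required")
        if self.fs <= 30000:
            raise ValueError("sample rate must exceed 30 kHz to support 15-kHz channels")


def compute_toa(ir: np.ndarray, fs: float) -> float:
    """Time of arrival: first crossing of max - 10 dB on the low-passed IR."""
    ir = np.asarray(ir, dtype=float)
    if not np.any(ir):
        raise ValueError("all-zero impulse response has no time of arrival")
    b, a = signal.butter(2, 3000.0, fs=fs)
    env = np.abs(signal.lfilter(b, a, ir))
    thr = env.max() * 10.0 ** (-10.0 / 20.0)
    idx = int(np.argmax(env >= thr))
    return idx / fs


def _toa_batch(irs: np.ndarray, fs: float) -> np.ndarray:
    """Vectorised :func:`compute_toa` over the leading axes of ``irs``."""
    b, a = signal.butter(2, 3000.0, fs=fs)
    env = np.abs(signal.lfilter(b, a, irs, axis=-1))
    thr = env.max(axis=-1, keepdims=True) * 10.0 ** (-10.0 / 20.0)
    return np.argmax(env >= thr, axis=-1) / fs


def compute_itd(left: np.ndarray, right: np.ndarray, fs: float) -> float:
    """ITD in seconds: ``TOA(left) - TOA(right)`` (positive = source right)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right impulse responses must have equal length")
    return compute_toa(left, fs) - compute_toa(right, fs)


_DEFAULT_JND = JndMap()


def itd_to_jnd(itd_s, jnd_map: JndMap | None = None):
    """Convert an ITD in seconds to JND units with the default map."""
    return (jnd_map or _DEFAULT_JND)(itd_s)


def gammatone_spectrum(
    x: np.ndarray,
    fs: float,
    bank: ErbBank,
    floor_db: float = SILENCE_FLOOR_DB,
    db_domain_average: bool = False,
) -> np.ndarray:
    """32-channel excitation spectrum (dB) of a signal.

    Default aggregation takes the RMS of each channel's rectified low-passed
    envelope and converts it to dB, which makes the output exactly
    level-equivariant (a gain of g dB shifts every channel by g dB).  Setting
    ``db_domain_average=True`` instead converts the envelope samples to dB
    first and averages in the dB domain; this alternative weights the dips of
    the envelope more heavily and is not exactly level-equivariant.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] < 256:
        raise ValueError("signal too short for a stable excitation estimate")
    out = np.empty(x.shape[:-1] + (bank.n_channels,))
    lin_floor = 10.0 ** (floor_db / 20.0)
    for ch in range(bank.n_channels):
        env = bank.channel_envelope(x, ch)
        if db_domain_average:
            val = np.mean(20.0 * np.log10(np.maximum(env, lin_floor)), axis=-1)
        else:
            rms = np.sqrt(np.mean(env * env, axis=-1))
            val = 20.0 * np.log10(np.maximum(rms, lin_floor))
        out[..., ch] = np.maximum(val, floor_db)
    return out


class AcousticTemplate:
    """Per-direction acoustic features: [T_itd, T_L, T_R].

    ``features`` is an (n, 65) array: column 0 the ITD in JND units, columns
    1..32 the left-ear spectrum (dB), columns 33..64 the right-ear spectrum.
    The template carries its grid and caches nearest-neighbour index maps
    per head orientation (quantised to 0.05 deg, far below the grid
    resolution), which the generative world and the observer query many
    times per trial.  Sharing one quantised lookup keeps the two sides of
    the simulation consistent to the last index.
    """

    ORI_QUANT_DEG = 0.05
    CACHE_MAX = 512

    def __init__(self, grid: DirectionGrid, itd_jnd: np.ndarray, left_db: np.ndarray, right_db: np.ndarray, bank: ErbBank):
        n = grid.n
        itd_jnd = np.asarray(itd_jnd, dtype=float)
        left_db = np.asarray(left_db, dtype=float)
        right_db = np.asarray(right_db, dtype=float)
        if itd_jnd.shape != (n,) or left_db.shape != (n, bank.n_channels) or right_db.shape != (n, bank.n_channels):
            raise ValueError("template component shapes do not match the grid/bank")
        if not (np.all(np.isfinite(left_db)) and np.all(np.isfinite(right_db)) and np.all(np.isfinite(itd_jnd))):
            raise ValueError("template features must be finite")
        self.grid = grid
        self.bank = bank
        self.itd = itd_jnd
        self.left = left_db
        self.right = right_db
        self.features = np.column_stack([itd_jnd, left_db, right_db])
        self._ori_cache: "OrderedDict[tuple, np.ndarray]" = OrderedDict()

    @property
    def n(self) -> int:
        return self.grid.n

    def _quant(self, v: float) -> int:
        return int(round(v / self.ORI_QUANT_DEG))

    def _rotated_points(self, key: tuple) -> np.ndarray:
        qy, qp, qr = (k * self.ORI_QUANT_DEG for k in key)
        rot = Rotation.from_euler("ZYX", [qy, -qp, qr], degrees=True)
        return rot.inv().apply(self.grid.points)

    def indices_for_orientation(self, h: HeadOrientation) -> np.ndarray:
        """Grid index of each direction as seen from head orientation ``h``.

        Maps are cached per quantised orientation (LRU) so the world and the
        observer share one nearest-neighbour query per look.
        """
        return self.indices_batch([h.yaw], h.pitch, h.roll)[0]

    def indices_for_yaw(self, yaw_deg: float) -> np.ndarray:
        """Index map for a pure yaw rotation of the head."""
        return self.indices_batch([yaw_deg], 0.0, 0.0)[0]

    def indices_batch(self, yaws, pitch: float, roll: float) -> np.ndarray:
        """(m, n) index maps for several yaws at one pitch/roll.

        Cache misses are answered with a single batched nearest-neighbour
        query.
        """
        qp, qr = self._quant(pitch), self._quant(roll)
        keys = [(self._quant(y), qp, qr) for y in np.atleast_1d(yaws)]
        missing = [k for k in keys if k not in self._ori_cache]
        if missing:
            pts = np.concatenate([self._rotated_points(k) for k in missing])
            idx = self.grid.nearest_many(pts).reshape(len(missing), self.grid.n)
            for k, row in zip(missing, idx):
                self._ori_cache[k] = row
            while len(self._ori_cache) > self.CACHE_MAX:
                self._ori_cache.popitem(last=False)
        out = np.empty((len(keys), self.grid.n), dtype=np.intp)
        for i, k in enumerate(keys):
            row = self._ori_cache.get(k)
            if row is None:  # evicted within this call; recompute directly
                row = self.grid.nearest_many(self._rotated_points(k))
            out[i] = row
        return out

    def save(self, path) -> None:
        np.savez(
            path,
            points=self.grid.points,
            weights=self.grid.weights,
            itd=self.itd,
            left=self.left,
            right=self.right,
            fs=self.bank.fs,
            bank_lo=self.bank.f_lo,
            bank_hi=self.bank.f_hi,
            n_channels=self.bank.n_channels,
        )

    @classmethod
    def load(cls, path) -> "AcousticTemplate":
        d = np.load(path)
        grid = DirectionGrid(d["points"], d["weights"])
        bank = ErbBank(fs=float(d["fs"]), n_channels=int(d["n_channels"]), f_lo=float(d["bank_lo"]), f_hi=float(d["bank_hi"]))
        return cls(grid, d["itd"], d["left"], d["right"], bank)


def build_template(hrirs: HRIRSet, grid: DirectionGrid, bank: ErbBank, jnd_map: JndMap | None = None) -> AcousticTemplate:
    """Extract the acoustic template from an HRIR set.

    The build is fully deterministic: identical inputs yield a bit-identical
    template.
    """
    if hrirs.grid is not grid and hrirs.grid.n != grid.n:
        raise ValueError("HRIR set and grid have different direction counts")
    jnd_map = jnd_map or _DEFAULT_JND
    toas = _toa_batch(hrirs.irs, hrirs.fs)  # (n, 2)
    itd_s = toas[:, 0] - toas[:, 1]
    itd_jnd = jnd_map(itd_s)
    left_db = gammatone_spectrum(hrirs.irs[:, 0, :], hrirs.fs, bank)
    right_db = gammatone_spectrum(hrirs.irs[:, 1, :], hrirs.fs, bank)
    return AcousticTemplate(grid, itd_jnd, left_db, right_db, bank)


@dataclass
class AcousticObservation:
    """One noisy acoustic 'look'.

    ``mask`` is ``"full"`` (ITD plus both ear spectra; always the first look
    of a trial) or ``"itd"`` (ITD only; every later look).
    """

    y_itd: float
    y_left: np.ndarray | None
    y_right: np.ndarray | None
    mask: str
    time_index: int = 0

    def __post_init__(self) -> None:
        if self.mask not in ("full", "itd"):
            raise ValueError("mask must be 'full' or 'itd'")
        has_spectra = self.y_left is not None and self.y_right is not None
        if self.mask == "full" and not has_spectra:
            raise ValueError("full look requires both ear spectra")
        if self.mask == "itd" and (self.y_left is not None or self.y_right is not None):
            raise ValueError("ITD-only look must not carry spectra")


def observe_features(
    true_dir: np.ndarray,
    head: HeadOrientation,
    template: AcousticTemplate,
    source_spectrum: np.ndarray,
    noise,
    mask: str,
    rng: np.random.Generator,
    time_index: int = 0,
    gain_db: float = 0.0,
) -> AcousticObservation:
    """Draw one noisy observation of a world-frame source direction.

    The generative world adds the true source spectrum (plus any per-trial
    level-roving gain) to the ear templates of the source's head-relative
    direction; the observer later subtracts its *expected* source spectrum.
    The head-relative lookup goes through the template's shared quantised
    index map, so a hypothesis at the true direction and orientation
    reproduces the noiseless features exactly.
    """
    j = int(np.argmax(template.grid.points @ np.asarray(true_dir, dtype=float)))
    idx = int(template.indices_for_orientation(head)[j])
    y_itd = float(template.itd[idx] + rng.normal(0.0, noise.sigma_itd))
    if mask == "itd":
        return AcousticObservation(y_itd, None, None, "itd", time_index)
    src = np.asarray(source_spectrum, dtype=float) + gain_db
    y_l = template.left[idx] + src + rng.normal(0.0, noise.sigma_I, template.bank.n_channels)
    y_r = template.right[idx] + src + rng.normal(0.0, noise.sigma_I, template.bank.n_channels)
    return AcousticObservation(y_itd, y_l, y_r, "full", time_index)
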