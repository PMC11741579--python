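"""Localisation performance metrics and spherical response statistics.

Error taxonomy (lateral-polar coordinates):

* local errors — lateral RMSE over all kept trials; polar RMSE restricted
  to targets within +/-30 deg lateral and to responses free of reversal
  flags, since the polar angle of a reversed response is not a local error.
* reversal errors, reported as percentages — quadrant error (QE): wrapped
  polar error above 90 deg; front-back confusion (FBC): response on the
  other side of the frontal plane than the target; up-down confusion (UDC):
  the same for the horizontal plane.  The flags are independent, so a
  single response can carry several (the plane-crossing definitions are
  deliberately coarse and confound reversals with local errors near a
  plane).  Responses exactly on a plane count as non-crossing.
* elevation gain — OLS slope of response elevation on target elevation;
  1 means unbiased, below 1 compression toward the horizon.

Rates are computed per subject and then averaged, so a summary row reports
the mean and SD over (virtual) listeners; pooled variants are available via
``per_subject=False``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import LateralPolar, latpolar_to_cart

__all__ = [
    "ResponseFlags",
    "MetricsReport",
    "KentFit",
    "classify_response",
    "wrap_polar_error",
    "local_errors",
    "reversal_rates",
    "elevation_gain",
    "fit_kent",
    "qe_spatial_split",
    "summarize",
]


@dataclass(frozen=True)
class ResponseFlags:
    qe: bool
    fbc: bool
    udc: bool

    @property
    def local(self) -> bool:
        return not (self.qe or self.fbc or self.udc)


@dataclass(frozen=True)
class MetricsReport:
    lateral_rmse: float
    polar_rmse: float
    qe_pct: float
    fbc_pct: float
    udc_pct: float
    elevation_gain: float
    n_trials: int
    n_polar: int


@dataclass(frozen=True)
class KentFit:
    """Moment summary of a spherical response cloud.

    ``major_axis``/``minor_axis`` are orthogonal unit tangent vectors at the
    centroid; the axis lengths are two sample SDs of the tangent-plane
    projections (chord units, i.e. approximately radians for tight
    clusters).
    """

    centroid: np.ndarray
    major_axis: np.ndarray
    minor_axis: np.ndarray
    major_length: float
    minor_length: float
    degenerate: bool


def wrap_polar_error(phi_true: float, phi_resp: float) -> float:
    """Absolute polar error wrapped to [0, 180] degrees."""
    d = abs(phi_resp - phi_true) % 360.0
    return min(d, 360.0 - d)


_PLANE_EPS = 1e-9


def _crosses(a, b):
    """Strictly opposite sides of a plane; on-plane (|coord| < 1e-9) never crosses."""
    a = np.where(np.abs(a) < _PLANE_EPS, 0.0, a)
    b = np.where(np.abs(b) < _PLANE_EPS, 0.0, b)
    return np.sign(a) * np.sign(b) < 0


def classify_response(true: LateralPolar, resp: LateralPolar) -> ResponseFlags:
    """QE/FBC/UDC flags for one response."""
    pe = wrap_polar_error(true.polar, resp.polar)
    ct = latpolar_to_cart(true)
    cr = latpolar_to_cart(resp)
    return ResponseFlags(
        qe=pe > 90.0,
        fbc=bool(_crosses(ct[0], cr[0])),
        udc=bool(_crosses(ct[2], cr[2])),
    )


def _flags_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Attach signed errors and reversal flags to a trial table."""
    out = df.copy()
    pe = np.abs(out["resp_polar"].to_numpy() - out["true_polar"].to_numpy()) % 360.0
    pe = np.minimum(pe, 360.0 - pe)
    out["polar_error"] = pe
    out["lateral_error"] = out["resp_lateral"].to_numpy() - out["true_lateral"].to_numpy()
    out["qe"] = pe > 90.0
    out["fbc"] = _crosses(out["true_x"].to_numpy(), out["resp_x"].to_numpy())
    out["udc"] = _crosses(out["true_z"].to_numpy(), out["resp_z"].to_numpy())
    return out


def local_errors(df: pd.DataFrame) -> tuple[float, float]:
    """Lateral and polar RMSE in degrees.

    The polar RMSE covers only targets within +/-30 deg lateral whose
    responses carry no reversal flag; it is NaN when that set is empty.
    """
    if len(df) == 0:
        raise ValueError("no trials to score")
    f = _flags_frame(df)
    lat_rmse = float(np.sqrt(np.mean(f["lateral_error"] ** 2)))
    sel = (np.abs(f["true_lateral"]) <= 30.0) & ~(f["qe"] | f["fbc"] | f["udc"])
    pol_rmse = float(np.sqrt(np.mean(f.loc[sel, "polar_error"] ** 2))) if sel.any() else float("nan")
    return lat_rmse, pol_rmse


def reversal_rates(df: pd.DataFrame, per_subject: bool = True) -> tuple[float, float, float]:
    """QE, FBC and UDC rates in percent (subject-averaged by default)."""
    f = _flags_frame(df)
    if per_subject and "subject" in f.columns and f["subject"].nunique() > 1:
        g = f.groupby("subject")[["qe", "fbc", "udc"]].mean() * 100.0
        return tuple(float(v) for v in g.mean())
    return (
        float(f["qe"].mean() * 100.0),
        float(f["fbc"].mean() * 100.0),
        float(f["udc"].mean() * 100.0),
    )


def elevation_gain(df: pd.DataFrame) -> float:
    """OLS slope of response elevation on true elevation (degrees)."""
    te = df["true_elevation"].to_numpy(dtype=float)
    re = df["resp_elevation"].to_numpy(dtype=float)
    if len(te) < 2 or np.ptp(te) == 0:
        return float("nan")
    slope, _ = np.polyfit(te, re, 1)
    return float(slope)


def fit_kent(responses: np.ndarray) -> KentFit:
    """Moment-based elliptical summary of responses on the sphere.

    The centroid is the normalised mean vector; the axes are the
    eigenvectors of the tangent-plane scatter at the centroid, with lengths
    of two sample SDs each.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2 or responses.shape[1] != 3 or responses.shape[0] < 3:
        raise ValueError("need at least three 3-D responses")
    mean = responses.mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm < 1e-12:
        raise ValueError("response cloud has no mean direction")
    centroid = mean / norm
    # deterministic tangent basis: start from the world axis least aligned
    ref = np.eye(3)[int(np.argmin(np.abs(centroid)))]
    e1 = np.cross(centroid, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(centroid, e1)
    tang = responses - np.outer(responses @ centroid, centroid)
    coords = np.column_stack([tang @ e1, tang @ e2])
    cov = np.cov(coords, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    major = evecs[0, 0] * e1 + evecs[1, 0] * e2
    minor = evecs[0, 1] * e1 + evecs[1, 1] * e2
    return KentFit(
        centroid=centroid,
        major_axis=major / np.linalg.norm(major),
        minor_axis=minor / np.linalg.norm(minor),
        major_length=float(2.0 * np.sqrt(evals[0])),
        minor_length=float(2.0 * np.sqrt(evals[1])),
        degenerate=bool(evals[0] < 1e-12),
    )


def qe_spatial_split(df: pd.DataFrame) -> tuple[float, float]:
    """Share of quadrant errors with frontal vs rear targets, in percent."""
    f = _flags_frame(df)
    qes = f[f["qe"]]
    if len(qes) == 0:
        return float("nan"), float("nan")
    front = float((qes["true_x"] > 0).mean() * 100.0)
    return front, 100.0 - front


def summarize(df: pd.DataFrame, groupby=("subject", "condition")) -> pd.DataFrame:
    """Per-group metric table (one row per subject x condition by default)."""
    rows = []
    for keys, g in df.groupby(list(groupby)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        lat, pol = local_errors(g)
        qe, fbc, udc = reversal_rates(g, per_subject=False)
        f = _flags_frame(g)
        sel = (np.abs(f["true_lateral"]) <= 30.0) & ~(f["qe"] | f["fbc"] | f["udc"])
        rows.append(
            dict(zip(groupby, keys))
            | {
                "lateral_rmse": lat,
                "polar_rmse": pol,
                "qe_pct": qe,
                "fbc_pct": fbc,
                "udc_pct": udc,
                "elevation_gain": elevation_gain(g),
                "n_trials": len(g),
                "n_polar": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)
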