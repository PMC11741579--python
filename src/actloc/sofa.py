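"""Reader for SOFA (Spatially Oriented Format for Acoustics) HRIR files.

Supports the ``SimpleFreeFieldHRIR`` convention: per-direction IR pairs
with the source positions in SOFA spherical coordinates (azimuth
counter-clockwise from the front, elevation up, both in degrees).  SOFA
files are HDF5 containers, so ``h5py`` reads them directly.

Only reading is provided; the package ships no measured data and defaults
to the synthetic spherical-head generator.
"""

from __future__ import annotations

import numpy as np

from .frontend import HRIRSet
from .geometry import DirectionGrid

__all__ = ["read_sofa"]


def _spherical_to_cart(az_deg: np.ndarray, el_deg: np.ndarray) -> np.ndarray:
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    return np.column_stack([np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)])


def read_sofa(path) -> HRIRSet:
    """Load a SimpleFreeFieldHRIR SOFA file into an :class:`HRIRSet`.

    The direction grid gets equal solid-angle weights ``4*pi/n``; measured
    sets that do not cover the sphere uniformly should re-weight before
    quadrature-sensitive use.
    """
    import h5py

    with h5py.File(path, "r") as f:
        irs = np.asarray(f["Data.IR"])  # (M, 2, N)
        fs = float(np.ravel(f["Data.SamplingRate"])[0])
        pos = np.asarray(f["SourcePosition"])  # (M, 3): az, el, radius
    if irs.ndim != 3 or irs.shape[1] != 2:
        raise ValueError("expected a binaural SimpleFreeFieldHRIR layout (M, 2, N)")
    if pos.shape[0] != irs.shape[0]:
        raise ValueError("SourcePosition count does not match Data.IR")
    points = _spherical_to_cart(pos[:, 0], pos[:, 1])
    points /= np.linalg.norm(points, axis=1, keepdims=True)
    n = points.shape[0]
    grid = DirectionGrid(points, np.full(n, 4.0 * np.pi / n))
    return HRIRSet(fs=fs, irs=irs, grid=grid)
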