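"""GLCM texture features of the QUS parametric maps.

Each of the six mapped parameters (MBF, SS, SI, AAC, ASD, SAS) is quantized
to a fixed gray scale (common across patients, so texture is comparable) and
summarized with four grey-level co-occurrence statistics -- energy, contrast,
homogeneity and correlation -- averaged over pixel distances 1-4 and angles
0/45/90/135 degrees.  Cells outside the ROI are undefined (NaN) and only
pairs with both cells defined enter the co-occurrence counts.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "QUANTIZATION_RANGES",
    "N_LEVELS",
    "DISTANCES",
    "ANGLES_DEG",
    "quantize_map",
    "glcm_matrix",
    "glcm_features",
    "aggregate_slices",
]

# fixed per-parameter gray scales (display color-bar ranges)
QUANTIZATION_RANGES: dict[str, tuple[float, float]] = {
    "MBF": (-10.0, 25.0),    # dB
    "SS": (-8.0, 22.0),      # dB/MHz
    "SI": (-10.0, 60.0),     # dB
    "AAC": (20.0, 170.0),    # dB
    "ASD": (1.0, 200.0),     # um
    "SAS": (0.2, 2.5),       # mm
}
N_LEVELS = 16
DISTANCES = (1, 2, 3, 4)
ANGLES_DEG = (0, 45, 90, 135)

# (row, col) step per unit distance for each angle; rows increase with depth
_ANGLE_STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize_map(grid: np.ndarray, quantization_range: tuple[float, float],
                 n_levels: int = N_LEVELS) -> np.ndarray:
    """Clip to the fixed range and bin uniformly into integer levels.

    Returns an integer grid with -1 marking undefined (NaN) cells.
    """
    lo, hi = quantization_range
    if lo >= hi:
        raise ValueError("quantization range must have lo < hi")
    grid = np.asarray(grid, dtype=float)
    defined = np.isfinite(grid)
    v = np.clip(np.where(defined, grid, lo), lo, hi)
    lev = np.floor((v - lo) / (hi - lo) * n_levels).astype(int)
    lev = np.clip(lev, 0, n_levels - 1)
    lev[~defined] = -1
    return lev


def glcm_matrix(qgrid: np.ndarray, distance: int, angle_deg: int,
                n_levels: int = N_LEVELS) -> np.ndarray | None:
    """Symmetric normalized co-occurrence matrix for one offset.

    Returns None when no valid (both-defined) pair exists at this offset.
    """
    dr, dc = _ANGLE_STEPS[angle_deg]
    dr, dc = dr * distance, dc * distance
    nr, nc = qgrid.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    if r0 >= r1 or c0 >= c1:
        return None
    a = qgrid[r0:r1, c0:c1]
    b = qgrid[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    ok = (a >= 0) & (b >= 0)
    if not ok.any():
        return None
    i = a[ok].ravel()
    j = b[ok].ravel()
    m = np.zeros((n_levels, n_levels))
    np.add.at(m, (i, j), 1.0)
    np.add.at(m, (j, i), 1.0)
    return m / m.sum()


def _features_of(p: np.ndarray) -> dict[str, float]:
    n = p.shape[0]
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    diff2 = (i - j) ** 2
    ene = float((p**2).sum())
    con = float((p * diff2).sum())
    hom = float((p / (1.0 + diff2)).sum())
    pi = p.sum(axis=1)
    mu = float((np.arange(n) * pi).sum())
    var = float(((np.arange(n) - mu) ** 2 * pi).sum())
    if var <= 0.0:
        cor = 1.0   # constant map: perfectly predictable by convention
    else:
        cov = float((p * (i - mu) * (j - mu)).sum())
        cor = cov / var
    return {"ENE": ene, "CON": con, "HOM": hom, "COR": cor}


def glcm_features(qgrid: np.ndarray,
                  distances: tuple[int, ...] = DISTANCES,
                  angles_deg: tuple[int, ...] = ANGLES_DEG,
                  n_levels: int = N_LEVELS) -> dict[str, float]:
    """ENE/CON/HOM/COR averaged over all (distance, angle) offsets.

    Offsets without a valid pair are skipped; if every offset is invalid a
    ValueError is raised.
    """
    qgrid = np.asarray(qgrid)
    per_offset = []
    for d in distances:
        for ang in angles_deg:
            m = glcm_matrix(qgrid, d, ang, n_levels)
            if m is not None:
                per_offset.append(_features_of(m))
    if not per_offset:
        raise ValueError("no valid co-occurrence pair at any offset")
    return {k: float(np.mean([f[k] for f in per_offset]))
            for k in ("ENE", "CON", "HOM", "COR")}


def offset_features(qgrid: np.ndarray,
                    distances: tuple[int, ...] = DISTANCES,
                    angles_deg: tuple[int, ...] = ANGLES_DEG,
                    n_levels: int = N_LEVELS) -> list[dict]:
    """Per-(distance, angle) feature rows, for inspection/debug output."""
    rows = []
    for d in distances:
        for ang in angles_deg:
            m = glcm_matrix(np.asarray(qgrid), d, ang, n_levels)
            if m is None:
                continue
            rows.append({"distance": d, "angle": ang, **_features_of(m)})
    return rows


def aggregate_slices(per_slice_values, slice_areas) -> float:
    """Area-weighted average of a per-slice quantity across slices."""
    v = np.asarray(per_slice_values, dtype=float)
    a = np.asarray(slice_areas, dtype=float)
    if v.shape != a.shape:
        raise ValueError("values and areas must have the same length")
    if len(v) < 1:
        raise ValueError("need at least one slice")
    if np.any(a <= 0):
        raise ValueError("slice areas must be positive")
    return float((v * a).sum() / a.sum())
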