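"""Radial fate profiles and pooled, aligned 3D density maps.

The radial pipeline works per organoid: distances of all cells to the
organoid centre of mass are sorted and split into equal-count bins (deciles
by default), per-bin type proportions are computed, and mean and standard
deviation are taken across organoids.

The density pipeline pools many organoids: each is size-normalised (centred,
scaled so the median absolute deviation of cell-to-centre distances is 1),
rotated so the centre of mass of a target type lies on the positive x-axis,
then all cells are pooled with binary labels (1 = target type) and smoothed
onto a regular grid by Gaussian-kernel weighted averaging (Nadaraya-Watson),
yielding presence values in [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import N_TYPES, TYPE_NAMES, etype_codes

__all__ = [
    "RadialProfile",
    "DensityMap",
    "radial_profile",
    "normalise_organoid",
    "align_to_type_axis",
    "pooled_density_map",
    "density_slice",
    "save_slice_image",
    "rim_enrichment_score",
]


@dataclass
class RadialProfile:
    """Mean and SD of per-bin type proportions across organoids."""

    mean: np.ndarray        # (n_bins, 4)
    sd: np.ndarray          # (n_bins, 4)
    n_bins: int
    n_organoids: int
    binning: str = "equal_count"

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for b in range(self.n_bins):
            for t in range(N_TYPES):
                rows.append((b, TYPE_NAMES[t], self.mean[b, t], self.sd[b, t]))
        return pd.DataFrame(rows, columns=["bin", "etype", "mean", "sd"])


@dataclass
class DensityMap:
    """Interpolated presence of one expression type on a regular 3D grid."""

    values: np.ndarray      # (nx, ny, nz) in [0, 1]
    weight: np.ndarray      # kernel mass per grid point (occupancy proxy)
    axes: tuple             # (x, y, z) grid coordinate arrays
    grid_spacing: float
    bandwidth: float
    n_pooled: int
    target: str


def _positions(cells: pd.DataFrame) -> np.ndarray:
    return cells[["x", "y", "z"]].to_numpy(dtype=float)


def _bin_proportions(codes: np.ndarray, order: np.ndarray,
                     n_bins: int) -> np.ndarray:
    out = np.empty((n_bins, N_TYPES))
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        counts = np.bincount(codes[chunk], minlength=N_TYPES)
        out[b] = counts / counts.sum()
    return out


def radial_profile(organoids, n_bins: int = 10,
                   binning: str = "equal_count") -> RadialProfile:
    """Per-decile fate proportions, averaged across organoids.

    Each organoid contributes one (n_bins, 4) proportion table computed from
    distances to its own centre of mass; bins hold equal cell counts
    (differing by at most one) in the default mode, or equal distance widths
    with ``binning="equal_width"``.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if binning not in ("equal_count", "equal_width"):
        raise ValueError("binning must be 'equal_count' or 'equal_width'")
    per = []
    for idx, org in enumerate(organoids):
        pos = _positions(org)
        if pos.shape[0] < n_bins:
            raise ValueError(
                f"organoid {idx} has {pos.shape[0]} cells, fewer than "
                f"{n_bins} bins")
        codes = etype_codes(org["etype"])
        d = np.linalg.norm(pos - pos.mean(axis=0), axis=1)
        if binning == "equal_count":
            order = np.argsort(d, kind="stable")
            per.append(_bin_proportions(codes, order, n_bins))
        else:
            edges = np.linspace(0.0, d.max() + 1e-12, n_bins + 1)
            which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
            tab = np.full((n_bins, N_TYPES), np.nan)
            for b in range(n_bins):
                counts = np.bincount(codes[which == b], minlength=N_TYPES)
                if counts.sum():
                    tab[b] = counts / counts.sum()
            per.append(tab)
    arr = np.array(per)
    return RadialProfile(mean=np.nanmean(arr, axis=0),
                         sd=np.nanstd(arr, axis=0, ddof=0),
                         n_bins=n_bins, n_organoids=len(per), binning=binning)


def normalise_organoid(cells: pd.DataFrame) -> pd.DataFrame:
    """Centre on the centre of mass and scale distances to unit MAD.

    The scale is the median absolute deviation (median of |d - median(d)|)
    of cell-to-centre distances — robust to outliers, unlike the standard
    deviation.  Idempotent within floating tolerance.
    """
    pos = _positions(cells)
    if pos.shape[0] < 2:
        raise ValueError("normalisation needs at least 2 cells")
    centred = pos - pos.mean(axis=0)
    d = np.linalg.norm(centred, axis=1)
    mad = float(np.median(np.abs(d - np.median(d))))
    if mad <= 0:
        raise ValueError("zero MAD of cell-to-centre distances; "
                         "cannot normalise this organoid")
    out = cells.copy()
    out[["x", "y", "z"]] = centred / mad
    return out


def align_to_type_axis(cells: pd.DataFrame, target) -> pd.DataFrame:
    """Rotate rigidly about the organoid centre of mass so the target-type
    centre of mass lands on the positive x-axis.

    Expects a centred organoid (run :func:`normalise_organoid` first); all
    pairwise distances are preserved.  Errors if no target-type cell exists
    or its centre of mass coincides with the organoid centre (the rotation
    is then undefined).
    """
    codes = etype_codes(cells["etype"])
    t = int(etype_codes([target])[0]) if not isinstance(target, (int, np.integer)) \
        else int(target)
    mask = codes == t
    if not np.any(mask):
        raise ValueError(f"no cells of target type {TYPE_NAMES[t]}")
    pos = _positions(cells)
    centre = pos.mean(axis=0)
    v = pos[mask].mean(axis=0) - centre
    norm = float(np.linalg.norm(v))
    if norm < 1e-12:
        raise ValueError("target-type centre of mass coincides with the "
                         "organoid centre; rotation undefined")
    R = _rotation_to_x(v / norm)
    out = cells.copy()
    out[["x", "y", "z"]] = (pos - centre) @ R.T + centre
    return out


def _rotation_to_x(u: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector u onto e_x (Rodrigues)."""
    ex = np.array([1.0, 0.0, 0.0])
    c = float(np.dot(u, ex))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:  # antiparallel: rotate pi about y
        return np.diag([-1.0, -1.0, 1.0])
    axis = np.cross(u, ex)
    s = np.linalg.norm(axis)
    axis = axis / s
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + s * K + (1 - c) * (K @ K)


def pooled_density_map(organoids, target, grid_spacing: float = 0.25,
                       bandwidth: float = 0.3, pad: float = 0.5) -> DensityMap:
    """Kernel-smoothed presence map of ``target`` over pooled organoids.

    Organoids must already be normalised and aligned to the target type.
    Cells carry binary labels (1 = target type); the map value at a grid
    point is the Gaussian-kernel weighted mean of the labels, hence lies in
    [0, 1] wherever any kernel mass exists and is 0 elsewhere.
    """
    if not organoids:
        raise ValueError("empty organoid pool")
    tcode = int(etype_codes([target])[0])
    pos = np.vstack([_positions(o) for o in organoids])
    labels = np.concatenate([
        (etype_codes(o["etype"]) == tcode).astype(float) for o in organoids])
    lo = pos.min(axis=0) - pad
    hi = pos.max(axis=0) + pad
    axes = tuple(np.arange(lo[k], hi[k] + grid_spacing, grid_spacing)
                 for k in range(3))
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    grid = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    values = np.zeros(grid.shape[0])
    weight = np.zeros(grid.shape[0])
    inv2h2 = 1.0 / (2.0 * bandwidth**2)
    chunk = max(1, int(2e7 // max(1, pos.shape[0])))
    for start in range(0, grid.shape[0], chunk):
        g = grid[start:start + chunk]
        d2 = ((g[:, None, :] - pos[None, :, :]) ** 2).sum(axis=2)
        w = np.exp(-d2 * inv2h2)
        wsum = w.sum(axis=1)
        weight[start:start + chunk] = wsum
        nz = wsum > 0
        values[start:start + chunk][nz] = (w @ labels)[nz] / wsum[nz]
    shape = gx.shape
    return DensityMap(values=values.reshape(shape),
                      weight=weight.reshape(shape), axes=axes,
                      grid_spacing=grid_spacing, bandwidth=bandwidth,
                      n_pooled=len(organoids), target=TYPE_NAMES[tcode])


def density_slice(dmap: DensityMap, axis: str = "z",
                  value: float = 0.0) -> np.ndarray:
    """2D slice of the map at the grid plane nearest to ``value``."""
    k = "xyz".index(axis)
    idx = int(np.argmin(np.abs(dmap.axes[k] - value)))
    return np.take(dmap.values, idx, axis=k)


def save_slice_image(dmap: DensityMap, path, axis: str = "z",
                     value: float = 0.0) -> None:
    """Write a black/white mid-plane slice image (black = presence)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sl = density_slice(dmap, axis=axis, value=value)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(sl.T, origin="lower", cmap="gray_r", vmin=0.0, vmax=1.0)
    ax.set_title(f"{dmap.target} presence, {axis}={value:g}")
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def rim_enrichment_score(profile: RadialProfile, target) -> float:
    """Mean target proportion in the outer 3 bins minus the inner 3 bins.

    Positive values indicate rim enrichment, negative core enrichment,
    ~0 uniform mixing; bounded in [-1, 1].
    """
    if profile.n_bins < 6:
        raise ValueError("rim_enrichment_score needs at least 6 bins")
    t = int(etype_codes([target])[0])
    return float(np.nanmean(profile.mean[-3:, t])
                 - np.nanmean(profile.mean[:3, t]))
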