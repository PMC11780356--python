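"""Superior-colliculus input analysis on a polar axis.

Each SC cell is placed in one of four 500 um anterior-posterior bins
(centers -3.05, -3.55, -4.05, -4.55 mm from bregma) and parameterized by an
angle theta along a polar axis where the ventral SC boundary is 0 degrees and
the midline is 90 degrees. Per-target theta probability densities use a
Gaussian kernel with boundary correction by reflection at both ends, and
samples are pooled across animals without weighting so inefficiently labeled
brains do not skew the distribution.

The polar origin per AP bin is the intersection of the midline with the
ventral SC boundary at the bin center; in the synthetic quarter-annulus this
is the sector center (0, 0) with the ventral-boundary ray along +x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import InsufficientDataError

AP_EDGES_MM = (-2.80, -3.30, -3.80, -4.30, -4.80)
AP_CENTERS_MM = (-3.05, -3.55, -4.05, -4.55)

SUPERFICIAL_LAYERS = ("zo", "sg", "op")
DEEP_LAYERS = ("ig", "iw", "dg", "dw")


@dataclass
class BinGeometry:
    """Polar-axis anchors for one AP bin: origin and ventral-boundary ray."""

    origin: tuple = (0.0, 0.0)
    ventral_ray_deg: float = 0.0  # direction of theta = 0 in map coordinates


def ap_bin(ap_mm: np.ndarray) -> np.ndarray:
    """Assign AP positions to four half-open 500 um bins (1..4); 0 = out of range.

    Bin k covers [edge_k, edge_{k+1}) moving posteriorly, with the most
    posterior bin closed at -4.80.
    """
    ap = np.asarray(ap_mm, dtype=float)
    out = np.zeros(ap.shape, dtype=int)
    for k in range(4):
        hi, lo = AP_EDGES_MM[k], AP_EDGES_MM[k + 1]  # hi > lo (more negative)
        if k < 3:
            mask = (ap <= hi) & (ap > lo)
        else:
            mask = (ap <= hi) & (ap >= lo)
        out[mask] = k + 1
    return out


def compute_theta(xy: np.ndarray, geometry: BinGeometry = BinGeometry()) -> np.ndarray:
    """Polar angle (degrees) of cells relative to the bin geometry.

    Theta is the angle between the origin->cell ray and the ventral-boundary
    ray, clipped to [0, 90]. Cells at the origin get NaN (undefined angle).
    """
    pts = np.atleast_2d(np.asarray(xy, dtype=float))
    dx = pts[:, 0] - geometry.origin[0]
    dy = pts[:, 1] - geometry.origin[1]
    at_origin = (dx == 0) & (dy == 0)
    ang = np.degrees(np.arctan2(dy, dx)) - geometry.ventral_ray_deg
    ang = (ang + 360.0) % 360.0
    # fold reflex angles so theta measures the separation from the ray
    ang = np.where(ang > 180.0, 360.0 - ang, ang)
    theta = np.clip(ang, 0.0, 90.0)
    theta[at_origin] = np.nan
    return theta


def theta_pdf(thetas, grid: np.ndarray | None = None):
    """Boundary-corrected Gaussian-kernel PDF of theta on [0, 90] degrees.

    Correction is by reflection: the sample is mirrored about both 0 and 90,
    the KDE estimated on the augmented sample, and the result folded back and
    truncated to the support, so the density integrates to 1 without leaking
    mass past either boundary.
    """
    t = np.asarray(list(thetas), dtype=float)
    t = t[np.isfinite(t)]
    if len(t) < 2:
        raise InsufficientDataError("theta PDF needs at least 2 angles")
    if grid is None:
        # resolve the kernel: at least 4 grid points per bandwidth
        h = 1.06 * max(t.std(ddof=1), 1e-3) * len(t) ** (-0.2)
        n_pts = int(np.clip(np.ceil(90.0 / (h / 4.0)), 361, 16_384)) + 1
        grid = np.linspace(0.0, 90.0, n_pts)
    if np.ptp(t) == 0:
        dens = np.zeros_like(grid)
        i = int(np.argmin(np.abs(grid - t[0])))
        dens[i] = 1.0 / np.mean(np.diff(grid))
        return grid, dens
    # Silverman bandwidth from the original sample; the mirrored copies are
    # only a boundary device and must not widen the kernel.
    h = float(np.sqrt(gaussian_kde(t, bw_method="silverman").covariance[0, 0]))
    augmented = np.concatenate([t, -t, 180.0 - t])
    kde = gaussian_kde(augmented, bw_method=h / augmented.std(ddof=1))
    dens = 3.0 * kde(grid)
    return grid, dens


def sc_layer_fractions(sc_cells: pd.DataFrame, total_inputs: int,
                       layers=SUPERFICIAL_LAYERS + DEEP_LAYERS) -> dict:
    """Per-lamina input expressed as a fraction of the experiment's total inputs.

    The laminar fractions sum to the experiment's overall SC fraction.
    """
    if total_inputs <= 0:
        raise ValueError("total_inputs must be positive")
    counts = sc_cells["layer"].value_counts()
    return {l: float(counts.get(l, 0)) / total_inputs for l in layers}


def pool_by_target(sc_frames) -> pd.DataFrame:
    """Concatenate per-animal SC cell tables without weighting.

    Simple concatenation: each labeled cell counts once, so brains with less
    efficient labeling contribute proportionally fewer cells rather than being
    reweighted.
    """
    frames = [f for f in sc_frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=["ap_mm", "x_um", "y_um", "layer", "target"])
    return pd.concat(frames, ignore_index=True)


def theta_table(sc_cells: pd.DataFrame,
                geometry: BinGeometry = BinGeometry()) -> pd.DataFrame:
    """Per-cell AP bin, depth class and theta for downstream pooling."""
    out = sc_cells.copy()
    out["ap_bin"] = ap_bin(out["ap_mm"].to_numpy())
    out["theta_deg"] = compute_theta(out[["x_um", "y_um"]].to_numpy(), geometry)
    out["depth_class"] = np.where(out["layer"].isin(SUPERFICIAL_LAYERS),
                                  "superficial", "deep")
    return out
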