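"""Descriptive quantities: input fractions, hexagonal densities, distance
distributions, within-radius proportions, pooled summaries and
relative-strength matrices.

Conventions (documented because each is a genuine choice):

* the distance reference point is the recorded injection site; when absent,
  the target polygon's centroid;
* hexagons are pointy-top with width = flat-to-flat distance (default
  180.6 um), the grid anchored at the map origin;
* kernel density estimates use a Gaussian kernel with Silverman's bandwidth
  and reflection at 0 so no mass leaks to negative distances;
* undefined fractions (zero denominators) are flagged and excluded from group
  medians rather than treated as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .errors import EmptyExperimentError, InsufficientDataError
from .synthgen import VISUAL_AREAS

HEX_WIDTH_UM = 180.6


# ---------------------------------------------------------------------------
# Fractions
# ---------------------------------------------------------------------------

def input_fractions(counts: dict) -> dict:
    """Per-region fractions of the total input population."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise EmptyExperimentError("experiment has zero total inputs")
    return {k: v / total for k, v in counts.items()}


def visual_normalized_fractions(cells: pd.DataFrame, layer: str,
                                visual_areas=VISUAL_AREAS):
    """Per-area fractions of the *visual cortical* input for one layer.

    Normalizing to visual input removes the leverage that outliers with large
    subcortical (SC) fractions would otherwise have on areal comparisons.
    Returns ``(fractions_dict, defined)``; when the layer has zero visual
    cells the fractions are NaN and ``defined`` is False (callers must exclude
    such experiments from group medians).
    """
    sub = cells[(cells["layer"] == layer) & (cells["area"].isin(visual_areas))]
    denom = len(sub)
    if denom == 0:
        return {a: float("nan") for a in visual_areas}, False
    counts = sub["area"].value_counts()
    return {a: float(counts.get(a, 0)) / denom for a in visual_areas}, True


# ---------------------------------------------------------------------------
# Hexagonal binning
# ---------------------------------------------------------------------------

@dataclass
class HexGrid:
    """Pointy-top hexagonal bin counts in axial coordinates."""

    width_um: float
    origin: tuple
    bins: pd.DataFrame  # columns q, r, cx_um, cy_um, count

    @property
    def total(self) -> int:
        return int(self.bins["count"].sum()) if len(self.bins) else 0


def hexbin_density(points: np.ndarray, width_um: float = HEX_WIDTH_UM,
                   origin=(0.0, 0.0)) -> HexGrid:
    """Bin 2D points into pointy-top hexagons of the given flat-to-flat width.

    Uses axial coordinates with cube rounding for exact nearest-center
    membership; bin counts always sum to the number of points.
    """
    if width_um <= 0:
        raise ValueError("hexagon width must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        empty = pd.DataFrame(columns=["q", "r", "cx_um", "cy_um", "count"])
        return HexGrid(width_um=width_um, origin=tuple(origin), bins=empty)
    size = width_um / np.sqrt(3.0)  # center-to-vertex radius
    x = (pts[:, 0] - origin[0])
    y = (pts[:, 1] - origin[1])
    qf = (np.sqrt(3.0) / 3.0 * x - y / 3.0) / size
    rf = (2.0 / 3.0 * y) / size
    q, r = _cube_round(qf, rf)
    df = pd.DataFrame({"q": q, "r": r})
    g = df.groupby(["q", "r"], sort=True).size().reset_index(name="count")
    g["cx_um"] = origin[0] + size * np.sqrt(3.0) * (g["q"] + g["r"] / 2.0)
    g["cy_um"] = origin[1] + size * 1.5 * g["r"]
    return HexGrid(width_um=width_um, origin=tuple(origin),
                   bins=g[["q", "r", "cx_um", "cy_um", "count"]])


def _cube_round(qf, rf):
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(int), r.astype(int)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceSample:
    """Cartesian distances (um) of cells to a target reference point."""

    distances_um: np.ndarray
    layer: str | None = None
    reference: tuple | None = None

    def __post_init__(self):
        self.distances_um = np.asarray(self.distances_um, dtype=float).ravel()
        if np.any(self.distances_um < 0):
            raise ValueError("distances must be nonnegative")

    def __len__(self):
        return len(self.distances_um)


def distances_to_target(cells: pd.DataFrame, reference_point,
                        layer: str | None = None) -> DistanceSample:
    """Euclidean distances of cells (optionally one layer) to a reference point."""
    ref = np.asarray(reference_point, dtype=float)
    if not np.isfinite(ref).all():
        raise ValueError("reference point must be finite")
    sub = cells if layer is None else cells[cells["layer"] == layer]
    d = np.hypot(sub["x_um"].to_numpy(float) - ref[0],
                 sub["y_um"].to_numpy(float) - ref[1])
    return DistanceSample(distances_um=d, layer=layer, reference=tuple(ref))


def proportion_within_radius(sample: DistanceSample, radius_um: float):
    """Closed-disc proportion of cells within the radius; returns (p, n).

    Empty samples yield ``(nan, 0)`` — an undefined proportion, to be excluded
    downstream rather than counted as zero.
    """
    n = len(sample)
    if n == 0:
        return float("nan"), 0
    return float(np.mean(sample.distances_um <= radius_um)), n


def distance_density(sample: DistanceSample, grid: np.ndarray | None = None):
    """Gaussian-kernel PDF of distances with reflection at zero.

    Returns ``(grid, density)``; the density is nonnegative and integrates to
    1 (within 0.01) over the evaluation grid.
    """
    d = sample.distances_um
    if len(d) < 2:
        raise InsufficientDataError("distance KDE needs at least 2 points")
    if np.ptp(d) == 0:
        # Degenerate sample: all mass at one value. Return a narrow spike.
        v = d[0]
        if grid is None:
            half = max(v * 0.05, 1.0)
            grid = np.linspace(max(v - half, 0.0), v + half, 512)
        dens = np.zeros_like(grid)
        i = int(np.argmin(np.abs(grid - v)))
        if len(grid) > 1:
            dens[i] = 1.0 / np.mean(np.diff(grid))
        return grid, dens
    # Bandwidth from the *original* sample (Silverman); estimating it on the
    # reflected sample would inflate the spread and oversmooth.
    h = float(np.sqrt(gaussian_kde(d, bw_method="silverman").covariance[0, 0]))
    aug = np.concatenate([d, -d])
    kde = gaussian_kde(aug, bw_method=h / aug.std(ddof=1))
    if grid is None:
        hi = d.max() + 4 * d.std()
        n_pts = int(np.clip(np.ceil(hi / (h / 4.0)), 512, 16_384)) + 1
        grid = np.linspace(0.0, hi, n_pts)
    dens = 2.0 * kde(grid)
    dens[grid < 0] = 0.0
    return grid, dens


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def pooled_mean_sem(values) -> tuple:
    """Arithmetic mean and standard error (sample SD / sqrt(n))."""
    v = np.asarray(list(values), dtype=float)
    if len(v) < 2:
        raise InsufficientDataError("SEM needs at least 2 values")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(len(v)))


def median_mad(values) -> tuple:
    """Median and unscaled median absolute deviation."""
    v = np.asarray(list(values), dtype=float)
    if len(v) == 0:
        raise InsufficientDataError("median of an empty sample")
    med = float(np.median(v))
    return med, float(np.median(np.abs(v - med)))


def relative_strength_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-normalized matrix: each target column divided by its maximum.

    Entries land in [0, 1] with (at least) one 1.0 per column; all-zero
    columns are left as zeros and reported via the ``attrs['zero_columns']``
    annotation.
    """
    out = matrix.astype(float).copy()
    zero_cols = []
    for col in out.columns:
        mx = out[col].max()
        if mx > 0:
            out[col] = out[col] / mx
        else:
            zero_cols.append(col)
    out.attrs["zero_columns"] = zero_cols
    return out
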