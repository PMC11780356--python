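"""Landmark-based affine registration and virtual flattening of section stacks.

Sectioned cortical tissue is aligned to the pial surface by fitting a full
6-parameter 2D affine transform to landmark pairs (radial blood vessels,
surface vessels, apical dendrites) between adjacent sections, composing the
pairwise fits down the stack, and warping the in-vivo border map into tissue
coordinates with surface-vessel landmarks. All landmark kinds are weighted
equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .errors import RankDeficiencyError
from .synthgen import FlatmapParcellation, SectionStack

DET_TOL = 1e-12  # invertibility tolerance on the linear part

LANDMARK_KINDS = ("radial_vessel", "surface_vessel", "apical_dendrite")


@dataclass
class AffineTransform2D:
    """2x3 matrix mapping (x, y) um -> linear part @ (x, y) + translation."""

    matrix: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(2, 3)
        if abs(np.linalg.det(self.matrix[:, :2])) <= DET_TOL:
            raise RankDeficiencyError("linear part is singular (|det| <= 1e-12)")

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return pts @ self.matrix[:, :2].T + self.matrix[:, 2]

    def invert(self) -> "AffineTransform2D":
        L = self.matrix[:, :2]
        Linv = np.linalg.inv(L)
        return AffineTransform2D(np.hstack([Linv, (-Linv @ self.matrix[:, 2])[:, None]]))


def compose(outer: AffineTransform2D, inner: AffineTransform2D) -> AffineTransform2D:
    """Transform mapping x -> outer(inner(x))."""
    Lo, to = outer.matrix[:, :2], outer.matrix[:, 2]
    Li, ti = inner.matrix[:, :2], inner.matrix[:, 2]
    return AffineTransform2D(np.hstack([(Lo @ Li), (Lo @ ti + to)[:, None]]))


def fit_affine(source: np.ndarray, target: np.ndarray):
    """Least-squares affine fit of target ~ A @ source + t.

    Parameters are point arrays of shape (n, 2) with n >= 3 non-collinear
    sources. Returns ``(AffineTransform2D, rms_um)`` where the RMS is over
    per-point residual magnitudes.
    """
    src = np.atleast_2d(np.asarray(source, dtype=float))
    dst = np.atleast_2d(np.asarray(target, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("source and target must both be (n, 2) point arrays")
    if not (np.isfinite(src).all() and np.isfinite(dst).all()):
        raise ValueError("landmark coordinates must be finite")
    n = len(src)
    if n < 3:
        raise RankDeficiencyError(
            f"affine fit needs >= 3 landmark pairs, got {n}"
        )
    sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise RankDeficiencyError(
            f"source landmarks are collinear (singular values {sv[0]:.3g}, {sv[1]:.3g})"
        )
    X = np.hstack([src, np.ones((n, 1))])
    coef, *_ = np.linalg.lstsq(X, dst, rcond=None)
    matrix = coef.T  # rows: [a b tx; c d ty]
    resid = X @ coef - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return AffineTransform2D(matrix), rms


def fit_affine_pairs(pairs) -> tuple:
    """Convenience wrapper for a list of LandmarkPair-like (source, target) tuples."""
    src = np.array([p[0] for p in pairs], dtype=float)
    dst = np.array([p[1] for p in pairs], dtype=float)
    return fit_affine(src, dst)


def flatten_stack(stack: SectionStack):
    """Per-section transforms into the surface frame.

    Section k's transform composes the fitted pairwise transforms
    k -> k-1 -> ... -> 0; section 0 (the surface section) gets the identity.
    Returns ``(transforms, pair_rms)`` where ``pair_rms[k]`` is the residual
    RMS of the fit for the (k, k+1) pair.
    """
    transforms = [AffineTransform2D.identity()]
    pair_rms = []
    for k, (src, dst) in enumerate(stack.pair_landmarks):
        try:
            A, rms = fit_affine(src, dst)
        except RankDeficiencyError as exc:
            raise RankDeficiencyError(
                f"section pair ({k}, {k + 1}): {exc}"
            ) from exc
        pair_rms.append(rms)
        transforms.append(compose(transforms[-1], A))
    return transforms, pair_rms


def warp_map(parcellation: FlatmapParcellation, source: np.ndarray,
             target: np.ndarray) -> FlatmapParcellation:
    """Warp an in-vivo border map into tissue coordinates.

    Fits an affine from surface-vessel landmark pairs and transforms every
    polygon vertex; area names and order are preserved. Disjointness is
    re-validated and violations raise a warning naming the offending areas.
    """
    T, _ = fit_affine(source, target)
    areas = []
    for name, poly in parcellation.areas:
        ext = np.asarray(poly.exterior.coords)
        areas.append((name, Polygon(T.apply(ext))))
    warped = FlatmapParcellation(animal_id=parcellation.animal_id, areas=areas)
    from .errors import GeometryError
    try:
        warped.validate()
    except GeometryError as exc:
        warnings.warn(f"warped map failed validation: {exc}", stacklevel=2)
    return warped


def warp_map_transform(parcellation: FlatmapParcellation,
                       transform: AffineTransform2D) -> FlatmapParcellation:
    """Apply a known affine to every polygon of a parcellation."""
    areas = [(name, Polygon(transform.apply(np.asarray(poly.exterior.coords))))
             for name, poly in parcellation.areas]
    return FlatmapParcellation(animal_id=parcellation.animal_id, areas=areas)
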