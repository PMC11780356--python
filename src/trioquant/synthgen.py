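"""Synthetic tracing experiments with the statistical structure the analyses assume.

This module is the generative twin of a projection-specific rabies-tracing
dataset: per-animal cortical flatmap parcellations with jittered borders, one
injected target higher visual area (HVA) per experiment, layer 5 / layer 6
corticothalamic input cells drawn from areal weight vectors with a configurable
reciprocal enrichment (L6) or depletion (L5) inside a disc around the injection
site, multinomial brain-wide region counts, starter-cell counts over thalamic
nuclei, superior-colliculus (SC) cells on an analytic quarter-annulus with
target-dependent polar concentration, and serial-section stacks with known
affine ground truth for registration recovery tests.

Everything is deterministic given the configuration seed: each experiment owns
a PRNG stream keyed by (seed, animal_id, target) so output does not depend on
generation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from .errors import ConfigError, GeometryError

# ---------------------------------------------------------------------------
# Controlled vocabularies
# ---------------------------------------------------------------------------

HVA_NAMES = ("PM", "AM", "RL", "AL", "LM")
VISUAL_AREAS = ("V1", "PM", "AM", "RL", "AL", "LM", "P", "POR")
NONVISUAL_AREAS = ("RSP", "PPC", "SS", "AUD", "TEa")
AREA_ORDER = VISUAL_AREAS + NONVISUAL_AREAS

THALAMIC_NUCLEI = ("Pulvinar/LP", "LD", "POm", "dLGN", "CL", "other")

BRAIN_REGIONS = (
    "CTX", "TRN", "SC", "PTN", "dLGN", "vLGN", "ZI", "STR",
    "TH_other", "MB_other", "HY", "HB",
)

# SC laminae ordered deep -> superficial, with radial shells of the synthetic
# quarter-annulus (inner radius, outer radius) in um from the sector origin.
SC_LAYERS = ("dw", "dg", "iw", "ig", "op", "sg", "zo")
SC_LAYER_SHELLS = {
    "dw": (400.0, 600.0),
    "dg": (600.0, 800.0),
    "iw": (800.0, 950.0),
    "ig": (950.0, 1150.0),
    "op": (1150.0, 1300.0),
    "sg": (1300.0, 1500.0),
    "zo": (1500.0, 1550.0),
}

SECTION_TOP_UM = 250.0   # first tangential section contains the surface vessels
SECTION_STEP_UM = 50.0   # subsequent sections

CELL_COLUMNS = (
    "cell_id", "animal_id", "target", "x_um", "y_um",
    "section", "depth_um", "layer", "area",
)


def _stable_hash(*tokens) -> int:
    """Deterministic 32-bit hash of string tokens (order-sensitive)."""
    h = hashlib.sha256("\x1f".join(str(t) for t in tokens).encode()).digest()
    return int.from_bytes(h[:4], "big")


def stream(seed: int, *tokens) -> np.random.Generator:
    """A PRNG stream keyed by the root seed plus arbitrary string tokens."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % (2**31), *(_stable_hash(t) for t in tokens)])
    )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def _default_areal_weights_l5() -> dict:
    # V1-dominant driver input; RSP is the second-largest source.
    w = {
        "V1": 0.60, "PM": 0.02, "AM": 0.02, "RL": 0.02, "AL": 0.02, "LM": 0.04,
        "P": 0.05, "POR": 0.02, "RSP": 0.13, "PPC": 0.02, "SS": 0.02,
        "AUD": 0.02, "TEa": 0.02,
    }
    return w


def _default_areal_weights_l6() -> dict:
    # Modulator input is broader across areas but still V1-led.
    w = {
        "V1": 0.40, "PM": 0.06, "AM": 0.06, "RL": 0.06, "AL": 0.06, "LM": 0.08,
        "P": 0.04, "POR": 0.02, "RSP": 0.10, "PPC": 0.03, "SS": 0.03,
        "AUD": 0.03, "TEa": 0.03,
    }
    return w


def _default_brainwide_weights() -> dict:
    # Pooled region means: cortex / TRN / SC / pretectum dominate.
    return {
        "CTX": 0.414, "TRN": 0.151, "SC": 0.110, "PTN": 0.108,
        "dLGN": 0.025, "vLGN": 0.030, "ZI": 0.040, "STR": 0.032,
        "TH_other": 0.050, "MB_other": 0.025, "HY": 0.010, "HB": 0.005,
    }


def _default_starter_weights() -> dict:
    # Starters concentrate (~82%) in the pulvinar.
    return {
        "Pulvinar/LP": 0.82, "LD": 0.09, "POm": 0.03, "dLGN": 0.03,
        "CL": 0.03, "other": 0.00,
    }


def _default_sc_theta_params() -> dict:
    # Medial (high-theta) concentration for LM and PM targets; broader,
    # more central distributions for AM, RL, AL.
    return {
        "PM": (70.0, 15.0),
        "AM": (45.0, 20.0),
        "RL": (45.0, 20.0),
        "AL": (50.0, 20.0),
        "LM": (75.0, 15.0),
    }


def _default_sc_layer_weights() -> dict:
    # Inputs concentrate near the op/ig border; sparse zonal layer.
    return {
        "zo": 0.02, "sg": 0.13, "op": 0.25, "ig": 0.35,
        "iw": 0.10, "dg": 0.10, "dw": 0.05,
    }


@dataclass
class SynthConfig:
    """Configuration of the synthetic study.

    Defaults describe the modeled study conditions: five target HVAs with
    4-5 animals each, a 9:1 L6CT:L5CT cell ratio, V1-dominant areal weights,
    reciprocal L6 enrichment and L5 depletion within 400 um of the injection
    site, cortex/TRN/SC/pretectum-dominated brain-wide counts and
    pulvinar-concentrated starter cells.
    """

    seed: int = 0
    n_animals_per_target: int = 5
    targets: tuple = HVA_NAMES
    n_L6_cells: int = 1800
    n_L5_cells: int = 200
    l6_reciprocal_multiplier: float = 3.0
    l5_reciprocal_multiplier: float = 0.2
    reciprocity_radius_um: float = 400.0
    areal_weights_L5: dict = field(default_factory=_default_areal_weights_l5)
    areal_weights_L6: dict = field(default_factory=_default_areal_weights_l6)
    brainwide_weights: dict = field(default_factory=_default_brainwide_weights)
    starter_weights: dict = field(default_factory=_default_starter_weights)
    sc_theta_params: dict = field(default_factory=_default_sc_theta_params)
    sc_layer_weights: dict = field(default_factory=_default_sc_layer_weights)
    border_jitter_um: float = 50.0
    n_brainwide_inputs: int = 4000
    n_starter_cells: int = 400
    n_sc_cells: int = 300
    l5_top_um: float = 550.0
    l5_bottom_um: float = 700.0
    l6_bottom_um: float = 950.0

    def __post_init__(self):
        self.targets = tuple(self.targets)
        self.sc_theta_params = {
            k: tuple(float(x) for x in v)
            for k, v in self.sc_theta_params.items()
        }
        for name, vec in (
            ("areal_weights_L5", self.areal_weights_L5),
            ("areal_weights_L6", self.areal_weights_L6),
            ("brainwide_weights", self.brainwide_weights),
            ("starter_weights", self.starter_weights),
            ("sc_layer_weights", self.sc_layer_weights),
        ):
            vals = np.asarray(list(vec.values()), dtype=float)
            if np.any(vals < 0):
                raise ConfigError(f"{name} has negative entries")
            if abs(vals.sum() - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {vals.sum():.12f})")
        if self.reciprocity_radius_um <= 0:
            raise ConfigError("reciprocity_radius_um must be > 0")
        if self.l5_reciprocal_multiplier < 0 or self.l6_reciprocal_multiplier < 0:
            raise ConfigError("reciprocal multipliers must be >= 0")
        if self.border_jitter_um < 0:
            raise ConfigError("border_jitter_um must be >= 0")
        for t in self.targets:
            if t not in self.sc_theta_params:
                raise ConfigError(f"sc_theta_params missing target {t!r}")

    def to_dict(self) -> dict:
        """Plain-container form (lists, not tuples) for YAML round-tripping."""
        d = asdict(self)
        d["targets"] = list(d["targets"])
        d["sc_theta_params"] = {k: list(v) for k, v in d["sc_theta_params"].items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# Template flatmap: a rectilinear schematic of visual cortex
# ---------------------------------------------------------------------------

# Grid lines in um. x grows laterally, y grows anteriorly.
_GRID_X = (0.0, 1200.0, 2400.0, 3600.0, 4800.0, 6000.0)
_GRID_Y = (-1000.0, 0.0, 1000.0, 2000.0, 3000.0, 4000.0, 5000.0)

# Each area is a set of grid cells (col, row): col indexes _GRID_X intervals,
# row indexes _GRID_Y intervals. The layout mimics the mouse posterior cortex:
# V1 with the five mapped HVAs on its anterior/lateral rim, P/POR behind,
# and RSP/PPC/SS/AUD/TEa as the non-visual surround.
_AREA_CELLS = {
    "V1": {(1, 1), (2, 1), (1, 2), (2, 2)},
    "PM": {(1, 3)},
    "AM": {(1, 4)},
    "RL": {(2, 3), (2, 4)},
    "AL": {(3, 3)},
    "LM": {(3, 1), (3, 2)},
    "P": {(1, 0), (2, 0)},
    "POR": {(3, 0), (4, 0)},
    "RSP": {(0, r) for r in range(6)},
    "PPC": {(3, 4)},
    "SS": {(1, 5), (2, 5), (3, 5)},
    "AUD": {(4, 3), (4, 4), (4, 5)},
    "TEa": {(4, 1), (4, 2)},
}


def _trace_ring(cells: set) -> list:
    """Counterclockwise boundary ring of a union of grid cells.

    Keeps every unit grid vertex on the boundary (no collinear
    simplification) so that shared borders between areas carry identical
    vertex chains and can be jittered consistently.
    """
    edges = {}
    for (c, r) in cells:
        x0, x1 = _GRID_X[c], _GRID_X[c + 1]
        y0, y1 = _GRID_Y[r], _GRID_Y[r + 1]
        if (c, r - 1) not in cells:
            edges[(x0, y0)] = (x1, y0)
        if (c + 1, r) not in cells:
            edges[(x1, y0)] = (x1, y1)
        if (c, r + 1) not in cells:
            edges[(x1, y1)] = (x0, y1)
        if (c - 1, r) not in cells:
            edges[(x0, y1)] = (x0, y0)
    start = min(edges)
    ring = [start]
    cur = edges[start]
    while cur != start:
        ring.append(cur)
        cur = edges[cur]
    return ring


def template_rings() -> dict:
    """Template polygon rings (name -> list of (x, y) um) in fixed area order."""
    return {name: _trace_ring(_AREA_CELLS[name]) for name in AREA_ORDER}


@dataclass
class FlatmapParcellation:
    """Named, non-overlapping 2D polygons in um in a fixed deterministic order.

    Coordinate convention: x increases laterally, y increases anteriorly,
    origin at the posteromedial corner of the template grid.
    """

    animal_id: str
    areas: list  # list of (name, Polygon)

    @property
    def names(self) -> list:
        return [n for n, _ in self.areas]

    def polygon(self, name: str) -> Polygon:
        for n, p in self.areas:
            if n == name:
                return p
        raise KeyError(name)

    def validate(self, tol: float = 1e-6):
        polys = [p for _, p in self.areas]
        names = self.names
        for i in range(len(polys)):
            if not polys[i].is_valid or not polys[i].is_simple:
                raise GeometryError(f"polygon {names[i]!r} is not simple/valid")
            for j in range(i + 1, len(polys)):
                inter = polys[i].intersection(polys[j]).area
                if inter > tol:
                    raise GeometryError(
                        f"interiors of {names[i]!r} and {names[j]!r} overlap "
                        f"(area {inter:.3g} um^2)"
                    )


def make_flatmap(config: SynthConfig, animal_id: str,
                 max_retries: int = 5) -> FlatmapParcellation:
    """Per-animal parcellation: template rings with jittered borders.

    Jitter displaces each *grid vertex* once (uniformly within a disc of
    radius ``border_jitter_um``) and applies the same displacement wherever
    that vertex occurs, so shared borders move together and interiors stay
    disjoint. If validation still fails the jitter is halved and regenerated,
    up to ``max_retries`` times.
    """
    rings = template_rings()
    jitter = float(config.border_jitter_um)
    for attempt in range(max_retries + 1):
        rng = stream(config.seed, "flatmap", animal_id, attempt)
        verts = sorted({v for ring in rings.values() for v in ring})
        offsets = {}
        for v in verts:
            if jitter == 0:
                offsets[v] = (0.0, 0.0)
            else:
                r = jitter * np.sqrt(rng.uniform())
                a = rng.uniform(0, 2 * np.pi)
                offsets[v] = (r * np.cos(a), r * np.sin(a))
        areas = []
        for name, ring in rings.items():
            pts = [(x + offsets[(x, y)][0], y + offsets[(x, y)][1])
                   for x, y in ring]
            areas.append((name, Polygon(pts)))
        parc = FlatmapParcellation(animal_id=animal_id, areas=areas)
        try:
            parc.validate()
            return parc
        except GeometryError:
            jitter /= 2.0
    raise GeometryError(
        f"could not produce a disjoint parcellation for {animal_id!r} "
        f"after {max_retries} retries"
    )


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

@dataclass
class Experiment:
    """One animal / one injected target HVA with all measured modalities."""

    animal_id: str
    target: str
    parcellation: FlatmapParcellation
    injection_site: tuple  # (x_um, y_um)
    cells: pd.DataFrame    # CELL_COLUMNS
    starter_counts: dict   # nucleus -> int
    brainwide_counts: dict  # region -> int
    sc_cells: pd.DataFrame
    truth: dict = field(default_factory=dict)


def _uniform_in_polygon(rng: np.random.Generator, poly: Polygon, n: int) -> np.ndarray:
    """Uniform points inside a polygon by rejection sampling in its bbox."""
    if poly.is_empty or poly.area <= 0:
        raise GeometryError("cannot sample from an empty polygon")
    minx, miny, maxx, maxy = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(32, int((n - got) / max(poly.area / ((maxx - minx) * (maxy - miny)), 1e-3)))
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        keep = shapely.contains_xy(poly, xs, ys)
        k = min(int(keep.sum()), n - got)
        idx = np.flatnonzero(keep)[:k]
        out[got:got + k, 0] = xs[idx]
        out[got:got + k, 1] = ys[idx]
        got += k
    return out


def _section_of(depth_um: np.ndarray) -> np.ndarray:
    s = np.where(
        depth_um < SECTION_TOP_UM, 0,
        1 + np.floor((depth_um - SECTION_TOP_UM) / SECTION_STEP_UM),
    )
    return s.astype(int)


def _draw_layer_cells(rng, config: SynthConfig, parc: FlatmapParcellation,
                      layer: str, n: int, weights: dict, site: np.ndarray,
                      multiplier: float) -> np.ndarray:
    """Positions of one layer's cells: area-weighted uniform placement with
    intensity multiplied by ``multiplier`` inside the reciprocity disc.

    The multiplier is realized by oversampling the base process and
    subsampling with probability proportional to the local intensity weight,
    which keeps the configured total exact.
    """
    names = [a for a in weights if weights[a] > 0]
    probs = np.array([weights[a] for a in names])
    probs = probs / probs.sum()

    def draw(n_draw):
        counts = rng.multinomial(n_draw, probs)
        chunks = [
            _uniform_in_polygon(rng, parc.polygon(a), c)
            for a, c in zip(names, counts) if c > 0
        ]
        return np.vstack(chunks) if chunks else np.empty((0, 2))

    if multiplier == 1.0 or n == 0:
        return draw(n)
    pool = draw(max(4 * n, n + 200))
    d = np.hypot(pool[:, 0] - site[0], pool[:, 1] - site[1])
    w = np.where(d <= config.reciprocity_radius_um, multiplier, 1.0)
    if w.sum() <= 0:
        raise ConfigError("intensity weights are all zero")
    idx = rng.choice(len(pool), size=n, replace=False, p=w / w.sum())
    return pool[np.sort(idx)]


def make_experiment(config: SynthConfig, target: str, animal_id: str) -> Experiment:
    """Generate one complete synthetic experiment.

    The injection site is a uniform interior point of the target polygon;
    L5/L6 cells are drawn area-wise from the areal weights and placed
    uniformly within each area, with intensity multiplied inside the
    reciprocity disc; brain-wide, starter and SC modalities are attached.
    """
    if target not in config.targets:
        raise ConfigError(f"target {target!r} not in configured targets {config.targets}")
    parc = make_flatmap(config, animal_id)
    rng = stream(config.seed, "experiment", animal_id, target)

    site = _uniform_in_polygon(rng, parc.polygon(target), 1)[0]

    frames = []
    for layer, n, weights, mult, d0, d1 in (
        ("L5", config.n_L5_cells, config.areal_weights_L5,
         config.l5_reciprocal_multiplier, config.l5_top_um, config.l5_bottom_um),
        ("L6", config.n_L6_cells, config.areal_weights_L6,
         config.l6_reciprocal_multiplier, config.l5_bottom_um, config.l6_bottom_um),
    ):
        xy = _draw_layer_cells(rng, config, parc, layer, n, weights, site, mult)
        depth = rng.uniform(d0, d1, len(xy))
        frames.append(pd.DataFrame({
            "x_um": xy[:, 0], "y_um": xy[:, 1],
            "depth_um": depth, "layer": layer,
        }))
    cells = pd.concat(frames, ignore_index=True)
    cells.insert(0, "cell_id", [f"{animal_id}-{i:05d}" for i in range(len(cells))])
    cells.insert(1, "animal_id", animal_id)
    cells.insert(2, "target", target)
    cells["section"] = _section_of(cells["depth_um"].to_numpy())
    cells["area"] = ""  # filled by the assignment stage
    cells = cells[list(CELL_COLUMNS)]

    bw_names = list(config.brainwide_weights)
    bw = rng.multinomial(config.n_brainwide_inputs,
                         np.array([config.brainwide_weights[r] for r in bw_names]))
    brainwide = dict(zip(bw_names, (int(v) for v in bw)))

    st_names = list(config.starter_weights)
    st = rng.multinomial(config.n_starter_cells,
                         np.array([config.starter_weights[k] for k in st_names]))
    starters = dict(zip(st_names, (int(v) for v in st)))

    sc = make_sc_sample(config, target, rng=stream(config.seed, "sc", animal_id, target))

    truth = {
        "injection_site": [float(site[0]), float(site[1])],
        "l5_multiplier": config.l5_reciprocal_multiplier,
        "l6_multiplier": config.l6_reciprocal_multiplier,
        "reciprocity_radius_um": config.reciprocity_radius_um,
    }
    return Experiment(
        animal_id=animal_id, target=target, parcellation=parc,
        injection_site=(float(site[0]), float(site[1])), cells=cells,
        starter_counts=starters, brainwide_counts=brainwide,
        sc_cells=sc, truth=truth,
    )


def make_study(config: SynthConfig) -> list:
    """All experiments of the configured study (targets x animals)."""
    out = []
    for target in config.targets:
        for i in range(config.n_animals_per_target):
            out.append(make_experiment(config, target, f"{target}{i + 1}"))
    return out


# ---------------------------------------------------------------------------
# Superior colliculus sample
# ---------------------------------------------------------------------------

SC_AP_RANGE_MM = (-4.80, -2.80)


def make_sc_sample(config: SynthConfig, target: str,
                   rng: np.random.Generator | None = None,
                   n: int | None = None) -> pd.DataFrame:
    """SC cells on the analytic quarter-annulus sector.

    AP positions are uniform over [-4.80, -2.80] mm; theta is drawn from a
    normal truncated to [0, 90] degrees with target-dependent location and
    scale; the radial position places each cell in one of the laminar shells.
    The sector origin sits at (0, 0) with the ventral SC boundary along +x
    (theta = 0) and the midline along +y (theta = 90).
    """
    if target not in config.sc_theta_params:
        raise ConfigError(f"sc_theta_params missing target {target!r}")
    if rng is None:
        rng = stream(config.seed, "sc-sample", target)
    if n is None:
        n = config.n_sc_cells
    loc, scale = config.sc_theta_params[target]
    if scale <= 1e-9:
        theta = np.full(n, float(loc))
    else:
        from scipy.stats import truncnorm
        a, b = (0.0 - loc) / scale, (90.0 - loc) / scale
        theta = truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    names = list(config.sc_layer_weights)
    counts = rng.multinomial(n, np.array([config.sc_layer_weights[k] for k in names]))
    layer = np.repeat(names, counts)
    rng.shuffle(layer)
    r0 = np.array([SC_LAYER_SHELLS[l][0] for l in layer])
    r1 = np.array([SC_LAYER_SHELLS[l][1] for l in layer])
    # uniform in area within each shell wedge
    u = rng.uniform(size=n)
    radius = np.sqrt(r0**2 + u * (r1**2 - r0**2))
    th = np.deg2rad(theta)
    return pd.DataFrame({
        "ap_mm": rng.uniform(*SC_AP_RANGE_MM, n),
        "x_um": radius * np.cos(th),
        "y_um": radius * np.sin(th),
        "layer": layer,
        "target": target,
    })


# ---------------------------------------------------------------------------
# Section stacks with affine ground truth
# ---------------------------------------------------------------------------

@dataclass
class SectionStack:
    """Serial tangential sections with per-adjacent-pair landmark lists.

    ``pair_landmarks[k]`` holds (source, target) arrays mapping section k+1
    coordinates onto section k; ``true_transforms[k]`` is the 2x3 ground-truth
    matrix for that pair.
    """

    n_sections: int
    pair_landmarks: list  # [(src (n,2), dst (n,2)), ...] length n_sections-1
    true_transforms: list  # 2x3 arrays, same length

    def section_depth_um(self, k: int) -> float:
        return 0.0 if k == 0 else SECTION_TOP_UM + (k - 1) * SECTION_STEP_UM


def make_section_stack(config: SynthConfig, n_sections: int,
                       n_landmarks: int = 8, noise_um: float = 0.0,
                       identity: bool = False,
                       rng: np.random.Generator | None = None) -> SectionStack:
    """Generate a stack with known pairwise affine perturbations.

    Each adjacent pair gets a small true affine (rotation, translation,
    isotropic scale, shear) and >= 4 landmarks seen in both frames, with
    optional isotropic Gaussian noise added to the *observed* target
    coordinates. Ground truth is stored for recovery tests.
    """
    if n_sections < 2:
        raise ConfigError("n_sections must be >= 2")
    if n_landmarks < 3:
        raise ConfigError("need at least 3 landmarks per section pair")
    if rng is None:
        rng = stream(config.seed, "stack", n_sections, n_landmarks)
    pairs, truths = [], []
    for k in range(n_sections - 1):
        if identity:
            A = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        else:
            ang = np.deg2rad(rng.normal(0, 2.0))
            s = 1.0 + rng.normal(0, 0.01)
            shear = rng.normal(0, 0.01)
            R = s * np.array([[np.cos(ang), -np.sin(ang)],
                              [np.sin(ang), np.cos(ang)]])
            R = R @ np.array([[1.0, shear], [0.0, 1.0]])
            t = rng.normal(0, 30.0, 2)
            A = np.hstack([R, t[:, None]])
        # scattered, non-collinear landmarks over a few mm
        while True:
            src = rng.uniform(0, 5000.0, (n_landmarks, 2))
            sv = np.linalg.svd(src - src.mean(0), compute_uv=False)
            if sv[1] > 1e-6:
                break
        dst = src @ A[:, :2].T + A[:, 2]
        if noise_um > 0:
            dst = dst + rng.normal(0, noise_um, dst.shape)
        pairs.append((src, dst))
        truths.append(A)
    return SectionStack(n_sections=n_sections, pair_landmarks=pairs,
                        true_transforms=truths)


# ---------------------------------------------------------------------------
# Serialization of the planted truth
# ---------------------------------------------------------------------------

def truth_json(experiments: Sequence[Experiment]) -> str:
    return json.dumps({e.animal_id: e.truth for e in experiments}, indent=2,
                      sort_keys=True)
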