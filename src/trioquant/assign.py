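"""Cell-to-area and cell-to-layer assignment, starter tabulation and QC.

Areas come from point-in-polygon tests against the (warped) flatmap
parcellation: each cell receives the name of the polygon containing it, with
boundary points resolved to the first area in the parcellation's fixed order;
cells outside every polygon stay ``unassigned``. Layers come from the depth of
each cell relative to the L5 marker band (the Ctip2-positive band), modeled as
a half-open depth interval [l5_top, l5_bottom): shallower cells are L2/3,
cells inside the band are L5, deeper cells are L6.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .errors import EmptyExperimentError
from .synthgen import Experiment, FlatmapParcellation, THALAMIC_NUCLEI

UNASSIGNED = "unassigned"


def assign_area(cells: pd.DataFrame, parcellation: FlatmapParcellation) -> pd.DataFrame:
    """Label each cell with the containing area (boundary-inclusive).

    Polygons are visited in the parcellation's fixed order, so a point on a
    shared border deterministically goes to the earlier area. Returns a copy
    with the ``area`` column replaced.
    """
    parcellation.validate()
    out = cells.copy()
    x = out["x_um"].to_numpy(dtype=float)
    y = out["y_um"].to_numpy(dtype=float)
    pts = shapely.points(x, y)
    area = np.full(len(out), UNASSIGNED, dtype=object)
    todo = np.ones(len(out), dtype=bool)
    for name, poly in parcellation.areas:
        if not todo.any():
            break
        hit = shapely.covers(poly, pts) & todo
        area[hit] = name
        todo &= ~hit
    out["area"] = area
    return out


@dataclass
class LayerBandModel:
    """Depth interval of the L5 marker band, in um below the pia."""

    l5_top_um: float
    l5_bottom_um: float

    def __post_init__(self):
        if not (0 < self.l5_top_um < self.l5_bottom_um):
            raise ValueError("require 0 < l5_top_um < l5_bottom_um")


def assign_layer(cells: pd.DataFrame, band: LayerBandModel) -> pd.DataFrame:
    """Label layers from depth with half-open band intervals.

    depth < l5_top -> L23; l5_top <= depth < l5_bottom -> L5; deeper -> L6.
    Cells with missing depth become ``unassigned`` with a warning.
    """
    out = cells.copy()
    depth = out["depth_um"].to_numpy(dtype=float)
    layer = np.where(depth < band.l5_top_um, "L23",
                     np.where(depth < band.l5_bottom_um, "L5", "L6")).astype(object)
    missing = ~np.isfinite(depth)
    if missing.any():
        warnings.warn(f"{int(missing.sum())} cells have no depth; left unassigned",
                      stacklevel=2)
        layer[missing] = UNASSIGNED
    out["layer"] = layer
    return out


def tabulate_starters(counts: dict) -> pd.DataFrame:
    """Starter-cell fractions per thalamic nucleus, as percent of the total.

    Returns a frame with ``count``, ``fraction`` and ``percent`` (the latter
    rounded to one decimal, the printing convention for these tables).
    """
    clean = {k: int(v) for k, v in counts.items()}
    if any(v < 0 for v in clean.values()):
        raise ValueError("starter counts must be nonnegative")
    total = sum(clean.values())
    if total == 0:
        raise EmptyExperimentError("no starter cells counted")
    rows = []
    for nucleus in list(THALAMIC_NUCLEI) + [k for k in clean if k not in THALAMIC_NUCLEI]:
        if nucleus not in clean:
            continue
        frac = clean[nucleus] / total
        rows.append({"nucleus": nucleus, "count": clean[nucleus],
                     "fraction": frac, "percent": round(100 * frac, 1)})
    return pd.DataFrame(rows)


def qc_experiment(experiment: Experiment, min_pulvinar_fraction: float = 0.5,
                  pulvinar_key: str = "Pulvinar/LP") -> dict:
    """Starter-bias quality control.

    Fails when the pulvinar fraction of starter cells falls below the
    configured threshold (a heavily off-target starter population means the
    traced inputs no longer reflect the intended projection). The threshold
    default is an artifact choice, not a biological constant.
    """
    table = tabulate_starters(experiment.starter_counts)
    row = table[table["nucleus"] == pulvinar_key]
    frac = float(row["fraction"].iloc[0]) if len(row) else 0.0
    passed = frac >= min_pulvinar_fraction
    reasons = [] if passed else [
        f"starter bias: pulvinar fraction {frac:.3f} < threshold {min_pulvinar_fraction:.3f}"
    ]
    return {"animal_id": experiment.animal_id, "target": experiment.target,
            "pass": bool(passed), "pulvinar_fraction": frac, "reasons": reasons}
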