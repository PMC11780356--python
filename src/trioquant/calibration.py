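"""Operating characteristics of the shuffled-target permutation test.

Two Monte-Carlo studies, shared by the test suite and the acceptance script:

* type-I error under the global null (reciprocity multipliers = 1) with
  areal weights proportional to polygon areas, i.e. a spatially homogeneous
  cell intensity, which makes the shuffled-assignment statistic exchangeable
  by symmetry;
* power to detect a planted reciprocal enrichment (L6, upper tail) and
  depletion (L5, lower tail) inside the 400 um disc.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import Polygon

from . import stats as _st
from .synthgen import (
    AREA_ORDER, SynthConfig, make_experiment, template_rings,
)


def _area_proportional_weights() -> dict:
    """Areal weight vector proportional to template polygon areas."""
    areas = {name: Polygon(ring).area for name, ring in template_rings().items()}
    total = sum(areas.values())
    w = {name: areas[name] / total for name in AREA_ORDER}
    # exact renormalization against float drift
    s = sum(w.values())
    last = AREA_ORDER[-1]
    w[last] += 1.0 - s
    return w


def _null_config(seed: int, n_cells: int) -> SynthConfig:
    w = _area_proportional_weights()
    return SynthConfig(
        seed=seed,
        n_L5_cells=0, n_L6_cells=n_cells,
        l5_reciprocal_multiplier=1.0, l6_reciprocal_multiplier=1.0,
        areal_weights_L5=dict(w), areal_weights_L6=dict(w),
        border_jitter_um=0.0,
        n_brainwide_inputs=10, n_starter_cells=10, n_sc_cells=10,
    )


def _replicate_seed(seed: int, rep: int) -> int:
    return int(np.random.SeedSequence([seed, rep]).generate_state(1)[0] % 2**31)


def _experiments(config: SynthConfig, targets, rep: int):
    return [make_experiment(config, t, f"{t}-r{rep}-{i}")
            for i, t in enumerate(targets)]


def type_i_error_rate(seed: int = 0, n_replicates: int = 200,
                      n_experiments: int = 4, n_cells: int = 800,
                      n_shuffles: int = 199, alpha: float = 0.05,
                      radius_um: float = 400.0) -> dict:
    """Rejection rate of the upper-tail shuffled-target test under the null.

    Each replicate regenerates ``n_experiments`` experiments (one target each,
    drawn round-robin over the five HVAs) with no planted effect and runs the
    within-radius permutation test at level ``alpha``.
    """
    targets = [SynthConfig().targets[i % 5] for i in range(n_experiments)]
    stat = _st.within_radius_statistic("L6", radius_um)
    rejections = 0
    for rep in range(n_replicates):
        cfg = _null_config(_replicate_seed(seed, rep), n_cells)
        exps = _experiments(cfg, targets, rep)
        res = _st.reciprocity_test(
            exps, layer="L6", tail="upper", statistic_fn=stat,
            radius_um=radius_um, n_shuffles=n_shuffles,
            seed=_replicate_seed(seed, 10_000 + rep),
        )
        rejections += int(res.p_raw <= alpha)
    return {"rejection_rate": rejections / n_replicates,
            "rejections": rejections, "n_replicates": n_replicates,
            "alpha": alpha, "n_shuffles": n_shuffles}


def planted_effect_power(seed: int = 0, n_replicates: int = 50,
                         n_experiments: int = 4, n_cells: int = 1000,
                         l6_multiplier: float = 3.0,
                         l5_multiplier: float = 0.2,
                         n_shuffles: int = 1000, alpha: float = 0.05,
                         radius_um: float = 400.0) -> dict:
    """Fraction of replicates whose BH-adjusted p-values detect the planted
    L6 enrichment (upper tail) and L5 depletion (lower tail)."""
    targets = [SynthConfig().targets[i % 5] for i in range(n_experiments)]
    hits_l6 = hits_l5 = 0
    for rep in range(n_replicates):
        cfg = SynthConfig(
            seed=_replicate_seed(seed, rep),
            n_L5_cells=n_cells, n_L6_cells=n_cells,
            l6_reciprocal_multiplier=l6_multiplier,
            l5_reciprocal_multiplier=l5_multiplier,
            reciprocity_radius_um=radius_um,
            n_brainwide_inputs=10, n_starter_cells=10, n_sc_cells=10,
        )
        exps = _experiments(cfg, targets, rep)
        r6 = _st.reciprocity_test(exps, "L6", "upper", radius_um=radius_um,
                                  n_shuffles=n_shuffles,
                                  seed=_replicate_seed(seed, 20_000 + rep))
        r5 = _st.reciprocity_test(exps, "L5", "lower", radius_um=radius_um,
                                  n_shuffles=n_shuffles,
                                  seed=_replicate_seed(seed, 30_000 + rep))
        adj = _st.bh_adjust([r6.p_raw, r5.p_raw])
        hits_l6 += int(adj[0] < alpha)
        hits_l5 += int(adj[1] < alpha)
    return {"power_l6": hits_l6 / n_replicates,
            "power_l5": hits_l5 / n_replicates,
            "n_replicates": n_replicates, "n_shuffles": n_shuffles,
            "alpha": alpha}
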