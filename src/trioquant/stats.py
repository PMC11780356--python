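"""Inferential core: shuffled-target permutation nulls, BH correction,
Kruskal-Wallis with Dunn-Sidak post hoc, Monte-Carlo Fisher exact tests,
Pearson chi-square and proportion standard errors.

The permutation framework tests reciprocity (upper tail, L6CT) and
antireciprocity (lower tail, L5CT) of cortico-thalamo-cortical connections:
each experiment's target area is re-drawn uniformly from the candidate HVA
set (original included) and the statistic recomputed against the shuffled
target's reference point. Because the statistic of a shuffle depends on each
experiment only through its assigned candidate, the null is computed from a
per-experiment-by-candidate table, which is exactly equivalent to
recomputation per shuffle and allows exhaustive enumeration on small designs.

Sampled nulls use the add-one permutation p-value (1 + #extreme)/(N + 1),
whose floor 1/(N + 1) at N = 10,000 reproduces the "p < 1.0e-4" reporting
convention; exhaustive enumerations use the plain proportion.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .synthgen import HVA_NAMES

from . import quantify as _q


# ---------------------------------------------------------------------------
# Results container
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Observed statistic with its (possibly resampled) null and p-values."""

    statistic: str
    observed: float
    tail: str  # upper | lower | two-sided
    p_raw: float
    n_shuffles: int = 0
    null_sample: np.ndarray | None = None
    p_adjusted: float | None = None
    adjustment: str | None = None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "observed": self.observed,
            "tail": self.tail,
            "p_raw": self.p_raw,
            "p_adjusted": self.p_adjusted,
            "adjustment": self.adjustment,
            "n_shuffles": self.n_shuffles,
            "seed": self.seed,
            "p_report": format_pvalue(self.p_raw, self.n_shuffles),
            **self.meta,
        }


def format_pvalue(p: float, n_shuffles: int = 0) -> str:
    """Report a resampled p at its resolution floor as '< floor'."""
    if n_shuffles > 0 and p <= 1.0 / (n_shuffles + 1) + 1e-15:
        return f"< {1.0 / (n_shuffles + 1):.1e}"
    return f"{p:.4g}"


# ---------------------------------------------------------------------------
# Shuffled-target permutation framework
# ---------------------------------------------------------------------------

def within_radius_statistic(layer: str, radius_um: float = 400.0,
                            visual_only: bool = False, visual_areas=None):
    """Statistic factory: proportion of one layer's cells within a radius of
    the reference point (closed disc).

    With ``visual_only`` the denominator is restricted to cells assigned to
    visual cortical areas (requires prior area assignment).
    """
    from .synthgen import VISUAL_AREAS
    areas = tuple(visual_areas or VISUAL_AREAS)

    def stat(experiment, target, ref_point):
        cells = experiment.cells
        sub = cells[cells["layer"] == layer]
        if visual_only:
            sub = sub[sub["area"].isin(areas)]
        sample = _q.distances_to_target(sub, ref_point)
        p, _n = _q.proportion_within_radius(sample, radius_um)
        return p

    stat.__name__ = f"within_{radius_um:g}um_{layer}"
    return stat


def reciprocal_fraction_statistic(layer: str, visual_areas=None):
    """Statistic factory: fraction of one layer's visual cells assigned to the
    (shuffled) target area itself — the area-count variant of the null."""
    from .synthgen import VISUAL_AREAS
    areas = tuple(visual_areas or VISUAL_AREAS)

    def stat(experiment, target, ref_point):
        cells = experiment.cells
        sub = cells[(cells["layer"] == layer) & (cells["area"].isin(areas))]
        if len(sub) == 0:
            return float("nan")
        return float((sub["area"] == target).mean())

    stat.__name__ = f"reciprocal_fraction_{layer}"
    return stat


def _candidate_reference(experiment, candidate: str):
    """Reference point for a shuffled candidate target.

    The true injection site exists only for the real target; any other
    candidate uses the centroid of that area's polygon in the animal's own
    map. Re-drawing the original target therefore reuses the true site,
    keeping the observed configuration inside the null support.
    """
    if candidate == experiment.target:
        return np.asarray(experiment.injection_site, dtype=float)
    names = experiment.parcellation.names
    if candidate not in names:
        raise ConfigError(
            f"shuffled target {candidate!r} absent from map of animal "
            f"{experiment.animal_id!r}"
        )
    c = experiment.parcellation.polygon(candidate).centroid
    return np.array([c.x, c.y])


def statistic_table(experiments, statistic_fn, candidates=HVA_NAMES) -> np.ndarray:
    """Per-experiment-by-candidate statistic values (rows follow experiments)."""
    table = np.empty((len(experiments), len(candidates)))
    for i, e in enumerate(experiments):
        for j, cand in enumerate(candidates):
            table[i, j] = statistic_fn(e, cand, _candidate_reference(e, cand))
    return table


def observed_statistic(experiments, statistic_fn, aggregate=np.mean) -> float:
    vals = [statistic_fn(e, e.target, np.asarray(e.injection_site, float))
            for e in experiments]
    return float(aggregate(np.asarray(vals)))


def shuffle_null(experiments, statistic_fn, n_shuffles: int = 10_000,
                 seed: int = 0, candidates=HVA_NAMES, aggregate=np.mean,
                 exhaustive: bool = False,
                 include_original: bool = True) -> np.ndarray:
    """Null sample of the aggregate statistic under uniform target shuffling.

    Per shuffle, each experiment independently receives a candidate target
    (uniform over ``candidates``; the original is included unless
    ``include_original`` is False, a sensitivity option) and the statistic is
    recomputed with the shuffled reference point. ``exhaustive`` enumerates
    every assignment (small designs only) instead of sampling.
    """
    if n_shuffles < 1 and not exhaustive:
        raise ConfigError("n_shuffles must be >= 1")
    candidates = list(candidates)
    table = statistic_table(experiments, statistic_fn, candidates)
    n_exp, n_cand = table.shape
    if not include_original:
        allowed = [
            [j for j, c in enumerate(candidates) if c != e.target]
            for e in experiments
        ]
    if exhaustive:
        if not include_original:
            spaces = allowed
        else:
            spaces = [range(n_cand)] * n_exp
        combos = np.array(list(itertools.product(*spaces)), dtype=int)
        vals = table[np.arange(n_exp)[None, :], combos]
    else:
        rng = np.random.default_rng(seed)
        if include_original:
            draws = rng.integers(0, n_cand, size=(n_shuffles, n_exp))
        else:
            draws = np.column_stack([
                np.asarray(allowed[i])[rng.integers(0, len(allowed[i]), n_shuffles)]
                for i in range(n_exp)
            ])
        vals = table[np.arange(n_exp)[None, :], draws]
    if aggregate is np.mean:
        return vals.mean(axis=1)
    return np.apply_along_axis(aggregate, 1, vals)


def permutation_pvalue(observed: float, null_sample, tail: str = "upper",
                       exhaustive: bool = False) -> float:
    """One- or two-tailed permutation p-value.

    Sampled nulls use (1 + #extreme)/(N + 1); a full enumeration (which
    already contains the observed configuration) uses the plain proportion.
    """
    null = np.asarray(null_sample, dtype=float)
    if null.size == 0:
        raise ValueError("null sample is empty")
    n = null.size
    upper = np.count_nonzero(null >= observed)
    lower = np.count_nonzero(null <= observed)
    if tail == "upper":
        extreme = upper
    elif tail == "lower":
        extreme = lower
    elif tail == "two-sided":
        extreme = 2 * min(upper, lower)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if exhaustive:
        return min(extreme / n, 1.0)
    return min((1 + extreme) / (n + 1), 1.0)


def reciprocity_test(experiments, layer: str, tail: str,
                     statistic_fn=None, radius_um: float = 400.0,
                     n_shuffles: int = 10_000, seed: int = 0,
                     candidates=HVA_NAMES, visual_only: bool = False) -> TestResult:
    """Shuffled-target test of reciprocity (upper tail) or antireciprocity
    (lower tail) for one layer's within-radius proportion."""
    if statistic_fn is None:
        statistic_fn = within_radius_statistic(layer, radius_um, visual_only)
    observed = observed_statistic(experiments, statistic_fn)
    null = shuffle_null(experiments, statistic_fn, n_shuffles, seed, candidates)
    p = permutation_pvalue(observed, null, tail)
    return TestResult(
        statistic=statistic_fn.__name__, observed=observed, tail=tail,
        p_raw=p, n_shuffles=n_shuffles, null_sample=null, seed=seed,
        meta={"reference_convention":
              "injection site for the original target, polygon centroid for shuffled targets"},
    )


# ---------------------------------------------------------------------------
# Multiple-comparison adjustments
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Rank tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups) -> tuple:
    """Kruskal-Wallis H (tie-corrected) and chi-square p with k-1 df."""
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise ValueError("all values identical: H undefined under total ties")
    H, p = sps.kruskal(*groups)
    return float(H), float(p)


def dunn_sidak(groups, labels=None, alpha: float = 0.05,
               gatekeep: bool = True) -> list:
    """Dunn's pairwise rank z-tests with Sidak adjustment.

    Applied post hoc only when the omnibus Kruskal-Wallis test is significant
    at ``alpha`` (gatekeeping); disable with ``gatekeep=False``. Returns a
    list of dicts with pair labels, z, raw and Sidak-adjusted p-values
    (p_adj = 1 - (1 - p)^m over the m comparisons).
    """
    groups = [np.asarray(list(g), dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need >= 2 groups")
    if labels is None:
        labels = [str(i) for i in range(k)]
    if gatekeep:
        _, p_omni = kruskal_wallis(groups)
        if p_omni >= alpha:
            return []
    pooled = np.concatenate(groups)
    N = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = [], [], 0
    for g in groups:
        mean_ranks.append(ranks[start:start + len(g)].mean())
        sizes.append(len(g))
        start += len(g)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (N - 1))
    base_var = N * (N + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(range(k), 2))
    m = len(pairs)
    out = []
    for i, j in pairs:
        se = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        out.append({
            "pair": (labels[i], labels[j]), "z": float(z),
            "p_raw": float(p), "p_sidak": float(sidak_adjust(p, m)), "m": m,
        })
    return out


def sidak_adjust(p: float, m: int) -> float:
    """Sidak family-wise adjustment 1 - (1 - p)^m."""
    return float(min(1.0, 1.0 - (1.0 - p) ** m))


# ---------------------------------------------------------------------------
# Contingency tables
# ---------------------------------------------------------------------------

def _table_log_prob(table: np.ndarray) -> float:
    """Log conditional probability of a table given both margins
    (multivariate hypergeometric)."""
    t = np.asarray(table)
    r = t.sum(axis=1)
    c = t.sum(axis=0)
    n = t.sum()
    return float(
        gammaln(r + 1).sum() + gammaln(c + 1).sum()
        - gammaln(n + 1) - gammaln(t + 1).sum()
    )


def _check_margins(table: np.ndarray):
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=1) == 0) or np.any(t.sum(axis=0) == 0):
        raise ValueError("degenerate margins: zero row or column total")
    return t


def fisher_mc(table, n_shuffles: int = 10_000, seed: int = 0,
              tie_tol: float = 1e-7, chunk: int = 200_000) -> tuple:
    """Monte-Carlo Fisher exact test for an r x c table.

    Samples tables with both margins fixed (Patefield's algorithm) and takes
    extremeness as conditional table probability <= the observed table's
    probability (classical definition, float tie tolerance on the log scale).
    Returns ``(p, mc_standard_error)`` with the add-one correction
    p = (1 + #extreme)/(1 + N).
    """
    t = _check_margins(table)
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    obs_lp = _table_log_prob(t)
    dist = sps.random_table(t.sum(axis=1), t.sum(axis=0))
    rng = np.random.default_rng(seed)
    extreme = 0
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        sims = dist.rvs(m, random_state=rng)
        lps = (
            gammaln(t.sum(axis=1) + 1).sum() + gammaln(t.sum(axis=0) + 1).sum()
            - gammaln(t.sum() + 1) - gammaln(sims + 1).sum(axis=(1, 2))
        )
        extreme += int(np.count_nonzero(lps <= obs_lp + tie_tol))
        done += m
    p = (1 + extreme) / (1 + n_shuffles)
    p_hat = extreme / n_shuffles
    se = float(np.sqrt(max(p_hat * (1 - p_hat), 0.0) / n_shuffles))
    return float(p), se


def fisher_exact_enumeration(table, tie_tol: float = 1e-7) -> float:
    """Exact Fisher p by full enumeration of tables with the observed margins.

    Brute-force oracle for small tables: sums the conditional probability of
    every table at most as probable as the observed one.
    """
    t = _check_margins(table)
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    obs_lp = _table_log_prob(t)
    total = 0.0
    nr, nc = t.shape

    def rec(i, remaining_cols, current):
        nonlocal total
        if i == nr - 1:
            last = remaining_cols
            if np.any(last < 0):
                return
            cand = np.vstack(current + [last])
            lp = _table_log_prob(cand)
            if lp <= obs_lp + tie_tol:
                total += np.exp(lp)
            return
        for combo in _compositions(rows[i], nc, remaining_cols):
            rec(i + 1, remaining_cols - combo, current + [combo])

    rec(0, cols.copy(), [])
    return float(min(total, 1.0))


def _compositions(total, k, caps):
    """All nonnegative integer k-vectors summing to total with per-entry caps."""
    if k == 1:
        if 0 <= total <= caps[0]:
            yield np.array([total])
        return
    for v in range(min(total, caps[0]) + 1):
        for rest in _compositions(total - v, k - 1, caps[1:]):
            yield np.concatenate([[v], rest])


def mc_shuffles_needed(half_width: float, confidence: float) -> int:
    """Shuffle count for a Monte-Carlo p-value of given precision.

    Worst case p = 0.5: N = ceil(z^2 * 0.25 / half_width^2) with z the
    two-sided normal quantile at the requested confidence.
    """
    if not (0 < half_width < 1) or not (0 < confidence < 1):
        raise ValueError("half_width and confidence must lie in (0, 1)")
    z = sps.norm.ppf(0.5 + confidence / 2.0)
    return int(np.ceil(z**2 * 0.25 / half_width**2))


def chi2_independence(table) -> tuple:
    """Pearson chi-square test of independence (no continuity correction)."""
    t = _check_margins(table)
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()
    zero = np.argwhere(expected == 0)
    if len(zero):
        i, j = zero[0]
        raise ValueError(f"expected count is zero in cell ({i}, {j})")
    chi2, p, dof, _ = sps.chi2_contingency(t, correction=False)
    return float(chi2), int(dof), float(p)


def se_proportion(p_hat: float, n: int) -> float:
    """Standard error of a proportion, sqrt(p(1-p)/n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= p_hat <= 1.0):
        raise ValueError("p_hat must lie in [0, 1]")
    return float(np.sqrt(p_hat * (1.0 - p_hat) / n))
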