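"""Published per-animal summary counts from the modeled tracing study.

The only machine-readable quantities the study prints are the per-animal
total input counts and the starter-cell counts over the five most populated
thalamic nuclei (24 animals, 4-5 per target HVA). They are reproduced here as
a small reference dataset for the starter tabulation and pooled-summary
operations.

The study's brain-wide per-region counts live in a separate supplementary
workbook that is not bundled; :func:`replicate_brainwide_summary` implements
the replication computation for users who have that file.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .assign import tabulate_starters
from .quantify import input_fractions, median_mad, pooled_mean_sem

# target, animal_id, total_inputs, pulvinar/LP, LD, POm, dLGN, CL counts,
# printed pulvinar percentage. The printed percentages are computed on the
# *full* starter total, which for some animals includes nuclei beyond the
# five tabulated ones, so they are kept as data rather than recomputed.
_STARTER_ROWS = [
    ("PM", "PM1", 8104, 141, 4, 2, 2, 4, 92.2),
    ("PM", "PM2", 4658, 403, 45, 1, 20, 1, 85.2),
    ("PM", "PM3", 2960, 835, 122, 0, 10, 7, 85.2),
    ("PM", "PM4", 1720, 666, 224, 5, 2, 8, 73.4),
    ("PM", "PM5", 4612, 377, 74, 19, 5, 26, 73.8),
    ("AM", "AM1", 1548, 313, 203, 0, 11, 0, 59.3),
    ("AM", "AM2", 5179, 337, 32, 2, 6, 8, 87.1),
    ("AM", "AM3", 1707, 292, 5, 17, 2, 0, 92.4),
    ("AM", "AM4", 2584, 158, 44, 58, 4, 14, 55.4),
    ("AM", "AM5", 1955, 200, 15, 10, 4, 0, 86.6),
    ("RL", "RL1", 5777, 527, 150, 12, 14, 6, 74.3),
    ("RL", "RL2", 9474, 1058, 148, 19, 2, 4, 86.0),
    ("RL", "RL3", 989, 300, 40, 0, 5, 2, 86.2),
    ("RL", "RL4", 2401, 339, 70, 39, 3, 5, 73.9),
    ("AL", "AL1", 9015, 1315, 82, 6, 27, 8, 91.1),
    ("AL", "AL2", 2991, 819, 24, 1, 1, 41, 92.3),
    ("AL", "AL3", 3124, 678, 36, 39, 52, 1, 83.3),
    ("AL", "AL4", 2139, 155, 5, 56, 3, 0, 68.3),
    ("AL", "AL5", 3692, 368, 0, 16, 8, 0, 92.7),
    ("LM", "LM1", 2627, 117, 0, 0, 3, 1, 95.9),
    ("LM", "LM2", 1743, 85, 0, 0, 0, 0, 100.0),
    ("LM", "LM3", 2562, 88, 10, 2, 9, 4, 75.2),
    ("LM", "LM4", 2732, 544, 56, 12, 28, 30, 81.1),
    ("LM", "LM5", 3280, 638, 100, 0, 78, 1, 77.9),
]

_NUCLEI = ("Pulvinar/LP", "LD", "POm", "dLGN", "CL")


def starter_cell_table() -> pd.DataFrame:
    """Per-animal total inputs, starter counts by thalamic nucleus and the
    printed pulvinar starter percentage."""
    return pd.DataFrame(
        _STARTER_ROWS,
        columns=["target", "animal_id", "total_inputs", *_NUCLEI,
                 "pulvinar_pct_printed"],
    )


def starter_counts(animal_id: str) -> dict:
    row = starter_cell_table().set_index("animal_id").loc[animal_id]
    return {n: int(row[n]) for n in _NUCLEI}


def starter_percentages(animal_id: str) -> dict:
    """Printed-style starter percentages (one decimal) for one animal."""
    table = tabulate_starters(starter_counts(animal_id))
    return dict(zip(table["nucleus"], table["percent"]))


def pooled_pulvinar_summary() -> tuple:
    """Mean and SEM (percent) of the pulvinar starter fraction over all animals.

    Pools the per-animal printed percentages (which are computed on full
    starter totals including unlisted nuclei), matching the summary
    convention of the source table.
    """
    return pooled_mean_sem(starter_cell_table()["pulvinar_pct_printed"])


# ---------------------------------------------------------------------------
# Brain-wide replication (requires the supplementary counts workbook)
# ---------------------------------------------------------------------------

def load_brainwide_workbook(path) -> pd.DataFrame:
    """Load per-animal brain-wide region counts from XLSX or CSV.

    Expected long format: columns ``animal_id``, ``target``, ``region``,
    ``count``. The supplementary workbook of the modeled study is not
    redistributed with this package; place it (or a CSV export) at the given
    path.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"brain-wide counts file not found: {path}. This replication "
            "requires the study's supplementary per-region count workbook "
            "(or a CSV export with columns animal_id, target, region, count)."
        )
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    missing = {"animal_id", "target", "region", "count"} - set(df.columns)
    if missing:
        raise ValueError(f"brain-wide counts file missing columns {sorted(missing)}")
    return df


def replicate_brainwide_summary(df: pd.DataFrame,
                                cortex_regions=("CTX",),
                                sc_region: str = "SC") -> dict:
    """Pooled cortex mean +/- SEM and per-target SC median +/- MAD.

    Converts each animal's region counts to fractions of its total inputs,
    then pools: the cortex fraction across all animals (mean, SEM) and the
    SC fraction per target (median, MAD), all in percent.
    """
    cortex_pcts, sc_by_target = [], {}
    for (animal, target), sub in df.groupby(["animal_id", "target"]):
        counts = dict(zip(sub["region"], sub["count"]))
        fracs = input_fractions(counts)
        cortex_pcts.append(100.0 * sum(fracs.get(r, 0.0) for r in cortex_regions))
        sc_by_target.setdefault(target, []).append(100.0 * fracs.get(sc_region, 0.0))
    mean, sem = pooled_mean_sem(cortex_pcts)
    sc_medians = {t: median_mad(v) for t, v in sc_by_target.items()}
    return {"cortex_mean_pct": mean, "cortex_sem_pct": sem,
            "sc_median_mad_pct": sc_medians}
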