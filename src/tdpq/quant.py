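"""Label-free quantification: abundance matrix assembly and normalization.

A proteoform's abundance in one replicate run is the sum of its feature
intensities over the SEC fractions of that run (a missing fraction
contributes nothing; a proteoform seen in no fraction of a run has a
missing cell, not zero). Proteoforms are matched across the runs by
re-clustering the union of per-run representatives with the same
protein + mass-window rule used for identification. Normalization follows
the Perseus-style LFQ recipe: per-row division by the reference run, per
-column division by the column median (so every column median is exactly 1),
then log2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import ClusterConfig, _greedy_groups

logger = logging.getLogger(__name__)


@dataclass
class QuantMatrix:
    """Proteoform x run abundance matrix.

    ``data``: DataFrame indexed by proteoform key with MultiIndex columns
    (condition, replicate); ``meta``: per-row metadata (protein accession,
    representative mass/proteoform); ``n_fractions``: fractions summed per run.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_fractions: int = 6

    def __post_init__(self):
        vals = self.data.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValueError("abundances must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))


def aggregate_fractions(members: pd.DataFrame, *, key_col: str = "cluster_id") -> pd.DataFrame:
    """Per-replicate proteoform abundance: sum over fractions.

    ``members`` must carry ``key_col``, ``condition``, ``replicate``,
    ``fraction`` and ``intensity`` columns. Within one fraction several PrSMs
    of the same proteoform share one feature; the maximum intensity is taken
    per (proteoform, run, fraction) before summing over fractions. Rows whose
    intensities are all missing yield a missing abundance.

    Returns a long DataFrame (key, condition, replicate, abundance).
    """
    if (members["intensity"].dropna() < 0).any():
        raise ValueError("negative intensity")
    per_frac = (members.groupby([key_col, "condition", "replicate", "fraction"],
                                sort=True, observed=True)["intensity"].max())
    agg = per_frac.groupby(level=[0, 1, 2], observed=True).sum(min_count=1)
    return agg.rename("abundance").reset_index()


def match_across_runs(per_run: pd.DataFrame, mass_tol: float = 2.2) -> QuantMatrix:
    """Match proteoforms across runs and build the abundance matrix.

    ``per_run`` has one row per (run, proteoform representative):
    ``protein_accession``, ``precursor_mass``, ``e_value``, ``spectrum_id``,
    ``condition``, ``replicate``, ``abundance`` (and optionally
    ``proteoform``). The union of representatives is re-clustered per protein
    with greedy best-E-value seeding at ``mass_tol``; each union cluster is a
    matrix row keyed ``accession@mass``. If several members of one run fall
    in a cluster the largest abundance is used.
    """
    cfg = ClusterConfig(mass_tol=mass_tol)
    cells: list[dict] = []
    meta_rows: list[dict] = []
    for acc, sub in per_run.groupby("protein_accession", sort=True):
        e = sub["e_value"].to_numpy(dtype=float)
        m = sub["precursor_mass"].to_numpy(dtype=float)
        ids = sub["spectrum_id"].to_numpy(dtype=object)
        groups = _greedy_groups(e, m, ids, cfg.mass_tol)
        groups.sort(key=lambda g: (e[g[0]], ids[g[0]]))
        for g in groups:
            rep = sub.iloc[g[0]]
            key = f"{acc}@{rep['precursor_mass']:.2f}"
            meta = {"key": key, "protein_accession": acc,
                    "precursor_mass": float(rep["precursor_mass"])}
            if "proteoform" in sub.columns:
                meta["proteoform"] = rep["proteoform"]
            meta_rows.append(meta)
            for i in g:
                r = sub.iloc[i]
                cells.append({"key": key, "condition": r["condition"],
                              "replicate": int(r["replicate"]),
                              "abundance": float(r["abundance"])
                              if pd.notna(r["abundance"]) else np.nan})
    if not cells:
        return QuantMatrix(pd.DataFrame(), pd.DataFrame())
    long = pd.DataFrame(cells)
    wide = (long.pivot_table(index="key", columns=["condition", "replicate"],
                             values="abundance", aggfunc="max"))
    meta = pd.DataFrame(meta_rows).drop_duplicates("key").set_index("key")
    meta = meta.loc[wide.index]
    return QuantMatrix(wide, meta)


def complete_case_filter(m: QuantMatrix) -> QuantMatrix:
    """Retain only proteoforms with a measured abundance in every run."""
    if m.data.empty:
        return QuantMatrix(m.data.copy(), m.meta.copy(), m.n_fractions)
    keep = m.data.notna().all(axis=1)
    return QuantMatrix(m.data.loc[keep].copy(),
                       m.meta.loc[keep].copy() if not m.meta.empty else m.meta,
                       m.n_fractions)


def normalize(m: QuantMatrix, reference_column) -> pd.DataFrame:
    """Perseus-style normalization to a log2-ratio matrix.

    1. each cell is divided by the same-row cell of ``reference_column``
       (rows with a zero or missing reference are dropped with a warning);
    2. each column is divided by its median, so every column median of the
       pre-log ratio matrix is exactly 1;
    3. log2 transform.

    ``reference_column`` is a (condition, replicate) pair, e.g.
    ``("SW480", 1)`` for the first run of the first condition.
    """
    if reference_column not in m.data.columns:
        raise KeyError(f"reference column {reference_column!r} not in matrix")
    ref = m.data[reference_column]
    bad = ref.isna() | (ref == 0)
    if bad.any():
        logger.warning("dropping %d row(s) with zero/missing reference abundance",
                       int(bad.sum()))
    data = m.data.loc[~bad]
    ratio = data.div(data[reference_column], axis=0)
    ratio = ratio.div(ratio.median(axis=0, skipna=True), axis=1)
    return np.log2(ratio)


def reproducibility_metrics(log2_abund: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson correlations between runs and per-row CV per condition.

    Parameters
    ----------
    log2_abund : DataFrame
        log2 abundances, columns = (condition, replicate). Needs >= 2 columns.

    Returns
    -------
    (pearson, cv) : pearson is a run x run matrix of correlation
    coefficients on pairwise-complete log2 abundances (NaN for a constant
    column); cv has one column per condition with the within-condition
    coefficient of variation (sample SD over mean) of each row computed on
    the linear scale.
    """
    if log2_abund.shape[1] < 2:
        raise ValueError("need at least two runs")
    cols = list(log2_abund.columns)
    rmat = np.full((len(cols), len(cols)), np.nan)
    for i, a in enumerate(cols):
        for j, b in enumerate(cols):
            x, y = log2_abund[a], log2_abund[b]
            ok = x.notna() & y.notna()
            if ok.sum() < 2 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
                continue
            rmat[i, j] = stats.pearsonr(x[ok], y[ok])[0]
    r = pd.DataFrame(rmat, index=pd.Index(cols), columns=pd.Index(cols))
    linear = np.power(2.0, log2_abund)
    conds = dict.fromkeys(c for c, _ in cols)
    cv = pd.DataFrame(index=log2_abund.index, columns=list(conds), dtype=float)
    for c in conds:
        block = linear[c]
        cv[c] = block.std(axis=1, ddof=1) / block.mean(axis=1)
    return r, cv
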