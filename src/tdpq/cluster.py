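"""Merging PrSMs into proteoform clusters.

PrSMs from all runs that match the same protein and whose neutral precursor
masses lie within a 2.2-Da window are treated as the same proteoform. The
window absorbs +/-1- and +/-2-Da isotope (deconvolution) errors. Clustering
is greedy: within each protein the unassigned PrSM with the lowest E-value
seeds a cluster and captures every unassigned PrSM within ``mass_tol`` of
the seed; the seed is the cluster representative. Ties in E-value are broken
by lexicographic spectrum id, which makes the procedure deterministic and
independent of input row order. Targets and decoys are clustered by the
identical procedure (decoy accessions never mix with targets because the
accession is part of the grouping key).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ClusterConfig:
    """Clustering options. ``mass_tol`` is the maximum |precursor mass -
    seed mass| in Da for cluster membership (boundary inclusive)."""

    mass_tol: float = 2.2

    def __post_init__(self):
        if self.mass_tol <= 0:
            raise ValueError(f"mass_tol must be > 0, got {self.mass_tol}")


def _greedy_groups(e_values: np.ndarray, masses: np.ndarray, ids: np.ndarray,
                   tol: float) -> list[np.ndarray]:
    """Greedy best-E-value seeding within one protein; returns index groups
    (positions into the input arrays), each group's first element the seed."""
    order = np.lexsort((ids, e_values))  # e_value asc, then spectrum_id asc
    unassigned = np.ones(len(e_values), dtype=bool)
    groups: list[np.ndarray] = []
    for seed in order:
        if not unassigned[seed]:
            continue
        members = np.flatnonzero(unassigned & (np.abs(masses - masses[seed]) <= tol))
        # seed first, then remaining members in (e_value, id) order
        rest = members[members != seed]
        rest = rest[np.lexsort((ids[rest], e_values[rest]))]
        groups.append(np.concatenate(([seed], rest)).astype(int))
        unassigned[members] = False
    return groups


def cluster_prsms(prsms: pd.DataFrame, cfg: ClusterConfig | None = None) -> pd.DataFrame:
    """Group PrSMs into proteoform clusters.

    Parameters
    ----------
    prsms : DataFrame
        PrSM table (see :mod:`tdpq.prsm_io`); normally already filtered at
        the spectrum-level FDR.
    cfg : ClusterConfig

    Returns
    -------
    DataFrame with one row per cluster: ``cluster_id``,
    ``protein_accession``, ``is_decoy``, representative ``spectrum_id`` /
    ``proteoform`` / ``e_value`` / ``precursor_mass``, ``prsm_count``,
    ``member_ids`` (tuple of spectrum ids) and ``runs`` (sorted tuple of
    (condition, replicate) pairs observed), plus any representative-row
    columns present in the input (start_pos, end_pos, ...).
    """
    cfg = cfg or ClusterConfig()
    if len(prsms) == 0:
        return pd.DataFrame(columns=["cluster_id", "protein_accession", "is_decoy",
                                     "spectrum_id", "proteoform", "e_value",
                                     "precursor_mass", "prsm_count", "member_ids", "runs"])
    rows = []
    has_run = "condition" in prsms.columns and "replicate" in prsms.columns
    for acc, sub in prsms.groupby("protein_accession", sort=True):
        e = sub["e_value"].to_numpy(dtype=float)
        m = sub["precursor_mass"].to_numpy(dtype=float)
        ids = sub["spectrum_id"].to_numpy(dtype=object)
        groups = _greedy_groups(e, m, ids, cfg.mass_tol)
        # deterministic cluster order: by seed (e_value, spectrum_id)
        groups.sort(key=lambda g: (e[g[0]], ids[g[0]]))
        for k, g in enumerate(groups):
            rep = sub.iloc[g[0]]
            row = rep.to_dict()
            row["cluster_id"] = f"{acc}|{k}"
            row["prsm_count"] = len(g)
            row["member_ids"] = tuple(ids[g])
            if has_run:
                runs = {(sub.iloc[i]["condition"], int(sub.iloc[i]["replicate"])) for i in g}
                row["runs"] = tuple(sorted(runs))
            else:
                row["runs"] = ()
            row["member_index"] = tuple(sub.index[g])
            rows.append(row)
    out = pd.DataFrame(rows)
    front = ["cluster_id", "protein_accession", "is_decoy", "spectrum_id", "proteoform",
             "e_value", "precursor_mass", "prsm_count", "member_ids", "runs"]
    out = out[[c for c in front if c in out.columns]
              + [c for c in out.columns if c not in front]]
    return out.reset_index(drop=True)


def representative_set(clusters: pd.DataFrame) -> pd.DataFrame:
    """One scored item per cluster (the representative PrSM), ready for
    proteoform-level FDR filtering with :func:`tdpq.fdr.filter_at_fdr`."""
    return clusters.copy()


def assign_members(prsms: pd.DataFrame, clusters: pd.DataFrame) -> pd.Series:
    """Map each PrSM (by input index) to its cluster_id."""
    mapping: dict = {}
    for row in clusters.itertuples(index=False):
        for idx in row.member_index:
            mapping[idx] = row.cluster_id
    return pd.Series(mapping, name="cluster_id").reindex(prsms.index)
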