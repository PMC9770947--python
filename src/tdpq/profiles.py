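"""Overlap matrices, PTM census, proteoform-family summaries, mean +/- SD.

These are the descriptive summaries of an identification run: asymmetric
run-vs-run proteoform overlap ratios, a census of proteoforms by nominal
modification mass bin (N-terminal acetylation +42, phosphorylation +80,
double phosphorylation +160, methylation +14, oxidation +16 and common
combination bins), per-gene proteoform-family profiles, and the mean +/- SD
convention used for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prsm_io import ParsedProteoform

# nominal bin centers (monoisotopic, Da) -> category name
PTM_BINS: dict[str, float] = {
    "nterm_acetyl_42": 42.01057,            # acetyl/trimethyl isobaric at +42
    "phospho_80": 79.96633,
    "double_phospho_160": 159.93266,
    "methyl_14": 14.01565,
    "oxidation_16": 15.99491,
    "acetyl_phospho_122": 121.97690,        # acetyl/trimethyl + phospho
    "phospho_oxidation_96": 95.96124,
    "acetyl_oxidation_58": 58.00548,        # acetyl/trimethyl + oxidation
}


def overlap_matrix(sets: dict[str, set]) -> pd.DataFrame:
    """Asymmetric overlap ratios between named proteoform-key sets.

    The cell at column A (x axis) and row B (y axis) is |A & B| / |B| — the
    fraction of B's proteoforms also seen in A. The diagonal is 1 for
    non-empty sets; cells with an empty denominator set are missing.
    """
    labels = list(sets)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for a in labels:
        for b in labels:
            if len(sets[b]) == 0:
                continue
            mat.loc[b, a] = len(sets[a] & sets[b]) / len(sets[b])
    return mat


@dataclass
class PtmCensus:
    """Counts per nominal modification bin plus the unmodified and
    unassigned (out-of-bin or unknown-mass) remainders."""

    counts: dict[str, int]
    unmodified: int
    unassigned: int
    tol: float

    @property
    def total(self) -> int:
        return sum(self.counts.values()) + self.unmodified + self.unassigned

    def to_series(self) -> pd.Series:
        s = dict(self.counts)
        s["unmodified"] = self.unmodified
        s["unassigned"] = self.unassigned
        return pd.Series(s, name="n_proteoforms")


def ptm_census(proteoforms: list[ParsedProteoform], tol: float = 1.5) -> PtmCensus:
    """Assign each proteoform to at most one nominal modification bin.

    The total modification mass (named modifications plus unexpected shifts;
    fixed carbamidomethylation is excluded as it is not a variable
    modification) is matched to the nearest bin center within ``tol`` Da.
    The +42 bin additionally requires the modification span to include core
    position 1 (N-terminal); +42 masses elsewhere are left unassigned, as
    are proteoforms with a named modification of unknown mass or a total
    mass matching no bin. Proteoforms with no modifications count as
    unmodified. Categories are disjoint by construction.
    """
    if tol <= 0:
        raise ValueError(f"tol must be > 0, got {tol}")
    centers = {k: v for k, v in PTM_BINS.items()}
    counts = {k: 0 for k in centers}
    unmodified = unassigned = 0
    for p in proteoforms:
        mods = [m for m in p.named_mods if m.name != "carbamidomethyl"]
        shifts = list(p.unexpected_shifts)
        if not mods and not shifts:
            unmodified += 1
            continue
        if any(m.mass is None for m in mods):
            unassigned += 1
            continue
        total = sum(m.mass for m in mods) + sum(s.mass for s in shifts)
        name, center = min(centers.items(), key=lambda kv: abs(total - kv[1]))
        if abs(total - center) > tol:
            unassigned += 1
            continue
        if name == "nterm_acetyl_42":
            spans_nterm = any(g.start == 1 for g in mods + shifts)
            if not spans_nterm:
                unassigned += 1
                continue
        counts[name] += 1
    return PtmCensus(counts, unmodified, unassigned, tol)


@dataclass
class FamilySummary:
    """Profile of one gene's proteoform family."""

    start_histogram: pd.Series
    prsm_shares: pd.Series
    intact_share: float
    truncated_share: float
    n_proteoforms: int = 0
    intact_flags: pd.Series = field(default_factory=pd.Series)


def family_summary(proteoforms: pd.DataFrame, protein_length: int,
                   intact_start_max: int = 2) -> FamilySummary:
    """Summarize the proteoform family of one gene.

    ``proteoforms`` needs ``start_pos``, ``end_pos`` and ``prsm_count``
    columns (one row per proteoform of the gene). The PrSM count of a
    proteoform is used as a rough relative-abundance proxy: shares are
    PrSM counts normalized to the family total. A proteoform is "intact"
    when it covers the full mature sequence — start <= ``intact_start_max``
    (allowing N-terminal Met removal) and end equal to the protein length.
    """
    if len(proteoforms) == 0:
        return FamilySummary(pd.Series(dtype=int), pd.Series(dtype=float), 0.0, 0.0, 0)
    counts = proteoforms["prsm_count"].astype(float)
    shares = counts / counts.sum()
    hist = proteoforms["start_pos"].value_counts().sort_index()
    intact = ((proteoforms["start_pos"] <= intact_start_max)
              & (proteoforms["end_pos"] == protein_length))
    intact_share = float(shares[intact].sum())
    return FamilySummary(hist, shares, intact_share, 1.0 - intact_share,
                         len(proteoforms), intact)


def mean_sd(values) -> tuple[float, float]:
    """Mean and sample SD (n-1 denominator); SD is NaN for a single value."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("mean_sd of empty input")
    if arr.size == 1:
        return float(arr[0]), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1))
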