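"""Variant protein entries, theoretical b/y fragments, and the SAAV filter.

Proteogenomic searches add, for every nonsynonymous single-nucleotide
variant, one extra database entry carrying a single amino acid substitution
(accession suffixed e.g. ``_P72R``). A proteoform identification that
covers a SAAV site is only trusted when the site is actually resolved by
fragment ions: if the proteoform carries no unexpected mass shift it is
confident outright; if it does, every SAAV site must be separated from the
shift's localization interval by at least three matched fragment ions,
otherwise the shift could equally well sit on the variant residue.

Fragments are HCD b/y ions with neutral monoisotopic masses; cysteines
carry the fixed +57.02146-Da carbamidomethylation. A modification
contributes to a fragment only when the fragment fully contains its span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .masses import RESIDUE_MASS, WATER, CARBAMIDOMETHYL
from .prsm_io import NamedMod


class VariantValidationError(ValueError):
    """One or more variants disagree with the reference sequence."""

    def __init__(self, offenders: list[str]):
        self.offenders = offenders
        super().__init__("reference mismatch for variant(s): " + "; ".join(offenders))


@dataclass(frozen=True)
class VariantRecord:
    """A single amino acid substitution on a reference protein."""

    protein_accession: str
    position: int  # 1-based
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        if self.ref_aa == self.alt_aa:
            raise ValueError("ref_aa and alt_aa must differ")

    @property
    def suffix(self) -> str:
        return f"{self.ref_aa}{self.position}{self.alt_aa}"


@dataclass
class SAAVCall:
    """A variant proteoform with its SAAV site(s), the optional unexpected
    shift interval, and (after filtering) per-site flanking-ion counts."""

    proteoform_key: str
    sites: list[int]  # 1-based positions on the core sequence
    shift_interval: tuple[int, int] | None = None
    shift_mass: float | None = None
    flanking_counts: dict[int, int] = field(default_factory=dict)
    confident: bool | None = None


def apply_variants(reference: dict[str, str], variants) -> dict[str, str]:
    """Build a variant-aware database: reference entries plus one entry per
    single-substitution variant, accession suffixed with the variant.

    ``variants`` is a DataFrame (protein_accession, position, ref, alt) or
    an iterable of :class:`VariantRecord`. All variants are validated
    against the reference first; any mismatch aborts with a
    :class:`VariantValidationError` listing every offending variant.
    """
    if isinstance(variants, pd.DataFrame):
        records = [VariantRecord(r.protein_accession, int(r.position), r.ref, r.alt)
                   for r in variants.itertuples(index=False)]
    else:
        records = list(variants)
    offenders = []
    for v in records:
        seq = reference.get(v.protein_accession)
        if seq is None:
            offenders.append(f"{v.protein_accession} {v.suffix} (unknown accession)")
        elif not 1 <= v.position <= len(seq):
            offenders.append(f"{v.protein_accession} {v.suffix} (position out of range)")
        elif seq[v.position - 1] != v.ref_aa:
            offenders.append(f"{v.protein_accession} {v.suffix} "
                             f"(reference has {seq[v.position - 1]})")
    if offenders:
        raise VariantValidationError(offenders)
    out = dict(reference)
    for v in records:
        seq = reference[v.protein_accession]
        out[f"{v.protein_accession}_{v.suffix}"] = (
            seq[:v.position - 1] + v.alt_aa + seq[v.position:])
    return out


def theoretical_fragments(core_sequence: str, named_mods: list[NamedMod] | None = None,
                          *, fixed_carbamidomethyl: bool = True) -> pd.DataFrame:
    """Neutral monoisotopic b/y fragment masses for a proteoform.

    b_k is the sum of residue masses 1..k plus every modification whose span
    lies within 1..k; y_k the sum of residues n-k+1..n plus water plus
    modifications within that range. Cysteines always carry the fixed
    +57.02146 Da. Fragments that cut through a modification span simply do
    not include that modification's mass.

    Returns a DataFrame with ``ion_type`` ('b' or 'y'), ``frag_index`` (k),
    ``cleavage`` (residues cleavage..cleavage+1 are separated; b_k cleaves
    at k, y_k at n-k) and ``mass``; 2(n-1) rows for an n-residue sequence.
    """
    n = len(core_sequence)
    if n == 0:
        raise ValueError("empty sequence")
    try:
        res = np.array([RESIDUE_MASS[aa] for aa in core_sequence])
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc
    if fixed_carbamidomethyl:
        res = res + np.array([CARBAMIDOMETHYL if aa == "C" else 0.0
                              for aa in core_sequence])
    mods = [m for m in (named_mods or []) if m.mass is not None]
    prefix = np.cumsum(res)
    rows = []
    for k in range(1, n):
        b = prefix[k - 1] + sum(m.mass for m in mods if m.end <= k)
        rows.append(("b", k, k, b))
    total = prefix[-1]
    for k in range(1, n):
        start = n - k + 1
        y = total - prefix[n - k - 1] + WATER + sum(
            m.mass for m in mods if m.start >= start)
        rows.append(("y", k, n - k, y))
    return pd.DataFrame(rows, columns=["ion_type", "frag_index", "cleavage", "mass"])


def match_fragments(theoretical: pd.DataFrame, observed_masses, tol_ppm: float = 15.0) -> pd.Series:
    """Boolean per theoretical fragment: some observed mass within tol_ppm."""
    if tol_ppm <= 0:
        raise ValueError(f"tol_ppm must be > 0, got {tol_ppm}")
    obs = np.sort(np.asarray(list(observed_masses), dtype=float))
    theo = theoretical["mass"].to_numpy(dtype=float)
    if obs.size == 0:
        return pd.Series(False, index=theoretical.index)
    pos = np.searchsorted(obs, theo)
    nearest = np.full(theo.shape, np.inf)
    left_ok = pos > 0
    nearest[left_ok] = np.abs(theo[left_ok] - obs[pos[left_ok] - 1])
    right_ok = pos < obs.size
    nearest[right_ok] = np.minimum(nearest[right_ok],
                                   np.abs(obs[pos[right_ok]] - theo[right_ok]))
    return pd.Series(nearest / theo * 1e6 <= tol_ppm, index=theoretical.index)


def flanking_cleavages(site: int, shift_interval: tuple[int, int], n_residues: int,
                       mode: str = "toward_shift") -> set[int]:
    """Cleavage positions whose fragment ions separate a SAAV site from an
    unexpected-shift interval.

    With the default ``toward_shift`` interpretation these are the cleavages
    strictly between the variant residue and the nearer edge of the shift
    interval. ``either_side`` additionally counts cleavages between the site
    and the sequence terminus on the side away from the shift.
    """
    a, b = shift_interval
    between: set[int]
    if a > site:  # shift to the right of the site
        between = set(range(site, a))
        away = set(range(1, site))
    elif b < site:  # shift to the left
        between = set(range(b, site))
        away = set(range(site, n_residues))
    else:  # site inside the shift interval: nothing can separate them
        between = set()
        away = set()
    if mode == "toward_shift":
        return between
    if mode == "either_side":
        return between | away
    raise ValueError(f"unknown mode {mode!r}")


def saav_confidence_filter(call: SAAVCall, theoretical: pd.DataFrame, observed_masses,
                           tol_ppm: float = 15.0, n_residues: int | None = None,
                           mode: str = "toward_shift") -> SAAVCall:
    """Decide whether a SAAV proteoform identification is confident.

    A proteoform with no unexpected mass shift is confident outright.
    Otherwise every SAAV site needs at least three matched fragment ions
    (b and y species counted separately) whose cleavage lies between the
    site and the nearer edge of the shift's localization interval.

    Returns the call with ``flanking_counts`` and ``confident`` filled in.
    """
    matched = match_fragments(theoretical, observed_masses, tol_ppm)
    counts: dict[int, int] = {}
    if call.shift_interval is None:
        call.flanking_counts = {s: 0 for s in call.sites}
        call.confident = True
        return call
    n = n_residues if n_residues is not None else int(theoretical["cleavage"].max()) + 1
    hit = theoretical.loc[matched.to_numpy()]
    for s in call.sites:
        ok = flanking_cleavages(s, call.shift_interval, n, mode)
        counts[s] = int(hit["cleavage"].isin(ok).sum())
    call.flanking_counts = counts
    call.confident = all(c >= 3 for c in counts.values())
    return call
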