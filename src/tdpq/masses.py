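"""Monoisotopic mass constants and modification name resolution.

Residue masses come from :mod:`pyteomics.mass`; this module adds the small
named-modification table used in proteoform string annotations and the
fixed cysteine carbamidomethylation applied throughout the workflow.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

#: Monoisotopic residue masses (Da), 20 standard amino acids.
RESIDUE_MASS: dict[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

#: Monoisotopic mass of water (Da); peptide neutral mass = sum(residues) + WATER.
WATER: float = 18.010565

#: Monoisotopic mass of a proton (Da).
PROTON: float = 1.00727646688

#: Averagine isotope spacing (Da) — the magnitude of a ±1-Da deconvolution error.
ISOTOPE_SPACING: float = 1.00235

#: Fixed cysteine carbamidomethylation (Da), applied to every C residue.
CARBAMIDOMETHYL: float = 57.02146

#: Named-modification monoisotopic masses (Da). Unknown names resolve to None.
MOD_MASS: dict[str, float] = {
    "acetyl": 42.01057,
    "phospho": 79.96633,
    "methyl": 14.01565,
    "trimethyl": 42.04695,
    "oxidation": 15.99491,
    "carbamidomethyl": 57.02146,
}

# accepted spellings -> canonical key in MOD_MASS
_ALIASES = {
    "acetyl": "acetyl",
    "acetylation": "acetyl",
    "phospho": "phospho",
    "phosphorylation": "phospho",
    "phosphorylated": "phospho",
    "methyl": "methyl",
    "methylation": "methyl",
    "trimethyl": "trimethyl",
    "trimethylation": "trimethyl",
    "oxidation": "oxidation",
    "oxidized": "oxidation",
    "carbamidomethyl": "carbamidomethyl",
    "carbamidomethylation": "carbamidomethyl",
}


def canonical_mod_name(name: str) -> str:
    """Normalize a modification name; unknown names are returned lower-cased."""
    key = name.strip().lower()
    return _ALIASES.get(key, key)


def mod_mass(name: str) -> float | None:
    """Monoisotopic mass of a named modification, or None if unknown."""
    return MOD_MASS.get(canonical_mod_name(name))


def peptide_mass(sequence: str, fixed_carbamidomethyl: bool = True) -> float:
    """Neutral monoisotopic mass of a plain peptide sequence.

    Parameters
    ----------
    sequence : str
        Residue string over the 20 standard amino acids.
    fixed_carbamidomethyl : bool
        Add +57.02146 Da per cysteine (the workflow's fixed modification).
    """
    try:
        m = sum(RESIDUE_MASS[aa] for aa in sequence)
    except KeyError as exc:  # pragma: no cover - message formatting
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from exc
    m += WATER
    if fixed_carbamidomethyl:
        m += CARBAMIDOMETHYL * sequence.count("C")
    return m
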