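"""Reading/writing PrSM tables, FASTA databases, and the proteoform string grammar.

The tab-separated PrSM dialect is modeled on TopPIC output: one row per
proteoform-spectrum match (PrSM) with run context (condition, replicate,
fraction), the matched protein, a proteoform string, the neutral
monoisotopic precursor mass, an E-value and a feature intensity.

Proteoform strings follow the flat notation used in top-down search
engines::

    A.GGK(ST)[phospho]AR(NNN) (mass shift: 96 Da, phospho and oxidation)K.R

i.e. an optional single-residue N-terminal context before the first dot, a
core sequence in which ``(residues)[modname]`` marks a named modification,
``(residues) (mass shift: N Da, <text>)`` marks an unexpected mass shift
localized to the parenthesized stretch, and an optional single-residue
C-terminal context after the last dot. ``(residues) (modname)`` is accepted
as an alternative named-modification spelling. Whitespace between groups is
normalized away.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .masses import mod_mass, canonical_mod_name

logger = logging.getLogger(__name__)

DECOY_PREFIX = "DECOY_"

#: Columns of the PrSM TSV dialect, in canonical order.
PRSM_COLUMNS = [
    "spectrum_id",
    "condition",
    "replicate",
    "fraction",
    "protein_accession",
    "is_decoy",
    "proteoform",
    "start_pos",
    "end_pos",
    "precursor_mass",
    "e_value",
    "intensity",
    "charge",
    "migration_time",
]

MANDATORY_COLUMNS = [
    "spectrum_id",
    "protein_accession",
    "proteoform",
    "precursor_mass",
    "e_value",
]


class FormatError(ValueError):
    """A table does not conform to the PrSM TSV dialect."""


class ProteoformParseError(ValueError):
    """A proteoform string does not follow the grammar."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


@dataclass(frozen=True)
class RunKey:
    """One CZE-MS/MS run: condition label, replicate index, fraction index."""

    condition: str
    replicate: int
    fraction: int

    def __post_init__(self):
        if self.replicate < 1 or self.fraction < 1:
            raise ValueError("replicate and fraction indices are 1-based (>= 1)")


@dataclass
class PrSMRecord:
    """One proteoform-spectrum match with its run context."""

    spectrum_id: str
    run: RunKey
    protein_accession: str
    is_decoy: bool
    proteoform: str
    precursor_mass: float
    e_value: float
    intensity: float | None = None
    start_pos: int | None = None
    end_pos: int | None = None
    charge: int | None = None
    migration_time: float | None = None

    def __post_init__(self):
        if self.e_value <= 0:
            raise ValueError("e_value must be > 0")
        if self.start_pos is not None and self.end_pos is not None and self.start_pos > self.end_pos:
            raise ValueError("start_pos must be <= end_pos")
        if self.is_decoy != self.protein_accession.startswith(DECOY_PREFIX):
            raise ValueError("is_decoy flag inconsistent with accession prefix")


@dataclass(frozen=True)
class NamedMod:
    """A named modification on a span of the core sequence (1-based inclusive)."""

    start: int
    end: int
    name: str
    mass: float | None = None


@dataclass(frozen=True)
class MassShift:
    """An unexpected mass shift localized to a span of the core sequence."""

    start: int
    end: int
    mass: float
    annotation: str = ""


@dataclass
class ParsedProteoform:
    """Structured form of a proteoform string."""

    core_sequence: str
    prefix_residue: str | None = None
    suffix_residue: str | None = None
    named_mods: list[NamedMod] = field(default_factory=list)
    unexpected_shifts: list[MassShift] = field(default_factory=list)

    def __post_init__(self):
        n = len(self.core_sequence)
        for g in list(self.named_mods) + list(self.unexpected_shifts):
            if not (1 <= g.start <= g.end <= n):
                raise ValueError(f"group span ({g.start},{g.end}) outside core of length {n}")
        if len(self.unexpected_shifts) > 1:
            raise ValueError("at most one unexpected mass shift per proteoform")

    @property
    def total_mod_mass(self) -> float | None:
        """Sum of all modification masses; None if a named mod has unknown mass."""
        total = 0.0
        for m in self.named_mods:
            if m.mass is None:
                return None
            total += m.mass
        for s in self.unexpected_shifts:
            total += s.mass
        return total


_GROUP_RE = re.compile(
    r"\(\s*([A-Z]+)\s*\)\s*"
    r"(?:"
    r"\[\s*([^\]]+?)\s*\]"  # [modname]
    r"|\(\s*mass\s+shift\s*:\s*(-?\d+(?:\.\d+)?)\s*Da\s*(?:,\s*([^)]*?)\s*)?\)"  # (mass shift: N Da, text)
    r"|\(\s*([^()]*?)\s*\)"  # (modname)
    r")"
)
_PLAIN_RE = re.compile(r"[A-Z]+")


def parse_proteoform_string(s: str) -> ParsedProteoform:
    """Parse a proteoform string into its core sequence and modification groups.

    Raises
    ------
    ProteoformParseError
        On unbalanced brackets, a non-numeric mass shift, or stray characters.
    """
    text = s.strip()
    prefix = suffix = None
    # N-terminal context: "X." or "." before any parenthesis
    first_special = len(text)
    for ch in "([":
        idx = text.find(ch)
        if idx != -1:
            first_special = min(first_special, idx)
    dot = text.find(".")
    if dot != -1 and dot < first_special and dot <= 1:
        prefix = text[:dot] or None
        if prefix is not None and not re.fullmatch(r"[A-Z]", prefix):
            raise ProteoformParseError(f"invalid N-terminal context {prefix!r}", 0)
        text = text[dot + 1:]
    # C-terminal context: ".X" or trailing "." after the last closing bracket
    last_special = max(text.rfind(")"), text.rfind("]"))
    dot = text.rfind(".")
    if dot != -1 and dot > last_special and len(text) - dot <= 2:
        suffix = text[dot + 1:] or None
        if suffix is not None and not re.fullmatch(r"[A-Z]", suffix):
            raise ProteoformParseError(f"invalid C-terminal context {suffix!r}", dot)
        text = text[:dot]

    core: list[str] = []
    named: list[NamedMod] = []
    shifts: list[MassShift] = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        m = _PLAIN_RE.match(text, pos)
        if m:
            core.append(m.group(0))
            pos = m.end()
            continue
        m = _GROUP_RE.match(text, pos)
        if m:
            residues = m.group(1)
            start = sum(len(c) for c in core) + 1
            end = start + len(residues) - 1
            core.append(residues)
            if m.group(2) is not None:  # [modname]
                name = canonical_mod_name(m.group(2))
                named.append(NamedMod(start, end, name, mod_mass(name)))
            elif m.group(3) is not None:  # mass shift
                shifts.append(MassShift(start, end, float(m.group(3)), (m.group(4) or "").strip()))
            else:  # (modname)
                raw = m.group(5)
                if raw.lower().lstrip().startswith("mass shift"):
                    raise ProteoformParseError(
                        f"malformed mass shift group {raw!r} (non-numeric shift?)", pos)
                name = canonical_mod_name(raw)
                named.append(NamedMod(start, end, name, mod_mass(name)))
            pos = m.end()
            continue
        raise ProteoformParseError(f"unexpected character {text[pos]!r}", pos)

    core_seq = "".join(core)
    if not core_seq:
        raise ProteoformParseError("empty core sequence")
    try:
        return ParsedProteoform(core_seq, prefix, suffix, named, shifts)
    except ValueError as exc:
        raise ProteoformParseError(str(exc)) from exc


def _fmt_mass(x: float) -> str:
    return f"{x:.10g}"


def format_proteoform(p: ParsedProteoform) -> str:
    """Render a :class:`ParsedProteoform` back to its string form.

    ``parse_proteoform_string(format_proteoform(p))`` reproduces ``p`` for any
    valid parse (named-mod masses are re-resolved from the bundled table).
    """
    groups = sorted(
        [(m.start, m.end, "named", m) for m in p.named_mods]
        + [(s.start, s.end, "shift", s) for s in p.unexpected_shifts]
    )
    out: list[str] = []
    cursor = 1
    for start, end, kind, g in groups:
        if start < cursor:
            raise ValueError("overlapping modification groups cannot be formatted")
        out.append(p.core_sequence[cursor - 1:start - 1])
        span = p.core_sequence[start - 1:end]
        if kind == "named":
            out.append(f"({span})[{g.name}]")
        else:
            annot = f", {g.annotation}" if g.annotation else ""
            out.append(f"({span}) (mass shift: {_fmt_mass(g.mass)} Da{annot})")
        cursor = end + 1
    out.append(p.core_sequence[cursor - 1:])
    body = "".join(out)
    pre = f"{p.prefix_residue}." if p.prefix_residue else ""
    suf = f".{p.suffix_residue}" if p.suffix_residue else ""
    return f"{pre}{body}{suf}"


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------

def read_prsm_table(path: str | Path, *, drop_invalid: bool = True) -> pd.DataFrame:
    """Read a PrSM TSV into a typed DataFrame.

    Rows with unparseable or non-positive masses/E-values are dropped (the
    count is logged) unless ``drop_invalid`` is False, in which case they
    raise. Missing intensities are encoded as "NA" on disk and NaN in memory.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"spectrum_id": str, "protein_accession": str,
                                            "proteoform": str, "condition": str},
                     na_values=["NA"], keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(missing)}")
    for col in ("precursor_mass", "e_value", "intensity", "migration_time"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("replicate", "fraction", "start_pos", "end_pos", "charge"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    bad = df["precursor_mass"].isna() | df["e_value"].isna() | (df["e_value"] <= 0)
    if bad.any():
        if not drop_invalid:
            raise FormatError(f"{int(bad.sum())} row(s) with invalid mass/E-value")
        logger.warning("%s: dropped %d row(s) with invalid mass/E-value", path.name, int(bad.sum()))
        df = df.loc[~bad]
    if "is_decoy" not in df.columns:
        df["is_decoy"] = df["protein_accession"].str.startswith(DECOY_PREFIX)
    else:
        df["is_decoy"] = df["is_decoy"].astype(bool)
        mismatch = df["is_decoy"] != df["protein_accession"].str.startswith(DECOY_PREFIX)
        if mismatch.any():
            raise FormatError(f"{int(mismatch.sum())} row(s) with is_decoy flag "
                              "inconsistent with the DECOY_ accession prefix")
    return df.reset_index(drop=True)


def write_prsm_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a PrSM DataFrame in the TSV dialect (UTF-8, tabs, NA for missing)."""
    cols = [c for c in PRSM_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", columns=cols)


def records_from_frame(df: pd.DataFrame) -> list[PrSMRecord]:
    """Convert a PrSM DataFrame into typed records (validates each row)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(PrSMRecord(
            spectrum_id=row.spectrum_id,
            run=RunKey(str(row.condition), int(row.replicate), int(row.fraction)),
            protein_accession=row.protein_accession,
            is_decoy=bool(row.is_decoy),
            proteoform=row.proteoform,
            precursor_mass=float(row.precursor_mass),
            e_value=float(row.e_value),
            intensity=None if pd.isna(row.intensity) else float(row.intensity),
            start_pos=None if pd.isna(row.start_pos) else int(row.start_pos),
            end_pos=None if pd.isna(row.end_pos) else int(row.end_pos),
        ))
    return out


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by accession (first whitespace-split token)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=acc, description="") for acc, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_variant_table(path: str | Path) -> pd.DataFrame:
    """Read a variant TSV (protein_accession, position, ref, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_accession": str, "ref": str, "alt": str})
    needed = {"protein_accession", "position", "ref", "alt"}
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"missing mandatory column(s): {', '.join(sorted(missing))}")
    df["position"] = df["position"].astype(int)
    return df


def write_variant_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)
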