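"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the statistical structure a post-identification
top-down workflow assumes, at desk scale:

* a reference proteome plus a same-size shuffled decoy database;
* per-run PrSM tables over a 2-condition x 3-replicate x 6-fraction design,
  where true hits draw low E-values (log-uniform) and false target and decoy
  hits draw from one shared high E-value distribution — the exchangeability
  that makes target-decoy FDR estimation valid;
* precursor masses jittered with ppm-scale noise and, occasionally, a
  +/-1.00235-Da isotope (deconvolution) error, which the 2.2-Da clustering
  window must absorb;
* per-fraction intensities following a unimodal elution profile scaled by a
  log-normal run effect, with intensity-dependent (logistic) missingness —
  so the "measured in all six runs" filter is meaningfully exercised;
* spiked log2 fold changes on a chosen number of proteoforms;
* SAAV proteoforms with known variant sites, optional unexpected-shift
  intervals, and partially covered fragment-ion ladders.

Every draw comes from one seeded generator: the same
:class:`SimConfig` yields byte-identical tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import saav as saav_mod
from .masses import ISOTOPE_SPACING, peptide_mass
from .prsm_io import (DECOY_PREFIX, MassShift, NamedMod, ParsedProteoform,
                      format_proteoform)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


class ConfigurationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design and noise parameters of the synthetic dataset.

    The defaults mirror the design the pipeline targets: two conditions
    (cell lines) in technical triplicate over six SEC fractions, replicate
    intensity scatter of about 0.35 log2 units (roughly a 25% relative SD),
    a small ppm-scale mass error with occasional 1-Da isotope errors, and
    true/false E-value ranges separated enough that a 5% spectrum-level
    filter keeps most true hits.
    """

    n_proteins: int = 120
    proteoforms_per_protein: float = 2.5  # mean of 1 + Poisson(mean-1)
    protein_length_range: tuple[int, int] = (60, 300)
    n_conditions: int = 2
    n_replicates: int = 3
    n_fractions: int = 6
    condition_labels: tuple[str, ...] | None = ("SW480", "SW620")
    true_hit_fraction: float = 0.85
    background_prsms_per_run: int = 30  # used when true_hit_fraction == 0
    true_evalue_log10_range: tuple[float, float] = (-12.0, -5.0)
    null_evalue_log10_range: tuple[float, float] = (-3.0, 1.0)
    mass_error_ppm_sd: float = 2.0
    isotope_error_prob: float = 0.02
    intensity_log2_mean_range: tuple[float, float] = (18.0, 26.0)
    intensity_log2_sd: float = 0.35
    run_effect_log2_sd: float = 0.15
    fraction_profile_width: float = 1.0
    detect_logistic_params: tuple[float, float] = (15.0, 1.0)  # midpoint, slope
    n_differential: int = 0
    fold_changes: tuple[float, ...] = (2.0, -2.0)
    n_saav_proteoforms: int = 0
    saav_shift_prob: float = 0.5
    fragment_coverage_prob: float = 0.7
    fragment_jitter_ppm: float = 12.0
    min_mass_separation: float = 5.0
    seed: int = 0

    def __post_init__(self):
        for name in ("true_hit_fraction", "isotope_error_prob", "saav_shift_prob",
                     "fragment_coverage_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_proteins", "n_conditions", "n_replicates", "n_fractions"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.proteoforms_per_protein < 1:
            raise ConfigurationError("proteoforms_per_protein must be >= 1")
        if self.condition_labels is None or len(self.condition_labels) != self.n_conditions:
            self.condition_labels = tuple(f"C{i+1}" for i in range(self.n_conditions))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TruthSet:
    """Ground truth behind one synthetic dataset."""

    proteins: dict[str, str]
    decoys: dict[str, str]
    registry: pd.DataFrame  # one row per true proteoform
    variants: pd.DataFrame  # protein_accession, position, ref, alt
    config: SimConfig
    mods: dict[str, tuple] = field(default_factory=dict)  # proteoform_id -> (named, shifts)

    @property
    def database(self) -> dict[str, str]:
        """Target + variant + decoy search database."""
        db = saav_mod.apply_variants(self.proteins, self.variants)
        db.update(self.decoys)
        return db


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(AMINO_ACIDS, size=length))


def generate_reference_proteome(cfg: SimConfig) -> tuple[dict[str, str], dict[str, str]]:
    """Target protein sequences plus a companion shuffled decoy set.

    Returns ``(targets, decoys)``; decoy accessions carry the ``DECOY_``
    prefix and each decoy is a residue-shuffle of its target (same length
    and composition).
    """
    if cfg.n_proteins < 1:
        raise ConfigurationError("n_proteins must be positive")
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.protein_length_range
    targets: dict[str, str] = {}
    decoys: dict[str, str] = {}
    for i in range(cfg.n_proteins):
        acc = f"PROT{i+1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = _random_sequence(rng, length)
        targets[acc] = seq
        shuffled = np.array(list(seq))
        rng.shuffle(shuffled)
        decoys[DECOY_PREFIX + acc] = "".join(shuffled)
    return targets, decoys


_MOD_MENU = (
    ("none", 0.35),
    ("nterm_acetyl", 0.30),
    ("phospho_shift", 0.15),
    ("acetyl_phospho_shift", 0.10),
    ("oxidation", 0.10),
)


def _draw_mods(rng: np.random.Generator, core_len: int):
    """Named mods and unexpected shifts for one proteoform (core coords)."""
    names = [m for m, _ in _MOD_MENU]
    probs = np.array([p for _, p in _MOD_MENU])
    probs = probs / probs.sum()
    choice = rng.choice(names, p=probs)
    named: list[NamedMod] = []
    shifts: list[MassShift] = []
    if choice in ("nterm_acetyl", "acetyl_phospho_shift"):
        from .masses import mod_mass
        named.append(NamedMod(1, 1, "acetyl", mod_mass("acetyl")))
    if choice in ("phospho_shift", "acetyl_phospho_shift") and core_len >= 8:
        start = int(rng.integers(2, max(3, core_len - 5)))
        end = min(core_len - 1, start + int(rng.integers(3, 10)))
        shifts.append(MassShift(start, end, 79.96633, "phospho"))
    if choice == "oxidation" and core_len >= 3:
        pos = int(rng.integers(2, core_len))
        from .masses import mod_mass
        named.append(NamedMod(pos, pos, "oxidation", mod_mass("oxidation")))
    return named, shifts


def generate_truth(cfg: SimConfig) -> TruthSet:
    """Proteoform registry with per-condition abundances, differential flags
    and SAAV annotations, all drawn from ``cfg.seed``."""
    targets, decoys = generate_reference_proteome(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    mu = (cfg.intensity_log2_mean_range[0] + cfg.intensity_log2_mean_range[1]) / 2
    sd = (cfg.intensity_log2_mean_range[1] - cfg.intensity_log2_mean_range[0]) / 4

    rows: list[dict] = []
    mods_by_id: dict[str, tuple] = {}
    pf_counter = 0
    for acc, seq in targets.items():
        length = len(seq)
        k = 1 + int(rng.poisson(cfg.proteoforms_per_protein - 1))
        masses_here: list[float] = []
        for j in range(k):
            for _attempt in range(8):
                if j == 0:
                    start = 2 if seq[0] == "M" and length > 1 else 1
                    end = length
                else:
                    start = int(rng.integers(1, max(2, length - 30)))
                    end = length if rng.random() < 0.6 else int(
                        rng.integers(min(start + 20, length), length + 1))
                core = seq[start - 1:end]
                if len(core) < 15:
                    continue
                named, shifts = _draw_mods(rng, len(core))
                mass = peptide_mass(core) + sum(m.mass for m in named) + sum(
                    s.mass for s in shifts)
                if all(abs(mass - m0) >= cfg.min_mass_separation for m0 in masses_here):
                    break
            else:
                continue
            masses_here.append(mass)
            pf_counter += 1
            pf_id = f"PF{pf_counter:05d}"
            abund = float(rng.normal(mu, sd))
            mods_by_id[pf_id] = (tuple(named), tuple(shifts))
            shift = shifts[0] if shifts else None
            rows.append({
                "proteoform_id": pf_id,
                "protein_accession": acc,
                "start": start, "end": end,
                "shift_mass": shift.mass if shift else np.nan,
                "shift_start": shift.start if shift else np.nan,
                "shift_end": shift.end if shift else np.nan,
                "mass": mass,
                "fraction_center": float(rng.uniform(1, cfg.n_fractions)),
                "saav_pos": np.nan, "saav_ref": "", "saav_alt": "",
                "differential": False, "log2_fc": 0.0,
                **{f"abund_{c}": abund for c in cfg.condition_labels},
            })
    registry = pd.DataFrame(rows)

    # differential spikes: condition 2 shifted by the spiked log2 fold change
    if cfg.n_differential > 0:
        if cfg.n_differential > len(registry):
            raise ConfigurationError("n_differential exceeds number of proteoforms")
        idx = rng.choice(len(registry), size=cfg.n_differential, replace=False)
        fcs = np.array(cfg.fold_changes)[np.arange(cfg.n_differential) % len(cfg.fold_changes)]
        second = cfg.condition_labels[1]
        registry.loc[registry.index[idx], "differential"] = True
        registry.loc[registry.index[idx], "log2_fc"] = fcs
        registry.loc[registry.index[idx], f"abund_{second}"] += fcs

    # SAAV proteoforms: substitute one residue, register the variant,
    # re-point the proteoform at the variant database entry
    variant_rows: list[dict] = []
    if cfg.n_saav_proteoforms > 0:
        eligible = registry.index[(registry["end"] - registry["start"]) >= 30].to_numpy()
        if len(eligible) < cfg.n_saav_proteoforms:
            raise ConfigurationError("not enough long proteoforms for SAAV assignment")
        chosen = rng.choice(eligible, size=cfg.n_saav_proteoforms, replace=False)
        for ridx in chosen:
            row = registry.loc[ridx]
            acc = row["protein_accession"]
            seq = targets[acc]
            start, end = int(row["start"]), int(row["end"])
            pos = int(rng.integers(start + 8, end - 7))  # room for flanking ions
            ref = seq[pos - 1]
            alt = str(rng.choice(AMINO_ACIDS[AMINO_ACIDS != ref]))
            variant_rows.append({"protein_accession": acc, "position": pos,
                                 "ref": ref, "alt": alt})
            named, shifts = mods_by_id[row["proteoform_id"]]
            core_len = end - start + 1
            core_pos = pos - start + 1
            if rng.random() < cfg.saav_shift_prob:
                # place a shift interval away from the SAAV site
                if core_pos < core_len / 2:
                    a = min(core_len - 2, core_pos + 6)
                    b = min(core_len - 1, a + 4)
                else:
                    b = max(2, core_pos - 6)
                    a = max(1, b - 4)
                shifts = (MassShift(int(a), int(b), 79.96633, "phospho"),)
            else:
                shifts = ()
            mods_by_id[row["proteoform_id"]] = (named, shifts)
            var_core = (seq[start - 1:pos - 1] + alt + seq[pos:end])
            mass = peptide_mass(var_core) + sum(m.mass for m in named) + sum(
                s.mass for s in shifts)
            registry.loc[ridx, ["saav_pos", "saav_ref", "saav_alt"]] = [pos, ref, alt]
            registry.loc[ridx, "protein_accession"] = f"{acc}_{ref}{pos}{alt}"
            registry.loc[ridx, "mass"] = mass
            registry.loc[ridx, "shift_mass"] = shifts[0].mass if shifts else np.nan
            registry.loc[ridx, "shift_start"] = shifts[0].start if shifts else np.nan
            registry.loc[ridx, "shift_end"] = shifts[0].end if shifts else np.nan
    variants = pd.DataFrame(variant_rows,
                            columns=["protein_accession", "position", "ref", "alt"])
    return TruthSet(targets, decoys, registry, variants, cfg, mods_by_id)


def proteoform_core(truth: TruthSet, pf_row: pd.Series) -> str:
    """Core sequence of a registry proteoform (variant residue applied)."""
    acc = pf_row["protein_accession"]
    base_acc = acc.split("_")[0] if not acc.startswith(DECOY_PREFIX) else acc
    seq = truth.proteins[base_acc]
    start, end = int(pf_row["start"]), int(pf_row["end"])
    core = seq[start - 1:end]
    if pf_row["saav_ref"]:
        cp = int(pf_row["saav_pos"]) - start + 1
        core = core[:cp - 1] + pf_row["saav_alt"] + core[cp:]
    return core


def proteoform_string(truth: TruthSet, pf_row: pd.Series) -> str:
    named, shifts = truth.mods[pf_row["proteoform_id"]]
    core = proteoform_core(truth, pf_row)
    base_acc = pf_row["protein_accession"].split("_")[0]
    seq = truth.proteins[base_acc]
    start, end = int(pf_row["start"]), int(pf_row["end"])
    prefix = seq[start - 2] if start > 1 else None
    suffix = seq[end] if end < len(seq) else None
    parsed = ParsedProteoform(core, prefix, suffix, list(named), list(shifts))
    return format_proteoform(parsed)


def generate_prsm_tables(cfg: SimConfig, truth: TruthSet) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-run PrSM records plus ground-truth labels.

    Returns ``(prsms, labels)``: ``prsms`` in the PrSM TSV dialect (all runs
    in one frame, ordered deterministically) and ``labels`` mapping each
    spectrum_id to ``is_true`` and, for true hits, the ``proteoform_id``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    reg = truth.registry
    n_pf = len(reg)
    conds = list(cfg.condition_labels)
    reps = list(range(1, cfg.n_replicates + 1))
    fracs = np.arange(1, cfg.n_fractions + 1)
    mid, slope = cfg.detect_logistic_params

    pf_strings = {row["proteoform_id"]: proteoform_string(truth, row)
                  for _, row in reg.iterrows()}

    # fraction weight profiles (unimodal, normalized per proteoform)
    centers = reg["fraction_center"].to_numpy()
    w = np.exp(-0.5 * ((fracs[None, :] - centers[:, None])
                       / cfg.fraction_profile_width) ** 2)
    w = w / w.sum(axis=1, keepdims=True)
    log2w = np.log2(w)

    run_effect = {(c, r): float(rng.normal(0.0, cfg.run_effect_log2_sd))
                  for c in conds for r in reps}

    records: list[dict] = []
    labels: list[dict] = []
    counter = 0
    emit_conds = conds if cfg.true_hit_fraction > 0 else []
    for c in emit_conds:
        abund = reg[f"abund_{c}"].to_numpy()
        for r in reps:
            eff = run_effect[(c, r)]
            noise = rng.normal(0.0, cfg.intensity_log2_sd, size=(n_pf, cfg.n_fractions))
            log2i = abund[:, None] + eff + log2w + noise
            pdet = 1.0 / (1.0 + np.exp(-(log2i - mid) / slope))
            detected = rng.random(size=log2i.shape) < pdet
            ppm = rng.normal(0.0, cfg.mass_error_ppm_sd * 1e-6, size=log2i.shape)
            iso = rng.random(size=log2i.shape) < cfg.isotope_error_prob
            iso_sign = np.where(rng.random(size=log2i.shape) < 0.5, 1.0, -1.0)
            log10e = rng.uniform(*cfg.true_evalue_log10_range, size=log2i.shape)
            masses = reg["mass"].to_numpy()
            for p in range(n_pf):
                row = reg.iloc[p]
                for fi, f in enumerate(fracs):
                    if not detected[p, fi]:
                        continue
                    counter += 1
                    sid = f"S{counter:07d}"
                    mass = masses[p] * (1.0 + ppm[p, fi])
                    if iso[p, fi]:
                        mass += iso_sign[p, fi] * ISOTOPE_SPACING
                    records.append({
                        "spectrum_id": sid, "condition": c, "replicate": r,
                        "fraction": int(f),
                        "protein_accession": row["protein_accession"],
                        "is_decoy": False,
                        "proteoform": pf_strings[row["proteoform_id"]],
                        "start_pos": int(row["start"]), "end_pos": int(row["end"]),
                        "precursor_mass": mass,
                        "e_value": 10.0 ** log10e[p, fi],
                        "intensity": float(2.0 ** log2i[p, fi]),
                        "charge": int(rng.integers(5, 30)),
                        "migration_time": float(rng.uniform(10, 90)),
                    })
                    labels.append({"spectrum_id": sid, "is_true": True,
                                   "proteoform_id": row["proteoform_id"]})

    n_true = len(records)
    if cfg.true_hit_fraction == 0:
        n_bg = cfg.background_prsms_per_run * len(conds) * len(reps) * cfg.n_fractions
    elif cfg.true_hit_fraction >= 1:
        n_bg = 0
    else:
        n_bg = int(round(n_true * (1 - cfg.true_hit_fraction) / cfg.true_hit_fraction))

    target_accs = sorted(truth.proteins)
    decoy_accs = sorted(truth.decoys)
    for _ in range(n_bg):
        counter += 1
        sid = f"S{counter:07d}"
        is_decoy = bool(rng.random() < 0.5)
        if is_decoy:
            acc = decoy_accs[int(rng.integers(len(decoy_accs)))]
            seq = truth.decoys[acc]
        else:
            acc = target_accs[int(rng.integers(len(target_accs)))]
            seq = truth.proteins[acc]
        length = len(seq)
        start = int(rng.integers(1, max(2, length - 25)))
        end = min(length, start + int(rng.integers(20, 60)))
        core = seq[start - 1:end]
        records.append({
            "spectrum_id": sid,
            "condition": conds[int(rng.integers(len(conds)))],
            "replicate": int(rng.integers(1, cfg.n_replicates + 1)),
            "fraction": int(rng.integers(1, cfg.n_fractions + 1)),
            "protein_accession": acc, "is_decoy": is_decoy,
            "proteoform": format_proteoform(ParsedProteoform(core)),
            "start_pos": start, "end_pos": end,
            "precursor_mass": float(rng.uniform(4000.0, 28000.0)),
            "e_value": 10.0 ** float(rng.uniform(*cfg.null_evalue_log10_range)),
            "intensity": float(2.0 ** rng.normal(14.0, 1.0)),
            "charge": int(rng.integers(5, 30)),
            "migration_time": float(rng.uniform(10, 90)),
        })
        labels.append({"spectrum_id": sid, "is_true": False, "proteoform_id": ""})

    prsms = pd.DataFrame(records)
    labels_df = pd.DataFrame(labels)
    return prsms, labels_df


def generate_fragment_data(truth: TruthSet, cfg: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed fragment-mass lists for every SAAV proteoform.

    Each theoretical b/y fragment of the variant proteoform is emitted with
    probability ``fragment_coverage_prob`` and jittered uniformly within
    +/-``fragment_jitter_ppm``. Fragments whose cleavage falls inside the
    unexpected-shift interval are never emitted (their mass would depend on
    the unknown shift position). Ground-truth per-site flanking-ion counts —
    the number of flanking theoretical fragments a 15-ppm matcher finds in
    the emitted list, recounted here with a plain O(n^2) loop — and the
    resulting confidence verdict are returned alongside.

    Returns ``(fragments, verdicts)``.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    frag_rows: list[dict] = []
    verdict_rows: list[dict] = []
    saav_reg = truth.registry[truth.registry["saav_ref"] != ""]
    for _, row in saav_reg.iterrows():
        pf_id = row["proteoform_id"]
        core = proteoform_core(truth, row)
        named, shifts = truth.mods[pf_id]
        theo = saav_mod.theoretical_fragments(core, list(named))
        site = int(row["saav_pos"]) - int(row["start"]) + 1
        shift_iv = None
        if shifts:
            shift_iv = (int(shifts[0].start), int(shifts[0].end))
            crossing = ((theo["cleavage"] >= shift_iv[0])
                        & (theo["cleavage"] <= shift_iv[1] - 1))
            theo = theo.loc[~crossing]
        keep = rng.random(len(theo)) < cfg.fragment_coverage_prob
        emitted = theo.loc[keep.astype(bool)].copy()
        jitter = rng.uniform(-cfg.fragment_jitter_ppm, cfg.fragment_jitter_ppm,
                             size=len(emitted)) * 1e-6
        emitted["observed_mass"] = emitted["mass"].to_numpy() * (1.0 + jitter)
        for t in emitted.itertuples(index=False):
            frag_rows.append({"proteoform_id": pf_id, "ion_type": t.ion_type,
                              "frag_index": int(t.frag_index), "cleavage": int(t.cleavage),
                              "observed_mass": float(t.observed_mass)})
        if shift_iv is None:
            count, confident = 0, True
        else:
            ok = saav_mod.flanking_cleavages(site, shift_iv, len(core))
            obs_masses = emitted["observed_mass"].to_numpy()
            count = 0
            for t in theo.itertuples(index=False):
                if t.cleavage not in ok:
                    continue
                if any(abs(o - t.mass) / t.mass * 1e6 <= 15.0 for o in obs_masses):
                    count += 1
            confident = count >= 3
        verdict_rows.append({"proteoform_id": pf_id, "site_core": site,
                             "shift_start": shift_iv[0] if shift_iv else np.nan,
                             "shift_end": shift_iv[1] if shift_iv else np.nan,
                             "flanking_count": count, "confident": confident})
    fragments = pd.DataFrame(frag_rows, columns=["proteoform_id", "ion_type", "frag_index",
                                                 "cleavage", "observed_mass"])
    verdicts = pd.DataFrame(verdict_rows, columns=["proteoform_id", "site_core",
                                                   "shift_start", "shift_end",
                                                   "flanking_count", "confident"])
    return fragments, verdicts


def simulate(cfg: SimConfig):
    """Convenience wrapper: truth, PrSM tables, labels, fragment data."""
    truth = generate_truth(cfg)
    prsms, labels = generate_prsm_tables(cfg, truth)
    fragments, verdicts = generate_fragment_data(truth, cfg)
    return truth, prsms, labels, fragments, verdicts
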