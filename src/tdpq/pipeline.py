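"""End-to-end orchestration: simulate -> identify -> quantify -> test -> profile -> saav.

Every stage writes its tables into the run directory; ``summary.json``
records the seed, a hash of the full configuration and the record count at
each filter stage, so two runs with the same configuration produce
identical summaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as cluster_mod
from . import diffexpr, fdr, profiles, quant, saav
from . import prsm_io, simulate as sim_mod

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs."""

    outdir: str = "tdpq_run"
    sim: sim_mod.SimConfig | None = None
    prsm_path: str | None = None  # alternative to sim: an existing PrSM TSV
    fdr: fdr.FdrConfig = field(default_factory=fdr.FdrConfig)
    cluster: cluster_mod.ClusterConfig = field(default_factory=cluster_mod.ClusterConfig)
    diff: diffexpr.DiffConfig = field(default_factory=diffexpr.DiffConfig)
    match_mass_tol: float = 2.2
    reference_run: tuple[str, int] | None = None  # default: first replicate, first condition
    saav_fdr: float = 0.05
    write_plots: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # the hash covers the analysis, not its location
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _counts_entry(summary: dict, stage: str, **counts) -> None:
    summary["stages"][stage] = {k: int(v) for k, v in counts.items()}


def identify(prsms: pd.DataFrame, fdr_cfg: fdr.FdrConfig,
             cl_cfg: cluster_mod.ClusterConfig,
             proteoform_fdr: float | None = None):
    """Spectrum-level FDR filter, clustering, proteoform-level FDR filter.

    Targets and decoys are clustered by the identical procedure so the
    proteoform-level decoy counts remain valid. Returns ``(accepted
    proteoform representatives, accepted-members PrSM table, diagnostics)``.
    """
    q_spec = fdr.q_values(prsms)
    pass_spec = prsms.loc[q_spec <= fdr_cfg.spectrum_fdr].copy()
    clusters = cluster_mod.cluster_prsms(pass_spec, cl_cfg)
    reps = cluster_mod.representative_set(clusters)
    level = proteoform_fdr if proteoform_fdr is not None else fdr_cfg.proteoform_fdr
    accepted = fdr.filter_at_fdr(reps, level)
    member_idx = [i for row in accepted.itertuples(index=False) for i in row.member_index]
    members = pass_spec.loc[member_idx].copy()
    members["cluster_id"] = cluster_mod.assign_members(pass_spec, clusters).loc[member_idx]
    diag = {
        "n_prsms": len(prsms),
        "n_prsms_pass_spectrum_fdr": len(pass_spec),
        "n_target_prsms_pass": int((~pass_spec["is_decoy"]).sum()),
        "n_clusters": len(clusters),
        "n_target_clusters": int((~clusters["is_decoy"]).sum()),
        "n_proteoforms_accepted": len(accepted),
    }
    return accepted, members, diag


def quantify(members: pd.DataFrame, accepted: pd.DataFrame,
             match_mass_tol: float = 2.2,
             reference_run: tuple[str, int] | None = None):
    """Fraction-summed abundances, cross-run matching, complete-case filter,
    Perseus-style normalization. Returns (QuantMatrix, complete-case
    QuantMatrix, log2 normalized DataFrame)."""
    per_rep = quant.aggregate_fractions(members)
    rep_info = accepted.set_index("cluster_id")
    per_rep = per_rep.join(rep_info[["protein_accession", "precursor_mass",
                                     "e_value", "spectrum_id", "proteoform"]],
                           on="cluster_id")
    qm = quant.match_across_runs(per_rep, mass_tol=match_mass_tol)
    cc = quant.complete_case_filter(qm)
    if len(cc.data) == 0:
        return qm, cc, pd.DataFrame()
    ref = reference_run or cc.data.columns[0]
    log2 = quant.normalize(cc, tuple(ref))
    return qm, cc, log2


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the machine-readable summary dict."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"config_hash": cfg.config_hash(), "stages": {}}
    log_lines: list[str] = []

    def log(stage: str, msg: str):
        line = f"[{stage}] {msg}"
        log_lines.append(line)
        logger.info(line)

    # --- simulate / load -------------------------------------------------
    truth = fragments = verdicts = None
    try:
        if cfg.sim is not None:
            summary["seed"] = cfg.sim.seed
            truth, prsms, labels, fragments, verdicts = sim_mod.simulate(cfg.sim)
            prsm_io.write_prsm_table(prsms, out / "prsms.tsv")
            labels.to_csv(out / "truth_labels.tsv", sep="\t", index=False)
            truth.registry.to_csv(out / "truth_registry.tsv", sep="\t", index=False)
            prsm_io.write_fasta({**truth.proteins, **truth.decoys}, out / "database.fasta")
            prsm_io.write_variant_table(truth.variants, out / "variants.tsv")
            fragments.to_csv(out / "fragments.tsv", sep="\t", index=False)
            log("simulate", f"{len(prsms)} PrSMs over "
                f"{cfg.sim.n_conditions}x{cfg.sim.n_replicates}x{cfg.sim.n_fractions} runs")
            _counts_entry(summary, "simulate", n_prsms=len(prsms),
                          n_true_proteoforms=len(truth.registry))
        elif cfg.prsm_path is not None:
            path = Path(cfg.prsm_path)
            if not path.exists():
                raise FileNotFoundError(f"PrSM table not found: {path}")
            prsms = prsm_io.read_prsm_table(path)
            _counts_entry(summary, "load", n_prsms=len(prsms))
        else:
            raise ValueError("PipelineConfig needs either sim or prsm_path")
    except Exception as exc:
        raise StageError(f"stage 'simulate/load' failed: {exc}") from exc

    # --- identify --------------------------------------------------------
    try:
        accepted, members, diag = identify(prsms, cfg.fdr, cfg.cluster)
        acc_out = accepted.drop(columns=["member_ids", "member_index"])
        acc_out["runs"] = acc_out["runs"].map(lambda r: ";".join(f"{c}:{x}" for c, x in r))
        acc_out.to_csv(out / "proteoforms.tsv", sep="\t", index=False)
        log("identify", f"{diag['n_prsms_pass_spectrum_fdr']} PrSMs at "
            f"{cfg.fdr.spectrum_fdr:.0%} spectrum FDR; {diag['n_proteoforms_accepted']} "
            f"proteoforms at {cfg.fdr.proteoform_fdr:.0%} proteoform FDR")
        _counts_entry(summary, "identify", **diag)
    except Exception as exc:
        raise StageError(f"stage 'identify' failed: {exc}") from exc

    # --- quantify --------------------------------------------------------
    try:
        has_runs = "condition" in members.columns and members["condition"].nunique() > 1
        if has_runs:
            qm, cc, log2 = quantify(members, accepted, cfg.match_mass_tol,
                                    cfg.reference_run)
            qm.data.to_csv(out / "quant_matrix.tsv", sep="\t", na_rep="NA")
            log2.to_csv(out / "quant_log2_normalized.tsv", sep="\t", na_rep="NA")
            _counts_entry(summary, "quantify", n_rows=len(qm.data),
                          n_complete=len(cc.data))
            log("quantify", f"{len(qm.data)} matched rows, {len(cc.data)} complete cases")
        else:
            log2 = pd.DataFrame()
            _counts_entry(summary, "quantify", n_rows=0, n_complete=0)
    except Exception as exc:
        raise StageError(f"stage 'quantify' failed: {exc}") from exc

    # --- differential test ----------------------------------------------
    try:
        if len(log2) >= 2 and log2.shape[1] >= 4:
            model = diffexpr.SamPermutationModel(log2, config=cfg.diff)
            res = model.fit()
            res.table.to_csv(out / "diff_results.tsv", sep="\t")
            res.volcano_table().to_csv(out / "volcano.tsv", sep="\t")
            (out / "diff_summary.txt").write_text(res.summary() + "\n")
            if cfg.write_plots:
                _volcano_plot(res, out / "volcano.png")
            _counts_entry(summary, "test", n_tested=len(res.table),
                          n_significant=res.n_significant)
            log("test", f"{res.n_significant} significant of {len(res.table)} "
                f"at permutation FDR {cfg.diff.fdr}")
        else:
            _counts_entry(summary, "test", n_tested=0, n_significant=0)
    except Exception as exc:
        raise StageError(f"stage 'test' failed: {exc}") from exc

    # --- profiles --------------------------------------------------------
    try:
        run_sets: dict[str, set] = {}
        if "condition" in members.columns:
            for (c, r), sub in members.groupby(["condition", "replicate"]):
                run_sets[f"{c}_{r}"] = set(sub["cluster_id"])
        if run_sets:
            om = profiles.overlap_matrix(run_sets)
            om.to_csv(out / "overlap_matrix.tsv", sep="\t", na_rep="NA")
        parsed = []
        for s in accepted.loc[~accepted["is_decoy"], "proteoform"]:
            try:
                parsed.append(prsm_io.parse_proteoform_string(s))
            except prsm_io.ProteoformParseError:
                continue
        census = profiles.ptm_census(parsed)
        census.to_series().to_csv(out / "ptm_census.tsv", sep="\t",
                                  header=["n_proteoforms"])
        _counts_entry(summary, "profile", n_parsed=len(parsed),
                      n_categorized=sum(census.counts.values()),
                      n_unmodified=census.unmodified, n_unassigned=census.unassigned)
        log("profile", f"PTM census over {len(parsed)} proteoforms")
    except Exception as exc:
        raise StageError(f"stage 'profile' failed: {exc}") from exc

    # --- saav ------------------------------------------------------------
    try:
        if truth is not None and fragments is not None and len(verdicts):
            calls = saav_calls_from_truth(truth, fragments)
            vt = pd.DataFrame([{"proteoform_id": c.proteoform_key,
                                "confident": c.confident,
                                "min_flanking": min(c.flanking_counts.values())
                                if c.flanking_counts else np.nan}
                               for c in calls])
            vt.to_csv(out / "saav_verdicts.tsv", sep="\t", index=False)
            _counts_entry(summary, "saav", n_calls=len(vt),
                          n_confident=int(vt["confident"].sum()))
            log("saav", f"{int(vt['confident'].sum())} of {len(vt)} SAAV "
                "proteoforms confident")
        else:
            _counts_entry(summary, "saav", n_calls=0, n_confident=0)
    except Exception as exc:
        raise StageError(f"stage 'saav' failed: {exc}") from exc

    (out / "pipeline.log").write_text("\n".join(log_lines) + "\n")
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def saav_calls_from_truth(truth, fragments: pd.DataFrame) -> list[saav.SAAVCall]:
    """Run the SAAV confidence filter on simulated fragment data."""
    calls = []
    reg = truth.registry
    for _, row in reg[reg["saav_ref"] != ""].iterrows():
        pf_id = row["proteoform_id"]
        core = sim_mod.proteoform_core(truth, row)
        named, shifts = truth.mods[pf_id]
        theo = saav.theoretical_fragments(core, list(named))
        obs = fragments.loc[fragments["proteoform_id"] == pf_id, "observed_mass"]
        site = int(row["saav_pos"]) - int(row["start"]) + 1
        shift_iv = ((int(shifts[0].start), int(shifts[0].end)) if shifts else None)
        call = saav.SAAVCall(pf_id, [site], shift_iv,
                             shifts[0].mass if shifts else None)
        calls.append(saav.saav_confidence_filter(call, theo, obs,
                                                 n_residues=len(core)))
    return calls


def _volcano_plot(res, path):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vt = res.volcano_table()
    colors = {"ns": "0.6"}
    g1, g2 = res.model.group_labels
    colors[f"higher_in_{g1}"] = "tab:red"
    colors[f"higher_in_{g2}"] = "tab:blue"
    fig, ax = plt.subplots(figsize=(5, 4))
    for flag, sub in vt.groupby("flag"):
        ax.scatter(sub["log2_fc"], sub["neg_log10_p"], s=8,
                   c=colors.get(flag, "k"), label=flag)
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
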