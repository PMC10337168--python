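"""End-to-end orchestration of the low-pass evaluation on synthetic data.

``run_pipeline`` wires the stages together — simulate, read QC, variant
filtering, dosage, DGV closeness, depth titration and methylation — on
generated data with known truth, writing tab-separated outputs and a
provenance manifest (package and library versions, seeds, SHA-256
digests of every output).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, dgv, dosage, methylation, read_qc, report, synthetic, titration
from .variant_filter import PanelIndex, VariantCall, call_zygosity, depth_rescue_filter

__all__ = ["PipelineError", "load_config", "run_pipeline"]

REQUIRED_SECTIONS = ("seed", "out_dir")

DEFAULT_CONFIG = {
    "population": {"n_individuals": 50, "n_snps": 500, "genome_length": 1_000_000},
    "reads": {"target_depth": 2.0, "base_error_rate": 0.01},
    "titration": {"depths": [0.5, 1.0, 1.5, 2.0], "replicates": 2},
    "methylation": {"n_sites": 2000, "mean_coverage": 12.0},
    "sam": {"n_reads": 200, "reference_length": 50_000},
}


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _validate(config: dict) -> dict:
    for key in REQUIRED_SECTIONS:
        if key not in config:
            raise ValueError(f"config missing required section {key!r}")
    merged = {**DEFAULT_CONFIG, **config}
    for section, defaults in DEFAULT_CONFIG.items():
        if isinstance(merged.get(section), dict):
            merged[section] = {**defaults, **merged[section]}
    return merged


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Run every configured stage; returns the provenance manifest.

    The configuration is validated up front so a missing input is
    reported before any compute. A stage failure halts the run with
    the failing stage named; outputs written so far are retained.
    """
    config = _validate(config)
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    outputs: dict[str, str] = {}

    def emit(name: str, frame: pd.DataFrame) -> None:
        path = out_dir / name
        frame.to_csv(path, sep="\t", index=False)
        outputs[name] = _digest(path)

    # --- simulate ---------------------------------------------------------
    try:
        pop = synthetic.PopulationConfig(seed=seed, **config["population"])
        readsim = synthetic.ReadSimConfig(seed=seed, **config["reads"])
        panel = synthetic.simulate_panel(pop)
        ref_counts, alt_counts = synthetic.simulate_pileups(panel, readsim)
        sam_cfg = config["sam"]
        rng = np.random.default_rng(seed)
        reference = "".join(rng.choice(list("ACGT"), size=sam_cfg["reference_length"]))
        reads = synthetic.simulate_sam_reads(reference, readsim, sam_cfg["n_reads"])
        sam_path = out_dir / "reads.sam"
        synthetic.write_sam(reads, str(sam_path), len(reference))
        outputs["reads.sam"] = _digest(sam_path)
        meth_truth = synthetic.simulate_methylation(
            synthetic.MethylConfig(seed=seed, **config["methylation"]))
        bed_path = out_dir / "methylation.bed"
        synthetic.write_bedmethyl(meth_truth, str(bed_path))
        outputs["methylation.bed"] = _digest(bed_path)
    except Exception as exc:
        raise PipelineError("simulate", exc) from exc

    # --- read QC ----------------------------------------------------------
    try:
        aligned = read_qc.reads_from_sam(str(sam_path))
        kept = read_qc.filter_reads(aligned)
        rows, _ = read_qc.accuracy_table(kept.retained)
        acc = read_qc.summarize_accuracy([r[3] for r in rows])
        cov = read_qc.sam_coverage(str(sam_path), len(reference))
        emit("read_qc.tsv", pd.DataFrame(
            rows, columns=["read", "tms", "length", "accuracy"]))
        readqc_summary = {
            "n_reads": acc.n_reads, "median_accuracy": acc.median,
            "mode_accuracy": acc.mode, "mean_depth": cov.mean_depth,
            "breadth": cov.breadth,
        }
    except Exception as exc:
        raise PipelineError("read_qc", exc) from exc

    # --- variant filter (on calls derived from the pileups, sample 0) -----
    try:
        calls = []
        for j in range(panel.n_snps):
            depth = int(ref_counts[0, j] + alt_counts[0, j])
            af = alt_counts[0, j] / depth if depth else 0.0
            calls.append(VariantCall(panel.chrom, int(panel.positions[j]),
                                     str(panel.ref[j]), str(panel.alt[j]),
                                     depth, af))
        panel_index = PanelIndex(
            (panel.chrom, int(p), str(a))
            for p, a in zip(panel.positions, panel.alt))
        retained, counts = depth_rescue_filter(calls, panel_index)
        retained = [call_zygosity(c) for c in retained]
        emit("variants.tsv", pd.DataFrame(
            [(c.chrom, c.pos, c.ref, c.alt, c.depth, c.alt_fraction,
              c.genotype_class) for c in retained],
            columns=["chrom", "pos", "ref", "alt", "depth", "af", "genotype"]))
        filter_summary = {"retained": counts.n_retained,
                          "rescued": counts.rescued_panel,
                          "discarded": counts.discarded_low_depth}
    except Exception as exc:
        raise PipelineError("variant_filter", exc) from exc

    # --- dosage + DGV closeness ------------------------------------------
    try:
        _, dosages = dosage.posterior_matrix(
            ref_counts, alt_counts, panel.allele_freqs,
            readsim.base_error_rate)
        emit("dosages.tsv", dosage.dosage_frame(
            panel.positions, panel.allele_freqs, dosages))
        effects = dgv.EffectsTable.from_panel(panel)
        closeness_rows = []
        for trait in effects.traits:
            truth = dgv.compute_dgv(panel.genotype_matrix, effects, trait)
            lps = dgv.compute_dgv(dosages, effects, trait)
            m = dgv.closeness(truth, lps)
            closeness_rows.append({
                "trait": trait, "r_squared": m.r_squared, "slope": m.slope,
                "intercept": m.intercept, "pearson": m.pearson,
                "spearman": m.spearman, "n": m.n})
        emit("dgv_closeness.tsv", pd.DataFrame(closeness_rows))
    except Exception as exc:
        raise PipelineError("dgv", exc) from exc

    # --- depth titration --------------------------------------------------
    try:
        tcfg = config["titration"]
        plan = titration.TitrationPlan(
            target_depths=tuple(tcfg["depths"]),
            replicates=int(tcfg["replicates"]), seed=seed)
        curve = titration.titration_curve(
            panel, ref_counts, alt_counts, readsim.target_depth, plan,
            error_rate=readsim.base_error_rate)
        emit("titration.tsv", curve)
        emit("titration_summary.tsv", titration.aggregate_curve(curve))
    except Exception as exc:
        raise PipelineError("titration", exc) from exc

    # --- methylation ------------------------------------------------------
    try:
        sites = methylation.read_bedmethyl(bed_path)
        meth_rows = []
        profiles = {}
        for threshold in (4, 7, 10):
            kept_sites = methylation.coverage_filter(sites, threshold)
            profiles[threshold] = methylation.bin_methylation(kept_sites)
            meth_rows.append({"min_coverage": threshold, "n_sites": len(kept_sites)})
        corr, n_shared = methylation.filter_agreement(profiles[4], profiles[10])
        emit("methylation_counts.tsv", pd.DataFrame(meth_rows))
        meth_summary = {"bin_correlation_4x_10x": corr, "shared_bins": n_shared}
    except Exception as exc:
        raise PipelineError("methylation", exc) from exc

    manifest = {
        "package": "epiglows",
        "version": __version__,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "seed": seed,
        "config": {k: v for k, v in config.items() if k != "out_dir"},
        "outputs": outputs,
        "summaries": {"read_qc": readqc_summary, "variant_filter": filter_summary,
                      "methylation": meth_summary},
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
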