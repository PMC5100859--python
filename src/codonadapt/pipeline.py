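"""End-to-end orchestration: configuration, stage ordering, manifest.

Stages run in dependency order (ingest -> metrics -> {ca, optimal} -> trna;
asm_stats and omics are independent).  Every output table is TSV with a
header row and deterministic float formatting, so a rerun with the same
config and seed is byte-identical.  A run manifest lists every output file
with a checksum plus the parameters and seed used.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .codon_metrics import (
    aggregate_counts,
    count_codons,
    gene_metrics_table,
    genome_rscu_table,
    rscu,
)
from .correspondence import axis_report, build_rscu_matrix, correspondence_analysis, genome_class_table
from .genome_stats import annotation_stats, assembly_stats, stats_table
from .omics import filter_deg, filter_dep, level_vs_change_correlation, pathway_correlations
from .optimal_codons import frequency_table, identify_optimal_codons
from .seqio import read_fasta, read_gff, validate_cds, write_validation_report
from .trna import concordance, read_inventory

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed", "out_dir", "stages", "genomes", "assembly", "trna_inventory",
    "omics", "params",
}
_KNOWN_STAGES = ["ingest", "metrics", "ca", "optimal", "trna", "asm_stats", "omics"]
_DEPS = {
    "metrics": ["ingest"],
    "ca": ["metrics"],
    "optimal": ["metrics"],
    "trna": ["optimal"],
}

_DEFAULT_PARAMS = {
    "alpha": 0.05,
    "bias_metric": "nc_prime",
    "background": "gene",
    "n_axes": 2,
    "deg_p_cutoff": 0.001,
    "dep_fc_cutoff": 1.5,
    "dep_min_unique_peptides": 2,
    "dep_fdr_cutoff": 0.01,
    "pathway_min_n": 3,
    "min_family_count": 1,
}


def load_config(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    return validate_config(config, base_dir=Path(path).parent)


def validate_config(config: dict, base_dir: Path | None = None) -> dict:
    unknown = set(config) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    stages = config.get("stages", ["ingest", "metrics", "ca", "optimal"])
    bad = [s for s in stages if s not in _KNOWN_STAGES]
    if bad:
        raise ValueError(f"unknown stages: {bad}")
    for stage in stages:
        for dep in _DEPS.get(stage, []):
            if dep not in stages:
                raise ValueError(
                    f"stage {stage!r} requires stage {dep!r} to be enabled"
                )
    params = dict(_DEFAULT_PARAMS)
    unknown_p = set(config.get("params", {})) - set(params)
    if unknown_p:
        raise ValueError(f"unknown parameters: {sorted(unknown_p)}")
    params.update(config.get("params", {}))
    out = dict(config)
    out["stages"] = stages
    out["params"] = params
    out.setdefault("seed", 0)
    if base_dir is not None:
        out["_base_dir"] = str(base_dir)
    # all referenced inputs must exist before work starts
    for p in _input_paths(out):
        if not Path(p).exists():
            raise FileNotFoundError(f"configured input does not exist: {p}")
    return out


def _input_paths(config: dict):
    paths = list((config.get("genomes") or {}).values())
    asm = config.get("assembly") or {}
    paths += [v for v in asm.values() if v]
    if config.get("trna_inventory"):
        paths.append(config["trna_inventory"])
    paths += [v for v in (config.get("omics") or {}).values() if v]
    return paths


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


class PipelineRun:
    """Mutable state threaded through the stages of one run."""

    def __init__(self, config: dict):
        self.config = config
        self.params = config["params"]
        self.out_dir = Path(config.get("out_dir", "codonadapt_out"))
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.status: dict[str, dict] = {}
        self.outputs: list[Path] = []
        self.sequences: dict[str, list] = {}
        self.counts: dict[str, list] = {}
        self.metrics: pd.DataFrame | None = None
        self.optimal: pd.DataFrame | None = None

    def emit(self, df: pd.DataFrame, name: str) -> None:
        path = self.out_dir / name
        write_tsv(df, path)
        self.outputs.append(path)


def _stage_ingest(run: PipelineRun) -> None:
    genomes = run.config.get("genomes") or {}
    if not genomes:
        raise ValueError("ingest: no genomes configured")
    reports = []
    for label, fasta in genomes.items():
        seqs = read_fasta(fasta, genome=label)
        kept = []
        for cds in seqs:
            codons, report = validate_cds(cds)
            reports.append(report)
            if report.status == "ok":
                kept.append(cds)
                run.counts.setdefault(label, []).append(
                    count_codons(codons, genome=label, unit_id=cds.id)
                )
        run.sequences[label] = kept
    path = run.out_dir / "validation_report.tsv"
    write_validation_report(reports, path)
    run.outputs.append(path)


def _stage_metrics(run: PipelineRun) -> None:
    frames = []
    for label, seqs in run.sequences.items():
        frames.append(gene_metrics_table(seqs, background=run.params["background"]))
        run.emit(genome_rscu_table(run.counts[label], label), f"rscu_{label}.tsv")
    run.metrics = pd.concat(frames, ignore_index=True)
    run.emit(run.metrics, "gene_metrics.tsv")


def _stage_ca(run: PipelineRun) -> None:
    vectors = [
        rscu(aggregate_counts(run.counts[label], unit_id=label))
        for label in run.sequences
    ]
    matrix = build_rscu_matrix(vectors)
    result = correspondence_analysis(matrix, n_axes=int(run.params["n_axes"]))
    run.emit(genome_class_table(result), "ca_row_coordinates.tsv")
    cols = result.col_coords.reset_index(names="codon")
    cols.insert(1, "ending_gc", [int(c[2] in "GC") for c in result.col_coords.index])
    run.emit(cols, "ca_column_coordinates.tsv")
    run.emit(axis_report(result), "ca_axis_report.tsv")


def _stage_optimal(run: PipelineRun) -> None:
    assert run.metrics is not None
    bias_col = {"nc": "nc", "ncprime": "nc_prime", "nc_prime": "nc_prime"}[
        str(run.params["bias_metric"]).lower()
    ]
    frames_corr, frames_opt = [], []
    for label in run.sequences:
        freq = frequency_table(
            run.counts[label], min_family_count=int(run.params["min_family_count"])
        )
        sub = run.metrics[run.metrics["genome"] == label].set_index("gene")
        bias = sub[bias_col]
        corr, optimal = identify_optimal_codons(
            freq, bias, alpha=float(run.params["alpha"])
        )
        corr.insert(0, "genome", label)
        optimal.insert(0, "genome", label)
        frames_corr.append(corr)
        frames_opt.append(optimal)
    run.emit(pd.concat(frames_corr, ignore_index=True), "codon_correlations.tsv")
    run.optimal = pd.concat(frames_opt, ignore_index=True)
    run.emit(run.optimal, "optimal_codons.tsv")


def _stage_trna(run: PipelineRun) -> None:
    assert run.optimal is not None
    inventory = read_inventory(run.config["trna_inventory"])
    frames = []
    for label, group in run.optimal.groupby("genome"):
        report, fraction = concordance(group, inventory)
        report.insert(0, "genome", label)
        frames.append(report)
        logger.info("tRNA concordance %s: %.3f", label, fraction)
    run.emit(pd.concat(frames, ignore_index=True), "trna_concordance.tsv")


def _stage_asm_stats(run: PipelineRun) -> None:
    asm_cfg = run.config.get("assembly") or {}
    if "genome" not in asm_cfg:
        raise ValueError("asm_stats: assembly.genome FASTA not configured")
    contigs = read_fasta(asm_cfg["genome"], as_contigs=True)
    asm = assembly_stats(contigs)
    ann = None
    if asm_cfg.get("gff"):
        models = read_gff(asm_cfg["gff"])
        ann = annotation_stats(models, contigs)
    run.emit(stats_table(asm, ann), "assembly_stats.tsv")


def _stage_omics(run: PipelineRun) -> None:
    cfg = run.config.get("omics") or {}
    for key in ("transcripts", "proteins", "pathways"):
        if key not in cfg:
            raise ValueError(f"omics: {key} table not configured")
    transcripts = pd.read_csv(cfg["transcripts"], sep="\t")
    proteins = pd.read_csv(cfg["proteins"], sep="\t")
    pathways = pd.read_csv(cfg["pathways"], sep="\t")
    deg, up, down = filter_deg(transcripts, p_cutoff=float(run.params["deg_p_cutoff"]))
    dep = filter_dep(
        proteins,
        fc_cutoff=float(run.params["dep_fc_cutoff"]),
        min_unique_peptides=int(run.params["dep_min_unique_peptides"]),
        fdr_cutoff=float(run.params["dep_fdr_cutoff"]),
    )
    run.emit(deg, "deg.tsv")
    run.emit(dep, "dep.tsv")
    summary = pd.DataFrame([
        {"metric": "deg_total", "value": len(deg)},
        {"metric": "deg_up", "value": up},
        {"metric": "deg_down", "value": down},
        {"metric": "dep_total", "value": len(dep)},
    ])
    run.emit(summary, "omics_summary.tsv")
    global_rec = level_vs_change_correlation(transcripts, proteins)
    run.emit(pd.DataFrame([global_rec]), "level_vs_change.tsv")
    run.emit(
        pathway_correlations(transcripts, proteins, pathways,
                             min_n=int(run.params["pathway_min_n"])),
        "pathway_correlations.tsv",
    )


_STAGE_FN = {
    "ingest": _stage_ingest,
    "metrics": _stage_metrics,
    "ca": _stage_ca,
    "optimal": _stage_optimal,
    "trna": _stage_trna,
    "asm_stats": _stage_asm_stats,
    "omics": _stage_omics,
}


def run_pipeline(config: dict | str | os.PathLike) -> dict:
    """Execute the enabled stages and write a manifest.

    A failing stage aborts its dependents with a causal message; stages on
    independent branches still run.  Returns the manifest dict; overall
    ``"ok"`` is False iff any enabled stage failed.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        config = validate_config(config)
    run = PipelineRun(config)
    order = [s for s in _KNOWN_STAGES if s in config["stages"]]
    for stage in order:
        failed_dep = next(
            (d for d in _DEPS.get(stage, [])
             if run.status.get(d, {}).get("status") != "ok"),
            None,
        )
        if failed_dep is not None:
            run.status[stage] = {
                "status": "skipped",
                "message": f"dependency {failed_dep!r} did not complete",
            }
            continue
        try:
            _STAGE_FN[stage](run)
            run.status[stage] = {"status": "ok", "message": ""}
        except Exception as exc:  # noqa: BLE001 - stage isolation is the point
            logger.error("stage %s failed: %s", stage, exc)
            run.status[stage] = {"status": "failed", "message": str(exc)}
    manifest = {
        "tool": "codonadapt",
        "version": __version__,
        "seed": config.get("seed", 0),
        "parameters": run.params,
        "stages": run.status,
        "inputs": {
            str(p): _sha256(Path(p)) for p in _input_paths(config)
        },
        "outputs": {
            str(p.relative_to(run.out_dir)): _sha256(p) for p in run.outputs
        },
        "ok": all(s["status"] == "ok" for s in run.status.values()),
    }
    with open(run.out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
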