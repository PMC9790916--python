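"""End-to-end orchestration: simulate -> detect -> quantify/DE -> enrich -> ceRNA.

Each stage writes its outputs under one run directory and records them, with
SHA-256 digests and a parameter echo, in ``manifest.json``; given the seed the
manifest suffices to reproduce byte-identical outputs.  The enrichment branch
and the ceRNA branch are independent: either can be toggled off without
disabling the other.  With the simulate stage toggled off, inputs are reloaded
from a previous run's files in the same directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from . import annotation, cerna, circdetect, enrich, expression, simdata

log = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "de", "enrich", "cerna")


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    preset: str = "full"
    sim: dict[str, Any] = field(default_factory=dict)  # SimConfig overrides
    stages: dict[str, bool] = field(default_factory=dict)
    anchor_len: int = circdetect.DEFAULT_ANCHOR_LEN
    filter: dict[str, Any] = field(default_factory=dict)  # FilterThresholds overrides
    norm: str = "tmm"
    dispersion: float | str = "auto"
    lfc_cut: float = 1.0
    p_cut: float = 0.05
    cerna_p_max: float = 0.05
    cerna_min_abs_scc: float = 0.0
    cerna_min_abs_pcc: float = 0.0
    restrict_cerna_to_de: bool = False

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s) in config: {sorted(unknown)}")
        if not 0 < self.p_cut <= 1:
            raise ValueError("p_cut must lie in (0, 1]")
        if self.lfc_cut < 0:
            raise ValueError("lfc_cut must be >= 0")

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update(overrides)
        return cls(**payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "preset": config.preset,
        "params": {
            k: v for k, v in asdict(config).items() if k not in ("outdir",)
        },
        "stages": {},
    }

    def record(stage: str, t0: float, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "elapsed_s": round(time.perf_counter() - t0, 3),
            "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in sorted(paths)},
        }

    sim_cfg = simdata.preset(config.preset, seed=config.seed, **config.sim)
    samples = sim_cfg.samples()
    group_of = sim_cfg.group_of()

    # ---- simulate -------------------------------------------------------
    if config.enabled("simulate"):
        t0 = time.perf_counter()
        try:
            genome, model = simdata.simulate_genome(sim_cfg)
            truth = simdata.plant_circrnas(genome, model, sim_cfg)
            reads, provenance = simdata.simulate_junction_reads(truth, genome, sim_cfg)
            bundle = simdata.simulate_counts_and_cerna(truth, sim_cfg)
        except Exception as exc:  # noqa: BLE001 - stage boundary
            raise PipelineError("simulate", str(exc)) from exc
        paths = _write_sim(outdir, genome, model, truth, reads, provenance, bundle)
        record("simulate", t0, paths)
    else:
        genome, model, truth, reads, bundle = _load_sim(outdir, sim_cfg)

    # ---- detect ---------------------------------------------------------
    if config.enabled("detect"):
        t0 = time.perf_counter()
        try:
            cands = circdetect.detect_junctions(reads, genome, anchor_len=config.anchor_len)
            records = circdetect.aggregate_candidates(cands, samples)
            thresholds = circdetect.FilterThresholds(**config.filter)
            filtered = circdetect.filter_reliable(records, len(samples), thresholds)
            annotated = circdetect.annotate_catalog(filtered, model)
        except Exception as exc:
            raise PipelineError("detect", str(exc)) from exc
        catalog_path = outdir / "catalog.tsv"
        circdetect.write_catalog(annotated, catalog_path)
        bed_path = outdir / "junctions.bed"
        circdetect.write_junction_bed(annotated, bed_path)
        paths = [catalog_path, bed_path]
        for name, df in circdetect.summarize_catalog(annotated).items():
            p = outdir / f"summary_{name}.tsv"
            df.to_csv(p, sep="\t")
            paths.append(p)
        record("detect", t0, paths)

    # ---- differential expression ---------------------------------------
    de_hits: dict[str, tuple[list, list]] = {}
    if config.enabled("de"):
        t0 = time.perf_counter()
        matrix = expression.CountMatrix(bundle.circ_counts, group_of)
        paths = []
        rpm_path = outdir / "circ_rpm.tsv"
        expression.rpm(matrix).to_csv(rpm_path, sep="\t", index_label="feature_id")
        paths.append(rpm_path)
        for comp in sim_cfg.comparisons:
            try:
                results = expression.exact_test(
                    matrix, comp.group_a, comp.group_b,
                    dispersion=config.dispersion, norm=config.norm,
                )
            except Exception as exc:
                raise PipelineError("de", f"comparison {comp.name}: {exc}") from exc
            up, down = expression.screen_de(results, config.lfc_cut, config.p_cut)
            de_hits[comp.name] = (up, down)
            table = expression.de_table(results)
            p = outdir / f"de_{comp.name}.tsv"
            table.to_csv(p, sep="\t", index=False)
            paths.append(p)
            p = outdir / f"top_changed_{comp.name}.tsv"
            expression.top_changed(results).to_csv(p, sep="\t", index=False)
            paths.append(p)
        record("de", t0, paths)

    truth_by_id = truth.by_id()

    # ---- enrichment -----------------------------------------------------
    if config.enabled("enrich"):
        if not config.enabled("de"):
            raise PipelineError("enrich", "requires the de stage")
        t0 = time.perf_counter()
        paths = []
        for comp in sim_cfg.comparisons:
            up, down = de_hits[comp.name]
            de_records = [
                _truth_record(truth_by_id[r.feature_id])
                for r in up + down
                if r.feature_id in truth_by_id
            ]
            hosts = enrich.hosts_of(de_records)
            rows = enrich.hypergeom_enrich(hosts, bundle.gene_sets)
            p = outdir / f"enrich_{comp.name}.tsv"
            enrich.enrichment_table(rows).to_csv(p, sep="\t", index=False)
            paths.append(p)
            p = outdir / f"enrich_top20_{comp.name}.tsv"
            enrich.top_table(rows).to_csv(p, sep="\t", index=False)
            paths.append(p)
        record("enrich", t0, paths)

    # ---- ceRNA ----------------------------------------------------------
    if config.enabled("cerna"):
        t0 = time.perf_counter()
        circ_rpm = expression.rpm(expression.CountMatrix(bundle.circ_counts, group_of))
        restrict = None
        if config.restrict_cerna_to_de:
            if not config.enabled("de"):
                raise PipelineError("cerna", "restrict_cerna_to_de requires the de stage")
            restrict = sorted(
                {r.feature_id for hits in de_hits.values() for r in hits[0] + hits[1]}
            )
        try:
            triads, graph = cerna.build_cerna(
                circ_rpm, bundle.mir_expr, bundle.mrna_expr, bundle.targets,
                cerna.CernaThresholds(
                    p_max=config.cerna_p_max,
                    min_abs_scc=config.cerna_min_abs_scc,
                    min_abs_pcc=config.cerna_min_abs_pcc,
                ),
                restrict_circ=restrict,
            )
        except Exception as exc:
            raise PipelineError("cerna", str(exc)) from exc
        triad_path = outdir / "cerna_triads.tsv"
        pd.DataFrame([asdict(t) for t in triads]).to_csv(triad_path, sep="\t", index=False)
        paths = [triad_path]
        paths += cerna.export_network(graph, outdir / "cerna.sif", "sif")
        paths += cerna.export_network(graph, outdir / "cerna.tsv", "edge-tsv")
        paths += cerna.export_network(graph, outdir / "cerna.graphml", "graphml")
        record("cerna", t0, paths)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest


def _truth_record(rec: simdata.CircTruth) -> circdetect.CircRecord:
    """View a truth entry as an annotated CircRecord (for host-gene lookup)."""
    return circdetect.CircRecord(
        circ_id=rec.circ_id, chrom=rec.chrom, strand=rec.strand,
        start=rec.start, end=rec.end, breakpoint=1, anchor_overlap=0, edit=0,
        n_uniq=0, best_qual_a=0, best_qual_b=0,
        origin=rec.origin, host_gene=rec.host_gene,
    )


def _write_sim(outdir, genome, model, truth, reads, provenance, bundle) -> list[Path]:
    paths = []
    p = outdir / "genome.fa"
    simdata.write_fasta(genome, p)
    paths.append(p)
    p = outdir / "annotation.gtf"
    annotation.write_gtf(model, p)
    paths.append(p)
    p = outdir / "annotation.bed12"
    annotation.write_bed12(model, p)
    paths.append(p)
    paths.extend(simdata.write_fastq(reads, outdir / "reads").values())
    p = outdir / "read_provenance.tsv"
    provenance.to_csv(p, sep="\t", index=False)
    paths.append(p)
    p = outdir / "truth.json"
    truth.to_json(p)
    paths.append(p)
    p = outdir / "circ_counts.tsv"
    simdata.write_matrix(bundle.circ_counts, p)
    paths.append(p)
    p = outdir / "samples.tsv"
    with open(p, "w") as fh:
        fh.write("sample_id\tgroup\n")
        for s, g in bundle.group_of.items():
            fh.write(f"{s}\t{g}\n")
    paths.append(p)
    p = outdir / "mir_expr.tsv"
    simdata.write_matrix(bundle.mir_expr, p)
    paths.append(p)
    p = outdir / "mrna_expr.tsv"
    simdata.write_matrix(bundle.mrna_expr, p)
    paths.append(p)
    p = outdir / "gene_sets.gmt"
    bundle.gene_sets.to_gmt(p)
    paths.append(p)
    bundle.targets.to_tsv(outdir / "targets_mir_gene.tsv", outdir / "targets_circ_mir.tsv")
    paths += [outdir / "targets_mir_gene.tsv", outdir / "targets_circ_mir.tsv"]
    return paths


def _load_sim(outdir: Path, sim_cfg: simdata.SimConfig):
    from .enrich import GeneSetCollection

    required = ["genome.fa", "annotation.gtf", "truth.json", "circ_counts.tsv"]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise PipelineError("simulate", f"stage disabled but inputs missing: {missing}")
    genome = simdata.read_fasta(outdir / "genome.fa")
    model = annotation.read_gtf(outdir / "annotation.gtf")
    truth = simdata.TruthSet.from_json(outdir / "truth.json")
    reads = simdata.read_fastq_dir(outdir / "reads") if (outdir / "reads").exists() else []
    bundle = simdata.CountBundle(
        circ_counts=simdata.read_matrix(outdir / "circ_counts.tsv"),
        group_of=sim_cfg.group_of(),
        mir_expr=simdata.read_matrix(outdir / "mir_expr.tsv"),
        mrna_expr=simdata.read_matrix(outdir / "mrna_expr.tsv"),
        gene_sets=GeneSetCollection.from_gmt(outdir / "gene_sets.gmt"),
        targets=cerna.TargetMap.from_tsv(
            outdir / "targets_mir_gene.tsv", outdir / "targets_circ_mir.tsv"
        ),
    )
    return genome, model, truth, reads, bundle
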