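"""End-to-end orchestration: synthetic study -> reads -> matrices -> analyses.

``run_pipeline`` executes the eight stages (simulate, read_processing,
quantify, qc, de, domains, splice_enrich, abundance) into a run directory and
writes a manifest recording parameters, seeds and output checksums, so reruns
with an identical config are verifiable as identical.  A single global seed
fans out to per-stage seeds through :meth:`SimConfig.rng`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pathlib
import time

import pandas as pd
import yaml

from . import abundance as ab
from . import cell_qc, diffexpr, exon_domain, quantify, read_processing, splice_enrich
from .quantify import AssignConfig
from .synthetic import (GroundTruth, SimConfig, emit_truth, generate_annotation,
                        generate_cell_population, make_embedding, simulate_reads,
                        write_fasta)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "read_processing", "quantify", "qc", "de", "domains",
          "splice_enrich", "abundance")


@dataclasses.dataclass
class PipelineConfig:
    outdir: str
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    qc_preset: str = "brain"
    de_config: diffexpr.DEConfig = dataclasses.field(default_factory=diffexpr.DEConfig)
    assign_config: AssignConfig = dataclasses.field(default_factory=AssignConfig)
    de_subtype: str = "MOL2"
    abundance_k: int = 60
    abundance_sampling_fraction: float = 0.2
    abundance_radius: float | None = None
    enrichment_threshold: float = 0.705
    seed: int = 0

    def __post_init__(self):
        # the global seed overrides the generator's
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ValueError("pipeline config must set outdir")
        sim = SimConfig(**{k: _tuplify(v) for k, v in raw.pop("sim", {}).items()})
        de = diffexpr.DEConfig(**raw.pop("de", {}))
        asg = AssignConfig(**raw.pop("assign", {}))
        return cls(sim=sim, de_config=de, assign_config=asg, **raw)


def _tuplify(v):
    return tuple(v) if isinstance(v, list) else v


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineRun:
    """Accumulates stage outputs and the manifest."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = pathlib.Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest: list[dict] = []

    def record(self, stage: str, params: dict, outputs: list[pathlib.Path],
               t0: float) -> None:
        self.manifest.append({
            "stage": stage,
            "params": params,
            "seed": [self.config.seed, STAGES.index(stage) + 1],
            "outputs": {p.name: _sha256(p) for p in outputs},
            "seconds": round(time.time() - t0, 2),
        })

    def write_manifest(self) -> None:
        with open(self.outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2)


def run_pipeline(config: PipelineConfig) -> PipelineRun:
    """Run all stages; a stage failure aborts with the stage name and cause,
    retaining partial outputs."""
    run = PipelineRun(config)
    state: dict = {}
    steps = {
        "simulate": _stage_simulate,
        "read_processing": _stage_read_processing,
        "quantify": _stage_quantify,
        "qc": _stage_qc,
        "de": _stage_de,
        "domains": _stage_domains,
        "splice_enrich": _stage_splice_enrich,
        "abundance": _stage_abundance,
    }
    for stage in STAGES:
        t0 = time.time()
        logger.info("stage %s ...", stage)
        try:
            params, outputs = steps[stage](run, state)
        except Exception as exc:
            run.write_manifest()
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        run.record(stage, params, outputs, t0)
    run.write_manifest()
    return run


# -- stages ------------------------------------------------------------------

def _stage_simulate(run: PipelineRun, state: dict):
    cfg = run.config.sim
    out = run.outdir
    db, seqs, domains = generate_annotation(cfg)
    db.to_gtf(out / "annotation.gtf")
    write_fasta(seqs, out / "transcripts.fa")
    exon_domain.write_domain_table(domains, out / "domains.tsv")
    cells, truth = generate_cell_population(cfg, db)
    emit_truth(truth, out)
    reads = simulate_reads(cells, db, truth, cfg)
    read_processing.reads_to_sam(reads, db.chromosome_lengths(), out / "reads.sam")
    make_embedding(cells, cfg).to_csv(out / "embedding.tsv", sep="\t", index=False)
    state.update(db=db, domains=domains, cells=cells, truth=truth)
    outputs = [out / f for f in ("annotation.gtf", "transcripts.fa", "domains.tsv",
                                 "reads.sam", "embedding.tsv", "truth_cells.tsv",
                                 "truth_genes.tsv", "truth_exons.tsv",
                                 "truth_factors.tsv")]
    return {"n_genes": cfg.n_genes, "n_cells": len(cells)}, outputs


def _stage_read_processing(run: PipelineRun, state: dict):
    out = run.outdir
    cfg = run.config.sim
    reads = read_processing.reads_from_sam(out / "reads.sam")
    dmx_cfg = demux_config_for(cfg)
    result = read_processing.demultiplex(reads, dmx_cfg)
    molecules = []
    for sample, sreads in result.samples.items():
        mols = read_processing.deduplicate(sreads)
        mols = mols.assign(sample=sample)
        molecules.append(mols)
    molecules = pd.concat(molecules, ignore_index=True) if molecules else reads.iloc[0:0]
    result.rejected.to_csv(out / "rejected_reads.tsv", sep="\t", index=False)
    summary = pd.DataFrame({
        "metric": ["input_reads", "assigned_reads", "rejected_reads", "molecules"],
        "count": [result.n_input, result.n_assigned, len(result.rejected),
                  len(molecules)],
    })
    summary.to_csv(out / "read_processing_summary.tsv", sep="\t", index=False)
    state["molecules"] = molecules
    return ({"max_edit_distance": 1},
            [out / "rejected_reads.tsv", out / "read_processing_summary.tsv"])


def _stage_quantify(run: PipelineRun, state: dict):
    out = run.outdir
    assigned = quantify.assign_bulk(state["molecules"], state["db"],
                                    run.config.assign_config)
    state["assigned"] = assigned
    gm, em = quantify.build_matrices(assigned, state["db"])
    state["gene_matrix"], state["exon_matrix"] = gm, em
    gm.write_mtx(out, prefix="gene_")
    em.write_mtx(out, prefix="exon_")
    quantify.assignment_summary(assigned).to_csv(
        out / "assignment_summary.tsv", sep="\t", index=False)
    outputs = [out / f"{p}{n}" for p in ("gene_", "exon_")
               for n in ("matrix.mtx", "features.tsv", "barcodes.tsv")]
    return ({"upstream_window": run.config.assign_config.upstream_window},
            outputs + [out / "assignment_summary.tsv"])


def _stage_qc(run: PipelineRun, state: dict):
    out = run.outdir
    qc_cfg = cell_qc.QCConfig.preset(run.config.qc_preset)
    gm, report = cell_qc.filter_cells(state["gene_matrix"], qc_cfg)
    scores = cell_qc.doublet_scores(gm, qc_cfg, seed=run.config.seed)
    keep = scores.loc[~scores["is_doublet"], "cell"].tolist()
    state["gene_matrix_qc"] = gm.subset_cells(keep)
    state["exon_matrix_qc"] = state["exon_matrix"].subset_cells(keep)
    state["doublet_scores"] = scores
    report.discarded.to_csv(out / "qc_discarded.tsv", sep="\t", index=False)
    scores.to_csv(out / "doublet_scores.tsv", sep="\t", index=False)
    return ({"preset": run.config.qc_preset, "n_kept": len(keep)},
            [out / "qc_discarded.tsv", out / "doublet_scores.tsv"])


def _stage_de(run: PipelineRun, state: dict):
    out = run.outdir
    cells = state["cells"].set_index("cell_id")
    subtype = run.config.de_subtype
    in_subtype = [c for c in state["gene_matrix_qc"].cell_ids
                  if cells.loc[c, "subtype"] == subtype]
    gm = state["gene_matrix_qc"].subset_cells(in_subtype)
    em = state["exon_matrix_qc"].subset_cells(in_subtype)
    labels = cells["condition"]
    table = diffexpr.run_combined_de(gm, em, labels,
                                     reference=run.config.sim.conditions[0],
                                     config=run.config.de_config)
    state["de_table"] = table
    table.to_csv(out / "de_table.tsv", sep="\t", index=False)
    return ({"subtype": subtype, "n_cells": len(in_subtype)},
            [out / "de_table.tsv"])


def _stage_domains(run: PipelineRun, state: dict):
    out = run.outdir
    table = state["de_table"]
    dees = table.loc[table["is_DEE"], "feature_id"].tolist()
    hits = exon_domain.map_dees_to_domains(dees, state["db"], state["domains"])
    hits.to_csv(out / "domain_hits.tsv", sep="\t", index=False)
    exon_domain.summarize_per_exon(hits).to_csv(
        out / "domain_summary.tsv", sep="\t", index=False)
    return ({"n_dees": len(dees), "n_hits": len(hits)},
            [out / "domain_hits.tsv", out / "domain_summary.tsv"])


def _stage_splice_enrich(run: PipelineRun, state: dict):
    out = run.outdir
    table = state["de_table"]
    truth: GroundTruth = state["truth"]
    factor_set = set(truth.genes.loc[truth.genes["is_splicing_factor"], "gene_id"])
    de_factors = splice_enrich.select_de_splicing_factors(table, factor_set)
    genes = table[table["kind"] == "gene"]
    universe = set(genes["feature_id"])
    dee_parents = set(table.loc[table["is_DEE"], "parent_gene"]) & universe
    targets = {f: set(g["target_gene_id"])
               for f, g in truth.factors.groupby("factor_id")}
    results = splice_enrich.fisher_target_enrichment(dee_parents, universe, targets)
    frame = splice_enrich.enrichment_frame(results)
    frame["factor_is_deg"] = frame["factor_id"].isin(set(de_factors["feature_id"]))
    frame.to_csv(out / "splice_enrichment.tsv", sep="\t", index=False)
    state["enrichment"] = frame
    return ({"n_factors": len(targets)}, [out / "splice_enrichment.tsv"])


def _stage_abundance(run: PipelineRun, state: dict):
    out = run.outdir
    cfg = run.config
    emb = pd.read_csv(out / "embedding.tsv", sep="\t")
    cells = state["cells"].set_index("cell_id")
    kept = state["gene_matrix_qc"].cell_ids
    emb = emb.set_index("cell_id").loc[kept]
    nh = ab.build_neighborhoods(emb[["x", "y"]].to_numpy(), kept,
                                k=cfg.abundance_k,
                                sampling_fraction=cfg.abundance_sampling_fraction,
                                seed=cfg.seed)
    ab.count_cells(nh, cells["sample"])
    res = ab.test_neighborhood_abundance(
        nh, cfg.sim.condition_of_sample(), reference=cfg.sim.conditions[0])
    labels = ab.expand_and_label(nh, cells["condition"],
                                 radius=cfg.abundance_radius,
                                 threshold=cfg.enrichment_threshold,
                                 conditions=cfg.sim.conditions)
    res.to_csv(out / "abundance_results.tsv", sep="\t", index=False)
    labels.to_csv(out / "abundance_labels.tsv", sep="\t", index=False)
    state["abundance_labels"] = labels
    return ({"k": cfg.abundance_k, "radius": nh.expansion_radius},
            [out / "abundance_results.tsv", out / "abundance_labels.tsv"])


def demux_config_for(sim: SimConfig) -> read_processing.DemuxConfig:
    """Demux config matching the generator's barcode layout."""
    rt = read_processing.packaged_whitelist("rt")
    lig = read_processing.packaged_whitelist("lig")
    samples = sim.samples
    chunk = len(rt) // len(samples)
    sample_of_rt = {}
    for si, s in enumerate(samples):
        for b in rt[si * chunk:(si + 1) * chunk]:
            sample_of_rt[b] = s
    return read_processing.DemuxConfig(rt_whitelist=rt, lig_whitelist=lig,
                                       sample_of_rt=sample_of_rt)


def make_demo(outdir, seed: int = 0, n_cells_per_replicate: int = 500) -> PipelineRun:
    """Generate and analyze the default synthetic study end to end.

    The default is the full study (2 conditions x 3 replicates x 500 cells,
    ~3,000 cells pre-QC); pass a smaller ``n_cells_per_replicate`` for a
    quick demo.
    """
    cfg = PipelineConfig(
        outdir=str(outdir),
        sim=SimConfig(n_cells_per_replicate=n_cells_per_replicate, seed=seed),
        abundance_k=min(60, max(5, n_cells_per_replicate // 2)),
        seed=seed,
    )
    return run_pipeline(cfg)
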