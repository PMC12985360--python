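"""Parameter-recovery evaluation of the pipeline on the default synthetic study.

Runs the full analysis chain in memory (generator -> barcode correction ->
deduplication -> assignment -> QC -> differential expression -> abundance)
and measures how well each stage recovers the generator's ground truth:
fold-change recovery, DEG recall and empirical FDR, intronic-fraction
recovery, doublet ranking, neighborhood labeling of a planted aged-expanded
subtype, and the null calibration of the NB LRT.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance as ab
from . import cell_qc, diffexpr, quantify, read_processing as rp
from .pipeline import demux_config_for
from .synthetic import (SimConfig, generate_annotation,
                        generate_cell_population, make_embedding,
                        simulate_reads)


@dataclass
class StudyArtifacts:
    config: SimConfig
    db: object
    domains: pd.DataFrame
    cells: pd.DataFrame
    truth: object
    demux: object
    assigned: pd.DataFrame
    gene_matrix: quantify.CountMatrix
    exon_matrix: quantify.CountMatrix
    doublet_scores: pd.DataFrame
    kept_cells: list[str]
    de_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def run_default_study(seed: int = 0, n_cells_per_replicate: int = 500,
                      de_subtypes: tuple[str, ...] = ("MOL2", "MOL56")
                      ) -> StudyArtifacts:
    """The default study (2 conditions x 3 replicates) through every stage."""
    cfg = SimConfig(seed=seed, n_cells_per_replicate=n_cells_per_replicate)
    db, _, domains = generate_annotation(cfg)
    cells, truth = generate_cell_population(cfg, db)
    reads = simulate_reads(cells, db, truth, cfg)

    demux = rp.demultiplex(reads, demux_config_for(cfg))
    del reads  # only the demultiplexed per-sample tables are needed now
    parts = []
    for sample in sorted(demux.samples):
        parts.append(rp.deduplicate(demux.samples.pop(sample)))
    molecules = pd.concat(parts, ignore_index=True)
    del parts
    assigned = quantify.assign_bulk(molecules, db)
    del molecules  # assigned carries every molecule column
    gene_matrix, exon_matrix = quantify.build_matrices(assigned, db)

    qc_cfg = cell_qc.QCConfig.preset("brain")
    filtered, _ = cell_qc.filter_cells(gene_matrix, qc_cfg)
    scores = cell_qc.doublet_scores(filtered, qc_cfg, seed=seed)
    kept = scores.loc[~scores["is_doublet"], "cell"].tolist()

    art = StudyArtifacts(
        config=cfg, db=db, domains=domains, cells=cells, truth=truth,
        demux=demux, assigned=assigned,
        gene_matrix=gene_matrix, exon_matrix=exon_matrix,
        doublet_scores=scores, kept_cells=kept)

    meta = cells.set_index("cell_id")
    for subtype in de_subtypes:
        in_sub = [c for c in kept if meta.loc[c, "subtype"] == subtype]
        gm = gene_matrix.subset_cells(in_sub)
        em = exon_matrix.subset_cells(in_sub)
        art.de_tables[subtype] = diffexpr.run_combined_de(
            gm, em, meta["condition"], reference=cfg.conditions[0])
    return art


# ---------------------------------------------------------------------------
# truth helpers
# ---------------------------------------------------------------------------

def true_gene_cpm(truth, subtype: str, condition: str) -> pd.Series:
    """Expected CPM per gene within one subtype/condition from the intensity
    model (molecule-depth free)."""
    lam = truth.lam[(subtype, condition)]
    gidx = truth.segments["gene_idx"].to_numpy()
    totals = pd.Series(lam).groupby(gidx).sum()
    cpm = totals / totals.sum() * 1e6
    cpm.index = truth.genes["gene_id"].to_numpy()
    return cpm


# ---------------------------------------------------------------------------
# recovery metrics
# ---------------------------------------------------------------------------

def lfc_recovery(art: StudyArtifacts, subtype: str = "MOL2",
                 high_cpm: float = 100.0, strong_lfc: float = 1.0) -> dict:
    """Fold-change recovery, DEG recall and empirical FDR against truth.

    High expression means true max-condition CPM >= ``high_cpm`` (well above
    the CPM>25 callability cutoff); strong effects are |drawn log2FC| >=
    ``strong_lfc``.  Fold-change error is measured on the CPM scale - the
    scale a total-count-normalized estimator can observe - so the truth is
    the expected CPM ratio (the intensity ratio net of the library
    composition shift), per subtype.
    """
    table = art.de_tables[subtype]
    genes = table[table["kind"] == "gene"].set_index("feature_id")
    truth = art.truth.genes.set_index("gene_id")
    cpm_y = true_gene_cpm(art.truth, subtype, art.config.conditions[0])
    cpm_a = true_gene_cpm(art.truth, subtype, art.config.conditions[1])
    max_cpm = pd.concat([cpm_y, cpm_a], axis=1).max(axis=1)
    cpm_scale_lfc = np.log2(cpm_a / cpm_y)

    high = max_cpm[max_cpm >= high_cpm].index
    err = genes.loc[high, "log2fc"] - cpm_scale_lfc[high]

    strong = truth.index[(np.abs(truth["drawn_log2fc"]) >= strong_lfc)
                         & (max_cpm >= high_cpm)]
    recall = float(genes.loc[strong, "is_DEG"].mean()) if len(strong) else np.nan

    called = genes.index[genes["is_DEG"]]
    false_calls = int((~truth.loc[called, "is_deg_true"]).sum())
    fdr = false_calls / len(called) if len(called) else 0.0
    return {
        "mean_lfc_error": float(err.mean()),
        "mean_abs_lfc_error": float(err.abs().mean()),
        "n_high_expression": int(len(high)),
        "deg_recall_strong": recall,
        "n_strong_truth": int(len(strong)),
        "deg_empirical_fdr": float(fdr),
        "n_deg_called": int(len(called)),
    }


def dee_summary(art: StudyArtifacts, subtype: str = "MOL2") -> dict:
    table = art.de_tables[subtype]
    exons = table[table["kind"] == "exon"]
    dees = exons[exons["is_DEE"]]
    frac_non_deg = float((dees["dee_class"] == "non-DEG-derived").mean()) \
        if len(dees) else np.nan
    return {"n_dee_called": int(len(dees)),
            "frac_non_deg_derived": frac_non_deg}


def shared_deg_correlation(art: StudyArtifacts, a: str = "MOL2",
                           b: str = "MOL56") -> dict:
    return diffexpr.shared_logfc_correlation(art.de_tables[a],
                                             art.de_tables[b], flag="is_DEG")


def intron_fraction_recovery(art: StudyArtifacts, z: float = 2.576) -> dict:
    """Per-gene, per-condition intronic fractions vs truth.

    The generator splits each gene's molecules binomially between exonic and
    intronic segments, so the pooled estimate is binomial around the true
    fraction; coverage is checked against the ``z``-score (99%) interval with
    continuity correction.
    """
    assigned = art.assigned
    cell = assigned["rt_barcode"].astype(str) + assigned["lig_barcode"].astype(str)
    cond = cell.map(art.cells.set_index("cell_id")["condition"])
    truth = art.truth.genes.set_index("gene_id")

    inside = deviations = 0
    max_dev = 0.0
    for condition, col in ((art.config.conditions[0], "intron_fraction_young"),
                           (art.config.conditions[1], "intron_fraction_aged")):
        sub = assigned[(cond == condition).to_numpy()
                       & assigned["gene_id"].notna().to_numpy()]
        grp = sub.groupby("gene_id", observed=True)
        n = grp.size()
        k = grp["exon_id"].agg(lambda s: s.isna().sum())
        p_hat = k / n
        p_true = truth.loc[n.index, col]
        half = z * np.sqrt(p_true * (1 - p_true) / n) + 0.5 / n
        dev = (p_hat - p_true).abs()
        inside += int((dev <= half).sum())
        deviations += len(dev)
        max_dev = max(max_dev, float(dev.max()))
    return {"intron_coverage": inside / deviations,
            "n_gene_condition_pairs": int(deviations),
            "intron_max_abs_dev": max_dev}


def intron_dynamic_gene_fractions(art: StudyArtifacts) -> dict:
    """Mean estimated intronic fraction over the intron-dynamic genes, per
    condition, plus the per-replicate t test for the first such gene."""
    truth = art.truth.genes
    dynamic = truth.loc[truth["intron_dynamic"], "gene_id"]
    assigned = art.assigned
    cell = assigned["rt_barcode"].astype(str) + assigned["lig_barcode"].astype(str)
    meta = art.cells.set_index("cell_id")
    cond = cell.map(meta["condition"]).to_numpy()
    out = {"n_dynamic_genes": int(len(dynamic))}
    for condition in art.config.conditions:
        sub = assigned[(cond == condition)
                       & assigned["gene_id"].isin(set(dynamic)).to_numpy()]
        out[f"intron_fraction_{condition}"] = float(sub["exon_id"].isna().mean())
    if len(dynamic):
        res = quantify.intronic_fraction_test(
            assigned, dynamic.iloc[0], meta["sample"].to_dict(),
            art.config.condition_of_sample())
        out["example_gene_t_test_p"] = res.p_value
    return out


def factor_target_enrichment(art: StudyArtifacts, subtype: str = "MOL2") -> pd.DataFrame:
    """Fisher enrichment of each splicing factor's targets among DEE parents."""
    from . import splice_enrich

    table = art.de_tables[subtype]
    genes = table[table["kind"] == "gene"]
    universe = set(genes["feature_id"])
    dee_parents = set(table.loc[table["is_DEE"], "parent_gene"]) & universe
    targets = {f: set(g["target_gene_id"])
               for f, g in art.truth.factors.groupby("factor_id")}
    results = splice_enrich.fisher_target_enrichment(dee_parents, universe,
                                                     targets)
    return splice_enrich.enrichment_frame(results)


def doublet_ranking(art: StudyArtifacts) -> dict:
    """AUROC of the doublet score against the generator's doublet flags."""
    from sklearn.metrics import roc_auc_score

    meta = art.cells.set_index("cell_id")
    scores = art.doublet_scores
    y = meta.loc[scores["cell"], "is_doublet"].to_numpy()
    return {"doublet_auroc": float(roc_auc_score(y, scores["doublet_score"])),
            "n_true_doublets_scored": int(y.sum())}


def aged_region_labeling(art: StudyArtifacts, k: int = 60,
                         sampling_fraction: float = 0.3,
                         region_subtype: str = "MOL_reactive") -> dict:
    """Neighborhood labeling on the synthetic embedding: fraction of
    neighborhoods indexed inside the planted aged-expanded subtype that are
    labeled Aged-enriched (raw proportions, 70.5% threshold)."""
    meta = art.cells.set_index("cell_id")
    kept = art.kept_cells
    emb = make_embedding(art.cells, art.config).set_index("cell_id").loc[kept]
    nh = ab.build_neighborhoods(emb[["x", "y"]].to_numpy(), kept, k=k,
                                sampling_fraction=sampling_fraction,
                                seed=art.config.seed)
    ab.count_cells(nh, meta["sample"])
    res = ab.test_neighborhood_abundance(
        nh, art.config.condition_of_sample(),
        reference=art.config.conditions[0])
    labels = ab.expand_and_label(nh, meta["condition"],
                                 conditions=art.config.conditions)
    idx_subtype = meta.loc[[kept[i] for i in nh.index_cells], "subtype"].to_numpy()
    in_region = idx_subtype == region_subtype
    labeled = labels["label"].to_numpy()[in_region] == "Aged-enriched"
    sig_pos = (res["significant"].to_numpy()[in_region]
               & (res["log2fc"].to_numpy()[in_region] > 0))
    return {
        "aged_region_labeled_fraction": float(labeled.mean()),
        "aged_region_sig_fraction": float(sig_pos.mean()),
        "n_region_neighborhoods": int(in_region.sum()),
        "n_neighborhoods": nh.n_neighborhoods,
    }


def conservation_checks(art: StudyArtifacts) -> dict:
    demux = art.demux
    again = rp.deduplicate(art.assigned)
    return {
        "reads_in": int(demux.n_input),
        "reads_assigned_plus_rejected": int(demux.n_assigned + len(demux.rejected)),
        "dedup_idempotent": bool(len(again) == len(art.assigned)),
        "gene_matrix_total": int(art.gene_matrix.X.sum()),
        "assigned_molecules": int(art.assigned["gene_id"].notna().sum()),
    }


# ---------------------------------------------------------------------------
# standalone calibrations (no study needed)
# ---------------------------------------------------------------------------

def nb_lrt_type1(n_features: int = 2000, n_cells: int = 150,
                 dispersion: float = 0.3, seed: int = 0) -> dict:
    """Type-I error of the NB LRT on null NB features at nominal 0.05."""
    rng = np.random.default_rng([seed, 101])
    cond = np.array(["a"] * (n_cells // 2) + ["b"] * (n_cells - n_cells // 2))
    s = rng.lognormal(6.0, 0.3, n_cells)
    hits = 0
    for _ in range(n_features):
        mu = s * rng.uniform(5e-4, 5e-3)
        y = rng.poisson(rng.gamma(1 / dispersion, mu * dispersion))
        p, _ = diffexpr.nb_lrt(y, cond, s)
        hits += p < 0.05
    rate = hits / n_features
    half = 2.576 * np.sqrt(0.05 * 0.95 / n_features)
    return {"type1_rate": float(rate), "n_features": n_features,
            "band_low": 0.05 - half, "band_high": 0.05 + half}


def permuted_label_de(art: StudyArtifacts, subtype: str = "MOL2",
                      seed: int = 0) -> dict:
    """Combined DE after permuting condition labels: calls should vanish."""
    rng = np.random.default_rng([seed, 102])
    meta = art.cells.set_index("cell_id")
    in_sub = [c for c in art.kept_cells if meta.loc[c, "subtype"] == subtype]
    gm = art.gene_matrix.subset_cells(in_sub)
    em = art.exon_matrix.subset_cells(in_sub)
    perm = pd.Series(rng.permutation(meta.loc[in_sub, "condition"].to_numpy()),
                     index=in_sub)
    table = diffexpr.run_combined_de(gm, em, perm,
                                     reference=art.config.conditions[0])
    return {"permuted_deg_calls": int(table["is_DEG"].sum()),
            "permuted_dee_calls": int(table["is_DEE"].sum()),
            "n_features_tested": int(len(table))}


def null_neighborhood_calibration(n_cells: int = 1500, k: int = 60,
                                  seed: int = 0) -> dict:
    """Fraction of neighborhoods significant at p<0.05 when cells are
    assigned to samples uniformly at random (no abundance effect)."""
    rng = np.random.default_rng([seed, 103])
    emb = rng.normal(0, 3, size=(n_cells, 2))
    ids = [f"c{i}" for i in range(n_cells)]
    samples = [f"{c}_r{r}" for c in ("young", "aged") for r in (1, 2, 3)]
    sample_of_cell = pd.Series(rng.choice(samples, n_cells), index=ids)
    nh = ab.build_neighborhoods(emb, ids, k=k, sampling_fraction=0.3,
                                seed=seed)
    ab.count_cells(nh, sample_of_cell)
    res = ab.test_neighborhood_abundance(
        nh, {s: s.split("_")[0] for s in samples}, reference="young")
    return {"null_nhood_rate": float((res["p"] < 0.05).mean()),
            "n_neighborhoods": int(len(res))}
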