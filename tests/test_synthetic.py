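"""The synthetic study generator: structure, determinism, and statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonsci.annotation import write_gtf
from exonsci.read_processing import packaged_whitelist
from exonsci.synthetic import (DEFAULT_SUBTYPES, SimConfig, emit_truth,
                               generate_annotation, generate_cell_population,
                               make_embedding, simulate_reads, write_fasta)


def tiny_config(**kw):
    defaults = dict(n_genes=25, n_cells_per_replicate=30,
                    mean_molecules_per_cell=200.0, seed=5)
    defaults.update(kw)
    return SimConfig(**defaults)


class TestConfigValidation:
    def test_subtype_proportions_must_sum_to_one(self):
        bad = dict(DEFAULT_SUBTYPES)
        bad["OPC"] = (0.5, 0.25)
        with pytest.raises(ValueError, match="sum"):
            SimConfig(subtypes=bad)

    def test_fractions_bounded(self):
        with pytest.raises(ValueError, match="doublet_rate"):
            SimConfig(doublet_rate=1.5)

    def test_duplication_rate_is_mean_copies(self):
        with pytest.raises(ValueError, match="copy"):
            SimConfig(umi_duplication_rate=0.5)


class TestAnnotationGeneration:
    def test_single_gene_trivial_protein_length(self):
        # 1 gene, one ~300 bp coding exon -> protein length = cds/3
        cfg = tiny_config(n_genes=1, exons_per_gene=(2, 2),
                          exon_length=(150, 150), cds_fraction=1.0)
        db, seqs, _ = generate_annotation(cfg)
        (t,) = db.transcripts.values()
        assert t.cds_length == 300 and t.protein_length == 100

    def test_every_cds_length_divisible_by_three(self):
        cfg = tiny_config(n_genes=50)
        db, _, _ = generate_annotation(cfg)
        assert len(db.transcripts) == 50
        for t in db.transcripts.values():
            assert t.cds_length % 3 == 0 and t.cds_length > 0
            # CDS lies within exonic bases
            exonic = {b for s, e in t.exons for b in range(s, e)}
            for s, e in t.cds:
                assert set(range(s, e)) <= exonic

    def test_both_strands_and_exon_sorting(self):
        cfg = tiny_config(n_genes=20)
        db, _, _ = generate_annotation(cfg)
        strands = {g.strand for g in db.genes.values()}
        assert strands == {"+", "-"}
        for g in db.genes.values():
            merged = sorted(g.merged_exons)
            for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
                assert e1 < s2  # disjoint

    def test_domains_within_protein(self):
        cfg = tiny_config(n_genes=40)
        db, _, domains = generate_annotation(cfg)
        for row in domains.itertuples():
            plen = db.transcripts[row.transcript_id].protein_length
            assert 0 <= row.aa_start < row.aa_end <= plen

    def test_transcript_sequence_lengths_match(self):
        cfg = tiny_config(n_genes=10)
        db, seqs, _ = generate_annotation(cfg)
        for tid, t in db.transcripts.items():
            assert len(seqs[tid]) == sum(e - s for s, e in t.exons)

    def test_rejects_impossible_cds(self):
        with pytest.raises(ValueError, match="codon"):
            cfg = tiny_config(exon_length=(5, 6), cds_fraction=0.01,
                              exons_per_gene=(2, 2))
            generate_annotation(cfg)

    def test_same_seed_identical_gtf_bytes(self, tmp_path):
        for run in ("a", "b"):
            cfg = tiny_config(seed=7)
            db, seqs, _ = generate_annotation(cfg)
            write_gtf(db, tmp_path / f"{run}.gtf")
            write_fasta(seqs, tmp_path / f"{run}.fa")
        assert (tmp_path / "a.gtf").read_bytes() == (tmp_path / "b.gtf").read_bytes()
        assert (tmp_path / "a.fa").read_bytes() == (tmp_path / "b.fa").read_bytes()


class TestCellPopulation:
    def test_zero_doublet_rate(self):
        cfg = tiny_config(doublet_rate=0.0)
        db, _, _ = generate_annotation(cfg)
        cells, truth = generate_cell_population(cfg, db)
        assert not cells["is_doublet"].any()
        assert len(cells) == 6 * 30

    def test_singlet_count_arithmetic(self):
        cfg = tiny_config(n_cells_per_replicate=50)
        db, _, _ = generate_annotation(cfg)
        cells, _ = generate_cell_population(cfg, db)
        assert (~cells["is_doublet"]).sum() == 2 * 3 * 50

    def test_doublet_count_within_binomial_bounds(self):
        cfg = SimConfig(n_cells_per_replicate=500, seed=8)
        db, _, _ = generate_annotation(cfg)
        cells, _ = generate_cell_population(cfg, db)
        n = cells["is_doublet"].sum()
        lo, hi = stats.binom.ppf([0.005, 0.995], 3000, 0.06)
        assert lo <= n <= hi
        assert cells.loc[cells["is_doublet"], "subtype2"].notna().all()

    def test_cells_unique_and_barcodes_legal(self):
        cfg = tiny_config()
        db, _, _ = generate_annotation(cfg)
        cells, _ = generate_cell_population(cfg, db)
        assert cells["cell_id"].is_unique
        rt = set(packaged_whitelist("rt"))
        lig = set(packaged_whitelist("lig"))
        assert set(cells["rt_barcode"]) <= rt
        assert set(cells["lig_barcode"]) <= lig

    def test_truth_flags_consistent_with_draws(self):
        cfg = tiny_config(n_genes=60)
        db, _, _ = generate_annotation(cfg)
        _, truth = generate_cell_population(cfg, db)
        g = truth.genes
        assert (g["is_deg_true"] == (g["drawn_log2fc"] != 0)).all()
        n_expected = round(cfg.gene_de_fraction * 60)
        assert g["is_deg_true"].sum() == n_expected
        # exon effects are usage shifts: they never move the gene total
        np.testing.assert_allclose(g["realized_log2fc"], g["drawn_log2fc"],
                                   atol=1e-9)

    def test_zero_de_fraction_gives_no_degs(self):
        cfg = tiny_config(gene_de_fraction=0.0, n_splicing_factors=0)
        db, _, _ = generate_annotation(cfg)
        _, truth = generate_cell_population(cfg, db)
        assert truth.genes["is_deg_true"].sum() == 0

    def test_opposed_exons_flip_sign(self):
        cfg = tiny_config(n_genes=80, opposed_exon_fraction=0.3)
        db, _, _ = generate_annotation(cfg)
        _, truth = generate_cell_population(cfg, db)
        opposed = truth.exons[truth.exons["opposed"]]
        assert len(opposed) > 0
        parents = truth.genes.set_index("gene_id")["realized_log2fc"]
        for row in opposed.itertuples():
            assert np.sign(row.realized_log2fc) != np.sign(parents[row.gene_id])

    def test_truth_tsvs_written(self, tmp_path):
        cfg = tiny_config()
        db, _, _ = generate_annotation(cfg)
        _, truth = generate_cell_population(cfg, db)
        emit_truth(truth, tmp_path)
        for name in ("cells", "genes", "exons", "factors"):
            assert (tmp_path / f"truth_{name}.tsv").exists()


class TestReads:
    def _study(self, **kw):
        cfg = tiny_config(**kw)
        db, _, _ = generate_annotation(cfg)
        cells, truth = generate_cell_population(cfg, db)
        return cfg, db, cells, truth

    def test_no_duplication_reads_equal_molecules(self):
        cfg, db, cells, truth = self._study(umi_duplication_rate=1.0)
        reads = simulate_reads(cells, db, truth, cfg)
        assert len(reads) == reads["molecule_id"].nunique()

    def test_zero_error_rate_keeps_whitelisted_barcodes(self):
        cfg, db, cells, truth = self._study(barcode_error_rate=0.0)
        reads = simulate_reads(cells, db, truth, cfg)
        assert set(reads["rt_barcode"]) <= set(packaged_whitelist("rt"))
        assert set(reads["lig_barcode"]) <= set(packaged_whitelist("lig"))

    def test_intron_share_within_binomial_bounds(self):
        cfg, db, cells, truth = self._study(
            n_genes=5, n_cells_per_replicate=100,
            mean_molecules_per_cell=400.0,
            intron_fraction_default=0.5, intron_dynamic_fraction=0.0,
            gene_de_fraction=0.0, exon_de_fraction=0.0, n_splicing_factors=0)
        reads = simulate_reads(cells, db, truth, cfg)
        mols = reads.drop_duplicates("molecule_id")
        seg_kind = truth.segments["kind"].to_numpy()
        for gid in sorted(db.genes)[:3]:
            in_gene = truth.segments["gene_id"].to_numpy()[mols["seg_idx"]] == gid
            sub = mols[in_gene]
            n = len(sub)
            assert n > 1000
            k = (seg_kind[sub["seg_idx"]] == "intron").sum()
            lo, hi = stats.binom.ppf([0.005, 0.995], n, 0.5)
            assert lo <= k <= hi

    def test_reads_lie_within_their_segments(self):
        cfg, db, cells, truth = self._study()
        reads = simulate_reads(cells, db, truth, cfg)
        seg = truth.segments
        s = seg["start"].to_numpy()[reads["seg_idx"]]
        e = seg["end"].to_numpy()[reads["seg_idx"]]
        assert (reads["start"] >= s).all() and (reads["end"] <= e).all()
        assert (reads["end"] > reads["start"]).all()

    def test_nb_variance_at_least_mean(self):
        """Gamma-Poisson counts are overdispersed: pooled per-gene variance
        across >= 1,000 same-condition singlets is at least the mean."""
        cfg = SimConfig(n_cells_per_replicate=400, n_genes=40,
                        mean_molecules_per_cell=500.0, doublet_rate=0.0,
                        subtypes={"A": (1.0, 1.0)}, subtype_marker_genes=0,
                        seed=12)
        db, _, _ = generate_annotation(cfg)
        cells, truth = generate_cell_population(cfg, db)
        reads = simulate_reads(cells, db, truth, cfg)
        mols = reads.drop_duplicates("molecule_id")
        young = cells.index[cells["condition"] == "young"].to_numpy()
        counts = pd.crosstab(mols["cell_idx"], mols["seg_idx"])
        counts = counts.reindex(index=young, fill_value=0)
        assert len(counts) >= 1000
        mean = counts.mean(axis=0).to_numpy()
        var = counts.var(axis=0).to_numpy()
        big = mean > 1.0
        assert (var[big] > mean[big] * 0.9).all()
        # substantially overdispersed on average
        assert (var[big] / mean[big]).mean() > 1.2

    def test_same_seed_byte_identical_reads(self):
        frames = []
        for _ in range(2):
            cfg, db, cells, truth = self._study(seed=9)
            frames.append(simulate_reads(cells, db, truth, cfg))
        pd.testing.assert_frame_equal(frames[0], frames[1])

    def test_different_seeds_differ(self):
        _, db9, c9, t9 = self._study(seed=9)
        cfg9 = tiny_config(seed=9)
        cfg10 = tiny_config(seed=10)
        db10, _, _ = generate_annotation(cfg10)
        c10, t10 = generate_cell_population(cfg10, db10)
        r9 = simulate_reads(c9, db9, t9, cfg9)
        r10 = simulate_reads(c10, db10, t10, cfg10)
        assert not r9.equals(r10)


class TestEmbedding:
    def test_subtypes_form_separated_clusters(self):
        cfg = tiny_config(n_cells_per_replicate=100)
        db, _, _ = generate_annotation(cfg)
        cells, _ = generate_cell_population(cfg, db)
        emb = make_embedding(cells, cfg)
        merged = emb.merge(cells[["cell_id", "subtype", "is_doublet"]], on="cell_id")
        singlets = merged[~merged["is_doublet"]]
        centers = singlets.groupby("subtype")[["x", "y"]].mean()
        spread = singlets.groupby("subtype")[["x", "y"]].std().mean(axis=1)
        dists = []
        for a in centers.index:
            for b in centers.index:
                if a < b:
                    dists.append(np.linalg.norm(centers.loc[a] - centers.loc[b]))
        assert min(dists) > 2 * spread.max()
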