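"""Gene/exon assignment rules, count matrices, and intronic fractions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonsci.annotation import FeatureIndex
from exonsci.quantify import (AssignConfig, CountMatrix, assign_bulk,
                              assign_exon, assign_gene, build_matrices,
                              intronic_fraction_test)

from conftest import make_db, make_gene, make_molecule


@pytest.fixture
def two_gene_db():
    # A: + strand, exons (1000,1200),(1800,2000); 3' end at 1999
    # B: + strand far downstream; C: - strand overlapping A
    return make_db(
        make_gene("A", "chr1", "+", [(1000, 1200), (1800, 2000)]),
        make_gene("B", "chr1", "+", [(5000, 5400)]),
        make_gene("C", "chr1", "-", [(1900, 2100), (1100, 1300)]),
    )


class TestAssignGene:
    def test_direct_single_overlap(self, two_gene_db):
        idx = FeatureIndex(two_gene_db)
        mol = make_molecule(start=5100, end=5160)
        assert assign_gene(mol, idx, AssignConfig()) == ("B", "direct")

    def test_dt_ambiguity_goes_to_closest_three_prime_end(self):
        # genes overlap; A's 3' end is 200 bp from the molecule's 3'-most
        # base, B's is 1,500 bp away
        db = make_db(make_gene("A", "chr1", "+", [(0, 1300)]),
                     make_gene("B", "chr1", "+", [(900, 2600)]))
        idx = FeatureIndex(db)
        mol = make_molecule(start=1040, end=1100, primer="dT")
        # |1299 - 1099| = 200 vs |2599 - 1099| = 1500
        gene, klass = assign_gene(mol, idx, AssignConfig())
        assert (gene, klass) == ("A", "direct-3prime-tiebreak")

    def test_ambiguous_hexamer_discarded_unless_configured(self):
        db = make_db(make_gene("A", "chr1", "+", [(0, 1300)]),
                     make_gene("B", "chr1", "+", [(900, 2600)]))
        idx = FeatureIndex(db)
        mol = make_molecule(start=1040, end=1100, primer="hexamer")
        assert assign_gene(mol, idx, AssignConfig()) == (None, "ambiguous-discarded")
        cfg = AssignConfig(ambiguous_nondt_closest=True)
        assert assign_gene(mol, idx, cfg)[0] == "A"

    @pytest.mark.parametrize("gap,expect", [(0, "A"), (1000, "A"), (1001, None)])
    def test_upstream_rescue_boundary(self, gap, expect):
        # + strand molecule ending `gap` bp before the gene start
        db = make_db(make_gene("A", "chr1", "+", [(10_000, 11_000)]))
        idx = FeatureIndex(db)
        mol = make_molecule(start=10_000 - gap - 60, end=10_000 - gap)
        gene, klass = assign_gene(mol, idx, AssignConfig())
        assert gene == expect
        if expect:
            assert klass == "upstream-rescued"

    @pytest.mark.parametrize("gap,expect", [(1000, "A"), (1001, None)])
    def test_upstream_rescue_boundary_minus_strand(self, gap, expect):
        db = make_db(make_gene("A", "chr1", "-", [(10_000, 11_000)]))
        idx = FeatureIndex(db)
        mol = make_molecule(start=11_000 + gap, end=11_000 + gap + 60, strand="-")
        assert assign_gene(mol, idx, AssignConfig())[0] == expect

    def test_antisense_rescue(self, two_gene_db):
        idx = FeatureIndex(two_gene_db)
        # only C (- strand) covers 2050; read on + strand
        mol = make_molecule(start=2020, end=2080, strand="+")
        assert assign_gene(mol, idx, AssignConfig()) == ("C", "antisense-rescued")
        cfg = AssignConfig(antisense_rescue=False)
        assert assign_gene(mol, idx, cfg) == (None, "unassigned")

    def test_upstream_rescue_takes_precedence_over_antisense(self):
        db = make_db(make_gene("A", "chr1", "+", [(10_000, 11_000)]),
                     make_gene("C", "chr1", "-", [(9_000, 9_800)]))
        idx = FeatureIndex(db)
        mol = make_molecule(start=9_500, end=9_560)
        assert assign_gene(mol, idx, AssignConfig()) == ("A", "upstream-rescued")

    def test_bulk_agrees_with_per_molecule_api(self, small_study):
        sub = small_study["molecules"].head(3000).reset_index(drop=True)
        idx = FeatureIndex(small_study["db"])
        cfg = AssignConfig()
        bulk = assign_bulk(sub, small_study["db"], cfg)
        for i in range(0, len(sub), 17):
            row = sub.iloc[i]
            gene, klass = assign_gene(row, idx, cfg)
            assert bulk.loc[i, "gene_id"] == (gene if gene else None)
            assert bulk.loc[i, "assign_class"] == klass

    def test_naive_overlap_oracle_with_rescue_disabled(self, rng):
        """With rescue off and non-overlapping single-isoform genes,
        assignment reduces to plain interval overlap."""
        genes = [make_gene(f"g{i}", "chr1", "+", [(i * 3000, i * 3000 + 1500)])
                 for i in range(20)]
        db = make_db(*genes)
        idx = FeatureIndex(db)
        cfg = AssignConfig(upstream_window=0, antisense_rescue=False)
        for _ in range(300):
            s = int(rng.integers(0, 62_000))
            mol = make_molecule(start=s, end=s + 60)
            expected = [g.gene_id for g in genes
                        if g.start < s + 60 and g.end > s]
            got, _ = assign_gene(mol, idx, cfg)
            assert got == (expected[0] if len(expected) == 1 else None)


class TestAssignExon:
    def test_fully_inside_exon(self, two_gene_db):
        mol = make_molecule(start=1850, end=1910)
        assert assign_exon(mol, "A", two_gene_db) == "A:2"

    def test_fully_intronic_is_none(self, two_gene_db):
        mol = make_molecule(start=1400, end=1460)
        assert assign_exon(mol, "A", two_gene_db) is None

    def test_boundary_straddle_goes_to_larger_overlap(self, two_gene_db):
        # 40 bases in exon A:1 (ends 1200), 20 in the intron
        mol = make_molecule(start=1160, end=1220)
        assert assign_exon(mol, "A", two_gene_db) == "A:1"

    def test_two_exon_straddle_tiebreak(self):
        db = make_db(make_gene("G", "chr1", "+", [(0, 100), (130, 190)]))
        # 30 bases in each exon: overlap tie; the molecule's 3'-most base
        # (159) is nearer exon 2's 3' end (189) than exon 1's (99)
        mol = make_molecule(start=70, end=160, primer="dT")
        assert assign_exon(mol, "G", db) == "G:2"
        # hexamer molecules fall back to the lowest exon index
        mol = make_molecule(start=70, end=160, primer="hexamer")
        assert assign_exon(mol, "G", db) == "G:1"


class TestBuildMatrices:
    def test_gene_and_exon_totals(self, two_gene_db):
        mols = pd.DataFrame([
            make_molecule(read_id="m1", start=1100, end=1160, umi="AAAAAAAA").__dict__,
            make_molecule(read_id="m2", start=1850, end=1910, umi="CCCCCCCC").__dict__,
            make_molecule(read_id="m3", start=1400, end=1460, umi="GGGGGGGG").__dict__,
        ])
        assigned = assign_bulk(mols, two_gene_db)
        gm, em = build_matrices(assigned, two_gene_db)
        assert gm.X.sum() == 3          # intronic counted at gene level
        assert em.X.sum() == 2
        a_cols = [i for i, f in enumerate(em.feature_ids) if f.startswith("A:")]
        assert em.X[:, a_cols].sum() <= gm.X[:, gm.feature_ids.index("A")].sum()

    def test_exon_features_have_gene_parents(self, small_study):
        gm, em = small_study["gene_matrix"], small_study["exon_matrix"]
        parents = {f.rsplit(":", 1)[0] for f in em.feature_ids}
        assert parents <= set(gm.feature_ids)

    def test_duplicate_molecules_rejected(self, two_gene_db):
        mols = pd.DataFrame([make_molecule(read_id="a").__dict__,
                             make_molecule(read_id="b").__dict__])
        assigned = assign_bulk(mols, two_gene_db)
        with pytest.raises(ValueError, match="deduplicate"):
            build_matrices(assigned, two_gene_db)

    def test_empty_molecule_set(self, two_gene_db, tmp_path):
        empty = pd.DataFrame(columns=pd.Index(
            make_molecule().__dict__.keys()))
        assigned = assign_bulk(empty, two_gene_db)
        gm, em = build_matrices(assigned, two_gene_db)
        assert gm.X.shape[0] == 0 and em.X.shape[0] == 0
        gm.write_mtx(tmp_path, "gene_")
        back = CountMatrix.read_mtx(tmp_path, "gene_")
        assert back.X.shape == gm.X.shape

    def test_grand_total_matches_generator(self, small_study):
        gm = small_study["gene_matrix"]
        assigned = small_study["assigned"]
        assert gm.X.sum() == assigned["gene_id"].notna().sum()
        # every simulated molecule lies inside its gene: all direct
        assert (assigned["assign_class"] == "direct").all()

    def test_mtx_round_trip(self, small_study, tmp_path):
        gm = small_study["gene_matrix"]
        gm.write_mtx(tmp_path, "gene_")
        back = CountMatrix.read_mtx(tmp_path, "gene_")
        assert back.feature_ids == gm.feature_ids
        assert back.cell_ids == gm.cell_ids
        assert (back.X != gm.X).nnz == 0


class TestIntronicFraction:
    def _study(self, fractions_by_rep):
        """Build an assigned-molecule table realizing exact per-replicate
        intronic fractions for gene G."""
        rows = []
        rep_of_cell, grp_of_rep = {}, {}
        for rep, (group, frac, total) in fractions_by_rep.items():
            cell = f"rt{rep}lig0"
            rep_of_cell[cell] = rep
            grp_of_rep[rep] = group
            n_intron = int(round(frac * total))
            for i in range(total):
                rows.append({
                    "rt_barcode": f"rt{rep}", "lig_barcode": "lig0",
                    "gene_id": "G",
                    "exon_id": None if i < n_intron else "G:1",
                })
        return pd.DataFrame(rows), rep_of_cell, grp_of_rep

    def test_simple_fraction(self):
        assigned, rep_of, grp_of = self._study({"r1": ("young", 0.75, 4)})
        res = intronic_fraction_test(assigned, "G", rep_of, grp_of)
        assert res.fractions["r1"] == 0.75
        assert res.p_value is None  # a single replicate cannot be tested

    def test_group_difference_significant(self):
        spec = {"y1": ("young", 0.96, 100), "y2": ("young", 0.95, 100),
                "y3": ("young", 0.97, 100),
                "a1": ("aged", 0.77, 100), "a2": ("aged", 0.78, 100),
                "a3": ("aged", 0.76, 100)}
        assigned, rep_of, grp_of = self._study(spec)
        res = intronic_fraction_test(assigned, "G", rep_of, grp_of)
        # independent oracle: textbook pooled-variance two-sample t
        a = np.array([0.96, 0.95, 0.97])
        b = np.array([0.77, 0.78, 0.76])
        sp2 = ((a.var(ddof=1) + b.var(ddof=1)) / 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        p_oracle = 2 * stats.t.sf(abs(t), df=4)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert res.p_value < 0.001
        assert res.group_means["young"] == pytest.approx(0.96, abs=1e-9)

    def test_identical_groups_p_one(self):
        spec = {"y1": ("young", 0.5, 10), "y2": ("young", 0.5, 10),
                "a1": ("aged", 0.5, 10), "a2": ("aged", 0.5, 10)}
        assigned, rep_of, grp_of = self._study(spec)
        res = intronic_fraction_test(assigned, "G", rep_of, grp_of)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_molecule_replicate_excluded(self):
        spec = {"y1": ("young", 0.5, 10), "y2": ("young", 0.4, 10),
                "a1": ("aged", 0.2, 10), "a2": ("aged", 0.3, 10)}
        assigned, rep_of, grp_of = self._study(spec)
        grp_of["a3"] = "aged"  # a3 has no molecules of G
        res = intronic_fraction_test(assigned, "G", rep_of, grp_of)
        assert res.excluded_replicates == ["a3"]
        assert res.p_value is not None
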