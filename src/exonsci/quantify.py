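"""Molecule -> gene/exon assignment, count matrices, intronic read fractions.

Assignment rules:

1. direct: the molecule overlaps exactly one gene on its own strand;
2. ambiguous oligo-dT molecules (direct overlap with >1 gene) go to the gene
   whose annotated 3' end is nearest the molecule's 3'-most aligned base
   (ties broken lexicographically by gene id); ambiguous hexamer molecules are
   discarded by default;
3. molecules with no direct hit are rescued by the unique gene starting at
   most ``upstream_window`` bp downstream of the molecule on the same strand
   (the molecule sits upstream of the gene), then by the unique antisense
   overlap;
4. anything else is unassigned and dropped from the matrices.

Exon assignment runs within the assigned gene over its merged exon intervals;
a gene-assigned molecule overlapping no exon is intronic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pyranges as pr
import scipy.io
import scipy.sparse as sp
from scipy import stats

from .annotation import AnnotationDB, FeatureIndex

ASSIGN_CLASSES = (
    "direct", "direct-3prime-tiebreak", "upstream-rescued", "antisense-rescued",
    "ambiguous-discarded", "unassigned",
)


@dataclass
class AssignConfig:
    upstream_window: int = 1000
    antisense_rescue: bool = True
    # apply the closest-3'-end rule to hexamer molecules too (default: discard)
    ambiguous_nondt_closest: bool = False

    def __post_init__(self):
        if self.upstream_window < 0:
            raise ValueError("upstream_window must be >= 0")


def _three_prime_base(start: int, end: int, strand: str) -> int:
    """3'-most aligned base of a read/molecule (0-based)."""
    return end - 1 if strand == "+" else start


def assign_gene(molecule, index: FeatureIndex, config: AssignConfig
                ) -> tuple[str | None, str]:
    """Assign one molecule to a gene; returns (gene_id or None, class).

    ``molecule`` needs chrom/start/end/strand/primer_type attributes
    (a :class:`~exonsci.read_processing.ReadRecord` or a DataFrame row).
    """
    db = index.db
    chrom, start, end, strand = molecule.chrom, molecule.start, molecule.end, molecule.strand
    hits = index.query(chrom, start, end, strand)
    if len(hits) == 1:
        return hits[0], "direct"
    if len(hits) > 1:
        if molecule.primer_type == "dT" or config.ambiguous_nondt_closest:
            mol3 = _three_prime_base(start, end, strand)
            best = min(hits, key=lambda g: (abs(db.genes[g].three_prime_end - mol3), g))
            return best, "direct-3prime-tiebreak"
        return None, "ambiguous-discarded"

    # upstream rescue: gene begins within the window downstream of the
    # molecule (gap 0 = adjacent); window 0 disables the rescue
    w = config.upstream_window
    if w > 0:
        if strand == "+":
            window = index.query(chrom, end, end + w + 1, strand)
            cands = [g for g in window if 0 <= db.genes[g].start - end <= w]
        else:
            window = index.query(chrom, max(0, start - w - 1), start + 1, strand)
            cands = [g for g in window if 0 <= start - db.genes[g].end <= w]
        if len(cands) == 1:
            return cands[0], "upstream-rescued"

    if config.antisense_rescue:
        anti = index.query(chrom, start, end, "-" if strand == "+" else "+")
        if len(anti) == 1:
            return anti[0], "antisense-rescued"
    return None, "unassigned"


def assign_exon(molecule, gene_id: str, db: AnnotationDB) -> str | None:
    """Assign a gene-assigned molecule to one of the gene's merged exons.

    Greatest overlap wins; remaining ties go to the 3'-nearest exon for dT
    molecules and to the lowest exon index otherwise.  ``None`` marks an
    intronic molecule.
    """
    g = db.genes[gene_id]
    start, end = molecule.start, molecule.end
    best: tuple | None = None
    mol3 = _three_prime_base(start, end, g.strand)
    for i, (es, ee) in enumerate(g.merged_exons):
        ov = min(end, ee) - max(start, es)
        if ov <= 0:
            continue
        exon3 = _three_prime_base(es, ee, g.strand)
        tiebreak = abs(exon3 - mol3) if molecule.primer_type == "dT" else i
        key = (-ov, tiebreak, i)
        if best is None or key < best[0]:
            best = (key, g.exon_id(i))
    return None if best is None else best[1]


# ---------------------------------------------------------------------------
# bulk assignment (vectorized; same rules as the per-molecule API)
# ---------------------------------------------------------------------------

def _gene_frame(db: AnnotationDB) -> pd.DataFrame:
    rows = [
        (g.chrom, g.start, g.end, g.strand, g.gene_id, g.three_prime_end)
        for g in db.genes.values()
    ]
    return pd.DataFrame(rows, columns=[
        "Chromosome", "Start", "End", "Strand", "gene_id", "three_prime"])


def _exon_frame(db: AnnotationDB) -> pd.DataFrame:
    rows = []
    for g in db.genes.values():
        for i, (es, ee) in enumerate(g.merged_exons):
            rows.append((g.chrom, es, ee, g.strand, g.gene_id, g.exon_id(i), i,
                         _three_prime_base(es, ee, g.strand)))
    return pd.DataFrame(rows, columns=[
        "Chromosome", "Start", "End", "Strand", "gene_id", "exon_id",
        "exon_index", "exon3"])


def _mol_ranges(mols: pd.DataFrame, strand: pd.Series | np.ndarray) -> pr.PyRanges:
    return pr.PyRanges(pd.DataFrame({
        "Chromosome": mols["chrom"].to_numpy(),
        "Start": mols["start"].to_numpy(),
        "End": mols["end"].to_numpy(),
        "Strand": np.asarray(strand),
        "midx": mols.index.to_numpy(),
    }))


def assign_bulk(molecules: pd.DataFrame, db: AnnotationDB,
                config: AssignConfig | None = None) -> pd.DataFrame:
    """Vectorized gene+exon assignment for a molecule table.

    Returns ``molecules`` with added ``gene_id``, ``assign_class`` and
    ``exon_id`` columns (NA where unassigned / intronic).
    """
    config = config or AssignConfig()
    molecules = molecules.reset_index(drop=True)
    n = len(molecules)
    gene_id = np.full(n, None, dtype=object)
    klass = np.full(n, "unassigned", dtype=object)
    if n:
        genes_df = _gene_frame(db)
        gene_pr = pr.PyRanges(genes_df)
        mol3 = np.where(molecules["strand"].to_numpy() == "+",
                        molecules["end"].to_numpy() - 1,
                        molecules["start"].to_numpy())
        is_dt = molecules["primer_type"].to_numpy() == "dT"

        joined = _mol_ranges(molecules, molecules["strand"]).join(
            gene_pr, strandedness="same").df
        if len(joined):
            counts = joined.groupby("midx")["gene_id"].transform("size")
            single = joined[counts == 1]
            gene_id[single["midx"].to_numpy()] = single["gene_id"].to_numpy()
            klass[single["midx"].to_numpy()] = "direct"

            multi = joined[counts > 1].copy()
            if len(multi):
                multi["dist3"] = np.abs(
                    multi["three_prime"].to_numpy() - mol3[multi["midx"].to_numpy()])
                eligible = is_dt[multi["midx"].to_numpy()] | config.ambiguous_nondt_closest
                keep = multi[eligible].sort_values(["midx", "dist3", "gene_id"])
                best = keep.drop_duplicates("midx", keep="first")
                gene_id[best["midx"].to_numpy()] = best["gene_id"].to_numpy()
                klass[best["midx"].to_numpy()] = "direct-3prime-tiebreak"
                discarded = np.setdiff1d(multi["midx"].unique(),
                                         best["midx"].to_numpy())
                klass[discarded] = "ambiguous-discarded"

        # upstream rescue on the still-unassigned molecules
        todo = np.flatnonzero(klass == "unassigned")
        if len(todo) and config.upstream_window > 0:
            sub = molecules.iloc[todo]
            plus = sub["strand"].to_numpy() == "+"
            ws = np.where(plus, sub["end"].to_numpy(),
                          np.maximum(0, sub["start"].to_numpy() - config.upstream_window - 1))
            we = np.where(plus, sub["end"].to_numpy() + config.upstream_window + 1,
                          sub["start"].to_numpy() + 1)
            wpr = pr.PyRanges(pd.DataFrame({
                "Chromosome": sub["chrom"].to_numpy(), "Start": ws, "End": we,
                "Strand": sub["strand"].to_numpy(), "midx": todo}))
            upj = wpr.join(gene_pr, strandedness="same").df
            if len(upj):
                mplus = molecules["strand"].to_numpy()[upj["midx"].to_numpy()] == "+"
                gap = np.where(
                    mplus,
                    upj["Start_b"].to_numpy() - molecules["end"].to_numpy()[upj["midx"].to_numpy()],
                    molecules["start"].to_numpy()[upj["midx"].to_numpy()] - upj["End_b"].to_numpy(),
                )
                upj = upj[(gap >= 0) & (gap <= config.upstream_window)]
                sizes = upj.groupby("midx")["gene_id"].transform("size")
                uniq = upj[sizes == 1]
                gene_id[uniq["midx"].to_numpy()] = uniq["gene_id"].to_numpy()
                klass[uniq["midx"].to_numpy()] = "upstream-rescued"

        # antisense rescue
        todo = np.flatnonzero(klass == "unassigned")
        if len(todo) and config.antisense_rescue:
            sub = molecules.iloc[todo]
            flipped = np.where(sub["strand"].to_numpy() == "+", "-", "+")
            antij = _mol_ranges(sub.reset_index(drop=True).set_index(pd.Index(todo)),
                                flipped).join(gene_pr, strandedness="same").df
            if len(antij):
                sizes = antij.groupby("midx")["gene_id"].transform("size")
                uniq = antij[sizes == 1]
                gene_id[uniq["midx"].to_numpy()] = uniq["gene_id"].to_numpy()
                klass[uniq["midx"].to_numpy()] = "antisense-rescued"

    out = molecules.copy()
    out["gene_id"] = gene_id
    out["assign_class"] = klass
    out["exon_id"] = _assign_exons_bulk(out, db)
    return out


def _assign_exons_bulk(assigned: pd.DataFrame, db: AnnotationDB) -> np.ndarray:
    exon_id = np.full(len(assigned), None, dtype=object)
    has_gene = assigned["gene_id"].notna().to_numpy()
    if not has_gene.any():
        return exon_id
    sub = assigned[has_gene]
    exons_pr = pr.PyRanges(_exon_frame(db))
    # molecules inherit the assigned gene's strand for the exon join so that
    # antisense-rescued molecules still match their gene's exons
    gstrand = sub["gene_id"].map(lambda g: db.genes[g].strand).to_numpy()
    joined = _mol_ranges(sub, gstrand).join(exons_pr, strandedness="same").df
    if not len(joined):
        return exon_id
    mgene = assigned["gene_id"].to_numpy()
    joined = joined[joined["gene_id"].to_numpy() == mgene[joined["midx"].to_numpy()]]
    if not len(joined):
        return exon_id
    joined = joined.copy()
    joined["overlap"] = (
        np.minimum(joined["End"], joined["End_b"])
        - np.maximum(joined["Start"], joined["Start_b"]))
    mol3 = np.where(assigned["strand"].to_numpy() == "+",
                    assigned["end"].to_numpy() - 1, assigned["start"].to_numpy())
    is_dt = (assigned["primer_type"].to_numpy() == "dT")[joined["midx"].to_numpy()]
    joined["tiebreak"] = np.where(
        is_dt, np.abs(joined["exon3"].to_numpy() - mol3[joined["midx"].to_numpy()]),
        joined["exon_index"].to_numpy())
    best = (joined.sort_values(["midx", "overlap", "tiebreak", "exon_index"],
                               ascending=[True, False, True, True])
            .drop_duplicates("midx", keep="first"))
    exon_id[best["midx"].to_numpy()] = best["exon_id"].to_numpy()
    return exon_id


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Cells x features sparse counts (feature kind: gene or exon)."""

    cell_ids: list[str]
    feature_ids: list[str]
    kind: str  # "gene" | "exon"
    X: sp.csr_matrix

    def __post_init__(self):
        self.X = sp.csr_matrix(self.X)
        if self.X.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise ValueError("matrix shape does not match cell/feature ids")
        if self.X.nnz and (self.X.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def totals(self) -> np.ndarray:
        return np.asarray(self.X.sum(axis=1)).ravel()

    def subset_cells(self, cells: list[str]) -> "CountMatrix":
        pos = {c: i for i, c in enumerate(self.cell_ids)}
        idx = [pos[c] for c in cells]
        return CountMatrix(list(cells), list(self.feature_ids), self.kind,
                           self.X[idx])

    # -- MatrixMarket I/O ---------------------------------------------------

    def write_mtx(self, outdir, prefix: str = "") -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(str(outdir / f"{prefix}matrix.mtx"), self.X.astype(int))
        pd.DataFrame({"feature_id": self.feature_ids, "kind": self.kind}).to_csv(
            outdir / f"{prefix}features.tsv", sep="\t", index=False, header=False)
        pd.Series(self.cell_ids).to_csv(
            outdir / f"{prefix}barcodes.tsv", sep="\t", index=False, header=False)

    @classmethod
    def read_mtx(cls, outdir, prefix: str = "") -> "CountMatrix":
        import pathlib

        outdir = pathlib.Path(outdir)
        X = sp.csr_matrix(scipy.io.mmread(str(outdir / f"{prefix}matrix.mtx")))

        def read_tsv(name):
            path = outdir / name
            if path.stat().st_size == 0:
                return pd.DataFrame()
            return pd.read_csv(path, sep="\t", header=None)

        feats = read_tsv(f"{prefix}features.tsv")
        cells = read_tsv(f"{prefix}barcodes.tsv")
        kind = str(feats.iloc[0, 1]) if len(feats) else "gene"
        return cls(cells[0].astype(str).tolist() if len(cells) else [],
                   feats[0].astype(str).tolist() if len(feats) else [],
                   kind, X)


def build_matrices(assigned: pd.DataFrame, db: AnnotationDB,
                   cells: list[str] | None = None
                   ) -> tuple[CountMatrix, CountMatrix]:
    """Gene and exon count matrices from an assigned molecule table.

    Gene counts include intronic molecules; exon counts only exon-overlapping
    ones, so exon column sums never exceed the parent gene's counts.  Raises
    if the table still contains PCR duplicates (dedup contract).
    """
    from .read_processing import MOLECULE_KEY

    if len(assigned) and assigned.duplicated(subset=MOLECULE_KEY).any():
        raise ValueError("duplicate molecules: deduplicate() before counting")

    # cell identity = RT + ligation barcode; work on integer codes so large
    # molecule tables never materialize millions of concatenated strings
    if len(assigned):
        rt_codes, rt_cats = _codes(assigned["rt_barcode"])
        lig_codes, lig_cats = _codes(assigned["lig_barcode"])
        combo = rt_codes.astype(np.int64) * len(lig_cats) + lig_codes
        combo_id = np.array([str(rt_cats[c // len(lig_cats)])
                             + str(lig_cats[c % len(lig_cats)])
                             for c in np.unique(combo)])
        combo_sorted = np.unique(combo)
    else:
        combo = np.empty(0, dtype=np.int64)
        combo_id = np.empty(0, dtype=object)
        combo_sorted = combo
    if cells is None:
        cells = sorted(combo_id)
    cell_pos = {c: i for i, c in enumerate(cells)}
    # position of each molecule's cell in `cells` (-1 when absent)
    combo_to_row = np.array([cell_pos.get(cid, -1) for cid in combo_id],
                            dtype=np.int64)
    mol_row = combo_to_row[np.searchsorted(combo_sorted, combo)] \
        if len(combo) else combo

    gene_ids = sorted(db.genes)
    exon_ids = [eid for gid in gene_ids for eid in db.genes[gid].exon_ids]

    def counts(feature_col: pd.Series, feature_ids: list[str]) -> sp.csr_matrix:
        fpos = {f: i for i, f in enumerate(feature_ids)}
        mask = feature_col.notna().to_numpy() & (mol_row >= 0)
        rows = mol_row[mask]
        cols = feature_col[mask].map(fpos).to_numpy(dtype=int)
        return sp.coo_matrix(
            (np.ones(len(rows), dtype=np.int64), (rows, cols)),
            shape=(len(cells), len(feature_ids))).tocsr()

    if len(assigned):
        gmat = counts(assigned["gene_id"], gene_ids)
        emat = counts(assigned["exon_id"], exon_ids)
    else:
        gmat = sp.csr_matrix((len(cells), len(gene_ids)), dtype=np.int64)
        emat = sp.csr_matrix((len(cells), len(exon_ids)), dtype=np.int64)
    return (CountMatrix(list(cells), gene_ids, "gene", gmat),
            CountMatrix(list(cells), exon_ids, "exon", emat))


def _codes(col: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(col.dtype, pd.CategoricalDtype):
        return col.cat.codes.to_numpy(), col.cat.categories.to_numpy()
    codes, cats = pd.factorize(col)
    return codes, np.asarray(cats)


def assignment_summary(assigned: pd.DataFrame) -> pd.DataFrame:
    """Molecule counts per assignment class (conservation log)."""
    counts = assigned["assign_class"].value_counts().reindex(
        ASSIGN_CLASSES, fill_value=0)
    return pd.DataFrame({"assign_class": counts.index,
                         "n_molecules": counts.to_numpy()})


# ---------------------------------------------------------------------------
# intronic read fraction
# ---------------------------------------------------------------------------

@dataclass
class IntronFractionResult:
    gene_id: str
    fractions: dict[str, float]          # replicate -> intronic fraction
    group_means: dict[str, float]
    group_sems: dict[str, float]
    p_value: float | None
    excluded_replicates: list[str] = field(default_factory=list)


def intronic_fraction_test(assigned: pd.DataFrame, gene_id: str,
                           replicate_of_cell: dict[str, str],
                           group_of_replicate: dict[str, str]
                           ) -> IntronFractionResult:
    """Per-replicate intronic fractions for one gene and a two-sided t test.

    Intronic = gene-assigned with no exon assignment.  Replicates without any
    molecule of the gene are excluded; with fewer than two replicates left in
    either group the p value is undefined (``None``).
    """
    sub = assigned[assigned["gene_id"] == gene_id]
    cell = sub["rt_barcode"].astype(str) + sub["lig_barcode"].astype(str)
    rep = cell.map(replicate_of_cell)

    fractions: dict[str, float] = {}
    excluded: list[str] = []
    for r in group_of_replicate:
        m = sub[rep == r]
        if len(m) == 0:
            excluded.append(r)
            continue
        fractions[r] = float(m["exon_id"].isna().mean())

    groups: dict[str, list[float]] = {}
    for r, f in fractions.items():
        groups.setdefault(group_of_replicate[r], []).append(f)
    means = {g: float(np.mean(v)) for g, v in groups.items()}
    sems = {g: float(stats.sem(v)) if len(v) > 1 else float("nan")
            for g, v in groups.items()}

    p = None
    vals = list(groups.values())
    if len(vals) == 2 and all(len(v) >= 2 for v in vals):
        p = float(stats.ttest_ind(vals[0], vals[1]).pvalue)
        if not np.isfinite(p):
            # zero within-group variance: p degenerates to 1 (no difference)
            # or 0 (any difference)
            p = 1.0 if np.isclose(np.mean(vals[0]), np.mean(vals[1])) else 0.0
    return IntronFractionResult(gene_id, fractions, means, sems, p, excluded)
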