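"""Synthetic study generator: annotation, cell populations, ground truth, reads.

Emulates the statistical structure the downstream analysis assumes: two age
conditions x 3 replicates, several oligodendrocyte-like subtypes with
condition-dependent mixing (including an aged-expanded reactive-like
subtype), gene-level fold changes, exon-level changes decoupled from (and
sometimes opposed to) their parent genes, condition-dependent intronic read
fractions, ~6% doublets, single-substitution barcode errors, PCR/UMI
duplication, and a dT/hexamer primer mix.

The generative model is gamma-Poisson (negative binomial): per cell, segment
counts are NB with mean ``size_factor x lambda(segment, subtype, condition)``
where segments are the gene's merged exons plus its introns.  Gene- and
exon-level log2 fold changes are drawn first; ground truth records both the
drawn effects and the realized log2 ratios of expected intensities (the two
differ where exon effects or intron-fraction shifts redistribute a gene's
signal).  Doublets are sums of two independently drawn cells' molecules.
All randomness flows from a single seed; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationDB, Gene, Transcript
from .read_processing import packaged_whitelist

_BASES = np.array(list("ACGT"))

DOMAIN_NAME_POOL = (
    "protein_kinase_dom", "SH2_dom", "homeobox_dom", "lipocalin_like",
    "HSP70_dom", "zf_C2H2", "RRM_dom", "Ig_like_dom", "ankyrin_rpt",
    "EGF_like_dom", "PDZ_dom", "WD40_rpt",
)

DEFAULT_SUBTYPES: dict[str, tuple[float, float]] = {
    # name -> (proportion in young, proportion in aged); the reactive-like
    # subtype expands with age, intermediate precursors are depleted
    "OPC": (0.25, 0.25),
    "COP": (0.10, 0.04),
    "NFOL": (0.10, 0.04),
    "MFOL": (0.15, 0.07),
    "MOL2": (0.20, 0.20),
    "MOL56": (0.18, 0.20),
    "MOL_reactive": (0.02, 0.20),
}


@dataclass
class SimConfig:
    """Study design and effect sizes for the synthetic generator."""

    n_genes: int = 150
    exons_per_gene: tuple[int, int] = (2, 6)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (200, 1500)
    cds_fraction: float = 0.6
    n_cells_per_replicate: int = 500
    replicates_per_condition: int = 3
    conditions: tuple[str, str] = ("young", "aged")
    subtypes: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPES))
    # condition effects
    gene_de_fraction: float = 0.25
    gene_log2fc: tuple[float, float] = (0.5, 2.0)       # |effect| range
    exon_de_fraction: float = 0.15
    exon_log2fc: tuple[float, float] = (0.5, 2.0)
    opposed_exon_fraction: float = 0.2                   # of exon effects
    # intronic reads
    intron_fraction_default: float = 0.25
    intron_dynamic_fraction: float = 0.1
    intron_fraction_dynamic: tuple[float, float] = (0.95, 0.77)  # young, aged
    # library structure
    doublet_rate: float = 0.06
    barcode_error_rate: float = 0.02
    umi_duplication_rate: float = 1.3    # mean PCR copies per molecule
    dt_primer_fraction: float = 0.5
    dispersion: float = 0.2
    mean_molecules_per_cell: float = 1200.0
    depth_sigma: float = 0.35
    umi_length: int = 8
    read_length: int = 60
    # subtype identity and splicing-factor structure
    subtype_marker_genes: int = 10
    subtype_marker_log2fc: float = 2.0
    n_splicing_factors: int = 2
    clip_target_fraction: float = 0.25
    clip_target_enrichment_odds: float = 4.0
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name in ("cds_fraction", "gene_de_fraction", "exon_de_fraction",
                     "opposed_exon_fraction", "intron_fraction_default",
                     "intron_dynamic_fraction", "doublet_rate",
                     "barcode_error_rate", "dt_primer_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        for name in ("exon_length", "intron_length"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be a positive range")
        if self.exons_per_gene[0] < 2:
            raise ValueError("genes need >= 2 exons so intron fractions are meaningful")
        if self.umi_duplication_rate < 1:
            raise ValueError("umi_duplication_rate is a mean copy count, >= 1")
        for c in range(2):
            tot = sum(p[c] for p in self.subtypes.values())
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(
                    f"subtype proportions for {self.conditions[c]} sum to {tot}, not 1")

    @property
    def samples(self) -> list[str]:
        return [f"{c}_r{r + 1}" for c in self.conditions
                for r in range(self.replicates_per_condition)]

    def condition_of_sample(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}

    def rng(self, stage: int) -> np.random.Generator:
        """Stage-fanned generator so stages are individually reproducible."""
        return np.random.default_rng([self.seed, stage])


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(config: SimConfig
                        ) -> tuple[AnnotationDB, dict[str, str], pd.DataFrame]:
    """Gene models (one transcript per gene), transcript FASTA sequences, and
    a per-transcript protein-domain table.

    Genes alternate strands over two chromosomes with intergenic gaps; CDS is
    a contiguous in-frame block of the spliced transcript (length divisible
    by 3); each transcript gets 0-3 domain intervals within protein length.
    """
    rng = config.rng(1)
    genes: dict[str, Gene] = {}
    seqs: dict[str, str] = {}
    dom_rows = []

    cursors = {"chr1": 10_000, "chr2": 10_000}
    for gi in range(config.n_genes):
        gid = f"G{gi + 1:04d}"
        tid = gid + ".t1"
        chrom = "chr1" if gi % 2 == 0 else "chr2"
        strand = "+" if (gi // 2) % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1,
                                 size=n_exons)
        intron_lens = rng.integers(config.intron_length[0],
                                   config.intron_length[1] + 1, size=n_exons - 1)
        start = cursors[chrom]
        exons_genomic = []
        pos = start
        for j in range(n_exons):
            exons_genomic.append((pos, pos + int(exon_lens[j])))
            pos += int(exon_lens[j])
            if j < n_exons - 1:
                pos += int(intron_lens[j])
        end = pos
        cursors[chrom] = end + int(rng.integers(5000, 10_000))

        # transcription order
        tx_exons = exons_genomic if strand == "+" else exons_genomic[::-1]
        L = int(exon_lens.sum())
        cds_len = 3 * int(config.cds_fraction * L // 3)
        if cds_len < 3:
            raise ValueError(
                f"cds_fraction {config.cds_fraction} leaves no room for a codon "
                f"in a {L} nt transcript")
        cds_off = int(rng.integers(0, L - cds_len + 1))
        cds_genomic = _transcript_to_genomic(tx_exons, strand, cds_off,
                                             cds_off + cds_len)

        t = Transcript(tid, gid, chrom, strand, exons=tx_exons, cds=cds_genomic)
        g = Gene(gid, chrom, strand, start, end)
        g.transcripts.append(t)
        genes[gid] = g

        seqs[tid] = "".join(_BASES[rng.integers(0, 4, size=L)])

        plen = cds_len // 3
        for _ in range(int(rng.integers(0, 4))):
            dlen = int(rng.integers(10, max(11, plen // 3 + 1)))
            dlen = min(dlen, plen)
            dstart = int(rng.integers(0, plen - dlen + 1))
            dom_rows.append((tid, str(rng.choice(DOMAIN_NAME_POOL)),
                             dstart, dstart + dlen))

    domains = pd.DataFrame(dom_rows, columns=[
        "transcript_id", "domain_name", "aa_start", "aa_end"])
    return AnnotationDB(genes), seqs, domains


def _transcript_to_genomic(tx_exons, strand, lo, hi):
    """Map a transcript-coordinate interval to genomic segments, in
    transcription order."""
    out = []
    cum = 0
    for s, e in tx_exons:
        n = e - s
        a, b = max(lo, cum), min(hi, cum + n)
        if a < b:
            if strand == "+":
                out.append((s + (a - cum), s + (b - cum)))
            else:
                out.append((e - (b - cum), e - (a - cum)))
        cum += n
    return out


def write_fasta(seqs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# ground truth containers
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Machine-readable truth for parameter-recovery tests."""

    cells: pd.DataFrame       # cell_id, sample, condition, replicate, subtype, subtype2, is_doublet
    genes: pd.DataFrame       # gene_id, drawn/realized log2FC, DEG flag, intron fractions
    exons: pd.DataFrame       # exon_id, gene_id, drawn/realized log2FC, DEE/opposed flags
    factors: pd.DataFrame     # factor_id, target_gene_id
    # segment intensity model used by simulate_reads
    segments: pd.DataFrame = field(repr=False, default=None)
    lam: dict[tuple[str, str], np.ndarray] = field(repr=False, default_factory=dict)

    def write(self, outdir) -> None:
        import pathlib

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(outdir / "truth_cells.tsv", sep="\t", index=False)
        self.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        self.exons.to_csv(outdir / "truth_exons.tsv", sep="\t", index=False)
        self.factors.to_csv(outdir / "truth_factors.tsv", sep="\t", index=False)


def emit_truth(truth: GroundTruth, outdir) -> None:
    """Write the ground-truth tables as TSVs."""
    truth.write(outdir)


# ---------------------------------------------------------------------------
# cell population and expression model
# ---------------------------------------------------------------------------

def generate_cell_population(config: SimConfig, db: AnnotationDB
                             ) -> tuple[pd.DataFrame, GroundTruth]:
    """Cells with sample/condition/subtype labels plus the full ground truth.

    Builds the segment intensity model lambda(segment, subtype, condition)
    that simulate_reads draws from; doublet cells are flagged and carry the
    partner subtype.
    """
    rng = config.rng(2)
    gene_ids = sorted(db.genes)
    n_genes = len(gene_ids)
    young, aged = config.conditions

    # -- per-gene baseline and condition effects ---------------------------
    w = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    w = w / w.sum()

    drawn_glfc = np.zeros(n_genes)
    n_deg = int(round(config.gene_de_fraction * n_genes))
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    mags = rng.uniform(*config.gene_log2fc, size=n_deg)
    signs = rng.choice([-1.0, 1.0], size=n_deg)
    drawn_glfc[deg_idx] = mags * signs

    # splicing factors: forced clearly-upregulated DEGs (|log2FC| >= 1)
    factor_idx = rng.choice(deg_idx, size=min(config.n_splicing_factors, n_deg),
                            replace=False)
    drawn_glfc[factor_idx] = np.maximum(np.abs(drawn_glfc[factor_idx]), 1.0)

    # intron fractions per gene per condition
    if_young = np.full(n_genes, config.intron_fraction_default)
    if_aged = np.full(n_genes, config.intron_fraction_default)
    n_dyn = int(round(config.intron_dynamic_fraction * n_genes))
    dyn_idx = rng.choice(n_genes, size=n_dyn, replace=False)
    if_young[dyn_idx] = config.intron_fraction_dynamic[0]
    if_aged[dyn_idx] = config.intron_fraction_dynamic[1]

    # -- per-exon weights and effects --------------------------------------
    exon_rows = []
    for gi, gid in enumerate(gene_ids):
        g = db.genes[gid]
        k = len(g.merged_exons)
        ew = rng.uniform(0.5, 1.5, size=k)
        ew = ew / ew.sum()
        for j in range(k):
            exon_rows.append((g.exon_id(j), gid, gi, j, ew[j]))
    exons = pd.DataFrame(exon_rows, columns=[
        "exon_id", "gene_id", "gene_idx", "exon_index", "weight"])
    n_exons = len(exons)

    drawn_elfc = np.zeros(n_exons)
    opposed = np.zeros(n_exons, dtype=bool)
    n_dee = int(round(config.exon_de_fraction * n_exons))
    dee_pos = rng.choice(n_exons, size=n_dee, replace=False)
    emags = rng.uniform(*config.exon_log2fc, size=n_dee)
    esigns = rng.choice([-1.0, 1.0], size=n_dee)
    drawn_elfc[dee_pos] = emags * esigns

    # Every exon effect is a usage (isoform) shift: the affected exon's share
    # moves while its sibling exons rescale so the gene's exonic total - and
    # therefore its realized gene-level fold change - is exactly the drawn
    # gene effect.  Exon dynamics are thus fully decoupled from gene
    # dynamics.  Opposed exons additionally pick their usage shift so the
    # exon's total change flips the sign of a DE parent gene's change;
    # intron-dynamic genes are excluded from the opposed pool so opposition
    # is not confounded with unspliced-fraction shifts.
    parent_lfc = drawn_glfc[exons["gene_idx"].to_numpy()]
    weights = exons["weight"].to_numpy()
    gene_idx_of_exon = exons["gene_idx"].to_numpy()

    n_opp = int(round(config.opposed_exon_fraction * n_dee))
    pool = [i for i in dee_pos
            if parent_lfc[i] != 0 and gene_idx_of_exon[i] not in set(dyn_idx)]
    by_gene: dict[int, int] = {}
    for i in sorted(pool, key=lambda i: (gene_idx_of_exon[i], weights[i])):
        by_gene.setdefault(gene_idx_of_exon[i], i)
    n_done = 0
    for gi, o in sorted(by_gene.items()):
        if n_done == n_opp:
            break
        glfc = parent_lfc[o]
        u = emags[n_done % len(emags)]
        if glfc < 0:
            # exon goes up by u overall; cap so siblings can absorb it
            u_max = -np.log2(weights[o]) + glfc
            u = min(u, 0.9 * u_max)
            if u < 0.3:
                continue
            drawn_elfc[o] = -glfc + u
        else:
            drawn_elfc[o] = -glfc - u
        opposed[o] = True
        n_done += 1

    comp = np.ones(n_exons)  # sibling compensation multiplier (aged)
    effect = drawn_elfc != 0
    for gi in np.unique(gene_idx_of_exon[effect]):
        in_gene = gene_idx_of_exon == gi
        eff = in_gene & effect
        non = in_gene & ~effect
        if not non.any():
            # a sibling must remain to absorb the shift: drop one effect
            drop = np.flatnonzero(eff)[-1]
            if opposed[drop]:
                drop = np.flatnonzero(eff)[0]
            drawn_elfc[drop] = 0.0
            opposed[drop] = False
            effect[drop] = False
            eff[drop] = False
            non[drop] = True
        # cap upward shifts so the effect exons never exceed the gene budget
        budget = 0.9
        used = 0.0
        order = sorted(np.flatnonzero(eff), key=lambda i: (not opposed[i], i))
        for i in order:
            m = 2.0 ** drawn_elfc[i]
            if used + weights[i] * m > budget:
                m_cap = (budget - used) / weights[i]
                if m_cap < 2.0 ** 0.3 or m_cap <= 0:
                    drawn_elfc[i] = 0.0
                    opposed[i] = False
                    effect[i] = False
                    non[i] = True
                    continue
                m = min(m, m_cap)
                drawn_elfc[i] = np.log2(m)
            used += weights[i] * m
        if not (effect & in_gene).any():
            continue
        comp[non] = (1.0 - used) / weights[non].sum()

    # -- subtype marker multipliers ----------------------------------------
    subtype_names = list(config.subtypes)
    marker_mult = {s: np.ones(n_genes) for s in subtype_names}
    for s in subtype_names:
        midx = rng.choice(n_genes, size=min(config.subtype_marker_genes, n_genes),
                          replace=False)
        marker_mult[s][midx] = 2.0 ** config.subtype_marker_log2fc

    # -- segment table and intensities -------------------------------------
    seg_rows = []
    for gi, gid in enumerate(gene_ids):
        g = db.genes[gid]
        for j, (es, ee) in enumerate(g.merged_exons):
            seg_rows.append((gid, gi, "exon", g.exon_id(j), j, g.chrom, es, ee,
                             g.strand))
        introns = _intron_intervals(g)
        for j, (s, e) in enumerate(introns):
            seg_rows.append((gid, gi, "intron", None, j, g.chrom, s, e, g.strand))
    segments = pd.DataFrame(seg_rows, columns=[
        "gene_id", "gene_idx", "kind", "exon_id", "seg_index", "chrom",
        "start", "end", "strand"])

    lam: dict[tuple[str, str], np.ndarray] = {}
    gidx = segments["gene_idx"].to_numpy()
    is_exon = (segments["kind"] == "exon").to_numpy()
    exw = np.zeros(len(segments))
    exw[is_exon] = exons["weight"].to_numpy()  # same construction order
    seg_len = (segments["end"] - segments["start"]).to_numpy().astype(float)
    # intron length weights within each gene
    intron_w = np.zeros(len(segments))
    intr = ~is_exon
    intron_totals = pd.Series(seg_len[intr]).groupby(gidx[intr]).transform("sum").to_numpy()
    intron_w[intr] = seg_len[intr] / intron_totals

    aged_exon_mult = (2.0 ** drawn_elfc) * comp
    for cond, ifrac, a in ((young, if_young, 0.0), (aged, if_aged, 1.0)):
        cond_gene = 2.0 ** (drawn_glfc * a)
        exon_mult = np.ones(len(segments))
        exon_mult[is_exon] = aged_exon_mult if a == 1.0 else 1.0
        for s in subtype_names:
            base = w * marker_mult[s] * cond_gene
            lam_vec = np.where(
                is_exon,
                base[gidx] * (1 - ifrac[gidx]) * exw * exon_mult,
                base[gidx] * ifrac[gidx] * intron_w)
            lam[(s, cond)] = lam_vec

    # -- realized truth ----------------------------------------------------
    # per-unit intensities for a baseline subtype (multipliers cancel in FCs)
    s0 = subtype_names[0]
    lam_y, lam_a = lam[(s0, young)], lam[(s0, aged)]
    gene_tot_y = pd.Series(lam_y).groupby(gidx).sum().to_numpy()
    gene_tot_a = pd.Series(lam_a).groupby(gidx).sum().to_numpy()
    realized_glfc = np.log2(gene_tot_a / gene_tot_y)
    realized_if_y = 1 - pd.Series(lam_y[is_exon]).groupby(gidx[is_exon]).sum().to_numpy() / gene_tot_y
    realized_if_a = 1 - pd.Series(lam_a[is_exon]).groupby(gidx[is_exon]).sum().to_numpy() / gene_tot_a
    realized_elfc = np.log2(lam_a[is_exon] / lam_y[is_exon])

    # measurable (CPM-scale) fold change: the intensity ratio minus the
    # library-composition shift a CPM-normalized estimator is subject to
    shift = np.log2(gene_tot_a.sum() / gene_tot_y.sum())
    genes_truth = pd.DataFrame({
        "gene_id": gene_ids,
        "base_weight": w,
        "drawn_log2fc": drawn_glfc,
        "realized_log2fc": realized_glfc,
        "cpm_log2fc": realized_glfc - shift,
        "is_deg_true": drawn_glfc != 0,
        "intron_fraction_young": realized_if_y,
        "intron_fraction_aged": realized_if_a,
        "intron_dynamic": np.isin(np.arange(n_genes), dyn_idx),
        "is_splicing_factor": np.isin(np.arange(n_genes), factor_idx),
    })
    exons_truth = exons.drop(columns=["gene_idx"]).assign(
        drawn_log2fc=drawn_elfc,
        realized_log2fc=realized_elfc,
        is_dee_true=np.abs(realized_elfc) > 1e-9,
        opposed=opposed,
    )

    # -- CLIP targets -------------------------------------------------------
    has_exon_effect = exons.assign(hit=drawn_elfc != 0).groupby("gene_id")["hit"].any()
    p0 = config.clip_target_fraction
    odds = config.clip_target_enrichment_odds
    p1 = odds * p0 / (1 - p0 + odds * p0)
    factor_rows = []
    for fi in sorted(factor_idx):
        fid = gene_ids[fi]
        for gid in gene_ids:
            p = p1 if has_exon_effect.get(gid, False) else p0
            if rng.random() < p:
                factor_rows.append((fid, gid))
    factors = pd.DataFrame(factor_rows, columns=["factor_id", "target_gene_id"])

    # -- cells --------------------------------------------------------------
    cells = _assign_cells(config, rng, subtype_names)

    truth = GroundTruth(cells=cells, genes=genes_truth, exons=exons_truth,
                        factors=factors, segments=segments, lam=lam)
    return cells, truth


def _intron_intervals(g: Gene) -> list[tuple[int, int]]:
    ex = sorted(g.merged_exons)
    return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)
            if ex[i + 1][0] > ex[i][1]]


def _assign_cells(config: SimConfig, rng: np.random.Generator,
                  subtype_names: list[str]) -> pd.DataFrame:
    rt_wl = packaged_whitelist("rt")
    lig_wl = packaged_whitelist("lig")
    samples = config.samples
    chunk = len(rt_wl) // len(samples)
    if chunk == 0:
        raise ValueError("more samples than RT barcodes")
    cond_of = config.condition_of_sample()
    young = config.conditions[0]
    props = {c: np.array([config.subtypes[s][i] for s in subtype_names])
             for i, c in enumerate(config.conditions)}

    rows = []
    for si, sample in enumerate(samples):
        cond = cond_of[sample]
        n_singlet = config.n_cells_per_replicate
        n_doublet = int(rng.binomial(n_singlet, config.doublet_rate))
        n_total = n_singlet + n_doublet
        rts = rt_wl[si * chunk:(si + 1) * chunk]
        combos = rng.choice(chunk * len(lig_wl), size=n_total, replace=False)
        sub1 = rng.choice(subtype_names, size=n_total, p=props[cond])
        sub2 = rng.choice(subtype_names, size=n_total, p=props[cond])
        for i in range(n_total):
            rt = rts[combos[i] // len(lig_wl)]
            lig = lig_wl[combos[i] % len(lig_wl)]
            dbl = i >= n_singlet
            rows.append((rt + lig, rt, lig, sample, cond,
                         sample.rsplit("_", 1)[1], sub1[i],
                         sub2[i] if dbl else None, dbl))
    return pd.DataFrame(rows, columns=[
        "cell_id", "rt_barcode", "lig_barcode", "sample", "condition",
        "replicate", "subtype", "subtype2", "is_doublet"])


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def simulate_reads(cells: pd.DataFrame, db: AnnotationDB, truth: GroundTruth,
                   config: SimConfig) -> pd.DataFrame:
    """Aligned-read table for the cell population (SAM-compatible columns).

    Per cell, segment molecule counts are NB draws from the intensity model;
    each molecule gets a position within its segment, a UMI, the cell's
    barcodes, a tagmentation site (its fragment 5' cut) and a primer label;
    PCR duplicates replicate all molecule fields; barcode errors substitute
    exactly one position of the combined barcode.  Reads are returned shuffled.
    """
    rng = config.rng(3)
    seg = truth.segments
    n_seg = len(seg)
    n_cells = len(cells)

    # size factors (molecule depth); doublets sum two independent profiles
    mu_log = np.log(config.mean_molecules_per_cell) - config.depth_sigma ** 2 / 2
    # Overdispersion acts at the gene level (transcriptional bursting): each
    # cell x gene draws one gamma multiplier shared by the gene's segments,
    # so per-segment marginals are NB(mu, dispersion) while the exon/intron
    # split of a gene's molecules stays exactly multinomial.
    counts = np.zeros((n_cells, n_seg), dtype=np.int64)
    gene_of_seg = seg["gene_idx"].to_numpy()
    n_genes = gene_of_seg.max() + 1
    shape = 1.0 / config.dispersion
    for pass_i, subtype_col in enumerate([cells["subtype"], cells["subtype2"]]):
        active = np.ones(n_cells, dtype=bool) if pass_i == 0 \
            else cells["is_doublet"].to_numpy()
        if not active.any():
            continue
        n_active = int(active.sum())
        sf = rng.lognormal(mu_log, config.depth_sigma, size=n_active)
        lam_rows = np.empty((n_active, n_seg))
        subs = subtype_col.to_numpy()[active]
        conds = cells["condition"].to_numpy()[active]
        for key, vec in truth.lam.items():
            m = (subs == key[0]) & (conds == key[1])
            if m.any():
                lam_rows[m] = vec
        burst = rng.gamma(shape, config.dispersion, size=(n_active, n_genes))
        mu = sf[:, None] * lam_rows * burst[:, gene_of_seg]
        counts[active] += rng.poisson(mu)

    # expand to molecules
    cell_idx = np.repeat(np.arange(n_cells)[:, None], n_seg, axis=1)
    seg_idx = np.repeat(np.arange(n_seg)[None, :], n_cells, axis=0)
    flat = counts.ravel()
    nz = flat > 0
    mol_cell = np.repeat(cell_idx.ravel()[nz], flat[nz])
    mol_seg = np.repeat(seg_idx.ravel()[nz], flat[nz])
    n_mol = len(mol_cell)

    seg_start = seg["start"].to_numpy()[mol_seg]
    seg_end = seg["end"].to_numpy()[mol_seg]
    span = np.maximum(seg_end - seg_start - config.read_length, 0)
    offset = (rng.random(n_mol) * (span + 1)).astype(np.int64)
    start = seg_start + offset
    end = np.minimum(start + config.read_length, seg_end)

    strand = seg["strand"].to_numpy()[mol_seg]
    chrom = seg["chrom"].to_numpy()[mol_seg]
    # UMIs as 2-bit-packed integers; the SAM writer renders them as ACGT
    umi = rng.integers(0, 4 ** config.umi_length, size=n_mol, dtype=np.int64)
    primer = np.where(rng.random(n_mol) < config.dt_primer_fraction,
                      "dT", "hexamer")
    tag_pos = np.where(strand == "+", start, end)

    molecules = pd.DataFrame({
        "molecule_id": np.arange(n_mol, dtype=np.int64),
        "cell_idx": mol_cell,
        "seg_idx": mol_seg,
        "chrom": pd.Categorical(chrom),
        "start": start,
        "end": end,
        "strand": pd.Categorical(strand),
        "umi": umi,
        "primer_type": pd.Categorical(primer),
        "tag_pos": tag_pos,
    })

    # PCR duplication
    copies = 1 + rng.poisson(config.umi_duplication_rate - 1.0, size=n_mol)
    reads = molecules.loc[molecules.index.repeat(copies)].reset_index(drop=True)
    n_reads = len(reads)
    reads["read_id"] = np.arange(n_reads, dtype=np.int64)
    reads["rt_barcode"] = cells["rt_barcode"].to_numpy()[reads["cell_idx"]]
    reads["lig_barcode"] = cells["lig_barcode"].to_numpy()[reads["cell_idx"]]
    reads["tag_chrom"] = reads["chrom"]
    reads["tag_strand"] = reads["strand"]

    # barcode errors: exactly one substitution in the combined barcode
    err = np.flatnonzero(rng.random(n_reads) < config.barcode_error_rate)
    if len(err):
        rt_len = len(reads["rt_barcode"].iloc[0])
        lig_len = len(reads["lig_barcode"].iloc[0])
        pos = rng.integers(0, rt_len + lig_len, size=len(err))
        subs = rng.integers(1, 4, size=len(err))  # shift to a different base
        rt = reads["rt_barcode"].to_numpy(dtype=object)
        lig = reads["lig_barcode"].to_numpy(dtype=object)
        base_ord = {b: i for i, b in enumerate("ACGT")}
        for i, p, sh in zip(err, pos, subs):
            if p < rt_len:
                s = rt[i]
                new = "ACGT"[(base_ord[s[p]] + sh) % 4]
                rt[i] = s[:p] + new + s[p + 1:]
            else:
                q = p - rt_len
                s = lig[i]
                new = "ACGT"[(base_ord[s[q]] + sh) % 4]
                lig[i] = s[:q] + new + s[q + 1:]
        reads["rt_barcode"] = rt
        reads["lig_barcode"] = lig

    order = rng.permutation(n_reads)
    reads = reads.iloc[order].reset_index(drop=True)
    cols = ["read_id", "chrom", "start", "end", "strand", "rt_barcode",
            "lig_barcode", "umi", "primer_type", "tag_chrom", "tag_pos",
            "tag_strand", "molecule_id", "cell_idx", "seg_idx"]
    return reads[cols]


def make_embedding(cells: pd.DataFrame, config: SimConfig,
                   noise_sd: float = 1.0, radius: float = 8.0) -> pd.DataFrame:
    """Synthetic 2-D embedding: subtype centers on a circle plus Gaussian
    noise; doublets sit midway between their two subtype centers."""
    rng = config.rng(4)
    names = list(config.subtypes)
    angles = 2 * np.pi * np.arange(len(names)) / len(names)
    centers = {s: np.array([radius * np.cos(a), radius * np.sin(a)])
               for s, a in zip(names, angles)}
    xy = np.vstack([centers[s] for s in cells["subtype"]]).astype(float)
    dbl = cells["is_doublet"].to_numpy()
    if dbl.any():
        xy2 = np.vstack([centers[s] for s in cells.loc[dbl, "subtype2"]])
        xy[dbl] = (xy[dbl] + xy2) / 2
    xy += rng.normal(0, noise_sd, size=xy.shape)
    return pd.DataFrame({"cell_id": cells["cell_id"], "x": xy[:, 0], "y": xy[:, 1]})
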