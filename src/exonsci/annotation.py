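"""Gene models, interval indexing, and genome -> CDS -> protein coordinate maps.

Internal coordinates are 0-based half-open throughout; GTF I/O converts to and
from the 1-based inclusive convention at the file boundary.  Exon features are
gene-level: the union of the gene's transcript exons is merged into disjoint
intervals and numbered ``gene:1``, ``gene:2``, ... in transcription order
(5' -> 3' on the gene's strand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

GTF_COLUMNS = (
    "seqname", "source", "feature", "start", "end",
    "score", "strand", "frame", "attribute",
)


class GtfParseError(ValueError):
    """Malformed GTF input; carries the offending line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    # exons / cds in transcription order, 0-based half-open genomic intervals
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def in_frame(self) -> bool:
        """Coding and with total CDS length divisible by 3."""
        n = self.cds_length
        return n > 0 and n % 3 == 0

    @property
    def protein_length(self) -> int:
        return self.cds_length // 3


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)
    # merged exonic intervals in transcription order; ids "<gene_id>:<i>" (1-based)
    merged_exons: list[tuple[int, int]] = field(default_factory=list)

    @property
    def three_prime_end(self) -> int:
        """Genomic position of the annotated 3' end (last transcribed base +/- strand)."""
        return self.end - 1 if self.strand == "+" else self.start

    def exon_id(self, i: int) -> str:
        return f"{self.gene_id}:{i + 1}"

    @property
    def exon_ids(self) -> list[str]:
        return [self.exon_id(i) for i in range(len(self.merged_exons))]


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals; returns sorted disjoint list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivs):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


class AnnotationDB:
    """Genes, transcripts and gene-level merged exons with an interval index."""

    def __init__(self, genes: dict[str, Gene]):
        self.genes = genes
        self.transcripts: dict[str, Transcript] = {}
        for g in genes.values():
            g.transcripts.sort(key=lambda t: t.transcript_id)
            for t in g.transcripts:
                self.transcripts[t.transcript_id] = t
            merged = _merge_intervals(
                [iv for t in g.transcripts for iv in t.exons]
            )
            if g.strand == "-":
                merged = merged[::-1]  # transcription order
            g.merged_exons = merged

    # -- accessors -------------------------------------------------------

    def gene_of_exon(self, exon_id: str) -> tuple[Gene, tuple[int, int]]:
        gene_id, idx = exon_id.rsplit(":", 1)
        g = self.genes[gene_id]
        return g, g.merged_exons[int(idx) - 1]

    def chromosome_lengths(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for g in self.genes.values():
            out[g.chrom] = max(out.get(g.chrom, 0), g.end + 2000)
        return out

    # -- GTF I/O ---------------------------------------------------------

    @classmethod
    def from_gtf(cls, path) -> "AnnotationDB":
        return parse_gtf(path)

    def to_gtf(self, path) -> None:
        write_gtf(self, path)


def parse_gtf(path) -> AnnotationDB:
    """Parse a GTF (Ensembl dialect) into an :class:`AnnotationDB`.

    Only ``gene``/``transcript``/``exon``/``CDS`` rows are used; attributes must
    carry ``gene_id`` (and ``transcript_id`` below gene level).  1-based
    inclusive coordinates become 0-based half-open.  Transcripts with no CDS are
    treated as non-coding; those whose CDS length is not divisible by 3 are
    flagged out of frame and excluded from protein mapping.
    """
    genes: dict[str, Gene] = {}
    transcripts: dict[str, Transcript] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 tab-separated fields, got {len(fields)}")
            seqname, _source, feature, start, end, _score, strand, _frame, attr = fields
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            try:
                start0, end0 = int(start) - 1, int(end)
            except ValueError:
                raise GtfParseError(lineno, f"non-integer coordinates {start!r}/{end!r}") from None
            if start0 < 0 or end0 <= start0:
                raise GtfParseError(lineno, f"invalid interval {start}-{end}")
            if strand not in "+-":
                raise GtfParseError(lineno, f"invalid strand {strand!r}")
            attrs = _parse_attributes(attr, lineno)
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise GtfParseError(lineno, "missing gene_id attribute")

            if feature == "gene":
                genes[gene_id] = Gene(gene_id, seqname, strand, start0, end0)
                continue
            tid = attrs.get("transcript_id")
            if tid is None:
                raise GtfParseError(lineno, f"missing transcript_id on {feature} row")
            if feature == "transcript":
                transcripts[tid] = Transcript(tid, gene_id, seqname, strand)
            else:
                t = transcripts.setdefault(tid, Transcript(tid, gene_id, seqname, strand))
                (t.exons if feature == "exon" else t.cds).append((start0, end0))

    for t in transcripts.values():
        reverse = t.strand == "-"
        t.exons = sorted(t.exons, reverse=reverse)
        t.cds = sorted(t.cds, reverse=reverse)
        g = genes.get(t.gene_id)
        if g is None:
            # gene row absent: synthesize the gene span from its transcripts
            g = genes[t.gene_id] = Gene(
                t.gene_id, t.chrom, t.strand,
                min(s for s, _ in t.exons), max(e for _, e in t.exons),
            )
        g.transcripts.append(t)

    # gene span covers its transcripts (3'-end definition depends on it)
    for g in genes.values():
        spans = [iv for t in g.transcripts for iv in t.exons]
        if spans:
            g.start = min(g.start, min(s for s, _ in spans))
            g.end = max(g.end, max(e for _, e in spans))
    return AnnotationDB(genes)


def _parse_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if " " not in chunk:
            raise GtfParseError(lineno, f"malformed attribute {chunk!r}")
        key, _, value = chunk.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def write_gtf(db: AnnotationDB, path) -> None:
    """Write the database back out as GTF; parse(write(parse(x))) == parse(x)."""
    rows: list[str] = []

    def emit(chrom, feature, s, e, strand, attrs):
        attr = " ".join(f'{k} "{v}";' for k, v in attrs)
        rows.append(f"{chrom}\texonsci\t{feature}\t{s + 1}\t{e}\t.\t{strand}\t.\t{attr}")

    for gid in sorted(db.genes):
        g = db.genes[gid]
        emit(g.chrom, "gene", g.start, g.end, g.strand, [("gene_id", gid)])
        for t in g.transcripts:
            a = [("gene_id", gid), ("transcript_id", t.transcript_id)]
            ts = min(s for s, _ in t.exons)
            te = max(e for _, e in t.exons)
            emit(g.chrom, "transcript", ts, te, g.strand, a)
            for s, e in t.exons:
                emit(g.chrom, "exon", s, e, g.strand, a)
            for s, e in t.cds:
                emit(g.chrom, "CDS", s, e, g.strand, a)
    with open(path, "w") as fh:
        fh.write("\n".join(rows) + ("\n" if rows else ""))


# ---------------------------------------------------------------------------
# interval index
# ---------------------------------------------------------------------------

class FeatureIndex:
    """Per-chromosome, per-strand interval trees over genes.

    ``query`` returns every gene overlapping the probe interval by at least one
    base, matching a brute-force scan.
    """

    def __init__(self, db: AnnotationDB):
        self.db = db
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        for g in db.genes.values():
            key = (g.chrom, g.strand)
            self._trees.setdefault(key, IntervalTree())[g.start:g.end] = g.gene_id

    def query(self, chrom: str, start: int, end: int, strand: str) -> list[str]:
        tree = self._trees.get((chrom, strand))
        if tree is None:
            return []
        return sorted(iv.data for iv in tree.overlap(start, end))

    def query_window(self, chrom: str, start: int, end: int, strand: str) -> list[str]:
        """Genes whose span intersects [start, end); alias used by rescue logic."""
        return self.query(chrom, start, end, strand)


def locate_overlaps(index: FeatureIndex, chrom: str, interval: tuple[int, int],
                    strand: str) -> list[str]:
    """Gene ids overlapping ``interval`` on ``strand`` (>=1 base). Unknown
    chromosome yields an empty list."""
    return index.query(chrom, interval[0], interval[1], strand)


# ---------------------------------------------------------------------------
# genome -> protein coordinates
# ---------------------------------------------------------------------------

def genomic_to_cds(transcript: Transcript, interval: tuple[int, int]) -> tuple[int, int] | None:
    """Map a genomic interval to CDS-relative nucleotide offsets (half-open).

    The CDS segments are concatenated in transcription order; the result is the
    bounding interval over all overlapped CDS bases (contiguous in CDS space
    whenever the genomic gaps are introns).  Returns ``None`` when the interval
    touches no CDS base.
    """
    a, b = interval
    offsets: list[tuple[int, int]] = []
    cum = 0
    for s, e in transcript.cds:
        lo, hi = max(a, s), min(b, e)
        if lo < hi:
            if transcript.strand == "+":
                offsets.append((cum + (lo - s), cum + (hi - s)))
            else:
                offsets.append((cum + (e - hi), cum + (e - lo)))
        cum += e - s
    if not offsets:
        return None
    return min(o[0] for o in offsets), max(o[1] for o in offsets)


def genomic_to_protein(transcript: Transcript, interval: tuple[int, int]) -> tuple[int, int] | None:
    """Amino-acid interval (0-based half-open) covered by a genomic interval.

    Partial codons are included: ``aa = (floor(cds_start/3), ceil(cds_end/3))``.
    Requires an in-frame CDS; returns ``None`` for UTR/intron-only intervals.
    """
    if not transcript.in_frame:
        raise ValueError(
            f"transcript {transcript.transcript_id} has no in-frame CDS"
        )
    nt = genomic_to_cds(transcript, interval)
    if nt is None:
        return None
    lo, hi = nt
    return lo // 3, -(-hi // 3)
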