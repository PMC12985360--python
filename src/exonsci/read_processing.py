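"""Barcode correction, sample demultiplexing, and PCR-duplicate collapsing.

Combinatorial-indexing reads carry an RT barcode (well of reverse
transcription, which also encodes the sample), a ligation barcode, a UMI, a
primer-type label (oligo-dT or random hexamer) and the tagmentation site.  A
cell is identified by the (RT, ligation) barcode combination; a molecule by
(RT, ligation, UMI, tagmentation site).

Reads are handled in bulk as a :class:`pandas.DataFrame` with the columns of
:data:`READ_COLUMNS`; :class:`ReadRecord` is the single-read view used by the
record-level API and the SAM reader.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pysam

READ_COLUMNS = (
    "read_id", "chrom", "start", "end", "strand",
    "rt_barcode", "lig_barcode", "umi", "primer_type",
    "tag_chrom", "tag_pos", "tag_strand",
)

_DNA = set("ACGT")


@dataclass(frozen=True)
class ReadRecord:
    """One aligned read with its combinatorial-indexing fields."""

    read_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    rt_barcode: str
    lig_barcode: str
    umi: str
    primer_type: str  # "dT" | "hexamer"
    tag_chrom: str
    tag_pos: int
    tag_strand: str

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("read interval must have positive length")

    @property
    def cell_barcode(self) -> str:
        return self.rt_barcode + self.lig_barcode


def packaged_whitelist(which: str) -> list[str]:
    """The shipped 10-nt whitelists ('rt' or 'lig'); pairwise Hamming >= 3."""
    name = {"rt": "rt_whitelist.txt", "lig": "lig_whitelist.txt"}[which]
    text = importlib.resources.files("exonsci.data").joinpath(name).read_text()
    return text.split()


@dataclass
class DemuxConfig:
    """Whitelists, the correction radius, and the RT-barcode -> sample map."""

    rt_whitelist: list[str]
    lig_whitelist: list[str]
    sample_of_rt: dict[str, str]
    max_edit_distance: int = 1  # reads at distance >= 2 are excluded
    metric: str = "hamming"  # "hamming" | "levenshtein"

    def __post_init__(self):
        for name, wl in (("rt", self.rt_whitelist), ("lig", self.lig_whitelist)):
            if len(set(wl)) != len(wl):
                raise ValueError(f"{name} whitelist entries are not unique")
            if len({len(b) for b in wl}) > 1:
                raise ValueError(f"{name} whitelist entries differ in length")
            for b in wl:
                if not set(b) <= _DNA:
                    raise ValueError(f"non-ACGT barcode {b!r} in {name} whitelist")
        if self.max_edit_distance != 1:
            raise ValueError("only max_edit_distance=1 is supported")


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def levenshtein(a: str, b: str) -> int:
    try:
        import edlib

        return edlib.align(a, b)["editDistance"]
    except ImportError:  # pragma: no cover - edlib present in supported envs
        prev = list(range(len(b) + 1))
        for i, x in enumerate(a, 1):
            cur = [i]
            for j, y in enumerate(b, 1):
                cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (x != y)))
            prev = cur
        return prev[-1]


def correct_barcode(observed: str, whitelist: list[str],
                    config: DemuxConfig | None = None) -> str | None:
    """Correct ``observed`` to its unique whitelist entry at distance <= 1.

    Exact matches return themselves; a single distance-1 hit returns that
    entry; ties at distance 1 or nothing within distance 1 return ``None``
    (the read is excluded, mirroring the edit-distance>=2 exclusion rule).
    """
    metric = (config.metric if config else "hamming")
    dist = hamming if metric == "hamming" else levenshtein
    if observed in whitelist:
        return observed
    hit = None
    for entry in whitelist:
        if dist(observed, entry) <= 1:
            if hit is not None:
                return None  # ambiguous: two entries within distance 1
            hit = entry
    return hit


def build_correction_map(whitelist: list[str]) -> dict[str, str | None]:
    """All barcodes within Hamming distance 1 of the whitelist -> correction.

    Ambiguous neighbors (distance 1 from two entries) map to ``None``; barcodes
    absent from the map are at distance >= 2 from every entry.
    """
    out: dict[str, str | None] = {}
    for entry in whitelist:
        out[entry] = entry
    for entry in whitelist:
        for i in range(len(entry)):
            for b in "ACGT":
                if b == entry[i]:
                    continue
                mut = entry[:i] + b + entry[i + 1:]
                if mut in out:
                    if out[mut] != entry and out[mut] is not None and mut not in whitelist:
                        out[mut] = None
                else:
                    out[mut] = entry
    return out


@dataclass
class DemuxResult:
    samples: dict[str, pd.DataFrame]
    rejected: pd.DataFrame  # read_id + reason
    n_input: int = 0
    n_assigned: int = 0


def demultiplex(reads: pd.DataFrame, config: DemuxConfig) -> DemuxResult:
    """Correct both barcodes and split reads by sample of the RT barcode.

    Every input read lands in exactly one sample stream or the rejection log
    (reasons: ``rt_uncorrectable``, ``lig_uncorrectable``, ``rt_unmapped``);
    counts are conserved.
    """
    reads = reads.reset_index(drop=True)
    if config.metric == "hamming":
        rt_map = build_correction_map(config.rt_whitelist)
        lig_map = build_correction_map(config.lig_whitelist)
        rt_fix = reads["rt_barcode"].map(rt_map)
        lig_fix = reads["lig_barcode"].map(lig_map)
    else:
        rt_fix = reads["rt_barcode"].map(
            lambda b: correct_barcode(b, config.rt_whitelist, config))
        lig_fix = reads["lig_barcode"].map(
            lambda b: correct_barcode(b, config.lig_whitelist, config))

    sample = rt_fix.map(config.sample_of_rt)
    reason = pd.Series(pd.NA, index=reads.index, dtype="object")
    reason[rt_fix.isna()] = "rt_uncorrectable"
    reason[rt_fix.notna() & lig_fix.isna()] = "lig_uncorrectable"
    reason[rt_fix.notna() & lig_fix.notna() & sample.isna()] = "rt_unmapped"

    ok = reason.isna()
    corrected = reads.loc[ok].copy()
    # categorical barcodes: the corrected values live on small whitelists
    corrected["rt_barcode"] = pd.Categorical(rt_fix[ok],
                                             categories=config.rt_whitelist)
    corrected["lig_barcode"] = pd.Categorical(lig_fix[ok],
                                              categories=config.lig_whitelist)
    corrected["sample"] = sample[ok]
    samples = {
        name: grp.drop(columns="sample").reset_index(drop=True)
        for name, grp in corrected.groupby("sample", sort=True)
    }
    rejected = pd.DataFrame({
        "read_id": reads.loc[~ok, "read_id"].to_numpy(),
        "reason": reason[~ok].to_numpy(),
    })
    return DemuxResult(samples=samples, rejected=rejected, n_input=len(reads),
                       n_assigned=int(ok.sum()))


MOLECULE_KEY = ["rt_barcode", "lig_barcode", "umi", "tag_chrom", "tag_pos", "tag_strand"]


def deduplicate(reads: pd.DataFrame, include_lig: bool = True) -> pd.DataFrame:
    """Collapse PCR duplicates to molecules.

    Duplicates share (RT barcode, ligation barcode, UMI, tagmentation site);
    the representative read is the first after sorting by aligned position, so
    the result is independent of input order.  ``include_lig=False`` drops the
    ligation barcode from the key (protocol variant switch).
    """
    key = [k for k in MOLECULE_KEY if include_lig or k != "lig_barcode"]
    ordered = reads.sort_values(
        ["chrom", "start", "end", "read_id"], kind="mergesort"
    )
    return (
        ordered.drop_duplicates(subset=key, keep="first")
        .sort_values(["chrom", "start", "end", "read_id"], kind="mergesort")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# SAM I/O
# ---------------------------------------------------------------------------
#
# Tags: CB = RT+ligation barcode (concatenated, fixed widths), UB = UMI,
#       pt = primer type, ts = tagmentation site "chrom:pos:strand".
# The bulk read table may carry integer read ids and 2-bit-packed UMIs
# (memory-light dialect); both are rendered as text at this boundary.

def decode_umi(codes: np.ndarray, length: int) -> np.ndarray:
    """2-bit-packed UMI integers -> fixed-width ACGT strings."""
    codes = np.asarray(codes, dtype=np.int64)
    shifts = 2 * np.arange(length - 1, -1, -1, dtype=np.int64)
    digits = (codes[:, None] >> shifts) & 3
    bases = np.array(list("ACGT"))
    return np.ascontiguousarray(bases[digits]).view(f"<U{length}").ravel()


def encode_umi(umis, length: int) -> np.ndarray:
    """ACGT strings -> 2-bit-packed integers (inverse of :func:`decode_umi`)."""
    lut = {b: i for i, b in enumerate("ACGT")}
    out = np.empty(len(umis), dtype=np.int64)
    for i, u in enumerate(umis):
        code = 0
        for ch in u:
            code = (code << 2) | lut[ch]
        out[i] = code
    return out


def _text_ids(reads: pd.DataFrame, umi_length: int = 8):
    rid = reads["read_id"]
    if pd.api.types.is_integer_dtype(rid):
        rid = "r" + rid.astype(str)
    umi = reads["umi"]
    if pd.api.types.is_integer_dtype(umi):
        umi = decode_umi(umi.to_numpy(), umi_length)
    return rid, umi


def reads_to_sam(reads: pd.DataFrame, chrom_lengths: dict[str, int], path,
                 rt_len: int = 10, umi_length: int = 8) -> None:
    """Write a read table as SAM text (unsequenced reads; CIGAR <len>M, SEQ *)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        flags = np.where(reads["strand"].to_numpy() == "-", 16, 0)
        lengths = (reads["end"] - reads["start"]).to_numpy()
        rid, umi = _text_ids(reads, umi_length)
        cols = zip(
            rid, flags, reads["chrom"], reads["start"].to_numpy() + 1,
            lengths, reads["rt_barcode"], reads["lig_barcode"], umi,
            reads["primer_type"], reads["tag_chrom"], reads["tag_pos"],
            reads["tag_strand"],
        )
        fh.writelines(
            f"{rid}\t{flag}\t{chrom}\t{pos}\t60\t{ln}M\t*\t0\t0\t*\t*\t"
            f"CB:Z:{rt}{lig}\tUB:Z:{umi}\tpt:Z:{pt}\tts:Z:{tc}:{tp}:{tstr}\n"
            for rid, flag, chrom, pos, ln, rt, lig, umi, pt, tc, tp, tstr in cols
        )


def reads_from_sam(path, rt_len: int = 10) -> pd.DataFrame:
    """Read a SAM/BAM with CB/UB/pt/ts tags back into the read table.

    Plain SAM text in the layout this package writes (match-only CIGAR, tags
    in CB/UB/pt/ts order) takes a vectorized pandas path; anything else falls
    back to the general pysam record loop.
    """
    if str(path).endswith(".sam"):
        try:
            return _reads_from_sam_fast(path, rt_len)
        except _FastSamUnsupported:
            pass
    return _reads_from_sam_pysam(path, rt_len)


class _FastSamUnsupported(Exception):
    pass


def _reads_from_sam_fast(path, rt_len: int) -> pd.DataFrame:
    import pyarrow as pa
    import pyarrow.compute as pc
    import pyarrow.csv as pacsv

    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("@"):
                break
            n_header += 1

    names = [f"c{i}" for i in range(15)]
    tab = pacsv.read_csv(
        str(path),
        read_options=pacsv.ReadOptions(skip_rows=n_header, column_names=names),
        parse_options=pacsv.ParseOptions(delimiter="\t"),
        convert_options=pacsv.ConvertOptions(
            include_columns=["c0", "c1", "c2", "c3", "c5",
                             "c11", "c12", "c13", "c14"],
            column_types={"c0": pa.string(), "c1": pa.int64(), "c2": pa.string(),
                          "c3": pa.int64(), "c5": pa.string(), "c11": pa.string(),
                          "c12": pa.string(), "c13": pa.string(),
                          "c14": pa.string()}),
    )
    if tab.num_rows == 0:
        return pd.DataFrame(columns=list(READ_COLUMNS))

    qname, flag, rname = tab["c0"], tab["c1"], tab["c2"]
    pos, cigar = tab["c3"], tab["c5"]
    cb, ub, pt, ts = tab["c11"], tab["c12"], tab["c13"], tab["c14"]

    def _all(b):
        return pc.all(b).as_py()

    if not (_all(pc.starts_with(cb, "CB:Z:")) and _all(pc.starts_with(ub, "UB:Z:"))
            and _all(pc.starts_with(pt, "pt:Z:")) and _all(pc.starts_with(ts, "ts:Z:"))
            and _all(pc.match_substring_regex(cigar, r"^[0-9]+M$"))):
        raise _FastSamUnsupported
    ts_parts = pc.split_pattern(pc.utf8_slice_codeunits(ts, 5, 1 << 30), ":")
    if not _all(pc.equal(pc.list_value_length(ts_parts), 3)):
        raise _FastSamUnsupported  # rsplit semantics need exactly 3 fields

    start = pc.subtract(pos, 1)
    length = pc.cast(pc.utf8_rtrim(cigar, "M"), pa.int64())
    barcode = pc.utf8_slice_codeunits(cb, 5, 1 << 30)

    def cat(arr):
        return pc.dictionary_encode(arr.combine_chunks()).to_pandas()

    return pd.DataFrame({
        "read_id": qname.to_pandas(),
        "chrom": cat(rname),
        "start": start.to_numpy(),
        "end": pc.add(start, length).to_numpy(),
        "strand": pd.Categorical(np.where(
            pc.bit_wise_and(flag, 16).to_numpy() != 0, "-", "+")),
        "rt_barcode": cat(pc.utf8_slice_codeunits(barcode, 0, rt_len)),
        "lig_barcode": cat(pc.utf8_slice_codeunits(barcode, rt_len, 1 << 30)),
        "umi": pc.utf8_slice_codeunits(ub, 5, 1 << 30).to_pandas(),
        "primer_type": cat(pc.utf8_slice_codeunits(pt, 5, 1 << 30)),
        "tag_chrom": cat(pc.list_element(ts_parts, 0)),
        "tag_pos": pc.cast(pc.list_element(ts_parts, 1), pa.int64()).to_numpy(),
        "tag_strand": cat(pc.list_element(ts_parts, 2)),
    })


def _reads_from_sam_pysam(path, rt_len: int = 10) -> pd.DataFrame:
    rows: dict[str, list] = {c: [] for c in READ_COLUMNS}
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                continue
            cb = aln.get_tag("CB")
            tc, tp, tstr = aln.get_tag("ts").rsplit(":", 2)
            rows["read_id"].append(aln.query_name)
            rows["chrom"].append(aln.reference_name)
            rows["start"].append(aln.reference_start)
            rows["end"].append(aln.reference_end)
            rows["strand"].append("-" if aln.is_reverse else "+")
            rows["rt_barcode"].append(cb[:rt_len])
            rows["lig_barcode"].append(cb[rt_len:])
            rows["umi"].append(aln.get_tag("UB"))
            rows["primer_type"].append(aln.get_tag("pt"))
            rows["tag_chrom"].append(tc)
            rows["tag_pos"].append(int(tp))
            rows["tag_strand"].append(tstr)
    return pd.DataFrame(rows)
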