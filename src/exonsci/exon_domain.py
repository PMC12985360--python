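"""Map differentially expressed exons to protein functional domains.

Each DEE (a gene-level merged exon) is projected through every in-frame
transcript of its parent gene into amino-acid coordinates and intersected
with that transcript's annotated domain intervals.  One hit is emitted per
(exon, transcript, overlapping domain); exons touching no CDS emit nothing.
The domain table is a TSV with 1-based inclusive amino-acid coordinates
(columns: transcript_id, domain_name, aa_start, aa_end), converted to 0-based
half-open internally.
"""

from __future__ import annotations

import logging

import pandas as pd

from .annotation import AnnotationDB, genomic_to_protein

logger = logging.getLogger(__name__)

HIT_COLUMNS = ("exon_id", "transcript_id", "exon_aa_start", "exon_aa_end",
               "domain_name", "domain_aa_start", "domain_aa_end", "overlap_aa")


def load_domain_table(path) -> pd.DataFrame:
    """Read a domain TSV; aa coordinates become 0-based half-open."""
    df = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "domain_name", "aa_start", "aa_end"}
    if not required <= set(df.columns):
        raise ValueError(f"domain table must have columns {sorted(required)}")
    df = df.copy()
    df["aa_start"] = df["aa_start"].astype(int) - 1
    df["aa_end"] = df["aa_end"].astype(int)
    return df


def write_domain_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    out["aa_start"] = out["aa_start"].astype(int) + 1
    out.to_csv(path, sep="\t", index=False)


def map_dees_to_domains(dee_ids: list[str], db: AnnotationDB,
                        domains: pd.DataFrame) -> pd.DataFrame:
    """Domain hits for a list of DEE exon ids.

    Deterministic ordering (exon, transcript, domain); a transcript absent
    from the domain table is logged and contributes no hits; minimum overlap
    is 1 aa.
    """
    by_tx = {tid: grp for tid, grp in domains.groupby("transcript_id")}
    rows = []
    for exon_id in dee_ids:
        gene, interval = db.gene_of_exon(exon_id)
        for t in gene.transcripts:
            if not t.in_frame:
                continue
            aa = genomic_to_protein(t, interval)
            if aa is None:
                continue  # UTR/intron-only footprint on this isoform
            if t.transcript_id not in by_tx:
                logger.info("transcript %s has no domain annotations", t.transcript_id)
                continue
            for dom in by_tx[t.transcript_id].itertuples():
                lo = max(aa[0], dom.aa_start)
                hi = min(aa[1], dom.aa_end)
                if hi - lo >= 1:
                    rows.append((exon_id, t.transcript_id, aa[0], aa[1],
                                 dom.domain_name, dom.aa_start, dom.aa_end,
                                 hi - lo))
    out = pd.DataFrame(rows, columns=HIT_COLUMNS)
    return out.sort_values(["exon_id", "transcript_id", "domain_name"]).reset_index(drop=True)


def summarize_per_exon(hits: pd.DataFrame) -> pd.DataFrame:
    """Per-exon union of domain names across isoforms."""
    if not len(hits):
        return pd.DataFrame(columns=["exon_id", "domains"])
    return (hits.groupby("exon_id")["domain_name"]
            .apply(lambda s: ";".join(sorted(set(s))))
            .rename("domains").reset_index())
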