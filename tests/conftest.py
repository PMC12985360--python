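import numpy as np
import pandas as pd
import pytest

from exonsci.annotation import AnnotationDB, Gene, Transcript


def make_gene(gene_id, chrom, strand, exons, cds=()):
    """Hand-built single-transcript gene; exons/cds given in transcription order."""
    t = Transcript(gene_id + ".t1", gene_id, chrom, strand,
                   exons=list(exons), cds=list(cds))
    flat = [b for iv in exons for b in iv]
    g = Gene(gene_id, chrom, strand, min(flat), max(flat))
    g.transcripts.append(t)
    return g


def make_db(*genes):
    return AnnotationDB({g.gene_id: g for g in genes})


def make_molecule(chrom="chr1", start=0, end=60, strand="+", primer="dT",
                  rt="AAAAAAAAAA", lig="CCCCCCCCCC", umi="ACGTACGT",
                  read_id="m1", tag_pos=None):
    from exonsci.read_processing import ReadRecord

    return ReadRecord(read_id=read_id, chrom=chrom, start=start, end=end,
                      strand=strand, rt_barcode=rt, lig_barcode=lig, umi=umi,
                      primer_type=primer, tag_chrom=chrom,
                      tag_pos=start if tag_pos is None else tag_pos,
                      tag_strand=strand)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete synthetic study processed through quantification.

    ~600 singlets (100 per replicate) at moderate depth; shared across tests
    that need realistic matrices with ground truth.
    """
    from exonsci import quantify as q
    from exonsci import read_processing as rp
    from exonsci.pipeline import demux_config_for
    from exonsci.synthetic import (SimConfig, generate_annotation,
                                   generate_cell_population, simulate_reads)

    cfg = SimConfig(n_cells_per_replicate=100, mean_molecules_per_cell=700.0,
                    seed=11)
    db, seqs, domains = generate_annotation(cfg)
    cells, truth = generate_cell_population(cfg, db)
    reads = simulate_reads(cells, db, truth, cfg)
    demux = rp.demultiplex(reads[list(rp.READ_COLUMNS)], demux_config_for(cfg))
    molecules = pd.concat([rp.deduplicate(df) for df in demux.samples.values()],
                          ignore_index=True)
    assigned = q.assign_bulk(molecules, db)
    gene_matrix, exon_matrix = q.build_matrices(assigned, db)
    return {
        "config": cfg, "db": db, "seqs": seqs, "domains": domains,
        "cells": cells, "truth": truth, "reads": reads, "demux": demux,
        "molecules": molecules, "assigned": assigned,
        "gene_matrix": gene_matrix, "exon_matrix": exon_matrix,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
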