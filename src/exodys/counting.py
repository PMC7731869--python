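"""Strand-aware exon-hit counting and RPKM normalization.

Counting rules:

* only reads with MAPQ >= ``min_mapq`` (default 1) are considered anywhere;
  the library size of a sample is the number of such reads, exonic or not;
* a read overlapping a gene's merged exon model by at least 1 bp on the
  matching strand counts once for that gene (gene-level "exon hits");
* at exon level a read counts for an exon only if it overlaps exactly one
  exon of that exon's transcript — reads overlapping two or more exons of
  the same transcript (junction-spanning alignments) are excluded from that
  transcript entirely;
* RPKM = count / (merged exon length in kb) / (library size in millions).
  FPKM is treated as a synonym.

Reads are single aligned segments; paired-end mates are counted
independently. A read overlapping merged exons of two different genes
increments both genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .annotation_io import AnnotationModel

logger = logging.getLogger(__name__)

ALIGNMENT_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "sample_id"]


@dataclass
class CountMatrix:
    """Exon-by-sample and gene-by-sample counts plus library sizes."""

    exon_counts: pd.DataFrame | None = None
    gene_counts: pd.DataFrame | None = None
    library_size: pd.Series | None = None
    rpkm: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        for frame in (self.exon_counts, self.gene_counts):
            if frame is not None and (frame.to_numpy() < 0).any():
                raise ValueError("negative counts")
        if self.rpkm is not None and (self.rpkm.to_numpy() < 0).any():
            raise ValueError("negative RPKM")


def _gene_trees(annotation: AnnotationModel, stranded: bool):
    trees: dict = {}
    for gid, spans in annotation.merged_exons.items():
        chrom = annotation.gene_chrom[gid]
        strand = annotation.gene_strand[gid] if stranded else "."
        tree = trees.setdefault((chrom, strand), IntervalTree())
        for start, end in spans:
            tree[start:end] = gid
    return trees


def _exon_trees(annotation: AnnotationModel, stranded: bool):
    trees: dict = {}
    for exon in annotation.exons:
        strand = exon.strand if stranded else "."
        tree = trees.setdefault((exon.chrom, strand), IntervalTree())
        tree[exon.start:exon.end] = (exon.transcript_id, exon.exon_id)
    return trees


def _check_columns(alignments: pd.DataFrame) -> None:
    missing = [c for c in ALIGNMENT_COLUMNS if c not in alignments.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")


def count_gene_hits(
    alignments: pd.DataFrame,
    annotation: AnnotationModel,
    min_mapq: int = 1,
    stranded: bool = True,
) -> tuple[pd.DataFrame, pd.Series]:
    """Gene-level exon hits and per-sample library sizes.

    Every read with mapq >= min_mapq contributes to its sample's library
    size; it increments each gene whose merged exons it overlaps by >= 1 bp
    on the matching strand (once per read per gene).
    """
    _check_columns(alignments)
    kept = alignments[alignments["mapq"] >= min_mapq]
    samples = sorted(alignments["sample_id"].astype(str).unique())
    library_size = (
        kept["sample_id"].astype(str).value_counts()
        .reindex(samples, fill_value=0).sort_index()
    )
    library_size.name = "library_size"
    trees = _gene_trees(annotation, stranded)
    genes = sorted(annotation.genes)
    gene_idx = {g: i for i, g in enumerate(genes)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    n_unknown_chrom = 0
    n_multi_gene = 0
    known_chroms = {c for (c, _s) in trees}
    for row in kept.itertuples(index=False):
        key = (row.chrom, row.strand if stranded else ".")
        tree = trees.get(key)
        if tree is None:
            if row.chrom not in known_chroms:
                n_unknown_chrom += 1
            continue
        hits = {iv.data for iv in tree.overlap(row.start, row.end)}
        if len(hits) > 1:
            n_multi_gene += 1
        j = sample_idx[str(row.sample_id)]
        for gid in hits:
            counts[gene_idx[gid], j] += 1
    if n_unknown_chrom:
        logger.info("%d reads on chromosomes absent from the annotation ignored",
                    n_unknown_chrom)
    if n_multi_gene:
        logger.info("%d reads overlapped merged exons of more than one gene "
                    "(counted for each)", n_multi_gene)
    gene_counts = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                               columns=samples)
    return gene_counts, library_size


def count_exon_hits(
    alignments: pd.DataFrame,
    annotation: AnnotationModel,
    min_mapq: int = 1,
    stranded: bool = True,
    multi_exon_rule: str = "per_transcript",
) -> pd.DataFrame:
    """Exon-level hits under the single-exon-overlap rule.

    With the default per-transcript rule, a qualifying read that overlaps
    exactly one exon of a transcript increments that exon; if it overlaps
    two or more exons of the same transcript, no exon of that transcript is
    incremented. The "global" rule drops a read entirely unless it overlaps
    exactly one exon across all transcripts.
    """
    if multi_exon_rule not in ("per_transcript", "global"):
        raise ValueError(f"unknown multi_exon_rule {multi_exon_rule!r}")
    _check_columns(alignments)
    kept = alignments[alignments["mapq"] >= min_mapq]
    samples = sorted(alignments["sample_id"].astype(str).unique())
    trees = _exon_trees(annotation, stranded)
    exon_ids = annotation.exon_ids()
    exon_idx = {e: i for i, e in enumerate(exon_ids)}
    sample_idx = {s: j for j, s in enumerate(samples)}
    counts = np.zeros((len(exon_ids), len(samples)), dtype=np.int64)
    for row in kept.itertuples(index=False):
        tree = trees.get((row.chrom, row.strand if stranded else "."))
        if tree is None:
            continue
        hits = [iv.data for iv in tree.overlap(row.start, row.end)]
        if not hits:
            continue
        j = sample_idx[str(row.sample_id)]
        if multi_exon_rule == "global":
            if len(hits) == 1:
                counts[exon_idx[hits[0][1]], j] += 1
            continue
        by_tid: dict[str, list[str]] = {}
        for tid, eid in hits:
            by_tid.setdefault(tid, []).append(eid)
        for tid, eids in by_tid.items():
            if len(eids) == 1:
                counts[exon_idx[eids[0]], j] += 1
    return pd.DataFrame(counts, index=pd.Index(exon_ids, name="exon_id"),
                        columns=samples)


def count_all(
    alignments: pd.DataFrame,
    annotation: AnnotationModel,
    min_mapq: int = 1,
    stranded: bool = True,
) -> CountMatrix:
    """Gene hits, exon hits, library sizes and RPKM in one pass."""
    gene_counts, library_size = count_gene_hits(
        alignments, annotation, min_mapq=min_mapq, stranded=stranded
    )
    exon_counts = count_exon_hits(
        alignments, annotation, min_mapq=min_mapq, stranded=stranded
    )
    matrix = CountMatrix(
        exon_counts=exon_counts,
        gene_counts=gene_counts,
        library_size=library_size,
        rpkm=rpkm(gene_counts, annotation.merged_length, library_size),
    )
    matrix.validate()
    return matrix


def rpkm(
    gene_counts: pd.DataFrame,
    merged_length: dict[str, int],
    library_size: pd.Series,
) -> pd.DataFrame:
    """Reads per kilobase of merged exon model per million library reads.

    Genes with merged length 0 are excluded (and logged); samples with
    library size 0 yield 0 for all genes (they can have no counts).
    """
    lengths = pd.Series(merged_length).reindex(gene_counts.index)
    bad = lengths[(lengths.isna()) | (lengths <= 0)].index
    if len(bad):
        logger.warning("excluding %d genes with undefined/zero merged length", len(bad))
        gene_counts = gene_counts.drop(index=bad)
        lengths = lengths.drop(index=bad)
    lib = library_size.reindex(gene_counts.columns).astype(float)
    denom = np.outer(lengths.to_numpy() / 1e3, lib.to_numpy() / 1e6)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(denom > 0, gene_counts.to_numpy() / denom, 0.0)
    return pd.DataFrame(values, index=gene_counts.index, columns=gene_counts.columns)
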