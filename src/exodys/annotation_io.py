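"""Gene annotation parsing and merged exon models.

Internally every interval is 0-based half-open ``[start, end)``; the GTF
reader converts from 1-based inclusive coordinates, the BED reader passes
coordinates through. Per gene, overlapping exons from all transcripts are
merged into a disjoint interval union whose total length is the RPKM
denominator ("merged length").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

#: Chromosomes retained by default: autosomes 1-22, X, Y and the
#: mitochondrial genome, with or without a "chr" prefix.
DEFAULT_CHROMOSOMES = frozenset(
    [str(i) for i in range(1, 23)] + ["X", "Y", "M", "MT"]
)


class AnnotationParseError(ValueError):
    """Raised when an annotation file cannot be parsed."""


class AnnotationError(ValueError):
    """Raised for structurally invalid annotation models."""


@dataclass(frozen=True)
class ExonInterval:
    """One exon of one transcript, 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    strand: str
    exon_id: str
    transcript_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise AnnotationError(
                f"exon {self.exon_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"exon {self.exon_id}: strand must be '+' or '-', got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def merge_exons(intervals: Sequence[ExonInterval]) -> list[tuple[int, int]]:
    """Union of one gene's exon intervals as a sorted disjoint list.

    All intervals must share gene_id, chromosome and strand. The result is
    invariant under input order and duplication; its total length equals the
    number of genomic bases covered by at least one exon.
    """
    if not intervals:
        return []
    genes = {iv.gene_id for iv in intervals}
    chroms = {iv.chrom for iv in intervals}
    strands = {iv.strand for iv in intervals}
    if len(genes) > 1:
        raise AnnotationError(f"merge_exons called across genes: {sorted(genes)}")
    if len(chroms) > 1 or len(strands) > 1:
        raise AnnotationError(
            f"gene {next(iter(genes))} spans multiple chromosomes/strands: "
            f"{sorted(chroms)} {sorted(strands)}"
        )
    spans = sorted((iv.start, iv.end) for iv in intervals)
    merged = [list(spans[0])]
    for start, end in spans[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


@dataclass
class AnnotationModel:
    """Genes -> transcripts -> exons, plus per-gene merged exon models."""

    exons: list[ExonInterval]
    transcripts: dict[str, list[ExonInterval]] = field(init=False)
    genes: dict[str, list[str]] = field(init=False)
    merged_exons: dict[str, list[tuple[int, int]]] = field(init=False)
    merged_length: dict[str, int] = field(init=False)
    gene_chrom: dict[str, str] = field(init=False)
    gene_strand: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        seen_ids: set[str] = set()
        self.transcripts = {}
        self.genes = {}
        for exon in self.exons:
            if exon.exon_id in seen_ids:
                raise AnnotationError(f"duplicate exon_id {exon.exon_id}")
            seen_ids.add(exon.exon_id)
            self.transcripts.setdefault(exon.transcript_id, []).append(exon)
        for tid, exons in self.transcripts.items():
            exons.sort(key=lambda e: (e.start, e.end))
            gids = {e.gene_id for e in exons}
            chroms = {e.chrom for e in exons}
            strands = {e.strand for e in exons}
            if len(gids) > 1 or len(chroms) > 1 or len(strands) > 1:
                raise AnnotationError(
                    f"transcript {tid} mixes genes/chromosomes/strands"
                )
            gid = exons[0].gene_id
            self.genes.setdefault(gid, [])
            if tid not in self.genes[gid]:
                self.genes[gid].append(tid)
        self.merged_exons = {}
        self.merged_length = {}
        self.gene_chrom = {}
        self.gene_strand = {}
        for gid, tids in self.genes.items():
            gene_exons = [e for tid in tids for e in self.transcripts[tid]]
            merged = merge_exons(gene_exons)
            self.merged_exons[gid] = merged
            self.merged_length[gid] = sum(e - s for s, e in merged)
            self.gene_chrom[gid] = gene_exons[0].chrom
            self.gene_strand[gid] = gene_exons[0].strand

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_ids(self) -> list[str]:
        return [e.exon_id for e in self.exons]

    def transcript_of(self) -> dict[str, str]:
        """Mapping exon_id -> transcript_id."""
        return {e.exon_id: e.transcript_id for e in self.exons}

    def gene_of_transcript(self) -> dict[str, str]:
        return {tid: exons[0].gene_id for tid, exons in self.transcripts.items()}


def _strip_chr(chrom: str) -> str:
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def _parse_gtf_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for piece in attr_field.strip().split(";"):
        piece = piece.strip()
        if not piece:
            continue
        if " " not in piece:
            continue
        key, _, value = piece.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_annotation(
    path,
    dialect: str = "gtf",
    chromosomes: Iterable[str] | None = DEFAULT_CHROMOSOMES,
) -> AnnotationModel:
    """Read a GTF (Ensembl dialect) or BED6+2 exon annotation.

    GTF: only ``exon`` feature lines are used; ``gene_id`` and
    ``transcript_id`` attributes are required, ``exon_id`` is synthesized
    from the transcript when absent. BED6+2 columns are
    chrom, start, end, exon_id, score, strand, transcript_id, gene_id.

    Records on chromosomes outside ``chromosomes`` (compared after removing
    any "chr" prefix; pass None to keep everything) are dropped with a
    logged count, as are records with start >= end.
    """
    if dialect not in ("gtf", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    allow = None if chromosomes is None else {_strip_chr(c) for c in chromosomes}
    exons: list[ExonInterval] = []
    n_dropped_chrom = 0
    n_rejected = 0
    per_transcript_index: dict[str, int] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gtf":
                    if len(fields) < 9:
                        raise ValueError("expected 9 tab-separated fields")
                    chrom, _, feature, start_s, end_s, _, strand, _, attr = fields[:9]
                    if feature != "exon":
                        continue
                    start = int(start_s) - 1  # 1-based inclusive -> 0-based
                    end = int(end_s)
                    attrs = _parse_gtf_attributes(attr)
                    if "gene_id" not in attrs or "transcript_id" not in attrs:
                        raise ValueError("missing gene_id/transcript_id attribute")
                    tid = attrs["transcript_id"]
                    gid = attrs["gene_id"]
                    exon_id = attrs.get("exon_id")
                    if exon_id is None:
                        per_transcript_index[tid] = per_transcript_index.get(tid, 0) + 1
                        exon_id = f"{tid}.e{per_transcript_index[tid]}"
                else:
                    if len(fields) < 8:
                        raise ValueError("expected >= 8 tab-separated fields (BED6+2)")
                    chrom, start_s, end_s, exon_id, _, strand, tid, gid = fields[:8]
                    start = int(start_s)
                    end = int(end_s)
            except ValueError as exc:
                raise AnnotationParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
            if allow is not None and _strip_chr(chrom) not in allow:
                n_dropped_chrom += 1
                continue
            if start >= end:
                n_rejected += 1
                logger.warning(
                    "%s: line %d: rejected exon %s with start >= end", path, lineno, exon_id
                )
                continue
            exons.append(
                ExonInterval(
                    chrom=chrom, start=start, end=end, strand=strand,
                    exon_id=exon_id, transcript_id=tid, gene_id=gid,
                )
            )
    if n_dropped_chrom:
        logger.info(
            "%s: dropped %d records on chromosomes outside the allow-list",
            path, n_dropped_chrom,
        )
    return AnnotationModel(exons=exons)


def write_annotation(model: AnnotationModel, path, dialect: str = "bed") -> None:
    """Write the exon model back out (GTF or BED6+2)."""
    if dialect not in ("gtf", "bed"):
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    with open(path, "w") as handle:
        for exon in model.exons:
            if dialect == "bed":
                handle.write(
                    f"{exon.chrom}\t{exon.start}\t{exon.end}\t{exon.exon_id}\t0\t"
                    f"{exon.strand}\t{exon.transcript_id}\t{exon.gene_id}\n"
                )
            else:
                attr = (
                    f'gene_id "{exon.gene_id}"; transcript_id "{exon.transcript_id}"; '
                    f'exon_id "{exon.exon_id}";'
                )
                handle.write(
                    f"{exon.chrom}\texodys\texon\t{exon.start + 1}\t{exon.end}\t.\t"
                    f"{exon.strand}\t.\t{attr}\n"
                )


def write_merged_exons(model: AnnotationModel, path) -> None:
    """TSV of per-gene merged exon intervals (gene_id, chrom, start, end)."""
    with open(path, "w") as handle:
        handle.write("gene_id\tchrom\tstart\tend\n")
        for gid in sorted(model.merged_exons):
            chrom = model.gene_chrom[gid]
            for start, end in model.merged_exons[gid]:
                handle.write(f"{gid}\t{chrom}\t{start}\t{end}\n")
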