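"""Synthetic annotation, count and alignment generation with known truth.

The generator emulates the design of a strand-specific peripheral-blood
RNA-seq case/control study: 8 controls versus 11 cases by default, a
transcript/exon structure scaled down from a genome-wide annotation, and
over-dispersed (negative-binomial) exon counts with per-sample library-size
factors. A configurable fraction of exons carries a planted case-specific
fold change; the truth table records exactly those exons so downstream
selection can be scored.

Planted effects emulate exon-specific dysregulation (e.g. altered exon
usage) rather than whole-transcript amplification: an exon is eligible for
an "up" effect only if its perturbed mean stays within the configured
baseline-mean range (mu * fold <= max), and for "down" only if mu / fold >=
min, and at most one exon per transcript is planted. A whole-transcript
shift would cancel exactly under within-transcript scaling and is therefore
not an exon-level signal at all.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotation_io import AnnotationModel, ExonInterval
from .samples import CASE, CONTROL, SampleSheet

logger = logging.getLogger(__name__)

READ_LENGTH = 50  # bp, Illumina GAII 51-cycle reads minus one
_PLANT_MIN_Z = 6.0  # predicted planted-exon shift, in units of its noise
_PLANT_MAX_SIBLING_Z = 2.0  # predicted sibling shift ceiling
_GENE_GAP = 5_000
_INTRON_RANGE = (200, 2_000)
_GENES_PER_CHROM = 25


class ConfigError(ValueError):
    """Raised for infeasible simulation configurations."""


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for the generator.

    Defaults mirror the emulated study: 8 control and 11 case samples;
    baseline per-exon expected counts log-uniform over ``baseline_mean``;
    a shared negative-binomial dispersion; log-normal library-size factors.
    """

    n_genes: int = 120
    transcripts_per_gene: tuple[int, int] = (1, 2)
    exons_per_transcript: tuple[int, int] = (4, 10)
    exon_length: tuple[int, int] = (80, 500)
    n_controls: int = 8
    n_cases: int = 11
    library_size_mean: float = 1.0  # mean library-size factor
    library_size_cv: float = 0.15
    nb_dispersion: float = 0.05
    baseline_mean: tuple[float, float] = (100.0, 8000.0)
    planted_fraction: float = 0.02
    fold_change: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("transcripts_per_gene", "exons_per_transcript",
                     "exon_length", "baseline_mean"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigError(f"{name}: max {hi} < min {lo}")
        if self.n_genes < 0 or self.n_controls < 0 or self.n_cases < 0:
            raise ConfigError("counts must be >= 0")
        if not 0.0 <= self.planted_fraction <= 1.0:
            raise ConfigError("planted_fraction must be in [0, 1]")
        if self.fold_change <= 1.0:
            raise ConfigError("fold_change must be > 1")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        if self.library_size_mean <= 0 or self.library_size_cv < 0:
            raise ConfigError("library size parameters must be positive")
        if self.exon_length[0] < 1 or self.baseline_mean[0] <= 0:
            raise ConfigError("exon_length and baseline_mean must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Planted exon effects: exon_id, direction (up/down), fold change."""

    frame: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["exon_id", "direction", "fold_change"]
        )
    )

    @property
    def exon_ids(self) -> set[str]:
        return set(self.frame["exon_id"])

    def direction_of(self) -> dict[str, str]:
        return dict(zip(self.frame["exon_id"], self.frame["direction"]))

    def __len__(self) -> int:
        return len(self.frame)

    def write(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TruthTable":
        return cls(frame=pd.read_csv(path, sep="\t"))


def make_sample_sheet(config: SimulationConfig) -> SampleSheet:
    """Control samples first (CO_*), then case samples (HD_*)."""
    ids = [f"CO_{i + 1:02d}" for i in range(config.n_controls)]
    ids += [f"HD_{i + 1:02d}" for i in range(config.n_cases)]
    conditions = [CONTROL] * config.n_controls + [CASE] * config.n_cases
    return SampleSheet(sample_ids=ids, conditions=conditions)


def simulate_annotation(config: SimulationConfig) -> AnnotationModel:
    """Lay out non-overlapping genes on synthetic chromosomes.

    Each gene's first transcript gets freshly drawn exon intervals;
    additional transcripts reuse a contiguous slice of the first
    transcript's exons, jittered by a few tens of bases, so that merged
    exon models genuinely merge overlapping intervals.
    """
    rng = np.random.default_rng([int(config.seed), 101])
    exons: list[ExonInterval] = []
    cursor = 1_000
    chrom_index = 1
    for g in range(config.n_genes):
        if g > 0 and g % _GENES_PER_CHROM == 0:
            chrom_index += 1
            cursor = 1_000
        chrom = f"chrS{chrom_index}"
        gid = f"G{g + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_tx = int(rng.integers(config.transcripts_per_gene[0],
                                config.transcripts_per_gene[1] + 1))
        first_spans: list[tuple[int, int]] = []
        gene_end = cursor
        for t in range(n_tx):
            tid = f"{gid}.t{t + 1}"
            if t == 0:
                n_ex = int(rng.integers(config.exons_per_transcript[0],
                                        config.exons_per_transcript[1] + 1))
                pos = cursor
                for i in range(n_ex):
                    length = int(rng.integers(config.exon_length[0],
                                              config.exon_length[1] + 1))
                    first_spans.append((pos, pos + length))
                    exons.append(ExonInterval(
                        chrom=chrom, start=pos, end=pos + length, strand=strand,
                        exon_id=f"{tid}.e{i + 1}", transcript_id=tid, gene_id=gid,
                    ))
                    pos += length + int(rng.integers(*_INTRON_RANGE))
                gene_end = first_spans[-1][1]
            else:
                lo = max(2, config.exons_per_transcript[0])
                n_ex = min(len(first_spans),
                           int(rng.integers(lo, config.exons_per_transcript[1] + 1))
                           if len(first_spans) > lo else len(first_spans))
                offset = int(rng.integers(0, len(first_spans) - n_ex + 1))
                for i, (s, e) in enumerate(first_spans[offset:offset + n_ex]):
                    jitter = int(rng.integers(-40, 41))
                    s2, e2 = s + jitter, e + jitter
                    exons.append(ExonInterval(
                        chrom=chrom, start=s2, end=e2, strand=strand,
                        exon_id=f"{tid}.e{i + 1}", transcript_id=tid, gene_id=gid,
                    ))
        cursor = gene_end + _GENE_GAP
    return AnnotationModel(exons=exons)


def _size_factors(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    cv = config.library_size_cv
    if cv == 0:
        return np.full(n, config.library_size_mean)
    sigma2 = math.log1p(cv * cv)
    mu = math.log(config.library_size_mean) - sigma2 / 2.0
    return rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)


def _predicted_shifts(means: np.ndarray, idx: int, new_value: float,
                      dispersion: float) -> tuple[np.ndarray, np.ndarray]:
    """First-order prediction of per-exon scaled-value shifts and noise.

    Returns (shift, sd): the change of each exon's within-transcript scaled
    value s_i when exon ``idx`` moves from means[idx] to ``new_value``, and
    the approximate control-sample standard deviation of each s_i (count
    noise propagated through the scaling; the sigma-hat sampling term is
    neglected, which makes the prediction conservative for siblings).
    """
    k = means.size
    mu0, sd0 = means.mean(), means.std()
    perturbed = means.copy()
    perturbed[idx] = new_value
    mu1, sd1 = perturbed.mean(), perturbed.std()
    if sd0 == 0 or sd1 == 0:
        return np.full(k, np.inf), np.full(k, 1e-12)
    s0 = (means - mu0) / sd0
    s1 = (perturbed - mu1) / sd1
    # delta method through s_i = (c_i - mu_hat)/sigma_hat:
    # d s_i = sum_j A_ij d c_j / sigma, A_ij = 1{i=j} - (1 + s_i s_j)/k
    var_counts = means ** 2 * dispersion + means  # NB variance
    coef = np.eye(k) - (1.0 + np.outer(s0, s0)) / k
    sd = np.sqrt((coef ** 2 @ var_counts)) / sd0
    return s1 - s0, np.maximum(sd, 1e-12)


def _plant_effects(
    annotation: AnnotationModel,
    mu: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> TruthTable:
    """Choose planted exons whose effect is separable by construction.

    A candidate (exon, direction) is eligible when the perturbed mean stays
    inside the baseline range and, under the first-order prediction of
    within-transcript scaling, the planted exon itself shifts by at least
    ``_PLANT_MIN_Z`` times its own noise level while every sibling exon
    shifts by at most ``_PLANT_MAX_SIBLING_Z`` times its noise level. This
    emulates exon-usage shifts the scan is designed to detect; effects that
    rescale a transcript's whole profile bleed into sibling exons (see the
    methods note) and are not planted.
    """
    n_planted = int(round(config.planted_fraction * annotation.n_exons))
    if n_planted == 0:
        return TruthTable()
    lo, hi = config.baseline_mean
    f = config.fold_change
    records = []
    tids = list(annotation.transcripts)
    rng.shuffle(tids)
    for tid in tids:
        if len(records) >= n_planted:
            break
        exons = annotation.transcripts[tid]
        if len(exons) < 3:
            continue
        means = np.array([float(mu[e.exon_id]) for e in exons])
        candidates = []
        for i, exon in enumerate(exons):
            m = means[i]
            for direction, new_value in (("up", m * f), ("down", m / f)):
                if not lo <= new_value <= hi:
                    continue
                shift, sd = _predicted_shifts(means, i, new_value,
                                              config.nb_dispersion)
                zpred = np.abs(shift) / sd
                sibling = np.delete(zpred, i)
                if zpred[i] >= _PLANT_MIN_Z and sibling.max() <= _PLANT_MAX_SIBLING_Z:
                    candidates.append((exon.exon_id, direction))
        if not candidates:
            continue
        exon_id, direction = candidates[int(rng.integers(len(candidates)))]
        records.append((exon_id, direction, f))
    if len(records) < n_planted:
        logger.warning(
            "planted only %d of %d requested exons (eligibility limits)",
            len(records), n_planted,
        )
    frame = pd.DataFrame(records, columns=["exon_id", "direction", "fold_change"])
    return TruthTable(frame=frame)


def simulate_counts(
    annotation: AnnotationModel,
    config: SimulationConfig,
    seed: int | None = None,
):
    """Draw a negative-binomial exon-by-sample count matrix with planted truth.

    Counts for exon e, sample j are NB with mean mu_e * s_j * effect(e, j)
    and dispersion ``nb_dispersion`` (variance m + disp * m^2); s_j is the
    sample's library-size factor and effect is the planted fold change for
    planted exons in case samples (x f for up, x 1/f for down), else 1.

    Returns a :class:`~exodys.counting.CountMatrix` (exon and gene counts,
    library sizes, size factors and exon means in ``meta``) and the
    :class:`TruthTable` of planted exons.
    """
    from .counting import CountMatrix  # deferred: counting imports nothing back

    if annotation.n_exons == 0:
        raise ConfigError("annotation is empty")
    rng = np.random.default_rng(
        [int(config.seed if seed is None else seed), 202]
    )
    sheet = make_sample_sheet(config)
    exon_ids = annotation.exon_ids()
    lo, hi = config.baseline_mean
    mu = pd.Series(
        np.exp(rng.uniform(math.log(lo), math.log(hi), size=annotation.n_exons)),
        index=exon_ids,
    )
    truth = _plant_effects(annotation, mu, config, rng)
    factors = _size_factors(config, rng, len(sheet))

    mean_matrix = np.outer(mu.to_numpy(), factors)
    if len(truth):
        direction = truth.direction_of()
        case_cols = np.array(
            [c == CASE for c in sheet.conditions], dtype=bool
        )
        index_of = {eid: i for i, eid in enumerate(exon_ids)}
        for eid, d in direction.items():
            eff = config.fold_change if d == "up" else 1.0 / config.fold_change
            mean_matrix[index_of[eid], case_cols] *= eff

    disp = config.nb_dispersion
    if disp == 0:
        counts = rng.poisson(mean_matrix)
    else:
        n_param = 1.0 / disp
        p_param = n_param / (n_param + mean_matrix)
        counts = rng.negative_binomial(n_param, p_param)

    exon_counts = pd.DataFrame(counts, index=exon_ids, columns=sheet.sample_ids)
    gene_of_tid = annotation.gene_of_transcript()
    gene_index = [gene_of_tid[e.transcript_id] for e in annotation.exons]
    gene_counts = exon_counts.groupby(pd.Index(gene_index, name="gene_id")).sum()
    matrix = CountMatrix(
        exon_counts=exon_counts,
        gene_counts=gene_counts,
        library_size=exon_counts.sum(axis=0),
        meta={
            "size_factors": pd.Series(factors, index=sheet.sample_ids),
            "exon_means": mu,
            "nb_dispersion": disp,
            "noise_model": "negative binomial, shared dispersion, "
                           "mean-parameterized",
        },
    )
    return matrix, truth


@dataclass
class DecoyConfig:
    """Reads the exon counter must exclude, emitted per sample."""

    n_antisense: int = 0
    n_mapq0: int = 0
    n_intergenic: int = 0
    n_junction: int = 0


ALIGNMENT_COLUMNS = ["chrom", "start", "end", "strand", "mapq", "sample_id"]


def simulate_alignments(
    annotation: AnnotationModel,
    counts,
    config: SimulationConfig,
    decoys: DecoyConfig | None = None,
) -> pd.DataFrame:
    """Emit one single-exon read per unit of count, plus optional decoys.

    For every (exon, sample) count c, c reads lie fully inside the exon on
    the matching strand with MAPQ 60, so exon-level re-counting recovers the
    generating counts exactly. Decoys are antisense reads (flipped strand),
    MAPQ-0 reads, intergenic reads, and junction-spanning reads covering two
    consecutive exons of one transcript; none of them may change exon-level
    counts.
    """
    decoys = decoys or DecoyConfig()
    rng = np.random.default_rng([int(config.seed), 303])
    exon_counts = counts.exon_counts if hasattr(counts, "exon_counts") else counts
    by_id = {e.exon_id: e for e in annotation.exons}
    rows: list[tuple] = []
    for sample in exon_counts.columns:
        col = exon_counts[sample]
        for exon_id, c in col.items():
            c = int(c)
            if c == 0:
                continue
            exon = by_id[exon_id]
            length = min(READ_LENGTH, exon.length)
            starts = rng.integers(exon.start, exon.end - length + 1, size=c)
            for s in starts:
                rows.append((exon.chrom, int(s), int(s) + length, exon.strand, 60, sample))
        rows.extend(_decoy_rows(annotation, decoys, rng, sample))
    frame = pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS)
    return frame.sort_values(["sample_id", "chrom", "start"], kind="stable").reset_index(drop=True)


def _decoy_rows(annotation, decoys: DecoyConfig, rng, sample) -> list[tuple]:
    rows = []
    exons = annotation.exons
    if not exons:
        return rows
    flip = {"+": "-", "-": "+"}
    for _ in range(decoys.n_antisense):
        exon = exons[int(rng.integers(len(exons)))]
        length = min(READ_LENGTH, exon.length)
        s = int(rng.integers(exon.start, exon.end - length + 1))
        rows.append((exon.chrom, s, s + length, flip[exon.strand], 60, sample))
    for _ in range(decoys.n_mapq0):
        exon = exons[int(rng.integers(len(exons)))]
        length = min(READ_LENGTH, exon.length)
        s = int(rng.integers(exon.start, exon.end - length + 1))
        rows.append((exon.chrom, s, s + length, exon.strand, 0, sample))
    max_end = {e.chrom: 0 for e in exons}
    for e in exons:
        max_end[e.chrom] = max(max_end[e.chrom], e.end)
    chroms = sorted(max_end)
    for _ in range(decoys.n_intergenic):
        chrom = chroms[int(rng.integers(len(chroms)))]
        s = max_end[chrom] + 10_000 + int(rng.integers(0, 1_000))
        strand = "+" if rng.random() < 0.5 else "-"
        rows.append((chrom, s, s + READ_LENGTH, strand, 60, sample))
    # junction decoys come from single-transcript genes only, so the read
    # cannot overlap exactly one exon of a sibling transcript
    multi = [
        tid for tid, exs in annotation.transcripts.items()
        if len(exs) >= 2 and len(annotation.genes[exs[0].gene_id]) == 1
    ]
    for _ in range(decoys.n_junction if multi else 0):
        tid = multi[int(rng.integers(len(multi)))]
        exs = annotation.transcripts[tid]
        i = int(rng.integers(len(exs) - 1))
        a, b = exs[i], exs[i + 1]
        s = max(a.start, a.end - READ_LENGTH // 2)
        e = min(b.end, b.start + READ_LENGTH // 2)
        rows.append((a.chrom, s, e, a.strand, 60, sample))
    return rows


def write_alignments(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_alignments(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
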