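"""Outlier-robust heatmap normalization and cross-study signature overlap.

The heatmap matrix is built from per-gene z-scores of log2(FPKM), with zero
FPKM floored at 0.01 before the log. Outlying entries are detected per gene
with the Iglewicz–Hoaglin modified z-score

    M_i = 0.6745 * (x_i - median) / MAD

(conventional cutoff 3.5) and winsorized to the most extreme non-outlier
value on their side before the z-scores are recomputed. Genes are ordered
by average-linkage hierarchical clustering on Euclidean distance; samples
stay in sheet order (controls left, cases right).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .samples import SampleSheet

logger = logging.getLogger(__name__)

MODIFIED_Z_CONSTANT = 0.6745  # 0.75 quantile of the standard normal
DEFAULT_OUTLIER_THRESHOLD = 3.5
DEFAULT_FPKM_FLOOR = 0.01


class ZeroMADError(ValueError):
    """Raised when the median absolute deviation is zero."""


def modified_zscore(values) -> np.ndarray:
    """Iglewicz–Hoaglin modified z-scores of a vector.

    M_i = 0.6745 * (x_i - median) / MAD, MAD the median absolute deviation
    from the median. Raises :class:`ZeroMADError` for MAD = 0 so callers can
    fall back to no outlier adjustment.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        raise ZeroMADError("median absolute deviation is zero")
    return MODIFIED_Z_CONSTANT * (x - med) / mad


def winsorize_by_modified_z(values, threshold: float = DEFAULT_OUTLIER_THRESHOLD):
    """Clip outliers (|M| > threshold) to the most extreme non-outlier value.

    High outliers are replaced by the maximum non-outlying entry, low
    outliers by the minimum. Returns (adjusted values, outlier mask); if
    MAD = 0 or every entry is flagged on one side, the input is returned
    unchanged with an all-False mask.
    """
    x = np.asarray(values, dtype=float)
    try:
        m = modified_zscore(x)
    except ZeroMADError:
        return x.copy(), np.zeros_like(x, dtype=bool)
    outlier = np.abs(m) > threshold
    if not outlier.any():
        return x.copy(), outlier
    keep = x[~outlier]
    if keep.size == 0:
        return x.copy(), np.zeros_like(x, dtype=bool)
    adjusted = x.copy()
    adjusted[outlier & (m > 0)] = keep.max()
    adjusted[outlier & (m < 0)] = keep.min()
    return adjusted, outlier


@dataclass
class ExpressionZMatrix:
    """Gene-by-sample outlier-adjusted z-scores of log2(FPKM)."""

    values: pd.DataFrame
    floor: float
    outlier_threshold: float
    gene_order: list[str]
    linkage_record: np.ndarray | None
    outlier_mask: pd.DataFrame | None = None
    zero_variance_genes: list[str] = field(default_factory=list)

    def ordered(self) -> pd.DataFrame:
        return self.values.loc[self.gene_order]


def _zscore_rows(x: np.ndarray, ddof: int = 1) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (x - mean) / sd
    flat = (sd == 0).ravel()
    z[flat] = 0.0
    return z, flat


def heatmap_matrix(
    fpkm: pd.DataFrame,
    sample_sheet: SampleSheet | None = None,
    floor: float = DEFAULT_FPKM_FLOOR,
    outlier_threshold: float = DEFAULT_OUTLIER_THRESHOLD,
    robust: bool = False,
) -> ExpressionZMatrix:
    """Outlier-adjusted per-gene z-scores of log2(FPKM), clustered.

    ``robust=True`` replaces the winsorize-then-restandardize scheme with
    direct robust standardization (modified z-scores as the values).
    Samples are kept in sheet order when a sheet is given (controls first),
    otherwise in input column order.
    """
    if sample_sheet is not None:
        columns = [s for s in sample_sheet.sample_ids if s in fpkm.columns]
        missing = [s for s in sample_sheet.sample_ids if s not in fpkm.columns]
        if missing:
            raise ValueError(f"samples missing from FPKM table: {missing}")
        fpkm = fpkm[columns]
    x = np.log2(np.maximum(fpkm.to_numpy(dtype=float), floor))
    genes = list(fpkm.index)
    if robust:
        values = np.empty_like(x)
        outliers = np.zeros_like(x, dtype=bool)
        flat = np.zeros(len(genes), dtype=bool)
        for i in range(x.shape[0]):
            try:
                values[i] = modified_zscore(x[i])
            except ZeroMADError:
                values[i] = 0.0
                flat[i] = True
    else:
        adjusted = np.empty_like(x)
        outliers = np.zeros_like(x, dtype=bool)
        for i in range(x.shape[0]):
            adjusted[i], outliers[i] = winsorize_by_modified_z(
                x[i], threshold=outlier_threshold
            )
        values, flat = _zscore_rows(adjusted)
    flat_genes = [g for g, f in zip(genes, flat) if f]
    if flat_genes:
        logger.info("%d genes with zero variance placed last, excluded from "
                    "clustering", len(flat_genes))
    keep = [g for g, f in zip(genes, flat) if not f]
    frame = pd.DataFrame(values, index=genes, columns=fpkm.columns)
    if len(keep) >= 2:
        link = linkage(frame.loc[keep].to_numpy(), method="average",
                       metric="euclidean")
        order = [keep[i] for i in leaves_list(link)]
    else:
        link = None
        order = list(keep)
    gene_order = order + flat_genes
    return ExpressionZMatrix(
        values=frame,
        floor=floor,
        outlier_threshold=outlier_threshold,
        gene_order=gene_order,
        linkage_record=link,
        outlier_mask=pd.DataFrame(outliers, index=genes, columns=fpkm.columns),
        zero_variance_genes=flat_genes,
    )


def plot_heatmap(matrix: ExpressionZMatrix, path, cmap: str = "RdBu_r") -> None:
    """Write a simple clustered-heatmap image (PNG/SVG by extension)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.ordered()
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * data.shape[1]), max(4, 0.12 * data.shape[0]))
    )
    vmax = np.abs(data.to_numpy()).max() or 1.0
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]))
    ax.set_xticklabels(data.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="z-score of log2(FPKM)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class GeneSignature:
    """Direction-annotated gene-symbol sets from one study."""

    study_id: str
    up: set[str] = field(default_factory=set)
    down: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.up = {s.strip().upper() for s in self.up}
        self.down = {s.strip().upper() for s in self.down}
        both = self.up & self.down
        if both:
            raise ValueError(
                f"signature {self.study_id}: genes in both up and down: {sorted(both)}"
            )


@dataclass
class OverlapReport:
    study_a: str
    study_b: str
    direction_mode: str
    shared: dict[str, list[str]]

    def counts(self) -> dict[str, int]:
        return {d: len(g) for d, g in self.shared.items()}

    def to_json(self) -> str:
        return json.dumps({
            "study_a": self.study_a,
            "study_b": self.study_b,
            "direction_mode": self.direction_mode,
            "shared": self.shared,
            "counts": self.counts(),
        }, indent=2)


def overlap(
    a: GeneSignature, b: GeneSignature, direction_mode: str = "matched"
) -> OverlapReport:
    """Shared genes between two signatures.

    ``matched`` intersects up-with-up and down-with-down; ``any``
    intersects the unions regardless of direction.
    """
    if direction_mode == "matched":
        shared = {
            "up": sorted(a.up & b.up),
            "down": sorted(a.down & b.down),
        }
    elif direction_mode == "any":
        shared = {"any": sorted((a.up | a.down) & (b.up | b.down))}
    else:
        raise ValueError(f"unknown direction_mode {direction_mode!r}")
    return OverlapReport(
        study_a=a.study_id, study_b=b.study_id,
        direction_mode=direction_mode, shared=shared,
    )


def overlap_regions(
    signatures: list[GeneSignature], direction: str = "up"
) -> dict[tuple[str, ...], int]:
    """Venn-style exclusive region counts across several signatures.

    For every non-empty subset of studies, the number of genes present in
    exactly those studies' ``direction`` sets and in no others.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    sets = {s.study_id: getattr(s, direction) for s in signatures}
    all_genes = set().union(*sets.values()) if sets else set()
    regions: dict[tuple[str, ...], int] = {}
    for gene in all_genes:
        members = tuple(sorted(sid for sid, gs in sets.items() if gene in gs))
        regions[members] = regions.get(members, 0) + 1
    return regions


def read_signatures(path) -> dict[str, GeneSignature]:
    """TSV with columns study_id, gene_symbol, direction (up/down)."""
    frame = pd.read_csv(path, sep="\t")
    out: dict[str, GeneSignature] = {}
    for study_id, group in frame.groupby("study_id"):
        up = set(group.loc[group["direction"] == "up", "gene_symbol"])
        down = set(group.loc[group["direction"] == "down", "gene_symbol"])
        out[str(study_id)] = GeneSignature(study_id=str(study_id), up=up, down=down)
    return out


def write_matrix(matrix: ExpressionZMatrix, path) -> None:
    matrix.ordered().to_csv(path, sep="\t")
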