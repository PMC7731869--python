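"""Exon-level dysregulation scan with a sample-label permutation null.

The scan standardizes each exon's count within its transcript and sample,
s_i = (c_i - mu) / sigma, where mu and sigma are the mean and standard
deviation of the exon counts of that transcript in that sample. Each case
sample's scaled value is then compared to the reference distribution of
scaled values in the control samples via a z-score, and an exon is called
dysregulated when it has more than ``min_control_reads`` raw reads summed
over the control samples and at least ``min_cases`` case samples with
z above ``z_threshold`` (up) or below ``-z_threshold`` (down).

Because the within-transcript scaling uses only one sample at a time, it is
independent of the condition labels; the permutation null therefore reuses
the scaled matrix and only recomputes the control reference, z-scores and
selection under shuffled labels. The empirical p-value for the observed
number of selected exons uses the plug-in convention r/R (fraction of
permutations with at least as many selections).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd

from .samples import CASE, CONTROL, SampleSheet

EXCLUDED_ZERO_VARIANCE = "zero_variance"
EXCLUDED_CONTROL_SD_ZERO = "control_sd_zero"
EXCLUDED_READ_FILTER = "read_filter"


@dataclass
class SelectionConfig:
    """Selection thresholds; the defaults are the scan's canonical values
    (strictly more than 50 control reads, |z| > 4 in at least 5 cases)."""

    min_control_reads: int = 50
    z_threshold: float = 4.0
    min_cases: int = 5
    control_reads_mode: str = "sum"  # or "per_sample"

    def __post_init__(self) -> None:
        if self.min_control_reads <= 0 or self.z_threshold <= 0 or self.min_cases <= 0:
            raise ValueError("all selection thresholds must be > 0")
        if self.control_reads_mode not in ("sum", "per_sample"):
            raise ValueError(f"unknown control_reads_mode {self.control_reads_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExonScanResult:
    """Selected exon sets plus exclusions and the per-exon detail table."""

    selected_up: list[str]
    selected_down: list[str]
    ambiguous: list[str]
    excluded: dict[str, list[str]]
    table: pd.DataFrame | None = None

    @property
    def n_selected(self) -> int:
        return len(self.selected_up) + len(self.selected_down) + len(self.ambiguous)

    def summary(self) -> dict:
        return {
            "n_up": len(self.selected_up),
            "n_down": len(self.selected_down),
            "n_ambiguous": len(self.ambiguous),
            "n_selected": self.n_selected,
        }


@dataclass
class PermutationNull:
    """Null distribution of the selection count under label permutation."""

    n_permutations: int
    null_counts: np.ndarray
    observed: int
    p_value: float
    seed: int | None = None
    exhaustive: bool = False
    config: SelectionConfig | None = None

    def write(self, path) -> None:
        pd.DataFrame({"n_selected": self.null_counts}).to_csv(
            path, sep="\t", index=False
        )

    def summary(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "observed_n_selected": self.observed,
            "p_value": self.p_value,
            "seed": self.seed,
            "exhaustive": self.exhaustive,
            "config": self.config.to_dict() if self.config else None,
        }


def scale_within_transcript(
    counts: pd.DataFrame,
    transcript_of: dict[str, str] | pd.Series,
    sd_mode: str = "population",
) -> pd.DataFrame:
    """Scale exon counts within each transcript, per sample.

    Returns a matrix of s_i = (c_i - mu) / sigma aligned with ``counts``;
    entries are NaN where scaling is undefined: transcripts with fewer than
    two exons, or zero count variance for that transcript in that sample.
    """
    if sd_mode not in ("population", "sample"):
        raise ValueError(f"unknown sd_mode {sd_mode!r}")
    ddof = 0 if sd_mode == "population" else 1
    tids = pd.Series(transcript_of).reindex(counts.index)
    if tids.isna().any():
        missing = counts.index[tids.isna()].tolist()[:5]
        raise ValueError(f"exons without transcript assignment, e.g. {missing}")
    values = counts.to_numpy(dtype=float)
    grouped = counts.groupby(tids.to_numpy())
    mu = grouped.transform("mean").to_numpy()
    sigma = grouped.transform("std", ddof=ddof).to_numpy()
    sizes = tids.map(tids.value_counts()).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        scaled = (values - mu) / sigma
    scaled[(sigma == 0) | np.isnan(sigma)] = np.nan
    scaled[sizes < 2, :] = np.nan
    return pd.DataFrame(scaled, index=counts.index, columns=counts.columns)


def _control_reference(
    scaled: np.ndarray, control_cols: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-exon control mean, SD (ddof) and number of defined control values."""
    sub = scaled[:, control_cols]
    ok = ~np.isnan(sub)
    n = ok.sum(axis=1)
    filled = np.where(ok, sub, 0.0)
    total = filled.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean = np.where(n > 0, total / n, np.nan)
        ss = (np.where(ok, sub - mean[:, None], 0.0) ** 2).sum(axis=1)
        sd = np.where(n > ddof, np.sqrt(ss / np.maximum(n - ddof, 1)), np.nan)
    return mean, sd, n


def exon_zscores(
    scaled: pd.DataFrame,
    sample_sheet: SampleSheet,
    ddof: int = 1,
) -> pd.DataFrame:
    """Case-sample z-scores against the control reference distribution.

    z(exon, case) = (s_case - mean of control s) / SD of control s, with the
    sample SD convention (ddof=1) by default. Rows with fewer than two
    defined control values or zero control SD are NaN throughout.
    """
    cols = list(scaled.columns)
    control_cols = np.array([c in set(sample_sheet.controls) for c in cols])
    case_names = [c for c in cols if c in set(sample_sheet.cases)]
    case_cols = np.array([c in set(sample_sheet.cases) for c in cols])
    arr = scaled.to_numpy(dtype=float)
    mean, sd, n = _control_reference(arr, control_cols, ddof=ddof)
    bad = (n < 2) | ~(sd > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (arr[:, case_cols] - mean[:, None]) / sd[:, None]
    z[bad] = np.nan
    return pd.DataFrame(z, index=scaled.index, columns=case_names)


def _select(
    z: np.ndarray,
    control_reads: np.ndarray,
    config: SelectionConfig,
    defined: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized up/down masks; ``defined`` marks rows with a valid
    control reference. control_reads is already reduced per the mode."""
    reads_ok = control_reads > config.min_control_reads
    with np.errstate(invalid="ignore"):
        n_up = (z > config.z_threshold).sum(axis=1)
        n_down = (z < -config.z_threshold).sum(axis=1)
    up = defined & reads_ok & (n_up >= config.min_cases)
    down = defined & reads_ok & (n_down >= config.min_cases)
    return up, down


def _control_read_stat(
    counts: np.ndarray, control_cols: np.ndarray, mode: str
) -> np.ndarray:
    sub = counts[:, control_cols]
    return sub.min(axis=1) if mode == "per_sample" else sub.sum(axis=1)


def select_exons(
    z: pd.DataFrame,
    control_total_reads: pd.Series,
    config: SelectionConfig | None = None,
) -> ExonScanResult:
    """Apply the selection thresholds to precomputed z-scores.

    ``control_total_reads`` must already be the per-exon statistic matching
    the configured mode (sum over controls by default).
    """
    config = config or SelectionConfig()
    reads = control_total_reads.reindex(z.index).to_numpy(dtype=float)
    arr = z.to_numpy(dtype=float)
    defined = ~np.all(np.isnan(arr), axis=1)
    up, down = _select(arr, reads, config, defined)
    both = up & down
    only_up = up & ~both
    only_down = down & ~both
    reads_ok = reads > config.min_control_reads
    excluded = {
        EXCLUDED_CONTROL_SD_ZERO: list(z.index[~defined]),
        EXCLUDED_READ_FILTER: list(z.index[defined & ~reads_ok]),
    }
    return ExonScanResult(
        selected_up=sorted(z.index[only_up]),
        selected_down=sorted(z.index[only_down]),
        ambiguous=sorted(z.index[both]),
        excluded=excluded,
    )


def scan(
    counts: pd.DataFrame,
    transcript_of: dict[str, str] | pd.Series,
    sample_sheet: SampleSheet,
    config: SelectionConfig | None = None,
    sd_mode: str = "population",
    reference_ddof: int = 1,
) -> ExonScanResult:
    """Full exon scan: scaling, control-referenced z-scores, selection.

    Returns an :class:`ExonScanResult` whose ``table`` holds per-exon
    control read totals, control reference statistics and per-case
    z-scores.
    """
    config = config or SelectionConfig()
    scaled = scale_within_transcript(counts, transcript_of, sd_mode=sd_mode)
    z = exon_zscores(scaled, sample_sheet, ddof=reference_ddof)
    control_cols = np.array([c in set(sample_sheet.controls) for c in counts.columns])
    reads = pd.Series(
        _control_read_stat(counts.to_numpy(dtype=float), control_cols,
                           config.control_reads_mode),
        index=counts.index,
    )
    result = select_exons(z, reads, config)
    # zero-variance scaling exclusions (per-exon: all samples NaN in scaled)
    all_nan_scaled = scaled.isna().all(axis=1)
    result.excluded[EXCLUDED_ZERO_VARIANCE] = list(scaled.index[all_nan_scaled])
    tids = pd.Series(transcript_of).reindex(counts.index)
    table = pd.DataFrame({
        "transcript_id": tids,
        "control_total_reads": reads,
    })
    table = table.join(z.add_prefix("z_"))
    status = pd.Series("not_selected", index=counts.index)
    status[result.selected_up] = "up"
    status[result.selected_down] = "down"
    status[result.ambiguous] = "ambiguous"
    status[result.excluded[EXCLUDED_CONTROL_SD_ZERO]] = EXCLUDED_CONTROL_SD_ZERO
    table["status"] = status
    result.table = table
    return result


def _n_selected_for_labels(
    scaled: np.ndarray,
    counts: np.ndarray,
    control_cols: np.ndarray,
    config: SelectionConfig,
    reference_ddof: int,
) -> int:
    mean, sd, n = _control_reference(scaled, control_cols, ddof=reference_ddof)
    defined = (n >= 2) & (sd > 0)
    case_cols = ~control_cols
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (scaled[:, case_cols] - mean[:, None]) / sd[:, None]
    z[~defined] = np.nan
    reads = _control_read_stat(counts, control_cols, config.control_reads_mode)
    up, down = _select(z, reads, config, defined)
    return int((up | down).sum())


def permutation_null(
    counts: pd.DataFrame,
    transcript_of: dict[str, str] | pd.Series,
    sample_sheet: SampleSheet,
    config: SelectionConfig | None = None,
    n_permutations: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
    exhaustive_cap: int = 200_000,
    sd_mode: str = "population",
    reference_ddof: int = 1,
    p_convention: str = "plugin",
) -> PermutationNull:
    """Permutation null for the number of selected exons.

    Labels are shuffled across all samples, preserving group sizes; scaling
    is label-independent and computed once. In exhaustive mode all distinct
    control/case assignments are enumerated (up to ``exhaustive_cap``).
    The plug-in p-value is the fraction of permutations whose selection
    count is at least the observed count; the (r+1)/(R+1) convention is
    available as ``p_convention="add_one"``.
    """
    config = config or SelectionConfig()
    if n_permutations < 1 and not exhaustive:
        raise ValueError("n_permutations must be >= 1")
    if p_convention not in ("plugin", "add_one"):
        raise ValueError(f"unknown p_convention {p_convention!r}")
    scaled = scale_within_transcript(counts, transcript_of, sd_mode=sd_mode).to_numpy()
    arr = counts.to_numpy(dtype=float)
    cols = list(counts.columns)
    control_set = set(sample_sheet.controls)
    observed_cols = np.array([c in control_set for c in cols])
    n_controls = int(observed_cols.sum())
    n_samples = len(cols)

    observed = _n_selected_for_labels(scaled, arr, observed_cols, config,
                                      reference_ddof)
    if exhaustive:
        n_distinct = math.comb(n_samples, n_controls)
        if n_distinct > exhaustive_cap:
            raise ValueError(
                f"{n_distinct} labelings exceed the exhaustive cap {exhaustive_cap}"
            )
        assignments = combinations(range(n_samples), n_controls)
        null_counts = np.empty(n_distinct, dtype=np.int64)
        for i, ctrl in enumerate(assignments):
            mask = np.zeros(n_samples, dtype=bool)
            mask[list(ctrl)] = True
            null_counts[i] = _n_selected_for_labels(scaled, arr, mask, config,
                                                    reference_ddof)
        n_perm = n_distinct
    else:
        rng = np.random.default_rng(seed)
        null_counts = np.empty(n_permutations, dtype=np.int64)
        for i in range(n_permutations):
            ctrl = rng.choice(n_samples, size=n_controls, replace=False)
            mask = np.zeros(n_samples, dtype=bool)
            mask[ctrl] = True
            null_counts[i] = _n_selected_for_labels(scaled, arr, mask, config,
                                                    reference_ddof)
        n_perm = n_permutations
    r = int((null_counts >= observed).sum())
    if p_convention == "plugin":
        p_value = r / n_perm
    else:
        p_value = (r + 1) / (n_perm + 1)
    return PermutationNull(
        n_permutations=n_perm,
        null_counts=null_counts,
        observed=observed,
        p_value=float(p_value),
        seed=seed,
        exhaustive=exhaustive,
        config=config,
    )


def write_scan_result(result: ExonScanResult, table_path, summary_path=None) -> None:
    """Write the per-exon detail table and an optional JSON summary."""
    if result.table is not None:
        result.table.to_csv(table_path, sep="\t")
    if summary_path is not None:
        with open(summary_path, "w") as handle:
            json.dump(result.summary(), handle, indent=2)
            handle.write("\n")
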