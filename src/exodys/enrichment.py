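"""Term over-representation by the one-sided hypergeometric test.

For a study gene set of size n drawn from a background of size N, a term
annotating K background genes and k study genes has upper-tail probability

    p_raw = sum_{j >= k} C(K, j) C(N - K, n - j) / C(N, n)

Bonferroni correction multiplies by the number of terms that still annotate
at least one background gene after intersection with the background. Only
over-representation is tested; annotations are used as given (no ontology
graph propagation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TermAnnotation:
    term_id: str
    term_name: str
    annotated_genes: frozenset[str]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # study genes annotated
    n: int  # study set size
    K: int  # background genes annotated
    N: int  # background size
    p_raw: float
    p_bonferroni: float


def canonical(symbol: str) -> str:
    return symbol.strip().upper()


def canonical_set(symbols) -> set[str]:
    return {canonical(s) for s in symbols if str(s).strip()}


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X hypergeometric(N, K, n)."""
    if not 0 <= k <= min(n, K):
        raise ValueError(f"impossible contingency: k={k}, n={n}, K={K}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich(
    study_set,
    background,
    annotations: list[TermAnnotation],
    lenient: bool = False,
) -> list[EnrichmentResult]:
    """Over-representation of every term in the study set vs the background.

    Study genes absent from the background raise an error naming them, or
    are dropped with a warning under ``lenient``. Results are sorted by
    Bonferroni-corrected p-value, then term_id.
    """
    study = canonical_set(study_set)
    bg = canonical_set(background)
    stray = sorted(study - bg)
    if stray:
        if not lenient:
            raise ValueError(f"study genes absent from background: {stray}")
        logger.warning("dropping %d study genes absent from background: %s",
                       len(stray), stray[:10])
        study -= set(stray)
    n = len(study)
    N = len(bg)
    tested = []
    for term in annotations:
        annotated = canonical_set(term.annotated_genes) & bg
        if not annotated:
            continue
        tested.append((term, annotated))
    m = len(tested)
    results = []
    for term, annotated in tested:
        K = len(annotated)
        k = len(annotated & study)
        p_raw = hypergeom_upper_tail(k, n, K, N)
        results.append(EnrichmentResult(
            term_id=term.term_id,
            term_name=term.term_name,
            k=k, n=n, K=K, N=N,
            p_raw=p_raw,
            p_bonferroni=min(1.0, p_raw * m),
        ))
    results.sort(key=lambda r: (r.p_bonferroni, r.term_id))
    return results


def results_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def read_term_annotations(path, dialect: str = "tsv") -> list[TermAnnotation]:
    """Read term -> gene annotations.

    ``tsv``: two or three columns (term_id, gene_symbol[, term_name]).
    ``gaf``: GAF 2.x; symbol from column 3, term from column 5.
    """
    genes_by_term: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            fields = line.split("\t")
            if dialect == "gaf":
                if len(fields) < 5:
                    continue
                symbol, term = fields[2], fields[4]
            elif dialect == "tsv":
                if len(fields) < 2:
                    raise ValueError(f"{path}: need at least 2 columns per line")
                term, symbol = fields[0], fields[1]
                if len(fields) >= 3:
                    names[term] = fields[2]
            else:
                raise ValueError(f"unknown annotation dialect {dialect!r}")
            if term == "term_id":  # header
                continue
            genes_by_term.setdefault(term, set()).add(canonical(symbol))
    return [
        TermAnnotation(term_id=t, term_name=names.get(t, t),
                       annotated_genes=frozenset(g))
        for t, g in sorted(genes_by_term.items())
    ]


def read_gene_list(path) -> set[str]:
    """One gene symbol per line."""
    with open(path) as handle:
        return canonical_set(line for line in handle)


def write_results(results: list[EnrichmentResult], path) -> None:
    results_frame(results).to_csv(path, sep="\t", index=False)
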