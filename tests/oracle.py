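"""Independent brute-force recomputation of the exon scan, pure Python.

Used as the reference in oracle-equivalence tests: recomputes the
within-transcript scaling, control-referenced z-scores and selection from
first principles with the ``statistics`` module, no numpy/pandas, no code
shared with the package implementation.
"""

import statistics


def oracle_scale(counts, transcript_of, sd_mode="population"):
    """counts: {exon: {sample: int}} -> {exon: {sample: float|None}}."""
    samples = sorted(next(iter(counts.values())).keys()) if counts else []
    exons_by_tid = {}
    for exon in counts:
        exons_by_tid.setdefault(transcript_of[exon], []).append(exon)
    scaled = {e: {} for e in counts}
    for tid, exons in exons_by_tid.items():
        for sample in samples:
            values = [counts[e][sample] for e in exons]
            if len(values) < 2:
                for e in exons:
                    scaled[e][sample] = None
                continue
            mu = statistics.mean(values)
            if sd_mode == "population":
                sigma = statistics.pstdev(values)
            else:
                sigma = statistics.stdev(values)
            for e in exons:
                if sigma == 0:
                    scaled[e][sample] = None
                else:
                    scaled[e][sample] = (counts[e][sample] - mu) / sigma
    return scaled


def oracle_zscores(scaled, controls, cases):
    """-> {exon: {case: float}} for exons with a valid control reference."""
    z = {}
    for exon, row in scaled.items():
        ctrl = [row[c] for c in controls if row.get(c) is not None]
        if len(ctrl) < 2:
            continue
        mean = statistics.mean(ctrl)
        sd = statistics.stdev(ctrl)
        if sd <= 0:
            continue
        z[exon] = {
            case: (row[case] - mean) / sd
            for case in cases
            if row.get(case) is not None
        }
    return z


def oracle_select(counts, transcript_of, controls, cases,
                  min_control_reads=50, z_threshold=4.0, min_cases=5,
                  sd_mode="population"):
    """Full scan from scratch -> (up set, down set, ambiguous set)."""
    scaled = oracle_scale(counts, transcript_of, sd_mode=sd_mode)
    z = oracle_zscores(scaled, controls, cases)
    up, down = set(), set()
    for exon, zc in z.items():
        reads = sum(counts[exon][c] for c in controls)
        if not reads > min_control_reads:
            continue
        n_up = sum(1 for v in zc.values() if v > z_threshold)
        n_down = sum(1 for v in zc.values() if v < -z_threshold)
        if n_up >= min_cases:
            up.add(exon)
        if n_down >= min_cases:
            down.add(exon)
    ambiguous = up & down
    return up - ambiguous, down - ambiguous, ambiguous


def oracle_hypergeom_tail(k, n, K, N):
    """P(X >= k) by explicit enumeration of the hypergeometric pmf."""
    from math import comb

    total = comb(N, n)
    acc = 0
    for j in range(k, min(n, K) + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return acc / total
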