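import numpy as np
import pandas as pd
import pytest

from exodys.counting import count_exon_hits, count_gene_hits
from exodys.synthetic_data import (
    ConfigError,
    DecoyConfig,
    SimulationConfig,
    make_sample_sheet,
    simulate_alignments,
    simulate_annotation,
    simulate_counts,
)


class TestConfig:
    def test_defaults_match_study_design(self):
        config = SimulationConfig()
        assert config.n_controls == 8
        assert config.n_cases == 11

    @pytest.mark.parametrize("kwargs", [
        {"exon_length": (500, 80)},
        {"planted_fraction": 1.5},
        {"fold_change": 1.0},
        {"nb_dispersion": -0.1},
    ])
    def test_infeasible_config_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs)


class TestSimulateAnnotation:
    def test_seeded_determinism(self):
        config = SimulationConfig(n_genes=10, seed=1)
        a = simulate_annotation(config)
        b = simulate_annotation(config)
        assert a.exons == b.exons

    def test_exon_arithmetic(self):
        config = SimulationConfig(
            n_genes=4, transcripts_per_gene=(1, 1), exons_per_transcript=(3, 3)
        )
        model = simulate_annotation(config)
        assert model.n_exons == 12
        assert len(model.genes) == 4

    def test_empty_model(self):
        assert simulate_annotation(SimulationConfig(n_genes=0)).n_exons == 0

    def test_genes_do_not_overlap(self):
        model = simulate_annotation(SimulationConfig(n_genes=30, seed=3))
        spans = {}
        for gid, merged in model.merged_exons.items():
            chrom = model.gene_chrom[gid]
            spans.setdefault(chrom, []).append((merged[0][0], merged[-1][1]))
        for intervals in spans.values():
            intervals.sort()
            assert all(a[1] <= b[0] for a, b in zip(intervals, intervals[1:]))


class TestSimulateCounts:
    def test_seeded_determinism(self):
        config = SimulationConfig(n_genes=5, seed=4)
        model = simulate_annotation(config)
        m1, t1 = simulate_counts(model, config)
        m2, t2 = simulate_counts(model, config)
        assert m1.exon_counts.equals(m2.exon_counts)
        assert t1.frame.equals(t2.frame)

    def test_no_planting_yields_empty_truth(self):
        config = SimulationConfig(n_genes=5, planted_fraction=0.0, seed=5)
        model = simulate_annotation(config)
        _, truth = simulate_counts(model, config)
        assert len(truth) == 0

    def test_truth_exons_exist_in_annotation(self):
        config = SimulationConfig(n_genes=60, planted_fraction=0.05, seed=6)
        model = simulate_annotation(config)
        _, truth = simulate_counts(model, config)
        assert len(truth) > 0
        assert truth.exon_ids <= set(model.exon_ids())

    def test_at_most_one_planted_exon_per_transcript(self):
        config = SimulationConfig(n_genes=80, planted_fraction=0.1, seed=7)
        model = simulate_annotation(config)
        _, truth = simulate_counts(model, config)
        tid_of = model.transcript_of()
        tids = [tid_of[e] for e in truth.frame["exon_id"]]
        assert len(tids) == len(set(tids))

    def test_nb_mean_variance_relation(self):
        # fixed baseline mean, no library variation: every draw is iid
        # NB(mean=500, var=500 + disp*500^2); >=10,000 draws
        config = SimulationConfig(
            n_genes=60, transcripts_per_gene=(1, 1), exons_per_transcript=(10, 10),
            baseline_mean=(500.0, 500.0), library_size_cv=0.0,
            nb_dispersion=0.05, planted_fraction=0.0, seed=8,
        )
        model = simulate_annotation(config)
        matrix, _ = simulate_counts(model, config)
        draws = matrix.exon_counts.to_numpy().ravel()
        assert draws.size >= 10_000
        expected_var = 500 + 0.05 * 500 ** 2
        se_mean = np.sqrt(expected_var / draws.size)
        assert abs(draws.mean() - 500) < 3 * se_mean
        assert abs(draws.var() - expected_var) / expected_var < 0.10

    def test_planted_fold_change_in_case_means(self):
        # low-noise counts: the mean case/control ratio over planted-up
        # exons (inverted for planted-down) must sit at the fold change
        config = SimulationConfig(
            n_genes=250, transcripts_per_gene=(1, 1),
            nb_dispersion=0.02, library_size_cv=0.0,
            planted_fraction=0.05, fold_change=8.0, seed=9,
        )
        model = simulate_annotation(config)
        matrix, truth = simulate_counts(model, config)
        sheet = make_sample_sheet(config)
        ratios = []
        for _, row in truth.frame.iterrows():
            ctrl = matrix.exon_counts.loc[row.exon_id, sheet.controls].mean()
            case = matrix.exon_counts.loc[row.exon_id, sheet.cases].mean()
            ratio = case / ctrl
            ratios.append(ratio if row.direction == "up" else 1 / ratio)
        ratios = np.asarray(ratios)
        assert len(ratios) >= 20
        se = ratios.std(ddof=1) / np.sqrt(len(ratios))
        assert abs(ratios.mean() - 8.0) < 3 * se + 0.2


class TestSimulateAlignments:
    @pytest.fixture
    def tiny(self):
        config = SimulationConfig(
            n_genes=4, transcripts_per_gene=(1, 1), exons_per_transcript=(3, 5),
            baseline_mean=(5.0, 20.0), planted_fraction=0.0,
            n_controls=2, n_cases=2, seed=10,
        )
        model = simulate_annotation(config)
        matrix, _ = simulate_counts(model, config)
        return config, model, matrix

    def test_round_trip_identity_without_decoys(self, tiny):
        config, model, matrix = tiny
        reads = simulate_alignments(model, matrix, config)
        counted = count_exon_hits(reads, model)
        expected = matrix.exon_counts
        assert counted.loc[expected.index, expected.columns].equals(
            expected.astype(counted.dtypes.iloc[0])
        )

    def test_decoys_do_not_change_exon_counts(self, tiny):
        config, model, matrix = tiny
        decoys = DecoyConfig(n_antisense=5, n_mapq0=5, n_intergenic=3, n_junction=3)
        reads = simulate_alignments(model, matrix, config, decoys=decoys)
        counted = count_exon_hits(reads, model)
        expected = matrix.exon_counts
        assert counted.loc[expected.index, expected.columns].equals(
            expected.astype(counted.dtypes.iloc[0])
        )

    def test_junction_decoys_raise_gene_counts_only(self, tiny):
        config, model, matrix = tiny
        plain = simulate_alignments(model, matrix, config)
        decoyed = simulate_alignments(
            model, matrix, config, decoys=DecoyConfig(n_junction=3)
        )
        g0, _ = count_gene_hits(plain, model)
        g1, _ = count_gene_hits(decoyed, model)
        n_samples = matrix.exon_counts.shape[1]
        assert g1.to_numpy().sum() == g0.to_numpy().sum() + 3 * n_samples

    def test_gene_counts_sum_exon_counts_for_single_exon_reads(self, tiny):
        # every simulated read hits exactly one exon, and these genes have a
        # single transcript, so gene hits must equal summed exon hits
        config, model, matrix = tiny
        reads = simulate_alignments(model, matrix, config)
        gene_counts, _ = count_gene_hits(reads, model)
        exon_counts = count_exon_hits(reads, model)
        gene_of = model.gene_of_transcript()
        tid_of = model.transcript_of()
        summed = exon_counts.groupby(
            exon_counts.index.map(lambda e: gene_of[tid_of[e]])
        ).sum()
        assert gene_counts.loc[summed.index, summed.columns].equals(summed)

    def test_reads_lie_within_their_exon(self, tiny):
        config, model, matrix = tiny
        reads = simulate_alignments(model, matrix, config)
        trees = {(e.chrom, e.strand, e.start, e.end) for e in model.exons}
        for row in reads.itertuples(index=False):
            assert any(
                c == row.chrom and s == row.strand and a <= row.start and row.end <= b
                for c, s, a, b in trees
            )
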