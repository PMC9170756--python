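import math

import numpy as np
import pytest

from silacpipe.enrichment import enrich
from silacpipe.io_formats import ExperimentDesign, SchemaError, with_orientations
from silacpipe.pattern_classifier import classify_summaries, summarize_patterns
from silacpipe.ratio_processing import summarize_records
from silacpipe.synthetic_data import (
    SimulationSpec,
    exemplar_summaries,
    read_truth_table,
    simulate_annotations,
    simulate_dataset,
    true_folds,
    write_truth_table,
)
from silacpipe.tf_overlap import filter_tf_targets


class TestSimulationSpec:
    def test_defaults_valid(self):
        SimulationSpec()

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"fold_up": 1.5},  # inside the no-change band
            {"fold_down": 0.6},
            {"enhancement_fold": 1.2},
            {"pattern_mix": {"P1": 0.5}},
            {"pattern_mix": {"P1": 0.5, "BAD": 0.5}},
            {"missing_prob": 1.0},
            {"log2_noise_sd": -0.1},
        ],
    )
    def test_infeasible_specs_rejected(self, kwargs):
        with pytest.raises(SchemaError):
            SimulationSpec(**kwargs)


class TestSimulateDataset:
    def test_zero_noise_p6_exact(self):
        spec = SimulationSpec(
            n_proteins=5, pattern_mix={"P6": 1.0}, log2_noise_sd=0.0, seed=3
        )
        records, truths = simulate_dataset(spec)
        assert all(t.true_pattern == "P6" for t in truths)
        summaries = summarize_records(records, spec.design)
        for s in summaries:
            assert s.pa_mean == pytest.approx(4.0, rel=1e-12)
            assert s.combined_mean == pytest.approx(1.0, rel=1e-12)

    def test_seeded_determinism(self, tmp_path):
        from silacpipe.io_formats import write_quant_table

        spec = SimulationSpec(n_proteins=50, seed=9, missing_prob=0.2)
        a, ta = simulate_dataset(spec)
        b, tb = simulate_dataset(spec)
        assert a == b and ta == tb
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_quant_table(a, p1)
        write_quant_table(b, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_substreams_stable_under_growth(self):
        small, truths_small = simulate_dataset(SimulationSpec(n_proteins=20, seed=4))
        large, truths_large = simulate_dataset(SimulationSpec(n_proteins=40, seed=4))
        assert truths_large[:20] == truths_small
        assert large[: len(small)] == small

    def test_missingness_rate(self):
        spec = SimulationSpec(n_proteins=2000, seed=5, missing_prob=0.3)
        records, _ = simulate_dataset(spec)
        observed_rate = len(records) / (2000 * 3)
        assert observed_rate == pytest.approx(0.7, abs=0.02)

    def test_noise_free_full_pipeline_recovery(self):
        spec = SimulationSpec(n_proteins=600, log2_noise_sd=0.0, seed=21)
        records, truths = simulate_dataset(spec)
        assignments = {
            a.protein_id: a.pattern
            for a in classify_summaries(summarize_records(records, spec.design))
        }
        assert all(assignments[t.protein_id] == t.true_pattern for t in truths)

    def test_forward_vs_reverse_only_identical_summaries(self):
        base = SimulationSpec(n_proteins=300, seed=13, log2_noise_sd=0.3)
        fwd_spec = SimulationSpec(
            **{**_spec_kwargs(base), "design": with_orientations(base.design, "forward")}
        )
        rev_spec = SimulationSpec(
            **{**_spec_kwargs(base), "design": with_orientations(base.design, "reverse")}
        )
        fwd_records, fwd_truth = simulate_dataset(fwd_spec)
        rev_records, rev_truth = simulate_dataset(rev_spec)
        assert fwd_truth == rev_truth
        fwd_summaries = summarize_records(fwd_records, fwd_spec.design)
        rev_summaries = summarize_records(rev_records, rev_spec.design)
        assert fwd_summaries == rev_summaries

    def test_null_fraction_matches_independent_generator(self):
        # same statistic from an independently coded vectorized generator
        n, sd = 10_000, 0.8
        spec = SimulationSpec(
            n_proteins=n, pattern_mix={"P1": 1.0}, log2_noise_sd=sd, seed=99
        )
        records, _ = simulate_dataset(spec)
        summary = summarize_patterns(
            classify_summaries(summarize_records(records, spec.design))
        )
        frac = 1.0 - summary.proportions["P1"]

        rng = np.random.default_rng(123456)  # independent stream
        pa = np.mean(2.0 ** (sd * rng.standard_normal((n, 3))), axis=1)
        combined = np.mean(2.0 ** (sd * rng.standard_normal((n, 3))), axis=1)
        null = (pa > 0.5) & (pa < 2.0) & (combined > 0.5) & (combined < 2.0)
        frac_oracle = 1.0 - null.mean()

        p = max(frac, frac_oracle, 1e-6)
        se = math.sqrt(2 * p * (1 - p) / n)
        assert abs(frac - frac_oracle) <= 4 * se


def _spec_kwargs(spec):
    return {
        "n_proteins": spec.n_proteins,
        "pattern_mix": dict(spec.pattern_mix),
        "log2_noise_sd": spec.log2_noise_sd,
        "missing_prob": spec.missing_prob,
        "seed": spec.seed,
    }


@pytest.fixture(scope="module")
def truth():
    spec = SimulationSpec(
        n_proteins=1500,
        pattern_mix={"P1": 0.7, "P6": 0.3},
        seed=17,
    )
    _, truths = simulate_dataset(spec)
    return truths


class TestSimulateAnnotations:
    def test_null_planting_indistinguishable(self, truth):
        factors = []
        for seed in range(15):
            annotated, gene_sets, _ = simulate_annotations(
                truth, n_sets=5, planted_set=("PLANTED", "P6", 1.0), seed=seed
            )
            background = {t.gene_symbol for t in truth}
            query = {t.gene_symbol for t in truth if t.true_pattern == "P6"}
            results = enrich(query, gene_sets, background)
            planted = next(r for r in results if r.set_name == "PLANTED")
            factors.append(planted.enrichment_factor)
        assert abs(float(np.median(factors)) - 1.0) < 0.35

    def test_planted_odds_enriched(self, truth):
        _, gene_sets, _ = simulate_annotations(
            truth, n_sets=5, planted_set=("PLANTED", "P6", 8.0), seed=0, set_size=50
        )
        background = {t.gene_symbol for t in truth}
        query = {t.gene_symbol for t in truth if t.true_pattern == "P6"}
        results = enrich(query, gene_sets, background)
        assert results[0].set_name == "PLANTED"
        assert results[0].passes_filters

    def test_no_filter_failures_means_identity(self, truth):
        annotated, _, tf_records = simulate_annotations(
            truth, n_sets=0, seed=2, filter_fail_frac=0.0
        )
        flagged = {t.gene_symbol for t in annotated if t.is_tf_target}
        assert filter_tf_targets(tf_records) == flagged

    def test_filter_failures_reduce_targets(self, truth):
        annotated, _, tf_records = simulate_annotations(
            truth, n_sets=0, seed=2, filter_fail_frac=0.5
        )
        flagged = {t.gene_symbol for t in annotated if t.is_tf_target}
        kept = filter_tf_targets(tf_records)
        assert kept < flagged
        assert len(kept) / len(flagged) == pytest.approx(0.5, abs=0.1)

    def test_memberships_recorded(self, truth):
        annotated, gene_sets, _ = simulate_annotations(truth, n_sets=3, seed=8)
        by_name = {gs.set_name: gs.genes for gs in gene_sets}
        for t in annotated[:200]:
            for name in t.member_sets:
                assert t.gene_symbol in by_name[name]

    def test_empty_truth_rejected(self):
        with pytest.raises(SchemaError):
            simulate_annotations([], n_sets=1)


class TestExemplarSummaries:
    def test_counts_realized_exactly(self, table2):
        counts, _ = table2
        summaries = exemplar_summaries(counts)
        assert len(summaries) == sum(counts.values())
        summary = summarize_patterns(classify_summaries(summaries))
        assert dict(summary.counts) == counts

    def test_folds_consistent_with_pattern(self):
        spec = SimulationSpec()
        for pattern in ("P1", "P4", "P6", "P9"):
            pa, combined = true_folds(pattern, spec)
            assert pa > 0 and combined > 0


def test_truth_table_roundtrip(tmp_path):
    spec = SimulationSpec(n_proteins=30, seed=2)
    _, truths = simulate_dataset(spec)
    truths, _, _ = simulate_annotations(truths, n_sets=2, seed=2)
    path = tmp_path / "truth.tsv"
    write_truth_table(truths, path)
    assert read_truth_table(path) == truths
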