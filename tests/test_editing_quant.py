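"""Editing-degree computation, germline filtering and the retention rule."""

import numpy as np
import pandas as pd
import pytest

from mitoedit import (
    EditingModel,
    GeneModel,
    NotACandidateError,
    call_sites,
    compute_observations,
    editing_degree,
    filter_germline,
)


class TestEditingDegree:
    def test_plus_strand_fraction(self):
        assert editing_degree({"C": 12, "T": 88}, "C", "+") == pytest.approx(88.0)

    def test_minus_strand_ignores_noise_bases(self):
        # plus-strand pileup of a minus-strand gene: G unedited, A edited
        assert editing_degree({"G": 50, "A": 50, "C": 1}, "G", "-") == pytest.approx(50.0)

    def test_zero_and_low_depth_are_null(self):
        assert editing_degree({}, "C", "+") is None
        assert editing_degree({"C": 4, "T": 5}, "C", "+", min_depth=10) is None
        assert editing_degree({"C": 5, "T": 5}, "C", "+", min_depth=10) == pytest.approx(50.0)

    def test_wrong_reference_base_is_not_a_candidate(self):
        with pytest.raises(NotACandidateError):
            editing_degree({"A": 10, "G": 90}, "A", "+")
        with pytest.raises(NotACandidateError):
            editing_degree({"C": 10, "T": 90}, "C", "-")


def _candidates(n, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "chrom": "m",
            "pos": np.arange(1, n + 1) * 10,
            "strand": rng.choice(["+", "-"], size=n),
            "degree": 50.0,
        }
    )


class TestGermlineFilter:
    def test_matching_alt_removed_and_empty_set_retains(self):
        cand = _candidates(1)
        alt = "T" if cand.loc[0, "strand"] == "+" else "A"
        assert len(filter_germline(cand, {("m", 10, alt)})) == 0
        assert len(filter_germline(cand, set())) == 1

    def test_mismatched_alt_retained(self):
        cand = _candidates(1)
        other = "A" if cand.loc[0, "strand"] == "+" else "T"
        assert len(filter_germline(cand, {("m", 10, other)})) == 1

    def test_set_difference_oracle(self):
        """Filtering matches a plain set difference: 10 candidates minus 3
        overlapping germline variants with the matching alt leaves 7."""
        cand = _candidates(10, seed=3)
        overlap = cand.iloc[[1, 4, 8]]
        germ = {
            ("m", int(r["pos"]), "T" if r["strand"] == "+" else "A")
            for _, r in overlap.iterrows()
        }
        kept = filter_germline(cand, germ)
        assert len(kept) == 7
        assert set(kept["pos"]) == set(cand["pos"]) - set(overlap["pos"])

    def test_never_removes_absent_sites_output_subset(self):
        cand = _candidates(20, seed=5)
        germ = {("m", 999999, "T"), ("other", 10, "T")}
        kept = filter_germline(cand, germ)
        assert kept.equals(cand.loc[kept.index])
        assert len(kept) == len(cand)


def _obs(degrees_by_tissue, pos=100):
    """Observation frame for one site from {tissue: [rep degrees]}."""
    rows = []
    for t, degs in degrees_by_tissue.items():
        for r, d in enumerate(degs, start=1):
            rows.append(
                {
                    "chrom": "m",
                    "pos": pos,
                    "gene_id": "g",
                    "strand": "+",
                    "sample_id": f"{t}{r}",
                    "tissue": t,
                    "replicate": r,
                    "degree": d,
                    "informative_depth": 100,
                }
            )
    return pd.DataFrame(rows)


def _design(tissues=("N", "SR", "UR"), n_rep=3):
    return pd.DataFrame(
        [
            {"sample_id": f"{t}{r}", "tissue": t, "replicate": r}
            for t in tissues
            for r in range(1, n_rep + 1)
        ]
    )


class TestCallSites:
    def test_retained_when_one_tissue_all_replicates_pass(self):
        obs = _obs({"N": [16, 17, 20], "SR": [2, 3, 1], "UR": [0, 1, 2]})
        sites = call_sites(obs, _design())
        assert len(sites) == 1
        assert sites.loc[0, "mean_N"] == pytest.approx(np.mean([16, 17, 20]))
        assert sites.loc[0, "sd_N"] == pytest.approx(np.std([16, 17, 20], ddof=1))

    def test_dropped_when_one_replicate_below_threshold(self):
        obs = _obs({"N": [16, 14, 20], "SR": [2, 3, 1], "UR": [0, 1, 2]})
        assert len(call_sites(obs, _design())) == 0

    def test_null_replicate_fails_the_all_replicates_clause(self):
        obs = _obs({"N": [16, np.nan, 20], "SR": [1, 1, 1], "UR": [0, 0, 0]})
        assert len(call_sites(obs, _design())) == 0

    def test_boundary_inclusive(self):
        obs = _obs({"N": [15.0, 15.0, 15.0], "SR": [0, 0, 0], "UR": [0, 0, 0]})
        assert len(call_sites(obs, _design())) == 1

    def test_invariant_to_row_order(self, study, editing_results):
        obs = compute_observations(study.pileups, study.genes)
        shuffled = obs.sample(frac=1.0, random_state=42)
        a = call_sites(obs, study.design)
        b = call_sites(shuffled, study.design)
        pd.testing.assert_frame_equal(a, b)

    def test_threshold_monotonicity(self, study):
        """Raising min_degree never adds sites on a simulated panel."""
        obs = compute_observations(study.pileups, study.genes)
        counts = [len(call_sites(obs, study.design, min_degree=thr)) for thr in (5, 15, 30, 60, 90)]
        assert counts == sorted(counts, reverse=True)

    def test_empty_design_is_an_error(self):
        with pytest.raises(ValueError):
            call_sites(_obs({"N": [20, 20, 20]}), pd.DataFrame(columns=["sample_id", "tissue", "replicate"]))


class TestEstimatorRecovery:
    def test_degree_error_within_binomial_bound(self):
        """Mean absolute error of the per-replicate degree stays within
        three binomial standard errors at depth >= 100."""
        rng = np.random.default_rng(2024)
        for p in (0.1, 0.2, 0.5, 0.8, 0.95):
            for depth in (100, 200, 500):
                edited = rng.binomial(depth, p, size=400)
                degrees = 100.0 * edited / depth
                mae = np.abs(degrees - 100.0 * p).mean()
                assert mae <= 3.0 * np.sqrt(p * (1 - p) / depth) * 100.0


class TestEditingModelEndToEnd:
    def test_recovers_planted_sites_and_excludes_germline(self, study, editing_results):
        truth = study.truth_sites
        called = set(editing_results.sites["pos"])
        expected = set(truth.loc[truth["expected_called"], "pos"])
        tp = len(called & expected)
        assert tp / len(expected) >= 0.95
        assert len(called - expected) / max(len(called), 1) <= 0.05
        assert not called & set(study.germline["pos"])

    def test_unfiltered_model_calls_germline_mimics(self, study):
        res = EditingModel(study.pileups, study.design, study.genes).fit()
        assert set(study.germline["pos"]) <= set(res.sites["pos"])

    def test_summary_rounds_to_whole_percent(self, editing_results):
        s = editing_results.summary()
        assert len(s) == len(editing_results.sites)
        assert s.iloc[0]["N"].count("±") == 1
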