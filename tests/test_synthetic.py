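"""Tests of the synthetic-data generators against their stated models."""

import numpy as np
import pandas as pd
import pytest

from cimexvir import (AnchorSet, CladeScenario, VirusSpec, distance_matrix,
                      find_orfs, group_mean_distances, simulate_abundance_table,
                      simulate_divergent_family, simulate_presence_matrix,
                      simulate_transcript_with_orfs, t_co, v_co, AlignedSet)

from _oracles import jc_mismatch


class TestPresenceMatrix:
    def test_perfect_fidelity_forces_identity(self):
        virus = VirusSpec("v", 2, prevalence=1.0, fidelity=1.0, spillover=0.0)
        matrix, truth = simulate_presence_matrix(10, [virus], seed=1)
        assert matrix.to_numpy().all()
        anchors = AnchorSet("v", ["v_seg0"])
        assert v_co("v_seg1", anchors, matrix) == 1.0
        assert t_co("v_seg1", anchors, matrix) == 1.0

    def test_anchor_column_equals_carrier_indicator(self):
        """Fidelity applies only to non-anchor segments: with spillover 0 and
        fidelity 1, companion columns equal the anchor column exactly."""
        virus = VirusSpec("v", 3, prevalence=0.5, fidelity=1.0, spillover=0.0)
        matrix, truth = simulate_presence_matrix(200, [virus], seed=5)
        anchor_col = truth.query("role == 'anchor'")["transcript_id"].item()
        for seg in truth.query("role == 'segment'")["transcript_id"]:
            assert (matrix[seg] == matrix[anchor_col]).all()

    def test_companion_rate_matches_fidelity(self):
        """Among carriers the companion is detected at the fidelity rate."""
        virus = VirusSpec("v", 2, prevalence=1.0, fidelity=0.9, spillover=0.0)
        matrix, _ = simulate_presence_matrix(2000, [virus], seed=11)
        rate = matrix["v_seg1"].mean()  # every sample is a carrier
        se = np.sqrt(0.9 * 0.1 / 2000)
        assert abs(rate - 0.9) < 3 * se

    def test_background_marginals(self):
        """Background column sums are Binomial(n_samples, bg_rate)."""
        counts = []
        for seed in range(20):
            matrix, _ = simulate_presence_matrix(
                50, [], n_background=20, bg_rate=0.2, seed=seed)
            counts.append(matrix.to_numpy().sum())
        total = sum(counts)
        n_cells = 20 * 50 * 20
        se = np.sqrt(n_cells * 0.2 * 0.8)
        assert abs(total - 0.2 * n_cells) < 4 * se

    def test_truth_labels_every_column(self):
        virus = VirusSpec("v", 3, anchor_segment_index=1, prevalence=0.5)
        matrix, truth = simulate_presence_matrix(8, [virus], n_background=4,
                                                 bg_rate=0.3, seed=2)
        assert set(truth["transcript_id"]) == set(matrix.columns)
        assert truth.query("role == 'anchor'")["transcript_id"].item() == "v_seg1"
        assert (truth["role"] == "background").sum() == 4

    def test_determinism(self):
        virus = VirusSpec("v", 2, prevalence=0.4, fidelity=0.8, spillover=0.1)
        a = simulate_presence_matrix(30, [virus], 10, 0.2, seed=42)
        b = simulate_presence_matrix(30, [virus], 10, 0.2, seed=42)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        c = simulate_presence_matrix(30, [virus], 10, 0.2, seed=43)
        assert not a[0].equals(c[0])

    def test_empty_design_errors(self):
        with pytest.raises(ValueError, match="empty design"):
            simulate_presence_matrix(0, [VirusSpec("v", 2)], seed=0)
        with pytest.raises(ValueError, match="nothing to simulate"):
            simulate_presence_matrix(5, [], n_background=0, seed=0)

    def test_virus_spec_validation(self):
        with pytest.raises(ValueError):
            VirusSpec("v", 2, prevalence=0.0)
        with pytest.raises(ValueError):
            VirusSpec("v", 2, spillover=1.0)
        with pytest.raises(ValueError):
            VirusSpec("v", 2, anchor_segment_index=2)


class TestDivergentFamily:
    def test_zero_divergence_all_identical(self):
        fam, groups = simulate_divergent_family(
            CladeScenario((3, 2), 100, 0.0, 0.0), seed=3)
        seqs = {s for _, s in fam}
        assert len(seqs) == 1
        assert set(groups.values()) == {"cladeA", "cladeB"}

    def test_within_clade_distance_matches_closed_form(self):
        """Mean within-clade p-distance across seeds matches the two-branch
        closed-form mismatch probability within 3 Monte-Carlo SEs."""
        w = 0.03
        scenario = CladeScenario((4,), 5000, w, 0.0)
        means = []
        for seed in range(25):
            fam, _ = simulate_divergent_family(scenario, seed=seed)
            D = distance_matrix(AlignedSet([i for i, _ in fam],
                                           [s for _, s in fam]))
            means.append(D.d[np.triu_indices(4, 1)].mean())
        means = np.array(means)
        expected = jc_mismatch([w, w])
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expected) < 3 * se

    def test_pure_between_divergence_is_constant_across_pairs(self):
        fam, groups = simulate_divergent_family(
            CladeScenario((3, 3), 2000, 0.0, 0.2), seed=9)
        D = distance_matrix(AlignedSet([i for i, _ in fam], [s for _, s in fam]))
        between = [D.d[i, j] for i in range(3) for j in range(3, 6)]
        within = [D.d[i, j] for i in range(3) for j in range(i + 1, 3)]
        assert len(set(between)) == 1
        assert all(d == 0 for d in within)

    def test_between_exceeds_within_when_model_says_so(self):
        """between_divergence > within_divergence separates the group means."""
        scenario = CladeScenario((3, 3), 2000, 0.02, 0.15)
        for seed in range(20):
            fam, groups = simulate_divergent_family(scenario, seed=seed)
            D = distance_matrix(AlignedSet([i for i, _ in fam],
                                           [s for _, s in fam]))
            summary = group_mean_distances(D, groups)
            within = summary.query("kind == 'within'")["mean_distance"]
            between = summary.query("kind == 'between'")["mean_distance"]
            assert between.min() > within.max()

    def test_determinism_and_length(self):
        scenario = CladeScenario((2, 2), 500, 0.05, 0.1)
        a, _ = simulate_divergent_family(scenario, seed=21)
        b, _ = simulate_divergent_family(scenario, seed=21)
        assert a == b
        assert all(len(s) == 500 for _, s in a)

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(ValueError):
            CladeScenario((3,), 0, 0.1, 0.1)
        with pytest.raises(ValueError):
            CladeScenario((3,), 100, 1.0, 0.1)
        with pytest.raises(ValueError):
            CladeScenario((), 100, 0.1, 0.1)


class TestAbundanceTable:
    def test_zero_noise_is_exactly_linear(self):
        table = simulate_abundance_table(3, 2.0, 1.0, 0.0, x_values=[0, 1, 2],
                                         seed=0)
        assert list(table["pct_virus"]) == [1.0, 3.0, 5.0]

    def test_truncation_at_zero(self):
        table = simulate_abundance_table(50, -1.0, 0.1, 2.0, seed=13)
        assert (table["pct_virus"] >= 0).all()

    def test_mean_fitted_slope_is_unbiased(self):
        """OLS on simulated tables recovers the generating slope on average
        (no truncation active: intercept far above the noise floor)."""
        from cimexvir import AbundanceRegression
        slopes = []
        x = np.linspace(0.2, 10, 22)
        for seed in range(300):
            table = simulate_abundance_table(22, -0.04, 50.0, 0.5,
                                             x_values=x, seed=seed)
            est = AbundanceRegression().fit(table["pct_wolbachia"],
                                            table["pct_virus"])
            slopes.append(est.slope_)
        slopes = np.array(slopes)
        se = slopes.std(ddof=1) / np.sqrt(len(slopes))
        assert abs(slopes.mean() - (-0.04)) < 3 * se

    def test_degenerate_designs_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_abundance_table(2, 1.0, 0.0, 0.1, seed=0)
        with pytest.raises(ValueError, match="constant"):
            simulate_abundance_table(3, 1.0, 0.0, 0.1, x_values=[1, 1, 1], seed=0)


class TestTranscriptWithOrfs:
    def test_single_implant_found_exactly(self):
        seq, truth = simulate_transcript_with_orfs([9], [1], seed=0)
        found = find_orfs(seq, mode="start_to_stop_nt", min_len=3)
        assert [(r.frame, r.start, r.end, r.nt_seq) for r in found] \
            == [(r.frame, r.start, r.end, r.nt_seq) for r in truth]

    @pytest.mark.parametrize("frames", [[1, -2, 3], [-1, -3, 2], [2, 1, -1]])
    def test_mixed_strand_implants_recovered(self, frames):
        seq, truth = simulate_transcript_with_orfs([21, 45, 12], frames, seed=8)
        found = find_orfs(seq, mode="start_to_stop_nt")
        assert {(r.frame, r.start, r.end, r.nt_seq) for r in found} \
            == {(r.frame, r.start, r.end, r.nt_seq) for r in truth}

    def test_truth_records_are_consistent(self):
        seq, truth = simulate_transcript_with_orfs([30], [-2], spacer_len=18, seed=2)
        (record,) = truth
        assert record.end - record.start == 30 == len(record.nt_seq)
        assert record.aa_seq.startswith("M") and "*" not in record.aa_seq
        from Bio.Seq import reverse_complement
        assert reverse_complement(seq[record.start:record.end]) == record.nt_seq

    def test_non_codon_length_rejected(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            simulate_transcript_with_orfs([8], [1], seed=0)

    def test_determinism(self):
        a = simulate_transcript_with_orfs([15, 24], [1, -1], seed=6)
        b = simulate_transcript_with_orfs([15, 24], [1, -1], seed=6)
        assert a[0] == b[0] and a[1] == b[1]
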