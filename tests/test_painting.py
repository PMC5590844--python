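"""Copying-model engine: oracle equivalence, E-M behaviour, path sampling."""

import numpy as np
import pytest

from endopop.core_io import GroupAssignment
from endopop.painting import (CopyingParams, average_segment_size,
                              em_loglik_trace, fit_copying_params, paint,
                              posterior_marginals, sample_paths)
from endopop.synthetic_data import simulate_copying

from conftest import lis_enumeration_oracle, make_alignment


def _random_instance(rng, n_donors, n_sites):
    H = rng.integers(0, 2, (n_donors + 1, n_sites)).astype(np.uint8)
    cM = np.sort(rng.uniform(0, 15, n_sites))
    ids = [f"d{i}" for i in range(n_donors)] + ["rec"]
    aln = make_alignment(H, cM=cM, ids=ids)
    groups = GroupAssignment({f"d{i}": f"g{i % 2}" for i in range(n_donors)})
    return aln, groups


class TestForwardBackward:
    @pytest.mark.parametrize("n_donors,n_sites,seed", [(3, 5, 0), (4, 6, 1),
                                                       (2, 6, 2), (4, 5, 3)])
    def test_marginals_match_exhaustive_enumeration(self, n_donors, n_sites, seed):
        rng = np.random.default_rng(seed)
        aln, groups = _random_instance(rng, n_donors, n_sites)
        params = CopyingParams(switch_rate=40.0, emission_mismatch=0.07)
        post = posterior_marginals(aln, groups, "rec", params)["chr1"]
        oracle = lis_enumeration_oracle(
            aln.haplotypes[:n_donors], aln.haplotypes[n_donors],
            aln.site_pos_cM, params.switch_rate, params.emission_mismatch)
        # the panel may reorder donors by group; compare in panel order
        assert np.abs(post["gamma"][0] - oracle[:, post["donor_rows"]]).max() < 1e-9

    def test_posteriors_sum_to_one_at_every_site(self, small_panel):
        aln, groups = small_panel
        params = CopyingParams(switch_rate=25.0, emission_mismatch=0.02)
        gam = posterior_marginals(aln, groups, "rec", params)["chr1"]["gamma"]
        assert np.abs(gam.sum(axis=2) - 1).max() < 1e-9

    def test_no_underflow_at_1e5_sites(self):
        rng = np.random.default_rng(11)
        S = 100_000
        H = rng.integers(0, 2, (5, S)).astype(np.uint8)
        H = np.vstack([H, H[0]])
        cM = np.linspace(0, 300, S)
        aln = make_alignment(H, cM=cM,
                             ids=[f"d{i}" for i in range(5)] + ["rec"])
        groups = GroupAssignment({f"d{i}": "g" for i in range(5)})
        summary = paint(aln, groups, "rec",
                        CopyingParams(switch_rate=50.0, emission_mismatch=0.01))
        assert np.isfinite(summary.copied_cM.to_numpy()).all()
        assert summary.profile.sum() == pytest.approx(1.0, abs=1e-9)


class TestPaint:
    def test_single_donor_group_profile_is_one(self):
        rng = np.random.default_rng(7)
        H = rng.integers(0, 2, (4, 10)).astype(np.uint8)
        aln = make_alignment(H, cM=np.linspace(0, 30, 10),
                             ids=["d0", "d1", "d2", "rec"])
        groups = GroupAssignment({f"d{i}": "only" for i in range(3)})
        s = paint(aln, groups, "rec",
                  CopyingParams(switch_rate=30.0, emission_mismatch=0.05))
        assert s.profile["only"] == pytest.approx(1.0)
        assert s.expected_segments.sum() >= 1.0

    def test_identical_recipient_copies_its_donor(self):
        rng = np.random.default_rng(8)
        d0 = rng.integers(0, 2, 30).astype(np.uint8)
        others = rng.integers(0, 2, (3, 30)).astype(np.uint8)
        aln = make_alignment(np.vstack([d0, others, d0]),
                             cM=np.linspace(0, 50, 30),
                             ids=["d0", "d1", "d2", "d3", "rec"])
        groups = GroupAssignment({"d0": "match", "d1": "other", "d2": "other",
                                  "d3": "other"})
        s = paint(aln, groups, "rec",
                  CopyingParams(switch_rate=2.0, emission_mismatch=1e-6))
        assert s.profile["match"] > 0.99

    def test_single_donor_no_switch_segment_size_is_chromosome_length(self):
        rng = np.random.default_rng(9)
        d0 = rng.integers(0, 2, 20).astype(np.uint8)
        aln = make_alignment(np.vstack([d0, d0]), cM=np.linspace(0, 40, 20),
                             ids=["d0", "rec"])
        groups = GroupAssignment({"d0": "g"})
        s = paint(aln, groups, "rec",
                  CopyingParams(switch_rate=20.0, emission_mismatch=1e-6))
        assert average_segment_size(s) == pytest.approx(40.0, rel=1e-6)

    def test_average_segment_size_is_total_length_over_segments(self, small_panel):
        aln, groups = small_panel
        s = paint(aln, groups, "rec",
                  CopyingParams(switch_rate=25.0, emission_mismatch=0.02))
        assert average_segment_size(s) == pytest.approx(
            s.copied_cM.sum() / s.expected_segments.sum())

    def test_doubling_gaps_weakly_increases_expected_segments(self, small_panel):
        aln, groups = small_panel
        params = CopyingParams(switch_rate=25.0, emission_mismatch=0.02)
        base = paint(aln, groups, "rec", params).expected_segments.sum()
        wide = make_alignment(aln.haplotypes, cM=2 * aln.site_pos_cM,
                              ids=list(aln.haplotype_ids))
        more = paint(wide, groups, "rec", params).expected_segments.sum()
        assert more >= base - 1e-12

    def test_leave_one_out_keeps_own_group_iff_nk_ge_2(self):
        rng = np.random.default_rng(10)
        H = rng.integers(0, 2, (5, 12)).astype(np.uint8)
        aln = make_alignment(H, cM=np.linspace(0, 20, 12),
                             ids=["a0", "a1", "b0", "b1", "b2"])
        groups = GroupAssignment({"a0": "A", "a1": "A", "b0": "B", "b1": "B",
                                  "b2": "B"})
        s = paint(aln, groups, "a0",
                  CopyingParams(switch_rate=25.0, emission_mismatch=0.02))
        assert "A" in s.donor_groups            # n_k = 2 -> one donor remains
        singleton = GroupAssignment({"a0": "A", "b0": "B", "b1": "B", "b2": "B"})
        s2 = paint(aln, singleton, "a0",
                   CopyingParams(switch_rate=25.0, emission_mismatch=0.02))
        assert "A" not in s2.donor_groups       # n_k = 1 -> own label vanishes

    def test_unknown_recipient_is_hard_error(self, small_panel):
        aln, groups = small_panel
        with pytest.raises(ValueError, match="unknown"):
            paint(aln, groups, "nobody",
                  CopyingParams(switch_rate=25.0, emission_mismatch=0.02))


class TestEM:
    def test_loglik_non_decreasing_over_em_steps(self, small_panel):
        aln, groups = small_panel
        trace = em_loglik_trace(aln, groups, ["rec"], n_em_steps=6)
        assert all(b >= a - 1e-8 for a, b in zip(trace, trace[1:]))

    def test_emission_shrinks_for_perfect_copy(self):
        rng = np.random.default_rng(12)
        d0 = rng.integers(0, 2, 80).astype(np.uint8)
        diverged = 1 - d0[None, :].repeat(3, axis=0)
        aln = make_alignment(np.vstack([d0, diverged, d0]),
                             cM=np.linspace(0, 100, 80),
                             ids=["d0", "d1", "d2", "d3", "rec"])
        groups = GroupAssignment({f"d{i}": "g" for i in range(4)})
        params = fit_copying_params(aln, groups, ["rec"], n_em_steps=8)
        assert params.emission_mismatch < 1e-3

    def test_switch_rate_recovered_within_factor_1p5(self):
        rng = np.random.default_rng(13)
        true_rate, emission = 20.0, 0.01
        S, D = 200, 50
        cM = np.sort(rng.uniform(0, 100, S))
        freq = rng.uniform(0.2, 0.8, S)
        founders = (rng.random((D, S)) < freq).astype(np.uint8)
        recipients = simulate_copying(founders, cM, 5, true_rate, emission, rng)
        H = np.vstack([founders, recipients])
        ids = [f"d{i}" for i in range(D)] + [f"r{i}" for i in range(5)]
        aln = make_alignment(H, cM=cM, ids=ids)
        groups = GroupAssignment({f"d{i}": "g" for i in range(D)})
        params = fit_copying_params(aln, groups, [f"r{i}" for i in range(5)],
                                    n_em_steps=10)
        assert true_rate / 1.5 <= params.switch_rate <= true_rate * 1.5

    def test_zero_genetic_length_is_hard_error(self):
        aln = make_alignment([[0, 1], [1, 0]], cM=np.array([2.0, 2.0]),
                             bp=np.array([10, 20]), ids=["d0", "rec"])
        groups = GroupAssignment({"d0": "g"})
        with pytest.raises(ValueError, match="genetic length"):
            fit_copying_params(aln, groups, ["rec"], n_em_steps=1)


class TestSamplePaths:
    def test_reports_requested_number_of_paths(self, small_panel):
        aln, groups = small_panel
        ps = sample_paths(aln, groups, "rec",
                          CopyingParams(switch_rate=25.0, emission_mismatch=0.02),
                          n_samples=10, seed=1)
        assert ps.n_samples == 10
        assert ps.labels["chr1"].shape == (1, 10, aln.n_sites)

    def test_sampled_frequencies_match_marginals(self):
        rng = np.random.default_rng(14)
        aln, groups = _random_instance(rng, 3, 5)
        params = CopyingParams(switch_rate=40.0, emission_mismatch=0.07)
        post = posterior_marginals(aln, groups, "rec", params)["chr1"]
        gam = post["gamma"][0]
        group_marg = np.stack(
            [gam[:, [g == grp for g in post["donor_groups"]]].sum(axis=1)
             for grp in ["g0", "g1"]], axis=1)
        ps = sample_paths(aln, groups, "rec", params, n_samples=5000, seed=2)
        lab = ps.labels["chr1"][0]
        freq = np.stack([(lab == k).mean(axis=0) for k in range(2)], axis=1)
        assert np.abs(freq - group_marg).max() < 0.02

    def test_perfect_match_gives_constant_paths(self):
        rng = np.random.default_rng(15)
        d0 = rng.integers(0, 2, 25).astype(np.uint8)
        far = 1 - d0
        aln = make_alignment(np.vstack([d0, far, d0]),
                             cM=np.linspace(0, 60, 25),
                             ids=["d0", "d1", "rec"])
        groups = GroupAssignment({"d0": "match", "d1": "other"})
        ps = sample_paths(aln, groups, "rec",
                          CopyingParams(switch_rate=5.0, emission_mismatch=1e-6),
                          n_samples=10, seed=3)
        match_code = ps.groups.index("match")
        assert (ps.labels["chr1"] == match_code).all()
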