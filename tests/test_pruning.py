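"""Greedy r2-maximization pruning against brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from popprs import (
    SyntheticConfig,
    ValidationError,
    compute_psprs,
    exhaustive_best_subset,
    fit_linear,
    generate_frequencies,
    generate_phenotype,
    leave_one_out_r2,
    prune_maximize_r2,
)


def _brute_force_r2(fm, panel, rsids):
    """Independent refit: r2 of the linear prevalence fit on a SNP set."""
    return fit_linear(compute_psprs(fm, rsids), panel).r2


def _random_instance(make_freqs, make_panel, seed, n_snps=8, n_pops=10):
    rng = np.random.default_rng(seed)
    fm = make_freqs({f"rs{i}": rng.uniform(0, 1, n_pops).tolist() for i in range(n_snps)})
    panel = make_panel(rng.normal(size=n_pops).tolist())
    return fm, panel


class TestLeaveOneOut:
    def test_matches_per_rsid_refit_oracle(self, make_freqs, make_panel):
        fm, panel = _random_instance(make_freqs, make_panel, seed=3, n_snps=5)
        loo = leave_one_out_r2(fm, panel, fm.snp_ids)
        assert set(loo) == set(fm.snp_ids)
        for rsid in fm.snp_ids:
            others = [r for r in fm.snp_ids if r != rsid]
            assert loo[rsid] == pytest.approx(_brute_force_r2(fm, panel, others))

    def test_removing_constant_snp_equals_single_snp_fit(self, make_freqs, make_panel):
        fm = make_freqs({"rs_a": [0.1, 0.5, 0.9, 0.3], "rs_b": [0.4, 0.4, 0.4, 0.4]})
        panel = make_panel([1.0, 2.5, 4.0, 1.8])
        loo = leave_one_out_r2(fm, panel, ["rs_a", "rs_b"])
        # a constant covariate only shifts the score: same r2 as rs_a alone,
        # which also equals the full two-SNP fit
        assert loo["rs_b"] == pytest.approx(_brute_force_r2(fm, panel, ["rs_a"]))
        # removing rs_a leaves only the constant SNP: fit undefined
        assert np.isnan(loo["rs_a"])

    def test_requires_two_snps(self, make_freqs, make_panel):
        fm, panel = _random_instance(make_freqs, make_panel, seed=0, n_snps=3)
        with pytest.raises(ValidationError):
            leave_one_out_r2(fm, panel, ["rs0"])


class TestGreedyPruning:
    def test_trace_monotone_and_final_r2_consistent(self, make_freqs, make_panel):
        for seed in range(10):
            fm, panel = _random_instance(make_freqs, make_panel, seed)
            trace = prune_maximize_r2(fm, panel, fm.snp_ids)
            r2s = [trace.initial_r2] + [r2 for _, r2 in trace.steps]
            assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))
            assert trace.final_r2 == pytest.approx(r2s[-1])
            # internal consistency: direct refit on the retained set
            assert trace.final_r2 == pytest.approx(
                _brute_force_r2(fm, panel, sorted(trace.retained))
            )
            # partition: removed and retained tile the input set
            assert set(trace.removed) | trace.retained == set(fm.snp_ids)
            assert not set(trace.removed) & trace.retained
            assert trace.retained

    def test_immediate_stop_when_no_removal_helps(self, make_freqs, make_panel):
        # two identical informative SNPs: dropping either halves the score
        # but leaves the correlation, so r2 stays equal and both get pruned
        # down to one; an anti-test uses SNPs whose removal strictly hurts.
        fm = make_freqs({"rs_a": [0.1, 0.5, 0.9, 0.2], "rs_b": [0.9, 0.1, 0.2, 0.8]})
        y = (fm.values.loc["rs_a"] + fm.values.loc["rs_b"]).tolist()
        panel = make_panel(y)
        trace = prune_maximize_r2(fm, panel, ["rs_a", "rs_b"])
        assert trace.steps == ()
        assert trace.retained == {"rs_a", "rs_b"}
        assert trace.final_r2 == trace.initial_r2 == pytest.approx(1.0)

    def test_single_decoy_removed_first_then_stop(self, make_freqs, make_panel):
        # four SNPs generate the phenotype; one decoy is anti-correlated
        rng = np.random.default_rng(42)
        universal = {f"rs{i}": rng.uniform(0.1, 0.9, 8).tolist() for i in range(4)}
        s = np.sum([universal[r] for r in universal], axis=0)
        decoy = (1.0 - (s - s.min()) / (s.max() - s.min())) * 0.8 + 0.1
        fm = make_freqs({**universal, "rs_decoy": decoy.tolist()})
        panel = make_panel(s.tolist())
        trace = prune_maximize_r2(fm, panel, fm.snp_ids)
        assert trace.removed[0] == "rs_decoy"
        assert trace.final_r2 == pytest.approx(1.0)
        # exhaustive search agrees the universal set is optimal
        best_set, best_r2 = exhaustive_best_subset(fm, panel, fm.snp_ids)
        assert trace.final_r2 == pytest.approx(best_r2)

    def test_final_r2_invariant_to_input_order(self, make_freqs, make_panel):
        fm, panel = _random_instance(make_freqs, make_panel, seed=5)
        rsids = fm.snp_ids
        base = prune_maximize_r2(fm, panel, rsids)
        rng = np.random.default_rng(0)
        for _ in range(5):
            perm = list(rng.permutation(rsids))
            other = prune_maximize_r2(fm, panel, perm)
            assert other.final_r2 == pytest.approx(base.final_r2)

    def test_batch_mode_removes_all_improving_snps_per_iteration(
        self, make_freqs, make_panel
    ):
        fm, panel = _random_instance(make_freqs, make_panel, seed=9, n_snps=10)
        full_loo = leave_one_out_r2(fm, panel, fm.snp_ids)
        full_r2 = _brute_force_r2(fm, panel, fm.snp_ids)
        first_batch = {r for r, v in full_loo.items() if v > full_r2}
        batch = prune_maximize_r2(fm, panel, fm.snp_ids, mode="batch")
        assert batch.retained  # never empties the set
        assert first_batch <= set(batch.removed)
        assert batch.final_r2 == pytest.approx(
            _brute_force_r2(fm, panel, sorted(batch.retained))
        )

    def test_constant_phenotype_rejected_before_iteration(self, make_freqs, make_panel):
        fm, _ = _random_instance(make_freqs, make_panel, seed=1)
        panel = make_panel([2.0] * 10)
        with pytest.raises(ValidationError, match="constant phenotype"):
            prune_maximize_r2(fm, panel, fm.snp_ids)


class TestExhaustiveBestSubset:
    def test_greedy_never_beats_exhaustive(self, make_freqs, make_panel):
        for seed in range(15):
            fm, panel = _random_instance(make_freqs, make_panel, seed, n_snps=6)
            trace = prune_maximize_r2(fm, panel, fm.snp_ids)
            _, best_r2 = exhaustive_best_subset(fm, panel, fm.snp_ids)
            assert trace.final_r2 <= best_r2 + 1e-12

    def test_matches_direct_enumeration(self, make_freqs, make_panel):
        fm, panel = _random_instance(make_freqs, make_panel, seed=2, n_snps=5)
        best_set, best_r2 = exhaustive_best_subset(fm, panel, fm.snp_ids)
        expected = max(
            (
                _brute_force_r2(fm, panel, list(combo))
                for size in range(1, 6)
                for combo in itertools.combinations(fm.snp_ids, size)
            ),
        )
        assert best_r2 == pytest.approx(expected)
        assert best_r2 == pytest.approx(_brute_force_r2(fm, panel, sorted(best_set)))

    def test_all_identical_snps_tie_to_largest_subset(self, make_freqs, make_panel):
        fm = make_freqs({f"rs{i}": [0.2, 0.5, 0.8, 0.4] for i in range(3)})
        panel = make_panel([1.0, 2.0, 3.0, 1.5])
        best_set, _ = exhaustive_best_subset(fm, panel, fm.snp_ids)
        assert best_set == set(fm.snp_ids)

    def test_singleton_set_returns_itself(self, make_freqs, make_panel):
        fm = make_freqs({"rs1": [0.2, 0.5, 0.8, 0.4]})
        panel = make_panel([1.0, 2.0, 3.0, 1.5])
        best_set, best_r2 = exhaustive_best_subset(fm, panel, ["rs1"])
        assert best_set == {"rs1"}
        assert best_r2 == pytest.approx(_brute_force_r2(fm, panel, ["rs1"]))

    def test_refuses_large_sets(self, make_freqs, make_panel):
        fm, panel = _random_instance(make_freqs, make_panel, seed=0, n_snps=16)
        with pytest.raises(ValidationError, match="15"):
            exhaustive_best_subset(fm, panel, fm.snp_ids)


def test_pruning_enriches_universal_snps_over_decoys():
    """With sign-flipped decoys, the retained set over-represents the
    SNPs that truly drive the phenotype (one-sided Fisher over replicates)."""
    from popprs import fisher_2x2, ContingencyTable2x2
    from scipy.stats import fisher_exact

    kept_universal = kept_decoy = removed_universal = removed_decoy = 0
    for seed in range(20):
        cfg = SyntheticConfig(
            seed=seed, n_snps=24, frac_universal=0.5,
            beta=1.0, decoy_beta=0.6, noise_sd=0.1, phenotype_kind="quantitative",
        )
        fm = generate_frequencies(cfg)
        panel, universal = generate_phenotype(fm, cfg)
        trace = prune_maximize_r2(fm, panel, fm.snp_ids)
        kept_universal += len(trace.retained & universal)
        kept_decoy += len(trace.retained - universal)
        removed_universal += len(set(trace.removed) & universal)
        removed_decoy += len(set(trace.removed) - universal)
    odds, p = fisher_exact(
        [[kept_universal, kept_decoy], [removed_universal, removed_decoy]],
        alternative="greater",
    )
    assert p < 0.05
    assert odds > 1
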