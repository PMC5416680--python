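"""Differential expression: size factors, dispersion, exact test, FDR, selection."""

from math import exp, lgamma, log

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from degnet import de
from degnet.io import CountMatrix
from degnet.simulate import SimulationDesign, simulate_counts


def _cm(counts, n_case=1):
    counts = np.asarray(counts)
    samples = [f"s{i}" for i in range(counts.shape[1])]
    groups = {s: ("case" if i < n_case else "control") for i, s in enumerate(samples)}
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountMatrix(genes, samples, counts, groups)


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        s = de.estimate_size_factors(_cm([[5, 5], [9, 9], [2, 2]]))
        assert np.allclose(s, [1.0, 1.0])

    def test_hand_evaluated_median_of_ratios(self):
        # counts [[2,4],[10,20]]: every ratio is (1/sqrt2, sqrt2) after rescale
        s = de.estimate_size_factors(_cm([[2, 4], [10, 20]]))
        assert np.allclose(s, [1 / np.sqrt(2), np.sqrt(2)])

    def test_scale_equivariance(self):
        base = np.array([[3, 6, 9], [10, 11, 12], [100, 90, 110]])
        s0 = de.estimate_size_factors(_cm(base))
        scaled = base.copy()
        scaled[:, 1] *= 4
        s1 = de.estimate_size_factors(_cm(scaled))
        # ratios between factors of untouched samples are preserved; the
        # scaled sample's factor grows 4x relative to them
        assert np.allclose((s1[1] / s1[0]) / (s0[1] / s0[0]), 4.0)

    def test_no_all_positive_gene_is_an_error(self):
        with pytest.raises(ValueError, match="filter"):
            de.estimate_size_factors(_cm([[0, 5], [3, 0]]))


class TestDispersions:
    def test_poisson_data_sits_at_floor_or_low(self):
        d = SimulationDesign(n_genes=800, n_case=10, n_control=10, dispersion=0.0,
                             de_fraction=0.0, seed=2, library_size_factors=np.ones(20))
        cm, _ = simulate_counts(d)
        s = de.estimate_size_factors(cm)
        alpha = de.estimate_dispersions(cm, s)
        assert np.median(alpha) < 0.02

    def test_parameter_recovery_at_alpha_point_two(self):
        d = SimulationDesign(n_genes=1500, n_case=20, n_control=20, dispersion=0.2,
                             de_fraction=0.0, seed=4, library_size_factors=np.ones(40))
        cm, _ = simulate_counts(d)
        alpha = de.estimate_dispersions(cm, de.estimate_size_factors(cm))
        assert 0.1 < np.median(alpha) < 0.4

    def test_constant_gene_gets_floor(self):
        # all-constant matrix: no overdispersion signal anywhere, so both the
        # per-gene estimates and the trend collapse to the floor
        cm = _cm([[7, 7, 7, 7], [12, 12, 12, 12], [5, 5, 5, 5]], n_case=2)
        alpha = de.estimate_dispersions(cm, np.ones(4))
        assert np.allclose(alpha, de.ALPHA_FLOOR)
        # in a noisy matrix the constant gene's own moment estimate still
        # floors even when the fitted trend lifts the final value
        cm = _cm([[7, 7, 7, 7], [1, 9, 3, 20], [5, 6, 7, 8]], n_case=2)
        _, alpha_raw, _ = de.estimate_dispersions(cm, np.ones(4), return_parts=True)
        assert alpha_raw[0] <= 0

    def test_single_replicate_group_rejected(self):
        cm = _cm([[1, 2, 3]], n_case=1)
        with pytest.raises(ValueError, match="replicates"):
            de.estimate_dispersions(cm, np.ones(3))


# --- independent exact-test oracle -----------------------------------------

def _oracle_logpmf(k, mu, var):
    """NB(mean, var) log-pmf from first principles (Poisson when var<=mu)."""
    if var <= mu * (1 + 1e-9):
        return k * log(mu) - mu - lgamma(k + 1)
    r = mu * mu / (var - mu)
    p = mu / var
    return lgamma(k + r) - lgamma(r) - lgamma(k + 1) + r * log(p) + k * log(1 - p)


def exact_p_oracle(k_a, k_b, q, alpha, s_a, s_b):
    """Direct summation over every partition of S = k_a + k_b."""
    s_a, s_b = np.asarray(s_a, float), np.asarray(s_b, float)
    mu_a, mu_b = q * s_a.sum(), q * s_b.sum()
    var_a = mu_a + alpha * q * q * (s_a**2).sum()
    var_b = mu_b + alpha * q * q * (s_b**2).sum()
    total = k_a + k_b
    probs = [
        exp(_oracle_logpmf(a, mu_a, var_a) + _oracle_logpmf(total - a, mu_b, var_b))
        for a in range(total + 1)
    ]
    p_obs = probs[k_a]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)) / sum(probs))


class TestExactTest:
    def test_balanced_counts_under_symmetric_model_give_p_one(self):
        p = de.nb_exact_test(5, 5, q=2.0, alpha=0.1, s_a=np.ones(2), s_b=np.ones(2))
        assert p == pytest.approx(1.0)

    def test_zero_total_is_uninformative(self):
        assert de.nb_exact_test(0, 0, 1.0, 0.1, np.ones(2), np.ones(2)) == 1.0

    @pytest.mark.parametrize("k_a,k_b,q,alpha", [
        (10, 0, 1.2, 0.1), (3, 7, 1.0, 0.1), (0, 10, 0.6, 0.3),
        (15, 5, 2.0, 0.05), (2, 18, 1.5, 0.2), (9, 11, 1.0, 1e-8),
    ])
    def test_matches_enumeration_oracle(self, k_a, k_b, q, alpha):
        s_a, s_b = np.array([1.0, 0.8]), np.array([1.1, 1.3])
        got = de.nb_exact_test(k_a, k_b, q, alpha, s_a, s_b)
        want = exact_p_oracle(k_a, k_b, q, alpha, s_a, s_b)
        assert got == pytest.approx(want, rel=1e-8)

    def test_group_label_swap_symmetry(self):
        s = np.array([1.0, 1.0])
        for k_a, k_b in [(12, 3), (1, 9), (7, 7)]:
            assert de.nb_exact_test(k_a, k_b, 1.0, 0.15, s, s) == pytest.approx(
                de.nb_exact_test(k_b, k_a, 1.0, 0.15, s, s)
            )

    def test_windowed_large_total_agrees_with_full_enumeration_regime(self):
        # just above/below the enumeration cutoff the p-value is continuous
        s = np.ones(4)
        p_small = de.nb_exact_test(9_000, 12_000, 2625.0, 0.01, s, s)
        assert 0.0 < p_small <= 1.0


class TestBH:
    def test_single_p_unchanged(self):
        assert de.adjust_bh(np.array([0.3]))[0] == pytest.approx(0.3)

    def test_hand_applied_step_up(self):
        got = de.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    @given(st.lists(st.floats(1e-9, 1.0, exclude_min=False), min_size=1, max_size=40))
    @settings(max_examples=60, deadline=None)
    def test_matches_sort_based_oracle(self, ps):
        p = np.array(ps)
        got = de.adjust_bh(p)
        # independent step-up oracle
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        want = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, p[i] * n / rank)
            want[i] = running
        assert np.allclose(got, want, atol=1e-12)
        assert np.all(got >= p - 1e-15) and np.all(got <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            de.adjust_bh(np.array([0.0, 0.5]))


class TestDEGSelection:
    @pytest.fixture
    def results(self):
        rng = np.random.default_rng(0)
        n = 400
        lfc = rng.normal(0, 1.5, n)
        p = np.clip(rng.random(n) ** 2, 1e-6, 1.0)
        return pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n)],
            "log2fc": lfc, "fold_change": 2.0 ** lfc,
            "p_raw": p, "p_adj": de.adjust_bh(p),
        })

    def test_empty_results_empty_set(self):
        assert len(de.select_degs(pd.DataFrame(), 2, 0.05)) == 0

    def test_members_satisfy_both_filters(self, results):
        degs = de.select_degs(results, 2.0, 0.05, "raw")
        sub = results.set_index("gene_id").loc[degs.gene_ids]
        assert (np.abs(sub["log2fc"]) >= 1.0).all()
        assert (sub["p_raw"] <= 0.05).all()

    def test_tightening_p_shrinks_the_set(self, results):
        loose = set(de.select_degs(results, 2.0, 0.05, "raw").gene_ids)
        tight = set(de.select_degs(results, 2.0, 0.01, "raw").gene_ids)
        assert tight <= loose

    def test_no_silent_filtering_at_trivial_thresholds(self, results):
        degs = de.select_degs(results, 1.0, 1.0, "raw")
        assert len(degs) == len(results)

    def test_direction_follows_sign(self, results):
        degs = de.select_degs(results, 2.0, 0.05, "adj")
        assert (degs.table.loc[degs.table["log2fc"] > 0, "direction"] == "up").all()
        assert degs.n_up + degs.n_down == len(degs)


class TestLocusGroupPartition:
    def test_counts_sum_to_total_with_missing_as_other(self, annotation_small):
        table = pd.DataFrame({
            "gene_id": ["g1", "g2", "g3", "gX"],
            "log2fc": [2, -2, 1.5, 3], "fold_change": [4, 0.25, 2.8, 8],
            "p": [0.01] * 4, "direction": ["up", "down", "up", "up"],
        })
        degs = de.DEGSet(table, 2.0, 0.05, "raw")
        out = de.partition_locus_groups(degs, annotation_small)
        assert out["total"] == 4 == sum(out[k] for k in
                                        ("protein_coding", "ncRNA", "pseudogene", "other"))
        assert out["n_unannotated"] == 1
        assert out["n_up"] + out["n_down"] == out["total"]

    def test_all_protein_coding(self, annotation_small):
        table = pd.DataFrame({"gene_id": ["g1"], "log2fc": [2.0], "fold_change": [4.0],
                              "p": [0.01], "direction": ["up"]})
        out = de.partition_locus_groups(de.DEGSet(table, 2, 0.05, "raw"), annotation_small)
        assert out["protein_coding"] == 1
        assert out["ncRNA"] == out["pseudogene"] == out["other"] == 0


class TestFullDEOnSimulation:
    def test_fold_changes_track_planted_effects(self):
        d = SimulationDesign(n_genes=600, de_fraction=0.1, log2fc_effect=2.0, seed=8)
        cm, truth = simulate_counts(d)
        res = de.de_test(cm)
        merged = res.merge(truth.genes, on="gene_id")
        up = merged[merged["true_log2fc"] > 0]
        down = merged[merged["true_log2fc"] < 0]
        assert np.median(up["log2fc"]) > 1.0
        assert np.median(down["log2fc"]) < -1.0
        assert (merged["p_adj"] >= merged["p_raw"] - 1e-15).all()
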