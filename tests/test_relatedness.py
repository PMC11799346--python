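import numpy as np
import pytest

from demekin.genio import estimate_allele_frequencies
from demekin.relatedness import (
    JacquardEstimate,
    calibrate_po_ranges,
    classify_po,
    flag_r1_outliers,
    ibs_counts_bruteforce,
    ibs_stats,
    jacquard_em,
    jacquard_tables,
    background_subset_report,
    pairwise_relatedness,
    summarize_relatedness,
)
from demekin.simulate import (
    SimConfig,
    inject_contamination,
    one_hot_likelihoods,
    simulate_cohort,
    simulate_dyads,
    simulate_genotype_likelihoods,
)
from tests.conftest import make_sitefreqs, onehot


def _estimate(delta):
    return JacquardEstimate(delta=np.array(delta), loglik=0.0, iterations=1, n_sites=1000)


class TestSummaries:
    def test_pure_parent_offspring(self):
        pr = summarize_relatedness(_estimate([0, 0, 0, 0, 0, 0, 0, 1, 0]))
        assert pr.theta == pytest.approx(0.25)
        assert pr.F_x == pr.F_y == 0.0
        assert pr.r_xy == pytest.approx(0.5)
        assert (pr.k0, pr.k1, pr.k2) == (0.0, 1.0, 0.0)

    def test_twin_case(self):
        pr = summarize_relatedness(_estimate([0, 0, 0, 0, 0, 0, 1, 0, 0]))
        assert pr.theta == pytest.approx(0.5)
        assert pr.r_xy == pytest.approx(1.0)

    def test_inbred_dyad_matches_printed_pair(self):
        # a dyad with kinship 0.28 and mean inbreeding 0.037 has
        # Hedrick-Lacy relatedness 0.54, the worked mother-offspring pair
        delta = [0.037, 0, 0, 0, 0, 0, 0.486, 0, 0.477]
        pr = summarize_relatedness(_estimate(delta))
        assert pr.theta == pytest.approx(0.28)
        assert (pr.F_x + pr.F_y) / 2 == pytest.approx(0.037)
        assert pr.r_xy == pytest.approx(0.54, abs=0.001)


class TestJacquardTables:
    def test_tables_are_distributions(self):
        f = np.array([0.1, 0.3, 0.5, 0.9])
        t = jacquard_tables(f)
        np.testing.assert_allclose(t.sum(axis=(2, 3)), 1.0, atol=1e-12)
        assert np.all(t >= 0)

    def test_state8_forbids_opposing_homozygotes(self):
        t = jacquard_tables(np.array([0.3]))
        assert t[7, 0, 0, 2] == 0 and t[7, 0, 2, 0] == 0


class TestJacquardEM:
    def test_self_comparison_limit(self):
        rng = np.random.default_rng(0)
        g = rng.binomial(2, 0.5, size=1000)
        gl = onehot(g)
        freqs = make_sitefreqs(np.full(1000, 0.5))
        est = jacquard_em(gl, gl, freqs, n_restarts=1)
        pr = summarize_relatedness(est)
        assert est.delta[6] > 0.9
        assert pr.theta == pytest.approx(0.5, abs=0.03)

    @pytest.mark.parametrize(
        "relationship,expected,tol",
        [("po", (0.0, 1.0, 0.0), 0.05), ("fullsib", (0.25, 0.5, 0.25), 0.07)],
    )
    def test_single_dyad_recovery(self, relationship, expected, tol):
        gx, gy, f = simulate_dyads(relationship, 1, 1000, seed=5)
        freqs = make_sitefreqs(f)
        est = jacquard_em(onehot(gx), onehot(gy), freqs, mode="k3", n_restarts=1)
        pr = summarize_relatedness(est)
        assert pr.k0 == pytest.approx(expected[0], abs=tol)
        assert pr.k1 == pytest.approx(expected[1], abs=tol)
        assert pr.k2 == pytest.approx(expected[2], abs=tol)

    def test_loglik_nondecreasing_over_iteration_budget(self):
        gx, gy, f = simulate_dyads("fullsib", 1, 400, seed=6)
        freqs = make_sitefreqs(f)
        lls = [
            jacquard_em(
                onehot(gx), onehot(gy), freqs, max_iter=n, tol=0.0, n_restarts=0
            ).loglik
            for n in (2, 5, 20, 100, 500)
        ]
        assert all(b >= a - 1e-9 for a, b in zip(lls, lls[1:]))

    def test_simplex_and_reliability(self):
        gx, gy, f = simulate_dyads("unrelated", 1, 30, seed=7)
        freqs = make_sitefreqs(f)
        est = jacquard_em(onehot(gx), onehot(gy), freqs, min_sites=50, n_restarts=1)
        assert est.delta.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(est.delta >= 0)
        assert not est.reliable  # 30 < 50 informative sites

    def test_degenerate_frequencies_raise(self):
        freqs = make_sitefreqs(np.zeros(100))
        gl = onehot(np.zeros(100, dtype=int))
        with pytest.raises(ValueError, match="fixed"):
            jacquard_em(gl, gl, freqs)

    def test_symmetry(self):
        gx, gy, f = simulate_dyads("po", 1, 600, seed=9)
        freqs = make_sitefreqs(f)
        a = summarize_relatedness(jacquard_em(onehot(gx), onehot(gy), freqs, n_restarts=0))
        b = summarize_relatedness(jacquard_em(onehot(gy), onehot(gx), freqs, n_restarts=0))
        assert a.theta == pytest.approx(b.theta, abs=1e-6)
        assert a.r_xy == pytest.approx(b.r_xy, abs=1e-6)
        assert a.F_x == pytest.approx(b.F_y, abs=1e-6)
        assert a.F_y == pytest.approx(b.F_x, abs=1e-6)


class TestIBSStats:
    def test_onehot_equals_bruteforce(self):
        rng = np.random.default_rng(3)
        gx = rng.integers(0, 3, 400)
        gy = rng.integers(0, 3, 400)
        f = rng.uniform(0.05, 0.95, 400)
        freqs = make_sitefreqs(f)
        r0, r1, king = ibs_stats(onehot(gx), onehot(gy), freqs, call=True)
        n = ibs_counts_bruteforce(gx, gy)
        opp = n[0, 2] + n[2, 0]
        disc = n[0, 1] + n[1, 0] + n[1, 2] + n[2, 1] + opp
        assert r0 == pytest.approx(opp / n[1, 1], abs=1e-12)
        assert r1 == pytest.approx(n[1, 1] / disc, abs=1e-12)
        assert king == pytest.approx(
            (n[1, 1] - 2 * opp) / (n[1].sum() + n[:, 1].sum()), abs=1e-12
        )

    def test_parent_offspring_anchors(self):
        gx, gy, f = simulate_dyads("po", 50, 1000, seed=10)
        freqs = make_sitefreqs(f)
        stats = np.array(
            [ibs_stats(onehot(gx[i]), onehot(gy[i]), freqs, call=True) for i in range(50)]
        )
        assert np.all(stats[:, 0] == 0.0)  # R0 exactly zero, no error
        assert stats[:, 1].mean() == pytest.approx(0.5, abs=0.03)
        assert stats[:, 2].mean() == pytest.approx(0.25, abs=0.02)

    def test_duplicate_individual(self):
        rng = np.random.default_rng(1)
        g = rng.binomial(2, 0.5, 800)
        freqs = make_sitefreqs(np.full(800, 0.5))
        r0, r1, king = ibs_stats(onehot(g), onehot(g), freqs, call=True)
        assert king == pytest.approx(0.5)
        assert r0 == 0.0
        assert np.isnan(r1)  # no discordant combinations at all

    def test_unrelated_at_half_frequency(self):
        # closed form under HWE at p = 1/2: n11 = 1/4, discordant = 5/8
        gx, gy, f = simulate_dyads("unrelated", 30, 2000, seed=11,
                                   freq_range=(0.5, 0.5))
        freqs = make_sitefreqs(f)
        stats = np.array(
            [ibs_stats(onehot(gx[i]), onehot(gy[i]), freqs, call=True) for i in range(30)]
        )
        assert stats[:, 1].mean() == pytest.approx(0.4, abs=0.02)
        assert stats[:, 2].mean() == pytest.approx(0.0, abs=0.02)


class TestPOClassification:
    def _po_table(self, n=14, seed=12):
        gx, gy, f = simulate_dyads("po", n, 1000, seed=seed)
        freqs = make_sitefreqs(f)
        rows = []
        for i in range(n):
            est = jacquard_em(onehot(gx[i]), onehot(gy[i]), freqs, n_restarts=0)
            pr = summarize_relatedness(est, f"p{i}", f"c{i}")
            pr.R0, pr.R1, pr.KING = ibs_stats(onehot(gx[i]), onehot(gy[i]), freqs, call=True)
            rows.append(pr.as_dict())
        import pandas as pd

        return pd.DataFrame(rows)

    def test_calibration_brackets_analytic_values(self):
        known = self._po_table()
        ranges = calibrate_po_ranges(known)
        lo, hi = ranges.ranges["R1"]
        assert lo <= 0.5 <= hi
        lo, hi = ranges.ranges["KING"]
        assert lo <= 0.25 <= hi
        assert ranges.ranges["R0"] == (0.0, 0.0)

    def test_single_known_pair_rejected(self):
        known = self._po_table(n=1)
        with pytest.raises(ValueError):
            calibrate_po_ranges(known)

    def test_degenerate_identical_ranges(self):
        known = self._po_table(n=2)
        known.loc[:, list(known.columns[2:-3])] = known.iloc[0, 2:-3].values
        ranges = calibrate_po_ranges(known)
        assert all(lo == hi for lo, hi in ranges.ranges.values())

    def test_known_pair_classified_po(self):
        known = self._po_table()
        ranges = calibrate_po_ranges(known)
        out = classify_po(known, ranges)
        assert out["is_po"].all()

    def test_rejection_reports_metric(self):
        known = self._po_table()
        ranges = calibrate_po_ranges(known)
        bad = known.iloc[[0]].copy()
        bad["R0"] = 0.5
        out = classify_po(bad, ranges)
        assert not out["is_po"].iloc[0]
        assert out["reject_reason"].iloc[0] == "R0"

    def test_undefined_metric_rejected(self):
        known = self._po_table()
        ranges = calibrate_po_ranges(known)
        bad = known.iloc[[0]].copy()
        bad["KING"] = np.nan
        out = classify_po(bad, ranges)
        assert not out["is_po"].iloc[0]
        assert out["reject_reason"].iloc[0] == "undefined:KING"

    def test_unrelated_dyads_not_called(self):
        known = self._po_table()
        ranges = calibrate_po_ranges(known)
        gx, gy, f = simulate_dyads("unrelated", 30, 1000, seed=13)
        freqs = make_sitefreqs(f)
        rows = []
        for i in range(30):
            est = jacquard_em(onehot(gx[i]), onehot(gy[i]), freqs, n_restarts=0)
            pr = summarize_relatedness(est, f"u{i}", f"v{i}")
            pr.R0, pr.R1, pr.KING = ibs_stats(onehot(gx[i]), onehot(gy[i]), freqs, call=True)
            rows.append(pr.as_dict())
        import pandas as pd

        out = classify_po(pd.DataFrame(rows), ranges)
        assert not out["is_po"].any()


@pytest.fixture(scope="module")
def founder_truth():
    cfg = SimConfig(seed=21, n_demes=1, deme_sizes=[14], n_generations=1,
                    n_sites=600, polymorphic_fraction=0.5)
    _, tg, _, _ = simulate_cohort(cfg)
    return cfg, tg


class TestOutlierFlagging:
    def test_homogeneous_cohort_clean(self, founder_truth):
        cfg, tg = founder_truth
        pairs = pairwise_relatedness(
            simulate_genotype_likelihoods(tg, cfg), mode="k3", n_restarts=0
        )
        assert flag_r1_outliers(pairs) == []

    def test_contaminated_individuals_flagged(self, founder_truth):
        from demekin.simulate import simulate_contaminated_likelihoods

        cfg, tg = founder_truth
        gl = simulate_contaminated_likelihoods(
            tg, cfg, {"I0003": ("I0007", 0.5), "I0010": ("I0002", 0.5)}
        )
        pairs = pairwise_relatedness(gl, mode="k3", n_restarts=0)
        assert set(flag_r1_outliers(pairs)) == {"I0003", "I0010"}

    def test_likelihood_mixing_elevates_r1(self, founder_truth):
        cfg, tg = founder_truth
        gl = inject_contamination(one_hot_likelihoods(tg), "I0003", "I0007", 0.5)
        pairs = pairwise_relatedness(gl, mode="k3", n_restarts=0)
        mixed = (pairs["id_x"] == "I0003") | (pairs["id_y"] == "I0003")
        assert pairs.loc[mixed, "R1"].median() > pairs.loc[~mixed, "R1"].median()


class TestBackgroundSubsetting:
    def test_low_diversity_deme_effect(self):
        # one deme founded by few individuals: fewer private polymorphic
        # sites, and pooled reference frequencies inflate its within-deme
        # relatedness relative to a deme-only reference
        cfg = SimConfig(seed=31, n_demes=3, deme_sizes=[6, 12, 12],
                        n_generations=2, n_sites=500, divergence_fst=0.25,
                        migration_rate=0.0)
        _, tg, _, truth = simulate_cohort(cfg)
        gl = one_hot_likelihoods(tg)
        groups = {}
        for ind, deme in truth.deme.items():
            groups.setdefault(f"deme{deme}", []).append(ind)
        report = background_subset_report(gl, groups, mode="k3", n_restarts=0)
        row = report.set_index("group").loc["deme0"]
        assert row["n_polymorphic_within"] < row["n_polymorphic_pooled"]
        assert row["mean_rxy_pooled"] > row["mean_rxy_within"]

    def test_single_group(self, small_cohort):
        *_, truth, gl = small_cohort
        members = [i for i, d in truth.deme.items() if d == 0][:6]
        report = background_subset_report(gl, {"g": members}, mode="k3", n_restarts=0)
        assert len(report) == 1

    def test_tiny_group_skipped(self, small_cohort):
        *_, truth, gl = small_cohort
        members = [i for i, d in truth.deme.items() if d == 0][:4]
        with pytest.warns(UserWarning, match="fewer than two"):
            report = background_subset_report(
                gl, {"a": members, "b": members[:1]}, mode="k3", n_restarts=0
            )
        assert list(report["group"]) == ["a"]
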