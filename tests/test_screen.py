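"""Modifier-screen statistics: rank tests, binomial tails, table summaries."""

import numpy as np
import pytest
from scipy import stats

from ldbscreen import (bristle_binomial_test, bristle_control_rate,
                       bristle_fdr_and_call, call_wing_interactor,
                       load_packaged_screen_table, parse_screen_table,
                       simulate_bristle_cross, summarize_screen,
                       wing_severity_test)
from ldbscreen.screen import (BristleCross, SeverityDistribution,
                              WingTestResult)

from ldbscreen import io as ldbio


def dist(counts, genotype="x", sex="female"):
    return SeverityDistribution(genotype, sex, np.array(counts))


class TestWingSeverityTest:
    def test_identical_samples_are_not_significant(self):
        a = dist([50, 30, 10, 5, 3, 2])
        res = wing_severity_test(a, dist([50, 30, 10, 5, 3, 2]))
        assert res.p > 0.99
        assert res.direction is None or res.p > 0.99

    def test_extreme_separation(self):
        res = wing_severity_test(dist([0, 0, 0, 0, 0, 100]),
                                 dist([100, 0, 0, 0, 0, 0]))
        assert res.direction == "enhancer"
        assert res.p < 1e-6

    def test_matches_permutation_oracle(self):
        control = dist([50, 30, 10, 5, 3, 2])
        test = dist([20, 20, 20, 15, 15, 10])
        res = wing_severity_test(test, control)
        tv, cv = test.expand(), control.expand()
        pooled = np.concatenate([tv, cv])
        ranks = stats.rankdata(pooled)
        obs = abs(ranks[: tv.size].sum() - tv.size * (len(pooled) + 1) / 2)
        rng = np.random.default_rng(0)
        n_shuffles = 10000
        count = 0
        for _ in range(n_shuffles):
            perm = rng.permutation(ranks)
            if abs(perm[: tv.size].sum() - tv.size * (len(pooled) + 1) / 2) >= obs - 1e-9:
                count += 1
        mc = count / n_shuffles
        assert abs(res.p - mc) < 3 * np.sqrt(mc * (1 - mc) / n_shuffles) + 0.01

    def test_symmetry_swapping_samples_flips_direction(self):
        a = dist([50, 30, 10, 5, 3, 2])
        b = dist([20, 20, 20, 15, 15, 10])
        r1 = wing_severity_test(b, a)
        r2 = wing_severity_test(a, b)
        assert r1.p == pytest.approx(r2.p, rel=1e-9)
        assert {r1.direction, r2.direction} == {"enhancer", "suppressor"}

    def test_mismatched_class_schemes_error(self):
        with pytest.raises(ValueError, match="class schemes"):
            wing_severity_test(dist([10, 10]), dist([10, 10, 10]))

    def test_small_samples_error(self):
        with pytest.raises(ValueError, match="10 flies"):
            wing_severity_test(dist([3, 2]), dist([50, 50]))

    def test_null_rejection_rate_is_calibrated(self):
        # each simulated cross draws its own control so rejections are
        # independent and the binomial bound applies
        probs = np.array([0.4, 0.25, 0.15, 0.1, 0.06, 0.04])
        rng = np.random.default_rng(42)
        rejections = 0
        n_sims = 400
        for i in range(n_sims):
            control = dist(rng.multinomial(600, probs), "control")
            test = dist(rng.multinomial(110, probs), "test")
            if wing_severity_test(test, control).p < 0.05:
                rejections += 1
        rate = rejections / n_sims
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_sims)


class TestWingInteractorCall:
    def _res(self, p, direction):
        return WingTestResult(p, direction, 0.0)

    def test_single_allele_both_sexes_significant(self):
        call = call_wing_interactor("g", "Dlmo", {
            "a1": {"female": self._res(0.01, "enhancer"),
                   "male": self._res(0.02, "enhancer")}})
        assert call.code == "+"

    def test_second_allele_significant_in_one_sex_still_interactor(self):
        call = call_wing_interactor("g", "Dlmo", {
            "a1": {"female": self._res(0.01, "enhancer"),
                   "male": self._res(0.02, "enhancer")},
            "a2": {"female": self._res(0.03, "enhancer"),
                   "male": self._res(0.4, "enhancer")}})
        assert call.code == "+"

    def test_conflicting_directions_give_conflict_flag(self):
        call = call_wing_interactor("g", "Dlmo", {
            "a1": {"female": self._res(0.01, "enhancer"),
                   "male": self._res(0.02, "enhancer")},
            "a2": {"female": self._res(0.03, "suppressor"),
                   "male": self._res(0.01, "suppressor")}})
        assert call.code == "0" and call.conflict

    def test_one_sex_only_is_not_an_interactor(self):
        call = call_wing_interactor("g", "Dlmo", {
            "a1": {"female": self._res(0.01, "suppressor"),
                   "male": self._res(0.5, None)}})
        assert call.code == "0" and not call.conflict

    def test_no_alleles_errors(self):
        with pytest.raises(ValueError):
            call_wing_interactor("g", "Dlmo", {})


class TestBristleStatistics:
    @pytest.mark.parametrize("d,n,expected", [(3, 99, 0.04), (0, 9, 0.1)])
    def test_control_rate_formula(self, d, n, expected):
        rate = bristle_control_rate(BristleCross("c", n, d, role="control"))
        assert rate == pytest.approx(expected)

    def test_control_rate_boundary(self):
        assert bristle_control_rate(
            BristleCross("c", 50, 50, role="control")) == pytest.approx(1.0)

    def test_suppression_tail_closed_form(self):
        res = bristle_binomial_test(BristleCross("t", 50, 0), p_hat=0.04)
        assert res.p_suppression == pytest.approx(0.96 ** 50, rel=1e-12)
        assert res.direction == "suppressor"

    def test_full_duplication_enhancement_tail(self):
        res = bristle_binomial_test(BristleCross("t", 30, 30), p_hat=0.2)
        assert res.p_enhancement == pytest.approx(0.2 ** 30, rel=1e-9)
        assert res.direction == "enhancer"

    def test_upper_tail_matches_summation_oracle(self):
        m, d, p = 50, 8, 0.04
        res = bristle_binomial_test(BristleCross("t", m, d), p_hat=p)
        oracle = sum(
            stats.binom.pmf(k, m, p) for k in range(d, m + 1))
        assert res.p_enhancement == pytest.approx(oracle, abs=1e-12)

    def test_tails_identity(self):
        m, p = 40, 0.13
        for d in (0, 3, 11, 40):
            res = bristle_binomial_test(BristleCross("t", m, d), p_hat=p)
            pmf = stats.binom.pmf(d, m, p)
            assert res.p_enhancement + res.p_suppression - pmf == pytest.approx(
                1.0, abs=1e-12)

    def test_enhancement_p_decreases_with_d(self):
        previous = 2.0
        for d in range(0, 20):
            res = bristle_binomial_test(BristleCross("t", 60, d), p_hat=0.1)
            assert res.p_enhancement <= previous + 1e-15
            previous = res.p_enhancement

    def test_role_and_rate_validation(self):
        with pytest.raises(ValueError):
            bristle_control_rate(BristleCross("t", 10, 1, role="test"))
        with pytest.raises(ValueError):
            bristle_binomial_test(BristleCross("t", 10, 1), p_hat=0.0)


class TestBristleFdrCall:
    def test_single_strong_test_is_called(self):
        res = [bristle_binomial_test(BristleCross("t", 100, 30), p_hat=0.05)]
        (call,) = bristle_fdr_and_call(res, "ssdp")
        assert call.code == "+" and call.q == pytest.approx(call.p)

    def test_flat_screen_calls_nothing(self):
        tests = [bristle_binomial_test(BristleCross(f"t{i}", 100, 5), p_hat=0.05)
                 for i in range(20)]
        calls = bristle_fdr_and_call(tests, "ssdp")
        assert all(c.code == "0" for c in calls)

    def test_simulated_screen_controls_fdr(self):
        # screens of 50 genes, 10% carrying a doubled duplication rate;
        # pooled over 100 seeded screens to beat Monte-Carlo noise
        false = called = 0
        for seed in range(100):
            tests, truth = [], []
            for i in range(50):
                is_true = i < 5
                p = 0.3 if is_true else 0.15
                cross = simulate_bristle_cross(p, 120, seed * 1000 + i + 1,
                                               genotype=f"g{i}")
                tests.append(bristle_binomial_test(cross, p_hat=0.15))
                truth.append(is_true)
            for call, is_true in zip(bristle_fdr_and_call(tests, "s"), truth):
                if call.code != "0":
                    called += 1
                    false += not is_true
        assert called > 0
        assert false / called <= 0.1


class TestScreenTable:
    def test_packaged_fixture_shape(self):
        table = load_packaged_screen_table()
        assert table.n_genes == 39
        assert list(table.SENSITIZERS) == ["Dlmo", "ssdp", "Chip"]

    def test_known_row_codes(self):
        table = load_packaged_screen_table()
        row = table.data[table.data["symbol"] == "xbp1"].iloc[0]
        assert (row["Dlmo"], row["ssdp"], row["Chip"]) == ("+", "-", "-")

    def test_invalid_code_reports_cell(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("dgrc\tsymbol\tDlmo\tssdp\tChip\n"
                        "CG1\tgeneA\t+\tx\t0\n")
        with pytest.raises(ValueError, match="CG1.*ssdp"):
            parse_screen_table(path)


class TestSummarizeScreen:
    def test_wing_column_counts(self):
        summary = summarize_screen(load_packaged_screen_table())
        dlmo = summary.per_sensitizer["Dlmo"]
        assert dlmo["tested"] == 39
        assert dlmo["interacting"] == 28
        assert dlmo["enhancers"] == 25
        assert dlmo["suppressors"] == 3
        assert dlmo["interacting_pct"] == pytest.approx(71.8)
        assert dlmo["enhancer_pct_of_interacting"] == pytest.approx(89.3)

    def test_bristle_column_counts(self):
        summary = summarize_screen(load_packaged_screen_table())
        assert summary.per_sensitizer["ssdp"]["interacting"] == 14
        assert summary.per_sensitizer["ssdp"]["enhancers"] == 9
        assert summary.per_sensitizer["ssdp"]["suppressors"] == 5
        assert summary.per_sensitizer["Chip"]["interacting"] == 14
        assert summary.per_sensitizer["Chip"]["enhancers"] == 4
        assert summary.per_sensitizer["Chip"]["suppressors"] == 10

    def test_combined_bristle_roles(self):
        b = summarize_screen(load_packaged_screen_table()).bristle
        assert b["tested"] == 28
        assert b["suppressor_genes"] == 12
        assert b["chip_suppressors"] == 10 and b["ssdp_suppressors"] == 5
        assert b["both_suppressors"] == 3
        assert b["enhancer_genes"] == 11
        assert b["ssdp_enhancers"] == 9 and b["chip_enhancers"] == 4
        assert b["both_enhancers"] == 2
        assert b["interacting_roles"] == 23

    def test_all_untested_table(self, tmp_path):
        path = tmp_path / "allna.tsv"
        path.write_text("dgrc\tsymbol\tDlmo\tssdp\tChip\n"
                        "CG1\tgeneA\tn\tn\tn\n")
        summary = summarize_screen(parse_screen_table(path))
        assert all(v["tested"] == 0 for v in summary.per_sensitizer.values())
        assert summary.bristle["interacting_roles"] == 0


class TestScreenIO:
    def test_severity_table_round_trip(self, tmp_path):
        dists = [dist([5, 4, 3, 2, 1, 0], "c1", "female"),
                 dist([1, 2, 3, 4, 5, 6], "c1", "male")]
        path = tmp_path / "sev.tsv"
        ldbio.write_severity_tables(dists, path)
        back = ldbio.read_severity_tables(path)
        for a, b in zip(dists, back):
            assert a.genotype == b.genotype and a.sex == b.sex
            assert np.array_equal(a.counts, b.counts)

    def test_bristle_table_round_trip(self, tmp_path):
        crosses = [BristleCross("c", 100, 25, role="control"),
                   BristleCross("t1", 50, 20, role="test")]
        path = tmp_path / "bristle.tsv"
        ldbio.write_bristle_table(crosses, path)
        back = ldbio.read_bristle_table(path)
        assert [(c.genotype, c.n, c.d, c.role) for c in back] == \
               [(c.genotype, c.n, c.d, c.role) for c in crosses]
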