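"""Detection and differential-expression cascades, in-vitro and clinical."""

import math

import numpy as np
import pytest
from scipy import integrate, special, stats

from conftest import make_clinical_experiment, make_invitro_experiment
from saspipe.config import FilterConfig
from saspipe.filters import de_filter, de_filter_clinical, detect_clinical, detect_in_vitro


def _flag_exp(flag_rows, **kwargs):
    expr = {pid: [100.0] * len(v) for pid, v in flag_rows.items()}
    return make_invitro_experiment(expr, flag_rows, **kwargs)


class TestDetectInVitro:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            (["P", "P", "M", "A", "A", "A"], True),   # P/M in all 3 ctrl reps
            (["P", "A", "P", "A", "A", "A"], False),  # one Absent breaks the rule
            (["M", "M", "M", "A", "A", "A"], True),
        ],
    )
    def test_all_replicates_rule(self, flags, expected):
        exp = _flag_exp({"ps1": flags})
        assert ("ps1" in detect_in_vitro(exp, "ctrl")) is expected

    def test_single_replicate_condition(self):
        exp = _flag_exp({"ps1": ["M", "P"]}, conditions=("ctrl", "trt"), n_reps=1)
        assert detect_in_vitro(exp, "ctrl") == {"ps1"}

    def test_unknown_condition_rejected(self):
        exp = _flag_exp({"ps1": ["P"] * 6})
        with pytest.raises(ValueError, match="unknown condition"):
            detect_in_vitro(exp, "nope")

    def test_sample_order_invariance(self):
        exp = _flag_exp({"ps1": ["P", "A", "P", "P", "P", "P"], "ps2": ["P"] * 6})
        shuffled = exp.expression.columns[::-1]
        from saspipe.filters import ExpressionExperiment

        exp2 = ExpressionExperiment(
            exp.expression[shuffled], exp.flags[shuffled], exp.design
        )
        for cond in ("ctrl", "trt"):
            assert detect_in_vitro(exp, cond) == detect_in_vitro(exp2, cond)


class TestDetectClinical:
    def _exp(self, n_pm, n_total=28):
        flags = {"ps1": ["P"] * n_pm + ["A"] * (n_total - n_pm)}
        expr = {"ps1": [100.0] * n_total}
        responses = ["CR", "PR", "SD", "PD"] * (n_total // 4)
        return make_clinical_experiment(expr, flags, responses)

    def test_strict_majority_boundary(self):
        assert detect_clinical(self._exp(15)) == {"ps1"}   # 15/28 > 50%
        assert detect_clinical(self._exp(14)) == set()     # exactly 50% fails
        assert detect_clinical(self._exp(0)) == set()

    def test_marginal_counts_toward_majority(self):
        exp = self._exp(0)
        exp.flags.loc["ps1"] = ["M"] * 15 + ["A"] * 13
        assert detect_clinical(exp) == {"ps1"}


class TestDeFilter:
    def test_identical_replicates_fold_one_not_de(self):
        exp = make_invitro_experiment(
            {"ps1": [100, 110, 90, 100, 110, 90]},
            {"ps1": ["P"] * 6},
        )
        res = de_filter(exp, "ctrl", "trt")
        assert res.stats.loc["ps1", "fold_change"] == pytest.approx(1.0)
        assert res.de == set()

    def test_analytic_t_example(self):
        # log2 values a=(0, .1, -.1), b=(1, 1.1, .9): pooled t = 1/(0.1*sqrt(2/3))
        a = [2**0, 2**0.1, 2**-0.1]
        b = [2**1, 2**1.1, 2**0.9]
        exp = make_invitro_experiment({"ps1": a + b}, {"ps1": ["P"] * 6})
        res = de_filter(exp, "ctrl", "trt")
        t_expected = 1.0 / (0.1 * math.sqrt(2.0 / 3.0))
        p_expected = 2.0 * special.stdtr(4, -t_expected)
        assert t_expected == pytest.approx(12.2474, abs=1e-4)
        assert res.stats.loc["ps1", "p_value"] == pytest.approx(p_expected, abs=1e-10)
        fold = np.mean(b) / np.mean(a)
        assert res.stats.loc["ps1", "fold_change"] == pytest.approx(fold)
        assert fold == pytest.approx(2.0, abs=0.01)
        assert res.de == {"ps1"}
        assert res.stats.loc["ps1", "direction"] == "up"

    def test_fold_threshold_is_inclusive(self):
        # zero-variance groups with unequal means: degenerate contrast, p=0,
        # fold exactly 1.3 passes the inclusive threshold
        exp = make_invitro_experiment(
            {"ps1": [100, 100, 100, 130, 130, 130]},
            {"ps1": ["P"] * 6},
        )
        res = de_filter(exp, "ctrl", "trt")
        assert res.stats.loc["ps1", "fold_change"] == pytest.approx(1.3)
        assert res.stats.loc["ps1", "degenerate"]
        assert res.stats.loc["ps1", "p_value"] == 0.0
        assert res.de == {"ps1"}
        assert res.warnings

    def test_zero_variance_equal_means_excluded(self):
        exp = make_invitro_experiment(
            {"ps1": [100.0] * 6}, {"ps1": ["P"] * 6}
        )
        res = de_filter(exp, "ctrl", "trt")
        assert res.stats.loc["ps1", "fold_change"] == 1.0
        assert res.stats.loc["ps1", "p_value"] == 1.0
        assert res.de == set()

    def test_undetected_probesets_never_tested(self):
        exp = make_invitro_experiment(
            {"ps1": [100, 100, 100, 200, 210, 190], "ps2": [100, 100, 100, 200, 210, 190]},
            {"ps1": ["P"] * 6, "ps2": ["A", "P", "P", "P", "P", "P"]},
        )
        res = de_filter(exp, "ctrl", "trt")
        assert "ps2" not in res.stats.index
        assert res.de <= (res.detected["ctrl"] & res.detected["trt"])

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(0)
        rows = {f"ps{i}": (rng.lognormal(5, 0.5, 6)).tolist() for i in range(40)}
        flags = {pid: ["P"] * 6 for pid in rows}
        exp = make_invitro_experiment(rows, flags)
        base = de_filter(exp, "ctrl", "trt", FilterConfig(fold_threshold=1.1, p_threshold=0.2))
        tighter_fold = de_filter(exp, "ctrl", "trt", FilterConfig(fold_threshold=1.5, p_threshold=0.2))
        tighter_p = de_filter(exp, "ctrl", "trt", FilterConfig(fold_threshold=1.1, p_threshold=0.01))
        assert tighter_fold.de <= base.de
        assert tighter_p.de <= base.de

    def test_requires_two_replicates(self):
        exp = _flag_exp({"ps1": ["P", "P"]}, conditions=("ctrl", "trt"), n_reps=1)
        with pytest.raises(ValueError, match="2 replicates"):
            de_filter(exp, "ctrl", "trt")


class TestDeFilterClinical:
    def _exp(self, group_means, n_per_group=7, noise=None):
        responses = []
        values = []
        for g, m in zip(("CR", "PR", "SD", "PD"), group_means):
            responses += [g] * n_per_group
            values += [m] * n_per_group
        flags = {"ps1": ["P"] * len(values)}
        return make_clinical_experiment({"ps1": values}, flags, responses)

    def test_identical_group_means_no_pass(self):
        res = de_filter_clinical(self._exp([10, 10, 10, 10]))
        assert res.de == set()

    def test_exact_threshold_passes(self):
        res = de_filter_clinical(self._exp([15, 10, 10, 10]))
        assert res.stats.loc["ps1", "fold_change"] == pytest.approx(1.5)
        assert res.de == {"ps1"}

    def test_one_vs_rest_arithmetic(self):
        # group PD mean 16 vs rest mean 10 -> fold 1.6, passes
        res = de_filter_clinical(self._exp([10, 10, 10, 16]))
        assert res.stats.loc["ps1", "fold_change"] == pytest.approx(1.6)
        assert res.stats.loc["ps1", "best_group"] == "PD"
        assert res.de == {"ps1"}

    def test_down_regulation_detected(self):
        res = de_filter_clinical(self._exp([10, 10, 10, 5]))
        assert res.stats.loc["ps1", "fold_change"] == pytest.approx(2.0)
        assert res.stats.loc["ps1", "direction"] == "down"

    def test_de_nested_in_detected(self, noiseless_world):
        *_, clinical = noiseless_world
        res = de_filter_clinical(clinical)
        assert res.de <= res.detected["all"]

    def test_missing_group_skipped_with_warning(self):
        exp = make_clinical_experiment(
            {"ps1": [10.0] * 8}, {"ps1": ["P"] * 8}, ["CR"] * 4 + ["PR"] * 4
        )
        res = de_filter_clinical(exp)
        assert res.de == set()
        assert not res.warnings  # both groups populated
        with pytest.raises(ValueError, match="2 response groups"):
            de_filter_clinical(
                make_clinical_experiment({"ps1": [10.0] * 4}, {"ps1": ["P"] * 4}, ["CR"] * 4)
            )


def analytic_joint_power(delta, sd, n, alpha=0.05, fold_threshold=1.3):
    """P(pooled two-sided t rejects AND |linear fold| >= threshold).

    The observed log2 mean difference D ~ N(delta, sd*sqrt(2/n)) is
    independent of the pooled variance Sp^2 ~ sd^2/(2n-2) * chi2(2n-2);
    the joint pass probability integrates the normal tail over the Sp
    density. Fold is evaluated on the log2 difference, an excellent proxy
    at small noise.
    """
    df = 2 * n - 2
    se = sd * math.sqrt(2.0 / n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    c = math.log2(fold_threshold)

    def integrand(s):
        cut = max(c, tcrit * s * math.sqrt(2.0 / n))
        upper = 1 - stats.norm.cdf((cut - delta) / se)
        lower = stats.norm.cdf((-cut - delta) / se)
        # s = pooled SD; Sp^2 * df / sd^2 ~ chi2(df)
        dens = 2 * s * df / sd**2 * stats.chi2.pdf(s**2 * df / sd**2, df)
        return (upper + lower) * dens

    val, _ = integrate.quad(integrand, 1e-9, sd * 8)
    return val


def test_power_recovery_matches_noncentral_t_oracle():
    """Planted-effect pass rate through the full cascade agrees with the
    analytic joint power of the pooled t-test and the fold filter."""
    import saspipe as sp
    from saspipe.simulate import design_platforms, generate_transcriptome, make_invitro_design, simulate_expression

    cfg = sp.SyntheticConfig(
        n_genes=1000, nat_fraction=0.0, shared_content_fraction=1.0,
        redundancy_generic=1.0, unassigned_fraction=0.0, de_fraction=1.0,
        effect_log2=1.0, noise_sd_log2=0.25, baseline_log2_range=(8.0, 12.0),
        flag_flip_rate=0.0, seed=0,
    )
    tx, truth = generate_transcriptome(cfg)
    _, dsa = design_platforms(tx, cfg, truth)
    exp = simulate_expression(dsa, make_invitro_design(3), truth, cfg)
    res = de_filter(exp, "parental_untreated", "parental_treated")
    planted = {f"DSA_S_{t}" for t in truth.planted_de["sensitive"]}
    rate = len(res.de & planted) / len(planted)
    expected = analytic_joint_power(1.0, 0.25, 3)
    # 99.9% binomial band around the analytic prediction
    band = 3.29 * math.sqrt(expected * (1 - expected) / len(planted))
    assert rate == pytest.approx(expected, abs=band)
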