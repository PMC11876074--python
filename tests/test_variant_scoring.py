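"""Cutoff, classification, contrasts, flags, and variant annotation."""

import numpy as np
import pytest

from speckscore import (
    ClassifierConfig,
    annotate_domain,
    annotate_variant,
    classify_variant,
    contrast_conditions,
    domain_density,
    flag_response,
    parse_variant_name,
    score_replicates,
    symptomatic_threshold,
)
from speckscore.variant_scoring import bh_adjust, load_domain_table, save_domain_table


class TestSymptomaticThreshold:
    def test_zero_spread_returns_mean(self):
        assert symptomatic_threshold([0.5, 0.5, 0.5, 0.5]) == pytest.approx(0.5)

    def test_normal_quantile_closed_form(self):
        cfg = ClassifierConfig(ci_method="normal")
        # mean 0.5, sem 0.1 -> 0.5 - 1.959964 * 0.1
        got = symptomatic_threshold([0.4, 0.6], cfg)
        assert got == pytest.approx(0.5 - 1.959964 * 0.1, abs=1e-4)

    def test_t_quantile_closed_form(self):
        cfg = ClassifierConfig(ci_method="t")
        # t(0.975, df=1) = 12.706
        got = symptomatic_threshold([0.4, 0.6], cfg)
        assert got == pytest.approx(0.5 - 12.706 * 0.1, abs=1e-3)

    def test_ci_level_to_zero_converges_to_mean(self):
        values = [0.2, 0.4, 0.6]
        for level in (0.5, 0.1, 0.001):
            cfg = ClassifierConfig(ci_level=level, ci_method="normal")
            got = symptomatic_threshold(values, cfg)
        assert got == pytest.approx(np.mean(values), abs=1e-3)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            symptomatic_threshold([0.5])


class TestClassification:
    def test_high_score_supports_pathogenic(self):
        score = score_replicates([0.88, 0.9, 0.92], "V", "untreated")
        reco = classify_variant(score, "VUS")
        assert reco.functional_call == "supports_pathogenic"

    def test_borderline_band_uses_sem(self):
        score = score_replicates([0.24, 0.29, 0.34], "V", "untreated")
        assert abs(score.mean - 0.281) <= score.sem
        assert classify_variant(score, "VUS").functional_call == "borderline"

    def test_low_score_with_pathogenic_prior_triggers_review(self):
        score = score_replicates([-0.01, 0.0, 0.01], "V", "untreated")
        reco = classify_variant(score, "pathogenic")
        assert reco.functional_call == "supports_benign_review"

    def test_low_score_with_benign_prior_stands(self):
        score = score_replicates([0.0, 0.01, 0.02], "V", "untreated")
        assert classify_variant(score, "VUS").functional_call == "below_cutoff"

    def test_order_invariance(self):
        a = classify_variant(score_replicates([0.1, 0.5, 0.9], "V", "u"), "VUS")
        b = classify_variant(score_replicates([0.9, 0.1, 0.5], "V", "u"), "VUS")
        assert a.functional_call == b.functional_call


class TestContrasts:
    def test_identical_groups_give_p_one(self):
        s = score_replicates([0.1, 0.2, 0.3], "V", "a")
        t = score_replicates([0.1, 0.2, 0.3], "V", "b")
        result = contrast_conditions(s, t)
        # same data in both groups: no evidence of any difference
        assert result.t_statistic == pytest.approx(0.0)
        assert result.p_value == pytest.approx(1.0)

    def test_student_t_closed_form(self):
        # pooled-variance t for {.1,.2,.3} vs {.6,.7,.8}: t = -6.1237, df = 4
        a = score_replicates([0.1, 0.2, 0.3], "V", "untreated")
        b = score_replicates([0.6, 0.7, 0.8], "V", "nigericin")
        result = contrast_conditions(a, b, "student")
        assert result.t_statistic == pytest.approx(-6.123724, abs=1e-5)
        from scipy import stats
        assert result.p_value == pytest.approx(2 * stats.t.sf(6.123724, 4), rel=1e-5)
        assert result.delta_mean == pytest.approx(0.5)

    def test_degenerate_unequal_constants_flagged(self):
        a = score_replicates([0.0, 0.0, 0.0], "V", "a")
        b = score_replicates([1.0, 1.0, 1.0], "V", "b")
        result = contrast_conditions(a, b)
        assert result.degenerate
        assert result.p_value <= np.finfo(float).tiny
        assert result.significant

    def test_insufficient_replicates_rejected(self):
        a = score_replicates([0.1], "V", "a")
        b = score_replicates([0.2, 0.3], "V", "b")
        with pytest.raises(ValueError, match="2 replicates"):
            contrast_conditions(a, b)

    def test_bh_adjustment_is_monotone(self):
        p = [0.001, 0.01, 0.04, 0.2, 0.9]
        adj = bh_adjust(p)
        assert (np.diff(adj[np.argsort(p)]) >= 0).all()
        assert (adj >= p).all()


class TestFlags:
    def _scores(self, untreated, treated, condition):
        return {
            "untreated": score_replicates(untreated, "V", "untreated"),
            condition: score_replicates(treated, "V", condition),
        }

    def test_nigericin_hypersensitivity_from_simulated_truth(self):
        # modifier 0.7 on r=1: true ASC50 goes 0 -> 0.3 under nigericin
        scores = self._scores([0.0, 0.01, -0.01], [0.28, 0.3, 0.32], "nigericin")
        contrast = contrast_conditions(scores["untreated"], scores["nigericin"])
        flags = flag_response({"nigericin": contrast}, scores)
        assert flags["nigericin_hypersensitive"] is True
        assert flags["cold_sensitive"] is None  # pair missing -> undetermined

    def test_mcc950_resistance_rule(self):
        # no significant decrease AND treated mean above the cutoff
        scores = self._scores([0.6, 0.62, 0.58], [0.59, 0.63, 0.6], "mcc950_12h")
        contrast = contrast_conditions(scores["untreated"], scores["mcc950_12h"])
        flags = flag_response({"mcc950_12h": contrast}, scores)
        assert flags["mcc950_resistant"] is True

    def test_mcc950_inhibited_variant_not_resistant(self):
        scores = self._scores([0.6, 0.62, 0.58], [0.1, 0.12, 0.09], "mcc950_12h")
        contrast = contrast_conditions(scores["untreated"], scores["mcc950_12h"])
        flags = flag_response({"mcc950_12h": contrast}, scores)
        assert flags["mcc950_resistant"] is False

    def test_wt_has_no_flags(self):
        scores = {"untreated": score_replicates([0.0, 0.01, -0.01], "WT",
                                                "untreated")}
        contrasts = {}
        for cond in ("nigericin", "cold_32C", "mcc950_12h"):
            scores[cond] = score_replicates([0.0, 0.02, -0.02], "WT", cond)
            contrasts[cond] = contrast_conditions(scores["untreated"],
                                                  scores[cond])
        flags = flag_response(contrasts, scores)
        assert flags["nigericin_hypersensitive"] is False
        assert flags["cold_sensitive"] is False
        assert flags["mcc950_resistant"] is False


class TestAnnotation:
    @pytest.mark.parametrize("label, pos, kind", [
        ("R262W", 262, "missense"),
        ("R556*", 556, "nonsense"),
        ("F257fs", 257, "frameshift"),
        ("T440del", 440, "deletion"),
    ])
    def test_variant_grammar(self, label, pos, kind):
        ann = parse_variant_name(label)
        assert ann.position == pos and ann.kind == kind

    @pytest.mark.parametrize("bad", ["262W", "Rx262W", "R0W", "B262W", "R262"])
    def test_unparseable_labels_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_variant_name(bad)

    @pytest.mark.parametrize("pos, subdomain, group", [
        (21, "PYD", "PYD"),
        (262, "NBD", "NACHT"),
        (355, "NBD", "NACHT"),
        (920, "cnLRR", "LRR"),
    ])
    def test_domain_lookup(self, pos, subdomain, group):
        name, grp = annotate_domain(pos)
        assert (name, grp) == (subdomain, group)

    def test_position_beyond_span_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            annotate_domain(2000)

    def test_domain_density_counts_per_residue(self):
        labels = ["D21H", "H51R", "R262W", "D305N", "Y861H"]
        dens = domain_density(labels)
        assert dens["PYD"]["count"] == 2
        assert dens["NBD"]["count"] == 2
        assert dens["cnLRR"]["count"] == 1
        assert dens["PYD"]["per_residue"] == pytest.approx(2 / 95)

    def test_domain_table_tsv_round_trip(self, tmp_path):
        from speckscore.variant_scoring import DEFAULT_DOMAIN_TABLE
        path = tmp_path / "domains.tsv"
        save_domain_table(DEFAULT_DOMAIN_TABLE, path)
        assert load_domain_table(path) == DEFAULT_DOMAIN_TABLE
        ann = annotate_variant("R262W", load_domain_table(path))
        assert ann.domain == "NBD"
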