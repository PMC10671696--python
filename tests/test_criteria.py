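"""Clinical criteria: point tables, categorical rules, boundaries."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from fhdx.config import default_config
from fhdx.criteria import (
    classify_hk_panel,
    classify_jfhmc,
    classify_medped,
    classify_simon_broome,
    evaluate_all_criteria,
    score_dlcnc,
    score_modified_dlcnc,
    select_ldl_for_scoring,
)
from fhdx.io import parse_regimen
from fhdx.models import (
    Category,
    FamilyHistory,
    GeneticResult,
    LdlProvenance,
    LipidPanel,
    ScoringError,
    Signs,
    Subject,
)


def subject(ldl=None, tc=None, age=40, **kwargs):
    pre = None
    if ldl is not None or tc is not None:
        pre = LipidPanel(ldl_c=ldl, total_cholesterol=tc, is_pretreatment=True)
    return Subject(id="t", age_years=age, pretreatment_lipids=pre, **kwargs)


class TestSelectLdl:
    def test_measured_pretreatment_passthrough(self):
        ldl, prov = select_ldl_for_scoring(subject(ldl=8.42))
        assert (ldl, prov) == (8.42, LdlProvenance.measured)

    def test_corrected_from_on_treatment(self):
        s = Subject(
            id="t",
            age_years=40,
            on_treatment_lipids=LipidPanel(ldl_c=3.0),
            regimen=parse_regimen("atorvastatin:40"),
        )
        ldl, prov = select_ldl_for_scoring(s)
        assert ldl == pytest.approx(6.0)
        assert prov == LdlProvenance.corrected

    def test_peak_only_under_peak_policy(self):
        cfg = default_config()
        s = subject(ldl=8.77)
        s = s.model_copy(update={"peak_ldl_c": 9.24})
        assert select_ldl_for_scoring(s, cfg)[0] == 8.77
        cfg.ldl_policy.source = "peak_first"
        ldl, prov = select_ldl_for_scoring(s, cfg)
        assert (ldl, prov) == (9.24, LdlProvenance.peak)

    def test_no_source_raises_naming_subject(self):
        with pytest.raises(ScoringError, match="'t'"):
            select_ldl_for_scoring(subject(tc=6.0))


class TestDlcnc:
    def test_band_plus_xanthoma_plus_family(self):
        s = subject(
            ldl=8.6,
            signs=Signs(tendon_xanthoma=True),
            family_history=FamilyHistory(first_degree_hyperlipidemia=True),
        )
        r = score_dlcnc(s)
        assert r.score == 15 and r.category == Category.definite

    @pytest.mark.parametrize("ldl, points", [(4.9, 1), (3.9, 0), (8.5, 8), (6.5, 5), (5.0, 3)])
    def test_ldl_band_boundaries(self, ldl, points):
        assert score_dlcnc(subject(ldl=ldl)).score == points

    def test_category_boundaries_exact(self):
        # score 9 -> definite, 8 -> probable, 3 -> possible, 2 -> negative
        def with_score(score):
            ldl = {8: 8.5, 1: 4.0, 0: 3.0}
            fam = FamilyHistory(first_degree_hyperlipidemia=True)
            if score == 9:
                return subject(ldl=8.5, family_history=fam)
            if score == 8:
                return subject(ldl=8.5)
            if score == 3:
                return subject(ldl=5.0)
            if score == 2:
                return subject(ldl=4.0, family_history=fam)
            raise AssertionError

        assert score_dlcnc(with_score(9)).category == Category.definite
        assert score_dlcnc(with_score(8)).category == Category.probable
        assert score_dlcnc(with_score(3)).category == Category.possible
        assert score_dlcnc(with_score(2)).category == Category.negative

    def test_dna_variant_points(self):
        s = subject(ldl=3.0, genetic=GeneticResult(variant_detected=True))
        assert score_dlcnc(s).score == 8

    def test_pediatric_flagged_and_suppressible(self):
        cfg = default_config()
        s = subject(ldl=5.0, age=10)
        r = score_dlcnc(s, cfg)
        assert r.binary_call is True and any("not validated" in n for n in r.notes)
        cfg.criteria.dlcnc.pediatric_policy = "suppress"
        assert score_dlcnc(s, cfg).binary_call is None

    def test_family_pcvd_separate_scoring_flag(self):
        cfg = default_config()
        s = subject(
            ldl=3.0,
            family_history=FamilyHistory(
                first_degree_pcvd=True, first_degree_hyperlipidemia=True
            ),
        )
        assert score_dlcnc(s, cfg).score == 1
        cfg.criteria.dlcnc.score_family_pcvd_separately = True
        assert score_dlcnc(s, cfg).score == 2

    def test_purity(self):
        s = subject(ldl=6.0, signs=Signs(tendon_xanthoma=True))
        assert score_dlcnc(s) == score_dlcnc(s)


class TestModifiedDlcnc:
    @pytest.mark.parametrize("ldl, points", [(6.0, 8), (2.4, 0), (5.0, 5), (3.5, 3), (2.5, 1)])
    def test_chinese_bands(self, ldl, points):
        assert score_modified_dlcnc(subject(ldl=ldl)).score == points

    @given(ldl=st.floats(0.1, 16.0))
    def test_dominates_dlcnc_over_ldl_grid(self, ldl):
        s = subject(ldl=ldl)
        assert score_modified_dlcnc(s).score >= score_dlcnc(s).score


class TestSimonBroome:
    def test_definite_via_xanthoma(self):
        s = subject(ldl=5.0, signs=Signs(tendon_xanthoma=True))
        assert classify_simon_broome(s).category == Category.definite

    def test_possible_child_via_family_history(self):
        s = subject(
            ldl=4.1, age=10,
            family_history=FamilyHistory(first_degree_hyperlipidemia=True),
        )
        assert classify_simon_broome(s).category == Category.possible

    def test_strict_boundary(self):
        s = subject(ldl=4.9, signs=Signs(tendon_xanthoma=True))
        assert classify_simon_broome(s).category == Category.negative

    def test_relative_xanthoma_config_switch(self):
        cfg = default_config()
        s = subject(
            ldl=5.0,
            family_history=FamilyHistory(relative_tendon_xanthoma=True),
        )
        assert classify_simon_broome(s, cfg).category == Category.definite
        cfg.criteria.simon_broome.include_relative_tendon_xanthoma = False
        assert classify_simon_broome(s, cfg).category == Category.negative


class TestMedped:
    def test_first_degree_threshold(self):
        s = subject(tc=6.3, age=25,
                    family_history=FamilyHistory(relative_with_fh_diagnosis=True))
        assert classify_medped(s).binary_call is True

    def test_general_population_negative(self):
        assert classify_medped(subject(tc=5.0, age=25)).binary_call is False

    def test_threshold_equality_is_negative(self):
        s = subject(tc=6.2, age=25,
                    family_history=FamilyHistory(relative_with_fh_diagnosis=True))
        assert classify_medped(s).binary_call is False

    def test_missing_tc_raises(self):
        with pytest.raises(ScoringError):
            classify_medped(subject(ldl=6.0))


class TestJfhmc:
    def test_adult_positive(self):
        s = subject(ldl=4.8, signs=Signs(tendon_xanthoma=True))
        assert classify_jfhmc(s).binary_call is True

    def test_homozygous_flag(self):
        r = classify_jfhmc(subject(ldl=4.0, tc=15.6))
        assert r.binary_call is True and r.notes

    def test_child_boundary_negative(self):
        s = subject(ldl=3.6, age=10, signs=Signs(tendon_xanthoma=True))
        assert classify_jfhmc(s).binary_call is False


class TestHkPanel:
    @pytest.mark.parametrize(
        "ldl, fam, expected",
        [(5.1, False, True), (4.6, True, True), (4.6, False, False)],
    )
    def test_adult_arms(self, ldl, fam, expected):
        s = subject(ldl=ldl,
                    family_history=FamilyHistory(first_degree_pcvd=fam))
        assert classify_hk_panel(s).binary_call is expected

    def test_child_arms(self):
        fam = FamilyHistory(relative_with_fh_diagnosis=True)
        assert classify_hk_panel(subject(ldl=3.7, age=10, family_history=fam)).binary_call
        assert classify_hk_panel(subject(ldl=5.0, age=10)).binary_call
        assert classify_hk_panel(
            subject(ldl=3.0, age=10, signs=Signs(xanthelasma=True))
        ).binary_call
        assert not classify_hk_panel(subject(ldl=3.7, age=10)).binary_call


class TestAllCriteria:
    def test_deterministic_order_and_one_result_each(self):
        s = subject(ldl=6.0, tc=8.0)
        results = evaluate_all_criteria(s)
        names = [r.criterion.value for r in results]
        assert names == [
            "DLCNC", "modified_DLCNC", "SimonBroome", "MEDPED", "JFHMC", "HK_panel",
        ]

    @given(
        ldl_lo=st.floats(1.0, 12.0),
        delta=st.floats(0.0, 4.0),
        xanthoma=st.booleans(),
        fam=st.booleans(),
    )
    def test_binary_calls_monotone_in_ldl(self, ldl_lo, delta, xanthoma, fam):
        fh = FamilyHistory(first_degree_hyperlipidemia=fam)
        lo = subject(ldl=ldl_lo, tc=ldl_lo + 1.6,
                     signs=Signs(tendon_xanthoma=xanthoma), family_history=fh)
        hi = subject(ldl=ldl_lo + delta, tc=ldl_lo + delta + 1.6,
                     signs=Signs(tendon_xanthoma=xanthoma), family_history=fh)
        for r_lo, r_hi in zip(evaluate_all_criteria(lo), evaluate_all_criteria(hi)):
            assert r_hi.binary_call >= r_lo.binary_call
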