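"""PNI-GARS engine: base tiers, upgrades, downgrades, stability, properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pnigars import (
    DensityType,
    NoduleRecord,
    PniGrade,
    ScreenLabel,
    apply_benign_adjustment,
    apply_malignant_signs,
    apply_stability,
    base_grade,
    classify_pnigars,
    dichotomize_pni,
    validate_record,
)
from pnigars.records import MALIGNANT_SIGNS

G = PniGrade


class TestBaseGrade:
    @pytest.mark.parametrize(
        "density, diameter, solid, expected",
        [
            ("SN", 4.0, None, G.I),        # micronodule
            ("GGN", 5.0, None, G.I),       # inclusive micronodule bound
            ("PSN", 4.0, 2.0, G.I),        # micronodule overrides PSN rules
            ("SN", 5.1, None, G.II),
            ("SN", 8.0, None, G.II),       # tier upper bounds inclusive
            ("GGN", 9.5, None, G.IIIA),
            ("GGN", 10.0, None, G.IIIA),
            ("SN", 14.9, None, G.IIIB),
            ("SN", 20.0, None, G.IIIB),
            ("SN", 20.1, None, G.IIIC),
            ("GGN", 30.0, None, G.IIIC),
            ("PSN", 9.0, 6.0, G.IV),       # solid component > 5 mm
            ("PSN", 6.0, 5.5, G.IV),
            ("PSN", 9.0, 5.0, G.IIIA),     # solid component exactly 5 mm: size tier
            ("PSN", 9.0, 4.0, G.IIIA),
        ],
    )
    def test_size_and_density_tiers(self, density, diameter, solid, expected):
        rec = NoduleRecord("x", DensityType(density), diameter, solid_component_diameter=solid)
        assert base_grade(validate_record(rec)) is expected

    @pytest.mark.parametrize(
        "diameter, expected",
        [(4.0, G.IIIA), (7.0, G.IIIA), (9.0, G.IIIA), (14.0, G.IIIB), (25.0, G.IIIC)],
    )
    def test_endobronchial_floor_at_grade_iii(self, diameter, expected):
        rec = NoduleRecord("x", DensityType.SN, diameter, endobronchial=True)
        assert base_grade(rec) is expected


class TestSignUpgrades:
    def test_one_special_sign_lifts_one_sublevel(self):
        assert apply_malignant_signs(G.IIIA, frozenset({"vascular_convergence"})) is G.IIIB
        assert apply_malignant_signs(G.II, frozenset({"vacuole"})) is G.IIIA
        assert apply_malignant_signs(G.IIIC, frozenset({"solid_component_in_ggn"})) is G.IV

    def test_two_signs_or_spiculation_force_grade_iv(self):
        assert (
            apply_malignant_signs(
                G.IIIB,
                frozenset({"vascular_convergence", "spiculation", "pleural_indentation"}),
            )
            is G.IV
        )
        assert apply_malignant_signs(G.II, frozenset({"spiculation"})) is G.IV
        assert apply_malignant_signs(G.II, frozenset({"vacuole", "pleural_indentation"})) is G.IV

    def test_no_signs_is_identity(self):
        for g in PniGrade:
            assert apply_malignant_signs(g, frozenset()) is g

    def test_micronodules_never_upgraded(self):
        assert apply_malignant_signs(G.I, frozenset({"spiculation", "vacuole"})) is G.I
        assert apply_malignant_signs(G.G0, frozenset({"spiculation"})) is G.G0

    def test_never_exceeds_iv(self):
        assert apply_malignant_signs(G.IV, frozenset({"vacuole"})) is G.IV


class TestBenignAdjustment:
    def test_satellite_lesions_downgrade_one_level(self):
        assert apply_benign_adjustment(G.IIIA, frozenset({"satellite_lesions"})) is G.II
        assert apply_benign_adjustment(G.IV, frozenset({"satellite_lesions"})) is G.IIIC

    def test_inflammation_requires_both_clinical_and_ct(self):
        assert apply_benign_adjustment(G.IIIB, frozenset({"inflammation_clinical"})) is G.IIIB
        assert (
            apply_benign_adjustment(
                G.IIIB, frozenset({"inflammation_clinical", "inflammation_ct"})
            )
            is G.IIIA
        )

    def test_no_features_is_identity(self):
        assert apply_benign_adjustment(G.IIIB, frozenset()) is G.IIIB

    def test_floor_is_grade_i_for_every_grade(self):
        # exhaustive sweep: no benign adjustment ever lands below I
        for g in PniGrade:
            out = apply_benign_adjustment(g, frozenset({"satellite_lesions"}))
            assert out >= G.I or g is G.G0


class TestStability:
    def test_solid_stable_two_years_becomes_grade_i(self, make_record):
        rec = make_record("SN", 14.0, stability_months=24.0, course="unchanged")
        assert apply_stability(rec, G.IIIB) is G.I

    def test_subsolid_needs_five_years(self, make_record):
        psn = make_record("PSN", 9.0, solid=4.0, stability_months=16.0, course="unchanged")
        assert apply_stability(psn, G.IIIA) is G.IIIA
        psn5y = psn.with_(stability_months=60.0)
        assert apply_stability(psn5y, G.IIIA) is G.I

    def test_regressing_course_downgrades_regardless_of_interval(self, make_record):
        for course in ("decreased", "disappeared"):
            rec = make_record("GGN", 12.0, course=course)
            assert apply_stability(rec, G.IIIB) is G.I

    def test_short_stability_leaves_grade(self, make_record):
        rec = make_record("SN", 14.0, stability_months=12.0, course="unchanged")
        assert apply_stability(rec, G.IIIB) is G.IIIB


class TestClassify:
    def test_figure_cases_reproduce_printed_grades(self, figure_cases):
        expected = {
            "hamartoma": G.G0,
            "ggn_one_sign": G.IIIB,
            "ggn_spiculated": G.IV,
            "stable_psn": G.IIIA,
        }
        for name, grade in expected.items():
            got, trace = classify_pnigars(figure_cases[name])
            assert got is grade, name
            assert trace.final_grade is grade

    def test_benign_definite_wins_over_signs_and_size(self, make_record):
        rec = make_record(
            "SN", 25.0,
            benign_features={"pure_calcification"},
            malignant_signs={"spiculation", "vacuole"},
        )
        grade, trace = classify_pnigars(rec)
        assert grade is G.G0
        assert trace.rule_ids() == ("benign_definite",)

    def test_long_stability_wins_over_signs(self, make_record):
        rec = make_record(
            "SN", 14.0, stability_months=30.0, course="unchanged",
            malignant_signs={"spiculation"},
        )
        grade, _ = classify_pnigars(rec)
        assert grade is G.I

    def test_downgraded_endobronchial_nodule_floors_at_iii(self, make_record):
        rec = make_record(
            "SN", 12.0, endobronchial=True, benign_features={"satellite_lesions"}
        )
        grade, trace = classify_pnigars(rec)
        assert grade is G.IIIB
        assert "endobronchial_floor" in trace.rule_ids()

    def test_trace_replays_to_final_grade(self, make_record):
        recs = [
            make_record("SN", 9.0, malignant_signs={"vacuole"}),
            make_record("PSN", 9.0, solid=6.0, benign_features={"satellite_lesions"}),
            make_record("GGN", 4.0),
            make_record("SN", 11.0, benign_features={"fat"}),
        ]
        for rec in recs:
            grade, trace = classify_pnigars(rec)
            assert trace.replay() is grade is trace.final_grade

    def test_identical_records_give_identical_traces(self, make_record):
        rec = make_record("GGN", 11.4, malignant_signs={"spiculation", "vacuole"})
        assert classify_pnigars(rec) == classify_pnigars(rec)


class TestDichotomization:
    @pytest.mark.parametrize(
        "grade, label",
        [
            (G.G0, ScreenLabel.NEGATIVE),
            (G.I, ScreenLabel.NEGATIVE),
            (G.II, ScreenLabel.NEGATIVE),
            (G.IIIA, ScreenLabel.POSITIVE),
            (G.IIIB, ScreenLabel.POSITIVE),
            (G.IIIC, ScreenLabel.POSITIVE),
            (G.IV, ScreenLabel.POSITIVE),
        ],
    )
    def test_grades_0_i_ii_negative_iii_iv_positive(self, grade, label):
        assert dichotomize_pni(grade) is label

    def test_dichotomization_monotone_in_grade(self):
        labels = [dichotomize_pni(g) for g in PniGrade]
        # once positive, always positive up the scale
        first_pos = labels.index(ScreenLabel.POSITIVE)
        assert all(l is ScreenLabel.POSITIVE for l in labels[first_pos:])


_sign_sets = st.frozensets(st.sampled_from(sorted(MALIGNANT_SIGNS)), max_size=3)
_densities = st.sampled_from(["SN", "PSN", "GGN"])


class TestEngineProperties:
    def test_size_monotonicity_exhaustive_sweep(self, make_record):
        """On a 0.1 mm grid, a larger nodule never gets a strictly lower grade."""
        feature_sets = [
            dict(),
            dict(malignant_signs={"vacuole"}),
            dict(malignant_signs={"vacuole", "spiculation"}),
            dict(benign_features={"satellite_lesions"}),
            dict(endobronchial=True),
            dict(malignant_signs={"vascular_convergence"},
                 benign_features={"satellite_lesions"}),
        ]
        for density in ("SN", "GGN"):
            for kw in feature_sets:
                grades = [
                    classify_pnigars(make_record(density, i / 10, **kw))[0]
                    for i in range(1, 301)
                ]
                assert grades == sorted(grades, key=list(PniGrade).index)
        # PSN with fixed solid component
        for kw in feature_sets:
            grades = [
                classify_pnigars(make_record("PSN", i / 10, solid=2.0, **kw))[0]
                for i in range(22, 301)
            ]
            assert grades == sorted(grades, key=list(PniGrade).index)

    @settings(derandomize=True, max_examples=300)
    @given(
        density=_densities,
        tenths=st.integers(min_value=1, max_value=300),
        signs=_sign_sets,
        extra=st.sampled_from(sorted(MALIGNANT_SIGNS)),
        satellite=st.booleans(),
    )
    def test_adding_a_sign_never_lowers_the_grade(self, density, tenths, signs, extra, satellite):
        d = tenths / 10
        kw = dict(benign_features=frozenset({"satellite_lesions"}) if satellite else frozenset())
        solid = d / 2 if density == "PSN" else None
        base = NoduleRecord("a", DensityType(density), d, solid_component_diameter=solid,
                            malignant_signs=signs, **kw)
        more = base.with_(malignant_signs=signs | {extra})
        assert classify_pnigars(more)[0] >= classify_pnigars(base)[0]

    @settings(derandomize=True, max_examples=300)
    @given(density=_densities, tenths=st.integers(min_value=1, max_value=300), signs=_sign_sets)
    def test_satellite_lesions_never_raise_and_cap_is_iv(self, density, tenths, signs):
        d = tenths / 10
        solid = d / 2 if density == "PSN" else None
        plain = NoduleRecord("a", DensityType(density), d, solid_component_diameter=solid,
                             malignant_signs=signs)
        sat = plain.with_(benign_features=frozenset({"satellite_lesions"}))
        g_plain = classify_pnigars(plain)[0]
        g_sat = classify_pnigars(sat)[0]
        assert g_sat <= g_plain
        assert g_plain <= PniGrade.IV and g_sat <= PniGrade.IV

    @settings(derandomize=True, max_examples=200)
    @given(
        density=_densities,
        tenths=st.integers(min_value=1, max_value=300),
        signs=_sign_sets,
        stability=st.one_of(st.none(), st.floats(0, 120)),
        course=st.sampled_from(["unchanged", "decreased", "disappeared", "increased", "unknown"]),
    )
    def test_every_valid_record_classifies(self, density, tenths, signs, stability, course):
        """Totality: anything that passes validation grades without error."""
        d = tenths / 10
        solid = d / 2 if density == "PSN" else None
        rec = validate_record(
            NoduleRecord("a", DensityType(density), d, solid_component_diameter=solid,
                         malignant_signs=signs, stability_months=stability, course=course)
        )
        grade, trace = classify_pnigars(rec)
        assert grade in PniGrade
        assert trace.replay() is grade
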