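import pytest

from pnigars import DensityType, NoduleRecord, classify_cohort, reconstruct_evaluation_cohort


@pytest.fixture
def make_record():
    """Factory for valid records with sensible defaults."""

    def _make(density="SN", diameter=10.0, solid=None, **kw):
        density = DensityType(density)
        if density is DensityType.PSN and solid is None:
            solid = round(diameter / 2, 1)
        return NoduleRecord(
            id=kw.pop("id", "x"),
            density_type=density,
            mean_diameter=diameter,
            solid_component_diameter=solid,
            **kw,
        )

    return _make


# Fully specified worked cases from the study's figures: the hamartoma with
# central calcification and fat (category 1 / grade 0), the 9.5 mm GGN with
# vascular convergence (2 / IIIb), the 11.4 mm GGN with spiculation and
# pleural indentation (2 / IV), the part-solid nodule stable > 6 months
# (2 / IIIa) and the 14.9 mm solid nodule stable ~5 months (Lung-RADS 3).
@pytest.fixture(scope="session")
def figure_cases():
    return {
        "hamartoma": NoduleRecord(
            "hamartoma", DensityType.SN, 11.0,
            benign_features=frozenset({"pure_calcification", "fat"}),
            pathology="benign",
        ),
        "ggn_one_sign": NoduleRecord(
            "ggn_one_sign", DensityType.GGN, 9.5,
            malignant_signs=frozenset({"vascular_convergence"}),
            pathology="malignant",
        ),
        "ggn_spiculated": NoduleRecord(
            "ggn_spiculated", DensityType.GGN, 11.4,
            malignant_signs=frozenset(
                {"vascular_convergence", "spiculation", "pleural_indentation"}
            ),
            pathology="malignant",
        ),
        "stable_psn": NoduleRecord(
            "stable_psn", DensityType.PSN, 9.0, solid_component_diameter=4.0,
            stability_months=16.0, course="unchanged", pathology="malignant",
        ),
        "stable_sn": NoduleRecord(
            "stable_sn", DensityType.SN, 14.9,
            stability_months=5.0, course="unchanged", pathology="malignant",
        ),
    }


@pytest.fixture(scope="session")
def classified_evaluation():
    """The reconstructed evaluation cohort, classified by both engines."""
    return classify_cohort(reconstruct_evaluation_cohort(tag_subtypes=True))
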