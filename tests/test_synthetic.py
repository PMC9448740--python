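"""The synthetic cohort generator and its ground truth."""

import numpy as np
import pytest

from ramandx.clinical import capra_group, capra_points
from ramandx.containers import trapezoid_area
from ramandx.errors import ValidationError
from ramandx.reference import ROSTER, SPECTRUM_INVENTORY
from ramandx.synthetic import (
    CohortDesign,
    default_axis,
    inject_outlier_biopsy,
    make_basis_library,
    make_clinical_table,
    simulate_cohort,
    simulate_score_cohort,
)


class TestBasisLibrary:
    def test_deterministic(self, axis):
        a = make_basis_library(axis=axis, seed=3)
        b = make_basis_library(axis=axis, seed=3)
        np.testing.assert_array_equal(a.spectra, b.spectra)

    def test_nonnegative_unit_area(self, library):
        assert library.spectra.min() >= 0.0
        areas = trapezoid_area(library.spectra, library.axis)
        np.testing.assert_allclose(areas, 1.0, atol=1e-9)

    def test_pairwise_cosine_bound(self, library):
        S = library.spectra / np.linalg.norm(library.spectra, axis=1, keepdims=True)
        G = S @ S.T
        np.fill_diagonal(G, 0.0)
        assert G.max() <= 0.8 + 1e-12

    def test_main_chemicals_lead_the_names(self, library):
        assert library.names[0] == "co-enzyme A"
        assert library.names[13] == "DNA"
        assert library.names[14] == "phenylalanine"
        assert len(library.names) == 31

    def test_calibration_band_isolated(self, library):
        """The phenylalanine entry peaks at the calibration wavenumber."""
        phe = library.spectra[library.index_of("phenylalanine")]
        apex = library.axis[int(np.argmax(phe))]
        assert abs(apex - 1003.0) <= 2.0


class TestSimulateCohort:
    def test_reference_inventory_totals_3905(self, library):
        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, use_reference_inventory=True, seed=0
        )
        spectra, truth, clin = simulate_cohort(design, library)
        assert spectra.n_spectra == 3905
        counts = spectra.meta.groupby("biopsy_id").size().to_dict()
        assert counts == SPECTRUM_INVENTORY

    def test_default_acquisition_structure(self, library):
        design = CohortDesign(class_scheme="ki67_2", axis_step=2.0, seed=1)
        spectra, _, _ = simulate_cohort(design, library)
        # 12 biopsies × 2 slices × 3 regions × 8×8 grid
        assert spectra.n_spectra == 12 * 2 * 3 * 64
        assert spectra.meta["grid_row"].max() == 7

    def test_noiseless_cohort_exactly_representable(self, library):
        from ramandx.nmf import fit_gbr_nmf, reconstruction_error

        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=4,
            noise_sd=0.0, background_amplitude=(0.0, 1e-12), cosmic_ray_rate=0.0,
            seed=2,
        )
        spectra, truth, _ = simulate_cohort(design, library)
        direct = truth.true_scores @ library.spectra
        np.testing.assert_allclose(spectra.intensities, direct, atol=1e-8)
        model = fit_gbr_nmf(spectra.intensities, library, n_iter=2000, tol=1e-12, seed=0)
        assert reconstruction_error(model, spectra.intensities) < 1e-3

    def test_ground_truth_aligned_with_spectra(self, library):
        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=3,
            cosmic_ray_rate=0.3, seed=3,
        )
        spectra, truth, _ = simulate_cohort(design, library)
        assert truth.true_scores.shape == (spectra.n_spectra, library.n_chemicals)
        assert truth.true_background.shape == spectra.intensities.shape
        for i, pt in truth.cosmic_ray_points:
            assert spectra.intensities[i, pt] > truth.true_background[i, pt]

    def test_artifact_recovery_sensitivity(self, library):
        """Injected cosmic rays are found with high sensitivity and clean
        spectra almost never rejected at default thresholds."""
        from ramandx.preprocess import PreprocessConfig, flag_artifacts

        design = CohortDesign(
            class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=25,
            cosmic_ray_rate=0.1, seed=4,
        )
        spectra, truth, _ = simulate_cohort(design, library)
        _, rejected = flag_artifacts(spectra, PreprocessConfig())
        flagged = {i for i, reason in rejected if reason == "cosmic_ray"}
        injected = set(truth.cosmic_ray_spectra)
        sensitivity = len(flagged & injected) / len(injected)
        false_pos = len(flagged - injected) / (spectra.n_spectra - len(injected))
        assert sensitivity >= 0.95
        assert false_pos <= 0.01

    def test_clinical_covariates_consistent_with_targets(self):
        design = CohortDesign(class_scheme="capra3", axis_step=2.0, seed=5)
        table = make_clinical_table(design)
        targets = {b: capra for b, _p, _a, _g, capra, _p4, _k, _psa in ROSTER}
        for rec in table.records:
            assert capra_group(capra_points(rec)) == targets[rec.biopsy_id]

    def test_determinism(self, library):
        design = CohortDesign(class_scheme="ki67_2", axis_step=2.0,
                              spectra_per_biopsy=3, seed=6)
        a, _, _ = simulate_cohort(design, library)
        b, _, _ = simulate_cohort(design, library)
        np.testing.assert_array_equal(a.intensities, b.intensities)

    def test_invalid_scheme_rejected(self):
        with pytest.raises(ValidationError):
            CohortDesign(class_scheme="nope")


class TestEffectMonotonicity:
    def test_bigger_effects_separate_better(self, library):
        """Score-space class separation grows with the designed effect size."""
        seps = []
        for effect in (0.5, 2.0, 4.0):
            design = CohortDesign(
                class_scheme="ki67_2", axis_step=2.0, spectra_per_biopsy=20,
                effect_size=effect, seed=7,
            )
            spectra, truth, _ = simulate_cohort(design, library)
            y = np.array(
                [truth.class_by_biopsy[b] for b in spectra.meta["biopsy_id"]]
            )
            chems = [library.index_of(c) for c in design.chemicals()]
            hi = truth.true_scores[np.ix_(y == "High", chems)].mean(axis=0)
            lo = truth.true_scores[np.ix_(y == "Low", chems)].mean(axis=0)
            sd = truth.true_scores[:, chems].std(axis=0).mean()
            seps.append(np.linalg.norm(hi - lo) / sd)
        assert seps[0] < seps[1] < seps[2]


class TestOutlierInjection:
    def test_outlier_profile_mixed_inversion(self, library):
        design = inject_outlier_biopsy(
            CohortDesign(class_scheme="ki67_2", axis_step=2.0,
                         spectra_per_biopsy=30, seed=8)
        )
        spectra, truth, _ = simulate_cohort(design, library)
        meta = spectra.meta
        scores = truth.true_scores

        def biopsy_mean(b, chem):
            rows = (meta["biopsy_id"] == b).to_numpy()
            return scores[rows, library.index_of(chem)].mean()

        high_normal = "86"
        for chem in ("phosphatidylinositol", "phosphatidylcholine"):
            assert biopsy_mean("99", chem) > biopsy_mean(high_normal, chem)
        for chem in ("co-enzyme A", "lactose"):
            assert biopsy_mean("99", chem) < biopsy_mean("75", chem)  # below Low

    def test_requires_ki67_scheme(self):
        with pytest.raises(ValidationError):
            inject_outlier_biopsy(CohortDesign(class_scheme="gleason3"))


class TestScoreCohort:
    def test_planted_structure(self):
        X, y = simulate_score_cohort(
            30, ["A", "B"], ["co-enzyme A"], effect_size=3.0, seed=0
        )
        assert X.shape == (60, 31)
        gap = X.loc[y == "B", "co-enzyme A"].mean() - X.loc[y == "A", "co-enzyme A"].mean()
        assert gap == pytest.approx(3.0, abs=0.8)
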