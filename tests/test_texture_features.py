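"""Closed-form feature values, degenerate limits, symmetry invariance,
and the full-vector extraction contract."""

import numpy as np
import pytest

from petradiomics import (
    FAMILIES,
    FEATURE_NAMES,
    N_FEATURES,
    ROIMask,
    SUVVolume,
    extract_all_features,
)
from petradiomics.registry import validate_registry
from petradiomics.texture import (
    compute_glcm,
    glcm_features,
    glszm_features,
    compute_glszm,
    suv_statistics,
)


class TestRegistry:
    def test_exactly_109_unique_features_partitioned_by_family(self):
        assert len(FEATURE_NAMES) == N_FEATURES == 109
        assert len(set(FEATURE_NAMES)) == 109
        assert sum(len(v) for v in FAMILIES.values()) == 109
        validate_registry()

    def test_clinically_reported_features_present(self):
        for name in ("SUV_max", "MTV", "TLG", "CV", "Skewness",
                     "NL_Entropy^GLCM", "NL_Homogeneity^GLCM",
                     "NL_Dissimilarity^GLCM", "ZP^GLSZM", "HILZE^GLSZM"):
            assert name in FEATURE_NAMES


class TestGLCMFeatures:
    def test_collinear_1124_closed_forms(self, q_1x1x4):
        f = glcm_features(compute_glcm(q_1x1x4))
        assert f["NL_Entropy^GLCM"] == pytest.approx(1.9183, abs=1e-4)
        assert f["NL_Homogeneity^GLCM"] == pytest.approx(0.8333, abs=1e-4)
        assert f["NL_Dissimilarity^GLCM"] == pytest.approx(0.3333, abs=1e-4)

    def test_constant_roi_degenerate_values(self, make_q):
        f = glcm_features(compute_glcm(make_q(np.full((3, 3, 3), 2), Ng=4)))
        assert f["NL_Entropy^GLCM"] == 0.0
        assert f["NL_Homogeneity^GLCM"] == 1.0
        assert f["NL_Dissimilarity^GLCM"] == 0.0
        assert f["NL_Correlation^GLCM"] == 0.0  # zero-variance convention

    def test_entropy_bounds_and_homogeneity_range(self, make_q):
        rng = np.random.default_rng(1)
        q = make_q(rng.integers(1, 7, size=(5, 5, 5)), Ng=6)
        f = glcm_features(compute_glcm(q))
        assert 0 <= f["NL_Entropy^GLCM"] <= 2 * np.log2(q.Ng)
        assert 0 < f["NL_Homogeneity^GLCM"] <= 1
        assert f["NL_Dissimilarity^GLCM"] >= 0


class TestGLSZMFeatures:
    def test_collinear_hand_values(self, q_1x1x4):
        f = glszm_features(compute_glszm(q_1x1x4))
        assert f["ZP^GLSZM"] == pytest.approx(0.5)
        # (1*1^2*2^2 + 1*2^2*2^2) / 2 zones
        assert f["HILZE^GLSZM"] == pytest.approx(10.0)

    def test_constant_roi_zp_is_one_over_n(self, make_q):
        q = make_q(np.full((3, 3, 3), 1), Ng=2)
        f = glszm_features(compute_glszm(q))
        assert f["ZP^GLSZM"] == pytest.approx(1 / 27)


class TestSUVStatistics:
    def test_closed_form_population_moments(self):
        values = np.array([2.0, 4.0, 6.0]).reshape(1, 1, 3)
        vol = SUVVolume(values=values, spacing=(10, 10, 10))
        mask = ROIMask(flags=np.ones_like(values, dtype=np.uint8))
        f = suv_statistics(vol, mask)
        assert f["SUV_mean"] == pytest.approx(4.0)
        assert f["SUV_SD"] == pytest.approx(1.63299, abs=1e-5)
        assert f["CV"] == pytest.approx(0.40825, abs=1e-5)
        assert f["MTV"] == pytest.approx(3.0)  # 3 voxels x 1 cm^3
        assert f["TLG"] == pytest.approx(12.0)

    def test_constant_roi_conventions(self):
        values = np.full((2, 2, 2), 5.0)
        vol = SUVVolume(values=values, spacing=(1, 1, 1))
        mask = ROIMask(flags=np.ones_like(values, dtype=np.uint8))
        f = suv_statistics(vol, mask)
        assert f["CV"] == 0.0
        assert f["Skewness"] == 0.0
        assert f["Kurtosis"] == 0.0

    def test_tlg_identity_holds(self, hetero_case):
        _, vol, _, seg = hetero_case
        f = suv_statistics(vol, seg.mask)
        assert f["TLG"] == pytest.approx(f["SUV_mean"] * f["MTV"], abs=1e-9)


class TestExtractAllFeatures:
    def test_returns_exactly_the_registry_finite(self, hetero_case):
        _, vol, _, seg = hetero_case
        f = extract_all_features(vol, seg.mask)
        assert list(f.keys()) == list(FEATURE_NAMES)
        assert all(np.isfinite(v) for v in f.values())

    def test_constant_tumor_degenerate_limits(self, constant_case):
        _, vol, _, seg = constant_case
        f = extract_all_features(vol, seg.mask)
        n = seg.n_voxels
        assert f["NL_Entropy^GLCM"] == 0.0
        assert f["NL_Homogeneity^GLCM"] == 1.0
        assert f["NL_Dissimilarity^GLCM"] == 0.0
        assert f["CV"] == 0.0
        assert f["ZP^GLSZM"] == pytest.approx(1.0 / n)
        assert f["Contrast^NGTDM"] == 0.0
        assert f["Coarseness^NGTDM"] < np.inf

    def test_axis_permutation_invariance_on_isotropic_roi(self):
        """Direction-aggregated features must be invariant under the 48
        axis permutations/reflections of an isotropic ROI."""
        rng = np.random.default_rng(4)
        values = rng.uniform(3.0, 12.0, size=(6, 6, 6))
        mask = np.ones((6, 6, 6), dtype=np.uint8)
        base = extract_all_features(
            SUVVolume(values=values, spacing=(2, 2, 2)),
            ROIMask(flags=mask, spacing=(2, 2, 2)),
        )
        from itertools import permutations, product

        checked = 0
        for perm in permutations(range(3)):
            for flips in product([False, True], repeat=3):
                v = np.transpose(values, perm)
                for ax, fl in enumerate(flips):
                    if fl:
                        v = np.flip(v, axis=ax)
                f = extract_all_features(
                    SUVVolume(values=np.ascontiguousarray(v), spacing=(2, 2, 2)),
                    ROIMask(flags=mask, spacing=(2, 2, 2)),
                )
                for name in FEATURE_NAMES:
                    assert f[name] == pytest.approx(base[name], rel=1e-9, abs=1e-12), name
                checked += 1
        assert checked == 48

    def test_entropy_rises_with_heterogeneity(self):
        """Mean GLCM entropy must increase with the phantom heterogeneity
        parameter (20 seeds per level)."""
        from petradiomics import PhantomSpec, make_tumor_phantom, segment_fixed_threshold

        means = []
        for sd in (0.1, 0.45):
            vals = []
            for seed in range(20):
                spec = PhantomSpec(semi_axes=(18, 18, 18), base_suv=8.0,
                                   heterogeneity_sd=sd, seed=seed)
                vol, _ = make_tumor_phantom(spec)
                seg = segment_fixed_threshold(vol)
                f = extract_all_features(vol, seg.mask)
                vals.append(f["NL_Entropy^GLCM"])
            means.append(np.mean(vals))
        assert means[0] < means[1]

    def test_archetype_entropy_in_clinical_range(self):
        """GLCM entropy of the archetype phantoms falls in the 2.5-7.0
        band observed across the three clinical phenotypes (natural-log
        units, the convention of the published per-cluster medians)."""
        from dataclasses import replace

        from petradiomics import PhantomSpec, make_tumor_phantom, segment_fixed_threshold
        from petradiomics.phantom import DEFAULT_ARCHETYPES
        from petradiomics.texture import ExtractionSettings

        nats = ExtractionSettings(log_base=np.e)
        for template in DEFAULT_ARCHETYPES:
            vol, _ = make_tumor_phantom(replace(template, seed=20))
            seg = segment_fixed_threshold(vol)
            f = extract_all_features(vol, seg.mask, nats)
            assert 2.5 <= f["NL_Entropy^GLCM"] <= 7.0
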