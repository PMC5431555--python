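"""Hand-enumerated examples and brute-force oracle agreement for every
texture matrix family."""

import numpy as np
import pytest

from petradiomics.texture import (
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    compute_ngldm,
    compute_ngtdm,
    compute_texture_spectrum,
    compute_tfc,
    compute_tfccm,
)

import oracles


def _trim(mat):
    """Drop trailing all-zero columns so shapes are comparable."""
    mat = np.asarray(mat)
    keep = np.flatnonzero(mat.any(axis=0))
    return mat[:, : keep.max() + 1] if keep.size else mat[:, :1]


class TestGLCM:
    def test_collinear_1124_hand_counts(self, q_1x1x4):
        m = compute_glcm(q_1x1x4)
        assert m.p[0, 0] == pytest.approx(1 / 3)
        assert m.p[1, 1] == pytest.approx(1 / 3)
        assert m.p[0, 1] == pytest.approx(1 / 6)
        assert m.p[1, 0] == pytest.approx(1 / 6)
        assert m.n_pairs == 6  # 3 adjacent pairs, both orientations

    def test_constant_roi_single_diagonal_entry(self, make_q):
        m = compute_glcm(make_q(np.full((3, 3, 3), 2), Ng=4))
        assert m.p[1, 1] == pytest.approx(1.0)
        assert m.p.sum() == pytest.approx(1.0)

    def test_symmetry_and_normalization(self, make_q):
        rng = np.random.default_rng(5)
        q = make_q(rng.integers(1, 5, size=(4, 4, 4)), Ng=4)
        m = compute_glcm(q)
        assert np.allclose(m.p, m.p.T)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_isolated_voxels_raise(self, make_q):
        lev = np.zeros((5, 5, 5), dtype=int)
        lev[0, 0, 0] = 1
        lev[4, 4, 4] = 2
        with pytest.raises(ValueError, match="no in-mask"):
            compute_glcm(make_q(lev, Ng=2))


class TestGLRLM:
    def test_collinear_single_direction_runs(self, make_q):
        q = make_q([1, 1, 2, 2], Ng=2)
        m = compute_glrlm(q, directions=((0, 0, 1),))
        assert m.r[0, 1] == 1  # level 1, run length 2
        assert m.r[1, 1] == 1
        assert m.r.sum() == 2

    def test_constant_line_single_axial_run(self, make_q):
        q = make_q(np.full((1, 1, 6), 3), Ng=4)
        m = compute_glrlm(q, directions=((0, 0, 1),))
        assert m.r[2, 5] == 1
        assert m.r.sum() == 1

    def test_voxel_conservation_per_direction(self, make_q):
        rng = np.random.default_rng(3)
        q = make_q(rng.integers(1, 4, size=(5, 5, 5)), Ng=4)
        for d in ((0, 0, 1), (1, 0, 0), (1, 1, 1), (1, -1, 0)):
            m = compute_glrlm(q, directions=(d,))
            lengths = np.arange(1, m.r.shape[1] + 1)
            assert (m.r * lengths).sum() == q.n_voxels


class TestGLSZM:
    def test_collinear_hand_zones(self, q_1x1x4):
        m = compute_glszm(q_1x1x4)
        assert m.n_zones == 2
        assert m.z[0, 1] == 1 and m.z[1, 1] == 1
        assert m.n_voxels == 4

    def test_constant_roi_single_zone(self, make_q):
        m = compute_glszm(make_q(np.full((3, 3, 2), 1), Ng=2))
        assert m.n_zones == 1
        assert m.z[0, 17] == 1

    def test_checkerboard_has_two_diagonal_zones(self, make_q):
        """Under 26-connectivity the two parity classes of a checkerboard
        each form one diagonally-connected zone."""
        idx = np.indices((4, 4, 4)).sum(axis=0)
        lev = (idx % 2) + 1
        m = compute_glszm(make_q(lev, Ng=2))
        z_oracle = oracles.oracle_glszm(lev, lev > 0, 2)
        assert np.array_equal(_trim(m.z), _trim(z_oracle))
        assert m.n_zones == 2

    def test_voxel_conservation(self, make_q):
        rng = np.random.default_rng(11)
        q = make_q(rng.integers(1, 5, size=(5, 4, 6)), Ng=5)
        m = compute_glszm(q)
        sizes = np.arange(1, m.z.shape[1] + 1)
        assert (m.z * sizes).sum() == q.n_voxels


class TestNGTDM:
    def test_constant_roi_zero_deviations(self, make_q):
        m = compute_ngtdm(make_q(np.full((3, 3, 3), 2), Ng=4))
        assert m.s.sum() == 0.0
        assert m.p[1] == pytest.approx(1.0)

    def test_2x2_hand_enumeration(self, make_q):
        q = make_q(np.array([[1, 2], [3, 4]]).reshape(2, 2, 1), Ng=4)
        m = compute_ngtdm(q)
        assert m.n_valid == 4
        assert m.s[0] == pytest.approx(2.0)  # |1 - mean(2,3,4)|
        assert m.s[1] == pytest.approx(2 / 3)
        assert m.s[2] == pytest.approx(2 / 3)
        assert m.s[3] == pytest.approx(2.0)
        assert np.all(m.p == 0.25)


class TestNGLDM:
    def test_constant_cube_center_has_26_dependents(self, make_q):
        m = compute_ngldm(make_q(np.full((3, 3, 3), 2), Ng=4))
        assert m.d[1, 26] == 1  # the center voxel
        assert m.d.sum() == 27

    def test_collinear_dependence_counts(self, make_q):
        m = compute_ngldm(make_q([1, 1, 2, 2], Ng=2), tolerance=0)
        assert m.d[0, 1] == 2 and m.d[1, 1] == 2
        assert m.d.sum() == 4

    def test_tolerance_ng_saturates(self, make_q):
        rng = np.random.default_rng(2)
        q = make_q(rng.integers(1, 5, size=(3, 3, 3)), Ng=4)
        m = compute_ngldm(q, tolerance=q.Ng)
        # every in-mask neighbor is dependent: counts match neighbor counts
        o = oracles.oracle_ngldm(q.levels, q.mask, q.Ng, tolerance=q.Ng)
        assert np.array_equal(m.d, o)
        assert m.d[:, 0].sum() == 0


class TestCodingSchemes:
    def test_constant_roi_single_texture_unit_and_zero_entropy(self, make_q):
        q = make_q(np.full((4, 4, 4), 3), Ng=4)
        ts = compute_texture_spectrum(q)
        assert len(ts.counts) == 1  # single all-"equal" unit
        tfccm = compute_tfccm(compute_tfc(q))
        p = tfccm.p[tfccm.p > 0]
        assert -(p * np.log2(p)).sum() == pytest.approx(0.0)

    def test_monotone_ramp_gives_single_tfc_class(self, make_q):
        q = make_q(np.arange(1, 9).reshape(1, 1, 8), Ng=8)
        tfc = compute_tfc(q)
        codes = tfc.codes[tfc.valid]
        assert set(codes) == {2}  # every interior voxel: one monotone pair

    def test_tfccm_symmetric_and_normalized(self, make_q):
        rng = np.random.default_rng(9)
        q = make_q(rng.integers(1, 4, size=(4, 4, 4)), Ng=4)
        m = compute_tfccm(compute_tfc(q))
        assert np.allclose(m.p, m.p.T)
        assert m.p.sum() == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(12))
def test_all_families_match_brute_force_oracles(seed):
    """Vectorized matrix builders agree exactly with independent per-voxel
    enumeration on random small ROIs (the full 50-ROI sweep runs in the
    acceptance suite)."""
    levels, mask = oracles.random_quantized_roi(seed)
    Ng = 6
    from petradiomics.quantize import QuantizedROI

    q = QuantizedROI(levels=levels, mask=mask, Ng=Ng, bin_width=1.0,
                     range_min=0.0, range_max=float(Ng))

    assert np.allclose(compute_glcm(q).p, oracles.oracle_glcm(levels, mask, Ng))
    assert np.array_equal(
        _trim(compute_glrlm(q).r), _trim(oracles.oracle_glrlm(levels, mask, Ng))
    )
    assert np.array_equal(
        _trim(compute_glszm(q).z), _trim(oracles.oracle_glszm(levels, mask, Ng))
    )
    p_o, s_o, n_o = oracles.oracle_ngtdm(levels, mask, Ng)
    m = compute_ngtdm(q)
    assert m.n_valid == n_o
    assert np.allclose(m.p, p_o) and np.allclose(m.s, s_o)
    assert np.array_equal(compute_ngldm(q).d, oracles.oracle_ngldm(levels, mask, Ng))

    ts = compute_texture_spectrum(q)
    spec_impl = {tuple(u): int(c) for u, c in zip(ts.units, ts.counts)}
    assert spec_impl == dict(oracles.oracle_texture_spectrum(levels, mask))

    tfc = compute_tfc(q)
    codes_o = oracles.oracle_tfc_codes(levels, mask)
    codes_impl = {tuple(v): int(tfc.codes[tuple(v)]) for v in np.argwhere(tfc.valid)}
    assert codes_impl == codes_o
    assert np.allclose(compute_tfccm(tfc).p, oracles.oracle_tfccm(levels, mask))
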