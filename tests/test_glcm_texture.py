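import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdfftex.glcm_texture import (GLCMatrix, OFFSETS_13, DegenerateROIError,
                                  bilateral_aggregate, build_glcm, glcm_features,
                                  glcm_features_per_direction, quantize)


def oracle_glcm(labels, mask, voxel_size=(1.0, 1.0, 1.0), ng=None,
                distance_correction=True):
    """Brute-force triple-loop pair enumeration over the 13 offsets."""
    ng = ng or int(labels[mask].max())
    P = np.zeros((ng, ng))
    shape = labels.shape
    for (dx, dy, dz) in OFFSETS_13:
        dist = math.sqrt((dx * voxel_size[0]) ** 2 + (dy * voxel_size[1]) ** 2
                         + (dz * voxel_size[2]) ** 2)
        w = min(voxel_size) / dist if distance_correction else 1.0
        for x in range(shape[0]):
            for y in range(shape[1]):
                for z in range(shape[2]):
                    x2, y2, z2 = x + dx, y + dy, z + dz
                    if not (0 <= x2 < shape[0] and 0 <= y2 < shape[1]
                            and 0 <= z2 < shape[2]):
                        continue
                    if mask[x, y, z] and mask[x2, y2, z2]:
                        i, j = labels[x, y, z] - 1, labels[x2, y2, z2] - 1
                        P[i, j] += w
                        P[j, i] += w
    total = P.sum()
    return P / total if total > 0 else P


def oracle_features(P, ng):
    """Literal-formula feature oracle (scalar loops, no vectorization)."""
    energy = contrast = entropy = homog = dissim = 0.0
    mu = sigma2 = 0.0
    p_i = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    for i in range(ng):
        mu += (i + 1) * p_i[i]
    for i in range(ng):
        sigma2 += (i + 1 - mu) ** 2 * p_i[i]
    ij_sum = variance = sum_avg = 0.0
    for i in range(ng):
        for j in range(ng):
            p = P[i, j]
            energy += p * p
            contrast += (i - j) ** 2 * p
            if p > 0:
                entropy -= p * math.log2(p)
            homog += p / (1 + abs(i - j))
            dissim += abs(i - j) * p
            ij_sum += (i + 1) * (j + 1) * p
            variance += (i + 1 - mu) ** 2 * p
            sum_avg += ((i + 1) + (j + 1)) * p
    corr = (ij_sum - mu * mu) / sigma2 if sigma2 > 0 else float("nan")
    return {
        "energy": energy, "contrast": contrast, "entropy": entropy,
        "homogeneity": homog, "correlation": corr,
        "variance": variance / ng**2, "sum_average": sum_avg / ng**2,
        "dissimilarity": dissim,
    }


class TestQuantize:
    def test_anchors(self):
        vals = np.array([[[0.0, 100.0]]])
        mask = np.ones_like(vals, dtype=bool)
        q = quantize(vals, mask, ng=200)
        assert q.labels[0, 0, 0] == 1
        assert q.labels[0, 0, 1] == 200

    def test_midpoint(self):
        vals = np.array([[[50.0]]])
        q = quantize(vals, np.ones_like(vals, dtype=bool), ng=200)
        assert q.labels[0, 0, 0] == 101  # floor(50/100*200)+1

    def test_monotone(self, rng):
        pairs = rng.uniform(0, 100, (1000, 2))
        v = np.sort(pairs, axis=1)
        vals = v.reshape(1, 1000, 2)
        q = quantize(vals, np.ones_like(vals, dtype=bool), ng=200)
        assert (q.labels[0, :, 0] <= q.labels[0, :, 1]).all()

    def test_out_of_range_rejected(self):
        vals = np.array([[[101.0]]])
        with pytest.raises(ValueError, match=r"\[0, 100\]"):
            quantize(vals, np.ones_like(vals, dtype=bool))


class TestBuildGLCM:
    def test_single_pair(self):
        vals = np.zeros((2, 1, 1))
        vals[0], vals[1] = 10.0, 30.0  # levels 2 and 4 at ng=10
        q = quantize(vals, np.ones_like(vals, dtype=bool), ng=10)
        P = build_glcm(q).P
        assert P[1, 3] == pytest.approx(0.5)
        assert P[3, 1] == pytest.approx(0.5)
        assert P.sum() == pytest.approx(1.0)
        assert np.count_nonzero(P) == 2

    def test_constant_roi_diagonal_atom(self):
        vals = np.full((3, 3, 3), 42.0)
        q = quantize(vals, np.ones_like(vals, dtype=bool), ng=8)
        P = build_glcm(q).P
        k = q.labels[0, 0, 0] - 1
        assert P[k, k] == pytest.approx(1.0)
        assert P.sum() == pytest.approx(1.0)

    def test_degenerate_single_voxel(self):
        vals = np.array([[[50.0]]])
        q = quantize(vals, np.ones_like(vals, dtype=bool), ng=4)
        with pytest.raises(DegenerateROIError):
            build_glcm(q)

    @pytest.mark.parametrize("seed", range(5))
    @pytest.mark.parametrize("distance_correction", [True, False])
    def test_matches_bruteforce(self, seed, distance_correction):
        r = np.random.default_rng(seed)
        vals = r.uniform(0, 100, (4, 4, 4))
        mask = r.random((4, 4, 4)) < 0.7
        mask[:2, :2, :2] = True
        q = quantize(vals, mask, ng=6)
        got = build_glcm(q, voxel_size=(1.5, 1.5, 1.5),
                         distance_correction=distance_correction).P
        want = oracle_glcm(q.labels, mask, voxel_size=(1.5, 1.5, 1.5), ng=6,
                           distance_correction=distance_correction)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_anisotropic_weights(self, rng):
        vals = rng.uniform(0, 100, (3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        q = quantize(vals, mask, ng=5)
        vsz = (1.0, 2.0, 3.0)
        got = build_glcm(q, voxel_size=vsz).P
        want = oracle_glcm(q.labels, mask, voxel_size=vsz, ng=5)
        np.testing.assert_allclose(got, want, atol=1e-12)

    def test_symmetric_and_normalized(self, rng):
        vals = rng.uniform(0, 100, (4, 4, 4))
        q = quantize(vals, np.ones((4, 4, 4), dtype=bool), ng=8)
        P = build_glcm(q).P
        np.testing.assert_allclose(P, P.T, atol=1e-15)
        assert P.sum() == pytest.approx(1.0)
        assert (P >= 0).all()


class TestGLCMFeatures:
    def test_diagonal_atom_limits(self):
        ng = 10
        P = np.zeros((ng, ng))
        P[4, 4] = 1.0
        f = glcm_features(GLCMatrix(P=P, ng=ng))
        assert f.energy == pytest.approx(1.0)
        assert f.entropy == pytest.approx(0.0)
        assert f.contrast == pytest.approx(0.0)
        assert f.dissimilarity == pytest.approx(0.0)
        assert f.homogeneity == pytest.approx(1.0)
        assert math.isnan(f.correlation)

    def test_uniform_glcm_closed_form(self):
        ng = 16
        P = np.full((ng, ng), 1.0 / ng**2)
        f = glcm_features(GLCMatrix(P=P, ng=ng))
        assert f.energy == pytest.approx(1.0 / ng**2)
        assert f.entropy == pytest.approx(2 * math.log2(ng))
        assert f.correlation == pytest.approx(0.0, abs=1e-12)

    def test_checkerboard_closed_form(self):
        # parity field: axis and body-diagonal offsets flip parity (a-b pairs),
        # face-diagonal offsets preserve it (a-a / b-b pairs)
        n = 4
        idx = np.indices((n, n, n)).sum(axis=0)
        vals = np.where(idx % 2 == 0, 10.0, 90.0)
        mask = np.ones((n, n, n), dtype=bool)
        q = quantize(vals, mask, ng=10)  # levels 2 and 10
        a, b = 2, 10
        got = build_glcm(q).P
        want = oracle_glcm(q.labels, mask, ng=10)
        np.testing.assert_allclose(got, want, atol=1e-12)
        # off-parity mass only at (a,b)/(b,a); like-parity only at (a,a),(b,b)
        nz = {(i + 1, j + 1) for i, j in zip(*np.nonzero(got))}
        assert nz == {(a, a), (b, b), (a, b), (b, a)}
        f = glcm_features(build_glcm(q))
        o = oracle_features(got, 10)
        for name, val in o.items():
            assert getattr(f, name) == pytest.approx(val, abs=1e-10)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_literal_formula_oracle(self, seed):
        r = np.random.default_rng(100 + seed)
        vals = r.uniform(0, 100, (4, 4, 4))
        mask = r.random((4, 4, 4)) < 0.8
        mask[:2, :2, :2] = True
        q = quantize(vals, mask, ng=7)
        glcm = build_glcm(q, voxel_size=(1.5, 1.5, 1.5))
        f = glcm_features(glcm).as_dict()
        o = oracle_features(glcm.P, 7)
        for name, val in o.items():
            assert f[name] == pytest.approx(val, abs=1e-10), name

    @pytest.mark.parametrize("seed", range(5))
    def test_bounds_invariants(self, seed):
        r = np.random.default_rng(200 + seed)
        vals = r.uniform(0, 100, (5, 5, 5))
        q = quantize(vals, np.ones((5, 5, 5), dtype=bool), ng=12)
        f = glcm_features(build_glcm(q))
        assert 0 < f.energy <= 1
        assert 0 < f.homogeneity <= 1
        assert f.entropy >= 0
        assert f.contrast >= 0 and f.dissimilarity >= 0
        assert f.variance >= 0 and f.sum_average >= 0
        assert -1 <= f.correlation <= 1 + 1e-12


class TestRotationInvariance:
    def test_all_48_symmetries(self, rng):
        vals = rng.uniform(0, 100, (5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        mask[:2, :2, :2] = True
        q = quantize(vals, mask, ng=8)
        base = glcm_features(build_glcm(q)).as_dict()
        for perm in itertools.permutations(range(3)):
            for flips in itertools.product([False, True], repeat=3):
                v = np.transpose(vals, perm)
                m = np.transpose(mask, perm)
                for ax, fl in enumerate(flips):
                    if fl:
                        v = np.flip(v, axis=ax)
                        m = np.flip(m, axis=ax)
                q2 = quantize(v.copy(), m.copy(), ng=8)
                f = glcm_features(build_glcm(q2)).as_dict()
                for name, val in base.items():
                    assert f[name] == pytest.approx(val, abs=1e-10), (name, perm, flips)


class TestPerDirectionAggregation:
    def test_agrees_on_uniform_texture_runs(self, rng):
        vals = rng.uniform(0, 100, (4, 4, 4))
        q = quantize(vals, np.ones((4, 4, 4), dtype=bool), ng=6)
        single = glcm_features(build_glcm(q)).as_dict()
        per_dir = glcm_features_per_direction(q).as_dict()
        # different estimators of the same texture: same order of magnitude,
        # identical entropy/energy is NOT expected
        for name in single:
            if not math.isnan(single[name]):
                assert np.isfinite(per_dir[name])

    def test_constant_roi(self):
        vals = np.full((3, 3, 3), 10.0)
        q = quantize(vals, np.ones((3, 3, 3), dtype=bool), ng=4)
        f = glcm_features_per_direction(q)
        assert f.energy == pytest.approx(1.0)
        assert f.entropy == pytest.approx(0.0)


class TestBilateralAggregate:
    def test_equal_volumes_arithmetic_mean(self):
        out = bilateral_aggregate({"f": 2.0}, {"f": 4.0}, 100.0, 100.0)
        assert out["f"] == pytest.approx(3.0)

    def test_zero_left_volume_returns_right(self):
        out = bilateral_aggregate({"f": 2.0}, {"f": 4.0}, 0.0, 100.0)
        assert out["f"] == pytest.approx(4.0)

    def test_weighted_example(self):
        out = bilateral_aggregate({"f": 1.0}, {"f": 5.0}, 300.0, 100.0)
        assert out["f"] == pytest.approx(2.0)  # (300*1 + 100*5)/400

    def test_nan_one_side_falls_back(self):
        out = bilateral_aggregate({"f": float("nan")}, {"f": 5.0}, 300.0, 100.0)
        assert out["f"] == pytest.approx(5.0)

    def test_nan_both_sides_propagates(self):
        out = bilateral_aggregate({"f": float("nan")}, {"f": float("nan")}, 1.0, 1.0)
        assert math.isnan(out["f"])

    def test_both_zero_volumes_error(self):
        with pytest.raises(ValueError):
            bilateral_aggregate({"f": 1.0}, {"f": 2.0}, 0.0, 0.0)

    @given(st.floats(-100, 100), st.floats(-100, 100),
           st.floats(0.1, 1000), st.floats(0.1, 1000))
    @settings(max_examples=100, deadline=None)
    def test_result_between_sides(self, fl, fr, vl, vr):
        out = bilateral_aggregate({"f": fl}, {"f": fr}, vl, vr)
        assert min(fl, fr) - 1e-9 <= out["f"] <= max(fl, fr) + 1e-9


class TestMonotoneTextureResponse:
    def test_contrast_decreases_with_correlation_length(self):
        # rougher fields (shorter correlation length) at fixed tau must give
        # higher contrast/dissimilarity and lower homogeneity
        from pdfftex import MUSCLES
        from pdfftex.synthetic_cohort import SubjectSpec, generate_subject, make_masks

        masks = make_masks((32, 32, 10))
        roi = masks[("ES", "left")]
        means = {}
        for cl in (0.8, 1.5, 3.0):
            feats = {"contrast": [], "dissimilarity": [], "homogeneity": []}
            for seed in range(20):
                spec = SubjectSpec(
                    subject_id="x", sex="male", age=40.0, bmi=24.0,
                    mean_pdff_target={m: 50.0 for m in MUSCLES},
                    tau={m: 5.0 for m in MUSCLES},
                    correlation_length=cl, seed=seed)
                vol = generate_subject(spec, masks)
                f = glcm_features(build_glcm(quantize(vol.values, roi.mask),
                                             vol.voxel_size))
                for k in feats:
                    feats[k].append(getattr(f, k))
            means[cl] = {k: np.mean(v) for k, v in feats.items()}
        for rough, smooth in [(0.8, 1.5), (1.5, 3.0)]:
            assert means[rough]["contrast"] > means[smooth]["contrast"]
            assert means[rough]["dissimilarity"] > means[smooth]["dissimilarity"]
            assert means[rough]["homogeneity"] < means[smooth]["homogeneity"]
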