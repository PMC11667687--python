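"""Macenko estimation and normalization against the generator's
ground-truth stain matrix."""

import numpy as np
import pytest

from hesubtype import stain, synthdata as sd
from hesubtype.stain import (DegenerateStainError, EmptyReferenceError,
                             InsufficientTissueError, angle_between_deg)

from conftest import tumor_tile

S_TRUE = sd.DEFAULT_STAIN_MATRIX


def max_column_angle(estimated: np.ndarray, truth: np.ndarray) -> float:
    return max(angle_between_deg(estimated[:, j], truth[:, j])
               for j in range(2))


class TestEstimateStain:
    def test_white_image_insufficient_tissue(self):
        img = np.full((64, 64, 3), 255, dtype=np.uint8)
        with pytest.raises(InsufficientTissueError):
            stain.estimate_stain(img)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_recovers_generating_stain_vectors(self, seed):
        prof = stain.estimate_stain(tumor_tile(class_index=2, seed=seed))
        assert max_column_angle(prof.stain_matrix, S_TRUE) < 2.0

    def test_hematoxylin_column_first(self):
        prof = stain.estimate_stain(tumor_tile(class_index=3))
        assert prof.stain_matrix[2, 0] > prof.stain_matrix[2, 1]

    def test_single_stain_image_degenerate(self):
        # hematoxylin only, no eosin: rank-1 OD cloud
        params = sd.TileParams("tumor", "BL", blob_density=40.0,
                               blob_radius=2.5, eosin_level=0.0,
                               noise_sd=0.0)
        img = sd.render_tile(params, 64, np.random.default_rng(0)).pixels
        with pytest.raises(DegenerateStainError):
            stain.estimate_stain(img)

    def test_rotation_and_flip_invariance(self):
        img = tumor_tile(class_index=1, seed=5)
        ref = stain.estimate_stain(img).stain_matrix
        for variant in (np.rot90(img), img[::-1], img[:, ::-1]):
            est = stain.estimate_stain(np.ascontiguousarray(variant))
            assert max_column_angle(est.stain_matrix, ref) < 1e-6


class TestNonnegConcentrations:
    def test_matches_scipy_nnls(self):
        from scipy.optimize import nnls
        rng = np.random.default_rng(0)
        S = S_TRUE
        od = rng.uniform(-0.2, 2.0, size=(200, 3))
        C = stain.nonneg_concentrations(S, od)
        for i in range(len(od)):
            c_ref, _ = nnls(S, od[i])
            assert np.allclose(C[i], c_ref, atol=1e-8)

    def test_nonnegative(self):
        rng = np.random.default_rng(1)
        od = rng.normal(0, 1, size=(500, 3))
        assert (stain.nonneg_concentrations(S_TRUE, od) >= 0).all()


class TestNormalizeTile:
    def test_self_normalization_near_identity(self):
        img = tumor_tile(class_index=2, seed=1)
        prof = stain.estimate_stain(img)
        out = stain.normalize_tile(img, prof)
        assert np.abs(out.astype(float) - img.astype(float)).mean() < 2.0

    def test_idempotence(self):
        img = tumor_tile(class_index=2, seed=2)
        ref = stain.estimate_stain(tumor_tile(class_index=1, seed=3))
        once = stain.normalize_tile(img, ref)
        twice = stain.normalize_tile(once, ref)
        assert np.abs(twice.astype(float) - once.astype(float)).mean() < 2.0

    def test_white_tile_passes_through(self):
        img = np.full((32, 32, 3), 250, dtype=np.uint8)
        ref = stain.estimate_stain(tumor_tile())
        assert np.array_equal(stain.normalize_tile(img, ref), img)

    def test_shared_concentrations_converge_after_normalization(self):
        """Two renders of identical concentration fields through different
        stain matrices agree after normalization to one reference."""
        S_alt = np.array([[0.55, 0.10], [0.75, 0.95], [0.37, 0.20]])
        S_alt /= np.linalg.norm(S_alt, axis=0)
        imgs = []
        for S in (S_TRUE, S_alt):
            params = sd.TileParams("tumor", "HER2", blob_density=40.0,
                                   blob_radius=2.5, stain_matrix=S,
                                   noise_sd=0.5)
            imgs.append(sd.render_tile(params, 64,
                                       np.random.default_rng(11)).pixels)
        ref = stain.estimate_stain(tumor_tile(class_index=3, seed=4))
        a = stain.normalize_tile(imgs[0], ref).astype(float)
        b = stain.normalize_tile(imgs[1], ref).astype(float)
        assert np.abs(a - b).mean() < 5.0

    def test_output_profile_matches_reference(self):
        img = tumor_tile(class_index=3, seed=6)
        ref = stain.estimate_stain(tumor_tile(class_index=2, seed=7))
        out = stain.normalize_tile(img, ref)
        est = stain.estimate_stain(out)
        assert max_column_angle(est.stain_matrix, ref.stain_matrix) < 5.0
        rel = np.abs(est.max_concentrations - ref.max_concentrations) \
            / ref.max_concentrations
        assert (rel < 0.10).all()


class TestBuildReference:
    def test_each_wsi_contributes_one_tile(self, small_cohort):
        _, manifest = small_cohort
        n_wsis = manifest.loc[manifest["tissue_class"] == "tumor",
                              "wsi_id"].nunique()
        mosaic, prof = stain.build_reference(manifest, n_wsis=n_wsis, rng=0)
        t = 48
        assert mosaic.shape[0] * mosaic.shape[1] >= n_wsis * t * t

    def test_deterministic(self, small_cohort):
        _, manifest = small_cohort
        m1, _ = stain.build_reference(manifest, n_wsis=6, rng=3)
        m2, _ = stain.build_reference(manifest, n_wsis=6, rng=3)
        assert np.array_equal(m1, m2)

    def test_profile_recovers_generating_matrix(self, small_cohort):
        _, manifest = small_cohort
        _, prof = stain.build_reference(manifest, n_wsis=8, rng=1)
        assert max_column_angle(prof.stain_matrix, S_TRUE) < 2.0

    def test_no_tumor_tiles_rejected(self, small_cohort):
        _, manifest = small_cohort
        stroma_only = manifest[manifest["tissue_class"] == "stroma"]
        with pytest.raises(EmptyReferenceError):
            stain.build_reference(stroma_only, n_wsis=4, rng=0)


class TestMacenkoNormalizerEstimator:
    def test_fit_transform_roundtrip(self):
        ref_img = tumor_tile(class_index=3, seed=8)
        norm = stain.MacenkoNormalizer().fit(ref_img)
        out = norm.transform(tumor_tile(class_index=1, seed=9))
        assert out.shape == (64, 64, 3) and out.dtype == np.uint8

    def test_get_set_params(self):
        norm = stain.MacenkoNormalizer(beta=0.2)
        assert norm.get_params()["beta"] == 0.2
        norm.set_params(alpha=2.0)
        assert norm.alpha == 2.0

    def test_profile_serialization_roundtrip(self, tmp_path):
        prof = stain.estimate_stain(tumor_tile(seed=10))
        prof.to_json(tmp_path / "p.json")
        back = stain.StainProfile.from_json(tmp_path / "p.json")
        assert np.allclose(back.stain_matrix, prof.stain_matrix)
        assert np.allclose(back.max_concentrations, prof.max_concentrations)
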