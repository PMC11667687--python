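import numpy as np
import pytest

from hesubtype import synthdata as sd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A small on-disk cohort shared by stain/cohort tests: 3 patients per
    class, one WSI each, 12 tiles per WSI at 48x48."""
    out = tmp_path_factory.mktemp("cohort")
    spec = sd.CohortSpec(n_patients_per_class=3, wsis_per_patient=1,
                         tiles_per_wsi=12, tile_size=48, seed=7)
    manifest = sd.generate_cohort(spec, out)
    return spec, manifest


def tumor_tile(class_index: int = 0, size: int = 64, seed: int = 0,
               noise_sd: float = 1.0) -> np.ndarray:
    """One rendered tumor tile of the given subtype index."""
    spec = sd.CohortSpec()
    params = sd._tile_params("tumor", spec.class_names[class_index],
                             class_index, spec)
    params.noise_sd = noise_sd
    return sd.render_tile(params, size=size,
                          rng=np.random.default_rng(seed)).pixels
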