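import numpy as np
import pandas as pd
import pytest

from asymscreen.screen import CountMatrix


def make_count_matrix(values: np.ndarray, n_pairs: int,
                      normalized: bool = False,
                      stage: str = "E8.5f") -> CountMatrix:
    """Build a CountMatrix from a genes x (2*n_pairs) array, columns
    ordered L, R per embryo."""
    cols, rows = {}, []
    for e in range(n_pairs):
        for k, side in enumerate(("L", "R")):
            sid = f"embryo_{e + 1}_{side}"
            cols[sid] = values[:, 2 * e + k]
            rows.append({"sample_id": sid, "embryo_id": f"embryo_{e + 1}",
                         "side": side, "stage": stage})
    genes = pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene")
    return CountMatrix(values=pd.DataFrame(cols, index=genes),
                       samples=pd.DataFrame(rows), normalized=normalized)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_image_params():
    """Cheap image-simulation settings for structural tests."""
    from asymscreen.synthetic import ImageSimParams

    def factory(**overrides):
        defaults = dict(shape_voxels=(32, 64, 64), n_nuclei_per_side=(60, 60),
                        spot_density_right=2e-3, margin_voxels=6)
        defaults.update(overrides)
        return ImageSimParams(**defaults)

    return factory
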