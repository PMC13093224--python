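import numpy as np
import pytest

from gala.affine_ga import AffineTransform, GAConfig
from gala.align_pipeline import AlignConfig, align
from gala.io_formats import PointDataset
from gala.synth import SynthSpec, generate_pair, random_affine


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_dataset():
    """A 30-point, 4-gene slice with layered structure."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(0, 10, size=(30, 2))
    expr = np.abs(rng.normal(1.0, 0.3, size=(30, 4)))
    expr[:, 0] += 3.0 * (coords[:, 1] > 5)  # one structured gene
    labels = np.where(coords[:, 1] > 5, "upper", "lower")
    return PointDataset(coords, expr, ["g0", "g1", "g2", "g3"], labels=labels)


def fast_config(seed=0, **kw):
    """Pipeline configuration scaled for second-scale test runs."""
    base = dict(seed=seed, grid_pixels=40, em_iters=2, lddmm_iters=15,
                ga=GAConfig(pop_size=40, n_generations=25, seed=seed))
    base.update(kw)
    return AlignConfig(**base)


@pytest.fixture(scope="session")
def small_alignment():
    """One complete alignment run on a small distorted pair, reused widely."""
    rng = np.random.default_rng(5)
    A = random_affine(rng, max_rotation=np.pi / 3, scale_range=(0.9, 1.1),
                      max_shift=6.0)
    spec = SynthSpec(seed=5, n_points=400, true_affine=A, warp_amplitude=1.0)
    source, target, truth = generate_pair(spec)
    cfg = AlignConfig(seed=3, grid_pixels=36, em_iters=2, lddmm_iters=12,
                      ga=GAConfig(pop_size=40, n_generations=25, seed=3))
    result = align(source, target, cfg)
    return {"source": source, "target": target, "truth": truth,
            "result": result, "cfg": cfg}
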