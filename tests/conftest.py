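import numpy as np
import pytest

from rodentseg.config import RunConfig, demo_cases, run_demo
from rodentseg.phantom import PhantomSpec, generate_phantom
from rodentseg.segnet import load_checkpoint, split_indices
from rodentseg.volio import Mask, Volume


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_phantom():
    """A quick 32^3 isotropic phantom with both ground-truth masks."""
    spec = PhantomSpec(style="leuven_like", matrix=(32, 32, 32),
                       spacing=(0.5, 0.5, 0.5), tumor_radius_frac=0.5,
                       base_snr=15.0, seed=11)
    return generate_phantom(spec)


@pytest.fixture()
def random_mask_pair(rng):
    def make(shape=(10, 10, 10), p=0.3, spacing=(1.0, 1.0, 1.0)):
        a = (rng.random(shape) < p).astype(np.uint8)
        b = (rng.random(shape) < p).astype(np.uint8)
        a.flat[0] = 1  # guarantee nonempty
        b.flat[0] = 1
        return Mask(a, spacing), Mask(b, spacing)
    return make


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full desk-scale pipeline run shared by the whole session.

    Twenty easy phantoms at 64^3, both cascade stages trained, held-out
    evaluation, a reduced noise sweep, and the simulated inter-observer
    comparison. This is the expensive fixture; every test that needs a
    trained cascade reuses it.
    """
    cfg = RunConfig(seed=2026)
    cfg.noise.sigmas = (1, 4, 8, 15)
    out = run_demo(cfg, tmp_path_factory.mktemp("demo"))
    return cfg, out


@pytest.fixture(scope="session")
def demo_nets(demo_run):
    cfg, out = demo_run
    return load_checkpoint(out / "model1.npz"), load_checkpoint(out / "model2.npz")


@pytest.fixture(scope="session")
def demo_val_cases(demo_run):
    """The held-out cases of the session demo run, regenerated."""
    cfg, _ = demo_run
    import numpy as np
    from rodentseg.config import _derive_seeds
    cases = demo_cases(cfg)
    train_seed = _derive_seeds(cfg.seed, 6)[3]
    val_idx, _ = split_indices(len(cases), cfg.train.val_split, train_seed)
    return [cases[i] for i in val_idx]
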