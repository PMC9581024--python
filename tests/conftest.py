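import numpy as np
import pytest

from smlmfit.geometry import PointCloud3D, normalise_cloud
from smlmfit.renderer import RenderConfig
from smlmfit.simulator import make_parametric_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    return RenderConfig(height=32, width=32)


@pytest.fixture
def cloud(rng):
    return PointCloud3D(rng.uniform(-0.8, 0.8, size=(40, 3)), label="random")


@pytest.fixture(scope="session")
def blob_model():
    """A 100-point asymmetric model normalised to the world cube."""
    return normalise_cloud(make_parametric_model("random_blob", n_points=100, seed=7))


@pytest.fixture(scope="session")
def recovery_run():
    """Scaled-down end-to-end recovery shared across the suite: 100-point
    model, 64px frames, 2,000 noise-free samples, 10 epochs; the CNN run,
    the direct pose-table ablation on the same data, and the matched
    random baseline."""
    from smlmfit.evaluation import best_aligned_rmsd, random_baseline
    from smlmfit.simulator import NoiseConfig, make_dataset
    from smlmfit.trainer import NetworkSpec, SigmaSchedule, TrainConfig, train, train_direct

    model = normalise_cloud(
        make_parametric_model(
            "two_cylinder",
            rings_large=7, points_per_ring_large=10,
            rings_small=3, points_per_ring_small=10,
        )
    )
    rc = RenderConfig(64, 64)
    ds = make_dataset(
        model, 500, 4, NoiseConfig(), sigma=5.0,
        rng=np.random.default_rng(108), render_config=rc,
    )
    spec = NetworkSpec(image_size=64, base_channels=8)
    cfg = TrainConfig(
        model_size=100, epochs=10, seed=108, batch_size=32,
        verts_learning_rate=0.002, dtype="float32",
    )
    sched = SigmaSchedule(sigma_start=5.0, sigma_floor=1.2, epochs=10)
    res = train(ds, spec, cfg, sched)
    cnn_rmsd = best_aligned_rmsd(res.reconstruction.vertices, model.vertices).rmsd

    direct = train_direct(ds, cfg, sched)
    direct_rmsd = best_aligned_rmsd(direct.reconstruction.vertices, model.vertices).rmsd

    baseline = random_baseline(100, 10, np.random.default_rng(109))
    return {
        "cnn_rmsd": cnn_rmsd,
        "direct_rmsd": direct_rmsd,
        "baseline": baseline,
        "trace": res.trace,
    }
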