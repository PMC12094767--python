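import numpy as np
import pytest
from hypothesis import settings

from shgfiber import morphometrics as mm
from shgfiber import synthetic as syn

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


def make_fiber_mask(mask: np.ndarray, skeleton: np.ndarray | None = None) -> mm.FiberMask:
    """FiberMask wrapper for hand-built binary arrays."""
    mask = np.asarray(mask, dtype=bool)
    skeleton = mask if skeleton is None else np.asarray(skeleton, dtype=bool)
    return mm.FiberMask(mask, skeleton, np.zeros(mask.shape, dtype=np.uint8))


def isolated_scene_params(seed: int, **overrides) -> syn.SceneParams:
    """Scene of well-separated, individually resolvable fibers."""
    base = dict(
        seed=seed,
        n_fibers=10,
        branch_prob=0.0,
        min_separation_px=40.0,
        step_angle_sd=2.0,
        length_mean=150.0,
        length_sd=30.0,
        length_min=60.0,
        background_level=2.0,
    )
    base.update(overrides)
    return syn.SceneParams(**base)


@pytest.fixture(scope="session")
def straight_fiber_image() -> mm.AveragedImage:
    """One bright horizontal fiber of width 15 crossing the full image."""
    fib = syn.FiberSpec(
        np.column_stack([np.linspace(-30.0, 285.0, 350), np.full(350, 128.0)]),
        width=15.0,
        peak_intensity=220.0,
        fb_ratio=50.0,
    )
    params = syn.SceneParams(image_shape=(256, 256), background_level=1.0)
    forward, _ = syn.rasterize_scene([fib], params)
    return mm.AveragedImage(np.clip(forward, 0, 255))


@pytest.fixture(scope="session")
def measured_isolated_scenes():
    """Three isolated-fiber scenes processed end to end, with ground truth."""
    out = []
    for seed in range(3):
        params = isolated_scene_params(seed)
        fibers, truth = syn.sample_fiber_network(params)
        ff, bf = syn.rasterize_scene(fibers, params)
        stack = syn.simulate_stack(ff, bf, params)
        image = mm.average_frames(stack)
        record = mm.measure_image(image)
        out.append((params, truth, image, record))
    return out
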