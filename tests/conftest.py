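import numpy as np
import pytest

from depthbcs.depth_io import BCS_GRID, BCSLabel, CameraView
from depthbcs.preprocess import build_channel_stack
from depthbcs.synthetic import (CowShapeParams, benchmark_scene_config,
                                default_poses, default_preprocess_for,
                                generate_cow_surface, render_depth)


@pytest.fixture(scope="session")
def bench_scene():
    return benchmark_scene_config()


@pytest.fixture(scope="session")
def bench_poses(bench_scene):
    return default_poses(bench_scene)


@pytest.fixture(scope="session")
def bench_preprocess(bench_scene, bench_poses):
    return default_preprocess_for(bench_scene, bench_poses)


@pytest.fixture(scope="session")
def gradient_signal_by_class(bench_scene, bench_poses, bench_preprocess):
    """Mean preprocessed |left-right gradient| per BCS class, 20 seeds each.

    The statistic is averaged over the three cameras; it is the learnable
    signal of the synthetic scenes and must decrease with BCS.
    """
    means = []
    for score in BCS_GRID:
        per_seed = []
        for seed in range(20):
            surface = generate_cow_surface(CowShapeParams(bcs=BCSLabel(score),
                                                          seed=seed))
            cams = []
            for view in CameraView:
                frame = render_depth(surface, bench_poses[view], bench_scene,
                                     rng=np.random.default_rng(10_000 + seed))
                stack = build_channel_stack(frame, bench_preprocess)
                cams.append(np.abs(stack.deriv).mean())
            per_seed.append(np.mean(cams))
        means.append(float(np.mean(per_seed)))
    return means
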