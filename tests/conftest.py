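import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noisy_scene():
    """One synthetic eye with lesion and vessels at moderate noise, plus truth."""
    from pteryquant import EyeSceneParams, generate_eye_image

    return generate_eye_image(EyeSceneParams(noise_sd=10, seed=3))


@pytest.fixture(scope="session")
def cohort(tmp_path_factory):
    """The default synthetic cohort (4 groups x 6 animals x 4 days) and its run output."""
    from pteryquant.pipeline import RunConfig, make_fixture, run

    root = tmp_path_factory.mktemp("cohort")
    manifest = make_fixture(root / "fixture", seed=11)
    bundle = run(RunConfig(manifest=manifest, out_dir=root / "out"))
    return root, manifest, bundle


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    from skimage import draw

    n = 2 * (radius + pad) + 1
    m = np.zeros((n, n), dtype=bool)
    rr, cc = draw.disk((n // 2, n // 2), radius)
    m[rr, cc] = True
    return m
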