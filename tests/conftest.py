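import numpy as np
import pytest

from headbcg import evaluate, synthetic


@pytest.fixture(scope="session")
def cohort6():
    """Six-subject, 90 s, artifact-free cohort shared across test modules."""
    return synthetic.gen_cohort(6, duration_sec=90.0, seed=1)


@pytest.fixture(scope="session")
def dataset6(cohort6):
    return evaluate.dataset_from_cohort(cohort6)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_patch_video(
    motion: np.ndarray,
    frame_size=(120, 160),
    patch_size=(60, 80),
    seed: int = 0,
    background: float = 0.5,
):
    """Tiny textured-patch renderer for tracking unit tests.

    Independent of the synthetic module's video generator: plain bilinear
    resampling of a smoothed random texture shifted by ``motion[k]`` pixels.
    Returns (frames array [n x h x w], patch box (x, y, w, h)).
    """
    from scipy.ndimage import gaussian_filter, map_coordinates

    rng = np.random.default_rng(seed)
    fh, fw = frame_size
    ph, pw = patch_size
    pad = int(np.ceil(np.max(np.abs(motion)))) + 2
    texture = gaussian_filter(rng.uniform(0, 1, size=(ph, pw)), 1.0)
    texture = 0.1 + 0.8 * (texture - texture.min()) / np.ptp(texture)
    y0, x0 = (fh - ph) // 2, (fw - pw) // 2
    # the whole (uniform-background) scene shifts, so the patch physically
    # translates through the viewport and can leave it
    canvas = np.full((fh + 2 * pad, fw), background)
    canvas[pad + y0:pad + y0 + ph, x0:x0 + pw] = texture
    rows, cols = np.mgrid[0:fh, 0:fw].astype(float)
    frames = np.empty((len(motion), fh, fw))
    for k, m in enumerate(motion):
        frames[k] = map_coordinates(canvas, [rows + pad - m, cols], order=1)
    return frames, (x0, y0, pw, ph)
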