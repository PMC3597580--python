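import numpy as np
import pytest

import cecalign as ca


@pytest.fixture(scope="session")
def mosaic250():
    """Reference 250-cell mosaic used across modules."""
    return ca.generate_mosaic(ca.MosaicSpec(n_cells=250, seed=7))


@pytest.fixture(scope="session")
def rendered250(mosaic250):
    """SM-like rendering of the reference mosaic (noise + vignette)."""
    return ca.render_image(
        mosaic250, border_width=2, noise_sigma=6.0, vignette_strength=0.4, seed=7
    )


@pytest.fixture(scope="session")
def mosaic150():
    return ca.generate_mosaic(ca.MosaicSpec(n_cells=150, seed=5))


@pytest.fixture(scope="session")
def spec_pair(mosaic250):
    """Synthetic pair at the reference difficulty: translation (25, -15) px,
    rotation 3 deg, uniform scale 1.02, 0.5 px centroid jitter, 10% dropout,
    60% overlap."""
    w, h = mosaic250.frame
    truth = ca.AffineTransform.from_params(
        scale=1.02, rotation=3.0, translation=(25.0, -15.0), center=(w / 2, h / 2)
    )
    pair = ca.make_pair(
        mosaic250,
        ca.PairSpec(
            true_transform=truth,
            overlap_fraction=0.6,
            centroid_jitter=0.5,
            dropout_rate=0.1,
            seed=2,
        ),
    )
    return pair


def grid_points(n, frame=(480, 480), pitch=20.0):
    """Deterministic well-separated points for count/guard tests."""
    w, h = frame
    cols = int(w // pitch)
    pts = []
    for i in range(n):
        r, c = divmod(i, cols)
        pts.append((pitch / 2 + c * pitch, pitch / 2 + r * pitch))
    return ca.CentroidSet(np.array(pts), w, h)


@pytest.fixture
def make_grid_set():
    return grid_points
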