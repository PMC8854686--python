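import numpy as np
import pytest

import celltrax as ct


def gaussian_blob(shape, center, sigma, amplitude):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


def disk_mask(shape, center, radius, label=1):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    out = np.zeros(shape, dtype=np.int32)
    out[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2] = label
    return out


@pytest.fixture(scope="session")
def default_movie():
    """The default well-separated regime: 15 cells, 30 frames, 2 divisions."""
    cfg = ct.SynthConfig(rng_seed=42)
    stack, masks, lineage = ct.generate_movie(cfg)
    return cfg, stack, masks, lineage


@pytest.fixture(scope="session")
def default_pipeline(default_movie):
    """Detection + linking output on the default movie (shared; read-only)."""
    _, stack, _, _ = default_movie
    rois = ct.detect_stack(stack, ct.DetectionParams())
    lineage = ct.track_rois(rois)
    return rois, lineage


@pytest.fixture
def toy_lineage():
    """Mother (1) ending at frame 4 with daughters 2 and 3 from frame 5."""
    lin = ct.Lineage()
    lin.add(ct.Track(1, [(t, 1) for t in range(5)]))
    lin.add(ct.Track(2, [(t, 2) for t in range(5, 10)], parent_id=1))
    lin.add(ct.Track(3, [(t, 3) for t in range(5, 10)], parent_id=1))
    return lin
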