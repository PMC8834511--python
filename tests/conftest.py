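import numpy as np
import pytest

from cardioquant.histology import train_segmenter
from cardioquant.synthetic import (
    AfogSimConfig,
    MovieSimConfig,
    generate_afog_section,
    generate_movie,
)


def scribbles_from_truth(labels, rng, per_class=1000):
    """Sparse scribbles sampled from a ground-truth map (encoding code+1)."""
    scr = np.zeros_like(labels, dtype=np.uint8)
    for code in range(4):
        idx = np.flatnonzero(labels.ravel() == code)
        if len(idx) == 0:
            continue
        take = rng.choice(idx, size=min(per_class, len(idx)), replace=False)
        scr.ravel()[take] = code + 1
    return scr


@pytest.fixture(scope="session")
def afog_section():
    cfg = AfogSimConfig(
        image_size_px=(384, 384),
        wound_fraction=0.10,
        collagen_fraction_of_wound=0.40,
        seed=11,
    )
    return generate_afog_section(cfg)


@pytest.fixture(scope="session")
def trained_model(afog_section):
    section, truth = afog_section
    rng = np.random.default_rng(7)
    scr = scribbles_from_truth(truth.labels, rng)
    return train_segmenter([section], [scr], seed=0)


@pytest.fixture(scope="session")
def small_movie():
    """5 round-ish cells + 10 sub-threshold debris, noise-free, 8 frames."""
    cfg = MovieSimConfig(
        n_cells=5,
        n_debris=10,
        frames=8,
        diffusion_um2_per_min=0.5,
        target_sphericity_mean=0.85,
        target_sphericity_sd=0.05,
        noise_model={"gaussian_sd": 0.0, "poisson_scaling": 0.0},
        seed=5,
    )
    return cfg, generate_movie(cfg)
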