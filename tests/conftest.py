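import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from blink import SpectrumSet, perturb_pair, preprocess_set, random_library

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

GRID = 0.05  # Da; > 2x default tolerance, so grid-locked spectra are tolerance-separated


def make_grid_suite(n: int, seed: int, jitter: float = 0.009):
    """Query library on a coarse m/z grid plus jittered reference partners.

    Every query-reference fragment distance is either <= jitter (same grid
    point) or >= GRID - jitter (different points) — never in the ambiguous
    band between the guaranteed linking tolerance and the tolerance
    parameter — so the fast path and the aligned-cosine oracle must agree
    exactly.
    """
    rng = np.random.default_rng(seed)
    q_raw = random_library(
        n, (6, 12), (50.0, 2000.0), grid_spacing=GRID, id_prefix="q", rng=rng
    )
    refs = []
    for i, s in enumerate(q_raw):
        refs.append(
            perturb_pair(
                s,
                shared_fraction=float(rng.uniform(0.3, 1.0)),
                jitter=jitter,
                intensity_noise=0.3,
                exclusion=0.02,
                grid_spacing=GRID,
                new_id=f"r_{i:05d}",
                rng=rng,
            )
        )
    r_raw = SpectrumSet(refs, source="synthetic", role="reference")
    q, _ = preprocess_set(q_raw)
    r, _ = preprocess_set(r_raw)
    return q, r


def make_unconstrained_suite(n_query: int, n_ref: int, n_planted: int, seed: int):
    """Free-m/z libraries with a block of related (jittered) reference spectra.

    The first ``n_planted`` reference spectra are perturbations of the
    corresponding query spectra with jitter spanning the ambiguous
    tolerance band, so a small fraction of pairs is expected to disagree
    with the oracle — the realistic regime.
    """
    rng = np.random.default_rng(seed)
    q_raw = random_library(n_query, (5, 25), (50.0, 2000.0), id_prefix="q", rng=rng)
    refs = []
    for i in range(n_planted):
        refs.append(
            perturb_pair(
                q_raw[i],
                shared_fraction=float(rng.uniform(0.3, 1.0)),
                jitter=0.012,
                intensity_noise=0.4,
                exclusion=0.03,
                new_id=f"r_{i:05d}",
                rng=rng,
            )
        )
    extra = random_library(
        n_ref - n_planted, (5, 25), (50.0, 2000.0), id_prefix="rx", rng=rng
    )
    r_raw = SpectrumSet(list(refs) + list(extra), source="synthetic", role="reference")
    q, _ = preprocess_set(q_raw)
    r, _ = preprocess_set(r_raw)
    return q, r


@pytest.fixture(scope="session")
def small_processed_lib():
    """25 tolerance-separated, preprocessed spectra (multi-link-free regime)."""
    lib = random_library(25, (5, 12), (50.0, 1200.0), min_spacing=0.025, seed=71)
    processed, dropped = preprocess_set(lib)
    assert not dropped
    return processed


@pytest.fixture(scope="session")
def grid_suite_small():
    return make_grid_suite(40, seed=202)
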