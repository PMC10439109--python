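"""Synthetic centroided MS/MS spectrum generation.

Emulates high-resolution centroided spectra: fragments at arbitrary m/z in
50–2000 Da with sub-0.01 Da mass accuracy, heavy-tailed (exponential)
intensities, and a precursor m/z above the largest fragment. Two knobs
matter for validating blur-and-link scoring:

- ``min_spacing`` controls within-spectrum fragment separation. Setting it
  above twice the tolerance removes the multi-link mechanism by which the
  fast score can exceed the aligned cosine, so both paths must agree
  exactly.
- ``grid_spacing`` locks fragment positions onto a coarse global grid, so
  cross-spectrum fragment distances are either ~0 (same grid point) or at
  least one grid step — never inside the ambiguous band between the
  guaranteed linking tolerance and the tolerance parameter.

:func:`perturb_pair` derives a related partner spectrum (shared fragments
with m/z jitter and intensity noise, plus fresh fragments), optionally
mass-shifted for analog-search tests.

All randomness flows through a single ``numpy.random.Generator``, so a
seed fully determines the output on every platform.
"""

from __future__ import annotations

import math

import numpy as np

from .spectrum import Spectrum, SpectrumSet

__all__ = ["random_library", "perturb_pair"]

_MAX_RETRIES = 50


def _rng(seed, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def _spaced_mz(
    rng: np.random.Generator,
    n: int,
    mz_range: tuple[float, float],
    min_spacing: float,
) -> np.ndarray:
    """Draw n fragment m/z values with all pairwise gaps > min_spacing."""
    lo, hi = mz_range
    if min_spacing <= 0:
        return np.sort(rng.uniform(lo, hi, n))
    if n * min_spacing >= (hi - lo):
        raise ValueError(
            f"cannot place {n} fragments with spacing {min_spacing} in "
            f"range {mz_range}"
        )
    for _ in range(_MAX_RETRIES):
        cand = np.sort(rng.uniform(lo, hi, max(4 * n, n + 20)))
        kept = [cand[0]]
        for v in cand[1:]:
            if v - kept[-1] > min_spacing:
                kept.append(v)
        if len(kept) >= n:
            idx = rng.choice(len(kept), size=n, replace=False)
            return np.sort(np.asarray(kept)[idx])
    raise ValueError(
        f"failed to satisfy min_spacing={min_spacing} over {mz_range} "
        f"for {n} fragments after {_MAX_RETRIES} attempts"
    )


def _grid_mz(
    rng: np.random.Generator,
    n: int,
    mz_range: tuple[float, float],
    grid_spacing: float,
) -> np.ndarray:
    lo, hi = mz_range
    first = int(math.ceil(lo / grid_spacing))
    last = int(math.floor(hi / grid_spacing))
    n_points = last - first + 1
    if n_points < n:
        raise ValueError(
            f"grid of {n_points} points in {mz_range} cannot host {n} fragments"
        )
    idx = rng.choice(n_points, size=n, replace=False) + first
    return np.sort(idx.astype(np.float64) * grid_spacing)


def random_library(
    n_spectra: int,
    n_frag_range: tuple[int, int] = (5, 30),
    mz_range: tuple[float, float] = (50.0, 2000.0),
    intensity_mean: float = 100.0,
    min_spacing: float = 0.0,
    grid_spacing: float | None = None,
    precursor_margin: tuple[float, float] = (5.0, 50.0),
    id_prefix: str = "syn",
    role: str = "query",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SpectrumSet:
    """Generate a reproducible synthetic spectrum library.

    Fragment m/z are uniform over ``mz_range`` (thinned to enforce pairwise
    spacing strictly greater than ``min_spacing``, or placed on distinct
    multiples of ``grid_spacing`` if given); intensities are exponential
    with mean ``intensity_mean`` (a heavy-tailed stand-in for real
    fragment-intensity distributions); the precursor m/z sits a uniform
    margin above the largest fragment.
    """
    if min_spacing < 0:
        raise ValueError("min_spacing must be non-negative")
    if not (0 < mz_range[0] < mz_range[1]):
        raise ValueError(f"invalid mz_range {mz_range}")
    lo_n, hi_n = n_frag_range
    if not (0 < lo_n <= hi_n):
        raise ValueError(f"invalid n_frag_range {n_frag_range}")
    gen = _rng(seed, rng)
    spectra = []
    for i in range(n_spectra):
        n = int(gen.integers(lo_n, hi_n + 1))
        if grid_spacing is not None:
            mz = _grid_mz(gen, n, mz_range, grid_spacing)
        else:
            mz = _spaced_mz(gen, n, mz_range, min_spacing)
        intensity = gen.exponential(intensity_mean, n)
        intensity = np.maximum(intensity, 1e-12)
        precursor = float(mz.max() + gen.uniform(*precursor_margin))
        spectra.append(
            Spectrum(
                id=f"{id_prefix}_{i:05d}",
                precursor_mz=precursor,
                mz=mz,
                intensity=intensity,
            )
        )
    return SpectrumSet(spectra, source="synthetic", role=role)


def perturb_pair(
    s: Spectrum,
    shared_fraction: float,
    jitter: float = 0.0,
    intensity_noise: float = 0.0,
    mass_shift: float = 0.0,
    exclusion: float = 0.02,
    mz_range: tuple[float, float] | None = None,
    grid_spacing: float | None = None,
    new_id: str | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Spectrum:
    """Derive a partner spectrum with a controlled fragment overlap.

    ``ceil(shared_fraction * n)`` fragments are kept (m/z perturbed
    uniformly within ±``jitter`` Da, intensity multiplied by lognormal
    noise with log-sd ``intensity_noise``); the rest are replaced by fresh
    fragments at least ``exclusion`` Da away from every original fragment,
    drawn uniformly (or on unused multiples of ``grid_spacing``). Finally
    ``mass_shift`` is added to every fragment and the precursor, producing
    a synthetic homolog for analog-search tests.
    """
    if not 0.0 <= shared_fraction <= 1.0:
        raise ValueError("shared_fraction must be in [0, 1]")
    gen = _rng(seed, rng)
    n = len(s)
    k = int(math.ceil(shared_fraction * n))
    keep_idx = np.sort(gen.choice(n, size=k, replace=False)) if k else np.empty(0, int)
    mz_kept = s.mz[keep_idx].copy()
    if jitter > 0 and k:
        mz_kept = mz_kept + gen.uniform(-jitter, jitter, k)
    int_kept = s.intensity[keep_idx].copy()
    if intensity_noise > 0 and k:
        int_kept = int_kept * gen.lognormal(0.0, intensity_noise, k)

    n_new = n - k
    if mz_range is None:
        mz_range = (50.0, max(2000.0, float(s.precursor_mz)))
    new_mz = np.empty(0)
    if n_new:
        if grid_spacing is not None:
            lo, hi = mz_range
            first = int(math.ceil(lo / grid_spacing))
            last = int(math.floor(hi / grid_spacing))
            points = np.arange(first, last + 1, dtype=np.float64) * grid_spacing
            far = np.all(
                np.abs(points[:, None] - s.mz[None, :]) > exclusion, axis=1
            )
            avail = points[far]
            if avail.size < n_new:
                raise ValueError("not enough free grid points for fresh fragments")
            new_mz = np.sort(gen.choice(avail, size=n_new, replace=False))
        else:
            collected: list[float] = []
            placed = np.array(s.mz)
            for _ in range(_MAX_RETRIES * max(n_new, 1)):
                if len(collected) == n_new:
                    break
                v = gen.uniform(*mz_range)
                if np.all(np.abs(placed - v) > exclusion) and all(
                    abs(v - w) > exclusion for w in collected
                ):
                    collected.append(v)
            if len(collected) < n_new:
                raise ValueError("could not place fresh fragments outside exclusion windows")
            new_mz = np.sort(np.asarray(collected))
        new_int = np.maximum(gen.exponential(float(s.intensity.mean() or 1.0), n_new), 1e-12)
    else:
        new_int = np.empty(0)

    mz = np.concatenate([mz_kept, new_mz]) + mass_shift
    intensity = np.concatenate([int_kept, new_int])
    return Spectrum(
        id=new_id or f"{s.id}_p",
        precursor_mz=float(s.precursor_mz + mass_shift),
        mz=mz,
        intensity=intensity,
        charge=s.charge,
    )
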