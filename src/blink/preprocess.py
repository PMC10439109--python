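"""Noise filtering and intensity transforms applied before scoring.

The canonical pipeline is fixed: :func:`filter_noise` -> :func:`sqrt_scale`
-> :func:`unit_normalize`. Normalization must come last — cosine scores are
the dot products of the stored intensity vectors, so anything applied after
normalization would silently change the score scale.
"""

from __future__ import annotations

import logging

import numpy as np

from .spectrum import Spectrum, SpectrumSet

__all__ = ["filter_noise", "sqrt_scale", "unit_normalize", "preprocess", "preprocess_set"]

logger = logging.getLogger("blink")


def filter_noise(
    s: Spectrum,
    base_peak_fraction: float = 0.01,
    remove_above_precursor: bool = True,
) -> Spectrum:
    """Remove noise ions from a spectrum.

    Drops fragments with intensity strictly below ``base_peak_fraction`` of
    the base peak (the most intense fragment), fragments with m/z strictly
    above the precursor m/z, and zero-intensity fragments. A fragment at
    exactly the base-peak fraction, or exactly at the precursor m/z, is kept.

    Returns an empty spectrum (to be excluded from scoring) if everything
    is removed.
    """
    if len(s) == 0:
        return s
    keep = s.intensity > 0
    base = s.intensity.max()
    if base > 0:
        keep &= s.intensity >= base_peak_fraction * base
    if remove_above_precursor:
        keep &= s.mz <= s.precursor_mz
    if not keep.any():
        logger.warning("spectrum %r empty after noise filtering", s.id)
    return s.replace(mz=s.mz[keep], intensity=s.intensity[keep])


def sqrt_scale(s: Spectrum) -> Spectrum:
    """Replace each intensity by its square root; m/z unchanged."""
    return s.replace(intensity=np.sqrt(s.intensity))


def unit_normalize(s: Spectrum) -> Spectrum:
    """Scale intensities so the vector has unit Euclidean norm."""
    norm = float(np.linalg.norm(s.intensity))
    if norm == 0.0:
        raise ValueError(
            f"spectrum {s.id!r}: cannot unit-normalize an all-zero intensity "
            "vector (should have been removed by filter_noise)"
        )
    return s.replace(intensity=s.intensity / norm)


def preprocess(
    s: Spectrum,
    base_peak_fraction: float = 0.01,
    apply_sqrt: bool = True,
    remove_above_precursor: bool = True,
) -> Spectrum:
    """Full single-spectrum pipeline: filter, sqrt-scale, unit-normalize.

    Returns the (possibly empty) filtered spectrum; empty spectra are not
    normalized.
    """
    s = filter_noise(s, base_peak_fraction, remove_above_precursor)
    if len(s) == 0:
        return s
    if apply_sqrt:
        s = sqrt_scale(s)
    return unit_normalize(s)


def preprocess_set(
    spectra: SpectrumSet,
    base_peak_fraction: float = 0.01,
    apply_sqrt: bool = True,
    remove_above_precursor: bool = True,
) -> tuple[SpectrumSet, list[str]]:
    """Preprocess every spectrum in a set, dropping spectra that become empty.

    Returns the processed set and the list of dropped spectrum ids (also
    logged). Dropping keeps downstream matrices free of zero columns that
    would make unit normalization meaningless.
    """
    kept: list[Spectrum] = []
    dropped: list[str] = []
    for s in spectra:
        p = preprocess(s, base_peak_fraction, apply_sqrt, remove_above_precursor)
        if len(p) == 0:
            dropped.append(s.id)
        else:
            kept.append(p)
    if dropped:
        logger.warning(
            "dropped %d spectra empty after filtering: %s",
            len(dropped),
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    return SpectrumSet(kept, source=spectra.source, role=spectra.role), dropped
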