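"""Domain containers for centroided MS/MS spectra.

A :class:`Spectrum` is one tandem mass spectrum: a precursor m/z and two
parallel arrays of fragment m/z (Da) and intensity. A :class:`SpectrumSet`
is an ordered collection; its order is load-bearing, because the column
index of every downstream sparse matrix equals the position in the set.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["Spectrum", "SpectrumSet"]


@dataclass(frozen=True)
class Spectrum:
    """One centroided MS/MS scan.

    Parameters
    ----------
    id : str
        Identifier, unique within a :class:`SpectrumSet`.
    precursor_mz : float
        m/z of the precursor ion selected for fragmentation, in Da.
    mz : array-like of float
        Fragment m/z values in Da. Stored strictly ascending; fragments at
        identical m/z are merged by summing their intensities.
    intensity : array-like of float
        Fragment intensities, same length as ``mz``, all >= 0.
    charge : int or None
        Precursor charge state; ``None`` means unknown. Charge is carried
        as metadata only — no scoring equation uses it.
    """

    id: str
    precursor_mz: float
    mz: np.ndarray
    intensity: np.ndarray
    charge: int | None = None

    def __post_init__(self) -> None:
        mz = np.asarray(self.mz, dtype=np.float64)
        inten = np.asarray(self.intensity, dtype=np.float64)
        if mz.ndim != 1 or inten.ndim != 1:
            raise ValueError("mz and intensity must be 1-D arrays")
        if mz.shape != inten.shape:
            raise ValueError(
                f"spectrum {self.id!r}: mz and intensity lengths differ "
                f"({mz.size} vs {inten.size})"
            )
        if np.any(inten < 0):
            raise ValueError(f"spectrum {self.id!r}: negative intensity")
        if np.any(mz <= 0):
            raise ValueError(f"spectrum {self.id!r}: non-positive fragment m/z")
        if not self.precursor_mz > 0:
            raise ValueError(f"spectrum {self.id!r}: precursor m/z must be positive")
        order = np.argsort(mz, kind="stable")
        mz, inten = mz[order], inten[order]
        # Merge duplicate m/z by summing intensity: binning sums anyway,
        # and it keeps the ascending-m/z invariant strict.
        uniq, inverse = np.unique(mz, return_inverse=True)
        if uniq.size != mz.size:
            summed = np.zeros(uniq.size, dtype=np.float64)
            np.add.at(summed, inverse, inten)
            mz, inten = uniq, summed
        mz.setflags(write=False)
        inten.setflags(write=False)
        object.__setattr__(self, "mz", mz)
        object.__setattr__(self, "intensity", inten)

    def __len__(self) -> int:
        return int(self.mz.size)

    @property
    def n_fragments(self) -> int:
        return len(self)

    def replace(self, **changes) -> "Spectrum":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)


@dataclass
class SpectrumSet:
    """Ordered collection of :class:`Spectrum` with provenance.

    The position of a spectrum in ``spectra`` is its column index in every
    matrix derived from the set, so order must never be perturbed silently.
    """

    spectra: list[Spectrum]
    source: str = "synthetic"
    role: str = "query"

    def __post_init__(self) -> None:
        self.spectra = list(self.spectra)
        seen: dict[str, int] = {}
        for i, s in enumerate(self.spectra):
            if s.id in seen:
                raise ValueError(
                    f"duplicate spectrum id {s.id!r} at positions "
                    f"{seen[s.id]} and {i} in set {self.source!r}"
                )
            seen[s.id] = i
        self._index = seen

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    def __getitem__(self, i: int) -> Spectrum:
        return self.spectra[i]

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.spectra]

    def by_id(self, spectrum_id: str) -> Spectrum:
        try:
            return self.spectra[self._index[spectrum_id]]
        except KeyError:
            raise KeyError(f"unknown spectrum id {spectrum_id!r}") from None

    def total_fragments(self) -> int:
        return sum(len(s) for s in self.spectra)

    def subset(self, indices: Sequence[int], role: str | None = None) -> "SpectrumSet":
        return SpectrumSet(
            [self.spectra[i] for i in indices],
            source=self.source,
            role=role or self.role,
        )
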