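"""Discretization of spectra into sparse bin matrices and the blur kernel.

Fragment m/z values are floor-binned at a user-chosen bin width (default
0.001 Da). Each spectrum set becomes a pair of sparse matrices over
(bin, spectrum) coordinates — one holding normalized intensities, one
holding fragment counts. Before scoring, one side is "blurred": every
occupied bin is expanded into a window of ``2 * half_width + 1`` bins, each
carrying the full fragment value. Two fragments are then linked exactly
when their bins are within ``half_width`` of each other, which yields the
effective-tolerance identity

    guaranteed linking tolerance = tolerance - bin_width,

with ``half_width = round(tolerance / bin_width) - 1`` under floor binning:
fragments closer than ``half_width * bin_width`` can differ by at most
``half_width`` bins regardless of bin phase, while fragments further apart
than ``tolerance`` always differ by more than ``half_width`` bins.

Matrices are stored in COO form with int64 *global* bin coordinates rather
than as 2-D arrays with one row per possible bin: at small bin widths the
bin space has billions of rows, but only occupied bins ever matter, and the
scoring step intersects the occupied-bin sets of the two operands before
multiplying.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .spectrum import SpectrumSet

__all__ = ["bin_index", "BinnedMatrices", "BlurKernel", "make_kernel", "discretize", "blur"]

logger = logging.getLogger("blink")

# Relative guard so that m/z values intended to be exact multiples of the
# bin width land in the upper bin despite binary rounding of the quotient.
_BIN_EPS = 1e-9


def bin_index(mz, bin_width: float):
    """Floor-bin m/z values: ``floor(mz / bin_width)`` with an epsilon guard.

    Accepts a scalar or array; returns int64 of the same shape (a Python int
    for scalar input). Inputs must be positive.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mz_arr = np.asarray(mz, dtype=np.float64)
    if np.any(mz_arr <= 0):
        raise ValueError("m/z values must be positive")
    idx = np.floor(mz_arr / bin_width * (1.0 + _BIN_EPS)).astype(np.int64)
    if np.isscalar(mz) or mz_arr.ndim == 0:
        return int(idx)
    return idx


@dataclass(frozen=True)
class BlurKernel:
    """Uniform linking kernel: a ones-window of ``2 * half_width + 1`` bins.

    ``half_width = round(tolerance / bin_width) - 1``. The guaranteed
    linking tolerance is ``half_width * bin_width = tolerance - bin_width``;
    fragment pairs further apart than ``tolerance`` are never linked, and
    pairs in between may or may not link depending on where the bin
    boundaries fall.
    """

    tolerance: float
    bin_width: float

    def __post_init__(self) -> None:
        if self.bin_width <= 0 or self.tolerance <= 0:
            raise ValueError("tolerance and bin_width must be positive")
        if self.bin_width > self.tolerance:
            raise ValueError("BLINK bin width cannot exceed tolerance")

    @property
    def half_width(self) -> int:
        return int(round(self.tolerance / self.bin_width)) - 1

    @property
    def effective_tolerance(self) -> float:
        """Largest m/z difference guaranteed to be linked, in Da."""
        return self.half_width * self.bin_width

    @property
    def width(self) -> int:
        return 2 * self.half_width + 1


def make_kernel(tolerance: float = 0.01, bin_width: float = 0.001) -> BlurKernel:
    """Build the blur kernel for a tolerance / bin width pair."""
    return BlurKernel(tolerance=tolerance, bin_width=bin_width)


@dataclass
class BinnedMatrices:
    """Paired sparse intensity and fragment-count matrices over m/z bins.

    COO representation: entry k lives at (``bins[k]``, ``cols[k]``) and
    holds ``intensity[k]`` in the intensity matrix and ``counts[k]`` in the
    count matrix. Before blurring the two matrices share one sparsity
    pattern (one entry per retained fragment, duplicates within a bin
    summed at scoring time); after blurring each entry is replicated across
    the kernel window.
    """

    bins: np.ndarray  # int64 global bin coordinates (may be huge or negative-free)
    cols: np.ndarray  # int64 spectrum/column indices
    intensity: np.ndarray  # float64
    counts: np.ndarray  # float64 (integral values)
    bin_width: float
    n_spectra: int
    ids: list[str]
    shift_mode: str = "none"  # none | precursor | fixed
    shift_delta: float = 0.0
    blurred: bool = False
    tolerance: float | None = None  # set by blur()

    @property
    def nnz(self) -> int:
        return int(self.bins.size)

    def column_fragment_counts(self) -> np.ndarray:
        """Number of stored fragments per spectrum (pre-blur: retained ions)."""
        out = np.zeros(self.n_spectra, dtype=np.int64)
        np.add.at(out, self.cols, np.rint(self.counts).astype(np.int64))
        return out

    def total_intensity(self) -> float:
        return float(self.intensity.sum())


def discretize(
    spectra: SpectrumSet,
    bin_width: float = 0.001,
    shift_mode: str = "none",
    shift_delta: float = 0.0,
) -> BinnedMatrices:
    """Convert a spectrum set into paired sparse bin matrices.

    ``shift_mode``:

    - ``"none"``: bin coordinate is the fragment m/z.
    - ``"precursor"``: neutral-loss coordinate ``precursor_mz - mz``, so
      equal neutral losses align across different precursors (analog
      search by precursor m/z difference).
    - ``"fixed"``: ``mz + shift_delta`` (any user-defined mass difference).

    Fragments whose shifted coordinate is not positive are dropped (their
    count is logged).
    """
    if len(spectra) == 0:
        raise ValueError("cannot discretize an empty SpectrumSet")
    if shift_mode not in ("none", "precursor", "fixed"):
        raise ValueError(f"unknown shift_mode {shift_mode!r}")

    bins_parts: list[np.ndarray] = []
    cols_parts: list[np.ndarray] = []
    inten_parts: list[np.ndarray] = []
    n_dropped = 0
    for j, s in enumerate(spectra):
        if shift_mode == "none":
            coord = s.mz
        elif shift_mode == "precursor":
            coord = s.precursor_mz - s.mz
        else:
            coord = s.mz + shift_delta
        valid = coord > 0
        n_dropped += int((~valid).sum())
        coord = coord[valid]
        if coord.size == 0:
            continue
        bins_parts.append(bin_index(coord, bin_width))
        cols_parts.append(np.full(coord.size, j, dtype=np.int64))
        inten_parts.append(s.intensity[valid])
    if n_dropped:
        logger.warning("dropped %d fragments with non-positive shifted m/z", n_dropped)
    if not bins_parts:
        bins = np.empty(0, dtype=np.int64)
        cols = np.empty(0, dtype=np.int64)
        inten = np.empty(0, dtype=np.float64)
    else:
        bins = np.concatenate(bins_parts)
        cols = np.concatenate(cols_parts)
        inten = np.concatenate(inten_parts)
    return BinnedMatrices(
        bins=bins,
        cols=cols,
        intensity=inten,
        counts=np.ones_like(inten),
        bin_width=bin_width,
        n_spectra=len(spectra),
        ids=spectra.ids,
        shift_mode=shift_mode,
        shift_delta=shift_delta if shift_mode == "fixed" else 0.0,
    )


def blur(m: BinnedMatrices, kernel: BlurKernel) -> BinnedMatrices:
    """Expand every occupied bin across the kernel window.

    Equivalent to left-multiplying both matrices by a symmetric banded
    ones-matrix of bandwidth ``half_width``: output bin r receives the sum
    of input bins ``r - half_width .. r + half_width``. Because bins are
    global coordinates, the expansion never truncates at matrix edges.
    """
    if m.blurred:
        raise ValueError("matrices are already blurred; blurring twice is invalid")
    if abs(kernel.bin_width - m.bin_width) > 1e-15 * max(kernel.bin_width, m.bin_width):
        raise ValueError(
            f"kernel bin_width {kernel.bin_width} does not match matrix "
            f"bin_width {m.bin_width}"
        )
    h = kernel.half_width
    if h == 0:
        blurred = BinnedMatrices(
            bins=m.bins.copy(),
            cols=m.cols.copy(),
            intensity=m.intensity.copy(),
            counts=m.counts.copy(),
            bin_width=m.bin_width,
            n_spectra=m.n_spectra,
            ids=list(m.ids),
            shift_mode=m.shift_mode,
            shift_delta=m.shift_delta,
            blurred=True,
            tolerance=kernel.tolerance,
        )
        return blurred
    offsets = np.arange(-h, h + 1, dtype=np.int64)
    bins = (m.bins[None, :] + offsets[:, None]).ravel()
    cols = np.broadcast_to(m.cols, (offsets.size, m.cols.size)).ravel()
    inten = np.broadcast_to(m.intensity, (offsets.size, m.intensity.size)).ravel().copy()
    cnts = np.broadcast_to(m.counts, (offsets.size, m.counts.size)).ravel().copy()
    return BinnedMatrices(
        bins=bins,
        cols=cols.copy(),
        intensity=inten,
        counts=cnts,
        bin_width=m.bin_width,
        n_spectra=m.n_spectra,
        ids=list(m.ids),
        shift_mode=m.shift_mode,
        shift_delta=m.shift_delta,
        blurred=True,
        tolerance=kernel.tolerance,
    )
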