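"""All-pairs cosine scores and matching-ion counts by sparse multiplication.

Given a blurred query matrix Q and an unblurred reference matrix R over a
shared bin coordinate system, the score matrix is simply ``Q.T @ R`` on the
intensity matrices and the matching-ion count matrix is ``Q.T @ R`` on the
count matrices. Because intensities are unit-normalized per spectrum and
each reference fragment occupies one bin, a linked fragment pair
contributes exactly the product of its two intensities — the same term a
loop-based aligned cosine would add — except that *all* fragments within
tolerance contribute, not just one chosen partner. That is the sole source
of BLINK's (one-sided, upward) deviation from alignment-based scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .binning import BinnedMatrices, BlurKernel, blur, discretize, make_kernel
from .preprocess import preprocess_set
from .spectrum import SpectrumSet

__all__ = ["ScoreResult", "score_all", "classify_similar", "score_sets", "analog_score_all"]


@dataclass
class ScoreResult:
    """Dense query x reference matrices of cosine scores and ion counts."""

    scores: np.ndarray  # float64, n_query x n_ref
    matches: np.ndarray  # int64, same shape
    query_ids: list[str]
    ref_ids: list[str]
    bin_width: float
    tolerance: float
    shift_mode: str = "none"
    shift_delta: float = 0.0

    def __post_init__(self) -> None:
        if self.scores.shape != self.matches.shape:
            raise ValueError("scores and matches must have identical shape")
        if self.scores.shape != (len(self.query_ids), len(self.ref_ids)):
            raise ValueError("result shape does not match id lists")

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape

    def transposed(self) -> "ScoreResult":
        return ScoreResult(
            scores=self.scores.T.copy(),
            matches=self.matches.T.copy(),
            query_ids=list(self.ref_ids),
            ref_ids=list(self.query_ids),
            bin_width=self.bin_width,
            tolerance=self.tolerance,
            shift_mode=self.shift_mode,
            shift_delta=self.shift_delta,
        )

    def to_frame(self):
        """Long-format pandas DataFrame: query_id, ref_id, score, matches."""
        import pandas as pd

        nq, nr = self.shape
        qi, ri = np.meshgrid(np.arange(nq), np.arange(nr), indexing="ij")
        return pd.DataFrame(
            {
                "query_id": np.asarray(self.query_ids, dtype=object)[qi.ravel()],
                "ref_id": np.asarray(self.ref_ids, dtype=object)[ri.ravel()],
                "score": self.scores.ravel(),
                "matches": self.matches.ravel(),
            }
        )


def _compact_product(a: BinnedMatrices, b: BinnedMatrices) -> tuple[np.ndarray, np.ndarray]:
    """Compute (A.T @ B) for intensity and count matrices.

    Only bins occupied in *both* operands contribute to the product, so the
    shared bins are found first and each operand is restricted to them
    before building compact scipy CSR matrices. This keeps memory bounded
    by the number of stored entries even when the global bin space has
    billions of coordinates (tiny bin widths).
    """
    shared = np.intersect1d(np.unique(a.bins), np.unique(b.bins))
    if shared.size == 0:
        z = np.zeros((a.n_spectra, b.n_spectra))
        return z, z.copy()

    def restrict(m: BinnedMatrices):
        pos = np.searchsorted(shared, m.bins)
        pos_clipped = np.clip(pos, 0, shared.size - 1)
        keep = shared[pos_clipped] == m.bins
        return pos_clipped[keep], m.cols[keep], m.intensity[keep], m.counts[keep]

    ra, ca, ia, na = restrict(a)
    rb, cb, ib, nb = restrict(b)
    A_int = sp.csr_matrix((ia, (ra, ca)), shape=(shared.size, a.n_spectra))
    B_int = sp.csr_matrix((ib, (rb, cb)), shape=(shared.size, b.n_spectra))
    scores = (A_int.T @ B_int).toarray()
    A_cnt = sp.csr_matrix((na, (ra, ca)), shape=(shared.size, a.n_spectra))
    B_cnt = sp.csr_matrix((nb, (rb, cb)), shape=(shared.size, b.n_spectra))
    counts = (A_cnt.T @ B_cnt).toarray()
    return scores, counts


def score_all(query: BinnedMatrices, ref: BinnedMatrices) -> ScoreResult:
    """Score a blurred query matrix against an unblurred reference matrix.

    The result is ``n_query x n_ref``; match counts are rounded to the
    nearest integer (they are integral in exact arithmetic under the
    ones-kernel; rounding guards float drift).
    """
    if abs(query.bin_width - ref.bin_width) > 1e-15 * max(query.bin_width, ref.bin_width):
        raise ValueError("query and reference bin widths differ")
    if not query.blurred or ref.blurred:
        raise ValueError(
            "score_all requires a blurred query and an unblurred reference "
            f"(got query.blurred={query.blurred}, ref.blurred={ref.blurred})"
        )
    if query.shift_mode != ref.shift_mode and "fixed" not in (
        query.shift_mode,
        ref.shift_mode,
    ):
        raise ValueError("query and reference shift modes are incompatible")
    scores, counts = _compact_product(query, ref)
    return ScoreResult(
        scores=scores,
        matches=np.rint(counts).astype(np.int64),
        query_ids=list(query.ids),
        ref_ids=list(ref.ids),
        bin_width=query.bin_width,
        tolerance=float(query.tolerance),
        shift_mode=query.shift_mode if query.shift_mode != "none" else ref.shift_mode,
        shift_delta=query.shift_delta or ref.shift_delta,
    )


def classify_similar(
    result: ScoreResult, min_score: float = 0.7, min_matches: int = 6
) -> np.ndarray:
    """Boolean matrix: score >= min_score AND matching ions >= min_matches.

    Both thresholds are inclusive; the defaults (0.7 / 6) are the common
    operating point for calling two spectra similar.
    """
    return (result.scores >= min_score) & (result.matches >= min_matches)


def score_sets(
    query: SpectrumSet,
    ref: SpectrumSet,
    bin_width: float = 0.001,
    tolerance: float = 0.01,
    shift_mode: str = "none",
    shift_delta: float = 0.0,
    blur_side: str = "auto",
    preprocessed: bool = True,
) -> ScoreResult:
    """End-to-end convenience: discretize, blur one side, multiply.

    ``blur_side`` is ``"query"``, ``"ref"`` or ``"auto"`` (blur the side
    with fewer stored fragments; the kernel matrix is symmetric so the
    result is identical either way, but blurring the smaller side is
    cheaper). Set ``preprocessed=False`` to run the standard noise filter /
    sqrt / unit-norm pipeline first.
    """
    if not preprocessed:
        query, _ = preprocess_set(query)
        ref, _ = preprocess_set(ref)
    kernel = make_kernel(tolerance, bin_width)
    if shift_mode == "fixed":
        qm = discretize(query, bin_width, "fixed", shift_delta)
        rm = discretize(ref, bin_width, "none")
    else:
        qm = discretize(query, bin_width, shift_mode)
        rm = discretize(ref, bin_width, shift_mode)
    if blur_side == "auto":
        blur_side = "query" if qm.nnz <= rm.nnz else "ref"
    if blur_side == "query":
        return score_all(blur(qm, kernel), rm)
    if blur_side == "ref":
        return score_all(blur(rm, kernel), qm).transposed()
    raise ValueError(f"blur_side must be 'auto', 'query' or 'ref', got {blur_side!r}")


def analog_score_all(
    query: SpectrumSet,
    ref: SpectrumSet,
    bin_width: float = 0.001,
    tolerance: float = 0.01,
    mode: str = "precursor",
    delta: float = 0.0,
) -> tuple[ScoreResult, ScoreResult, ScoreResult]:
    """Analog search: combine unshifted and mass-shifted scoring.

    ``mode="precursor"`` scores both sets in neutral-loss coordinates
    (precursor m/z minus fragment m/z), so spectra of homologs whose
    fragments and precursor share a common offset still align.
    ``mode="fixed"`` shifts the query fragments by ``delta`` Da instead.

    Returns ``(regular, shifted, combined)`` where ``combined`` takes the
    element-wise maximum of the two score matrices and the match count of
    whichever term attained it (ties favor the regular term). Both raw
    results are returned so any other combination rule can be applied
    downstream.
    """
    if mode == "precursor":
        for s in list(query) + list(ref):
            if not s.precursor_mz > 0:
                raise ValueError(f"spectrum {s.id!r} lacks a precursor m/z")
    elif mode != "fixed":
        raise ValueError(f"analog mode must be 'precursor' or 'fixed', got {mode!r}")

    regular = score_sets(query, ref, bin_width, tolerance, "none")
    shifted = score_sets(
        query, ref, bin_width, tolerance, mode, shift_delta=delta
    )
    take_shifted = shifted.scores > regular.scores
    combined = ScoreResult(
        scores=np.where(take_shifted, shifted.scores, regular.scores),
        matches=np.where(take_shifted, shifted.matches, regular.matches),
        query_ids=list(regular.query_ids),
        ref_ids=list(regular.ref_ids),
        bin_width=bin_width,
        tolerance=tolerance,
        shift_mode=mode,
        shift_delta=delta,
    )
    return regular, shifted, combined
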