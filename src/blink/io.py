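"""Reading and writing spectra (MGF) and scoring results (TSV / sparse text).

MGF value parsing is delegated to :mod:`pyteomics.mgf`; a cheap structural
prescan runs first so that malformed files fail with messages naming the
offending block or line (unterminated blocks, non-numeric peak lines),
which pyteomics does not report. Hit lists are plain TSV — the natural
product of a thresholded search is sparse, so a flat table beats a matrix
dump; the full score matrix can still be written in coordinate form.
"""

from __future__ import annotations

import logging
import os
from typing import Iterable

import numpy as np
import pandas as pd
from pyteomics import mgf as _mgf

from .scoring import ScoreResult
from .spectrum import Spectrum, SpectrumSet

__all__ = [
    "MGFParseError",
    "read_mgf",
    "write_mgf",
    "write_scores",
    "write_matrix",
    "read_hits",
]

logger = logging.getLogger("blink")

HIT_COLUMNS = ["query_id", "ref_id", "score", "matches"]


class MGFParseError(ValueError):
    """Raised for structurally invalid MGF input."""


def _prescan(path: str) -> None:
    """Validate block structure; raise MGFParseError with location info."""
    block = 0
    in_block = False
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                if in_block:
                    raise MGFParseError(
                        f"block {block} is not terminated (nested BEGIN IONS "
                        f"at line {lineno})"
                    )
                in_block = True
                block += 1
                continue
            if line == "END IONS":
                if not in_block:
                    raise MGFParseError(f"stray END IONS at line {lineno}")
                in_block = False
                continue
            if in_block and "=" not in line:
                fields = line.split()
                if len(fields) < 2:
                    raise MGFParseError(
                        f"malformed peak line {lineno} in block {block}: {line!r}"
                    )
                try:
                    float(fields[0]), float(fields[1])
                except ValueError:
                    raise MGFParseError(
                        f"non-numeric peak line {lineno} in block {block}: {line!r}"
                    ) from None
    if in_block:
        raise MGFParseError(f"block {block} has no END IONS (unexpected end of file)")


def read_mgf(path: str, role: str = "query") -> SpectrumSet:
    """Read an MGF file into a :class:`SpectrumSet`.

    One spectrum per BEGIN IONS / END IONS block, in file order. Peak
    lists are sorted ascending by m/z (duplicates merged). Blocks without
    a PEPMASS are skipped with a logged warning; an empty file yields an
    empty set with a logged warning. Spectra without a TITLE get ids
    ``scan_<ordinal>``.
    """
    _prescan(path)
    spectra: list[Spectrum] = []
    with _mgf.read(path, use_index=False, convert_arrays=1) as reader:
        for ordinal, entry in enumerate(reader, start=1):
            params = entry.get("params", {})
            pepmass = params.get("pepmass")
            if pepmass is None or pepmass[0] is None:
                logger.warning("skipping MGF block %d: missing PEPMASS", ordinal)
                continue
            charge = params.get("charge")
            charge_val = int(charge[0]) if charge else None
            title = str(params.get("title", "")).strip() or f"scan_{ordinal}"
            spectra.append(
                Spectrum(
                    id=title,
                    precursor_mz=float(pepmass[0]),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    charge=charge_val,
                )
            )
    if not spectra:
        logger.warning("MGF file %s contained no usable spectra", path)
    return SpectrumSet(spectra, source=os.fspath(path), role=role)


def write_mgf(spectra: SpectrumSet, path: str) -> None:
    """Write a spectrum set to MGF (round-trips ids, precursors, peaks)."""
    entries = []
    for s in spectra:
        params = {"title": s.id, "pepmass": s.precursor_mz}
        if s.charge is not None:
            params["charge"] = s.charge
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(entries, output=path, file_mode="w")


def hits_frame(
    result: ScoreResult, min_score: float = 0.0, min_matches: int = 0
) -> pd.DataFrame:
    """Thresholded long-format hit table, sorted for stable output.

    Rows with score >= min_score and matches >= min_matches, sorted by
    descending score with ties broken by (query_id, ref_id).
    """
    if min_score < 0 or min_matches < 0:
        raise ValueError("thresholds must be non-negative")
    qi, ri = np.nonzero(
        (result.scores >= min_score) & (result.matches >= min_matches)
    )
    frame = pd.DataFrame(
        {
            "query_id": np.asarray(result.query_ids, dtype=object)[qi],
            "ref_id": np.asarray(result.ref_ids, dtype=object)[ri],
            "score": result.scores[qi, ri],
            "matches": result.matches[qi, ri],
        }
    )
    return frame.sort_values(
        ["score", "query_id", "ref_id"], ascending=[False, True, True]
    ).reset_index(drop=True)


def write_scores(
    result: ScoreResult,
    path: str,
    min_score: float = 0.0,
    min_matches: int = 0,
) -> int:
    """Write the thresholded hit list as TSV; returns the row count."""
    frame = hits_frame(result, min_score, min_matches)
    frame.to_csv(path, sep="\t", index=False, float_format="%.9f")
    return len(frame)


def write_matrix(result: ScoreResult, path: str) -> int:
    """Write all non-zero scores in coordinate form (row, col, score, matches)."""
    qi, ri = np.nonzero((result.scores != 0) | (result.matches != 0))
    frame = pd.DataFrame(
        {
            "row": qi,
            "col": ri,
            "score": result.scores[qi, ri],
            "matches": result.matches[qi, ri],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.9f")
    return len(frame)


def read_hits(path: str) -> pd.DataFrame:
    """Read a hit-list TSV produced by :func:`write_scores`."""
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in ("query_id", "ref_id") if c not in frame.columns]
    if missing:
        raise ValueError(f"hit list {path} lacks columns: {missing}")
    return frame
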