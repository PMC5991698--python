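"""Scoring an alignment against substances of known identity.

The error metric follows the mode-row convention: for each known substance
the aligned row holding most of its occurrences is its *mode row*, and any
occurrence assigned elsewhere counts as misaligned.  The error rate is the
ratio of misaligned to total retention times, over known substances only.
The metric is label-free: it measures concentration of each substance into
a single row, not which row that is.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .alignment import AlignmentResult
from .peak_io import RetentionMatrix, to_matrix

__all__ = [
    "KnownSubstanceMap",
    "EvaluationReport",
    "error_rate",
    "evaluation_report",
    "retention_deviation",
]

_ATOL = 1e-9


@dataclass
class KnownSubstanceMap:
    """Occurrences of identified substances, in raw input coordinates.

    ``occurrences[substance]`` lists ``(sample_id, retention_time)`` pairs
    as they appear in the *input* peak list; the per-sample shifts recorded
    in an :class:`AlignmentResult` are applied when locating them in the
    aligned matrix.
    """

    occurrences: dict[str, list[tuple[str, float]]] = field(default_factory=dict)

    @property
    def n_substances(self) -> int:
        return len(self.occurrences)

    def total_occurrences(self) -> int:
        return sum(len(v) for v in self.occurrences.values())

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        lines = ["substance_id\tsample_id\tretention_time"]
        for sub, occs in self.occurrences.items():
            for sample, rt in occs:
                lines.append(f"{sub}\t{sample}\t{rt!r}")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    @classmethod
    def read(cls, path: str | Path) -> "KnownSubstanceMap":
        occurrences: dict[str, list[tuple[str, float]]] = {}
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        for ln in lines[1:]:
            if not ln.strip():
                continue
            sub, sample, rt = ln.split("\t")
            occurrences.setdefault(sub, []).append((sample, float(rt)))
        return cls(occurrences)


@dataclass
class EvaluationReport:
    rate: float
    total: int                 # occurrences present in the final matrix
    misaligned: int
    removed: int               # occurrences deleted by blank/singleton filters
    per_substance: pd.DataFrame

    def __str__(self) -> str:
        return (f"alignment error rate: {self.rate:.4f} "
                f"({self.misaligned}/{self.total} misaligned, "
                f"{self.removed} removed by filters)")


def _locate(matrix: RetentionMatrix, sample: str, rt: float) -> Optional[int]:
    """Row index of the cell holding ``rt`` for ``sample``, or None."""
    try:
        col = matrix.sample_ids.index(sample)
    except ValueError:
        return None
    hits = np.nonzero(np.abs(matrix.rt[:, col] - rt) <= _ATOL)[0]
    return int(hits[0]) if hits.size else None


def _locate_occurrences(result: AlignmentResult, known: KnownSubstanceMap,
                        ) -> tuple[dict[str, list[int]], int]:
    """Map each substance to the final-matrix rows of its occurrences.

    Occurrences deleted by the blank/singleton filters are counted
    separately; an occurrence found nowhere signals a bookkeeping bug and
    raises ``LookupError``.
    """
    removed_matrices = [m for m in (result.removed_blank_rows,
                                    result.removed_singleton_rows)
                        if m is not None]
    rows: dict[str, list[int]] = {}
    removed = 0
    for sub, occs in known.occurrences.items():
        sub_rows: list[int] = []
        for sample, rt in occs:
            shifted = rt + result.shifts.get(sample, 0.0)
            row = _locate(result.matrix, sample, shifted)
            if row is not None:
                sub_rows.append(row)
                continue
            if any(_locate(m, sample, shifted) is not None
                   for m in removed_matrices):
                removed += 1
                continue
            raise LookupError(
                f"occurrence of {sub!r} in sample {sample!r} at {rt} min "
                "not found in the aligned matrix or the filter logs")
        rows[sub] = sub_rows
    return rows, removed


def _mode_row(row_list: list[int]) -> int:
    """Row holding most occurrences; ties go to the earlier row."""
    counts = Counter(row_list)
    return min(counts, key=lambda r: (-counts[r], r))


def evaluation_report(result: AlignmentResult,
                      known: KnownSubstanceMap) -> EvaluationReport:
    """Full mode-row evaluation of an alignment against known substances."""
    rows, removed = _locate_occurrences(result, known)
    records = []
    total = 0
    misaligned = 0
    for sub, sub_rows in rows.items():
        if not sub_rows:
            records.append((sub, 0, np.nan, 0))
            continue
        mode = _mode_row(sub_rows)
        mis = sum(1 for r in sub_rows if r != mode)
        total += len(sub_rows)
        misaligned += mis
        records.append((sub, len(sub_rows), mode, mis))
    per_substance = pd.DataFrame(
        records, columns=["substance", "n", "mode_row", "misaligned"]
    ).set_index("substance")
    rate = misaligned / total if total else 0.0
    return EvaluationReport(rate=rate, total=total, misaligned=misaligned,
                            removed=removed, per_substance=per_substance)


def error_rate(result: AlignmentResult, known: KnownSubstanceMap) -> float:
    """Mode-row alignment error rate in ``[0, 1]`` over known substances."""
    return evaluation_report(result, known).rate


def retention_deviation(result: AlignmentResult,
                        known: KnownSubstanceMap) -> pd.DataFrame:
    """Per-substance row-offset deviation, aligned versus unaligned.

    For each known substance the mean absolute offset (in rows) of its
    occurrences from their mode row is computed in the final matrix and in
    the initial, unaligned matrix; effective alignment should reduce it.
    Occurrences removed by filters are excluded from both sides.
    """
    aligned_rows, _ = _locate_occurrences(result, known)
    raw_matrix = to_matrix(result.input_snapshot)
    records = []
    for sub, occs in known.occurrences.items():
        rows_aligned = aligned_rows[sub]
        rows_raw: list[int] = []
        for sample, rt in occs:
            shifted = rt + result.shifts.get(sample, 0.0)
            if _locate(result.matrix, sample, shifted) is None:
                continue  # filtered out; keep the two sides comparable
            row = _locate(raw_matrix, sample, rt)
            if row is None:  # pragma: no cover - inconsistent truth file
                raise LookupError(
                    f"occurrence of {sub!r} in sample {sample!r} at {rt} min "
                    "not found in the input peak list")
            rows_raw.append(row)
        def _dev(rows: list[int]) -> float:
            if not rows:
                return np.nan
            mode = _mode_row(rows)
            return float(np.mean([abs(r - mode) for r in rows]))
        dev_aligned = _dev(rows_aligned)
        dev_raw = _dev(rows_raw)
        records.append((sub, len(rows_aligned), dev_aligned, dev_raw,
                        dev_aligned - dev_raw))
    return pd.DataFrame(
        records,
        columns=["substance", "n", "aligned_deviation", "raw_deviation",
                 "change"],
    ).set_index("substance")
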