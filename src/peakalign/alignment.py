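"""The three-step retention-time alignment algorithm for peak lists.

Step 1 (*full alignment*) removes systematic, sample-wide drift: every
sample's retention times are translated by the linear shift, found on a
fixed grid, that minimises the summed nearest-neighbour deviation against a
reference chromatogram.  Step 2 (*partial alignment*) sorts individual
peaks into rows of a retention matrix by comparing each peak with the
running mean of the peaks already placed in its row; peaks deviating by
more than a threshold ``a`` (``max_diff_peak2mean``, minutes) are moved to
the next row.  Step 3 merges adjacent rows whose mean retention times
differ by less than ``b`` (``min_diff_peak2peak``, minutes) whenever no
sample holds a peak in both rows, so the merge loses no information.

Optional filters then delete substances shared with negative-control
(blank) samples and substances present in only a single sample.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .peak_io import (PeakDataset, RetentionMatrix, ValidationFailure,
                      check_input, to_matrix)

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "RetentionMatrix",
    "select_reference",
    "score_shift",
    "best_shift",
    "full_align",
    "partial_align",
    "merge_rows",
    "remove_blanks",
    "remove_singletons",
    "align",
]


@dataclass
class AlignmentParams:
    """Tuning parameters of the alignment.

    All thresholds are in minutes.  ``max_linear_shift`` is the half-width
    of the shift window searched during full alignment; ``shift_step`` its
    grid interval.  ``max_diff_peak2mean`` (*a*) bounds the deviation of a
    focal peak from the row mean during partial alignment, and
    ``min_diff_peak2peak`` (*b*) is the expected minimum retention-time
    difference between distinct substances, below which adjacent rows are
    merged.  Defaults follow common practice for capillary GC runs.
    """

    max_linear_shift: float = 0.05
    max_diff_peak2mean: float = 0.02
    min_diff_peak2peak: float = 0.08
    shift_step: float = 0.01
    reference: Optional[str] = None  # None = automatic selection
    blanks: tuple[str, ...] = ()
    delete_single_peak: bool = False

    def __post_init__(self) -> None:
        if self.max_linear_shift < 0 or self.max_diff_peak2mean < 0 \
                or self.min_diff_peak2peak < 0:
            raise ValueError("alignment thresholds must be >= 0")
        if self.shift_step <= 0:
            raise ValueError("shift_step must be > 0")
        self.blanks = tuple(self.blanks)
        if self.max_diff_peak2mean >= self.min_diff_peak2peak:
            warnings.warn(
                "max_diff_peak2mean >= min_diff_peak2peak: split substances "
                "cannot be re-merged and error rates typically increase",
                UserWarning, stacklevel=2)

    def as_dict(self) -> dict:
        return {
            "max_linear_shift": self.max_linear_shift,
            "max_diff_peak2mean": self.max_diff_peak2mean,
            "min_diff_peak2peak": self.min_diff_peak2peak,
            "shift_step": self.shift_step,
            "reference": self.reference,
            "blanks": list(self.blanks),
            "delete_single_peak": self.delete_single_peak,
        }


@dataclass
class AlignmentResult:
    """Aligned matrix plus the provenance of every decision taken."""

    matrix: RetentionMatrix
    input_snapshot: PeakDataset
    reference: str
    shifts: dict[str, float]
    params: AlignmentParams
    removed_blank_rows: Optional[RetentionMatrix] = None
    removed_singleton_rows: Optional[RetentionMatrix] = None
    log: list[dict] = field(default_factory=list)

    @property
    def n_substances(self) -> int:
        return self.matrix.n_rows

    def summary(self) -> str:
        """Plain-text account of the run: call, defaults, steps, counts."""
        lines = ["peak alignment summary", "=" * 22, "", "parameters:"]
        for k, v in self.params.as_dict().items():
            lines.append(f"  {k} = {v!r}")
        lines += ["", f"reference sample: {self.reference}", "", "shifts (min):"]
        for s, sh in self.shifts.items():
            lines.append(f"  {s}: {sh:+.2f}")
        lines += ["", "steps:"]
        for entry in self.log:
            detail = ", ".join(f"{k}={v}" for k, v in entry.items()
                               if k != "step")
            lines.append(f"  {entry['step']}: {detail}")
        lines += ["", f"aligned substances: {self.n_substances}"]
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# step 1: reference selection and linear-shift full alignment
# ---------------------------------------------------------------------------

def _nearest_deviation(ref: np.ndarray, query: np.ndarray) -> np.ndarray:
    """For each reference peak, distance to the nearest query peak."""
    return np.abs(ref[:, None] - query[None, :]).min(axis=1)


def select_reference(dataset: PeakDataset,
                     blanks: Sequence[str] = ()) -> str:
    """Automatically pick the sample most similar on average to the others.

    For each candidate the mean nearest-neighbour deviation against every
    other sample is computed (normalised by the candidate's peak count, so
    samples with few peaks gain no advantage), and the candidate with the
    lowest median per-pair deviation wins.  Blank samples are excluded.
    Ties go to the sample with more peaks, then the lexicographically
    smaller identifier.
    """
    excluded = set(blanks) | set(dataset.blanks)
    candidates = [s for s in dataset.sample_ids
                  if s not in excluded and dataset.n_peaks(s) > 0]
    if len(candidates) < 2:
        raise ValueError("reference selection needs at least two non-blank, "
                         "non-empty samples")
    rts = {s: dataset.retention_times(s) for s in candidates}
    scores: dict[str, float] = {}
    for ref in candidates:
        pair_scores = [float(_nearest_deviation(rts[ref], rts[q]).mean())
                       for q in candidates if q != ref]
        scores[ref] = statistics.median(pair_scores)
    return min(candidates,
               key=lambda s: (scores[s], -dataset.n_peaks(s), s))


def score_shift(ref_rts: np.ndarray, query_rts: np.ndarray,
                shift: float) -> float:
    """Summed deviation between each reference peak and its nearest query
    peak after translating the query by ``shift`` minutes.

    Converges to zero as homologous peaks overlap; peaks unique to either
    list behave independently and contribute little.
    """
    ref = np.asarray(ref_rts, dtype=float)
    query = np.asarray(query_rts, dtype=float)
    if ref.size == 0 or query.size == 0:
        raise ValueError("score_shift requires non-empty peak lists")
    return float(_nearest_deviation(ref, query + shift).sum())


def best_shift(ref_rts: np.ndarray, query_rts: np.ndarray,
               window: float = 0.05, step: float = 0.01) -> float:
    """Grid search for the linear shift minimising :func:`score_shift`.

    The grid spans ``[-window, +window]`` inclusive in steps of ``step``.
    Ties are broken towards the smallest absolute shift, then the more
    negative one, so identical samples are a fixed point.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if step <= 0:
        raise ValueError("step must be > 0")
    n = int(round(window / step))
    grid = step * np.arange(-n, n + 1)
    if not np.isclose(grid[-1], window) and window > 0:
        grid = np.unique(np.concatenate([grid, [-window, window]]))
    best = min(((score_shift(ref_rts, query_rts, s), abs(s), s)
                for s in grid))
    return float(best[2]) + 0.0  # normalise -0.0


def full_align(dataset: PeakDataset, reference: str,
               window: float = 0.05, step: float = 0.01,
               ) -> tuple[PeakDataset, dict[str, float]]:
    """Translate every sample by its best linear shift against a reference.

    The reference is left untouched; intensity measures are carried along
    unchanged.  Returns the shifted dataset and the applied shift per
    sample (0 for the reference and for empty samples).
    """
    if reference not in dataset.sample_ids:
        raise ValueError(f"unknown reference sample {reference!r}")
    ref_rts = dataset.retention_times(reference)
    shifted = dataset.copy()
    shifts: dict[str, float] = {}
    for sid in dataset.sample_ids:
        if sid == reference or dataset.n_peaks(sid) == 0:
            shifts[sid] = 0.0
            continue
        s = best_shift(ref_rts, dataset.retention_times(sid), window, step)
        shifts[sid] = s
        shifted.peaks[sid][dataset.rt_variable] = [
            rt + s for rt in dataset.peaks[sid][dataset.rt_variable]]
    return shifted, shifts


# ---------------------------------------------------------------------------
# step 2: partial alignment
# ---------------------------------------------------------------------------

def partial_align(matrix: RetentionMatrix, a: float) -> RetentionMatrix:
    """Sort peaks into substance rows by a single top-to-bottom pass.

    Cells of a row are visited left to right; zeros are skipped and never
    enter the running mean.  A focal peak larger than the mean of the
    previous peaks in its row plus ``a`` is moved to the next row (together
    with everything below it in its column, preserving column order); a
    focal peak smaller than the mean minus ``a`` instead demotes all
    previous peaks of the row.  New rows grow at the bottom as needed and
    are themselves processed until the end of the matrix.
    """
    if a < 0:
        raise ValueError("max_diff_peak2mean must be >= 0")
    n0, nc = matrix.rt.shape
    capacity = n0 + matrix.total_peaks() + 1
    rt = np.zeros((capacity, nc))
    rt[:n0] = matrix.rt
    meas = {}
    for k, v in matrix.measures.items():
        arr = np.zeros((capacity, nc))
        arr[:n0] = v
        meas[k] = arr
    # last occupied row per column
    last = np.full(nc, -1, dtype=int)
    for c in range(nc):
        nz = np.nonzero(rt[:n0, c])[0]
        if nz.size:
            last[c] = int(nz[-1])

    def push_down(c: int, r: int) -> None:
        # move the column tail starting at row r down one row
        L = last[c]
        rt[r + 1:L + 2, c] = rt[r:L + 1, c]
        rt[r, c] = 0.0
        for arr in meas.values():
            arr[r + 1:L + 2, c] = arr[r:L + 1, c]
            arr[r, c] = 0.0
        last[c] = L + 1

    r = 0
    while r <= last.max(initial=-1):
        prev_cols: list[int] = []
        prev_sum = 0.0
        for c in range(nc):
            v = rt[r, c]
            if v == 0.0:
                continue
            if not prev_cols:
                prev_cols.append(c)
                prev_sum = v
                continue
            mu = prev_sum / len(prev_cols)
            if v > mu + a:
                push_down(c, r)
            elif v < mu - a:
                for pc in prev_cols:
                    push_down(pc, r)
                prev_cols = [c]
                prev_sum = v
            else:
                prev_cols.append(c)
                prev_sum += v
        r += 1

    n_rows = int(last.max(initial=-1)) + 1
    return RetentionMatrix(rt=rt[:n_rows],
                           measures={k: v[:n_rows] for k, v in meas.items()},
                           sample_ids=list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# step 3: merging rows
# ---------------------------------------------------------------------------

def merge_rows(matrix: RetentionMatrix, b: float) -> RetentionMatrix:
    """Merge adjacent rows representing one substance, without losing data.

    A pair of adjacent rows is merged iff their mean retention times differ
    by less than ``b`` *and* no sample holds a peak in both rows; the merge
    then simply takes each sample's unique peak of the pair.  Scanning
    repeats until a full pass performs no merge; all-zero rows are deleted.
    """
    if b < 0:
        raise ValueError("min_diff_peak2peak must be >= 0")
    rt = matrix.rt.copy()
    meas = {k: v.copy() for k, v in matrix.measures.items()}
    nonzero = (rt > 0).any(axis=1)
    rt = rt[nonzero]
    meas = {k: v[nonzero] for k, v in meas.items()}

    changed = True
    while changed:
        changed = False
        r = 0
        while r + 1 < rt.shape[0]:
            top, bottom = rt[r], rt[r + 1]
            overlap = bool(((top > 0) & (bottom > 0)).any())
            mean_top = top[top > 0].mean()
            mean_bottom = bottom[bottom > 0].mean()
            if not overlap and abs(mean_top - mean_bottom) < b:
                rt[r] = top + bottom
                for arr in meas.values():
                    arr[r] = arr[r] + arr[r + 1]
                rt = np.delete(rt, r + 1, axis=0)
                meas = {k: np.delete(v, r + 1, axis=0) for k, v in meas.items()}
                changed = True
            else:
                r += 1
    return RetentionMatrix(rt=rt, measures=meas,
                           sample_ids=list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def remove_blanks(matrix: RetentionMatrix, blanks: Sequence[str],
                  ) -> tuple[RetentionMatrix, RetentionMatrix]:
    """Delete substances shared with negative controls, then the controls.

    Returns ``(kept, removed)``; the removed rows retain all columns
    (including the blanks) so deletions remain traceable.
    """
    unknown = [s for s in blanks if s not in matrix.sample_ids]
    if unknown:
        raise ValueError(f"unknown blank sample(s): {unknown}")
    blank_cols = [matrix.sample_ids.index(s) for s in blanks]
    shared = (matrix.rt[:, blank_cols] > 0).any(axis=1)
    removed = matrix.take_rows(np.nonzero(shared)[0])
    kept = matrix.take_rows(np.nonzero(~shared)[0])
    keep_cols = [j for j, s in enumerate(matrix.sample_ids) if s not in blanks]
    kept = RetentionMatrix(
        rt=kept.rt[:, keep_cols],
        measures={k: v[:, keep_cols] for k, v in kept.measures.items()},
        sample_ids=[matrix.sample_ids[j] for j in keep_cols])
    return kept, removed


def remove_singletons(matrix: RetentionMatrix,
                      ) -> tuple[RetentionMatrix, RetentionMatrix]:
    """Delete substances present in exactly one sample (uninformative for
    similarity analyses).  Returns ``(kept, removed)``."""
    prevalence = matrix.prevalence()
    singleton = prevalence == 1
    return (matrix.take_rows(np.nonzero(~singleton)[0]),
            matrix.take_rows(np.nonzero(singleton)[0]))


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def align(dataset: PeakDataset, params: AlignmentParams | None = None,
          ) -> AlignmentResult:
    """Run the full pipeline: validate, full-align, partial-align, merge,
    filter.  Deterministic for fixed input and parameters."""
    params = params or AlignmentParams()
    report = check_input(dataset)
    if not report.ok:
        raise ValidationFailure(
            "input failed validation; fix the reported errors first:\n"
            + str(report))

    blanks = list(params.blanks) or list(dataset.blanks)
    unknown = [b for b in blanks if b not in dataset.sample_ids]
    if unknown:
        raise ValueError(f"unknown blank sample(s): {unknown}")

    log: list[dict] = []
    n_input_peaks = dataset.total_peaks()
    non_blank = [s for s in dataset.sample_ids if s not in blanks]

    if params.reference is not None:
        if params.reference not in dataset.sample_ids:
            raise ValueError(f"unknown reference sample {params.reference!r}")
        reference = params.reference
    elif len(non_blank) >= 2:
        reference = select_reference(dataset, blanks=blanks)
    else:
        reference = non_blank[0] if non_blank else dataset.sample_ids[0]
    log.append({"step": "select_reference", "reference": reference})

    if len(dataset.sample_ids) > 1:
        shifted, shifts = full_align(dataset, reference,
                                     window=params.max_linear_shift,
                                     step=params.shift_step)
    else:
        shifted, shifts = dataset.copy(), {dataset.sample_ids[0]: 0.0}
    log.append({"step": "full_align",
                "max_abs_shift": max((abs(v) for v in shifts.values()),
                                     default=0.0)})

    matrix = to_matrix(shifted)
    matrix = partial_align(matrix, params.max_diff_peak2mean)
    log.append({"step": "partial_align", "rows": matrix.n_rows})
    matrix = merge_rows(matrix, params.min_diff_peak2peak)
    log.append({"step": "merge_rows", "rows": matrix.n_rows})

    if matrix.total_peaks() != n_input_peaks:  # pragma: no cover - guard
        raise AssertionError("peak conservation violated before filtering")

    removed_blank = None
    if blanks:
        matrix, removed_blank = remove_blanks(matrix, blanks)
        log.append({"step": "remove_blanks",
                    "removed_rows": removed_blank.n_rows,
                    "blanks": blanks})
    removed_single = None
    if params.delete_single_peak:
        matrix, removed_single = remove_singletons(matrix)
        log.append({"step": "remove_singletons",
                    "removed_rows": removed_single.n_rows})

    return AlignmentResult(matrix=matrix, input_snapshot=dataset.copy(),
                           reference=reference, shifts=shifts, params=params,
                           removed_blank_rows=removed_blank,
                           removed_singleton_rows=removed_single, log=log)
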