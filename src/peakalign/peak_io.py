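"""Reading, validating and writing GC-FID peak-list files.

The on-disk dialect carries two header rows followed by per-sample column
blocks:

* row 1 — sample identifiers, one per block (padding cells may be empty);
* row 2 — variable names (retention time plus any intensity measures),
  either repeated once per sample block or written once and applied
  cyclically;
* body — one column per (sample, variable); samples with fewer peaks are
  padded with empty cells or zeros, both of which encode absence.

Retention times are in minutes throughout.  The decimal separator is ``.``;
the field separator is configurable (tab by default).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PeakDataset",
    "RetentionMatrix",
    "ValidationReport",
    "ValidationFailure",
    "Issue",
    "read_peak_list",
    "write_peak_list",
    "check_input",
    "to_matrix",
    "write_aligned",
    "save_result",
    "load_result",
]

_NAME_RE = re.compile(r"^[A-Za-z0-9_]+$")


class ValidationFailure(ValueError):
    """Raised when a dataset with validation errors is passed to alignment."""


@dataclass
class Issue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    location: str = ""


@dataclass
class ValidationReport:
    issues: list[Issue] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not any(i.severity == "error" for i in self.issues)

    @property
    def errors(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[Issue]:
        return [i for i in self.issues if i.severity == "warning"]

    def __str__(self) -> str:
        if not self.issues:
            return "input OK: no issues found"
        lines = [f"{i.severity.upper():7s} [{i.code}] {i.message}"
                 + (f" ({i.location})" if i.location else "")
                 for i in self.issues]
        status = "PASS" if self.ok else "FAIL"
        return "\n".join(lines + [f"input check: {status}"])


@dataclass
class PeakDataset:
    """An ordered collection of per-sample peak tables.

    ``peaks[sample][variable]`` is the list of values of one variable for
    one sample, one entry per integrated peak.  All variables of a sample
    have equal length; retention times are expected sorted ascending.
    """

    sample_ids: list[str]
    variable_names: list[str]
    peaks: dict[str, dict[str, list[float]]]
    rt_variable: str = "time"
    blanks: list[str] = field(default_factory=list)

    @property
    def measure_variables(self) -> list[str]:
        return [v for v in self.variable_names if v != self.rt_variable]

    def n_peaks(self, sample: str) -> int:
        return len(self.peaks[sample][self.rt_variable])

    def retention_times(self, sample: str) -> np.ndarray:
        return np.asarray(self.peaks[sample][self.rt_variable], dtype=float)

    def total_peaks(self) -> int:
        return sum(self.n_peaks(s) for s in self.sample_ids)

    def copy(self) -> "PeakDataset":
        return PeakDataset(
            sample_ids=list(self.sample_ids),
            variable_names=list(self.variable_names),
            peaks={s: {v: list(vals) for v, vals in pv.items()}
                   for s, pv in self.peaks.items()},
            rt_variable=self.rt_variable,
            blanks=list(self.blanks),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeakDataset):
            return NotImplemented
        return (self.sample_ids == other.sample_ids
                and self.variable_names == other.variable_names
                and self.rt_variable == other.rt_variable
                and self.peaks == other.peaks)


@dataclass
class RetentionMatrix:
    """Substances x samples matrix of retention times; 0 encodes absence.

    ``measures[variable]`` carries each intensity variable at the same
    positions as ``rt``.  Within each sample column the non-zero retention
    times are strictly increasing down the rows.
    """

    rt: np.ndarray  # shape (n_rows, n_samples), float, 0 = absent
    measures: dict[str, np.ndarray]
    sample_ids: list[str]

    @property
    def n_rows(self) -> int:
        return int(self.rt.shape[0])

    @property
    def n_samples(self) -> int:
        return int(self.rt.shape[1])

    def present(self) -> np.ndarray:
        return self.rt > 0

    def row_means(self) -> np.ndarray:
        """Mean retention time per row over non-zero cells (NaN if empty)."""
        present = self.rt > 0
        counts = present.sum(axis=1)
        sums = self.rt.sum(axis=1)
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    def prevalence(self) -> np.ndarray:
        """Number of samples sharing each row's substance."""
        return (self.rt > 0).sum(axis=1)

    def peaks_per_sample(self) -> np.ndarray:
        return (self.rt > 0).sum(axis=0)

    def total_peaks(self) -> int:
        return int((self.rt > 0).sum())

    def copy(self) -> "RetentionMatrix":
        return RetentionMatrix(
            rt=self.rt.copy(),
            measures={k: v.copy() for k, v in self.measures.items()},
            sample_ids=list(self.sample_ids),
        )

    def take_rows(self, rows: np.ndarray) -> "RetentionMatrix":
        return RetentionMatrix(
            rt=self.rt[rows],
            measures={k: v[rows] for k, v in self.measures.items()},
            sample_ids=list(self.sample_ids),
        )


def _split_line(line: str, sep: str) -> list[str]:
    return [c.strip() for c in line.rstrip("\r\n").split(sep)]


def read_peak_list(path: str | Path, rt_col_name: str = "time",
                   sep: str = "\t") -> PeakDataset:
    """Read a two-header-row peak-list file into a :class:`PeakDataset`.

    Trailing empty cells (and explicit zeros) in a sample's retention-time
    column are treated as padding and dropped, so samples may hold different
    numbers of peaks.  Peaks are returned sorted by retention time.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such peak list: {path}")
    lines = path.read_text(encoding="utf-8").splitlines()
    lines = [ln for ln in lines if ln.strip() != ""]
    if len(lines) < 2:
        raise ValueError(f"{path}: expected two header rows")

    header1 = _split_line(lines[0], sep)
    header2 = _split_line(lines[1], sep)
    sample_ids = [c for c in header1 if c != ""]
    if not sample_ids:
        raise ValueError(f"{path}: first row holds no sample identifiers")
    n_samples = len(sample_ids)

    var_cells = [c for c in header2 if c != ""]
    if not var_cells:
        raise ValueError(f"{path}: second row holds no variable names")
    # Variable names may be repeated once per sample block, or given once.
    k, rem = divmod(len(var_cells), n_samples)
    if n_samples > 1 and rem == 0 and k >= 1 and var_cells == var_cells[:k] * n_samples:
        variable_names = var_cells[:k]
    else:
        variable_names = var_cells
    if rt_col_name not in variable_names:
        raise ValueError(
            f"{path}: variable containing peak retention times "
            f"{rt_col_name!r} not found among {variable_names}")
    n_vars = len(variable_names)
    rt_idx = variable_names.index(rt_col_name)

    body = [_split_line(ln, sep) for ln in lines[2:]]
    peaks: dict[str, dict[str, list[float]]] = {}
    for si, sid in enumerate(sample_ids):
        cols: dict[str, list[float]] = {v: [] for v in variable_names}
        for row in body:
            block = row[si * n_vars:(si + 1) * n_vars]
            block += [""] * (n_vars - len(block))
            rt_cell = block[rt_idx]
            vals: list[float | None] = []
            for cell in block:
                if cell == "":
                    vals.append(None)
                    continue
                try:
                    vals.append(float(cell))
                except ValueError:
                    raise ValueError(
                        f"{path}: non-numeric cell {cell!r} in sample {sid}")
            rt_val = vals[rt_idx]
            if rt_val is None or rt_val == 0.0:
                if any(v not in (None, 0.0) for v in vals):
                    raise ValueError(
                        f"{path}: sample {sid} has a measure value without "
                        f"a retention time (ragged variable lengths)")
                continue  # padding row for this sample
            for v, val in zip(variable_names, vals):
                cols[v].append(math.nan if val is None else val)
        # sort by retention time, carrying measures along
        order = np.argsort(np.asarray(cols[rt_col_name]), kind="stable")
        peaks[sid] = {v: [cols[v][i] for i in order] for v in variable_names}

    return PeakDataset(sample_ids=sample_ids, variable_names=variable_names,
                       peaks=peaks, rt_variable=rt_col_name)


def write_peak_list(dataset: PeakDataset, path: str | Path,
                    sep: str = "\t") -> Path:
    """Write a dataset back to the two-header-row dialect (lossless)."""
    path = Path(path)
    n_vars = len(dataset.variable_names)
    header1: list[str] = []
    header2: list[str] = []
    for sid in dataset.sample_ids:
        header1 += [sid] + [""] * (n_vars - 1)
        header2 += list(dataset.variable_names)
    max_peaks = max((dataset.n_peaks(s) for s in dataset.sample_ids), default=0)
    rows = []
    for r in range(max_peaks):
        cells: list[str] = []
        for sid in dataset.sample_ids:
            for v in dataset.variable_names:
                vals = dataset.peaks[sid][v]
                cells.append(repr(vals[r]) if r < len(vals) else "")
        rows.append(cells)
    lines = [sep.join(header1), sep.join(header2)]
    lines += [sep.join(r) for r in rows]
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def check_input(dataset: PeakDataset) -> ValidationReport:
    """Interrogate a dataset for typical formatting errors and missing data.

    Problems are reported, never raised; alignment refuses to run on a
    report containing errors.
    """
    report = ValidationReport()
    add = report.issues.append

    seen: set[str] = set()
    for sid in dataset.sample_ids:
        if sid in seen:
            add(Issue("error", "duplicate_sample_id",
                      f"sample name {sid!r} occurs more than once", sid))
        seen.add(sid)
        if not _NAME_RE.match(sid):
            add(Issue("warning", "invalid_sample_name",
                      f"sample name {sid!r} contains characters outside "
                      "letters, digits and underscore", sid))

    if dataset.rt_variable not in dataset.variable_names:
        add(Issue("error", "rt_variable_missing",
                  f"retention-time variable {dataset.rt_variable!r} is not "
                  f"among the declared variables {dataset.variable_names}"))
        return report

    for sid in dataset.sample_ids:
        pv = dataset.peaks.get(sid)
        if pv is None:
            add(Issue("error", "missing_sample_block",
                      f"sample {sid!r} has no peak table", sid))
            continue
        lengths = {v: len(vals) for v, vals in pv.items()}
        if len(set(lengths.values())) > 1:
            add(Issue("error", "ragged_lengths",
                      f"sample {sid!r} variables differ in length: {lengths}",
                      sid))
            continue
        rts = pv[dataset.rt_variable]
        if not rts:
            add(Issue("warning", "empty_sample",
                      f"sample {sid!r} contains no peaks", sid))
            continue
        for v, vals in pv.items():
            if any(x is None or (isinstance(x, float) and math.isnan(x))
                   for x in vals):
                add(Issue("error", "missing_value",
                          f"sample {sid!r} variable {v!r} has missing/NA "
                          "cells", sid))
        finite = [x for x in rts
                  if x is not None and not math.isnan(float(x))]
        if any(x <= 0 for x in finite):
            add(Issue("error", "nonpositive_rt",
                      f"sample {sid!r} has non-positive retention times", sid))
        if any(b < a for a, b in zip(finite, finite[1:])):
            add(Issue("warning", "unsorted_rt",
                      f"retention times of sample {sid!r} are not sorted "
                      "ascending", sid))
        if len(set(finite)) < len(finite):
            add(Issue("warning", "duplicate_rt",
                      f"sample {sid!r} has duplicated retention times", sid))

    if not (set(dataset.blanks) <= set(dataset.sample_ids)):
        unknown = sorted(set(dataset.blanks) - set(dataset.sample_ids))
        add(Issue("error", "unknown_blank",
                  f"blank sample(s) {unknown} not present in the dataset"))
    return report


def to_matrix(dataset: PeakDataset) -> RetentionMatrix:
    """Convert a dataset to the initial retention-matrix working format.

    Each sample's peaks occupy the leading rows of its column in ascending
    retention-time order, padded below with zeros; intensity variables sit
    at the same positions.
    """
    n_rows = max((dataset.n_peaks(s) for s in dataset.sample_ids), default=0)
    n_samples = len(dataset.sample_ids)
    rt = np.zeros((n_rows, n_samples))
    measures = {v: np.zeros((n_rows, n_samples))
                for v in dataset.measure_variables}
    for j, sid in enumerate(dataset.sample_ids):
        rts = dataset.retention_times(sid)
        order = np.argsort(rts, kind="stable")
        rt[:len(rts), j] = rts[order]
        for v in dataset.measure_variables:
            vals = np.asarray(dataset.peaks[sid][v], dtype=float)
            measures[v][:len(vals), j] = vals[order]
    return RetentionMatrix(rt=rt, measures=measures,
                           sample_ids=list(dataset.sample_ids))


def _matrix_frame(matrix: RetentionMatrix, values: np.ndarray):
    import pandas as pd

    frame = pd.DataFrame(values, columns=matrix.sample_ids)
    frame.insert(0, "mean_RT", matrix.row_means())
    return frame


def write_aligned(result, outdir: str | Path) -> Path:
    """Write an alignment result as tab-delimited tables plus a run summary.

    Produces ``aligned_rt.tsv`` (the retention-time matrix with a mean-RT
    row label), one ``aligned_<variable>.tsv`` per intensity measure, and
    ``summary.txt`` restating the full parameterisation of the run,
    including defaults the user did not alter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix = result.matrix
    _matrix_frame(matrix, matrix.rt).to_csv(
        outdir / "aligned_rt.tsv", sep="\t", index=False)
    for v, arr in matrix.measures.items():
        _matrix_frame(matrix, arr).to_csv(
            outdir / f"aligned_{v}.tsv", sep="\t", index=False)
    (outdir / "summary.txt").write_text(result.summary(), encoding="utf-8")
    return outdir


def _matrix_to_json(matrix: RetentionMatrix | None):
    if matrix is None:
        return None
    return {"sample_ids": list(matrix.sample_ids),
            "rt": matrix.rt.tolist(),
            "measures": {k: v.tolist() for k, v in matrix.measures.items()}}


def _matrix_from_json(obj) -> RetentionMatrix | None:
    if obj is None:
        return None
    n_cols = len(obj["sample_ids"])
    rt = np.asarray(obj["rt"], dtype=float).reshape(-1, n_cols)
    measures = {k: np.asarray(v, dtype=float).reshape(-1, n_cols)
                for k, v in obj["measures"].items()}
    return RetentionMatrix(rt=rt, measures=measures,
                           sample_ids=list(obj["sample_ids"]))


def save_result(result, outdir: str | Path) -> Path:
    """Persist a full alignment result to a directory.

    Besides the :func:`write_aligned` tables and summary this stores a
    machine-readable run log (reference, shifts, parameters, filter
    deletions) and a copy of the input peak list, so the result can be
    reloaded losslessly for evaluation or normalisation.
    """
    import json

    outdir = Path(outdir)
    write_aligned(result, outdir)
    write_peak_list(result.input_snapshot, outdir / "input_snapshot.txt")
    payload = {
        "reference": result.reference,
        "shifts": result.shifts,
        "params": result.params.as_dict(),
        "rt_variable": result.input_snapshot.rt_variable,
        "input_blanks": list(result.input_snapshot.blanks),
        "log": result.log,
        "matrix_sample_ids": list(result.matrix.sample_ids),
        "measure_variables": sorted(result.matrix.measures),
        "removed_blank_rows": _matrix_to_json(result.removed_blank_rows),
        "removed_singleton_rows": _matrix_to_json(
            result.removed_singleton_rows),
    }
    (outdir / "run_log.json").write_text(json.dumps(payload, indent=2),
                                         encoding="utf-8")
    return outdir


def load_result(outdir: str | Path):
    """Reconstruct an :class:`~peakalign.alignment.AlignmentResult` from a
    directory written by :func:`save_result`."""
    import json

    import pandas as pd

    from .alignment import AlignmentParams, AlignmentResult

    outdir = Path(outdir)
    payload = json.loads((outdir / "run_log.json").read_text(encoding="utf-8"))
    sample_ids = payload["matrix_sample_ids"]

    def _read_table(path: Path) -> np.ndarray:
        frame = pd.read_csv(path, sep="\t")
        return frame[sample_ids].to_numpy(dtype=float)

    rt = _read_table(outdir / "aligned_rt.tsv")
    measures = {v: _read_table(outdir / f"aligned_{v}.tsv")
                for v in payload["measure_variables"]}
    matrix = RetentionMatrix(rt=rt, measures=measures,
                             sample_ids=list(sample_ids))
    params_dict = dict(payload["params"])
    params_dict["blanks"] = tuple(params_dict.get("blanks", ()))
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", UserWarning)
        params = AlignmentParams(**params_dict)
    snapshot = read_peak_list(outdir / "input_snapshot.txt",
                              rt_col_name=payload["rt_variable"])
    snapshot.blanks = list(payload.get("input_blanks", []))
    return AlignmentResult(
        matrix=matrix,
        input_snapshot=snapshot,
        reference=payload["reference"],
        shifts={k: float(v) for k, v in payload["shifts"].items()},
        params=params,
        removed_blank_rows=_matrix_from_json(payload["removed_blank_rows"]),
        removed_singleton_rows=_matrix_from_json(
            payload["removed_singleton_rows"]),
        log=payload["log"],
    )
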