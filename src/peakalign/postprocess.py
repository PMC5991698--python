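"""Normalisation of aligned abundance measures to relative concentrations.

Sample concentration differs between injections for reasons unrelated to
composition, so downstream similarity analyses work on the relative
concentration of each substance within its sample, expressed in percent.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignmentResult

__all__ = ["normalise_peaks", "write_abundance_table"]


def normalise_peaks(result: AlignmentResult, conc_col_name: str,
                    rt_digits: int = 2) -> pd.DataFrame:
    """Convert an abundance measure to percent-per-sample relative values.

    Returns a samples x substances table (community-matrix orientation,
    ready for ordination tools); column labels are the substances' mean
    retention times formatted to ``rt_digits`` decimals.  Each sample row
    sums to 100 unless the sample carries no abundance at all, in which
    case it is all zeros.
    """
    matrix = result.matrix
    if conc_col_name not in matrix.measures:
        raise ValueError(
            f"unknown abundance variable {conc_col_name!r}; available: "
            f"{sorted(matrix.measures)}")
    values = matrix.measures[conc_col_name]
    if (values < 0).any():
        raise ValueError("negative abundance values cannot be normalised")
    totals = values.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(totals > 0, 100.0 * values / totals, 0.0)
    labels = [f"{m:.{rt_digits}f}" for m in matrix.row_means()]
    return pd.DataFrame(rel.T, index=list(matrix.sample_ids), columns=labels)


def write_abundance_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the normalised table as tab-delimited text."""
    path = Path(path)
    table.to_csv(path, sep="\t", index=True, index_label="sample")
    return path
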