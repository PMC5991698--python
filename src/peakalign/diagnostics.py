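"""Diagnostic summaries of an alignment, as plain data tables.

Computes the quantities behind the standard four diagnostic plots — peak
counts before/after, the histogram of applied linear shifts, per-substance
retention-time variation, and substance prevalence — plus a heatmap matrix
of signed deviations from each substance's mean retention time.  Rendering
is optional and isolated so the core stays free of plotting dependencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import AlignmentResult

__all__ = ["DiagnosticsBundle", "summarize", "heatmap_matrix",
           "write_diagnostics", "plot_diagnostics", "plot_heatmap"]


@dataclass
class DiagnosticsBundle:
    peak_counts: pd.DataFrame   # per sample: before, after (NaN for blanks)
    shifts: pd.Series           # applied linear shift per sample, minutes
    rt_variation: np.ndarray    # per substance: max - min retention time
    prevalence: np.ndarray      # per substance: number of samples sharing it
    heatmap: pd.DataFrame       # substance x sample signed deviations


def heatmap_matrix(result: AlignmentResult) -> pd.DataFrame:
    """Signed deviation of every peak from its substance's mean retention
    time; absences are NaN (0 is a legal deviation).  Row-wise, present
    deviations sum to zero by construction."""
    matrix = result.matrix
    means = matrix.row_means()
    dev = np.where(matrix.rt > 0, matrix.rt - means[:, None], np.nan)
    labels = [f"{m:.4f}" for m in means]
    return pd.DataFrame(dev, index=labels, columns=list(matrix.sample_ids))


def summarize(result: AlignmentResult) -> DiagnosticsBundle:
    """Compute all diagnostic quantities for an alignment result."""
    snapshot = result.input_snapshot
    matrix = result.matrix
    before = {s: snapshot.n_peaks(s) for s in snapshot.sample_ids}
    after_counts = matrix.peaks_per_sample()
    after = {s: np.nan for s in snapshot.sample_ids}
    for j, s in enumerate(matrix.sample_ids):
        after[s] = int(after_counts[j])
    peak_counts = pd.DataFrame(
        {"before": pd.Series(before), "after": pd.Series(after)},
    ).loc[list(snapshot.sample_ids)]

    present = matrix.rt > 0
    with np.errstate(invalid="ignore"):
        rt_max = np.where(present, matrix.rt, -np.inf).max(axis=1)
        rt_min = np.where(present, matrix.rt, np.inf).min(axis=1)
    any_present = present.any(axis=1)
    rt_variation = np.where(any_present, rt_max - rt_min, np.nan)

    return DiagnosticsBundle(
        peak_counts=peak_counts,
        shifts=pd.Series(result.shifts, name="shift"),
        rt_variation=rt_variation,
        prevalence=matrix.prevalence(),
        heatmap=heatmap_matrix(result),
    )


def write_diagnostics(bundle: DiagnosticsBundle, outdir: str | Path) -> Path:
    """Export the diagnostic tables as tab-delimited text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.peak_counts.to_csv(outdir / "peak_counts.tsv", sep="\t",
                              index_label="sample")
    bundle.shifts.to_frame().to_csv(outdir / "shifts.tsv", sep="\t",
                                    index_label="sample")
    pd.DataFrame({"rt_variation": bundle.rt_variation,
                  "prevalence": bundle.prevalence}).to_csv(
        outdir / "substances.tsv", sep="\t", index_label="substance_row")
    bundle.heatmap.to_csv(outdir / "heatmap.tsv", sep="\t",
                          index_label="mean_RT")
    return outdir


def plot_diagnostics(bundle: DiagnosticsBundle, path: str | Path) -> Path:
    """Render the four diagnostic panels to a static image file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    counts = bundle.peak_counts
    x = np.arange(len(counts))
    axes[0, 0].bar(x - 0.2, counts["before"], width=0.4, label="before")
    axes[0, 0].bar(x + 0.2, counts["after"], width=0.4, label="after")
    axes[0, 0].set_title("peaks per sample")
    axes[0, 0].set_xlabel("sample")
    axes[0, 0].legend()
    axes[0, 1].hist(bundle.shifts.to_numpy(), bins=11)
    axes[0, 1].set_title("linear shifts (min)")
    axes[1, 0].hist(bundle.rt_variation[~np.isnan(bundle.rt_variation)],
                    bins=20)
    axes[1, 0].set_title("retention-time variation per substance (min)")
    axes[1, 1].hist(bundle.prevalence,
                    bins=np.arange(0.5, bundle.prevalence.max() + 1.5))
    axes[1, 1].set_title("samples sharing a substance")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_heatmap(bundle: DiagnosticsBundle, path: str | Path,
                 threshold: float | None = None) -> Path:
    """Render the deviation heatmap; cells past ``threshold`` are flagged."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = bundle.heatmap.to_numpy()
    fig, ax = plt.subplots(figsize=(8, 6))
    lim = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    im = ax.imshow(data, aspect="auto", cmap="coolwarm",
                   vmin=-lim, vmax=lim, interpolation="nearest")
    if threshold is not None:
        flagged = np.argwhere(np.abs(data) > threshold)
        ax.scatter(flagged[:, 1], flagged[:, 0], marker="x", s=12, c="black")
    ax.set_xlabel("sample")
    ax.set_ylabel("substance")
    fig.colorbar(im, ax=ax, label="deviation from mean RT (min)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
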