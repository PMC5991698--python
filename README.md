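# peakalign

Retention-time alignment of gas-chromatography (GC-FID) peak lists.

GC-FID characterises the chemical composition of biological samples — skin
swabs, gland secretions, cuticular extracts — as a list of peaks, each
described only by its retention time and intensity (no mass spectra).
Before any similarity analysis, homologous substances must be matched
across samples, which is hard because retention times drift between runs
(temperature, carrier-gas flow, column ageing) and each peak carries
additional random jitter.  `peakalign` solves this with a three-step
procedure designed for diverse multi-sample datasets in chemical ecology,
where only a subset of substances is shared between any two samples:

1. **Full alignment.**  A reference sample is chosen (the one with the
   lowest median nearest-neighbour deviation against all others, each
   pairwise score normalised by the reference's peak count), and every
   other sample is translated by the linear shift `s` on the grid
   `[-w, +w]` (step 0.01 min) minimising

   `score(s) = Σᵢ minⱼ | refᵢ − (queryⱼ + s) |`,

   the sum running over the reference's peaks.  This removes systematic,
   sample-wide drift.
2. **Partial alignment.**  Peaks are arranged in a retention matrix (rows =
   putative substances, columns = samples, 0 = absent) and swept once top
   to bottom, left to right.  A focal peak `rt_m` is compared with the mean
   `μ` of the previous non-zero peaks in its row: if `rt_m > μ + a` the
   peak (and its column tail) moves down one row; if `rt_m < μ − a` all
   previous peaks of the row move down instead.
3. **Merging.**  Adjacent rows whose mean retention times differ by less
   than `b` are merged whenever no sample holds a peak in both rows, so the
   merge can never lose information.

Optional filters remove substances shared with negative controls (blanks)
and substances present in a single sample.  Normalisation converts an
intensity measure to percent-per-sample relative concentrations, ready for
ordination.  Alignments with known substance identities can be scored with
the mode-row error rate: for each known substance, occurrences outside the
row holding most of its occurrences count as misaligned, and the error is
`misaligned / total` over known substances.

A seeded simulator generates multi-sample peak lists with ground truth
(shared substances, per-sample drift, per-peak jitter, presence/absence,
sample-unique peaks, blanks, log-normal abundances) so the whole pipeline
is testable without instrument data.

## Worked example

```sh
peakalign simulate --seed 11 --out sim
peakalign check sim/peak_list.txt
peakalign align sim/peak_list.txt --delete-single-peak --out aligned
peakalign normalise aligned --conc-col-name area
peakalign evaluate aligned sim/ground_truth.tsv
```

prints

```
simulated 30 samples (40 substances, 0 blanks) in sim
input OK: no issues found
aligned 40 substances (reference: Sample_22); output in aligned
wrote 30 samples x 40 substances to aligned/normalised.tsv
alignment error rate: 0.0000 (0/1084 misaligned, 0 removed by filters)
```

The simulated experiment has 30 samples drawn from a pool of 40 substances
(each present with probability 0.9, jitter sd 0.005 min, per-sample drift
within ±0.04 min) plus 3 sample-exclusive peaks per sample.  With the
default thresholds (`a = 0.02`, `b = 0.08`, shift window ±0.05 min) the
alignment recovers exactly the 40 true substances once single-sample rows
are deleted, and all 1084 occurrences of the true substances land in their
substance's row — an error rate of 0.  `aligned/` contains the aligned
retention-time and area matrices, a plain-text run summary restating every
parameter (including untouched defaults), diagnostic tables (peak counts
before/after, applied shifts, per-substance retention-time variation and
prevalence, a deviation heatmap) and a machine-readable run log.

The same workflow is available as a library:

```python
from peakalign import SimConfig, generate, AlignmentParams, align, error_rate

dataset, truth = generate(SimConfig(seed=11))
result = align(dataset, AlignmentParams(delete_single_peak=True))
print(result.n_substances, error_rate(result, truth.known_map()))
# 40 0.0
```

## Input format

Tab-delimited text (separator configurable): first header row holds sample
identifiers, second row the per-sample variable names (retention time plus
any intensity measures, repeated per sample block or written once), then
one column block per sample.  Samples may hold different peak counts;
empty cells and zeros pad short columns.  Retention times are minutes.

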