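# Methods

## The alignment model

`peakalign` treats a multi-sample GC-FID experiment as noisy observations
of a latent set of substances.  Substance `k` has a true retention time
`t_k`; its observation in sample `s` (if present) is

```
rt = t_k + d_s + ε,    ε ~ Normal(0, σ)
```

where `d_s` is a sample-wide systematic drift (injection-to-injection
variation of the run) and `ε` per-peak jitter.  Samples also carry peaks
with no homologue elsewhere.  The algorithm inverts this model in three
steps: estimate and remove `d_s` (full alignment), cluster the residual
retention times into substance rows (partial alignment), and repair
clusters that were split across adjacent rows (merging).  It is entirely
deterministic: no randomness exists outside the simulator.

### Full alignment

The drift of each sample is estimated by grid search against a reference:
`score(s) = Σᵢ minⱼ |refᵢ − (queryⱼ + s)|`, summed over the reference's
peaks, evaluated on the inclusive grid `{−w, …, −0.01, 0, 0.01, …, +w}`
(`w = max_linear_shift`, step `shift_step`, default 0.01 min).  Score ties
are broken towards the smallest absolute shift, then the more negative
one, so identical samples are a fixed point.  The automatic reference is
the sample with the lowest *median* per-pair mean nearest-neighbour
deviation; dividing each pairwise sum by the reference's peak count keeps
peak-poor samples from winning by default, and the median makes the choice
robust to a few dissimilar samples.  Ties go to the larger peak count,
then the lexicographically smaller identifier.  Blanks are excluded from
both sides of reference selection — a solvent control's sparse peak list
says nothing about which chromatogram is "central" — but are themselves
shifted and aligned like any sample, since the blank filter needs their
peaks placed next to their homologues.

Shift estimation is only identifiable when the reference and query share
most of their peaks.  Every unmatched reference peak contributes a term
whose derivative in `s` is ±1, so when the query is sparse (a blank with a
handful of peaks) these terms dominate and the arg-min tends to clamp at
±`w` regardless of the true drift.  See *Limitations*.

### Partial alignment

One top-to-bottom pass over the retention matrix; within a row, cells are
visited in column order and zeros are skipped (absence never enters a
mean).  With `μ` the running mean of the previous peaks in the row and `a
= max_diff_peak2mean`:

* `rt > μ + a` — the focal peak moves to the next row, pushing its
  column's tail down one row so column order is preserved;
* `rt < μ − a` — every previous peak of the row (each with its column
  tail) moves down one row and the focal peak stays, becoming the row's
  new running mean.

Both inequalities are strict; equality keeps the peak in place.  Rows
created at the bottom are processed when the sweep reaches them.  The pass
conserves the multiset of peaks per column and their order; the output
guarantees that every retained peak was within `a` of its row's running
mean at the moment of its evaluation (not that final row spreads are
bounded by `2a` — later arrivals move the mean).

### Merging

Adjacent row pairs are merged when (i) their mean retention times (over
non-zero cells) differ by less than `b = min_diff_peak2peak`, strictly,
and (ii) no sample occupies both rows, so the merge loses no information.
Scanning restarts until a full pass performs no merge, and row means are
recomputed after every merge; `b = 0` therefore never merges, and merging
cannot place two peaks of one sample in a row.  All-zero rows are deleted
here.

### Filters and normalisation

Blank filtering deletes every row with a peak in any blank column, then
the blank columns; singleton filtering then deletes rows with exactly one
peak.  Blanks run first so a contaminant peak cannot rescue an otherwise
singleton row.  Both filters log the removed rows in full, which keeps
evaluation able to distinguish "filtered" from "lost".  Normalisation maps
an intensity variable to `100 · x / Σx` per sample (percent; all-zero
samples stay zero), oriented samples × substances for downstream
ordination.

### Evaluation

For substances of known identity, the *mode row* is the aligned row
holding the largest number of that substance's occurrences (ties to the
earlier row); occurrences elsewhere are misaligned, and the error rate is
total misaligned over total occurrences, across known substances only.
The metric is label-free: two substances each fully concentrated in a row
score zero even if swapped.  Occurrences deleted by filters are excluded
from numerator and denominator and reported separately.  Retention-time
deviation per substance is the mean absolute row offset from the mode row,
compared between the final matrix and the unaligned (stacked) matrix.
Known-substance maps store occurrences in raw input coordinates; the
recorded per-sample shifts are applied when locating them, so a simulator
ground-truth file written before alignment can be used directly.

## Parameters

| parameter | unit | default | role |
|---|---|---|---|
| `max_linear_shift` | min | 0.05 | half-width of the drift search window; should cover the expected systematic drift between any sample and the reference |
| `max_diff_peak2mean` (`a`) | min | 0.02 | peak-to-row-mean tolerance of partial alignment; of the order of a few jitter standard deviations |
| `min_diff_peak2peak` (`b`) | min | 0.08 | expected minimum separation of distinct substances; rows closer than this merge when disjoint |
| `shift_step` | min | 0.01 | drift grid resolution |
| `reference` | — | automatic | fixed reference sample, if desired |
| `delete_single_peak` | — | off | drop substances present in one sample |

A warning is emitted when `a ≥ b`: substances split by partial alignment
can then never be re-merged, and error rates rise sharply (the sweep in
`tests/test_acceptance.py` and `scripts/acceptance.py` reproduces this).

## The simulator

`SimConfig` defaults describe the study conditions used throughout the
tests: 30 samples × 40 substances in a 5–35 min window, pairwise substance
spacing ≥ 0.15 min, jitter sd 0.005 min, drifts uniform in ±0.04 min, 90%
presence, three sample-exclusive peaks per sample, log-normal abundances
(log-mean 4, log-sd 1).  Substance and unique-peak positions are drawn
jointly with the global spacing constraint — unique peaks are kept ≥
`min_spacing` from substances *and* from each other, so each forms its own
singleton row under a correct alignment and "recovered substance count"
is well-defined.  A sample whose jittered peaks would swap the true
substance order is redrawn, keeping ground truth unambiguous.  Blanks
contain only the designated contaminant substances, with their own drift
and jitter.  All draws derive from a single `numpy` generator seeded by
`config.seed`; sweep replicate `r` uses `seed + r`.

The simulator emulates retention-time structure, not chromatography: no
co-elution or peak-shape effects, no intensity-dependent integration bias,
no missingness correlated with abundance, no non-linear drift.  Passing
tests therefore demonstrate correctness of the alignment machinery under
the stated noise model, not instrument-grade performance.

## Numerical choices and problem sizes

Retention times are minutes throughout; absence is encoded as 0 in
matrices (retention times must be strictly positive) and as NaN in the
deviation heatmap, where 0 is a legal value.  Eq-style comparisons use
exact floating-point arithmetic; evaluation locates occurrences with a
1e-9 absolute tolerance (shifted coordinates are computed by the same
float operation that produced the matrix, so matches are exact in
practice).  The exhaustive small-matrix check enumerates every initial
matrix of ≤ 4 samples × ≤ 4 peaks over a 4-point retention grid (69 904
matrices) against an independent list-based transliteration of the
procedure; simulation-based tests use 20 seeds for recovery properties and
a 7 × 7 grid × 5 replicates for the parameter sweep — sizes chosen so the
full suite completes in well under a minute of compute per property while
the statistical assertions remain stable.

## Design decisions taken where the procedure was open

* Reference scoring aggregates per-pair mean deviations by the median (see
  above); this combines the per-pair normalisation with robustness across
  samples.
* The partial-alignment pass runs once (its definition is procedural, row
  by row to the end of the matrix), not to a fixed point; merging, by
  contrast, iterates to a fixed point with means recomputed between scans.
* Collisions during demotion are resolved by pushing the whole column tail
  down recursively; this is the only resolution that preserves column
  order without reordering peaks.
* Blank declaration is call-time (an argument), not encoded in the input
  file.
* Filter order: blanks before singletons.

## Limitations

* Linear drift only: non-linear (warping-type) retention-time distortion
  is out of scope; only the constant per-sample component is corrected.
* Sparse blanks: with very few blank peaks the blank's own shift estimate
  is weakly identified and tends to clamp at ±`max_linear_shift` (the
  score is summed over *reference* peaks, most of which have no blank
  homologue).  The blank's peaks can then land just beyond `b` of their
  homologues, letting a contaminant escape the blank filter — observed in
  roughly one in ten simulated 10-sample datasets with 4 contaminant
  substances.  Blanks sharing many substances with the samples, or a
  user-fixed smaller window, avoid this.
* The mode-row error rate is blind to consistent relabelling: substances
  merged into one row with *another* substance's majority still count
  their own majority row as correct.  It measures concentration, not
  identity.
* One peak per sample per substance is assumed; co-eluting isomers
  integrated as one peak cannot be split.
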