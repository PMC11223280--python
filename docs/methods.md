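# Methods

## Signal model and preprocessing assumptions

The pipeline consumes *preprocessed* scalp EEG: re-referenced,
broadband-filtered, artifact-cleaned recordings, 19 channels in the
10–20 montage.  No artifact handling is performed here; a recording
containing non-finite samples is rejected at load.

Band filtering uses a 4th-order Butterworth band-pass applied
forward–backward (`sosfiltfilt`).  The zero-phase property matters: a
causal filter's group delay would differ slightly between channels with
different spectra and could masquerade as a phase lag in the PLI.  The
order is a package decision (a common EEG default); the band edges are
fixed at delta 0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma
30–45 Hz.

Filtering precedes epoching (filter the continuous record, then cut),
so filter transients fall at the record boundaries only.  Epochs are
12.288 s with 50% overlap by default (6144 samples at 500 Hz); epoch
length in samples is rounded to the nearest sample, the stride is
`round(L·(1−overlap))`, and a trailing partial window is discarded.

Analytic phase and envelope are computed per epoch, not on the
continuous record.  Because the FFT-based Hilbert transform is
circular, the first and last 5% of samples of each epoch are excluded
from PLI/AEC estimation (`EDGE_TRIM_FRACTION`, configurable).  Both
choices are package decisions — the alternative (continuous-record
transform) is defensible but couples epochs through the transform.

## Connectivity estimators

**PLI** = `|mean(sign(sin(φ_x − φ_y)))|` over the retained samples of
one epoch, averaged across epochs.  Samples with an exact zero (or π)
phase difference contribute 0.  PLI is invariant to amplitude rescaling
and symmetric in its arguments.

**AEC-c**: for a pair (x, y), x is regressed on y (mean-centered least
squares) and the residual's Hilbert envelope is correlated with y's
envelope; the same is done with the roles swapped; the two correlations
are taken in absolute value and averaged.  Decisions, all configurable:

- *Symmetrization by averaging both directions*, because single-direction
  orthogonalization is asymmetric.
- *Absolute values*, giving a coupling strength in [0, 1] consistent
  with PLI's range.
- *Raw (not log-transformed) envelopes.*
- A pair whose residual is numerically degenerate (colinear channels —
  i.e. coupling **only** at zero lag) raises a degenerate-input error
  rather than contributing a silent zero.  This surfaces rank-deficient
  data instead of biasing group means.

Per-subject matrices are arithmetic means of per-epoch estimates; group
matrices are entrywise means over subjects; the scalar summary
`mean connectivity` is the mean of the strict upper triangle.

## Threshold rule and graph parameters

The binary network keeps an edge where weight ≥ threshold.  The
threshold is the largest value producing no isolated node; for one
matrix this is `min_i max_j w_ij`.  With several subjects per band,
two modes exist: `per_subject_min` (default) takes the minimum of the
per-subject thresholds, guaranteeing no isolated node in *any*
subject's network; `group_mean` thresholds the grand-average matrix.
A band's threshold can also be pinned to an externally given value for
reproduction runs, in which case reports flag it as "pinned" and the
no-isolated-node guarantee is not enforced.

Graph parameters follow the standard conventions: clustering and local
efficiency are 0 for nodes of degree < 2 (and those zeros count in the
means); characteristic path length averages over *reachable* ordered
pairs only, while the efficiency formulas use 1/∞ = 0 for unreachable
pairs.  Shortest paths and triangle counts are delegated to networkx;
the test suite verifies all five parameters exactly against an
independent brute-force implementation on hundreds of random small
graphs.  Regional values are nodal values computed on the whole graph,
then averaged within the electrode partition (frontal: Fp1 Fp2 F3 F4
Fz; temporal: T3 T4 T5 T6 F7 F8; parietal: P3 Pz P4; occipital: O1 O2;
central: C3 Cz C4).

## Permutation inference

The omnibus statistic is the between-group sum of squares
`Σ_g n_g (mean_g − grand)²` under uniformly random label permutation;
any location statistic could be substituted, this one was chosen as the
one-way-ANOVA numerator.  Pairwise tests use `|Δmean|`, with an
exhaustive-enumeration option for small samples.  p-values use the +1
correction `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, so they are never
exactly 0; default `n_perm` = 10,000.  Pairwise tests run only when the
omnibus p falls below the significance level, and are multiplied by 3
(Bonferroni over the three group pairs), capped at 1.  Per-cell seeds
are derived from one root seed via `SeedSequence`, so a full analysis
is reproducible from a single integer.

## Synthetic data: what it emulates and what it does not

The generator plants three coupling archetypes in band-limited signals:

- **phase_lag** — one band-limited Gaussian-noise carrier and its copy
  rotated by a constant angle in the analytic domain.  The phase
  difference is constant and nonzero, so PLI = 1 exactly at zero noise.
  Lag 0 is the explicit null: the copy is bit-identical, PLI = 0
  exactly (the volume-conduction case).
- **envelope_share** — two *unit-modulus* carriers (band-limited noise
  normalized to constant Hilbert modulus) multiplied by slow positive
  envelopes that mix a common and an independent standardized process
  with weights √r and √(1−r), giving envelope correlation r.  Carriers
  are modulus-normalized because raw band-pass noise has
  Rayleigh-fluctuating intrinsic envelopes that would attenuate the
  planted correlation well beyond the ±0.1 recovery tolerance the test
  suite enforces at 60 s.  Envelope modulation depth is 0.4 about a
  unit mean, floored at 0.05 (clipping is rare and correlation is
  affine-invariant).
- **none** — independent band-limited noise.

A study plants `round(base_pairs · effect)` *disjoint* pairs per band
per subject (disjoint so pairwise couplings compose channel-wise;
19 channels cap this at 9 pairs), with phase-lag couplings in delta and
theta and envelope-share couplings (target correlation 0.9, the value
the coupling examples use throughout) in the higher bands; remaining
channels carry independent band noise, and band components are summed
per channel.  Defaults state the emulated world: 19-channel 10–20
montage, 500 Hz, three groups of 36/23/29, 60 s per subject (the
source recordings are minutes long; 60 s gives 9 overlapping epochs,
enough for stable per-subject estimates at tractable cost),
`base_pairs` = 4 (≈2% pair density of baseline coupling).

Not emulated: realistic EEG spectra (1/f background, alpha peaks),
artifacts, inter-channel volume-conduction mixing beyond the zero-lag
pair case, or spatial correlation structure of a real head.  A green
synthetic test therefore establishes that the estimators and the
inference chain recover *planted* coupling and group structure — it
does not validate conclusions on any real dataset.

## Scaling in tests

The acceptance-style tests scale the world down to keep the suite
within minutes on one CPU — 250 Hz sampling (band edges unchanged;
gamma's 45 Hz stays below Nyquist) and 31 s per subject (4 overlapping
epochs), with effect multipliers 2.0 (theta) and 0.25 (alpha) in both
patient groups at 12 subjects per group.  The statistics calibration
test draws per-subject scalar summaries directly from a null
distribution (500 replicates at `n_perm` = 500): it exercises the test
itself at the sample sizes the pipeline produces, which is what
calibration means; signal-level null behaviour is covered by the
smaller full-study tests.

## Known limitations

- The AEC-c conventions (orientation averaging, absolute values, raw
  envelopes) follow one common toolbox lineage; other lineages differ
  and produce systematically different magnitudes.
- The no-isolated-node threshold is sensitive to the weakest node of
  the weakest subject under `per_subject_min`; with very noisy subjects
  the networks become dense.
- Disconnected graphs are summarized under the reachable-pairs
  convention for L; comparing L across networks with different
  components mixes component sizes.
- EDF support covers continuous, unannotated, single-rate EDF only;
  EEGLAB support covers MATLAB v5 `.set` (embedded data or `.fdt`
  sidecar), not v7.3/HDF5.
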