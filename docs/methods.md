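# Methods

This note documents the models, conventions and numerical choices behind
sleepmap, and what its synthetic validation does and does not establish.

## Hypnogram statistics

Epochs are fixed-length (default 8 s) and gap-free; gaps or artifacts must
be encoded as the reserved label X.  Zeitgeber windows are half-open
[start, end) with ZT0 = lights-on; constant-darkness (CT) data use the
same binning under a timebase flag.

Transition probabilities are per-window count ratios,
P_WS = N_WS/(N_WS+N_WW) and P_SW = N_SW/(N_SW+N_SS), with the three-state
(W/N/R) matrix handled identically row by row.  Conventions:

* **Window boundaries.** Adjacent-epoch pairs straddling a window edge are
  not counted, so counts are additive over a partition of the recording.
* **Artifacts.** An X epoch voids both adjacent pairs, contributes to no
  state duration, and terminates bouts (the abutting bout is flagged
  edge-censored, as are bouts touching window edges); censored bouts are
  included in mean bout durations.  This keeps the approximate duality
  mean bout length ≈ 1/P(leave state).
* **Degenerate windows.** When a row of counts is empty (e.g. an all-sleep
  window), the away-from-state probability is reported as 1 — a domain
  convention for "an observed period of uninterrupted state" — applied
  uniformly to two- and three-state rows.  A strict mode
  (`degenerate="nan"`) returns NaN instead.
* **Pooling.** A window's probability pools counts before dividing; pooling
  across non-contiguous windows is therefore supported by construction.

## Sleep-deprivation metrics

Basal metrics average over the provided basal days (typically three).
Cumulative sleep loss is the running per-bin sum of (SD − basal) sleep
minutes; its value at ZT24 equals the total daily difference.  The rebound
ratio is SD/basal inside ZT12–24 (dark phase) by default; paired Δ metrics
default to ZT12–15.  Δ = basal × (ratio − 1) holds whenever the windows
match.

**Rebound onset** has no standard definition; this package defines it as
the hour (at or after deprivation end) where the 1-h-smoothed cumulative
loss curve attains its minimum and is nondecreasing for at least 1 h
afterwards, returning NaN when no recovery exists.  Outputs based on it
should be treated as a package convention.

Pharmacological designs (saline vs drug day) reuse the same operations
with relabelled days; there is no drug-specific code path.

## Spectral analysis

Per-epoch PSDs use Welch averaging with 2-s Hann segments and 50% overlap
(0.5-Hz bins), chosen to resolve the 0.5–1 Hz slow-oscillation band while
averaging seven segments per 8-s epoch.  Total power is integrated over
0.5 Hz–Nyquist (DC excluded; amplifier-dependent offset).  Band edges are
half-open on bin centers so delta (0.5–4) and SO (0.5–1) partition
cleanly.  Parseval consistency (total power within 1% of time-domain
variance) is enforced by test.

Artifact epochs are flagged when EEG or EMG RMS exceeds
median + 6×MAD (normal-scaled), computed per vigilance state so that
state-dependent amplitudes are not themselves flagged; the exclusion
criterion is a package decision — the scoring literature states the
exclusion but no threshold.

Two normalizations of "delta power" are available: percentage of total
power (always computed), and per-subject normalization to the basal-day
mean (the `delta_rebound_percent` metric reports a percentage change
against basal, which is invariant to the choice).

## Vigilance staging

Features per epoch: EEG/EMG RMS, delta and theta fractions, theta/delta
ratio.  Rule precedence is fixed: (1) high EMG → wake, (2) high-amplitude
delta-dominant EEG with low EMG → NREM, (3) theta-dominant EEG with EMG
atonia → REM, (4) wake.  EMG goes first because it is the least ambiguous
cue.  Thresholds are data-driven by default — EMG wake cutoff at the
geometric midpoint of an exact two-class split of log EMG RMS (hence
scale-equivariant), atonia at the 10th percentile of EMG RMS, EEG
amplitude at the median RMS, delta dominance 0.4, theta/delta ratio 1.5 —
and all overridable; constant features fall back to absolute cutoffs with
a warning.  No minimum-bout smoothing is applied by default (an optional
3-epoch majority filter exists).  All numeric cutoffs are package
decisions: the scoring criteria they implement are qualitative.

## Cell-map statistics

Distances are computed in the registered (expanded) space in which the
16-µm rule is stated; the native-tissue radius is reporting-only
(16/1.5 ≈ 10.67 µm).  The double-positive search is a uniform grid hash
with cell size equal to the radius, contractually identical to exhaustive
search (verified exactly in tests).  Cerebellar subtrees are excluded by
default before any counting, reflecting lower detection accuracy there.
Region statistics roll leaf counts up the ontology (child counts sum to
parent counts); densities divide subtree counts by subtree volumes.

Voxel-wise comparisons bin cells into 100-µm cubic voxels (size is a
package default; any isotropic size can be set) and Welch-test per-voxel
counts across brains.  A voxel is valid with ≥2 brains per group, nonzero
variance in at least one group and a nonzero mean somewhere; raw P-values
are reported (matching the heat-map display convention), with FDR
correction available as a switch.

The chance colocalization rate under a Poisson reference channel of
intensity λ is 1 − exp(−λ·(4/3)πr³); planted-fraction recovery corrects
measured rates by this closed form.

## Statistical dispatch

Two samples: Shapiro–Wilk per sample and a two-sided F-test at 0.05;
both normal + equal variance → Student's t (paired variant for paired
designs), normal + unequal variance → Welch, otherwise the two-sample
Wilcoxon test (rank-sum unpaired, signed-rank paired).  The F-test is
applied to the raw samples even in paired designs, following the
procedure as stated; a strict mode substitutes Shapiro on the paired
differences (variance equality is immaterial for a paired t).

Many groups: one-sample KS normality per group against a normal with the
group's estimated mean/SD, and Bartlett's test.  Plain KS with estimated
parameters is conservative; a Lilliefors-corrected variant is available
behind a switch (off by default, since the procedure names only the
KS test).  Parametric branches run pairwise tests (many-one against a
reference when given, otherwise all pairs) with Bonferroni over the
comparisons actually made.  The nonparametric branch is the Steel
many-one rank test: standardized control-vs-treatment rank sums (tie
corrected) referred to their joint asymptotic multivariate normal with
Dunnett-type correlations, so reported p-values are familywise.  Groups
smaller than 6 fall back to rank-sum + Bonferroni, flagged in the branch
trace, because the asymptotic approximation is poor there and exact Steel
tables for arbitrary sizes are impractical.

Zero-variance samples raise a degenerate-input error naming the branch
rather than silently passing through a t-test.

## Synthetic study conditions

The generators define the package's reference conditions and were frozen
at design time:

* **Two-state chain** (8-s epochs): light phase p_ws=0.08, p_sw=0.04
  (sleep-dominated, mean sleep bout ≈ 3.3 min); dark phase p_ws=0.05,
  p_sw=0.08 (wake-dominated, fragmented sleep).  Daily sleep ≈ 12.5 h —
  adult-mouse-like architecture with bout lengths in the range reported
  for respiration-based phenotyping.  These base rates also give the
  planted rebound (below) enough statistical signal to be detected in a
  single simulated experiment, which was checked by power analysis before
  any validation test was written.
* **Three-state chain**: default matrix with stationary occupancy
  ≈ 49% W / 45% N / 6% R, near-absent direct wake→REM transitions and
  ~1-min REM bouts.
* **Deprivation**: sleep attempts during ZT0–6 are blocked at the epoch
  level with probability 1 (configurable), preserving Markov semantics;
  afterwards p_ws is multiplied by 1+(k_ws−1)e^(−t/τ) and p_sw by
  1−(1−k_sw)e^(−t/τ) with defaults k_ws=2, k_sw=0.5, τ=6 h.  Because the
  modulation decays from deprivation end, end-to-end validation evaluates
  the rebound signature over ZT6–24; the ZT12–24 default of the rebound
  ratio (the dark-phase study convention) is unchanged.
* **EEG/EMG synthesis**: per-state recipes (NREM: 2-Hz delta oscillation,
  high amplitude; REM: 7-Hz theta, near-zero EMG; wake: broadband,
  high EMG) over a 1/f background, with a per-epoch lognormal amplitude
  jitter (σ=0.35) applied equally to all EEG components so band
  *fractions* stay at their closed-form recipe values while absolute
  amplitudes vary.  Oscillator phases are globally continuous.  The
  jitter level was calibrated so the stager scores 90–98% — separable but
  not trivially so — rather than 100%.
* **Cell maps**: regions are disjoint cubes with per-channel homogeneous
  Poisson densities; a planted fraction of query cells is placed uniformly
  within a jitter sphere (8 µm default) around reference cells, clipped to
  the region (projection onto the box can only shrink the anchor
  distance).

Every generator emits a ground-truth manifest next to its data.

**What passing tests do not show.** The synthetic recordings lack real
EEG nonstationarities (spindles, within-epoch state transitions,
electrode drift), the cell maps lack anisotropic registration error and
detection false positives, and the Markov chain has no ultradian or
homeostatic structure beyond the planted rebound.  Validation therefore
establishes correctness of the estimators and calibration of the tests
under their stated assumptions, not field performance on real recordings.

## Problem sizes used in validation

Validation runs use desk-scale sizes chosen once: 3-day chains (32,400
epochs) for recovery, ≥10⁴-epoch stationary chains for the bout/
probability duality, 100 simulated experiments for rebound sign
consistency, 6-h recordings (2,700 epochs) for staging, 2,000+2,000-point
clouds for the exact-search check, ~5,000 cells per channel for
colocalization recovery, 2,000 replicates for dispatcher calibration and
two groups of six brains over ~3,400 voxels for the voxel-wise null.

## Known limitations

* The rebound-onset definition is a stand-in; no consensus definition
  exists and the supplementary analyses it mimics do not state one.
* The Steel implementation is asymptotic; exact small-sample critical
  values are not embedded.
* EDF writing implements the minimal 16-bit/1-s-record subset of the
  format (sufficient for round trips with standard readers).
* Double-positive rates pool cells within a region subtree before
  dividing; per-region averaging of rates is available but not the
  default.
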