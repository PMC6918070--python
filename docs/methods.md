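# Methods

## The generative model

`mmphys` simulates one mother-machine lineage at a time (the old-pole
cell in a dead-end channel) with an event-driven engine.  The model
state is the cell volume *V*, the origin count *n*, and the per-origin
initiator level; three event types advance it.

**Growth.**  Volume grows exponentially at a per-generation rate λ drawn
from a truncated normal around ln2/τ.  Volume — not length — is the
primary growing quantity: balanced biosynthesis makes initiator
production proportional to volume growth, the initiation threshold is a
volume, and all the cell-cycle closed forms
(S_d = S_i·e^{(C+D)λ}, C+D = [n_oc + log2(S_d/S_i)]·τ) are then exact
identities of the simulated world rather than approximations.  Length is
derived from volume by inverting the spherocylinder relation
V = π(W/2)²(L − W/3), with the width W drawn once per generation.
Because of the polar-cap offset W/3, length is exponential only up to an
additive constant; the trace pipeline therefore fits elongation rates on
the volume series (the `fit_elongation_rate` primitive is a generic
log-linear slope and accepts either).

**Initiation.**  The initiator accumulates per origin as dV/n; when the
accumulated per-origin volume reaches a threshold δ, all origins fire
simultaneously: the origin count doubles, the overshoot carries over,
and a fresh δ is sampled.  The stationary per-origin volume at
initiation is the fixed point of v ← v/2 + δ, i.e. 2δ, so δ is
parameterized as s_i,mean/2.  Two consequences worth knowing:

* the map averages successive thresholds, so the *measured* CV of s_i is
  the configured threshold CV divided by √3 (≈ 0.046 at the default
  0.08) — the 15%-relative CV-recovery test is scoped to directly
  sampled parameters (λ, C, D, W) for this reason;
* per-origin volume added between consecutive initiations equals the
  freshly sampled δ, independent of the current initiation size — the
  initiation-adder phenotype is built in.  Division, by contrast, is
  threshold-plus-timer here (each initiation commits a division C + D
  later), which makes division-size control sizer-like rather than
  adder-like; reproducing a division *adder* would require a second,
  correlated division threshold and is out of scope.

**Division.**  Each initiation cohort terminates after its sampled C
period and commits a division D minutes later; the earliest pending
commitment executes the next division.  The septum fraction f (truncated
normal around 0.5) splits the *volume*: the tracked daughter keeps f·V,
half the origins, half of each active cohort's fork pairs, and its
per-origin initiator level (molecules and origins halve together).
Volume is conserved exactly; summed daughter length exceeds the mother
length by W/3 — the two new poles.  Two measurement-side consequences:
the observed septum position (daughter length / mother length) has mean
≈ 0.53 and its CV (~0.09) is inflated by per-generation width
resampling, though it stays in the lowest-CV group; and the
birth-vs-division variability relation CV(S_b) ≥ CV(S_d) is exact for
volumes but can invert marginally for lengths, because the cap offset
damps relative length variation more strongly in small cells.  A 6-min
septation refractory interval defers a commitment that would execute
within one imaging frame of the previous division (real septation is not
instantaneous, and frame-level division detection would otherwise merge
the two events).

**Initial state.**  Each lineage is seeded at the canonical steady state
of the noiseless model — a newborn of the right size carrying the
in-flight rounds and pending commitments it would have in steady growth.
The threshold dynamics are neutral in the origin number (initiations
double it, divisions halve it, and the two balance), so an empty initial
state would drift the lineage to twice the canonical ploidy during the
first C+D minutes.  Analyses discard births before a configurable
equilibration time (default 180 min) regardless.

**Nutrient shifts.**  A schedule is a sequence of (start time,
condition) segments.  At an upshift, rates change immediately.  At a
downshift, growth and fork progression pause for a duration drawn
uniformly from a configurable range (default 60–120 min): active rounds'
termination and commitment times shift by the pause, divisions already
past termination (in D) proceed on schedule, and initiation resumes only
when the unchanged per-origin threshold is reached again — which is what
makes the initiation size invariant through the transition.

## Default parameters

All conditions share s_i,mean = 1.2 µm³ (the invariant), with doubling
times 24–65 min, C 40–48 min, D 18–26 min and widths 0.85–1.0 µm so
that only the initiation *volume* per origin, not the length, is
constant across conditions.  The per-parameter noise CVs are not printed
in the source data; the defaults (width 0.035, septum 0.04, threshold
0.08, λ 0.07, C 0.12, D 0.25) were chosen once to reproduce the observed
variability hierarchy (width, septum, s_i, λ tightest; D more variable
than C) and are configurable, not fitted.

## Observation model

Frames sample length every 1.5 min (phase contrast) and replisome-pair
counts every 3 min (fluorescence).  The pair count at a frame is the
summed fork-pair multiplicity of active cohorts — a cohort firing at n
origins contributes n pairs, halved at each division — which reproduces
the 1→2 plateau transition of slow growth (with its brief termination
dip) and the 2→4 transition of fast growth.  Axial focus positions are
cosmetic (midcell / quarter positions with Gaussian jitter); only counts
feed the analysis.  No intensity noise is added to lengths: the
measurement imperfections the pipeline must survive are frame
quantization (the 2^{1/k} − 1 discretization error) and event/frame
asynchrony, and those are modeled exactly.

## Analysis choices

* Division detection runs on the per-frame spherocylinder volume (drop
  > 35% between consecutive frames): septation conserves volume, so the
  drop is the septum fraction itself, whereas the length ratio is
  diluted by the caps and by mother/daughter width differences.
* Generation boundary times are the midpoint of the two frames spanning
  the division — the unbiased estimate under uniform event timing —
  which removes a +half-frame bias in D.
* Initiation sizes are interpolated at the annotated initiation time
  from the generation's fitted exponential (exact here, since volume is
  exponential within a generation).
* Each initiation is matched to its division FIFO-style: the earliest
  unclaimed division after its termination, with a 2-min tolerance so a
  round with a near-zero D whose division lands one frame early is not
  skipped.  n_oc counts divisions strictly between initiation and that
  division.  Cell-cycle assignment requires ≥ 4 recorded consecutive
  generations per lineage.
* The outlier filter keeps records with septum position, elongation
  rate, generation time, birth, division and added length all within
  4 sample SDs of the unfiltered means (single pass); population
  snapshots use the separate 3-SD length/width shape filter.
* The ensemble initiation-size estimator takes the size at the maximum
  finite-difference derivative of the count profile (0.2 µm step on
  0.1 µm length bins; 0.1 µm³ step on 0.05 µm³ volume bins), masking
  bins with fewer than 50 contributing cells, ties toward the smaller
  size.  Per-generation width noise skews the *length* at initiation
  right, so the length estimate sits at the mode, a few percent below
  the mean; the volume profile is symmetric and is what the recovery
  test compares.
* Marker-frequency C estimation regresses log2(frequency) on (1 − m)
  with an intercept (statsmodels OLS); the intercept absorbs any global
  normalization and is reported as a diagnostic.  Both arms are folded
  to |m|.  A two-point ori:ter estimator is provided as a cross-check.
  At 5% per-locus noise the estimator's precision is limited by the
  shallow slope C/τ at slow growth: the pooled-median relative error
  over the tested (C, τ) grid is ~4.6% with the nine assayed loci.
* Turbidostat doublings per interval are computed from the fitted
  exponential evaluated at the dilution boundaries, so the noiseless
  0.05 → 0.2 cycle yields exactly log2(4) = 2.
* Time-series binning uses fixed-width bins anchored at the series
  start (12 min and a minimum of 5 points per bin for shift analyses;
  both configurable), with SEM = SD/√n per bin; shift series are
  normalized to the mean of the 4 h before the shift-up.

## What the synthetic data does and does not establish

The generator emulates steady-state and shift mother-machine lineages,
turbidostat OD traces and qPCR marker frequencies under the threshold
model with independent, truncated-normal noise on each sampled quantity.
It does not emulate segmentation error, fluorescence background,
focus-splitting artifacts (a replisome pair transiently resolving into
two foci), filamentation, correlated noise between C and D, or real
chloramphenicol pharmacology (perturbed conditions differ only by their
parameters).  A green recovery test therefore establishes that the
estimators are consistent and unbiased for the stated model at the
stated noise — not that the model is true of any particular organism,
nor that the estimators are robust to imaging artifacts they never see.

## Numerical notes

Event times are resolved analytically (logarithms of volume ratios), so
threshold crossings carry no integration error; events closer than
1e-6 min are treated as simultaneous with divisions executing first.
Truncated normals are sampled by rejection at ±4 SD.  Every simulation
takes an explicit integer seed (NumPy `SeedSequence` spawning one stream
per lineage); identical seeds give bit-identical output tables.  Tables
are tab-delimited UTF-8 with 6-significant-digit floats, so identical
runs produce byte-identical files; unassigned cell-cycle fields are
empty cells, never zeros.
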