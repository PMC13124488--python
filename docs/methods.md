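# Methods

This note documents the models, conventions and numerical choices behind
`isletca`, including the places where the underlying procedure is stated
qualitatively in the literature and this package had to fix an exact
operationalisation.

## Time and windows

Everything is frame-indexed internally (0-based), with seconds derived as
`frame × frame_interval_s`; all analysis windows are half-open
`[start, end)`. The stimulation timeline defines four windows: 3 mM
baseline `[0, g11)`, first phase `[g11, first_phase_end)` (default end:
the 25 mM step), second phase `[g25, kcl)`, and KCl `[kcl, n_frames)`.
The default protocol is 2 frames/s for 42 min (5,040 frames) with 11 mM
glucose at frame 360, 25 mM at frame 2,160 and KCl at frame 4,800.
Stimulus frames are configuration, never inferred from the trace: they are
experimenter-controlled events.

## Signal conditioning

**Smoothing** is a centred moving average whose edge windows shrink to the
frames available, so output length equals input length and a constant
trace is a fixed point. The default window is 15 frames (7.5 s at 2
frames/s); values outside 3–15 warn, because under-smoothing leaves noise
extrema that disturb valley anchoring and over-smoothing masks small
waves.

**General fold change** is `(F − F_min)/F_min` with `F_min` the minimum
over the 3 mM window. It requires `F_min > 0` (fluorescence is an
intensity); a non-positive baseline raises an error that tells the user to
offset-correct rather than silently producing signed nonsense. Fold change
is invariant to multiplying the raw trace by any positive gain, which is
what makes downstream calls comparable across cells with different
expression levels.

**Min-max normalisation** maps a window to [0, 1] via
`(F − F_min)/(F_max − F_min)`. For single-cell first-phase latencies,
`F_min` is taken before the glucose response (3 mM window) and `F_max`
over the first-phase window. A constant trace has no defined
normalisation; the cell is flagged unanalysable instead of dividing by
zero.

## Adaptive baseline

The oscillatory section is first expressed as *section fold change*
against its own minimum, then detrended:

1. strict local maxima and minima are detected (plateaus report their
   first frame; trace endpoints are never extrema);
2. valleys are filtered: each valley's *reference peak* is the nearest
   preceding peak at least 12.5 s (25 frames at 2 frames/s) before it —
   peaks closer than that belong to the deactivating wave itself and are
   discarded from the pairing; the valley is kept only when
   `(Peak − Valley)/Peak ≥ 0.30`. Valleys with no (surviving) preceding
   peak are retained, which anchors the pre-activation segment;
3. surviving valleys are connected by straight lines, extended flat beyond
   the terminal anchors; zero surviving valleys fall back to a constant
   baseline at the section minimum (logged).

The pairing in step 2 is deliberately *per-valley* rather than a global
peak deletion. On any noisy trace, essentially every peak has some noise
micro-valley within 25 frames, so a global rule deletes the entire peak
set, every valley is then "before the first peak", and the baseline
anchors onto wave plateaus — the opposite of detrending. The per-valley
reading keeps the stated intent (the wave peak is what gets discarded from
a too-close pairing) while remaining robust: plateau micro-valleys always
compare against a reference at or below their own level and are rejected;
gap valleys compare against the preceding wave peak and are kept. A valley
whose reference peak is not positive cannot show a 30% relative drop and
is rejected.

Re-expression against the adaptive baseline divides by the baseline, which
in section-fold-change units can legitimately touch 0. The ratio is
therefore taken in intensity space: `SF = (1 + F)/(1 + BL) − 1`. On raw
intensities this is algebraically identical to `(F − BL)/BL`; on
fold-change traces it preserves the "fraction above the local baseline"
meaning while keeping the divisor positive.

## Wave detection and global metrics

A Ca²⁺ wave opens at the first frame with detrended fold change strictly
above 0.2 and closes at the first later frame strictly below it; a value
exactly at the threshold toggles nothing (the binarisation convention
`1 iff x > 0.2` fixes strictness everywhere). Events sustained for less
than 2 s are discarded; an event open at the trace end is kept but flagged
truncated. Frequency is the wave count over the window length in minutes;
second-phase amplitude and width are means of per-event peak fold change
and active duration.

The first-phase width runs from the T₂₀ crossing to the first frame back
below threshold. The literature describes the endpoint qualitatively
("the next oscillation or significant activity decrease"); the
below-threshold return is this package's operationalisation and is the
same convention the wave detector uses.

AUC comes in two flavours: `AUC_app`, the plain sum of fold-change values
over the window (unitless, frame-rate dependent), and the trapezoid rule
(fold-change·s). The half-open frame window `[s, e)` covers the time span
`[s·Δt, e·Δt]`, so the trapezoid integral includes the closing sample when
the trace extends that far; this makes areas exactly additive over
adjacent windows.

## Subpopulations

**KCl filter.** A cell is quantifiable only if its general fold change
exceeds 0.2 somewhere in the KCl window; all flags are restricted to
included cells.

**First-responders.** FR-T₂₀ per cell is the first frame at or above 0.20
of the normalised trace inside the first-phase window, in seconds from the
11 mM step. The `⌈0.10 · n_included⌉` fastest cells are labelled; absent
latencies rank last; ties resolve by latency then cell order (stable
sort).

**Wave windows and leaders.** Per-wave windows run from the baseline
valley anchor preceding each islet wave's activation to the anchor
following its deactivation, clipped to the section and made disjoint
(waves sharing an inter-anchor span split at the gap midpoint). Within
each window a cell *participates* when its detrended fold change exceeds
the 0.2 activity threshold; for participants the window is min-max
rescaled and the T₂₀ crossing timed from the window start. The absolute
participation gate matters: without it, rescaling a non-participating
cell's flat window amplifies noise to full range and produces a spurious
near-zero latency. Cells participating in fewer than half the waves are
excluded from leader eligibility (their mean would rest on a handful of
windows). Leaders are the cells whose mean latency is at or below the
10th percentile (inclusive, linear interpolation) of eligible cells.

**Coactivity and hubs.** Binarised activity (active iff detrended fold
change > 0.2) gives per-cell active times `T_i` and pairwise co-active
times `T_ij`; the coefficient `C_ij = T_ij/√(T_i T_j)` satisfies the
stated contracts (identical → 1, half-time coordination → 0.5, disjoint
→ 0, silent cell → 0). Chance coactivity uses independent circular
rotations of each vector, which preserve burst-length structure and total
activity while destroying alignment — the standard conservative surrogate
for autocorrelated activity (independent frame permutation is available
but anticonservative for bursty traces). Because `C` under a relative
rotation is a circular cross-correlation, the full surrogate distribution
is computed by FFT and sampled, making 10,000 shuffles over 100+ cells a
matter of seconds. A pair is significant when observed `C` exceeds the
surrogate mean by more than two standard deviations (the 2-SD rule,
approximately p < 0.01 one-sided under normality); calibration on
independent stationary bursty cells flags ~3% of pairs. `C_islet`
averages all off-diagonal coefficients (a significant-only variant is a
config option); class bins are continuous (low ≤ 0.5 < medium ≤ 0.75 <
high) so values like 0.505 fall in the higher class rather than a gap.
Hub calls: criterion hubs need ≥80% of their significant partners at
C ≥ 0.8 (cells with no significant partner are never hubs; non-significant
pairs are not counted in the denominator); top-10% hubs are ranked by
significant-connection count with mean-C then cell-order tie-breaks.

## Synthetic islets

The generator emulates the three input artifacts with planted truth. The
signal model is additive and phenomenological — baseline `f0`, optional
linear + slow sinusoidal drift, a trapezoidal first-phase pulse at a
per-cell onset latency, a second-phase square-wave train, a terminal KCl
step, Gaussian noise — because the pipeline consumes fluorescence
statistics, not biophysics, and oracles must be closed-form. It does not
model GCaMP photophysics (Hill kinetics, dynamic range), bleaching, or
spatial coupling, so passing recovery tests demonstrates correctness of
the detection/classification machinery under the stated noise and drift,
not performance on arbitrary real recordings.

Default study conditions: 50 cells at 2 frames/s under the standard
protocol; noise σ = 2% of `f0` (smoothing reduces it ~√15-fold); first
phase amplitude 100% fold change with onset ~N(180 s, 40 s) (planted fast
cells: N(60 s, 10 s) — a 3σ gap); second-phase waves of amplitude 60%
fold change, width 12 s, period 44 s (29 waves in the 22-min 25 mM
section, 1.3 waves/min — within the physiological 0.5–3/min range);
followers lag wave onset by 1.5 s (± 0.3 s per wave), leaders lead;
ordinary cells join each wave with probability 0.78, planted
high-participation cells and leaders always. The participation/period
choice is deliberate arithmetic: with full participants active in every
wave, an ordinary cell active in `m` of `W` waves has
`C(hub, cell) = √(m/W)`, so the planted contrast across the 0.8 hub
threshold needs `W` large enough that binomial granularity in `m` does not
straddle the bar (at W = 29, p = 0.78: ordinary-pair C ≈ 0.78 below it,
hub-pair C ≈ √0.78 ≈ 0.88 above it, each several standard deviations
clear). The dead-cell plant (3 cells, flat everywhere) exercises the KCl
filter. `drifting` raises the linear drift to 150% of `f0` across the
recording — enough that the section fold change sits permanently above
threshold in the later section and merges the tail of the wave train —
with all cells participating; `no_heterogeneity` removes every planted
set for label-bias checks.

Wave-recovery scoring matches detected events to planted waves one-to-one
(an event matches the first unclaimed planted wave whose span, with 10 s
of leading slack for smoothing-induced early crossings, contains the
event's activation). This prevents a single merged detection from
claiming an entire train.

## Determinism and output

Every stochastic step (simulation, surrogate rotation offsets) takes a
seed; the resolved configuration is written next to the results, and
reruns of the same config + seed are byte-identical (floats are written
with 12 significant digits). The whole-islet trace is the polygon ROI
when present (flagged), otherwise the mean of the single-cell traces.

## Known limitations

- The valley-anchored baseline assumes waves are separated by returns
  toward baseline; continuous plateau activity (e.g. sub-second transient
  regimes) leaves no valleys to anchor and falls back to a constant
  baseline.
- Leader latencies are referenced to the wave-window start (a baseline
  valley), not to the islet-level wave activation; with heterogeneous
  participation this admits a small selection effect on per-cell means,
  which shrinks as the number of waves grows.
- The "<25 frames" valley-separation rule is interpreted in seconds
  (12.5 s) and converted by the frame interval, so recordings at other
  frame rates keep the intended physical meaning.
- Connectivity alternatives (Pearson correlation, Granger causality,
  mutual information) and power-law degree analysis are out of scope.
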