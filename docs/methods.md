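# Methods

This note documents the models and procedures implemented in `whiskermap`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic generator does and does not emulate.

## Trial structure and evoked responses

Sessions consist of ~80 s movies at 30 Hz. Stimuli are nine whiskers
(rows C/D/E × arcs 1/2/3) plus a blank, interleaved in random order at a
5 s inter-stimulus interval, with equal repetition counts (default 60).
The per-trial evoked response of an ROI is

    mean ΔF/F over [onset, onset + 1 s)  −  mean ΔF/F over [onset − 0.5 s, onset)

with half-open windows and frame counts `round(duration × rate)` (30 and
15 frames at 30 Hz). All tuning, correlation and decoding statistics are
built from this one quantity.

## ΔF/F pipeline

Per movie: optional neuropil subtraction `F ← F_soma − r·F_ring`
(r ∈ [0, 1]; 0.3 is the conventional weight for L4, 0 for L2/3), a
trailing 4-frame moving median (true median, i.e. the mean of the middle
pair for even windows; the leading frames use the available prefix), then
ΔF/F = (F_t − F₀)/F₀ with F₀ the 20th percentile of the whole movie
(linear-interpolation convention). A non-positive F₀ is reported as an
error naming the ROI and movie, since it signals neuropil over-correction.

The neuropil ring is the set of pixels whose Chebyshev distance to the
somatic mask lies in [2, 12) — a square ring, the natural metric for pixel
offsets — minus all somatic pixels and minus pixels whose raw trace
correlates with any soma trace at Pearson r > 0.2. An ROI whose ring
empties falls back to r = 0 with a warning. Movies whose ROI-averaged
brightness drops by more than 10 % (first vs last frame-decile means) are
excluded before analysis; this operationalizes as a fixed rule what is
usually a manual inspection step.

Order of operations is neuropil subtraction → median filter → ΔF/F. For
mean-over-mask ROI signals this is equivalent (up to mask averaging) to
smoothing pixels before extraction. The pixel–soma exclusion correlation
is computed on raw traces over the full movie.

## Responsiveness and tuning statistics

The permutation test pools the two samples, redraws group labels
preserving sizes, and ranks the observed difference in means against
`n_perm` permuted differences (default 10 000). p-values use the
add-one convention (1 + #{permuted ≥ observed})/(n_perm + 1), which never
returns 0 and at α = 0.05 matches a 95th-percentile rejection rule.
Degenerate pooled samples return p = 1.

Responsiveness: per whisker, a one-sided whisker-vs-blank test;
Benjamini–Hochberg FDR across the nine whiskers per ROI (the correction is
per-ROI, reading "corrected for nine whiskers" as a within-cell family);
an ROI is responsive if any adjusted p < α. At least five blank trials are
required.

Receptive fields: per-whisker median evoked ΔF/F; z-scores use the mean
and SD (ddof = 1) of the blank-trial evoked responses, making magnitudes
comparable across cells with different GCaMP expression. Spontaneous
activity = median blank evoked ΔF/F.

BW/eBW: the best whisker maximizes the mean evoked response (exact ties
break to the lexicographically smallest label, C1 < … < E3). Each other
whisker joins the equal-best set unless a **two-sided** BW-vs-whisker
permutation test (BH across the eight comparisons) rejects at α. Two-sided
was a deliberate choice: "indistinguishable from the BW" is an equality
hypothesis, and because the BW is selected as the maximum, a one-sided
test inherits that selection bias — under flat tuning it keeps ≥8 whiskers
in only ≈81 % of cells, versus ≈94 % for the two-sided form, which is the
behaviour a null eBW criterion should have.

Group contrasts between conditions use two-sided permutation tests on
means; tuned-fraction contrasts use two-sided Fisher's exact tests on the
2×2 tuned/untuned tables, computed separately per distance bin. Per-bin
p-values are reported uncorrected (matching per-bin testing conventions);
`PipelineConfig.contrast_fdr` adds BH across bins if wanted.

## Anatomical reference frame

ROIs are assigned to the barrel column whose boundary polygon contains
their centroid (boundary-inclusive; overlapping polygons are an invalid
map) or to the septum otherwise. For cross-field pooling, coordinates are
translated so the reference column centroid is the origin and rotated by
−row_axis_angle so the within-row axis lies along +x. The transform is an
isometry. For synthetic maps the row-axis angle is exact by construction;
for real maps it should be fit as the least-squares line through the three
same-row centroids of the reference row. Normalized polar coordinates
express distance as a fraction of the mean barrel radius, computed from
barrel areas assuming circularity (r = √(area/π), averaged over the nine
barrels). Distance profiles use half-open 75 μm bins; empty bins are
reported as missing, never as 0. Spatial 2-D binning uses k-means on
reference-frame positions (10 restarts, fixed seed), which equalizes ROI
counts per bin. L4 analyses can optionally be restricted to columns C1–C3
via `PipelineConfig.l4_column_filter`.

## Correlations

Signal correlation: Pearson correlation of two ROIs' 9-element mean
tuning vectors (per-vector z-scoring leaves it unchanged; it is applied
for interpretability). Noise correlation: per whisker, the Pearson
correlation of the two ROIs' trial-response vectors, averaged unweighted
over the nine whiskers; zero-variance whisker vectors are skipped. Pairs
are restricted to simultaneously imaged (same-field), responsive,
barrel-assigned ROIs; septal ROIs are excluded to avoid boundary
ambiguity. `boundary_axis` labels across-column pairs that share a row
(within_row) or an arc (within_arc); it is NA for within-column pairs.
The 4-frame median filter, being nonlinear, attenuates trial noise
correlations slightly below the generator's frame-level target (≈0.27
observed for a 0.31 target at the default settings); recovery checks
therefore measure at the trial-response level with the filter disabled.

## Decoder

Each ROI × whisker gets a logistic model P(stimulus | x) =
σ(β₀ + β₁·x) on the single-trial evoked ΔF/F, fit by Newton/IRLS with a
negligible ridge (1e-6) so separable data converge; the fit agrees with
scikit-learn's LogisticRegression to numerical precision. Performance is
repeated stratified cross-validation: each repeat holds out 1/5 of trials
(K = 5 read from the 80/20 split), fits on the rest, and predicts stimulus
when the modeled probability exceeds 0.5; accuracies are averaged over
repeats (500 for single-ROI decoders by default). Ensembles sum each
member's probability pair (p, 1−p) with equal weight — each unit
contributes one normalized probability distribution — and predict the
class with the larger summed score, ties going to blank (conservative
detection). All members share the same trial partition on every repeat,
so an ensemble of one reproduces its single ROI exactly; per-ROI held-out
probabilities are cached per repeat, making ensemble evaluation cost
independent of how many ensembles are scored.

Random ensembles of sizes {1, 2, 3, 5, 10, 15, 20, 25, 30} are drawn per
field (the lesser of 500 or N-choose-K distinct sets; oversizes skipped),
and are evaluated averaged across the distinct columnar whiskers of the
members' columns. Clustered ensembles come from k-means on reference-frame
positions for k from 2 to N, keeping clusters of 2–42 members and
recording the centroid distance to the reference column center; detection
performance is profiled in half-open 77 μm centroid-distance bins. The
decoding feature is the 1 s evoked-window mean: with 100 ms pulse spacing
the five GCaMP6s transients overlap, so the train-level window is the
meaningful single-trial quantity (a configurable window is available for
single-deflection variants).

## Synthetic generator

`generate_session` emulates one imaging field: ROI centroids uniform over
the field; a 3×3 barrel grid (centroid spacing 300 μm, radius 151 μm, the
reported mean anatomical column radius) with each circular boundary
clipped to its lattice cell so polygons are disjoint (<0.1 % area loss);
each ROI prefers its columnar whisker with probability `p_cw`, else a
uniformly chosen row/arc neighbour (salt-and-pepper control). The response
amplitude to whisker w is A_roi · exp(−(Δrow²/2σ_row² + Δarc²/2σ_arc²))
in whisker-grid units — tuning is organized by whisker identity, not
cortical distance. Evoked traces are that amplitude times a
difference-of-exponentials kernel (τ_rise = 0.1 s, τ_decay = 1 s,
unit-peak pulses) summed over the 5-pulse train; the kernel is truncated
at ISI − baseline − filter-width so one trial's transient never leaks into
the next trial's analysis windows. Spontaneous activity is Poisson-timed
single-pulse events (0.05 Hz). Frame noise is private Gaussian
(SD 0.3) plus a shared latent with loading 0.2: the shared term mixes a
global factor (weight √b) with per-column factors (weight √(1−b)), so the
within-column trial correlation tends to s²/(s²+p²) and the cross-column
correlation to b·s²/(s²+p²), with b = `boundary_attenuation`. Raw
fluorescence is f₀·(1 + signal), f₀ = 1000 a.u. One RNG stream per
session, draws ordered placement → tuning → trial order → noise, so a
seed fully determines the session.

Amplitudes are the one free scale (the source data report magnitudes only
as blank-z-scores): A ~ |N(0.03, 0.01)| per pulse puts the 5-pulse train
peak at ≈0.14 ΔF/F, the evoked-window mean at ≈0.09, and single-trial
d′ ≈ 0.8 — chosen so the synthetic operating point matches the reported
population statistics (single-ROI detection accuracy ≈0.65, central-bin
blank-z ≈0.6–0.8, within-column noise correlation ≈0.3).

Presets: `NH_like` (p_cw = 0.65, σ_row = σ_arc = 1.0, b = 1.0) and
`EN_like` (p_cw = 0.85, σ_row = 0.6 < σ_arc = 1.0, b = 0.5), mirroring
the enriched condition's higher columnar tuning, row-axis-asymmetric
receptive-field sharpening, and cross-column decorrelation.

What the generator does **not** emulate: trial-to-trial response-amplitude
fluctuations beyond frame noise (real sensory responses have large
multiplicative variability), slow drift and bleaching, motion artifacts,
pixel-level movies (traces are primary; pixel masks optional), spike-level
dynamics, or septum-specific physiology. Passing tests therefore establish
the correctness and calibration of the estimators under the assumed
statistical structure, not robustness to every artifact of real data.

## Problem sizes and numerical choices

Default analysis parameters are α = 0.05, n_perm = 10 000, 75 μm distance
bins, 77 μm decoder bins, 500 CV repeats. The test suite and the
acceptance script scale the simulation sizes to what the statistical
margins require — e.g. 500 null ROIs for type-I calibration at
n_perm = 2000, 200 ROIs for eBW recovery, 540 trials for correlation
recovery, 200 fields for ensemble monotonicity, and an end-to-end
contrast of two 300-ROI fields per condition with n_perm = 1000 and 15 CV
repeats — sizes at which each check's expected effect exceeds its Monte
Carlo error severalfold. Tie-breaks are deterministic (BW ties →
smallest label; prediction ties → blank; k-means seeded with 10
restarts). Degenerate inputs (zero-variance samples, empty bins, empty
neuropil rings, missing reference barrels) return the documented
p = 1 / NaN / warning / error behaviours rather than silently propagating.

## Known limitations

- The eBW criterion is one construction of "statistically
  indistinguishable from the BW"; the selection of the BW as the maximum
  makes any such criterion approximate, and the two-sided choice trades a
  little power for null calibration.
- Noise correlations estimated after the median filter are mildly
  attenuated (see above); comparisons between conditions are unaffected
  because both are filtered identically.
- With only two fields per condition the home-column decoder contrast
  between presets is close to its sampling noise floor; the tuned-fraction
  and correlation contrasts are robust at that size.
- Barrel polygons are inputs; no histology image processing is performed.
  Motion correction is assumed done upstream.
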