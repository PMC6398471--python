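# Methods

## Single-molecule binding model and simulator

Motor landings on the microtubule lattice are a homogeneous Poisson process
with rate density k_on·C per µm of microtubule (k_on in events s⁻¹ µm⁻¹
pM⁻¹, C the motor concentration in pM), positions uniform along the pooled
microtubule length, and dwell times i.i.d. exponential with mean τ = 1/k_off.
Rendering integrates each molecule's presence over camera frames — frame f
covers [f·Δt, (f+1)·Δt) and an event contributes in proportion to its
temporal overlap — spreads it spatially with a Gaussian PSF integrated over
pixels (σ 0.17 µm at 0.16 µm/pixel; 0.3 µm in the 0.86 µm/pixel binned
mode), and adds Gaussian noise (sd 1) on a constant background (10) with a
peak-pixel amplitude of 10 for a molecule present a full frame. The
amplitude/noise choice gives a peak-pixel SNR of 10, typical of EMCCD
single-fluorophore imaging; no photon-count (Poisson) noise model is used.

Deliberately omitted: photobleaching (it would shorten apparent dwells and
bias off-rates — a documented limitation, not a tunable); lateral diffusion
of bound molecules defaults to 0 (a 1D diffusion coefficient is available,
but the kinetic analyses use durations only). Kymograph columns run
minus→plus end; polarity is metadata because none of the analyses here are
end-specific.

Frame intervals follow the two real acquisition modes: 130 ms per frame at
0.16 µm/pixel for slow off-rates, and 15 ms per frame at 0.86 µm/pixel
(8×8 binning) for fast ones.

## Event detection

Pixels above background + 5σ are grouped per frame into contiguous spots;
spots are linked across frames allowing ≤ max_jump pixels of drift per
frame step (default 2 at 0.16 µm/pixel, 1 in binned mode) and ≤ 1 dark
frame (max_gap). Background and σ are the image median and scaled MAD,
valid when events are sparse. Tracks shorter than min_frames (default 3,
the "longer than three consecutive frames" rule, read as ≥ 3 frames and
configurable) are discarded for dwell fitting; tracks touching the first or
last frame are censored — excluded from dwell fits, and start-censored
tracks are also excluded from landing counts since their landing was not
observed.

Two detection-level confounds matter and are characterized by the tests
rather than hidden: (i) molecules dwelling less than about half a frame
never cross threshold, so visible-landing counts (and hence on-rates)
underestimate true landings by ≈ k_off·Δt/2; (ii) a molecule landing within
the gap window of a departing one at the same position merges into a single
track, inflating dwells — the convenience pipelines keep occupancy near
0.01 molecules/µm so this stays at the percent level.

## Dwell-time fitting

Measured durations are k·Δt with k the spanned frame count. For an
exponential dwell, conditioning on k ≥ m leaves k − m geometric with
parameter 1 − q, q = e^(−Δt/τ), *regardless* of the end-frame threshold
convention (memorylessness absorbs it). The default estimator is the exact
MLE of that law, τ̂ = −Δt/ln(ŝ/(1+ŝ)) with ŝ = mean(k − m); with no frame
interval supplied it reduces to the continuous left-truncated MLE
τ̂ = mean(t − t_min). The naive continuous formula applied to quantized data
is biased by ≈ −Δt/2 in mean dwell (≈ +20% in k_off at τ ≈ 2.6 frames),
which is why the discrete form is the default; both are exposed. A
least-squares fit of the empirical survival curve to e^(−(t−t_min)/τ) is
provided as a cross-check and agrees with the MLE within a few percent on
clean data. Confidence intervals are percentile bootstrap (1000 resamples,
seeded); the off-rate is 1/τ̂ with CI endpoints propagated by reciprocal.

## Depolymerization tracing and rates

The simulator shrinks a bright segment inward from both ends at constant
per-end rates (µm min⁻¹) with per-frame positional jitter (default 0.1 µm),
Gaussian-blurred edges and camera noise, stopping when the ends meet.
Tracing takes, per frame, the longest contiguous above-threshold pixel run
and refines each end by linear interpolation of the intensity crossing; the
default threshold is the half-maximum between robust background and signal
plateaus because the half-max of a Gaussian-blurred edge sits at the true
edge position, giving sub-pixel accuracy. Per-end rates are least-squares
slopes over valid frames (≥ 5 required), in µm min⁻¹; the per-microtubule
value is the mean of the two ends (a total-length-loss sum is also
available — the choice of convention is exposed because reported rates in
the literature do not always say which they use). Growth comes out as a
negative rate, never clipped. No changepoint detection: pauses and rescues
are out of scope, the fit is linear over the whole valid trace.

Acquisition modes mirror practice: 2 s frames (30 frames/min) for fast
depolymerizers over 10 min, 10 s frames (6 frames/min) over 15 min for slow
ones. At 0.03 µm min⁻¹ and 6 fpm the displacement is ~0.005 pixel/frame;
recovery there rests entirely on sub-pixel edge interpolation averaged over
many frames, and the tests hold it to 10% with 20 microtubules.

## Hill concentration–response fit

The "modified" Hill form adopted is v(C) = v₀ + (v_max − v₀)·Cʰ/(Kʰ + Cʰ)
with the baseline v₀ free by default — phospho-forms of the motor retain
residual activity, which a zero-baseline form would force into the other
parameters. Fitting is weighted least squares (weights 1/sem² when sems are
given) via trust-region-reflective optimization from ≥ 10 seeded random
starts (K log-uniform around the data range, h in [0.5, 4]); the best-RSS
solution wins, and a dense grid search is used as an oracle in the tests.
At least 4 distinct concentrations are required (3 with v₀ fixed).

## Crosslink–structure validation

Distances are Euclidean Cα–Cα; the BS3 limit defaults to 27 Å. Solvent-
accessible surface distance is noted as future work — Cα–Cα with this
cutoff is the field's standard first-pass check. For a protein mapped to
several chains (e.g. a homodimer in the asymmetric unit), the minimum
distance over single-chain assignments (intra) and over two-chain
assignments (inter) are computed separately; classification precedence is
intra_satisfied → inter_satisfied → violated, because XL-MS cannot
distinguish intra- from inter-molecular links in a homo-oligomer and the
most permissive satisfied reading is reported. Residues missing from every
mapped chain mark the pair unmapped rather than raising. PDB parsing (via
biotite) keeps one Cα per residue, resolves altlocs by highest occupancy,
preserves insertion codes, and ignores heteroatoms, waters and non-standard
residues. Residue numbering follows the structure's author numbering;
construct-vs-crystal offsets are the caller's responsibility.

The toy-structure generator provides analytically checkable geometry:
an ideal α-helix (1.5 Å rise, 100° turn, 2.3 Å radius → consecutive Cα
≈ 3.8 Å), an extended chain at 3.8 Å spacing, or a 3.8 Å-step random walk,
with identical chains offset along +y. Crosslinkable residues are the BS3
set (N-terminus, Lys, Ser, Thr, Tyr). Simulated crosslink tables sample
residue pairs whose minimum-over-assignments distance is ≤ d_max (true) or
> d_max (decoy — so no chain assignment can rescue them), with labels in a
separate truth table.

## Quantitative XL-MS comparison

The replicate design mirrors a six-analysis layout per condition (3
reaction replicates × 2 injection replicates, treated as n = 6 independent
observations; a collapse-injections option averages injections first for a
conservative n = 3). Run-to-run normalization multiplies each run by
(geometric-mean panel total)/(run panel total), using the summed area of a
38-linear-peptide panel; after normalization all panel totals are equal,
making the operation idempotent. Per-pair condition summaries are medians
over available runs; pairs observed in only one condition are flagged
condition-unique and excluded from ratios and tests rather than imputed.
The test is Welch's two-sample t on log2 intensities (intensity noise is
multiplicative, so logs make it additive; unequal variances are not
assumed), significance at raw P < 0.05 by default with Benjamini–Hochberg
available behind a flag — raw-α matches the common practice of reporting
P < 0.05 tables, and the type-I error of the whole pipeline is verified
empirically against α. The generator plants log-normal intensities with
per-run global scale factors and known per-link log2 fold changes; its cv
parameter is the multiplicative coefficient of variation.

What the generator does not emulate: missingness correlated with intensity
(real low-abundance crosslinks drop out non-randomly), retention-time drift,
and interference between co-eluting species. Passing tests therefore show
estimator correctness under the stated noise model, not robustness to those
acquisition artifacts.

## Problem sizes and numerical choices

Recovery runs use 20 microtubules of 40 µm; concentrations are chosen to
keep occupancy ≈ 0.01 molecules/µm (16–100 pM, inside the real assay's
5–100 pM range) and acquisition lengths sized so ≥ 1000 (slow modes) or
≥ 2000 (fast modes) dwells survive the three-frame filter, using the
geometric retention law q²(1−q)/(k_off·Δt). Depolymerization targets use 20
kymographs per condition, positional noise 0.1 µm. Seeds thread explicitly
through every generator; identical configurations are bit-reproducible.
Degenerate inputs fail loudly: non-positive rates, thresholds and cutoffs
raise; an all-background kymograph yields an empty event table (not an
error); fewer than 10 dwells or 5 valid trace frames raise estimation
errors advising longer acquisition.
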