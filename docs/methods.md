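# Methods

## Signal model and rationale

Free-breathing bSSFP lung imaging produces a voxel signal that is, to first
order, a superposition of a static anatomical baseline, a slow
respiration-induced modulation (typically 0.2–0.4 Hz), and a small
cardiac-frequency oscillation (0.8–2 Hz) caused by pulsatile blood volume
changes in the parenchyma. The amplitude of the cardiac component is
proportional to local perfusion; in a voxel that is entirely blood
(cardiac chambers, central pulmonary vessels) it reaches its maximum,
S_Blood. Expressing the parenchymal amplitude Q as a fraction of S_Blood,

    Q_N = 100 · Q / S_Blood   [%],

cancels global intensity scaling, coil sensitivity common to both regions,
and any amplitude convention applied identically to numerator and
denominator. Voxels with Q_N below a threshold (default 2%) are counted as
perfusion defects; the perfusion defect percentage (QDP) is their share of
the analyzed parenchyma. These two numbers, plus a segmental reading of
the defect map, are the clinically reported outputs.

Because the frames sample the cardiac cycle asynchronously, the cardiac
phase of each frame must be estimated from the data itself. The pipeline
does this from the spatially averaged signal of automatically detected
blood-pool clusters (R_sort), fits a sinusoid, assigns each frame a phase,
and reconstructs one cardiac cycle at 15 equidistant phases. Fifteen
phases correspond to a nominal temporal resolution of 50 ms at a heart
rate of 80 bpm — fine enough to separate systole from diastole, coarse
enough that each phase bin still averages several frames.

## Pipeline stages and numerical choices

**Respiratory high-pass (default 0.75 Hz).** A 5th-order Butterworth
high-pass applied forward–backward (`filtfilt`) with reflective edge
padding of at least three cutoff periods. The forward–backward pass makes
the filter zero-phase, which matters because phases are fitted downstream;
its squared magnitude response attenuates 0.25 Hz by ≈ 5·10⁻⁵ and passes
1.2 Hz at ≈ 0.99. A finite record leaves a small residual per-voxel mean
after recursive filtering; this mean is subtracted explicitly (a linear,
zero-phase correction), so the filtered series is exactly DC-free.

**Search region and candidate selection.** A_s is the union of the lung
and mediastinum masks; without a mediastinum mask the inter-lung gap is
bridged by morphological closing with the smallest disk radius that makes
the union connected. Candidates for R_sort are voxels strictly above the
98th percentile (linear interpolation between order statistics) of both
the temporal SD map and the temporal maximum-intensity map over A_s. The
strict inequality means a degenerate (all-equal) map selects nothing and
raises, rather than silently lowering the threshold. Candidates are
grouped by 4-connectivity (8-connectivity is a config option).

**Piecewise sinusoidal fit.** The cardiac frequency is initialized at the
periodogram peak inside the search band (default 0.5–2.0 Hz, config
`cardiac_band`) and refined by bounded 1-D optimization of the
least-squares residual. The fit is piecewise: contiguous windows share the
global frequency but have free per-window amplitude, phase, and baseline,
absorbing slow heart-rate and amplitude drift. Windows span one cardiac
period but never fewer than 12 frames — at the default timing (0.248 s
frames, ~1.2 Hz cardiac) one period is only ~3.4 frames, fewer than the
three linear parameters per window, so a strict one-cycle window would fit
anything exactly; the 12-frame floor keeps each window over-determined. A
single global sinusoid is available via `piecewise=False`.

Goodness of fit is the coefficient of determination R² pooled over
windows. Because the piecewise model has three parameters per window, pure
noise still produces a nonzero R² (≈ 0.27 on 250 frames); the
low-confidence flag therefore uses the degrees-of-freedom-adjusted R²,
which stays near zero on noise, with a 0.2 cutoff. Cluster pruning is a
greedy loop: test the removal of each cluster, remove the one whose
removal improves R² the most, repeat until no removal helps or one cluster
remains; at least one cluster always survives, and R² is non-decreasing
across iterations by construction.

**Phase sorting.** Each frame's phase is frac(f·t + φ/2π) with the phase
offset of its window. Frames are sorted by phase; frames falling in the
same circular phase bin (width 1/15 of the cycle) are averaged — this
averaging over repeated visits of the same phase is what suppresses frame
noise — and the bin means are moved onto the exact equidistant grid by
circular linear interpolation between mean bin phases. The result is
invariant to frame order, and a densely, uniformly sampled sinusoid is
reproduced to within 1% of its amplitude. Fewer distinct phases than half
the requested grid raises an "insufficient phase coverage" error.

**Amplitude convention.** Q and S_Blood both use the peak-to-trough
(max − min) amplitude over the 15-phase cycle, so their ratio is
convention-free; a first-harmonic alternative is available
(`amplitude_convention="first_harmonic"`). S_Blood averages over all
voxels of the pruned R_sort rather than taking a single brightest voxel:
signal variability inside blood-filled regions is substantial, and the
mean is robust to single outliers. Voxels with undefined phase coverage
are excluded from both the QDP numerator and denominator and logged.

**Scoring.** The 18-segment model (R1–R10, L1–L8) is read with the
segmental rule: defect fraction strictly greater than 0.75 scores 2,
otherwise a defect at or above the floor scores 1. Visual readers give no
explicit minimum area for a subsegmental defect; the default floor of 5%
of the segment area suppresses single-voxel speckle and is the main
divergence from visual reading (config `score_floor`). A patient is
positive with ≥ 1 segmental or ≥ 2 subsegmental defects. Multi-slice
studies union their defect masks before scoring — a defect visible on any
slice counts against the segment; this 2D-reading convention is a
documented choice, not anatomy. Defects explained by parenchymal pathology
can be removed with an exclusion mask (`preful score --exclusion-mask`).

**Agreement statistics.** Proportions carry exact binomial
(Clopper–Pearson) 95% CIs; the exact method was chosen because it
reproduces the published bracket for 35/36 sensitivity ([85, 100] after
integer rounding) where a Wilson interval does not. Reported percents are
rounded half-up to integers, as such tables print them. Cohen's κ is
unweighted, κ = (p_o − p_e)/(1 − p_e), with the large-sample standard
error and κ ± 1.96·SE clipped to [−1, 1]; when all mass sits in one cell,
p_e = 1 and κ is undefined (flagged, not raised). Agreement bands: almost
perfect strictly above 0.8, substantial 0.60–0.80, moderate 0.40–0.59,
fair 0.20–0.39, slight below 0.20 (including negative κ). A κ of exactly
0.80 is banded substantial, because the almost-perfect band requires κ to
*exceed* 0.8.

## The phantom: what it emulates and what it does not

The generator produces

    s(x,t) = baseline(x) + resp_amplitude·w_resp(x)·sin(2π f_resp t)
             + A_card(x)·sin(2π f_card t + φ(x)) + ε(x,t)

on a procedural anatomy: two elliptical lungs, a mediastinal block, and a
blood-pool region of ~2.5% of A_s inside it. A_card is
qn_truth·blood_amplitude in the lung and blood_amplitude on the blood
pool, with a deterministic ±3% spatial spread (mean exactly 1) that
mimics intra-ROI blood-signal variability and keeps the strict percentile
selection non-degenerate even in the noise-free limit. The respiratory
weight w_resp grows linearly toward the diaphragm, giving the high-pass
filter a realistic spatially varying component to remove. ε is i.i.d.
Gaussian; at the SNR of interest the Rician magnitude bias is negligible,
so magnitude-noise modeling is deliberately omitted. φ(x) is 0 by default,
with an optional linear gradient (`phase_gradient`) to exercise phase
sorting under spatial de-phasing.

Defaults mirror a typical acquisition and are the conditions under which
all recovery results are quoted: 250 frames at 0.248 s (62 s per slice),
f_card = 1.2 Hz, f_resp = 0.25 Hz, blood amplitude 100 (arbitrary units —
only the Q/S_Blood ratio matters), healthy parenchymal Q_N = 10%,
respiratory amplitude 30, noise σ = 2 (2% of the blood amplitude). Planted
defect voxels get Q_N = 0.5%, well below the 2% threshold, so ground-truth
QDP is unambiguous; healthy parenchyma must be specified at or above 2%.
The 18 segments are equal-area row-major bands per lung (10 right,
8 left), tiling the lung mask exactly — segment geometry is bookkeeping,
not anatomy.

The phantom does **not** emulate through-plane motion, bSSFP banding,
cardiac motion artifacts, vascular tree structure, regional heart-rate
variability, or registration error (series are generated perfectly
registered; the pipeline only checks registration coarsely by phase
cross-correlation against the first frame and warns above 1 voxel of
drift). Passing phantom-recovery tests therefore demonstrates the
correctness of the numerical chain under the stated signal model, not
robustness to scanner physics or failed registration.

## Problem sizes used in tests and the acceptance script

Phantom tests run on 64×64 (default) or 48×48 grids with 200–250 frames;
one full pipeline run takes a fraction of a second, and the multi-seed
recovery suites (20 noise realizations) a few seconds each. The acceptance
script uses 10 seeded noise realizations of the default 64×64 phantom with
a planted ~25% defect load, plus one noise-free run for phase-coherence
measurement. These sizes were chosen as the smallest at which the
phantom's search region comfortably supports 98th-percentile blood-pool
selection (~2000 A_s voxels) and segment areas are large enough for the
5% score floor to be meaningful.

## Known limitations

- The frequency search assumes a single dominant cardiac peak in the band;
  severe arrhythmia (frequency jumps between windows) is only partially
  absorbed by the piecewise fit, which shares one global frequency.
- QDP at the 2% threshold is sensitive to residual noise in the
  phase-resolved stack when fewer than ~10 frames fall in a phase bin
  (short series or high heart rates); the binning average is the only
  noise control at that stage.
- The segment model is procedural; mapping scores onto anatomical segments
  requires supplying a real segment-label map.
- Absolute perfusion (mL/min/100 mL) is out of scope; Q_N is a relative
  measure, and cross-field-strength or cross-sequence comparability of the
  2% threshold is not addressed.
- Observer-variability statistics can only be recomputed from score
  tables; the bundled fixtures cover the detection and classification
  tables of the validation cohort, not its intra/inter-observer readings,
  whose underlying per-patient scores were never published.
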