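# Methods

## The measurement model

A single-ROI recording is modeled as

    F(i) = a · (i + 1)^b · [1 + g · r(t_i) + Σ_k m_k(t_i)] + ε_i

with photobleaching of the resting fluorescence as a power curve
PC(x) = a·x^b in the 1-based frame index x = i + 1 (so the curve is
defined at the first frame; the offset is configurable), an evoked
response r(t) scaled by a genotype factor g, spontaneous miniature events
m_k, and additive noise ε. Multiplicative structure is deliberate: evoked
and spontaneous signals ride on the bleaching baseline, so dividing by the
fitted curve both flattens the baseline and converts the trace to ΔF/F
units in one step (ΔF/F = F/PC − 1).

Bleach fitting is ordinary least squares on log F versus log x over the
pre-stimulation frames. The closed form is exact on noiseless power-law
data, needs no iteration or starting values, and is scale-equivariant
(multiplying the trace by c multiplies a by c and leaves b untouched). The
log transform introduces a small multiplicative bias under additive noise,
negligible at the noise levels of interest (recovered b is within 0.005 of
the truth at 100 pre-stimulation frames and noise SD 0.25% of baseline,
checked by simulation).

ΔF/F is computed on the bleach-corrected trace as corrected − 1, and the
5-frame centered rolling average is applied to the corrected trace before
feature extraction; at the edges the window shrinks symmetrically rather
than inventing padding values. Feature definitions:

* resting_F — fitted curve at the last pre-stimulation frame;
* max_F, ΔF — maximum of the raw trace and its difference from resting_F;
* max_dff — maximum ΔF/F at or after stimulation onset (pre-stimulation
  transients belong to mini detection, not evoked features);
* min_dff_post_stim — minimum ΔF/F from onset to onset + 2 s (captures
  the ER release dip; the window length is a parameter, as no principled
  universal value exists);
* time_to_peak_s — onset to ΔF/F peak;
* t50 / t100 recovery — peak to the first sample at or below half peak /
  within k·σ of the pre-stimulation corrected baseline (k = 1 by default;
  there is no canonical criterion for "fully recovered", so the noise
  band is explicit). Both are None when the trace never crosses the
  level within the recording.

Three normalizations support cross-group figures: division by a control
group's mean (control maps to 1), per-batch division by that batch's
control mean (removes microscope-gain differences before pooling), and
pairwise time-course scaling by the single factor 100 / (max − min) of the
control trace, after which the control span is exactly 100.

## Preprocessing

Rolling-ball background subtraction (radius 50 px by default, the scale
appropriate to NMJ structures on 512×512 EMCCD frames) uses the classic
ball-under-surface estimate per frame, clipped at zero. Registration is
translation-only, matching the capability of the stabilizer tools these
recordings are processed with: each frame is aligned to the first frame by
masked (Padfield) phase cross-correlation restricted to the NMJ ROI, which
is insensitive to the photobleaching trend; shifts are integer pixels, and
vacated pixels are filled with the frame median — a neutral fill that does
not bias ROI means at the edges. A frame whose post-correction correlation
with the reference inside the ROI falls below 0.5 (or a featureless
reference) raises an uncorrectable-motion error. QC discards traces with
residual motion (mean absolute frame-to-reference difference inside the
ROI, normalized by the ROI mean, above 0.2 — the original criterion was by
eye, so the threshold is our construction and a parameter) or an
out-of-focus flag, and then discards NMJs left with fewer than 3 usable
ROIs.

## Miniature-event detection

Minis are detected on resting ΔF/F traces as local maxima of the
median-subtracted signal above 3 robust SDs, with three shape gates
reflecting the physics of a one-frame rise and multi-frame decay:
persistence (the next sample stays above half threshold — rejects
single-frame noise spikes), a sharp rise (the largest single-frame
increment just before the peak is at least the threshold and 40% of the
peak height — rejects ripples riding an earlier event's decay tail), and
elevation (the peak stands a full threshold above the median of the frames
preceding its rise — rejects bounces after a noise dip). The noise SD is
estimated from first differences (MAD/√2): sparse transients occupy many
frames but contribute one large increment each, so the difference-based
estimate stays calibrated where the plain MAD of the trace is inflated by
event tails (by ~40% at 0.5 events/s with a 0.2-s decay). The reported
event time is the rising edge — the onset at sampling resolution — and
the amplitude is the peak's median-subtracted ΔF/F.

The minimum-separation parameter (default 0.2 s) trades double-counting
against merging; detector validation against ground truth uses the
sampling-resolution setting (2 frames), since homogeneous Poisson trains
at 0.5 events/s place ~9% of events within 0.2 s of a neighbour. Measured
operating characteristics at amplitude ≈10σ (100 seeds, 20-s recordings at
50 frames/s): recall 0.97, precision 0.99, and a null false-positive rate
of ~0.003 events/s on pure-noise traces at the 3σ threshold.

## Static-image quantification

The NMJ mask comes from a manually chosen threshold on the reference
(plasma-membrane marker) channel and is applied unchanged to the marker
channel. Intermodes thresholding smooths the 256-bin min–max histogram
with an iterative 3-bin mean until exactly two local maxima remain and
takes their midpoint (8-bit convention of the source tooling; iteration
cap 10,000; a histogram that never becomes bimodal is an error, except in
puncta partitioning where it yields the degenerate no-puncta result so
control images flow through batch analyses). Puncta partitioning reports
mean intensities over the whole NMJ, the puncta ROI, and the complement;
the three sums conserve mass exactly because the masks partition the NMJ.
Object sizes use 8-connected components, matching the default particle
analysis of the source tooling.

## Statistics

The unit of replication is the larva: each larva contributes the mean of
its NMJ values, and n counts larvae. Routing: every group is tested with
Shapiro-Wilk at α = 0.05; all-normal routes to parametric tests (pooled-
variance two-tailed Student's t for two groups — Welch is available as an
option — or ANOVA), otherwise Mann-Whitney U / Kruskal-Wallis. Levene's
test on variances is computed and reported, but normality alone drives the
routing. Mann-Whitney uses exact enumeration when the smaller group has
n ≤ 8 and there are no ties, and the tie-corrected normal approximation
otherwise.

The genotype × stimulation-frequency design is analyzed with a
mixed-effects repeated-measures model: fixed effects genotype * frequency
with sum-to-zero contrasts (so each first-order coefficient group is a
main effect averaged over the other factor), a random intercept per larva,
REML estimation, and Wald chi-square tests per term. The mixed formulation
tolerates unbalanced larva counts and missing cells; a larva observed at a
single frequency triggers a warning but is retained. With a single
frequency level the design collapses to a one-way between-subject
comparison (F = t² for two groups). Post-hoc: Tukey HSD for all pairs,
Dunnett for each-versus-control.

## The synthetic-data generator

The generator emulates the statistical and kinetic structure the analysis
assumes, with compartment defaults chosen once as realistic study
conditions: 50 frames/s for cytosolic and postsynaptic recordings, 10
frames/s for ER and mitochondrial ones; bleach a = 1000 a.u., b = −0.05;
a 5-s pre-stimulation baseline (a choice — protocols rarely state one);
2-s trains; genotype scale 1.0 for wild type and 0.5 for mutant presets
(evoked responses reduced to about half).

Evoked kernels (all zero before onset, and identically zero for a
zero-frequency train):

* cytosol/postsynaptic — saturating exponential rise during the train to
  peak_dff at train end, then exponential decay. The cytosolic rise time
  constant (2 s) is comparable to the train: a slow indicator integrates
  Ca²⁺ over the whole train, so the peak is well localized at train end
  rather than sitting on a flat plateau (an earlier 0.2-s rise made
  time-to-peak unidentifiable at any noise level). Decay 1 s; peak ΔF/F
  1.5.
* er — an immediate lumenal dip (store release; default amplitude 0.15,
  recovery 2 s) plus a slow positive uptake component (alpha shape,
  10 s) that starts when the train ends, so the dip amplitude is by
  construction the kernel minimum.
* mito — rise during the train to peak ΔF/F 2.0, rapid partial decline
  (1 s) to a plateau at 40% of peak, then a slow (30 s) return, giving a
  total recovery beyond 40 s.

Kernel amplitudes equal their stated parameters whenever the train
frequency is positive; frequency dependence enters at the cohort level
through a saturating factor f/(f + 20 Hz) applied to the amplitudes, plus
a lognormal per-larva factor (CV 0.1). Minis are a homogeneous Poisson
process with instantaneous rise, exponential decay (0.2 s), and
truncated-normal amplitudes. Shot noise is Poisson with mean equal to the
signal; camera gain is not modeled. Movies render boutons as 2-D Gaussian
spots (σ = radius/2) whose brightness follows independently simulated
traces, with optional integer-pixel whole-field drift (what translation
registration must undo; subpixel drift is out of scope). Static pairs
render puncta as uniform-intensity disks so ground-truth pixel membership
is unambiguous; real puncta are diffraction-blurred, so threshold-accuracy
results on synthetic images are an idealized upper bound. All randomness
flows from a single seed; identical configurations are byte-identical.

What passing tests show — and what they do not: recovery and operating-
characteristic results certify the pipeline's correctness on data obeying
the forward model (power-law bleach, linear indicator response, additive
Gaussian/Poisson noise, rigid drift). Real recordings add indicator
nonlinearity and saturation, muscle-contraction artifacts, focus drift,
bleed-through and non-rigid motion, none of which the generator emulates;
results on real data therefore depend on QC catching those violations.

## Problem sizes and numerical choices

Simulated validation sizes (chosen as desk-scale defaults and stated here
once): 200 traces for evoked-feature recovery at 2% noise; 20
larvae/genotype for the contrast recovery and 60 repetitions of the
10-larvae power check; 100 seeds each for detector recall/precision and
the null false-positive rate; 100 random traces for the rolling-average
oracle. Tolerances: bleach-model identity to 1e−9 relative; rolling
average bitwise against brute force (direct per-window means, no running
sums); mass conservation to 1e−12 relative; Mann-Whitney exact against
enumeration to 1e−9. Tie-breaks: argmax takes the first index (relevant
only on noiseless plateaus); the peak-search window starts at the
stimulation-onset frame (floor of onset × frame rate). Degenerate inputs
raise typed errors: empty ROIs, non-positive pre-stimulation values in the
log-log fit, even smoothing windows, zero-variance groups, flat control
traces in span normalization, batches without control datapoints.
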