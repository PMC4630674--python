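# Methods

This note records the models and procedures implemented in `locogait`,
the assumptions behind them, the constants that matter and why they have
the defaults they do, and the choices made where the design was genuinely
open.

## Imaging geometry and coordinates

A single camera records the corridor; each frame is a composite with the
side view on top and the mirror-reflected bottom view below a horizontal
split row.  The two views share the horizontal (forward) axis; a 1D
affine correction fitted by least squares on a calibration object
(thresholded at 80% of intensity) aligns side-view x to bottom-view x.
Physical coordinates are millimetres: x forward (enforced by mirroring
frames of left-walking animals), y lateral with the corridor midline at
zero and the animal's right positive, z height above the floor.  When a
video has been mirrored, reported y flips sign, so "the animal's right"
stays the animal's right.

## Tracking

**Preprocessing.** The pre-session corridor image is subtracted from
every frame (clipped at zero).  Per view, a tight bounding box spans the
first/last rows and columns above 10% of the stack's maximum intensity
after median filtering; its final size is fixed at
min(mean + 3·SD, max observed) per dimension so single-frame noise cannot
inflate it, and the center trajectory is smoothed with a width-5 moving
average.  Boxes are computed separately for the two views: the location
priors below normalize positions to the box, which must therefore hug the
animal's silhouette in its own view.

**Detection.** Each feature class (paw, snout, tail) in each view has a
linear detector — a weight template plus bias from a linear SVM trained
on labeled patches — with window sizes (full resolution): paw 30×30
bottom / 20×30 side, snout 40×40 / 20×40, tail 30×30 / 25×30, scaled by
`detector_scale` for reduced-resolution work.  Scoring slides the window
over the (padded) bounding box.  The training protocol for synthetic
renderings uses positives at true feature centers and three kinds of
negatives: other features' neighborhoods (centers plus offsets up to
3 px — a detector must reject the whole neighborhood of a wrong feature,
not just its center pixel), points on the foreground silhouette boundary
(body-outline edges otherwise produce paw-like blob responses), and
random background windows.

**Non-maximum suppression.** Candidates are above-zero pixels accepted
greedily in score order (ties to the smallest row, col) subject to a
minimum separation.  The suppression radius is *half* the detector window
per axis; the side view, where features overlap heavily, uses a quarter.
Rationale: the window spans two to three paw diameters, and front and
hind paws of a trotting mouse approach within one paw length every
stride — suppression over the full window would merge their candidates
exactly when identity is hardest, and the half-window radius resolved
every such approach in the rendered-fixture round trip while the
full-window radius failed ~5% of frames.

**Cross-view fusion.** A side candidate matches a bottom candidate when
their horizontal positions agree within 30% of the detector width; each
side candidate joins at most one bottom candidate (nearest in x), one
bottom candidate may collect several side candidates, and equidistant
ambiguities are resolved by agreement of the moving/not-moving flag
(frame-difference pixels above 10% of the window area), with genuinely
unresolvable cases keeping both pairings.

**Location priors.** Paw identity comes from the corridor configuration:
on the unit-normalized bottom-view box, each paw is anchored to its
corner (front-right paw to the front-right corner, etc., with the snout
anchored front-center), and the prior is the inverse distance
1/(d + 0.05) to that corner, zero beyond d = 0.6.  The 0.05 cap bounds
the otherwise unbounded inverse at the corner itself.

**MAP multi-target tracking.** Trajectories maximize
`C(x) = Σ_o [Σ_t U(x_{o,t}) + α Σ_t P(x_{o,t}, x_{o,t+1})]` with
`U` = detection score × location prior (multiplicative weighting),
`P = 1/(1 + d)` (finite at zero displacement), α = 0.1, and transitions
longer than the bounding-box displacement plus 15 px infeasible
(Euclidean displacement).  Exclusivity — one object per candidate per
frame — couples the objects, so the exact optimum is found by dynamic
programming over joint per-frame states: injective partial maps from
objects to candidates, with gaps allowed.  A gap carries zero detection
score; transitions into and out of a gap carry zero transition score and
no feasibility constraint.  (The alternative — carrying the last-seen
position through the gap and testing the bridged distance against a
gap-scaled limit — requires non-Markov state and an exploding state
space; with the per-frame candidate cap below, gaps are rare and short,
and interpolation across them stayed within tolerance in every fixture
test.)  Ties break lexicographically by candidate index, gaps first.
With four paws and the per-frame candidate cap of 6, the joint state
space holds ~1 000 states and a 200-frame video tracks in about two
seconds.  The side-view z trajectory is found afterwards by the same
recursion as a single-object problem over side candidates compatible
with the fixed bottom x; the tail is detected independently per frame as
the largest bottom-view region with an overlapping side-view region,
its medial line sampled at 15 equidistant stations.

## Stride segmentation

Stance and swing separate on the forward-velocity derivative with a
Schmitt trigger: definitely stance below 20 mm/s, definitely swing above
40 mm/s, state held in between.  Velocity is computed by central
differences on the *raw* positions: any centered pre-smoother leaks swing
displacement across the touchdown frame and biases onsets by up to two
frames, which is why the width-3 first-order smoother used elsewhere for
trajectory averaging is not applied here.  Noise robustness comes from
the trigger's dead band, a width-3 boolean median that removes isolated
misclassified frames, a 3-frame transition hysteresis (backdated to the
run start once confirmed), and a 5-frame minimum phase duration.  At
400 fps this combination recovers noiseless onsets within ±1 frame and,
with 0.1 px positional noise at full camera resolution (σ ≈ 0.046 mm),
stance onsets within ±2 frames in ≈98% of cycles.  It assumes positional
noise well below ~0.1 mm per frame; heavier noise at 400 fps would
require pre-smoothing and the corresponding onset bias.

Each stance→stance interval yields one stride record; walking speed is
the body-center forward displacement over the stride divided by its
duration, with the body center defined as the centroid of the four paw
x positions when no dedicated track exists.  Strides sort into half-open
speed bins [k·0.05, (k+1)·0.05) m/s anchored at zero; an animal
contributes to a bin only with ≥ 5 strides.  Per-stride trajectories are
linearly resampled to 100 points; per-animal per-bin averages are
smoothed with a first-order Savitzky-Golay filter, 3-point window.

## Coordination

Phases are fractions of the reference stride cycle, aggregated with
circular statistics (mean resultant vector).  Support categories pool
homolateral and homologous two-paw configurations into "two other"
(diagonal is kept separate); fractions are computed by dense sampling of
the stride (1000 points), equivalent to interval arithmetic on the event
grid, against which it is tested.  Signed double support looks backwards
up to 25% of the cycle for the contralateral lift-off; lift-offs deeper
in the past are reported missing rather than clamped.  Feature phases
(tail segments, nose) are the circular cross-correlation lag, computed
by FFT, that maximizes correlation with the hind-paw difference signal
x_HR − x_HL normalized to the stride; a fixed time delay D shows up as
phase = cadence·D (mod 1), so regressing unwrapped phase on cadence
estimates D as the slope.  Unwrapping assumes |Δphase| < 0.5 between
adjacent ascending cadence bins and flags violations.

## Mixed-effects models

Stride-parameter–speed relations are linearized by the best of seven
families (linear, quadratic, cubic, inverse, logarithmic, exponential,
power); exponential and power fits are initialized from log-space least
squares and refined by nonlinear least squares on the original scale.
Selection is by goodness of fit with a BIC parameter penalty (a cubic
must earn its two extra coefficients), with the Shapiro-Wilk residual
normality p-value reported as a diagnostic and near-ties going to the
simpler family; degenerate data (all families at R² ≈ 0) returns a
flagged linear fit.

The mixed model is `response ~ 1 + fixed terms + (1 | subject)`
(optionally a random slope), fitted by maximum likelihood — not REML —
so that likelihood-ratio comparisons of fixed-effect structures are
valid; statsmodels' MixedLM does the estimation, and because single
optimizers can stall at the zero-variance boundary (reporting an
infinite likelihood), the fit tries Powell, L-BFGS and CG and keeps the
best finite-likelihood result.  Marginal R² is
var(fixed predictions) / (var fixed + var random + var residual);
conditional R² adds the random variance to the numerator.  Model
comparison uses 2·ΔlogLik against χ² with the parameter-count
difference; Satterthwaite-corrected conditional F tests are deliberately
out of scope — the LRT replaces them.  Prediction for a new animal uses
the fixed effects only, passing speed through the linearization's
transform and back.

## Passive tail/nose model

Three steps: (1) hind-paw forward trajectories from stride parameters
with constant swing velocity (stride length / swing duration) and
stationary stance, the two paws offset by the alternation phase; (2) the
body-axis angle of the perpendicular bisector of the segment joining the
paws, θ = atan((x_R − x_L)/w) — widening the base w strictly *shrinks*
the oscillation for the same forward offset; (3) each tail segment as a
lever about the oscillation center, S_yi = L_i·sin θ delayed by D_i, and
the nose anti-directed, N_y = −L·sin θ delayed by D_nose.  Default
delays: 31 ms at the tail base, 96 ms for the nose (values obtained by
phase-vs-cadence regression), and increments of max(−0.23·k + 3.97, 0) ms
between segments k and k+1, counted from the base — so the base segment
carries exactly the 31 ms and increments shrink toward the tip (the
negative tail of the schedule floors at zero).  Readouts needing drive
history before the recorded start are flagged missing rather than
extrapolated.  Fixed time delays make each segment's phase grow linearly
with cadence at slope D_i (time-locked); zero delays give a perfectly
phase-locked model.

## Synthetic data

The generator encodes the study conditions the analyses assume.  Stride
laws: cadence = (2.5 + 7·v)·(20 g/weight)^0.25 strides/s and stride
length = v/cadence, so cadence and stride length rise with speed, larger
animals take longer, less frequent strides at the same speed, and
speed = stride length × cadence holds exactly; duty factor
0.68 − 0.8·v clipped to [0.35, 0.75], falling steeply with speed (so
stance duration does too).  The law coefficients are this package's
documented choices of realistic magnitudes (~4 strides/s and ~59 mm
strides at 0.25 m/s for a 20 g mouse); the functional shapes, not the
exact numbers, carry the content.  Phasing is a symmetric trot (FR = 0,
FL = 0.5, HL = front-hind phase, HR = front-hind + 0.5); the front-hind
phase is the mutant-like dial and left-right alternation never moves.
The stride period, stance duration and phase offsets snap to the frame
grid so ground-truth events fall on sampled frames, and each paw's phase
offset is compensated in its anchor so the *mean* paw positions keep
their anatomical spacing.  Vertical paw motion is a half-sine during
swing.  The tail is either rigid — riding the hind-limb difference
signal with a constant fractional lag per segment, hence phase-locked at
every speed — or passive, driven through the model above by the actual
generated hind-paw trajectories (extended backwards so delayed readouts
have history), hence time-locked.  Gaussian positional noise is optional
and seed-reproducible.

The renderer draws body ellipses, paw discs, snout disc and tail
polyline in both views at a quarter-resolution corridor
(360 × 104 px, 0.545 px/mm) by default and returns the exact drawn
positions as ground truth.  What the fixtures do **not** emulate: fur
texture and lighting variation, motion blur, paw-over-paw occlusion in
the bottom view (paws are drawn over the body at full intensity),
reflections, and the detector-confusing appearance variation of real
video.  Passing the round-trip tests therefore certifies the geometry,
optimization and analysis chain — not detection robustness on real
footage, where detector quality dominates.

## Problem sizes and numerical choices

Unit and acceptance tests run at sizes chosen to exercise each property
fully: 200-frame quarter-scale renderings, 100 random tracker instances
capped at 20 000 joint paths (so exhaustive enumeration stays exact),
2–3 s gait trials, 100 mixed-model replicates at 30 subjects × 100
strides for coefficient coverage, and 1000 smaller replicates
(8 subjects × 25 strides) for likelihood-ratio type-I calibration — the
smaller design keeps a thousand maximum-likelihood fits cheap without
changing the asymptotics the test checks.  Coefficient coverage is
counted per coefficient (each within 2 SE ≈ 95% of the time for a
calibrated estimator).  Exact score ties anywhere break
lexicographically; optimizer tolerances are the library defaults with
maxiter 500; degenerate inputs (empty frames, constant signals,
zero-variance trajectories, single subjects) raise or return flagged
missing values rather than silently guessing.

## Known limitations

Tail z from the side view maps stations by nearest-x and is coarse when
the tail curls steeply; the gap convention in the tracker is the simple
zero-score bridge described above; stance detection assumes sub-0.1 mm
positional noise at 400 fps; the fixture renderer's realism limits are
listed above; and conditional F tests with Satterthwaite degrees of
freedom are intentionally not provided.
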