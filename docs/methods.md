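# Methods

## Scope

The package models and analyzes adaptation of visual responses in
superficial superior colliculus (SCS) units probed with bright round spots
on a dark background. Three components interlock: a mechanistic model of
the ON channel (`scadapt.model`), a phenomenological synthetic-population
generator with exact ground truth (`scadapt.population`), and the
quantification pipeline (`scadapt.analysis`). The generator, not the
mechanistic model, backs the pipeline tests, so that every fitted quantity
has a closed-form true value; the model is validated against the recorded
population numbers separately. OFF-pathway mechanics and the inhibitory
surround are out of scope: the model is ON-only, and facilitation appears
only phenomenologically in the generator.

## Stimulus representation

All geometry is in degrees of visual angle (origin at the mapping-grid
centre, x rightward, y upward); an on-screen extent of c cm at viewing
distance D cm subtends atan(c/D) — 1 cm at 16 cm is 3.58°, the familiar
"~3.6°/cm". Protocols are ordered lists of spot events; rendering
discretizes them onto a uniform grid (default 1° spacing, 80°×80° extent,
dt = 5 ms) as hard discs of luminance 1 on background 0 (a node is lit if
its centre falls inside the disc; no anti-aliasing — immaterial at 1°
spacing against ≥2.5° spots). Gratings render as
0.5·(1 + contrast·sin(2π(f_s·x′ − f_t·t))). The default dt resolves the
shortest (0.05 s) adaptor with ten frames.

## The mechanistic model

Luminance S(x,y,t) feeds, per grid node:

1. **Front-end integration**: du/dt = (S − u)/τ_f. This photoreceptor/
   bipolar integration stage sets the high-temporal-frequency roll-off;
   without it the transient stage below is a pure high-pass and the grating
   temporal tuning saturates instead of peaking.
2. **Transient (ON-only) extraction**: dm/dt = (u − m)/τ_m and
   q = max(u − m, 0). Only luminance *increments* pass; a static scene
   produces no drive. τ_f and τ_m jointly place the band-pass peak near
   1/(2π√(τ_f τ_m)) ≈ 2 Hz.
3. **Local adaptation field**: da/dt = (S − a)/τ_Lr while charging
   (S ≥ a), (S − a)/τ_Ld while decaying — fast onset, slow recovery. The
   divisive gain follows a through one more brief stage
   db/dt = (a − b)/τ_g (the latency of retinal gain control), is blurred
   spatially with a Gaussian of width σ_spread, and acts before pooling:
   g = 1/(1 + κ_L·blur(b)). Because of τ_g the first burst of a response
   largely escapes the adaptation it itself induces, as in the recordings,
   where the first presentation elicits a full burst and later ones are
   scaled down.
4. **Pooling and normalization**: the drive is p = Σ w·q·g with w a
   unit-sum Gaussian of width σ_RF = RF_diameter/√2 (the diameter follows
   the mapping convention √(a²+b²)); the RF-pooled flux Σ w·S passes
   through an asymmetric low-pass (charge τ_Nr, decay τ_Nd) into the
   normalization pool A_non, and

       r(t) = r_0 + R_max · p / (σ_50 + p + κ_N·A_non).

Transient extraction *precedes* gain and pooling. The alternative order
(pool, then rectify a single scalar against a low-passed copy) makes the
window-mean response nearly invariant to the gain at stimulus onset — the
integral of a rectified high-pass approaches τ_m times the late drive, which
adaptation has equalized across presentations — and cannot reproduce the
measured 60% second-response reduction. Which order the original gain-control
formulation used is not decidable from the available description; the choice
here is the package's own, made for the reason just stated.

Local adaptation (blurred a at the stimulated site) reproduces co-localized
suppression with slow recovery and the sigmoidal spatial release;
A_non reproduces the distance-independent, sub-second-recovering component
seen with displaced adaptors inside the RF.

### Integration

States advance with the exact exponential update for piecewise-constant
input (one luminance frame per step), dt = 5 ms. This matches the
closed-form exponentials for constant stimuli to machine precision and
keeps window-mean amplitudes stable under dt refinement (halving dt moves
flash amplitudes by <1%). Forward Euler at the same dt would leave ~0.2%
closed-form error and larger amplitude drift for no gain in simplicity.

### Parameters (calibrated defaults)

| parameter | value | meaning / why |
|---|---|---|
| τ_f | 0.05 s | front-end integration; high-TF roll-off |
| τ_m | 0.10 s | transient subtractor; with τ_f puts the TF peak at 2 Hz |
| τ_Lr | 0.078 s | local charging = measured ON onset τ (anchor, not tuned) |
| τ_Ld | 2.5 s (small RF) / 1.0 s (large RF) | slow recovery; ≥90% at 11 s, t50 > 1 s |
| τ_g | 0.05 s | gain latency; sets the 2nd/1st contrast achievable |
| σ_spread | 1.6° | blur of the adaptation field; displacement d50 ≈ 3.5° |
| κ_L | 100 | local gain weight; 2nd-ON reduction ≈ 61% |
| τ_Nr / τ_Nd | 0.06 / 0.30 s | non-local pool charge/decay; non-local t50 ≈ 0.29 s |
| κ_N | 40 | non-local weight; depth of displaced-adaptor suppression |
| σ_50 | 0.1 | semi-saturation (drive units; RF-pooled drive ≤ 1) |
| R_max, r_0 | 40 Hz, 2 Hz | output scale and baseline |

Calibration was performed once, by direct search on the battery
(flash-train reduction, 11 s recovery, co-localized and non-local t50,
displacement d50, grating temporal peak), and frozen. With these defaults
the model gives: 61.1% second-ON reduction, 95.5% recovery at 11 s,
co-localized t50 = 2.6 s, non-local (large-RF, 12° displacement)
t50 = 0.29 s, displacement d50 = 3.5°, and grating temporal tuning with an
interior maximum at the 2 Hz sample of the standard sweep. The model's
spatial-frequency cutoff at 2 Hz lies near 0.05 c/deg — reported as the
model's own value, not as a reproduction target.

## The synthetic-population generator

The generator is separable by construction — onset × recovery × space —
so pipeline estimates have exact targets. Per channel (ON, OFF) and per
stimulus location, an adaptation state A charges toward 1 during a stimulus
with τ_on and decays with τ_rec between stimuli. The expected response to
an event is

    amplitude = peak · (1 − ρ · Σ_L A_L · Σ(d_L)) · F,

ON evaluated at stimulus onset (state before charging), OFF at offset
(after charging — so a control OFF response is itself partially adapted by
its own 0.6 s stimulus, exactly as in the recordings, where OFF responses
are always preceded by the stimulus that elicits them). Σ(d) is the
sigmoidal spatial release, 1/(1+exp((d−d50)/slope)) for a *displaced*
adaptor and exactly 1 for co-localized stimuli (same location, same state);
the discontinuity is a deliberate definitional choice that makes every
calibration identity exact. F is an optional facilitation factor
(1 + φ·e^(−gap/τ_φ)) applied to ON responses of flagged units when the
immediately preceding event sat outside the RF but within 10° of its edge.

Central (population-mean) unit: ρ_on = 0.86, τ_rec^ON = 2.5 s gives
ρ_on·(1−e^(−0.6/0.078))·e^(−0.9/2.5) = 0.600 — the 60% flash-train
reduction — and ~99% ON recovery at 11 s; ρ_off = 1.0, τ_rec^OFF = 0.9 s,
τ_on^OFF = 0.28 s give a 32.5% second-OFF reduction and ~100% OFF recovery
at 11 s. d50^ON = 3.9°, d50^OFF = 5.4° with slopes 1.2° / 0.8°;
peaks 30 / 20 Hz on a 2 Hz baseline; φ = 0.3, τ_φ = 0.3 s (facilitation
magnitude is a qualitative default — per-unit variance for it is not
published).

Population sampling (seeded, deterministic): RF diameters are log-normal
with median 15° and shape set so the expected fraction below 20° is 2/3.
Per-unit flash-train reductions are drawn from truncated normals whose
pre-truncation location is solved so the *post-truncation* mean equals the
population value (0.60 ON with SD 0.33 = SEM 6%·√31; 0.32 OFF, capped at
the structural OFF maximum 1−e^(−0.6/τ_on^OFF) ≈ 0.88); each draw maps
deterministically onto (ρ, τ_rec) — ρ varies below the cap, τ_rec stretches
above it — so the realized reductions match the draws exactly. Where no
spread is printed, fields use a 20% CV. The OFF d50 spread (0.8°) is set
narrower than ON (1.6°), following the histogram-fit ordering rather than
SEM·√n, which would invert it. 7/11 of small-RF units are flagged
facilitating.

Rate traces superpose alpha-function kernels (time-to-peak 0.05 s ON,
0.10 s OFF) on the baseline, each scaled so its *mean over the measurement
window* equals the event's expected amplitude — the window-mean measure
then returns ground truth exactly on noiseless traces. Spikes come from an
inhomogeneous Poisson process via thinning against the trace maximum, with
the rate piecewise-constant over samples; counts in any window are Poisson
with the matching integral. No refractoriness, bursting, inter-unit
correlation or eye movements are modelled: passing spike-level tests shows
correct Poisson statistics, not realistic spike-train microstructure.

## Analysis pipeline

- **PSTH**: half-open bins [left, right), default 25 ms; counts =
  rate·n_trials·bin_width holds identically, also after subtraction
  (counts become fractional).
- **Response measure**: mean rate in a fixed window after onset (ON) or
  offset (OFF) minus baseline, floored at zero. Default window 0.02–0.32 s
  — the recordings mark the measurement bins on PSTHs without printing
  bounds; this window covers the transient and excludes the 0.6 s stimulus
  tail. Baseline is the 0.5 s before each cycle's first stimulus (the
  pre-test interval is contaminated by the adaptor's OFF response). Fixed
  windows are used; per-unit latency tracking is not.
- **Adaptor subtraction**: ratewise difference of combined and
  adaptor-alone PSTHs, negatives preserved so window means stay unbiased;
  flooring happens only at the amplitude stage.
- **Fits** (scipy least squares, deterministic initializations): the 2-D
  Gaussian RF fit is initialized from amplitude moments, with the printed
  equation's sign read as a decaying Gaussian — the only reading with a
  finite RF diameter — and the a↔b/θ+90° degeneracy broken by a ≥ b,
  θ ∈ [0, π); the spatial sigmoid from (max, distance at half-max, 1°); the
  onset exponential from (1, shortest duration). All three recover
  noiseless self-generated parameters to ≤1e-6 relative error. Degenerate
  inputs (all-zero maps, constant reductions, monotone-decreasing release
  data) are rejected or flagged rather than fitted.
- **t50**: midpoint halfway between the shortest-gap amplitude and 1,
  located by linear interpolation in log(gap); when the data never cross
  the midpoint the result is a labelled bound, not a number.
- **Rank tests**: Kruskal-Wallis H with tie correction and χ² p;
  Wilcoxon signed-rank exact for n ≤ 25 without ties, otherwise normal
  approximation; Mann-Whitney two-tailed. The ON-vs-OFF population
  comparison that the recordings ran with an unspecified Kruskal-Wallis
  variant is implemented as Mann-Whitney on per-unit reductions.
- **Classification**: adapting = KW across ≤6 presentations significant at
  α = 0.05 *and* later-presentation median below the first; facilitating =
  any gap condition significantly above the control by Mann-Whitney with a
  larger median. No multiple-testing correction is applied, matching the
  original analysis; the measured false-positive rate of the adapting call
  on null units is ≤7% at α = 5%.

## Problem sizes

Simulations use the default 80°×80°, 1°, 5 ms rendering; recovery-type
experiments simulate each gap from rest (the 30 s cycle of the recording
protocol makes carry-over negligible — its own 11 s recovery shows this).
Gratings run 6 s with the final 3 s scored. Population-level statistical
tests use n = 3000 sampled units for distributional checks, 500 spike-noise
seeds for the false-positive rate, and 50 seeds × 40 trials/condition for
the Poisson τ-recovery check; these sizes give the quoted rates to within
a couple of percent.

## Known limitations

- The model is a concrete instantiation chosen to satisfy the published
  architecture constraints; the original's exact equations are not
  reproducible from the available text, and other instantiations could fit
  the same anchors.
- The generator's OFF d50 sigmoid stands in for "OFF responses largely
  unaffected beyond 10°"; it is not a fitted mechanism.
- Facilitation magnitude/kinetics are qualitative defaults.
- The model's grating responses are small in absolute rate (its output
  scale is calibrated to transient spot responses); tuning conclusions rest
  on relative amplitudes.
- Synthetic tests demonstrate pipeline correctness against the generator's
  assumptions (Poisson noise, separable adaptation, alpha kernels), not
  against real recording artefacts (sorting errors, drift, correlated
  noise).
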