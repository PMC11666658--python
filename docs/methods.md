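# Methods

## The analysis

The pipeline analyses minutes-resolution monitoring traces from a staged
haemorrhagic-shock / total-aortic-occlusion experiment in two arms of pigs:
normal ICP (NICPG) and elevated ICP (EICPG, an epidural balloon inflated
during haemorrhage to 25–30 mmHg). Times are minutes relative to T0 =
balloon inflation; phases are half-open intervals `[start, next)` —
stabilisation [−90, −30), bleeding [−30, 0), occlusion [0, 120), reperfusion
[120, 135] — so the boundary samples at T0 and T120 belong unambiguously to
the later phase. The default 5-min grid has 46 points.

Derived quantities per animal:

- **CPP = MAP − ICP**, no zero-level correction (transducers are zeroed at a
  common level by the experimental setup). Missing inputs propagate.
- **mL-PRx**: Pearson correlation of each window of 6 consecutive
  (pMAP, ICP) pairs at 5-min spacing, stride one sample. The raw
  product-moment correlation of recorded values is used — no detrending, no
  epoch averaging — because the index is defined directly on the manually
  recorded 5-min values. Values are assigned to the window's end (causal
  convention; configurable to the centre). Windows containing a missing
  sample are flagged `missing`; zero-variance windows are `undefined`
  rather than 0, because a constant channel carries no reactivity
  information and coding 0 would silently count as "preserved".
  `mL-PRx ≤ 0` (inclusive) is classified preserved, `> 0` impaired; 0.2 is
  carried as a configurable secondary threshold (the conventional
  mortality-associated level) but plays no role in the primary analysis.
- **Episodes**: maximal runs of ≥ 2 consecutive impaired windows (≥ 10 min
  of persistence; single-window excursions are noise at this resolution,
  while the 15–25-min episodes of interest are retained). Missing/undefined
  windows break runs. An episode's start is the first impaired window's
  *data onset* (assigned time minus the 25-min window span); its end is the
  last impaired window's assigned time. Because of this convention,
  successive episodes' reported spans may overlap even though the underlying
  window runs are disjoint.
- **ICP dose**: trapezoidal integral of `max(0, ICP − 20 mmHg)` over a
  window, in mmHg·min; threshold and window are parameters.
- An optional flag censors index windows that straddle a phase boundary, so
  an index value never mixes physiological regimes (used in the
  parameter-recovery analyses; off by default).

Group statistics follow the study's scheme: median, quartiles by linear
interpolation between order statistics (stated explicitly because printed
IQRs cannot adjudicate the convention), and the unscaled MAD (no 1.4826
factor — it is an error bar, not a σ estimate). Shapiro–Wilk is computed as
a descriptive screen only; inference is always nonparametric. Between arms:
Wilcoxon rank-sum per timepoint; within an arm: Wilcoxon signed-rank of each
timepoint against the T−30 reference, pairing within animal. Exact p-values
are computed by full enumeration when n₁+n₂ ≤ 16 (rank-sum) or n ≤ 14
(signed-rank) and the data are tie-free — limits chosen so the study's
n = 11 per arm always takes the exact branch in the tie-free case — and
otherwise by the mid-rank normal approximation with tie correction and a
directional continuity correction. At the exact-branch boundary the
approximation tracks the enumerated p to ~0.015 in the mid-range (far
tighter in the tails); each result records which branch produced it.
P-values are displayed to exactly four decimals (half-up), full precision
kept internally, and no multiplicity adjustment is applied across
timepoints — each is flagged at two-sided 0.05 on its own, mirroring the
study's per-timepoint asterisk convention; the caveat is that ~5 % of null
timepoints will flag by chance.

## The synthetic-cohort simulator

No animal data were deposited, so the analysis is exercised on simulated
cohorts built to carry the structure the pipeline assumes — and nothing
more.

**MAP.** Each arm has a piecewise-linear skeleton through the published
group medians: NICPG 94 (baseline) → 45 (end of bleeding) → 125 (T15
maximum) → 85 (T90); EICPG 99 → 41 → 163 → 124. Beyond T90 no medians are
published; the skeleton holds a plateau to T120 (NICPG 80, EICPG 110) and
falls during balloon deflation to 55/60 at T135. Per animal, MAP = skeleton
+ a level offset (N(0, 8 mmHg), the between-animal spread; deliberately
conservative relative to the published baseline IQRs so that group medians
stay calibrated at n = 11) + stationary AR(1) noise (SD 4 mmHg, ρ = 0.6 at
5-min spacing). Adrenaline rescue is a hard floor at 40 mmHg during
bleeding only. Haemorrhage volume acts through the skeleton; the bleed-rate
arithmetic (estimated blood volume = 8 % of body weight; drainage =
fraction × EBV / 30 min, default fraction 0.40, fraction 1 recovering the
plain EBV/30 formula) is exposed for reporting.

**ICP.** A monoexponential craniospinal pressure–volume law,
`ICP = p0 · exp(k·(V_balloon + ΔCBV))`, k = 0.12 ml⁻¹, p0 = 17 mmHg with
N(0, 2) between-animal jitter clipped to [10, 24]. This is the minimal
model that yields realistic ICP nonlinearity and a closed-form balloon
calibration: the EICPG balloon ramp rises linearly over the bleeding phase
to `ln(target/p0)/k − ΔCBV(T0)`, where the ΔCBV offset is taken from the
noise-free trajectory, so the noise-free ICP at T0 equals the 27.5-mmHg
midpoint of the 25–30 aim band exactly — the analogue of experimenters
titrating the balloon against measured ICP. At ~4–6 ml the implied volumes
match an epidural Foley balloon. ICP sensor noise is AR(1) with SD =
0.05 × the MAP noise SD (≈0.2 mmHg), independent of the MAP channel —
any MAP↔ICP correlation must come from the mechanism, not the noise
generator. `noise_sd = 0` switches off every stochastic component.

**Autoregulation.** A two-state gain model, not a vasomotor ODE: the
analysis only needs the sign structure of MAP→ICP coupling that a pressure
reactivity index detects. The cerebral-blood-volume deviation responds to
the deviation of MAP from a slowly adapting vascular reference (first-order
tracking, τ_ref = 20 min): intact vessels constrict when pressure rises
(ΔCBV = −g_i·ΔMAP, g_i = 0.03 ml/mmHg), passive vessels dilate with it
(+g_p·ΔMAP, g_p = 0.06 ml/mmHg — passive transmission stronger than active
compensation). The state's target is passive whenever MAP leaves the
[50, 150] mmHg autoregulatory plateau or a configured impairment interval
forces it, and the state blends toward its target with τ = 5 min (the
narrative of autoregulation normalising within ~10 min of occlusion).
The adapting reference is what makes the post-occlusion ICP rise a
transient — a peak shortly after inflation followed by gradual decline
without full return to baseline, as observed — rather than a sustained
step; the post-occlusion kinetics are emergent, not fitted (no time
constants were published). Default forced-impairment intervals encode the
published narrative that MAP limits cannot explain: NICPG [20, 40] min
(its MAP is inside the plateau there) and EICPG [60, 85] min (MAP < 150
during its third episode); EICPG's mid-occlusion impairment emerges on its
own from the skeleton exceeding 150 mmHg from ~T5 to ~T40.

**Cohort.** 11 animals per arm; weights drawn through a piecewise-linear
quantile function anchored at the published Q1/median/Q3 (44/47.5/52 kg).
Everything is reproducible from a single seed; animals are numbered pig01–11
(NICPG) and pig12–22 (EICPG).

**What the simulator does *not* emulate** — and hence what passing tests do
not show about real data: cardiac output and distal haemodynamics, baroreflex
and vasopressor pharmacology, fluid resuscitation dynamics, CSF-volume
kinetics, metabolic (lactate) sequelae, sex differences, and any
non-stationarity of measurement noise. MAP/ICP fidelity is limited to the
published group medians at the key timepoints plus plausible interpolation.
The between-animal spread is narrower than the published IQRs by design;
real data would put more timepoints on the approximate (tied) test branch
and produce noisier reactivity indices.

## Parameter-recovery validation

The recovery experiment forces an impairment interval at [20, 40] min of
occlusion in an 11-animal cohort and asks whether episode detection recovers
an overlapping episode with both boundaries within one window span (25 min —
the intrinsic resolution of a 6×5-min windowed index). Two methodological
points:

- It runs on the **normal-ICP arm**, whose MAP stays inside the plateau, so
  the forced schedule is the only impairment source (this is also the arm
  whose published narrative places an impairment at 20–40 min). In the
  elevated-ICP arm the experiment is confounded by design: that arm's MAP
  exceeds the upper autoregulation limit from ~T5 until T40–T55 depending on
  the animal's level offset, so true pressure-passivity genuinely extends
  past the forced interval and the detected end boundary reflects the
  physiology, not the schedule.
- The index is computed with phase-boundary censoring, so windows straddling
  bleeding→occlusion cannot merge the (real) haemorrhage-phase impairment
  with the occlusion-phase episode under study.

Under the default configuration the interval is recovered in 11/11 animals
across all seeds tried.

## Numerical choices and degenerate inputs

- Pearson windows require ≥ 3 points; the 6-point window is exact to
  ~1e-13 against the raw sum-of-products formula.
- CSV values are written at full float precision (`repr`), so read-back is
  bit-exact; empty cells are the only missing-value encoding.
- Quantile draws, AR(1) noise and per-animal seeds derive from
  `(config.seed, animal_seed)` streams, so cohorts are reproducible and
  animals independent.
- Degenerate statistics: all-zero signed-rank differences give p = 1; a
  zero-variance rank-sum (all values identical) gives p = 1; `icp_dose`
  needs ≥ 2 non-missing samples and rejects windows outside the record.
- The balloon calibration rejects targets at or below the unloaded ICP
  (a monotone elastance cannot lower pressure).

## Known limitations

- The simulator's impairment forcing is binary with first-order blending;
  graded autoregulation deficits are not modelled.
- Episode boundaries are quantised to the window stride and biased outward
  by up to one window span by construction.
- The exact Wilcoxon branches require tie-free data; heavily tied real data
  always take the approximate branch.
- The reperfusion phase (3 grid points after T120) is too short for windowed
  indices; mL-PRx there mostly reflects occlusion-phase data unless
  phase-censoring is enabled, in which case it is censored entirely.
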