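# Methods

`painrct` implements, end to end, the analysis of a two-arm,
parallel-group neonatal procedural-pain trial in which parents stroke
their baby's leg either just before (intervention) or well after
(control) a clinically required heel lance, together with a synthetic
trial generator so that every stage can be exercised and validated
without access to any real data. This note records the models, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic validation does and does not establish.

## Primary outcome: template-regression EEG magnitude

Noxious stimulation in neonates evokes a characteristic biphasic
event-related potential at the vertex (Cz). The trial quantifies it with
a fixed-shape response template: the template is regressed, without an
intercept, onto the baseline-corrected Cz signal in a 400–700 ms
post-stimulus window, and the regression coefficient is the outcome,

    beta = <t, x> / <t, t>,

evaluated at the latency shift (bounded, default ±50 ms) that maximises
the signed cross-correlation between template and signal. The magnitude
scale is calibrated so that 1.0 corresponds to the expected response of
a term-aged neonate to a heel lance.

The validated template waveform itself is not in the public domain, so
the package ships a **surrogate**: a difference of two Gaussians
(negative deflection centred at 450 ms, SD 40 ms; positive at 560 ms,
SD 60 ms; amplitude ratio 1:1.25), truncated to the analysis window and
scaled to a 20 µV peak. Any waveform can be dropped in through the
`Template` type; every scoring property tested here (projection
identity, linearity, unbiased recovery) is template-agnostic. One
numerical subtlety: with those Gaussian parameters about 1.4 % of the
raw waveform's energy falls outside the 400–700 ms window, so the
builder truncates the waveform to the window (the support invariant)
and rejects parameter sets whose raw out-of-window energy exceeds a
configurable 2 %.

**Preprocessing** is a zero-phase 4th-order Butterworth band-pass
(0.5–30 Hz) followed by subtraction of the pre-stimulus baseline mean
(−500–0 ms). The 0.5 Hz high-pass has a settle time longer than a 1.5 s
epoch, so the epoch is reflect-padded by four low-edge cycles before
filtering; without this the filter transient contaminates the whole
epoch. Because the band-pass slightly attenuates the template band
(~4 % in amplitude), scoring is done against the *identically filtered*
template (the matched-regressor construction); this removes the
attenuation bias exactly and is what makes the Monte-Carlo recovery
unbiased. **Artefact rejection** is rule-based: peak-to-peak above
200 µV or RMS below 0.1 µV on the analysis channel. These preprocessing
constants are declared defaults, not claims about any particular
laboratory pipeline.

## Secondary outcomes

**PIPP-R** (0–21) sums seven indicators banded 0–3: heart-rate increase
(max post − baseline mean, clipped at 0; bands 0–4 / 5–14 / 15–24 / ≥25
bpm), SpO2 decrease (0–2.4 / 2.5–4.9 / 5–7.4 / ≥7.5 %), three facial
actions banded by fraction of the 30 s observation window (<9 / 9–39 /
40–69 / ≥70 %), gestational age (≥36 / 32–35⁺⁶ / 28–31⁺⁶ / <28 wk) and
behavioural state (active awake → quiet asleep). The two contextual
indicators count only when the physiological + facial subtotal is
positive. The banding table ships as a package CSV so rubric
disagreements are data fixes, not code changes. The generator records
behavioural state only as awake/asleep; scoring maps these to the quiet
variants (the rubric itself stays four-level).

**Tachycardia** is a threshold-crossing rule: no heart-rate sample
*above* 160 bpm in the 15 s pre-lance baseline and at least one sample
*at or above* 160 bpm within 30 s post-lance — both wordings admit
equality at 160, and the implementation honours both boundaries. The
effect is reported as a covariate-adjusted logistic odds ratio plus a
risk ratio from model-standardised predicted risks (mean predicted risk
with everyone allocated vs no one). On separation the fit falls back to
Firth's penalised likelihood (hand-implemented; no installed package
provides it) and is flagged.

**STAI-State** totals follow the standard 20-item keying with ten
reverse-scored anxiety-absent items (1, 2, 5, 8, 10, 11, 15, 16, 19,
20), giving totals in 20–80.

**Rescoring reliability** uses the intraclass correlation from the
two-way ANOVA decomposition (single measure; absolute agreement ICC(A,1)
by default, consistency ICC(C,1) optional), with F-based 95 % CIs, via
pingouin.

## Randomisation

Allocation is Pocock–Simon minimisation over five equally weighted
factors — gestational-age stratum (35–36⁺⁶ / 37–38⁺⁶ / ≥39 wk),
postnatal-age stratum (0–2 / 3–7 d), sex, site and blood-test reason —
with range-type marginal imbalance and a biased coin: the
imbalance-minimising arm is chosen with probability 0.8, ties by a fair
coin. The strata cut-points, weights and coin probability are declared
configuration (the provider algorithms used in practice are
unpublished); with `p_assign = 1` the rule is deterministic and is
verified against a brute-force imbalance enumeration.

## Effect estimation

The analysis frame has one row per randomised participant: allocation,
received exposure (compliant pre-lance stroking), the five minimisation
covariates, and the scored outcomes. The full analysis set for each
outcome is all randomised participants with that outcome measured
(per-outcome complete cases; no imputation).

* **ITT** — Huber M-estimation robust linear regression (tuning 1.345)
  of outcome on allocation plus the minimisation covariates (plus
  baseline STAI-State for the anxiety outcome); the allocation
  coefficient is the estimate, the CI comes from the robust covariance.
  When the fit is exact (all residuals zero) the M-estimator's MAD scale
  is degenerate and the implementation returns the (identical) OLS
  solution.
* **CACE** — two-stage least squares with randomised allocation
  instrumenting exposure, covariates in both stages. Non-compliance is
  one-sided (a control parent cannot stroke before the lance), so the
  complier average causal effect equals the per-protocol effect in
  compliers. Intervention babies who stroked too early are modelled as
  unexposed. Without covariates the estimator reduces exactly to the
  Wald ratio (ITT difference ÷ compliance-rate difference), which is
  used as an independent oracle in the tests. A vanishing
  instrument–exposure covariance raises a weak-instrument error.
* **P-values** — randomisation inference: the estimator is recomputed
  under re-drawn allocations and
  p = (1 + #{|T*| ≥ |T|}) / (1 + B). Two reference sets are provided.
  *Free label permutation* (the pipeline default; the allocation and
  exposure indicators travel together so the instrument–exposure link
  survives) is simple but measurably **conservative under minimisation**
  when covariates are adjusted: the observed allocation is better
  balanced on covariates than a random relabelling, so the permutation
  distribution over-disperses. At n = 40 with the five covariates this
  pushed the type-I rate to ~0.033 and the Holm familywise rate to
  ~0.016. The *exact* alternative re-runs the minimisation algorithm
  itself for each draw (`batch_minimisation_allocations`, vectorised
  across draws and verified draw-for-draw against the sequential
  algorithm); with it the simulated type-I rate is 0.047, the Holm
  familywise rate 0.031 and the null p-value distribution uniform
  (KS ≈ 0.02). The calibration studies therefore use the
  re-randomisation set; at the full trial size the free-permutation
  conservativeness is mild and it remains the default reported scheme.
  CIs are model-based (robust/IV covariance), not inverted permutation
  intervals.
* **Multiplicity** — one alpha of 0.05 for the primary outcome; one
  family alpha of 0.05 shared across the three secondary outcomes by
  Holm's step-down method (monotone, capped at 1).

The simulation studies use the ordinary-least-squares allocation
coefficient as the permutation statistic, computed by
Frisch–Waugh–Lovell residualisation: permuting thousands of draws then
costs two matrix products yet reproduces the full covariate refit
exactly. On the Gaussian outcomes the generator produces, this is also
the statistic the Huber fit converges to.

## Design calculator

`sample_size_two_means` solves the two-sample t-test power equation
iteratively (noncentral t, via statsmodels), not the normal
approximation — the latter gives 100 where the t-based answer is 102 for
the default design (control mean 1.07 a.u., 40 % reduction, SD 0.66,
90 % power, two-sided 5 %, 1:1). `inflate_for_loss` multiplies by
(1 + loss) and rounds down to the nearest even total, a convention that
keeps 1:1 allocation exact (102 → 112 at 10 % loss).

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes;
its defaults are the study conditions, chosen once:

* **Cohort** — gestational age truncated-normal on [35, 42] wk (mean
  38.4, SD 1.8); postnatal age binomial(7, 0.45) days; 61 % male; site A
  74 %; mother strokes 65 %; blood-test reasons jaundice .48 / sepsis
  .29 / screening .07 / glucose .05 / other .11; 27 % awake at baseline;
  prior painful procedures ≈ gamma(2, 2) rounded.
* **True magnitudes** — control draws N(1.07, 0.66²); compliant
  intervention babies are multiplied by (1 − r) (default r = 0.4, i.e. a
  −0.428 a.u. complier effect). Covariates are independent of magnitude.
* **EEG** — 8 channels at 256 Hz over −0.5–1.0 s; 1/f background noise
  (RMS 5 µV per channel), optional 50 Hz mains component; the template
  enters on Cz at its nominal latency plus truncated-Gaussian jitter
  (SD 20 ms, bound ±50 ms), with a 0.5 attenuated copy on the other
  channels; sham epochs contain no template. At these defaults the
  scorer's single-epoch sampling SD is ≈ 0.17 a.u.
* **Vitals** — baseline heart rate N(135, 10) capped at 155 bpm; the
  post-lance surge peak is drawn above 160 bpm with probability
  `p_cross` (default 0.10) or below 156 otherwise, with margins wide
  enough (noise SD 0.5 bpm) that the detector reproduces `p_cross`
  exactly in expectation; linear 5 s rise, 15 s exponential decay; SpO2
  dips up to 5 % with 20 s recovery.
* **Compliance** — intervention stroke-to-lance delays are log-normal
  with median 17 s and log-SD 0.8 (≈ 11 % exceed the 45 s threshold,
  matching the reported median/IQR of observed delays); setting a target
  compliance rate solves the log-SD in closed form so the rate is exact.
  Control stroking starts uniformly 30–60 s after the lance and is
  always compliant.
* **Facial actions** — durations increase linearly with magnitude
  (8 s per a.u., weights 1.0/0.9/0.8 across the three actions), plus
  Gaussian noise, clipped to [0, 30] s.
* **STAI** — a latent per-parent anxiety score (scale 6) shifts the
  trait/state/post totals around means 38/35/35; totals are decomposed
  into 20 item responses consistent with the standard reverse keying, so
  re-scoring the sheets recovers the totals exactly.
* **Missingness** — completely at random, per outcome, rate 0 by
  default; artefact-rejected epochs additionally become missing EEG
  outcomes.

All randomness flows from one root seed through named substreams
(cohort, allocation, truth, signals, missingness, permutation), so a
given configuration is byte-reproducible. `generate_trial` produces the
full signal-level dataset; `generate_outcome_frame` is a score-level
shortcut for simulation studies (observed magnitude = truth + N(0,
0.15), matching the measured sampling SD of the scorer), used where
thousands of replicate trials are needed.

**What the synthetic validation does not show.** The generator's noise
is stationary 1/f; real neonatal EEG has movement artefacts,
state-dependent spectra and inter-electrode correlation it does not
model. Facial-action durations and heart-rate dynamics are convenient
monotone links, not physiological models; parental anxiety does not
respond to the procedure by default. Passing recovery and calibration
tests therefore establishes that the *estimators and rules* behave as
specified under the assumed structure — not that the structure matches
any particular cohort.

## I/O and reproduction

Datasets are plain text: participant/allocation/compliance/facial/STAI
CSVs, per-participant vitals CSVs, and EEG epochs in a documented
long-format CSV (channel, time_s, microvolts) with a JSON sidecar for
the grid. An EDF epoch container was considered and not included — the
environment provides an EDF reader but no writer — and the CSV container
round-trips bit-exactly (the reader uses round-trip float parsing).
Results reports carry provenance (seed, SHA-256 config hash, package
version) and are byte-identical across repeat runs of the same
configuration.

Problem sizes used by the validation suite: 500 epochs per planted
magnitude for scorer calibration; 200 replicate trials of n = 112 for
CACE/ITT recovery; 1000 replicate trials of n = 40 with 1000
re-randomisation draws each for type-I error and familywise error; 500
replicate trials for the minimisation balance comparison. One further
calibration note: the familywise-error simulation lands near the lower
edge of its band (0.031) because the generator's EEG-magnitude and
PIPP-R outcomes share the same latent pain magnitude, so their null
p-values are positively correlated and Holm is conservative — a property
of the assumed outcome structure, not of the testing machinery.
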