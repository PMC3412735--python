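# Methods

## The measurement being modelled

A magnetic test meal is followed through the rat gut with an AC
susceptometric sensor: two coaxial excitation/detection coil pairs in a
first-order gradiometric arrangement, the near pair the probe and the
far pair (15 cm away) the reference. Signal intensity grows with the
amount of magnetic material under the probe and falls steeply with
source–sensor distance, so a reading over the gastric projection tracks
stomach content and a reading over the cecal projection tracks cecal
accumulation. The protocol samples both sites every 10 min for at least
7 h after ingestion of either a ferrofluid liquid meal or a ferrite
pellet solid meal.

## Normalization

Raw mV traces carry arbitrary gain and offset, so analysis works on
dimensionless curves.

*Gastric retention* R(t): a baseline b is removed and the curve rescaled
affinely, R(tᵢ) = (S(tᵢ) − b) / (S(t₀) − b), so R(t₀) = 1. Two baseline
modes exist: `tail` (default; b = mean of the last 3 samples, assuming
the stomach has emptied by the end of the record) and `zero` (no
offset). Values below −0.1 after normalization flag a wrong baseline;
negative values are floored at zero during integration.

*Cecal arrival* C(t): the pre-arrival baseline (mean of the first 2
samples — no meal can be at the cecum 5–10 min after ingestion) is
removed and the curve divided by its maximum C_max, then clipped to
[0, 1]. Noise can make the cumulative curve locally non-monotone; an
optional pool-adjacent-violators (isotonic) fit is available but off by
default, since the area integrals are unbiased under zero-mean noise.

The meal is entirely gastric at t = 0, so R = 1 and C = 0 are assumed on
[0, t_first] when the first sample comes later; curves are never
time-shifted.

## Moment estimators

MGET = ∫ R dt and MCAT = ∫ (1 − C) dt, trapezoidal on the native grid.
These are the first moments of the emptying- and arrival-rate
distributions whenever the record is complete (R → 0, C → 1): summation
by parts shows the area form is algebraically identical to the
rate-weighted midpoint average Σ t_mid (Rᵢ − Rᵢ₊₁)/(R₀ − R_end), which
the package exposes separately (`mget_rate_weighted`) purely so the
identity can be tested. MSITT = MCAT − MGET, enforced exactly in the
result type; a negative value is reported with a warning rather than
hidden, since it signals mutually inconsistent curves.

Incomplete records: if the final retention exceeds `plateau_epsilon`
(default 0.02) the default policy integrates what is there and warns
("truncated"); the alternative `exponential_extrapolate` fits a
mono-exponential to the last 5 samples by log-linear least squares and
adds its analytic tail area out to 5 time constants. The arrival plateau
is judged by the final normalized value ≥ 1 − ε; note that for a
monotone noiseless curve this criterion cannot fire (the maximum is the
final sample), so plateau censoring is flagged reliably only in the
presence of noise — a limitation inherited from judging the plateau from
the normalized curve alone.

t₅₀ (first linear-interpolated crossing of R = 0.5) is provided for
comparison only: it equals ln 2 · MGET under pure exponential emptying
and has no such interpretation for lagged (solid-meal) curves, which is
precisely why the moment estimators are preferred.

## Generative model

There is no public corpus of such recordings, so the package carries a
generative stand-in used by all end-to-end tests:

dS/dt = −e(t)·S, dq₁/dt = e(t)·S − k_t q₁, dq_j/dt = k_t(q_{j−1} − q_j),
dCec/dt = k_t q_N — a stomach draining through a chain of N well-mixed
small-intestine compartments into the cecum. The emptying hazard e(t)
is constant k_e for liquids (retention e^{−k_e t}) and the hazard of the
power-exponential retention e^{−(kt)^β} for solids (β > 1 gives the lag
phase; at t = 0 the hazard is 0, so no singularities). The chain was
chosen because its moments are analytic and therefore serve as free
oracles: the mean gastric residence is 1/k_e or Γ(1 + 1/β)/k, mean
residence times add along the chain, and the mean cecal arrival is the
gastric mean + N/k_t. Integration is classical fixed-step RK4 with a
0.1-min internal step; total mass is conserved to ≤ 10⁻⁶ relative and
the liquid stomach trajectory matches the closed form to 10⁻⁶.

Sensor: V(m, d) = gain · m · (d⁻ᵖ − (d + L)⁻ᵖ), the far term being the
reference pair at the gradiometer baseline L = 15 cm. The falloff
exponent defaults to p = 6 (dipole excitation × dipole detection,
d⁻³·d⁻³); it is a parameterization, not a coil-geometry computation. By
default the stomach sensor sees only the stomach compartment (at 2 cm)
and the cecal sensor only the cecum; an optional distance matrix lets
any compartment contribute to either site for cross-talk studies.

### Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| k_e (liquid) | 0.01 | 1/min | mean emptying time 1/k_e = 100 min, the magnitude observed for liquid meals in rats |
| k, β (solid) | Γ(1.5)/140 ≈ 0.00633, 2 | 1/min, — | mean Γ(1 + 1/β)/k ≈ 140 min with a solid-meal lag |
| N, k_t | 10, 0.1 | —, 1/min | mean small-intestinal transit N/k_t = 100 min, matching observed MSITT magnitudes; N = 10 gives 10-cm front resolution |
| duration, Δt | 420, 10 | min | the 7-h, 10-min recording protocol |
| gain, d, p, L | 300, 2, 6, 15 | mV·cmᵖ, cm, —, cm | peak gastric signal ≈ 4.7 mV, a realistic mV scale |
| σ (recording) | 0.02 × peak | mV | 2% additive Gaussian noise per sample |
| population CV | 15% | — | lognormal between-animal variability of k_e (or k) and k_t; of the magnitude implied by reported group SDs (≈ 14–25%) |

These defaults are the study conditions; simulated group tables echo
the magnitudes of published rat data (liquid MGET ≈ 100 min, solid ≈
140 min, MSITT ≈ 100 min) by construction of the presets — echoes, not
claims of reproducing any specific animal.

The kill-and-measure validation study simulates 18 solid-meal animals
sacrificed in threes at 10–60 min; the tracer front is the most distal
compartment holding ≥ 1% of the meal (the analogue of "a continuous
1-cm trace" of marker), mapped onto a configurable 100-cm intestine —
the length is a placeholder, not a measured value. Its noise default is
σ = 0.005 × peak, quieter than the recording default: these are brief
stationary point readings, not 7-h ambulatory traces, and at the
recording noise level the 10–60-min gastric decrease (0.4–13% of peak)
would be dominated by measurement error rather than biology. With these
conditions the Pearson correlation between gastric signal decrease and
front distance is ≈ 0.95–0.98 across seeds.

### What the generator does not emulate

Antral grinding and fed-state motor patterns, sensor repositioning
error between sessions, baseline drift, non-point-like meal geometry
under the probe, and absorption or degradation of the tracer. Passing
end-to-end tests therefore demonstrate correctness of the estimators
under the stated kinetic model and noise, not robustness to every
artifact of live recordings.

## Statistics

Mean ± sample SD (n − 1); paired two-sided Student t-test
t = mean(d)/(sd(d)/√n), df = n − 1, with the tail probability computed
from the regularized incomplete beta I_{df/(df+t²)}(df/2, ½) by the
standard continued-fraction (modified Lentz) evaluation — implemented
in-package so an external statistics library remains an independent
cross-check rather than the implementation. Pearson correlation and the
repeatability coefficient of variation (100·sd/mean) complete the layer.
Three paired comparisons are run without multiplicity adjustment,
mirroring standard practice for this design.

## The embedded reference table

A six-rat table of integer transit times under both meals is embedded
as a frozen reference. Two arithmetic facts about it are worth stating
plainly. First, its per-animal integers were rounded independently from
unrounded source values (the running-text group values, e.g. MSITT
103.28 ± 18.73 min, cannot be produced by any integer column), so
round(MCAT) − round(MGET) differs from the printed MSITT by 1 min in
exactly one cell (rat 5, liquid: 138 printed vs 139 recomputed); the
printed Mean row is consistent only with the printed 138. The
verification routine checks the identity exactly, reports that cell,
and accepts only discrepancies within the ±1-min independent-rounding
bound. Second, the source's significance claim (p < 0.04 for MGET and
MCAT) was computed from the unrounded, unpublished per-animal values;
recomputing from the rounded integers gives p ≈ 0.057 (MGET) and
p ≈ 0.12 (MCAT). Both numbers are reported; they are not forced to
agree.

## Numerical and design choices

- Trapezoidal integration on the native grid: transparent, unbiased
  under zero-mean noise, and exact for the piecewise-linear curves the
  protocol actually records. Convergence toward dense-grid oracles is
  property-tested.
- The tail-estimated gastric baseline is biased on truncated
  exponentials: at the default 420-min record a liquid meal with
  100-min mean still retains ~1.5% of the meal, which tail estimation
  absorbs into the baseline, and the subtraction integrates to an MGET
  ~7% low. Parameter-recovery experiments against the simulator
  therefore use the `zero` baseline (the simulated sensor has no
  offset); `tail` remains the default for field data, where an unknown
  instrument offset is the greater evil, and the incomplete-emptying /
  baseline warnings surface the tension on any given record.
- Parameter-recovery conditions: 20 noise seeds at the 2% recording
  noise with fixed (undrawn) transit parameters, judged against the
  generating 1/k_e; median relative MGET error is well under 5%.
- End-to-end oracle checks run the slow 4-compartment chain (k_e =
  0.01, k_t = 0.05) over a 700-min grid: at 420 min that chain's
  arrival has not plateaued and the (correctly warned) censoring biases
  MCAT low; 700 min is the grid its analytic oracle is valid on.
- Randomness: one seeded `numpy` generator per simulation entry point;
  cohort and validation studies derive per-animal seeds from it, so any
  study is reproducible from a single integer.
- Rounding for reference-table reproduction is half-away-from-zero to
  integer minutes, applied only in that report, never inside the
  estimators.

## Known limitations

Moment estimates are right-censoring–biased whenever a record ends
early, and the plateau detector cannot flag censoring on noiseless
monotone curves (see above). The simulator's compartment chain has a
single transfer rate (no regional heterogeneity, no ileocecal braking).
The tracer-front distance is quantized at intestine_length/N. The
validation-study intestine length (100 cm) is configurable, not
measured. Same-animal repeatability in simulation reflects measurement
noise only (a few percent CV for MGET), a lower bound on the biological
session-to-session variability of real animals.
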