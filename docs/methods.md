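# Methods

## The problem

Composite clinical scales (the working example throughout is a motor
examination scale of 33 items, each scored 0–4, total score 0–132) are often
analysed only at the total-score (TS) level because item-level data are
unavailable. The TS is a bounded integer whose conditional variability
shrinks toward the scale boundaries, so the homoscedastic residual of a
standard continuous-variable (CV) analysis is misspecified, and linear
disease-progression models on the TS scale conflict with the S-shaped
relation between the underlying severity and the score.

When a graded-response item response theory (IRT) model exists for the same
scale, its item characteristic curves fully determine the conditional
distribution of the TS given the latent severity Ψ. `irtlink` exploits this:
it derives analytic link functions from Ψ to the mean and SD of the TS (and
of the probit-scale Z score used by bounded-integer models), approximates
them with low-degree Chebyshev polynomials, and plugs them into nonlinear
mixed-effects total-score models.

## Graded response model

Item *m* has discrimination *a<sub>m</sub>* > 0 and ordered thresholds
*b<sub>m,s</sub>*; the cumulative category probabilities are logistic,

P(Y<sub>m</sub> ≥ s | Ψ) = 1 / (1 + exp(−a<sub>m</sub>(Ψ − b<sub>m,s</sub>))),

and category probabilities are differences of adjacent cumulative curves.
Category scores are stored explicitly in the scale file (not inferred from
the category index) because the mean link sums over score values.

Item information is the score variance Σ<sub>s</sub> (∂P<sub>s</sub>/∂Ψ)² /
P<sub>s</sub>, with the derivative taken analytically; probabilities are
floored at 1e−12 when dividing (categories below 1e−300 contribute zero).

## Link functions

Conditional on Ψ the items are independent, so

* E(TS | Ψ) = Σ<sub>m</sub> Σ<sub>s</sub> s · P(Y<sub>m</sub>=s | Ψ),
* Var(TS | Ψ) = Σ<sub>m</sub> Σ<sub>s</sub> (s − E(Y<sub>m</sub>|Ψ))² ·
  P(Y<sub>m</sub>=s | Ψ),

i.e. the variance is the sum of **per-item** conditional variances, each
around its own item mean. (A variance written around the total-score mean
inside the per-item sum would not be the variance of the sum; the test
suite checks the implemented form against exact joint enumeration and
against the exact convolution of the per-item score distributions.)

The bounded-integer (BI) model partitions the real line into
n = maxTS − minTS + 1 intervals by the probit cut points
Z<sub>k/n</sub> = Φ<sup>−1</sup>(k/n). The Z-scale link uses a
representative-z convention: interior category k is represented by the
midpoint of its two cut points, and the two boundary categories by the
conditional mean of a standard normal in the corresponding tail (these tail
means keep the representative values finite and reproduce the near-linear
mean and mid-scale SD nadir expected on the Z scale). Then
E(Z | Ψ) = Σ<sub>k</sub> P(TS=k | Ψ) ẑ<sub>k</sub> and SD(Z | Ψ) is the SD
of the same discrete distribution, with P(TS=k | Ψ) computed by exact
convolution. This convention is the package's own; it is what the fitted
Z-scale polynomials mean here.

### Chebyshev approximation

Each of the four links (pn1: E(TS), pn2: SD(TS), pn3: E(Z), pn4: SD(Z)) is
approximated over Ψ ∈ [−4, 8] by the smallest-degree Chebyshev interpolant
(function values at the Chebyshev points of the candidate degree) whose
maximum deviation on a 2001-point equispaced grid is below its tolerance:
0.01 / 0.01 for the CV mean/SD and 0.01 / 0.005 for the BI mean/SD. The
degree search is strictly smallest-first with a guard at degree 60.
SD links are floored at 1e−3 on evaluation so a polynomial dip near the
domain edges can never produce a non-positive SD inside a likelihood.
Evaluation outside [−4, 8] proceeds but logs a warning.

## Total-score model families

Eight families cross CV/BI × mean scale × SD structure:

| name | family | mean | SD |
|------|--------|------|----|
| S-CV  | CV | linear on TS | homoscedastic σ (estimated) |
| SDI-CV| CV | linear on TS | pn2(Ψ̂) fixed |
| MI-CV | CV | pn1(h(Ψ)) | homoscedastic σ |
| I-CV  | CV | pn1(h(Ψ)) | pn2(h(Ψ)) fixed |
| S-BI  | BI | linear on Z | homoscedastic σ |
| SDI-BI| BI | linear on Z | pn4(Ψ̂) fixed |
| MI-BI | BI | pn3(h(Ψ)) | homoscedastic σ |
| I-BI  | BI | pn3(h(Ψ)) | pn4(h(Ψ)) fixed |

with h(·) = θ₁ + θ₂·t − θ₃·X₁ (+ η terms), additive normal random effects on
baseline and slope (uncorrelated by default, correlation optional). SD
elaborations on top of the fixed IRT SD: a positive scale factor, lognormal
inter-individual variability (IIV) on the SD, both, or an additive positive
term with lognormal IIV.

For the SD-only-informed models the structural model lives on the
observation scale, so there is no Ψ in the model itself; the SD link is
evaluated at the Ψ obtained by inverting the mean link at the model's own
prediction (a monotone interpolation table over the domain). This realises
"SD as a function of the model's own mean".

BI scores map to categories k = TS − minTS + 1 on the full n = 133 grid.
Category log-probabilities are computed in log space (`log_ndtr` with
tail mirroring), so extreme means keep finite log-likelihoods wherever the
mass is representable in double precision.

## Estimation

Random effects are integrated out per subject by a Laplace approximation at
the per-subject joint mode; adaptive Gauss–Hermite quadrature (default 9
nodes per dimension, centred and scaled at the same mode) is available as a
verification integrator and agrees with Laplace to < 0.5 OFV points on the
test fixtures. OFV is −2·log marginal likelihood with all constants kept
(CV densities include their 2π terms), so values are comparable across
model families; AIC = OFV + 2p.

The inner mode search is a damped Newton iteration run simultaneously for
all subjects on vectorized conditional log-likelihoods; derivatives with
respect to the (≤ 3) random effects are central finite differences (step
1e−4). Where the negative Hessian is not positive definite — which happens
when a link polynomial saturates at the domain edge and creates a spurious
shoulder — the eigenvalues are shifted to force an ascent direction, and
per-subject backtracking guarantees monotone progress. Cold starts probe a
small set of prior-scaled candidate modes (0, ±ω, ±2ω per axis) before the
first Newton step; warm starts reuse the previous modes across outer
iterations.

The outer maximization is Nelder–Mead on transformed parameters (log for
positive quantities, atanh for correlations), terminating at a simplex
spread of 1e−3 in parameters and 5e−3 in OFV; it is derivative-free because
the inner optimization contributes noise (~1e−5 OFV) that defeats
finite-difference outer gradients, and it is deterministic given the start.
Optional restarts perturb the incumbent with a seeded RNG. Non-convergence
is reported in the result, never silent.

## Simulation experiments

The simulator draws item-level responses from the graded-response truth:
Ψ<sub>ij</sub> = (baseline + η<sub>b,i</sub>) + (slope + η<sub>s,i</sub>)·t<sub>j</sub>,
then one categorical draw per item, summed to the TS. Everything is
deterministic given a seed; replicate seeds derive from a master seed.

Study conditions:

* design: 1000 subjects × 10 equispaced occasions over 4 years (reduced
  sizes are used in the test suite, and the recovery study runs at
  100 subjects × 10 occasions with 20 replicates; the delta-OFV experiments
  in `scripts/acceptance.py` use the full 1000 × 10 design);
* no-progression scenario: baseline 0.654, slope 0, between-subject SD of
  the latent baseline ω<sub>b</sub> = 1.0 (the conventional unit-SD
  standardization of an IRT latent variable). Subjects are constant over
  time. A between-subject spread is essential here: if every subject sat at
  exactly Ψ = 0.654, all subjects would share a single conditional SD and
  the SD-informed models would be exactly equivalent to the homoscedastic
  ones, so the experiment would be vacuous;
* progression scenario: baseline 0.654, slope 0.449 / year,
  ω<sub>b</sub> = 0.5, ω<sub>s</sub> = 0.2, uncorrelated.

The fitted standard models in the progression scenario estimate six
parameters (baseline, slope, two ωs, their correlation, σ); the fully
informed models estimate five (no σ).

The recovery study reports, per parameter, the mean estimate, percent bias
against the truth, and the 2.5–97.5 percentile width across replicates;
failed replicate fits are excluded and counted.

The VPC routine bins observations by time, computes observed 5/50/95
percentiles per bin, and compares them with the 95% interval of the same
percentiles across simulated replicates of the fitted model. CV
simulations draw real values — deliberately so, since predicting outside
the scale range is a documented artefact of CV total-score models — while
BI simulations draw integer scores from the probit partition.

## The synthetic reference scale

The packaged scale (`reference_scale()`) is a deterministic synthetic
stand-in emulating the shape of a 33-item motor subscale: 33 items × 5
categories scored 0–4 (max TS 132), discriminations log-normal with median
1.5, per-item threshold sets spanning roughly Ψ ∈ [−2, 6], fixed seed. On
this scale the fitted links give an S-shaped mean curve, an SD(TS|Ψ) curve
with an interior maximum and a max/min fold of ≈ 3.9, and Z-scale links
with a near-linear mean and a mid-scale SD nadir.

What the synthetic scale does **not** emulate: published item parameters of
any real instrument, residual inter-item correlations beyond the single
latent variable, Markovian carry-over between visits, dropout, or real
covariate structure. Quantities that depend on the exact item parameters —
selected polynomial degrees, the SD fold ratio, and especially ΔOFV
magnitudes of the simulation experiments — are therefore properties of this
scale, not of any published instrument; directions and orderings (SD links
improve fit with one parameter fewer; fully informed models beat standard
ones; TS-level information never exceeds item-level information) are the
transferable content. A real scale definition file can be supplied to every
entry point and overrides the synthetic one.

## Information curves

Score-variance Fisher information about Ψ per observation model:

* IRT: Σ<sub>m</sub> Σ<sub>s</sub> (∂P<sub>ms</sub>/∂Ψ)²/P<sub>ms</sub>;
* I-CV: (pn1′/pn2)² + 2(pn2′/pn2)² (heteroscedastic normal);
* I-BI: Σ<sub>k</sub> (∂P<sub>k</sub>/∂Ψ)²/P<sub>k</sub> with central
  differences (step 1e−4) on the BI category probabilities;
* S-CV: (dE(TS|Ψ)/dΨ)²/σ̂², with σ̂² either user-supplied or implied by an
  empirical score distribution (scores are mapped back to Ψ through the
  inverse mean link and σ̂² is the average conditional variance there — the
  residual variance a homoscedastic fit would absorb if the item model held).

Data processing guarantees I-BI ≤ IRT pointwise (the TS is a compression of
the items); this is asserted in the tests. The homoscedastic S-CV model
misstates the information profile in a characteristic way: relative to the
TS-level truth (I-CV) it overstates information wherever the conditional SD
exceeds its pooled σ̂ — the mid-scale SD peak — and understates it toward
the extremes, and the item-level model's absolute advantage is largest at
the centre of the scale. Note that the popular intuition "a homoscedastic
model overestimates information at the scale boundaries" corresponds to
viewing its information as flat per unit of its own prediction scale
(constant 1/σ̂²); expressed per unit of Ψ through (dE/dΨ)², the S-CV curve
in fact decays faster than the item-level curve at the extremes, since
(dE/dΨ)² ≤ (Σ<sub>m</sub> E[s²|Ψ]) · I<sub>IRT</sub>(Ψ) and the first
factor vanishes at the floor of the scale.

## Numerical choices and limitations

* Chebyshev interpolation at nodes + independent equispaced check grid:
  deterministic, near-minimax, no least-squares fitting.
* SD floor 1e−3 (TS and Z scales); probability floors 1e−12 (information),
  1e−300 (category contributions).
* Inner Newton: gradient tolerance 1e−8, max 100 iterations, FD step 1e−4.
* Dataset fingerprints (order-invariant content hashes) gate model
  comparisons so ΔOFV is only ever formed on identical data.
* Limitations: no standard errors / covariance matrix of the estimates
  (OFV-based comparison and replicate spreads are the supported precision
  measures); no Markov or serial-correlation residuals; no beta-regression,
  coarsened-grid, or logit-transform CV variants; single latent variable
  (one subscale) only; ICC parameters are taken as known, with no
  uncertainty propagation.
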