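# Methods

`stenoshape` implements a geometry-aware, data-driven lumped (0D) model of
an arterial stenosis.  The chain is: synthesize a cohort of axisymmetric
stenotic lesions; compress their geometric variability into a few
statistical shape coefficients; generate reference pressure-drop data over
a Reynolds sweep; fit each lesion's viscous and expansion loss
coefficients; learn the map from shape coefficients to loss coefficients
with Gaussian-process regression; and deploy the result as an algebraic
pressure-flow element that also yields an FFR estimate.  This note records
the model assumptions, the defaults and why they were chosen, and the
numerical decisions taken where the design was genuinely open.

## Lumped pressure-drop model

The trans-stenotic pressure drop is written as a two-term polynomial in the
flow rate q:

    dp = Kv * h1(q) + Kt * h2(q^2)
    h1(q)   = 8 mu ls / (pi a0^4) * q          (Poiseuille-type viscous loss)
    h2(q^2) = rho / 2 * (q / (pi a0^2))^2      (expansion / inertial loss)

with blood density rho = 1060 kg/m^3, dynamic viscosity mu = 0.0035 Pa s,
reference lumen radius a0 = 1.5 mm and nominal lesion length ls = 10 mm.
Kv and Kt are dimensionless, geometry-specific loss coefficients; the whole
point of the package is to predict them from lesion shape.  The model is
quasi-steady: no dQ/dt inertial term, no pulsatility, rigid walls, laminar
flow.  The classical geometry-based comparator (cosinusoidal-lesion
assumption) uses the same structure with the quadratic term scaled by the
Borda-Carnot area factor ((a0/a_s)^2 - 1)^2 of the minimal lumen a_s.

## Synthetic lesion cohort

A vessel is 20 cross-sectional planes, 1 mm apart (plane i at z = (i-1) mm).
Planes 1-5 and 16-20 stay at a0; a single focal lesion occupies the central
segment (planes 6-15).  Per lesion:

- severity S in [0.3, 0.8] from an unscrambled Sobol sequence — the
  clinically ambiguous window between "rarely stented" (< 30%) and "almost
  always revascularized" (> 80%).  The radical-inverse sequence makes any
  equal-width severity binning of a power-of-two cohort exactly uniform.
- boundary planes s ~ U{6..10}, e ~ U{11..15}; the minimum-lumen plane
  c = s + 2 + T(beta (e - s - 3)), beta ~ U[0,1), T truncation toward zero.
  For short initial regions c may land on the region boundary or (for the
  two-plane region) on plane 12; both are accepted as extra variability.
- radius reduction: a_i = a0 - (a0 - a_s) exp(-(i-c)^2 / (2 sigma^2))
  (1 + eps_i) with taper width sigma ~ U[1,3] plane units and per-plane
  noise eps_i ~ U[-0.1, 0.1]; plane c always receives exactly
  a_s = (1 - S) a0, with no noise.  Radii are not clamped from below at
  a_s (neighbouring planes may slightly undercut it) but must stay
  positive; the noise vector is redrawn otherwise.
- the flow domain appends a cylindrical outflow extension of ten reference
  diameters (30 mm), i.e. a 35 mm total outlet extension past the lesion.

Profiles are lofted with a natural cubic spline through the plane radii and
sampled on a fixed surface grid (4 axial samples per mm, 32 circumferential
samples).  Severities and the nuisance draws use separate seeded
substreams, so the severity distribution is invariant to everything else;
a fixed seed reproduces the cohort bit for bit.

What this generator does *not* emulate: eccentric plaques, vessel
curvature, bifurcations, multi-focal disease, wall compliance.  Results on
this cohort therefore demonstrate the pipeline's internal consistency, not
clinical accuracy.

## Statistical shape model

All cohort meshes share the template's vertex grid, so template-to-target
correspondence is exact by construction and each lesion is represented by
its per-vertex displacement field from the straight-tube template
(flattened x/y/z blocks, length 3 Nv).  PCA of the displacement matrix is
computed by SVD of the centered data (more stable than forming the
3Nv x 3Nv covariance); variances use the (N-1) denominator; each mode's
sign is fixed so its largest-magnitude component is positive, making the
coefficients alpha reproducible.  The default keeps five modes — on a
1024-lesion cohort they capture about 95% of the variance (the
`n_modes="auto"` policy instead keeps the smallest count reaching a 90%
threshold).  Note that PCA on registration momenta (an alternative
representation that smooths with the deformation kernel) would yield a
somewhat different variance profile; the displacement representation keeps
slightly more of the per-plane noise in the trailing modes.

## Reference pressure-drop generator

A desk-scale, deterministic ground-truth generator stands in for a 3D CFD
campaign.  Its coefficients are geometry functionals chosen to mirror the
two loss mechanisms:

- kv_star = (1/ls) Int (a0/a(z))^4 dz over the lesion window (z in
  [4.5, 14.5] mm — the central-segment span widened by half a plane spacing
  so the window length equals ls and a straight tube gives exactly 1),
  evaluated on the splined radius by trapezoidal quadrature at 40
  subdivisions per mm;
- kt_star = ((a0/a_min)^2 - 1)^2, the Borda-Carnot sudden-expansion
  coefficient at the minimal lumen.

Each (geometry, Re) sample then satisfies dp = kv_star h1 + kt_star h2
exactly, optionally perturbed by multiplicative log-normal noise, a
Reynolds-proportional mismatch term, and random convergence failures.
Because the ground truth lies exactly in the model family, the downstream
stages can be validated by parameter recovery.  The Reynolds sweep is
[0.1, 1, 10, 50, 100, ..., 500]; Re = 428 corresponds to the mean
hyperemic flow of about 200 mL/min at a0 = 1.5 mm.  Samples whose stenotic
drop exceeds 60 mmHg are flagged (not deleted) as physiologically
implausible; the fitter drops flagged rows by default.  The Poiseuille
baseline over the straight segments (lext = 40 mm total) is computed and
subtracted analytically, mirroring how a CFD inlet-outlet drop would be
reduced to the stenotic contribution.

## Loss-coefficient fitting

Per geometry the samples split at Re = 10 (Re = 10 itself is high-Re).
Kv is the through-origin OLS slope of dp against h1 over the low-Re subset,
where the quadratic term is *assumed* negligible; Kt is the through-origin
OLS slope of the residual dp - Kv h1 against h2 over the high-Re subset.
Both fits are closed-form, unweighted, without robustification; negative
coefficients are reported with a warning, never clipped.

A known systematic of this two-step procedure: the quadratic term does not
vanish at Re <= 1, so the fitted Kv carries a positive bias of
4.65e-3 * kt_star (with the default constants), i.e. a relative error of
4.65e-3 * kt_star/kv_star.  For mild and moderate lesions this is well
under 1%; for severe, sharply tapered lesions (kt_star/kv_star above ~4)
it exceeds 2% and reaches ~6-9% at S = 0.8 with sigma = 1.  The 60 mmHg
exclusions additionally remove the largest-flow rows of severe lesions,
which amplifies the propagation of this bias into Kt (worst observed ~2%).
This is a property of the prescribed fitting procedure itself, not of its
implementation, and is asserted exactly by the property tests.

## Coefficient regression

Two Gaussian-process regressors map alpha to Kv and Kt.  Kernel:
C * k_base + White, k_base an anisotropic RBF or Matern (nu in {0.5, 1.5,
2.5}), per-dimension length scales initialized at 1 and bounded to
[1e-3, 1e5], C in [1e-1, 1e5], noise variance in [1e-6, 1e1].  Features may
be enriched with degree-2 or degree-3 monomials of alpha and are
standardized with training statistics (without standardization, unit
initial length scales are meaningless across enriched features).  Targets
may be log-transformed, y = ln(K + 1e-6).  Continuous kernel parameters are
refined by maximizing the log marginal likelihood with 3 restarts within
bounds; the discrete choices and the (C, noise) starting values come from a
seeded 20-trial search minimizing mean 5-fold CV MSE on the transformed
target scale, using a TPE-style sampler (10 random startup trials, top-25%
good/bad split, density-ratio proposals with 24 candidates per parameter;
a pure random sampler is available).  Infeasible trials (log transform on
non-positive targets) score infinity rather than aborting.  The Reynolds
number is deliberately not an input feature; the loss coefficients are
per-geometry constants.

Log-scale predictions are mapped back with the log-normal moments: mean
exp(mu + s^2/2) - 1e-6 and the log-normal standard deviation.  A caveat
worth knowing: model selection by CV MSE on the *log* scale weights all
geometries equally, whereas identity-line R^2 on the original scale is
dominated by the severe (large-coefficient) geometries; the CV winner is
therefore not generally the R^2 winner, and at a few hundred training
geometries this gap is noticeable (several points of R^2).

## 0D element, coupling, FFR

The element evaluates dp = Kv_hat h1 + Kt_hat h2 with the posterior means,
and propagates the two predictive standard deviations independently:
dp_sigma = sqrt((h1 sd_Kv)^2 + (h2 sd_Kt)^2).  For waveform coupling the
same relation is exposed as R(Q) = Kv 8 mu ls/(pi a0^4) + Kt rho/(2 pi^2
a0^4) |Q|_sm; the coupling magnitude is under-relaxed, |Q|_sm(n) = 0.3
|Q|_sm(n-1) + 0.7 |Q(n)|, initialized at |Q(0)| to avoid a startup
transient, and the signed drop is dP = R Q so reversed flow reverses the
drop.  FFR is the fixed-pressure surrogate 1 - dp / P_aorta with
P_aorta = 100 mmHg (mean of typical systolic/diastolic); values are
reported unclipped.  A synthetic two-phase coronary-like waveform generator
(suppressed, briefly reversed systolic flow; dominant diastolic flow) is
included for driving the element.  No 1D pulse-wave solver is included;
the element consumes user-supplied or synthetic waveforms.

## Evaluation

Identity-line R^2 (residuals about y = x, matching the identity-line
framing of predicted-vs-true scatter; the fitted-line variant is available
behind a flag), RMSE, mean predictive sigma and the RMSE/sigma calibration
ratio (~1 for a calibrated model; larger means overconfident).
Bland-Altman bias and 1.96 SD limits (sample SD).  FFR agreement: fraction
within 0.02 of the reference, plus the 2x2 classification at the 0.80
ischemia threshold (FFR <= 0.80 positive).  ROC AUC via the Mann-Whitney
statistic with half tie credit; two correlated AUCs compared with the
DeLong structural-components test, two-sided p.  The pipeline's built-in
comparator for these metrics is the geometry-based model with unit loss
coefficients, which needs no training data.

## Problem sizes and determinism

Default pipeline scale mirrors the full study (1024 geometries, 13
Reynolds numbers, 90/10 geometry-wise split stratified by severity decile,
floor on the training count).  The test suite and the acceptance script
run the same code at reduced scale — 16-250 geometries for unit and
end-to-end checks, the full 1024 for the cohort-level counts and the
shape-model compactness — chosen so the whole suite completes in minutes
on one CPU.  Every random draw is derived from explicit seeds
(SeedSequence substreams per geometry and per Reynolds index), so all
artifacts, including the campaign CSVs and summary JSON, are byte-stable
across reruns.

## Known limitations

- The reference generator is an analytic surrogate; it shares the lumped
  model's family by construction, so recovery results bound implementation
  correctness, not CFD fidelity.
- The two-regime fit's Kv bias for severe sharp lesions (above) is
  inherited by anything trained on the fitted coefficients.
- Axisymmetric, single-lesion geometry only; quasi-steady flow only.
- The GP predictive sigma is known to underestimate actual errors when the
  targets are deterministic functions of the inputs (the calibration ratio
  is reported for exactly this reason).
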