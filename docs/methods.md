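# Methods

`hippomeg` asks a single question of a simulated MEG dataset: does a
generative model that includes the hippocampal surface explain the data
decisively better than one restricted to neocortex?  This note documents
the models, the synthetic study conditions, the numerical choices, and what
the package's tests do and do not establish about real data.

## Generative models and model comparison

A generative model here is (i) a source space — surface mesh vertices with
fixed outward-normal dipole orientations, the direction of net pyramidal-
cell current flow, (ii) a lead field mapping unit dipole moments to sensor
fields, and (iii) Gaussian covariance priors at source and sensor level.
Two anatomical models are compared on identical data: *cortical* (one
hemisphere's cortex-like shell) and *combined* (the same shell plus a
nested hippocampus-like tube).  Sensor data reduced to temporal modes
Y (channels × modes) are modelled as zero-mean Gaussian,

    Sigma(lambda) = exp(lambda_0) I + sum_i exp(lambda_i) L Q_i L'

with the sensor-level component fixed to the identity (uncorrelated white
noise).  The source-covariance components Q_i encode the functional
scheme:

- **MNE** — one identity component: equal prior variance everywhere;
- **EBB** — one diagonal component with per-vertex variances from the
  unit-gain minimum-variance estimate q_j = 1/(l_j' C^-1 l_j), C the
  ridge-regularized covariance of the reduced data (ridge 1e-3 × mean
  diagonal), normalized to unit maximum;
- **MSP** — 100 rank-1 patch components Q_i = q_i q_i', each q_i a
  Gaussian patch over graph-geodesic distance (FWHM 6 mm).  90 cortical
  patches are shared between the two anatomical models; each model adds 10
  of its own (extra cortical vs hippocampal, the latter containing the
  simulated seeds, mirroring the matched-prior design).  Both MSP models
  live on the combined source space; the priors alone carry the anatomy.

Log hyperparameters are optimized by Fisher-scoring ReML with Gaussian
hyperpriors (mean −5, variance 256, on the scale where data and components
are trace-normalized).  The reported objective is the Laplace (variational)
free energy

    F = accuracy − complexity,
    accuracy  = log N(Y; 0, Sigma(lambda*))            (per-mode average × modes)
    complexity = ½ (lambda*−nu)' Pi (lambda*−nu) + ½ log det(I + H Pi^-1)

with H the expected information of the hyperparameters, so complexity ≥ 0.
ΔF = F_combined − F_cortical > 3 (odds > e³ ≈ 20:1) is read as decisive
evidence for hippocampal engagement; the posterior model probability is
p = 1/(1+exp(−ΔF)).

**Component pruning.** Rank-1 (patch) components whose log hyperparameter
falls below −10 are pruned from the model and from F.  Without pruning the
resting position of unsupported patches — which the likelihood barely
constrains — leaks into the Occam term and makes F path-dependent by
several nats.  Pruning is the ARD limit of the optimization; a greedy
search over patch subsets is deliberately out of scope, as prior locations
are matched to the simulation design.  Residual local-extrema scatter of a
few nats remains visible in MSP control comparisons (means stay below the
3-nat threshold).

**A bounded artifact of the log-scale Laplace form.** Duplicating a
covariance component leaves the accuracy unchanged but can *raise* F by at
most ½ ln 2 ≈ 0.35 nats, because the information about the summed weight
halves when split across two log-scale coordinates.  This is inherent to
the formulation, bounded, and an order of magnitude below the decision
threshold; tests assert the analytic bound.

## Group-level inference

Across a batch of datasets, random-effects Bayesian model selection treats
the winning model as varying between datasets: responsibilities
u_nk ∝ exp(F_nk + ψ(α_k) − ψ(Σα)) and Dirichlet updates α_k = 1 + Σ u_nk
iterate to convergence (tolerance 1e-6 on α).  `prob_combined_wins` is the
posterior probability that the combined model's frequency exceeds ½
(Beta tail for two models); a posterior-mean variant is available.  The
Bayes Omnibus Risk BOR = 1/(1+exp(F_rfx − F_null)) compares the
random-effects evidence with the fixed equal-frequency null; BOR < 0.05
rejects model equivalence.

## Synthetic study conditions

No subject anatomy is distributed with the original study, so the geometry
is parametric, built to reproduce the contrasts the method exploits: a
deep, curved structure whose surface normals disagree with the surrounding
shell.

- **Cortex**: Fibonacci lattice on a hemisphere, convex-hull triangulated,
  scaled to the requested mean vertex spacing, with a smooth low-order
  radial perturbation (4% amplitude) so normals vary realistically rather
  than being exactly radial (a perfectly radial source in a spherical
  conductor is silent).  Desk scale: 2000 vertices at 3.7 mm; full scale:
  10595 at 3.73 mm.
- **Hippocampus**: a capsule ("banana") bent around a 45 mm arc, tube
  radius solved from the vertex count and spacing, 162 vertices at
  3.69-3.7 mm, centroid 28 mm below the shell.  The axis-length parameter
  (default 50 mm, the adult hippocampus' extent) is defined as the
  tip-to-tip geodesic of the surface meridian; this contract is exact for
  the straight capsule and shortened by ~a/ρ on the inner side once bent.
- **Sensors**: 274 axial magnetometers on a spherical cap centred on the
  conductor centre (the cortical centroid), 30 mm outside the outermost
  source.  Gradiometer baselines are not modelled; noise is injected at a
  stated SNR, so absolute sensor physics cancels in model comparisons.
- **Simulations**: 20 Hz sinusoid, 300 ms (six cycles) at 600 Hz, total
  patch moment 20 nAm spread over a 6 mm-FWHM geodesic Gaussian and
  normalized to sum to the total (resolution-invariant); batches of 30
  sources drawn without replacement; SNR ∈ {0, −5, −10, −15, −20} dB
  defined as the pooled power ratio 10·log10(P_signal/P_noise) — note the
  RMS-amplitude reading 20·log10(rms_s/rms_n) is numerically identical,
  so no separate switch is needed.  Mixtures: four simultaneous dipoles,
  1-80 Hz band-limited unit-RMS waveforms, 100 nAm cortical / 200 nAm
  hippocampal moments, absolute noise 10 fT RMS, 16 temporal modes.
- **Co-registration error**: 0-3 mm Gaussian perturbation of three
  fiducials (9 i.i.d. draws), rigid Procrustes fit from true to perturbed
  fiducials, applied to the *inversion-side* anatomy only; the data are
  never altered.  Zero error reproduces the unperturbed pipeline
  bit-exactly.

## Forward model

The lead field is the closed-form current-dipole-in-a-homogeneous-sphere
(Sarvas) solution, with the sphere centre fitted to the cortical centroid
and units fixed to mm / nAm / fT.  It is oracle-testable: radial dipoles
are silent, and the radial field component equals the free-space primary
term because volume currents contribute no radial field.  A realistic
single-shell correction is an extension point, not implemented; the
spherical conductor preserves the depth and orientation physics that the
anatomical model comparison exploits.

## What the synthetic conditions do and do not show

The desk-scale geometry reproduces every qualitative mechanism: positive,
decisive ΔF for hippocampal sources (EBB and MSP), null ΔF for cortical
sources and for nearest-cortical-neighbour controls, degradation of ΔF
with co-registration error and noise, specificity of the correct
hippocampal placement against 24 shifted alternatives, and a monotone
mixture trend.  Quantitatively the synthetic hippocampus is *easier* than
real anatomy: its lead-field column norms are only ~1.6× weaker than
cortical ones (at a real 8.7 cm sensor distance the attenuation is much
larger), so ΔF magnitudes run higher than the full-scale reference values
and partially hippocampal mixtures already reach significance, where the
full-scale study finds only the all-hippocampal condition decisive.
Correlated (structured) sensor noise, hippocampal subfields and
neighbouring structures (amygdala, parahippocampal cortex) are not
modelled.

Variance explained on the reduced data is ~98.5% at SNR −5 dB for all
schemes — the noise share of the dominant temporal mode (total noise
spread over ~180 spectral modes leaves ~1.7% in the first) bounds it —
and, unlike F, barely separates schemes or anatomies.

## Numerical choices

- Geodesics are graph shortest paths over mesh edges (Dijkstra); the
  discretization bias at 3.7 mm spacing is absorbed by a 10% tolerance on
  patch-weight checks.  Patch weights below 1e-3 of the peak truncate to
  zero (sparse components).
- ReML: hyperparameters start at −log(k) (equal split of the normalized
  data variance); Fisher steps are trust-region limited to 4 log units
  with backtracking; convergence requires |ΔF| < 1e-3 nats *and*
  stationary hyperparameters (max move < 0.02), at most 128 iterations;
  non-convergence is flagged on the result, which carries the best F.
  λ is clamped to [−32, 32]; EBB's data covariance uses a 1e-3 ridge.
- No depth re-weighting of lead fields, no lead-field dimension
  reduction: both would bias one anatomical model against the other.
- Ties in the source-amplitude argmax break to the lowest vertex index;
  ties in pruning resolve by component order.
- Per-dataset seeds derive from the master seed by CRC32 hashing of the
  cell coordinates, so no random stream is reused across cells; every run
  is bit-reproducible from (config, master seed).
- The rotation control rotates the hippocampus about its centroid, default
  axis head-z (axial plane); axis and angle are configurable.
- Problem sizes: the default ("desk") preset uses a 2000-vertex cortex,
  162-vertex hippocampus, 274 sensors and 30 simulations per condition;
  the full-scale ("paper") preset (10595/162/274) is available for
  bookkeeping and scale checks.
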