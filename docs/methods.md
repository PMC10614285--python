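# Methods

This note documents the models and procedures implemented in
`kinesens`, the defaults they ship with, the numerical choices behind
them, and what the synthetic stages do and do not represent.

## Coordinate conventions

Spine geometry lives in a sagittal frame with x anterior-positive and
z superior-positive (mm).  Positive rotations are counter-clockwise in
the (x, z) plane viewed from the subject's left.  Kinematic *outputs*
are reported in a vehicle-fixed frame with x forward and z **downward**
positive, applied only at the reporting boundary (z ↦ −z); everything
internal stays superior-positive.

Segment angles are signed so that positive values match positive
population means: lordosis positive for the lumbar (L1 superior vs L5
inferior endplate) and cervical (C2 inferior vs C7 inferior) segments,
kyphosis positive for the thoracic segment (T5 superior vs T12
inferior).  Endplate vectors run posterior → anterior.

## Spinal realignment

Each vertebra carries four sagittal corner landmarks, a measurement
node at approximately the centre of gravity, and the pivot
(instantaneous axis of rotation) of the joint beneath it.  Pivot
locations are data: the template CSV may carry any pivot column, and
the built-in template defaults to the midpoint of the inferior
endplate of the joint's upper vertebra.  This keeps the algorithm
exact while the anatomy stays configurable.

Alignment of a segment to a target angle proceeds in sweeps: the
residual (target − current) is divided by the number of joints in the
segment, and each joint is rotated by that amount in turn from most
inferior to most superior, all vertebrae above the moving joint
rotating rigidly about its pivot.  The per-joint division is
recomputed every sweep.  Because the lower reference endplate sits
below all of a segment's joints and rigid rotations compose
additively on the upper endplate's orientation, a sweep lands on the
target up to floating-point error; the iteration loop remains for
robustness and stops at a tolerance of 0.01° (default, far below
measurement precision) with a 100-sweep cap that reports the final
residual on failure.

Segments are aligned lumbar → thoracic → cervical; later segments
only move vertebrae above the earlier segments' references, so
achieved angles are preserved.  Finally the whole spine rotates
rigidly about the sacrum measurement node until the C7–sacrum
horizontal offset matches the target; of the two candidate rotations
the smaller-magnitude one is chosen (the correction is a small
posture adjustment, not a somersault).  Targets with |dx| larger than
the sacrum–C7 distance are infeasible and fail loudly.

## Shape model

Covariance PCA (not correlation: all features are mm) over the
stacked (x, z) measurement nodes of the aligned spines.  The sacrum
node is excluded — it is the fixed origin of the alignment and has
zero variance by construction.  Scores are reported in SD units of
the training population.  Signs are fixed deterministically: positive
PC1 moves the C7 node posteriorly (more reclined); other components
take a positive largest-magnitude loading entry.  Two components are
retained by default (the upright/reclined and straight/slouched modes
dominate; on the default synthetic population they explain ~98% of
the variance).

Generated spines place measurement nodes at mean + Σ scoreₖ·sdₖ·vₖ and
rebuild full vertebrae by rigidly placing each template vertebra at
its generated node, rotating it by the local change in the
node-chain's tangent direction (central differences along the chain).
This preserves every vertebra's internal geometry exactly and is
linear in the scores, so generation is affine and training spines are
recovered exactly when all components are retained.

## Parameter distributions (defaults = the study conditions)

| parameter | family | defaults | units |
|---|---|---|---|
| spine_pc1, spine_pc2 | normal | (0, 1) | score SD |
| neural_delay | normal | (20, 3.16) | ms (neck; lumbar = 25/20 × neck) |
| muscle_pcsa | normal | (1, 0.19) | scale factor |
| adipose_props, muscle_props | uniform | [0.5, 1.5] | stiffness scale |
| skin_mu (across lines) | lognormal | (−1.45, 0.45) in log space | strain parameter |
| skin along lines (coupled) | normal | (0.1, 0.028) | strain parameter |

Coefficient-of-variation pooling is two-stage and unweighted: average
within each study over its reported conditions, then average the
per-study means.  The neural-delay per-study averages (0.22, 0.15,
0.10) pool to 0.157 (printed 0.16); the muscle-CSA averages (0.14,
0.21, 0.24, 0.16) pool to 0.1875 (printed 0.19).  The default delay
SD of 3.16 ms corresponds to the unrounded pooled CoV (0.158) times
the 20 ms neck nominal — the printed per-study values are rounded, so
`pooled_cov` of the printed numbers (0.157) and the SD actually used
differ in the third decimal; the module computes the from-printed
value and accepts unrounded per-study inputs rather than guessing
them.

Quartile fits: a normal distribution is fitted to (median, q25, q75)
by least squares over the three quantile equations (closed form via
the normal equations; exact for symmetric triples with
sd = (q75−q25)/(2·z₀.₇₅)); the lognormal fit applies the same rule in
log space, preserving the median exactly.  Least squares was chosen
for asymmetric triples because no fitting criterion is canonical and
it degrades gracefully.

The two skin directions vary together: a single score drives both
marginals comonotonically (across value → its CDF level → along
quantile).  The lognormal (across) marginal is the one integrated by
the quadrature, matching how the parameter enters the sensitivity
integral.

The uniform bounds for the tissue factors ([0.5, 1.5] around a
nominal of 1) are the package's own choice of a plausible
between-study stiffness range; they are configuration data, not
literature values.

## M-DRM estimator

Cut-point: the centre quadrature node of every rule — the mean for
normal/uniform parameters and the median for lognormal.  This is what
makes the shared-nominal n(N−1)+1 design possible (29 runs at n = 7,
N = 5); even N or a nominal displaced from the centre node raises a
design error instead of silently evaluating nN runs.

Quadrature: probabilists' Gauss–Hermite scaled/shifted for normal
parameters (5-point nodes at 0, ±1.356, ±2.857 SD with weights
0.533, 0.222, 0.0113), Gauss–Legendre mapped to [low, high] for
uniform, Gauss–Hermite in log space with exponentiated nodes for
lognormal.  Weights are normalized to probabilities; each rule is
exact for polynomials of degree ≤ 2N−1 in the transformed variable
(property-tested to 1e-10).

Indices: Sᵢ = (θᵢ/ρᵢ² − 1) / Σₖ (θₖ/ρₖ² − 1), the standard normalized
ratio.  This is the form that yields Sᵢ = 1/7 when all seven
parameters enter exchangeably, sums to 1 by construction, and equals
the first-order Sobol share of multiplicative responses in the
small-variation limit.  Tiny negative contributions from round-off
(Jensen guarantees θ ≥ ρ²) are clipped at −1e-9.  A parameter with
ρᵢ = 0 makes the ratio undefined — possible for signed metrics whose
cut passes through zero — and the estimator fails loudly rather than
regularizing; re-zeroing or offsetting the metric is the caller's
modelling decision.  If no parameter contributes variance the result
is all-NaN with a warning.

The optional multiplicative surrogate ĥ(x) = h₀^(1−n) ∏ᵢ fᵢ(xᵢ)
interpolates each factor through its evaluated nodes with a monotone
piecewise cubic (PCHIP — no overshoot between nodes, constant beyond
the extreme nodes).  It is exact at the cut-point and at every design
point of a truly multiplicative response; it is *not* used in the
index computation.

## Occupant surrogate

A planar double inverted pendulum on a horizontally accelerating
base: link 1 pelvis→T1 (lumped torso mass 34 kg at T1), link 2
T1→head CG (4.5 kg).  Geometry comes from the generated spine; the
head CG sits at 1.25 × the T1→C2 chord rotated 20° posteriorly, i.e.
the head balances above the upper thorax rather than continuing the
forward-leaning chord.  Each joint carries a passive rotational
spring-damper (base stiffness 750 / 45 N·m rad⁻¹ lumbar/neck, scaled
by the weighted tissue factor 0.45·adipose + 0.45·muscle +
0.10·skin), a constant gravity-compensating tonus making the initial
posture an exact equilibrium, and a delayed PD controller holding the
reference posture (gains 450/15 and 35/1.5 N·m rad⁻¹, N·m·s rad⁻¹,
scaled by the PCSA factor) whose torque saturates at a PCSA-scaled
bound (160 / 60 N·m) — binding only at extreme demand, so the default
configuration is weakly interacting.  Delays follow the neural-delay
parameter at the nominal 20:25 neck:lumbar ratio and are realized by
a ring buffer of past states at round(delay/dt) steps.

The braking pulse is trapezoidal: 0.15 s ramps, 10 m/s² plateau,
1.3 s duration, entering as an inertial force in the vehicle frame.
Integration is fixed-step semi-implicit Euler at dt = 0.5 ms
(bit-reproducible; halving dt changes the head peak by < 0.5%),
recorded every 4 steps (2 ms), default horizon 1.5 s.  The integrator
is vectorized over a batch axis, which is what makes the 1e4-sample
pick-freeze Sobol oracle (9·10⁴ simulations) run in tens of seconds
on one CPU.

What the surrogate emulates: the direction and rough magnitude of the
levers in an active human body model — posture changes geometry and
effective stiffness, PCSA scales active torque, delay shifts phase,
tissue factors scale passive stiffness; head peak forward displacement
is ~140 mm with the first peak near 0.45 s.  What it does not: contact
with seat and belt, 3D and lateral motion (y is identically zero),
muscle-level anatomy, gravity settling, or the magnitudes of any
particular finite-element model.  Passing tests therefore validate
the *pipeline and estimator*, not occupant biofidelity.

The Sobol oracle uses the Saltelli (2010) pick-freeze estimator on
mean-centred outputs with seeded sampling; it reports per-parameter
asymptotic standard errors.  Draws of the normal PCSA/delay marginals
are floored at a tiny positive value (sub-zero tail mass < 1e-7 at
the default CoVs) because the mechanics require positivity.

## Metrics

Peak forward displacement: first interior local maximum of x(t) with
≥ 1 mm prominence inside [0.1, 0.8] s (window and prominence
configurable); if none qualifies the window maximum is returned with
a flag.  Average vertical displacement: trapezoidal time-average of
z(t) (downward positive) over [0, 1.3] s — the full pulse duration,
a package choice since no canonical window exists.  Displacements are
zero at maneuver onset by construction, making the metrics invariant
to pre-onset offsets.

## Pipeline, seeds and problem sizes

All randomness flows from one root seed split per stage
(numpy SeedSequence); the only stochastic stage in the default
pipeline is the fixture population (36 subjects, matching the source
cohort size), drawn from independent normals with segment-angle
means/SDs of 0.9 (9.2), 20.5 (8.0), 1.3 (8.8) degrees and a C7–sacrum
offset of −100 (30) mm.  The offset distribution is the package's
choice: it yields an overall torso recline of ~13° ± 4°, plausible
for a 23° seat back, and makes the first PCA mode an upright/reclined
mode.  The generator draws the four measurements independently;
real populations correlate them, so the synthetic PC structure is
cleaner than x-ray data would give.

Default problem sizes: 36 subjects, 29 design runs at 1.5 s × 0.5 ms,
10⁴ pick-freeze samples for the surrogate oracle and 10⁵ Monte-Carlo
samples for the analytic test-function oracle — sizes at which the
full pipeline runs in under a second and the complete validation
suite in about two minutes on one CPU.

## Known limitations

* The alignment is strictly sagittal; out-of-plane deformity is out
  of scope.
* Pivot defaults are generic; subject-specific instantaneous axes of
  rotation must be supplied as data.
* The M-DRM form assumes independent parameters and captures no
  interaction terms; the indices are primary (first-order) only.
* The surrogate's equality of the two tissue factors' indices is an
  artifact of their symmetric entry into the joint stiffness; a
  finite-element model would break that symmetry.
* Signed metrics whose cut crosses zero (ρ ≈ 0) are not estimable by
  the multiplicative form; the package fails loudly there.
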