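# Methods

`vasotone` simulates the regulation of vascular tone in a single arterial
segment embedded in a minimal systemic circulation.  Two models are
coupled in both directions:

* a **0D (lumped-parameter) network** of three segments in series —
  upstream artery (R1, C1), segment of interest (R_S(p), C_S(p)),
  downstream vasculature (R3, C3) — driven by a pulsatile cardiac inflow
  and closed by a fixed outflow pressure, evolving on the fast (heartbeat)
  time scale;
* a **2D finite-element cross-section model** of the segment's wall, whose
  mechanics (and hence the tube law A_s(p_s) behind R_S and C_S) depends
  on the biochemical state of the tissue, evolving on the slow
  (minutes-hours) time scale.

The link from fast to slow is the time-averaged wall shear stress (TAWSS)
sensed by the endothelium; the link from slow to fast is the sigmoid
pressure-area surrogate fitted to finite-element inflation sweeps.

## Wall mechanics

Generalized plane strain: deformation confined to the cross-sectional
plane with a fixed axial pre-stretch λ_z = 1.3 and no axial shear.

* **ECM (media + adventitia)**: incompressible Neo-Hookean elastin
  (μ = 10 kPa on the isochoric first invariant) plus two exponential
  collagen fiber families at ±45° from the circumferential direction,
  Ψ_c = (k1/2k2)[exp(k2⟨I4e−1⟩²) − 1] with k1 = 10 kPa, k2 = 2.5.
  Compressed fibers store no energy (Macaulay bracket).  Collagen carries
  an inelastic straightening stretch λ_c^s through a multiplicative split,
  so its elastic invariant is I4e = I4/(λ_c^s)²; λ_c^s < 1 pre-tensions
  the fibers and reduces distensibility at high pressure.
* **Smooth muscle (healthy media only)**: active-strain formulation,
  F = F_e F_a with F_a an incompressible uniaxial contraction of
  magnitude λ_a along the circumferential direction.  The elastic SMC
  stretch is λ_e = λ_θ/λ_a and the scalar first Piola-Kirchhoff stress is
  the sigmoid P = P_max tanh(C_smc(λ_e−1)/P_max) (C_smc = P_max =
  100 kPa): slope C_smc at the isometric point, saturation at ±P_max.
* **Calcified deposit**: a three-term Yeoh solid (c1 = 302, c2 = −228,
  c3 = 261 kPa) replaces the composite.  Its stress-free reference is the
  isochorically axially-accommodated state diag(λ_z^{-1/2}, λ_z^{-1/2},
  λ_z): deposits form in vivo, in the axially stretched vessel, so they
  must not inherit the fictitious pre-compression that the unloaded-mesh
  reference would imply (with that choice the deposit sits under ~150 kPa
  of in-plane compression at zero load and the section buckles; with the
  in-vivo reference it is stress-free exactly where the healthy ring is
  in its axially-accommodated state, and the two remain volumetrically
  compatible).  Species diffusivity, reaction and production vanish in
  the deposit.

**Quasi-incompressibility** (κ = 100 MPa) is enforced with an
element-constant pressure-like multiplier condensed statically: the
mean-dilatation form p_e = κ(J̄_e − 1), the exact algebraic equivalent of
the perturbed-Lagrangian stationarity condition at the element level.
Elements are bilinear quadrilaterals with 2×2 Gauss quadrature (Q1/P0).

The lumen pressure acts as a **follower load** on the deformed intima
(per unit reference axial length, hence scaled by λ_z).  Rigid-body modes
are removed by three **global Lagrange constraints** (zero mean
translation and zero mean rotation): point constraints would tie the
rigid modes to the thin ring's tiny bending stiffness and leave the
tangent near-singular under non-axisymmetric (calcified) loads.

**Solver**: Newton with an exact complex-step element tangent,
backtracking on element inversion, adaptive load stepping (halving budget
restored after each accepted step), and two fallbacks for cold starts:
bulk-modulus continuation in half-decade steps at a stabilizing pressure
(the κ(J−1) drive under λ_z is the stiff part of the problem), then a
Levenberg-damped pseudo-transient iteration.  Convergence: residual
2-norm (rigid components projected out) below 1e-8 of the load scale.

A 1D **radial-quadrature oracle** (incompressible thick-walled tube with
the same constitutive laws, numerically differentiated energy) verifies
the FE solver on axisymmetric configurations; agreement is ~5e-4 in
inner radius at production resolution and is asserted at 1% in the tests.

## NO-ROS chemistry

Material concentrations (nM per unit reference volume) on the reference
mesh; diffusion uses the pulled-back metric D J C⁻¹ from the converged
mechanical state at the most recent mean arterial pressure.  Kinetics:
first-order NO decay η_NO, second-order NO+ROS scavenging K_RNS, constant
basal productions.  The basal ROS values close the homogeneous steady
state exactly:

    C_ROS_b = (P_NO_b/C_NO_b − η_NO)/K_RNS ,  P_ROS_b = K_RNS C_ROS_b C_NO_b.

The tabulated decay constant is printed as "0.01 s", which is
inconsistent with the printed basal chain (80 nM/s, 10 nM, 69.9 nM/s,
1.74 nM); η_NO = 1.01 s⁻¹ — the unique value consistent with that chain —
is the default and is config-exposed.

**Endothelium**: shear-driven Michaelis-Menten NO production
P_NO,e = P_NO_b + (1−α_dys)·[R_NO^max P_O2/(K_m+P_O2)]·(τ̄ − τ̄_b), with
ROS production scaling linearly with P_NO,e (hence the endothelial ROS
concentration is identically basal).  These set Dirichlet values on the
intima; the outer boundary is zero-flux.  The dysfunction level α_dys
scales only the shear-sensitive term.

**A consequence worth knowing**: with the closure-consistent kinetics the
effective NO turnover is η_NO + K_RNS·C_ROS_b ≈ 8 s⁻¹, giving a
reaction-limited penetration depth √(D/8) ≈ 30 µm.  At steady state the
bulk of the wall is pinned at the basal concentrations and only a thin
layer at the intima (and at calcification boundaries) deviates.  Tone
regulation therefore acts through the intima-adjacent elements, and its
strength is weaker than the source study reports (whose 15-minute
diffusive-transient narrative implies much slower kinetics than any
parameter set consistent with its printed basal values).  The element
size at the intima partially sets the regulated response through the
element-averaged NO; this is an acknowledged, documented sensitivity.
The Galerkin discretization under-resolves the 30 µm layer, producing a
bounded local undershoot below the basal value; mass balance and the
basal fixed point are unaffected.

**Tone coupling**: λ_a(C_NO) is a sigmoid through (C_NO_b, 0.75) with
limits 0.59 / 1.3 and sensitivity k_λ = 100; the published intercept
coefficient does not satisfy the basal condition and is replaced by the
algebraically consistent a_λ = λ⁻ + b_λ.  Collagen straightening follows
λ_c^s = 1 + ξ_c(λ_a − 1) with ξ_c = 0.15.  Both are element-wise constant,
driven by the element-average nodal NO.

Time stepping: backward Euler with a Newton solve of the bilinear
reaction at each step (stable for steps 0.1–60 s); the steady state is a
direct Newton solve with continuation from basal on failure.

## Hemodynamics and coupling

Inflow: raised-cosine systolic half-beat with amplitude 4 f_h V_h
(per-beat volume V_h = 93.33 mL from 5.6 L/min at 60 bpm; stroke volume
constant as f_h varies).  Backward Euler at 200 steps/beat, preceded by
≥5 s of fictitious pre-beats from y = P_out·1; the physical window is
n_h = 3 beats.  R_S = 8πμ_b ℓ_S/A², C_S = ℓ_S dA/dp from the fitted
sigmoid A(p) = a/(1+exp(−b(p/c−1))) + d (constrained least squares,
c > 0, multi-start).  Wall shear τ = 4μ_b q_S/(π r_S³) with r_S from the
surrogate area at the instantaneous mean pressure; TAWSS averages the
physical window.

The pressure sweep (default [0, 250] mmHg in 10 steps) anchors at a
mid-range pressure and walks down/up with warm starts; unloaded
calcified sections can sit on an unstable (wrinkling) branch at p ≈ 0,
in which case the failed lowest steps are dropped and the fit uses the
partial results — the network never visits those pressures.

**Fixed point**: the transfer map g(τ) = (chemistry → tone → sweep →
surrogate → network → TAWSS) is solved by Aitken-Steffensen iteration
(standard "−" update; the printed "+" variant fails the affine
one-step-exactness property), with memoized evaluations, convergence on
the endothelial-NO error |ΔC_NO,e|/C_NO_b < 1e-3, and averaging of
consecutive guesses when the error grows.  Chemistry inside g always
restarts from the state committed at the previous slow step, making g a
pure function of τ.

**Blood viscosity**: μ_b is not printed in the source.  It is calibrated
(geometrically convergent scaled iteration) so that the basal network run
returns exactly the tabulated basal TAWSS of 1.74 Pa — the same
construction by which that value was produced — which makes basal
homeostasis an exact fixed point.  With this package's wall model the
calibrated value is ≈ 4.4 mPa s (physiological for whole blood);
the conventional 3.5 mPa s is the config default and is used where a
nominal value is required.

## Scenarios

* `basal_equilibrium`, `calcified_equilibrium`,
  `calcified_equilibrium_frozen` (regulation disabled): constant
  schedules; the slow loop reduces to the coupled equilibrium.
* `local_tawss_up/down`: prescribed ±50% TAWSS ramps over 2 minutes
  (local-only mode; no network, no fixed point).
* `heart_rate_ramp`, `dysfunction_mild/severe`: 60 → 120 → 180 bpm
  plateaus at ≈0, 12, 26 min with 2-minute linear transitions over
  60 minutes; α_dys ∈ {0, 0.5, 0.9}.  The plateau timing between the
  anchor points is not specified in the source; 2-minute ramps are used
  and config-exposed.

## Synthetic-data / fixture scope

There is no external data: all inputs are the tabulated constants.  The
fixture generator provides a coarse (24×5) section for unit tests and the
production (96×15 ≈ 1440-element) section for integration work.  A green
test on the coarse fixture establishes correctness of the algorithms, not
mesh-converged values; mesh sensitivity of the reported quantities is
itself a reported target of the acceptance script.

## Known limitations

* The NO penetration depth makes the regulated response dependent on the
  intima-adjacent element size (see above); reported regulated changes
  undershoot the source study.
* The relaxed-to-basal radius reduction at 120 mmHg is ~18% with the
  printed parameters, not the ~30% the source's calibration footnote
  claims (~30% would require ξ_c ≈ 0.5, or occurs near 80 mmHg).
* No residual stresses/opening angle, no viscoelasticity, no growth and
  remodeling, single chemo-active segment, 2D cross-section only.
* At zero pressure a calcified section sits near a wrinkling instability;
  the unloaded-state area is then extrapolated by the surrogate rather
  than computed.
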