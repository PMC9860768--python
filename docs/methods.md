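# Methods

## Scope and intent

`aerodep` is a desk-scale re-implementation of an extrathoracic aerosol
dosimetry pipeline: Lagrangian tracking of inert 1–30 µm spheres through
mouth–throat airway geometries under steady flow, regional
deposition-efficiency statistics against the impaction parameter
*d*<sub>a</sub>²*Q*, and coupling of the oral filter to a multiple-breath
whole-lung model. Because no public airway CT geometries back this class of
analysis, every input is synthetic and parameterized; the package's claims
are therefore about the *machinery* — transport physics against analytic
oracles, conservation audits, fit recovery, trend properties — not about
reproducing any specific subject's deposition values.

## Airway geometry

The synthetic airway is a swept-section duct along a planar (sagittal)
centerline: a straight 245 mm mouthpiece extension tube (Ø 20 mm), an
elliptical mouth cavity (26 × 14 mm, 70 mm long), a 90° downward bend
through the oropharynx (bend radius max(1.2 · pharynx Ø, 14 mm)), a
laryngeal segment with a mid-length glottal constriction (pharynx Ø 12 mm →
glottis Ø 7 mm), and a straight trachea (Ø 15 mm, 60 mm). Cross-section
semi-axes are piecewise-linear in arclength. Dimensions are anatomically
plausible round numbers; the mouthpiece tube diameter is a free parameter
(no standard value exists). Gravity is −Z; the tube axis is horizontal,
matching a seated subject inhaling through a mouthpiece.

Region labels (TUBE, MOUTH, OROPHARYNX, LARYNX, TRACHEA) partition the wall
by planes of constant centerline arclength; a face whose centroid falls
exactly on a boundary belongs to the downstream region. Meshes are
exchanged as STL (ASCII or binary) with a `face_index,label` CSV sidecar,
since STL carries no attributes. Mesh validity requires positive face
areas and exactly two boundary loops (inlet and outlet). Enclosed volume
caps the openings with centroid fans and uses the signed-tetrahedron sum.

Intersubject variability is modeled as anatomical: the cohort generator
applies seeded log-normal multipliers (σ = 0.20 on transverse dimensions,
0.10 on lengths) and draws the glottis-to-pharynx ratio uniformly from
[0.3, 0.7]. Healthy/COPD group labels are carried but draw from the same
distribution, reflecting the absence of a geometric group difference in
the motivating data.

## Flow surrogate

The Navier–Stokes equations are *not* solved. The velocity field is an
analytic duct flow built from the centerline: axial advance rate
`w(s, ρ) = (Q/A(s)) · f(ρ)` with `ρ` the normalized elliptical radius,
times the curved-frame metric `(1 − kζ)` (k the centerline curvature, ζ the
in-plane offset), plus the continuity-implied wall-parallel components
`w · (y/a) · da/ds` and `w · (z/b) · db/ds` in tapers. This field carries
exactly Q through every cross-section (the odd metric term integrates to
zero) and its streamlines preserve `(y/a, z/b)`, so inertia-free tracers
never touch the wall — the property that makes the tracer-limit test
meaningful. Secondary (Dean) vortices, jet separation downstream of the
glottis, pressure and turbulence are absent by construction; bend and
constriction impaction still occur because the axial direction and section
area vary while particle inertia resists.

Profiles: parabolic `2(1−ρ²)`, plug, and a power-law
`(n+1)(2n+1)/(2n²) · (1−ρ)^{1/n}` (default n = 7). The pipeline default is
the blunt power-law at *both* flow rates. Rationale: at 18 L/min the tube
Reynolds number is ≈ 1250 and the laminar entrance length (0.05 · Re · D ≈
1.25 m) far exceeds the 245 mm tube, so the profile delivered to the mouth
is a developing blunt one rather than fully-developed Poiseuille; at
45 L/min the power-law is the usual surrogate for a turbulent mean profile.
A fully-developed parabolic profile is retained as an option and is used
where an oracle assumes it (the horizontal-tube sedimentation benchmark).
Its near-wall creep layer (u → 0 with no entrance or turbulent
replenishment over a 0.6 m path) exaggerates mouth-floor sedimentation at
resting flow and is not a realistic default for this geometry.

Expiratory flow reverses the field pointwise (`u → −u`); particles are then
injected at the tracheal outlet and escape at the tube inlet, with the tube
still reflecting.

## Particle transport

Equation of motion: `du_p/dt = F_D (u − u_p) + g (ρ_p − ρ)/ρ_p` with
`F_D = 18μ/(ρ_p d_p²) · (C_D Re_p/24)`. The drag dialect is
Schiller–Naumann, `C_D Re_p/24 = 1 + 0.15 Re_p^0.687`, standard for
Re_p < 800 and exact to the Stokes limit as Re_p → 0; a pure-Stokes option
exists for benchmarks. No Cunningham slip correction (particles ≥ 1 µm;
at 1 µm this biases drag by ≲ 15%, and the modeled equation of motion omits
it), no Brownian diffusion, no turbulent dispersion (the flow surrogate has
no turbulence statistics to drive one), one-way coupling only.

Air: ρ = 1.204 kg/m³, μ = 1.825×10⁻⁵ kg/(m·s). Particles: ρ_p =
1000 kg/m³, so geometric diameter = aerodynamic diameter.

**Integrator.** Velocities advance by the exponential update (exact for
flow and drag frozen over a step); positions advance by the closed-form
time integral of the relaxing velocity, which is exact in both the
ballistic and tracer limits. Each step evaluates the fluid velocity in two
Heun stages (start point and provisional endpoint). Both choices were
necessary: with first-order stepping, inertia-free tracers spiral outward
through the 90° bend by ~16% of the duct radius and deposit spuriously.
The time step is `dt = min(0.1 s, 0.1 · r_local / max(|u|, |v|))` — a tenth
of the local duct radius per step. No relaxation-time cap is applied: the
exponential update is unconditionally stable and exact in the drag term, so
resolving τ (≈ 6×10⁻⁶ s at 1 µm) would multiply the step count ~10⁴-fold
without accuracy benefit. At these settings the residual numerical
deposition of perfect tracers on the curved/tapered walls is ≈ 1% of the
ensemble and flat in particle size.

**Walls.** Collisions are resolved against the analytic swept surface: a
step endpoint with normalized radius ρ ≥ 1 is backtracked linearly to the
crossing; the region at that arclength decides trap (airway regions),
specular reflect (TUBE: the mouthpiece is outside the region of interest),
or — past either end — escape. Arclength classification is identical to
face-label classification because the mesh triangulation and the analytic
surface come from the same parameterization. Particles are tracked in
arclength coordinates incrementally (metric-corrected tangent projection
plus one foot-point refinement per step), so no global point-in-mesh
queries are needed.

**Injection.** The default `blunt` release scatters particles uniformly
over 99% of the opening area (`ρ ≤ 0.995`, strictly inside the rim) with
the local fluid velocity. A `flux_weighted` option samples positions in
proportion to the local axial velocity; it exists because analytic
penetration formulas (below) are flux-weighted, and is used only in those
benchmarks. Ensembles default to 10,000 particles; counts are integers and
`N_injected = Σ N_region + N_escaped + N_lost` holds exactly on every run.
Runs losing more than 0.1% of particles to the step budget are flagged.

**Oracles.** Two closed forms anchor the integrator: (1) terminal settling
velocity `v_s = ρ_p d_p² g/(18μ)`, matched to 10⁻⁶ relative with Stokes
drag and buoyancy off (the Schiller–Naumann/buoyancy corrections are
physical, not numerical, and are checked separately); (2) gravitational
deposition in a horizontal circular tube under Poiseuille flow,

```
DE(κ) = (2/π)[2κ√(1−κ^{2/3}) − κ^{1/3}√(1−κ^{2/3}) + arcsin(κ^{1/3})],
κ = 3 v_s L / (8 R ū),
```

matched within two binomial standard errors at n = 10,000 for
κ ∈ {0.01, 0.05, 0.1}.

## Deposition statistics

The impaction parameter x = d_a²Q always carries its unit system
(µm²·L/min or µm²·mL/s; conversion factor 1000/60). The semi-empirical
oral deposition correlation η = 1 − (3.5×10⁻⁸ x^1.7 + 1)⁻¹ uses the mL/s
convention, and all sigmoid fits run internally in that system; β₁ is
converted to the requested system afterwards by the exact relation
β₁′ = β₁ c^{−β₂}, which makes unit equivariance hold to machine precision
rather than to optimizer tolerance.

The fit is nonlinear least squares on DE fractions in (log β₁, β₂)
(positivity enforced by parameterization), initialized from the exact
linearization logit(DE) = log β₁ + β₂ log x, with randomized restarts on
non-convergence. Confidence intervals come from the asymptotic covariance
(t-quantile, n − 2 dof); the β₁ interval is formed on the log scale and
exponentiated. Zero-DE points stay in the fit (no logit transformation of
the data). Fits whose β₁ interval spans more than a factor of 10 — the
signature of input covering too narrow an x range — are flagged rather than
returned as silently confident. All (subject, size, flow) points are pooled
with equal weight.

## Whole-lung model

A deliberately simple symmetric-generation stand-in for multiple-path
dosimetry codes — the coupling arithmetic is the point, not airway-tree
realism. Morphometry is Weibel model A (24 generations, counts 2^g),
linearly scaled by (FRC/3.3 L)^(1/3); gas volume not accounted for by the
scaled ducts is carried as a distal alveolar reservoir so the model holds
exactly FRC. Generations 0–16 are tracheobronchial, 17–23 alveolated.

Per-generation single-pass efficiencies (all within [0, 1], combined as
1 − Π(1 − η)):

- impaction, Yeh–Schum form: η = 1 − (2/π)·arccos(θ·Stk) +
  (1/π)·sin(2·arccos(θ·Stk)) for θ·Stk < 1 (else 1), with
  Stk = ρ_p d_p² u / (9 μ d) and branching angle θ = 35° (zeroed in the
  trachea, which has no upstream bifurcation here);
- sedimentation, Yeh–Schum tube form:
  η = 1 − exp(−2 g ρ_p d_p² L cos φ / (9 π μ d u)), gravity angle φ = 45°
  (upright orientation);
- diffusion, Gormley–Kennedy/Ingham-style penetration in μ′ = D L/Q_gen
  with D = kT/(3πμd_p); negligible above 1 µm but kept for completeness.

A breath of tidal volume TV advects as a volume front: the parcel of tidal
air terminating in generation k (weights from TV against cumulative
generation volumes) deposits through generations 0..k in, pauses, and
deposits back out through k..0 at the exhalation flow. Of the parcel
penetrating past the last generation, a mixing fraction m (default 0.3,
configurable — published alveolar-mixing equations are not available to
match) remains with residual air and is scored as alveolar retention over
the breath series; an end-inspiratory pause deposits alveolar-resident
aerosol by settling across a 300 µm air space. Oral coupling: η_oral_in of
each inhaled unit mass deposits before the lung; η_oral_ex of the exhaled
mass deposits on the way out. The five-way ledger (oral-in, TB, alveolar,
oral-ex, exhaled-to-ambient) sums to 1 exactly (closed against float
rounding, with a 10⁻⁹ drift guard); breaths use constant subject-specific
inspiratory/expiratory flows from the packaged table, five per condition.

Known limitations: no asymmetric lung paths or ventilation heterogeneity,
no inter-breath re-dispersion of mixed aerosol, no hygroscopic growth,
constant-flow square-wave breathing.

## Synthetic data and what passing tests mean

The noisy deposition generator produces DE_ij =
logistic(logit(sigmoid(x_j)) + b_i) with per-subject b_i ~ N(0, σ): every
pseudo-subject is a parallel logit-shift of the generating sigmoid. This
matches the fit's own error model up to clustering, so the coverage test
(generating exponent inside the 95% CI in ≥ 90/100 replicates) validates
the fit-and-CI machinery, not robustness to structured real-world error.
Similarly, transport tests against duct oracles validate the integrator
and wall logic, not CFD fidelity: the synthetic airway has no secondary
flows, no turbulence, no surface roughness, and deposition magnitudes on it
should not be read as subject predictions. Problem sizes in the test suite
(10,000-particle oracle and trend runs; 200-particle conservation grids,
where the count identity is exact at any n) were chosen to keep the full
suite at a few minutes on one core.

## Numerical conventions

SI meters and seconds internally; µm and L/min at user interfaces only.
Region-boundary ties go downstream. Wall reflection is specular with the
particle re-seated just inside the surface (ρ = 0.998). All randomness
flows from explicit integer seeds; grid runs split one root seed per
condition via CRC32-keyed SeedSequence, so results are independent of row
order and process. Fixed seeds reproduce deposition counts bit-for-bit.
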