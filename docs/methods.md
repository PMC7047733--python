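# Methods

## Problem and scope

After DORV correction, the intraventricular tunnel behaves hydraulically
like a curved conduit: left-ventricular blood enters at the VSD, turns
toward the aortic valve plane, and discharges through the valve orifice.
The analysis here asks how three geometric factors — the VSD-to-valve
distance D_SA, the ejection angle A_LT, and the turning radius R_TT —
control the trans-tunnel pressure difference ΔP, using a balanced
orthogonal experiment, main-effects ANOVA with LSD post-hoc comparisons,
and a single-factor radius sweep with a plateau rule.

The packaged 25-run reference experiment carries CFD-computed ΔP responses;
all statistics run on those printed responses. The 3D flow solution itself
is out of scope: this package replaces it with a one-dimensional
reduced-order model (ROM) whose role is qualitative — reproducing the sign
structure and rank ordering of the factor effects — not quantitative field
prediction.

## Geometry

The centerline is planar, built in the x–y plane: the jet leaves the VSD
(origin) at angle A_LT above the valve plane, turns through
`theta = 90° − A_LT` on a circular arc of radius R_TT, and runs straight to
the valve plane `y = D_SA`. Closing the path gives

    L_out = D_SA − L_in·sin(A_LT) − R_TT·cos(A_LT),

and a configuration is feasible iff `L_out ≥ 0`. Conventions chosen where
the source geometry is figure-only:

* **A_LT reference axis** — measured from the valve plane, so A_LT = 0 is a
  full 90° turn and larger angles give gentler bends. This is the
  convention under which the observed group means decrease monotonically
  with A_LT, and is documented as an assumption, not an established fact.
* **Inlet straight** `L_in = 0` by default (the VSD opens directly into the
  bend); configurable.
* **Lumen bore 13.33 mm** — not reported by the study; derived from the
  stated transitional regime, Re = ρvD/μ ≈ 4000 at v = 1 m/s, which the
  default bore reproduces to within 0.03%. Configurable.
* `R_TT = 0` degenerates to a sharp elbow (two straights); it has a valid
  centerline but cannot be swept into a non-self-intersecting surface.

The lumen surface sweeps a circle along the centerline with
rotation-minimizing frames (trivially exact for a planar path: the plane
normal is a constant frame axis). Caps are triangle fans about the end
centroids, so a capped mesh is watertight by construction and its volume
equals `π(D/2)²·L` up to the inscribed-polygon deficit
(≈ 2π²/3n² ≈ 0.16% at the default 64 circumferential points; Pappus'
theorem makes the bent-tube volume exact in the continuum). Sweeping
raises a self-intersection error when `R_TT < D/2` on a bent path. Mesh
export (binary/ASCII STL, PLY) goes through trimesh.

## Reduced-order pressure model

Steady, incompressible, Newtonian flow (peak systole: 1 m/s inlet,
110 mmHg outlet; ρ = 1050 kg/m³, μ = 0.0035 Pa·s). ΔP is a minor-loss
budget in units of dynamic pressure q = ½ρv² = 525 Pa ≈ 3.938 mmHg:

    dP = (k_entrance + K_bend + f·L/D + k_exit) · q,
    K_bend = c1 · (theta/90)² · exp(−c2 · R_TT / D).

* Friction: Darcy `f = 64/Re` below Re 2000, Blasius `0.316·Re^−0.25`
  above 4000, linear blend in Re between — a deliberate, simple bridge
  across the transitional band the tunnel sits in.
* The bend term is finite at the mitered limit (K = c1 at R_TT = 0,
  theta = 90°), vanishes for a straight tunnel, and decays exponentially
  with the radius-to-bore ratio. The quadratic angle dependence and
  exponential radius decay are standard curved-conduit behaviour, and they
  carry the model's two monotone contracts: ΔP strictly decreasing in
  R_TT and A_LT (bend decay dominates the slow friction growth from the
  longer arc over the 0–10 mm range), weakly increasing in D_SA (friction
  only).
* The "small steps" at the VSD and valve orifice are not meshed; their
  effect is carried by the entrance/exit coefficients. Defaults
  k_entrance = 0.5 (sharp-edged entry), k_exit = 1.0 (jet discharge),
  c1 = 1.2, c2 = 2.0 are conventional hydraulics magnitudes.
* mmHg conversion fixed at 133.322 Pa/mmHg.

`calibrate` refits (c1, c2, k_entrance = k_exit) by bounded least squares
(scipy trust-region, fixed start point, hence deterministic) against
observed responses, reporting SSE and the Spearman rank correlation
between model and observation. On the reference experiment the calibrated
model reaches Spearman ≈ 0.94; rank agreement, not absolute accuracy, is
the claim. Constant responses or a vanishing bend amplitude are flagged as
a degenerate fit rather than reported silently.

The calibrated coefficients (c2 ≈ 1.5) decay more slowly than the
defaults, so the calibrated sweep plateaus later than the default one
(which plateaus at 3 mm under the 5% rule on the 12-point grid); the
clinical recommendation of ~6 mm is treated as a qualitative, not exact,
target since the underlying sweep responses are not published numerically.

## Orthogonal design and ANOVA

The design is an L25(5³): each level occurs 5 times, each ordered
cross-factor level pair exactly once. `verify_balance` checks both
invariants by brute-force counting and lists every violation.
`construct_balanced_design` generates fresh arrays by the Latin-square
index rule `C = (A + 2B) mod 5`. The packaged reference array is taken as
ground truth and pinned by checksum.

ANOVA uses the balanced closed form (type I = type III here):
`SS_f = Σ_l T_l²/r − G²/N` on 4 df per factor, pooled error on 12 df,
upper-tail F(4, 12) p-values. Post-hoc comparisons are Fisher's LSD —
unadjusted two-sided t tests on 12 df with the pooled
`SE = √(2·MS_err/5)` — chosen because it exactly reproduces the published
pairwise table; no multiplicity adjustment is applied, matching that
output. Zero-variance responses yield p = 1 with a diagnostic flag.

Two published numbers are knowingly not reproduced and are excluded from
all checks: the published ANOVA SS/F column is inconsistent with the
published responses (the abstract's P = 0.459 for D_SA is reproduced
exactly; the published A_LT P = 0.263 is not — recomputation makes A_LT
strongly significant), and two LSD cells (0.379 for 5 vs 7.5 and the
0.032 mirror of 2.5 vs 5) contradict their own mirrored cells. The eight
internally consistent LSD cells reproduce to three decimals.

## Sweep and plateau rule

The radius sweep evaluates the model from 0 mm in 1 mm steps (12 points by
default), holding the other factors at the base configuration (the source
does not state which base was used; it is a config choice, defaulting to
D_SA = 30 mm, A_LT = 0°). The per-step change rate is the backward
relative difference in percent; the plateau radius is the smallest swept
value reached by a sub-threshold step with no super-threshold step after
it ("all subsequent steps", to avoid false plateaus on noisy curves). The
rule is monotone non-increasing in the threshold. Infeasible sweep points
(R_TT > D_SA at A_LT = 0) are dropped with a warning.

## Synthetic data

`generate_response` draws `y = μ + a_i + b_j + c_k + ε`,
`ε ~ N(0, σ²)` (PCG64, seeded, bit-reproducible), with each factor's five
offsets summing to zero — the same additive structure the ANOVA fits, so
generator offsets are exactly the estimands, and
`E[SS_factor] = 5·Σ offsets² + 4σ²`. `generate_sweep_curve` draws
`ΔP(r) = p_inf + A·exp(−r/decay) + ε`, the saturating shape the radius
sweep exhibits. What the generators deliberately do *not* emulate:
interactions, non-Gaussian CFD discretization error, pulsatility, or any
spatial field structure — so passing statistical tests validates the
inference machinery, not the fidelity of CFD data.

Problem sizes used in the validation suite: 2000 null replicates for the
type-I error band [0.03, 0.07] at α = 0.05, 500 replicates for power
(≥ 95% at a 4σ offset range), 100 random balanced designs for agreement
with an independent GLM reference (statsmodels OLS + anova_lm) at 1e−8
relative, and 10,000 permutations for the nonparametric cross-check of
the radius p-value.

## Known limitations

* The ROM is one-dimensional: no secondary flows, no turbulence model, no
  fluid–structure interaction, valves or moving walls; only trend
  agreement with 3D CFD is claimed, and only steady peak-systole flow is
  represented.
* Centerlines are planar; out-of-plane tunnels are not modelled.
* The LSD procedure makes no multiplicity correction by design; with 10
  pairwise tests its family-wise error rate is well above 0.05.
* Whether the reference ΔP values are mean or peak differences is not
  stated; they are treated as steady values.
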