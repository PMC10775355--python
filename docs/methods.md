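# Methods

## Model

The tissue is a confluent tiling of `N` polygonal cells on a periodic
rectangle (torus), every vertex trivalent, with mechanical energy

    E = Σᵢ ½ k_a (aᵢ − a₀)² + ½ k_p (pᵢ − p₀,ᵢ)²

over alive cells. `aᵢ` and `pᵢ` are the polygon area and perimeter
(minimum-image convention), `a₀` a shared preferred area and `p₀,ᵢ` a
per-cell preferred perimeter. We nondimensionalize with
`a₀ = k_a = k_p = 1`: lengths in units of √a₀, forces and tensions in
units of k_p √a₀. The x axis of the box is the anterior–posterior (AP)
axis. Forces are the exact analytic gradient; junction tension is the
sum of the two adjacent cells' perimeter-spring tensions,
`τ_J = k_p (pᵢ − p₀,ᵢ) + k_p (pⱼ − p₀,ⱼ)`.

Force balance is reached with an energy-monotone FIRE variant
(semi-implicit Euler, velocity mixing α₀ = 0.1, dt ∈ [5·10⁻⁵, 0.2],
growth 1.1 / backtracking 0.5): any trial step that raises the energy is
reverted and the timestep cut, so accepted iterates are non-increasing
in E and the descent property is testable. Convergence means the
largest force component falls below `tol` (default 10⁻⁷ for direct
minimization; the closure protocol uses 10⁻⁵, one order below the 10⁻⁴
tension floor used for rigidity classification, because marginally
rigid polydisperse states exhibit glassy residual tails). When 10⁵
FIRE iterations fail to converge, a quasi-Newton (L-BFGS) polish is run
in reduced coordinates where every pinned rosette group moves as a
single vertex — the energy is smooth there, and second-order steps
resolve the nearly-flat soft modes that first-order descent crawls on;
FIRE then resumes from the polished state.

### Rosette (collapsed-edge) handling

Under tension a junction can contract to zero length while its
neighbor-exchange is energetically unfavorable. The tension term makes
E non-smooth there (linear in the separation), which would stall any
descent. Edges shorter than `pin_threshold = 10⁻⁴ √a₀` whose junction
tension exceeds `−10⁻³` are therefore treated as a single merged
higher-order vertex: the pair's force and velocity are replaced by the
pair mean (iterated so chains of collapsed edges converge to a common
group mean), and the convergence criterion uses the merged residual.
Pairs under meaningful compression (tension below `−10⁻³ k_p √a₀`) are
left free, since re-extension lowers the energy at a rate far above
the force tolerance and regular dynamics separates them quickly;
weakly compressed pairs are pinned too, as their re-opening force is
below any practical tolerance and would only make the residual creep.
Biologically these merged vertices are rosettes, which are observed in
the amnioserosa.

### T1 moves

A neighbor exchange is tested, never forced: the state is first relaxed
to a (rosette-pinned) minimum; each edge shorter than
`ℓ_T1 = 0.02 √a₀` is then flipped (rotated 90°, re-placed at
`1.5 ℓ_T1`), re-relaxed, and kept only if the relaxed energy dropped by
more than a relative margin of 10⁻⁸. Athermal quasistatic dynamics
cannot cross barriers, and an exchange that releases no energy is a
marginal rosette rearrangement, not a plastic event. Rejected flips are
reverted; each vertex pair may flip at most 4 times per minimization
call (suppressing flip-flop cycling of zero-tension edges in the floppy
regime). Every accepted T1 is logged with its closure stage, so "no T1
events" in a run is an observation. This deviates from the simpler
"flip any short edge during descent" convention, which we found to
produce flip storms and spurious, immediately-reverted exchanges.

T2 removal (ingression) collapses a cell to one trivalent vertex at its
centroid. Cells with more than three sides are first retracted by
collapsing their shortest edges through neighbor exchanges; these
junction losses belong to the ingression event and are logged there,
not in the spontaneous-T1 count (matching the convention that
ingression-linked junction loss is not a neighbor exchange between
persisting cells).

## Closure protocol

One run is a pure function of its `RunConfig`:

| parameter | default | meaning |
|---|---|---|
| `n_cells` | 400 (256 in the acceptance runs) | initial cell count |
| `aspect` | 2.0 | initial box aspect (AP axis twice the height) |
| `q0_mean` | 4.2 | mean initial preferred shape index |
| `q0_sd` | 0.45 | SD of the initial preferred shape index |
| `delta` | 0.00125 | per-step height decrement, fraction of initial height |
| `dA_max` | 0.8 | final fractional area loss |
| `shrink_slope` (c) | 0.65 | preferred-perimeter loss per unit ΔA |
| `ingression_fraction` | 0.1 | fraction of cells removed over a run |
| `mode` | uniaxial | `isotropic` removes equal area per step on both axes |

Each step: affine box deformation → `p₀,ᵢ(ΔA) = p₀,ᵢ(0)(1 − c ΔA)`
(preferred area untouched) → possibly one random ingression (per-step
probability `f_I N₀ / n_steps`) → T1-enabled minimization. With the
uniaxial schedule ΔA = k·δ exactly after k steps. Observables are
recorded every 0.01 in ΔA.

Preferred shape indices are drawn once from N(q̄₀, σ_q,0), resampling
non-positive draws; a parameterization in which more than 1 % of draws
would be non-positive is rejected as misconfigured. The preparation
quench that follows runs *without* neighbor exchanges
(`t1_in_preparation = False`): the initial state keeps the Voronoi
topology and its frustration — the developing tissue arrives at closure
onset by growth, not by our relaxation — and T1 activity is an
observable of the driven protocol only.

### Calibration of q̄₀(0) and c

σ_q,0 = 0.45 is fixed by the measured width of the initial shape-index
distribution. The initial mean q̄₀(0) = 4.2 places the post-quench
shape-index distribution above the rigidity point with a strongly
percolating tense network at onset (f_r(0) ≈ 0.95). The shrink slope
c = 0.65 reproduces the experiment-side constraint that the mean
junction perimeter decreases linearly by roughly half over the run,
and with it the simulated tissue shows the reported phenomenology:
q̄(ΔA) non-monotonic with an interior minimum near ΔA ≈ 0.5, τ̄_J(ΔA)
peaking near the same stage, q̄ above the standard-model fluidization
value throughout, and rising AP orientational order under uniaxial
(but not isotropic) deformation. Slopes of 0.5–0.6 let the tissue
fluidize mid-run at this polydispersity, so 0.65 is the smallest slope
consistent with the solid-throughout observation; these two numbers
were fixed once against the stated study conditions and are ordinary
config parameters.

## Rigidity percolation

A junction is rigid when `τ_J > ε_τ = 10⁻⁴` (config-exposed; in rigid
states the verdict is insensitive over ε_τ ∈ [10⁻⁵, 10⁻³] because
physical tensions are orders larger). Wrapping is decided exactly on
the torus with a union-find that tracks integer periodic image offsets:
a cluster wraps in x when some cycle of rigid junctions has non-zero
winding in x. The tissue is classified solid when the rigid
sub-network wraps in both directions; `f_r` versus `f_c` is reported as
the scalar summary. The threshold `f_c` is calibrated by marking
junctions of random periodic Voronoi tilings with i.i.d. uniform values
and sweeping the occupation fraction (the one-pass coupled form of a
bisection); affine deformation leaves the junction graph — and hence
every per-trial threshold — unchanged, which the tests verify exactly.

The standard-model rigidity point is located by a warm-started
quasistatic sweep of the uniform preferred shape index over
[3.70, 3.95] (monodisperse, undeformed, no shrinkage, T1s enabled); the
onset is the first grid value at which the rigid fraction drops below
f_c. In this implementation the onset lies near 3.90 ± 0.02 — robust
against sweep direction, cold versus warm starts, N between 64 and 256,
the T1 threshold, and perturbation annealing — i.e. somewhat above the
mean-field/energy-barrier literature value 3.81 that finite-threshold
athermal quenches are not expected to reach exactly.

## Experiment-side analysis

Closure stage: ΔA = (A₀ − A)/A₀ with A₀ = 11,000 µm², frames before
the A₀ crossing dropped. Central region: cells whose centroid satisfies
(x'/(0.75 a))² + (y'/(0.90 b))² ≤ 1 in fitted-ellipse coordinates.
Aspect ratio and orientation come from the area-weighted second-moment
tensor of the cell polygon (exact polygon moment formulas, not vertex
scatter); cells with aspect ratio within 10⁻⁷ of 1 have no defined
orientation and are excluded from Q̄ (the exact definition used by the
imaging pipeline may differ, e.g. a fitted ellipse; the choice is
isolated in one function). Recoil fits use the model
`d(t) = A₁ e^{b₀ t} + A₂ e^{d₀ t} + C` with rates multi-started on a
grid spanning the trace duration, amplitudes initialized by linear
least squares at fixed rates, nonlinear refinement, and
`v_r = A₁ b₀ + A₂ d₀`; failure from every start raises with
diagnostics. The S–v_r crossover is a continuous flat-then-linear
hinge, profiled over a knot grid with exact linear sub-fits and a
bootstrap percentile interval; the knot is flagged unidentifiable when
the hinge explains less than 20 % of the variance a constant fit
leaves.

## Synthetic data

The cohort generator emulates segmented tracking output: linear
tissue-area decrease in time (embryo-varied slope), an AP-elongating
fitted ellipse, per-cell shape indices = drift(ΔA) + embryo offset +
cell offset with pooled SD 0.45, orientations aligning as closure
proceeds, ~10 % ingression, and junction (contour, end-to-end) pairs
with straightness near 1. The mean-shape drift is an explicit
piecewise-linear input with a minimum at configurable ΔA (default
0.55), never inferred silently. Ablation traces are exact double
exponentials (relaxation times ≈ 7 s and 70 s, 80 % of v_r in the fast
mode, 5 Hz, 576 frames) with Gaussian noise proportional to the
pre-cut separation — tracking noise does not scale with recoil
amplitude; with amplitude-proportional noise of the same nominal level
the initial slope is information-theoretically unrecoverable to 5 %.
What these generators do not emulate: segmentation errors, curvature
projection artifacts, canthi geometry, or temporal correlations of real
embryos — passing recovery tests therefore demonstrates correctness of
the estimators, not robustness to every imaging pathology.

## Problem sizes and numerical choices

The shipped verification runs use N = 256 cells and five initial
configurations for the closure protocol, N = 128 and five seeds for the
rigidity sweep, and 50 tilings of 256 cells for the threshold
calibration — reduced from the sizes a production study would use, and
chosen as the smallest systems in which the trajectory features are
stable across seeds. Seed-averaged trajectory extrema are read off
after a 5-point moving average over the ΔA grid (stride 0.01) to avoid
locking onto single-record noise. Degenerate Voronoi seed sets are
jittered by 10⁻⁸ √a₀ and rebuilt; snapshot JSON round-trips at full
float precision.

## Known limitations

- The default closure runs exhibit genuine energy-releasing T1 events
  (several hundred over 640 steps at N = 256, concentrated at late
  compression and during the release of initial frustration) rather
  than strictly zero; the mean shape index nevertheless stays above the
  fluidization value and the tense network re-rigidifies immediately.
  See the discussion of the athermal T1 gate above.
- The frustrated initial state sheds part of its tension through early
  gated exchanges, so the rigid-junction fraction dips transiently just
  after onset (seed-averaged minimum ≈ 0.6–0.75 against the random-bond
  threshold 0.66) before shrinkage drives it back to ≈ 1 for the rest
  of the run.
- The orientational order declines mildly above ΔA ≈ 0.72 (late
  plastic events relax cell elongation) after rising monotonically to
  Q̄ ≈ 0.8–0.9.
- The rigidity onset of finite-threshold quenches sits near 3.90, above
  the ideal 3.81 (see Rigidity percolation).
- Parallel (multi-)edges between the same vertex pair can occur on very
  small tori (≲ 8 cells); half-edge pairing is then order-dependent.
  Production tilings (N ≥ 32) are unaffected.
- No curved-shell geometry, open boundaries, leading-edge cable, cell
  division, or finite-rate (viscous) dynamics.
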