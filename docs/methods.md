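# Methods

This note records the models, conventions and numerical choices behind
`dnapull`, in the spirit of the methods documentation of simulation
packages: what is computed, under which assumptions, and where the
implementation had to make a choice the mathematics leaves open.

## Contact-map collective variable

The binding descriptor is a sum of smoothed pairwise contacts between
hydrogen-bond donor atoms on the protein and one hydrogen-bond acceptor
atom per DNA nucleobase:

    c(r) = 1                                     r < d0
    c(r) = (1 − x^nn)/(1 − x^mm),  x = (r − d0)/r0,   r ≥ d0

with mm > nn ≥ 1 so the weight decays to zero. The limitation to one
contact point per nucleobase is what makes contact counts comparable
across sequences; the spec container enforces it.

Two parameter sets, both exposed as module constants:

| set | r0 (nm) | d0 (nm) | nn | mm | purpose |
|---|---|---|---|---|---|
| `CONTACT_PARAMS` | 0.4 | 0.25 | 2 | 4 | counting/characterizing: H-bond distances weigh 1, 0.7 nm weighs ½ |
| `STEER_PARAMS` | 3.0 | 0.3 | 1 | 12 | steering: near-linear decay (R² ≥ 0.98 on 0.3–3.0 nm), so each contact moves at a constant rate during the pull |

Numerical choices:

* x = 1 is a removable 0/0 singularity with limit nn/mm. The analytic
  limit is substituted inside |x − 1| < 1e−6 to avoid catastrophic
  cancellation; continuity is asserted in the tests from both sides.
* Distances are computed **without** periodic-image wrapping by default:
  during a pull, the nearest periodic image of a separating partner must
  not silently replace the real one. An explicit `minimum_image=True`
  flag enables orthorhombic wrapping for other uses.
* Contact counts are dimensionless floats; nothing in the pipeline
  rounds them.

The steering coordinate is the affine normalization
λ = (C − c_end)/(c_start − c_end); `HNS_LAMBDA` fixes 108 → λ=1 (fully
inserted) and 65 → λ=0 (backbone-bound) for the H-NS systems. λ is not
clamped — fluctuations legitimately overshoot the endpoints and are
logged, not truncated. One λ map must be shared across the systems being
compared; the comparison is meaningless otherwise.

## Selection conventions

Minor groove, one acceptor per base: purines (A, G) → N3, pyrimidines
(T, C) → O2. Major groove: G → O6, A → N7, T → O4; cytosine exposes no
default acceptor there (its N4 is an H-bond donor) and enters only via a
user override table. Residue-name dialects (DA/ADE/A, terminal DA5/DA3,
…) are normalized through an alias table on selection.

The bundled H-NS donor preset is Q112 {N, NE2}, G113 {N}, R114 {N, NE,
NH1, NH2}, R93 {N, NE, NH1, NH2}. A requested NZ on an arginine — which
arginine does not have — is remapped to NE with a logged warning rather
than rejected, since NE is the guanidinium donor such a request almost
certainly intends; any other absent atom is an error with a
nearest-name suggestion.

## Steering protocol

Start frames for the pull ensemble are drawn uniformly without
replacement from the frames satisfying **all** per-donor contact windows
simultaneously (H-NS defaults: C_Q112 = 10.25 ± 0.125 and
C_R114 = 23 ± 0.25), under an explicit seed. The restraint center then
moves linearly from c_start to c_end over the pull duration.

The emitted engine input (PLUMED dialect) writes the switching
parameters as shortest round-tripping decimal literals, one
ATOMS/SWITCH entry per pair with resolved serial numbers, a moving
harmonic restraint between the λ endpoints, and a CV table printed every
`stride` steps (default 1000). Emission is deterministic: identical
inputs give byte-identical text.

Work is accumulated from a recorded CV series as the discrete integral

    w(t_k) = Σ_{j≤k} k_f (c_ref(t_j) − C(t_j)) (c_ref(t_j) − c_ref(t_{j−1}))

and attributed to the **restraint-center** grid, not the instantaneous
contact count, so all runs of an ensemble share a λ axis by
construction. The force constant is interpreted as kJ/mol per squared
contact count (the CV is dimensionless), hence work in kJ/mol. Both the
engine-reported work column and post-hoc accumulation from the cv/center
columns are supported; on toy data they agree exactly at full recording
resolution and to discretization error at coarser strides.

## Free-energy estimators

All free energies are reported in kcal/mol (conversion 4.184 kJ/kcal
fixed); k_B T is computed from the molar gas constant, ≈ 0.5922 kcal/mol
at the default 298 K. Toy data in reduced units ("kT") are converted
through the same layer.

* **PMF.** Φ(λ) = −(1/β)[logsumexp(−β w_i(λ)) − ln N], pointwise, with
  log-sum-exp stabilization. Φ is anchored at the bound state
  (Φ(λ=1) = 0, automatic since every curve starts at zero work). A
  single-curve ensemble degenerates to Φ = w with a warning.
* **Error band.** σ(λ) = (β/2)·SD[w(λ)] with the *population* variance,
  exactly as the formula is written; the plain SD in kcal/mol is
  emitted alongside, since the band is usually drawn on an energy axis.
* **ΔW, ΔΔW.** ΔW = max Φ − min Φ over the grid (the maximum need not
  sit at an endpoint); ΔΔW = |ΔW_A − ΔW_B|, symmetric.
* **Jensen bound.** Φ ≤ ⟨w⟩ pointwise with equality only for identical
  curves; asserted as a property test in both directions.
* **2D mechanism surface.** All (C_x, C_y, w) samples of all runs are
  binned on a 100 × 100 grid spanning the observed ranges; each
  occupied bin carries the Boltzmann-weighted mean work
  Σ w e^{−βw}/Σ e^{−βw}, evaluated with a per-bin shift by the bin
  minimum for stability. Empty bins are filled with 1.05 × the maximum
  observed work (configurable; guarded to stay strictly above the
  maximum even for non-positive work), so unexplored regions read as
  barriers. The binned construction is authoritative; a polynomial
  least-squares fit of the occupied bins exists purely as a cosmetic
  post-process and is off by default.
* **Pathway classes.** At the *first* time the total contact count
  crosses the threshold (default 30) from above, the Q-donor count is
  read off by linear interpolation between the bracketing samples:
  C_Q < 5 → R-G-Q, C_Q > 5 → Q-G-R. The defining inequalities are
  non-strict on both sides and therefore overlap at exactly 5; ties are
  labeled R-G-Q (the branch written first) and flagged per run. The
  interpolation makes the label invariant under uniform time
  resampling.
* **Work–deformation correlation.** Pearson product-moment r over per-run
  (max work, max RMSD) pairs; undefined (reported as absent) when either
  coordinate has zero variance.

Out of scope by design: bidirectional estimators (Crooks/BAR),
bootstrap error bars beyond the ensemble SD, and temperature
reweighting.

## Geometry observables

**Groove width.** The full curvilinear-axis groove definition
(helical-axis fitting, spline-based groove tracing) is *not*
implemented. The width at base-pair position i is the minimum
cross-strand P–P distance over a register offset of 1–3 steps toward
the paired residue, minus 0.58 nm (twice the phosphate van-der-Waals
radius), NaN where the needed phosphates are missing (5′ termini). This
dialect preserves the relative narrowing/widening trends the protocol
reads off the profile — AT-tracts narrow, GC widens — but absolute
values should not be compared against curvilinear-axis numbers beyond
the ~0.05 nm level.

**RMSD.** Optimal-superposition (rotation + translation removed) RMSD
per frame, computed via scipy's least-squares rotation alignment and
cross-checked in the tests against an independent hand-rolled
Kabsch/SVD oracle.

Structure and trajectory I/O (PDB, GRO, XTC, DCD, multi-model PDB) is
delegated to MDAnalysis behind plain containers; coordinates are stored
in nm (PDB Å converted on read/write, which quantizes a PDB round trip
at 1e−4 nm), frames indexed from 0, and duplicate
(chain, residue, atom-name) triplets rejected on ingestion.

## Toy simulator

The toy layer emulates exactly what the estimators need from an engine:
ensembles of work–λ curves from a harmonically restrained coordinate
dragged at a constant rate, with tunable dissipation (via drag speed and
friction) and run-to-run variance (via temperature and trap stiffness).

* Overdamped Euler–Maruyama:
  x ← x + dt·F/γ + sqrt(2 k_BT dt/γ)·η, η ∼ N(0,1) from a seeded
  generator; bit-for-bit reproducible under the same seed, which is
  recorded in every output header. Euler–Maruyama suffices for
  overdamped scalar dynamics; the stability bound
  dt·(stiffness)/γ < 0.1 is enforced and divergence raises an error
  citing it.
* Landscapes: flat (exact ΔF = 0 between trap positions), harmonic
  (ΔF = ½·κk/(κ+k)·(x₁² − x₀²), → ½κ(x₁² − x₀²) in the stiff-trap
  limit), and a quartic double well. Initial positions are drawn from
  the exact Gaussian equilibrium of V + trap where available, else from
  a short equilibration — Jarzynski requires equilibrium starts.
* The work accumulator is the same discrete rule as the steering layer.
  The λ grid is the normalized schedule progress (identical to the
  center-based map for a linear schedule, and still well defined for a
  zero-speed drag).
* Gaussian terminal-work ensembles give the closed-form oracle
  Φ = μ − βs²/2.
* Geometric fixtures: a deliberately degenerate point-group "complex"
  with every donor–acceptor pair at one prescribed distance (analytic
  contact totals), an ideal B-DNA cylinder (rise 0.34 nm, twist 36°,
  phosphate radius 0.94 nm, backbone phase −144°, giving an interior
  minor-groove width of ≈ 0.59 nm), and a synthetic four-residue
  stand-in for an H-NS DNA-binding-domain fragment. These exercise the
  selection and geometry code paths; they are *not* realistic
  structures, and passing tests on them demonstrates correctness of the
  operations, not force-field-level realism.

What the toy data do not emulate: multidimensional CVs, inertial
dynamics, correlated per-donor contact series driven by actual
dissociation events, and the heavy-tailed work distributions of
strongly driven all-atom pulls. Estimator convergence rates observed on
toy ensembles therefore do not transfer quantitatively to engine data.

## Problem sizes

The test suite and the acceptance script run at desk scale, chosen so
the statistical oracles are decisive while the whole suite stays fast:
10⁵ Gaussian curves for the closed-form check (error ≪ 3 SE of the
estimator), 500 flat-drag runs of 2000 steps (dissipation ≈ 0.5 k_BT,
small enough for the exponential average to converge), 200 stiff-spring
runs of 5×10⁴ steps at dt = 2×10⁻⁴ (trap 100× stiffer than the well,
systematic offset ≈ 1%, drag slow enough that dissipation ≈ 0.1 k_BT),
and 10⁵ decorrelated samples for the equilibrium-histogram χ² check.

## Known limitations

* The Jarzynski exponential average is biased at finite N when the work
  spread approaches or exceeds a few k_BT; the toolkit reports the
  ensemble SD but does not correct the bias.
* The groove-width dialect is an approximation (see above).
* The PLUMED emitter covers the single dialect and the linear one-stage
  schedule the protocol uses; multi-stage schedules would need manual
  editing of the emitted file.
* `classify_pathway` assumes the total contact series starts above the
  threshold; runs that begin already below it are rejected rather than
  guessed at.
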