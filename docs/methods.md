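# Methods

This note records the model, the numerical choices, and the limits of
what the bundled test surfaces can demonstrate.

## The freezing string algorithm

The FSM approximates a minimum-energy path between two endpoint
geometries by growing two strings of nodes inward from the reactant and
product. Per growth cycle, a dense chain-of-states is interpolated
between the frontier nodes; new nodes are placed an arc distance `s`
inward from each frontier; each is relaxed perpendicular to the path and
then frozen permanently. Because every node is optimized exactly once,
the cost in gradient evaluations is bounded by
`N_nodes · N_opt · (1 + N_ls)` plus the two endpoint evaluations — the
point of the method. After joining, the highest-energy node (endpoints
included) is returned as the transition-state guess; refining it to a
true saddle (eigenvector following, frequency analysis, IRC) is the job
of downstream tools and out of scope here.

Key parameters (`FSMConfig`):

| parameter | default | meaning |
|---|---|---|
| `n_nodes` | 18 | nominal node count; `s` = initial path arc length / `n_nodes` |
| `n_opt` | 2 | max quasi-Newton steps per new node; 0 = pure interpolation |
| `n_ls` | 3 | max energy/gradient calls per line search |
| `max_disp` | 0.3 Å | per-coordinate bound on any single optimization step |
| `interpolator` | `ric` | `ric` or `lst` |
| `grad_tol` | 1e-4 | max-norm of g⊥ that counts a node as converged |
| `join_threshold` | 1.5 | strings meet when the frontier gap ≤ threshold × s |
| `nfractions` | 21 | dense-grid size per frontier-pair interpolation |

The join criterion (gap ≤ 1.5·s) and the dense-grid size are our own
choices: the first stops growth when there is no room for two more nodes
a full step apart, the second makes the arc-length placement error of
`take_step` (one densification segment at worst) small relative to `s`.
When the gap is between 1.5·s and 2·s, a single midpoint node is placed
from the left string before joining, so odd node counts are handled.

Node optimization is performed in Cartesian coordinates. The tangent is
determined once at placement time (from a cubic spline through the
interpolated pathway, anchored at the frozen frontier nodes) and held
fixed for that node's whole optimization; re-deriving it per step would
require re-interpolating the path for no observed benefit on the test
surfaces. The optimizer is a limited-memory quasi-Newton iteration
(10 correction pairs, two-loop recursion) on the energy with the
gradient replaced by `g⊥ = (I − t̂t̂ᵀ)g`. Each step is bounded per
coordinate by `max_disp` relative to the step's starting point and its
length is set by a backtracking Armijo line search (c₁ = 1e-4). The
backtracking uses quadratic interpolation of the rejected trial
(safeguarded into [0.05, 0.5]·α) rather than plain halving: with only
`n_ls` = 3 evaluations available, halving from the displacement bound
frequently fails to reach the Armijo region on stiff surfaces, whereas
the quadratic model lands on the right scale in one or two trials. On
exhaustion the best-seen point is accepted if it improves the energy;
otherwise the node stays put.

## Redundant internal coordinates

Primitives are detected from a covalent-radius bond criterion
(`r_ab < 1.3 · (r_cov,a + r_cov,b)`, Cordero-style radii versioned in
`data.py`); disconnected fragments are joined by shortest inter-fragment
auxiliary distances (a minimum-spanning connection). Angles are assigned
to every bonded A–B–C, torsions to every bonded A–B–C–D, one Wilson
out-of-plane bend to each trivalent center. The endpoint union is pruned
so every coordinate is well defined at both endpoints:

* angles within 5° of linearity in either endpoint become two orthogonal
  linear-bend coordinates. The bending axes are fixed deterministically
  from the reactant (the lab axis most perpendicular to A–C, projected,
  plus its cross product with A–C) and stored in the primitive so every
  geometry measures the bend against identical axes. The bend value is
  `w·(ê_BA + ê_BC)` — zero at linearity, radian-scale, smooth through
  the linear configuration;
* a linear bend is dropped if the angle bends more than 45° away from
  linearity (below 135°) in either endpoint. (The obvious alternative
  reading — prune when the *angle* exceeds 45° — would prune every
  near-linear bend the previous rule just created, so it cannot be
  meant.);
* torsions with |φ| ≥ 175° in either endpoint are replaced by an A–D
  distance; torsions containing a near-linear internal bend are dropped;
* out-of-plane bends are dropped when their improper dihedral is ≥ 175°
  or when their center's bond set differs between the endpoints (a
  "broken" bonding center);
* if no torsion survives for N > 3, atom 4-tuples are scanned in a fixed
  order for a valid one; failing that the whole set becomes all unique
  atom–atom distances.

The nonredundant basis `U` is the set of eigenvectors of
`G = Bᵖʳⁱᵐ(Bᵖʳⁱᵐ)ᵀ` with eigenvalue above 1e-10 times the largest,
built on the **reactant** geometry (the choice of geometry is a
convention; the basis only has to be used consistently). Eigenvector
signs are fixed by making the largest-magnitude component positive, so
runs are bit-reproducible. All B-matrix rows are analytic gradients
(bond, angle, torsion, out-of-plane via unit-vector Jacobians) and are
verified against central finite differences in the tests.

The back-transformation iterates
`x ← x + (B(x)ᵀ)⁻¹ [q_target − q(x)]` with `(Bᵀ)⁻¹ = (BBᵀ)⁻¹B`,
torsion differences wrapped into (−π, π] before projection into the
delocalized basis, steps capped at 0.5 Å per coordinate, convergence at
1e-7 Å max coordinate change, 100 iterations. The target is supplied in
primitive space (the wrap cannot be applied to a delocalized-space
vector); on non-convergence the smallest-residual iterate is returned
flagged approximate, and sustained residual growth raises an error
carrying the best iterate. Note that Cartesians recovered this way are
only determined up to a rigid motion — path comparisons are made in
internal coordinates or after Kabsch alignment.

## Interpolators

**RIC**: `q(f) = (1−f)q_R + f q_P` on a uniform fraction grid, torsions
along the shortest arc, each point back-transformed seeded from its
already-converted neighbor (walking outward from the left frontier).
Endpoint frames pass through bit-exactly.

**LST**: per node, minimize
`S = Σ_{a>b} (r_ab(f) − r_ab)²/r_ab(f)⁴ + w Σ (x_j(f) − x_j)²` over the
node's Cartesians (L-BFGS-B, analytic gradient, projected-gradient
tolerance 1e-8, 500 iterations, started from the Cartesian interpolant;
`w` = 1e-6 nominally). The `r(f)⁴` denominator is floored at (0.5 Å)⁴
against near-coincident interpolated distances. Nodes are independent in
the objective and are optimized independently. For a single particle
there are no pair distances and LST degrades exactly to Cartesian linear
interpolation, which is how the 2-D analytic surfaces are driven.

**Arc length and tangents**: the path metric is the unweighted Euclidean
norm over all 3N Cartesians. Tangents come from a cubic spline of each
coordinate against arc length with not-a-knot end conditions (exact for
low-order paths; zero-curvature "natural" ends were measurably worse on
curved-path tangent tests); 2-node paths fall back to the secant.

## Calculators

* **Müller–Brown**: the standard four-Gaussian 2-D PES (parameters from
  Müller & Brown, Theor. Chim. Acta 53, 75 (1979)), exposed as a
  one-pseudo-atom molecule with z frozen; analytic gradient and Hessian
  (the Hessian serves the independent Newton saddle/minimum searches in
  tests). RIC mode is refused for single atoms.
* **Toy force field**: Morse bonds, harmonic angles, cosine torsions
  `V(1 + cos(nφ − γ))`, and soft `ε(σ/r)¹²` repulsion between pairs that
  are neither bonded nor 1-3. Terms are functions of internals only, so
  the energy is exactly invariant under rigid motion. Arbitrary
  consistent units.
* **External adapter**: writes the geometry as XYZ, runs a user command
  (`{input}`/`{output}` placeholders, shell), and parses the contract
  file — line 1 `<energy Hartree> [angstrom|bohr]`, then N lines of
  three gradient components in Hartree per declared length unit
  (bohr-declared gradients are multiplied by 1.8897259886 bohr/Å).
  Nonzero exit, missing or unparseable output raise with the captured
  stderr path; non-finite energies mark the FSM run `failed` without
  crashing.

## Synthetic fixtures

Templates (diatomic, bent/linear triatomic, four-atom torsion chain,
united-atom butane, two separated fragments) are constructed Z-matrix
style (NeRF placement) from idealized constants (C–C 1.54 Å, C–C–C 111°,
O–H 0.96 Å, ...), so measured internals reproduce the declared values to
machine precision. The butane-like template ships a matched toy force
field whose torsional term has minima at the anti (180°) and gauche
(±60°) conformers — the classic hindered-rotation path: the FSM's TS
guess can be compared against a dense 1-D torsion scan of the same
surface. All randomness (rigid perturbations, coordinate noise) goes
through one seeded NumPy generator.

What these fixtures do *not* emulate: real electronic structure —
bond-breaking chemistry, charge transfer, near-degenerate surfaces,
gradient noise from SCF convergence. Passing tests demonstrate the
correctness of the algorithmic machinery (coordinates, interpolation,
growth loop, bookkeeping), not chemical accuracy of TS guesses on real
systems; problem sizes (≤ 4 sites, one benchmark 2-D surface) were
chosen so the full suite runs in seconds.

## Numerical details and degenerate inputs

* Identical endpoints: step-size computation raises (zero-length path).
* A torsion with exactly collinear internal atoms raises an error naming
  the primitive; the pruning rules keep such primitives out of endpoint
  unions.
* Back-transformed targets that are infeasible (mutually inconsistent
  redundant coordinates) converge to the least-squares solution in the
  delocalized projection; diagnostics record the residual.
* Evaluation accounting is exact: the string's `grad_calls` equals the
  calculator's own counter equals the sum of per-node evaluations, and
  with `n_opt = 0` the run is pure interpolation with exactly one energy
  evaluation per node (TS-guess selection only).
* Determinism: the core loop has no randomness; fixed inputs give
  bit-identical strings.

## Known limitations

* Frozen nodes are never re-relaxed (that is the growing string method's
  job); strongly curved paths can leave kinks the single-pass
  optimization cannot remove.
* The tangent is frozen during a node's optimization; with large
  `n_opt` this biases the relaxed position slightly.
* Linear-bend axes are fixed from the reactant frame; paths that rotate
  a linear fragment by large angles would need axis transport.
* No translation/rotation-augmented or hybrid coordinate sets; no
  mass-weighted arc lengths.
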