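# fsmpath

Freezing string method (FSM) for generating transition-state (TS) guess
structures and approximate reaction pathways between two molecular
geometries, with interpolation in either redundant internal coordinates
(RIC) or by linear synchronous transit (LST).

## Who this is for

Locating a first-order saddle point on a potential energy surface is the
expensive step of computing a reaction barrier: local TS optimizers need a
starting structure already close to the saddle. The FSM produces that
starting structure cheaply. Two strings of geometries ("nodes") grow
inward from the reactant and the product; each newly placed node is
relaxed a little in the directions perpendicular to the pathway and then
frozen, so no node is ever revisited. When the strings meet, the
highest-energy node is the TS guess.

The energy/gradient backend is pluggable, so the complete algorithm runs
and is tested on analytic surfaces (Müller–Brown, double well) and on a
small toy force field — no quantum chemistry required — while a file-based
adapter lets any external electronic-structure code supply gradients for
production use.

## The method

Given aligned endpoints (Kabsch superposition), the step size is
`s = L / N_nodes`, with `L` the arc length of the initial interpolated
path. Each growth cycle:

1. interpolate a dense path between the current frontier nodes —
   either linearly in the pruned redundant internals,
   `q(f) = (1−f) q_R + f q_P` (torsions along the shortest signed arc),
   converting each point back to Cartesians with the iterative Wilson
   B-matrix back-transformation
   `x_{k+1} = x_k + (B(x_k)ᵀ)⁻¹ [q_target − q(x_k)]`,
   or by LST, where each node minimizes
   `S = Σ_{a>b} (r_ab(f) − r_ab)² / r_ab(f)⁴ + w Σ_j (x_j(f) − x_j)²`;
2. place new nodes an arc distance `s` in from each frontier;
3. take the tangent `t̂` from a cubic spline through the interpolated
   pathway, and relax each new node on the perpendicular gradient
   `g⊥ = (I − t̂ t̂ᵀ) g` — a bounded limited-memory quasi-Newton step with a
   backtracking line search, at most `N_opt` steps of at most `N_ls`
   energy/gradient calls, no coordinate moving more than 0.3 Å per step;
4. freeze both nodes and repeat until the strings meet.

The delocalized nonredundant coordinate basis `U` comes from
diagonalizing `G = Bᵖʳⁱᵐ(Bᵖʳⁱᵐ)ᵀ`; primitive detection and the pruning of
near-linear angles/torsions are described in `docs/methods.md`.

## Worked example

Generate the butane-like torsion fixture (anti → gauche rotation of a
four-site chain under a matched toy force field) and run FSM-RIC with a
nominal 9 nodes:

```
$ fsm fixtures --template butane-like --out pair
wrote reactant.xyz, product.xyz, toyff.yaml to pair
$ fsm run --reactant pair/reactant.xyz --product pair/product.xyz \
      --calc toyff:pair/toyff.yaml --interp ric --n-nodes 9 --out run
status: joined
nodes: 10  gradient calls: 38
TS guess energy: 9.91048297 (written to run/ts_guess.xyz)
```

`run/profile.tsv` holds the energy profile along the string:

```
node  arc_angstrom  energy         grad_calls_total
0     0.000000      0.0000162334   38
...
5     0.834720      9.9104829748   38
...
9     1.501631      0.0003711512   38
```

The two endpoints are (near-)minima of the toy surface (energies ≈ 0),
the profile rises to a single maximum of 9.91 at node 5, and the whole
run cost 38 gradient evaluations. The TS-guess torsion measured from
`run/ts_guess.xyz` is 115.3°, close to the 1-D torsional barrier top of
the force field (the cosine term alone peaks at 120°; the nonbonded
repulsion shifts it slightly). Other calculators: `--calc mb`
(Müller–Brown, one pseudo-atom) and
`--calc "external:<command with {input} {output}>"` for file-based
exchange with an electronic-structure program (contract format in
`docs/methods.md`).

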