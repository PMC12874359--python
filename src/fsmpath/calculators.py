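"""Pluggable energy/gradient backends.

Three families:

* analytic 2-D benchmark surfaces (Müller–Brown, a symmetric double well)
  represented as a one-pseudo-atom "molecule" moving in the xy-plane with
  z frozen at 0;
* a toy molecular force field (Morse bonds, harmonic angles, cosine
  torsions, soft nonbonded repulsion) that exercises the full
  internal-coordinate stack without quantum chemistry;
* a file-based external-command adapter exchanging XYZ/gradient text
  files with any electronic-structure program.

Every backend counts its evaluations; the string method reconciles its
gradient-call ledger against this counter.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import numpy as np
import yaml

from .data import BOHR_IN_ANGSTROM
from .geometry import Geometry, write_xyz
from .internal_coords import _angle, _bond, _torsion


class CalculatorError(RuntimeError):
    """An energy/gradient evaluation failed."""


@dataclass
class CalculatorResult:
    energy: float
    gradient: np.ndarray  # flat 3N, energy units per Å
    eval_index: int


class Calculator:
    """Base class: subclasses implement `_compute(geometry) -> (E, g)`."""

    def __init__(self):
        self.eval_count = 0

    def evaluate(self, geometry: Geometry) -> CalculatorResult:
        energy, gradient = self._compute(geometry)
        self.eval_count += 1
        gradient = np.asarray(gradient, dtype=float).ravel()
        if gradient.shape != (3 * geometry.natoms,):
            raise CalculatorError(
                f"gradient length {gradient.size} != 3N={3 * geometry.natoms}"
            )
        return CalculatorResult(float(energy), gradient, self.eval_count)

    def _compute(self, geometry):  # pragma: no cover - abstract
        raise NotImplementedError


class MullerBrown(Calculator):
    """Müller–Brown surface: the standard four-Gaussian 2-D test PES.

    E(x, y) = Σ_k A_k exp[a_k (x−x0_k)² + b_k (x−x0_k)(y−y0_k) + c_k (y−y0_k)²]

    with the standard literature parameters (see docs/methods.md for the
    citation).  The geometry must contain exactly one atom; z is frozen
    (its gradient component is identically zero).
    """

    A = np.array([-200.0, -100.0, -170.0, 15.0])
    a = np.array([-1.0, -1.0, -6.5, 0.7])
    b = np.array([0.0, 0.0, 11.0, 0.6])
    c = np.array([-10.0, -10.0, -6.5, 0.7])
    x0 = np.array([1.0, 0.0, -0.5, -1.0])
    y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def _terms(self, x, y):
        dx = x - self.x0
        dy = y - self.y0
        return self.A * np.exp(self.a * dx**2 + self.b * dx * dy + self.c * dy**2), dx, dy

    def energy_xy(self, x: float, y: float) -> float:
        return float(self._terms(x, y)[0].sum())

    def gradient_xy(self, x: float, y: float) -> np.ndarray:
        t, dx, dy = self._terms(x, y)
        gx = float(np.sum(t * (2 * self.a * dx + self.b * dy)))
        gy = float(np.sum(t * (self.b * dx + 2 * self.c * dy)))
        return np.array([gx, gy])

    def hessian_xy(self, x: float, y: float) -> np.ndarray:
        t, dx, dy = self._terms(x, y)
        u = 2 * self.a * dx + self.b * dy
        v = self.b * dx + 2 * self.c * dy
        hxx = float(np.sum(t * (u * u + 2 * self.a)))
        hyy = float(np.sum(t * (v * v + 2 * self.c)))
        hxy = float(np.sum(t * (u * v + self.b)))
        return np.array([[hxx, hxy], [hxy, hyy]])

    def _compute(self, geometry):
        if geometry.natoms != 1:
            raise CalculatorError("Müller–Brown is a one-particle 2-D surface")
        x, y, _ = geometry.coords[0]
        g = np.zeros(3)
        g[:2] = self.gradient_xy(x, y)
        return self.energy_xy(x, y), g


class DoubleWell2D(Calculator):
    """Symmetric double well E = h·(x² − d²)²/d⁴ + k·y², one pseudo-atom.

    Minima at (±d, 0), saddle at the origin with barrier height h.
    """

    def __init__(self, barrier: float = 5.0, d: float = 1.0, k: float = 2.0):
        super().__init__()
        self.h, self.d, self.k = barrier, d, k

    def _compute(self, geometry):
        if geometry.natoms != 1:
            raise CalculatorError("DoubleWell2D is a one-particle 2-D surface")
        x, y, _ = geometry.coords[0]
        e = self.h * (x**2 - self.d**2) ** 2 / self.d**4 + self.k * y**2
        g = np.array([4 * self.h * x * (x**2 - self.d**2) / self.d**4, 2 * self.k * y, 0.0])
        return e, g


# ---------------------------------------------------------------------------
# toy force field


@dataclass
class MorseBond:
    atoms: tuple[int, int]
    D: float  # well depth (energy)
    a: float  # width (1/Å)
    r0: float  # equilibrium length (Å)


@dataclass
class HarmonicAngle:
    atoms: tuple[int, int, int]
    k: float  # energy/rad²
    theta0: float  # radians


@dataclass
class CosineTorsion:
    atoms: tuple[int, int, int, int]
    V: float  # barrier scale (energy)
    n: int  # periodicity
    gamma: float = 0.0  # phase, radians


@dataclass
class ToyFFSpec:
    """Parameters of the toy force field.

    Nonbonded soft repulsion eps·(sigma/r)¹² acts between atom pairs that
    are neither bonded nor 1-3 neighbors.
    """

    bonds: list[MorseBond] = field(default_factory=list)
    angles: list[HarmonicAngle] = field(default_factory=list)
    torsions: list[CosineTorsion] = field(default_factory=list)
    eps: float = 0.0
    sigma: float = 2.0

    def __post_init__(self):
        for b in self.bonds:
            if b.D < 0:
                raise ValueError("Morse well depth must be nonnegative")
        for a in self.angles:
            if a.k < 0:
                raise ValueError("angle force constant must be nonnegative")
        for t in self.torsions:
            if t.V < 0:
                raise ValueError("torsion barrier must be nonnegative")

    def max_atom(self) -> int:
        idx = [i for b in self.bonds for i in b.atoms]
        idx += [i for a in self.angles for i in a.atoms]
        idx += [i for t in self.torsions for i in t.atoms]
        return max(idx) if idx else -1

    def excluded_pairs(self) -> set[tuple[int, int]]:
        ex = {tuple(sorted(b.atoms)) for b in self.bonds}
        for a in self.angles:
            ex.add(tuple(sorted((a.atoms[0], a.atoms[2]))))
        return ex

    def to_yaml(self, filename) -> None:
        doc = {
            "bonds": [
                {"atoms": [int(i) for i in b.atoms], "D": float(b.D),
                 "a": float(b.a), "r0": float(b.r0)}
                for b in self.bonds
            ],
            "angles": [
                {"atoms": [int(i) for i in a.atoms], "k": float(a.k),
                 "theta0": float(a.theta0)}
                for a in self.angles
            ],
            "torsions": [
                {"atoms": [int(i) for i in t.atoms], "V": float(t.V),
                 "n": int(t.n), "gamma": float(t.gamma)}
                for t in self.torsions
            ],
            "nonbonded": {"eps": float(self.eps), "sigma": float(self.sigma)},
        }
        with open(filename, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, filename) -> "ToyFFSpec":
        with open(filename) as fh:
            doc = yaml.safe_load(fh)
        nb = doc.get("nonbonded", {})
        return cls(
            bonds=[
                MorseBond(tuple(b["atoms"]), b["D"], b["a"], b["r0"])
                for b in doc.get("bonds", [])
            ],
            angles=[
                HarmonicAngle(tuple(a["atoms"]), a["k"], a["theta0"])
                for a in doc.get("angles", [])
            ],
            torsions=[
                CosineTorsion(tuple(t["atoms"]), t["V"], t["n"], t.get("gamma", 0.0))
                for t in doc.get("torsions", [])
            ],
            eps=nb.get("eps", 0.0),
            sigma=nb.get("sigma", 2.0),
        )


class ToyForceField(Calculator):
    """Morse + harmonic-angle + cosine-torsion + soft-repulsion force field.

    Built from internal coordinates only, so the energy is exactly
    invariant under rigid rotation and translation.
    """

    def __init__(self, spec: ToyFFSpec):
        super().__init__()
        self.spec = spec

    def _compute(self, geometry):
        if self.spec.max_atom() >= geometry.natoms:
            raise CalculatorError("force-field spec references missing atoms")
        c = geometry.coords
        e = 0.0
        grad = np.zeros((geometry.natoms, 3))

        def add(dEdq, qgrad):
            for atom, g in qgrad.items():
                grad[atom] += dEdq * g

        for b in self.spec.bonds:
            r, gr = _bond(c, *b.atoms)
            ex = np.exp(-b.a * (r - b.r0))
            e += b.D * (1 - ex) ** 2
            add(2 * b.D * b.a * (1 - ex) * ex, gr)
        for an in self.spec.angles:
            th, gr = _angle(c, *an.atoms)
            e += an.k * (th - an.theta0) ** 2
            add(2 * an.k * (th - an.theta0), gr)
        for t in self.spec.torsions:
            phi, gr = _torsion(c, *t.atoms)
            e += t.V * (1 + np.cos(t.n * phi - t.gamma))
            add(-t.V * t.n * np.sin(t.n * phi - t.gamma), gr)
        if self.spec.eps > 0:
            excluded = self.spec.excluded_pairs()
            n = geometry.natoms
            for i in range(n):
                for j in range(i + 1, n):
                    if (i, j) in excluded:
                        continue
                    r, gr = _bond(c, i, j)
                    er = self.spec.eps * (self.spec.sigma / r) ** 12
                    e += er
                    add(-12 * er / r, gr)
        return e, grad.ravel()


# ---------------------------------------------------------------------------
# external-command adapter


class ExternalCalculator(Calculator):
    """File-based adapter to an external energy/gradient program.

    The command template must contain ``{input}`` and ``{output}``
    placeholders.  Per evaluation the geometry is written as standard XYZ
    to the input path, the command is run in ``workdir``, and the output
    contract file is parsed:

    * line 1: ``<energy-in-Hartree> [angstrom|bohr]`` — the optional
      second token declares the gradient length unit (default angstrom);
    * next N lines: three gradient components each, Hartree per declared
      length unit.

    Gradients declared in bohr are converted to Hartree/Å by multiplying
    with 1/0.529177210903 (i.e. bohr per Å).
    """

    def __init__(self, cmd_template: str, workdir):
        super().__init__()
        if "{input}" not in cmd_template or "{output}" not in cmd_template:
            raise CalculatorError("command template needs {input} and {output}")
        self.cmd_template = cmd_template
        self.workdir = FilePath(workdir).resolve()
        self.workdir.mkdir(parents=True, exist_ok=True)

    def _compute(self, geometry):
        inp = self.workdir / "input.xyz"
        out = self.workdir / "output.dat"
        err = self.workdir / "stderr.log"
        if out.exists():
            out.unlink()
        write_xyz(inp, geometry)
        cmd = self.cmd_template.format(input=str(inp), output=str(out))
        with open(err, "w") as errfh:
            proc = subprocess.run(cmd, shell=True, cwd=self.workdir, stderr=errfh,
                                  stdout=subprocess.DEVNULL)
        if proc.returncode != 0:
            raise CalculatorError(
                f"external command exited {proc.returncode}; stderr at {err}"
            )
        if not out.exists():
            raise CalculatorError(f"external command wrote no output; stderr at {err}")
        try:
            lines = out.read_text().split("\n")
            head = lines[0].split()
            energy = float(head[0])
            unit = head[1].lower() if len(head) > 1 else "angstrom"
            vals = []
            for line in lines[1:]:
                vals.extend(float(v) for v in line.split())
            grad = np.array(vals, dtype=float)
        except (ValueError, IndexError) as exc:
            raise CalculatorError(
                f"unparseable external output {out}; stderr at {err}"
            ) from exc
        if grad.size != 3 * geometry.natoms:
            raise CalculatorError(
                f"external gradient has {grad.size} components, expected {3 * geometry.natoms}"
            )
        if unit.startswith("bohr"):
            grad = grad / BOHR_IN_ANGSTROM
        elif not unit.startswith("angstrom"):
            raise CalculatorError(f"unknown gradient unit {unit!r} in {out}")
        return energy, grad
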