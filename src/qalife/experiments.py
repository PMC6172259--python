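"""Reconstruction of the five circuit experiments and their run-group
mutation protocol.

The logical register is always |g1 p1 g2 p2>.  Five experiment families are
provided:

* ``I``    — two individuals are created (amplitude half-angles pi/8 and
  3pi/8) and undergo the conditional phenotype exchange.
* ``II``   — one individual (half-angle pi/3) ages one discrete step,
  self-replicates, and both phenotypes age one further step (so p1
  accumulates two u3(pi/8) steps, p2 one).
* ``III``  — the circuit of II measured in the sigma_x basis (a Hadamard on
  every qubit before readout).
* ``IVa-IVd`` — the circuit of II with sigma_x mutation variants: none
  (IVa), on g1 before the self-replication (IVb, so the flip is inherited
  by the second individual), on g2 after the second individual is complete
  (IVc), or both (IVd).
* ``Va-Vf`` — the complete model: the circuit of I with sigma_x mutations
  applied to the genotypes before the interaction (Vd: g1, Ve: g2, Vf:
  both; Va-Vc unmutated) and two u3(pi/8) aging steps on each phenotype
  after it.

Run groups of 1024 mutated / 8192 unmutated shots realise mutation rates
2/19 (IV, where the counts of II also contribute) and 2/27 (V) by purely
classical aggregation of counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

from .core import StateVector, apply_gate, bitstrings, expectation, probabilities
from .gates import GATES, SIGMA_Z, interaction_permutation, make_u3

ROLES = ("g1", "p1", "g2", "p2")

#: printed device assignments (device qubit order, most significant first)
DEVICE_MAPS = {
    "I": ("p2", "g2", "p1", "g1"),     # |Q0 Q1 Q2 Q3|
    "II": ("p2", "g2", "g1", "p1"),    # |Q0 Q1 Q2 Q4|
}

#: one discrete aging step (u3 angle, sigma_z factor cos(pi/8))
THETA_STEP = math.pi / 8


@dataclass(frozen=True)
class ExperimentSpec:
    """A fully specified circuit experiment."""

    id: str
    ops: tuple                      # ordered (UnitaryGate, target roles)
    device_order: tuple             # role order on the device register
    shots: int = 8192
    basis: str = "z"

    def __post_init__(self):
        if self.basis not in ("z", "x"):
            raise ValueError("basis must be 'z' or 'x'")
        if sorted(self.device_order) != sorted(ROLES):
            raise ValueError("device order must be a permutation of the roles")


def _clone(control, target):
    return (GATES["CNOT"], (control, target))


def _prep(role, half_angle):
    return (make_u3(2 * half_angle, 0, 0), (role,))


def _step(role):
    return (make_u3(THETA_STEP, 0, 0), (role,))


def _mut(role):
    return (GATES["X"], (role,))


def _interaction():
    return (interaction_permutation(), ROLES)


def _circuit_I(mutations: Sequence[str] = (), dissipation_steps: int = 0):
    ops = [
        _prep("g1", math.pi / 8),
        _prep("g2", 3 * math.pi / 8),
        _clone("g1", "p1"),
        _clone("g2", "p2"),
    ]
    ops += [_mut(g) for g in mutations]
    ops.append(_interaction())
    for _ in range(dissipation_steps):
        ops += [_step("p1"), _step("p2")]
    return tuple(ops)


def _circuit_II(mutate_g1: bool = False, mutate_g2: bool = False):
    ops = [
        _prep("g1", math.pi / 3),
        _clone("g1", "p1"),
        _step("p1"),
    ]
    if mutate_g1:                      # before the self-replication: inherited
        ops.append(_mut("g1"))
    ops += [_clone("g1", "g2"), _clone("g2", "p2")]
    if mutate_g2:                      # after the second individual exists
        ops.append(_mut("g2"))
    ops += [_step("p1"), _step("p2")]  # next time step ages both phenotypes
    return tuple(ops)


def build_experiment(exp_id: str, shots: int = 8192) -> ExperimentSpec:
    """Reconstruct one of the named circuits."""
    dev_I, dev_II = DEVICE_MAPS["I"], DEVICE_MAPS["II"]
    table = {
        "I": (_circuit_I(), dev_I, "z"),
        "II": (_circuit_II(), dev_II, "z"),
        "III": (_circuit_II() + tuple((GATES["H"], (r,)) for r in ROLES),
                dev_II, "x"),
        "IVa": (_circuit_II(), dev_II, "z"),
        "IVb": (_circuit_II(mutate_g1=True), dev_II, "z"),
        "IVc": (_circuit_II(mutate_g2=True), dev_II, "z"),
        "IVd": (_circuit_II(mutate_g1=True, mutate_g2=True), dev_II, "z"),
        "Va": (_circuit_I(dissipation_steps=2), dev_I, "z"),
        "Vb": (_circuit_I(dissipation_steps=2), dev_I, "z"),
        "Vc": (_circuit_I(dissipation_steps=2), dev_I, "z"),
        "Vd": (_circuit_I(mutations=("g1",), dissipation_steps=2), dev_I, "z"),
        "Ve": (_circuit_I(mutations=("g2",), dissipation_steps=2), dev_I, "z"),
        "Vf": (_circuit_I(mutations=("g1", "g2"), dissipation_steps=2),
               dev_I, "z"),
    }
    if exp_id not in table:
        raise KeyError(f"unknown experiment id {exp_id!r}")
    ops, dev, basis = table[exp_id]
    return ExperimentSpec(exp_id, ops, dev, shots, basis)


def simulate(spec: ExperimentSpec) -> StateVector:
    """Exact final state of the circuit (basis rotation included for x)."""
    state = StateVector.blank(ROLES)
    for gate, targets in spec.ops:
        state = apply_gate(state, gate, targets)
    return state


def ideal_state_expectations(spec: ExperimentSpec) -> np.ndarray:
    """Per-qubit <sigma_z> of the final state, in |g1 p1 g2 p2> order (for
    an x-basis spec these are the z-expectations after rotation)."""
    state = simulate(spec)
    return np.array([expectation(state, SIGMA_Z.on(r)) for r in ROLES])


def ideal_distribution(spec: ExperimentSpec) -> np.ndarray:
    """Exact outcome distribution over the 16 bitstrings of |g1 p1 g2 p2>.

    Simulation runs directly in the logical register; the device reordering
    of the published tables is metadata (those tables are printed after
    inverting the mapping, so logical order is the comparison order).
    """
    return probabilities(simulate(spec), ROLES)


def predicted_events(dist: np.ndarray, shots: int) -> np.ndarray:
    """Per-cell expected counts, rounded half away from zero.  The rounded
    row may miss ``shots`` by a unit or two; it is reported as-is."""
    dist = np.asarray(dist, dtype=float)
    if shots < 1:
        raise ValueError("shots must be >= 1")
    if abs(dist.sum() - 1.0) > 1e-6:
        raise ValueError("distribution must be normalised")
    return np.floor(dist * shots + 0.5).astype(int)


# ---------------------------------------------------------------------------
# run-group ensembles (mutation protocol)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunGroup:
    spec: ExperimentSpec
    runs: int
    mutated: tuple = ()     # which individuals (1, 2) carry a mutation


@dataclass(frozen=True)
class RunGroupEnsemble:
    """A weighted set of circuit variants realising a mutation rate."""

    groups: tuple

    def __post_init__(self):
        if not self.groups:
            raise ValueError("ensemble must contain at least one run group")

    @property
    def total_runs(self) -> int:
        return sum(g.runs for g in self.groups)

    def mutation_rate(self, individual: int) -> Fraction:
        """Fraction of runs in which the given individual's genotype is
        flagged mutated, in exact rational arithmetic."""
        hit = sum(g.runs for g in self.groups if individual in g.mutated)
        return Fraction(hit, self.total_runs)

    def mixture_distribution(self) -> np.ndarray:
        """Run-weighted average of the member circuits' ideal distributions."""
        total = self.total_runs
        out = np.zeros(16)
        for g in self.groups:
            out += (g.runs / total) * ideal_distribution(g.spec)
        return out

    def mixture_expectations(self) -> np.ndarray:
        """Run-weighted per-qubit <sigma_z> vector of the ensemble."""
        total = self.total_runs
        out = np.zeros(4)
        for g in self.groups:
            out += (g.runs / total) * ideal_state_expectations(g.spec)
        return out


def mutation_ensemble(family: str) -> RunGroupEnsemble:
    """The paper-faithful run-group ensembles.

    ``IV``: the 8192-run counts of II plus a second unmutated 8192-run group
    and three 1024-run mutation variants (rate 2/19 per individual).
    ``V``: three unmutated 8192-run groups and three 1024-run mutation
    variants (rate 2/27 per individual).
    """
    if family == "IV":
        groups = (
            RunGroup(build_experiment("II"), 8192),
            RunGroup(build_experiment("IVa"), 8192),
            RunGroup(build_experiment("IVb", 1024), 1024, (1,)),
            RunGroup(build_experiment("IVc", 1024), 1024, (2,)),
            RunGroup(build_experiment("IVd", 1024), 1024, (1, 2)),
        )
    elif family == "V":
        groups = (
            RunGroup(build_experiment("Va"), 8192),
            RunGroup(build_experiment("Vb"), 8192),
            RunGroup(build_experiment("Vc"), 8192),
            RunGroup(build_experiment("Vd", 1024), 1024, (1,)),
            RunGroup(build_experiment("Ve", 1024), 1024, (2,)),
            RunGroup(build_experiment("Vf", 1024), 1024, (1, 2)),
        )
    else:
        raise KeyError(f"no mutation ensemble for family {family!r}")
    return RunGroupEnsemble(groups)


# ---------------------------------------------------------------------------
# OpenQASM 2.0 export (provenance only)
# ---------------------------------------------------------------------------

def to_qasm(spec: ExperimentSpec) -> str:
    """Render the circuit as OpenQASM 2.0 in the device qubit order."""
    idx = {role: i for i, role in enumerate(spec.device_order)}
    lines = ["OPENQASM 2.0;", 'include "qelib1.inc";',
             "qreg q[4];", "creg c[4];"]
    for gate, targets in spec.ops:
        qs = ", ".join(f"q[{idx[t]}]" for t in targets)
        name = gate.name
        if name.startswith("u3(") or name.startswith("u2("):
            lines.append(f"{name} {qs};")
        elif name == "CNOT":
            lines.append(f"cx {qs};")
        elif name == "H":
            lines.append(f"h {qs};")
        elif name == "X":
            lines.append(f"x {qs};")
        elif name == "U_I":
            lines.append(f"// conditional phenotype exchange on {qs}")
        else:
            lines.append(f"// {name} {qs}")
    lines += [f"measure q[{i}] -> c[{i}];" for i in range(4)]
    return "\n".join(lines) + "\n"
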