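"""Minimal exact simulator for few-qubit circuits.

Pure states are the default engine; density operators appear only where a
channel (amplitude damping) or a classical mixture genuinely requires them.
Qubits are addressed by *role* labels (``g1``, ``p1``, ...) rather than wire
indices, and every bitstring produced anywhere in the package follows the
same convention: the leftmost character corresponds to the first role of the
requested ordering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: tolerance for algebraic invariants (unitarity, hermiticity, normalisation)
ATOL = 1e-9


# ---------------------------------------------------------------------------
# operators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitaryGate:
    """A k-qubit unitary with its arity and a human-readable name."""

    matrix: np.ndarray
    name: str = "U"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError(f"gate {self.name!r}: matrix must be square")
        k = int(np.log2(m.shape[0]))
        if 2**k != m.shape[0]:
            raise ValueError(f"gate {self.name!r}: dimension must be a power of two")
        if not np.allclose(m.conj().T @ m, np.eye(m.shape[0]), atol=ATOL):
            raise ValueError(f"gate {self.name!r} is not unitary")

    @property
    def arity(self) -> int:
        return int(np.log2(self.matrix.shape[0]))

    @property
    def dagger(self) -> "UnitaryGate":
        return UnitaryGate(self.matrix.conj().T, name=self.name + "^dag")

    def __matmul__(self, other: "UnitaryGate") -> "UnitaryGate":
        return UnitaryGate(self.matrix @ other.matrix,
                           name=f"{self.name}*{other.name}")


@dataclass(frozen=True)
class Observable:
    """A Hermitian operator acting on the qubits named in ``roles``."""

    matrix: np.ndarray
    roles: tuple = ()
    name: str = "O"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=complex)
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "roles", tuple(self.roles))
        if not np.allclose(m, m.conj().T, atol=ATOL):
            raise ValueError(f"observable {self.name!r} is not Hermitian")

    @property
    def arity(self) -> int:
        return int(np.log2(self.matrix.shape[0]))

    def on(self, *roles: str) -> "Observable":
        """The same operator bound to different target roles."""
        return Observable(self.matrix, roles, self.name)


# ---------------------------------------------------------------------------
# states
# ---------------------------------------------------------------------------

def _check_roles(roles: Sequence[str]) -> tuple:
    roles = tuple(roles)
    if len(set(roles)) != len(roles):
        raise ValueError(f"qubit roles must be unique, got {roles}")
    return roles


@dataclass
class StateVector:
    """A pure n-qubit state with ordered role labels.

    ``amplitudes[i]`` is the coefficient of the basis ket whose bitstring is
    the n-digit binary expansion of ``i`` read with the first role as the
    most significant bit.
    """

    amplitudes: np.ndarray
    roles: tuple

    def __post_init__(self):
        self.amplitudes = np.asarray(self.amplitudes, dtype=complex)
        self.roles = _check_roles(self.roles)
        if self.amplitudes.shape != (2 ** self.n_qubits,):
            raise ValueError("amplitude vector length must be 2**n_qubits")
        norm = np.linalg.norm(self.amplitudes)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"state is not normalised (norm={norm})")

    @property
    def n_qubits(self) -> int:
        return len(self.roles)

    def tensor(self) -> np.ndarray:
        return self.amplitudes.reshape((2,) * self.n_qubits)

    def density(self) -> "DensityOperator":
        rho = np.outer(self.amplitudes, self.amplitudes.conj())
        return DensityOperator(rho, self.roles)

    def overlap(self, other: "StateVector") -> float:
        """Phase-insensitive overlap |<phi|psi>| in a common role order."""
        other = permute(other, self.roles)
        return abs(np.vdot(other.amplitudes, self.amplitudes))

    @classmethod
    def computational(cls, bits: str, roles: Sequence[str]) -> "StateVector":
        n = len(roles)
        if len(bits) != n or set(bits) - {"0", "1"}:
            raise ValueError(f"bad bitstring {bits!r} for {n} qubits")
        amp = np.zeros(2 ** n, dtype=complex)
        amp[int(bits, 2)] = 1.0
        return cls(amp, tuple(roles))

    @classmethod
    def blank(cls, roles: Sequence[str]) -> "StateVector":
        return cls.computational("0" * len(roles), roles)


@dataclass
class DensityOperator:
    """A mixed n-qubit state (Hermitian, unit trace, positive)."""

    matrix: np.ndarray
    roles: tuple

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=complex)
        self.roles = _check_roles(self.roles)
        d = 2 ** self.n_qubits
        if self.matrix.shape != (d, d):
            raise ValueError("density matrix has wrong dimension")
        if not np.allclose(self.matrix, self.matrix.conj().T, atol=ATOL):
            raise ValueError("density matrix is not Hermitian")
        if abs(np.trace(self.matrix).real - 1.0) > 1e-6:
            raise ValueError("density matrix trace differs from one")
        if np.linalg.eigvalsh(self.matrix).min() < -1e-7:
            raise ValueError("density matrix has a negative eigenvalue")

    @property
    def n_qubits(self) -> int:
        return len(self.roles)

    @classmethod
    def mixture(cls, weight: float, roles: Sequence[str] = ("g",)) -> "DensityOperator":
        """The incoherent single-qubit mixture a|0><0| + (1-a)|1><1|."""
        if not 0.0 <= weight <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")
        return cls(np.diag([weight, 1.0 - weight]).astype(complex), roles)


State = StateVector | DensityOperator


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def _target_axes(roles: Sequence[str], targets: Sequence[str]) -> list:
    axes = []
    for t in targets:
        if t not in roles:
            raise ValueError(f"role {t!r} not present in state roles {roles}")
        axes.append(tuple(roles).index(t))
    if len(set(axes)) != len(axes):
        raise ValueError(f"duplicate target roles in {tuple(targets)}")
    return axes


def embed_operator(matrix: np.ndarray, positions: Sequence[int], n: int) -> np.ndarray:
    """Embed a k-qubit operator on the given qubit positions of an n-qubit
    register (position 0 = most significant bit), identity elsewhere."""
    k = len(positions)
    m = np.asarray(matrix, dtype=complex)
    if m.shape != (2 ** k, 2 ** k):
        raise ValueError("operator dimension does not match position count")
    op = m.reshape((2,) * (2 * k))
    full = np.eye(2 ** n, dtype=complex).reshape((2,) * (2 * n))
    # contract identity's ket axes at `positions` with the operator
    out = np.tensordot(op, full, axes=(range(k, 2 * k), positions))
    # tensordot puts the operator's output axes first; restore row-axis order
    perm = [None] * n
    for i, d in enumerate(positions):
        perm[d] = i
    nontargets = [q for q in range(n) if q not in positions]
    for q, ax in zip(nontargets, range(k, n)):
        perm[q] = ax
    out = np.transpose(out, perm + [n + q for q in range(n)])
    return out.reshape(2 ** n, 2 ** n)


def apply_gate(state: State, gate: UnitaryGate, targets: Sequence[str]) -> State:
    """Return U|psi> (or U rho U^dag) with U embedded on the target roles."""
    targets = tuple(targets)
    if len(targets) != gate.arity:
        raise ValueError(
            f"gate {gate.name!r} has arity {gate.arity} but got "
            f"{len(targets)} target roles")
    axes = _target_axes(state.roles, targets)
    n = state.n_qubits
    k = gate.arity
    if isinstance(state, StateVector):
        tens = state.tensor()
        op = gate.matrix.reshape((2,) * (2 * k))
        out = np.tensordot(op, tens, axes=(range(k, 2 * k), axes))
        # restore axis order: tensordot moved target axes to the front
        perm = [None] * n
        for i, ax in enumerate(axes):
            perm[ax] = i
        rest = iter(range(k, n))
        for q in range(n):
            if perm[q] is None:
                perm[q] = next(rest)
        out = np.transpose(out, perm)
        return StateVector(out.reshape(-1), state.roles)
    U = embed_operator(gate.matrix, axes, n)
    return DensityOperator(U @ state.matrix @ U.conj().T, state.roles)


def expectation(state: State, obs: Observable,
                targets: Sequence[str] | None = None) -> float:
    """<psi|O|psi> or Tr[rho O] for a local observable on the target roles."""
    targets = tuple(targets) if targets is not None else tuple(obs.roles)
    if not targets:
        raise ValueError("observable has no target roles")
    axes = _target_axes(state.roles, targets)
    n = state.n_qubits
    O = embed_operator(obs.matrix, axes, n)
    if isinstance(state, StateVector):
        val = np.vdot(state.amplitudes, O @ state.amplitudes)
    else:
        val = np.trace(O @ state.matrix)
    if abs(val.imag) > 1e-8:
        raise ValueError("expectation value is not real; observable invalid?")
    return float(val.real)


def permute(state: StateVector, order: Sequence[str]) -> StateVector:
    """The same state with its roles listed (and bits ordered) as ``order``."""
    order = tuple(order)
    if sorted(order) != sorted(state.roles):
        raise ValueError(f"{order} is not a permutation of {state.roles}")
    axes = [state.roles.index(r) for r in order]
    tens = np.transpose(state.tensor(), axes)
    return StateVector(tens.reshape(-1), order)


def probabilities(state: StateVector, order: Sequence[str] | None = None) -> np.ndarray:
    """Measurement distribution over the 2^n bitstrings of ``order``.

    Index ``i`` of the returned vector is the bitstring ``format(i, '0nb')``
    whose leftmost bit belongs to the first role of ``order``.
    """
    if order is not None:
        state = permute(state, order)
    p = np.abs(state.amplitudes) ** 2
    return p / p.sum()


def bitstrings(n: int) -> list:
    return [format(i, f"0{n}b") for i in range(2 ** n)]


def sample_counts(dist: np.ndarray, shots: int, seed: int):
    """Multinomial sampling of measurement outcomes; reproducible per seed.

    Returns a plain dict ``bitstring -> count`` (the richer CountsTable
    wrapper lives in :mod:`qalife.analytics`).
    """
    dist = np.asarray(dist, dtype=float)
    if shots < 1:
        raise ValueError("shots must be a positive integer")
    if abs(dist.sum() - 1.0) > 1e-6 or (dist < -1e-12).any():
        raise ValueError("distribution must be normalised and non-negative")
    n = int(np.log2(len(dist)))
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(shots, dist / dist.sum())
    return dict(zip(bitstrings(n), (int(c) for c in draws)))


def partial_trace(rho: DensityOperator, keep: Sequence[str]) -> DensityOperator:
    """Marginal of ``rho`` on the kept roles (in the order given)."""
    keep = tuple(keep)
    if not keep:
        raise ValueError("must keep at least one role")
    axes = _target_axes(rho.roles, keep)
    n = rho.n_qubits
    k = len(keep)
    tens = rho.matrix.reshape((2,) * (2 * n))
    drop = [q for q in range(n) if q not in axes]
    for q in reversed(drop):
        tens = np.trace(tens, axis1=q, axis2=q + tens.ndim // 2 )
    # remaining ket axes follow the original role order among kept roles
    kept_sorted = [q for q in range(n) if q in axes]
    perm = [kept_sorted.index(q) for q in axes]
    m = tens.reshape((2,) * (2 * k))
    m = np.transpose(m, perm + [k + i for i in perm])
    return DensityOperator(m.reshape(2 ** k, 2 ** k), keep)
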