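"""Named gates, the device-style u2/u3 factories, and the verified
decompositions of the four-qubit conditional-exchange gate.

Composition convention: a product written ``A B C`` is applied C-first,
i.e. it is the ordinary matrix product ``A @ B @ C``.  This is the textbook
operator order, *not* circuit (left-to-right) order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import ATOL, Observable, UnitaryGate, bitstrings, embed_operator

# ---------------------------------------------------------------------------
# Pauli operators / single-qubit constants
# ---------------------------------------------------------------------------

SIGMA_X = Observable(np.array([[0, 1], [1, 0]]), name="sigma_x")
SIGMA_Y = Observable(np.array([[0, -1j], [1j, 0]]), name="sigma_y")
SIGMA_Z = Observable(np.array([[1, 0], [0, -1]]), name="sigma_z")

#: the decay operator sigma = |0><1| driving phenotypes to their dark state
LOWERING = np.array([[0.0, 1.0], [0.0, 0.0]], dtype=complex)


def make_u2(phi: float, lam: float) -> UnitaryGate:
    """Device-native single-qubit gate u2(phi, lambda)."""
    if not (math.isfinite(phi) and math.isfinite(lam)):
        raise ValueError("angles must be finite")
    m = np.array(
        [[1.0, -np.exp(1j * lam)],
         [np.exp(1j * phi), np.exp(1j * (lam + phi))]]) / math.sqrt(2)
    return UnitaryGate(m, name=f"u2({phi:.4g},{lam:.4g})")


def make_u3(theta: float, phi: float, lam: float) -> UnitaryGate:
    """Device-native single-qubit gate u3(theta, phi, lambda).

    ``u3(theta, 0, 0)`` is the real rotation about sigma_y by ``theta``
    (half-angle matrix entries cos(theta/2), sin(theta/2)); it prepares
    ``cos(theta/2)|0> + sin(theta/2)|1>`` from |0>.
    """
    if not all(map(math.isfinite, (theta, phi, lam))):
        raise ValueError("angles must be finite")
    c, s = math.cos(theta / 2), math.sin(theta / 2)
    m = np.array(
        [[c, -np.exp(1j * lam) * s],
         [np.exp(1j * phi) * s, np.exp(1j * (phi + lam)) * c]])
    return UnitaryGate(m, name=f"u3({theta:.4g},{phi:.4g},{lam:.4g})")


def _phase_gate(angle: float, name: str) -> UnitaryGate:
    return UnitaryGate(np.diag([1.0, np.exp(1j * angle)]), name=name)


def elementary_gates() -> dict:
    """The named fixed gates used throughout: Paulis, H, CNOT, the phase
    roots P = sqrt(sigma_z), T = sqrt(P), SWAP and controlled-sqrt(NOT)."""
    X = UnitaryGate(SIGMA_X.matrix, "X")
    Z = UnitaryGate(SIGMA_Z.matrix, "Z")
    H = UnitaryGate(np.array([[1, 1], [1, -1]]) / math.sqrt(2), "H")
    CNOT = UnitaryGate(np.array([[1, 0, 0, 0],
                                 [0, 1, 0, 0],
                                 [0, 0, 0, 1],
                                 [0, 0, 1, 0]]), "CNOT")
    SWAP = UnitaryGate(np.array([[1, 0, 0, 0],
                                 [0, 0, 1, 0],
                                 [0, 1, 0, 0],
                                 [0, 0, 0, 1]]), "SWAP")
    # principal square root of X: eigenphases halved into (-pi/2, pi/2]
    sqrt_x = 0.5 * np.array([[1 + 1j, 1 - 1j], [1 - 1j, 1 + 1j]])
    C = np.eye(4, dtype=complex)
    C[2:, 2:] = sqrt_x
    return {
        "X": X,
        "Y": UnitaryGate(SIGMA_Y.matrix, "Y"),
        "Z": Z,
        "H": H,
        "P": _phase_gate(math.pi / 2, "P"),
        "T": _phase_gate(math.pi / 4, "T"),
        "CNOT": CNOT,
        "SWAP": SWAP,
        "CSX": UnitaryGate(C, "CSX"),
    }


GATES = elementary_gates()


def reverse_cnot(cnot: UnitaryGate | None = None) -> UnitaryGate:
    """CNOT with control and target exchanged, built as (H(x)H) U12 (H(x)H)."""
    cnot = cnot or GATES["CNOT"]
    HH = np.kron(GATES["H"].matrix, GATES["H"].matrix)
    return UnitaryGate(HH @ cnot.matrix @ HH, name="CNOT_reversed")


# ---------------------------------------------------------------------------
# decomposition verification
# ---------------------------------------------------------------------------

@dataclass
class DecompositionReport:
    """Numerical comparison of a composed operator against its target.

    ``max_deviation`` is the largest elementwise modulus of (compiled -
    e^{i phase} target) after choosing the global phase that best aligns the
    two; ``action`` records, for each input basis state, the output basis
    state of largest amplitude and its complex amplitude, so that relative
    phases left on nominally invariant states are visible rather than
    assumed away.
    """

    target_name: str
    max_deviation: float
    action: dict
    two_qubit_gate_count: int = 0

    def __post_init__(self):
        if self.max_deviation < 0:
            raise ValueError("deviation must be non-negative")


def _optimal_global_phase(compiled: np.ndarray, target: np.ndarray) -> complex:
    tr = np.trace(target.conj().T @ compiled)
    if abs(tr) < 1e-12:
        return 1.0 + 0j
    return tr / abs(tr)


def compare_to_target(compiled: np.ndarray, target: np.ndarray,
                      name: str, two_qubit_gates: int = 0) -> DecompositionReport:
    phase = _optimal_global_phase(compiled, target)
    dev = float(np.abs(compiled - phase * target).max())
    n = int(np.log2(compiled.shape[0]))
    action = {}
    for j, bits in enumerate(bitstrings(n)):
        col = compiled[:, j]
        i = int(np.argmax(np.abs(col)))
        action[bits] = (format(i, f"0{n}b"), complex(col[i]))
    return DecompositionReport(name, dev, action, two_qubit_gates)


def controlled_sqrt_not_decomposition() -> tuple:
    """Controlled-sqrt(NOT) compiled from CNOTs, phase roots and u3 gates:

        C12 = (T (x) P u3(-pi/4,0,0)) U12 (1 (x) u3(pi/4,0,0)) U12 (1 (x) P^dag)

    Returns the compiled two-qubit gate together with a report of its
    deviation from the canonical controlled principal sqrt(X).
    """
    I2 = np.eye(2)
    T, P, U12 = GATES["T"].matrix, GATES["P"].matrix, GATES["CNOT"].matrix
    left = np.kron(T, P @ make_u3(-math.pi / 4, 0, 0).matrix)
    mid = np.kron(I2, make_u3(math.pi / 4, 0, 0).matrix)
    right = np.kron(I2, P.conj().T)
    compiled = left @ U12 @ mid @ U12 @ right
    report = compare_to_target(compiled, GATES["CSX"].matrix,
                               "controlled-sqrt-NOT", two_qubit_gates=2)
    return UnitaryGate(compiled, "CSX_compiled"), report


def interaction_permutation() -> UnitaryGate:
    """The canonical conditional-exchange gate on |g1 p1 g2 p2>.

    Swaps the two phenotypes exactly when the genotypes disagree:
    |xxyy> <-> |xyyx| for x != y, i.e. the transpositions
    |0011> <-> |0110> and |1100> <-> |1001>; all twelve remaining basis
    states are left untouched.  An involution.
    """
    U = np.eye(16, dtype=complex)
    for a, b in ((0b0011, 0b0110), (0b1100, 0b1001)):
        U[a, a] = U[b, b] = 0.0
        U[a, b] = U[b, a] = 1.0
    return UnitaryGate(U, "U_I")


def _embed2(gate: np.ndarray, control: int, target: int) -> np.ndarray:
    """Embed a two-qubit gate on 1-based wire indices of a 4-qubit register."""
    return embed_operator(gate, [control - 1, target - 1], 4)


def interaction_from_decomposition() -> tuple:
    """The conditional-exchange gate compiled from CNOT/SWAP/controlled-sqrt(NOT):

        U_I = S23 U12 (1 (x) F) U12 S23,
        F   = U43 C34 C24 U23 C34^dag U43 U23

    (first subindex = control, second = target; products apply right-to-left).
    Returns the 16x16 compiled operator and a report comparing it against the
    explicit permutation — including the per-basis-state phase table, since
    the compilation is only guaranteed to reproduce the exchange action, not
    the identity block's phases.
    """
    U = GATES["CNOT"].matrix
    C = GATES["CSX"].matrix
    Cdag = C.conj().T

    # two-qubit embeddings on the 4-qubit register (wires 1..4)
    def cnot(c, t):
        return _embed2(U, c, t)

    F = (cnot(4, 3) @ _embed2(C, 3, 4) @ _embed2(C, 2, 4) @ cnot(2, 3)
         @ _embed2(Cdag, 3, 4) @ cnot(4, 3) @ cnot(2, 3))
    S23 = _embed2(GATES["SWAP"].matrix, 2, 3)
    U12 = cnot(1, 2)
    compiled = S23 @ U12 @ F @ U12 @ S23
    report = compare_to_target(compiled, interaction_permutation().matrix,
                               "U_I", two_qubit_gates=19)
    return UnitaryGate(compiled, "U_I_compiled"), report
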