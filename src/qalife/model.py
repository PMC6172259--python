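"""Biomimetic primitives for quantum living units.

A living unit is a genotype/phenotype qubit pair.  Replication copies the
genotype's <sigma_z> into blank qubits through CNOTs (partial quantum
cloning), aging is amplitude damping on phenotypes (approximated in circuits
by small sigma_y rotations), mutation is a sigma_x (or partial u3) kick on a
genotype, and two units interact by conditionally exchanging phenotypes when
their genotypes disagree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import bisect

from .core import (DensityOperator, Observable, StateVector, apply_gate,
                   expectation, partial_trace)
from .gates import (GATES, LOWERING, SIGMA_X, SIGMA_Z, interaction_permutation,
                    make_u3)


@dataclass(frozen=True)
class LivingUnit:
    """A genotype/phenotype role pair forming one individual."""

    genotype: str
    phenotype: str
    creation_step: int = 0

    def __post_init__(self):
        if self.genotype == self.phenotype:
            raise ValueError("genotype and phenotype roles must differ")


@dataclass(frozen=True)
class DissipationParams:
    """Either a continuous (gamma, t) amplitude-damping segment or a single
    discrete sigma_y rotation step of angle theta_step (u3 convention, so one
    step multiplies the phenotype's <sigma_z> by cos(theta_step))."""

    gamma: float = 0.0
    t: float = 0.0
    theta_step: float = 0.0

    def __post_init__(self):
        if self.gamma < 0 or self.t < 0:
            raise ValueError("decay rate and duration must be non-negative")


@dataclass(frozen=True)
class PrecursorSpec:
    """Precursor genotype: the pure state cos(alpha)|0> + sin(alpha)|1>, or
    (for the classical counterpart) the mixture a|0><0| + (1-a)|1><1|."""

    alpha: float | None = None
    mixture_weight: float | None = None

    def __post_init__(self):
        if (self.alpha is None) == (self.mixture_weight is None):
            raise ValueError("give exactly one of alpha / mixture_weight")
        if self.mixture_weight is not None and not 0 <= self.mixture_weight <= 1:
            raise ValueError("mixture weight must lie in [0, 1]")


def _assert_blank(state, role):
    zz = expectation(state, SIGMA_Z.on(role))
    if abs(zz - 1.0) > 1e-9:
        raise ValueError(f"role {role!r} is not blank (|0>)")


def create_individual(state, precursor: PrecursorSpec, unit: LivingUnit):
    """Prepare the precursor genotype and clone its <sigma_z> into the blank
    phenotype, yielding cos(alpha)|00> + sin(alpha)|11> on the pair."""
    _assert_blank(state, unit.genotype)
    _assert_blank(state, unit.phenotype)
    if precursor.alpha is not None:
        state = apply_gate(state, make_u3(2 * precursor.alpha, 0, 0),
                           [unit.genotype])
    else:
        # classical counterpart: an incoherent genotype mixture
        if not isinstance(state, DensityOperator):
            state = state.density()
        a = precursor.mixture_weight
        theta = math.acos(max(-1.0, min(1.0, 2 * a - 1)))
        # dephased preparation: same diagonal, no coherence
        state = apply_gate(state, make_u3(theta, 0, 0), [unit.genotype])
        state = _dephase(state, unit.genotype)
    return apply_gate(state, GATES["CNOT"], [unit.genotype, unit.phenotype])


def _dephase(rho: DensityOperator, role: str) -> DensityOperator:
    """Remove single-qubit coherences on ``role`` (sigma_z twirl)."""
    flipped = apply_gate(rho, GATES["Z"], [role])
    return DensityOperator((rho.matrix + flipped.matrix) / 2, rho.roles)


def self_replicate(state, parent: LivingUnit, child: LivingUnit):
    """Two partial cloning events: parent genotype -> child genotype ->
    child phenotype.  All four <sigma_z> agree afterwards and the precursor's
    <sigma_x> migrates into the joint x-correlation."""
    _assert_blank(state, child.genotype)
    _assert_blank(state, child.phenotype)
    state = apply_gate(state, GATES["CNOT"], [parent.genotype, child.genotype])
    return apply_gate(state, GATES["CNOT"], [child.genotype, child.phenotype])


# ---------------------------------------------------------------------------
# environment: death by dissipation
# ---------------------------------------------------------------------------

def dissipate_continuous(rho: DensityOperator, phenotype: str,
                         params: DissipationParams) -> DensityOperator:
    """Amplitude damping of one phenotype for a time t at rate gamma.

    Closed-form channel for the Lindblad operator sqrt(gamma)|0><1|:
    damping probability p = 1 - e^{-gamma t}; <sigma_z> relaxes as
    1 - e^{-gamma t}(1 - <sigma_z>_0) toward the |0> dark state while
    coherences shrink by e^{-gamma t / 2}.
    """
    if not isinstance(rho, DensityOperator):
        rho = rho.density()
    p = 1.0 - math.exp(-params.gamma * params.t)
    K0 = np.array([[1.0, 0.0], [0.0, math.sqrt(1.0 - p)]], dtype=complex)
    K1 = math.sqrt(p) * LOWERING
    axis = rho.roles.index(phenotype)
    from .core import embed_operator
    out = np.zeros_like(rho.matrix)
    for K in (K0, K1):
        Kfull = embed_operator(K, [axis], rho.n_qubits)
        out += Kfull @ rho.matrix @ Kfull.conj().T
    return DensityOperator(out, rho.roles)


def dissipate_discrete(state, phenotype: str, theta_step: float):
    """One discrete aging step: the sigma_y rotation u3(theta_step, 0, 0) on
    the phenotype.  k steps compose to u3(k*theta_step, 0, 0)."""
    return apply_gate(state, make_u3(theta_step, 0, 0), [phenotype])


def effective_lifetime(a: float, gamma: float, eps: float) -> float:
    """Time for the phenotype's excited population e^{-gamma t}(1-a) to fall
    below eps — the genotype-dependent lifetime.  Closed form
    ln((1-a)/eps) / gamma, clipped at zero when the unit is already dead."""
    if not 0 <= a < 1:
        raise ValueError("genotype ground weight a must lie in [0, 1)")
    if gamma <= 0:
        raise ValueError("decay rate must be positive")
    if not 0 < eps < 1:
        raise ValueError("error threshold must lie in (0, 1)")
    if eps >= 1 - a:
        return 0.0
    return math.log((1 - a) / eps) / gamma


def effective_lifetime_bisect(a: float, gamma: float, eps: float) -> float:
    """Lifetime found by bisection on the channel itself (cross-check for
    the closed form)."""
    if eps >= 1 - a:
        return 0.0

    def excited(t):
        rho = DensityOperator.mixture(a, ("p",))
        rho = dissipate_continuous(rho, "p", DissipationParams(gamma=gamma, t=t))
        return rho.matrix[1, 1].real - eps

    hi = 1.0
    while excited(hi) > 0:
        hi *= 2
    return bisect(excited, 0.0, hi, xtol=1e-12)


# ---------------------------------------------------------------------------
# mutation and interaction
# ---------------------------------------------------------------------------

def mutate(state, genotype: str, theta_mut: float | None = None):
    """Mutation kick on a genotype: a full sigma_x flip by default, or the
    partial rotation u3(theta_mut, 0, 0) when an angle is given."""
    if theta_mut is None:
        return apply_gate(state, GATES["X"], [genotype])
    return apply_gate(state, make_u3(theta_mut, 0, 0), [genotype])


def interact(state, unit_a: LivingUnit, unit_b: LivingUnit):
    """Conditional phenotype exchange between two units: the canonical
    permutation on (g_a, p_a, g_b, p_b)."""
    roles = (unit_a.genotype, unit_a.phenotype,
             unit_b.genotype, unit_b.phenotype)
    if len(set(roles)) != 4:
        raise ValueError("interacting units must occupy four distinct roles")
    return apply_gate(state, interaction_permutation(), roles)


# ---------------------------------------------------------------------------
# consistency of discrete aging with the dissipative model
# ---------------------------------------------------------------------------

def eq2_residuals(a: float, gamma: float, t1: float, t2: float,
                  theta1: float, theta2: float) -> tuple:
    """Residuals of the three conditions a discrete-rotation surrogate must
    satisfy to match the dissipative dynamics in both bases:

        e^{-gamma(t1+t2)/2} <sigma_x> = cos(theta1) cos(theta2) <sigma_x>
        1 - 2 e^{-gamma(t1+t2)} (1-a) = (2a-1) cos(theta1)
        1 - 2 e^{-gamma t2} (1-a)     = (2a-1) cos(theta2)

    with <sigma_x> = 2 sqrt(a(1-a)) for the pure precursor of ground weight a.
    """
    sx = 2 * math.sqrt(a * (1 - a))
    r1 = math.exp(-gamma * (t1 + t2) / 2) * sx - math.cos(theta1) * math.cos(theta2) * sx
    r2 = 1 - 2 * math.exp(-gamma * (t1 + t2)) * (1 - a) - (2 * a - 1) * math.cos(theta1)
    r3 = 1 - 2 * math.exp(-gamma * t2) * (1 - a) - (2 * a - 1) * math.cos(theta2)
    return (r1, r2, r3)


def solve_eq2(a: float, gamma: float, t1: float, t2: float) -> tuple:
    """Invert the two z-basis conditions for (theta1, theta2) and report the
    x-basis residual that remains.  A nonzero residual that *varies with a*
    at fixed (gamma, t1, t2) is the obstruction: no angle choice mimics the
    dissipation independently of the genotype.

    Real angles only exist for ground weight a < 1/2 with gamma*t below
    ln(2(1-a)) — dissipation drives <sigma_z> toward +1 while a sigma_y
    rotation can only shrink it toward 0, so for a > 1/2 the required
    cosine exceeds one for any positive duration.
    """
    if a == 0.5:
        raise ValueError("a = 1/2 leaves the z-conditions degenerate")
    c1 = (1 - 2 * math.exp(-gamma * (t1 + t2)) * (1 - a)) / (2 * a - 1)
    c2 = (1 - 2 * math.exp(-gamma * t2) * (1 - a)) / (2 * a - 1)
    if abs(c1) > 1 or abs(c2) > 1:
        raise ValueError("no real rotation angle solves the z-condition "
                         f"(cos would be {c1:.4g}, {c2:.4g})")
    theta1, theta2 = math.acos(c1), math.acos(c2)
    r1 = eq2_residuals(a, gamma, t1, t2, theta1, theta2)[0]
    return theta1, theta2, r1


# ---------------------------------------------------------------------------
# quantum vs classical: time correlations through a lineage
# ---------------------------------------------------------------------------

def causal_correlation_demo(alpha: float) -> tuple:
    """Joint four-qubit x-correlation for a replicated lineage versus two
    causally independent individuals.

    ``alpha`` is <sigma_x> of the precursor genotype, so the precursor is
    cos(h)|0> + sin(h)|1> with sin(2h) = alpha.  Replication propagates
    <sigma_x> into the joint correlation (value alpha); two independently
    created individuals with the same single-qubit statistics only reach
    alpha**2; an incoherent mixture precursor yields exactly zero however it
    is replicated.
    """
    if abs(alpha) > 1:
        raise ValueError("alpha is an x-expectation, |alpha| <= 1")
    half = math.asin(alpha) / 2
    roles = ("g1", "p1", "g2", "p2")
    xxxx = Observable(_kron4(SIGMA_X.matrix), roles, "XXXX")

    # one lineage: create then self-replicate
    state = StateVector.blank(roles)
    state = create_individual(state, PrecursorSpec(alpha=half),
                              LivingUnit("g1", "p1"))
    state = self_replicate(state, LivingUnit("g1", "p1"),
                           LivingUnit("g2", "p2", creation_step=1))
    replicated = expectation(state, xxxx)

    # two causally unrelated individuals with identical statistics
    state = StateVector.blank(roles)
    state = create_individual(state, PrecursorSpec(alpha=half),
                              LivingUnit("g1", "p1"))
    state = create_individual(state, PrecursorSpec(alpha=half),
                              LivingUnit("g2", "p2"))
    independent = expectation(state, xxxx)
    return replicated, independent


def mixture_correlation(a: float) -> float:
    """Four-qubit x-correlation when the precursor is the classical mixture
    a|0><0| + (1-a)|1><1|: identically zero, whatever a."""
    roles = ("g1", "p1", "g2", "p2")
    state = StateVector.blank(roles).density()
    state = create_individual(state, PrecursorSpec(mixture_weight=a),
                              LivingUnit("g1", "p1"))
    state = self_replicate(state, LivingUnit("g1", "p1"),
                           LivingUnit("g2", "p2"))
    xxxx = Observable(_kron4(SIGMA_X.matrix), roles, "XXXX")
    return expectation(state, xxxx)


def _kron4(m: np.ndarray) -> np.ndarray:
    out = m
    for _ in range(3):
        out = np.kron(out, m)
    return out
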