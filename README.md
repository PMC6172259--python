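# qalife — quantum artificial life on a few-qubit simulator

`qalife` implements a minimal Darwinian scenario encoded in quantum
circuits: *living units* made of a genotype qubit and a phenotype qubit
that self-replicate, age, mutate, and conditionally exchange phenotypes
when they meet.  It is written for people studying quantum biomimetics —
how biological behaviours can be compiled into small unitary circuits —
and it reconstructs, and checks itself against, the published ibmqx4
chip experiments of this protocol together with their measured count
tables, which ship as fixtures.

## The model

* **Self-replication by partial cloning.**  A precursor genotype
  cos α|0⟩ + sin α|1⟩ is copied through a CNOT onto a blank qubit:
  ⟨σ_z⟩ is duplicated (the no-cloning theorem is sidestepped by cloning
  one observable, not the state), producing cos α|00⟩ + sin α|11⟩.  Two
  further clonings (g₁→g₂→p₂) create a child individual; the precursor's
  ⟨σ_x⟩ migrates into the joint correlation
  ⟨σ_x⊗σ_x⊗σ_x⊗σ_x⟩ = sin 2α — an entanglement witness that the two
  individuals share a timeline, since two *independently* created
  individuals with identical single-qubit statistics only reach
  (sin 2α)², and a classical mixture precursor propagates exactly 0.
* **Death by dissipation.**  Each phenotype couples to a bath with
  Lindblad operator σ = |0⟩⟨1| (amplitude damping): ⟨σ_z⟩ relaxes as
  1 − e^{−γt}(1 − ⟨σ_z⟩₀) toward the dark state |0⟩ and coherences decay
  as e^{−γt/2}.  The *effective lifetime* ln((1−a)/ε)/γ depends on the
  genotype weight a — better-adapted genotypes die sooner or later.  On
  hardware the channel is approximated by discrete σ_y rotations
  u3(θ,0,0); matching the z-relaxation with an angle necessarily breaks
  the x-decay (no genotype-independent (θ₁,θ₂) solves all three
  consistency equations), and the package exposes that obstruction as
  `solve_eq2`.
* **Mutation.**  σ_x kicks on genotypes, applied in weighted run groups
  (1024-shot mutated groups against 8192-shot unmutated ones) so that
  classical aggregation of counts realises exact rational mutation rates
  2/19 and 2/27.
* **Interaction.**  A four-qubit gate U_I exchanges the two phenotypes
  exactly when the genotypes disagree (|xxyy⟩ ↔ |xyyx⟩, identity on the
  other twelve basis states).  The shipped decomposition into CNOT,
  SWAP and controlled-√NOT gates is verified to equal the permutation
  exactly.

Measured counts are compared with ideal distributions through the
Bhattacharyya coefficient F(p,q) = Σⱼ √(pⱼqⱼ), per-qubit ⟨σ_z⟩
estimators, and the signed-popcount x-parity estimator (counts taken
after a Hadamard on every qubit).

## Worked example

```python
>>> import qalife as q
>>> report = q.compare("I", q.load_fixture("I"))
>>> round(100 * report.fidelity, 2)
71.58
>>> [round(v, 2) for v in report.measured_sigmaz]
[0.7, -0.26, -0.27, 0.41]
>>> [round(v, 2) for v in report.ideal_sigmaz]
[0.71, -0.71, -0.71, 0.71]
```

Experiment `I` creates two individuals (amplitude half-angles π/8 and
3π/8) and lets them interact: ideally the phenotypes swap, so the ideal
⟨σ_z⟩ pattern is (0.71, −0.71, −0.71, 0.71).  The measured table from
the chip reproduces the ideal distribution with 71.58% overlap; the
measured phenotype values (−0.26, 0.41) sit well short of the ideal
exchange — two-qubit gate errors dominate this, the deepest circuit.

The same pipeline from the command line:

```
qalife simulate --experiment II --shots 8192 --seed 7 --out run.json
qalife analyze --counts run.json
qalife reproduce          # all golden checks; exit code 0 iff all pass
```

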