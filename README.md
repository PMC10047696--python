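# qphi — mechanism integrated information for qubit registers

`qphi` computes the *mechanism integrated information* (φ) of subsets of
small quantum systems evolving under unitary dynamics, in the tradition of
integrated information theory (IIT).  It is aimed at researchers in quantum
information and mathematical consciousness science who want to analyze the
compositional causal structure of 2–3 qubit states and gates: which subsets
of a register specify irreducible causes and effects, over which purviews,
in which states, and how strongly.

The same package contains an independent classical mechanism-φ engine
(probability vectors over a transition probability matrix), because a
defining requirement of the quantum formulation is *convergence*: a
reversible logic gate applied to a computational basis state must yield
exactly the same φ values, purviews and intrinsic states under both
formalisms.  This is tested exhaustively for all 24 two-bit reversible gates
and all four basis states.

## The quantities computed

For a register Q of n qubits in state ρ evolving as ρ ↦ UρU†, a *mechanism*
is a subset M ⊆ Q in its reduced state ρᴹ, and a *purview* Z ⊆ Q is the
subset over which the mechanism's causal constraint is assessed.

**Repertoires.** The effect repertoire πₑ(Z|m) is the state the mechanism
alone pins down for Z one step ahead: the mechanism's complement is replaced
by maximally mixed noise (causal marginalization),

    ρ_{t+1}^{Z|m} = tr_{Z'} [ U (ρᴹ ⊗ ρ_mm^{M'}) U† ],

and the result is factorized across its maximal separability partition P*
(the finest grouping of Z into mutually unentangled blocks), so that
correlations induced by shared noise from outside the mechanism are
discounted while genuine entanglement inside Z is kept intact:

    πₑ(Z|m) = ⊗ᵢ ρ_{t+1}^{Z(i)|m},   Z(i) ∈ P*(ρ_{t+1}^{Z|m}).

The cause repertoire runs the adjoint channel backwards from the P*-blocks
of the mechanism state separately and combines the per-block conditionals
by operator product, normalized by the trace.

**The measure.** With ρ = Σᵢ pᵢ|i⟩⟨i|, σ = Σⱼ qⱼ|j⟩⟨j| and overlaps
P_ij = |⟨i|j⟩|², the quantum intrinsic difference is

    QID(ρ‖σ) = maxᵢ pᵢ [ log₂ pᵢ − Σⱼ P_ij log₂ qⱼ ]   (unit: ibit),

the state-specific counterpart of the quantum relative entropy (which
averages over i instead of maximizing).  The maximizing eigenvector — or
degenerate eigenspace — is the *intrinsic state* z′.

**Integrated information.** φ(m,Z,θ) scores the intrinsic state of the
unpartitioned repertoire against the repertoire computed under a
*disintegrating partition* θ of (M, Z) into independent parts.  The minimum
information partition (MIP) minimizes φ normalized by the number of severed
mechanism–purview unit pairs; φ(m,Z) is the unnormalized value at the MIP,
and φ(m) maximizes over purviews (larger purviews win ties).  A mechanism
with φ > 0 in both directions is a *distinction*; the set of all
distinctions is the system's cause–effect structure.

## A worked example

CNOT applied to |+0⟩ creates the Bell state B⁺ = (|00⟩+|11⟩)/√2 — a
transition with no classical circuit equivalent:

```python
import qphi as q

cnot = q.named_gate("CNOT", ("A", "B"))
result = q.unfold(cnot, q.parse_state("+0", ("A", "B")))
for d in result["effect"].distinctions:
    print("".join(d.mechanism.units), d.phi, "".join(d.purview))
for d in result["effect"].reducible:
    print("".join(d.mechanism.units), d.phi)
```

prints

```
AB 2.0 AB
A 0.0
B 0.0
```

Only the second-order mechanism is irreducible, at φ = 2 ibit (the full
two-qubit content: any cut of the mechanism destroys the entanglement of
the Bell repertoire entirely), while each qubit alone specifies nothing.
Contrast this with the classical-basis input `"10"`, where the analysis
returns the COPY-XOR structure (φ = 1 ibit for the control copy and for the
whole mechanism, 0.5 ibit of cause information for the XOR output with tied
past states 10/01), identical to the classical engine's output.

The `examples/` directory has one short narrative script per capability:
causal marginalization, Bell-state φ, the GHZ-vs-W intrinsic-structure
comparison, and classical convergence.  A thin CLI wraps the same library:

```
qphi scenarios                # list built-in scenarios
qphi run cnot_bell            # unfold a scenario, JSON report to stdout
qphi phi cnot_bell --mechanism AB --purview AB --all-partitions
qphi repertoire cnot_10 --mechanism B --purview AB
```

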