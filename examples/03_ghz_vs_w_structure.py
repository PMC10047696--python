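"""Intrinsic structure of three-qubit entangled states.

Under the identity channel, the analysis reads out the constraints a state
places on itself.  The GHZ and W states are both maximally entangled, yet
their internal structure differs sharply: GHZ specifies a single
third-order constraint and nothing below it (every reduced state is an
unentangled even mixture), while the W state constrains every subset of
qubits — its two-qubit reductions remain entangled.
"""

import qphi as q

ghz = q.unfold(None, q.parse_state("ghz", ("A", "B", "C")), mode="self")
w = q.unfold(None, q.parse_state("w", ("A", "B", "C")), mode="self")

for name, res in [("GHZ", ghz), ("W", w)]:
    ces = res["constraint"]
    print(f"{name} state: positive-phi mechanisms per order "
          f"(1st, 2nd, 3rd) = {ces.order_histogram()}")
    for d in ces.distinctions:
        print(f"  {''.join(d.mechanism.units)}: phi = {d.phi:.3f} ibit "
              f"over {''.join(d.purview)}")

diff = q.compare_structures(ghz["constraint"], w["constraint"])
print("\nstructured diff:", diff["order_histograms"])
print("A holistic system-level summary would treat both states as 'maximally")
print("entangled'; the compositional analysis separates them.")
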