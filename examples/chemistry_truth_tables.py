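"""Readout logic of the five conversion chemistries.

Prints, for each protocol, the probability that an unmodified C, a 5mC or
a 5hmC is sequenced as C — first under ideal enzymes (the design truth
table: 0 or 1), then under the default efficiencies calibrated to the
achieved spike-in rates.  The CD/CT columns show why these assays read
5mC directly: only the CMD1-protected mark survives conversion.
"""

from duomod import chemistry as ch

for label, config in (("ideal", ch.ideal_config()),
                      ("default", ch.default_config())):
    print(f"\n--- {label} efficiencies ---")
    print(f"{'protocol':<10}{'P(C->C)':>10}{'P(5mC->C)':>12}{'P(5hmC->C)':>12}")
    for proto in ch.PROTOCOL_NAMES:
        ps = [ch.prob_read_C(s, proto, config) for s in ("C", "5mC", "5hmC")]
        print(f"{proto:<10}" + "".join(f"{p:>12.4f}" for p in ps))

print("\nA value near 1 means the state is read as C (protected); near 0"
      "\nmeans it deaminates/converts and is read as T.")
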