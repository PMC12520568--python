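# Default conversion efficiencies for the five built-in chemistries.
# Values are per-step, per-substrate Bernoulli conversion probabilities,
# calibrated so the simulated assays reproduce the achieved spike-in
# rates: CD-seq deaminates ~97% of 5hmC and retains ~93% of 5mC as C
# (attributing the ~7% loss entirely to CMD1 efficiency); TAB-seq leaves
# ~2% of 5mC reading as C (residual TET oxidation failure).  Protected
# states (5gmC under DEA, 5ghmC under DEA) default to full resistance
# and may be given nonzero leakage here.
seq_error: 0.001
protocols:
  BS:
    BISULFITE: {C: 0.995, 5fC: 1.0, 5caC: 1.0}
  TAB:
    BGT: {5hmC: 0.95}
    TET: {5mC: 0.98, 5hmC: 0.98}
    BISULFITE: {C: 0.995, 5fC: 1.0, 5caC: 1.0}
  ACE:
    BGT: {5hmC: 0.98}
    DEA: {C: 0.998, 5mC: 0.995, 5hmC: 0.97, 5gmC: 0.0, 5ghmC: 0.0, 5fC: 1.0, 5caC: 1.0}
  CD:
    CMD1: {5mC: 0.93}
    DEA: {C: 0.998, 5mC: 0.995, 5hmC: 0.97, 5gmC: 0.0, 5ghmC: 0.0, 5fC: 1.0, 5caC: 1.0}
  CT:
    CMD1: {5mC: 0.93}
    TET: {5mC: 0.98, 5hmC: 0.98}
    BISULFITE: {C: 0.995, 5fC: 1.0, 5caC: 1.0}
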