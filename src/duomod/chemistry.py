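"""Probabilistic models of cytosine-conversion sequencing chemistries.

Five chemistries are built in, each an ordered composition of enzymatic
steps followed by a C/T readout:

* **BS**  — bisulfite sequencing: unmodified C deaminates to U (read T);
  5mC and 5hmC both resist, so the two marks are confounded.
* **TAB** — beta-glucosyltransferase (BGT) protects 5hmC as 5ghmC, TET
  oxidises 5mC to 5caC, bisulfite then sends C and 5caC to T; only 5hmC
  reads C.
* **ACE** — BGT protection followed by an APOBEC-family deaminase (DEA)
  that converts C, 5mC and unprotected 5hmC to T; only 5hmC reads C.
* **CD**  — CMD1 glycerylates 5mC to 5gmC, which resists DEA; C and 5hmC
  deaminate to T; only 5mC reads C.
* **CT**  — CMD1 protection, TET oxidation of the remaining convertible
  states, bisulfite conversion; only 5mC reads C.

Each molecule is treated as an independent sequence of Bernoulli step
applications; the closed-form marginal probability of reading C is exact
under that assumption (no within-molecule correlation).  5fC and 5caC are
collapsed into a single oxidised state that reads T after bisulfite or
deaminase treatment, because none of the built-in chemistries reads them
out separately.

Default per-step efficiencies ship in ``duomod/data/default_chemistry.yaml``
and are calibrated to the spike-in rates achieved by the assays (CD-seq
deaminates ~97% of 5hmC and retains ~93% of 5mC; TAB-seq leaves ~2% of
5mC reading as C).  Every entry can be overridden by the user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Mapping

import yaml

__all__ = [
    "CytosineState",
    "EnzymeStep",
    "AssayProtocol",
    "ChemistryConfig",
    "ChemistryError",
    "PROTOCOL_NAMES",
    "default_config",
    "ideal_config",
    "get_protocol",
    "state_distribution",
    "prob_read_C",
    "expected_raw_level",
    "truth_table",
]


class ChemistryError(ValueError):
    """Raised for invalid chemistry configuration or domain errors."""


class CytosineState(str, Enum):
    """Chemical identity of a cytosine before/after enzymatic treatment."""

    C = "C"
    MC = "5mC"
    HMC = "5hmC"
    GMC = "5gmC"          # 5-glyceryl-methylcytosine, CMD1 product of 5mC
    FC = "5fC"
    CAC = "5caC"
    GHMC = "5ghmC"        # glucosylated 5hmC, BGT product
    READS_T = "readsT"    # terminal deaminated/converted state


#: States a user may pass as the *initial* identity of a genomic cytosine.
INPUT_STATES = (CytosineState.C, CytosineState.MC, CytosineState.HMC,
                CytosineState.GMC, CytosineState.FC, CytosineState.CAC,
                CytosineState.GHMC)

PROTOCOL_NAMES = ("BS", "TAB", "ACE", "CD", "CT")

# Substrate -> product wiring of each enzymatic step.  Efficiencies are
# supplied by the config; substrates not listed pass through unchanged.
_STEP_PRODUCTS: dict[str, dict[CytosineState, CytosineState]] = {
    # CMD1 transfers a glyceryl group onto 5mC only.
    "CMD1": {CytosineState.MC: CytosineState.GMC},
    # BGT glucosylates 5hmC only.
    "BGT": {CytosineState.HMC: CytosineState.GHMC},
    # TET oxidises 5mC and 5hmC towards 5fC/5caC (collapsed to 5caC here);
    # glyceryl/glucosyl-protected states are not substrates.
    "TET": {CytosineState.MC: CytosineState.CAC,
            CytosineState.HMC: CytosineState.CAC},
    # DNA deaminase mix: converts C, 5mC, 5hmC (and the oxidised states)
    # to a T readout; bulky 5gmC/5ghmC resist (efficiency ~0).
    "DEA": {CytosineState.C: CytosineState.READS_T,
            CytosineState.MC: CytosineState.READS_T,
            CytosineState.HMC: CytosineState.READS_T,
            CytosineState.FC: CytosineState.READS_T,
            CytosineState.CAC: CytosineState.READS_T,
            CytosineState.GMC: CytosineState.READS_T,
            CytosineState.GHMC: CytosineState.READS_T},
    # Bisulfite: deaminates C and the oxidised states; 5mC, 5hmC and the
    # protected states resist.
    "BISULFITE": {CytosineState.C: CytosineState.READS_T,
                  CytosineState.FC: CytosineState.READS_T,
                  CytosineState.CAC: CytosineState.READS_T},
}

# Substrates each step is *designed* to convert: under an ideal config
# these run at efficiency 1 and everything else (protection leakage such
# as DEA attacking 5gmC) at 0.
_STEP_IDEAL_SUBSTRATES: dict[str, tuple[CytosineState, ...]] = {
    "CMD1": (CytosineState.MC,),
    "BGT": (CytosineState.HMC,),
    "TET": (CytosineState.MC, CytosineState.HMC),
    "DEA": (CytosineState.C, CytosineState.MC, CytosineState.HMC,
            CytosineState.FC, CytosineState.CAC),
    "BISULFITE": (CytosineState.C, CytosineState.FC, CytosineState.CAC),
}

_PROTOCOL_STEPS: dict[str, tuple[str, ...]] = {
    "BS": ("BISULFITE",),
    "TAB": ("BGT", "TET", "BISULFITE"),
    "ACE": ("BGT", "DEA"),
    "CD": ("CMD1", "DEA"),
    "CT": ("CMD1", "TET", "BISULFITE"),
}


@dataclass(frozen=True)
class EnzymeStep:
    """One enzymatic treatment: substrate -> (product, efficiency).

    Substrates not listed pass through with probability 1.
    """

    name: str
    transitions: Mapping[CytosineState, tuple[CytosineState, float]]

    def __post_init__(self) -> None:
        for substrate, (product, eff) in self.transitions.items():
            if not 0.0 <= eff <= 1.0:
                raise ChemistryError(
                    f"step {self.name}: efficiency for substrate "
                    f"{substrate.value} is {eff}, outside [0, 1]")

    def apply(self, dist: dict[CytosineState, float]) -> dict[CytosineState, float]:
        out: dict[CytosineState, float] = {}
        for state, mass in dist.items():
            if state in self.transitions:
                product, eff = self.transitions[state]
                if eff > 0.0:
                    out[product] = out.get(product, 0.0) + mass * eff
                if eff < 1.0:
                    out[state] = out.get(state, 0.0) + mass * (1.0 - eff)
            else:
                out[state] = out.get(state, 0.0) + mass
        return out


@dataclass(frozen=True)
class AssayProtocol:
    """Ordered enzymatic steps plus a terminal-state -> base readout."""

    name: str
    steps: tuple[EnzymeStep, ...]
    readout: Mapping[CytosineState, str] = field(
        default_factory=lambda: _default_readout())

    def final_distribution(self, state: CytosineState) -> dict[CytosineState, float]:
        dist = {state: 1.0}
        for step in self.steps:
            dist = step.apply(dist)
        return dist


def _default_readout() -> dict[CytosineState, str]:
    # Any cytosine that survives conversion is sequenced as C; the
    # deaminated/converted terminal state is sequenced as T.
    table = {s: "C" for s in CytosineState}
    table[CytosineState.READS_T] = "T"
    return table


@dataclass
class ChemistryConfig:
    """Per-protocol, per-step, per-substrate conversion efficiencies.

    ``efficiencies[protocol][step][substrate_label] = value in [0, 1]``.
    ``seq_error`` is a symmetric C<->T flip applied after chemistry by the
    read simulator (not by :func:`prob_read_C`).
    """

    efficiencies: dict[str, dict[str, dict[str, float]]]
    seq_error: float = 0.001

    def __post_init__(self) -> None:
        if not 0.0 <= self.seq_error <= 1.0:
            raise ChemistryError(f"seq_error {self.seq_error} outside [0, 1]")
        for proto, steps in self.efficiencies.items():
            for step_name, subs in steps.items():
                if step_name not in _STEP_PRODUCTS:
                    raise ChemistryError(
                        f"unknown enzymatic step {step_name!r} in protocol "
                        f"{proto!r}; known steps: {sorted(_STEP_PRODUCTS)}")
                for label, eff in subs.items():
                    try:
                        state = CytosineState(label)
                    except ValueError:
                        raise ChemistryError(
                            f"unknown cytosine state {label!r} in "
                            f"{proto}/{step_name}") from None
                    if state not in _STEP_PRODUCTS[step_name]:
                        raise ChemistryError(
                            f"{proto}/{step_name}: {label} is not a substrate "
                            f"of this step")
                    if not 0.0 <= eff <= 1.0:
                        raise ChemistryError(
                            f"{proto}/{step_name}/{label}: efficiency {eff} "
                            f"outside [0, 1]")

    @classmethod
    def from_yaml(cls, path) -> "ChemistryConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(efficiencies=raw["protocols"],
                   seq_error=float(raw.get("seq_error", 0.001)))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"seq_error": self.seq_error,
                            "protocols": self.efficiencies}, fh,
                           sort_keys=True)


def default_config() -> ChemistryConfig:
    """Default efficiencies calibrated to the assays' achieved spike-in rates."""
    ref = resources.files("duomod").joinpath("data/default_chemistry.yaml")
    with resources.as_file(ref) as path:
        return ChemistryConfig.from_yaml(path)


def ideal_config() -> ChemistryConfig:
    """Every designed conversion at efficiency 1, every protection perfect."""
    eff: dict[str, dict[str, dict[str, float]]] = {}
    for proto, step_names in _PROTOCOL_STEPS.items():
        eff[proto] = {}
        for step_name in step_names:
            eff[proto][step_name] = {
                s.value: (1.0 if s in _STEP_IDEAL_SUBSTRATES[step_name] else 0.0)
                for s in _STEP_PRODUCTS[step_name]
            }
    return ChemistryConfig(efficiencies=eff, seq_error=0.0)


def get_protocol(name: str, config: ChemistryConfig | None = None) -> AssayProtocol:
    """Build one of the five built-in protocols from a config."""
    if name not in _PROTOCOL_STEPS:
        raise ChemistryError(
            f"unknown protocol {name!r}; built-ins: {PROTOCOL_NAMES}")
    if config is None:
        config = default_config()
    if name not in config.efficiencies:
        raise ChemistryError(f"config has no efficiencies for protocol {name!r}")
    steps = []
    for step_name in _PROTOCOL_STEPS[name]:
        step_eff = config.efficiencies[name].get(step_name, {})
        transitions = {}
        for substrate, product in _STEP_PRODUCTS[step_name].items():
            eff = float(step_eff.get(substrate.value, 0.0))
            transitions[substrate] = (product, eff)
        steps.append(EnzymeStep(name=step_name, transitions=transitions))
    return AssayProtocol(name=name, steps=tuple(steps))


def _as_protocol(protocol, config: ChemistryConfig | None) -> AssayProtocol:
    if isinstance(protocol, AssayProtocol):
        return protocol
    return get_protocol(str(protocol), config)


def state_distribution(state: CytosineState | str, protocol,
                       config: ChemistryConfig | None = None
                       ) -> dict[CytosineState, float]:
    """Distribution over chemical states after the full protocol."""
    try:
        state = CytosineState(state)
    except ValueError:
        raise ChemistryError(f"unknown cytosine state {state!r}") from None
    if state not in INPUT_STATES:
        raise ChemistryError(f"{state.value} is not a valid input state")
    proto = _as_protocol(protocol, config)
    return proto.final_distribution(state)


def prob_read_C(state: CytosineState | str, protocol,
                config: ChemistryConfig | None = None) -> float:
    """Closed-form probability that *state* is sequenced as C.

    Steps are applied sequentially and independently; the result is the
    marginal mass of the final distribution whose readout is C.
    """
    proto = _as_protocol(protocol, config)
    dist = state_distribution(state, proto)
    return sum(mass for s, mass in dist.items() if proto.readout[s] == "C")


def expected_raw_level(m: float, h: float, protocol,
                       config: ChemistryConfig | None = None) -> float:
    """Expected C-fraction at a site with 5mC level ``m`` and 5hmC level ``h``.

    The site's molecules are a (m, h, 1-m-h) mixture of 5mC, 5hmC and
    unmodified C; the expected converted-read C-fraction is the matching
    mixture of per-state read-C probabilities.
    """
    if m < 0 or h < 0 or m + h > 1 + 1e-12:
        raise ChemistryError(f"invalid site levels m={m}, h={h}: need "
                             f"m, h >= 0 and m + h <= 1")
    proto = _as_protocol(protocol, config)
    p_m = prob_read_C(CytosineState.MC, proto)
    p_h = prob_read_C(CytosineState.HMC, proto)
    p_c = prob_read_C(CytosineState.C, proto)
    return m * p_m + h * p_h + (1.0 - m - h) * p_c


def truth_table(protocol) -> dict[str, str]:
    """Ideal-efficiency readout of {C, 5mC, 5hmC} for a built-in protocol."""
    name = protocol.name if isinstance(protocol, AssayProtocol) else str(protocol)
    proto = get_protocol(name, ideal_config())
    table = {}
    for state in (CytosineState.C, CytosineState.MC, CytosineState.HMC):
        p = prob_read_C(state, proto)
        table[state.value] = "C" if p >= 0.5 else "T"
    return table
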