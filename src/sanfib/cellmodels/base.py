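"""Cell-parameter and cell-state containers shared by the three phenotypes.

``CellParams`` carries the *modifiers* of a published cell model, never the
model equations themselves: multiplicative scale factors on the randomised
maximal conductances, fractional current blocks, and the autonomic state
(ACh concentration in nM, isoprenaline on/off).  A block fraction ``b`` on a
current is exactly equivalent to a ``(1 - b)`` multiplier on its maximal
conductance, and is folded in that way before the kernels run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from . import san


class Phenotype(Enum):
    SAN = "SAN"
    ATRIAL = "ATRIAL"
    FIBROBLAST = "FIBROBLAST"


#: multiplier names accepted per phenotype (heterogeneity is SAN-only;
#: the atrium supports the tissue-wide fast-sodium scaling)
SUPPORTED_MULTIPLIERS = {
    Phenotype.SAN: set(san.MULT_NAMES),
    Phenotype.ATRIAL: {"gNa"},
    Phenotype.FIBROBLAST: set(),
}

#: current-block name -> conductance/permeability parameter it scales
BLOCK_TO_PARAM = {
    "If": "gf",
    "ICaL": "PCaL",
    "ICaT": "PCaT",
    "IKr": "gKr",
    "IKs": "gKs",
    "INa": "gNa",
    "Ito": "gto",
    "IKur": "gKur",
}

MEMBRANE_CAPACITANCE_PF = {
    Phenotype.SAN: 57.0,
    Phenotype.ATRIAL: 50.0,
    Phenotype.FIBROBLAST: 6.3,
}


@dataclass(frozen=True)
class CellParams:
    phenotype: Phenotype
    multipliers: dict = field(default_factory=dict)
    block_fractions: dict = field(default_factory=dict)
    ach_concentration: float = 0.0  # nM
    iso_active: bool = False

    def __post_init__(self):
        allowed = SUPPORTED_MULTIPLIERS[self.phenotype]
        for name, m in self.multipliers.items():
            if name not in allowed:
                raise ValueError(
                    f"unknown multiplier {name!r} for phenotype {self.phenotype.value}"
                )
            if not (m > 0):
                raise ValueError(f"multiplier {name!r} must be > 0, got {m}")
        for name, b in self.block_fractions.items():
            if name not in BLOCK_TO_PARAM:
                raise ValueError(f"unknown current {name!r} in block_fractions")
            if BLOCK_TO_PARAM[name] not in allowed and self.phenotype is not Phenotype.SAN:
                raise ValueError(
                    f"block on {name!r} unsupported for {self.phenotype.value}"
                )
            if not (0.0 <= b <= 1.0):
                raise ValueError(f"block fraction {name!r} must be in [0, 1], got {b}")
        if self.ach_concentration < 0:
            raise ValueError("ach_concentration must be >= 0 nM")
        if self.phenotype is not Phenotype.SAN and (
            self.ach_concentration > 0 or self.iso_active
        ):
            raise ValueError("autonomic modulation is supported on SAN cells only")

    @property
    def membrane_capacitance(self) -> float:
        """Membrane capacitance in pF (model-native)."""
        return MEMBRANE_CAPACITANCE_PF[self.phenotype]

    def mult_vector(self) -> np.ndarray:
        """Effective multiplier vector in ``san.MULT_NAMES`` order (SAN) or a
        single-element ``[gNa]`` vector (atrial); blocks folded in."""
        if self.phenotype is Phenotype.SAN:
            vec = np.ones(san.N_MULT)
            for name, m in self.multipliers.items():
                vec[san.MULT_NAMES.index(name)] *= m
            for name, b in self.block_fractions.items():
                vec[san.MULT_NAMES.index(BLOCK_TO_PARAM[name])] *= 1.0 - b
            return vec
        if self.phenotype is Phenotype.ATRIAL:
            g = self.multipliers.get("gNa", 1.0)
            g *= 1.0 - self.block_fractions.get("INa", 0.0)
            return np.array([g])
        return np.zeros(0)

    @property
    def ach_mM(self) -> float:
        return self.ach_concentration * 1e-6


def apply_autonomic(params: CellParams, ach: float, iso: bool,
                    additive: bool = True) -> CellParams:
    """Install ACh (nM) and/or ISO modulation on a SAN parameter set.

    With both agonists active the model combines their parameter shifts
    additively on each affected parameter; ``additive=False`` is rejected
    for the combined case since no other combination rule is defined.
    """
    if params.phenotype is not Phenotype.SAN:
        raise ValueError("autonomic modulation is SAN-only in this model")
    if ach < 0:
        raise ValueError("ACh concentration must be >= 0 nM")
    if ach > 0 and iso and not additive:
        raise ValueError("combined ACh+ISO is only defined additively")
    return replace(params, ach_concentration=ach, iso_active=iso)


@dataclass
class CellState:
    phenotype: Phenotype
    vector: np.ndarray

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=float)
        expected = state_size(self.phenotype)
        if self.vector.shape != (expected,):
            raise ValueError(
                f"{self.phenotype.value} state must have length {expected}, "
                f"got {self.vector.shape}"
            )
        if not np.all(np.isfinite(self.vector)):
            bad = int(np.flatnonzero(~np.isfinite(self.vector))[0])
            raise ValueError(
                f"non-finite state variable {state_names(self.phenotype)[bad]!r} "
                f"in {self.phenotype.value} cell"
            )

    @property
    def voltage(self) -> float:
        return float(self.vector[0])


def state_size(phenotype: Phenotype) -> int:
    from . import atrial, fibroblast
    return {
        Phenotype.SAN: san.N_STATES,
        Phenotype.ATRIAL: atrial.N_STATES,
        Phenotype.FIBROBLAST: fibroblast.N_STATES,
    }[phenotype]


def state_names(phenotype: Phenotype) -> tuple:
    from . import atrial, fibroblast
    return {
        Phenotype.SAN: san.STATE_NAMES,
        Phenotype.ATRIAL: atrial.STATE_NAMES,
        Phenotype.FIBROBLAST: fibroblast.STATE_NAMES,
    }[phenotype]
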