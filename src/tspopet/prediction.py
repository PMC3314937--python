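"""Deterministic in vivo prediction: permeability -> K1 -> k2 -> per-class BP_ND.

The one-tissue compartment parameters of a radioligand are predicted from its
in silico / in vitro characterisation under a passive-diffusion brain-entry
model (Renkin-Crone capillary extraction with an empirically scaled K1) and an
equilibrium binding model with one or two affinity sites per binding class:

    log10 P = -0.121 (clogD - 2.2982)^2 - 2.544 log10(Vx^(1/3)) - 2.525
    K1      = scale * f * (1 - exp(-P S / f))
    k2      = (Vaq_P / Vaq_T) * K1 * f_ND / f_P
    BP_ND   = f_ND * Bmax_H / Ki_H                      (HAB)
            = f_ND * (Bmax_MH / Ki_H + Bmax_ML / Ki_L)  (MAB)
            = f_ND * Bmax_L / Ki_L                      (LAB)

Disease states scale every class's Bmax by a common multiplier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .ligands import (
    BindingClass,
    LigandProperties,
    LigandRecord,
    PhysiologicalConstants,
    TSPOTarget,
)

__all__ = [
    "DiseaseState",
    "CONTROL",
    "DISEASE_I",
    "DISEASE_II",
    "KineticParameters",
    "permeability",
    "influx_rate",
    "efflux_rate",
    "binding_potential",
    "predict_kinetics",
]


@dataclass(frozen=True)
class DiseaseState:
    """Uniform TSPO up-regulation: Bmax of every class times ``bmax_multiplier``."""

    bmax_multiplier: float = 1.0
    label: str = "control"

    def __post_init__(self):
        if self.bmax_multiplier < 0:
            raise ValueError("bmax_multiplier must be >= 0")


#: control, moderate (+50%, e.g. schizophrenia-like) and high (+400%,
#: ALS-like) TSPO density increases.
CONTROL = DiseaseState(1.0, "control")
DISEASE_I = DiseaseState(1.5, "disease_I")
DISEASE_II = DiseaseState(5.0, "disease_II")


@dataclass(frozen=True)
class KineticParameters:
    """Predicted 1TCM parameters: K1 (mL cm^-3 min^-1), k2 (min^-1) and the
    binding potential of each binding class."""

    k1: float
    k2: float
    bp_nd: Mapping[BindingClass, float]

    def __post_init__(self):
        if not (self.k1 > 0 and self.k2 > 0):
            raise ValueError("k1 and k2 must be > 0")
        if any(v < 0 for v in self.bp_nd.values()):
            raise ValueError("bp_nd must be >= 0")


def permeability(clogd: float, vx: float) -> float:
    """Passive BBB permeability P (cm min^-1) from lipophilicity and size.

    Lipophilicity enters through a parabolic penalty centred at
    clogD = 2.2982; molecular size through the McGowan volume.
    """
    if not vx > 0:
        raise ValueError(f"vx must be > 0, got {vx}")
    log10_p = (
        -0.121 * (clogd - 2.2982) ** 2
        - 2.544 * math.log10(vx ** (1.0 / 3.0))
        - 2.525
    )
    return 10.0**log10_p


def influx_rate(p: float, constants: PhysiologicalConstants | None = None) -> float:
    """K1 from permeability via the capillary extraction model,
    K1 = scale * f * (1 - exp(-P S / f)); bounded above by scale * f."""
    if constants is None:
        constants = PhysiologicalConstants()
    if not p > 0:
        raise ValueError(f"permeability must be > 0, got {p}")
    f = constants.perfusion_f
    return constants.k1_scale * f * (1.0 - math.exp(-p * constants.surface_s / f))


def efflux_rate(
    k1: float,
    f_p: float,
    f_nd: float,
    constants: PhysiologicalConstants | None = None,
) -> float:
    """k2 from K1 and the free fractions; k2/K1 is independent of permeability."""
    if constants is None:
        constants = PhysiologicalConstants()
    if not f_p > 0:
        raise ValueError(f"f_p must be > 0, got {f_p}")
    return (constants.v_aq_p / constants.v_aq_t) * k1 * f_nd / f_p


def binding_potential(
    ligand: LigandProperties,
    target: TSPOTarget,
    cls: BindingClass,
    disease: DiseaseState = CONTROL,
) -> float:
    """Class-specific BP_ND; MABs sum the two sites with Bmax_M split by
    ``target.mab_high_fraction``."""
    m = disease.bmax_multiplier
    f_nd = ligand.f_nd
    if cls is BindingClass.HAB:
        return f_nd * m * target.bmax_hab / ligand.ki_high
    if cls is BindingClass.LAB:
        return f_nd * m * target.bmax_lab / ligand.ki_low
    bmax_mh = target.mab_high_fraction * target.bmax_mab
    bmax_ml = (1.0 - target.mab_high_fraction) * target.bmax_mab
    return f_nd * m * (bmax_mh / ligand.ki_high + bmax_ml / ligand.ki_low)


def predict_kinetics(
    record: LigandRecord,
    constants: PhysiologicalConstants | None = None,
    disease: DiseaseState = CONTROL,
) -> KineticParameters:
    """Full deterministic prediction for one ligand record."""
    if constants is None:
        constants = PhysiologicalConstants()
    lig = record.properties
    p = permeability(lig.clogd, lig.vx)
    k1 = influx_rate(p, constants)
    k2 = efflux_rate(k1, lig.f_p, lig.f_nd, constants)
    bp = {
        cls: binding_potential(lig, record.target, cls, disease)
        for cls in BindingClass
    }
    return KineticParameters(k1=k1, k2=k2, bp_nd=bp)
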