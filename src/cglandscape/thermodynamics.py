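"""Closed-form binding thermodynamics: Kd <-> dG and the equilibrium
shift ratio.

Conventions: the gas constant is 0.0019872 kcal/mol/K, the standard
concentration 1 M, and binding affinities are reported as positive
magnitudes (dG = -RT ln(Kd / c0) > 0 for Kd < 1 M).  The default
temperature is 300 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

R_GAS = 0.0019872  # kcal/mol/K


@dataclass(frozen=True)
class ThermoContext:
    temperature: float = 300.0
    gas_constant: float = R_GAS
    standard_concentration: float = 1.0  # molar

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self):
        return self.gas_constant * self.temperature


DEFAULT = ThermoContext()


def kd_to_dg(kd, ctx=DEFAULT):
    """Binding affinity magnitude (kcal/mol) from a dissociation constant.

    dG = -RT ln(Kd / c0); a 15.8 uM Kd at 300 K gives about 6.6 kcal/mol.
    """
    if kd <= 0:
        raise ValueError("Kd must be positive")
    return -ctx.rt * math.log(kd / ctx.standard_concentration)


def dg_to_kd(dg, ctx=DEFAULT):
    """Dissociation constant (molar) from a binding affinity magnitude."""
    if not math.isfinite(dg):
        raise ValueError("dG must be finite")
    return ctx.standard_concentration * math.exp(-dg / ctx.rt)


def shift_ratio(ddg, ctx=DEFAULT, abundance_factor=1.0):
    """Equilibrium partitioning ratio implied by an affinity difference.

    ratio = abundance_factor * exp(ddG / RT): the ratio of ligand bound to
    the higher-affinity receptor form over the lower-affinity form when
    both forms are equally abundant (abundance_factor rescales for unequal
    abundances).  A 2 kcal/mol difference at 300 K gives about 29.
    """
    if not math.isfinite(ddg):
        raise ValueError("ddG must be finite")
    return abundance_factor * math.exp(ddg / ctx.rt)
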