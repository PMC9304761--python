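"""Reference binding data for the FKBP12-rapamycin benchmark system.

Published headline numbers for the association of rapamycin with wild-type
FKBP12 and the two hydrogen-bond-removal mutants D37V and Y82F: the
lower-bound PMF plateau (``dg_pmf``), the standard-state corrected binding
free energy (``dg_bind0``), and enzymatic-inhibition measurements
temperature-corrected to the simulation temperature of 295.0 K
(``dg_exp`` in kcal/mol, ``k_exp`` in nM, with stated uncertainties).
These serve as worked-example inputs for the free-energy arithmetic
utilities (mutant-vs-wild-type differences, dG <-> Kd conversion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .binding import k_to_dg
from .constants import T_SIM_K


@dataclass(frozen=True)
class VariantRecord:
    name: str
    dg_pmf: float            # kcal/mol, lower-bound PMF plateau (negated)
    dg_bind0: float          # kcal/mol, standard-state corrected
    dg_exp: float            # kcal/mol, measurement at 295.0 K
    dg_exp_err: float
    k_exp_nM: float          # dissociation constant at 295.0 K, nM
    k_exp_err_nM: float


#: Benchmark table, indexed by variant.
FKBP12_RAPAMYCIN: Dict[str, VariantRecord] = {
    "WT": VariantRecord("WT", -11.09, -13.98, -12.53, 0.23, 0.54, 0.21),
    "Y82F": VariantRecord("Y82F", -10.21, -13.22, -11.98, 0.23, 1.37, 0.50),
    "D37V": VariantRecord("D37V", -8.08, -10.78, -9.61, 0.09, 77.70, 11.97),
}

#: Temperature the table refers to (the simulation temperature).
TABLE_TEMPERATURE_K = T_SIM_K

#: Temperature at which the original inhibition assay was run.
ASSAY_TEMPERATURE_K = 288.15


def ddg_bind0(mutant: str, wild_type: str = "WT") -> float:
    """Computed binding free-energy difference mutant - wild type."""
    return FKBP12_RAPAMYCIN[mutant].dg_bind0 - FKBP12_RAPAMYCIN[wild_type].dg_bind0


def ddg_exp(mutant: str, wild_type: str = "WT") -> float:
    """Measured binding free-energy difference mutant - wild type."""
    return FKBP12_RAPAMYCIN[mutant].dg_exp - FKBP12_RAPAMYCIN[wild_type].dg_exp


def dg_from_table_kd(variant: str, temperature: float = TABLE_TEMPERATURE_K) -> float:
    """Binding dG recovered from the tabulated dissociation constant via
    -- independently of the tabulated dG column --  kBT ln(Kd / 1 M)."""
    return k_to_dg(FKBP12_RAPAMYCIN[variant].k_exp_nM * 1e-9, temperature)
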