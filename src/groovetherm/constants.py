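"""Physical constants — the single source of truth for every module.

Energies are handled in kJ/mol internally; the melting module works in
kcal/mol at its boundaries (UV-melting thermodynamics are conventionally
reported in kcal/mol) and converts here.
"""

from __future__ import annotations

#: Gas constant in kcal/(mol K), the unit of the van 't Hoff analysis.
R_GAS_KCAL: float = 1.987204e-3

#: Gas constant / Boltzmann constant in molar units, kJ/(mol K).
K_B_KJ: float = 8.3144626e-3

#: Avogadro's number, 1/mol.
N_AVOGADRO: float = 6.02214076e23

#: kcal -> kJ.
KCAL_TO_KJ: float = 4.184


def kBT_kJ(T: float) -> float:
    """Thermal energy k_B*T in kJ/mol at temperature ``T`` (K).

    kBT_kJ(300.0) == 2.494 kJ/mol to the printed precision.
    """
    return K_B_KJ * T


def kj_to_kBT(value_kj: float, T: float) -> float:
    """Convert an energy in kJ/mol to units of k_B*T at ``T`` (K)."""
    return value_kj / kBT_kJ(T)


def kBT_to_kj(value_kbt: float, T: float) -> float:
    """Convert an energy in k_B*T units at ``T`` (K) to kJ/mol."""
    return value_kbt * kBT_kJ(T)
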