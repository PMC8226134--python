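"""Physical constants and the package unit conventions.

Unit conventions used throughout:

* coordinates and distances: Angstrom
* energies (potential, kinetic, bias): kJ mol^-1
* forces: kJ mol^-1 A^-1
* masses: amu
* entropies: J K^-1 mol^-1 (T*S products reported in kJ mol^-1)
* temperature: K

Conversions to SI happen only inside the vibrational-frequency math.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant, J K^-1
KB_SI = 1.380649e-23
#: Planck constant, J s
H_SI = 6.62607015e-34
#: Avogadro constant, mol^-1
NA = 6.02214076e23
#: Gas constant, J K^-1 mol^-1 (kB per mole)
R_GAS = KB_SI * NA
#: kB in kJ mol^-1 K^-1 (molar convention used for kB*T in energy units)
KB_KJ_MOL = R_GAS / 1000.0

#: kJ mol^-1 A^-1  ->  J m^-1 (per molecule)
FORCE_TO_SI = 1000.0 / NA / 1.0e-10
#: amu -> kg
AMU_TO_KG = 1.0e-3 / NA
#: kJ mol^-1 -> J (per molecule)
ENERGY_TO_SI = 1000.0 / NA
#: amu A^2 -> kg m^2 (moment of inertia)
INERTIA_TO_SI = AMU_TO_KG * 1.0e-20
#: torque kJ mol^-1 (per rad) -> J per molecule
TORQUE_TO_SI = ENERGY_TO_SI


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants bundle passed through the entropy pipeline.

    ``sigma_water`` is the rotational symmetry number of the water
    molecule (2), fixed by molecular symmetry.
    """

    T: float = 298.0
    kB: float = KB_SI
    h: float = H_SI
    sigma_water: int = 2

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")

    @property
    def kBT_kj_mol(self) -> float:
        """kB*T in kJ mol^-1."""
        return KB_KJ_MOL * self.T

    @property
    def kBT_si(self) -> float:
        """kB*T in J (per molecule)."""
        return self.kB * self.T


DEFAULT_CONSTANTS = PhysicalConstants()
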