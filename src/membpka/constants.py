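"""Physical constants and unit conversions.

Internal unit system: lengths in Å, energies in kcal/mol, charges in
elementary charges e, potentials in kcal/(mol·e).  In these units the
Coulomb interaction of two unit charges at distance r in a medium of
relative permittivity eps_r is ``COULOMB_CONSTANT / (eps_r * r)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

#: Boltzmann constant, kcal/(mol·K)
KB_KCAL_PER_MOL_K = 0.0019872

#: e^2 / (4*pi*eps0) in kcal·Å/(mol·e^2)
COULOMB_CONSTANT = 332.06

#: 1 kcal/mol expressed in eV (per elementary charge): 1 eV = 23.060548 kcal/mol
KCAL_PER_MOL_PER_EV = 23.060548

#: number density (particles/Å^3) of a 1 mol/L solution
PARTICLES_PER_A3_PER_MOLAR = 6.02214076e-4


@dataclass(frozen=True)
class PhysicalConstants:
    """Temperature, ionic strength and the derived thermal/screening scales.

    Parameters
    ----------
    temperature:
        Absolute temperature in K.  Defaults to 310 K (physiological).
    ionic_strength:
        Bulk 1:1 electrolyte concentration in mol/L used for Debye
        screening in the solvent region.  Default 0.15 M.
    coulomb_constant:
        kcal·Å/(mol·e^2); exposed so alternative unit conventions are a
        configuration change rather than a code change.
    """

    temperature: float = 310.0
    ionic_strength: float = 0.15
    coulomb_constant: float = COULOMB_CONSTANT
    kb: float = field(default=KB_KCAL_PER_MOL_K, repr=False)

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.ionic_strength < 0:
            raise ValueError("ionic strength must be non-negative")

    @property
    def kbt(self) -> float:
        """Thermal energy k_B·T in kcal/mol."""
        return self.kb * self.temperature

    @property
    def kbt_over_e_mv(self) -> float:
        """Thermal voltage k_B·T/e in millivolts."""
        return self.kbt / KCAL_PER_MOL_PER_EV * 1000.0

    @property
    def ln10_kbt(self) -> float:
        """ln(10)·k_B·T, the energy per pKa unit, kcal/mol."""
        import math

        return math.log(10.0) * self.kbt

    def kappa_bar_sq(self, ion_concentrations: dict[float, float] | None = None) -> float:
        """Modified screening coefficient Σ_i z_i² e² c∞,i / (k_B T).

        Pre-multiplied by the unit conversions of the internal system so
        that the linearized PB equation reads
        ``div(eps grad phi) - kappa_bar_sq * phi = -4*pi*k_c*rho``.
        Units: Å⁻² per unit relative permittivity (divide by the solvent
        eps to obtain the squared inverse Debye length).

        Parameters
        ----------
        ion_concentrations:
            Optional map valence -> mol/L.  Defaults to a symmetric 1:1
            electrolyte at ``ionic_strength``.
        """
        if ion_concentrations is None:
            c = self.ionic_strength
            ion_concentrations = {+1.0: c, -1.0: c}
        total = sum(z * z * conc for z, conc in ion_concentrations.items())
        return (
            4.0
            * 3.141592653589793
            * self.coulomb_constant
            * total
            * PARTICLES_PER_A3_PER_MOLAR
            / self.kbt
        )

    def debye_kappa(self, eps_solvent: float) -> float:
        """Inverse Debye length κ (Å⁻¹) in a solvent of permittivity eps_solvent."""
        return (self.kappa_bar_sq() / eps_solvent) ** 0.5
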