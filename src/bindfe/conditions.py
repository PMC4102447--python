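"""Thermodynamic conditions shared by every sampler and estimator.

Units across the package: energies in kcal/mol, lengths in Å, angles in
degrees (converted to radians only inside angular quadratures), time in ps,
temperature in K.  The default temperature is 310 K and the standard
concentration C° = 1 M corresponds to one molecule per 1661 Å³.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041

#: Inverse standard concentration (1 M) in Å³.
STANDARD_VOLUME = 1661.0


@dataclass(frozen=True)
class SimulationConditions:
    """Temperature, Boltzmann constant and standard-state reference volume.

    ``beta`` is derived exactly as 1/(kB·T); ``standard_volume`` is the volume
    per molecule at the standard concentration (1661 Å³ for 1 M).
    """

    temperature: float = 310.0
    boltzmann_constant: float = KB_KCAL
    standard_volume: float = STANDARD_VOLUME

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")
        if self.boltzmann_constant <= 0:
            raise ValueError("boltzmann_constant must be > 0")
        if self.standard_volume <= 0:
            raise ValueError("standard_volume must be > 0")

    @property
    def kt(self) -> float:
        """Thermal energy kB·T in kcal/mol (≈0.61603 at 310 K)."""
        return self.boltzmann_constant * self.temperature

    @property
    def beta(self) -> float:
        """Inverse thermal energy 1/(kB·T) in mol/kcal."""
        return 1.0 / self.kt
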