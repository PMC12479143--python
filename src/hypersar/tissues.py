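"""Tissue dielectric property registry.

The registry ships as a plain-text table (``data/tissues.tsv``) of density,
relative permittivity and electrical conductivity at 915 MHz for the tissues
of the five-layer head model plus the applicator's coupling water.  The
wavelength of each tissue is derived from the lossy-dielectric dispersion
relation (see :mod:`hypersar.physics`) rather than stored.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

from .constants import DEFAULT_FREQUENCY_HZ, SPEED_OF_LIGHT
from .errors import InvalidArgumentError

__all__ = ["TissueProperties", "load_tissue_registry", "BRAIN_VARIANTS"]

#: Tissue labels usable as the brain compartment of the head phantom.
BRAIN_VARIANTS = ("white_matter", "gray_matter", "brain_average")


@dataclass(frozen=True)
class TissueProperties:
    """Dielectric and mass properties of one tissue at the operating frequency.

    Parameters
    ----------
    name
        Registry label, e.g. ``"muscle"``.
    density
        Mass density rho, kg/m^3.
    rel_permittivity
        Relative permittivity eps_r (dimensionless, >= 1).
    conductivity
        Electrical conductivity sigma, S/m.
    frequency
        Frequency at which the properties apply, Hz.
    """

    name: str
    density: float
    rel_permittivity: float
    conductivity: float
    frequency: float = DEFAULT_FREQUENCY_HZ
    _wavelength: float = field(init=False, repr=False, default=0.0)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise InvalidArgumentError(f"density must be > 0, got {self.density}")
        if self.rel_permittivity < 1:
            raise InvalidArgumentError(
                f"relative permittivity must be >= 1, got {self.rel_permittivity}"
            )
        if self.conductivity < 0:
            raise InvalidArgumentError(
                f"conductivity must be >= 0, got {self.conductivity}"
            )
        if self.frequency <= 0:
            raise InvalidArgumentError(f"frequency must be > 0, got {self.frequency}")
        from .physics import lossy_wavelength

        lam = lossy_wavelength(self.rel_permittivity, self.conductivity, self.frequency)
        object.__setattr__(self, "_wavelength", lam)

    @property
    def wavelength(self) -> float:
        """Wavelength in this tissue at ``frequency``, cm (derived, cached)."""
        return self._wavelength

    @property
    def free_space_wavelength(self) -> float:
        """Vacuum wavelength c/f at ``frequency``, cm."""
        return SPEED_OF_LIGHT / self.frequency * 100.0


def load_tissue_registry(frequency: float = DEFAULT_FREQUENCY_HZ) -> dict[str, TissueProperties]:
    """Load the shipped tissue table as a name -> :class:`TissueProperties` map."""
    text = (
        importlib.resources.files("hypersar")
        .joinpath("data/tissues.tsv")
        .read_text(encoding="utf-8")
    )
    registry: dict[str, TissueProperties] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        name, rho, er, sigma = line.split("\t")
        registry[name] = TissueProperties(
            name=name,
            density=float(rho),
            rel_permittivity=float(er),
            conductivity=float(sigma),
            frequency=frequency,
        )
    return registry
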