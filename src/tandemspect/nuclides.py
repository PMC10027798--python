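"""Nuclide constants for the tandem Lu-177 / Ac-225 setting.

Physical half-lives and emission data are standard nuclear-data values
(ICRP-107 level of precision); they are plain dataclass fields so a config
can override any of them.  ``energy_per_decay_MeV`` is the locally deposited
(charged-particle) energy used by the dose kernel: for Ac-225 it is the full
decay-chain alpha+beta energy under the full-local-deposition assumption,
for Lu-177 the mean beta plus conversion/Auger electron energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["NuclideSpec", "LU177", "AC225", "BI213", "get_nuclide"]

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class NuclideSpec:
    name: str
    half_life_h: float
    #: photon emissions as (energy keV, probability per decay)
    photon_emissions: tuple[tuple[float, float], ...] = ()
    energy_per_decay_MeV: float = 0.0
    rbe: float = 1.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be > 0")
        if any(not (0.0 <= p <= 1.0) for _, p in self.photon_emissions):
            raise ValueError("emission probabilities must lie in [0, 1]")
        if self.rbe < 1.0:
            raise ValueError("rbe must be >= 1")

    def decay_factor(self, dt_h: float) -> float:
        """Fraction of activity remaining after ``dt_h`` hours."""
        return 2.0 ** (-dt_h / self.half_life_h)


LU177 = NuclideSpec(
    name="Lu-177",
    half_life_h=6.647 * HOURS_PER_DAY,
    photon_emissions=((208.4, 0.1041), (112.9, 0.0617)),
    energy_per_decay_MeV=0.147,
    rbe=1.0,
)

#: Ac-225 in secular equilibrium with its chain; imaging uses the progeny
#: gammas (Fr-221 218 keV, Bi-213 440 keV).  27.6 MeV is the full-chain
#: charged-particle energy assuming local deposition of all daughters.
AC225 = NuclideSpec(
    name="Ac-225",
    half_life_h=9.920 * HOURS_PER_DAY,
    photon_emissions=((218.0, 0.114), (440.4, 0.259)),
    energy_per_decay_MeV=27.6,
    rbe=5.0,
)

BI213 = NuclideSpec(
    name="Bi-213",
    half_life_h=45.6 / 60.0,
    photon_emissions=((440.4, 0.259),),
    energy_per_decay_MeV=1.42,
    rbe=5.0,
)

_REGISTRY = {"lu177": LU177, "ac225": AC225, "bi213": BI213}


def get_nuclide(key: str | NuclideSpec) -> NuclideSpec:
    if isinstance(key, NuclideSpec):
        return key
    norm = key.lower().replace("-", "").replace("_", "")
    try:
        return _REGISTRY[norm]
    except KeyError:
        raise KeyError(f"unknown nuclide {key!r}; known: {sorted(_REGISTRY)}") from None
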