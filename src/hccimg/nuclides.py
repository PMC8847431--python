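"""Embedded nuclide emission tables.

Each nuclide is a list of emission lines with absolute intensities
(photons per decay).  ``annihilation-pair`` lines are counted in pairs
per decay; the simulator emits the two 511 keV photons back to back.
Line energies and intensities are digitized from standard decay-data
compilations (only the lines relevant at >= ~50 keV are kept; low-energy
X-rays below the detector range are omitted).
"""

from __future__ import annotations

from dataclasses import dataclass

GAMMA = "gamma"
PAIR = "annihilation-pair"


@dataclass(frozen=True)
class EmissionLine:
    energy_kev: float
    intensity: float  # photons (or pairs) per decay
    kind: str = GAMMA

    def __post_init__(self):
        if not (0.0 < self.intensity <= 2.0):
            raise ValueError("intensity must be in (0, 2]")
        if self.kind not in (GAMMA, PAIR):
            raise ValueError(f"unknown emission kind {self.kind!r}")


NUCLIDES: dict[str, tuple[EmissionLine, ...]] = {
    "cs137": (EmissionLine(661.66, 0.851),),
    "am241": (EmissionLine(59.54, 0.359),),
    "na22": (
        EmissionLine(511.0, 0.903, PAIR),
        EmissionLine(1274.5, 0.999),
    ),
    "ga67": (
        EmissionLine(93.3, 0.388),
        EmissionLine(184.6, 0.212),
        EmissionLine(300.2, 0.168),
        EmissionLine(393.5, 0.047),
    ),
    "in111": (
        EmissionLine(171.3, 0.907),
        EmissionLine(245.4, 0.941),
    ),
    # At-211: Po K X-rays near 79 keV (EC branch) plus a weak gamma.
    "at211": (
        EmissionLine(79.0, 0.21),
        EmissionLine(570.0, 0.0034),
    ),
    "ba133": (
        EmissionLine(53.2, 0.0214),
        EmissionLine(79.6, 0.0265),
        EmissionLine(81.0, 0.329),
        EmissionLine(276.4, 0.0716),
        EmissionLine(302.9, 0.1831),
        EmissionLine(356.0, 0.6205),
        EmissionLine(383.8, 0.0894),
    ),
}


def emission_lines(nuclide: str) -> tuple[EmissionLine, ...]:
    """Emission table of ``nuclide`` (case-insensitive, e.g. ``"Cs137"``)."""
    key = nuclide.lower().replace("-", "")
    try:
        return NUCLIDES[key]
    except KeyError:
        raise ValueError(f"no emission table for nuclide {nuclide!r}") from None
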