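"""Archetype geometry: zones, envelope areas and layout constants.

Eight dwelling archetypes with fixed internal layout. Geometry is a box
approximation: square footprint, storeys and exposed-surface fractions by
archetype. Zone volumes are fixed fractions of the dwelling volume
(kitchen / living / bedroom / rest-of-dwelling); layouts are held constant
across the stock, only overall floor area, ceiling height and glazing vary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ARCHETYPES = (
    "end_terrace",
    "mid_terrace",
    "semi",
    "detached",
    "bungalow",
    "converted_flat",
    "low_rise_flat",
    "high_rise_flat",
)

ZONES = ("kitchen", "living", "bedroom", "rest")

#: fraction of total dwelling volume per zone; sums to 1
ZONE_VOLUME_FRACTIONS = {"kitchen": 0.10, "living": 0.25, "bedroom": 0.20, "rest": 0.45}

# storeys, exposed-wall fraction, exposed-roof fraction, exposed-ground fraction
_ARCHETYPE_FORM = {
    "end_terrace":    (2, 0.75, 1.0, 1.0),
    "mid_terrace":    (2, 0.50, 1.0, 1.0),
    "semi":           (2, 0.75, 1.0, 1.0),
    "detached":       (2, 1.00, 1.0, 1.0),
    "bungalow":       (1, 1.00, 1.0, 1.0),
    "converted_flat": (1, 0.50, 0.5, 0.5),
    "low_rise_flat":  (1, 0.50, 0.33, 0.33),
    "high_rise_flat": (1, 0.40, 0.10, 0.10),
}

FLAT_ARCHETYPES = frozenset({"converted_flat", "low_rise_flat", "high_rise_flat"})


@dataclass
class ArchetypeModel:
    """Zoned physical model of one dwelling archetype instance.

    The interzonal exchange is a common-mixing-node scheme: every zone
    exchanges ``mix_rate`` (h⁻¹, relative to its own volume) with a shared
    node whose concentration is the volume-weighted dwelling mean, so total
    air mass is conserved by construction.
    """

    archetype_id: str
    floor_area: float              # m²
    ceiling_height: float          # m
    glazing_ratio: float = 0.2
    terrain: str = "urban"         # exposure class: city | urban | rural
    mix_rate: float = 0.5          # h⁻¹ interzonal exchange with mixing node
    zone_names: tuple = ZONES
    zone_volumes: np.ndarray = field(init=False)
    envelope_area: float = field(init=False)

    def __post_init__(self) -> None:
        if self.archetype_id not in _ARCHETYPE_FORM:
            raise ValueError(f"unknown archetype: {self.archetype_id!r}")
        if self.floor_area <= 0 or self.ceiling_height <= 0:
            raise ValueError("floor_area and ceiling_height must be positive")
        volume = self.floor_area * self.ceiling_height
        self.zone_volumes = np.array(
            [ZONE_VOLUME_FRACTIONS[z] * volume for z in self.zone_names]
        )
        self.envelope_area = envelope_area(
            self.archetype_id, self.floor_area, self.ceiling_height
        )

    @property
    def volume(self) -> float:
        return float(self.zone_volumes.sum())


def envelope_area(archetype_id: str, floor_area, ceiling_height):
    """Exposed envelope area (m²) from the box approximation.

    Square footprint of ``floor_area / storeys``; exposed wall, roof and
    ground-floor areas scaled by archetype-specific fractions (party walls,
    flats above/below reduce the exposed fraction).
    """
    storeys, wall_f, roof_f, ground_f = _ARCHETYPE_FORM[archetype_id]
    footprint = np.asarray(floor_area, dtype=float) / storeys
    side = np.sqrt(footprint)
    walls = 4.0 * side * np.asarray(ceiling_height, dtype=float) * storeys
    area = wall_f * walls + roof_f * footprint + ground_f * footprint
    return area if np.ndim(area) else float(area)
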