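"""Phantom geometry and embolization-plug packing arithmetic.

The idealized aneurysm model is an axisymmetric cylinder (the vessel) with a
spherical sac at its center and a uniform wall.  After endograft deployment
the excluded sac volume is the spherical sac volume minus the cylindrical
graft volume across the sac, and plug packing volumes are expressed as a
percentage of that excluded volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ModelGeometry",
    "PackingState",
    "sphere_volume",
    "cylinder_volume",
    "excluded_sac_volume",
    "packing_state",
]

#: Nominal fully-expanded volume of a single shape-memory-polymer plug, cm³.
PLUG_VOLUME_CM3 = 1.25

#: Canonical plug-count → packing-label mapping used for the study conditions.
LABEL_BY_PLUG_COUNT = {0: 0, 15: 100, 30: 200, 45: 300, 60: 400}

#: Permitted graft oversizing relative to the landing-zone vessel diameter.
MAX_GRAFT_OVERSIZE = 0.30


@dataclass(frozen=True)
class ModelGeometry:
    """Dimensions of the idealized aneurysm model, all in mm.

    Defaults describe a 28-mm vessel with a 50-mm spherical sac, a 2.5-mm
    wall, and a 34-mm endograft (≈21% oversized to the vessel).
    """

    vessel_diameter: float = 28.0
    aneurysm_diameter: float = 50.0
    wall_thickness: float = 2.5
    graft_diameter: float = 34.0

    def __post_init__(self) -> None:
        if self.vessel_diameter <= 0 or self.aneurysm_diameter <= 0:
            raise ValueError("vessel and aneurysm diameters must be positive")
        if self.wall_thickness <= 0:
            raise ValueError("wall thickness must be positive")
        if self.graft_diameter < 0:
            raise ValueError("graft diameter must be non-negative")
        if self.aneurysm_diameter <= self.vessel_diameter:
            raise ValueError("aneurysm diameter must exceed vessel diameter")
        if self.graft_diameter > self.vessel_diameter * (1.0 + MAX_GRAFT_OVERSIZE):
            raise ValueError(
                f"graft diameter {self.graft_diameter} mm exceeds "
                f"{MAX_GRAFT_OVERSIZE:.0%} oversizing of the "
                f"{self.vessel_diameter} mm vessel"
            )


@dataclass(frozen=True)
class PackingState:
    """Plug packing of the excluded sac.

    ``nominal_fraction`` is the exact total plug volume as a percentage of
    the excluded sac volume; ``label_fraction`` is the rounded label used to
    name the condition (100%, 200%, ...), which for the canonical plug counts
    does not exactly equal the nominal value (15 plugs × 1.25 cm³ = 18.75 cm³
    is 93.75% of a 20.0 cm³ sac but is labelled "100%").
    """

    n_plugs: int
    plug_volume: float  # cm³
    sac_volume: float  # cm³
    nominal_fraction: float  # %
    label_fraction: int  # %


def sphere_volume(diameter: float) -> float:
    """Volume of a sphere, diameter in mm, returned in cm³."""
    if diameter < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi * diameter**3 / 6.0 / 1000.0


def cylinder_volume(diameter: float, length: float) -> float:
    """Volume of a circular cylinder, dimensions in mm, returned in cm³."""
    if diameter < 0 or length < 0:
        raise ValueError("diameter and length must be non-negative")
    return math.pi * (diameter / 2.0) ** 2 * length / 1000.0


def excluded_sac_volume(
    geometry: ModelGeometry, graft_length: float | None = None
) -> float:
    """Excluded sac volume (cm³): spherical sac minus the graft cylinder.

    The graft length across the sac defaults to the aneurysm diameter, i.e.
    the graft spans the sphere diametrically.  Raises if the graft does not
    fit inside the sac (negative remainder).
    """
    if geometry.graft_diameter >= geometry.aneurysm_diameter:
        raise ValueError("graft diameter must be smaller than the aneurysm diameter")
    if graft_length is None:
        graft_length = geometry.aneurysm_diameter
    sac = sphere_volume(geometry.aneurysm_diameter)
    graft = cylinder_volume(geometry.graft_diameter, graft_length)
    excluded = sac - graft
    if excluded < 0:
        raise ValueError("graft volume exceeds sac volume")
    return excluded


def packing_state(
    n_plugs: int,
    plug_volume: float = PLUG_VOLUME_CM3,
    sac_volume: float = 20.0,
) -> PackingState:
    """Packing state for ``n_plugs`` plugs in a sac of ``sac_volume`` cm³.

    The exact nominal fraction is kept alongside the conventional rounded
    label (nearest multiple of 100%, with the canonical 15/30/45/60-plug
    counts mapped to 100–400%).
    """
    if n_plugs < 0:
        raise ValueError("plug count must be non-negative")
    if plug_volume < 0:
        raise ValueError("plug volume must be non-negative")
    if sac_volume <= 0:
        raise ValueError("sac volume must be positive")
    nominal = n_plugs * plug_volume / sac_volume * 100.0
    if n_plugs in LABEL_BY_PLUG_COUNT and plug_volume == PLUG_VOLUME_CM3:
        label = LABEL_BY_PLUG_COUNT[n_plugs]
    else:
        label = int(round(nominal / 100.0) * 100)
    return PackingState(
        n_plugs=n_plugs,
        plug_volume=plug_volume,
        sac_volume=sac_volume,
        nominal_fraction=nominal,
        label_fraction=label,
    )
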