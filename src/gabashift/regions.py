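"""Region-of-interest composition: bilateral averaging and volume-weighted composites.

Three functional cortical composites are built from ten component ROIs:
Association Cortex (DLPFC, OFC, MPFC, ACC), Sensory Cortex (PC, OC) and
the limbic Medial Temporal Lobe (AMY, HIP, ENT, PHG).  Composites are
volume-weighted means of the component outcome values; the shipped default
volumes are the study's mean sampled ROI volumes in mm^3, overridden by
subject-specific volumes when available.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "RegionSpec",
    "DEFAULT_VOLUMES_MM3",
    "DEFAULT_COMPOSITES",
    "bilateral_average",
    "composite_value",
    "composite_table",
    "load_region_config",
    "save_region_config",
]

# mean sampled ROI volumes (mm^3)
DEFAULT_VOLUMES_MM3 = {
    "DLPFC": 19390.0,
    "OFC": 10260.0,
    "MPFC": 5001.0,
    "ACC": 2587.0,
    "PC": 74583.0,
    "OC": 49286.0,
    "AMY": 2410.0,
    "HIP": 4729.0,
    "ENT": 960.0,
    "PHG": 6021.0,
}

DEFAULT_COMPOSITES = {
    "Association Cortex": ["DLPFC", "OFC", "MPFC", "ACC"],
    "Sensory Cortex": ["PC", "OC"],
    "Medial Temporal Lobe": ["AMY", "HIP", "ENT", "PHG"],
}


@dataclass(frozen=True)
class RegionSpec:
    """A named composite region with component members and their volumes."""

    name: str
    members: tuple
    volumes: tuple

    def __post_init__(self):
        if len(self.members) != len(self.volumes):
            raise ValueError("one volume per member required")
        if any(v <= 0 for v in self.volumes):
            raise ValueError("volumes must be positive")
        if len(set(self.members)) != len(self.members):
            raise ValueError("composite members must be distinct")


def bilateral_average(left_value: float, right_value: float) -> float:
    """Arithmetic mean of left and right hemisphere values for one region."""
    return 0.5 * (left_value + right_value)


def composite_value(component_values, component_volumes) -> float:
    """Volume-weighted mean: sum(v_i x_i) / sum(v_i)."""
    x = np.asarray(component_values, dtype=float)
    v = np.asarray(component_volumes, dtype=float)
    if x.shape != v.shape:
        raise ValueError("values and volumes must have equal length")
    if np.any(v <= 0):
        raise ValueError("volumes must be positive")
    return float(np.sum(v * x) / np.sum(v))


def region_specs(composites: dict | None = None, volumes: dict | None = None) -> list:
    """Build validated RegionSpec objects from (configurable) membership/volumes."""
    composites = composites or DEFAULT_COMPOSITES
    volumes = volumes or DEFAULT_VOLUMES_MM3
    specs = []
    seen = set()
    for name, members in composites.items():
        if seen.intersection(members):
            raise ValueError(f"composite {name}: members overlap another composite")
        seen.update(members)
        specs.append(
            RegionSpec(name=name, members=tuple(members), volumes=tuple(volumes[m] for m in members))
        )
    return specs


def composite_table(values_by_region: dict, composites: dict | None = None, volumes: dict | None = None) -> pd.DataFrame:
    """Append volume-weighted composite rows to per-region values.

    ``values_by_region`` maps component region -> scalar value.  Returns a
    DataFrame with columns region, value, is_composite; composite rows only
    include composites whose members are all present.
    """
    rows = [
        {"region": r, "value": v, "is_composite": False} for r, v in values_by_region.items()
    ]
    for spec in region_specs(composites, volumes):
        if all(m in values_by_region for m in spec.members):
            val = composite_value([values_by_region[m] for m in spec.members], spec.volumes)
            rows.append({"region": spec.name, "value": val, "is_composite": True})
    return pd.DataFrame(rows)


def load_region_config(path) -> tuple[dict, dict]:
    """Read composite membership and volumes from a YAML/JSON config file."""
    cfg = yaml.safe_load(Path(path).read_text())
    composites = cfg.get("composites", DEFAULT_COMPOSITES)
    volumes = cfg.get("volumes_mm3", DEFAULT_VOLUMES_MM3)
    region_specs(composites, volumes)  # validate
    return composites, volumes


def save_region_config(path, composites: dict | None = None, volumes: dict | None = None) -> None:
    cfg = {
        "composites": composites or DEFAULT_COMPOSITES,
        "volumes_mm3": volumes or DEFAULT_VOLUMES_MM3,
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
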