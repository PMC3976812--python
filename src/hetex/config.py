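"""Run configuration shared across the pipeline.

All defaults here are the package-wide conventions: 64 gray levels for
tumor-wise redigitization, unit Chebyshev distance and 26-connectivity for
the matrix builders, and a 3-voxel cube with 8 local levels for parametric
maps. CLI flags override config-file values which override these defaults.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

__all__ = ["HetexConfig", "load_config"]


@dataclasses.dataclass
class HetexConfig:
    levels: int = 64            # quantization.levels
    distance: int = 1           # matrix.distance (Chebyshev step)
    connectivity: int = 26      # matrix.connectivity (zones / neighborhoods)
    ngldm_a: int = 0            # dependence tolerance
    tfc_delta: float = 0.0      # gradient threshold for texture feature coding
    cube_edge: int = 3          # parametric map cube edge (odd)
    cube_levels: int = 8        # local redigitization levels per cube
    sul_scale: float = 1.0      # lean-mass / body-weight ratio for SUL_peak

    def replace(self, **kwargs) -> "HetexConfig":
        return dataclasses.replace(self, **kwargs)


_KEY_MAP = {
    "quantization.levels": "levels",
    "matrix.distance": "distance",
    "matrix.connectivity": "connectivity",
    "ngldm.a": "ngldm_a",
    "tfc.delta": "tfc_delta",
    "parametric.cube_edge": "cube_edge",
    "parametric.levels": "cube_levels",
    "suv.sul_scale": "sul_scale",
}


def load_config(path: str | Path | None) -> HetexConfig:
    """Load a config file (YAML mapping or ``key = value`` lines).

    Keys may use either the dotted external names (``quantization.levels``)
    or the attribute names (``levels``).
    """
    cfg = HetexConfig()
    if path is None:
        return cfg
    text = Path(path).read_text()
    try:
        import yaml
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ValueError
    except Exception:
        data = {}
        for line in text.splitlines():
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            data[key.strip()] = value.strip()
    updates = {}
    for key, value in _flatten(data).items():
        attr = _KEY_MAP.get(key, key)
        if not hasattr(cfg, attr):
            raise KeyError(f"unknown config key {key!r}")
        field_type = type(getattr(cfg, attr))
        updates[attr] = field_type(value)
    return cfg.replace(**updates)


def _flatten(data: dict, prefix: str = "") -> dict:
    out = {}
    for key, value in data.items():
        full = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, full + "."))
        else:
            out[full] = value
    return out
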