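"""Pipeline configuration: every tunable threshold in one flat structure.

Defaults target patent-style structure images rendered at roughly 40 px per
bond after the preprocessing upscale; most geometric thresholds are relative
to the median detected bond length and therefore scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields


@dataclass
class Config:
    # raster preprocessing
    pad: int = 16
    min_dim: int = 300
    binarize_threshold: str | int = "otsu"
    # circle detection
    circle_rmin: int = 10
    circle_rmax: int = 90
    circle_min_arc_deg: float = 200.0
    # FM line detection
    hough_rho_res: float = 2.0
    hough_theta_res: float = 2.0
    hough_min_votes: int = 10
    fm_angle_threshold: float = 6.0
    fm_dist_threshold: float = 3.0
    # bond typing
    multibond_angle_tol: float = 5.0
    multibond_lateral_frac: float = 0.35
    multibond_len_ratio: float = 0.6
    multibond_overlap: float = 0.6
    wedge_num_samples: int = 20
    wedge_center_fraction: float = 0.6
    wedge_min_max_width: int = 4
    wedge_min_ratio: float = 1.0
    dashed_max_angle: float = 20.0
    dashed_min_group: int = 4
    wavy_min_circles: int = 3
    # symbols
    noise_min_area: int = 4
    symbol_gap_factor: float = 0.6
    orient_tol: float = 15.0
    # resolve
    enum_limit: int = 20
    bp_sweeps: int = 50
    bp_damping: float = 0.5
    coverage_samples: int = 16

    @classmethod
    def from_file(cls, path: str) -> "Config":
        """Read a flat ``key = value`` config file (unknown keys rejected)."""
        cfg = cls()
        valid = {f.name: f.type for f in fields(cls)}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in valid:
                    raise KeyError(f"unknown config key {key!r}")
                current = getattr(cfg, key)
                if isinstance(current, bool):
                    setattr(cfg, key, value.lower() in ("1", "true", "yes"))
                elif isinstance(current, int):
                    setattr(cfg, key, int(value))
                elif isinstance(current, float):
                    setattr(cfg, key, float(value))
                else:
                    setattr(cfg, key, value)
        return cfg
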