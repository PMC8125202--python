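"""Run configuration: flat dotted keys in YAML, mirrored as CLI flags.

Defaults follow the validated settings of the measurement procedure:
curvature-flow time step 0.01 with 10 iterations, and a 0-50 degree tangent
sweep at 5 degree coarse / 0.5 degree fine steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

from .gap_measurement import ProfileConfig, SweepConfig
from .head_segmentation import SegmentationConfig
from .preprocess import DenoiseConfig
from .reference_geometry import GeometryConfig
from .volume_io import VOIBox


@dataclass
class RunConfig:
    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    sweep: SweepConfig = field(default_factory=SweepConfig)
    profile: ProfileConfig = field(default_factory=ProfileConfig)
    voi: Optional[VOIBox] = None
    laterality: Optional[str] = None

    @classmethod
    def from_flat(cls, flat: dict) -> "RunConfig":
        """Build from flat dotted keys, e.g. {"denoise.time_step": 0.02}."""
        def pick(prefix, klass, **renames):
            kwargs = {}
            for key, val in flat.items():
                if key.startswith(prefix + "."):
                    name = renames.get(key, key[len(prefix) + 1:])
                    kwargs[name] = val
            return klass(**kwargs)

        voi = None
        if all(k in flat for k in ("voi.x_range", "voi.y_range", "voi.z_range")):
            voi = VOIBox(
                x_range=tuple(flat["voi.x_range"]),
                y_range=tuple(flat["voi.y_range"]),
                z_range=tuple(flat["voi.z_range"]),
            )
        return cls(
            denoise=pick("denoise", DenoiseConfig),
            segmentation=pick("segmentation", SegmentationConfig),
            geometry=pick("geometry", GeometryConfig),
            sweep=pick("sweep", SweepConfig),
            profile=pick("profile", ProfileConfig),
            voi=voi,
            laterality=flat.get("laterality"),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            flat = yaml.safe_load(fh) or {}
        if not isinstance(flat, dict):
            raise ValueError("config file must contain a mapping of dotted keys")
        return cls.from_flat(flat)

    def to_flat(self) -> dict:
        flat = {
            "denoise.time_step": self.denoise.time_step,
            "denoise.iterations": self.denoise.iterations,
            "segmentation.components": self.segmentation.components,
            "segmentation.seed": self.segmentation.seed,
            "segmentation.tol": self.segmentation.tol,
            "segmentation.var_floor": self.segmentation.var_floor,
            "geometry.contact_tol_voxels": self.geometry.contact_tol_voxels,
            "sweep.theta_max": self.sweep.theta_max,
            "sweep.coarse_step": self.sweep.coarse_step,
            "sweep.fine_step": self.sweep.fine_step,
            "sweep.step_threshold_mm": self.sweep.step_threshold_mm,
            "profile.step_factor": self.profile.step_factor,
            "profile.peak_frac": self.profile.peak_frac,
            "profile.min_offset_samples": self.profile.min_offset_samples,
        }
        if self.voi is not None:
            flat["voi.x_range"] = list(self.voi.x_range)
            flat["voi.y_range"] = list(self.voi.y_range)
            flat["voi.z_range"] = list(self.voi.z_range)
        if self.laterality is not None:
            flat["laterality"] = self.laterality
        return flat
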