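"""Run configuration and provenance.

One :class:`RunConfig` carries every tunable of the pipeline; all
randomness flows from its single root seed, split deterministically per
stage, so a run is reproducible from the config file alone.  Defaults are
the standard analysis constants: 48/6/1.2/0 box counting, 2.56 um pixels,
4 cm^-1 spectral step, windows 1720-1470 / 1299-1184 / 1360-1184 cm^-1.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InvalidSpecError
from .types import BoxCountConfig

_STAGE_SALT = {"simulate": 1, "morpho": 2, "ftir": 3, "stats": 4, "pipeline": 5}


@dataclass
class RunConfig:
    seed: int = 0
    voxel_size_um: float = 0.89
    pixel_size_um: float = 2.56
    wavenumber_step_cm1: float = 4.0
    box_initial_px: int = 48
    box_smallest_px: int = 6
    box_scale_factor: float = 1.2
    box_grid_translation: int = 0
    hca_k: int = 2
    protein_window: tuple[float, float] = (1720.0, 1470.0)
    collagen_window: tuple[float, float] = (1299.0, 1184.0)
    amide3_window: tuple[float, float] = (1360.0, 1184.0)
    alpha_helix_centroid_cm1: float = 1319.0
    sg_window_points: int = 9
    sg_polyorder: int = 3
    mil_directions: int = 512
    mil_line_spacing_vox: float = 6.0
    output_dir: str = "stromakit_out"
    log_level: str = "INFO"

    def box_config(self) -> BoxCountConfig:
        return BoxCountConfig(
            initial_box_px=self.box_initial_px,
            smallest_box_px=self.box_smallest_px,
            scale_factor=self.box_scale_factor,
            grid_translation=self.box_grid_translation,
        )

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the root seed."""
        if stage not in _STAGE_SALT:
            raise InvalidSpecError(f"unknown stage {stage!r}")
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "little") % (2**31 - 1)

    def to_yaml(self, path=None) -> str:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "RunConfig":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and "\n" not in str(source) else str(source)
        d = yaml.safe_load(text)
        if not isinstance(d, dict):
            raise InvalidSpecError("config file must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise InvalidSpecError(f"unknown config keys: {sorted(unknown)}")
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


def provenance_record(config: RunConfig, stage: str, inputs: dict[str, str] | None = None,
                      with_timestamp: bool = True) -> dict:
    """Provenance stamp attached to every written artifact."""
    import numpy
    import scipy

    from . import __version__

    rec = {
        "stromakit_version": __version__,
        "numpy_version": numpy.__version__,
        "scipy_version": scipy.__version__,
        "stage": stage,
        "stage_seed": config.stage_seed(stage),
        "config": yaml.safe_load(config.to_yaml()),
        "input_digests": inputs or {},
    }
    if with_timestamp:
        rec["timestamp_utc"] = datetime.datetime.now(datetime.timezone.utc).isoformat()
    return rec
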