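"""Pipeline configuration: YAML schema, validation, and hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    """Everything one pipeline run needs.

    Anchors are the three trunk positions (first two trunks of row 1, first
    trunk of row 2), supplied either as pixel ``(row, col)`` pairs
    (``anchors_px``) or projected ``(x, y)`` pairs (``anchors_xy``).
    """

    raster: Path
    anchors_px: list[tuple[float, float]] | None = None
    anchors_xy: list[tuple[float, float]] | None = None
    d_intra: float = 2.0
    d_inter: float = 6.0
    max_crown_diameter: float = 3.0
    band_names: list[str] | None = None
    k: int = 3
    seed: int = 0
    out_dir: Path = Path("orchard_out")
    expected_tree_count: int | None = None
    validation_truth_mask: Path | None = None
    validation_windows_csv: Path | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.raster = Path(self.raster)
        self.out_dir = Path(self.out_dir)
        if self.validation_truth_mask is not None:
            self.validation_truth_mask = Path(self.validation_truth_mask)
        if self.validation_windows_csv is not None:
            self.validation_windows_csv = Path(self.validation_windows_csv)
        if self.k < 2:
            raise ConfigError(f"k must be >= 2, got {self.k}")
        anchors = self.anchors_px if self.anchors_px is not None else self.anchors_xy
        if anchors is None:
            raise ConfigError("config must supply anchors_px or anchors_xy")
        if len(anchors) != 3:
            raise ConfigError("exactly three anchor positions are required "
                              "(row-1 trunk 1, row-1 trunk 2, row-2 trunk 1)")
        for d, name in ((self.d_intra, "d_intra"), (self.d_inter, "d_inter"),
                        (self.max_crown_diameter, "max_crown_diameter")):
            if d <= 0:
                raise ConfigError(f"{name} must be > 0, got {d}")

    def check_paths(self) -> None:
        if not self.raster.exists():
            raise ConfigError(f"input raster not found: {self.raster}")
        for p in (self.validation_truth_mask, self.validation_windows_csv):
            if p is not None and not p.exists():
                raise ConfigError(f"validation input not found: {p}")

    def canonical_dict(self) -> dict:
        d = asdict(self)
        for key in ("raster", "out_dir", "validation_truth_mask",
                    "validation_windows_csv"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path, **overrides) -> PipelineConfig:
    """Load a pipeline config from YAML; keyword overrides win."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} is not a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in raw.items() if k in known}
    kwargs["extra"] = {k: v for k, v in raw.items() if k not in known}
    kwargs.update({k: v for k, v in overrides.items() if v is not None})
    if "raster" not in kwargs:
        raise ConfigError("config must name the input raster")
    # paths in the config are relative to the config file
    base = path.parent
    for key in ("raster", "out_dir", "validation_truth_mask",
                "validation_windows_csv"):
        if key in kwargs and kwargs[key] is not None:
            p = Path(kwargs[key])
            kwargs[key] = p if p.is_absolute() else base / p
    return PipelineConfig(**kwargs)
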