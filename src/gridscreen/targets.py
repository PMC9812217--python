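"""Target-list interchange schema and tile→atlas coordinate plumbing.

The ML detectors this package emulates exchange their results as JSON: a
top-level object ``{schema_version, magnification_level, image_shape,
targets: [...]}`` where each target carries a centre, optional area and
mean intensity, a score in [0, 1] and a free-form metadata map.  The same
file format is used at every magnification level of the multi-scale
imaging hierarchy (atlas → square → hole).

Tile transforms are pure translations: an atlas mosaic is acquired tile by
tile and each tile's pixel coordinates map into atlas coordinates by adding
the tile offset.
"""

from __future__ import annotations

import json
import math
from typing import Any, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator, model_validator

from .errors import SchemaValidationError

SCHEMA_VERSION = "1.0"

__all__ = [
    "SCHEMA_VERSION",
    "Target",
    "TargetList",
    "TileTransform",
    "write_target_list",
    "read_target_list",
    "write_tile_transforms",
    "read_tile_transforms",
    "tile_to_atlas",
    "atlas_to_tile",
]


class Target(BaseModel):
    """One target at some magnification level.

    ``kind`` distinguishes acquisition targets from the focus target that
    is placed on film between holes.
    """

    model_config = ConfigDict(extra="forbid")

    center: tuple[float, float]
    score: float
    area: Optional[float] = None
    mean_intensity: Optional[float] = None
    kind: Literal["acquisition", "focus"] = "acquisition"
    extra: dict[str, Any] = Field(default_factory=dict)

    @field_validator("center")
    @classmethod
    def _finite_center(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not all(math.isfinite(c) for c in v):
            raise ValueError("center coordinates must be finite")
        return v

    @field_validator("score")
    @classmethod
    def _score_range(cls, v: float) -> float:
        if not (math.isfinite(v) and 0.0 <= v <= 1.0):
            raise ValueError("score must be finite and within [0, 1]")
        return v

    @field_validator("area")
    @classmethod
    def _positive_area(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (math.isfinite(v) and v > 0):
            raise ValueError("area must be positive and finite")
        return v


class TargetList(BaseModel):
    """A validated set of targets tied to the image/atlas they live on."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = SCHEMA_VERSION
    magnification_level: Literal["atlas", "square", "hole"]
    image_shape: tuple[int, int]  # (rows, columns)
    targets: list[Target] = Field(default_factory=list)

    @model_validator(mode="after")
    def _centers_in_bounds(self) -> "TargetList":
        h, w = self.image_shape
        if h < 1 or w < 1:
            raise ValueError("image_shape must be at least 1x1")
        for i, t in enumerate(self.targets):
            x, y = t.center
            # pixel-area convention: the image spans [-0.5, w-0.5) x [-0.5, h-0.5)
            if not (-0.5 <= x <= w - 0.5 and -0.5 <= y <= h - 0.5):
                raise ValueError(
                    f"targets[{i}].center {t.center} outside image bounds {(w, h)}"
                )
        return self


def write_target_list(target_list: TargetList, path: str) -> None:
    """Serialise a target list to JSON (schema version recorded in file)."""
    with open(path, "w") as fh:
        fh.write(target_list.model_dump_json(indent=1))


def read_target_list(path: str) -> TargetList:
    """Read and validate a target-list JSON file.

    Raises
    ------
    SchemaValidationError
        Naming the offending fields when validation fails.
    """
    with open(path) as fh:
        try:
            payload = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaValidationError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return TargetList.model_validate(payload)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(loc) for loc in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise SchemaValidationError(f"{path}: invalid target list (fields: {fields})") from exc


class TileTransform(BaseModel):
    """Placement of one mosaic tile in atlas coordinates.

    ``offset`` translates tile pixel coordinates into atlas coordinates.
    ``exclusive_bounds`` optionally restricts the tile to the atlas region
    it owns (the Voronoi cell of the tile grid) so that overlapping mosaic
    strips are counted once during detection; ``(x0, y0, x1, y1)``,
    half-open, in atlas coordinates.
    """

    model_config = ConfigDict(extra="forbid")

    tile_id: str
    offset: tuple[float, float]
    overlap_fraction: float = 0.0
    tile_shape: Optional[tuple[int, int]] = None  # (rows, columns)
    exclusive_bounds: Optional[tuple[float, float, float, float]] = None

    @field_validator("offset")
    @classmethod
    def _finite_offset(cls, v: tuple[float, float]) -> tuple[float, float]:
        if not all(math.isfinite(c) for c in v):
            raise ValueError("offset must be finite")
        return v

    @field_validator("overlap_fraction")
    @classmethod
    def _overlap_range(cls, v: float) -> float:
        if not (0.0 <= v < 0.5):
            raise ValueError("overlap_fraction must be in [0, 0.5)")
        return v

    def footprint(self) -> tuple[float, float, float, float]:
        """Tile pixel footprint (x0, y0, x1, y1) in atlas coordinates, half-open."""
        if self.tile_shape is None:
            raise ValueError(f"tile {self.tile_id!r} has no tile_shape")
        h, w = self.tile_shape
        ox, oy = self.offset
        return (ox, oy, ox + w, oy + h)


def tile_to_atlas(point: tuple[float, float], transform: TileTransform) -> tuple[float, float]:
    """Map a point from tile coordinates into atlas coordinates."""
    return (point[0] + transform.offset[0], point[1] + transform.offset[1])


def atlas_to_tile(point: tuple[float, float], transform: TileTransform) -> tuple[float, float]:
    """Inverse of :func:`tile_to_atlas`."""
    return (point[0] - transform.offset[0], point[1] - transform.offset[1])


def write_tile_transforms(transforms: list[TileTransform], path: str) -> None:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "transforms": [t.model_dump() for t in transforms],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_tile_transforms(path: str) -> list[TileTransform]:
    with open(path) as fh:
        payload = json.load(fh)
    try:
        return [TileTransform.model_validate(t) for t in payload["transforms"]]
    except (KeyError, ValidationError) as exc:
        raise SchemaValidationError(f"{path}: invalid tile transforms: {exc}") from exc


def targets_from_arrays(
    centers: np.ndarray,
    scores: np.ndarray,
    magnification_level: Literal["atlas", "square", "hole"],
    image_shape: tuple[int, int],
    **per_target: Any,
) -> TargetList:
    """Convenience constructor from parallel arrays (used by the CLI)."""
    targets = []
    for i, (c, s) in enumerate(zip(np.asarray(centers), np.asarray(scores))):
        extra_fields = {k: v[i] for k, v in per_target.items()}
        targets.append(Target(center=(float(c[0]), float(c[1])), score=float(s), **extra_fields))
    return TargetList(
        magnification_level=magnification_level, image_shape=image_shape, targets=targets
    )
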