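"""Unattended multi-grid screening workflow (dry-run state machine).

Drives the full multi-scale imaging hierarchy over directories of (real or
synthetic) images, one grid at a time: atlas tiles → square detection and
seam merging → area filter → grouped selection of ``N_s`` squares → one
hole-magnification image per square → lattice detection → exclusion border
→ ice-stratified sampling of ``N_h`` holes → exposure-target emission with
a lattice-centred focus target.  Microscope hardware actions (grid
exchange, eucentric height, focusing, aperture handling) are represented
as no-op events on a simulated clock with configurable durations, so the
state machine keeps its shape without a microscope.

Robustness contract: any failure inside a square or a grid is logged as an
error event followed by a continuation event, and the queue always runs to
completion, after which a completion message is emitted (stdout/file by
default; the notifier is pluggable).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Literal, Optional, Sequence

from pydantic import BaseModel, ConfigDict, ValidationError

from .errors import (
    ConfigurationError,
    FocusPlacementError,
    GridScreenError,
    SchemaValidationError,
)
from .holes import apply_exclusion_border, detect_hole_lattice, place_focus, sample_holes
from .image_io import read_image
from .selection import SelectionConfig, filter_squares_by_area, group_and_select
from .squares import detect_squares, merge_tile_squares
from .targets import read_tile_transforms

__all__ = [
    "WorkflowSettings",
    "GridEntry",
    "SessionRecord",
    "QualityTable",
    "import_settings",
    "export_settings",
    "run_autoscreen",
    "summarize_hole_quality",
    "mean_percentage_good",
]

HOLE_LABELS = ("good", "empty", "contaminated", "cracked")


class HoleFilterSettings(BaseModel):
    """Hole-magnification filters applied before sampling."""

    model_config = ConfigDict(extra="forbid")

    min_inside_fraction: float = 0.80
    ice_min: Optional[float] = None
    ice_max: Optional[float] = None
    score_min: Optional[float] = None  # disabled by default


class WorkflowSettings(BaseModel):
    """Everything recallable from an example session."""

    model_config = ConfigDict(extra="forbid")

    schema_version: str = "1.0"
    selection: SelectionConfig = SelectionConfig()
    hole_filters: HoleFilterSettings = HoleFilterSettings()
    patch_halfwidth: int = 2
    match_tolerance: Optional[float] = None  # px; default 1% of tile width
    #: simulated hardware durations, minutes
    grid_exchange_min: float = 5.0
    square_acquisition_min: float = 1.0
    exposure_min: float = 0.5


def export_settings(settings: WorkflowSettings, path: str) -> None:
    """Write settings so a later session can recall them (round-trip exact)."""
    with open(path, "w") as fh:
        fh.write(settings.model_dump_json(indent=1))


def import_settings(path: str) -> WorkflowSettings:
    """Recall settings from a specified example-session file."""
    try:
        with open(path) as fh:
            payload = json.load(fh)
    except FileNotFoundError:
        raise ConfigurationError(f"example session file not found: {path}") from None
    except json.JSONDecodeError as exc:
        raise ConfigurationError(f"{path}: not valid JSON: {exc}") from exc
    try:
        return WorkflowSettings.model_validate(payload)
    except (ValidationError, ConfigurationError) as exc:
        raise ConfigurationError(f"{path}: invalid settings: {exc}") from exc


@dataclass
class GridEntry:
    """One grid in the screening queue."""

    grid_id: str
    label: str = ""
    project: str = ""
    task: Literal["full_MSI", "atlas_only"] = "full_MSI"
    tile_paths: list[str] = field(default_factory=list)
    transforms_path: str = ""
    #: hole-magnification image "acquired" for the k-th selected square
    #: (cycled when fewer images than squares are provided)
    hole_image_paths: list[str] = field(default_factory=list)


@dataclass
class Event:
    time_min: float
    kind: str
    detail: str = ""


@dataclass
class SquareEntry:
    square_index: int
    center: tuple[float, float]
    area: float
    score: float
    hole_image: str = ""
    sampled_holes: list[tuple[float, float]] = field(default_factory=list)
    focus: Optional[tuple[float, float]] = None
    exposure_targets: int = 0


@dataclass
class SessionRecord:
    """Audit trail of one grid's screening session."""

    grid_id: str
    config: dict
    squares: list[SquareEntry] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    completion_message: str = ""

    @property
    def exposure_target_count(self) -> int:
        return sum(sq.exposure_targets for sq in self.squares)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)


class _Clock:
    """Simulated session clock, minutes since queue start."""

    def __init__(self) -> None:
        self.t = 0.0

    def advance(self, minutes: float) -> float:
        self.t += minutes
        return self.t


def _derived_seed(seed: int, grid_id: str, square_index: int) -> int:
    digest = hashlib.sha256(f"{seed}:{grid_id}:{square_index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_autoscreen(
    queue: Sequence[GridEntry],
    settings: WorkflowSettings,
    seed: int = 0,
    notifier: Optional[Callable[[str], None]] = None,
) -> list[SessionRecord]:
    """Screen every grid in the queue unattended; never aborts mid-queue.

    ``atlas_only`` grids stop after square detection and merging.  A
    failure inside any square or grid is logged and the run continues; the
    completion message is emitted through ``notifier`` (default: print)
    after the last grid even for an empty queue.
    """
    notifier = notifier or print
    clock = _Clock()
    records: list[SessionRecord] = []
    for entry in queue:
        record = SessionRecord(
            grid_id=entry.grid_id,
            config=settings.model_dump(),
        )
        records.append(record)
        try:
            _screen_grid(entry, settings, seed, clock, record)
        except Exception as exc:  # noqa: BLE001 - queue isolation
            record.events.append(Event(clock.t, "error", f"grid failed: {exc}"))
            record.events.append(Event(clock.t, "continue", "moving to next grid"))
        record.events.append(Event(clock.advance(settings.grid_exchange_min),
                                   "grid_unloaded", entry.grid_id))
    message = f"Autoscreen complete: {len(records)} grid(s) screened."
    for record in records:
        record.completion_message = message
    notifier(message)
    return records


def _screen_grid(
    entry: GridEntry,
    settings: WorkflowSettings,
    seed: int,
    clock: _Clock,
    record: SessionRecord,
) -> None:
    ev = record.events
    ev.append(Event(clock.advance(settings.grid_exchange_min), "grid_loaded", entry.grid_id))
    transforms = read_tile_transforms(entry.transforms_path)

    candidates = []
    for path, transform in zip(entry.tile_paths, transforms):
        try:
            tile = read_image(path)
        except (GridScreenError, OSError, ValueError) as exc:
            ev.append(Event(clock.t, "error", f"unreadable tile {path}: {exc}"))
            ev.append(Event(clock.t, "continue", "tile skipped"))
            continue
        candidates.extend(detect_squares(tile, transform))
    ev.append(Event(clock.t, "squares_detected", f"{len(candidates)} candidates"))
    merged = merge_tile_squares(candidates, transforms, settings.match_tolerance)
    ev.append(Event(clock.t, "squares_merged", f"{len(merged)} squares"))

    if entry.task == "atlas_only":
        ev.append(Event(clock.t, "atlas_only_done", ""))
        return

    config = settings.selection
    if config.area_range is not None:
        merged = filter_squares_by_area(merged, config.area_range)
    if not merged:
        ev.append(Event(clock.t, "error", "no squares after area filter"))
        ev.append(Event(clock.t, "continue", "grid skipped"))
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        selected = group_and_select(merged, config)
    ev.append(Event(clock.t, "squares_selected", f"{len(selected)} of N_s={config.N_s}"))

    for k, square in enumerate(selected):
        sq = SquareEntry(
            square_index=k,
            center=square.centroid,
            area=square.area,
            score=square.score,
        )
        record.squares.append(sq)
        ev.append(Event(clock.advance(settings.square_acquisition_min),
                        "eucentric_height_set", f"square {k}"))
        if not entry.hole_image_paths:
            ev.append(Event(clock.t, "error", f"square {k}: no hole image available"))
            ev.append(Event(clock.t, "continue", "square skipped"))
            continue
        path = entry.hole_image_paths[k % len(entry.hole_image_paths)]
        sq.hole_image = path
        try:
            hole_img = read_image(path)
            lattice, holes = detect_hole_lattice(
                hole_img, patch_halfwidth=settings.patch_halfwidth
            )
        except (GridScreenError, OSError, ValueError) as exc:
            ev.append(Event(clock.t, "error", f"square {k}: {exc}"))
            ev.append(Event(clock.t, "continue", "square skipped"))
            continue
        kept = apply_exclusion_border(
            holes, hole_img.shape, settings.hole_filters.min_inside_fraction
        )
        filters = {
            "ice_min": settings.hole_filters.ice_min,
            "ice_max": settings.hole_filters.ice_max,
            "score_min": settings.hole_filters.score_min,
        }
        sampled = sample_holes(
            kept, config.N_h, filters, seed=_derived_seed(seed, entry.grid_id, k)
        )
        if not sampled:
            ev.append(Event(clock.t, "error", f"square {k}: no holes survive the filters"))
            ev.append(Event(clock.t, "continue", "square skipped"))
            continue
        try:
            focus = place_focus(lattice, hole_img.shape)
        except FocusPlacementError as exc:
            ev.append(Event(clock.t, "warning", f"square {k}: {exc}; using image centre"))
            focus = hole_img.center
        sq.sampled_holes = [h.center for h in sampled]
        sq.focus = focus
        sq.exposure_targets = len(sampled)
        ev.append(Event(clock.advance(settings.exposure_min * len(sampled)),
                        "exposures_acquired", f"square {k}: {len(sampled)} targets"))
    ev.append(Event(clock.t, "grid_done",
                    f"{record.exposure_target_count} exposure targets"))


# ---------------------------------------------------------------------------
# quality accounting


@dataclass(frozen=True)
class QualityTable:
    """Good/empty/contaminated/cracked accounting for one session."""

    good: int
    empty: int
    contaminated: int
    cracked: int

    @property
    def total(self) -> int:
        return self.good + self.empty + self.contaminated + self.cracked

    @property
    def percentage_good(self) -> float:
        """100 * good / total, rounded half-up to one decimal for display."""
        if self.total == 0:
            return 0.0
        frac = Decimal(100 * self.good) / Decimal(self.total)
        return float(frac.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))

    def as_row(self) -> dict:
        return {
            "good": self.good,
            "empty": self.empty,
            "contaminated": self.contaminated,
            "cracked": self.cracked,
            "total": self.total,
            "percentage_good": self.percentage_good,
        }


def summarize_hole_quality(annotations: Sequence[str]) -> QualityTable:
    """Count hole-quality labels into a :class:`QualityTable`.

    Labels must be in ``{good, empty, contaminated, cracked}``; anything
    else raises ``SchemaValidationError``.
    """
    counts = dict.fromkeys(HOLE_LABELS, 0)
    for lab in annotations:
        if lab not in counts:
            raise SchemaValidationError(
                f"unknown hole label {lab!r}; expected one of {HOLE_LABELS}"
            )
        counts[lab] += 1
    return QualityTable(**counts)


def mean_percentage_good(tables: Sequence[QualityTable]) -> float:
    """Mean of per-session displayed percentages, half-up to one decimal."""
    if not tables:
        return 0.0
    vals = [Decimal(str(t.percentage_good)) for t in tables]
    mean = sum(vals) / Decimal(len(vals))
    return float(mean.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
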