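"""Area filtering, grouping and ranked selection of mesh squares.

Screening wants diversity: squares are partitioned into ``N_g`` groups by a
chosen parameter (square area, mean intensity or detector score) and the
highest-scoring squares of each group are taken until ``N_s`` squares are
targeted in total.  With ``N_g = 4`` and ``N_s = 8``, two squares come from
each group.  Two grouping modes exist:

* ``equal_count`` — groups are contiguous runs of as-equal-as-possible size
  after sorting by the group parameter (the de-novo screening default);
* ``predefined_range`` — groups are ``N_g`` equal-width bins spanning a
  user-supplied area range.  This serves prior knowledge (``N_g = 1`` with
  a restricted range collects only the best squares of the right size) and
  unbalanced grids where, say, 90% of squares are dry: equal-count groups
  would mostly contain dry squares, while area bins keep the icy range
  represented.  Empty bins are skipped (with a warning) rather than
  refilled from other bins, so the total may fall below ``N_s``.
"""

from __future__ import annotations

import warnings
from typing import Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .errors import ConfigurationError
from .squares import SquareCandidate

__all__ = ["SelectionConfig", "filter_squares_by_area", "group_and_select"]

GroupParameter = Literal["area", "mean_intensity", "score"]


class SelectionConfig(BaseModel):
    """Targeting parameters of one screening session.

    ``N_g`` groups of squares, ``N_s`` squares targeted in total, ``N_h``
    holes sampled per square.
    """

    model_config = ConfigDict(extra="forbid")

    N_g: int = 4
    N_s: int = 4
    N_h: int = 5
    group_parameter: GroupParameter = "area"
    grouping_mode: Literal["equal_count", "predefined_range"] = "equal_count"
    area_range: Optional[tuple[float, float]] = None
    rank_parameter: Literal["score"] = "score"
    seed: int = 0

    @model_validator(mode="after")
    def _consistent(self) -> "SelectionConfig":
        if self.N_g < 1 or self.N_s < 1 or self.N_h < 1:
            raise ConfigurationError("N_g, N_s and N_h must all be positive")
        if self.N_s < self.N_g:
            raise ConfigurationError(
                f"N_s={self.N_s} < N_g={self.N_g}: every group must contribute at least one square"
            )
        if self.area_range is not None and self.area_range[0] > self.area_range[1]:
            raise ConfigurationError("area_range must satisfy min <= max")
        if self.grouping_mode == "predefined_range" and self.area_range is None:
            raise ConfigurationError("predefined_range grouping requires area_range")
        return self


def filter_squares_by_area(
    squares: list[SquareCandidate], area_range: tuple[float, float]
) -> list[SquareCandidate]:
    """Keep exactly the squares with area inside ``area_range`` (inclusive)."""
    lo, hi = area_range
    if lo > hi:
        raise ConfigurationError("area_range must satisfy min <= max")
    return [s for s in squares if lo <= s.area <= hi]


def _param(square: SquareCandidate, name: GroupParameter) -> float:
    return {"area": square.area, "mean_intensity": square.mean_intensity,
            "score": square.score}[name]


def _sort_key(square: SquareCandidate, name: GroupParameter) -> tuple:
    # deterministic total order: parameter, then larger area, lower y, lower x
    return (_param(square, name), -square.area, square.centroid[1], square.centroid[0])


def _rank_key(square: SquareCandidate) -> tuple:
    # within-group ranking: higher score first; ties to larger area, lower y, lower x
    return (-square.score, -square.area, square.centroid[1], square.centroid[0])


def group_and_select(
    squares: list[SquareCandidate], config: SelectionConfig
) -> list[SquareCandidate]:
    """Partition squares into ``N_g`` groups and take the best per group.

    Returns up to ``N_s`` squares — exactly ``N_s`` whenever enough squares
    are available (equal_count mode) or the bins are populated
    (predefined_range mode) — ordered by group, then descending score.
    """
    if not squares:
        raise ConfigurationError("no squares to select from (empty after filtering)")

    if config.grouping_mode == "equal_count":
        ordered = sorted(squares, key=lambda s: _sort_key(s, config.group_parameter))
        n_groups = min(config.N_g, len(ordered))
        groups = [list(g) for g in np.array_split(np.arange(len(ordered)), n_groups)]
        groups = [[ordered[i] for i in g] for g in groups]
        redistribute = True
    else:
        lo, hi = config.area_range
        edges = np.linspace(lo, hi, config.N_g + 1)
        groups = []
        for g in range(config.N_g):
            upper_ok = (
                (lambda a, e=edges[g + 1]: a <= e) if g == config.N_g - 1
                else (lambda a, e=edges[g + 1]: a < e)
            )
            members = [s for s in squares if edges[g] <= s.area and upper_ok(s.area)]
            if not members:
                warnings.warn(
                    f"area bin [{edges[g]:.1f}, {edges[g + 1]:.1f}] contains no squares; "
                    "selection will fall short of N_s",
                    stacklevel=2,
                )
            groups.append(members)
        redistribute = False

    for g in groups:
        g.sort(key=_rank_key)

    # per-group quotas: floor(N_s / N_g) each, remainder (one each) to the
    # groups with the best top score
    n_groups = len(groups)
    base, rem = divmod(config.N_s, n_groups)
    order_by_best = sorted(
        range(n_groups),
        key=lambda gi: _rank_key(groups[gi][0]) if groups[gi] else (np.inf,),
    )
    quotas = [base] * n_groups
    for gi in order_by_best[:rem]:
        quotas[gi] += 1

    taken = [g[:q] for g, q in zip(groups, quotas)]
    if redistribute:
        # groups short of their quota hand the deficit to the group with the
        # best remaining candidate, repeatedly, so the total reaches
        # min(N_s, available)
        want = min(config.N_s, len(squares))
        while sum(len(t) for t in taken) < want:
            best_gi, best_key = None, None
            for gi, g in enumerate(groups):
                if len(taken[gi]) < len(g):
                    key = _rank_key(g[len(taken[gi])])
                    if best_key is None or key < best_key:
                        best_gi, best_key = gi, key
            taken[best_gi].append(groups[best_gi][len(taken[best_gi])])

    out: list[SquareCandidate] = []
    for t in taken:
        out.extend(t)
    return out
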