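"""Fuzzy Linear membership transform and Fuzzy Product overlay.

A raw gridded layer (an effort metric, or a Persistence Index map) is
rescaled to a [0, 1] possibility scale with the Fuzzy Linear membership
function anchored at (min, max):

    mu(x) = 0                      if x < min
    mu(x) = 1                      if x > max
    mu(x) = (x - min)/(max - min)  otherwise

Two or more membership layers on the same grid and time frame are combined
cellwise with the Fuzzy Product (their product), so a value near 1 flags a
cell where *all* criteria are simultaneously high — here, intense fishing
effort coinciding with a persistent unwanted-catch hotspot — and 0 means
no overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import math

from .grid import StudyGrid, TimeFrame
from .effort import EffortLayer
from .uwc import PersistenceLayer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FuzzyTransformSpec:
    """Anchors of a Fuzzy Linear transform and where they came from."""

    min: float
    max: float
    source: str = ""

    def __post_init__(self):
        if not (math.isfinite(self.min) and math.isfinite(self.max)):
            raise ValueError("fuzzy anchors must be finite")
        if self.min > self.max:
            raise ValueError(f"min {self.min} > max {self.max}")


@dataclass
class FuzzyLayer:
    """Per-cell memberships in [0, 1] for one time frame."""

    frame: TimeFrame
    memberships: dict[int, float] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        bad = {c: m for c, m in self.memberships.items() if not 0.0 <= m <= 1.0}
        if bad:
            raise ValueError(f"memberships outside [0,1]: {bad}")


def fuzzy_linear_value(x: float, spec: FuzzyTransformSpec) -> float:
    """The piecewise Fuzzy Linear membership of a single value."""
    if spec.min == spec.max:
        # Degenerate distribution: a constant positive layer is everywhere
        # maximal, a zero layer everywhere null.
        return 1.0 if x > 0 else 0.0
    if x < spec.min:
        return 0.0
    if x > spec.max:
        return 1.0
    return (x - spec.min) / (spec.max - spec.min)


def fuzzy_linear(
    values: dict[int, float], spec: FuzzyTransformSpec, frame: TimeFrame,
    provenance: str = "",
) -> FuzzyLayer:
    """Apply the Fuzzy Linear transform to a gridded layer."""
    if spec.min == spec.max:
        logger.warning(
            "degenerate fuzzy anchors (min = max = %g) for %s: memberships set "
            "to 1 where values are positive", spec.min, provenance or "layer"
        )
    return FuzzyLayer(
        frame,
        {c: fuzzy_linear_value(v, spec) for c, v in values.items()},
        provenance,
    )


def fuzzy_product(layers: list[FuzzyLayer]) -> FuzzyLayer:
    """Cellwise product of two or more membership layers on one frame."""
    if len(layers) < 2:
        raise ValueError("fuzzy product needs at least two layers")
    frames = {l.frame for l in layers}
    if len(frames) > 1:
        raise ValueError(f"mismatched time frames: {sorted(map(str, frames))}")
    domains = [set(l.memberships) for l in layers]
    if any(d != domains[0] for d in domains[1:]):
        raise ValueError("fuzzy product requires identical cell domains")
    out: dict[int, float] = {}
    for c in domains[0]:
        p = 1.0
        for l in layers:
            p *= l.memberships[c]
        out[c] = p
    prov = " × ".join(l.provenance or "?" for l in layers)
    return FuzzyLayer(frames.pop(), out, prov)


def _dense(values: dict[int, float], grid: StudyGrid) -> dict[int, float]:
    """Layer values over every grid cell, absent cells as 0."""
    return {int(c): float(values.get(int(c), 0.0)) for c in grid.cell_ids}


def anchors_from_values(values_iter, source: str) -> FuzzyTransformSpec:
    vals = [v for vs in values_iter for v in vs]
    if not vals:
        raise ValueError(f"no values to anchor the fuzzy transform for {source}")
    return FuzzyTransformSpec(min(vals), max(vals), source)


def fuzzy_overlay_pipeline(
    effort_layers: dict[TimeFrame, EffortLayer],
    pi_layer: PersistenceLayer,
    grid: StudyGrid,
    anchor_mode: str = "global",
) -> dict[TimeFrame, FuzzyLayer]:
    """Fuzzy-transform effort and PI, then take their Fuzzy Product per frame.

    The PI layer is held constant across frames (unwanted-catch maps are
    treated as stable across seasons relative to effort).  Anchors are the
    min/max over all grid cells: with ``anchor_mode="global"`` the effort
    anchors pool every frame so overlay values are comparable across time;
    ``"per_frame"`` anchors each frame to its own distribution.  When the
    PI layer carries a year range, it must cover every effort year
    (coherent, fully overlapping time ranges).
    """
    if anchor_mode not in ("global", "per_frame"):
        raise ValueError(f"anchor_mode must be 'global' or 'per_frame', got {anchor_mode!r}")
    if not effort_layers:
        raise ValueError("no effort layers supplied")
    metrics = {l.metric for l in effort_layers.values()}
    if len(metrics) > 1:
        raise ValueError(f"mixed effort metrics: {sorted(metrics)}")
    metric = metrics.pop()
    if pi_layer.years:
        missing = {f.year for f in effort_layers} - set(pi_layer.years)
        if missing:
            raise ValueError(
                "effort and UWC time ranges must overlap completely: effort "
                f"years {sorted(missing)} are not covered by the PI series "
                f"{pi_layer.years}"
            )

    dense_effort = {
        frame: _dense(layer.values, grid) for frame, layer in effort_layers.items()
    }
    dense_pi = _dense(pi_layer.pi, grid)
    pi_spec = anchors_from_values([dense_pi.values()], f"pi:{pi_layer.species}")
    if anchor_mode == "global":
        effort_spec = anchors_from_values(
            [v.values() for v in dense_effort.values()], f"effort:{metric}"
        )

    out: dict[TimeFrame, FuzzyLayer] = {}
    for frame in sorted(dense_effort, key=str):
        spec = (
            effort_spec
            if anchor_mode == "global"
            else anchors_from_values(
                [dense_effort[frame].values()], f"effort:{metric}:{frame}"
            )
        )
        mu_e = fuzzy_linear(dense_effort[frame], spec, frame, metric)
        mu_p = fuzzy_linear(dense_pi, pi_spec, frame, f"pi:{pi_layer.species}")
        out[frame] = fuzzy_product([mu_e, mu_p])
    return out
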