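"""Synthetic contour shapes and controlled alterations.

This module generates the benchmark inputs on which the measures are
validated: a closed 1-pixel-thick contour (square, ellipse or star polygon)
that is then translated, rotated or scaled in controlled increments, with
optional speckle false positives and dropout false negatives emulating a noisy
detector.  Scoring the altered candidate against the unaltered ground truth
over a series of steps produces the score trajectories used to judge whether a
measure behaves as a pose-assessment score should: near 1 for small
displacements, decaying smoothly and monotonically as the shape recedes,
rotates away, or changes scale.

Transforms are applied to the *continuous* outline and re-rasterized at every
step; rotating or scaling the raster itself would punch holes into a thin
contour and manufacture spurious false negatives.  Pixels that leave the
canvas are clipped; the canvas size never changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage.draw import line as _draw_line

from .edgemap import EdgeMap
from .errors import ValidationError
from .measures import MEASURES, MeasureParams, confusion_counts, score_all

__all__ = [
    "ShapeSpec",
    "Alteration",
    "ScoreSeries",
    "square",
    "ellipse",
    "star",
    "default_star",
    "make_contour_shape",
    "alter",
    "add_speckle_noise",
    "dropout",
    "run_trajectory",
    "behavior_report",
]

_ELLIPSE_SAMPLES = 720  # outline samples; dense enough for 1-px rasterization


@dataclass(frozen=True)
class ShapeSpec:
    """A continuous closed outline on a pixel canvas.

    kind : 'polygon', 'ellipse' or 'star' (a concave star polygon).
    canvas : (height, width) in pixels.
    vertices : closed polyline control points as (row, col) floats; for an
        ellipse, (center, radii) packed as two rows; for a star, generated
        from the geometry fields below.
    """

    kind: str
    canvas: tuple[int, int]
    vertices: tuple[tuple[float, float], ...] = ()
    center: tuple[float, float] | None = None
    radii: tuple[float, float] | None = None
    r_outer: float | None = None
    r_inner: float | None = None
    n_arms: int = 5
    phase_deg: float = -90.0

    def outline(self) -> np.ndarray:
        """The continuous closed outline as an (n, 2) float array of (row, col)."""
        if self.kind == "polygon":
            if len(self.vertices) < 1:
                raise ValidationError("polygon spec needs at least one vertex")
            return np.asarray(self.vertices, dtype=float)
        if self.kind == "ellipse":
            if self.center is None or self.radii is None:
                raise ValidationError("ellipse spec needs center and radii")
            t = np.linspace(0.0, 2.0 * math.pi, _ELLIPSE_SAMPLES, endpoint=False)
            r0, c0 = self.center
            ra, rb = self.radii
            return np.column_stack([r0 + ra * np.sin(t), c0 + rb * np.cos(t)])
        if self.kind == "star":
            if self.center is None or self.r_outer is None or self.r_inner is None:
                raise ValidationError("star spec needs center, r_outer and r_inner")
            if self.n_arms < 3:
                raise ValidationError("star needs at least 3 arms")
            n = 2 * self.n_arms
            ang = np.deg2rad(self.phase_deg) + np.arange(n) * math.pi / self.n_arms
            rad = np.where(np.arange(n) % 2 == 0, self.r_outer, self.r_inner)
            r0, c0 = self.center
            return np.column_stack([r0 + rad * np.sin(ang), c0 + rad * np.cos(ang)])
        raise ValidationError(f"unknown shape kind {self.kind!r}")


def square(canvas: tuple[int, int], top_left: tuple[float, float], side: int) -> ShapeSpec:
    """An axis-aligned square contour of ``side`` pixels per edge."""
    if side < 1:
        raise ValidationError("side must be >= 1")
    r, c = top_left
    s = side - 1  # side pixels span indices r .. r+side-1
    return ShapeSpec(kind="polygon", canvas=canvas,
                     vertices=((r, c), (r, c + s), (r + s, c + s), (r + s, c)))


def ellipse(canvas: tuple[int, int], center: tuple[float, float],
            radii: tuple[float, float]) -> ShapeSpec:
    return ShapeSpec(kind="ellipse", canvas=canvas, center=center, radii=radii)


def star(canvas: tuple[int, int], center: tuple[float, float], r_outer: float,
         r_inner: float, n_arms: int = 5, phase_deg: float = -90.0) -> ShapeSpec:
    return ShapeSpec(kind="star", canvas=canvas, center=center, r_outer=r_outer,
                     r_inner=r_inner, n_arms=n_arms, phase_deg=phase_deg)


def default_star(canvas: tuple[int, int] = (100, 100)) -> ShapeSpec:
    """The default benchmark shape: a concave five-armed star centered on the
    canvas, outer radius 30 % of the smaller canvas side, inner radius 45 % of
    the outer."""
    h, w = canvas
    r = 0.3 * min(h, w)
    return star(canvas, ((h - 1) / 2.0, (w - 1) / 2.0), r_outer=r, r_inner=0.45 * r)


# ---------------------------------------------------------------------------
# rasterization


def _rasterize(outline: np.ndarray, canvas: tuple[int, int], *,
               clip: bool) -> EdgeMap:
    """Rasterize a closed continuous polyline into a 1-px 8-connected contour.

    Consecutive outline points are joined with Bresenham segments between
    their rounded positions.  With ``clip=False`` an outline pixel outside the
    canvas is an error; with ``clip=True`` it is silently dropped.
    """
    h, w = canvas
    pts = np.rint(outline).astype(int)
    mask = np.zeros((h, w), dtype=bool)
    n = len(pts)
    for i in range(n):
        r0, c0 = pts[i]
        r1, c1 = pts[(i + 1) % n] if n > 1 else pts[i]
        rr, cc = _draw_line(r0, c0, r1, c1)
        inside = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        if not clip and not inside.all():
            raise ValidationError("shape outline exits the canvas")
        mask[rr[inside], cc[inside]] = True
    return EdgeMap(mask)


def make_contour_shape(spec: ShapeSpec) -> EdgeMap:
    """Rasterize a spec's outline; deterministic, errors if it exits the canvas."""
    return _rasterize(spec.outline(), spec.canvas, clip=False)


# ---------------------------------------------------------------------------
# alterations


@dataclass(frozen=True)
class Alteration:
    """A gradual geometric alteration applied over ``steps`` increments.

    type : 'translate' (magnitude in pixels, along +col, i.e. a horizontal
        straight line), 'rotate' (magnitude in degrees about the outline
        centroid) or 'scale' (magnitude is the final scale factor, about the
        centroid; intermediate steps interpolate the factor linearly from 1).
    Step 0 is always the unaltered shape; the final step applies the full
    magnitude.
    """

    type: str
    magnitude: float
    steps: int

    def __post_init__(self):
        if self.type not in ("translate", "rotate", "scale"):
            raise ValidationError(f"unknown alteration type {self.type!r}")
        if self.steps < 1:
            raise ValidationError("steps must be >= 1")
        if self.type == "scale" and self.magnitude <= 0:
            raise ValidationError("scale factor must be positive")

    def fraction(self, step: int) -> float:
        if not 0 <= step < self.steps:
            raise ValidationError(f"step {step} out of range [0, {self.steps})")
        return 0.0 if self.steps == 1 else step / (self.steps - 1)


def alter(spec: ShapeSpec, alteration: Alteration, step: int) -> EdgeMap:
    """The shape at one alteration step, transformed continuously then
    re-rasterized; pixels leaving the canvas are clipped."""
    t = alteration.fraction(step)
    outline = spec.outline()
    centroid = outline.mean(axis=0)
    if alteration.type == "translate":
        outline = outline + np.array([0.0, alteration.magnitude * t])
    elif alteration.type == "rotate":
        a = math.radians(alteration.magnitude * t)
        rot = np.array([[math.cos(a), -math.sin(a)], [math.sin(a), math.cos(a)]])
        outline = (outline - centroid) @ rot.T + centroid
    else:  # scale
        factor = 1.0 + (alteration.magnitude - 1.0) * t
        outline = (outline - centroid) * factor + centroid
    return _rasterize(outline, spec.canvas, clip=True)


# ---------------------------------------------------------------------------
# detector-noise emulation


def add_speckle_noise(edge_map: EdgeMap, n_points: int, seed: int = 0) -> EdgeMap:
    """Mark ``n_points`` uniformly chosen background pixels (false positives)."""
    if n_points < 0:
        raise ValidationError("n_points must be non-negative")
    if n_points == 0:
        return EdgeMap(edge_map.mask.copy())
    background = np.flatnonzero(~edge_map.mask.ravel())
    if n_points > background.size:
        raise ValidationError(
            f"cannot add {n_points} speckle points; only {background.size} "
            "background pixels available")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(background, size=n_points, replace=False)
    mask = edge_map.mask.copy()
    mask.ravel()[chosen] = True
    return EdgeMap(mask)


def dropout(edge_map: EdgeMap, fraction: float, seed: int = 0) -> EdgeMap:
    """Remove ``round(fraction · |points|)`` marked pixels uniformly at random
    (false negatives)."""
    if not 0.0 <= fraction <= 1.0:
        raise ValidationError("fraction must lie in [0, 1]")
    n_remove = int(round(fraction * edge_map.n_points))
    if n_remove == 0:
        return EdgeMap(edge_map.mask.copy())
    marked = np.flatnonzero(edge_map.mask.ravel())
    rng = np.random.default_rng(seed)
    removed = rng.choice(marked, size=n_remove, replace=False)
    mask = edge_map.mask.copy()
    mask.ravel()[removed] = False
    return EdgeMap(mask)


# ---------------------------------------------------------------------------
# trajectories


@dataclass
class ScoreSeries:
    """Per-step scores of one alteration trajectory.

    data : tidy frame with columns step, measure, score, tp, fp, fn.
    metadata : resolved run description (alteration, parameters, seed, and the
        automatic scales actually used), sufficient to reproduce the run.
    """

    data: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def scores(self, measure: str) -> np.ndarray:
        """Score sequence of one measure, ordered by step."""
        sub = self.data[self.data["measure"] == measure].sort_values("step")
        if sub.empty:
            raise ValidationError(f"measure {measure!r} not in series")
        return sub["score"].to_numpy()

    @property
    def measures(self) -> list[str]:
        return list(dict.fromkeys(self.data["measure"]))

    @property
    def n_steps(self) -> int:
        return int(self.data["step"].nunique())


def run_trajectory(gt_spec: ShapeSpec, alteration: Alteration,
                   measures: Sequence[str] | None = None,
                   params: MeasureParams | None = None,
                   speckle: int = 0, dropout_fraction: float = 0.0,
                   seed: int = 0) -> ScoreSeries:
    """Score every step of an alteration against the unaltered ground truth.

    The ground truth is rasterized once from ``gt_spec``; its automatic scale
    parameters (μFP, μFN) are resolved once and reused for every step, so the
    normalization is identical across the whole series.  Optional speckle
    false positives and dropout false negatives are injected into each
    candidate frame with a per-step derived seed.
    """
    gt = make_contour_shape(gt_spec)
    params = (params or MeasureParams()).resolve_mu(gt)
    rows = []
    for step in range(alteration.steps):
        dc = alter(gt_spec, alteration, step)
        step_seed = (seed * 100003 + step) % (2**31)
        if speckle:
            dc = add_speckle_noise(dc, speckle, seed=step_seed)
        if dropout_fraction:
            dc = dropout(dc, dropout_fraction, seed=step_seed + 1)
        c = confusion_counts(gt, dc)
        names = list(MEASURES) if measures is None else list(measures)
        if dc.is_empty and "rde" in names:
            # RDE's FP-side mean is undefined for an empty candidate; in a
            # trajectory the shape clipping away entirely is the far limit,
            # where RDE diverges — record +inf rather than aborting the run.
            scores = score_all(gt, dc, params, [n for n in names if n != "rde"])
            scored = {s.name: s.value for s in scores}
            scored["rde"] = math.inf
            step_scores = [(n, scored[n]) for n in names]
        else:
            step_scores = [(s.name, s.value) for s in score_all(gt, dc, params, names)]
        for name, value in step_scores:
            rows.append({"step": step, "measure": name, "score": value,
                         "tp": c.tp, "fp": c.fp, "fn": c.fn})
    meta = {
        "alteration": {"type": alteration.type, "magnitude": alteration.magnitude,
                       "steps": alteration.steps},
        "canvas": list(gt_spec.canvas),
        "shape_kind": gt_spec.kind,
        "mu_fp": params.mu_fp,
        "mu_fn": params.mu_fn,
        "kappa": params.kappa,
        "speckle": speckle,
        "dropout_fraction": dropout_fraction,
        "seed": seed,
    }
    return ScoreSeries(data=pd.DataFrame(rows), metadata=meta)


def behavior_report(series: ScoreSeries) -> dict[str, Mapping[str, float]]:
    """Per-measure trajectory diagnostics.

    For each measure: counts of increasing and decreasing single steps
    (monotonicity violations for the respective expected direction), total
    variation, final score, and the largest single-step gap (error peak).
    """
    if series.data.empty:
        raise ValidationError("empty score series")
    report: dict[str, dict[str, float]] = {}
    for name in series.measures:
        s = series.scores(name)
        with np.errstate(invalid="ignore"):
            diffs = np.diff(s)
        # consecutive infinite scores (RDE's clipped-away limit) are "no change"
        diffs = np.nan_to_num(diffs, nan=0.0)
        report[name] = {
            "n_steps": int(s.size),
            "final": float(s[-1]),
            "increases": int(np.count_nonzero(diffs > 0)),
            "decreases": int(np.count_nonzero(diffs < 0)),
            "total_variation": float(np.abs(diffs).sum()),
            "max_gap": float(np.abs(diffs).max()) if diffs.size else 0.0,
        }
    return report
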