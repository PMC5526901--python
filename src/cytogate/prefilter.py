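"""Directed Automated Gating (DAG): sequential 2D density-contour prefiltering.

Manual pregating of cytometry data walks an ordered sequence of 2D dot
plots (lymphocytes on SSC-A vs FSC-A, singlets on FSC-H vs FSC-A, live
cells on the viability channel), drawing a gate around the target mode in
each.  DAG automates this: on every configured 2D projection it estimates
an event density, traces iso-density contour lines, and keeps the events
inside the largest closed contour that fits entirely within a
user-supplied rectangle.  The survivors are passed to the next projection
until the sequence is exhausted.

The procedure is fully deterministic: no randomness enters at any step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter
from skimage import measure
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EventTable

logger = logging.getLogger(__name__)


@dataclass
class GateStep:
    """One filtering step: a 2D projection (by channel role) and a
    rectangle, in the channels' analysis-scale units, within which the
    target density contour must lie."""

    x_role: str
    y_role: str
    rect: tuple[float, float, float, float]  # (xmin, xmax, ymin, ymax)

    def __post_init__(self) -> None:
        xmin, xmax, ymin, ymax = self.rect
        if not (xmin < xmax and ymin < ymax):
            raise ValueError(f"degenerate rectangle {self.rect}")


@dataclass
class GateSequenceConfig:
    """Ordered gate steps plus density-estimation parameters."""

    steps: list[GateStep] = field(default_factory=list)
    bins: int = 128
    smoothing: float = 2.0  # Gaussian sigma, in bin widths
    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.bins < 16:
            raise ValueError("bins must be >= 16")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")


@dataclass
class DensityGrid:
    """Smoothed, normalized 2D histogram with bin edges in data units."""

    grid: np.ndarray  # (bins_x, bins_y), sums to 1
    x_edges: np.ndarray
    y_edges: np.ndarray

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])


@dataclass
class PolygonGate:
    """A closed iso-density contour in data units."""

    vertices: np.ndarray  # (n, 2), first == last
    level: float
    area: float

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Even-odd point-in-polygon; points on the boundary count inside
        (tested with a tolerance of one millionth of the polygon extent)."""
        pts = np.column_stack([x, y])
        path = MplPath(self.vertices)
        span = float(max(np.ptp(self.vertices[:, 0]), np.ptp(self.vertices[:, 1])))
        eps = 1e-6 * span if span > 0 else 1e-12
        # radius sign flips with path orientation; the union is inclusive
        # of the boundary for either orientation.
        return path.contains_points(pts, radius=eps) | path.contains_points(
            pts, radius=-eps
        )


def shoelace_area(vertices: np.ndarray) -> float:
    """Absolute polygon area by the shoelace formula."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


# ----------------------------------------------------------------------


def estimate_density2d(
    table: EventTable, step: GateStep, bins: int = 128, smoothing: float = 2.0
) -> DensityGrid:
    """Estimate the event density on the step's 2D projection.

    A `bins` x `bins` histogram over the observed per-channel range (padded
    by 1% on each side), Gaussian-smoothed with sigma = `smoothing` bin
    widths, normalized to total mass 1.
    """
    if table.n_events == 0:
        raise ValueError("estimate_density2d: table has no events")
    x = table.get_role(step.x_role)
    y = table.get_role(step.y_role)

    def padded_range(v: np.ndarray) -> tuple[float, float]:
        lo, hi = float(v.min()), float(v.max())
        pad = 0.01 * (hi - lo) if hi > lo else max(abs(hi), 1.0) * 0.01
        return lo - pad, hi + pad

    xr, yr = padded_range(x), padded_range(y)
    hist, x_edges, y_edges = np.histogram2d(x, y, bins=bins, range=[xr, yr])
    grid = gaussian_filter(hist, sigma=smoothing, mode="constant")
    total = grid.sum()
    if total > 0:
        grid = grid / total
    return DensityGrid(grid=grid, x_edges=x_edges, y_edges=y_edges)


def extract_contours(density: DensityGrid, n_levels: int = 32) -> list[PolygonGate]:
    """Trace iso-density contours at evenly spaced levels in (0, max).

    Levels are max * i / n_levels for i = 1 .. n_levels-1.  Contours that
    touch the grid boundary (open curves) are discarded; vertices are
    returned in data units (bin-center coordinates).
    """
    dmax = float(density.grid.max())
    out: list[PolygonGate] = []
    if dmax <= 0:
        return out
    nx, ny = density.grid.shape
    dx = density.x_edges[1] - density.x_edges[0]
    dy = density.y_edges[1] - density.y_edges[0]
    x0 = density.x_edges[0] + 0.5 * dx
    y0 = density.y_edges[0] + 0.5 * dy
    levels = dmax * np.arange(1, n_levels) / n_levels
    for level in levels:
        for contour in measure.find_contours(density.grid, level):
            closed = np.allclose(contour[0], contour[-1])
            touches_edge = (
                contour[:, 0].min() <= 0
                or contour[:, 1].min() <= 0
                or contour[:, 0].max() >= nx - 1
                or contour[:, 1].max() >= ny - 1
            )
            if not closed or touches_edge:
                continue
            verts = np.column_stack(
                [x0 + contour[:, 0] * dx, y0 + contour[:, 1] * dy]
            )
            area = shoelace_area(verts)
            if verts.shape[0] >= 4 and area > 0:
                out.append(PolygonGate(vertices=verts, level=float(level), area=area))
    return out


def select_largest_contour(
    contours: Sequence[PolygonGate], rect: tuple[float, float, float, float]
) -> PolygonGate | None:
    """Pick the contour of maximal enclosed area among closed contours whose
    vertices all lie inside `rect`; ties broken toward the lower density
    level.  Returns None when no contour qualifies."""
    xmin, xmax, ymin, ymax = rect
    eligible = [
        c
        for c in contours
        if c.vertices[:, 0].min() >= xmin
        and c.vertices[:, 0].max() <= xmax
        and c.vertices[:, 1].min() >= ymin
        and c.vertices[:, 1].max() <= ymax
    ]
    if not eligible:
        return None
    return min(eligible, key=lambda c: (-c.area, c.level))


def dag_filter(
    table: EventTable, config: GateSequenceConfig
) -> tuple[EventTable, pd.DataFrame]:
    """Run the DAG sequence and return (filtered table, retention report).

    At each step, events inside the selected contour are kept.  If no
    closed contour fits inside the rectangle, the rectangle itself is used
    as the gate and a warning is logged.  The report has one row per step:
    step index, roles, kept, total, fraction, fallback_used.
    """
    current = table
    rows = []
    for i, step in enumerate(config.steps):
        for role in (step.x_role, step.y_role):
            if not current.has_role(role):
                raise ValueError(f"dag_filter: channel role {role!r} missing from table")
        total = current.n_events
        if total == 0:
            rows.append(
                dict(step=i, x_role=step.x_role, y_role=step.y_role, kept=0,
                     total=0, fraction=float("nan"), fallback_used=False)
            )
            continue
        density = estimate_density2d(current, step, config.bins, config.smoothing)
        contours = extract_contours(density, config.n_levels)
        gate = select_largest_contour(contours, step.rect)
        x = current.get_role(step.x_role)
        y = current.get_role(step.y_role)
        fallback = gate is None
        if fallback:
            logger.warning(
                "dag_filter step %d (%s vs %s): no closed contour inside the "
                "rectangle; falling back to the rectangle gate",
                i, step.y_role, step.x_role,
            )
            xmin, xmax, ymin, ymax = step.rect
            mask = (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)
        else:
            mask = gate.contains(x, y)
        kept = int(mask.sum())
        rows.append(
            dict(step=i, x_role=step.x_role, y_role=step.y_role, kept=kept,
                 total=total, fraction=kept / total, fallback_used=fallback)
        )
        current = current.take(np.flatnonzero(mask))
    return current, pd.DataFrame(
        rows, columns=["step", "x_role", "y_role", "kept", "total", "fraction",
                       "fallback_used"]
    )


# ----------------------------------------------------------------------
# Default gate sequence for the synthetic panel scale
# ----------------------------------------------------------------------

#: Rectangles in raw scatter units / arcsinh fluorescence units, sized for
#: the synthetic generator's default intensity scale.
DEFAULT_LYMPH_RECT = (26_000.0, 88_000.0, 0.0, 55_000.0)  # FSC-A x SSC-A
DEFAULT_SINGLET_RECT = (20_000.0, 90_000.0, 26_000.0, 88_000.0)  # FSC-H x FSC-A
DEFAULT_VIABILITY_RECT = (-0.5, 4.0, 26_000.0, 88_000.0)  # viability x FSC-A


def default_gate_sequence(
    include_viability: bool = True,
    bins: int = 128,
    smoothing: float = 2.0,
    n_levels: int = 32,
) -> GateSequenceConfig:
    """Lymphocytes (SSC-A vs FSC-A), then singlets (FSC-A vs FSC-H), then —
    when a viability stain is present — live cells (FSC-A vs viability).

    Fluorescence rectangles assume arcsinh-transformed channels.
    """
    steps = [
        GateStep("FSC-A", "SSC-A", DEFAULT_LYMPH_RECT),
        GateStep("FSC-H", "FSC-A", DEFAULT_SINGLET_RECT),
    ]
    if include_viability:
        steps.append(GateStep("viability", "FSC-A", DEFAULT_VIABILITY_RECT))
    return GateSequenceConfig(steps=steps, bins=bins, smoothing=smoothing,
                              n_levels=n_levels)


class DAGPrefilter(TransformerMixin, BaseEstimator):
    """Directed-automated-gating prefilter as a scikit-learn transformer.

    ``fit`` learns one polygon gate per configured step from the supplied
    sample (sequentially, each step on the survivors of the previous);
    ``transform`` applies the learned polygons to any table with the same
    channel roles.  ``fit_transform`` is the usual per-sample gating run.

    Parameters
    ----------
    steps : list of GateStep or None
        Gate sequence; None selects :func:`default_gate_sequence` (with the
        viability step dropped when the table lacks the role).
    bins, smoothing, n_levels
        Density-estimation parameters, see :func:`estimate_density2d` and
        :func:`extract_contours`.

    Attributes
    ----------
    gates_ : list of (GateStep, PolygonGate or None)
        Selected contour per step (None = rectangle fallback).
    report_ : pandas.DataFrame
        Per-step retention on the fit sample.
    """

    def __init__(self, steps: list[GateStep] | None = None, bins: int = 128,
                 smoothing: float = 2.0, n_levels: int = 32):
        self.steps = steps
        self.bins = bins
        self.smoothing = smoothing
        self.n_levels = n_levels

    def _config(self, table: EventTable) -> GateSequenceConfig:
        if self.steps is not None:
            steps = list(self.steps)
        else:
            steps = default_gate_sequence(
                include_viability=table.has_role("viability")
            ).steps
        return GateSequenceConfig(steps=steps, bins=self.bins,
                                  smoothing=self.smoothing, n_levels=self.n_levels)

    def fit(self, X: EventTable, y=None) -> "DAGPrefilter":
        config = self._config(X)
        current = X
        gates: list[tuple[GateStep, PolygonGate | None]] = []
        rows = []
        for i, step in enumerate(config.steps):
            density = estimate_density2d(current, step, config.bins, config.smoothing)
            contours = extract_contours(density, config.n_levels)
            gate = select_largest_contour(contours, step.rect)
            gates.append((step, gate))
            xv = current.get_role(step.x_role)
            yv = current.get_role(step.y_role)
            if gate is None:
                xmin, xmax, ymin, ymax = step.rect
                mask = (xv >= xmin) & (xv <= xmax) & (yv >= ymin) & (yv <= ymax)
            else:
                mask = gate.contains(xv, yv)
            rows.append(dict(step=i, x_role=step.x_role, y_role=step.y_role,
                             kept=int(mask.sum()), total=current.n_events,
                             fraction=float(mask.mean()),
                             fallback_used=gate is None))
            current = current.take(np.flatnonzero(mask))
        self.gates_ = gates
        self.report_ = pd.DataFrame(rows)
        self._fit_result = current
        return self

    def transform(self, X: EventTable) -> EventTable:
        if not hasattr(self, "gates_"):
            raise RuntimeError("DAGPrefilter is not fitted")
        current = X
        for step, gate in self.gates_:
            xv = current.get_role(step.x_role)
            yv = current.get_role(step.y_role)
            if gate is None:
                xmin, xmax, ymin, ymax = step.rect
                mask = (xv >= xmin) & (xv <= xmax) & (yv >= ymin) & (yv <= ymax)
            else:
                mask = gate.contains(xv, yv)
            current = current.take(np.flatnonzero(mask))
        return current

    def fit_transform(self, X: EventTable, y=None, **fit_params) -> EventTable:
        self.fit(X)
        return self._fit_result
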