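"""Diversity tree plot: clonotype spots on a V x J mosaic grid.

Each clonotype is one spot; spot area is proportional to its relative
transcript frequency (one global constant for the whole plot), position
is determined by the clonotype's (V, J) combination — column widths
proportional to V usage, cell heights within a column proportional to
cell mass, so cell area is proportional to the frequency mass it holds —
and each spot has a unique color.  Dominant clones appear as large spots;
an even repertoire appears as a fine mist.

Rendering is plain SVG text, byte-stable for identical layouts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotate import Repertoire

__all__ = [
    "PlotSpec",
    "Spot",
    "cell_rects",
    "layout_diversity_plot",
    "render",
    "floored_spots",
]

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class PlotSpec:
    width: float = 800.0
    height: float = 600.0
    v_order: tuple[str, ...] | None = None  # x-axis order; sorted labels if None
    j_order: tuple[str, ...] | None = None  # y-axis order
    color_seed: int = 0
    min_radius: float = 0.2  # px floor keeping rare clones visible
    area_budget: float = 0.15  # fraction of canvas area covered by spots
    output_format: str = "svg"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas dimensions must be positive")


@dataclass(frozen=True)
class Spot:
    junction_nt: str
    v_id: str
    j_id: str
    x: float
    y: float
    radius: float  # rendered radius (after floor/fit adjustments)
    nominal_radius: float  # exact area-proportional radius
    color: str
    floored: bool = False
    clamped: bool = False


def _color(i: int, seed: int) -> str:
    """Unique color per spot index: a bijective scramble of 24-bit RGB."""
    v = ((i + seed * 7919) * 2654435761) % (1 << 24)
    return f"#{v:06x}"


def cell_rects(
    rep: Repertoire, spec: PlotSpec = PlotSpec()
) -> dict[tuple[str, str], tuple[float, float, float, float]]:
    """Mosaic grid geometry: (x, y, width, height) per (V, J) cell.

    Column widths are proportional to V-marginal frequency mass; cell
    heights within a column to the cell's share of the column mass, so
    every cell's area is proportional to the frequency mass it holds.
    """
    if not rep.clonotypes:
        return {}
    total = sum(c.frequency for c in rep.clonotypes)
    v_mass: dict[str, float] = {}
    cell_mass: dict[tuple[str, str], float] = {}
    for c in rep.clonotypes:
        v_mass[c.v_id] = v_mass.get(c.v_id, 0.0) + c.frequency / total
        key = (c.v_id, c.j_id)
        cell_mass[key] = cell_mass.get(key, 0.0) + c.frequency / total

    v_order = list(spec.v_order) if spec.v_order else sorted(v_mass)
    j_order = list(spec.j_order) if spec.j_order else sorted({j for _, j in cell_mass})
    missing = (set(v_mass) - set(v_order)) | ({j for _, j in cell_mass} - set(j_order))
    if missing:
        raise ValueError(f"axis orders do not cover labels: {sorted(missing)}")

    rects: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    x = 0.0
    for v in v_order:
        col = v_mass.get(v, 0.0)
        w = spec.width * col
        y = 0.0
        for j in j_order:
            m = cell_mass.get((v, j), 0.0)
            h = spec.height * (m / col) if col else 0.0
            rects[(v, j)] = (x, y, w, h)
            y += h
        x += w
    return rects


def layout_diversity_plot(rep: Repertoire, spec: PlotSpec = PlotSpec()) -> list[Spot]:
    """Compute spot geometry for a repertoire.

    Spots are packed per (V, J) cell on a deterministic golden-angle
    spiral ordered by descending frequency.  ``nominal_radius`` encodes
    exact area proportionality (sum of nominal areas = area_budget *
    canvas area); the rendered radius applies the minimum-radius floor
    and, where a cell is too cramped, a fit clamp — both recorded on the
    spot and retrievable via :func:`floored_spots`.
    """
    if not rep.clonotypes:
        return []
    clonos = sorted(rep.clonotypes, key=lambda c: (-c.frequency, c.junction_nt))
    total = sum(c.frequency for c in clonos)
    rects = cell_rects(rep, spec)
    x0 = {v: x for (v, _), (x, _, _, _) in rects.items()}
    cw = {v: w for (v, _), (_, _, w, _) in rects.items()}
    y0 = {k: y for k, (_, y, _, _) in rects.items()}
    ch = {k: h for k, (_, _, _, h) in rects.items()}

    area_scale = spec.area_budget * spec.width * spec.height / total
    per_cell_index: dict[tuple[str, str], int] = {}
    spots: list[Spot] = []
    for i, c in enumerate(clonos):
        key = (c.v_id, c.j_id)
        k = per_cell_index.get(key, 0)
        per_cell_index[key] = k + 1
        r_nom = math.sqrt(area_scale * c.frequency / math.pi)
        w, h = cw[c.v_id], ch[key]
        cx = x0[c.v_id] + w / 2.0
        cy = y0[key] + h / 2.0
        if k == 0:
            px, py = cx, cy
        else:
            ncell = sum(1 for cl in clonos if (cl.v_id, cl.j_id) == key)
            rad = math.sqrt(k / max(ncell, 1)) * 0.5 * min(w, h) * 0.9
            ang = k * _GOLDEN_ANGLE
            px = cx + rad * math.cos(ang)
            py = cy + rad * math.sin(ang)
        r = r_nom
        clamped = False
        if 2 * r > min(w, h):
            r = min(w, h) / 2.0
            clamped = True
        floored = r < spec.min_radius
        if floored:
            r = spec.min_radius
        # keep the disc inside its cell
        px = min(max(px, x0[c.v_id] + r), x0[c.v_id] + max(w - r, r))
        py = min(max(py, y0[key] + r), y0[key] + max(h - r, r))
        spots.append(
            Spot(c.junction_nt, c.v_id, c.j_id, px, py, r, r_nom,
                 _color(i, spec.color_seed), floored, clamped)
        )
    return spots


def floored_spots(spots: Sequence[Spot]) -> pd.DataFrame:
    """Sidecar log of spots whose rendered size deviates from proportionality."""
    rows = [
        {
            "junction": s.junction_nt,
            "nominal_radius": s.nominal_radius,
            "rendered_radius": s.radius,
            "reason": "floored" if s.floored else "clamped",
        }
        for s in spots
        if s.floored or s.clamped
    ]
    return pd.DataFrame(rows, columns=["junction", "nominal_radius", "rendered_radius", "reason"])


def render(
    spots: Sequence[Spot], path: str | Path, spec: PlotSpec = PlotSpec()
) -> Path:
    """Write the layout as a deterministic SVG file."""
    path = Path(path)
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{spec.width:.1f}" '
        f'height="{spec.height:.1f}" viewBox="0 0 {spec.width:.1f} {spec.height:.1f}">',
        f'<rect width="{spec.width:.1f}" height="{spec.height:.1f}" fill="white"/>',
    ]
    for s in spots:
        lines.append(
            f'<circle cx="{s.x:.4f}" cy="{s.y:.4f}" r="{s.radius:.4f}" '
            f'fill="{s.color}" fill-opacity="0.85"/>'
        )
    lines.append("</svg>")
    path.write_text("\n".join(lines) + "\n")
    return path
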