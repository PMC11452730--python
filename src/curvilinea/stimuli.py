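"""Torso stimulus synthesis and geometric WHR / MMD measurement.

A stimulus is built from a single left-side body contour (chest to thigh,
one Bézier curve) by *rigid* placement: the contour is translated — never
horizontally rescaled — so that its most lateral point sits at half the
requested hip width from the body midline, then mirrored to form the right
side.  Because the placement is rigid, the contour's curviness is identical
across all hip widths, while the waist-to-hip ratio follows the closed form

    WHR = 1 - D / W,    D = hip width - waist width = 2 * lateral range,

so the same WHR can arise from contours of different curviness at different
widths — the non-uniqueness that motivates measuring curviness directly.

Horizontal cross-section widths are measured from the geometry alone: the
lateral extrema of each Bézier segment are located exactly from the real
roots of the derivative polynomial of x(t).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from curvilinea import geometry as geo
from curvilinea.geometry import BezierPath, BezierSegment, Curve

__all__ = [
    "DegenerateContourError",
    "OverlapError",
    "AsymmetryError",
    "Contour",
    "TorsoStimulus",
    "StimulusSet",
    "normalize_height",
    "synthesize_torso",
    "measure_whr",
    "measure_mmd",
    "build_stimulus_set",
    "export_stimuli",
    "torso_from_svg",
    "torso_svg_text",
]


class DegenerateContourError(ValueError):
    """Contour has no vertical extent or is not traversable top to bottom."""


class OverlapError(ValueError):
    """Hip width too small: the two body sides would cross the midline."""

    def __init__(self, hip_width: float, min_width: float):
        self.min_width = min_width
        super().__init__(
            f"hip width {hip_width:g} px infeasible; smallest feasible width "
            f"is {min_width:g} px (2 * lateral range + 1 px waist gap)"
        )


class AsymmetryError(ValueError):
    """Torso outline is not bilaterally mirror-symmetric."""


def _x_extrema(curve: Curve) -> tuple[float, float, float, float]:
    """(x_min, x_max) over [0,1] and (x_min, x_max) over the open interior.

    Exact up to root-finding precision: per segment, candidates are the real
    roots of d/dt x(t) in (0, 1) plus segment endpoints; the two curve
    endpoints are excluded from the interior extrema.
    """
    interior: list[float] = []
    endpoints: list[float] = []
    segments = curve.segments
    for j, seg in enumerate(segments):
        cx = seg.x_power_coeffs()
        dcx = np.polynomial.polynomial.polyder(cx)
        if np.allclose(dcx, 0.0):
            # x constant on this segment: every point is an extremum
            interior.append(float(cx[0]))
        else:
            roots = np.polynomial.polynomial.polyroots(dcx)
            for r in roots:
                if abs(r.imag) < 1e-9 and 1e-12 < r.real < 1 - 1e-12:
                    interior.append(float(np.polynomial.polynomial.polyval(r.real, cx)))
        x0 = float(np.polynomial.polynomial.polyval(0.0, cx))
        x1 = float(np.polynomial.polynomial.polyval(1.0, cx))
        (endpoints if j == 0 else interior).append(x0)
        (endpoints if j == len(segments) - 1 else interior).append(x1)
    all_x = interior + endpoints
    xi_min = min(interior) if interior else min(all_x)
    xi_max = max(interior) if interior else max(all_x)
    return min(all_x), max(all_x), xi_min, xi_max


@dataclass
class Contour:
    """A left-side body contour: one curve from chest (top) to thigh (bottom)."""

    curve: Curve

    def __post_init__(self) -> None:
        t = np.linspace(0.0, 1.0, 2049)
        y = np.atleast_2d(self.curve.point(t))[:, 1]
        if not np.all(np.diff(y) > 0):
            raise DegenerateContourError(
                "contour must be strictly monotone in height (y increasing "
                "from chest to thigh)"
            )
        if y[-1] - y[0] <= 0:
            raise DegenerateContourError("contour has no vertical extent")

    @property
    def height(self) -> float:
        p0 = self.curve.point(0.0)
        p1 = self.curve.point(1.0)
        return float(p1[1] - p0[1])

    @property
    def lateral_range(self) -> float:
        """max x - min x along the curve (the MMD of one body side)."""
        x_min, x_max, _, _ = _x_extrema(self.curve)
        return x_max - x_min

    def curviness(self, n: int = 2048) -> float:
        return geo.mean_abs_curvature(self.curve, n=n)


@dataclass
class TorsoStimulus:
    """A mirrored closed torso outline at a fixed hip width.

    The midline is the vertical axis x = 0; ``left`` lies at x <= 0 and
    ``right`` is its mirror image.
    """

    left: Contour
    right: Contour
    hip_width: float
    waist_width: float
    whr: float
    curviness: float
    level_ids: tuple[int, int] | None = None  # (curviness_level, width_level)

    @property
    def stimulus_id(self) -> str:
        if self.level_ids is None:
            return f"torso_w{self.hip_width:g}"
        c, w = self.level_ids
        return f"c{c}w{w}"


@dataclass
class StimulusSet:
    """A full factorial curviness x width design with its summary table."""

    stimuli: list[TorsoStimulus]
    table: pd.DataFrame       # one row per stimulus: C, W, WHR and levels
    correlations: pd.DataFrame  # pairwise Pearson r, t, df among (C, W, WHR)


def normalize_height(contour: Contour, target_height: float) -> Contour:
    """Uniformly scale a contour so its vertical extent equals ``target_height``.

    Curviness is divided by the scale factor (curvature has units 1/px).
    """
    if target_height <= 0:
        raise ValueError("target height must be positive")
    h = contour.height
    if h <= 0:
        raise DegenerateContourError("cannot normalize a zero-height contour")
    factor = target_height / h
    if abs(factor - 1.0) < 1e-15:
        return contour
    return Contour(geo.scale(contour.curve, factor))


def synthesize_torso(
    contour: Contour,
    hip_width: float,
    level_ids: tuple[int, int] | None = None,
    margin: float = 1.0,
    n_quad: int = 2048,
) -> TorsoStimulus:
    """Rigidly place a contour at a hip width and mirror it into a torso.

    The contour is translated so that its most lateral point sits at
    ``hip_width / 2`` left of the midline; no horizontal rescaling takes
    place, so the contour's curviness is the same at every width.  A
    ``margin`` (default 1 px) keeps a visible waist gap between the sides.
    """
    d = 2.0 * contour.lateral_range
    min_width = d + margin
    if hip_width < min_width:
        raise OverlapError(hip_width, min_width)
    x_min, _, _, _ = _x_extrema(contour.curve)
    # left side: most lateral point at x = -hip_width / 2
    left_curve = geo.translate(contour.curve, -hip_width / 2.0 - x_min, 0.0)
    left = Contour(left_curve)
    right = Contour(geo.mirror_x(left_curve))
    waist = hip_width - d
    return TorsoStimulus(
        left=left,
        right=right,
        hip_width=hip_width,
        waist_width=waist,
        whr=waist / hip_width,
        curviness=geo.mean_abs_curvature(left_curve, n=n_quad),
        level_ids=level_ids,
    )


def measure_whr(torso: TorsoStimulus, symmetry_tol: float = 1e-6) -> float:
    """Waist-to-hip ratio measured from the outline geometry alone.

    Hip width is the maximum horizontal separation between the two sides;
    waist width is the minimum separation over the torso *interior* (the two
    end cross-sections are excluded, so a chest or thigh edge never counts
    as the waist).  No stored metadata is consulted.
    """
    lp = torso.left.curve.control_points
    rp = torso.right.curve.control_points
    if lp.shape != rp.shape or not np.allclose(
        lp * np.array([-1.0, 1.0]), rp, atol=symmetry_tol * max(1.0, torso.hip_width)
    ):
        raise AsymmetryError("torso sides are not mirror images of each other")
    x_min, _, xi_min, xi_max = _x_extrema(torso.left.curve)
    # left side lies at x <= 0; width at height y is -2 * x_left(y)
    hip = -2.0 * min(x_min, xi_min)
    waist = -2.0 * xi_max
    if hip <= 0:
        raise AsymmetryError("left side does not lie left of the midline")
    return waist / hip


def measure_mmd(contour: Contour) -> float:
    """Max-min distance of one body side: the horizontal distance between
    its most lateral and most medial points (equals ``lateral_range``).

    Under mirror symmetry, hip width - waist width = 2 * MMD.
    """
    return contour.lateral_range


def build_stimulus_set(
    contours: Sequence[Contour],
    widths: Sequence[float],
    n_quad: int = 2048,
) -> StimulusSet:
    """Cross every contour with every hip width into a full factorial set.

    Returns the stimuli, a per-stimulus covariate table (curviness C, hip
    width W, measured WHR) and the pairwise Pearson correlations among
    (C, W, WHR) with their t statistics on n - 2 degrees of freedom.
    """
    from curvilinea.stats import pearson_r_t

    stimuli: list[TorsoStimulus] = []
    rows = []
    for ci, contour in enumerate(contours, start=1):
        curv = contour.curviness(n=n_quad)
        for wi, w in enumerate(widths, start=1):
            try:
                torso = synthesize_torso(contour, w, level_ids=(ci, wi),
                                         n_quad=n_quad)
            except OverlapError as e:
                raise OverlapError(w, e.min_width) from None
            stimuli.append(torso)
            rows.append({
                "stimulus_id": torso.stimulus_id,
                "curv_level": ci,
                "width_level": wi,
                "hip_width_px": torso.hip_width,
                "waist_width_px": torso.waist_width,
                "whr": torso.whr,
                "mean_abs_curvature": curv,
            })
    if not rows:
        return StimulusSet(
            stimuli=[], table=pd.DataFrame(columns=MANIFEST_COLUMNS),
            correlations=pd.DataFrame(columns=["pair", "r", "t", "df"]))
    table = pd.DataFrame(rows)
    pairs = [("mean_abs_curvature", "hip_width_px"),
             ("mean_abs_curvature", "whr"),
             ("hip_width_px", "whr")]
    short = {"mean_abs_curvature": "C", "hip_width_px": "W", "whr": "WHR"}
    corr_rows = []
    for a, b in pairs:
        r, t, df = pearson_r_t(table[a].to_numpy(), table[b].to_numpy())
        corr_rows.append({"pair": f"{short[a]}~{short[b]}", "r": r, "t": t,
                          "df": df})
    return StimulusSet(stimuli=stimuli, table=table,
                       correlations=pd.DataFrame(corr_rows))


# ---------------------------------------------------------------------------
# SVG export / re-import
# ---------------------------------------------------------------------------

def _side_path_data(curve: Curve, digits: int = 9) -> str:
    parts = []
    for seg in curve.segments:
        cp = seg.control_points
        if len(cp) > 4:
            raise ValueError("SVG export supports degree <= 3 segments only")
        if len(cp) == 2:
            cp = np.vstack([cp[0], cp[0] + (cp[1] - cp[0]) / 3,
                            cp[0] + 2 * (cp[1] - cp[0]) / 3, cp[1]])
        elif len(cp) == 3:
            cp = np.vstack([cp[0], cp[0] + 2.0 / 3.0 * (cp[1] - cp[0]),
                            cp[2] + 2.0 / 3.0 * (cp[1] - cp[2]), cp[2]])
        fmt = f"{{:.{digits}f}}"
        if not parts:
            parts.append("M " + " ".join(fmt.format(v) for v in cp[0]))
        parts.append("C " + " ".join(fmt.format(v) for v in cp[1:].ravel()))
    return " ".join(parts)


def torso_svg_text(torso: TorsoStimulus) -> str:
    """Render a torso as SVG: the left contour as the first path (exact
    control points, re-importable), plus a closed display outline.

    Closure segments joining the two sides at top and bottom are cosmetic
    and excluded from all measurements.
    """
    left = _side_path_data(torso.left.curve)
    right = _side_path_data(torso.right.curve)
    l0 = torso.left.curve.point(0.0)
    l1 = torso.left.curve.point(1.0)
    half = torso.hip_width / 2.0 + 5
    top, bot = l0[1] - 5, l1[1] + 5
    return "\n".join([
        '<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{-half:.1f} {top:.1f} {2 * half:.1f} {bot - top:.1f}">',
        f'<path id="left" d="{left}" fill="none" stroke="black" '
        'stroke-width="1.5"/>',
        f'<path id="right" d="{right}" fill="none" stroke="black" '
        'stroke-width="1.5"/>',
        f'<line x1="{l0[0]:.4f}" y1="{l0[1]:.4f}" x2="{-l0[0]:.4f}" '
        f'y2="{l0[1]:.4f}" stroke="black" stroke-width="1.5"/>',
        f'<line x1="{l1[0]:.4f}" y1="{l1[1]:.4f}" x2="{-l1[0]:.4f}" '
        f'y2="{l1[1]:.4f}" stroke="black" stroke-width="1.5"/>',
        "</svg>",
    ])


def torso_from_svg(path) -> TorsoStimulus:
    """Rebuild a torso from an exported SVG (first path = placed left side)."""
    left_curve = geo.read_svg_path(path)
    left = Contour(left_curve)
    right = Contour(geo.mirror_x(left_curve))
    x_min, _, xi_min, xi_max = _x_extrema(left_curve)
    hip = -2.0 * min(x_min, xi_min)
    waist = -2.0 * xi_max
    return TorsoStimulus(
        left=left, right=right, hip_width=hip, waist_width=waist,
        whr=waist / hip, curviness=geo.mean_abs_curvature(left_curve),
    )


MANIFEST_COLUMNS = ["stimulus_id", "curv_level", "width_level",
                    "hip_width_px", "waist_width_px", "whr",
                    "mean_abs_curvature"]


def export_stimuli(stimulus_set: StimulusSet, directory) -> pd.DataFrame:
    """Write one SVG per stimulus plus a manifest CSV; returns the manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for torso in stimulus_set.stimuli:
        (directory / f"{torso.stimulus_id}.svg").write_text(
            torso_svg_text(torso))
    manifest = stimulus_set.table[MANIFEST_COLUMNS] if len(stimulus_set.table) \
        else pd.DataFrame(columns=MANIFEST_COLUMNS)
    manifest.to_csv(directory / "manifest.csv", index=False)
    return manifest
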