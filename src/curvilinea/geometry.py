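"""Parametric Bézier curves and their differential geometry.

This module provides the geometric vocabulary used throughout the package:
Bézier curves (single segments of arbitrary degree and piecewise-cubic
paths), signed curvature computed from analytic derivatives, arc-length
sampling and quadrature, the arc-length-weighted mean absolute curvature
("curviness") statistic, curvature combs for visualization, and a
height-normalized RMSD between S-shaped contour lines.

Conventions
-----------
Coordinates are in pixels with ``y`` increasing downward (screen/SVG
convention).  Curvature is signed via

    kappa(t) = (x' y'' - y' x'') / (x'^2 + y'^2)^(3/2)

with derivatives taken analytically from the Bézier hodograph, so the sign
flips under mirroring and the magnitude is invariant under rigid motion and
scales as ``1/s`` under uniform scaling by ``s``.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

__all__ = [
    "CuspError",
    "BezierSegment",
    "BezierPath",
    "Curve",
    "SampledCurve",
    "CurvatureProfile",
    "CurvatureComb",
    "evaluate",
    "signed_curvature",
    "sample_with_arclength",
    "curvature_profile",
    "mean_abs_curvature",
    "translate",
    "mirror_x",
    "scale",
    "curvature_comb",
    "rmsd_between",
    "read_contour_csv",
    "write_contour_csv",
    "read_svg_path",
    "comb_to_svg",
]

# Tolerance (relative to the bounding-box diagonal) below which a tangent is
# treated as vanishing, i.e. the parameter is flagged as a cusp.
_CUSP_REL_TOL = 1e-9


class CuspError(ValueError):
    """The curve has a (near-)vanishing tangent at some parameter value."""

    def __init__(self, t: float):
        self.t = float(t)
        super().__init__(f"vanishing tangent (cusp) at t={t:.6g}")


def _as_points(points: Iterable) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("control points must be an (n, 2) array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("control points must be finite")
    return pts


class BezierSegment:
    """A single Bézier curve of arbitrary degree (>= 1).

    Parameters
    ----------
    control_points : array-like, shape (n, 2)
        Ordered control points; the degree is ``n - 1``.
    """

    def __init__(self, control_points: Iterable):
        pts = _as_points(control_points)
        if len(pts) < 2:
            raise ValueError("a Bézier curve needs at least 2 control points")
        if np.allclose(pts, pts[0]):
            raise ValueError("control points must not all coincide")
        self.control_points = pts

    @property
    def degree(self) -> int:
        return len(self.control_points) - 1

    def point(self, t):
        """Evaluate by de Casteljau's algorithm (vectorized over ``t``)."""
        t = np.asarray(t, dtype=float)
        beta = self.control_points[:, None, :] * np.ones_like(t)[None, :, None] \
            if t.ndim else self.control_points.copy()
        if t.ndim:
            for _ in range(self.degree):
                beta = (1.0 - t)[None, :, None] * beta[:-1] + t[None, :, None] * beta[1:]
            return beta[0]
        for _ in range(self.degree):
            beta = (1.0 - t) * beta[:-1] + t * beta[1:]
        return beta[0]

    def hodograph(self) -> "BezierSegment":
        """The derivative curve B'(t), itself a Bézier segment."""
        d = self.degree * np.diff(self.control_points, axis=0)
        if len(d) == 1:
            # constant derivative: represent as degenerate 2-point "curve"
            d = np.vstack([d, d])
            return _ConstSegment(d[0])
        return BezierSegment.__new__(BezierSegment)._init_raw(d)

    def _init_raw(self, pts: np.ndarray) -> "BezierSegment":
        self.control_points = np.asarray(pts, dtype=float)
        return self

    def derivatives(self, t):
        """First and second derivative vectors at ``t`` (analytic)."""
        h1 = self.hodograph()
        d1 = h1.point(t)
        if isinstance(h1, _ConstSegment) or h1.degree == 0:
            d2 = np.zeros_like(np.atleast_2d(d1)) if np.ndim(d1) > 1 else np.zeros(2)
        else:
            d2 = h1.hodograph().point(t)
        return d1, d2

    def bbox_diagonal(self) -> float:
        lo = self.control_points.min(axis=0)
        hi = self.control_points.max(axis=0)
        return float(np.hypot(*(hi - lo)))

    def x_power_coeffs(self) -> np.ndarray:
        """Monomial coefficients of x(t), ascending order."""
        return _bernstein_to_power(self.control_points[:, 0])

    def y_power_coeffs(self) -> np.ndarray:
        return _bernstein_to_power(self.control_points[:, 1])

    @property
    def segments(self):
        return [self]

    def transformed(self, fn) -> "BezierSegment":
        return BezierSegment(fn(self.control_points))

    def __repr__(self) -> str:  # pragma: no cover
        return f"BezierSegment(degree={self.degree})"


class _ConstSegment:
    """Internal: a constant vector-valued 'curve' (derivative of a line)."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=float)
        self.degree = 0

    def point(self, t):
        t = np.asarray(t, dtype=float)
        if t.ndim:
            return np.broadcast_to(self.value, (t.size, 2)).copy()
        return self.value.copy()

    def hodograph(self):
        return _ConstSegment(np.zeros(2))


class BezierPath:
    """A piecewise Bézier curve: ordered segments joined end to end.

    The global parameter ``t`` in [0, 1] maps uniformly onto the segments.
    Curvature is invariant under this reparameterization, so all curvature
    statistics agree with the per-segment values.
    """

    def __init__(self, segments: Sequence[BezierSegment]):
        segments = list(segments)
        if not segments:
            raise ValueError("path needs at least one segment")
        for a, b in zip(segments, segments[1:]):
            if not np.allclose(a.control_points[-1], b.control_points[0], atol=1e-6):
                raise ValueError("path segments must be contiguous")
        self.segments = segments

    @property
    def control_points(self) -> np.ndarray:
        pts = [self.segments[0].control_points]
        pts += [s.control_points[1:] for s in self.segments[1:]]
        return np.vstack(pts)

    def _locate(self, t):
        m = len(self.segments)
        t = np.asarray(t, dtype=float)
        idx = np.minimum((t * m).astype(int), m - 1)
        local = t * m - idx
        return idx, local

    def point(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx, local = self._locate(t_arr)
        out = np.empty((t_arr.size, 2))
        for i, seg in enumerate(self.segments):
            mask = idx == i
            if mask.any():
                out[mask] = seg.point(local[mask])
        return out if np.ndim(t) else out[0]

    def derivatives(self, t):
        """Global-parameter derivatives (chain rule with factor m)."""
        m = len(self.segments)
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        idx, local = self._locate(t_arr)
        d1 = np.empty((t_arr.size, 2))
        d2 = np.empty((t_arr.size, 2))
        for i, seg in enumerate(self.segments):
            mask = idx == i
            if mask.any():
                a, b = seg.derivatives(local[mask])
                d1[mask] = m * np.atleast_2d(a)
                d2[mask] = m * m * np.atleast_2d(b)
        if np.ndim(t):
            return d1, d2
        return d1[0], d2[0]

    def bbox_diagonal(self) -> float:
        pts = self.control_points
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return float(np.hypot(*(hi - lo)))

    def transformed(self, fn) -> "BezierPath":
        return BezierPath([s.transformed(fn) for s in self.segments])

    def __repr__(self) -> str:  # pragma: no cover
        return f"BezierPath(n_segments={len(self.segments)})"


Curve = Union[BezierSegment, BezierPath]


@dataclass
class SampledCurve:
    """A curve discretized on a monotone parameter grid with arc length."""

    params: np.ndarray      # t values, strictly increasing in [0, 1]
    points: np.ndarray      # (n, 2)
    arc_length: np.ndarray  # cumulative s(t), arc_length[0] == 0

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])


@dataclass
class CurvatureProfile:
    """Signed curvature along a curve with arc-length quadrature weights."""

    params: np.ndarray
    kappa: np.ndarray       # signed curvature, 1/px
    ds_weights: np.ndarray  # trapezoid weights in arc length, px
    mean_abs: float         # (1/L) * integral |kappa| ds


@dataclass
class CurvatureComb:
    """Normal-direction 'teeth' of length proportional to |kappa|."""

    base_points: np.ndarray
    teeth_tips: np.ndarray
    tooth_values: np.ndarray  # |kappa| at each base point
    scale: float


def _bernstein_to_power(b: np.ndarray) -> np.ndarray:
    """Convert 1-D Bernstein coefficients to monomial coefficients."""
    n = len(b) - 1
    c = np.zeros(n + 1)
    for j in range(n + 1):
        s = sum((-1) ** (j - i) * math.comb(j, i) * b[i] for i in range(j + 1))
        c[j] = math.comb(n, j) * s
    return c


def evaluate(curve: Curve, t):
    """Point on the curve at parameter ``t`` in [0, 1]."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("parameter t must lie in [0, 1]")
    return curve.point(t)


def _check_cusp(curve: Curve, t, speed) -> None:
    tol = _CUSP_REL_TOL * curve.bbox_diagonal()
    speed = np.atleast_1d(speed)
    if np.any(speed < tol):
        bad = np.atleast_1d(t)[np.argmin(speed)]
        raise CuspError(float(bad))


def signed_curvature(curve: Curve, t):
    """Signed curvature kappa(t) from the analytic Bézier derivatives."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or np.any(t_arr > 1):
        raise ValueError("parameter t must lie in [0, 1]")
    d1, d2 = curve.derivatives(t)
    d1a, d2a = np.atleast_2d(d1), np.atleast_2d(d2)
    speed = np.hypot(d1a[:, 0], d1a[:, 1])
    _check_cusp(curve, t, speed)
    cross = d1a[:, 0] * d2a[:, 1] - d1a[:, 1] * d2a[:, 0]
    kappa = cross / speed**3
    return kappa if np.ndim(t) else float(kappa[0])


def sample_with_arclength(curve: Curve, n: int) -> SampledCurve:
    """Sample ``n`` points on a uniform parameter grid with cumulative arc length.

    Arc length is computed by trapezoidal quadrature of the speed |B'(t)|,
    which converges at second order for regular curves.
    """
    if n < 2:
        raise ValueError("need n >= 2 sample points")
    t = np.linspace(0.0, 1.0, n)
    pts = curve.point(t)
    d1, _ = curve.derivatives(t)
    speed = np.hypot(d1[:, 0], d1[:, 1])
    dt = t[1] - t[0]
    seg = 0.5 * (speed[:-1] + speed[1:]) * dt
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return SampledCurve(params=t, points=pts, arc_length=s)


def curvature_profile(curve: Curve, n: int = 2048) -> CurvatureProfile:
    """Signed curvature on a uniform grid with arc-length trapezoid weights."""
    if n < 2:
        raise ValueError("need n >= 2 sample points")
    t = np.linspace(0.0, 1.0, n)
    d1, d2 = curve.derivatives(t)
    speed = np.hypot(d1[:, 0], d1[:, 1])
    _check_cusp(curve, t, speed)
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    kappa = cross / speed**3
    dt = t[1] - t[0]
    # trapezoid weights for integrating f(t) |B'(t)| dt
    w = np.empty(n)
    w[0] = 0.5 * speed[0]
    w[-1] = 0.5 * speed[-1]
    w[1:-1] = speed[1:-1]
    w *= dt
    total = float(w.sum())
    mean_abs = float(np.abs(kappa) @ w / total)
    return CurvatureProfile(params=t, kappa=kappa, ds_weights=w, mean_abs=mean_abs)


def mean_abs_curvature(curve: Curve, n: int = 2048) -> float:
    """Arc-length-weighted mean absolute curvature, (1/L) * int |kappa| ds.

    This is the scalar "curviness" statistic: invariant under translation
    and mirroring, and divided by ``s`` under uniform scaling by ``s``.
    """
    return curvature_profile(curve, n=n).mean_abs


def translate(curve: Curve, dx: float, dy: float) -> Curve:
    return curve.transformed(lambda p: p + np.array([dx, dy]))


def mirror_x(curve: Curve) -> Curve:
    """Reflect about the vertical axis x = 0."""
    return curve.transformed(lambda p: p * np.array([-1.0, 1.0]))


def scale(curve: Curve, factor: float) -> Curve:
    """Uniform scaling about the origin; ``factor`` must be positive."""
    if factor <= 0:
        raise ValueError("scale factor must be positive")
    return curve.transformed(lambda p: p * factor)


def curvature_comb(curve: Curve, n_teeth: int, scale: float) -> CurvatureComb:
    """Curvature comb: teeth along the unit normal, length = scale * |kappa|.

    Teeth sit at (approximately) equally spaced arc-length stations; the
    |kappa| values are returned for external color mapping.
    """
    if n_teeth < 2:
        raise ValueError("need at least 2 teeth")
    fine = sample_with_arclength(curve, max(4096, 4 * n_teeth))
    targets = np.linspace(0.0, fine.total_length, n_teeth)
    t = np.interp(targets, fine.arc_length, fine.params)
    base = curve.point(t)
    d1, d2 = curve.derivatives(t)
    speed = np.hypot(d1[:, 0], d1[:, 1])
    _check_cusp(curve, t, speed)
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    kappa = cross / speed**3
    # unit normal: left-hand normal of the tangent
    normal = np.column_stack([-d1[:, 1], d1[:, 0]]) / speed[:, None]
    tips = base + scale * np.abs(kappa)[:, None] * normal
    return CurvatureComb(base_points=base, teeth_tips=tips,
                         tooth_values=np.abs(kappa), scale=scale)


def _x_of_height(curve: Curve, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalize to unit height, align start point, return x at height stations."""
    fine = sample_with_arclength(curve, max(2048, 2 * n))
    pts = fine.points
    y = pts[:, 1]
    height = y[-1] - y[0]
    if height <= 0 or np.any(np.diff(y) <= 0):
        raise ValueError("curve is not monotone in height after normalization")
    ynorm = (y - y[0]) / height
    xnorm = (pts[:, 0] - pts[0, 0]) / height
    stations = np.linspace(0.0, 1.0, n)
    return stations, np.interp(stations, ynorm, xnorm)


def rmsd_between(curve_a: Curve, curve_b: Curve, n: int = 1000) -> float:
    """Height-normalized, endpoint-aligned RMSD between two S-curves.

    Both curves are uniformly scaled to unit height and translated so their
    start points coincide; the RMSD of the horizontal offsets is taken at
    ``n`` equally spaced height stations.  Symmetric in its arguments and
    zero iff the normalized curves coincide at every station.
    """
    if n < 2:
        raise ValueError("need n >= 2 stations")
    for name, c in (("curve_a", curve_a), ("curve_b", curve_b)):
        try:
            _x_of_height(c, n)
        except ValueError as e:
            raise ValueError(f"{name}: {e}") from None
    _, xa = _x_of_height(curve_a, n)
    _, xb = _x_of_height(curve_b, n)
    return float(np.sqrt(np.mean((xa - xb) ** 2)))


# ---------------------------------------------------------------------------
# I/O: contour CSV, SVG path import, comb SVG export
# ---------------------------------------------------------------------------

def read_contour_csv(path) -> BezierSegment:
    """Read one control point per row (columns x, y; header required)."""
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"x", "y"} <= set(reader.fieldnames):
            raise ValueError(f"{path}: expected header with columns x,y")
        pts = [(float(row["x"]), float(row["y"])) for row in reader]
    return BezierSegment(pts)


def write_contour_csv(curve: Curve, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for x, y in curve.control_points:
            writer.writerow([repr(float(x)), repr(float(y))])


_SVG_TOKEN = re.compile(r"([MmCcZz])|(-?\d*\.?\d+(?:[eE][-+]?\d+)?)")


def parse_svg_path_data(d: str) -> BezierPath:
    """Parse an SVG path 'd' string restricted to M/m and cubic C/c commands."""
    tokens = _SVG_TOKEN.findall(d)
    pos = np.zeros(2)
    segments: list[BezierSegment] = []
    i = 0
    nums: list[float] = []

    def take(k: int) -> list[float]:
        nonlocal i
        vals = []
        while len(vals) < k:
            cmd, num = tokens[i]
            i += 1
            if cmd:
                raise ValueError(f"unexpected command '{cmd}' inside coordinates")
            vals.append(float(num))
        return vals

    started = False
    while i < len(tokens):
        cmd, num = tokens[i]
        if not cmd:
            raise ValueError("path data must start with a command letter")
        i += 1
        if cmd in "Mm":
            x, y = take(2)
            pos = np.array([x, y]) if cmd == "M" else pos + [x, y]
            started = True
        elif cmd in "Cc":
            if not started:
                raise ValueError("cubic segment before any moveto")
            while i < len(tokens) and not tokens[i][0]:
                c = np.array(take(6)).reshape(3, 2)
                if cmd == "c":
                    c = c + pos
                segments.append(BezierSegment(np.vstack([pos, c])))
                pos = c[-1]
        elif cmd in "Zz":
            break
        else:  # pragma: no cover
            raise ValueError(f"unsupported path command '{cmd}'")
        nums.clear()
    if not segments:
        raise ValueError("path contains no cubic segments")
    return BezierPath(segments)


def read_svg_path(path) -> BezierPath:
    """Import the first <path> element of an SVG file (cubic segments only)."""
    import xml.etree.ElementTree as ET

    root = ET.parse(path).getroot()
    for el in root.iter():
        if el.tag.endswith("path") and "d" in el.attrib:
            return parse_svg_path_data(el.attrib["d"])
    raise ValueError(f"{path}: no <path> element with a 'd' attribute found")


def _path_data(curve: Curve) -> str:
    parts = []
    for seg in curve.segments:
        cp = seg.control_points
        if not parts:
            parts.append(f"M {cp[0, 0]:.4f} {cp[0, 1]:.4f}")
        if len(cp) == 4:
            c = cp[1:].ravel()
        elif len(cp) == 3:  # exact degree elevation quadratic -> cubic
            c = np.vstack([cp[0] + 2.0 / 3.0 * (cp[1] - cp[0]),
                           cp[2] + 2.0 / 3.0 * (cp[1] - cp[2]), cp[2]]).ravel()
        elif len(cp) == 2:  # promote a line to a cubic
            c = np.vstack([cp[0] + (cp[1] - cp[0]) / 3,
                           cp[0] + 2 * (cp[1] - cp[0]) / 3, cp[1]]).ravel()
        else:
            raise ValueError("SVG export supports degree <= 3 segments only")
        parts.append("C " + " ".join(f"{v:.4f}" for v in c))
    return " ".join(parts)


def comb_to_svg(curve: Curve, comb: CurvatureComb, path,
                colormap: str = "jet") -> None:
    """Write the curve and its curvature comb to an SVG file.

    Teeth are colored by |kappa| through a matplotlib heat-map colormap.
    """
    from matplotlib import colormaps
    from matplotlib.colors import to_hex

    cmap = colormaps[colormap]
    vals = comb.tooth_values
    vmax = vals.max() if vals.max() > 0 else 1.0
    pts = np.vstack([comb.base_points, comb.teeth_tips])
    lo = pts.min(axis=0) - 10
    hi = pts.max(axis=0) + 10
    w, h = hi - lo
    lines = [
        f'<svg xmlns="http://www.w3.org/2000/svg" '
        f'viewBox="{lo[0]:.1f} {lo[1]:.1f} {w:.1f} {h:.1f}">',
        f'<path d="{_path_data(curve)}" fill="none" stroke="black" '
        f'stroke-width="1.5"/>',
    ]
    for base, tip, v in zip(comb.base_points, comb.teeth_tips, vals):
        color = to_hex(cmap(float(v / vmax)))
        lines.append(
            f'<line x1="{base[0]:.3f}" y1="{base[1]:.3f}" x2="{tip[0]:.3f}" '
            f'y2="{tip[1]:.3f}" stroke="{color}" stroke-width="0.8"/>'
        )
    lines.append("</svg>")
    Path(path).write_text("\n".join(lines))
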