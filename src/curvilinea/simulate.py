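"""Synthetic contour families and rater populations.

Real S-shaped body contours are not redistributable, so this module builds
a parametric stand-in family: left-side contours are cubic splines x(y)
through four anatomical anchor stations (chest, waist, hip, thigh) whose
waist indentation controls the curviness.  Indentations decrease across
levels, which makes the measured mean absolute curvature strictly
decreasing, and the family's default spans roughly 0.0026-0.012 per px at
300 px body height — the range that spans realistically curvy to nearly
straight torso outlines.

Raters share a single attractiveness surface — an inverted U in curviness
plus a linear width effect — and differ by a Gaussian intercept; residual
noise is added per rating and the result is clipped to the 1-100
visual-analog scale.  Randomness is organised as one seed with per-rater
substreams, so enlarging the panel never perturbs existing raters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import CubicSpline

from curvilinea import geometry as geo
from curvilinea import stats as st
from curvilinea.geometry import BezierPath, BezierSegment
from curvilinea.stimuli import Contour, StimulusSet, build_stimulus_set

__all__ = [
    "DEFAULT_WIDTHS",
    "ContourFamilySpec",
    "AttractivenessSurface",
    "RaterModel",
    "SimulationConfig",
    "contour_at_indentation",
    "generate_contour_family",
    "expected_rating",
    "simulate_ratings",
    "parameter_recovery_study",
    "RecoveryReport",
]

# hip widths (px): chosen so the curviest default contour (lateral range
# 52.5 px) spans WHR 0.50..0.70 in steps of 0.05
DEFAULT_WIDTHS = (210.0, 233.0, 262.0, 300.0, 350.0)


@dataclass(frozen=True)
class ContourFamilySpec:
    """A family of left-side contours ordered from most to least curvy.

    ``indentation_range`` gives the (largest, smallest) waist indentation in
    px at ``height`` px body height; levels are geometrically spaced between
    them, and the indentation equals the contour's lateral range exactly
    (the spline is rescaled horizontally after construction, so overshoot
    never widens the hip-waist offset).

    Anchors run chest, bust, waist, hip, thigh from top to bottom.  The
    waist sits at the full indentation (most medial) and the hip at zero
    (most lateral); chest, bust and thigh offsets are fractions of the
    indentation.  The default layout places the bust as lateral as the hip
    with a deep waist between them — a corset-like silhouette — which at
    lateral range 52.5 px yields a mean absolute curvature near 0.012 per
    px at the top level and near 0.003 at the bottom, the realistic span
    from tightly curved to nearly straight torso outlines.
    """

    n_levels: int = 5
    indentation_range: tuple[float, float] = (52.5, 8.0)
    stations: tuple[float, float, float, float, float] = (
        0.0, 0.10, 0.38, 0.64, 1.0)
    chest_frac: float = 0.70   # chest offset as fraction of the indentation
    bust_frac: float = 0.0     # bust offset (0 = as lateral as the hip)
    thigh_frac: float = 0.50   # thigh offset as fraction of the indentation
    height: float = 300.0

    def indentations(self) -> np.ndarray:
        hi, lo = self.indentation_range
        if not (hi > lo > 0):
            raise ValueError("indentation_range must be (largest, smallest), "
                             "both positive")
        if self.n_levels < 2:
            raise ValueError("need at least 2 curviness levels")
        return np.geomspace(hi, lo, self.n_levels)


def _spline_to_bezier(ys: np.ndarray, xs: np.ndarray) -> BezierPath:
    """Natural cubic spline x(y) through anchors, as cubic Bézier segments."""
    cs = CubicSpline(ys, xs, bc_type="natural")
    segments = []
    for i in range(len(ys) - 1):
        y0, y1 = ys[i], ys[i + 1]
        h = y1 - y0
        # cs.c[:, i] are coefficients of (y - y0)^3 .. (y - y0)^0
        c3, c2, c1, c0 = cs.c[:, i]
        # compose with y = y0 + t h to get x(t) monomials
        a = np.array([c0, c1 * h, c2 * h**2, c3 * h**3])
        bx = np.array([a[0],
                       a[0] + a[1] / 3.0,
                       a[0] + 2.0 * a[1] / 3.0 + a[2] / 3.0,
                       a[0] + a[1] + a[2] + a[3]])
        by = np.array([y0, y0 + h / 3.0, y0 + 2.0 * h / 3.0, y1])
        segments.append(BezierSegment(np.column_stack([bx, by])))
    return BezierPath(segments)


def contour_at_indentation(spec: ContourFamilySpec, indent: float) -> Contour:
    """A single contour of the family at an arbitrary waist indentation.

    ``indent = 0`` yields a straight vertical contour (curviness 0); for
    positive indentations the lateral range equals ``indent`` exactly.
    """
    if indent < 0:
        raise ValueError("indentation must be non-negative")
    ys = np.asarray(spec.stations, dtype=float) * spec.height
    if not np.all(np.diff(ys) > 0):
        raise ValueError("anchor stations must be strictly increasing")
    xs = np.array([spec.chest_frac * indent, spec.bust_frac * indent,
                   indent, 0.0, spec.thigh_frac * indent])
    path = _spline_to_bezier(ys, xs)
    contour = Contour(path)
    lr = contour.lateral_range
    if indent == 0 or lr <= 0:
        return contour
    factor = indent / lr
    if abs(factor - 1.0) > 1e-12:
        contour = Contour(path.transformed(
            lambda p: p * np.array([factor, 1.0])))
    return contour


def generate_contour_family(spec: ContourFamilySpec = ContourFamilySpec()
                            ) -> list[Contour]:
    """Build the contour family; curviness is strictly decreasing in level.

    Each contour is an S-curve through chest / bust / waist / hip / thigh
    anchors: the hip is the most lateral point (x = 0 in the contour's
    local frame) and the waist the most medial (x = indentation).  After
    construction the x coordinates are rescaled so the measured lateral
    range equals the indentation exactly.
    """
    indents = spec.indentations()
    contours = []
    prev_curv = np.inf
    for level, indent in enumerate(indents, start=1):
        try:
            contour = contour_at_indentation(spec, indent)
        except (ValueError, ArithmeticError) as e:
            raise ValueError(f"level {level}: {e}") from None
        curv = contour.curviness()
        if not curv < prev_curv:
            raise ValueError(
                f"level {level}: curviness {curv:g} not below previous level "
                f"{prev_curv:g}; indentations must decrease strictly")
        prev_curv = curv
        contours.append(contour)
    return contours


@dataclass(frozen=True)
class AttractivenessSurface:
    """Shared rating surface: inverted U in curviness, linear in width.

    expected = baseline - curvature_penalty (C - C*)^2 + width_slope W
               [+ interaction (C - C*) W],   clipped to [1, 100].

    Defaults place the peak at the middle curviness level of the default
    contour family (measured mean |kappa| 0.0064 per px) and use a width
    slope of -0.185 rating units per px, so noise-free cell means land in
    the upper teens to high sixties across the default 5 x 5 design.
    """

    peak_curviness: float = 0.0064       # C*, 1/px
    curvature_penalty: float = 7.0e5     # rating units per (1/px)^2
    width_slope: float = -0.185          # rating units per px
    baseline: float = 108.0              # rating units at C = C*, W = 0
    interaction_slope: float = 0.0       # rating units per (1/px * px)

    def __post_init__(self) -> None:
        if self.curvature_penalty <= 0:
            raise ValueError("curvature_penalty must be positive "
                             "(inverted-U surface)")


def expected_rating(surface: AttractivenessSurface, c, w) -> np.ndarray:
    """Noise-free expected rating at curviness ``c`` and hip width ``w``."""
    c = np.asarray(c, dtype=float)
    w = np.asarray(w, dtype=float)
    dc = c - surface.peak_curviness
    val = (surface.baseline - surface.curvature_penalty * dc**2
           + surface.width_slope * w + surface.interaction_slope * dc * w)
    return np.clip(val, st.RATING_MIN, st.RATING_MAX)


@dataclass(frozen=True)
class RaterModel:
    """A panel of raters: Gaussian intercepts plus per-rating residual noise."""

    n_raters: int = 98
    rater_intercept_sd: float = 8.0
    residual_sd: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_raters < 1:
            raise ValueError("need at least one rater")
        if self.rater_intercept_sd < 0 or self.residual_sd < 0:
            raise ValueError("noise SDs must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    family: ContourFamilySpec = ContourFamilySpec()
    widths: tuple[float, ...] = DEFAULT_WIDTHS
    surface: AttractivenessSurface = AttractivenessSurface()
    raters: RaterModel = RaterModel()
    replications: int = 1


def build_design(config: SimulationConfig) -> StimulusSet:
    """The stimulus set implied by a simulation config."""
    contours = generate_contour_family(config.family)
    return build_stimulus_set(contours, config.widths)


def simulate_ratings(config: SimulationConfig,
                     stimulus_set: StimulusSet | None = None,
                     seed=None) -> pd.DataFrame:
    """Simulate a complete ratings table (every rater rates every stimulus).

    rating = expected surface value + rater intercept + residual noise,
    clipped to [1, 100].  Each rater draws from an independent substream of
    the seed, so rater r's data do not change when ``n_raters`` grows.
    """
    if stimulus_set is None:
        stimulus_set = build_design(config)
    table = stimulus_set.table
    mu = expected_rating(config.surface,
                         table["mean_abs_curvature"].to_numpy(),
                         table["hip_width_px"].to_numpy())
    if seed is None:
        seed = config.raters.seed
    seed_key = list(np.atleast_1d(np.asarray(seed, dtype=np.uint64)))
    frames = []
    n_stim = len(table)
    for r in range(config.raters.n_raters):
        rng = np.random.default_rng(seed_key + [r])
        intercept = rng.normal(0.0, config.raters.rater_intercept_sd)
        eps = rng.normal(0.0, config.raters.residual_sd, n_stim)
        ratings = np.clip(mu + intercept + eps, st.RATING_MIN, st.RATING_MAX)
        frames.append(pd.DataFrame({
            "rater_id": f"r{r + 1:03d}",
            "stimulus_id": table["stimulus_id"].to_numpy(),
            "rating": ratings,
        }))
    return pd.concat(frames, ignore_index=True)


@dataclass
class RecoveryReport:
    """Outcome of a simulate-and-refit study over many replications."""

    replications: pd.DataFrame   # one row per replication
    summary: dict

    def to_dict(self) -> dict:
        return {"summary": self.summary,
                "replications": self.replications.to_dict(orient="records")}


def parameter_recovery_study(config: SimulationConfig,
                             stimulus_set: StimulusSet | None = None
                             ) -> RecoveryReport:
    """Simulate ratings from the curviness surface and refit both hypotheses.

    Per replication: simulate a full panel, take per-stimulus cell means,
    fit the curviness model and the WHR model, and record R², AIC, the raw
    width coefficient of the curviness model and its 95% confidence
    interval.  The summary reports the width-slope bias (against the
    generating value), CI coverage, the distribution of ΔR² and ΔAIC
    (curviness - WHR), and the rate at which the generating curviness model
    wins on AIC.
    """
    if config.replications < 1:
        raise ValueError("need at least one replication")
    if stimulus_set is None:
        stimulus_set = build_design(config)
    table = stimulus_set.table
    base_seed = config.raters.seed
    true_slope = config.surface.width_slope
    rows = []
    for rep in range(config.replications):
        ratings = simulate_ratings(config, stimulus_set,
                                   seed=[base_seed, rep])
        cm = st.cell_means(ratings, stimulus_ids=table["stimulus_id"])
        cells = cm.aligned_to(table)
        fit_c = st.fit_curviness_model(cells)
        fit_w = st.fit_whr_model(cells)
        est = fit_c.terms.loc["W", "estimate"]
        se = fit_c.terms.loc["W", "se"]
        tcrit = float(sps.t.ppf(0.975, fit_c.df_resid))
        rows.append({
            "replication": rep,
            "r2_curviness": fit_c.r_squared,
            "r2_whr": fit_w.r_squared,
            "aic_curviness": fit_c.aic,
            "aic_whr": fit_w.aic,
            "delta_r2": fit_c.r_squared - fit_w.r_squared,
            "delta_aic": fit_c.aic - fit_w.aic,
            "width_slope_est": est,
            "width_slope_se": se,
            "covers_truth": bool(abs(est - true_slope) <= tcrit * se),
            "curviness_wins_aic": bool(fit_c.aic < fit_w.aic),
        })
    reps = pd.DataFrame(rows)
    summary = {
        "n_replications": config.replications,
        "aic_win_rate": float(reps["curviness_wins_aic"].mean()),
        "mean_delta_aic": float(reps["delta_aic"].mean()),
        "mean_delta_r2": float(reps["delta_r2"].mean()),
        "mean_r2_curviness": float(reps["r2_curviness"].mean()),
        "mean_r2_whr": float(reps["r2_whr"].mean()),
        "width_slope_true": true_slope,
        "width_slope_mean": float(reps["width_slope_est"].mean()),
        "width_slope_bias": float(reps["width_slope_est"].mean() - true_slope),
        "width_slope_mc_se": float(reps["width_slope_est"].std(ddof=1)
                                   / np.sqrt(len(reps))) if len(reps) > 1 else np.nan,
        "ci_coverage": float(reps["covers_truth"].mean()),
    }
    return RecoveryReport(replications=reps, summary=summary)
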