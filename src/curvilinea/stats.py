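"""Statistical models for attractiveness ratings.

Two rival accounts of how attractive a torso looks are expressed as ordinary
least-squares models of the per-stimulus mean rating A:

* WHR hypothesis:        A ~ poly(WHR, 2) + W
* curviness hypothesis:  A ~ poly(C, 2) + W

where ``poly`` is an orthogonal (centered, unit-norm) quadratic polynomial
basis, W is the hip width in px and C the mean absolute curvature in 1/px.
The orthogonal basis leaves fitted values, R² and AIC identical to the raw
power basis but decorrelates the coefficient estimates, which is why the
linear and quadratic terms of one predictor share the same standard error.

The module also provides the rating-side toolkit around those models:
per-stimulus cell means, an augmented-prediction F test for comparing the
two non-nested hypotheses, a two-way fully-within-subjects ANOVA with
Greenhouse–Geisser correction and generalized eta squared, Bonferroni
paired t tests, and the ICC(C,k) inter-rater consistency coefficient.

AIC is reported under the full Gaussian-likelihood convention

    AIC = n log(2 pi RSS / n) + n + 2 (k + 1)

(the error variance counts as a parameter), the convention used by R's
``AIC`` on ``lm`` fits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RATING_MIN",
    "RATING_MAX",
    "CellMeans",
    "ModelFit",
    "ModelComparison",
    "ICCResult",
    "validate_ratings",
    "read_ratings_csv",
    "cell_means",
    "orthogonal_poly",
    "ols_fit",
    "fit_whr_model",
    "fit_curviness_model",
    "fit_interaction_variant",
    "augmented_prediction_test",
    "rm_anova",
    "bonferroni_pairwise",
    "icc_c_k",
    "pearson_r_t",
]

RATING_MIN = 1.0
RATING_MAX = 100.0


# ---------------------------------------------------------------------------
# Ratings tables and cell means
# ---------------------------------------------------------------------------

def validate_ratings(ratings: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format ratings table (rater_id, stimulus_id, rating)."""
    required = {"rater_id", "stimulus_id", "rating"}
    missing = required - set(ratings.columns)
    if missing:
        raise ValueError(f"ratings table missing columns: {sorted(missing)}")
    r = ratings["rating"].to_numpy(dtype=float)
    if np.any(~np.isfinite(r)) or r.min() < RATING_MIN or r.max() > RATING_MAX:
        raise ValueError(
            f"ratings must lie on the visual-analog scale "
            f"[{RATING_MIN:g}, {RATING_MAX:g}]")
    if ratings.duplicated(["rater_id", "stimulus_id"]).any():
        dup = ratings[ratings.duplicated(["rater_id", "stimulus_id"])]
        raise ValueError(
            "duplicate (rater, stimulus) pairs, e.g. "
            f"{dup.iloc[0]['rater_id']!r}/{dup.iloc[0]['stimulus_id']!r}")
    return ratings


def read_ratings_csv(path) -> pd.DataFrame:
    return validate_ratings(pd.read_csv(path))


@dataclass
class CellMeans:
    """Per-stimulus mean ratings with grand summary statistics."""

    per_stimulus: pd.Series  # indexed by stimulus_id
    grand_mean: float
    grand_sd: float

    def aligned_to(self, manifest: pd.DataFrame) -> pd.DataFrame:
        """Merge means onto a stimulus manifest (key: stimulus_id)."""
        out = manifest.copy()
        out["rating"] = out["stimulus_id"].map(self.per_stimulus)
        if out["rating"].isna().any():
            missing = out.loc[out["rating"].isna(), "stimulus_id"].tolist()
            raise ValueError(f"no ratings for stimuli: {missing}")
        return out


def cell_means(ratings: pd.DataFrame,
               stimulus_ids: Sequence | None = None) -> CellMeans:
    """Arithmetic mean rating per stimulus.

    If ``stimulus_ids`` is given, every listed stimulus must have at least
    one rating.
    """
    validate_ratings(ratings)
    means = ratings.groupby("stimulus_id")["rating"].mean()
    if stimulus_ids is not None:
        missing = [s for s in stimulus_ids if s not in means.index]
        if missing:
            raise ValueError(f"stimuli without any rating: {missing}")
        means = means.loc[list(stimulus_ids)]
    return CellMeans(per_stimulus=means,
                     grand_mean=float(means.mean()),
                     grand_sd=float(means.std(ddof=1)) if len(means) > 1 else 0.0)


# ---------------------------------------------------------------------------
# Design matrices and OLS
# ---------------------------------------------------------------------------

def orthogonal_poly(x, degree: int) -> np.ndarray:
    """Orthogonal polynomial design columns of degree 1..degree.

    QR-based construction on the raw power basis (the construction behind
    R's ``poly``): columns are centered, mutually orthogonal and unit-norm,
    and span the same space as ``x, x**2, ..., x**degree``.
    """
    x = np.asarray(x, dtype=float)
    if len(np.unique(x)) < degree + 1:
        raise ValueError(
            f"need at least {degree + 1} distinct x values for degree "
            f"{degree}, got {len(np.unique(x))}")
    xc = x - x.mean()
    raw = np.column_stack([xc**d for d in range(degree + 1)])
    q, r = np.linalg.qr(raw)
    z = q[:, 1:degree + 1]
    # fix signs so the linear column correlates positively with x
    for j in range(z.shape[1]):
        lead = np.sign(r[j + 1, j + 1])
        if lead < 0:
            z[:, j] = -z[:, j]
    # unit norm (QR already gives it; renormalize defensively)
    z = z / np.linalg.norm(z, axis=0)
    return z


@dataclass
class ModelFit:
    """An OLS fit: per-term table plus global fit statistics."""

    terms: pd.DataFrame       # index: term name; estimate, se, t, p
    r_squared: float
    aic: float
    df_model: int             # number of non-intercept columns
    df_resid: int
    fittedvalues: np.ndarray
    resid: np.ndarray
    design: pd.DataFrame = field(repr=False)
    y: np.ndarray = field(repr=False)
    condition_number: float = np.nan
    formula: str = ""

    @property
    def nobs(self) -> int:
        return len(self.y)

    @property
    def rss(self) -> float:
        return float(self.resid @ self.resid)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "r_squared": self.r_squared,
            "aic": self.aic,
            "df_model": self.df_model,
            "df_resid": self.df_resid,
            "condition_number": self.condition_number,
            "terms": self.terms.reset_index()
                         .rename(columns={"index": "term"})
                         .to_dict(orient="records"),
        }


class CollinearityError(np.linalg.LinAlgError):
    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; dependent "
                         f"columns involve {self.columns}")


def _gaussian_aic(n: int, rss: float, k: int) -> float:
    """AIC with the full Gaussian constant; k = regression coefficients."""
    return n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * (k + 1)


def ols_fit(y, design: pd.DataFrame, formula: str = "") -> ModelFit:
    """Ordinary least squares of ``y`` on named design columns.

    An intercept column named ``Intercept`` is prepended if absent.  The fit
    itself is delegated to statsmodels; AIC is recomputed under the
    R-compatible Gaussian convention (see module docstring).
    """
    import statsmodels.api as sm

    y = np.asarray(y, dtype=float)
    X = design.copy()
    if "Intercept" not in X.columns:
        X.insert(0, "Intercept", 1.0)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more observations ({n}) than columns ({k})")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < k:
        # name columns involved in the dependency via QR pivoting
        _, r = np.linalg.qr(X.to_numpy())
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-10 * diag.max())[0]]
        raise CollinearityError(bad or list(X.columns))
    res = sm.OLS(y, X).fit()
    terms = pd.DataFrame({
        "estimate": res.params,
        "se": res.bse,
        "t": res.tvalues,
        "p": res.pvalues,
    })
    rss = float(res.ssr)
    cond = float(np.linalg.cond(X.to_numpy()))
    return ModelFit(
        terms=terms,
        r_squared=float(res.rsquared),
        aic=_gaussian_aic(n, rss, k),
        df_model=k - 1,
        df_resid=n - k,
        fittedvalues=np.asarray(res.fittedvalues, dtype=float),
        resid=np.asarray(res.resid, dtype=float),
        design=X,
        y=y,
        condition_number=cond,
        formula=formula,
    )


def _poly_design(cells: pd.DataFrame, predictor: str, label: str,
                 basis: str, interaction: bool) -> pd.DataFrame:
    x = cells[predictor].to_numpy(dtype=float)
    w = cells["hip_width_px"].to_numpy(dtype=float)
    if basis == "orthogonal":
        z = orthogonal_poly(x, 2)
        cols = {label: z[:, 0], f"{label}^2": z[:, 1]}
    elif basis == "raw":
        cols = {label: x, f"{label}^2": x**2}
    else:
        raise ValueError("basis must be 'orthogonal' or 'raw'")
    cols["W"] = w
    if interaction:
        names = [label, f"{label}^2"]
        for name in names:
            cols[f"{name}:W"] = cols[name] * w
    return pd.DataFrame(cols, index=cells.index)


def _require_cells(cells: pd.DataFrame, predictor: str, minimum: int) -> None:
    if len(cells) < minimum:
        raise ValueError(f"need at least {minimum} stimuli, got {len(cells)}")
    for col in ("rating", predictor, "hip_width_px"):
        if col not in cells.columns:
            raise ValueError(f"cells table missing column {col!r}")


def fit_whr_model(cells: pd.DataFrame, basis: str = "orthogonal") -> ModelFit:
    """The WHR hypothesis: A ~ poly(WHR, 2) + W on per-stimulus means.

    ``cells`` must carry columns ``rating``, ``whr``, ``hip_width_px``.
    """
    _require_cells(cells, "whr", 5)
    design = _poly_design(cells, "whr", "WHR", basis, interaction=False)
    return ols_fit(cells["rating"], design, formula="A ~ poly(WHR,2) + W")


def fit_curviness_model(cells: pd.DataFrame,
                        basis: str = "orthogonal") -> ModelFit:
    """The curviness hypothesis: A ~ poly(C, 2) + W on per-stimulus means.

    ``cells`` must carry columns ``rating``, ``mean_abs_curvature``,
    ``hip_width_px``.
    """
    _require_cells(cells, "mean_abs_curvature", 5)
    design = _poly_design(cells, "mean_abs_curvature", "C", basis,
                          interaction=False)
    return ols_fit(cells["rating"], design, formula="A ~ poly(C,2) + W")


def fit_interaction_variant(cells: pd.DataFrame, predictor: str,
                            basis: str = "orthogonal") -> ModelFit:
    """Interaction variant A ~ poly(X, 2) * W for X in {WHR, C}.

    Adds width-by-polynomial product columns; the condition number of the
    design is reported as the collinearity diagnostic.
    """
    key = {"WHR": "whr", "C": "mean_abs_curvature"}.get(predictor)
    if key is None:
        raise ValueError("predictor must be 'WHR' or 'C'")
    _require_cells(cells, key, 7)
    design = _poly_design(cells, key, predictor, basis, interaction=True)
    return ols_fit(cells["rating"], design,
                   formula=f"A ~ poly({predictor},2) * W")


# ---------------------------------------------------------------------------
# Model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """Augmented-prediction comparison of two hypothesis models."""

    base: ModelFit
    donor: ModelFit
    augmented: ModelFit | None
    delta_r_squared: float
    delta_aic: float          # donor AIC - base AIC
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "base_formula": self.base.formula,
            "donor_formula": self.donor.formula,
            "base_r_squared": self.base.r_squared,
            "donor_r_squared": self.donor.r_squared,
            "base_aic": self.base.aic,
            "donor_aic": self.donor.aic,
            "delta_r_squared": self.delta_r_squared,
            "delta_aic": self.delta_aic,
            "f_statistic": self.f_statistic,
            "df_num": self.df_num,
            "df_den": self.df_den,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
        }


def augmented_prediction_test(base: ModelFit, donor: ModelFit) -> ModelComparison:
    """Test whether the donor model's predictions improve on the base model.

    The base design is refit with one extra column — the donor model's
    fitted values — and the added column is tested with an F statistic on
    (1, n - p_base - 2) degrees of freedom.  If the donor predictions are
    (numerically) collinear with the base design the result is flagged as
    degenerate rather than raised.
    """
    if base.nobs != donor.nobs or not np.allclose(base.y, donor.y):
        raise ValueError("base and donor must be fit to the same response")
    delta_aic = donor.aic - base.aic
    aug_design = base.design.drop(columns="Intercept").copy()
    aug_design["donor_pred"] = donor.fittedvalues
    try:
        augmented = ols_fit(base.y, aug_design,
                            formula=f"{base.formula} + fitted[{donor.formula}]")
    except (CollinearityError, ValueError):
        return ModelComparison(base=base, donor=donor, augmented=None,
                               delta_r_squared=0.0, delta_aic=delta_aic,
                               f_statistic=np.nan, df_num=1, df_den=0,
                               p_value=np.nan, degenerate=True)
    df_den = augmented.df_resid
    rss_base, rss_aug = base.rss, augmented.rss
    if rss_aug <= 0 or (rss_base - rss_aug) / max(rss_base, 1e-300) < 1e-12:
        f = 0.0 if rss_aug > 0 else np.inf
    else:
        f = (rss_base - rss_aug) / (rss_aug / df_den)
    degenerate = augmented.condition_number > 1e12
    p = float(sps.f.sf(f, 1, df_den)) if np.isfinite(f) else 0.0
    return ModelComparison(
        base=base, donor=donor, augmented=augmented,
        delta_r_squared=augmented.r_squared - base.r_squared,
        delta_aic=delta_aic, f_statistic=float(f), df_num=1, df_den=df_den,
        p_value=p, degenerate=degenerate)


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA, pairwise tests, ICC
# ---------------------------------------------------------------------------

def _complete_within_matrix(ratings: pd.DataFrame,
                            cell_of: Mapping) -> tuple[np.ndarray, list, list, list]:
    """Rater x (A-level x B-level) cell matrix for a fully-crossed design."""
    df = ratings.copy()
    df["_a"] = df["stimulus_id"].map(lambda s: cell_of[s][0])
    df["_b"] = df["stimulus_id"].map(lambda s: cell_of[s][1])
    cell = df.groupby(["rater_id", "_a", "_b"])["rating"].mean().unstack(["_a", "_b"])
    a_levels = sorted({a for a, _ in cell.columns})
    b_levels = sorted({b for _, b in cell.columns})
    cell = cell.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
    if cell.isna().any().any():
        missing = [str(c) for c in cell.columns[cell.isna().any()]]
        raise ValueError(f"incomplete design; missing cells: {missing}")
    return cell.to_numpy(), list(cell.index), a_levels, b_levels


def _gg_epsilon(Y: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the covariance of within contrasts."""
    df = contrast.shape[0]
    if df <= 1:
        return 1.0
    S = np.cov(Y, rowvar=False)
    M = contrast @ S @ contrast.T
    tr = np.trace(M)
    tr2 = np.trace(M @ M)
    if tr2 <= 0:
        return 1.0
    return float(min(1.0, tr**2 / (df * tr2)))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrasts (Helmert-like, rows sum to zero)."""
    h = np.zeros((k - 1, k))
    for i in range(k - 1):
        h[i, : i + 1] = 1.0
        h[i, i + 1] = -(i + 1.0)
        h[i] /= np.linalg.norm(h[i])
    return h


def rm_anova(ratings: pd.DataFrame, cell_of: Mapping,
             factor_names: tuple[str, str] = ("A", "B")) -> pd.DataFrame:
    """Two-way fully-within-subjects ANOVA on a complete crossed design.

    ``cell_of`` maps each stimulus_id to its (factor_a level, factor_b
    level); several stimuli may share a cell, in which case the rater's cell
    mean enters the analysis.  For each effect the table carries the F ratio
    against its own subject-interaction error term, uncorrected and
    Greenhouse–Geisser-corrected degrees of freedom, the corrected p value
    and generalized eta squared (error denominator pooled over the subject
    terms, the convention for fully-within designs).
    """
    validate_ratings(ratings)
    Y, raters, a_levels, b_levels = _complete_within_matrix(ratings, cell_of)
    if len(raters) < 2:
        raise ValueError("need at least 2 raters")
    r, a, b = len(raters), len(a_levels), len(b_levels)
    cube = Y.reshape(r, a, b)
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_ab = cube.mean(axis=0)
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    ss_s = a * b * np.sum((m_s - grand) ** 2)
    ss_a = r * b * np.sum((m_a - grand) ** 2)
    ss_b = r * a * np.sum((m_b - grand) ** 2)
    ss_ab = r * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_tot = np.sum((cube - grand) ** 2)
    ss_abs = ss_tot - ss_s - ss_a - ss_b - ss_ab - ss_as - ss_bs
    ss_subj_all = ss_s + ss_as + ss_bs + ss_abs

    ca = _orthonormal_contrasts(a)
    cb = _orthonormal_contrasts(b)
    effects = [
        (factor_names[0], ss_a, a - 1, ss_as, (a - 1) * (r - 1),
         _gg_epsilon(cube.mean(axis=2), ca)),
        (factor_names[1], ss_b, b - 1, ss_bs, (b - 1) * (r - 1),
         _gg_epsilon(cube.mean(axis=1), cb)),
        (f"{factor_names[0]} * {factor_names[1]}", ss_ab, (a - 1) * (b - 1),
         ss_abs, (a - 1) * (b - 1) * (r - 1),
         _gg_epsilon(Y, np.kron(ca, cb))),
    ]
    rows = []
    tiny = 1e-12 * max(float(ss_tot), 1.0)  # guard against rounding noise
    for name, ss_eff, df1, ss_err, df2, eps in effects:
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ss_eff < tiny:
            f = 0.0
        elif ms_err > max(ms_eff * 1e-15, 0.0):
            f = ms_eff / ms_err
        else:
            f = np.inf
        ges = ss_eff / (ss_eff + ss_subj_all)
        p_unc = float(sps.f.sf(f, df1, df2))
        p_gg = float(sps.f.sf(f, eps * df1, eps * df2))
        rows.append({
            "effect": name, "ss": ss_eff, "ss_error": ss_err,
            "df1": df1, "df2": df2, "eps": eps,
            "df1_corr": eps * df1, "df2_corr": eps * df2,
            "F": f, "p_uncorrected": p_unc, "p_gg": p_gg, "ges": ges,
        })
    return pd.DataFrame(rows)


def bonferroni_pairwise(ratings: pd.DataFrame, cell_of: Mapping,
                        factor_names: tuple[str, str] = ("A", "B")
                        ) -> pd.DataFrame:
    """Paired t tests between the first factor's levels within each level of
    the second, Bonferroni-adjusted over the comparisons in each stratum.

    The adjusted p value is ``min(1, m * p_raw)`` with m the number of level
    pairs compared within the stratum.
    """
    validate_ratings(ratings)
    Y, raters, a_levels, b_levels = _complete_within_matrix(ratings, cell_of)
    if len(raters) < 2:
        raise ValueError("need at least 2 raters for a paired t test")
    r, a, b = len(raters), len(a_levels), len(b_levels)
    cube = Y.reshape(r, a, b)
    m = a * (a - 1) // 2
    rows = []
    for bj, b_level in enumerate(b_levels):
        for i, j in combinations(range(a), 2):
            x, y = cube[:, i, bj], cube[:, j, bj]
            if np.allclose(x, y):
                t, p = 0.0, 1.0
            else:
                t, p = sps.ttest_rel(x, y)
            rows.append({
                factor_names[1]: b_level,
                "level_1": a_levels[i], "level_2": a_levels[j],
                "t": float(t), "df": r - 1, "p_raw": float(p),
                "p_bonferroni": min(1.0, m * float(p)),
            })
    return pd.DataFrame(rows)


@dataclass
class ICCResult:
    """Two-way consistency ICC, average of k raters: ICC(C,k)."""

    icc_c_k: float
    k: int   # raters
    n: int   # stimuli (targets)
    ms_targets: float
    ms_error: float


def icc_c_k(ratings: pd.DataFrame) -> ICCResult:
    """ICC(C,k) = (MS_targets - MS_error) / MS_targets.

    Mean squares come from the two-way (targets + raters, no interaction)
    decomposition of the complete rater-by-stimulus matrix; consistency
    definition, average of the k raters.
    """
    validate_ratings(ratings)
    mat = ratings.pivot(index="stimulus_id", columns="rater_id",
                        values="rating")
    if mat.isna().any().any():
        raise ValueError("incomplete rater x stimulus matrix")
    Y = mat.to_numpy(dtype=float)
    n, k = Y.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 stimuli and 2 raters")
    grand = Y.mean()
    ms_targets = k * np.sum((Y.mean(axis=1) - grand) ** 2) / (n - 1)
    ss_total = np.sum((Y - grand) ** 2)
    ss_raters = n * np.sum((Y.mean(axis=0) - grand) ** 2)
    ss_error = ss_total - ms_targets * (n - 1) - ss_raters
    ms_error = ss_error / ((n - 1) * (k - 1))
    icc = (ms_targets - ms_error) / ms_targets if ms_targets > 0 else np.nan
    return ICCResult(icc_c_k=float(icc), k=k, n=n,
                     ms_targets=float(ms_targets), ms_error=float(ms_error))


def pearson_r_t(x, y) -> tuple[float, float, int]:
    """Pearson correlation with its t statistic: t = r sqrt((n-2)/(1-r²))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: a vector has zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    df = n - 2
    if abs(r) >= 1.0 - 1e-15:
        warnings.warn("|r| = 1: t statistic is infinite", RuntimeWarning)
        return (1.0 if r > 0 else -1.0), float(np.sign(r) * np.inf), df
    t = r * np.sqrt(df / (1.0 - r * r))
    return r, float(t), df
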