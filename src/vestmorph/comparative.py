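"""Allometric regression with and without phylogenetic correction.

The allometry battery regresses shape (ordination scores, or the full
descriptor matrix) and canal dimensions on size.  Size variables follow
the convention that volumes enter as natural logs of their CUBE ROOTS
(so ln Vol and ln VolSC have the dimensions of a log length) — under
isometry the expected slope of ln VolSC^(1/3) on ln L is therefore 1,
and a 95% CI for the slope excluding unity, alongside a significant
correlation, reads as allometry.

Ordinary fits run per specimen; phylogenetic generalized least squares
(PGLS) runs on species means with error covariance proportional to the
Brownian matrix C (λ = 1 throughout, i.e. pure BM).  The grade-shift
question — equal slopes, different intercepts between hominids and the
rest — is a classical two-stage ANCOVA of partial F tests.

Model fitting is delegated to statsmodels (OLS / GLS); this module owns
the phylogenetic plumbing, the GLS R² convention, the multivariate
shape-on-size permutation test, and the isometry verdicts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .shapes import ShapeTable
from .trees import PhyloTree

__all__ = [
    "RegressionResult",
    "AncovaResult",
    "AllometryTable",
    "ols_fit",
    "pgls_fit",
    "shape_size_regression",
    "ancova",
    "isometry_test",
]


@dataclass
class RegressionResult:
    """A bivariate regression fit: slope, intercept, uncertainties, R²."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_ci: tuple[float, float]
    intercept_ci: tuple[float, float]
    r2: float
    pvalue: float
    method: str  # "OLS" | "PGLS"
    n: int

    def summary(self) -> str:
        return (
            f"{self.method} (n = {self.n}): R2 = {self.r2:.3f}, p = {self.pvalue:.4g}\n"
            f"  slope     {self.slope: .3f}  SE {self.slope_se:.3f}  "
            f"95% CI [{self.slope_ci[0]:.3f}, {self.slope_ci[1]:.3f}]\n"
            f"  intercept {self.intercept: .3f}  SE {self.intercept_se:.3f}  "
            f"95% CI [{self.intercept_ci[0]:.3f}, {self.intercept_ci[1]:.3f}]"
        )

    def to_row(self) -> dict:
        return {
            "method": self.method, "n": self.n, "R2": self.r2, "p": self.pvalue,
            "slope": self.slope, "slope_SE": self.slope_se,
            "slope_CI_low": self.slope_ci[0], "slope_CI_high": self.slope_ci[1],
            "intercept": self.intercept, "intercept_SE": self.intercept_se,
            "intercept_CI_low": self.intercept_ci[0],
            "intercept_CI_high": self.intercept_ci[1],
        }


@dataclass
class AncovaResult:
    """Homogeneity-of-slopes and homogeneity-of-intercepts partial F tests."""

    f_slopes: float
    p_slopes: float
    f_intercepts: float
    p_intercepts: float
    df_slopes: tuple[int, int]
    df_intercepts: tuple[int, int]

    def summary(self) -> str:
        return (
            f"ANCOVA slopes:     F({self.df_slopes[0]}, {self.df_slopes[1]}) = "
            f"{self.f_slopes:.3f}, p = {self.p_slopes:.4g}\n"
            f"ANCOVA intercepts: F({self.df_intercepts[0]}, {self.df_intercepts[1]}) = "
            f"{self.f_intercepts:.3f}, p = {self.p_intercepts:.4g}"
        )


class AllometryTable:
    """Per-specimen size measurements: vestibular volume Vol (mm³),
    semicircular-canal volume VolSC (mm³), summed streamline length L (mm).

    ``ln_vol``/``ln_volsc`` are natural logs of the CUBE ROOTS of the
    volumes; ``ln_l`` is the natural log of the length.
    """

    REQUIRED = ["specimen", "species", "group", "Vol", "VolSC", "L"]

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        if (df[["Vol", "VolSC", "L"]] <= 0).any().any():
            raise ValueError("all measurements must be positive")
        self.df = df.reset_index(drop=True)

    @classmethod
    def read(cls, path) -> "AllometryTable":
        return cls(pd.read_csv(path, sep="\t"))

    def write(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def ln_vol(self) -> pd.Series:
        return np.log(np.cbrt(self.df["Vol"]))

    @property
    def ln_volsc(self) -> pd.Series:
        return np.log(np.cbrt(self.df["VolSC"]))

    @property
    def ln_l(self) -> pd.Series:
        return np.log(self.df["L"])

    def species_means(self) -> "AllometryTable":
        rows = []
        for sp, sub in self.df.groupby("species", sort=True):
            rows.append(
                {
                    "specimen": sp,
                    "species": sp,
                    "group": sub["group"].iloc[0],
                    # geometric means keep the log-scale averaging exact
                    "Vol": float(np.exp(np.log(sub["Vol"]).mean())),
                    "VolSC": float(np.exp(np.log(sub["VolSC"]).mean())),
                    "L": float(np.exp(np.log(sub["L"]).mean())),
                }
            )
        return AllometryTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# bivariate fits
# ---------------------------------------------------------------------------


def ols_fit(x, y) -> RegressionResult:
    """Ordinary least-squares line with t-based SEs, CIs and slope p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        r2=float(fit.rsquared),
        pvalue=float(fit.pvalues[1]),
        method="OLS",
        n=n,
    )


def pgls_fit(tree: PhyloTree, x, y, lam: float = 1.0) -> RegressionResult:
    """Phylogenetic GLS of one tip value on another under BM covariance.

    β̂ = (X'C⁻¹X)⁻¹X'C⁻¹y with X = [1, x]; SEs from (X'C⁻¹X)⁻¹ scaled by
    the GLS residual variance on n-2 df.  R² is 1 - GLS-RSS / GLS-TSS
    about the phylogenetic mean (a documented convention — GLS has no
    unique R²).  ``lam`` rescales C's off-diagonal first (default 1 =
    pure BM).
    """
    if not isinstance(x, pd.Series) or not isinstance(y, pd.Series):
        raise TypeError("x and y must be pandas Series indexed by tip name")
    if set(x.index) != set(y.index):
        raise ValueError(
            f"tip sets differ: only-x {sorted(set(x.index) - set(y.index))}, "
            f"only-y {sorted(set(y.index) - set(x.index))}"
        )
    taxa = list(x.index)
    extra = sorted(set(taxa) - set(tree.tip_names))
    if extra:
        raise ValueError(f"tips absent from tree: {extra}")
    C = tree.covariance(taxa).lambda_transform(lam).matrix
    yv = y.reindex(taxa).to_numpy(dtype=float)
    xv = x.to_numpy(dtype=float)
    n = len(taxa)
    X = sm.add_constant(xv)
    fit = sm.GLS(yv, X, sigma=C).fit()
    ci = fit.conf_int(alpha=0.05)
    # GLS R^2 about the phylogenetic (GLS) mean
    Cinv = np.linalg.inv(C)
    ones = np.ones(n)
    a_hat = (ones @ Cinv @ yv) / (ones @ Cinv @ ones)
    resid = yv - X @ fit.params
    rss = resid @ Cinv @ resid
    tss = (yv - a_hat) @ Cinv @ (yv - a_hat)
    r2 = float(1.0 - rss / tss) if tss > 0 else np.nan
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        intercept_se=float(fit.bse[0]),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
        intercept_ci=(float(ci[0, 0]), float(ci[0, 1])),
        r2=r2,
        pvalue=float(fit.pvalues[1]),
        method="PGLS",
        n=n,
    )


# ---------------------------------------------------------------------------
# multivariate shape-on-size regression
# ---------------------------------------------------------------------------


def shape_size_regression(
    table: ShapeTable,
    size,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Multivariate regression of all descriptors on size, permutation-tested.

    R² = SS_model / SS_total with sums of squared deviations pooled across
    descriptor columns; p permutes the size vector (>= 999 recommended,
    seed mandatory).  Returns (R², p).
    """
    Y = table.X
    x = np.asarray(size, dtype=float)
    n = len(x)
    if n != Y.shape[0]:
        raise ValueError(f"{n} sizes for {Y.shape[0]} specimens")
    if n < 5:
        raise ValueError("need at least 5 specimens")
    if np.ptp(x) == 0:
        raise ValueError("constant size")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    rng = np.random.default_rng(seed)

    Yc = Y - Y.mean(axis=0)
    ss_total = float((Yc**2).sum())

    def r2_of(xv: np.ndarray) -> float:
        xc = xv - xv.mean()
        beta = (xc @ Yc) / (xc @ xc)  # per-descriptor slopes
        ss_model = float((xc @ xc) * (beta**2).sum())
        return ss_model / ss_total

    r2_obs = r2_of(x)
    perm = np.array([r2_of(rng.permutation(x)) for _ in range(n_perm)])
    p = float((1 + np.sum(perm >= r2_obs)) / (n_perm + 1))
    return r2_obs, p


# ---------------------------------------------------------------------------
# ANCOVA
# ---------------------------------------------------------------------------


def _rss(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r), len(y) - np.linalg.matrix_rank(X)


def ancova(x, y, groups) -> AncovaResult:
    """Homogeneity of slopes and intercepts between groups.

    F_slopes is the partial F of the group x covariate interaction
    (full model y ~ x * group vs. common-slope y ~ x + group);
    F_intercepts is the partial F of the group main effect within the
    common-slope model (vs. y ~ x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    counts = {gl: int((groups == gl).sum()) for gl in labels}
    small = [gl for gl, c in counts.items() if c < 3]
    if small:
        raise ValueError(f"groups with fewer than 3 observations: {small}")
    # dummy-coded design matrices (first group is the reference level)
    D = np.stack([(groups == gl).astype(float) for gl in labels[1:]], axis=1)
    ones = np.ones((len(x), 1))
    X_x = np.hstack([ones, x[:, None]])
    X_common = np.hstack([ones, x[:, None], D])
    X_full = np.hstack([ones, x[:, None], D, D * x[:, None]])
    rss_x, df_x = _rss(y, X_x)
    rss_common, df_common = _rss(y, X_common)
    rss_full, df_full = _rss(y, X_full)
    g1 = len(labels) - 1
    f_slopes = ((rss_common - rss_full) / g1) / (rss_full / df_full)
    p_slopes = float(stats.f.sf(f_slopes, g1, df_full))
    f_int = ((rss_x - rss_common) / g1) / (rss_common / df_common)
    p_int = float(stats.f.sf(f_int, g1, df_common))
    return AncovaResult(
        f_slopes=float(f_slopes),
        p_slopes=p_slopes,
        f_intercepts=float(f_int),
        p_intercepts=p_int,
        df_slopes=(g1, df_full),
        df_intercepts=(g1, df_common),
    )


# ---------------------------------------------------------------------------
# isometry verdict
# ---------------------------------------------------------------------------


def isometry_test(result: RegressionResult, expected_slope: float = 1.0) -> str:
    """Position of the isometric slope relative to the fitted 95% CI.

    Returns ``"isometry-not-rejected"`` when the CI covers the expected
    slope, ``"negative-allometry"`` when the CI sits entirely below it,
    ``"positive-allometry"`` when entirely above.
    """
    lo, hi = result.slope_ci
    if not (np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("confidence interval is not finite")
    if hi < expected_slope:
        return "negative-allometry"
    if lo > expected_slope:
        return "positive-allometry"
    return "isometry-not-rejected"
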