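"""Natural cubic spline regression helpers shared by the gap and disparity models."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import patsy


@dataclass
class SplineBasis:
    """Natural cubic regression spline design with ``df`` degrees of freedom.

    ``transform`` returns the complete design matrix (df + 1 columns whose
    span includes the constant, equivalent to an intercept plus R's
    ``ns(x, df)``), with knots placed at quantiles of the training data.
    ``df=1`` degenerates to ``[1, x]``, so spline models reduce exactly to
    (log-)linear ones.
    """

    df: int
    _design_info: Any = field(default=None, repr=False)
    _x_min: float = 0.0
    _x_max: float = 1.0

    @classmethod
    def fit(cls, x, df: int) -> "SplineBasis":
        x = np.asarray(x, dtype=float)
        if df < 1:
            raise ValueError("df must be >= 1")
        basis = cls(df=df, _x_min=float(np.min(x)), _x_max=float(np.max(x)))
        if df >= 2:
            dm = patsy.dmatrix("cr(x, df=%d) - 1" % (df + 1), {"x": x})
            basis._design_info = dm.design_info
        return basis

    @property
    def n_columns(self) -> int:
        return self.df + 1

    def transform(self, x_new) -> np.ndarray:
        x_new = np.atleast_1d(np.asarray(x_new, dtype=float))
        if self.df == 1:
            return np.column_stack([np.ones(len(x_new)), x_new])
        (mat,) = patsy.build_design_matrices([self._design_info], {"x": x_new})
        return np.asarray(mat)

    def grid(self, n: int = 101) -> np.ndarray:
        return np.linspace(self._x_min, self._x_max, n)


@dataclass
class SplineFit:
    """A fitted univariate spline regression and its curve on a grid."""

    predictor: str
    response: str
    df: int
    grid: np.ndarray
    fitted: np.ndarray
    params: np.ndarray
    stratum: str | None = None
    adjustment: str = "none"
    basis: SplineBasis = field(default=None, repr=False)
    result: Any = field(default=None, repr=False)

    def predict(self, x_new) -> np.ndarray:
        X = self.basis.transform(x_new)
        return X @ self.params[: X.shape[1]]


def fit_spline_ols(x, y, df=4, predictor="x", response="y", grid_n=101):
    """Ordinary least squares of y on a natural cubic spline of x."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < df + 2:
        raise ValueError(f"need at least df+2={df + 2} observations, got {len(x)}")
    basis = SplineBasis.fit(x, df)
    X = basis.transform(x)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient spline design (predictor too coarse)")
    res = sm.OLS(y, X).fit()
    grid = basis.grid(grid_n)
    fitted = basis.transform(grid) @ res.params
    return SplineFit(predictor=predictor, response=response, df=df, grid=grid,
                     fitted=fitted, params=res.params, basis=basis, result=res)
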