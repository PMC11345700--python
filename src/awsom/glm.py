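"""Voxelwise general linear model for 4D fMRI series.

:class:`GLMModel` is built from a 4D series, a design matrix and a brain
mask; :meth:`GLMModel.fit` returns a :class:`GLMResults` carrying the
contrast parameter estimate (COPE), its variance (varcope), the residual
field, the z map and the degrees of freedom — the inputs consumed by both
adaptive-weights smoothing and cluster-corrected inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import GLMError

__all__ = ["DesignMatrix", "GLMModel", "GLMResults", "build_design_matrix", "compute_z"]

_Z_CLAMP = 38.0


@dataclass(frozen=True)
class DesignMatrix:
    """Design with the task regressor first, then intercept and drift columns."""

    matrix: np.ndarray
    names: tuple[str, ...]
    task_index: int = 0

    def __post_init__(self) -> None:
        X = np.asarray(self.matrix, dtype=float)
        if X.ndim != 2 or X.shape[0] <= X.shape[1]:
            raise GLMError("design must be a tall (n_volumes x p) matrix")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise GLMError("design matrix is rank deficient")

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    @property
    def contrast(self) -> np.ndarray:
        c = np.zeros(self.matrix.shape[1])
        c[self.task_index] = 1.0
        return c


def build_design_matrix(regressor: np.ndarray, drift_order: int = 2) -> DesignMatrix:
    """Task regressor plus Legendre drift columns up to ``drift_order``.

    The task regressor is max-normalized; Legendre polynomials on [-1, 1]
    provide a well-conditioned intercept + polynomial drift basis.
    """
    reg = np.asarray(regressor, dtype=float)
    peak = np.max(np.abs(reg))
    if peak > 0:
        reg = reg / peak
    n = reg.shape[0]
    x = np.linspace(-1.0, 1.0, n)
    drift = [np.polynomial.legendre.Legendre.basis(k)(x) for k in range(drift_order + 1)]
    X = np.column_stack([reg] + drift)
    names = ("task",) + tuple(f"drift{k}" for k in range(drift_order + 1))
    return DesignMatrix(matrix=X, names=names)


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Map t statistics to standard-normal quantiles with symmetric tails."""
    if dof <= 0:
        raise GLMError("degrees of freedom must be positive")
    tail = stats.t.sf(np.abs(t), dof)
    z = stats.norm.isf(np.clip(tail, 1e-320, 1.0))
    z = np.clip(z, 0.0, _Z_CLAMP)
    return np.sign(t) * z


def compute_z(cope: np.ndarray, varcope: np.ndarray, dof: int,
              mask: np.ndarray | None = None) -> np.ndarray:
    """z map from a COPE/varcope pair; zero outside the mask."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(varcope > 0, cope / np.sqrt(varcope), 0.0)
    z = _t_to_z(t, dof)
    if mask is not None:
        z = np.where(mask, z, 0.0)
    return z


class GLMModel:
    """Mass-univariate GLM over the in-mask voxels of a 4D series.

    Parameters
    ----------
    series:
        4D array ``(x, y, z, t)``.
    design:
        :class:`DesignMatrix` (or a bare regressor, which is wrapped with the
        default quadratic drift basis).
    brain_mask:
        3D boolean array of voxels to fit.
    """

    def __init__(self, series: np.ndarray, design: DesignMatrix | np.ndarray,
                 brain_mask: np.ndarray):
        if not isinstance(design, DesignMatrix):
            design = build_design_matrix(np.asarray(design))
        series = np.asarray(series)
        if series.ndim != 4:
            raise GLMError("series must be 4D (x, y, z, t)")
        if series.shape[-1] != design.n_volumes:
            raise GLMError(
                f"series has {series.shape[-1]} volumes, design {design.n_volumes} rows"
            )
        if series.shape[-1] < 20:
            raise GLMError("at least 20 timepoints are required")
        brain_mask = np.asarray(brain_mask, dtype=bool)
        if brain_mask.shape != series.shape[:3]:
            raise GLMError("mask and series grids differ")
        if not brain_mask.any():
            raise GLMError("brain mask is empty")
        self.series = series
        self.design = design
        self.brain_mask = brain_mask

    # -- fitting ------------------------------------------------------------

    @staticmethod
    def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """OLS coefficients and residuals for stacked voxel series Y (T x N)."""
        pinv = np.linalg.pinv(X)
        beta = pinv @ Y
        resid = Y - X @ beta
        return beta, resid

    def fit(self, prewhiten: str = "none") -> "GLMResults":
        """Fit the model; ``prewhiten`` is ``none`` or ``ar1``.

        With ``ar1`` a single Cochrane–Orcutt pass is applied: the lag-1
        autocorrelation is pooled over all in-mask residual series and both
        sides of the regression are quasi-differenced before refitting.
        """
        if prewhiten not in ("none", "ar1"):
            raise GLMError(f"unknown prewhitening {prewhiten!r}")
        X = self.design.matrix
        mask = self.brain_mask
        Y = self.series[mask].T.astype(np.float64)  # T x N
        if float(Y.std(axis=0).max()) == 0.0:
            raise GLMError("series has no temporal variance inside the mask")
        beta, resid = self._ols(X, Y)
        rho = 0.0
        if prewhiten == "ar1":
            num = float(np.sum(resid[1:] * resid[:-1]))
            den = float(np.sum(resid * resid))
            rho = num / den if den > 0 else 0.0
            rho = float(np.clip(rho, -0.98, 0.98))
            Xw = np.empty_like(X)
            Xw[0] = X[0] * np.sqrt(1.0 - rho**2)
            Xw[1:] = X[1:] - rho * X[:-1]
            Yw = np.empty_like(Y)
            Yw[0] = Y[0] * np.sqrt(1.0 - rho**2)
            Yw[1:] = Y[1:] - rho * Y[:-1]
            beta, resid = self._ols(Xw, Yw)
            X = Xw
        dof = X.shape[0] - X.shape[1]
        sigma2 = np.sum(resid**2, axis=0) / dof
        c = self.design.contrast
        xtx_inv = np.linalg.inv(X.T @ X)
        c_var = float(c @ xtx_inv @ c)
        cope_v = c @ beta
        varcope_v = sigma2 * c_var

        shape = self.series.shape[:3]
        cope = np.zeros(shape)
        varcope = np.zeros(shape)
        s2 = np.zeros(shape)
        cope[mask] = cope_v
        varcope[mask] = varcope_v
        s2[mask] = sigma2
        residuals = np.zeros(self.series.shape, dtype=np.float32)
        residuals[mask] = resid.T.astype(np.float32)
        return GLMResults(
            model=self, cope=cope, varcope=varcope, sigma2=s2,
            residuals=residuals, dof=dof, prewhiten=prewhiten, ar1_rho=rho,
        )


@dataclass
class GLMResults:
    """First-level GLM output (the SPM set consumed by smoothing/inference)."""

    model: GLMModel
    cope: np.ndarray
    varcope: np.ndarray
    sigma2: np.ndarray
    residuals: np.ndarray
    dof: int
    prewhiten: str = "none"
    ar1_rho: float = 0.0
    _zmap: np.ndarray | None = field(default=None, repr=False)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.model.brain_mask

    @property
    def zmap(self) -> np.ndarray:
        if self._zmap is None:
            self._zmap = compute_z(self.cope, self.varcope, self.dof, self.brain_mask)
        return self._zmap

    def summary(self) -> str:
        m = self.brain_mask
        lines = [
            "General linear model (voxelwise OLS)",
            f"  voxels fitted     : {int(m.sum())}",
            f"  volumes / dof     : {self.model.design.n_volumes} / {self.dof}",
            f"  prewhitening      : {self.prewhiten}"
            + (f" (rho={self.ar1_rho:.3f})" if self.prewhiten == "ar1" else ""),
            f"  cope  mean (mask) : {self.cope[m].mean():.5g}",
            f"  |z|   max  (mask) : {np.abs(self.zmap[m]).max():.3f}",
        ]
        return "\n".join(lines)
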