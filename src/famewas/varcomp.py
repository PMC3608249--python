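"""Polygenic variance-component modelling on pedigree kinship.

The trait model is multivariate normal with mean ``X @ beta`` and
covariance ``2*Phi*sigma2_a + I*sigma2_e``, where Phi is the pairwise
kinship matrix.  The standardized additive genetic variance
h2 = sigma2_a / (sigma2_a + sigma2_e) is the trait's heritability.

Fitting is by full maximum likelihood.  A single eigendecomposition of
2*Phi rotates the model to independent coordinates; for a trial h2 the
fixed effects and the total variance have closed-form profile estimates,
leaving a bounded one-dimensional likelihood search over h2 in [0, 1).

Hypothesis tests are likelihood-ratio tests: fixed effects against
chi-squared with df equal to the number of dropped parameters, and h2
(tested on its lower boundary) against the 0.5:0.5 mixture of chi2_1 and
a point mass at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .pedigree import KinshipMatrix

__all__ = [
    "VarCompFit",
    "AssociationResult",
    "PolygenicModel",
    "rank_normalize",
    "covariate_design",
    "fit_polygenic",
    "heritability_test",
    "association_test",
    "covariate_scan",
    "back_transform_effect",
    "normalize_expression",
]

_H2_UPPER = 1.0 - 1e-6


def rank_normalize(values, c: float = 0.5) -> np.ndarray:
    """Rank-based inverse normal transformation.

    z_i = Phi^{-1}((r_i - c) / (n - 2c + 1)) with average ranks for ties;
    missing values propagate.  The default offset c = 0.5 gives
    (r - 0.5)/n; c = 3/8 is the Blom convention.
    """
    vals = np.asarray(values, dtype=float)
    out = np.full(vals.shape, np.nan)
    mask = ~np.isnan(vals)
    v = vals[mask]
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 non-missing values to rank-normalize")
    if np.all(v == v[0]):
        raise ValueError("all values identical: no ordering information")
    r = stats.rankdata(v, method="average")
    out[mask] = stats.norm.ppf((r - c) / (n - 2.0 * c + 1.0))
    return out


def covariate_design(
    age: Sequence[float],
    female: Sequence[bool],
    center_age: bool = True,
) -> pd.DataFrame:
    """Standard fixed-effect design: intercept, sex, age, age^2 and interactions.

    Sex is coded 1 for female; age is mean-centered by default for
    conditioning (slopes at the cohort mean age).
    """
    age = np.asarray(age, dtype=float)
    fem = np.asarray(female, dtype=float)
    a = age - age.mean() if center_age else age
    return pd.DataFrame(
        {
            "intercept": np.ones_like(a),
            "sex": fem,
            "age": a,
            "age2": a**2,
            "sex_age": fem * a,
            "sex_age2": fem * a**2,
        }
    )


@dataclass
class VarCompFit:
    """A fitted polygenic model."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    h2_se: float
    beta: np.ndarray
    beta_se: np.ndarray
    loglik: float
    n: int
    columns: list[str] = field(default_factory=list)
    h2_fixed: bool = False

    def coef(self, name: str) -> tuple[float, float]:
        i = self.columns.index(name)
        return float(self.beta[i]), float(self.beta_se[i])


@dataclass
class AssociationResult:
    """Association of a focal predictor with a trait under the polygenic model."""

    beta: float
    se: float
    lrt_statistic: float
    p_value: float
    variance_explained: float
    raw_change_per_percent: float = float("nan")
    n: int = 0


class PolygenicModel:
    """Reusable eigen-rotation of a kinship kernel for repeated fits.

    The eigendecomposition 2*Phi = U diag(lam) U' is computed once; every
    subsequent fit on the same subject set costs only a 1-D likelihood
    search.
    """

    def __init__(self, kinship: KinshipMatrix | np.ndarray, psd_tol: float = 1e-8):
        phi = kinship.phi if isinstance(kinship, KinshipMatrix) else np.asarray(kinship, float)
        self.ids = list(kinship.ids) if isinstance(kinship, KinshipMatrix) else None
        A = 2.0 * phi
        if not np.allclose(A, A.T, atol=1e-10):
            raise ValueError("kinship matrix must be symmetric")
        lam, U = np.linalg.eigh(A)
        if lam.min() < -psd_tol * max(1.0, lam.max()):
            raise ValueError(f"2*Phi is not positive semidefinite (min eigenvalue {lam.min():.3g})")
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.n = len(lam)

    # -- likelihood machinery -------------------------------------------------

    def _profile(self, yt: np.ndarray, Xt: np.ndarray, h2: float):
        """Profile loglik pieces at fixed h2 on rotated data."""
        d = h2 * self.lam + (1.0 - h2)
        w = 1.0 / np.sqrt(d)
        beta, *_ = np.linalg.lstsq(Xt * w[:, None], yt * w, rcond=None)
        resid = (yt - Xt @ beta) * w
        rss = float(resid @ resid)
        n = self.n
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sigma2) + np.sum(np.log(d)) + n)
        return ll, beta, sigma2, d

    def fit(
        self,
        y: Sequence[float],
        X: pd.DataFrame | np.ndarray,
        h2_fixed: float | None = None,
        xatol: float = 1e-8,
    ) -> VarCompFit:
        """Maximum-likelihood fit; ``h2_fixed`` pins the variance ratio (0 = null)."""
        y = np.asarray(y, dtype=float)
        columns = list(X.columns) if isinstance(X, pd.DataFrame) else [f"x{i}" for i in range(np.asarray(X).shape[1])]
        X = np.asarray(X, dtype=float)
        if y.shape[0] != self.n or X.shape[0] != self.n:
            raise ValueError("y/X rows must match the kinship dimension")
        if np.isnan(y).any() or np.isnan(X).any():
            raise ValueError("missing values must be removed before fitting")
        if X.shape[1] + 2 > self.n:
            raise ValueError("too few observations for the design")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("singular design matrix")

        yt = self.U.T @ y
        Xt = self.U.T @ X

        if h2_fixed is not None:
            h2 = float(h2_fixed)
            se_h2 = float("nan")
        else:
            res = optimize.minimize_scalar(
                lambda h: -self._profile(yt, Xt, h)[0],
                bounds=(0.0, _H2_UPPER),
                method="bounded",
                options={"xatol": xatol},
            )
            h2 = float(res.x)
            # snap to the boundary when it is at least as likely
            ll_opt = -res.fun
            ll0 = self._profile(yt, Xt, 0.0)[0]
            if ll0 >= ll_opt - 1e-10:
                h2 = 0.0
            se_h2 = self._h2_se(yt, Xt, h2)

        ll, beta, sigma2, d = self._profile(yt, Xt, h2)
        Xw = Xt / np.sqrt(d)[:, None]
        cov_beta = sigma2 * np.linalg.inv(Xw.T @ Xw)
        return VarCompFit(
            sigma2_a=h2 * sigma2,
            sigma2_e=(1.0 - h2) * sigma2,
            h2=h2,
            h2_se=se_h2,
            beta=beta,
            beta_se=np.sqrt(np.diag(cov_beta)),
            loglik=ll,
            n=self.n,
            columns=columns,
            h2_fixed=h2_fixed is not None,
        )

    def _h2_se(self, yt, Xt, h2: float, step: float = 1e-4) -> float:
        """SE from the numerical curvature of the profile log-likelihood."""
        lo = max(h2 - step, 0.0)
        hi = min(h2 + step, _H2_UPPER)
        if hi - lo < step:  # pinned at a boundary
            return float("nan")
        f = lambda h: self._profile(yt, Xt, h)[0]
        mid = 0.5 * (lo + hi)
        d2 = (f(hi) - 2.0 * f(mid) + f(lo)) / ((0.5 * (hi - lo)) ** 2)
        return float(1.0 / np.sqrt(-d2)) if d2 < 0 else float("nan")


def fit_polygenic(
    y, X, phi: KinshipMatrix | np.ndarray, h2_fixed: float | None = None
) -> VarCompFit:
    """Convenience wrapper building a :class:`PolygenicModel` for one fit."""
    return PolygenicModel(phi).fit(y, X, h2_fixed=h2_fixed)


def heritability_test(fit_full: VarCompFit, fit_h0: VarCompFit) -> float:
    """LRT p-value for h2 = 0 under the boundary-mixture null.

    The statistic T = 2 * (ll_full - ll_null), clipped at zero, follows a
    0.5:0.5 mixture of chi2_1 and a point mass at zero; p = 1 when T = 0,
    else 0.5 * Pr(chi2_1 >= T).
    """
    if fit_full.n != fit_h0.n or fit_full.columns != fit_h0.columns:
        raise ValueError("full and null fits must share the same design")
    if fit_full.loglik < fit_h0.loglik - 1e-6:
        raise ValueError("full-model likelihood below the null: optimization failure")
    T = max(2.0 * (fit_full.loglik - fit_h0.loglik), 0.0)
    return 1.0 if T == 0.0 else float(0.5 * stats.chi2.sf(T, df=1))


def association_test(
    y,
    X: pd.DataFrame,
    phi: KinshipMatrix | np.ndarray | PolygenicModel,
    x_focal,
    rank_normalize_focal: bool = True,
    meth_raw_sd: float | None = None,
    trait_raw_sd: float | None = None,
) -> AssociationResult:
    """LRT of a focal predictor's fixed effect under the polygenic model.

    The focal predictor is rank-normalized by default (the convention
    applied to percent-methylation predictors); the trait ``y`` is used
    as supplied.  ``variance_explained`` is beta^2 * Var(x) / Var(y) on
    the analysis scale.  When both raw-scale standard deviations are
    supplied, the raw trait change per 1% methylation is also reported.
    """
    x = np.asarray(x_focal, dtype=float)
    if np.nanstd(x) == 0:
        raise ValueError("focal predictor is constant")
    if rank_normalize_focal:
        x = rank_normalize(x)
    model = phi if isinstance(phi, PolygenicModel) else PolygenicModel(phi)
    X_full = pd.DataFrame(X).copy()
    X_full["_focal"] = x
    fit_full = model.fit(y, X_full)
    fit_null = model.fit(y, X)
    T = max(2.0 * (fit_full.loglik - fit_null.loglik), 0.0)
    p = float(stats.chi2.sf(T, df=1)) if T > 0 else 1.0
    beta, se = fit_full.coef("_focal")
    y_arr = np.asarray(y, dtype=float)
    ve = float(beta**2 * np.var(x) / np.var(y_arr))
    raw = float("nan")
    if meth_raw_sd is not None and trait_raw_sd is not None:
        raw = back_transform_effect(beta, trait_raw_sd, meth_raw_sd)
    return AssociationResult(
        beta=beta,
        se=se,
        lrt_statistic=T,
        p_value=p,
        variance_explained=ve,
        raw_change_per_percent=raw,
        n=model.n,
    )


def covariate_scan(
    meth_raw,
    X: pd.DataFrame,
    phi: KinshipMatrix | np.ndarray | PolygenicModel,
) -> dict:
    """Heritability plus age and sex effects for one methylation unit.

    The unit's raw fractions are rank-normalized and modelled as the
    trait.  Each covariate effect is a 1-df LRT dropping that column
    (``age`` and ``sex`` main effects); reported betas are converted back
    to the raw fraction scale (per year of age, and female-minus-male)
    by multiplying the z-scale coefficient by the unit's raw standard
    deviation.
    """
    meth_raw = np.asarray(meth_raw, dtype=float)
    y = rank_normalize(meth_raw)
    raw_sd = float(np.nanstd(meth_raw, ddof=1))
    model = phi if isinstance(phi, PolygenicModel) else PolygenicModel(phi)

    fit_full = model.fit(y, X)
    fit_null_h2 = model.fit(y, X, h2_fixed=0.0)
    p_h2 = heritability_test(fit_full, fit_null_h2)

    out = {
        "h2": fit_full.h2,
        "h2_se": fit_full.h2_se,
        "p_h2": p_h2,
        "n": fit_full.n,
    }
    y_var = float(np.var(y))
    for name in ("age", "sex"):
        if name not in X.columns:
            continue
        fit_drop = model.fit(y, X.drop(columns=[name]))
        T = max(2.0 * (fit_full.loglik - fit_drop.loglik), 0.0)
        p = float(stats.chi2.sf(T, df=1)) if T > 0 else 1.0
        b_z, se_z = fit_full.coef(name)
        x = np.asarray(X[name], dtype=float)
        out[f"beta_{name}"] = b_z * raw_sd
        out[f"se_{name}"] = se_z * raw_sd
        out[f"p_{name}"] = p
        out[f"ve_{name}"] = float(b_z**2 * np.var(x) / y_var)
    return out


def back_transform_effect(beta_z: float, trait_raw_sd: float, meth_raw_sd: float) -> float:
    """Raw trait change per one percentage point of methylation.

    With both trait and methylation analyzed on the z scale, a coefficient
    beta_z corresponds to beta_z * trait_sd / meth_sd raw trait units per
    unit methylation fraction, i.e. times 0.01 per 1% methylation.
    """
    if trait_raw_sd <= 0 or meth_raw_sd <= 0:
        raise ValueError("standard deviations must be positive")
    return float(beta_z * trait_raw_sd * (0.01 / meth_raw_sd))


def normalize_expression(intensities: pd.DataFrame) -> pd.DataFrame:
    """Log2 transform and quantile-normalize expression intensities.

    Rows are subjects, columns probes.  After normalization every subject
    shares the same sorted value multiset (the column-mean order
    statistics), with ties averaged.
    """
    vals = intensities.to_numpy(dtype=float)
    if np.any(vals <= 0):
        i, j = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive intensity at subject {intensities.index[i]!r}, "
            f"probe {intensities.columns[j]!r}"
        )
    logged = np.log2(vals)
    order_stats = np.sort(logged, axis=1).mean(axis=0)
    n = logged.shape[1]
    out = np.empty_like(logged)
    for i in range(logged.shape[0]):
        ranks = stats.rankdata(logged[i], method="average")
        out[i] = np.interp(ranks, np.arange(1, n + 1), order_stats)
    return pd.DataFrame(out, index=intensities.index, columns=intensities.columns)
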