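"""Distance-matrix and linear regression with commonality analysis.

Implements the two-stage testing framework: multiple regression on unfolded
distance matrices (MRDM) with permutation inference for inter-population
responses, ordinary linear regression (LR) with parametric inference for
intra-population responses, all-subsets commonality analysis decomposing the
model R² into unique (U) and common (C) contributions per predictor,
total-suppressor detection, Benjamini–Hochberg correction of the per-model β
p-value family, and the batch suppressor-removal second stage.

All variables are standardized (z-scores) before fitting, so β are
standardized regression weights and the commonality identities
T = U + C = r² hold exactly.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PredictorSet",
    "PredictorStats",
    "RegressionReport",
    "vectorize",
    "mrdm_fit",
    "lr_fit",
    "commonality_analysis",
    "detect_suppressors",
    "bh_adjust",
    "two_stage_analysis",
]

MAX_CA_PREDICTORS = 12
COLLINEARITY_CONDITION = 1e10
SUPPRESSOR_TAU = 0.1
SIGN_TOL = 1e-8


def vectorize(d: DistanceMatrix) -> np.ndarray:
    """Unfold a symmetric matrix into its upper triangle (row-major).

    The inverse mapping is :meth:`DistanceMatrix.from_condensed` with the
    same label order.
    """
    return d.condensed()


@dataclass
class PredictorSet:
    """A response and named predictors on a common observational basis.

    ``level`` is ``inter_population`` (vectors are unfolded distance
    matrices; permutation inference permutes the response matrix's object
    labels) or ``intra_population`` (vectors are per-population values;
    parametric inference).
    """

    response_name: str
    response: np.ndarray
    predictors: dict[str, np.ndarray]
    level: str
    response_matrix: DistanceMatrix | None = None  # required for MRDM permutation

    def __post_init__(self) -> None:
        if self.level not in ("inter_population", "intra_population"):
            raise ValueError(f"unknown level {self.level!r}")
        self.response = np.asarray(self.response, dtype=float)
        self.predictors = {
            k: np.asarray(v, dtype=float) for k, v in self.predictors.items()
        }
        n = len(self.response)
        for name, v in self.predictors.items():
            if len(v) != n:
                raise ValueError(
                    f"predictor {name!r} length {len(v)} != response length {n}"
                )
            if np.ptp(v) == 0.0:
                raise ValueError(f"predictor {name!r} is constant")
        if np.ptp(self.response) == 0.0:
            raise ValueError("response is constant")

    @classmethod
    def from_distance_matrices(
        cls,
        response: DistanceMatrix,
        predictors: Mapping[str, DistanceMatrix],
        response_name: str | None = None,
    ) -> "PredictorSet":
        """Build an inter-population set from labeled distance matrices.

        All predictor matrices are reordered to the response's label order
        before unfolding.
        """
        preds = {
            name: d.submatrix(response.labels).condensed()
            for name, d in predictors.items()
        }
        return cls(
            response_name=response_name or response.metric_name,
            response=response.condensed(),
            predictors=preds,
            level="inter_population",
            response_matrix=response,
        )

    @classmethod
    def from_table(
        cls,
        table: pd.DataFrame,
        response: str,
        predictors: Sequence[str],
    ) -> "PredictorSet":
        """Build an intra-population set from a per-population table.

        Rows with any missing value among the used columns are dropped.
        """
        cols = [response, *predictors]
        sub = table[cols].dropna()
        return cls(
            response_name=response,
            response=sub[response].to_numpy(dtype=float),
            predictors={p: sub[p].to_numpy(dtype=float) for p in predictors},
            level="intra_population",
        )

    def drop(self, names: Sequence[str]) -> "PredictorSet":
        keep = {k: v for k, v in self.predictors.items() if k not in set(names)}
        return PredictorSet(
            response_name=self.response_name,
            response=self.response,
            predictors=keep,
            level=self.level,
            response_matrix=self.response_matrix,
        )

    @property
    def names(self) -> list[str]:
        return list(self.predictors.keys())


@dataclass
class PredictorStats:
    name: str
    r: float  # zero-order Pearson correlation with the response
    beta: float  # standardized regression weight
    beta_p: float | None = None
    beta_p_adjusted: float | None = None
    u: float | None = None  # unique contribution
    c: float | None = None  # common contribution
    t: float | None = None  # total contribution (= r^2)


@dataclass
class RegressionReport:
    response_name: str
    level: str
    method: str  # "mrdm" | "lr"
    predictors: list[PredictorStats]
    r_squared: float
    r_squared_p: float | None
    n_obs: int
    stage: str = "initial"
    suppressors_removed: list[str] = field(default_factory=list)
    commonality_coefficients: dict[tuple[str, ...], float] = field(
        default_factory=dict
    )

    def stats_for(self, name: str) -> PredictorStats:
        for p in self.predictors:
            if p.name == name:
                return p
        raise KeyError(name)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "predictor": p.name,
                "r": p.r,
                "beta": p.beta,
                "beta_p": p.beta_p,
                "beta_p_adjusted": p.beta_p_adjusted,
                "U": p.u,
                "C": p.c,
                "T": p.t,
            }
            for p in self.predictors
        ]
        df = pd.DataFrame(rows)
        df.attrs["r_squared"] = self.r_squared
        df.attrs["r_squared_p"] = self.r_squared_p
        return df

    def to_dict(self) -> dict:
        return {
            "response": self.response_name,
            "level": self.level,
            "method": self.method,
            "stage": self.stage,
            "n_obs": self.n_obs,
            "r_squared": self.r_squared,
            "r_squared_p": self.r_squared_p,
            "suppressors_removed": self.suppressors_removed,
            "predictors": [
                {
                    "name": p.name,
                    "r": p.r,
                    "beta": p.beta,
                    "beta_p": p.beta_p,
                    "beta_p_adjusted": p.beta_p_adjusted,
                    "U": p.u,
                    "C": p.c,
                    "T": p.t,
                }
                for p in self.predictors
            ],
        }


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    return (v - v.mean()) / sd


def _design(ps: PredictorSet) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Standardized response vector, predictor matrix and names."""
    y = _standardize(ps.response)
    names = ps.names
    x = np.column_stack([_standardize(ps.predictors[n]) for n in names])
    _check_collinearity(x, names)
    return y, x, names


def _check_collinearity(x: np.ndarray, names: Sequence[str]) -> None:
    if x.shape[1] < 2:
        return
    cond = np.linalg.cond(x)
    if cond > COLLINEARITY_CONDITION:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"collinear predictors (condition number {cond:.3g}): "
            f"{names[i]!r} and {names[j]!r} (|r| = {abs(corr[i, j]):.6f})"
        )


def _ols_beta_r2(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float]:
    """Standardized OLS (no intercept needed: everything is centered)."""
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    r2 = 1.0 - float(resid @ resid) / float(y @ y)
    return beta, r2


def _zero_order_r(ps: PredictorSet) -> np.ndarray:
    y = ps.response
    return np.array(
        [float(np.corrcoef(ps.predictors[n], y)[0, 1]) for n in ps.names]
    )


def _permuted_response_vectors(
    rmat: DistanceMatrix, perms: np.ndarray
) -> np.ndarray:
    """Unfold the response matrix under each object relabeling.

    ``perms`` has shape (n_perm, n_objects); returns (n_pairs, n_perm).
    """
    v = rmat.values
    iu = np.triu_indices(rmat.n, k=1)
    out = np.empty((len(iu[0]), perms.shape[0]))
    for p in range(perms.shape[0]):
        shuffled = v[np.ix_(perms[p], perms[p])]
        out[:, p] = shuffled[iu]
    return out


def mrdm_fit(
    ps: PredictorSet,
    n_perm: int = 1000,
    seed: int | None = None,
    permutations: str = "random",
    with_commonality: bool = True,
) -> RegressionReport:
    """Multiple regression on distance matrices with permutation inference.

    Significance is assessed by permuting the object labels of the response
    matrix (rows and columns jointly), re-unfolding and refitting against the
    fixed predictors.  With ``permutations="random"``, p-values use the
    add-one estimator p = (1 + #{|stat_perm| >= |stat_obs|}) / (1 + n_perm);
    with ``permutations="all"`` every relabeling is enumerated (n <= 8) and
    p is the exact proportion over all n! permutations.
    """
    if ps.level != "inter_population":
        raise ValueError("mrdm_fit requires an inter_population PredictorSet")
    if ps.response_matrix is None:
        raise ValueError("MRDM permutation requires the response DistanceMatrix")
    y, x, names = _design(ps)
    n_objects = ps.response_matrix.n
    if len(y) < len(names) + 2:
        raise ValueError("too few observations for the number of predictors")
    beta_obs, r2_obs = _ols_beta_r2(y, x)

    pinv = np.linalg.pinv(x)
    hat = x @ pinv
    if permutations == "all":
        if n_objects > 8:
            raise ValueError("exhaustive permutation limited to n <= 8 objects")
        perms = np.array(list(itertools.permutations(range(n_objects))))
        add_one = 0
        n_total = len(perms)
    elif permutations == "random":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        perms = np.array(
            [rng.permutation(n_objects) for _ in range(n_perm)]
        )
        add_one = 1
        n_total = n_perm
    else:
        raise ValueError(f"unknown permutation scheme {permutations!r}")

    ymat = _permuted_response_vectors(ps.response_matrix, perms)
    ymat = (ymat - ymat.mean(axis=0)) / ymat.std(axis=0, ddof=1)
    beta_perm = pinv @ ymat  # (p, n_perm)
    fitted = hat @ ymat
    ss_res = ((ymat - fitted) ** 2).sum(axis=0)
    ss_tot = (ymat**2).sum(axis=0)
    r2_perm = 1.0 - ss_res / ss_tot

    beta_p = (
        add_one + (np.abs(beta_perm) >= np.abs(beta_obs)[:, None] - 1e-12).sum(axis=1)
    ) / (add_one + n_total)
    r2_p = float(
        (add_one + (r2_perm >= r2_obs - 1e-12).sum()) / (add_one + n_total)
    )

    r = _zero_order_r(ps)
    preds = [
        PredictorStats(name=n, r=float(r[i]), beta=float(beta_obs[i]),
                       beta_p=float(beta_p[i]))
        for i, n in enumerate(names)
    ]
    report = RegressionReport(
        response_name=ps.response_name,
        level=ps.level,
        method="mrdm",
        predictors=preds,
        r_squared=r2_obs,
        r_squared_p=r2_p,
        n_obs=len(y),
    )
    _apply_bh(report)
    if with_commonality:
        _attach_commonality(report, ps)
    return report


def lr_fit(ps: PredictorSet, with_commonality: bool = True) -> RegressionReport:
    """Standardized linear regression with parametric inference.

    β p-values are two-sided t-tests (df = n - p - 1, matching the
    with-intercept model on raw data); the model p-value is the overall
    F-test.
    """
    if ps.level != "intra_population":
        raise ValueError("lr_fit requires an intra_population PredictorSet")
    y, x, names = _design(ps)
    n, p = x.shape
    if n < p + 2:
        raise ValueError("too few observations for the number of predictors")
    beta, r2 = _ols_beta_r2(y, x)
    df_resid = n - p - 1
    resid = y - x @ beta
    sigma2 = float(resid @ resid) / df_resid
    xtx_inv = np.linalg.inv(x.T @ x)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    tvals = beta / se
    beta_p = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    if r2 >= 1.0 - 1e-14:
        f_stat = np.inf
    else:
        f_stat = (r2 / p) / ((1.0 - r2) / df_resid)
    r2_p = float(stats.f.sf(f_stat, p, df_resid))

    r = _zero_order_r(ps)
    preds = [
        PredictorStats(name=nm, r=float(r[i]), beta=float(beta[i]),
                       beta_p=float(beta_p[i]))
        for i, nm in enumerate(names)
    ]
    report = RegressionReport(
        response_name=ps.response_name,
        level=ps.level,
        method="lr",
        predictors=preds,
        r_squared=r2,
        r_squared_p=r2_p,
        n_obs=n,
    )
    _apply_bh(report)
    if with_commonality:
        _attach_commonality(report, ps)
    return report


def _subset_r2(cxy: np.ndarray, cxx: np.ndarray, mask: int, p: int) -> float:
    """R² of the sub-model using the predictors in the bitmask."""
    idx = [i for i in range(p) if mask >> i & 1]
    if not idx:
        return 0.0
    sub_xx = cxx[np.ix_(idx, idx)]
    sub_xy = cxy[idx]
    return float(sub_xy @ np.linalg.solve(sub_xx, sub_xy))


def commonality_analysis(
    ps: PredictorSet,
) -> tuple[dict[str, tuple[float, float, float]], dict[tuple[str, ...], float]]:
    """All-subsets commonality decomposition of the regression R².

    Computes R² for all 2^p - 1 predictor subsets, then each subset's
    commonality coefficient by Möbius inversion over the subset lattice:
    the coefficient of subset S is sum over B subset-of S of
    (-1)^(|S| - |B| + 1) R²(all predictors except B).

    Returns
    -------
    per_predictor : dict name -> (U, C, T)
        U is the unique contribution, C the (possibly negative) common
        contribution, T = U + C = r² the total.
    coefficients : dict tuple-of-names -> value
        All 2^p - 1 commonality coefficients; they sum to the full-model R².
    """
    y, x, names = _design(ps)
    p = len(names)
    if p > MAX_CA_PREDICTORS:
        raise ValueError(
            f"commonality analysis limited to {MAX_CA_PREDICTORS} predictors, got {p}"
        )
    n = len(y)
    cxx = (x.T @ x) / (n - 1)  # correlation matrix (x standardized)
    cxy = (x.T @ y) / (n - 1)
    full = (1 << p) - 1
    r2 = {mask: _subset_r2(cxy, cxx, mask, p) for mask in range(full + 1)}

    coeffs: dict[tuple[str, ...], float] = {}
    for s in range(1, full + 1):
        total = 0.0
        b = s
        while True:  # iterate submasks b of s, including the empty set
            k = bin(s).count("1") - bin(b).count("1")
            total += ((-1.0) ** (k + 1)) * r2[full & ~b]
            if b == 0:
                break
            b = (b - 1) & s
        subset_names = tuple(names[i] for i in range(p) if s >> i & 1)
        coeffs[subset_names] = total

    r = _zero_order_r(ps)
    per_predictor: dict[str, tuple[float, float, float]] = {}
    for i, nm in enumerate(names):
        u = coeffs[(nm,)]
        t = float(r[i] ** 2)
        per_predictor[nm] = (u, t - u, t)
    return per_predictor, coeffs


def _attach_commonality(report: RegressionReport, ps: PredictorSet) -> None:
    per_predictor, coeffs = commonality_analysis(ps)
    for pred in report.predictors:
        u, c, t = per_predictor[pred.name]
        pred.u, pred.c, pred.t = u, c, t
    report.commonality_coefficients = coeffs


def detect_suppressors(
    rep: RegressionReport, tau: float = SUPPRESSOR_TAU, tol: float = SIGN_TOL
) -> list[str]:
    """Names of predictors acting as total suppressors.

    A predictor is flagged when its regression and correlation coefficients
    have opposite signs (both beyond ``tol``), or when its unique
    contribution is counterbalanced by a negative common contribution
    (C < 0 and U + C <= tau * U).
    """
    flagged = []
    for p in rep.predictors:
        opposite = (
            abs(p.beta) > tol and abs(p.r) > tol and np.sign(p.beta) != np.sign(p.r)
        )
        counterbalanced = (
            p.c is not None
            and p.u is not None
            and p.c < 0.0
            and (p.u + p.c) <= tau * p.u
        )
        if opposite or counterbalanced:
            flagged.append(p.name)
    return flagged


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0.0) | (p > 1.0)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def _apply_bh(report: RegressionReport) -> None:
    """BH family = the β p-values of one fitted model."""
    ps = [p.beta_p for p in report.predictors]
    if any(v is None for v in ps):
        return
    adj = bh_adjust(ps)
    for pred, a in zip(report.predictors, adj):
        pred.beta_p_adjusted = float(a)


def _fit(ps: PredictorSet, n_perm: int, seed: int | None,
         permutations: str = "random") -> RegressionReport:
    if ps.level == "inter_population":
        return mrdm_fit(ps, n_perm=n_perm, seed=seed, permutations=permutations)
    return lr_fit(ps)


def two_stage_analysis(
    ps: PredictorSet,
    n_perm: int = 1000,
    seed: int | None = None,
    tau: float = SUPPRESSOR_TAU,
    permutations: str = "random",
) -> tuple[RegressionReport, RegressionReport]:
    """Fit, flag total suppressors, remove them in one batch, refit.

    Returns the (initial, final) reports.  With no suppressors the final
    report equals the initial one (stage label aside).  If every predictor
    is flagged, the final report is an empty model with R² = 0.
    """
    initial = _fit(ps, n_perm, seed, permutations)
    suppressors = detect_suppressors(initial, tau=tau)
    if not suppressors:
        final = replace(initial, stage="final", suppressors_removed=[])
        return initial, final
    if len(suppressors) == len(ps.names):
        logger.warning(
            "all predictors flagged as suppressors for response %s",
            ps.response_name,
        )
        final = RegressionReport(
            response_name=ps.response_name,
            level=ps.level,
            method=initial.method,
            predictors=[],
            r_squared=0.0,
            r_squared_p=None,
            n_obs=initial.n_obs,
            stage="final",
            suppressors_removed=suppressors,
        )
        return initial, final
    final = _fit(ps.drop(suppressors), n_perm, seed, permutations)
    final.stage = "final"
    final.suppressors_removed = suppressors
    return initial, final
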