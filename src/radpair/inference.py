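"""Statistical machinery: transforms, mixed models, and distance-matrix
regression.

Mixed models are linear with random intercepts (REML), simplified by
backward elimination of fixed effects with Wald F-tests at a chosen
significance level, interactions always eliminable before their main
effects.  Denominator degrees of freedom use a residual-df approximation
(n - p); a Satterthwaite approximation is not available in the fitting
backend and the substitution is documented.

Multivariate distance matrix regression (MDMR) follows the
McArdle-Anderson trace formulation: the squared dissimilarity matrix is
Gower-centered to G = -1/2 C A C, a hat matrix H is built from the full
design (with intercept), and the omnibus pseudo-R^2 is tr(HGH)/tr(G).
Per-predictor pseudo-R^2 is the marginal (drop-one) trace difference
divided by tr(G).  Significance comes from jointly permuting the rows
and columns of the dissimilarity matrix; negative eigenvalue mass of G
is retained in the traces, not truncated.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TransformSpec",
    "MixedModelSpec",
    "MixedModelResult",
    "MDMRResult",
    "transform",
    "fit_mixed",
    "mdmr",
]


@dataclass(frozen=True)
class TransformSpec:
    """Response transformation.

    ``log``: natural log.  ``logit_capped``: logit(x / cap) for counts
    with a plausible ceiling (default 30,000 loci).  ``logit_offset``:
    logit(x + offset) for proportions that can be exactly zero (default
    offset 0.001).
    """

    kind: str
    cap: float = 30_000.0
    offset: float = 0.001

    def __post_init__(self) -> None:
        if self.kind not in ("log", "logit_capped", "logit_offset"):
            raise ValueError(f"unknown transform {self.kind!r}")
        if self.cap <= 0 or self.offset <= 0:
            raise ValueError("cap and offset must be positive")


def transform(x, spec: TransformSpec):
    """Apply ``spec`` to a scalar or array; domain violations raise."""
    x = np.asarray(x, dtype=float)
    if spec.kind == "log":
        if np.any(x <= 0):
            raise ValueError(f"log transform requires x > 0, got {x[x <= 0][:3]}")
        out = np.log(x)
    elif spec.kind == "logit_capped":
        if np.any(x <= 0) or np.any(x >= spec.cap):
            bad = x[(x <= 0) | (x >= spec.cap)][:3]
            raise ValueError(f"logit_capped requires 0 < x < {spec.cap}, got {bad}")
        q = x / spec.cap
        out = np.log(q / (1 - q))
    else:  # logit_offset
        if np.any(x < 0) or np.any(x > 1):
            bad = x[(x < 0) | (x > 1)][:3]
            raise ValueError(f"logit_offset requires 0 <= x <= 1, got {bad}")
        q = x + spec.offset
        out = np.log(q / (1 - q))
    return float(out) if out.ndim == 0 else out


@dataclass
class MixedModelSpec:
    """A mixed model to fit and simplify.

    ``fixed`` lists fixed-effect terms; interactions are written
    ``"a:b"``.  ``random`` lists random-intercept grouping columns; a
    nested factor is written ``"inner@outer"`` (intercepts for the
    combined levels).  ``alpha`` is the elimination threshold.
    """

    response: str
    fixed: list[str]
    random: list[str] = field(default_factory=list)
    transform_spec: TransformSpec | None = None
    alpha: float = 0.05


@dataclass
class MixedModelResult:
    retained: list[str]
    estimates: pd.Series
    pvalues: pd.Series
    elimination_trail: list[tuple[str, float]]  # (term dropped, its p-value)
    singular: bool = False
    model: object = None

    def estimate(self, term: str) -> float:
        return float(self.estimates[term])


def _term_columns(term: str, data: pd.DataFrame) -> pd.DataFrame:
    """Design columns for one term (numeric as-is; categorical dummy-coded
    with first level dropped; ':' builds interaction products)."""
    parts = term.split(":")
    blocks = []
    for p in parts:
        col = data[p]
        if col.dtype.kind in "biufc" and col.dtype.kind != "b":
            blocks.append(pd.DataFrame({p: col.astype(float)}))
        else:
            d = pd.get_dummies(col.astype(str), prefix=p, drop_first=True).astype(float)
            blocks.append(d)
    out = blocks[0]
    for b in blocks[1:]:
        cols = {}
        for c1 in out.columns:
            for c2 in b.columns:
                cols[f"{c1}:{c2}"] = out[c1] * b[c2]
        out = pd.DataFrame(cols, index=data.index)
    return out


def _design(fixed: list[str], data: pd.DataFrame):
    """Full design matrix with intercept; returns (X, column slices per term)."""
    X = pd.DataFrame({"Intercept": np.ones(len(data))}, index=data.index)
    slices: dict[str, list[str]] = {}
    for term in fixed:
        block = _term_columns(term, data)
        slices[term] = list(block.columns)
        X = pd.concat([X, block], axis=1)
    return X, slices


def _eliminable(fixed: list[str]) -> list[str]:
    """Terms not participating in a higher-order retained interaction."""
    inters = [t for t in fixed if ":" in t]
    protected = {p for t in inters for p in t.split(":")}
    return [t for t in fixed if ":" in t or t not in protected]


def _fit_once(spec: MixedModelSpec, data: pd.DataFrame, fixed: list[str]):
    import statsmodels.api as sm

    y = data[spec.response].astype(float)
    if spec.transform_spec is not None:
        y = pd.Series(transform(y.to_numpy(), spec.transform_spec), index=data.index)
    X, slices = _design(fixed, data)
    aliased = _aliased_columns(X)
    if aliased:
        raise ValueError(f"unestimable (aliased) design columns: {aliased}")

    singular = False
    if spec.random:
        work = data.copy()
        vc_cols = []
        for r in spec.random:
            if "@" in r:
                inner, outer = r.split("@")
                cname = f"__vc_{inner}_{outer}"
                work[cname] = work[outer].astype(str) + "/" + work[inner].astype(str)
            else:
                cname = f"__vc_{r}"
                work[cname] = work[r].astype(str)
            vc_cols.append(cname)
        groups = np.ones(len(work))
        vc = {c: f"0 + C({c})" for c in vc_cols}
        model = sm.MixedLM(y, X, groups=groups,
                           exog_vc=_vc_design(work, vc_cols),
                           exog_re=None)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = model.fit(reml=True, method="lbfgs", maxiter=200)
            except Exception:
                fit = model.fit(reml=True, maxiter=200)
        if getattr(fit, "converged", True) is False:
            singular = True
        params = fit.fe_params
        cov = fit.cov_params().loc[params.index, params.index]
        resid_df = len(data) - X.shape[1]
    else:
        fit = sm.OLS(y, X).fit()
        params = fit.params
        cov = fit.cov_params()
        resid_df = fit.df_resid
    return fit, X, slices, params, cov, resid_df, singular


def _vc_design(work: pd.DataFrame, vc_cols: list[str]):
    from statsmodels.regression.mixed_linear_model import VCSpec

    names, colnames, mats = [], [], []
    for c in vc_cols:
        d = pd.get_dummies(work[c].astype(str)).astype(float)
        names.append(c.removeprefix("__vc_"))
        colnames.append([list(d.columns)])
        mats.append([d.to_numpy()])
    return VCSpec(names, colnames, mats)


def _term_f_test(params, cov, cols: list[str], resid_df: float) -> float:
    """Wald F-test p-value that all ``cols`` coefficients are zero."""
    from scipy import stats

    b = params[cols].to_numpy()
    V = cov.loc[cols, cols].to_numpy()
    q = len(cols)
    try:
        stat = float(b @ np.linalg.solve(V, b)) / q
    except np.linalg.LinAlgError:
        stat = float(b @ np.linalg.pinv(V) @ b) / q
    return float(stats.f.sf(stat, q, max(resid_df, 1)))


def fit_mixed(spec: MixedModelSpec, data: pd.DataFrame) -> MixedModelResult:
    """Fit with REML and simplify by backward elimination.

    Repeatedly drops the least-significant eliminable fixed term whose
    Wald F-test p-value exceeds ``spec.alpha`` (interactions before the
    main effects they contain), refitting after each drop.  ``alpha >= 1``
    returns the full model.
    """
    used = [spec.response] + [p for t in spec.fixed for p in t.split(":")]
    used += [p for r in spec.random for p in r.split("@")]
    miss = data[sorted(set(used))].isna().any()
    if miss.any():
        raise ValueError(f"missing values in columns {list(miss[miss].index)}")

    fixed = list(spec.fixed)
    trail: list[tuple[str, float]] = []
    while True:
        fit, X, slices, params, cov, resid_df, singular = _fit_once(spec, data, fixed)
        pvals = {t: _term_f_test(params, cov, slices[t], resid_df) for t in fixed}
        drop_candidates = [
            (t, pvals[t]) for t in _eliminable(fixed) if pvals[t] > spec.alpha
        ]
        if not drop_candidates:
            break
        worst = max(drop_candidates, key=lambda tp: tp[1])
        fixed.remove(worst[0])
        trail.append(worst)
    est = params
    pv = pd.Series({t: pvals[t] for t in fixed})
    return MixedModelResult(
        retained=fixed, estimates=est, pvalues=pv,
        elimination_trail=trail, singular=singular, model=fit,
    )


@dataclass
class MDMRResult:
    omnibus_pseudo_r2: float
    omnibus_p: float
    per_predictor: pd.DataFrame  # columns pseudo_r2, p
    n_permutations: int
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.omnibus_pseudo_r2 <= 1 + 1e-9:
            raise ValueError("omnibus pseudo-R^2 out of [0, 1]")


def _hat(X: np.ndarray) -> np.ndarray:
    Q, R = np.linalg.qr(X)
    rank = np.sum(np.abs(np.diag(R)) > 1e-10 * max(abs(np.diag(R)).max(), 1))
    if rank < X.shape[1]:
        raise ValueError("rank-deficient design")
    return Q @ Q.T


def gower_center(d: np.ndarray) -> np.ndarray:
    """G = -1/2 C A C with A the squared dissimilarities and C centering."""
    a = -0.5 * np.asarray(d, dtype=float) ** 2
    n = a.shape[0]
    c = np.eye(n) - np.ones((n, n)) / n
    return c @ a @ c


def mdmr(
    dm,
    predictors: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> MDMRResult:
    """Distance-matrix regression with permutation inference.

    ``dm`` is a :class:`~radpair.distances.DistanceMatrix` (or a labeled
    square DataFrame) complete over the rows of ``predictors``, which
    must be indexed by the same labels.  Categorical predictors are
    dummy-coded.  P-values are ``(1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    if hasattr(dm, "labels"):
        labels = list(predictors.index)
        d = dm.subset(labels).values
    else:
        labels = list(predictors.index)
        d = dm.loc[labels, labels].to_numpy(dtype=float)
    if np.isnan(d).any():
        raise ValueError("distance matrix has missing values over the included labels")
    n = d.shape[0]

    G = gower_center(d)
    trG = np.trace(G)
    if trG <= 0:
        raise ValueError("degenerate distance matrix: tr(G) <= 0")

    X_full, slices = _design(list(predictors.columns), predictors)
    aliased = _aliased_columns(X_full)
    if aliased:
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    H = _hat(X_full.to_numpy())
    H_minus = {}
    for term in predictors.columns:
        keep = [c for c in X_full.columns if c not in slices[term]]
        H_minus[term] = _hat(X_full[keep].to_numpy())

    def stats_for(Gp: np.ndarray) -> tuple[float, dict[str, float]]:
        # H idempotent & symmetric: tr(HGH) = tr(HG) = sum(H * G)
        omni = float(np.sum(H * Gp))
        per = {t: omni - float(np.sum(H_minus[t] * Gp)) for t in predictors.columns}
        return omni, per

    omni_obs, per_obs = stats_for(G)
    rng = np.random.default_rng(seed)
    ge_omni = 0
    ge_per = {t: 0 for t in predictors.columns}
    for _ in range(n_permutations):
        p = rng.permutation(n)
        Gp = G[np.ix_(p, p)]
        omni, per = stats_for(Gp)
        if omni >= omni_obs - 1e-12:
            ge_omni += 1
        for t in predictors.columns:
            if per[t] >= per_obs[t] - 1e-12:
                ge_per[t] += 1

    # negative eigenvalue mass of G (non-Euclidean dissimilarities) can push
    # the raw trace ratio slightly outside [0, 1]; permutations use the raw
    # statistic, the reported pseudo-R^2 is clipped
    per_table = pd.DataFrame(
        {
            "pseudo_r2": {
                t: float(np.clip(per_obs[t] / trG, 0.0, 1.0))
                for t in predictors.columns
            },
            "p": {t: (1 + ge_per[t]) / (1 + n_permutations) for t in predictors.columns},
        }
    )
    return MDMRResult(
        omnibus_pseudo_r2=float(np.clip(omni_obs / trG, 0.0, 1.0)),
        omnibus_p=(1 + ge_omni) / (1 + n_permutations),
        per_predictor=per_table,
        n_permutations=n_permutations,
        seed=seed,
    )


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    arr = X.to_numpy(dtype=float)
    _q, R = np.linalg.qr(arr)
    diag = np.abs(np.diag(R))
    tol = 1e-10 * max(diag.max(), 1.0)
    return [c for c, d in zip(X.columns, diag) if d <= tol]
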