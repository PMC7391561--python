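"""Binomial GLM machinery: single-predictor screens, adjusted D-squared,
and three-matrix variation partitioning.

The explained-deviance coefficient of a binomial GLM is
``D2 = (null_deviance - residual_deviance) / null_deviance``; the
adjusted form penalizes for the number of fitted coefficients (intercept
included):

    adj_D2 = 1 - [(n - 1) / (n - p)] * (1 - D2)

Variation partitioning over three predictor matrices (ecology A,
colonization history B, apomict occurrence C) fits the seven models A, B,
C, AB, AC, BC, ABC and decomposes adj_D2(ABC) into three unique, three
pairwise-joint and one three-way-joint fraction; fractions can be
negative and are reported unclamped.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from refugeo.errors import SeparationWarning

log = logging.getLogger("refugeo")

SEPARATION_COEF = 15.0  # |coef| x sd(x) beyond this flags quasi-separation


@dataclass
class GLMFitResult:
    """Summary of one binomial GLM fit."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    null_deviance: float
    residual_deviance: float
    n: int
    p_params: int
    d2: float
    adj_d2: float
    separation: bool = False
    term_names: list[str] = field(default_factory=list)


def _aliased_columns(X: pd.DataFrame) -> list:
    """Columns that add no rank to the design matrix (left-to-right scan)."""
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return []
    aliased = []
    rank = 0
    for k in range(arr.shape[1]):
        r = np.linalg.matrix_rank(arr[:, : k + 1])
        if r == rank:
            aliased.append(X.columns[k])
        rank = r
    return aliased


def fit_binomial_glm(
    y, X: pd.DataFrame, add_intercept: bool = True, drop_aliased: bool = False
) -> GLMFitResult:
    """Fit a logit-link binomial GLM by IRLS.

    ``X`` must not already contain a constant when ``add_intercept`` is
    true.  A rank-deficient design raises naming the aliased columns,
    unless ``drop_aliased`` is set, in which case aliased columns are
    silently removed (the convention of partial-regression partitioning,
    where blocks may share collinear variables).  Perfect or quasi-perfect
    separation is flagged (warning, and ``separation=True`` on the
    result) rather than raised; deviances are still reported at the
    convergence cutoff.
    """
    y = np.asarray(y, dtype=float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    X = pd.DataFrame(X).astype(float)
    design = sm.add_constant(X, prepend=True) if add_intercept else X.copy()
    aliased = _aliased_columns(design)
    if aliased:
        if not drop_aliased:
            raise ValueError(f"rank-deficient design; aliased column(s): {aliased}")
        design = design.drop(columns=aliased)
    n, p = design.shape
    if n <= p:
        raise ValueError(f"need n > number of parameters ({n} <= {p})")
    separation = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        res = model.fit(maxiter=200, tol=1e-13)
    for w in caught:
        if "separation" in str(w.message).lower() or "PerfectSeparation" in str(w.category):
            separation = True
    # quasi-separation heuristic: huge coefficient on the predictor's own scale
    sds = design.std(ddof=0).replace(0.0, 1.0)
    if (np.abs(res.params * sds) > SEPARATION_COEF).any():
        separation = True
    if separation:
        warnings.warn("possible (quasi-)separation: coefficients diverge", SeparationWarning)
    null_dev = float(res.null_deviance)
    resid_dev = float(res.deviance)
    d2 = 0.0 if null_dev == 0 else (null_dev - resid_dev) / null_dev
    adj_d2 = 1.0 - ((n - 1.0) / (n - p)) * (1.0 - d2)
    return GLMFitResult(
        params=res.params,
        bse=res.bse,
        zvalues=res.tvalues,
        pvalues=res.pvalues,
        null_deviance=null_dev,
        residual_deviance=resid_dev,
        n=n,
        p_params=p,
        d2=float(d2),
        adj_d2=float(adj_d2),
        separation=separation,
        term_names=list(design.columns),
    )


def single_predictor_screen(
    y, predictors: pd.DataFrame, family_size: int | None = None
) -> pd.DataFrame:
    """One binomial GLM per predictor, with Bonferroni-adjusted p values.

    ``family_size`` defaults to the number of predictors screened;
    ``p_adj = min(1, p * family_size)``, and the significance flag is
    ``p_adj < 0.05``.
    """
    if family_size is None:
        family_size = predictors.shape[1]
    if family_size < predictors.shape[1]:
        raise ValueError("family_size must cover all screened predictors")
    rows = []
    for name in predictors.columns:
        fit = fit_binomial_glm(y, predictors[[name]])
        p = float(fit.pvalues.iloc[1])
        p_adj = min(1.0, p * family_size)
        rows.append(
            {
                "predictor": name,
                "coef": float(fit.params.iloc[1]),
                "se": float(fit.bse.iloc[1]),
                "z": float(fit.zvalues.iloc[1]),
                "p": p,
                "p_adj": p_adj,
                "significant": p_adj < 0.05,
                "d2": fit.d2,
                "adj_d2": fit.adj_d2,
                "separation": fit.separation,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class PartitionFractions:
    """The seven fractions + residual of three-matrix variation partitioning.

    ``a_eco``/``b_hist``/``c_apo`` are unique fractions, ``d``/``e``/``f``
    pairwise joint, ``g_all`` three-way joint; all sum to adj_D2 of the
    full model by construction.  Negative fractions are reported as
    computed (the convention of partial-regression partitioning).
    """

    a_eco: float
    b_hist: float
    c_apo: float
    d_eco_hist: float
    e_hist_apo: float
    f_eco_apo: float
    g_all: float
    residual: float
    adj_d2_full: float
    model_adj_d2: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "a_eco": self.a_eco,
            "b_hist": self.b_hist,
            "c_apo": self.c_apo,
            "d_eco_hist": self.d_eco_hist,
            "e_hist_apo": self.e_hist_apo,
            "f_eco_apo": self.f_eco_apo,
            "g_all": self.g_all,
            "residual": self.residual,
        }


def varpart3(y, X_A: pd.DataFrame, X_B: pd.DataFrame, X_C: pd.DataFrame) -> PartitionFractions:
    """Three-matrix variation partitioning on adjusted D-squared.

    Fits the seven models A, B, C, AB, AC, BC, ABC and, with
    ``R(.) = adj_D2``, computes

        a = R(ABC) - R(BC)          (unique to A)
        b = R(ABC) - R(AC)          (unique to B)
        c = R(ABC) - R(AB)          (unique to C)
        d = R(AC) + R(BC) - R(ABC) - R(C)
        e = R(AB) + R(AC) - R(ABC) - R(A)
        f = R(AB) + R(BC) - R(ABC) - R(B)
        g = R(ABC) - a - b - c - d - e - f
        residual = 1 - R(ABC)
    """
    blocks = {"A": pd.DataFrame(X_A), "B": pd.DataFrame(X_B), "C": pd.DataFrame(X_C)}
    for name, X in blocks.items():
        if X.shape[1] == 0:
            raise ValueError(f"predictor matrix {name} is empty")
    n_set = {len(X) for X in blocks.values()}
    if len(n_set) > 1:
        raise ValueError("predictor matrices must share the same observations")
    R: dict[str, float] = {}
    for r in (1, 2, 3):
        for combo in itertools.combinations("ABC", r):
            name = "".join(combo)
            X = pd.concat(
                [blocks[b].add_prefix(f"{b}__") for b in combo], axis=1
            )
            try:
                R[name] = fit_binomial_glm(y, X, drop_aliased=True).adj_d2
            except Exception as exc:
                raise RuntimeError(f"variation-partitioning fit failed for model {name}") from exc
    a = R["ABC"] - R["BC"]
    b = R["ABC"] - R["AC"]
    c = R["ABC"] - R["AB"]
    d = R["AC"] + R["BC"] - R["ABC"] - R["C"]
    e = R["AB"] + R["AC"] - R["ABC"] - R["A"]
    f = R["AB"] + R["BC"] - R["ABC"] - R["B"]
    g = R["ABC"] - a - b - c - d - e - f
    return PartitionFractions(
        a_eco=a,
        b_hist=b,
        c_apo=c,
        d_eco_hist=d,
        e_hist_apo=e,
        f_eco_apo=f,
        g_all=g,
        residual=1.0 - R["ABC"],
        adj_d2_full=R["ABC"],
        model_adj_d2=R,
    )


def apomict_cross_occurrence(
    table: pd.DataFrame,
    cytotypes: tuple[str, ...] = ("present_5x", "present_7x", "present_8x"),
    family_size: int = 3,
    restrict: bool = True,
) -> pd.DataFrame:
    """Pairwise cross-occurrence regressions among apomictic cytotypes.

    By default restricted to populations containing at least one apomictic
    cytotype (the subset the question concerns).  Note that conditioning
    on that union induces negative dependence even between occurrences
    that are marginally independent; ``restrict=False`` analyses all
    populations.  For each unordered pair both regression directions are
    fitted; the coefficient, z and p are identical across directions (a
    property of the 2x2 log odds ratio) while D2 depends on the response,
    so both are reported.  Bonferroni family defaults to the 3 pairs.
    """
    present = [c for c in cytotypes if c in table.columns and table[c].sum() > 0]
    skipped = sorted(set(cytotypes) - set(present))
    if skipped:
        log.warning("cytotype(s) absent from all populations, pairs skipped: %s", skipped)
    if len(present) < 2:
        raise ValueError("need at least 2 apomictic cytotypes with occurrences")
    if restrict:
        sub = table.loc[table[present].sum(axis=1) > 0]
    else:
        sub = table
    rows = []
    for c1, c2 in itertools.combinations(present, 2):
        fits = {}
        for resp, pred in ((c2, c1), (c1, c2)):
            fits[(resp, pred)] = fit_binomial_glm(sub[resp], sub[[pred]])
        f12 = fits[(c2, c1)]
        f21 = fits[(c1, c2)]
        if not (f12.separation or f21.separation):
            if abs(float(f12.zvalues.iloc[1]) - float(f21.zvalues.iloc[1])) > 1e-6:
                raise AssertionError("z values differ across regression directions")
        rows.append(
            {
                "pair": f"{c1}~{c2}",
                "coef": float(f12.params.iloc[1]),
                "se": float(f12.bse.iloc[1]),
                "z": float(f12.zvalues.iloc[1]),
                "p": float(f12.pvalues.iloc[1]),
                "p_adj": min(1.0, float(f12.pvalues.iloc[1]) * family_size),
                "d2_fwd": f12.d2,
                "d2_rev": f21.d2,
                "separation": f12.separation or f21.separation,
                "n": int(len(sub)),
            }
        )
    return pd.DataFrame(rows)
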