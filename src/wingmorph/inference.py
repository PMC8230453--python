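"""Hypothesis tests for the wing study: MANOVA, multivariate regression,
two-factor ANOVA and Pearson correlation.

The multivariate tests all reduce to Wilks' lambda, |E| / |E + H|, where E
is the residual cross-product matrix of the full linear model and H the
hypothesis cross-products of one term.  The study design is an unbalanced
2x2 (area x period) over colony-level units, handled with effect coding
(+1/-1) and Type III sums of cross-products, so each factor is tested
adjusted for the other and for the interaction.  Every hypothesis here has
a single degree of freedom, for which the F transform of Wilks' lambda is
exact: F = (1 - L)/L * (nu - p + 1)/p on (p, nu - p + 1) df.

Determinants are evaluated through slogdet for numerical stability at
p = 34 response dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats


@dataclass
class EffectTest:
    """One tested effect: Wilks' lambda (or SS), F, df pair, p."""

    name: str
    statistic: float  # Wilks' lambda for multivariate, F's SS for ANOVA
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class ManovaResult:
    effects: dict[str, EffectTest]  # keys: factor_a, factor_b, interaction

    def __getitem__(self, key: str) -> EffectTest:
        return self.effects[key]


@dataclass
class AnovaResult:
    effects: dict[str, EffectTest]
    cell_means: pd.DataFrame  # per (A, B) cell: mean, n, ci_low, ci_high

    def __getitem__(self, key: str) -> EffectTest:
        return self.effects[key]


def _two_level_codes(factor: Sequence, name: str) -> tuple[np.ndarray, list]:
    levels = list(dict.fromkeys(factor))
    if len(levels) != 2:
        raise ValueError(f"{name} must have exactly 2 levels, got {levels}")
    codes = np.where(np.asarray(list(factor), dtype=object) == levels[0], 1.0, -1.0)
    return codes, levels


def _wilks_one_df(E: np.ndarray, H: np.ndarray, nu: int, p: int) -> EffectTest:
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_eh, logdet_eh = np.linalg.slogdet(E + H)
    if sign_e <= 0 or sign_eh <= 0:
        raise ValueError("residual cross-product matrix is singular; reduce k")
    lam = float(np.exp(logdet_e - logdet_eh))
    df1, df2 = p, nu - p + 1
    F = (1.0 - lam) / lam * df2 / df1
    pval = float(scipy.stats.f.sf(F, df1, df2))
    return EffectTest("", lam, float(F), df1, df2, pval)


def _type3_terms(
    Y: np.ndarray, X: np.ndarray, term_cols: dict[str, int]
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Type III hypothesis cross-products per single-column term.

    With effect coding, the Type III SSCP of term j is
    (b_j b_j^T) / [(X'X)^-1]_jj evaluated in the full model.
    Returns {name: (H, E)} with E shared.
    """
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # (q, p)
    resid = Y - X @ beta
    E = resid.T @ resid
    out = {}
    for name, j in term_cols.items():
        bj = beta[j][None, :]  # (1, p)
        H = (bj.T @ bj) / XtX_inv[j, j]
        out[name] = (H, E)
    return out


def manova_two_factor(
    responses: np.ndarray,
    factor_a: Sequence,
    factor_b: Sequence,
    names: tuple[str, str] = ("factor_a", "factor_b"),
) -> ManovaResult:
    """Two-factor MANOVA with Wilks' lambda (Type III, effect coding).

    ``responses`` is the (n, p) matrix of colony-level shape scores; both
    factors must be two-level.  Residual df must exceed p, otherwise the
    caller is advised to reduce the response dimension.
    """
    Y = np.atleast_2d(np.asarray(responses, dtype=float))
    n, p = Y.shape
    a, _ = _two_level_codes(factor_a, names[0])
    b, _ = _two_level_codes(factor_b, names[1])
    if len(a) != n or len(b) != n:
        raise ValueError("factor length does not match responses")
    nu = n - 4
    if nu <= p:
        raise ValueError(
            f"residual df {nu} <= response dimension {p}: reduce the number "
            "of retained components before testing"
        )
    X = np.column_stack([np.ones(n), a, b, a * b])
    terms = _type3_terms(Y, X, {names[0]: 1, names[1]: 2, "interaction": 3})
    effects = {}
    for key, (H, E) in terms.items():
        t = _wilks_one_df(E, H, nu, p)
        t.name = key
        effects[key] = t
    # map positional keys onto canonical names expected by callers
    return ManovaResult(effects={
        "factor_a": effects[names[0]],
        "factor_b": effects[names[1]],
        "interaction": effects["interaction"],
    })


def multivariate_regression_wilks(
    responses: np.ndarray, covariate: Sequence[float]
) -> tuple[float, float, tuple[int, int], float, np.ndarray]:
    """Multivariate regression of responses on one covariate, Wilks test.

    Returns (lambda, F, (df1, df2), p, coefficient vector), the coefficient
    being the per-unit shape change along the covariate.  Exact F for a
    single predictor.
    """
    Y = np.atleast_2d(np.asarray(responses, dtype=float))
    x = np.asarray(list(covariate), dtype=float)
    n, p = Y.shape
    if x.shape != (n,):
        raise ValueError("covariate length does not match responses")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant")
    nu = n - 2
    if nu <= p:
        raise ValueError(
            f"residual df {nu} <= response dimension {p}: reduce k"
        )
    X = np.column_stack([np.ones(n), x])
    terms = _type3_terms(Y, X, {"slope": 1})
    H, E = terms["slope"]
    t = _wilks_one_df(E, H, nu, p)
    beta = np.linalg.lstsq(X, Y, rcond=None)[0]
    return t.statistic, t.F, (t.df1, t.df2), t.p, beta[1]


def anova_two_factor(
    y: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    names: tuple[str, str] = ("factor_a", "factor_b"),
    ci_level: float = 0.95,
) -> AnovaResult:
    """Two-factor ANOVA (Type III, effect coding) for a univariate trait.

    Returns per-effect F tests plus per-cell means with t-based confidence
    intervals (the numbers behind cell-mean plots).
    """
    yv = np.asarray(list(y), dtype=float)
    n = yv.size
    a, la = _two_level_codes(factor_a, names[0])
    b, lb = _two_level_codes(factor_b, names[1])
    fa = np.asarray(list(factor_a), dtype=object)
    fb = np.asarray(list(factor_b), dtype=object)
    for u in la:
        for v in lb:
            if not np.any((fa == u) & (fb == v)):
                raise ValueError(f"empty cell ({u!r}, {v!r})")
    X = np.column_stack([np.ones(n), a, b, a * b])
    nu = n - 4
    terms = _type3_terms(yv[:, None], X, {names[0]: 1, names[1]: 2, "interaction": 3})
    effects = {}
    keymap = {names[0]: "factor_a", names[1]: "factor_b", "interaction": "interaction"}
    (_, E0) = next(iter(terms.values()))
    mse = float(E0[0, 0]) / nu
    for key, (H, _) in terms.items():
        ss = float(H[0, 0])
        F = ss / mse if mse > 0 else (0.0 if ss == 0 else np.inf)
        pval = float(scipy.stats.f.sf(F, 1, nu)) if np.isfinite(F) else 0.0
        effects[keymap[key]] = EffectTest(keymap[key], ss, F, 1, nu, pval)

    rows = []
    tcrit = scipy.stats.t.ppf(0.5 + ci_level / 2, nu)
    for u in la:
        for v in lb:
            cell = yv[(fa == u) & (fb == v)]
            m = float(cell.mean())
            se = float(cell.std(ddof=1) / np.sqrt(cell.size)) if cell.size > 1 else np.nan
            rows.append({
                names[0]: u, names[1]: v, "n": cell.size, "mean": m,
                "ci_low": m - tcrit * se, "ci_high": m + tcrit * se,
            })
    return AnovaResult(effects=effects, cell_means=pd.DataFrame(rows))


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with the two-sided t-based p-value."""
    xv = np.asarray(list(x), dtype=float)
    yv = np.asarray(list(y), dtype=float)
    if xv.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance input")
    r, p = scipy.stats.pearsonr(xv, yv)
    return float(r), float(p)
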