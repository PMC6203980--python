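"""Downstream statistics: PCA over the trait matrix, Pearson correlation
screening against bending strength, bidirectional stepwise OLS selected by
AIC, and regression diagnostics.

Bending strength (BS) is the maximum load Fmax (N) sustained in a
three-point bending test; it enters purely as a numeric column.  The AIC
used for model ranking is the step-search convention
``n*log(RSS/n) + 2k`` with k the number of estimated coefficients
(intercept included); additive constants are irrelevant to ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import CollinearityError, InputError
from .traits import TRAIT_NAMES


@dataclass
class RegressionModel:
    predictors: list[str]
    coef_table: pd.DataFrame  # index: const + predictors; Estimate/Std.error/t/p
    r2: float
    adj_r2: float
    aic: float
    fitted: object  # statsmodels results, for diagnostics

    def summary_text(self) -> str:
        lines = ["Coefficients:", self.coef_table.to_string(float_format="%.6g")]
        lines.append(f"R^2: {self.r2:.4f}   Adjusted R^2: {self.adj_r2:.4f}")
        lines.append(f"AIC (n*log(RSS/n) + 2k): {self.aic:.4f}")
        return "\n".join(lines)


def _trait_matrix(m: pd.DataFrame, columns: list[str] | None = None) -> pd.DataFrame:
    cols = columns or [c for c in TRAIT_NAMES if c in m.columns]
    missing = [c for c in (columns or []) if c not in m.columns]
    if missing:
        raise InputError(f"columns not in table: {missing}")
    if not cols:
        raise InputError("no trait columns found in table")
    x = m[cols].astype(float)
    if x.isna().any().any():
        raise InputError("trait matrix contains missing values")
    return x


def pca_traits(
    m: pd.DataFrame, columns: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Correlation-matrix PCA of the trait table.

    Columns are standardized to zero mean and unit variance before the
    decomposition; constant columns are dropped with a warning.  Returns
    ``(loadings, explained_fractions, scores)`` with components ordered by
    decreasing variance and fractions summing to 1.
    """
    x = _trait_matrix(m, columns)
    if len(x) < 3:
        raise InputError("PCA needs at least 3 samples")
    sd = x.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant columns from PCA: {constant}", stacklevel=2)
        x = x.drop(columns=constant)
        sd = sd.drop(constant)
    z = (x - x.mean()) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s**2 / (len(x) - 1)
    frac = var / var.sum()
    loadings = pd.DataFrame(
        vt.T,
        index=x.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    scores = u * s
    return loadings, frac, scores


def correlation_screen(
    m: pd.DataFrame,
    bs_column: str = "BS",
    alpha: float = 0.05,
    columns: list[str] | None = None,
    bh_adjust: bool = False,
) -> pd.DataFrame:
    """Pearson correlation of every trait against bending strength.

    Two-sided p-values from the t distribution with n-2 df; traits with
    ``p < alpha`` are flagged significant.  Zero-variance traits are
    excluded with a warning.  ``bh_adjust`` optionally adds a
    Benjamini-Hochberg adjusted p column (off by default).
    """
    if bs_column not in m.columns:
        raise InputError(f"no bending-strength column {bs_column!r}")
    x = _trait_matrix(m, columns)
    if len(x) < 4:
        raise InputError("correlation screen needs at least 4 samples")
    y = m[bs_column].to_numpy(dtype=float)
    rows = []
    for t in x.columns:
        v = x[t].to_numpy()
        if v.std() == 0 or y.std() == 0:
            warnings.warn(f"zero-variance column {t!r} excluded", stacklevel=2)
            continue
        r, p = sps.pearsonr(v, y)
        rows.append({"trait": t, "r": r, "p": p})
    out = pd.DataFrame(rows)
    if bh_adjust and len(out):
        out["p_bh"] = sps.false_discovery_control(out["p"], method="bh")
    out["significant"] = out["p"] < alpha
    return out


def _aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def _fit(m: pd.DataFrame, bs_column: str, predictors: list[str]):
    y = m[bs_column].to_numpy(dtype=float)
    x = sm.add_constant(m[list(predictors)].astype(float), has_constant="add")
    res = sm.OLS(y, x).fit()
    return res


def _check_collinearity(m: pd.DataFrame, candidates: list[str]) -> None:
    x = m[candidates].to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    rank = np.linalg.matrix_rank(xc)
    if rank < len(candidates):
        # name a minimal aliased set: columns whose removal restores full rank
        aliased = []
        for j, name in enumerate(candidates):
            sub = np.delete(xc, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                aliased.append(name)
        raise CollinearityError(aliased or list(candidates))


def stepwise_aic(
    m: pd.DataFrame,
    candidates: list[str],
    bs_column: str = "BS",
) -> RegressionModel:
    """Bidirectional stepwise OLS of bending strength on the candidate
    traits, selected by lowest AIC.

    Starts from the full candidate model; at each step the single
    addition or removal that most reduces AIC is taken, stopping at a
    local AIC minimum (the ``step``-style search).
    """
    candidates = list(candidates)
    if not candidates:
        raise InputError("no candidate predictors")
    _trait_matrix(m, candidates)  # validates presence / missing values
    n = len(m)
    if n <= len(candidates) + 2:
        raise InputError("need n > number of candidates + 2")
    _check_collinearity(m, candidates)

    current = list(candidates)
    res = _fit(m, bs_column, current)
    best_aic = _aic(res.ssr, n, len(current) + 1)
    while True:
        moves: list[tuple[float, list[str]]] = []
        for t in current:
            trial = [c for c in current if c != t]
            if not trial:
                continue
            r = _fit(m, bs_column, trial)
            moves.append((_aic(r.ssr, n, len(trial) + 1), trial))
        for t in candidates:
            if t in current:
                continue
            trial = current + [t]
            r = _fit(m, bs_column, trial)
            moves.append((_aic(r.ssr, n, len(trial) + 1), trial))
        if not moves:
            break
        aic_new, trial = min(moves, key=lambda kv: kv[0])
        if aic_new < best_aic - 1e-10:
            best_aic = aic_new
            current = trial
        else:
            break

    current = [c for c in candidates if c in current]  # stable order
    res = _fit(m, bs_column, current)
    names = ["(Intercept)"] + current
    coef_table = pd.DataFrame(
        {
            "Estimate": res.params.to_numpy(),
            "Std. error": res.bse.to_numpy(),
            "t-value": res.tvalues.to_numpy(),
            "Pr(>|t|)": res.pvalues.to_numpy(),
        },
        index=names,
    )
    return RegressionModel(
        predictors=current,
        coef_table=coef_table,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        aic=float(best_aic),
        fitted=res,
    )


def exhaustive_aic(
    m: pd.DataFrame, candidates: list[str], bs_column: str = "BS"
) -> tuple[list[str], float]:
    """Best subset by AIC over all 2^k candidate subsets (k <= 15).

    Intended as the reference search for validating the stepwise
    procedure on small candidate sets.
    """
    candidates = list(candidates)
    if len(candidates) > 15:
        raise InputError("exhaustive search limited to 15 candidates")
    n = len(m)
    best: tuple[float, list[str]] | None = None
    for mask in range(2 ** len(candidates)):
        subset = [c for i, c in enumerate(candidates) if mask >> i & 1]
        if subset:
            res = _fit(m, bs_column, subset)
            rss = res.ssr
        else:
            y = m[bs_column].to_numpy(dtype=float)
            rss = float(np.sum((y - y.mean()) ** 2))
        a = _aic(rss, n, len(subset) + 1)
        if best is None or a < best[0] - 1e-12:
            best = (a, subset)
    assert best is not None
    return best[1], best[0]


def model_diagnostics(model: RegressionModel, m: pd.DataFrame) -> pd.DataFrame:
    """Per-sample residual, leverage and Cook's distance; samples with
    Cook's distance > 4/n are flagged for quality control."""
    res = model.fitted
    infl = res.get_influence()
    n = int(res.nobs)
    cooks = infl.cooks_distance[0]
    out = pd.DataFrame(
        {
            "residual": res.resid,
            "leverage": infl.hat_matrix_diag,
            "cooks_distance": cooks,
            "flagged": cooks > 4.0 / n,
        }
    )
    if "source_id" in m.columns:
        out.insert(0, "source_id", m["source_id"].to_numpy())
    return out
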