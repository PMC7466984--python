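"""Per-site linear regression of mutation state on stage methylation levels.

Each common site contributes one row: the response is 1 if a CpG-type SNP
lies at the site and 0 otherwise, and the 13 predictors are the site's raw
methylation levels in the canonical stage order. The model is a linear
probability model fit by ordinary least squares (the coefficient table of
the source analysis is an OLS table), with greedy stepwise AIC selection
("both" direction, starting from the full model) to find the stages that
matter most. A logistic option exists for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from methmut.mutability import cpg_snp_sites
from methmut.stages import STAGES


@dataclass
class RegressionResult:
    """Coefficient table plus model metadata for one OLS fit."""

    table: pd.DataFrame  # term, estimate, se, tvalue, pvalue
    aic: float
    terms: tuple[str, ...]
    nobs: int
    selected: tuple[str, ...] | None = None  # set by stepwise_select

    def estimate(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])

    def conf_int(self, term: str, level: float = 0.95):
        from scipy import stats
        df = self.nobs - len(self.terms) - 1
        t = stats.t.ppf(0.5 + level / 2, df)
        est, se = self.estimate(term), self.se(term)
        return est - t * se, est + t * se


def build_design(common: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Design frame: 13 stage-level predictors and a 0/1 mutation response.

    *common* is the common-site frame (``level_<stage>`` columns); the
    response is 1 iff a CpG-type SNP (any of the three CpG types) lies at
    the site. Row count equals the common-site count.
    """
    cols = [f"level_{s}" for s in STAGES]
    missing = [c for c in cols if c not in common.columns]
    if missing:
        raise ValueError(f"common-site frame missing stage levels: {missing}")
    if common[cols].isna().any().any():
        raise ValueError("missing methylation level at a common site")
    design = common[["chrom", "pos", *cols]].copy()
    y = np.zeros(len(design), dtype=np.int8)
    for chrom, idx in design.groupby("chrom", sort=False).indices.items():
        snps = cpg_snp_sites(catalog, chrom=chrom)
        y[idx] = np.isin(design["pos"].to_numpy(dtype=np.int64)[idx], snps)
    design["mutated"] = y
    return design


def design_from_arrays(levels: np.ndarray, mutated: np.ndarray) -> pd.DataFrame:
    """Design frame from a (n, 13) level matrix and a 0/1 response vector."""
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 2 or levels.shape[1] != len(STAGES):
        raise ValueError(f"levels must be (n, {len(STAGES)})")
    df = pd.DataFrame(levels, columns=[f"level_{s}" for s in STAGES])
    df.insert(0, "pos", np.arange(len(df)))
    df.insert(0, "chrom", "chr1")
    df["mutated"] = np.asarray(mutated, dtype=np.int8)
    return df


def fit_ols(design: pd.DataFrame, terms=STAGES) -> RegressionResult:
    """OLS of the mutation indicator on the given stage terms, with intercept.

    Classical (non-robust) standard errors; two-sided p-values from the t
    distribution with n − k − 1 degrees of freedom. Rank deficiency is an
    error naming the collinear terms.
    """
    terms = tuple(terms)
    X = design[[f"level_{s}" for s in terms]].to_numpy(dtype=float)
    X = sm.add_constant(X, has_constant="add")
    y = design["mutated"].to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise np.linalg.LinAlgError(
            f"design matrix rank {rank} < {X.shape[1]}; collinear terms among {terms}"
        )
    fit = sm.OLS(y, X).fit()
    names = ["intercept", *terms]
    table = pd.DataFrame({
        "term": names,
        "estimate": fit.params,
        "se": fit.bse,
        "tvalue": fit.tvalues,
        "pvalue": fit.pvalues,
    })
    return RegressionResult(table=table.reset_index(drop=True), aic=float(fit.aic),
                            terms=terms, nobs=int(fit.nobs))


def _rss_aic(X: np.ndarray, y: np.ndarray) -> float:
    """Gaussian-likelihood AIC from an lstsq fit (matches statsmodels OLS)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    llf = -n / 2 * (np.log(2 * np.pi) + np.log(rss / n) + 1)
    return -2 * llf + 2 * X.shape[1]


def stepwise_select(design: pd.DataFrame, terms=STAGES, direction: str = "both") -> RegressionResult:
    """Greedy stepwise AIC selection starting from the full model.

    At each step every single-term deletion (and, with direction="both",
    every re-addition of a dropped term) is scored by AIC; the best move is
    taken while it lowers AIC. Deterministic given the design. The returned
    result is the refitted selected model with ``selected`` set.
    """
    if direction not in ("both", "backward"):
        raise ValueError("direction must be 'both' or 'backward'")
    terms = list(terms)
    cols = {t: design[f"level_{t}"].to_numpy(dtype=float) for t in terms}
    y = design["mutated"].to_numpy(dtype=float)
    ones = np.ones(len(y))

    def aic_of(subset: list[str]) -> float:
        X = np.column_stack([ones] + [cols[t] for t in subset]) if subset else ones[:, None]
        return _rss_aic(X, y)

    current = list(terms)
    current_aic = aic_of(current)
    while True:
        moves: list[tuple[float, str, str]] = []
        for t in current:
            trial = [u for u in current if u != t]
            moves.append((aic_of(trial), "drop", t))
        if direction == "both":
            for t in terms:
                if t not in current:
                    moves.append((aic_of(current + [t]), "add", t))
        best_aic, action, term = min(moves, key=lambda m: m[0])
        if best_aic >= current_aic - 1e-10:
            break
        if action == "drop":
            current.remove(term)
        else:
            current.append(term)
        current_aic = best_aic

    selected = tuple(t for t in terms if t in current)
    result = fit_ols(design, terms=selected) if selected else fit_ols(design, terms=())
    result.selected = selected
    return result


def regression_table(full: RegressionResult, stepwise: RegressionResult) -> pd.DataFrame:
    """Coefficient-table analogue: full-model estimate/SE/p plus the
    stepwise estimate for selected stages (blank otherwise)."""
    tab = full.table.set_index("term")
    step = stepwise.table.set_index("term")
    rows = []
    for stage in STAGES:
        est, se, p = tab.loc[stage, ["estimate", "se", "pvalue"]]
        in_step = stepwise.selected is not None and stage in stepwise.selected
        rows.append({
            "term": stage,
            "estimate": est,
            "se": se,
            "pvalue": p,
            "stepwise_estimate": step.loc[stage, "estimate"] if in_step else np.nan,
        })
    return pd.DataFrame(rows)
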