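"""Endosymbiont-versus-virus read-abundance regression.

Wolbachia, a nutritional endosymbiont of bed bugs, suppresses RNA-virus
replication in several other insect taxa.  A first-pass test of whether the
same holds in bed bugs is to regress, across samples, the percentage of reads
mapping to the detected virus genomes (response y) on the percentage mapping
to the Wolbachia genome (predictor x): ordinary least squares with the Pearson
correlation r and its two-sided p-value from t = r*sqrt(n-2)/sqrt(1-r^2) on
n-2 degrees of freedom (identical to the regression F test for a single
predictor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "RegressionResult",
    "AbundanceRegression",
    "correlate",
    "validate_abundance_table",
    "format_result",
]

COLUMNS = ("sample", "pct_virus", "pct_wolbachia")


@dataclass(frozen=True)
class RegressionResult:
    slope: float      # % virus reads per % Wolbachia reads
    intercept: float  # % virus reads at x = 0
    r: float          # Pearson correlation
    p: float          # two-sided p-value
    n: int


def validate_abundance_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a per-sample read-percentage table (sample, pct_virus, pct_wolbachia)."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table missing columns: {missing}")
    if table["sample"].duplicated().any():
        raise ValueError("duplicate sample IDs in abundance table")
    vals = table[["pct_virus", "pct_wolbachia"]].to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError("read percentages must be finite and >= 0")
    return table


class AbundanceRegression(BaseEstimator, RegressorMixin):
    """Simple linear regression of virus read % on Wolbachia read %.

    Fit with ``fit(x, y)`` where x is 1-d or (n, 1).  Fitted attributes:
    ``slope_``, ``intercept_``, ``rvalue_``, ``pvalue_``, ``n_``.
    """

    def fit(self, X, y):
        x = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if x.shape != y.shape:
            raise ValueError("x and y must have the same length")
        if x.size < 3:
            raise ValueError("degenerate regression design: need n >= 3")
        if np.ptp(x) == 0:
            raise ValueError("zero variance in predictor")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.intercept_ = float(res.intercept)
        self.rvalue_ = float(res.rvalue)
        self.pvalue_ = float(res.pvalue)
        self.n_ = int(x.size)
        return self

    def predict(self, X):
        x = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.slope_ * x

    def result_(self) -> RegressionResult:
        return RegressionResult(self.slope_, self.intercept_, self.rvalue_,
                                self.pvalue_, self.n_)


def correlate(table: pd.DataFrame, drop_samples: tuple[str, ...] = ()) -> RegressionResult:
    """OLS of pct_virus on pct_wolbachia; thin wrapper over AbundanceRegression.

    ``drop_samples`` removes named samples before fitting (e.g. a suspected
    outlier); the default keeps every row.
    """
    table = validate_abundance_table(table)
    if drop_samples:
        unknown = set(drop_samples) - set(table["sample"])
        if unknown:
            raise ValueError(f"unknown samples to drop: {sorted(unknown)}")
        table = table[~table["sample"].isin(drop_samples)]
    est = AbundanceRegression().fit(table["pct_wolbachia"], table["pct_virus"])
    return est.result_()


def format_result(res: RegressionResult) -> dict:
    """Reporting-layer rounding: slope 3 decimals, intercept/r 2, p 2."""
    return {
        "slope": round(res.slope, 3),
        "intercept": round(res.intercept, 2),
        "r": round(res.r, 2),
        "p": round(res.p, 2),
        "n": res.n,
    }
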