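"""Gene abundance vs phosphate concentration regressions.

Metagenomic surveys pair per-sample relative gene abundances with measured
phosphate concentrations (uM).  Two ordinary-least-squares forms are
supported per gene: *linear* (abundance ~ phosphate) and *log-linear*
(log(abundance + pseudocount) ~ phosphate, the usual reading of an
"exponential" fit), both against the raw phosphate concentration, with a
two-sided t-test on the slope.  Extrapolation to hypothetical phosphate
levels and a threshold median drop-off ratio complete the picture of how a
gene partitions between phosphate-poor and phosphate-replete waters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "AbundanceTable",
    "RegressionResult",
    "fit_abundance_model",
    "predict_abundance",
    "threshold_ratio",
]


@dataclass
class AbundanceTable:
    """Samples x (phosphate, per-gene relative abundance).

    ``data`` has a ``sample`` column, a ``phosphate_uM`` column, and one
    non-negative abundance column per gene.  Samples with missing phosphate
    are dropped (counted in ``n_dropped``) — fits use complete cases only.
    """

    data: pd.DataFrame
    n_dropped: int = 0

    def __post_init__(self):
        df = self.data
        for col in ("sample", "phosphate_uM"):
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        keep = df["phosphate_uM"].notna()
        self.n_dropped = int((~keep).sum())
        df = df.loc[keep].reset_index(drop=True)
        if len(df) < 3:
            raise ValueError("need at least 3 samples with phosphate measurements")
        if (df["phosphate_uM"] < 0).any():
            raise ValueError("negative phosphate concentration")
        for g in self.genes(df):
            if (df[g].dropna() < 0).any():
                raise ValueError(f"negative abundance for gene {g!r}")
        self.data = df

    @staticmethod
    def genes(df=None) -> list:
        cols = df.columns if df is not None else None
        return [c for c in cols if c not in ("sample", "phosphate_uM")]

    @property
    def gene_ids(self) -> list:
        return self.genes(self.data)

    @classmethod
    def from_tsv(cls, source) -> "AbundanceTable":
        return cls(pd.read_csv(source, sep="\t"))

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class RegressionResult:
    gene: str
    form: str  # linear | log-linear
    slope: float
    intercept: float
    p_value: float
    df_resid: int
    n: int
    pseudocount: float = 0.0
    slope_se: float = float("nan")


def _default_pseudocount(y: np.ndarray) -> float:
    nz = y[y > 0]
    if nz.size == 0:
        raise ValueError(
            "all abundances are zero: the log-linear form needs a positive "
            "pseudocount (supply one explicitly)"
        )
    return float(nz.min()) / 2.0


def fit_abundance_model(
    table: AbundanceTable,
    gene: str,
    form: str = "linear",
    pseudocount: float | None = None,
) -> RegressionResult:
    """OLS fit of (transformed) abundance on raw phosphate concentration.

    ``form='log-linear'`` regresses ``log(abundance + pseudocount)`` on
    phosphate (default pseudocount: half the smallest non-zero abundance).
    Reports the two-sided slope p-value and ``df = n - 2``.
    """
    if gene not in table.gene_ids:
        raise ValueError(f"unknown gene {gene!r}")
    if form not in ("linear", "log-linear"):
        raise ValueError(f"form must be 'linear' or 'log-linear', got {form!r}")
    sub = table.data[["phosphate_uM", gene]].dropna()
    x = sub["phosphate_uM"].to_numpy(float)
    y = sub[gene].to_numpy(float)
    if len(x) < 3:
        raise ValueError(f"fewer than 3 complete samples for gene {gene!r}")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in phosphate concentration")
    if np.ptp(y) == 0 and form == "linear":
        # constant response: exactly flat line, no evidence against slope 0
        return RegressionResult(
            gene=gene, form=form, slope=0.0, intercept=float(y[0]),
            p_value=1.0, df_resid=len(x) - 2, n=len(x), slope_se=0.0,
        )
    pc = 0.0
    if form == "log-linear":
        pc = _default_pseudocount(y) if pseudocount is None else float(pseudocount)
        if np.any(y + pc <= 0):
            raise ValueError("non-positive abundance + pseudocount under log form")
        y = np.log(y + pc)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = model.params
    p = float(model.pvalues[1])
    if math.isnan(p):  # zero residual variance with zero slope: no evidence
        p = 1.0
    return RegressionResult(
        gene=gene,
        form=form,
        slope=float(slope),
        intercept=float(intercept),
        p_value=p,
        df_resid=int(model.df_resid),
        n=len(x),
        pseudocount=pc,
        slope_se=float(model.bse[1]),
    )


def predict_abundance(fit: RegressionResult, phosphate: float) -> float:
    """Predicted abundance at a (possibly hypothetical) phosphate level.

    Log-linear predictions invert the transform and are floored at zero, so
    extrapolations far beyond the observed range degrade gracefully.
    """
    if phosphate < 0:
        raise ValueError("negative phosphate concentration")
    eta = fit.intercept + fit.slope * phosphate
    if fit.form == "linear":
        return float(eta)
    return float(max(math.exp(eta) - fit.pseudocount, 0.0))


def threshold_ratio(table: AbundanceTable, gene: str, threshold: float) -> float:
    """Median abundance below vs at-or-above a phosphate threshold.

    A ratio of 4 means the gene's median abundance is four times higher in
    samples with phosphate under the threshold.  Returns ``inf`` when the
    high-phosphate median is zero.
    """
    if gene not in table.gene_ids:
        raise ValueError(f"unknown gene {gene!r}")
    sub = table.data[["phosphate_uM", gene]].dropna()
    below = sub.loc[sub["phosphate_uM"] < threshold, gene]
    above = sub.loc[sub["phosphate_uM"] >= threshold, gene]
    if below.empty or above.empty:
        raise ValueError(
            f"threshold {threshold} uM leaves an empty side "
            f"({len(below)} below, {len(above)} at/above)"
        )
    denom = float(above.median())
    num = float(below.median())
    if denom == 0:
        return math.inf
    return num / denom
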