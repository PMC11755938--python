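"""Residual Variation Intolerance Score (RVIS).

For each gene, count X = total protein-coding variants (missense + LoF +
synonymous) and Y = common functional variants (missense + LoF with
allele frequency >= a MAF threshold).  Regress Y on X by ordinary least
squares across all genes and take the studentized residuals as the
constraint score: a gene with fewer common functional variants than its
total mutational burden predicts (score < 0) is constrained / mutation
intolerant.

Scores are externally studentized by default (residual scaled by the
leave-one-out error estimate and leverage) and then re-centered so the
fitted scores have mean exactly 0.  Genes with extreme positive scores
(default > 11, matching the removal of hypervariable outliers such as
MUC16) can be excluded and the model refit once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .qc import CODING_EFFECTS, FUNCTIONAL_EFFECTS, VariantRecord

#: Default common/rare MAF split for the score numerator (0.1%), the
#: convention of the original human RVIS.
DEFAULT_MAF_THRESHOLD = 1e-3

#: Default one-sided outlier cutoff on the score.
DEFAULT_OUTLIER_THRESHOLD = 11.0


@dataclass(frozen=True)
class GeneCounts:
    """Per-gene variant tallies feeding the regression."""

    gene: str
    x_total_coding: int
    y_common_functional: int

    def __post_init__(self):
        if self.y_common_functional > self.x_total_coding:
            raise ValueError(
                f"{self.gene}: y={self.y_common_functional} exceeds "
                f"x={self.x_total_coding}"
            )
        if self.x_total_coding < 0:
            raise ValueError(f"{self.gene}: negative count")


@dataclass
class RVISTable:
    """Fitted constraint scores plus regression metadata.

    ``table`` has one row per gene with columns ``gene``, ``x``, ``y``,
    ``raw_residual``, ``studentized`` (leave-one-out studentized
    residual), ``rvis`` (studentized re-centered to mean 0) and
    ``excluded_outlier``.  Excluded genes carry NaN scores.
    """

    table: pd.DataFrame
    intercept: float
    slope: float
    residual_standard_error: float
    n_genes_fit: int
    degenerate_variance: bool = False
    residual_flavor: str = "external"

    def scores(self, include_excluded: bool = False) -> pd.Series:
        """RVIS per gene (index = gene label), fitted genes only by default."""
        t = self.table
        if not include_excluded:
            t = t[~t["excluded_outlier"]]
        return t.set_index("gene")["rvis"]


def count_gene_variants(
    records: Iterable[VariantRecord],
    gene_models: pd.DataFrame,
    maf_threshold: float = DEFAULT_MAF_THRESHOLD,
) -> list[GeneCounts]:
    """Tally per-gene X (coding) and Y (common functional) counts.

    Every gene in ``gene_models`` (column ``gene``) appears, zero counts
    allowed.  A variant contributes to its annotated gene only; variants
    annotated to genes absent from the models trigger a warning but are
    still counted under that gene.  Noncoding and un-annotated variants
    contribute to neither X nor Y.
    """
    known = list(dict.fromkeys(gene_models["gene"].astype(str)))
    known_set = set(known)
    x: dict[str, int] = {g: 0 for g in known}
    y: dict[str, int] = {g: 0 for g in known}
    unknown: set[str] = set()
    for rec in records:
        if rec.gene is None or rec.effect is None:
            continue
        if rec.effect not in CODING_EFFECTS:
            continue
        g = rec.gene
        if g not in known_set and g not in unknown:
            unknown.add(g)
            warnings.warn(
                f"variant gene {g!r} absent from gene models; counted anyway",
                stacklevel=2,
            )
        x[g] = x.get(g, 0) + 1
        if (
            rec.effect in FUNCTIONAL_EFFECTS
            and rec.allele_freq is not None
            and rec.allele_freq >= maf_threshold
        ):
            y[g] = y.get(g, 0) + 1
    order = known + sorted(unknown)
    return [GeneCounts(g, x[g], y[g]) for g in order]


def _studentized(
    resid: np.ndarray, mse: float, leverage: np.ndarray, flavor: str, dof: int
) -> np.ndarray:
    if flavor == "internal":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = resid / np.sqrt(mse * (1.0 - leverage))
        out[np.isnan(out)] = 0.0
        return out
    # external: variance re-estimated with each point left out
    with np.errstate(divide="ignore", invalid="ignore"):
        s2_loo = (mse * dof - resid**2 / (1.0 - leverage)) / (dof - 1)
        # a leave-one-out fit that is numerically exact leaves zero
        # residual variance: the point is infinitely surprising
        s2_loo[s2_loo < 1e-10 * mse] = 0.0
        out = resid / np.sqrt(s2_loo * (1.0 - leverage))
    out[np.isnan(out)] = 0.0  # 0/0: zero residual on a zero-variance fit
    return out


def compute_rvis(
    counts: Iterable[GeneCounts],
    residual_flavor: str = "external",
) -> RVISTable:
    """OLS of Y on X with intercept; studentized residuals as scores.

    Output is order-invariant (rows sorted by gene label).  If the fit is
    exact (zero residual variance) all scores are 0 and the table is
    flagged ``degenerate_variance``.  Requires >= 3 genes and variation
    in X.
    """
    counts = list(counts)
    if len(counts) < 3:
        raise ValueError(f"need >= 3 genes to fit RVIS, got {len(counts)}")
    if residual_flavor not in ("external", "internal"):
        raise ValueError(f"unknown residual flavor {residual_flavor!r}")
    df = pd.DataFrame(
        {
            "gene": [c.gene for c in counts],
            "x": [c.x_total_coding for c in counts],
            "y": [c.y_common_functional for c in counts],
        }
    ).sort_values("gene", kind="mergesort", ignore_index=True)
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].iloc[0]
        raise ValueError(f"duplicate gene in counts: {dup!r}")
    xv = df["x"].to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError("all X counts identical: regression is degenerate")
    fitted = _fit_scores(df, residual_flavor)
    return fitted


def _fit_scores(df: pd.DataFrame, residual_flavor: str) -> RVISTable:
    """Fit on rows not flagged excluded; excluded rows get NaN scores."""
    if "excluded_outlier" not in df:
        df = df.assign(excluded_outlier=False)
    fit_mask = ~df["excluded_outlier"].to_numpy()
    sub = df[fit_mask]
    X = sm.add_constant(sub["x"].to_numpy(float))
    yv = sub["y"].to_numpy(float)
    model = sm.OLS(yv, X).fit()
    resid = model.resid
    n, p = X.shape
    dof = n - p
    mse = float(model.mse_resid) if dof > 0 else 0.0
    leverage = (X * np.linalg.solve(X.T @ X, X.T).T).sum(axis=1)
    degenerate = dof <= 1 or mse <= 1e-12 * max(1.0, float(np.mean(yv**2)))
    if degenerate:
        stud = np.zeros(n)
    else:
        stud = _studentized(resid, mse, leverage, residual_flavor, dof)
    # center on the finite scores; an infinite score (exact LOO fit
    # elsewhere) stays infinite and is left for outlier screening
    finite = np.isfinite(stud)
    rvis = stud - (stud[finite].mean() if finite.any() else 0.0)
    out = df.copy()
    out["raw_residual"] = np.nan
    out["studentized"] = np.nan
    out["rvis"] = np.nan
    out.loc[fit_mask, "raw_residual"] = resid
    out.loc[fit_mask, "studentized"] = stud
    out.loc[fit_mask, "rvis"] = rvis
    return RVISTable(
        table=out,
        intercept=float(model.params[0]),
        slope=float(model.params[1]),
        residual_standard_error=float(np.sqrt(mse)),
        n_genes_fit=int(n),
        degenerate_variance=bool(degenerate),
        residual_flavor=residual_flavor,
    )


def remove_outliers(
    result: RVISTable, threshold: float = DEFAULT_OUTLIER_THRESHOLD
) -> RVISTable:
    """Exclude genes with score > threshold (one-sided) and refit once.

    Mirrors the removal of hypervariable genes scoring above +11; very
    negative (constrained) genes are never excluded.  A single pass: the
    refit scores are not re-screened.
    """
    if threshold <= 0:
        raise ValueError("outlier threshold must be positive")
    df = result.table.copy()
    flag = df["rvis"] > threshold
    if not flag.any():
        return result
    df["excluded_outlier"] = df["excluded_outlier"] | flag
    return _fit_scores(df, result.residual_flavor)


def write_rvis_table(result: RVISTable, path) -> None:
    result.table.to_csv(path, sep="\t", index=False)


def read_rvis_scores(path) -> pd.Series:
    """Read gene -> rvis scores from a written table (excluded dropped)."""
    df = pd.read_csv(path, sep="\t")
    df = df[~df["excluded_outlier"].astype(bool)]
    return df.set_index("gene")["rvis"]
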