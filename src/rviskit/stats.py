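"""Group-difference and association statistics for constraint scores.

Disease gene sets (ASD, ID, epilepsy, schizophrenia, essentialome) are
compared against the background genome on RVIS via a Welch unequal-
variance t-test and a univariate logistic regression of set membership
on the score, reported as an odds ratio per 1-unit RVIS: constrained
sets (lower scores) yield OR < 1.  Cross-species agreement of two score
tables is a Pearson correlation over the inner gene join with a
Fisher-z confidence interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm


@dataclass(frozen=True)
class GeneSet:
    """Named gene membership list."""

    name: str
    members: frozenset

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    @classmethod
    def from_file(cls, path, name: Optional[str] = None) -> "GeneSet":
        """One gene symbol per line; blank lines and '#' comments ignored."""
        import pathlib

        p = pathlib.Path(path)
        genes = [
            ln.strip()
            for ln in p.read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls(name or p.stem, frozenset(genes))


@dataclass
class GroupTestResult:
    """Welch t-test plus logistic odds ratio for one set vs background."""

    set_name: str
    n_set: int
    mean_set: float
    sd_set: float
    n_background: int
    mean_background: float
    sd_background: float
    t_statistic: float
    df: float
    p_value: float
    beta: float
    se_beta: float
    odds_ratio: float
    or_p_value: float


def welch_t_test(scores_set, scores_background) -> tuple[float, float, float]:
    """Two-sided Welch t-test; returns (t, Welch-Satterthwaite df, p)."""
    a = np.asarray(scores_set, float)
    b = np.asarray(scores_background, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values for a t-test")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


class PerfectSeparationError(RuntimeError):
    """Logistic MLE does not exist: the score separates the classes."""


def logistic_association(
    membership, scores
) -> tuple[float, float, float, float]:
    """ML logistic fit of membership (0/1) on score; returns
    (beta, se, odds_ratio, p) with OR = exp(beta) per 1-unit score."""
    y = np.asarray(membership, float)
    x = np.asarray(scores, float)
    if y.shape != x.shape:
        raise ValueError("membership and scores must align")
    classes = np.unique(y)
    if not np.array_equal(classes, [0.0, 1.0]):
        if len(classes) == 1:
            raise ValueError("membership has a single class; cannot fit")
        raise ValueError("membership must be binary 0/1")
    # univariate complete separation: the classes occupy disjoint score
    # ranges, so the MLE diverges
    if x[y == 1].min() > x[y == 0].max() or x[y == 1].max() < x[y == 0].min():
        raise PerfectSeparationError(
            "the score perfectly separates members from non-members; "
            "the logistic MLE does not exist"
        )
    X = sm.add_constant(x)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0)
        except Exception as exc:
            raise PerfectSeparationError(
                f"logistic fit failed (separation or no convergence): {exc}"
            ) from exc
    if not np.all(np.isfinite(fit.bse)):
        raise PerfectSeparationError(
            "logistic fit degenerate: infinite standard errors "
            "(quasi-separation)"
        )
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    p = float(fit.pvalues[1])
    return beta, se, math.exp(beta), p


def cross_species_correlation(
    scores_a: pd.Series, scores_b: pd.Series
) -> tuple[float, tuple[float, float], float, int]:
    """Pearson correlation of two gene-indexed score tables.

    Joins on gene label (inner join); genes missing from either table
    are excluded.  Returns (r, (ci_lo, ci_hi), p, n_joined) with a
    Fisher-z 95% interval.
    """
    joined = pd.concat(
        {"a": scores_a, "b": scores_b}, axis=1, join="inner"
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValueError(f"only {n} shared genes; need >= 3")
    r, p = sps.pearsonr(joined["a"], joined["b"])
    r = float(r)
    if abs(r) >= 1.0:
        ci = (r, r)
    elif n <= 3:
        ci = (-1.0, 1.0)  # Fisher z needs n > 3; CI is vacuous
    else:
        z = math.atanh(r)
        hw = sps.norm.ppf(0.975) / math.sqrt(n - 3)
        ci = (math.tanh(z - hw), math.tanh(z + hw))
    return r, ci, float(p), n


def gene_set_constraint_test(
    scores: pd.Series, gene_set: GeneSet, normalize_symbols: bool = False
) -> GroupTestResult:
    """Full set-vs-background comparison on a gene-indexed score table.

    Background = all scored genes not in the set.  Symbol matching is
    case-sensitive exact match unless ``normalize_symbols`` uppercases
    both sides.
    """
    idx = scores.index.astype(str)
    members = set(gene_set.members)
    if normalize_symbols:
        idx = idx.str.upper()
        members = {m.upper() for m in members}
    mask = idx.isin(members)
    in_set = scores.to_numpy(float)[mask]
    background = scores.to_numpy(float)[~mask]
    if len(in_set) < 2 or len(background) < 2:
        raise ValueError(
            f"set {gene_set.name!r}: need >= 2 scored genes in set and "
            f"background (got {len(in_set)}, {len(background)})"
        )
    t, df, p = welch_t_test(in_set, background)
    beta, se, orr, orp = logistic_association(
        mask.astype(int), scores.to_numpy(float)
    )
    return GroupTestResult(
        set_name=gene_set.name,
        n_set=len(in_set),
        mean_set=float(np.mean(in_set)),
        sd_set=float(np.std(in_set, ddof=1)),
        n_background=len(background),
        mean_background=float(np.mean(background)),
        sd_background=float(np.std(background, ddof=1)),
        t_statistic=t,
        df=df,
        p_value=p,
        beta=beta,
        se_beta=se,
        odds_ratio=orr,
        or_p_value=orp,
    )


def results_table(results: Iterable[GroupTestResult]) -> pd.DataFrame:
    """One row per gene set, suitable for TSV export."""
    return pd.DataFrame([vars(r) for r in results])
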