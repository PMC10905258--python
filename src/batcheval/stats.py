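"""Statistical evaluation battery for multi-batch expression data.

Four complementary tests are applied to per-observation total counts (the
library-size proxy most sensitive to platform/depth differences):

* one-way ANOVA with an F reference value at the configured alpha,
* the Kruskal-Wallis H rank test (robust to the variance heterogeneity that
  cross-platform data rarely satisfies),
* pairwise two-sample Kolmogorov-Smirnov tests of the total-count
  distributions,
* a contingency-table association between an experimental condition and the
  batch label (Cramér's V and the contingency coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class AnovaResult:
    n_batch: int
    n_sample: int
    F: float
    p_value: float
    F_ref: float
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {"n_batch": self.n_batch, "n_sample": self.n_sample, "F": self.F,
                "p_value": self.p_value, "F_ref": self.F_ref, "alpha": self.alpha}


@dataclass
class KWResult:
    H: float
    p_value: float
    N: int
    k: int
    n_i: dict[str, int]
    rank_sums: dict[str, float]

    def to_dict(self) -> dict:
        return {"H": self.H, "p_value": self.p_value, "N": self.N, "k": self.k,
                "n_i": self.n_i, "rank_sums": self.rank_sums}


@dataclass
class KSResult:
    pair: tuple[str, str]
    n_sample: int
    stat: float
    p_value: float

    def to_dict(self) -> dict:
        return {"pair": list(self.pair), "n_sample": self.n_sample,
                "stat": self.stat, "p_value": self.p_value}


@dataclass
class AssociationResult:
    table: pd.DataFrame
    chi2: float
    p_value: float
    pearson_c: float
    cramers_v: float

    def to_dict(self) -> dict:
        return {"chi2": self.chi2, "p_value": self.p_value,
                "pearson_c": self.pearson_c, "cramers_v": self.cramers_v,
                "table": self.table.to_dict()}


@dataclass
class StatTestBundle:
    """Everything the report's statistical-evaluation section shows."""

    anova: AnovaResult
    kruskal: KWResult
    ks_pairs: list[KSResult]
    association: AssociationResult | None = None
    condition_source: str = "user"

    def to_dict(self) -> dict:
        return {
            "anova": self.anova.to_dict(),
            "kruskal": self.kruskal.to_dict(),
            "ks_pairs": [r.to_dict() for r in self.ks_pairs],
            "association": None if self.association is None else self.association.to_dict(),
            "condition_source": self.condition_source,
        }


def f_critical(df1: int, df2: int, quantile: float = 0.95) -> float:
    """Quantile of the F distribution (the report's "F ref" column)."""
    if df1 < 1 or df2 < 1:
        raise ValueError(f"invalid degrees of freedom ({df1}, {df2})")
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    return float(sps.f.ppf(quantile, df1, df2))


def anova_total_counts(totals: np.ndarray, batch: np.ndarray,
                       alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA of per-observation totals grouped by batch."""
    totals = np.asarray(totals, dtype=float)
    batch = np.asarray(batch).astype(str)
    groups = [totals[batch == b] for b in sorted(set(batch))]
    if len(groups) < 2:
        raise ValueError("ANOVA requires at least two batches")
    if any(len(g) < 2 for g in groups):
        raise ValueError("every batch needs at least two observations")
    k, n = len(groups), len(totals)
    F, p = sps.f_oneway(*groups)
    return AnovaResult(n_batch=k, n_sample=n, F=float(F), p_value=float(p),
                       F_ref=f_critical(k - 1, n - k, 1 - alpha), alpha=alpha)


def kruskal_wallis_h(values: np.ndarray, groups: np.ndarray) -> KWResult:
    """Kruskal-Wallis H with average ranks for ties and the standard
    tie-correction divisor 1 - sum(t^3 - t)/(N^3 - N).

    H = 12/(N(N+1)) * sum_i R_i^2/n_i - 3(N+1), chi-square p-value on k-1 df.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups).astype(str)
    names = sorted(set(groups))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    n = len(values)
    if n < 3:
        raise ValueError("need at least three observations")
    ranks = sps.rankdata(values)  # average ranks for ties
    n_i: dict[str, int] = {}
    rank_sums: dict[str, float] = {}
    h = 0.0
    for name in names:
        mask = groups == name
        n_i[name] = int(mask.sum())
        rank_sums[name] = float(ranks[mask].sum())
        h += rank_sums[name] ** 2 / n_i[name]
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, counts = np.unique(values, return_counts=True)
    correction = 1.0 - ((counts ** 3 - counts).sum()) / (n ** 3 - n)
    if correction == 0.0:  # all values identical
        return KWResult(H=0.0, p_value=1.0, N=n, k=len(names), n_i=n_i,
                        rank_sums=rank_sums)
    h /= correction
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, len(names) - 1))
    return KWResult(H=float(h), p_value=p, N=n, k=len(names), n_i=n_i,
                    rank_sums=rank_sums)


def ks_pairwise(totals: np.ndarray, batch: np.ndarray) -> list[KSResult]:
    """Two-sample Kolmogorov-Smirnov test for every unordered batch pair.

    stat = sup_x |F_a(x) - F_b(x)| on per-observation totals; asymptotic
    two-sided p-value; n_sample is the pooled size of the pair.
    """
    totals = np.asarray(totals, dtype=float)
    batch = np.asarray(batch).astype(str)
    names = sorted(set(batch))
    if len(names) < 2:
        raise ValueError("need at least two batches")
    results = []
    for a, b in combinations(names, 2):
        xa, xb = totals[batch == a], totals[batch == b]
        res = sps.ks_2samp(xa, xb, method="asymp")
        results.append(KSResult(pair=(a, b), n_sample=len(xa) + len(xb),
                                stat=float(res.statistic), p_value=float(res.pvalue)))
    return results


def contingency_association(condition: np.ndarray,
                            batch: np.ndarray) -> AssociationResult:
    """Association between an experimental condition and batch membership.

    Pearson chi-square (no continuity correction) on the cross-tabulation;
    Cramér's V = sqrt(chi2 / (N (k-1))) with k the smaller table dimension,
    and the contingency coefficient C = sqrt(chi2 / (chi2 + N)).
    """
    condition = np.asarray(condition).astype(str)
    batch = np.asarray(batch).astype(str)
    if len(condition) != len(batch):
        raise ValueError("condition and batch must have equal length")
    table = pd.crosstab(pd.Series(condition, name="condition"),
                        pd.Series(batch, name="batch"))
    if min(table.shape) < 2:
        raise ValueError(
            "association undefined: need at least two levels in both condition "
            f"and batch (table shape {table.shape})"
        )
    chi2, p, _, _ = sps.chi2_contingency(table.to_numpy(), correction=False)
    n = int(table.to_numpy().sum())
    k = min(table.shape)
    v = float(np.sqrt(chi2 / (n * (k - 1))))
    c = float(np.sqrt(chi2 / (chi2 + n)))
    return AssociationResult(table=table, chi2=float(chi2), p_value=float(p),
                             pearson_c=c, cramers_v=v)


def quartile_condition(totals: np.ndarray) -> np.ndarray:
    """Fallback proxy condition when the user supplies none: total-count
    quartile membership (documented in the report as such)."""
    totals = np.asarray(totals, dtype=float)
    return pd.qcut(pd.Series(totals).rank(method="first"), 4,
                   labels=["Q1", "Q2", "Q3", "Q4"]).astype(str).to_numpy()


def run_stat_battery(dataset, condition: np.ndarray | None = None,
                     alpha: float = 0.05) -> StatTestBundle:
    """Run the full battery on a merged dataset."""
    from .preprocess import per_cell_total_counts

    totals = per_cell_total_counts(dataset)
    batch = np.asarray(dataset.batch).astype(str)
    source = "user"
    if condition is None:
        if dataset.cell_type is not None:
            condition = np.asarray(dataset.cell_type).astype(str)
            source = "cell_type"
        else:
            condition = quartile_condition(totals)
            source = "total-count quartiles"
    assoc = None
    try:
        assoc = contingency_association(condition, batch)
    except ValueError:
        source += " (association skipped: single-level table)"
    return StatTestBundle(
        anova=anova_total_counts(totals, batch, alpha=alpha),
        kruskal=kruskal_wallis_h(totals, batch),
        ks_pairs=ks_pairwise(totals, batch),
        association=assoc,
        condition_source=source,
    )
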