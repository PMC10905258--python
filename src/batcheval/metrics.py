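"""Neighborhood-mixing and biology-preservation metrics and the composite score.

Three families of metrics are computed on a low-dimensional embedding of the
merged dataset:

* **k-BET**: a Pearson chi-square test per neighborhood comparing the local
  batch composition against the global batch frequencies,
  kappa_j = sum_i (n_ji - f_i k)^2 / (f_i k) ~ chi2 on l-1 df; the accept
  rate is the fraction of tested neighborhoods whose p-value exceeds alpha.
* **LISI**: the inverse Simpson diversity 1 / sum p^2 of labels in each
  observation's neighborhood, min-max normalized across observations and
  averaged; computed with batch labels (iLISI, higher = better mixing) and
  with cell/domain-type labels (cLISI, lower = better preservation), combined
  by F1 = 2 (1-cLISI) iLISI / ((1-cLISI) + iLISI).
* **Silhouette**: mean silhouette coefficient with batch labels (iSS) and
  type labels (cSS), combined by F1 (see :func:`f1_ss` for the two modes).

The composite BatchEval score is the unweighted mean of F1_LISI, F1_SS and
the domain classifier's accept rate (1 - DomainAcc); all three lie in [0, 1]
and higher means a better-mixed, biology-preserving integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .preprocess import NeighborGraph


@dataclass
class KbetResult:
    chi_mean: float
    p_summary: float          # mean p-value over tested neighborhoods
    accept_rate: float        # fraction of neighborhoods with p > alpha
    reject_rate: float
    k: int
    l: int                    # number of batches with non-zero frequency
    f: dict[str, float]       # global batch frequencies
    n_tested: int
    alpha: float = 0.05

    def to_dict(self) -> dict:
        return {"chi_mean": self.chi_mean, "p_summary": self.p_summary,
                "accept_rate": self.accept_rate, "reject_rate": self.reject_rate,
                "k": self.k, "l": self.l, "f": self.f,
                "n_tested": self.n_tested, "alpha": self.alpha}


@dataclass
class LisiResult:
    iLISI: float
    cLISI: float
    f1: float | None = None
    raw_batch_mean: float | None = None
    raw_type_mean: float | None = None

    def to_dict(self) -> dict:
        return {"iLISI": self.iLISI, "cLISI": self.cLISI, "f1": self.f1,
                "raw_batch_mean": self.raw_batch_mean,
                "raw_type_mean": self.raw_type_mean}


@dataclass
class SilhouetteResult:
    iSS: float
    cSS: float
    f1: float | None = None
    mode: str = "table_consistent"

    def to_dict(self) -> dict:
        return {"iSS": self.iSS, "cSS": self.cSS, "f1": self.f1, "mode": self.mode}


@dataclass
class SummaryScore:
    f1_lisi: float
    f1_ss: float
    accept_rate: float
    batcheval: float

    def to_dict(self) -> dict:
        return {"f1_lisi": self.f1_lisi, "f1_ss": self.f1_ss,
                "accept_rate": self.accept_rate, "batcheval": self.batcheval}


@dataclass
class MetricBundle:
    """All per-variant metric rows of the report (classifier + k-BET + LISI + SS)."""

    classifier: "object"
    kbet: KbetResult
    lisi: LisiResult
    silhouette: SilhouetteResult
    summary: SummaryScore
    types_source: str = "cell_type"

    def to_dict(self) -> dict:
        return {"classifier": self.classifier.to_dict(),
                "kbet": self.kbet.to_dict(), "lisi": self.lisi.to_dict(),
                "silhouette": self.silhouette.to_dict(),
                "summary": self.summary.to_dict(),
                "types_source": self.types_source}


# -- k-BET ------------------------------------------------------------------

def kbet(graph: NeighborGraph, batch: np.ndarray, alpha: float = 0.05,
         sample_fraction: float = 0.1, seed: int = 0,
         min_sample: int = 100) -> KbetResult:
    """k-BET chi-square mixing test over sampled neighborhoods.

    For each sampled observation the batch counts among its k neighbors are
    compared with the expected counts f_i * k under perfect mixing; the
    statistic follows chi-square with l-1 degrees of freedom (batches with
    zero global frequency are dropped from the df).
    """
    batch = np.asarray(batch).astype(str)
    n = graph.n_obs
    if len(batch) != n:
        raise ValueError("batch labels must match graph size")
    names = sorted(set(batch))
    if len(names) < 2:
        raise ValueError("k-BET needs at least two batches")
    if graph.k < 10:
        warnings.warn(f"k={graph.k} < 10: chi-square approximation is weak")
    codes = np.searchsorted(names, batch)
    freqs = np.bincount(codes, minlength=len(names)) / n
    keep = freqs > 0
    l = int(keep.sum())

    rng = np.random.default_rng(seed)
    n_test = min(n, max(min_sample, int(np.ceil(sample_fraction * n))))
    tested = rng.choice(n, size=n_test, replace=False) if n_test < n else np.arange(n)

    neigh_codes = codes[graph.indices[tested]]            # (n_test, k)
    counts = np.zeros((n_test, len(names)))
    for i in range(len(names)):
        counts[:, i] = (neigh_codes == i).sum(axis=1)
    expected = freqs * graph.k
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (counts - expected) ** 2 / expected
    kappa = terms[:, keep].sum(axis=1)
    p = sps.chi2.sf(kappa, l - 1)
    accept = float(np.mean(p > alpha))
    return KbetResult(chi_mean=float(kappa.mean()), p_summary=float(p.mean()),
                      accept_rate=accept, reject_rate=1.0 - accept,
                      k=graph.k, l=l,
                      f=dict(zip(names, freqs.tolist())),
                      n_tested=n_test, alpha=alpha)


# -- LISI -------------------------------------------------------------------

def inverse_simpson(graph: NeighborGraph, labels: np.ndarray) -> np.ndarray:
    """Per-observation inverse Simpson index 1 / sum_l p(l)^2 over the
    neighborhood (the observation itself plus its k neighbors).

    Values lie in [1, #labels]: 1 when the neighborhood is pure, #labels when
    labels are uniformly represented.
    """
    labels = np.asarray(labels).astype(str)
    names, codes = np.unique(labels, return_inverse=True)
    hood = np.concatenate([np.arange(graph.n_obs)[:, None], graph.indices], axis=1)
    hood_codes = codes[hood]                              # (N, k+1)
    size = hood.shape[1]
    sumsq = np.zeros(graph.n_obs)
    for i in range(len(names)):
        p = (hood_codes == i).sum(axis=1) / size
        sumsq += p ** 2
    return 1.0 / sumsq


def _minmax_unit(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def lisi_scores(graph: NeighborGraph, batch: np.ndarray,
                types: np.ndarray) -> LisiResult:
    """iLISI (batch labels) and cLISI (type labels), each the mean of the
    min-max-normalized per-observation inverse Simpson vector."""
    out = {}
    raw_means = {}
    for key, labels in (("iLISI", batch), ("cLISI", types)):
        labels = np.asarray(labels).astype(str)
        if len(set(labels)) < 2:
            warnings.warn(f"{key}: single-level label set, score defined as 0")
            out[key] = 0.0
            raw_means[key] = 1.0
            continue
        raw = inverse_simpson(graph, labels)
        raw_means[key] = float(raw.mean())
        out[key] = float(_minmax_unit(raw).mean())
    return LisiResult(iLISI=out["iLISI"], cLISI=out["cLISI"],
                      raw_batch_mean=raw_means["iLISI"],
                      raw_type_mean=raw_means["cLISI"])


def f1_lisi(iLISI: float, cLISI: float) -> float:
    """F1 combiner 2 (1-cLISI) iLISI / ((1-cLISI) + iLISI); 0 on a zero
    denominator."""
    num = 2.0 * (1.0 - cLISI) * iLISI
    den = (1.0 - cLISI) + iLISI
    return 0.0 if den == 0.0 else float(num / den)


# -- silhouette -------------------------------------------------------------

def silhouette_scores(embedding: np.ndarray, batch: np.ndarray,
                      types: np.ndarray, subsample: int = 10_000,
                      seed: int = 0) -> SilhouetteResult:
    """Mean silhouette coefficient with batch labels (iSS) and type labels
    (cSS), Euclidean, full pairwise; subsampled (seeded) above the cap to
    keep the O(N^2) distance matrix desk-scale."""
    from sklearn.metrics import silhouette_score

    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if n < 3:
        raise ValueError("silhouette needs at least three observations")
    idx = np.arange(n)
    if n > subsample:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
    scores = {}
    for key, labels in (("iSS", batch), ("cSS", types)):
        labels = np.asarray(labels).astype(str)[idx]
        if len(set(labels)) < 2:
            warnings.warn(f"{key}: single-level label set, score defined as 0")
            scores[key] = 0.0
            continue
        scores[key] = float(silhouette_score(embedding[idx], labels,
                                             metric="euclidean"))
    return SilhouetteResult(iSS=scores["iSS"], cSS=scores["cSS"])


def f1_ss(iSS: float, cSS: float, mode: str = "table_consistent") -> float:
    """F1 combiner of the silhouette pair.

    ``table_consistent`` (default): 2 (1-iSS) cSS / ((1-iSS) + cSS) on the
    raw coefficients clipped to [0, 1]. ``equation_9``: rescale both to
    primes (1+s)/2 in [0, 1] first, then combine — the textbook harmonic
    form; the two disagree and both are exposed (see docs/methods.md).
    A zero denominator yields 0.
    """
    if mode == "table_consistent":
        a = min(max(iSS, 0.0), 1.0)
        b = min(max(cSS, 0.0), 1.0)
        num = 2.0 * (1.0 - a) * b
        den = (1.0 - a) + b
    elif mode == "equation_9":
        ip = (1.0 + iSS) / 2.0
        cp = (1.0 + cSS) / 2.0
        num = 2.0 * (1.0 - ip) * cp
        den = (1.0 - ip) + cp
    else:
        raise ValueError(f"unknown f1_ss mode {mode!r}")
    return 0.0 if den == 0.0 else float(num / den)


# -- composite --------------------------------------------------------------

def batcheval_score(f1_lisi_value: float, f1_ss_value: float,
                    accept_rate: float) -> SummaryScore:
    """Composite score: unweighted mean of F1_LISI, F1_SS and the classifier
    accept rate (1 - DomainAcc)."""
    for name, v in (("f1_lisi", f1_lisi_value), ("f1_ss", f1_ss_value),
                    ("accept_rate", accept_rate)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return SummaryScore(f1_lisi=f1_lisi_value, f1_ss=f1_ss_value,
                        accept_rate=accept_rate,
                        batcheval=(f1_lisi_value + f1_ss_value + accept_rate) / 3.0)


# -- fallback type labels ---------------------------------------------------

def leiden_fallback_types(graph: NeighborGraph, resolution: float = 1.0,
                          seed: int = 0) -> np.ndarray:
    """Cluster labels from Leiden community detection on the kNN graph,
    used as stand-in type labels when no cell/domain annotation exists."""
    import igraph as ig
    import leidenalg

    n = graph.n_obs
    edges = {(min(i, j), max(i, j))
             for i in range(n) for j in graph.indices[i]}
    g = ig.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution, seed=seed)
    return np.asarray([f"cluster{m}" for m in part.membership], dtype=object)


def evaluate_embedding(dataset, embedding_name: str = "pca",
                       classifier_result=None, *,
                       kbet_k: int = 25, lisi_k: int = 90, alpha: float = 0.05,
                       sample_fraction: float = 0.1, seed: int = 0,
                       f1_ss_mode: str = "table_consistent",
                       silhouette_subsample: int = 10_000) -> MetricBundle:
    """Compute the full metric bundle for one embedding of a dataset.

    Type labels come from ``dataset.cell_type`` when present, otherwise from
    Leiden clustering of the kNN graph (reported as cluster-based).
    """
    from .classifier import ClassifierConfig, train_domain_classifier
    from .preprocess import knn_neighbors

    n = dataset.n_obs
    batch = np.asarray(dataset.batch).astype(str)
    graph_lisi = knn_neighbors(dataset, embedding_name, k=min(lisi_k, n - 1))
    graph_kbet = (graph_lisi if min(kbet_k, n - 1) == graph_lisi.k
                  else knn_neighbors(dataset, embedding_name, k=min(kbet_k, n - 1)))

    if dataset.cell_type is not None:
        types = np.asarray(dataset.cell_type).astype(str)
        types_source = "cell_type"
    else:
        types = leiden_fallback_types(graph_kbet, seed=seed)
        types_source = "leiden_clusters"

    if classifier_result is None:
        classifier_result = train_domain_classifier(
            dataset,
            ClassifierConfig(seed=seed, features="pca"),
            features=dataset.embeddings[embedding_name])

    kb = kbet(graph_kbet, batch, alpha=alpha, sample_fraction=sample_fraction,
              seed=seed)
    li = lisi_scores(graph_lisi, batch, types)
    li.f1 = f1_lisi(li.iLISI, li.cLISI)
    ss = silhouette_scores(dataset.embeddings[embedding_name], batch, types,
                           subsample=silhouette_subsample, seed=seed)
    ss.mode = f1_ss_mode
    ss.f1 = f1_ss(ss.iSS, ss.cSS, mode=f1_ss_mode)
    summary = batcheval_score(li.f1, ss.f1, classifier_result.accept_rate)
    return MetricBundle(classifier=classifier_result, kbet=kb, lisi=li,
                        silhouette=ss, summary=summary, types_source=types_source)
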