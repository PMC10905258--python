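"""Benchmark loop: evaluate the raw integration and each registered
batch-correction method, then recommend the best-scoring method.

Correction methods are pluggable: a method is a callable taking an
:class:`~batcheval.datamodel.IntegratedDataset` and returning either a
corrected embedding (N x d array) or a corrected expression layer. The
algorithms themselves (Harmony, BBKNN, spatiAlign, ...) are external;
adapters register only when their package imports, and a dependency-free
per-batch center/scale baseline is always available so the loop is
exercisable anywhere. Each variant is evaluated in its own output space with
identical seeds, and the recommendation is the argmax of the composite score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .metrics import MetricBundle, evaluate_embedding

log = logging.getLogger("batcheval")

CONCLUSION_BATCH_EFFECT = (
    'This dataset has batch effect and requires further processing. '
    'Recommend to use "{method}".'
)
CONCLUSION_NO_EFFECT = (
    "This dataset shows no substantial batch effect; no further processing required."
)
CONCLUSION_RAW_ONLY = (
    "This dataset has batch effect and requires further processing. "
    "No correction methods were evaluated."
)


@dataclass
class CorrectionMethod:
    name: str
    transform: Callable
    provenance: str = "builtin"  # or "plugin"


@dataclass
class BenchmarkSummary:
    bundles: dict[str, MetricBundle]          # "Raw" + one per method
    recommended: str | None
    conclusion: str
    failed: dict[str, str] = field(default_factory=dict)

    def score_row(self) -> dict[str, float]:
        return {name: b.summary.batcheval for name, b in self.bundles.items()}

    def kbet_row(self) -> dict[str, float]:
        return {name: b.kbet.accept_rate for name, b in self.bundles.items()}

    def p_row(self) -> dict[str, float]:
        return {name: b.kbet.p_summary for name, b in self.bundles.items()}

    def to_dict(self) -> dict:
        return {
            "variants": {name: b.to_dict() for name, b in self.bundles.items()},
            "kbet_row": self.kbet_row(),
            "p_row": self.p_row(),
            "batcheval_row": self.score_row(),
            "recommended": self.recommended,
            "conclusion": self.conclusion,
            "failed": self.failed,
        }


class MethodRegistry:
    """Named registry of correction methods."""

    def __init__(self) -> None:
        self._methods: dict[str, CorrectionMethod] = {}

    def register(self, name: str, transform: Callable,
                 provenance: str = "builtin") -> CorrectionMethod:
        if name in self._methods:
            raise ValueError(f"method {name!r} already registered")
        entry = CorrectionMethod(name=name, transform=transform, provenance=provenance)
        self._methods[name] = entry
        return entry

    def names(self) -> list[str]:
        return sorted(self._methods)

    def get(self, name: str) -> CorrectionMethod:
        if name not in self._methods:
            raise KeyError(f"unknown method {name!r}; registered: {self.names()}")
        return self._methods[name]


def baseline_center_scale(dataset) -> np.ndarray:
    """Per-batch standardization of the PCA scores.

    Subtracts each batch's mean and divides by its standard deviation in PCA
    space; removes pure location/scale batch shifts while leaving within-batch
    structure untouched. A batch of size 1 keeps sd = 1.
    """
    if "pca" not in dataset.embeddings:
        raise KeyError("baseline_center_scale requires the 'pca' embedding")
    x = dataset.embeddings["pca"].copy()
    batch = np.asarray(dataset.batch).astype(str)
    for name in sorted(set(batch)):
        mask = batch == name
        sub = x[mask]
        mu = sub.mean(axis=0)
        if mask.sum() > 1:
            sd = sub.std(axis=0, ddof=0)
            sd[sd == 0.0] = 1.0
        else:
            sd = np.ones(x.shape[1])
        x[mask] = (sub - mu) / sd
    return x


def _harmony_adapter(dataset) -> np.ndarray:
    import pandas as pd
    import harmonypy

    meta = pd.DataFrame({"batch": np.asarray(dataset.batch).astype(str)})
    ho = harmonypy.run_harmony(dataset.embeddings["pca"], meta, ["batch"])
    return ho.Z_corr.T


def default_registry(include_plugins: bool = True) -> MethodRegistry:
    """Registry with the built-in baseline plus whichever optional plug-ins
    (harmony, ...) import in this environment; missing ones are skipped with
    a logged notice."""
    reg = MethodRegistry()
    reg.register("baseline", baseline_center_scale, provenance="builtin")
    if include_plugins:
        try:
            import harmonypy  # noqa: F401

            reg.register("harmony", _harmony_adapter, provenance="plugin")
        except ImportError:
            log.info("optional plug-in 'harmony' unavailable (harmonypy not installed)")
    return reg


def run_benchmark(dataset, methods: list[CorrectionMethod] | None = None,
                  *, seed: int = 0, threshold: float = 0.5,
                  f1_ss_mode: str = "table_consistent",
                  kbet_k: int = 25, lisi_k: int = 90, alpha: float = 0.05,
                  sample_fraction: float = 0.1,
                  silhouette_subsample: int = 10_000) -> BenchmarkSummary:
    """Evaluate the raw integration and every method; identical seeds across
    variants. A method that raises is marked failed, the rest proceed."""
    kwargs = dict(kbet_k=kbet_k, lisi_k=lisi_k, alpha=alpha,
                  sample_fraction=sample_fraction, seed=seed,
                  f1_ss_mode=f1_ss_mode,
                  silhouette_subsample=silhouette_subsample)
    bundles: dict[str, MetricBundle] = {}
    failed: dict[str, str] = {}
    bundles["Raw"] = evaluate_embedding(dataset, "pca", **kwargs)

    for method in methods or []:
        try:
            out = np.asarray(method.transform(dataset), dtype=float)
            if out.shape[0] != dataset.n_obs:
                raise ValueError(
                    f"method {method.name!r} returned {out.shape[0]} rows, "
                    f"expected {dataset.n_obs}")
            if not np.all(np.isfinite(out)):
                raise ValueError(f"method {method.name!r} returned non-finite values")
            variant = dataset.copy()
            if out.shape[1] == dataset.n_genes:
                # corrected expression layer: re-embed before scoring
                variant.layers["normalized"] = out
                from .preprocess import pca_embed

                pca_embed(variant, n_components=min(50, min(out.shape) - 1), seed=seed)
            else:
                variant.embeddings["pca"] = out
            bundles[method.name] = evaluate_embedding(variant, "pca", **kwargs)
        except Exception as exc:  # a failing method must not sink the run
            log.warning("method %s failed: %s", method.name, exc)
            failed[method.name] = str(exc)

    recommended, conclusion = recommend_from_scores(
        {k: b.summary.batcheval for k, b in bundles.items()}, threshold)
    return BenchmarkSummary(bundles=bundles, recommended=recommended,
                            conclusion=conclusion, failed=failed)


def recommend_from_scores(scores: dict[str, float],
                          threshold: float = 0.5) -> tuple[str | None, str]:
    """Recommendation logic on a {variant: composite score} row.

    If the raw score is below the threshold the dataset is judged to carry a
    batch effect and the best-scoring corrected variant is recommended (ties
    broken alphabetically); otherwise no further correction is advised.
    """
    if "Raw" not in scores:
        raise ValueError('scores must include the "Raw" variant')
    corrected = {k: v for k, v in scores.items() if k != "Raw"}
    if scores["Raw"] >= threshold:
        return None, CONCLUSION_NO_EFFECT
    if not corrected:
        return None, CONCLUSION_RAW_ONLY
    best = max(sorted(corrected), key=lambda k: corrected[k])
    return best, CONCLUSION_BATCH_EFFECT.format(method=best)


def recommend(summary: BenchmarkSummary,
              threshold: float = 0.5) -> tuple[str | None, str]:
    return recommend_from_scores(summary.score_row(), threshold)
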