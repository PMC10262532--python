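"""Corpus-level distribution statistics for classified reactions.

Two complementary summaries are computed for every axis (kinetics type,
reaction type, or their 160-cell cross product):

* the *pooled* distribution — each category's share of all reactions
  from all models taken together, and
* the *per-model mean* — the average, over models, of each category's
  within-model share, with a standard error across models
  (sample standard deviation / sqrt(number of models)).

The pooled view weights big models more; the per-model view weights
every model equally.  Both sum to one on a fully classified corpus.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .classifier import ClassificationResult, K_TYPES, R_TYPES, RType

__all__ = [
    "DistributionTable",
    "KByRSlice",
    "ComparisonReport",
    "axis_categories",
    "pooled_distribution",
    "per_model_distribution",
    "build_distribution",
    "k_by_r_table",
    "compare_corpora",
    "query_top",
    "results_frame",
    "write_per_reaction_csv",
    "write_per_model_csv",
]

AXES = ("K", "R", "KxR")


def axis_categories(axis: str) -> tuple[str, ...]:
    """Canonical category order for an axis."""
    if axis == "K":
        return K_TYPES
    if axis == "R":
        return tuple(r.label for r in R_TYPES)
    if axis == "KxR":
        return tuple(f"{k}|{r.label}" for k in K_TYPES for r in R_TYPES)
    raise ValueError(f"unknown axis {axis!r}; expected one of {AXES}")


def _category_of(result: ClassificationResult, axis: str) -> str:
    if axis == "K":
        return result.k_type
    if axis == "R":
        return result.r_type.label
    return f"{result.k_type}|{result.r_type.label}"


@dataclass
class DistributionTable:
    """Category shares of a corpus, pooled and per-model, with counts."""

    axis: str
    categories: tuple[str, ...]
    counts: dict[str, int]
    pooled: dict[str, float]
    per_model_mean: dict[str, float]
    per_model_se: dict[str, float]
    n_models: int
    n_reactions: int
    se_degenerate: bool = False  # single-model corpora have no spread

    def to_json(self, path: Optional[str | Path] = None) -> str:
        payload = {
            "axis": self.axis,
            "n_models": self.n_models,
            "n_reactions": self.n_reactions,
            "se_degenerate": self.se_degenerate,
            "categories": [
                {
                    "category": c,
                    "count": self.counts[c],
                    "pooled": self.pooled[c],
                    "mean": self.per_model_mean[c],
                    "se": self.per_model_se[c],
                }
                for c in self.categories
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "DistributionTable":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        cats = tuple(row["category"] for row in payload["categories"])
        return cls(
            axis=payload["axis"],
            categories=cats,
            counts={r["category"]: r["count"] for r in payload["categories"]},
            pooled={r["category"]: r["pooled"] for r in payload["categories"]},
            per_model_mean={r["category"]: r["mean"] for r in payload["categories"]},
            per_model_se={r["category"]: r["se"] for r in payload["categories"]},
            n_models=payload["n_models"],
            n_reactions=payload["n_reactions"],
            se_degenerate=payload.get("se_degenerate", False),
        )


def results_frame(results: Sequence[ClassificationResult]) -> pd.DataFrame:
    """Tidy per-reaction table used by every aggregation."""
    return pd.DataFrame(
        {
            "model_id": [r.model_id for r in results],
            "reaction_id": [r.reaction_id for r in results],
            "reaction": [r.reaction for r in results],
            "kinetic_law": [r.kinetic_law for r in results],
            "k_type": [r.k_type for r in results],
            "r_type": [r.r_type.label for r in results],
        }
    )


def build_distribution(
    results: Sequence[ClassificationResult], axis: str = "K"
) -> DistributionTable:
    """Pooled and per-model distribution over the axis categories.

    Models contribute to the per-model average only if they have at
    least one classified reaction (a 0/0 share is undefined).
    """
    if not results:
        raise ValueError("cannot build a distribution from zero reactions")
    cats = axis_categories(axis)
    labels = [_category_of(r, axis) for r in results]
    models = [r.model_id for r in results]
    df = pd.DataFrame({"model_id": models, "category": labels})

    counts = df["category"].value_counts().reindex(cats, fill_value=0)
    total = int(counts.sum())
    pooled = {c: int(counts[c]) / total for c in cats}

    per_model = (
        df.groupby("model_id")["category"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=cats, fill_value=0.0)
    )
    n_models = len(per_model)
    mean = per_model.mean(axis=0)
    if n_models > 1:
        se = per_model.std(axis=0, ddof=1) / np.sqrt(n_models)
        degenerate = False
    else:
        se = pd.Series(0.0, index=mean.index)
        degenerate = True

    return DistributionTable(
        axis=axis,
        categories=cats,
        counts={c: int(counts[c]) for c in cats},
        pooled=pooled,
        per_model_mean={c: float(mean[c]) for c in cats},
        per_model_se={c: float(se[c]) for c in cats},
        n_models=n_models,
        n_reactions=total,
        se_degenerate=degenerate,
    )


def pooled_distribution(
    results: Sequence[ClassificationResult], axis: str = "K"
) -> DistributionTable:
    """Distribution over all reactions from all models pooled together."""
    return build_distribution(results, axis)


def per_model_distribution(
    results: Sequence[ClassificationResult], axis: str = "K"
) -> DistributionTable:
    """Average of within-model shares, with a standard error across models."""
    return build_distribution(results, axis)


@dataclass
class KByRSlice:
    """Conditional kinetics-type distribution for one reaction type."""

    r_type: str
    share_pooled: float  # this R type's share of all reactions
    share_per_model_mean: float  # mean over models of the within-model share
    n_reactions: int
    table: Optional[DistributionTable]  # None when the cell is empty


def k_by_r_table(
    results: Sequence[ClassificationResult],
) -> dict[str, KByRSlice]:
    """For each of the 16 reaction types, the conditional K distribution
    plus that reaction type's share of the corpus."""
    if not results:
        raise ValueError("cannot build a table from zero reactions")
    shares = build_distribution(results, "R")
    out: dict[str, KByRSlice] = {}
    for r in R_TYPES:
        subset = [x for x in results if x.r_type == r]
        out[r.label] = KByRSlice(
            r_type=r.label,
            share_pooled=shares.pooled[r.label],
            share_per_model_mean=shares.per_model_mean[r.label],
            n_reactions=len(subset),
            table=build_distribution(subset, "K") if subset else None,
        )
    return out


@dataclass
class ComparisonReport:
    axis: str
    categories: tuple[str, ...]
    pooled_a: dict[str, float]
    pooled_b: dict[str, float]
    difference: dict[str, float]  # |a - b| per category
    top_a: str
    top_b: str

    def to_text(self, name_a: str = "corpus A", name_b: str = "corpus B") -> str:
        lines = [
            f"{'category':<14}{name_a:>12}{name_b:>12}{'abs diff':>12}",
        ]
        for c in self.categories:
            lines.append(
                f"{c:<14}{self.pooled_a[c]:>12.4f}{self.pooled_b[c]:>12.4f}"
                f"{self.difference[c]:>12.4f}"
            )
        lines.append(f"top category of {name_a}: {self.top_a}")
        lines.append(f"top category of {name_b}: {self.top_b}")
        return "\n".join(lines)


def compare_corpora(
    a: DistributionTable, b: DistributionTable
) -> ComparisonReport:
    """Side-by-side pooled fractions of two corpora on the same axis."""
    if a.axis != b.axis or a.categories != b.categories:
        raise ValueError(
            f"axis mismatch: {a.axis}/{len(a.categories)} categories vs "
            f"{b.axis}/{len(b.categories)}"
        )
    diff = {c: abs(a.pooled[c] - b.pooled[c]) for c in a.categories}
    return ComparisonReport(
        axis=a.axis,
        categories=a.categories,
        pooled_a=dict(a.pooled),
        pooled_b=dict(b.pooled),
        difference=diff,
        top_a=query_top(a, 1)[0],
        top_b=query_top(b, 1)[0],
    )


def query_top(table: DistributionTable, n: int = 1) -> list[str]:
    """Categories sorted by pooled share, descending; ties broken by the
    canonical category order.  ``n`` beyond the category count returns all."""
    if n < 1:
        raise ValueError("n must be positive")
    order = {c: i for i, c in enumerate(table.categories)}
    ranked = sorted(table.categories, key=lambda c: (-table.pooled[c], order[c]))
    return ranked[: min(n, len(ranked))]


# ---------------------------------------------------------------------------
# tidy exports
# ---------------------------------------------------------------------------


def write_per_reaction_csv(
    results: Sequence[ClassificationResult], path: str | Path
) -> Path:
    """Per-reaction table: model id, reaction id, reaction, law, K and R type."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(path, index=False)
    return path


def write_per_model_csv(
    results: Sequence[ClassificationResult], path: str | Path
) -> Path:
    """Per-model table: reaction count and the ten kinetics-type fractions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = results_frame(results)
    frac = (
        df.groupby("model_id")["k_type"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(columns=K_TYPES, fill_value=0.0)
    )
    frac.insert(0, "n_reactions", df.groupby("model_id").size())
    frac.sort_index().to_csv(path)
    return path
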