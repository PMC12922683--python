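"""Cluster-level expression aggregation by canonical-marker cell classes.

Consumes published clusters × genes mean-expression tables (each cluster's
value is used as provided, on that dataset's normalized scale), removes
excluded populations, assigns each cluster to a major cell class by marker
scores, summarizes a query gene per class (unweighted over clusters), and
compares class rankings across datasets.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

#: canonical marker genes per major class; direction 'high' unless noted
DEFAULT_RULEBOOK: dict[str, list[tuple[str, str]]] = {
    "astrocytes": [("Aldh1l1", "high")],
    "ependymal": [("Ttr", "high"), ("Foxj1", "high"), ("Aqp1", "high")],
    "endothelial": [("Pecam1", "high")],
    "mural": [("Pdgfrb", "high"), ("Acta2", "high")],
    "fibroblasts": [("Dcn", "high"), ("Col1a1", "high"), ("Pdgfra", "high")],
    "OPC": [("Sox10", "high"), ("Pdgfra", "high")],
    "oligodendrocytes": [("Olig2", "high"), ("Sox10", "high"), ("Mog", "high")],
    "immune": [("Aif1", "high")],
    "neuroblasts": [("Sox4", "high")],
    "excitatory_neurons": [("Slc17a7", "high"), ("Slc17a6", "high")],
    "inhibitory_neurons": [("Gad1", "high"), ("Gad2", "high")],
    "cholinergic_neurons": [("Chat", "high")],
}

#: deterministic tie-break: earlier wins
DEFAULT_PRIORITY = (
    "cholinergic_neurons", "inhibitory_neurons", "excitatory_neurons",
    "other_neurons", "OPC", "astrocytes", "endothelial", "ependymal",
    "fibroblasts", "immune", "mural", "neuroblasts", "oligodendrocytes",
)


@dataclass
class MarkerRulebook:
    """Map class → [(gene, 'high'|'low')] with a class priority order."""

    rules: Mapping[str, Sequence[tuple[str, str]]] = field(
        default_factory=lambda: dict(DEFAULT_RULEBOOK))
    priority: Sequence[str] = DEFAULT_PRIORITY
    ambiguity_tolerance: float = 1e-9

    def __post_init__(self) -> None:
        for cls, markers in self.rules.items():
            genes = [g for g, _ in markers]
            if len(set(genes)) != len(genes):
                raise ValueError(f"duplicate marker genes in class {cls!r}")
            if not any(d == "high" for _, d in markers):
                raise ValueError(f"class {cls!r} needs >= 1 'high' marker")

    @classmethod
    def from_simple(cls, simple: Mapping[str, Sequence[str]],
                    priority: Sequence[str] | None = None) -> "MarkerRulebook":
        rules = {k: [(g, "high") for g in v] for k, v in simple.items()}
        return cls(rules=rules, priority=tuple(priority or simple.keys()))


@dataclass
class ClassSummary:
    class_name: str
    n_populations: int
    mean: float
    sem: float | None
    rank: int


def filter_populations(matrix: pd.DataFrame, meta: pd.Series | None,
                       exclusions: Sequence[str]) -> tuple[pd.DataFrame, dict]:
    """Drop clusters whose annotation matches an exclusion name.

    ``meta`` maps cluster index → annotation; when absent the matrix index
    itself is matched.  Unresolvable names raise a warning and are
    reported, never silently dropped.
    """
    labels = meta if meta is not None else pd.Series(matrix.index, index=matrix.index)
    report: dict[str, int] = {}
    drop = pd.Series(False, index=matrix.index)
    for name in exclusions:
        hit = labels.astype(str).str.contains(name, regex=False)
        n = int(hit.sum())
        report[name] = n
        if n == 0:
            warnings.warn(f"exclusion name {name!r} matched no cluster")
        drop |= hit
    out = matrix[~drop]
    report["_removed_total"] = int(drop.sum())
    report["_empty_result"] = out.empty
    return out, report


def assign_classes(matrix: pd.DataFrame,
                   rulebook: MarkerRulebook | None = None) -> pd.DataFrame:
    """Score each cluster per class and assign the argmax class.

    Score = mean of the class's 'high' markers minus mean of its 'low'
    markers, on the matrix's own expression scale.  Ties break by the
    rulebook priority order; near-ties are flagged ambiguous; clusters
    with all-zero marker expression are 'unassigned'.  Missing rulebook
    genes are reported via a warning and skipped.
    """
    rulebook = rulebook or MarkerRulebook()
    missing = sorted({g for ms in rulebook.rules.values() for g, _ in ms}
                     - set(matrix.columns))
    if missing:
        warnings.warn(f"rulebook genes absent from matrix: {missing}")
    order = {c: i for i, c in enumerate(rulebook.priority)}
    class_names = sorted(rulebook.rules, key=lambda c: order.get(c, len(order)))
    scores = pd.DataFrame(index=matrix.index, dtype=float)
    all_genes: set[str] = set()
    for cls in class_names:
        high = [g for g, d in rulebook.rules[cls] if d == "high" and g in matrix.columns]
        low = [g for g, d in rulebook.rules[cls] if d == "low" and g in matrix.columns]
        all_genes.update(high + low)
        s = matrix[high].mean(axis=1) if high else pd.Series(0.0, index=matrix.index)
        if low:
            s = s - matrix[low].mean(axis=1)
        scores[cls] = s
    arr = scores.to_numpy()
    best = arr.argmax(axis=1)  # first max wins -> priority order
    sorted_scores = np.sort(arr, axis=1)
    gap = sorted_scores[:, -1] - (sorted_scores[:, -2] if arr.shape[1] > 1
                                  else sorted_scores[:, -1])
    marker_total = matrix[sorted(all_genes)].abs().sum(axis=1) if all_genes else 0
    out = pd.DataFrame(
        {
            "assigned_class": [class_names[i] for i in best],
            "score": arr[np.arange(len(best)), best],
            "ambiguous": gap <= rulebook.ambiguity_tolerance,
        },
        index=matrix.index,
    )
    out.loc[np.asarray(marker_total) == 0, "assigned_class"] = "unassigned"
    return out


def apply_overrides(assignments: pd.DataFrame,
                    overrides: Mapping[str, str]) -> pd.DataFrame:
    """Explicit manual reassignments (cluster → class); never heuristic."""
    out = assignments.copy()
    for cluster, cls in overrides.items():
        if cluster not in out.index:
            raise KeyError(f"override names unknown cluster {cluster!r}")
        out.loc[cluster, "assigned_class"] = cls
        out.loc[cluster, "ambiguous"] = False
    return out


def class_summary(matrix: pd.DataFrame, labels: pd.Series,
                  gene: str) -> list[ClassSummary]:
    """Unweighted per-class mean/SEM of one gene over member clusters.

    Classes are dense-ranked by mean, 1 = highest.
    """
    if gene not in matrix.columns:
        raise KeyError(f"gene {gene!r} absent from matrix")
    values = matrix[gene]
    grouped = values.groupby(labels.reindex(matrix.index))
    stats = grouped.agg(["mean", "count", "sem"])
    stats["rank"] = stats["mean"].rank(ascending=False, method="dense").astype(int)
    return [
        ClassSummary(
            class_name=cls,
            n_populations=int(row["count"]),
            mean=float(row["mean"]),
            sem=float(row["sem"]) if row["count"] >= 2 else None,
            rank=int(row["rank"]),
        )
        for cls, row in stats.iterrows()
    ]


def rank_consistency(summaries: Mapping[str, Sequence[ClassSummary]]) -> pd.DataFrame:
    """Spearman rank correlation between dataset pairs over shared classes.

    Also reports each class's rank spread (max − min) across datasets via
    the ``attrs['rank_spread']`` of the returned table.
    """
    if len(summaries) < 2:
        raise ValueError("need >= 2 datasets")
    per_ds = {ds: {s.class_name: s.mean for s in lst} for ds, lst in summaries.items()}
    names = list(per_ds)
    rows = []
    for i, j in itertools.combinations(names, 2):
        shared = sorted(set(per_ds[i]) & set(per_ds[j]))
        if len(shared) < 3:
            raise ValueError(f"datasets {i!r} and {j!r} share < 3 classes")
        xi = np.array([per_ds[i][c] for c in shared])
        xj = np.array([per_ds[j][c] for c in shared])
        rho, p = sps.spearmanr(xi, xj)
        ri = sps.rankdata(xi)
        rj = sps.rankdata(xj)
        if np.unique(ri).size == ri.size and np.unique(rj).size == rj.size:
            # untied ranks: exact rank-difference formula (1.0 stays exact)
            n = len(shared)
            rho = 1.0 - 6.0 * ((ri - rj) ** 2).sum() / (n * (n * n - 1))
        rows.append({"dataset1": i, "dataset2": j, "spearman_rho": float(rho),
                     "p": float(p), "n_shared": len(shared)})
    out = pd.DataFrame(rows)
    shared_all = set.intersection(*(set(v) for v in per_ds.values()))
    spread = {}
    for cls in sorted(shared_all):
        ranks = []
        for ds in names:
            vals = per_ds[ds]
            order = sorted(vals, key=lambda c: -vals[c])
            ranks.append(order.index(cls) + 1)
        spread[cls] = max(ranks) - min(ranks)
    out.attrs["rank_spread"] = spread
    return out
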