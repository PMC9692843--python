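"""Cross-run consensus analysis: overlaps, relation categories, threads, and
the six-level agreement grouping.

Given several clusterings of the same image set, each pair of runs is
compared through its contingency (overlap) table.  Each sufficiently large
overlap cell becomes an :class:`OverlapRelation` carrying the overlap count,
a Jaccard similarity, a *separation index* (the rank of this partner among
the cluster's overlaps, descending by count), and a category:

* ``identical`` — Jaccard at or above ``tau_identical`` (default 0.9);
* ``related``   — Jaccard in [``tau_related``, ``tau_identical``);
* ``none``      — reported but below both thresholds.

Chains of categorized relations whose nodes span three or more distinct runs
are *threads*.  Finally, the six proposed runs are condensed into a per-image
agreement level: for image *i*, the level is the largest number of runs that
assign *i* exactly the same set of cluster-mates, mapped onto the groups
SI (6) > SS (5) > SM (4) > NS (3) > PS (2) > PD (1) — from strongly
identical (all runs agree) down to possibly different (no two runs agree).
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .clustering import ClusteringRun
from .errors import InvalidInputError
from .synthetic import WallClass

__all__ = [
    "OverlapConfig",
    "OverlapRelation",
    "Thread",
    "AgreementPartition",
    "AGREEMENT_GROUPS",
    "GROUP_BY_LEVEL",
    "contingency_table",
    "classify_relations",
    "relate_runs",
    "all_pairwise_relations",
    "find_threads",
    "agreement_grouping",
    "combination_count",
    "compare_to_human",
    "relations_frame",
]

AGREEMENT_GROUPS = ("SI", "SS", "SM", "NS", "PS", "PD")
GROUP_BY_LEVEL = {6: "SI", 5: "SS", 4: "SM", 3: "NS", 2: "PS", 1: "PD"}


@dataclasses.dataclass(frozen=True)
class OverlapConfig:
    """Thresholds of the overlap analysis.

    ``report_floor`` is the minimum overlap count a cell must reach to be
    reported at all (the reporting threshold; higher tiers are filters on
    the same relations, not different algorithms).  The Jaccard thresholds
    operationalize "identical" and "related".
    """

    tau_identical: float = 0.9
    tau_related: float = 0.5
    report_floor: int = 500

    def __post_init__(self):
        if not 0.0 < self.tau_related < self.tau_identical <= 1.0:
            raise InvalidInputError("need 0 < tau_related < tau_identical <= 1")
        if self.report_floor < 0:
            raise InvalidInputError("report_floor must be >= 0")


@dataclasses.dataclass(frozen=True)
class OverlapRelation:
    """One (run A, cluster a) ↔ (run B, cluster b) overlap link."""

    a: tuple[str, int]
    b: tuple[str, int]
    overlap: int
    size_a: int
    size_b: int
    jaccard: float
    separation_index: int
    category: str

    def __post_init__(self):
        if self.overlap > min(self.size_a, self.size_b):
            raise InvalidInputError("overlap cannot exceed either cluster size")
        if not 0.0 <= self.jaccard <= 1.0:
            raise InvalidInputError("jaccard must be in [0, 1]")
        if self.separation_index < 1:
            raise InvalidInputError("separation_index must be >= 1")
        if self.category not in ("identical", "related", "none"):
            raise InvalidInputError("category must be identical/related/none")


@dataclasses.dataclass(frozen=True)
class Thread:
    """A chain of categorized relations spanning >= 3 distinct runs."""

    nodes: tuple[tuple[str, int], ...]

    @property
    def runs_spanned(self) -> int:
        return len({code for code, _ in self.nodes})

    def __post_init__(self):
        if self.runs_spanned < 3:
            raise InvalidInputError("a thread must span at least 3 runs")
        codes = [code for code, _ in self.nodes]
        if len(codes) != len(set(codes)):
            raise InvalidInputError("thread node run codes must be distinct")


@dataclasses.dataclass
class AgreementPartition:
    """Per-image agreement level (1..6) and group (PD..SI), plus group counts."""

    assignment: dict[str, str]
    level: dict[str, int]
    counts: dict[str, int]

    @property
    def n(self) -> int:
        return len(self.assignment)


# ---------------------------------------------------------------------------
# Contingency and relations
# ---------------------------------------------------------------------------

def _aligned_labels(run_a: ClusteringRun, run_b: ClusteringRun):
    if run_a.image_ids and run_b.image_ids:
        if set(run_a.image_ids) != set(run_b.image_ids):
            raise InvalidInputError("runs label different image sets")
        if run_a.image_ids == run_b.image_ids:
            return run_a.labels, run_b.labels
        order = {img: i for i, img in enumerate(run_b.image_ids)}
        idx = np.array([order[img] for img in run_a.image_ids])
        return run_a.labels, run_b.labels[idx]
    if len(run_a.labels) != len(run_b.labels):
        raise InvalidInputError("runs label different numbers of images")
    return run_a.labels, run_b.labels


def contingency_table(run_a: ClusteringRun, run_b: ClusteringRun) -> np.ndarray:
    """kA × kB matrix of shared-image counts between two runs."""
    la, lb = _aligned_labels(run_a, run_b)
    table = np.zeros((run_a.k, run_b.k), dtype=int)
    np.add.at(table, (la, lb), 1)
    return table


def classify_relations(table: np.ndarray,
                       config: OverlapConfig | None = None,
                       code_a: str = "A", code_b: str = "B") -> list[OverlapRelation]:
    """Turn a contingency table into categorized overlap relations.

    Every nonzero cell with overlap >= ``report_floor`` is reported.  The
    separation index ranks a row cluster's reported overlaps in descending
    count, ties broken by ascending partner cluster index.
    """
    config = config or OverlapConfig()
    table = np.asarray(table, dtype=int)
    row_sizes = table.sum(axis=1)
    col_sizes = table.sum(axis=0)
    relations: list[OverlapRelation] = []
    for i in range(table.shape[0]):
        cells = [(int(table[i, j]), j) for j in range(table.shape[1])
                 if table[i, j] > 0 and table[i, j] >= config.report_floor]
        cells.sort(key=lambda c: (-c[0], c[1]))
        for rank, (count, j) in enumerate(cells, start=1):
            union = int(row_sizes[i] + col_sizes[j] - count)
            jac = count / union if union > 0 else 0.0
            if jac >= config.tau_identical:
                category = "identical"
            elif jac >= config.tau_related:
                category = "related"
            else:
                category = "none"
            relations.append(OverlapRelation(
                a=(code_a, i), b=(code_b, j), overlap=count,
                size_a=int(row_sizes[i]), size_b=int(col_sizes[j]),
                jaccard=jac, separation_index=rank, category=category,
            ))
    return relations


def relate_runs(run_a: ClusteringRun, run_b: ClusteringRun,
                config: OverlapConfig | None = None) -> list[OverlapRelation]:
    """Contingency + classification for one pair of runs."""
    table = contingency_table(run_a, run_b)
    return classify_relations(table, config, code_a=run_a.code, code_b=run_b.code)


def all_pairwise_relations(runs: Sequence[ClusteringRun],
                           config: OverlapConfig | None = None):
    """Relations for every unordered pair of runs.

    Returns ``(relations, n_tables)``; the number of tables equals
    C(len(runs), 2).
    """
    relations: list[OverlapRelation] = []
    n_tables = 0
    for i in range(len(runs)):
        for j in range(i + 1, len(runs)):
            relations.extend(relate_runs(runs[i], runs[j], config))
            n_tables += 1
    return relations, n_tables


def relations_frame(relations: Iterable[OverlapRelation]) -> pd.DataFrame:
    """Relations as a tidy table (the CSV schema of the report)."""
    rows = [{
        "run_a": r.a[0], "cluster_a": r.a[1],
        "run_b": r.b[0], "cluster_b": r.b[1],
        "overlap": r.overlap, "size_a": r.size_a, "size_b": r.size_b,
        "jaccard": r.jaccard, "separation": r.separation_index,
        "category": r.category,
    } for r in relations]
    cols = ["run_a", "cluster_a", "run_b", "cluster_b", "overlap",
            "size_a", "size_b", "jaccard", "separation", "category"]
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# Threads
# ---------------------------------------------------------------------------

def find_threads(relations: Iterable[OverlapRelation]) -> list[Thread]:
    """Maximal simple chains of categorized relations spanning >= 3 runs.

    Nodes are (run code, cluster index); edges are relations whose category
    is not ``none``; along a chain every node comes from a distinct run.
    Each maximal chain is reported once, in canonical endpoint order.

    The enumeration is exhaustive, so chain depth is bounded by the number
    of distinct runs in ``relations``; when many runs produce identical
    partitions the relation graph contains cliques and the chain count
    grows factorially with the run count.  Intended for the six proposed
    runs (or a human axis plus machine runs), not for pooled run sets.
    """
    adj: dict[tuple[str, int], set[tuple[str, int]]] = {}
    for r in relations:
        if r.category == "none":
            continue
        adj.setdefault(r.a, set()).add(r.b)
        adj.setdefault(r.b, set()).add(r.a)

    found: set[tuple[tuple[str, int], ...]] = set()

    def extensions(path):
        used_runs = {code for code, _ in path}
        for nbr in adj[path[-1]]:
            if nbr not in path and nbr[0] not in used_runs:
                yield nbr

    def dfs(path):
        extended = False
        for nbr in extensions(path):
            dfs(path + (nbr,))
            extended = True
        if not extended and len({c for c, _ in path}) >= 3:
            canonical = min(path, path[::-1])
            found.add(canonical)

    for start in sorted(adj):
        dfs((start,))

    # Drop chains that are contiguous sub-chains of longer recorded chains
    # (a chain found from an interior start can be extendable at its head).
    maximal = []
    as_list = sorted(found, key=len, reverse=True)
    kept: list[tuple] = []

    def is_subchain(small, big):
        if len(small) > len(big):
            return False
        for seq in (big, big[::-1]):
            for off in range(len(big) - len(small) + 1):
                if seq[off:off + len(small)] == small:
                    return True
        return False

    for path in as_list:
        if any(is_subchain(path, other) for other in kept):
            continue
        kept.append(path)
    for path in sorted(kept):
        maximal.append(Thread(nodes=path))
    return maximal


# ---------------------------------------------------------------------------
# Agreement grouping
# ---------------------------------------------------------------------------

def _mates_per_run(run: ClusteringRun, ids: Sequence[str]):
    order = {img: i for i, img in enumerate(run.image_ids)} if run.image_ids else None
    labels = run.labels
    members: dict[int, set[str]] = {}
    for pos, img in enumerate(ids):
        lab = int(labels[order[img]] if order else labels[pos])
        members.setdefault(lab, set()).add(img)
    mates = {}
    for img in ids:
        lab = int(labels[order[img]] if order else labels[ids.index(img)])
        mates[img] = frozenset(members[lab] - {img})
    return mates


def agreement_level(mates_sets: Sequence[frozenset]) -> int:
    """Largest number of runs whose mates sets are pairwise identical.

    Pairwise identity of sets is plain equality, so the level is the
    largest multiplicity among equal mates sets (at least 1).
    """
    return max(Counter(mates_sets).values())


def agreement_grouping(runs: Sequence[ClusteringRun]) -> AgreementPartition:
    """Condense exactly six runs into the SI..PD agreement partition."""
    if len(runs) != 6:
        raise InvalidInputError(
            f"agreement grouping requires exactly 6 runs, got {len(runs)}"
        )
    base = runs[0]
    ids = list(base.image_ids) if base.image_ids else [
        f"i{j}" for j in range(len(base.labels))
    ]
    if not base.image_ids:
        runs = [dataclasses.replace(r, image_ids=tuple(ids)) for r in runs]
    for r in runs[1:]:
        if set(r.image_ids) != set(ids):
            raise InvalidInputError("all runs must label the same image set")
    per_run = [_mates_per_run(r, ids) for r in runs]
    level = {}
    assignment = {}
    for img in ids:
        lvl = agreement_level([m[img] for m in per_run])
        level[img] = lvl
        assignment[img] = GROUP_BY_LEVEL[lvl]
    counts = {g: 0 for g in AGREEMENT_GROUPS}
    for g in assignment.values():
        counts[g] += 1
    return AgreementPartition(assignment=assignment, level=level, counts=counts)


def combination_count(n: int, k: int) -> int:
    """Number of ways to choose k objects from n without repetition: n!/(k!(n−k)!)."""
    if n < 0 or k < 0:
        raise InvalidInputError("n and k must be non-negative")
    if k > n:
        raise InvalidInputError("k must not exceed n")
    return math.comb(n, k)


# ---------------------------------------------------------------------------
# Human-vs-machine comparison
# ---------------------------------------------------------------------------

def _truth_partition(truth: dict[str, WallClass], ids: Sequence[str],
                     axis: str) -> ClusteringRun:
    values = []
    for img in ids:
        wc = truth[img]
        values.append(getattr(wc, axis).value)
    classes = sorted(set(values))
    index = {c: i for i, c in enumerate(classes)}
    labels = np.array([index[v] for v in values])
    return ClusteringRun(code=f"H-{axis[:3].upper()}", method="kmeans",
                         representation=axis, k=len(classes), labels=labels,
                         seed=0, image_ids=tuple(ids), criterion=None)


def compare_to_human(runs: Sequence[ClusteringRun], truth: dict[str, WallClass],
                     config: OverlapConfig | None = None):
    """Compare machine runs to the human annotation axes.

    Each axis (anticlinal, periclinal) becomes a reference partition; every
    machine run is related to it through contingency → relation
    classification, and threads are searched in the pooled relation graph.

    Returns ``(relations, threads, table)`` where ``table`` has one row per
    (truth class, run, cluster, separation).
    """
    if not truth:
        raise InvalidInputError("truth labels are required")
    base_ids = list(runs[0].image_ids)
    missing = [i for i in base_ids if i not in truth]
    if missing:
        raise InvalidInputError(f"missing truth for images: {missing[:5]} ...")
    relations: list[OverlapRelation] = []
    axis_classes = {}
    for axis in ("anticlinal", "periclinal"):
        ref = _truth_partition(truth, base_ids, axis)
        axis_classes[ref.code] = sorted({getattr(truth[i], axis).value
                                         for i in base_ids})
        for run in runs:
            relations.extend(relate_runs(ref, run, config))
    threads = find_threads(relations)
    rows = []
    for r in relations:
        ref_code, class_idx = r.a
        rows.append({
            "truth_axis": ref_code,
            "truth_class": axis_classes[ref_code][class_idx],
            "run": r.b[0], "cluster": r.b[1],
            "overlap": r.overlap, "jaccard": r.jaccard,
            "separation": r.separation_index, "category": r.category,
        })
    table = pd.DataFrame(rows, columns=["truth_axis", "truth_class", "run",
                                        "cluster", "overlap", "jaccard",
                                        "separation", "category"])
    return relations, threads, table
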