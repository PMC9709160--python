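"""Behavioral motif post-processing: usage, syntax, and communities.

Frame-wise motif labels (from upstream pose-estimation + unsupervised
segmentation, e.g. 38 motifs at 60 frames/s) are summarized three ways:

* **usage** — the fraction of frames a session spends in each motif;
* **syntax** — the motif-to-motif transition matrix, computed after
  collapsing runs of repeated labels so the chain describes transitions
  between successive *distinct* motifs (motifs persist over many frames and
  a frame-level diagonal would swamp everything else);
* **communities** — a hierarchical tree built by average-linkage
  agglomeration on the symmetrized transition affinity, pruned to a target
  number of behavioral communities (e.g. walk, turn, rear, groom ...).

Community names are never inferred; they are applied only through an
explicit user-supplied label map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MotifSequence",
    "TransitionMatrix",
    "CommunityTree",
    "motif_usage",
    "transition_matrix",
    "pooled_transition_matrix",
    "build_community_tree",
    "prune_tree",
    "community_usage",
    "group_compare",
    "CommunityModel",
    "CommunityResults",
]


@dataclass
class MotifSequence:
    """Frame-wise motif labels for one session."""

    mouse_id: str
    group: str
    condition: str
    labels: np.ndarray
    frame_rate: float = 60.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.size == 0:
            raise ValueError("label sequence must be non-empty")
        if self.labels.min() < 0:
            raise ValueError("motif labels must be non-negative")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be > 0")


@dataclass
class TransitionMatrix:
    """Conditional transition probabilities between successive distinct motifs.

    Rows with at least one observed outgoing transition sum to one; rows
    with none are left all-zero and flagged in ``empty_rows``.
    """

    probs: np.ndarray      # (K, K), diagonal 0 when runs are collapsed
    row_counts: np.ndarray  # (K,) observed outgoing transitions per motif

    @property
    def n_motifs(self) -> int:
        return self.probs.shape[0]

    @property
    def empty_rows(self) -> np.ndarray:
        return np.flatnonzero(self.row_counts == 0)


@dataclass
class CommunityTree:
    """Agglomerative merge structure over motifs, optionally pruned.

    ``merges`` lists tuples ``(id_a, id_b, new_id, affinity)`` in merge
    order; leaves are ids ``0..K-1`` and internal nodes continue from
    ``K``. ``members`` maps every node id to its motif set. ``partition``
    (motif -> community id, communities renumbered by smallest member) is
    set by :func:`prune_tree`.
    """

    n_leaves: int
    merges: list[tuple[int, int, int, float]]
    members: dict[int, tuple[int, ...]]
    partition: dict[int, int] | None = None
    labels: dict[int, str] | None = None

    @property
    def n_communities(self) -> int | None:
        if self.partition is None:
            return None
        return len(set(self.partition.values()))


def collapse_runs(labels: np.ndarray) -> np.ndarray:
    """Collapse runs of repeated labels to the sequence of distinct motifs."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return labels
    keep = np.ones(labels.size, dtype=bool)
    keep[1:] = labels[1:] != labels[:-1]
    return labels[keep]


def motif_usage(seq: MotifSequence | Sequence[int], n_motifs: int) -> np.ndarray:
    """Frame-fraction usage vector of length ``n_motifs`` (sums to 1)."""
    labels = seq.labels if isinstance(seq, MotifSequence) else np.asarray(seq, dtype=int)
    if labels.size == 0:
        raise ValueError("empty label sequence")
    if labels.min() < 0 or labels.max() >= n_motifs:
        raise ValueError(
            f"motif label {int(labels.max())} outside [0, {n_motifs - 1}]"
        )
    return np.bincount(labels, minlength=n_motifs) / labels.size


def _transition_counts(labels: np.ndarray, n_motifs: int, collapse: bool) -> np.ndarray:
    if labels.min() < 0 or labels.max() >= n_motifs:
        raise ValueError(f"motif label {int(labels.max())} outside [0, {n_motifs - 1}]")
    seq = collapse_runs(labels) if collapse else labels
    counts = np.zeros((n_motifs, n_motifs))
    if seq.size >= 2:
        np.add.at(counts, (seq[:-1], seq[1:]), 1.0)
    return counts


def transition_matrix(
    seq: MotifSequence | Sequence[int],
    n_motifs: int,
    collapse: bool = True,
) -> TransitionMatrix:
    """Motif transition matrix for one session (runs collapsed by default)."""
    if n_motifs < 2:
        raise ValueError("need at least 2 motifs")
    labels = seq.labels if isinstance(seq, MotifSequence) else np.asarray(seq, dtype=int)
    counts = _transition_counts(labels, n_motifs, collapse)
    return _normalize_counts(counts)


def pooled_transition_matrix(
    seqs: Iterable[MotifSequence],
    n_motifs: int,
    collapse: bool = True,
) -> TransitionMatrix:
    """Transition matrix from counts pooled across sessions (no cross-session
    transition is ever counted)."""
    if n_motifs < 2:
        raise ValueError("need at least 2 motifs")
    total = np.zeros((n_motifs, n_motifs))
    for seq in seqs:
        total += _transition_counts(seq.labels, n_motifs, collapse)
    return _normalize_counts(total)


def _normalize_counts(counts: np.ndarray) -> TransitionMatrix:
    row_counts = counts.sum(axis=1)
    probs = np.zeros_like(counts)
    nz = row_counts > 0
    probs[nz] = counts[nz] / row_counts[nz, None]
    return TransitionMatrix(probs=probs, row_counts=row_counts.astype(int))


def build_community_tree(tm: TransitionMatrix) -> CommunityTree:
    """Average-linkage agglomeration on the symmetrized transition affinity.

    The affinity between motifs i and j is ``A = (P + P.T) / 2`` and the
    leaf-level distance is ``1 - A``. Clusters are merged greedily by
    smallest average pairwise distance until a single root remains; exact
    distance ties are broken by the lexicographically smallest pair of
    cluster-minimum motif indices, making the merge order deterministic.
    Motifs never observed have affinity 0 to everything and therefore
    attach last, as singleton leaves.
    """
    P = tm.probs
    K = P.shape[0]
    if not np.any(P > 0):
        raise ValueError("all-zero transition matrix")
    if int((tm.row_counts > 0).sum()) < 2:
        raise ValueError("need at least 2 motifs with observed transitions")
    A = (P + P.T) / 2.0
    D = 1.0 - A
    np.fill_diagonal(D, 0.0)

    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(K)}
    active: dict[int, tuple[int, ...]] = dict(members)
    merges: list[tuple[int, int, int, float]] = []
    next_id = K

    def cluster_dist(a: tuple[int, ...], b: tuple[int, ...]) -> float:
        return float(D[np.ix_(a, b)].mean())

    while len(active) > 1:
        best = None
        for ia in sorted(active):
            for ib in sorted(active):
                if ib <= ia:
                    continue
                d = cluster_dist(active[ia], active[ib])
                key_pair = tuple(sorted((min(active[ia]), min(active[ib]))))
                cand = (d, key_pair, ia, ib)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, ia, ib = best
        merged = tuple(sorted(active[ia] + active[ib]))
        members[next_id] = merged
        merges.append((ia, ib, next_id, 1.0 - d))
        del active[ia], active[ib]
        active[next_id] = merged
        next_id += 1
    return CommunityTree(n_leaves=K, merges=merges, members=members)


def prune_tree(tree: CommunityTree, n_communities: int) -> CommunityTree:
    """Cut the tree into exactly ``n_communities`` communities.

    Replays the first ``K - n_communities`` merges (merges happen in
    non-decreasing distance order, so this equals cutting at the
    corresponding height) and records the resulting partition; community
    ids are renumbered by their smallest member motif.
    """
    K = tree.n_leaves
    if not 1 <= n_communities <= K:
        raise ValueError(f"n_communities must be in [1, {K}], got {n_communities}")
    n_merges = K - n_communities
    if n_merges > len(tree.merges):
        raise ValueError("tree is degenerate: cannot reach the requested community count")
    clusters: dict[int, tuple[int, ...]] = {i: (i,) for i in range(K)}
    for ia, ib, new_id, _ in tree.merges[:n_merges]:
        clusters[new_id] = tuple(sorted(clusters.pop(ia) + clusters.pop(ib)))
    roots = sorted(clusters.values(), key=min)
    partition = {m: ci for ci, memb in enumerate(roots) for m in memb}
    return CommunityTree(
        n_leaves=K,
        merges=list(tree.merges),
        members=dict(tree.members),
        partition=partition,
        labels=tree.labels,
    )


def community_usage(
    seqs: Iterable[MotifSequence],
    partition: Mapping[int, int],
    n_motifs: int | None = None,
    labels: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Per-mouse community usage: sum of member-motif frame fractions.

    Returns a tidy DataFrame with one row per sequence, the design columns
    (``mouse_id``, ``group``, ``condition``) and one usage column per
    community (named through ``labels`` when given, else ``community_<id>``).
    Per-row usages sum to 1.
    """
    seqs = list(seqs)
    if n_motifs is None:
        n_motifs = max(int(s.labels.max()) for s in seqs) + 1
    communities = sorted(set(partition.values()))
    col_of = {c: (labels[c] if labels and c in labels else f"community_{c}") for c in communities}
    rows = []
    for s in seqs:
        observed = np.unique(s.labels)
        missing = [int(m) for m in observed if int(m) not in partition]
        if missing:
            raise ValueError(f"motifs missing from partition: {missing}")
        usage = motif_usage(s, n_motifs)
        row: dict = {"mouse_id": s.mouse_id, "group": s.group, "condition": s.condition}
        for c in communities:
            member = [m for m, ci in partition.items() if ci == c and m < n_motifs]
            row[col_of[c]] = float(usage[member].sum())
        rows.append(row)
    return pd.DataFrame(rows)


def group_compare(usage: pd.DataFrame) -> pd.DataFrame:
    """Standard community-usage comparisons across the 2x2 design.

    Per community: Welch's unpaired t-test of control vs stress within each
    condition, and a paired t-test of saline vs CNO within each group (a
    mouse missing either condition is dropped from the paired test with a
    warning). Returns a tidy DataFrame of test rows with mean difference,
    statistic, p-value and sample sizes.
    """
    design_cols = {"mouse_id", "group", "condition"}
    value_cols = [c for c in usage.columns if c not in design_cols]
    rows = []
    conditions = sorted(usage["condition"].unique())
    groups = sorted(usage["group"].unique())
    for col in value_cols:
        for cond in conditions:
            sub = usage[usage["condition"] == cond]
            if len(groups) == 2:
                a = sub.loc[sub["group"] == groups[0], col].to_numpy()
                b = sub.loc[sub["group"] == groups[1], col].to_numpy()
                if len(a) >= 2 and len(b) >= 2:
                    if np.ptp(np.concatenate([a, b])) == 0:
                        t, p, df = 0.0, 1.0, float(len(a) + len(b) - 2)
                    else:
                        res = stats.ttest_ind(a, b, equal_var=False)
                        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
                    rows.append(
                        {
                            "community": col,
                            "test": "welch_unpaired",
                            "comparison": f"{groups[0]} vs {groups[1]} ({cond})",
                            "mean_diff": float(np.mean(a) - np.mean(b)),
                            "statistic": t,
                            "p_value": p,
                            "n_a": len(a),
                            "n_b": len(b),
                        }
                    )
        if len(conditions) == 2:
            c0, c1 = conditions
            for group in groups:
                sub = usage[usage["group"] == group]
                wide = sub.pivot_table(index="mouse_id", columns="condition", values=col)
                complete = wide.dropna()
                dropped = len(wide) - len(complete)
                if dropped:
                    warnings.warn(
                        f"{dropped} mice missing a condition dropped from paired "
                        f"comparison of {col!r} in group {group!r}"
                    )
                if len(complete) >= 2:
                    a, b = complete[c0].to_numpy(), complete[c1].to_numpy()
                    if np.ptp(a - b) == 0 and np.allclose(a, b):
                        t, p = 0.0, 1.0
                    else:
                        res = stats.ttest_rel(a, b)
                        t, p = float(res.statistic), float(res.pvalue)
                    rows.append(
                        {
                            "community": col,
                            "test": "paired",
                            "comparison": f"{c0} vs {c1} ({group})",
                            "mean_diff": float(np.mean(a) - np.mean(b)),
                            "statistic": t,
                            "p_value": p,
                            "n_a": len(complete),
                            "n_b": len(complete),
                        }
                    )
    return pd.DataFrame(rows)


class CommunityModel:
    """Community model over a collection of motif-label sequences."""

    def __init__(self, seqs: Sequence[MotifSequence], n_motifs: int, collapse: bool = True):
        if len(seqs) == 0:
            raise ValueError("need at least one sequence")
        self.seqs = list(seqs)
        self.n_motifs = int(n_motifs)
        self.collapse = collapse

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_motifs: int, frame_rate: float = 60.0, **kw):
        """Build from a long table with columns mouse_id, group, condition, frame, motif."""
        seqs = []
        for (mouse, group, cond), sub in df.groupby(["mouse_id", "group", "condition"]):
            sub = sub.sort_values("frame")
            seqs.append(
                MotifSequence(str(mouse), str(group), str(cond), sub["motif"].to_numpy(), frame_rate)
            )
        return cls(seqs, n_motifs, **kw)

    def fit(self, n_communities: int = 8, labels: Mapping[int, str] | None = None) -> "CommunityResults":
        tm = pooled_transition_matrix(self.seqs, self.n_motifs, collapse=self.collapse)
        tree = build_community_tree(tm)
        pruned = prune_tree(tree, n_communities)
        if labels:
            pruned.labels = dict(labels)
        return CommunityResults(self, tm, pruned)


class CommunityResults:
    """Fitted community structure plus usage tables and comparisons."""

    def __init__(self, model: CommunityModel, transition: TransitionMatrix, tree: CommunityTree):
        self.model = model
        self.transition = transition
        self.tree = tree

    @property
    def partition(self) -> dict[int, int]:
        return dict(self.tree.partition)

    def motif_usage_table(self) -> pd.DataFrame:
        rows = []
        for s in self.model.seqs:
            usage = motif_usage(s, self.model.n_motifs)
            row = {"mouse_id": s.mouse_id, "group": s.group, "condition": s.condition}
            row.update({f"motif_{m}": usage[m] for m in range(self.model.n_motifs)})
            rows.append(row)
        return pd.DataFrame(rows)

    def community_usage_table(self) -> pd.DataFrame:
        return community_usage(
            self.model.seqs, self.tree.partition, self.model.n_motifs, self.tree.labels
        )

    def compare(self) -> pd.DataFrame:
        return group_compare(self.community_usage_table())

    def summary(self) -> str:
        part = self.tree.partition
        n_comm = self.tree.n_communities
        lines = [
            "Behavioral community summary",
            f"  sequences: {len(self.model.seqs)}   motifs: {self.model.n_motifs}   "
            f"communities: {n_comm}",
            f"  transitions observed: {int(self.transition.row_counts.sum())}"
            f"   motifs without outgoing transitions: {len(self.transition.empty_rows)}",
        ]
        by_comm: dict[int, list[int]] = {}
        for m, c in part.items():
            by_comm.setdefault(c, []).append(m)
        usage = self.community_usage_table()
        design_cols = {"mouse_id", "group", "condition"}
        for c in sorted(by_comm):
            name = (self.tree.labels or {}).get(c, f"community_{c}")
            members = sorted(by_comm[c])
            col = name if name in usage.columns else f"community_{c}"
            mean_pct = 100.0 * usage[col].mean() if col in usage.columns else float("nan")
            lines.append(f"  {name:>24s}: motifs {members}  mean usage {mean_pct:.1f}%")
        return "\n".join(lines)
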