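"""Redundancy reduction by identity clustering of TMD+flank subsequences.

Pairwise identity comes from an optimal global alignment under a
match=1 / mismatch=0 / gap=-1 (per gap position) scoring scheme; among
co-optimal alignments the one with the most matches is used, which makes
the identity fraction a well-defined function of the sequence pair.
Records whose candidate subsequences are connected by a chain of pairs
above the identity threshold share a cluster (single linkage), and the
longest member (ties: lexicographically smallest id) represents it.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

# Alignment scoring constants (config-exposed via keyword arguments).
MATCH_SCORE = 1
MISMATCH_SCORE = 0
GAP_PENALTY = 1


def pairwise_identity(
    seq_a: str,
    seq_b: str,
    match: int = MATCH_SCORE,
    mismatch: int = MISMATCH_SCORE,
    gap: int = GAP_PENALTY,
) -> float:
    """Fraction of identical positions in the optimal global alignment.

    The DP maximizes (alignment score, number of matches)
    lexicographically, so the reported identity does not depend on
    traceback tie-breaking. Identity = matches / alignment length, where
    the alignment length counts match, mismatch and gap columns.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    n, m = len(seq_a), len(seq_b)
    NEG = (float("-inf"), 0)
    # dp[j] = (best score, most matches at that score) for prefix alignment
    prev = [(-gap * j, 0) for j in range(m + 1)]
    for i in range(1, n + 1):
        curr = [NEG] * (m + 1)
        curr[0] = (-gap * i, 0)
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            is_match = ai == seq_b[j - 1]
            ds, dm = prev[j - 1]
            diag = (
                ds + (match if is_match else mismatch),
                dm + (1 if is_match else 0),
            )
            us, um = prev[j]
            up = (us - gap, um)
            ls, lm = curr[j - 1]
            left = (ls - gap, lm)
            curr[j] = max(diag, up, left)
        prev = curr
    score, matches = prev[m]
    # With mismatch=0 and unit gaps: score = ma - (n + m - 2M)  with
    # M = aligned pairs, so M and the alignment length are determined.
    if mismatch != 0 or gap == 0:
        raise ValueError("identity is only well-defined for mismatch=0 and gap!=0")
    aligned_pairs = (score / gap - matches * match / gap + n + m) / 2
    alignment_length = n + m - aligned_pairs
    return matches / alignment_length


@dataclasses.dataclass
class ClusterSet:
    """A partition of record ids with one representative per cluster."""

    clusters: list[frozenset[str]]
    representatives: list[str]
    threshold: float

    def __post_init__(self) -> None:
        all_ids = [i for c in self.clusters for i in c]
        if len(all_ids) != len(set(all_ids)):
            raise ValueError("clusters must be disjoint")
        for cluster, rep in zip(self.clusters, self.representatives):
            if rep not in cluster:
                raise ValueError(f"representative {rep!r} not in its cluster")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster(
    sequences: Mapping[str, str],
    threshold: float = 0.30,
    **identity_kwargs,
) -> ClusterSet:
    """Single-linkage clustering at the given identity threshold.

    ``sequences`` maps record id -> candidate (TMD+flank) subsequence.
    Two records share a cluster iff connected by a chain of pairs with
    identity strictly greater than ``threshold``. The representative of a
    cluster is its longest sequence (ties: smallest id). Clusters are
    ordered by their smallest member id.
    """
    ids = sorted(sequences)
    if not ids:
        raise ValueError("cluster requires at least one record")
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            if find(id_a) == find(id_b):
                continue
            if pairwise_identity(sequences[id_a], sequences[id_b], **identity_kwargs) > threshold:
                parent[find(id_b)] = find(id_a)

    groups: dict[str, set[str]] = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    clusters = sorted(groups.values(), key=min)
    representatives = [
        min(c, key=lambda i: (-len(sequences[i]), i)) for c in clusters
    ]
    return ClusterSet(
        clusters=[frozenset(c) for c in clusters],
        representatives=representatives,
        threshold=threshold,
    )


def select_representatives(
    clusterset: ClusterSet, records: Sequence
) -> list:
    """One record per cluster, ordered by record id."""
    by_id = {r.id: r for r in records}
    missing = [r for r in clusterset.representatives if r not in by_id]
    if missing:
        raise KeyError(f"representative id(s) not among records: {missing}")
    return sorted(
        (by_id[r] for r in clusterset.representatives), key=lambda r: r.id
    )
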