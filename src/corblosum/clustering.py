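"""Pairwise-identity clustering of block sequences under the three variants.

The BLOSUM family down-weights redundant sequences by merging, within each
block, all sequences that share at least a user-chosen percent identity
(the "clustering value" C) into clusters.  The historical 1992 C code
computes the minimum identity *count* for a block of width w as the integer
truncation of C*w/100: at w=93 and C=62 the real threshold is 57.66
identical residues, but the code requires only 57, an effective clustering
value of 61.29 % — sequence pairs can be linked even though they fall short
of the requested threshold.  The corrected policy instead takes the
smallest integer k with 100*k >= C*w, evaluated in exact integer
arithmetic.

Three named variants combine the threshold fix with the cluster-membership
fix of the single-linkage step:

============  ==================  =======================
variant       threshold           linkage
============  ==================  =======================
BLOSUM        legacy_truncated    legacy_single_pass
RBLOSUM       legacy_truncated    fixpoint_single_linkage
CorBLOSUM     exact_fractional    fixpoint_single_linkage
============  ==================  =======================

``fixpoint_single_linkage`` is the transitive closure of the relation
identity(i, j) >= k_min and is invariant under reordering of the block's
sequences.  ``legacy_single_pass`` emulates the order-dependent behaviour
of the historical code: one sweep in file order, joining each sequence to
the first earlier cluster any member of which it matches, without
re-evaluating earlier sequences against grown clusters.  It is exposed
behind a policy interface so a byte-faithful port of the historical code
can be swapped in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .blocks_io import Block

THRESHOLD_MODES = ("legacy_truncated", "exact_fractional")
LINKAGE_MODES = ("fixpoint_single_linkage", "legacy_single_pass")
VARIANTS = ("BLOSUM", "RBLOSUM", "CorBLOSUM")


def _as_fraction(percent) -> Fraction:
    # str() round-trip keeps user-facing decimals exact (62.5 -> 125/2),
    # avoiding binary-float artifacts in the integer comparison.
    if isinstance(percent, Fraction):
        return percent
    if isinstance(percent, float):
        return Fraction(str(percent))
    return Fraction(percent)


@dataclass(frozen=True)
class ThresholdPolicy:
    """How the percent clustering value C maps to an integer identity count.

    ``legacy_truncated``: k_min = trunc(C*w/100), the historical rule.
    ``exact_fractional``: k_min = smallest k with 100*k >= C*w, evaluated
    with integer (rational) arithmetic so the exact boundary is never
    decided by floating point.
    """

    mode: str
    clustering_percent: Fraction

    def __post_init__(self):
        object.__setattr__(
            self, "clustering_percent", _as_fraction(self.clustering_percent)
        )
        if self.mode not in THRESHOLD_MODES:
            raise ValueError(f"unknown threshold mode {self.mode!r}")
        if not (0 < self.clustering_percent <= 100):
            raise ValueError("clustering_percent must be in (0, 100]")


@dataclass(frozen=True)
class LinkagePolicy:
    mode: str

    def __post_init__(self):
        if self.mode not in LINKAGE_MODES:
            raise ValueError(f"unknown linkage mode {self.mode!r}")


@dataclass(frozen=True)
class VariantConfig:
    """A named variant bound to its threshold and linkage policies."""

    variant: str
    threshold_policy: ThresholdPolicy
    linkage_policy: LinkagePolicy

    @classmethod
    def for_variant(cls, variant: str, clustering_percent) -> "VariantConfig":
        """Build the canonical policy combination for a variant name."""
        v = variant.upper().replace("CORBLOSUM", "CorBLOSUM")
        if v == "CORBLOSUM":  # pragma: no cover - normalized above
            v = "CorBLOSUM"
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
        threshold = {
            "BLOSUM": "legacy_truncated",
            "RBLOSUM": "legacy_truncated",
            "CorBLOSUM": "exact_fractional",
        }[v]
        linkage = {
            "BLOSUM": "legacy_single_pass",
            "RBLOSUM": "fixpoint_single_linkage",
            "CorBLOSUM": "fixpoint_single_linkage",
        }[v]
        return cls(v, ThresholdPolicy(threshold, clustering_percent),
                   LinkagePolicy(linkage))


@dataclass
class ClusterPartition:
    """Assignment of a block's sequence indices to clusters."""

    block_id: str
    cluster_of: dict[int, int]
    sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.sizes:
            sizes: dict[int, int] = {}
            for c in self.cluster_of.values():
                sizes[c] = sizes.get(c, 0) + 1
            self.sizes = sizes

    @property
    def n_clusters(self) -> int:
        return len(self.sizes)

    def as_sets(self) -> frozenset[frozenset[int]]:
        """Label-free view for order-invariance comparisons."""
        members: dict[int, set[int]] = {}
        for i, c in self.cluster_of.items():
            members.setdefault(c, set()).add(i)
        return frozenset(frozenset(s) for s in members.values())


def pairwise_identity(seg_a: str, seg_b: str) -> int:
    """Number of positions at which two equal-length segments carry the
    exact same character (case-normalized).

    Identity is a plain string property: non-standard letters count when
    equal (X matches X).  Alphabet filtering belongs to pair counting.
    """
    if len(seg_a) != len(seg_b):
        raise ValueError(
            f"segments differ in length ({len(seg_a)} vs {len(seg_b)})"
        )
    a, b = seg_a.upper(), seg_b.upper()
    return sum(1 for x, y in zip(a, b) if x == y)


def identity_threshold(width: int, policy: ThresholdPolicy) -> int:
    """Minimum integer identity count linking two sequences, per policy."""
    if width < 1:
        raise ValueError("width must be >= 1")
    exact = policy.clustering_percent * width / 100  # Fraction
    if policy.mode == "legacy_truncated":
        return math.floor(exact)
    return math.ceil(exact)


def exact_threshold_residues(width: int, policy: ThresholdPolicy) -> float:
    """The real-valued identity requirement C*w/100 (e.g. 57.66 at w=93,
    C=62) before any integer policy is applied."""
    return float(policy.clustering_percent * width / 100)


def effective_clustering_percent(width: int, policy: ThresholdPolicy) -> float:
    """The percent identity actually enforced: 100*k_min/width, to 2 decimals."""
    k = identity_threshold(width, policy)
    return round(float(Fraction(100 * k, width)), 2)


def _identity_matrix(block: Block) -> np.ndarray:
    arr = np.array(
        [np.frombuffer(seg.encode("ascii"), dtype=np.uint8)
         for _, seg in block.segments]
    )
    n = arr.shape[0]
    ident = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        ident[i] = (arr == arr[i]).sum(axis=1)
    return ident


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_block(block: Block, config: VariantConfig) -> ClusterPartition:
    """Partition a block's sequences into clusters under the variant policy.

    A singleton block yields one singleton cluster.  In fixpoint mode the
    partition is the transitive closure of the >=k_min relation and does
    not depend on segment order; in legacy mode it deliberately does.
    """
    n = block.n_sequences
    k_min = identity_threshold(block.width, config.threshold_policy)
    if n == 1:
        return ClusterPartition(block.block_id, {0: 0})
    ident = _identity_matrix(block)

    if config.linkage_policy.mode == "fixpoint_single_linkage":
        uf = _UnionFind(n)
        for i in range(n):
            for j in range(i + 1, n):
                if ident[i, j] >= k_min:
                    uf.union(i, j)
        roots: dict[int, int] = {}
        cluster_of = {}
        for i in range(n):
            r = uf.find(i)
            cluster_of[i] = roots.setdefault(r, len(roots))
        return ClusterPartition(block.block_id, cluster_of)

    # legacy_single_pass: one sweep in file order; join the first earlier
    # cluster containing any matching member; clusters never merge.
    clusters: list[list[int]] = []
    cluster_of = {}
    for i in range(n):
        placed = False
        for c_idx, members in enumerate(clusters):
            if any(ident[i, m] >= k_min for m in members):
                members.append(i)
                cluster_of[i] = c_idx
                placed = True
                break
        if not placed:
            cluster_of[i] = len(clusters)
            clusters.append([i])
    return ClusterPartition(block.block_id, cluster_of)
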