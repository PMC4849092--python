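"""Synthetic fixtures with planted ground truth, plus brute-force oracles.

Two generator families back the test suite and worked examples:

* :func:`generate_block` plants exact pairwise identity counts — each
  derived sequence differs from a master sequence at an exact number of
  positions, each mutated position receiving a uniformly chosen *different*
  residue, so identity(master, derived) = width - mutation_count holds by
  construction.

* :func:`generate_scenario` plants a superfamily partition together with a
  closed-form quadratic coverage: per superfamily a chosen fraction of the
  possible ordered true-positive relations is emitted, plus a chosen number
  of cross-superfamily false positives.  E-values are drawn log-uniformly
  in [1e-50, 10] and rank-adjusted so every planted true positive sorts
  below every false positive, which makes the planted coverage recoverable
  exactly under errors-per-query filtering.

The brute-force oracles re-derive the matrix pipeline and the coverage
equations directly from their definitions with naive enumeration (exact
rational pair weights, explicit pair loops).  They are deliberately slow
and independent of the optimized implementations they are tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .blocks_io import ALPHABET, Block
from .clustering import VariantConfig, identity_threshold
from .coverage_eval import Relation, SuperfamilyMap
from .matrix_builder import round_half_away_from_zero


@dataclass(frozen=True)
class BlockSpec:
    """Recipe for one block with planted identities to a master sequence."""

    width: int
    mutation_counts: tuple[int, ...]
    seed: int
    block_id: str = "synthetic"
    master: str | None = None

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("width must be >= 1")
        for m in self.mutation_counts:
            if not (0 <= m <= self.width):
                raise ValueError(
                    f"mutation count {m} outside [0, width={self.width}]"
                )
        if self.master is not None and len(self.master) != self.width:
            raise ValueError("master length must equal width")


def generate_block(spec: BlockSpec) -> Block:
    """Deterministically generate a block from its spec.

    The first segment is the master; segment k+1 differs from it at exactly
    ``mutation_counts[k]`` positions.
    """
    rng = np.random.default_rng(spec.seed)
    aa = np.array(list(ALPHABET))
    if spec.master is None:
        master = "".join(rng.choice(aa, size=spec.width))
    else:
        master = spec.master.upper()
    segments = [("master", master)]
    for k, m in enumerate(spec.mutation_counts):
        seq = list(master)
        positions = rng.choice(spec.width, size=m, replace=False)
        for pos in positions:
            choices = [c for c in ALPHABET if c != seq[pos]]
            seq[pos] = choices[rng.integers(len(choices))]
        segments.append((f"seq{k + 1}", "".join(seq)))
    return Block(spec.block_id, spec.width, segments)


def random_blocks(
    rng: np.random.Generator,
    n_blocks: int = 2,
    max_sequences: int = 6,
    max_width: int = 12,
) -> list[Block]:
    """Small random block databases for oracle-equivalence testing.

    Sequences are correlated (mutated copies of a per-block master) so that
    clustering at moderate thresholds is non-trivial.
    """
    blocks = []
    for b in range(n_blocks):
        width = int(rng.integers(3, max_width + 1))
        n_seq = int(rng.integers(2, max_sequences + 1))
        counts = tuple(int(rng.integers(0, width + 1)) for _ in range(n_seq - 1))
        spec = BlockSpec(width, counts, seed=int(rng.integers(2**31)),
                         block_id=f"rb{b}")
        blocks.append(generate_block(spec))
    return blocks


@dataclass(frozen=True)
class ScenarioSpec:
    """Recipe for a search-result scenario with planted coverage.

    ``tp_fractions[i]`` must make fraction * (s_i^2 - s_i) an integer for
    superfamilies of size s_i >= 2 so the planted coverage is exact.
    """

    sizes: tuple[int, ...]
    tp_fractions: tuple[float, ...]
    n_false_positives: int
    seed: int

    def __post_init__(self):
        if len(self.sizes) != len(self.tp_fractions):
            raise ValueError("sizes and tp_fractions must align")
        if not any(s >= 2 for s in self.sizes):
            raise ValueError("at least one superfamily must have size >= 2")
        for s, f in zip(self.sizes, self.tp_fractions):
            if not (0.0 <= f <= 1.0):
                raise ValueError("tp fractions must lie in [0, 1]")
            if s >= 2:
                k = f * (s * s - s)
                if abs(k - round(k)) > 1e-9:
                    raise ValueError(
                        f"fraction {f} of {s*s - s} possible relations is "
                        f"not an integer"
                    )


def generate_scenario(
    spec: ScenarioSpec,
) -> tuple[list[Relation], SuperfamilyMap, float]:
    """Generate ``(relations, superfamily map, planted Q_quad)``.

    Domains are named ``d0000, d0001, ...``; superfamily labels are sccs
    prefixes ``a.<i>.1``.  All true positives sort below all false
    positives by E-value, so the planted coverage is recovered whenever the
    errors-per-query budget admits every true positive.
    """
    rng = np.random.default_rng(spec.seed)
    label_of: dict[str, str] = {}
    members: list[list[str]] = []
    idx = 0
    for i, s in enumerate(spec.sizes):
        label = f"a.{i + 1}.1"
        group = []
        for _ in range(s):
            dom = f"d{idx:04d}"
            label_of[dom] = label
            group.append(dom)
            idx += 1
        members.append(group)
    smap = SuperfamilyMap(label_of)

    tp_pairs: list[tuple[str, str]] = []
    planted_terms = []
    for group, frac, s in zip(members, spec.tp_fractions, spec.sizes):
        if s < 2:
            continue
        pairs = [(q, t) for q in group for t in group if q != t]
        k = int(round(frac * len(pairs)))
        chosen = rng.choice(len(pairs), size=k, replace=False) if k else []
        tp_pairs.extend(pairs[j] for j in sorted(int(c) for c in chosen))
        planted_terms.append(k / len(pairs))
    S = len(planted_terms)
    planted_q = (sum(planted_terms) / S) if S else 0.0

    all_domains = list(smap.domains)
    fp_pairs: set[tuple[str, str]] = set()
    while len(fp_pairs) < spec.n_false_positives:
        q, t = rng.choice(all_domains, size=2, replace=False)
        if label_of[q] != label_of[t]:
            fp_pairs.add((str(q), str(t)))
    fp_list = sorted(fp_pairs)
    rng.shuffle(fp_list)

    n_total = len(tp_pairs) + len(fp_list)
    evalues = np.sort(10.0 ** rng.uniform(-50, 1, size=n_total))
    relations = [
        Relation(float(evalues[r]), q, t)
        for r, (q, t) in enumerate(tp_pairs + fp_list)
    ]
    return sorted(relations), smap, planted_q


def relations_to_tabular(relations: list[Relation]) -> str:
    """Render relations as 12-column BLAST-tabular text."""
    lines = [
        f"{r.query_id}\t{r.subject_id}\t90.0\t100\t0\t0\t1\t100\t1\t100\t"
        f"{r.evalue!r}\t200.0"
        for r in relations
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def annotations_to_fasta(smap: SuperfamilyMap) -> str:
    """Render a superfamily map as ASTRAL-style FASTA (dummy sequences)."""
    out = []
    for dom in smap.domains:
        out.append(f">{dom} {smap.label_of[dom]}.1 (A:) synthetic domain")
        out.append("MSYNTHETIC")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Brute-force oracles, coded directly from the definitions.
# ---------------------------------------------------------------------------

def _oracle_identity(a: str, b: str) -> int:
    count = 0
    for x, y in zip(a.upper(), b.upper()):
        if x == y:
            count += 1
    return count


def _oracle_k_min(width: int, percent: Fraction, mode: str) -> int:
    percent = Fraction(str(percent)) if not isinstance(percent, Fraction) \
        else percent
    if mode == "legacy_truncated":
        return int(percent * width / 100)  # int() truncates a Fraction
    for k in range(width + 1):  # smallest k with 100k >= C*w
        if 100 * k >= percent * width:
            return k
    return width


def oracle_cluster(block: Block, config: VariantConfig) -> list[set[int]]:
    """Naive clustering: pair loops plus, in fixpoint mode, repeated merge
    passes until no pair of clusters is linked any more."""
    n = block.n_sequences
    k_min = _oracle_k_min(
        block.width, config.threshold_policy.clustering_percent,
        config.threshold_policy.mode,
    )
    segs = [s for _, s in block.segments]
    linked = {
        (i, j): _oracle_identity(segs[i], segs[j]) >= k_min
        for i in range(n) for j in range(n) if i != j
    }
    if config.linkage_policy.mode == "fixpoint_single_linkage":
        clusters = [{i} for i in range(n)]
        changed = True
        while changed:
            changed = False
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    if any(linked[(i, j)] for i in clusters[a]
                           for j in clusters[b]):
                        clusters[a] |= clusters[b]
                        del clusters[b]
                        changed = True
                        break
                if changed:
                    break
        return clusters
    clusters = []
    for i in range(n):
        for c in clusters:
            if any(linked[(i, m)] for m in c):
                c.add(i)
                break
        else:
            clusters.append({i})
    return clusters


def oracle_pipeline(
    blocks: list[Block],
    config: VariantConfig,
    scale_denominator: int,
    pseudocount: Fraction | float = 0,
) -> dict:
    """Whole matrix pipeline with exact rational pair weights.

    Returns ``{"counts", "q", "p", "e", "entropy", "scores"}`` where counts
    and frequencies are keyed by sorted residue pairs as
    :class:`~fractions.Fraction` values, and scores is the integer grid as
    a dict keyed by (a, b) pairs.
    """
    counts: dict[tuple[str, str], Fraction] = {}
    for block in blocks:
        clusters = oracle_cluster(block, config)
        cluster_of = {}
        for ci, members in enumerate(clusters):
            for m in members:
                cluster_of[m] = ci
        sizes = [len(c) for c in clusters]
        segs = [s for _, s in block.segments]
        n = len(segs)
        for x in range(n):
            for y in range(x + 1, n):
                cx, cy = cluster_of[x], cluster_of[y]
                if cx == cy:
                    continue
                w = Fraction(1, sizes[cx] * sizes[cy])
                for col in range(block.width):
                    a, b = segs[x][col], segs[y][col]
                    if a not in ALPHABET or b not in ALPHABET:
                        continue
                    key = (a, b) if a <= b else (b, a)
                    counts[key] = counts.get(key, Fraction(0)) + w
    if pseudocount:
        eps = Fraction(str(pseudocount))
        for i, a in enumerate(ALPHABET):
            for b in ALPHABET[i:]:
                key = (a, b) if a <= b else (b, a)
                counts[key] = counts.get(key, Fraction(0)) + eps
    total = sum(counts.values(), Fraction(0))
    if total == 0:
        raise ValueError("oracle: empty counts")
    q = {k: v / total for k, v in counts.items()}
    p: dict[str, Fraction] = {a: Fraction(0) for a in ALPHABET}
    for (a, b), qv in q.items():
        if a == b:
            p[a] += qv
        else:
            p[a] += qv / 2
            p[b] += qv / 2
    e: dict[tuple[str, str], Fraction] = {}
    for i, a in enumerate(ALPHABET):
        for b in ALPHABET[i:]:
            key = (a, b) if a <= b else (b, a)
            e[key] = p[a] * p[b] if a == b else 2 * p[a] * p[b]
    entropy = 0.0
    for key, qv in q.items():
        if qv > 0:
            entropy += float(qv) * math.log2(float(qv / e[key]))
    scores: dict[tuple[str, str], int] = {}
    nsc = scale_denominator
    for key, qv in q.items():
        s = nsc * math.log2(float(qv / e[key]))
        scores[key] = round_half_away_from_zero(s)
    return {"counts": counts, "q": q, "p": p, "e": e,
            "entropy": entropy, "scores": scores}


def oracle_coverage(
    relations: list[Relation],
    smap: SuperfamilyMap,
    epq_limit: float,
    weights: dict[str, float] | None = None,
) -> float:
    """Quadratic coverage by direct enumeration of every prefix cutoff.

    With weights, implements the weighted selection and the bootstrap
    coverage equations with explicit double loops.
    """
    w = weights or {d: 1.0 for d in smap.domains}
    rels = sorted(relations)
    total_w = sum(w[d] for d in smap.domains)
    budget = epq_limit * total_w
    best_m = 0
    for m in range(len(rels) + 1):  # largest prefix within the FP budget
        fp_mass = 0.0
        for r in rels[:m]:
            if smap.label_of[r.query_id] != smap.label_of[r.subject_id]:
                fp_mass += w[r.query_id] * w[r.subject_id]
        if fp_mass <= budget:
            best_m = m
    retained = rels[:best_m]
    by_label: dict[str, list[str]] = {}
    for d in smap.domains:
        by_label.setdefault(smap.label_of[d], []).append(d)
    terms = []
    for label in sorted(by_label):
        group = by_label[label]
        if len(group) < 2:
            continue
        w_i = 0.0
        for k in group:
            for l in group:
                w_i += w[k] * w[l]
        w_i -= sum(w[k] ** 2 for k in group)
        q_i = 0.0
        for r in retained:
            if (smap.label_of[r.query_id] == label
                    and smap.label_of[r.subject_id] == label):
                q_i += w[r.query_id] * w[r.subject_id]
        if w_i > 0:
            terms.append(q_i / w_i)
    return sum(terms) / len(terms) if terms else 0.0
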