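"""From clustered blocks to weighted pair counts, frequencies and log-odds.

Pair counting follows the classical block-substitution construction:
within every block and alignment column, each pair of sequences lying in
*different* clusters contributes 1/(|cluster_u| * |cluster_v|) to the count
of its residue pair; within-cluster pairs contribute nothing.  Counts are
accumulated over all blocks and normalized globally into joint frequencies
q_ij, marginals p_i and expected frequencies e_ij (e_ii = p_i^2,
e_ij = 2 p_i p_j).  Scores are log-odds log2(q_ij/e_ij) expressed in 1/n-bit
units and rounded to the nearest integer, half away from zero; the relative
entropy H = sum q_ij log2(q_ij/e_ij) (in bits) summarizes how far the joint
distribution is from independence and determines the customary scale n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .blocks_io import ALPHABET, EXTENSIONS, Block
from .clustering import ClusterPartition, VariantConfig, cluster_block
from .errors import EmptyCountsError, ZeroFrequencyError

N_AA = len(ALPHABET)
N_PAIRS = N_AA * (N_AA + 1) // 2  # 210 unique entries of the 20x20 grid


@dataclass
class FrequencyTable:
    """Weighted pair counts and the frequencies derived from them.

    All four grids are stored as full symmetric 20x20 arrays in canonical
    alphabet order.  Off-diagonal entries hold the *full* unordered-pair
    quantity (so the unique-entry sums run over the upper triangle plus the
    diagonal): sum_{i<=j} q_ij = 1 and sum_{i<=j} e_ij = 1, while
    p_i = q_ii + sum_{j!=i} q_ij / 2.
    """

    counts: np.ndarray
    q: np.ndarray | None = None
    p: np.ndarray | None = None
    e: np.ndarray | None = None

    def total_count(self) -> float:
        c = self.counts
        return float(np.trace(c) + np.triu(c, 1).sum())


def accumulate_pair_counts(
    blocks: list[Block], partitions: list[ClusterPartition]
) -> np.ndarray:
    """Accumulate cluster-weighted residue pair counts over all blocks.

    Returns the symmetric 20x20 count grid.  Positions where either
    residue falls outside the 20-letter alphabet are skipped; the weight
    denominator remains the full cluster size.  Raises
    :class:`EmptyCountsError` when no cross-cluster pair exists anywhere.
    """
    if len(blocks) != len(partitions):
        raise ValueError("blocks and partitions must align 1:1")
    counts = np.zeros((N_AA, N_AA), dtype=np.float64)
    for block, part in zip(blocks, partitions):
        if block.n_sequences < 2 or part.n_clusters < 2:
            continue
        res = block.residue_matrix()  # (n, w); -1 marks non-standard
        cl = np.array([part.cluster_of[i] for i in range(block.n_sequences)])
        sizes = np.array([part.sizes[c] for c in range(part.n_clusters)],
                         dtype=np.float64)
        k = part.n_clusters
        for col in range(block.width):
            r = res[:, col]
            valid = r >= 0
            if valid.sum() < 2:
                continue
            # per-cluster residue tallies, each row scaled by cluster size
            tal = np.zeros((k, N_AA), dtype=np.float64)
            np.add.at(tal, (cl[valid], r[valid]), 1.0)
            f = tal / sizes[:, None]
            total = f.sum(axis=0)
            # ordered cross-cluster pair mass; halve the diagonal to count
            # unordered pairs once
            g = np.outer(total, total) - f.T @ f
            g[np.diag_indices(N_AA)] *= 0.5
            counts += g
    total = float(np.trace(counts) + np.triu(counts, 1).sum())
    if total <= 0:
        raise EmptyCountsError(
            "no cross-cluster sequence pair contributed any count; every "
            "block collapsed into a single cluster"
        )
    # clip tiny negative dust from the outer-product rearrangement
    np.clip(counts, 0, None, out=counts)
    return counts


def counts_to_frequencies(counts: np.ndarray, pseudocount: float = 0.0) -> FrequencyTable:
    """Normalize counts into joint, marginal and expected frequencies.

    ``pseudocount`` (epsilon > 0) is added to all 210 unique cells before
    normalization; intended only for toy inputs that would otherwise carry
    zero-frequency pairs.
    """
    c = np.asarray(counts, dtype=np.float64).copy()
    if c.shape != (N_AA, N_AA):
        raise ValueError(f"counts must be {N_AA}x{N_AA}")
    if pseudocount:
        c += pseudocount
    total = float(np.trace(c) + np.triu(c, 1).sum())
    if total <= 0:
        raise EmptyCountsError("total pair count is zero")
    q = c / total
    diag = np.diag(q)
    p = diag + (q.sum(axis=1) - diag) / 2.0
    e = 2.0 * np.outer(p, p)
    np.fill_diagonal(e, p * p)
    return FrequencyTable(counts=c, q=q, p=p, e=e)


def relative_entropy(freq: FrequencyTable) -> float:
    """Relative entropy H = sum_{i<=j, q>0} q_ij log2(q_ij / e_ij), in bits."""
    q, e = freq.q, freq.e
    iu = np.triu_indices(N_AA)
    qs, es = q[iu], e[iu]
    mask = qs > 0
    return float(np.sum(qs[mask] * np.log2(qs[mask] / es[mask])))


def round_half_away_from_zero(x: float) -> int:
    """Nearest integer, ties away from zero (matches published BLOSUM grids
    at sign boundaries, unlike banker's rounding)."""
    return int(math.floor(x + 0.5)) if x >= 0 else int(math.ceil(x - 0.5))


_round_vec = np.vectorize(round_half_away_from_zero, otypes=[np.int64])


@dataclass
class SubstitutionMatrix:
    """Integer log-odds matrix plus the unrounded scores and metadata."""

    variant: str
    clustering_percent: float
    scale_denominator: int
    unrounded_scores: np.ndarray
    scores: np.ndarray
    relative_entropy_bits: float
    alphabet: tuple[str, ...] = ALPHABET
    extended_scores: np.ndarray | None = None  # 24x24 incl. B Z X *
    extended_alphabet: tuple[str, ...] | None = None
    metadata: dict = field(default_factory=dict)


def log_odds_scores(
    freq: FrequencyTable,
    scale_denominator: int,
    variant: str = "custom",
    clustering_percent: float = float("nan"),
) -> SubstitutionMatrix:
    """Score s_ij = n * log2(q_ij / e_ij); integers rounded half away from zero.

    Raises :class:`ZeroFrequencyError` listing the missing pairs when any of
    the 210 unique joint frequencies is zero (apply a pseudocount in
    :func:`counts_to_frequencies` for toy inputs).
    """
    n = int(scale_denominator)
    if n < 1:
        raise ValueError("scale_denominator must be a positive integer")
    q, e = freq.q, freq.e
    iu, ju = np.triu_indices(N_AA)
    zero = q[iu, ju] <= 0
    if zero.any():
        missing = [(ALPHABET[i], ALPHABET[j])
                   for i, j in zip(iu[zero], ju[zero])]
        raise ZeroFrequencyError(missing)
    unrounded = n * np.log2(q / e)
    scores = _round_vec(unrounded)
    return SubstitutionMatrix(
        variant=variant,
        clustering_percent=clustering_percent,
        scale_denominator=n,
        unrounded_scores=unrounded,
        scores=scores,
        relative_entropy_bits=relative_entropy(freq),
    )


def suggest_scale(entropy_bits: float) -> int:
    """Customary 1/n-bit scale for a given relative entropy.

    Step function consistent with the published pairing of entropies to bit
    units: H >= 0.60 -> 2; 0.30 <= H < 0.60 -> 3; 0.20 <= H < 0.30 -> 4;
    H < 0.20 -> 5.  A user-supplied n always overrides this convenience.
    """
    if entropy_bits <= 0:
        raise ValueError("entropy must be positive")
    if entropy_bits >= 0.60:
        return 2
    if entropy_bits >= 0.30:
        return 3
    if entropy_bits >= 0.20:
        return 4
    return 5


_GROUPS = {"B": ("N", "D"), "Z": ("Q", "E"), "X": ALPHABET}


def extend_ambiguity_codes(matrix: SubstitutionMatrix,
                           freq: FrequencyTable) -> SubstitutionMatrix:
    """Add B, Z, X and * rows/columns as a compatibility extension.

    B is the marginal-weighted combination of {N, D}, Z of {Q, E}, X of all
    20 residues; every * entry is the minimum off-diagonal core score.
    These rows are derived from the core integer grid, not from counts.
    """
    p = freq.p
    core = matrix.scores.astype(np.float64)
    weights = {}
    for i, aa in enumerate(ALPHABET):
        w = np.zeros(N_AA)
        w[i] = 1.0
        weights[aa] = w
    for code, members in _GROUPS.items():
        w = np.zeros(N_AA)
        for m in members:
            w[ALPHABET.index(m)] = p[ALPHABET.index(m)]
        weights[code] = w
    ext = tuple(ALPHABET) + EXTENSIONS
    n_ext = len(ext)
    grid = np.zeros((n_ext, n_ext), dtype=np.int64)
    off_diag_min = int(core[~np.eye(N_AA, dtype=bool)].min())
    for i, a in enumerate(ext):
        for j, b in enumerate(ext):
            if a == "*" or b == "*":
                grid[i, j] = off_diag_min
                continue
            wa, wb = weights[a], weights[b]
            val = wa @ core @ wb / (wa.sum() * wb.sum())
            grid[i, j] = round_half_away_from_zero(val)
    out = SubstitutionMatrix(
        variant=matrix.variant,
        clustering_percent=matrix.clustering_percent,
        scale_denominator=matrix.scale_denominator,
        unrounded_scores=matrix.unrounded_scores,
        scores=matrix.scores,
        relative_entropy_bits=matrix.relative_entropy_bits,
        metadata=dict(matrix.metadata),
    )
    out.extended_scores = grid
    out.extended_alphabet = ext
    return out


@dataclass
class MatrixDiff:
    """Cell-level comparison of two matrices over the 210 unique entries."""

    cell_deltas: np.ndarray  # a - b, full 20x20
    n_differing: int
    n_lower: int   # entries where a < b
    n_higher: int  # entries where a > b

    @property
    def percent_differing(self) -> float:
        return 100.0 * self.n_differing / N_PAIRS


def matrix_diff(a, b) -> MatrixDiff:
    """Compare two matrices entry-wise over the 210 unique core cells.

    Accepts :class:`SubstitutionMatrix` or any object exposing 20x20
    ``scores`` in canonical order (e.g. ``MatrixFile.core_scores()``
    output wrapped appropriately).
    """
    sa = np.asarray(a.scores if hasattr(a, "scores") else a)
    sb = np.asarray(b.scores if hasattr(b, "scores") else b)
    if sa.shape != (N_AA, N_AA) or sb.shape != (N_AA, N_AA):
        raise ValueError("matrix_diff compares 20x20 core grids")
    deltas = sa - sb
    iu = np.triu_indices(N_AA)
    d = deltas[iu]
    return MatrixDiff(
        cell_deltas=deltas,
        n_differing=int(np.count_nonzero(d)),
        n_lower=int(np.sum(d < 0)),
        n_higher=int(np.sum(d > 0)),
    )


def build_matrix(
    blocks: list[Block],
    config: VariantConfig,
    scale_denominator: int | None = None,
    pseudocount: float = 0.0,
) -> SubstitutionMatrix:
    """Full pipeline: cluster every block, count, normalize, score.

    ``scale_denominator=None`` selects n from the relative entropy via
    :func:`suggest_scale`.
    """
    partitions = [cluster_block(b, config) for b in blocks]
    counts = accumulate_pair_counts(blocks, partitions)
    freq = counts_to_frequencies(counts, pseudocount=pseudocount)
    h = relative_entropy(freq)
    n = scale_denominator if scale_denominator is not None else suggest_scale(h)
    m = log_odds_scores(
        freq, n,
        variant=config.variant,
        clustering_percent=float(config.threshold_policy.clustering_percent),
    )
    m.metadata["n_blocks"] = len(blocks)
    m.metadata["pseudocount"] = pseudocount
    m.metadata["frequencies"] = freq
    return m
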