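"""Coverage-versus-errors-per-query evaluation of homology-search results.

Given all-vs-all search results over a domain database with SCOP-style
superfamily annotations, a hit is a *true positive* when query and subject
share the superfamily (the first three dot-separated fields of the sccs
string) and a *false positive* otherwise — same-fold/different-superfamily
hits count as false positives, so the reported coverage is a lower bound.

The E-value cutoff is chosen adaptively: relations are scanned in
ascending E-value order and the retained prefix is the largest one whose
accumulated false-positive mass does not exceed ``epq_limit`` times the
total query weight (with unit weights: epq * database size, e.g. at most
72 false positives for a 7290-sequence database at 0.01 epq).

Coverage is quadratically normalized over superfamilies::

    Q_quad = (1/S) * sum_i  t_i / (s_i^2 - s_i)

where t_i counts retained ordered true-positive relations within
superfamily i of size s_i, and S counts superfamilies with s_i >= 2
(singletons admit no homologous relation and are excluded).

Significance is assessed by Concerted Bayesian bootstrapping: per round,
sequence weights are drawn from a flat Dirichlet distribution scaled to
sum to the database size (mean weight 1), the cutoff is re-selected under
the weighted false-positive mass, and the weighted coverage is::

    Qhat_i  = sum_j sum_m delta(theta_j, theta_m) w_j w_m   (retained TPs)
    W_i     = (sum_{k in i} w_k)^2 - sum_{k in i} w_k^2
    Qhat    = (1/S) * sum_i Qhat_i / W_i

The same weight vectors are reused across every matrix/gap combination
under comparison ("concerted"), so per-round differences are paired.  Two
bootstrap distributions are compared with a two-sample parametric means
test, Z = (Qbar_p - Qbar_q) / sqrt((var_p + var_q)/N), significant at
Z >= 1.96.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .errors import AnnotationError, SearchResultFormatError

DEFAULT_EPQ = 0.01
DEFAULT_BOOTSTRAP_ROUNDS = 500
SIGNIFICANCE_Z = 1.96


@dataclass(frozen=True, order=True)
class Relation:
    """One ordered query->subject search hit with its E-value."""

    evalue: float
    query_id: str
    subject_id: str


def parse_search_results(stream) -> list[Relation]:
    """Parse 12-column BLAST/SSEARCH tabular output (outfmt 6 style).

    Columns 1, 2 and 11 hold query id, subject id and E-value.  Self-hits
    are removed; duplicate (query, subject) pairs are collapsed keeping the
    smallest E-value; the result is stably ordered by
    (evalue, query_id, subject_id).
    """
    if hasattr(stream, "read"):
        stream = stream.read()
    best: dict[tuple[str, str], float] = {}
    for lineno, raw in enumerate(io.StringIO(stream), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 11:
            raise SearchResultFormatError(
                f"line {lineno}: expected >= 11 tab-separated columns, got "
                f"{len(fields)}"
            )
        query, subject = fields[0], fields[1]
        try:
            evalue = float(fields[10])
        except ValueError as exc:
            raise SearchResultFormatError(
                f"line {lineno}: non-numeric E-value {fields[10]!r}"
            ) from exc
        if evalue < 0:
            raise SearchResultFormatError(
                f"line {lineno}: negative E-value {evalue!r}"
            )
        if query == subject:
            continue
        key = (query, subject)
        if key not in best or evalue < best[key]:
            best[key] = evalue
    rels = [Relation(e, q, s) for (q, s), e in best.items()]
    rels.sort()
    return rels


@dataclass
class SuperfamilyMap:
    """Domain-id -> superfamily labels plus derived sizes.

    The superfamily label is the first three dot-separated fields of the
    sccs classification string (class.fold.superfamily).
    """

    label_of: dict[str, str]
    n_skipped: int = 0
    domains: tuple[str, ...] = field(init=False)
    sizes: dict[str, int] = field(init=False)

    def __post_init__(self):
        self.domains = tuple(sorted(self.label_of))
        sizes: dict[str, int] = {}
        for lab in self.label_of.values():
            sizes[lab] = sizes.get(lab, 0) + 1
        self.sizes = sizes

    @property
    def database_size(self) -> int:
        return len(self.domains)

    @property
    def n_superfamilies(self) -> int:
        return len(self.sizes)

    def eligible_superfamilies(self) -> list[str]:
        """Superfamilies with >= 2 members, in sorted label order."""
        return sorted(lab for lab, s in self.sizes.items() if s >= 2)


_SCCS_RE = re.compile(r"^[a-l]\.\d+\.\d+(\.\d+)?$")


def superfamily_from_sccs(sccs: str) -> str:
    """``a.1.1.2`` -> ``a.1.1`` (class.fold.superfamily)."""
    return ".".join(sccs.split(".")[:3])


def parse_astral_annotations(stream) -> SuperfamilyMap:
    """Extract domain -> superfamily labels from ASTRAL FASTA headers.

    Headers look like ``>d1dlwa_ a.1.1.1 (A:) description``; the second
    token is the sccs string.  Headers without a recognizable sccs token
    are skipped (counted in ``n_skipped``).
    """
    if hasattr(stream, "read"):
        stream = stream.read()
    label_of: dict[str, str] = {}
    skipped = 0
    for record in SeqIO.parse(io.StringIO(stream), "fasta"):
        tokens = record.description.split()
        sccs = next((t for t in tokens[1:] if _SCCS_RE.match(t)), None)
        if sccs is None:
            skipped += 1
            continue
        label_of[record.id] = superfamily_from_sccs(sccs)
    return SuperfamilyMap(label_of, n_skipped=skipped)


def parse_annotation_table(stream) -> SuperfamilyMap:
    """Two-column TSV ``domain<TAB>superfamily-or-sccs`` alternative."""
    if hasattr(stream, "read"):
        stream = stream.read()
    label_of: dict[str, str] = {}
    for raw in io.StringIO(stream):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        dom, lab = line.split()[:2]
        label_of[dom] = superfamily_from_sccs(lab)
    return SuperfamilyMap(label_of)


def _check_annotated(relations: list[Relation], smap: SuperfamilyMap) -> None:
    for rel in relations:
        for did in (rel.query_id, rel.subject_id):
            if did not in smap.label_of:
                raise AnnotationError(
                    f"domain {did!r} appears in search results but carries "
                    f"no superfamily annotation"
                )


class _RelationArrays:
    """Sorted relations unpacked into numpy arrays for repeated filtering."""

    def __init__(self, relations: list[Relation], smap: SuperfamilyMap):
        _check_annotated(relations, smap)
        rels = sorted(relations)
        dom_idx = {d: i for i, d in enumerate(smap.domains)}
        labels = sorted(smap.sizes)
        lab_idx = {l: i for i, l in enumerate(labels)}
        n = len(rels)
        self.relations = rels
        self.evalues = np.array([r.evalue for r in rels])
        self.q_idx = np.array([dom_idx[r.query_id] for r in rels], dtype=np.int64)
        self.s_idx = np.array([dom_idx[r.subject_id] for r in rels], dtype=np.int64)
        q_lab = np.array([lab_idx[smap.label_of[r.query_id]] for r in rels],
                         dtype=np.int64) if n else np.zeros(0, dtype=np.int64)
        s_lab = np.array([lab_idx[smap.label_of[r.subject_id]] for r in rels],
                         dtype=np.int64) if n else np.zeros(0, dtype=np.int64)
        self.is_tp = q_lab == s_lab
        self.tp_sf = q_lab  # superfamily index of the TP relation
        self.labels = labels
        self.domain_label_idx = np.array(
            [lab_idx[smap.label_of[d]] for d in smap.domains], dtype=np.int64
        )
        self.sizes = np.array([smap.sizes[l] for l in labels], dtype=np.float64)

    def prefix_length(self, weights: np.ndarray | None, epq_limit: float) -> int:
        """Largest prefix whose accumulated FP mass <= epq * total query weight."""
        if len(self.evalues) == 0:
            return 0
        if weights is None:
            pair_w = np.ones(len(self.evalues))
            total_w = float(len(self.domain_label_idx))
        else:
            pair_w = weights[self.q_idx] * weights[self.s_idx]
            total_w = float(weights.sum())
        fp_mass = np.cumsum(np.where(self.is_tp, 0.0, pair_w))
        budget = epq_limit * total_w
        return int(np.searchsorted(fp_mass, budget, side="right"))


@dataclass
class CoverageResult:
    """Point estimate of quadratic-normalized coverage."""

    Q_quad: float
    t_i: dict[str, float]
    epq_limit: float | None = None
    evalue_cutoff: float | None = None
    n_retained: int = 0
    n_retained_fp: int = 0


def epq_threshold(
    relations: list[Relation],
    smap: SuperfamilyMap,
    epq_limit: float,
    weights: np.ndarray | None = None,
) -> tuple[float, list[Relation]]:
    """Adaptive E-value thresholding at an errors-per-query limit.

    Returns ``(evalue_cutoff, retained)`` where ``retained`` is the largest
    E-value-sorted prefix whose accumulated false-positive mass stays
    within ``epq_limit`` times the total query weight (inclusive
    comparison).  Unit weights make the FP mass a plain count and the
    budget epq * database size.  Ties in E-value are admitted in stable
    (evalue, query, subject) order until the budget would be exceeded.
    """
    if epq_limit <= 0:
        raise ValueError("epq_limit must be positive")
    arrays = _RelationArrays(relations, smap)
    m = arrays.prefix_length(weights, epq_limit)
    retained = arrays.relations[:m]
    cutoff = float(arrays.evalues[m - 1]) if m > 0 else 0.0
    return cutoff, retained


def quadratic_coverage(
    retained: list[Relation], smap: SuperfamilyMap
) -> CoverageResult:
    """Quadratic-normalized coverage over the retained relations.

    Averages t_i / (s_i^2 - s_i) over the S superfamilies with s_i >= 2;
    t_i counts retained ordered true-positive relations within
    superfamily i.
    """
    eligible = smap.eligible_superfamilies()
    t = {lab: 0.0 for lab in eligible}
    n_fp = 0
    for rel in retained:
        ql = smap.label_of[rel.query_id]
        sl = smap.label_of[rel.subject_id]
        if ql == sl:
            t[ql] += 1.0
        else:
            n_fp += 1
    S = len(eligible)
    if S == 0:
        return CoverageResult(0.0, t, n_retained=len(retained),
                              n_retained_fp=n_fp)
    acc = 0.0
    for lab in eligible:
        s = smap.sizes[lab]
        acc += t[lab] / (s * s - s)
    return CoverageResult(acc / S, t, n_retained=len(retained),
                          n_retained_fp=n_fp)


def draw_bootstrap_weights(
    database_size: int, n_rounds: int, seed: int
) -> np.ndarray:
    """Flat-Dirichlet sequence weights for the Bayesian bootstrap.

    Each of the ``n_rounds`` rows is drawn from Dirichlet(1, ..., 1) over
    all sequences and scaled to sum to ``database_size`` (mean weight 1),
    fully reproducible from ``seed``.  Reusing the same array across every
    matrix/gap combination under comparison makes the bootstrap concerted.
    """
    if database_size < 1:
        raise ValueError("database_size must be >= 1")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(database_size), size=n_rounds)
    return w * database_size


def bootstrap_coverage(
    relations,
    smap: SuperfamilyMap,
    weights: np.ndarray,
    epq_limit: float,
    fixed_prefix: int | None = None,
) -> float:
    """Weighted quadratic coverage for one bootstrap weight vector.

    The cutoff is re-selected under the weighted false-positive mass
    (pair weight w_query * w_subject, budget epq * sum of weights) unless
    ``fixed_prefix`` pins the retained prefix chosen from unit weights.
    With all weights equal to 1 the result equals
    :func:`quadratic_coverage` exactly.
    """
    arrays = relations if isinstance(relations, _RelationArrays) else \
        _RelationArrays(relations, smap)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (len(arrays.domain_label_idx),):
        raise ValueError("weight vector does not align with the database")
    m = fixed_prefix if fixed_prefix is not None else \
        arrays.prefix_length(weights, epq_limit)
    n_sf = len(arrays.labels)
    # Qhat_i: retained TP pair mass per superfamily
    q_hat = np.zeros(n_sf)
    if m > 0:
        tp = arrays.is_tp[:m]
        pw = weights[arrays.q_idx[:m]] * weights[arrays.s_idx[:m]]
        np.add.at(q_hat, arrays.tp_sf[:m][tp], pw[tp])
    # W_i = (sum w)^2 - sum w^2 per superfamily
    wsum = np.zeros(n_sf)
    wsq = np.zeros(n_sf)
    np.add.at(wsum, arrays.domain_label_idx, weights)
    np.add.at(wsq, arrays.domain_label_idx, weights**2)
    w_i = wsum**2 - wsq
    mask = w_i > 0
    if not mask.any():
        return 0.0
    return float(np.sum(q_hat[mask] / w_i[mask]) / mask.sum())


@dataclass
class BootstrapRun:
    """Distribution of weighted coverages over concerted bootstrap rounds."""

    n_rounds: int
    q_hats: np.ndarray
    seed: int | None = None

    def __post_init__(self):
        self.q_hats = np.asarray(self.q_hats, dtype=np.float64)
        if self.n_rounds != len(self.q_hats):
            raise ValueError("n_rounds does not match q_hats length")
        if self.n_rounds < 2:
            raise ValueError("need at least 2 bootstrap rounds")

    @property
    def mean(self) -> float:
        return float(self.q_hats.mean())

    @property
    def variance(self) -> float:
        return float(self.q_hats.var(ddof=1))


@dataclass
class ZScoreResult:
    z: float
    significant: bool
    infinite: bool = False


def z_score(run_p: BootstrapRun, run_q: BootstrapRun) -> ZScoreResult:
    """Two-sample parametric means test on two bootstrap distributions.

    Z = (Qbar_p - Qbar_q) / sqrt((var_p + var_q)/N); differences with
    Z >= 1.96 are considered significant (97.5 percentile).  When both
    variances vanish, equal means give Z = 0 and unequal means are
    reported as infinite with the significance flag set.
    """
    if run_p.n_rounds != run_q.n_rounds:
        raise ValueError("bootstrap runs must use the same number of rounds")
    diff = run_p.mean - run_q.mean
    denom_sq = (run_p.variance + run_q.variance) / run_p.n_rounds
    if denom_sq == 0:
        if diff == 0:
            return ZScoreResult(0.0, False)
        z = float("inf") if diff > 0 else float("-inf")
        return ZScoreResult(z, True, infinite=True)
    z = diff / denom_sq**0.5
    return ZScoreResult(z, z >= SIGNIFICANCE_Z)


def evaluate_run(
    results,
    annotations,
    epq_limit: float = DEFAULT_EPQ,
    n_rounds: int = DEFAULT_BOOTSTRAP_ROUNDS,
    seed: int = 0,
    weights: np.ndarray | None = None,
    fixed_cutoff: bool = False,
) -> dict:
    """End-to-end evaluation of one search run.

    ``results`` is tabular text (or a parsed relation list); ``annotations``
    is ASTRAL FASTA / annotation-TSV text (or a :class:`SuperfamilyMap`).
    Precomputed concerted ``weights`` (rounds x database size) override the
    seed-drawn ones.  ``fixed_cutoff=True`` pins the per-round retained
    prefix to the unit-weight selection instead of re-selecting it under
    each weight vector.

    Returns a JSON-serializable report with the point coverage, cutoff,
    retained counts, bootstrap mean/variance/per-round values, and the
    configuration (including the weight-vector seed for concerted reuse).
    """
    if isinstance(results, (str, bytes)) or hasattr(results, "read"):
        relations = parse_search_results(results)
    else:
        relations = sorted(results)
    if isinstance(annotations, SuperfamilyMap):
        smap = annotations
    else:
        text = annotations.read() if hasattr(annotations, "read") else annotations
        if text.lstrip().startswith(">"):
            smap = parse_astral_annotations(text)
        else:
            smap = parse_annotation_table(text)

    arrays = _RelationArrays(relations, smap)
    m = arrays.prefix_length(None, epq_limit)
    retained = arrays.relations[:m]
    point = quadratic_coverage(retained, smap)
    point.epq_limit = epq_limit
    point.evalue_cutoff = float(arrays.evalues[m - 1]) if m > 0 else 0.0

    if weights is None:
        weights = draw_bootstrap_weights(smap.database_size, n_rounds, seed)
    weights = np.asarray(weights, dtype=np.float64)
    if weights.shape != (n_rounds, smap.database_size):
        raise ValueError("weights must be (n_rounds, database_size)")
    fixed_prefix = m if fixed_cutoff else None
    q_hats = np.array([
        bootstrap_coverage(arrays, smap, weights[r], epq_limit,
                           fixed_prefix=fixed_prefix)
        for r in range(n_rounds)
    ])
    run = BootstrapRun(n_rounds, q_hats, seed=seed)
    return {
        "config": {
            "epq_limit": epq_limit,
            "n_rounds": n_rounds,
            "seed": seed,
            "fixed_cutoff": fixed_cutoff,
        },
        "database_size": smap.database_size,
        "n_superfamilies": smap.n_superfamilies,
        "n_superfamilies_eligible": len(smap.eligible_superfamilies()),
        "n_relations": len(relations),
        "evalue_cutoff": point.evalue_cutoff,
        "n_retained": point.n_retained,
        "n_retained_fp": point.n_retained_fp,
        "q_quad": point.Q_quad,
        "bootstrap": {
            "mean": run.mean,
            "variance": run.variance,
            "q_hats": [float(x) for x in q_hats],
        },
    }
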