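"""Readers/writers for BLOCKS flat files and square substitution-matrix text.

The BLOCKS databases are collections of ungapped multiple-alignment segments
("blocks") of conserved protein regions.  Several releases exist (5, 13+,
14.3) whose header conventions drift slightly; this parser therefore keys
only on segment lines and the ``//`` record terminator and treats every
header line as opaque metadata, which makes it robust across releases.

Sequence names duplicated within one block (the same protein contributing
two segments) are kept as distinct rows: clustering operates on segments,
not on names.

Matrix text follows the NCBI/EMBOSS square-matrix convention: ``#`` comment
lines, a column-label row, then one space-padded integer row per residue in
the order ``A R N D C Q E G H I L K M F P S T W Y V`` (optionally extended
with ``B Z X *``).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import BlocksFormatError, MatrixFormatError

#: Canonical residue order of published BLOSUM-style matrix files.
ALPHABET = tuple("ARNDCQEGHILKMFPSTWYV")
#: Compatibility extensions carried by published matrix files.
EXTENSIONS = ("B", "Z", "X", "*")

AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass
class Block:
    """One ungapped multiple-alignment block.

    Parameters
    ----------
    block_id:
        Identifier (BLOCKS ``AC`` accession when available).
    width:
        Number of alignment columns; every segment has exactly this length.
    segments:
        Ordered ``(sequence_name, residues)`` pairs.  Residues are stored
        uppercase; alphabet membership is checked downstream during pair
        counting, not here.
    header_lines:
        Opaque metadata lines preserved from the source record.
    """

    block_id: str
    width: int
    segments: list[tuple[str, str]]
    header_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width < 1:
            raise BlocksFormatError(f"block {self.block_id!r}: width must be >= 1")
        norm = []
        for name, residues in self.segments:
            residues = residues.upper()
            if len(residues) != self.width:
                raise BlocksFormatError(
                    f"block {self.block_id!r}: segment {name!r} has length "
                    f"{len(residues)}, expected width {self.width}"
                )
            norm.append((name, residues))
        self.segments = norm

    @property
    def n_sequences(self) -> int:
        return len(self.segments)

    def residue_matrix(self) -> np.ndarray:
        """Residue indices as an ``(n_sequences, width)`` int array.

        Residues outside the 20-letter alphabet are encoded as -1.
        """
        out = np.full((self.n_sequences, self.width), -1, dtype=np.int64)
        for r, (_, seg) in enumerate(self.segments):
            for c, aa in enumerate(seg):
                out[r, c] = AA_INDEX.get(aa, -1)
        return out


# Segment line: "name ( start) SEGMENT [weight]"; the parenthesized start and
# the numeric weight are both optional in hand-written fixtures.
_SEGMENT_RE = re.compile(
    r"^\s*(?P<name>\S+)\s+"
    r"(?:\(\s*(?P<start>\d+)\s*\)\s+)?"
    r"(?P<residues>[A-Za-z]+)"
    r"(?:\s+(?P<weight>\d+(?:\.\d+)?))?\s*$"
)
_HEADER_KEYS = ("ID", "AC", "DE", "BL", "CC", "MA")
_WIDTH_RE = re.compile(r"width=(\d+)")
_AC_RE = re.compile(r"^AC\s+([^;\s]+)")
_ID_RE = re.compile(r"^ID\s+([^;\s]+)")


def _looks_like_header(line: str) -> bool:
    key = line.split(None, 1)[0] if line.split() else ""
    return key in _HEADER_KEYS


def read_blocks(stream) -> list[Block]:
    """Parse BLOCKS-format text into a list of :class:`Block`.

    ``stream`` may be a string or a file-like object.  An empty stream
    yields an empty list.  A declared width (``BL ... width=N``) that
    disagrees with the observed segment length raises
    :class:`BlocksFormatError` naming the offending block.

    Per-segment trailing numeric weights are parsed but not used: the
    matrix algorithm derives its own weights from clustering.
    """
    if hasattr(stream, "read"):
        text = stream.read()
    else:
        text = stream

    blocks: list[Block] = []
    header_lines: list[str] = []
    segments: list[tuple[str, str]] = []
    declared_width: int | None = None
    block_id: str | None = None
    counter = 0

    def flush() -> None:
        nonlocal header_lines, segments, declared_width, block_id, counter
        if not segments and not header_lines:
            return
        counter += 1
        bid = block_id or f"block{counter}"
        if not segments:
            raise BlocksFormatError(f"block {bid!r}: record has no segment lines")
        widths = {len(seg) for _, seg in segments}
        if len(widths) > 1:
            raise BlocksFormatError(
                f"block {bid!r}: segments have inconsistent lengths {sorted(widths)}"
            )
        width = widths.pop()
        if declared_width is not None and declared_width != width:
            raise BlocksFormatError(
                f"block {bid!r}: declared width={declared_width} but segments "
                f"have length {width}"
            )
        blocks.append(Block(bid, width, segments, header_lines))
        header_lines, segments, declared_width, block_id = [], [], None, None

    for raw in io.StringIO(text):
        line = raw.rstrip()
        if not line.strip():
            continue
        if line.strip() == "//":
            flush()
            continue
        if _looks_like_header(line.strip()):
            header_lines.append(line)
            stripped = line.strip()
            if stripped.startswith("BL"):
                m = _WIDTH_RE.search(stripped)
                if m:
                    declared_width = int(m.group(1))
            elif stripped.startswith("AC"):
                m = _AC_RE.match(stripped)
                if m:
                    block_id = m.group(1)
            elif stripped.startswith("ID") and block_id is None:
                m = _ID_RE.match(stripped)
                if m:
                    block_id = m.group(1)
            continue
        m = _SEGMENT_RE.match(line)
        if m:
            segments.append((m.group("name"), m.group("residues").upper()))
        else:
            header_lines.append(line)
    flush()
    return blocks


def write_blocks(blocks: list[Block]) -> str:
    """Serialize blocks to canonical BLOCKS text (round-trips through
    :func:`read_blocks`)."""
    out = []
    for b in blocks:
        out.append(f"ID   {b.block_id}; BLOCK")
        out.append(f"AC   {b.block_id};")
        out.append(f"BL   width={b.width}; seqs={b.n_sequences};")
        name_w = max(len(n) for n, _ in b.segments)
        for name, seg in b.segments:
            out.append(f"{name:<{name_w}} (   1) {seg}")
        out.append("//")
    return "\n".join(out) + ("\n" if out else "")


@dataclass
class MatrixFile:
    """A square integer substitution matrix keyed by residue labels."""

    alphabet_order: tuple[str, ...]
    scores: np.ndarray  # square int grid aligned with alphabet_order
    comment_lines: list[str] = field(default_factory=list)

    def score(self, a: str, b: str) -> int:
        i = self.alphabet_order.index(a)
        j = self.alphabet_order.index(b)
        return int(self.scores[i, j])

    def core_scores(self) -> np.ndarray:
        """20x20 grid in canonical order, regardless of file column order."""
        idx = [self.alphabet_order.index(aa) for aa in ALPHABET]
        return self.scores[np.ix_(idx, idx)]


_KNOWN_LABELS = set(ALPHABET) | set(EXTENSIONS)


def read_matrix(text) -> MatrixFile:
    """Parse NCBI/EMBOSS-style square matrix text.

    ``#`` comments are tolerated anywhere; the column-label row may list
    residues in any order (the matrix is keyed by label, not position).
    An asymmetric grid raises :class:`MatrixFormatError`.
    """
    if hasattr(text, "read"):
        text = text.read()
    comments: list[str] = []
    labels: list[str] | None = None
    rows: dict[str, list[int]] = {}
    for raw in io.StringIO(text):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            comments.append(line)
            continue
        fields = line.split()
        if labels is None:
            for lab in fields:
                if lab not in _KNOWN_LABELS:
                    raise MatrixFormatError(f"unknown residue label {lab!r}")
            labels = fields
            continue
        lab = fields[0]
        if lab not in _KNOWN_LABELS:
            raise MatrixFormatError(f"unknown residue label {lab!r}")
        try:
            values = [int(v) for v in fields[1:]]
        except ValueError as exc:
            raise MatrixFormatError(f"non-integer score on row {lab!r}") from exc
        if len(values) != len(labels):
            raise MatrixFormatError(
                f"row {lab!r} has {len(values)} scores, expected {len(labels)}"
            )
        rows[lab] = values
    if labels is None or not rows:
        raise MatrixFormatError("no matrix grid found")
    if set(rows) != set(labels):
        raise MatrixFormatError("row labels do not match column labels")
    missing = [aa for aa in ALPHABET if aa not in labels]
    if missing:
        raise MatrixFormatError(f"matrix lacks standard residues: {missing}")
    grid = np.array([rows[lab] for lab in labels], dtype=np.int64)
    if not np.array_equal(grid, grid.T):
        bad = np.argwhere(grid != grid.T)[0]
        a, b = labels[bad[0]], labels[bad[1]]
        raise MatrixFormatError(
            f"matrix is not symmetric: [{a}][{b}]={grid[bad[0], bad[1]]} "
            f"but [{b}][{a}]={grid[bad[1], bad[0]]}"
        )
    return MatrixFile(tuple(labels), grid, comments)


def write_matrix(matrix, include_extensions: bool = False,
                 extra_comments: list[str] | None = None) -> str:
    """Serialize a :class:`~corblosum.matrix_builder.SubstitutionMatrix`.

    The comment header records the variant, clustering value, scale and
    relative entropy; rows/columns follow the canonical order, optionally
    extended with ``B Z X *``.
    """
    alphabet = list(ALPHABET)
    grid = np.asarray(matrix.scores)
    if include_extensions:
        if matrix.extended_scores is None:
            raise MatrixFormatError(
                "matrix has no ambiguity-code extension; call "
                "extend_ambiguity_codes first"
            )
        alphabet = list(ALPHABET) + list(EXTENSIONS)
        grid = np.asarray(matrix.extended_scores)
    lines = []
    for c in extra_comments or []:
        lines.append(c if c.startswith("#") else f"# {c}")
    lines.append(
        f"# variant={matrix.variant} clustering={matrix.clustering_percent}"
    )
    lines.append(
        f"# scale=1/{matrix.scale_denominator} bits "
        f"entropy={matrix.relative_entropy_bits:.4f}"
    )
    width = max(3, max(len(str(int(v))) for v in grid.ravel()) + 1)
    lines.append(" " + "".join(f"{aa:>{width}}" for aa in alphabet))
    for i, aa in enumerate(alphabet):
        lines.append(aa + "".join(f"{int(v):>{width}}" for v in grid[i]))
    return "\n".join(lines) + "\n"
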