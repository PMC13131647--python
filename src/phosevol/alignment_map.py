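"""Multiple-sequence-alignment handling: coordinate maps, conservation,
and projection of the C-terminal domain boundary onto every species.

Cross-species claims about a particular residue (say, position 294 of the
human protein) only make sense through the alignment: a reference residue
is located in its alignment column, and every other species is read out at
that column.  ``ColumnMap`` holds the bidirectional residue<->column
mapping for one reference species; ``project_cterm_boundary`` converts a
reference-coordinate domain boundary into each species' own coordinates by
counting non-gap characters before the boundary column.

Column indices are 1-based, matching residue-numbering conventions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from Bio import AlignIO

GAP_CHARS = "-."


@dataclass
class Alignment:
    """Rows of (species_id, aligned sequence); all rows share one width."""

    rows: list[tuple[str, str]]
    width: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("alignment has no rows")
        self.width = len(self.rows[0][1])
        for sid, seq in self.rows:
            if len(seq) != self.width:
                raise ValueError(
                    f"ragged alignment: row {sid!r} has length {len(seq)}, "
                    f"expected {self.width}"
                )
        ids = [sid for sid, _ in self.rows]
        dup = [s for s, c in Counter(ids).items() if c > 1]
        if dup:
            raise ValueError(f"duplicate species ids in alignment: {dup}")
        self._index = {sid: seq for sid, seq in self.rows}

    @property
    def species_ids(self) -> list[str]:
        return [sid for sid, _ in self.rows]

    def row(self, species_id: str) -> str:
        try:
            return self._index[species_id]
        except KeyError:
            raise KeyError(f"species {species_id!r} absent from alignment") from None

    def ungapped(self, species_id: str) -> str:
        seq = self.row(species_id)
        return "".join(c for c in seq if c not in GAP_CHARS)


@dataclass
class ColumnMap:
    """Bidirectional map between reference residue positions and columns.

    ``res_to_col[k]`` is the 1-based alignment column holding the k-th
    residue of the reference sequence; ``col_to_res`` is the partial
    inverse (gap columns of the reference are absent).
    """

    reference_id: str
    res_to_col: dict[int, int]
    col_to_res: dict[int, int]
    _alignment: Alignment

    def aligned_row(self, species_id: str) -> str:
        return self._alignment.row(species_id)


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read an alignment in aligned-FASTA (``"fasta"``) or Clustal format.

    Sequences are upper-cased; rows keep file order.  Mixed row lengths and
    unknown formats fail loudly.
    """
    fmt = {"fasta": "fasta", "aligned-fasta": "fasta", "clustal": "clustal"}.get(
        format.lower()
    )
    if fmt is None:
        raise ValueError(f"unknown alignment format {format!r}")
    try:
        aln = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        raise ValueError(f"{path}: cannot parse as {format}: {exc}") from exc
    return Alignment([(r.id, str(r.seq).upper()) for r in aln])


def build_column_map(aln: Alignment, reference_id: str) -> ColumnMap:
    """Map the reference species' residue positions to alignment columns."""
    row = aln.row(reference_id)
    res_to_col: dict[int, int] = {}
    col_to_res: dict[int, int] = {}
    k = 0
    for col, char in enumerate(row, start=1):
        if char not in GAP_CHARS:
            k += 1
            res_to_col[k] = col
            col_to_res[col] = k
    if not res_to_col:
        raise ValueError(f"reference row {reference_id!r} is entirely gaps")
    return ColumnMap(reference_id, res_to_col, col_to_res, aln)


def conservation_profile(aln: Alignment) -> list[float]:
    """Per-column absolute conservation: modal non-gap residue count / rows.

    Strict identity only — chemically similar residues get no credit, and
    gaps never count toward the modal residue (a gap is a mismatch).
    """
    n_rows = len(aln.rows)
    scores: list[float] = []
    for col in range(aln.width):
        counts = Counter(
            seq[col] for _, seq in aln.rows if seq[col] not in GAP_CHARS
        )
        scores.append(max(counts.values()) / n_rows if counts else 0.0)
    return scores


def project_cterm_boundary(
    aln: Alignment, colmap: ColumnMap, ref_boundary: int
) -> dict[str, int]:
    """Project a reference-coordinate domain boundary onto every species.

    For each species, ``cterm_start`` = 1 + number of non-gap characters
    strictly before the boundary column in that species' row, i.e. the
    first residue of its own C-terminal domain.  A species whose row is
    entirely gapped from the boundary column onwards gets
    ``cterm_start`` = length + 1 (an empty, flagged domain).
    """
    if ref_boundary not in colmap.res_to_col:
        raise ValueError(
            f"ref_boundary {ref_boundary} outside reference "
            f"({colmap.reference_id}) length {len(colmap.res_to_col)}"
        )
    bcol = colmap.res_to_col[ref_boundary]
    out: dict[str, int] = {}
    for sid, seq in aln.rows:
        before = sum(1 for c in seq[: bcol - 1] if c not in GAP_CHARS)
        out[sid] = before + 1
    return out


def write_conservation_tsv(scores: list[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("column\tscore\n")
        for i, s in enumerate(scores, start=1):
            fh.write(f"{i}\t{s:.6g}\n")


def write_boundaries_tsv(boundaries: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("species_id\tcterm_start\n")
        for sid, b in boundaries.items():
            fh.write(f"{sid}\t{b}\n")
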