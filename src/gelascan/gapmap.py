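"""Coordinate liftover between residue, alignment-column and reference coordinates.

A multiple sequence alignment assigns every residue of every member sequence to
an alignment column; gap characters pad the columns a sequence does not occupy.
A :class:`GapMap` indexes one aligned row so positions can be translated from a
sequence's own residue numbering into alignment columns and back.  Chaining two
gap-maps through the shared column space lifts a site annotated on one
orthologue onto the residue numbering of a reference sequence (here typically
the Danio rerio gelatinase A row).

All coordinates are 1-based and closed, matching biological residue numbering.
A lookup at a gap column returns ``None`` explicitly — it is never silently
snapped to a neighbouring residue, which would fabricate conservation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateError, ValidationError

GAP_CHARS = frozenset("-.")
#: 20 standard residues plus X (unknown).
RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class GapMap:
    """Bidirectional residue ↔ alignment-column index for one aligned row.

    Attributes
    ----------
    seq_id : str
        Identifier of the aligned sequence.
    residue_to_col : np.ndarray
        ``residue_to_col[i-1]`` is the 1-based column housing residue ``i``;
        strictly increasing.
    col_to_residue : np.ndarray
        ``col_to_residue[c-1]`` is the 1-based residue index at column ``c``,
        or 0 where the row is gapped.
    alignment_length : int
    """

    seq_id: str
    residue_to_col: np.ndarray
    col_to_residue: np.ndarray
    alignment_length: int = field(default=0)

    @property
    def ungapped_length(self) -> int:
        return int(self.residue_to_col.size)


def build_gapmap(seq_id: str, aligned_row: str) -> GapMap:
    """Index an aligned row (residues plus ``-``/``.`` gaps).

    Raises
    ------
    ValidationError
        If the row is empty or contains a character that is neither a
        standard residue, ``X``, nor a gap.
    """
    if not aligned_row:
        raise ValidationError(f"{seq_id}: empty aligned row")
    bad = set(aligned_row.upper()) - RESIDUES - GAP_CHARS
    if bad:
        raise ValidationError(
            f"{seq_id}: invalid characters in aligned row: {sorted(bad)!r}"
        )
    chars = np.frombuffer(aligned_row.upper().encode("ascii"), dtype="S1")
    is_res = ~np.isin(chars, [b"-", b"."])
    residue_to_col = np.flatnonzero(is_res) + 1
    col_to_residue = np.where(is_res, np.cumsum(is_res), 0)
    return GapMap(
        seq_id=seq_id,
        residue_to_col=residue_to_col,
        col_to_residue=col_to_residue,
        alignment_length=len(aligned_row),
    )


def seq_to_aln(gmap: GapMap, pos: int) -> int:
    """Alignment column housing residue ``pos`` (1-based)."""
    if not 1 <= pos <= gmap.ungapped_length:
        raise CoordinateError(
            f"{gmap.seq_id}: residue {pos} outside 1..{gmap.ungapped_length}"
        )
    return int(gmap.residue_to_col[pos - 1])


def aln_to_seq(gmap: GapMap, column: int) -> int | None:
    """Residue index at ``column``, or ``None`` if the row is gapped there."""
    if not 1 <= column <= gmap.alignment_length:
        raise CoordinateError(
            f"{gmap.seq_id}: column {column} outside 1..{gmap.alignment_length}"
        )
    res = int(gmap.col_to_residue[column - 1])
    return res if res else None


def liftover_site(pos: int, source: GapMap, reference: GapMap) -> int | None:
    """Lift residue ``pos`` of ``source`` onto ``reference`` numbering.

    Returns ``None`` when the reference is gapped at the housing column, i.e.
    the site has no homologous reference residue.
    """
    if source.alignment_length != reference.alignment_length:
        raise ValidationError(
            "gap-maps come from alignments of different lengths "
            f"({source.alignment_length} vs {reference.alignment_length})"
        )
    return aln_to_seq(reference, seq_to_aln(source, pos))


def liftover_table(
    sites: list[tuple[str, int]],
    gapmaps: dict[str, GapMap],
    reference_id: str,
) -> list[dict]:
    """Lift (sequence id, position) pairs onto the reference; NA when gapped.

    Returns one dict per site with keys ``seq_id``, ``pos``, ``column``,
    ``ref_pos`` (None where unmappable), suitable for TSV export.
    """
    ref = gapmaps[reference_id]
    rows = []
    for seq_id, pos in sites:
        gmap = gapmaps[seq_id]
        column = seq_to_aln(gmap, pos)
        rows.append(
            {
                "seq_id": seq_id,
                "pos": pos,
                "column": column,
                "ref_pos": aln_to_seq(ref, column),
            }
        )
    return rows
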