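"""Orthologue set curation and alignment-membership filtering.

Orthologue collections pulled from sequence databases carry isoforms,
truncated entries and mis-annotated start positions.  Before a signal-peptide
or phosphosite analysis can compare the N-termini of an aligned family, the
set is reduced to one (longest) isoform per gene and rows whose alignment
start looks unreliable are dropped: any row with a gap inside the N-terminal
window, or whose first aligned column diverges from the family consensus.

FASTA reading/writing is delegated to Biopython; gene identity travels in the
header as a ``gene=<id>`` token.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .gapmap import GAP_CHARS, RESIDUES

#: removal reasons emitted by :func:`filter_alignment_members`
REASON_GAP = "gap-in-window"
REASON_START = "divergent-start"
REASON_SHORT = "short-sequence"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its accession and (optional) gene identity."""

    id: str
    sequence: str
    gene_id: str | None = None
    description: str = ""

    def ungapped_length(self) -> int:
        return sum(1 for c in self.sequence if c not in GAP_CHARS)


@dataclass
class CurationReport:
    """Partition of an input set into retained and removed members.

    ``retained`` and ``removed`` ids are disjoint and their union is the
    input; each removed id carries a machine-readable reason.
    """

    retained: list[ProteinRecord]
    removed: list[tuple[str, str]] = field(default_factory=list)

    @property
    def retained_ids(self) -> list[str]:
        return [r.id for r in self.retained]

    @property
    def removed_ids(self) -> list[str]:
        return [rid for rid, _ in self.removed]

    def to_tsv(self) -> str:
        lines = ["id\tstatus\treason"]
        lines += [f"{r.id}\tretained\t" for r in self.retained]
        lines += [f"{rid}\tremoved\t{reason}" for rid, reason in self.removed]
        return "\n".join(lines) + "\n"


def _parse_gene_token(description: str) -> str | None:
    for token in description.split():
        if token.startswith("gene="):
            return token[5:] or None
    return None


def read_fasta(text: str) -> list[ProteinRecord]:
    """Parse (possibly aligned) protein FASTA into :class:`ProteinRecord`.

    Sequences are upper-cased, ``.`` gaps normalised to ``-``; a ``gene=``
    token in the header populates ``gene_id``.  Malformed headers or empty
    sequences raise :class:`FormatError` with the offending line number.
    """
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        first_bad = next(
            i for i, ln in enumerate(text.splitlines(), 1) if ln.strip()
        )
        raise FormatError("expected FASTA header ('>')", line=first_bad)
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        seq = str(rec.seq).upper().replace(".", "-")
        if not rec.id:
            raise FormatError("empty FASTA header", line=_header_line(text, ""))
        if not seq:
            raise FormatError(
                f"empty sequence for {rec.id!r}", line=_header_line(text, rec.id)
            )
        bad = set(seq) - RESIDUES - GAP_CHARS
        if bad:
            raise FormatError(
                f"invalid residues {sorted(bad)!r} in {rec.id!r}",
                line=_header_line(text, rec.id),
            )
        desc = rec.description[len(rec.id) :].strip()
        records.append(
            ProteinRecord(
                id=rec.id,
                sequence=seq,
                gene_id=_parse_gene_token(desc),
                description=desc,
            )
        )
    return records


def _header_line(text: str, rec_id: str) -> int | None:
    for i, line in enumerate(text.splitlines(), 1):
        if line.startswith(">") and line[1:].split() and line[1:].split()[0] == rec_id:
            return i
        if line.startswith(">") and not rec_id:
            return i
    return None


def write_fasta(records: list[ProteinRecord], width: int = 60) -> str:
    """Serialise records to FASTA; gene identity re-emitted as ``gene=``."""
    out = []
    for r in records:
        desc_parts = []
        if r.gene_id and _parse_gene_token(r.description) is None:
            desc_parts.append(f"gene={r.gene_id}")
        if r.description:
            desc_parts.append(r.description)
        out.append(
            SeqRecord(Seq(r.sequence), id=r.id, description=" ".join(desc_parts))
        )
    buf = io.StringIO()
    SeqIO.write(out, buf, "fasta")
    return buf.getvalue()


def select_longest_per_gene(records: list[ProteinRecord]) -> list[ProteinRecord]:
    """Keep, per gene, the isoform with maximal ungapped length.

    Length ties break toward the lexicographically smallest accession, so the
    result does not depend on input order.  Records missing a ``gene_id``
    raise :class:`ValidationError`.
    """
    missing = [r.id for r in records if not r.gene_id]
    if missing:
        raise ValidationError(f"records without gene_id: {missing}")
    best: dict[str, ProteinRecord] = {}
    for r in records:
        cur = best.get(r.gene_id)
        if (
            cur is None
            or r.ungapped_length() > cur.ungapped_length()
            or (r.ungapped_length() == cur.ungapped_length() and r.id < cur.id)
        ):
            best[r.gene_id] = r
    return [best[g] for g in sorted(best)]


def _first_residue_column(sequence: str) -> int | None:
    """1-based first non-gap column, or None for an all-gap row."""
    for i, c in enumerate(sequence, 1):
        if c not in GAP_CHARS:
            return i
    return None


def filter_alignment_members(
    records: list[ProteinRecord],
    window: int = 15,
    start_tolerance: int = 0,
) -> CurationReport:
    """Apply the N-terminal reliability filters to an aligned family.

    A row is removed, with the first matching reason, when:

    ``short-sequence``
        its ungapped length is below ``window`` (the gap rule is undefined);
    ``divergent-start``
        its first non-gap column differs from the modal first non-gap column
        by more than ``start_tolerance`` columns (modal ties break toward the
        smallest column index);
    ``gap-in-window``
        it has any gap character within the first ``window`` alignment
        columns of the (already trimmed) block.

    Idempotent: filtering the retained set removes nothing further.
    """
    if not records:
        return CurationReport(retained=[])
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise FormatError(f"ragged alignment: row lengths {sorted(lengths)}")

    starts = {
        r.id: _first_residue_column(r.sequence)
        for r in records
    }
    counts = Counter(s for s in starts.values() if s is not None)
    modal_start = min(
        (s for s in counts if counts[s] == max(counts.values())), default=None
    )

    retained, removed = [], []
    for r in records:
        if r.ungapped_length() < window:
            removed.append((r.id, REASON_SHORT))
        elif abs(starts[r.id] - modal_start) > start_tolerance:
            removed.append((r.id, REASON_START))
        elif any(c in GAP_CHARS for c in r.sequence[:window]):
            removed.append((r.id, REASON_GAP))
        else:
            retained.append(r)
    return CurationReport(retained=retained, removed=removed)
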