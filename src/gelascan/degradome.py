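"""TAILS degradome filtering and P1' cleavage-site classification.

In a TAILS (terminal amine isotopic labeling of substrates) experiment,
protein N-termini are isotopically labelled in two conditions — here,
zebrafish embryos with and without broad-spectrum metalloproteinase
inhibition — and quantified as heavy:light (H/L) ratios.  An N-terminal
peptide enriched in the uninhibited control (H/L strictly above 3 by
default) marks a cleavage protected by inhibition, i.e. a candidate
protease substrate.  The first residue of such a neo-N-terminal peptide is
the P1' residue of the cleaved bond; Ile, Leu and Val at P1' are
characteristic of gelatinase A cleavage.

Peptide-to-protein assignment is taken from the input table (an upstream
search engine's job); categories such as "myosin" are keyword matches
against the protein description.
"""

from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError, ValidationError

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
STANDARD_AA = frozenset(AA3_TO_1.values())

REQUIRED_COLUMNS = ("peptide", "protein_description", "hl_ratio")


@dataclass(frozen=True)
class PeptideRecord:
    """One N-terminal peptide with its protein assignment and H/L ratio."""

    peptide: str
    protein_description: str
    hl_ratio: float

    def __post_init__(self):
        if not self.peptide:
            raise ValidationError("empty peptide sequence")
        if not self.hl_ratio > 0:
            raise ValidationError(
                f"{self.peptide}: hl_ratio must be positive, got {self.hl_ratio}"
            )


@dataclass(frozen=True)
class DegradomeParams:
    ratio_threshold: float = 3.0           # strict >
    gelA_p1prime: frozenset[str] = frozenset("ILV")
    category_rules: tuple[tuple[str, str], ...] = (("myosin", "myosin"),)
    normalization: str = "none"            # "none" | "median-center"

    def __post_init__(self):
        if not self.ratio_threshold > 0:
            raise ConfigurationError("ratio_threshold must be positive")
        if not set(self.gelA_p1prime) <= STANDARD_AA:
            raise ConfigurationError("gelA_p1prime must be standard residues")
        if self.normalization not in ("none", "median-center"):
            raise ConfigurationError(
                f"unknown normalization {self.normalization!r}"
            )


@dataclass
class DegradomeSummary:
    """Counts and fractions over a filtered degradome table.

    Fractions are ``None`` (never 0/0) when no peptide passes the filter.
    Percentages round half-to-even to integer percent, so 12/49 reports 24.
    """

    n_total: int
    n_passing: int
    category_counts: dict[str, int]
    category_fractions: dict[str, float | None]
    category_percent: dict[str, int | None]
    p1prime_counts: dict[str, int]
    n_gelA_like: int
    gelA_like_by_category: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def parse_peptide_table(text: str) -> list[PeptideRecord]:
    """Parse a degradome TSV (peptide, protein_description, hl_ratio).

    The header is required; missing columns raise :class:`FormatError`.
    Rows with non-numeric or non-positive ratios, or with non-standard
    peptide characters, are rejected individually with a logged reason.
    """
    try:
        df = pd.read_csv(io.StringIO(text), sep="\t", dtype=str,
                         comment="#", skip_blank_lines=True)
    except pd.errors.EmptyDataError as exc:
        raise FormatError("empty table (header required)") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")

    records, n_rejected = [], 0
    for row in df.itertuples(index=False):
        peptide = (row.peptide or "").strip().upper()
        try:
            ratio = float(row.hl_ratio)
        except (TypeError, ValueError):
            n_rejected += 1
            logger.warning("rejected row %r: non-numeric ratio %r",
                           peptide, row.hl_ratio)
            continue
        if not peptide or set(peptide) - STANDARD_AA or not ratio > 0:
            n_rejected += 1
            logger.warning("rejected row %r: invalid peptide or ratio", peptide)
            continue
        records.append(
            PeptideRecord(peptide, str(row.protein_description or ""), ratio)
        )
    if n_rejected:
        logger.info("%d row(s) rejected during parse", n_rejected)
    return records


def normalize_ratios(
    records: list[PeptideRecord], mode: str = "median-center"
) -> list[PeptideRecord]:
    """Median-center log2 ratios so the bulk of the proteome sits at H/L = 1."""
    if mode == "none" or not records:
        return list(records)
    if mode != "median-center":
        raise ConfigurationError(f"unknown normalization {mode!r}")
    log2 = np.log2([r.hl_ratio for r in records])
    shift = np.median(log2)
    return [
        PeptideRecord(r.peptide, r.protein_description,
                      float(2.0 ** (lg - shift)))
        for r, lg in zip(records, log2)
    ]


def filter_enriched(
    records: list[PeptideRecord], params: DegradomeParams | None = None
) -> list[PeptideRecord]:
    """Keep exactly the records with H/L strictly above the threshold."""
    params = params or DegradomeParams()
    return [r for r in records if r.hl_ratio > params.ratio_threshold]


def p1_prime(record: PeptideRecord | str) -> str:
    """P1' residue of a neo-N-terminal peptide: its first residue.

    Returned as a three-letter code (e.g. ``Ile``), the convention used in
    degradome tables.
    """
    peptide = record.peptide if isinstance(record, PeptideRecord) else record
    if not peptide:
        raise ValidationError("empty peptide has no P1' residue")
    first = peptide[0].upper()
    if first not in AA1_TO_3:
        raise ValidationError(f"non-standard P1' residue {first!r}")
    return AA1_TO_3[first]


def classify_gelA_like(residue: str, params: DegradomeParams | None = None) -> bool:
    """True iff the P1' residue is in the gelatinase A set (Ile/Leu/Val)."""
    params = params or DegradomeParams()
    one = AA3_TO_1.get(residue, residue.upper() if len(residue) == 1 else None)
    if one not in STANDARD_AA:
        raise ValidationError(f"unknown residue {residue!r}")
    return one in params.gelA_p1prime


def categorize(record: PeptideRecord, params: DegradomeParams) -> str | None:
    """First matching category whose keyword occurs in the description."""
    desc = record.protein_description.lower()
    for category, keyword in params.category_rules:
        if keyword.lower() in desc:
            return category
    return None


def _round_percent(numerator: int, denominator: int) -> int:
    """Integer percent, round half to even (12/49 -> 24)."""
    return round(100.0 * numerator / denominator)


def summarize_degradome(
    records: list[PeptideRecord], params: DegradomeParams | None = None
) -> DegradomeSummary:
    """Normalise (if configured), filter, categorise and tally P1' residues.

    Counts are invariant to record order; with normalization "none" the
    summary is a pure function of the input table.
    """
    params = params or DegradomeParams()
    normalized = normalize_ratios(records, params.normalization)
    passing = filter_enriched(normalized, params)

    category_counts = {cat: 0 for cat, _ in params.category_rules}
    gelA_by_cat = {cat: 0 for cat, _ in params.category_rules}
    p1_counts: dict[str, int] = {}
    n_gelA = 0
    for rec in passing:
        res = p1_prime(rec)
        p1_counts[res] = p1_counts.get(res, 0) + 1
        is_gelA = classify_gelA_like(res, params)
        n_gelA += is_gelA
        cat = categorize(rec, params)
        if cat is not None:
            category_counts[cat] += 1
            gelA_by_cat[cat] += is_gelA

    n_pass = len(passing)
    fractions = {
        cat: (c / n_pass if n_pass else None)
        for cat, c in category_counts.items()
    }
    percents = {
        cat: (_round_percent(c, n_pass) if n_pass else None)
        for cat, c in category_counts.items()
    }
    return DegradomeSummary(
        n_total=len(records),
        n_passing=n_pass,
        category_counts=category_counts,
        category_fractions=fractions,
        category_percent=percents,
        p1prime_counts=dict(sorted(p1_counts.items())),
        n_gelA_like=n_gelA,
        gelA_like_by_category=gelA_by_cat,
    )


def passing_table_tsv(
    records: list[PeptideRecord], params: DegradomeParams | None = None
) -> str:
    """TSV of filter-passing peptides with p1_prime/gelA_like/category added."""
    params = params or DegradomeParams()
    normalized = normalize_ratios(records, params.normalization)
    lines = ["peptide\tprotein_description\thl_ratio\tp1_prime\tgelA_like\tcategory"]
    for r in filter_enriched(normalized, params):
        res = p1_prime(r)
        lines.append(
            f"{r.peptide}\t{r.protein_description}\t{r.hl_ratio:.4f}"
            f"\t{res}\t{classify_gelA_like(res, params)}"
            f"\t{categorize(r, params) or ''}"
        )
    return "\n".join(lines) + "\n"
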