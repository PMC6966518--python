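"""Cross-species phosphosite conservation on a reference coordinate system.

Per-orthologue phosphorylation predictions (NetPhos-style: sequence id,
residue position, residue, score) are lifted through the family alignment
onto a reference sequence.  A reference position is *supported* by an
orthologue when that orthologue carries a prediction scoring strictly above
the threshold whose liftover lands on the position and whose residue
satisfies the match mode.  Sites are then tiered by the fraction of
orthologues supporting them (inclusive ``>=`` at each tier fraction), and
annotated with the reference protein's domain architecture.

Defaults mirror the gelatinase A analysis: score threshold 0.65 (strict),
tiers 100%/99%/97%, and the zebrafish Mmp2 domain intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, FormatError
from .gapmap import GapMap, liftover_site

logger = logging.getLogger(__name__)

ACCEPTORS = frozenset("STY")


@dataclass(frozen=True)
class SiteCall:
    """One predicted phosphosite on one orthologue (1-based position)."""

    seq_id: str
    position: int
    residue: str
    score: float
    kinase: str | None = None


@dataclass(frozen=True)
class ConservationParams:
    score_threshold: float = 0.65          # strict >
    tier_fractions: tuple[float, ...] = (1.00, 0.99, 0.97)  # inclusive >=
    residue_match: str = "exact"           # "exact" | "acceptor-class"

    def __post_init__(self):
        if not 0 <= self.score_threshold < 1:
            raise ConfigurationError("score_threshold must lie in [0, 1)")
        if any(not 0 < f <= 1 for f in self.tier_fractions):
            raise ConfigurationError("tier fractions must lie in (0, 1]")
        if list(self.tier_fractions) != sorted(self.tier_fractions, reverse=True):
            raise ConfigurationError("tier fractions must be strictly decreasing")
        if self.residue_match not in ("exact", "acceptor-class"):
            raise ConfigurationError(f"unknown residue_match {self.residue_match!r}")


@dataclass
class ConservedSite:
    """A reference position with its cross-species support."""

    ref_pos: int
    residue: str
    count: int
    n_orthologues: int
    supporting_ids: tuple[str, ...]
    tier: str = "below"

    @property
    def fraction(self) -> float:
        return self.count / self.n_orthologues


#: Zebrafish gelatinase A domain architecture, 1-based closed intervals.
MMP2_DOMAINS: dict[str, tuple[int, int]] = {
    "signal": (1, 29),
    "propeptide": (30, 107),
    "catalytic": (118, 446),
    "hemopexin": (463, 657),
}


@dataclass(frozen=True)
class DomainAnnotation:
    intervals: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(MMP2_DOMAINS)
    )

    def __post_init__(self):
        spans = sorted(self.intervals.values())
        for (_, hi), (lo, _) in zip(spans, spans[1:]):
            if lo <= hi:
                raise ConfigurationError("domain intervals overlap")


def annotate_domains(position: int, annotation: DomainAnnotation | None = None) -> str:
    """Domain label housing ``position``, or ``inter-domain``."""
    annotation = annotation or DomainAnnotation()
    for name, (lo, hi) in annotation.intervals.items():
        if lo <= position <= hi:
            return name
    return "inter-domain"


def load_site_predictions(
    text: str, sequences: dict[str, str]
) -> list[SiteCall]:
    """Parse a NetPhos-like TSV (id, position, residue, score[, kinase]).

    Each row is validated against the ungapped sequence it names: the residue
    at the stated position must match the stated residue and the score must
    lie in [0, 1].  Invalid rows are skipped with a logged warning rather
    than aborting the load; an unknown sequence id or a malformed numeric
    field is a hard :class:`FormatError`.
    """
    calls: list[SiteCall] = []
    lines = text.splitlines()
    start = 0
    if lines and lines[0].lower().startswith(("id\t", "#")):
        start = 1
    for lineno, line in enumerate(lines[start:], start + 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 4:
            raise FormatError("expected >=4 tab-separated fields", line=lineno)
        seq_id, residue = parts[0], parts[2].upper()
        try:
            position, score = int(parts[1]), float(parts[3])
        except ValueError as exc:
            raise FormatError(str(exc), line=lineno) from exc
        kinase = parts[4] if len(parts) > 4 and parts[4] else None
        if seq_id not in sequences:
            raise FormatError(f"unknown sequence id {seq_id!r}", line=lineno)
        seq = sequences[seq_id].replace("-", "").replace(".", "").upper()
        if not 1 <= position <= len(seq) or seq[position - 1] != residue:
            logger.warning(
                "line %d: %s position %d does not hold %s; row skipped",
                lineno, seq_id, position, residue,
            )
            continue
        if not 0 <= score <= 1:
            logger.warning("line %d: score %s outside [0,1]; row skipped",
                           lineno, score)
            continue
        calls.append(SiteCall(seq_id, position, residue, score, kinase))
    return calls


def min_count_for_fraction(n: int, fraction: float) -> int:
    """Smallest integer c with c/n >= fraction (e.g. 202 of 208 at 0.97).

    Float-robust: the naive ceiling is verified and nudged so that the
    defining inequality holds exactly under rational comparison.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    c = max(1, math.ceil(fraction * n - 1e-9))
    while c > 1 and (c - 1) / n >= fraction:
        c -= 1
    while c / n < fraction:
        c += 1
    return c


def _residue_supports(call_residue: str, ref_residue: str, mode: str) -> bool:
    if mode == "exact":
        return call_residue == ref_residue
    return call_residue in ACCEPTORS and ref_residue in ACCEPTORS


def conservation_tally(
    calls: list[SiteCall],
    gapmaps: dict[str, GapMap],
    reference_id: str,
    reference_sequence: str,
    params: ConservationParams | None = None,
) -> list[ConservedSite]:
    """Tally distinct supporting orthologues per reference position.

    The denominator is the number of sequences in ``gapmaps`` (the reference
    counts as one of them and may support its own sites).  Calls at or below
    the score threshold never count; calls whose housing column is gapped in
    the reference are unmappable and logged.  Multiple qualifying calls from
    one orthologue landing on the same reference position count once.
    """
    params = params or ConservationParams()
    if reference_id not in gapmaps:
        raise ConfigurationError(f"no gap-map for reference {reference_id!r}")
    missing = {c.seq_id for c in calls} - set(gapmaps)
    if missing:
        raise ConfigurationError(f"no gap-map for sequences: {sorted(missing)}")

    ref_map = gapmaps[reference_id]
    ref_seq = reference_sequence.replace("-", "").replace(".", "").upper()
    n = len(gapmaps)
    support: dict[int, set[str]] = {}
    n_unmappable = 0
    for call in calls:
        if not call.score > params.score_threshold:
            continue
        ref_pos = liftover_site(call.position, gapmaps[call.seq_id], ref_map)
        if ref_pos is None:
            n_unmappable += 1
            continue
        if _residue_supports(call.residue, ref_seq[ref_pos - 1],
                             params.residue_match):
            support.setdefault(ref_pos, set()).add(call.seq_id)
    if n_unmappable:
        logger.info("%d qualifying calls unmappable to %s (reference gapped)",
                    n_unmappable, reference_id)

    sites = [
        ConservedSite(
            ref_pos=pos,
            residue=ref_seq[pos - 1],
            count=len(ids),
            n_orthologues=n,
            supporting_ids=tuple(sorted(ids)),
        )
        for pos, ids in sorted(support.items())
    ]
    return tier_sites(sites, n, params)


def tier_sites(
    sites: list[ConservedSite],
    n: int,
    params: ConservationParams | None = None,
) -> list[ConservedSite]:
    """Assign each site the highest tier whose minimum count it meets."""
    params = params or ConservationParams()
    thresholds = {
        f: min_count_for_fraction(n, f) for f in params.tier_fractions
    }
    for site in sites:
        if site.count > n:
            raise ConfigurationError(
                f"site {site.ref_pos}: count {site.count} exceeds n={n}"
            )
        site.tier = "below"
        for f in sorted(params.tier_fractions, reverse=True):
            if site.count >= thresholds[f]:
                site.tier = _tier_label(f)
                break
    return sites


def _tier_label(fraction: float) -> str:
    pct = fraction * 100
    return f"{pct:.0f}%" if abs(pct - round(pct)) < 1e-9 else f"{pct:g}%"


def tier_report(
    sites: list[ConservedSite], n: int, params: ConservationParams | None = None
) -> dict:
    """Cumulative and disjoint-band tier counts.

    ``cumulative[f]`` counts sites whose fraction meets tier f or better;
    ``bands[f]`` counts sites whose highest tier is exactly f, plus a
    ``below`` band.  Cumulative counts are monotone non-increasing as the
    tier fraction rises.
    """
    params = params or ConservationParams()
    fractions = sorted(params.tier_fractions, reverse=True)
    thresholds = {f: min_count_for_fraction(n, f) for f in fractions}
    cumulative = {
        _tier_label(f): sum(1 for s in sites if s.count >= thresholds[f])
        for f in fractions
    }
    bands = {_tier_label(f): 0 for f in fractions}
    bands["below"] = 0
    for s in sites:
        bands[s.tier] = bands.get(s.tier, 0) + 1
    return {"n_orthologues": n, "cumulative": cumulative, "bands": bands}


def sites_to_tsv(
    sites: list[ConservedSite], annotation: DomainAnnotation | None = None
) -> str:
    """Export sites as TSV (ref_pos, residue, count, fraction, tier, domain)."""
    lines = ["ref_pos\tresidue\tcount\tfraction\ttier\tdomain"]
    for s in sites:
        lines.append(
            f"{s.ref_pos}\t{s.residue}\t{s.count}\t{s.fraction:.6f}"
            f"\t{s.tier}\t{annotate_domains(s.ref_pos, annotation)}"
        )
    return "\n".join(lines) + "\n"
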