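"""Secretion-signal score comparison across protein families.

Signal-peptide predictors summarise each protein with a handful of scores;
the mean per-residue "signal-peptideness" score (S_mean) is the quantity
compared here across orthologue families (gelatinase A vs vitronectin vs the
other secreted MMPs).  Because S_mean distributions are bounded on [0, 1] and
visibly skewed, families are compared with a two-sided Mann-Whitney rank-sum
test, Holm step-down correction over all pairs, and the resulting
indistinguishability structure is rendered as a compact letter display (CLD):
families sharing a letter are statistically indistinguishable at level alpha.

The rank-sum test is implemented from the definition of the U statistic —
exact enumeration of group assignments for small samples (both n <= 8),
normal approximation with continuity and tie corrections otherwise.
"""

from __future__ import annotations

import itertools
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SignalScoreRecord:
    """One protein's secretion-signal predictor summary."""

    protein_id: str
    family: str
    s_mean: float
    c_max: float | None = None
    y_max: float | None = None
    d_score: float | None = None

    def __post_init__(self):
        if not self.family:
            raise ValidationError(f"{self.protein_id}: empty family label")
        for name, v in (("s_mean", self.s_mean), ("c_max", self.c_max),
                        ("y_max", self.y_max), ("d_score", self.d_score)):
            if v is not None and not 0 <= v <= 1:
                raise ValidationError(
                    f"{self.protein_id}: {name}={v} outside [0, 1]"
                )


def parse_signalp_summary(text: str, family: str | None = None) -> list[SignalScoreRecord]:
    """Parse a SignalP-4.1-style short summary.

    Data lines are whitespace-delimited ``name Cmax pos Ymax pos Smean D``;
    ``#``-prefixed comment lines are ignored.  ``family`` labels every
    record; when omitted, the label is the record-name prefix before the
    first underscore (the convention the synthetic writer uses).
    """
    records = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise FormatError("expected 7 whitespace-delimited fields", line=lineno)
        name = parts[0]
        try:
            cmax, ymax = float(parts[1]), float(parts[3])
            smean, d = float(parts[5]), float(parts[6])
        except ValueError as exc:
            raise FormatError(str(exc), line=lineno) from exc
        fam = family if family is not None else name.split("_", 1)[0]
        try:
            records.append(
                SignalScoreRecord(name, fam, smean, cmax, ymax, d)
            )
        except ValidationError as exc:
            raise FormatError(str(exc), line=lineno) from exc
    return records


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #{a_i > b_j} + 0.5 * #{a_i == b_j}."""
    gt = (a[:, None] > b[None, :]).sum()
    eq = (a[:, None] == b[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def rank_sum_test(a, b, exact_max_n: int = 8) -> float:
    """Two-sided Mann-Whitney rank-sum p-value.

    Exact when both samples have at most ``exact_max_n`` observations (or
    the pooled size is at most 12): the null distribution of U is enumerated
    over all C(n+m, n) assignments of the pooled values, and the p-value is
    P(|U - nm/2| >= |u_obs - nm/2|).  Otherwise the normal approximation is
    used, with continuity correction and the tie-corrected variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("rank_sum_test requires two non-empty samples")
    n, m = a.size, b.size
    u_obs = _u_statistic(a, b)
    mu = n * m / 2.0

    if (n <= exact_max_n and m <= exact_max_n) or n + m <= 12:
        pooled = np.concatenate([a, b])
        dev = abs(u_obs - mu)
        hits = total = 0
        for idx in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(idx)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        return hits / total

    pooled = np.concatenate([a, b])
    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / (big_n * (big_n - 1))
    var = n * m / 12.0 * ((big_n + 1) - tie_term)
    if var <= 0:
        return 1.0  # every observation tied
    # continuity correction shrinks the deviation toward the mean
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(max(z, 0.0))))


def holm_adjust(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    k = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(k)
    running_max = 0.0
    for rank, idx in enumerate(order):
        running_max = max(running_max, (k - rank) * p[idx])
        adjusted[idx] = min(1.0, running_max)
    return adjusted


def compact_letter_display(different: np.ndarray) -> list[set[str]]:
    """Insert-and-absorb compact letter display.

    ``different`` is a symmetric boolean matrix with a False diagonal;
    entry (i, j) True means groups i and j are significantly different.
    Returns one set of letters per group satisfying the two CLD axioms:
    every non-different pair shares at least one letter, and every different
    pair shares none.  Letters are assigned 'a', 'b', ... in first-use order
    over group index.
    """
    diff = np.asarray(different, dtype=bool)
    k = diff.shape[0]
    if diff.shape != (k, k) or not np.array_equal(diff, diff.T):
        raise ValidationError("significance matrix must be square and symmetric")
    if diff.diagonal().any():
        raise ValidationError("diagonal must be False (a group equals itself)")

    groups: list[frozenset[int]] = [frozenset(range(k))] if k else []
    for i, j in itertools.combinations(range(k), 2):
        if not diff[i, j]:
            continue
        updated: list[frozenset[int]] = []
        for g in groups:
            if i in g and j in g:
                updated.extend(s for s in (g - {i}, g - {j}) if s)
            else:
                updated.append(g)
        # absorb duplicates and subsets
        groups = [
            g for idx, g in enumerate(updated)
            if not any(
                g < other or (g == other and idx > jdx)
                for jdx, other in enumerate(updated)
            )
        ]

    groups.sort(key=lambda g: (min(g), sorted(g)))
    letters: list[set[str]] = [set() for _ in range(k)]
    for letter, g in zip(_letter_stream(), groups):
        for member in g:
            letters[member].add(letter)
    return letters


def _letter_stream():
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for size in itertools.count(1):
        for combo in itertools.product(alphabet, repeat=size):
            yield "".join(combo)


@dataclass
class FamilyComparison:
    """Pairwise family comparison with letter groups.

    ``p_raw`` and ``p_adjusted`` are symmetric matrices with unit diagonal,
    indexed like ``families`` (sorted by name); ``letters[f]`` is the letter
    set of family f; ``like_reference[f]`` flags families sharing a letter
    with the designated reference family.
    """

    families: list[str]
    stats: dict[str, dict[str, float]]
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    alpha: float
    letters: dict[str, set[str]]
    like_reference: dict[str, bool] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        mat = self.p_adjusted < self.alpha
        np.fill_diagonal(mat, False)
        return mat

    def to_json(self) -> str:
        return json.dumps(
            {
                "alpha": self.alpha,
                "families": self.families,
                "stats": self.stats,
                "p_raw": self.p_raw.tolist(),
                "p_adjusted": self.p_adjusted.tolist(),
                "letters": {f: sorted(s) for f, s in self.letters.items()},
                "like_reference": self.like_reference,
                "excluded": self.excluded,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["family\tn\tmean\tmedian\tq1\tq3\tletters"]
        for f in self.families:
            s = self.stats[f]
            lines.append(
                f"{f}\t{s['n']:.0f}\t{s['mean']:.6f}\t{s['median']:.6f}"
                f"\t{s['q1']:.6f}\t{s['q3']:.6f}\t{''.join(sorted(self.letters[f]))}"
            )
        return "\n".join(lines) + "\n"


def family_comparison(
    records: list[SignalScoreRecord],
    alpha: float = 0.05,
    reference_family: str | None = None,
) -> FamilyComparison:
    """Compare S_mean distributions across families.

    Summary statistics per family, all pairwise rank-sum tests, Holm
    adjustment, significance at ``alpha``, and a compact letter display.
    Families with fewer than two members are excluded with a warning; at
    least two usable families are required.
    """
    by_family: dict[str, list[float]] = {}
    for r in records:
        by_family.setdefault(r.family, []).append(r.s_mean)

    excluded = sorted(f for f, v in by_family.items() if len(v) < 2)
    for f in excluded:
        logger.warning("family %s has n=%d < 2; excluded", f, len(by_family[f]))
    families = sorted(f for f in by_family if f not in excluded)
    if len(families) < 2:
        raise ValidationError("need at least two families with n >= 2")

    samples = {f: np.asarray(by_family[f]) for f in families}
    stats = {
        f: {
            "n": float(v.size),
            "mean": float(v.mean()),
            "median": float(np.median(v)),
            "q1": float(np.quantile(v, 0.25)),
            "q3": float(np.quantile(v, 0.75)),
        }
        for f, v in samples.items()
    }

    k = len(families)
    p_raw = np.ones((k, k))
    pairs = list(itertools.combinations(range(k), 2))
    flat = [rank_sum_test(samples[families[i]], samples[families[j]])
            for i, j in pairs]
    adj = holm_adjust(flat)
    p_adj = np.ones((k, k))
    for (i, j), pr, pa in zip(pairs, flat, adj):
        p_raw[i, j] = p_raw[j, i] = pr
        p_adj[i, j] = p_adj[j, i] = pa

    diff = p_adj < alpha
    np.fill_diagonal(diff, False)
    letter_sets = compact_letter_display(diff)
    letters = dict(zip(families, letter_sets))

    like_reference: dict[str, bool] = {}
    if reference_family is not None:
        if reference_family not in letters:
            raise ValidationError(
                f"reference family {reference_family!r} not among {families}"
            )
        ref_letters = letters[reference_family]
        like_reference = {
            f: bool(letters[f] & ref_letters) for f in families
        }

    return FamilyComparison(
        families=families,
        stats=stats,
        p_raw=p_raw,
        p_adjusted=p_adj,
        alpha=alpha,
        letters=letters,
        like_reference=like_reference,
        excluded=excluded,
    )


def records_to_long_tsv(records: list[SignalScoreRecord]) -> str:
    """Violin-ready long format: one (family, protein, s_mean) row each."""
    lines = ["family\tprotein_id\ts_mean"]
    lines += [f"{r.family}\t{r.protein_id}\t{r.s_mean:.6f}" for r in records]
    return "\n".join(lines) + "\n"
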