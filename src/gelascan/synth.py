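"""Synthetic inputs with controlled ground truth for every pipeline stage.

Each generator emulates one class of real input — an aligned orthologue
family with planted phospho-acceptor sites, per-family signal-score
distributions, a degradome quantification table with a planted myosin
fraction, and anti-phased periodic intensity profiles — and returns, next to
the records, a :class:`SyntheticTruth` recording exactly what was planted so
recovery can be asserted.

Design notes
------------
* Planted-site presence is *controlled*: for a family of n orthologues and a
  presence fraction p, exactly round(p*n) randomly chosen members carry a
  high-scoring site (uniform on (0.65, 1]); the rest score uniformly on
  [0, 0.65), so the strict >0.65 filter separates present from absent
  perfectly in the noiseless case.
* Indels are independent per-orthologue gap columns; the reference row is
  never gapped and planted-site columns are never gapped in any row, so
  every planted site has a defined coordinate in every sequence.
* All randomness flows from one ``numpy`` Generator per call: a fixed seed
  reproduces outputs byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .errors import ParameterError

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NON_MYOSIN_DESCRIPTIONS = (
    "alpha-actinin-2",
    "vitellogenin 1 precursor",
    "collagen alpha-1(I) chain",
    "keratin, type I cytoskeletal",
    "parvalbumin beta",
    "creatine kinase M-type",
)
MYOSIN_DESCRIPTION = "myosin heavy chain, fast skeletal muscle"


@dataclass(frozen=True)
class PlantedSite:
    """A phospho-acceptor planted at a reference position.

    ``presence`` is the controlled fraction of family members carrying a
    high-scoring prediction at the homologous column; score ranges give the
    uniform supports for present ((low, high]) and absent ([low, high))
    draws.
    """

    ref_pos: int
    residue: str  # S, T or Y
    presence: float
    present_score_range: tuple[float, float] = (0.65, 1.0)
    absent_score_range: tuple[float, float] = (0.0, 0.65)


@dataclass(frozen=True)
class FamilySimParams:
    n_orthologues: int
    ref_length: int
    indel_rate: float = 0.02
    substitution_rate: float = 0.05
    planted_sites: tuple[PlantedSite, ...] = ()
    reference_id: str = "ref"
    seed: int = 0

    def __post_init__(self):
        if self.n_orthologues < 1 or self.ref_length < 1:
            raise ParameterError("n_orthologues and ref_length must be >= 1")
        for rate in (self.indel_rate, self.substitution_rate):
            if not 0 <= rate <= 1:
                raise ParameterError(f"rate {rate} outside [0, 1]")
        seen = set()
        for site in self.planted_sites:
            if not 1 <= site.ref_pos <= self.ref_length:
                raise ParameterError(
                    f"planted position {site.ref_pos} outside 1..{self.ref_length}"
                )
            if site.residue not in "STY":
                raise ParameterError(f"planted residue {site.residue!r} not S/T/Y")
            if not 0 <= site.presence <= 1:
                raise ParameterError(f"presence {site.presence} outside [0, 1]")
            if site.ref_pos in seen:
                raise ParameterError(f"duplicate planted position {site.ref_pos}")
            seen.add(site.ref_pos)


@dataclass(frozen=True)
class DegradomeSimParams:
    n_peptides: int
    myosin_fraction: float = 0.0
    log_ratio_mean: float = 0.0   # natural-log scale
    log_ratio_sd: float = 1.0
    p1prime_bias: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_peptides < 1:
            raise ParameterError("n_peptides must be > 0")
        if not 0 <= self.myosin_fraction <= 1:
            raise ParameterError("myosin_fraction outside [0, 1]")
        if self.log_ratio_sd < 0:
            raise ParameterError("log_ratio_sd must be >= 0")
        if self.p1prime_bias is not None:
            bad = set(self.p1prime_bias) - set(AA20)
            if bad:
                raise ParameterError(f"unknown residues in p1prime_bias: {bad}")
            if any(w < 0 for w in self.p1prime_bias.values()) or \
                    sum(self.p1prime_bias.values()) <= 0:
                raise ParameterError("p1prime_bias weights must be >= 0, sum > 0")


@dataclass
class SyntheticTruth:
    """What the generator actually planted, aligned with the emitted records."""

    site_presence: dict[int, dict[str, bool]] | None = None
    site_presence_fraction: dict[int, float] | None = None
    family_means: dict[str, float] | None = None
    myosin: list[bool] | None = None
    extras: dict = field(default_factory=dict)


def simulate_orthologue_family(
    params: FamilySimParams,
) -> tuple[str, str, SyntheticTruth]:
    """Emit (aligned FASTA text, NetPhos-like site TSV, truth).

    The alignment has one column per reference residue; the reference row is
    ungapped.  Every member carries the planted residue at each planted
    column; ``presence`` controls only whether the member's prediction there
    scores above or below the 0.65 threshold (exactly round(presence*n)
    members score high).  All other columns mutate independently: gapped
    with ``indel_rate``, substituted with ``substitution_rate``.
    """
    rng = np.random.default_rng(params.seed)
    n, length = params.n_orthologues, params.ref_length
    planted_cols = {s.ref_pos for s in params.planted_sites}

    ref = rng.choice(list(AA20), size=length)
    for site in params.planted_sites:
        ref[site.ref_pos - 1] = site.residue

    ids = [params.reference_id] + [f"orth{i:04d}" for i in range(1, n)]
    rows = [ref.copy() for _ in range(n)]
    for row in rows[1:]:
        gap = rng.random(length) < params.indel_rate
        sub = rng.random(length) < params.substitution_rate
        for col in range(length):
            if (col + 1) in planted_cols:
                continue
            if gap[col]:
                row[col] = "-"
            elif sub[col]:
                row[col] = AA20[rng.integers(0, 20)]

    presence: dict[int, dict[str, bool]] = {}
    for site in params.planted_sites:
        n_present = int(round(site.presence * n))
        carriers = set(rng.permutation(n)[:n_present].tolist())
        presence[site.ref_pos] = {ids[i]: (i in carriers) for i in range(n)}

    fasta_lines = []
    for seq_id, row in zip(ids, rows):
        fasta_lines.append(f">{seq_id}")
        fasta_lines.append("".join(row))
    fasta_text = "\n".join(fasta_lines) + "\n"

    tsv_lines = ["id\tposition\tresidue\tscore\tkinase"]
    for i, (seq_id, row) in enumerate(zip(ids, rows)):
        residue_index = np.cumsum(row != "-")
        for site in params.planted_sites:
            col = site.ref_pos - 1
            pos = int(residue_index[col])
            lo, hi = (
                site.present_score_range
                if presence[site.ref_pos][seq_id]
                else site.absent_score_range
            )
            u = rng.random()
            # present draws lie in (lo, hi], absent in [lo, hi)
            score = hi - (hi - lo) * u if presence[site.ref_pos][seq_id] \
                else lo + (hi - lo) * u
            tsv_lines.append(
                f"{seq_id}\t{pos}\t{site.residue}\t{score:.6f}\tunsp"
            )
    tsv_text = "\n".join(tsv_lines) + "\n"

    truth = SyntheticTruth(
        site_presence=presence,
        site_presence_fraction={
            p: sum(d.values()) / n for p, d in presence.items()
        },
    )
    return fasta_text, tsv_text, truth


def _beta_params(mean: float, sd: float) -> tuple[float, float]:
    var = sd * sd
    limit = mean * (1 - mean)
    if var >= limit:
        raise ParameterError(
            f"spread {sd} too large for a Beta with mean {mean} "
            f"(needs sd < {limit ** 0.5:.4f})"
        )
    concentration = limit / var - 1
    return mean * concentration, (1 - mean) * concentration


def simulate_signal_scores(
    family_specs: list[tuple[str, int, float, float]], seed: int = 0
):
    """Draw per-family S_mean samples from Beta distributions.

    Each family spec is (name, n, mean, spread); spread is the target
    standard deviation of a Beta on (0, 1) with the stated mean (the Beta
    mean is exact, so large-n sample means converge to it).  ``spread == 0``
    degenerates to a constant.  Returns (records, truth); family names must
    not contain underscores (record ids are ``<family>_<i>``).

    The companion C/Y/D scores are drawn from the same Beta — they are
    carried through parsing but not analysed.
    """
    from .sigscores import SignalScoreRecord

    rng = np.random.default_rng(seed)
    records = []
    means = {}
    for family, n, mean, spread in family_specs:
        if not 0 < mean < 1:
            raise ParameterError(f"{family}: mean {mean} outside (0, 1)")
        if spread < 0:
            raise ParameterError(f"{family}: negative spread")
        if "_" in family:
            raise ParameterError(f"family name {family!r} contains '_'")
        if n < 1:
            raise ParameterError(f"{family}: n must be >= 1")
        means[family] = mean
        if spread == 0:
            draws = np.full((n, 4), mean)
        else:
            alpha, beta = _beta_params(mean, spread)
            draws = rng.beta(alpha, beta, size=(n, 4))
        for i in range(n):
            s, c, y, d = draws[i]
            records.append(
                SignalScoreRecord(
                    protein_id=f"{family}_{i:04d}",
                    family=family,
                    s_mean=float(s),
                    c_max=float(c),
                    y_max=float(y),
                    d_score=float(d),
                )
            )
    return records, SyntheticTruth(family_means=means)


def write_signalp_summary(records) -> str:
    """Serialise records in the SignalP-4.1-like short format."""
    lines = [
        "# SignalP-4.1 euk predictions (synthetic)",
        "# name Cmax pos Ymax pos Smean D",
    ]
    for r in records:
        lines.append(
            f"{r.protein_id}  {r.c_max:.3f}  22  {r.y_max:.3f}  22"
            f"  {r.s_mean:.6f}  {r.d_score:.3f}"
        )
    return "\n".join(lines) + "\n"


def lognormal_pass_probability(
    log_mean: float, log_sd: float, threshold: float = 3.0
) -> float:
    """P(ratio > threshold) for a log-normal H/L ratio (closed form)."""
    if log_sd == 0:
        return float(np.exp(log_mean) > threshold)
    return float(norm.sf((np.log(threshold) - log_mean) / log_sd))


def log_mean_for_pass_probability(
    p: float, log_sd: float, threshold: float = 3.0
) -> float:
    """Log-mean giving P(ratio > threshold) = p at the stated log-sd."""
    if not 0 < p < 1:
        raise ParameterError("target probability must lie in (0, 1)")
    return float(np.log(threshold) - log_sd * norm.ppf(1 - p))


def simulate_degradome(params: DegradomeSimParams):
    """Emit (PeptideRecord list, truth) with a planted myosin fraction.

    Peptides are random amino-acid strings (length 8-20) whose first (P1')
    residue follows ``p1prime_bias``; each record is myosin with probability
    ``myosin_fraction`` (Bernoulli, recorded per record in the truth);
    ratios are log-normal.
    """
    from .degradome import PeptideRecord

    rng = np.random.default_rng(params.seed)
    aa = np.array(list(AA20))
    if params.p1prime_bias is None:
        weights = np.ones(20)
    else:
        weights = np.array([params.p1prime_bias.get(c, 0.0) for c in AA20])
    weights = weights / weights.sum()

    records, myosin = [], []
    for i in range(params.n_peptides):
        length = int(rng.integers(8, 21))
        first = rng.choice(aa, p=weights)
        rest = rng.choice(aa, size=length - 1)
        peptide = str(first) + "".join(map(str, rest))
        is_myosin = bool(rng.random() < params.myosin_fraction)
        desc = (
            MYOSIN_DESCRIPTION
            if is_myosin
            else _NON_MYOSIN_DESCRIPTIONS[
                int(rng.integers(0, len(_NON_MYOSIN_DESCRIPTIONS)))
            ]
        )
        ratio = float(
            np.exp(params.log_ratio_mean + params.log_ratio_sd * rng.normal())
        )
        records.append(PeptideRecord(peptide, desc, ratio))
        myosin.append(is_myosin)
    return records, SyntheticTruth(myosin=myosin)


def write_degradome_tsv(records) -> str:
    """Serialise peptide records; ratios keep full float precision."""
    lines = ["peptide\tprotein_description\thl_ratio"]
    lines += [
        f"{r.peptide}\t{r.protein_description}\t{r.hl_ratio!r}" for r in records
    ]
    return "\n".join(lines) + "\n"


def simulate_profiles(
    period: float,
    phase_shift: float,
    length: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Two periodic nonnegative profiles offset by ``phase_shift`` periods.

    With zero noise, phase 0 gives identical profiles and phase 0.5 an
    exactly anti-phased pair (Pearson r = -1); noise is additive Gaussian,
    clipped at zero.
    """
    from .profiles import IntensityProfile

    if period < 4:
        raise ParameterError("period must be >= 4 pixels")
    if length < 3:
        raise ParameterError("length must be >= 3")
    rng = np.random.default_rng(seed)
    x = np.arange(length, dtype=float)
    offset, amplitude = 2.0, 1.0
    a = offset + amplitude * np.sin(2 * np.pi * x / period)
    b = offset + amplitude * np.sin(2 * np.pi * (x / period + phase_shift))
    if noise_sd > 0:
        a = a + rng.normal(0, noise_sd, length)
        b = b + rng.normal(0, noise_sd, length)
    return (
        IntensityProfile(np.clip(a, 0, None)),
        IntensityProfile(np.clip(b, 0, None)),
    )
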