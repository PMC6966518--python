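# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic generators do and do not emulate, and
the design decisions taken where more than one reading was defensible.

## Coordinate liftover (gap-map)

A gap-map indexes one aligned row: residue position i (1-based) maps to the
alignment column housing it, and columns map back to residue positions,
with gap columns returning an explicit undefined (`None`). Lifting a site
from orthologue *o* to the reference is the composition
`aln_to_seq(ref) ∘ seq_to_aln(o)`; when the reference is gapped at the
housing column the site is reported unmappable rather than snapped to a
neighbouring residue — nearest-residue fallback would fabricate
conservation at whatever residue happens to flank an indel. Coordinates
are 1-based and closed throughout, matching biological residue numbering
and the domain intervals below. Gap characters are `-` and `.` (the latter
normalised to `-` on read); any other non-residue character is an error.

## Orthologue curation

`select_longest_per_gene` keeps the isoform with maximal ungapped length
per gene, breaking length ties toward the lexicographically smallest
accession so the result is order-independent. The alignment-membership
filter removes rows for three reasons, checked in this order:

* `short-sequence` — ungapped length below the window (the gap rule is
  undefined for such rows, so they are removed explicitly);
* `divergent-start` — first non-gap column differs from the modal first
  non-gap column by more than `start_tolerance` (default 0; modal ties
  break toward the smallest column index);
* `gap-in-window` — any gap character within the first `window` (default
  15) alignment columns.

The "first fifteen amino acids" rule is interpreted in *alignment columns*
of the already-trimmed block, because gaps only exist in alignment
coordinates; the window is a parameter for anyone preferring the
per-sequence-residue reading. Alignment trimming itself is not
re-implemented — inputs are taken as trimmed. The filter is idempotent and
its retained/removed partition always covers the input exactly.

## Phosphosite conservation tiering

A reference position is supported by an orthologue iff that orthologue has
a prediction (a) scoring **strictly above** the threshold (default 0.65 —
"higher than" is strict), (b) lifting onto that reference position, and
(c) residue-compatible under the match mode. Distinct orthologues are
counted, not calls: several qualifying calls from one sequence landing on
the same reference position count once. The reference's own calls count
toward its sites (it is one of the n sequences; a 202-of-208 count
includes it).

Tier membership is **inclusive**: a site meets tier f when its count
reaches `min_count_for_fraction(n, f)`, the smallest integer c with
c/n ≥ f (202 for n = 208, f = 0.97; computed with a verified ceiling so
float rounding can never shift the boundary). Reports give both
*cumulative* counts (sites meeting ≥ f) and *disjoint bands* (highest tier
reached), because banded presentations of 100/99/97% classes are ambiguous
between the two; neither is privileged.

The default residue-match mode is `exact` (a serine call supports only a
serine at the reference position), since serine, threonine and tyrosine
sites are biologically distinct phospho-acceptors; `acceptor-class`
(any S/T/Y supports any S/T/Y) is available as an option for the looser
question "is a phosphorylatable residue conserved here?".

Domain annotation uses the zebrafish gelatinase A architecture — signal
1–29, propeptide 30–107, catalytic 118–446, hemopexin 463–657, 1-based
closed — with positions 108–117 and 447–462 (and anything past 657)
reported as `inter-domain`.

## Signal-score comparison

The compared quantity is S_mean as read from predictor output; per-residue
S tracks are never recomputed. The statistical machinery is a deliberate
choice the upstream analysis left open, and is therefore configurable:

* **Test**: two-sided Mann–Whitney rank-sum. S_mean is bounded and
  skewed, so a rank test is assumption-light. Implemented from the
  definition of U (pair counting, ties at half weight): exact enumeration
  of all C(n+m, n) group assignments when both samples are ≤ 8 or the
  pooled size is ≤ 12, otherwise the normal approximation with continuity
  correction and tie-corrected variance. The exact branch's two-sided
  p-value is P(|U − nm/2| ≥ |u_obs − nm/2|) under permutation.
* **Multiplicity**: Holm step-down over all family pairs, α = 0.05 by
  default.
* **Letters**: insert-and-absorb compact letter display. The output
  satisfies two axioms — every pair *not* significantly different shares a
  letter, every significantly different pair shares none — and letters are
  assigned in first-use order over families sorted by name, so reports are
  reproducible. A `reference_family` (vitronectin in the motivating
  analysis) can be designated; families sharing a letter with it are
  flagged indistinguishable-from-reference.

Families with fewer than two members are excluded with a warning; a
comparison needs at least two usable families.

## Degradome filtering

Ratios are taken as already normalized (optional median-centering of log2
ratios is provided for raw tables, default off). The enrichment filter is
strict: H/L > threshold (default 3; a ratio of exactly 3 fails). The P1′
residue of a neo-N-terminal peptide is its first residue; Ile/Leu/Val at
P1′ is the gelatinase A–characteristic set (configurable). Categories are
case-insensitive keyword matches on the protein description (default rule:
"myosin" — note the keyword list must be chosen so unintended matches such
as tropo*myosin* are acceptable or excluded for the table at hand).
Percentages round half-to-even to integer percent (12/49 = 24.49% → 24).
When nothing passes the filter, fractions are reported as undefined, never
0. Peptide-to-protein assignment is taken from the input table.

## Profile correlation

The sample Pearson correlation coefficient between two equal-length
intensity profiles, with Spearman available by flag: the upstream analysis
reports only "correlation coefficients", and Pearson is the default
reading for intensity data. Constant profiles and length mismatches are
errors, not NaNs. Extracting profiles from micrographs is out of scope.

## Synthetic data

The generators emit exactly the dialects the readers parse, and return the
planted truth alongside the records. Defaults and key choices:

* **Orthologue family** — the alignment has one column per reference
  residue; the reference row is never gapped and planted columns are never
  gapped in any row, so every planted site has defined coordinates
  everywhere. Other columns are independently gapped (`indel_rate`,
  default 0.02) or substituted (`substitution_rate`, default 0.05) per
  orthologue. Site presence is *controlled*: exactly round(presence·n)
  randomly chosen members carry a high-scoring site — uniform on
  (0.65, 1] — and the rest score uniformly on [0, 0.65), making the strict
  0.65 filter a perfect separator in the noiseless case. The reference
  scale used in tests (n = 208, reference length 60, three planted sites)
  keeps the 100-seed recovery check fast while preserving the count
  arithmetic of the 208-orthologue analysis, which depends on n, not on
  sequence length.
* **Signal scores** — Beta distributions parameterised by mean and target
  standard deviation (mean exact by construction, support (0, 1) exact);
  spread 0 degenerates to a constant. The planted default 0.795 mirrors
  the zebrafish gelatinase A S_mean as a realistic low-recognition value.
* **Degradome** — peptide lengths 8–20, first residue drawn from
  `p1prime_bias` (uniform by default), myosin identity Bernoulli per
  peptide, ratios log-normal. `log_mean_for_pass_probability` inverts the
  closed-form tail P(ratio > t) = Φ̄((ln t − μ)/σ) so pass rates can be set
  analytically.
* **Profiles** — sinusoids (offset 2, amplitude 1) with a phase shift in
  periods; phase 0.5 gives an exactly anti-phased pair (r = −1), additive
  Gaussian noise is clipped at zero.

What the generators do **not** emulate: phylogenetic correlation between
orthologues (substitutions are independent), predictor score correlation
with sequence context, realistic amino-acid composition, peptide
detectability bias, or sarcomere-shaped (non-sinusoidal) intensity
profiles. Passing recovery tests therefore demonstrates that the pipeline
arithmetic — liftover, counting, filtering, testing — is correct, not that
any upstream predictor is accurate on real sequences.

## Numerical choices and degenerate inputs

* `min_count_for_fraction` verifies its ceiling against the defining
  inequality, immune to float artefacts like 0.97·100 = 96.999….
* Rank-test p-values under total ties are 1 (zero variance handled
  explicitly); exact-branch comparisons use a 1e-12 slack so boundary
  permutations are never dropped.
* All-gap alignment rows build valid gap-maps with zero mapped residues;
  any lookup on them is undefined rather than an error.
* Empty prediction files load as empty call lists; invalid rows
  (residue/position mismatch, score outside [0, 1], non-numeric ratios)
  are skipped per row with a logged reason, so one bad export line does
  not abort an analysis, while structural problems (missing columns,
  unknown ids, ragged alignments) are hard errors.
* Every stochastic routine takes a single integer seed through
  `numpy.random.default_rng`; fixed seed means byte-identical outputs.

## CLI configuration

`gelascan simulate` reads a YAML config with up to four blocks (`family`,
`signal`, `degradome`, `profiles`), whose keys mirror the corresponding
`synth` parameter dataclasses, e.g.:

```yaml
family:
  n_orthologues: 208
  ref_length: 60
  planted_sites:
    - {ref_pos: 10, residue: S, presence: 1.0}
    - {ref_pos: 25, residue: T, presence: 0.98}
    - {ref_pos: 40, residue: Y, presence: 0.5}
  seed: 1
signal:
  families:            # name, n, mean, spread
    - [MMP2, 80, 0.795, 0.06]
    - [MMP9, 80, 0.93, 0.04]
    - [Vtn, 80, 0.95, 0.03]
  seed: 1
degradome:
  n_peptides: 321
  myosin_fraction: 0.24
  log_ratio_mean: -0.0293   # P(ratio > 3) = 49/321 at sd 1.1
  log_ratio_sd: 1.1
  seed: 1
```

Analysis subcommands expose the thresholds (score 0.65, tiers, ratio 3,
window 15, α) as options with the defaults above. Every output carries a
provenance header (package version, a hash of the effective configuration,
and the seed where randomness was involved); logs go to stderr and results
only to declared output paths. Validation failures exit non-zero with a
single-line `ERROR <class>: <message>`.

## Known limitations

* The letter groups depend on the chosen test/α; other defensible choices
  (t-tests, Dunn's test, different α) can merge or split groups.
* Keyword-based categories inherit the quirks of free-text protein
  descriptions (substring collisions, inconsistent naming).
* The conservation denominator is the full sequence set handed to the
  tally; pre-filtering (curation) changes n and therefore tier boundaries.
* Exact rank-sum enumeration grows combinatorially; beyond the small-sample
  branch the normal approximation is used even when samples are moderately
  small with heavy ties.
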