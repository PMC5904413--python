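# Methods

## The duplex model

A spacer is a 32-nt DNA string (the nontarget-strand sense), position 1
being the PAM-proximal base; a target site is a 3-nt PAM immediately 5′ of
a 32-nt protospacer on the same strand. Spacer and protospacer are
compared base-for-base in the DNA alphabet. Positions 6, 12, 18, 24 and 30
are flipped out of the crRNA:DNA duplex by the Cas7 backbone, so they are
excluded from every mechanistic quantity:

* **L**, the PAM-proximal contiguous match length, is the position before
  the first *non-flipped* mismatch (a lone mismatch at position 6 leaves
  L = 32);
* window requirements ("all positions 4–18 matched") and mismatch tallies
  are evaluated over non-flipped positions only.

The seed is positions 1–5 and 7–8; the "extension" positions 7–9 are
tracked separately because they compensate for suboptimal PAMs.

## PAM classes

PAMs are classified by a total 64-entry table: AAG → optimal, CCG → null,
everything else → suboptimal. Only AAG (optimal) and CCG (dead) are firmly
established in vivo; mapping the remaining 62 3-mers to an intermediate
class is a deliberate simplification and the table is user-editable.

## The outcome classifier

The in vivo panel data give outcomes, not rules; the classifier encodes the
minimal rule set consistent with all 13 variants, fully exposed in
`ClassifierConfig`:

| tier | default rule |
| --- | --- |
| stable binding | PAM ≠ null, non-flipped 4–18 all matched, ≤ 3 mismatches in 1–3 |
| transient binding | not stable; positions 1–`k_seed` (=5) matched; PAM optimal, or suboptimal with ≥ 2 matches at 7–9 |
| primed adaptation | stable and non-flipped 4–24 all matched |
| interference | priming, non-flipped 4–32 all matched, position 1 matched, ≤ 2 non-flipped mismatches in 1–8 |

Notes on genuinely open points:

* The rules imply interference ⇒ priming ⇒ stable binding, which holds for
  every profile × PAM class (property-tested), and adding a match never
  downgrades an outcome (monotonicity, property-tested).
* Variant xiii (mismatches at 7–24) classifies as *transient*: its intact
  1–5 seed plus AAG PAM satisfies the same rule that detects genuine
  off-target sites genome-wide. Bulk enrichment assays score such a
  single-copy site as background; the transient tier is the model's
  statement that Cascade still samples it. All boundary results (four
  priming-only variants; inert binding up to L = 18) are unaffected.
* Position 6 shows statistical match enrichment at bound sites (the
  binomial test below) but is mechanistically flipped out, so it never
  counts toward any rule window.
* Seed length plausibly varies between crRNAs (5–10 nt); `k_seed` is a
  parameter, not a constant.
* The crRNA handle lengths default to 8 nt (5′) and 21 nt (3′) so a 32-nt
  spacer yields the canonical 61-nt processed crRNA; handle base content is
  user-supplied (placeholder N runs otherwise) since only lengths matter
  downstream.
* The Chi-similarity window is ambiguous by one position (an 8-nt motif
  against a −1…+8 span); the default window is the last PAM base plus
  spacer positions 1–7, and any 8-position window over PAM/spacer
  coordinates can be selected instead.

## The 13-variant panel

Variants i–xiii: i AAG/full match; ii CCG/full; iii ATT/full; iv
AAG/mm{1,2,3}; v, vi AAG/mm{1,3} with different substituted bases; vii,
viii AAG/mm{2,3} with different substituted bases; ix AAG/mm{25–32}; x
AAG/mm{19–32}; xi AAG/mm{1–6}; xii AAG/mm{1–6, 25–32}; xiii AAG/mm{7–24}.
Forced mismatches use the transversion partner (A↔C, G↔T) by default —
guaranteed to differ whatever the spacer base — and the transition partner
for the "alternative substitution" variants vi and viii.

## Genome scanning

Enumeration is exhaustive: every offset on both strands is evaluated as a
3 + 32 window against every spacer (no index or seeding heuristic —
desk-scale genomes don't need one, and the scanner is verified window by
window against a brute-force oracle on every run of the test suite). The
inner loop is vectorized over offsets with numpy; windows containing
ambiguity codes are skipped and counted. A window is a hit when the
classifier's binding tier is nonzero. Coordinates are 0-based half-open
(BED convention) on the forward strand. On i.i.d. random sequence the
AAG-gated seed-5 rule expects 2·(L−34)/64/4⁵ ≈ 30.5 hits per Mb; the
empirical count is checked within 3 Poisson SD.

## ChIP quantification

Coverage is fragment-pileup depth at single-base resolution; relative
coverage divides by (total reads / 100,000). The peak caller is plumbing,
not a contribution: maximal runs above a threshold, merged across gaps
≤ `merge_gap` (default 100 bp), discarded below `min_width`, center =
leftmost argmax. R² between datasets is the squared *Pearson* correlation
of normalized coverage at peak centers (the conventional meaning of R²);
zero-variance inputs report a missing value. A peak is associated with the
best-scoring candidate site within ±250 bp of its center (most matched
non-flipped positions, then nearest, then leftmost) — the association rule
is a design choice, as is the ±250 bp radius (comparable to ChIP fragment
scale).

## Exact tests

Both hypothesis tests are computed by enumeration with exact integer
arithmetic, not asymptotics:

* **Fisher (positions 7–9 vs PAM class).** The printed per-site means and
  class sizes determine a position-pooled 2×2 table
  [matched, mismatched] × [non-AAG, AAG] with row totals 3·n per class;
  that construction is adopted here (a per-site ≥2-of-3 dichotomization is
  the obvious alternative and can be built from the same matrix). The
  two-sided p sums hypergeometric weights ≤ the observed table's weight;
  weights are exact integers, so ties need no floating-point slack. The
  test suite checks it against an independent factorial/Fraction oracle
  (exhaustively for small tables, randomized up to total 200, 1e-12
  relative) and against `scipy.stats.fisher_exact`.
* **Binomial (position-6 enrichment).** One-sided tail P(X ≥ k | n, p₀)
  with p₀ = 0.25 (one of four bases), computed by direct summation — in
  exact rational arithmetic when p₀ has a small rational form (the default
  does), correct to the last float bit for n ≤ 10⁴; otherwise by
  log-space summation with `math.fsum` (~1e-11 relative at n = 10⁴). The
  one-sided alternative reflects the directional question (enrichment
  above chance); two-sided is available by flag.

Sites with ≥ 27 matched non-flipped positions (i.e. a complete non-flipped
duplex) are treated as on-target and excluded from motif statistics.

## Pooled-variant estimators

Reads are assigned by exact occurrence of a variant's *distinguishing
window* — the shortest, then leftmost, substring of its reference absent
from every other reference in either orientation — searching both the read
and its reverse complement; reads matching zero or ≥ 2 windows are
unassigned. Exact matching only: a sequencing-error tolerance would need
an error model that is out of scope.

Estimators (reference variant maps to exactly 1.0; all are invariant to
per-condition depth):

* ChIP enrichment: e_v = (chip share / input share), normalized to the
  optimal variant;
* interference efficiency: i_v = (no-cas3 share / +cas3 share), normalized
  to the dead-PAM variant — larger means stronger depletion under Cas3;
* transformation efficiency: (cas3/vector colony ratio) over the
  empty-vector control's ratio, zero numerators reported against the
  assay's limit of detection (3e-5);
* adaptation: reporter-positive fraction, and array-expansion units
  round((amplicon − parental)/61), one unit = 32-nt spacer + 29-nt repeat
  (the repeat length is a design constant; only the spacer length is
  mechanistically fixed at 32).

Pseudocount policy: 0.5 is added to *all* counts only when some cell is
zero, and the affected variants are flagged (`is_bound`) — their ratios
are detection bounds, not point estimates, matching how zeros are reported
against a limit of detection rather than as ratios at zero.

## The synthetic-data generator

`make_genome` draws i.i.d. bases at a given GC fraction. `plant_sites`
writes 35-nt PAM+protospacer blocks whose per-position match profile
against a chosen spacer is exact by construction (forced mismatches use
the transversion partner); minus-strand blocks are written so the reverse
complement of the genomic slice reads PAM-then-protospacer.

`simulate_chip_coverage` models each bound site as a Poisson number of
fragments (mean = affinity weight) adding unit-area Gaussian kernels
(default sd 60 bp, a typical sonication fragment scale) at the site
midpoint, over per-base Poisson background (default 1 fragment/base); the
realized fragment total is reported for depth normalization.
`simulate_pool_counts` draws one multinomial over renormalized
abundance × effect.

The default off-target cohort (one on-target site plus 60 off-target
sites, 41 AAG : 19 suboptimal-PAM, intact 1–5 seed everywhere, position-6
match probability 0.45, mean 7–9 matches 1.2/3 for AAG vs 2.2/3 for
suboptimal-PAM sites, PAM-distal positions at the 1-in-4 background rate)
mirrors the structure of in vivo Cascade binding-site sets: suboptimal-PAM
sites persist only with extension matches, so the cohort reproduces the
extension-vs-PAM association by construction. Off-target affinity weights
are log-uniform at < 20% of the on-target weight, with optimal-PAM sites
drawing mildly higher affinities so the most enriched regions skew toward
AAG. What the generator deliberately does **not** emulate: sequencing
error, read-level alignment artifacts, mappability and copy-number biases,
chromatin accessibility, or crosslinking chemistry — so passing tests
demonstrate correctness of the arithmetic and detection logic on idealized
signal, not robustness to real-data noise.

## Problem sizes and numerical choices

The test suite and analysis scripts run at desk scale by design: oracle
equivalence on 20 random 2–10 kb genomes, hit-rate calibration on one
1-Mb genome, ChIP recovery on a 220-kb genome with 50–61 sites, pooled
estimators at 10⁵ reads × 13 variants × 3 seeds. Stochastic checks use
3-SD bands derived from the relevant Poisson/multinomial error (delta
method on log ratios). All randomness flows from explicit integer seeds;
fixed seeds give byte-identical outputs. Degenerate inputs (empty spacer
sets, zero reference counts, all-zero effect vectors, zero-variance R²
inputs, windows off contig ends) raise `ValueError` or report missing
values rather than guessing.

## Known limitations

The classifier is a rule set over match geometry, not a thermodynamic or
kinetic model: it predicts outcome tiers, not binding free energies or
ChIP signal magnitudes. PAM classes other than AAG/CCG are a single
undifferentiated "suboptimal" tier. The scanner's ungapped model cannot
represent bulged R-loops. The peak caller makes no claim of equivalence to
any published ChIP peak-calling method.
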