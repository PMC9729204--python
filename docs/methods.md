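# Methods

This note documents the models, numerical conventions and design choices
behind `ampliscore`, and what the synthetic test fixtures do and do not
establish about behaviour on real genomes.

## Piecewise logistic scoring

Every feature score comes from the six-parameter curve
`(MinO, MaxO, Min, Max, MinL, MaxL)` described in the README: a plateau of 1
over the optimal range `[MinO, MaxO]`, logistic tails on both sides with
steepness `k = 10/(MinO−MinL)` (so the tail spans ±5 logistic units over the
`[MinL, MinO]` interval), zero crossings exactly at `Min`/`Max`, and
saturation toward `−y0` beyond the limits. Scores are never clamped: a
severely out-of-range feature contributes a negative score, which is what
lets one catastrophic feature (e.g. heavy off-target load) sink an otherwise
good pair without any hard filter.

Boundary conventions, chosen once and pinned by tests:

* `x = MinO` evaluates the **left tail** (`f_GC(0.55) ≈ 0.97511`, not 1);
  the plateau is the half-open interval `(MinO, MaxO]`. The discontinuity
  is bounded by `(1+y0)·e⁻⁵/(1+e⁻⁵)` (≈ 2.5 % for the GC model).
* Exception: when `MinO = MaxO` the optimal "range" is a single point, which
  would otherwise be unattainable; that point scores exactly 1. This is what
  makes a primer with exactly one 3′-terminal adenine (`EndA` model
  `(1, 1, 0, 4, −1, 7)`) a full-score primer, so that an all-optimal primer
  totals exactly 100.
* A branch with `MinO = MinL` (or `MaxO = MaxL`) is disabled — score 1 on
  that whole side. Several built-in models use this deliberately: Self has
  no lower penalty, the bound-Tm and mismatch-distance models have no upper
  penalty, the oEff and SNP/poly-position models have no lower penalty.
* Exponents are guarded at 700 before `exp()`; beyond that the tail returns
  its asymptote `−y0` directly.

Built-in parameter sets (configuration order `MinO, MaxO, Min, Max, MinL,
MaxL`): Tm `(T, T+1, T−2, T+5, T−5, T+10)` around the user's optimum T
(default 60 °C); GC `(0.55, 0.6, 0.45, 0.65, 0.3, 0.7)` as fractions;
Self `(−50, 45, −50, 50, −50, 55)` °C; EndA `(1, 1, 0, 4, −1, 7)` bases;
EnddG `(−9, −7, −12, −6, −14, −5)` kcal/mol; SNP/poly position
`(0, 0, 0, 10, 0, 10)` bases from the 3′ end; poly length
`(15, 100, 0, 100, 0, 100)`; SNP length `(15, 100, −15, 100, −15, 100)`;
bound Tm `(60, 100, 45, 100, 45, 100)` °C; mismatch distance
`(25, 100, 0.95, 100, 0.95, 100)`; Tmdiff `(0, 1, 0, 4, 0, 8)` °C; Lendiff
`(0, 2, 0, 6, 0, 10)` bases; Pos `(10, 20, 5, 45, 5, 45)` bases; Dis
`(120, 160, 100, 180, 80, 200)` bases; oEff `(0, 0, 0, 0.02, 0, 0.1)`.
The mismatch-distance lower limit of 0.95 is deliberate: a 3′-terminal
mismatch still amplifies a trace of product, and with these constants its
factor is ≈ 1.406·10⁻⁴, just above the default 10⁻⁴ efficiency cutoff.

SNP/poly composite penalty: `1 − Σⱼ a·[f(pⱼ)+b]·f(lⱼ)` with `a = 4,
b = 0.2` for SNPs and `a = 2, b = 2` for polys; `pⱼ` is the 0-based distance
of the site from the 3′ end (a 3′-terminal variant is penalized most) and
`lⱼ` the variant/run length. An empty list scores exactly 1; the result is
unclamped. Note that with the boundary convention above a poly of length 15
at the 3′ terminus scores `1 − 6·(1−e⁻⁵) ≈ −4.9596` (the length factor
evaluates the left tail at its own MinO), not −5 exactly.

### Weights

Only the column sums (100 per table) are externally constrained; the split
is this package's choice and is fully configurable. Defaults: primer
features Tm 30, GC 15, Self 15, EnddG 15, SNP 15, poly 7, EndA 3; relation
features oEff 50, Dis 25, Pos 15, Tmdiff 6, Lendiff 4; pair composition
Primer1 25, Primer2 25, relation 50. Rationale: Tm, GC, product size and
specificity dominate amplification efficiency in multiplex practice, while
3′-adenine count and inter-primer Tm/length differences have little effect.
For tasks without a target spot (generic, full-coverage tiling) the Pos
feature does not exist; its weight is redistributed proportionally over the
remaining relation features.

## Thermodynamics

Two-state nearest-neighbor model with the unified (1998) DNA parameter set;
`Tm = ΔH·1000/(ΔS_salt + R·ln(Cₜ/4)) − 273.15` for bimolecular duplexes at
equal strand concentrations, with entropy salt correction
`ΔS + 0.368·(N−1)·ln[Na⁺]_eq` and divalent-to-monovalent conversion
`[Na⁺]_eq = [mono] + 120·√([divalent]−[dNTP])` (mM inside the root).
Defaults: 50 nM oligo, 50 mM monovalent, 1.5 mM divalent, 0.6 mM dNTP —
the conventional defaults of the widely used oligo-Tm tools, exposed in
configuration.

Mismatched hybrids (primer vs. genomic site, ungapped, full primer length):
a mismatched position voids its flanking stacks (they contribute no ΔH/ΔS)
and additionally pays a fixed **+2.0 kcal/mol** enthalpy penalty; both
duplex-initiation terms are always charged even when a terminus is
mismatched. These two constants are what make destabilization strictly
monotone — waiving the (unfavourable) A·T initiation on a mismatched
terminus would make that mismatch *stabilizing*, and in hot GC-rich duplexes
the removal of a weak TA stack alone can otherwise raise the two-state Tm.
Exact equivalence with any specific external engine is *not* a contract of
this module; the contracts are: perfect-match Tm equals the standard unified
NN value (cross-checked against an independent implementation), mismatches
never increase Tm, and all outputs are deterministic. An external
thermodynamics engine can be substituted by passing any object with the same
five methods (`oligo_tm`, `duplex_tm`, `self_tm`, `cross_dimer`, `end_dg`).

Self feature: the maximum of the best antiparallel self-dimer alignment
(all ungapped offsets with ≥ 4 overlapping bases, scored as a duplex) and
the best perfect-stem hairpin (stem ≥ 4 bp, loop ≥ 3 nt, unimolecular
`Tm = ΔH/ΔS` with a fixed −11.3 cal/mol/K loop-closure entropy, i.e.
≈ 3.5 kcal/mol at 37 °C). A sequence with no complementary stretch at all
(e.g. poly-A) reports −100 °C, "no structure". 3′-end stability is the sum
of the four stack ΔG° (37 °C) terms of the terminal five bases.

IUPAC-degenerate bases inside an evaluated primer are resolved to the
weakest-stacking allele (preference A, T, C, G) for Tm purposes; the
degenerate code itself is consumed by the SNP feature.

## Candidates and masking

Common variants are folded into the reference as IUPAC codes
(multi-allelic sites merge into one code); indels cannot be expressed as a
single-base code and are recorded in a side-channel interval table covering
`max(len(ref), len(alt)) − 1` bases (the bases after the anchor for a
deletion, the two junction bases for an insertion). Candidate walking emits
one candidate per (start, length) grid point and strand — defaults 18–30 nt
in steps of 2, position step 1 — ordered deterministically. SNP annotations
are parsed back out of each candidate's degenerate sequence (dist-to-3′-end
per code, length 1 unless covered by an indel interval); polys are
homopolymer runs ≥ 4 (configurable; di-/tri-nucleotide repeats are not
detected by the default detector, a conscious narrowing).

## Specificity search and products

Binding sites are found by exact k-mer seeding (word size 7, every primer
offset) over both strands, extended ungapped to the full primer length,
scored by the bound-efficiency model `f(btm)·Πⱼ f(mⱼ)` and kept at
≥ cutoff. The detection
contract is exact: any site sharing at least one exact 7-mer with the primer
is examined, so a 20-mer site with 7 substitutions (35 %) arranged to
preserve one 7-mer is still detected. Sites are deduplicated by locus and
sorted; partial-length dangling alignments are excluded (their bound Tm is
far below the 45 °C zero point anyway). The efficiency cutoff is a
parameter: the default 10⁻⁴ governs design, while a cutoff of 0 turns the
search into a pure detection-sensitivity instrument (used when measuring the
35 % contract, where the heavily mismatched site's efficiency is 0 by
construction).

Orientation geometry (0-based half-open coordinates):

* **face-to-face**: converging primers on opposite strands; `bdis` is the
  product size, the inclusive span from the plus-site 5′ end to the
  minus-site 5′ end (`minus.end − plus.start`). The product-efficiency
  distance model uses the task's optimal/permitted range with fixed limits
  MinL = 30 (shorter amplicons are not formed) and MaxL = maximum PCR size
  (default 2000, configurable).
* **back-to-back**: diverging primers (inverse PCR on a circularized
  template); `bdis` is the gap between the two 5′ ends
  (`plus.start − minus.end`), 0 when they are adjacent.
* **unidirectional**: outer and nested primer on the same strand; `bdis` is
  nested 5′ start minus outer 3′ end, negative when nested starts inside
  the outer primer (the anchored-PCR default range is −15…−10).

The same distance model is applied to non-target products of every
orientation. Product efficiencies `E₁·E₂·f(bdis)` are clamped at 0 (a
negative logistic factor means "no amplification") and products below the
cutoff are dropped. A pair's oEff is the total efficiency of all products —
cross products plus each primer's self-products, deduplicated by unordered
locus pair — minus its own target product.

## Design orchestration

All geometry- and position-legal candidate pairs are scored and ranked
descending; ties break by smaller oEff, then product size closest to the
optimal midpoint, then primer ids (the tie-break order is this package's
convention). The top `n_return` (default 3) pairs are reported per region or
target; fewer are returned, with a warning, if fewer legal pairs exist, and
an empty list with a warning is the only failure mode. Genotyping places
Primer1 upstream of the target within the position range; ARMS fixes the
Primer1 3′-terminal base on the target, one candidate per allele (read from
the target spot or the masked base), with no deliberate secondary mismatch
added; full-coverage tiling partitions the template into equal-width
half-open windows (`spacing` converts to a count by ceiling division) and
designs each window independently. Cross-dimer checking screens all
selected primers all-vs-all (self-pairings included) with the duplex engine
and reports hits at or above 45 °C (the Self model's MaxO; configurable) —
reporting only, no automatic re-selection.

Task presets map the published four-number ranges (optimal min/max,
permitted min/max) to the six-parameter form by adding the same saturation
margins the built-in defaults carry: ±20 bases for distance models, ±0 for
position models. Presets: generic and ARMS dis `(120, 160, 80, 200)`;
Sanger genotyping dis `(530, 570, 500, 600)`, pos `(100, 150, 70, 300)`;
inverse dis `(5, 10, 0, 15)`; anchored dis `(−15, −10, −30, −5)`; ARMS pos
`(0, 0, 0, 0)` (a fully degenerate model scoring 1 everywhere, correct since
the ARMS primer's 3′ end sits on the target by construction).

### Performance bounds

Single-primer features, scores, binding sites and pair products are cached
per distinct sequence (pair). For product accounting each primer
contributes its `max_sites_per_primer` most efficient sites (default 30):
on pathological repeat templates a primer can bind hundreds of loci, the
enumeration is quadratic in site count, and the oEff score model already
saturates at 0.1 summed efficiency — far below what 30 near-perfect sites
contribute — so the truncation cannot change any score materially. The
full, uncapped site list is always available from `find_binding_sites`.

## Synthetic fixtures: what they show and what they do not

The generator emulates the features the engine's logic depends on: random
references with controlled GC, duplicated segments at controlled divergence
(predictable off-target products), planted primer sites with chosen mismatch
counts preserving one exact seed word, SNPs emitted as VCF, homopolymer
insertions and target spots, all reproducible from a seed with a
machine-readable truth table. Test problem sizes are deliberately desk
scale — references of 1–10 kb, templates of a few hundred bases, coarsened
walking grids in the slower end-to-end tests — chosen so the whole suite
runs in about a minute while still exercising every code path, including a
brute-force oracle equivalence over 20 seeded fixtures and a 100-template
no-failure sweep over hostile (extreme-GC, repeat-riddled) sequences.

What passing these tests does **not** establish: behaviour on mammalian-
genome-scale references (the in-memory k-mer index targets references up to
a few Mb; genome-scale search would use the pluggable aligner hook), the
wet-lab accuracy of the efficiency predictions (the model constants are
taken as given, not re-calibrated here), dimer detection sensitivity for
weak minor dimers, and any claim about real sequence composition biases —
synthetic references are i.i.d. draws plus planted structure, which real
genomes are not.

## Known limitations

* Ungapped alignment only, full primer length; bulge/gap binding modes and
  partial 3′-dangling hybrids are not modelled.
* The thermodynamic engine has no mismatch-specific NN corrections (a
  uniform penalty stands in for the full mismatch tables) and no partition-
  function secondary structure.
* Degenerate masking approximates indels with an interval side-channel
  rather than an extended degenerate alphabet.
* Multi-tube distribution / compatible-set selection is out of scope; the
  cross-dimer report is informational.
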