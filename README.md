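# ampliscore

Score-based primer design for multiple PCR variants — generic (face-to-face),
genotyping and ARMS, inverse (back-to-back), anchored (unidirectional) and
fully-covered tiling panels — with in-silico prediction of the amplification
efficiency of every target and non-target product.

Most primer-design tools filter candidates against hard parameter cutoffs and
fail outright when no candidate survives, forcing users to loosen parameters
and start over. `ampliscore` instead **scores** every candidate and always
returns the highest-scoring pairs: a design can be poor, but it cannot fail
(unless no geometrically legal pair exists at all). It is aimed at anyone
designing mono- or multiplex PCR panels — genotyping assays, amplicon
sequencing, fusion detection with anchored primers, inverse PCR on
circularized templates.

## The scoring model

Every feature *x* (melting temperature, GC fraction, product size, …) is
mapped to a score by a piecewise logistic curve with six parameters, written
in the order `(MinO, MaxO, Min, Max, MinL, MaxL)`:

```
        ⎧ L /(1+e^(−k(x−x0))) − y0    x ≤ MinO        (left sigmoid tail)
f(x) =  ⎨ 1                           MinO < x ≤ MaxO  (optimal range)
        ⎩ L′/(1+e^(−k′(x−x0′))) − y0′ x > MaxO        (right sigmoid tail)

k = 10/(MinO−MinL),  x0 = (MinO+MinL)/2,  y0 = e^(k(Min−x0)),  L = 1+y0
```

(mirrored for the primed right-branch constants). By construction
`f(Min) = f(Max) = 0` and the score saturates near `−y0` beyond the limits.
A branch with `MinO = MinL` is disabled and scores 1 on that side.

Seven single-primer features (Tm, GC, Self, EndA, EnddG, SNPs, polys) and
five pair-relation features (Tmdiff, Lendiff, Pos, Dis, oEff) are scored this
way and combined as weighted sums; each weight table sums to 100, so an
all-optimal primer scores exactly 100, and the pair score is the weighted
mean of Primer1, Primer2 and the relation. Covered common variants and
homopolymers are penalized as `1 − Σⱼ a·[f(pⱼ)+b]·f(lⱼ)` over their distances
to the 3′ end and lengths.

Specificity is evaluated by enumerating products: every binding site of a
primer on the reference (exact-word seeding, word size 7, so sites with up to
35 % mismatches remain detectable) gets a bound efficiency
`E = f(btm)·Πⱼ f(mⱼ)` from its bound Tm and mismatch positions, every legal
site pair gets a product efficiency `E_prod = E₁·E₂·f(bdis)`, and the sum of
all non-target product efficiencies (oEff) is scored as the pair's
specificity feature. Products below an efficiency cutoff (default `1e−4`)
are discarded. Melting temperatures come from a built-in nearest-neighbor
thermodynamic engine (unified parameter set, salt-corrected two-state model);
any object with the same five methods can be plugged in instead.

## Worked example

Generate a reproducible 1.2 kb synthetic reference with six common SNPs,
then design generic primers against it:

```bash
ampliscore fixture --seed 11 --length 1200 --snps 6 --out fx
ampliscore design --preset generic --templates fx/reference.fa \
    --vcf fx/variants.vcf --opt-tm 60 --out pairs.tsv --dimer-out dimers.tsv
```

The log reports `wrote 3 ranked pair(s) for 1 region(s)/target(s)` and
`cross-dimer screen: 0 hit(s) in 21 comparisons`; `pairs.tsv` echoes the
full effective configuration in its header and then the ranked pairs
(abridged columns):

```
target         rank  primer1_seq             score1   score2   relation_score  final_score  dis  oeff
synth1:0-1200  1     GAGGCGCTGATCAACGCA      99.3983  99.3983  100.0           99.6991      158  0.0
synth1:0-1200  2     GTTTGGGAATATCAGCACCCGA  97.3549  96.8411  100.0           98.549       146  0.0
synth1:0-1200  3     GAGTGTCTATCAGCCTAGCGCA  98.0708  96.3983  99.0361        98.1353      124  0.0
```

Reading the top row: both primers score ≈ 99.4 of 100 (every feature inside
or near its optimal range), the relation score is a full 100 — product size
158 bp sits in the optimal 120–160 window, the primers' Tm and length
differences are negligible, and `oeff = 0` means the pair amplifies nothing
but its target on this reference — giving a final pair score of 99.7.
`dimers.tsv` lists any primer–primer duplexes with melting temperature at or
above 45 °C across the whole selected panel (none here, in 21 pairwise
comparisons of the 6 selected primers, self-pairings included).

Other entry points: `ampliscore design --preset arms|inverse|anchored
--targets targets.bed …`, `ampliscore evaluate --primers list.tsv` for
pre-designed primers, `ampliscore mask` to fold a VCF of common variants
into a reference as IUPAC degenerate bases. The same functionality is
available as a library (`ampliscore.design.design`,
`ampliscore.specificity.find_binding_sites`, …).

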