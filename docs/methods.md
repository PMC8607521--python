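# Methods

## Problem

Protein domains are annotated in peptide coordinates (PfamScan alignment
start/end on a translated transcript), while somatic cancer mutations are
catalogued in genomic coordinates. To ask whether a domain family is
mutated more often than expected, the two must share a coordinate system.
This package converts domain peptide coordinates to genomic coordinates
through the transcript's exon structure, counts type-filtered somatic
mutations inside the resulting exonic blocks per cancer type, normalises the
counts by each family's cumulative length, and calls significantly mutated
domains (SMDs) with an empirical-null local false discovery rate.

## Coordinate model

All coordinates are 1-based and fully inclusive (Ensembl GTF convention);
every length is `end − start + 1`. Amino acid `i` occupies coding-sequence
nucleotides `(i−1)·3+1 … i·3`. The stop codon is the final three CDS
nucleotides and never counts toward the peptide length, so a CDS of
`3·(L+1)` nucleotides codes `L` amino acids; fixtures may declare a CDS
without a stop (`has_stop=False`). Transcripts whose coding length is not a
positive multiple of 3, or that have no CDS (directly annotated or
derivable as exon minus UTR), are excluded with a warning — incomplete
annotations are skipped rather than guessed at.

Conversion walks the ordered coding blocks 5′→3′ and slices out the
nucleotide range of the requested amino-acid span, splitting at every exon
boundary. Codons may straddle exon boundaries. Reported endpoints follow
transcript orientation, so reverse-strand output has start > end;
downstream interval queries normalise to (min, max). Two span conventions
are exposed: the inclusive span (`max − min + 1`) and the plain endpoint
difference (`|end − start|`), because printed tables sometimes quote the
latter; on the six-exon reference fixture these are 2428 and 2427. The
correctness oracle in the test suite is a per-base brute force: enumerate
every CDS nucleotide 5′→3′, assign codon index `⌈i/3⌉`, and collect; the
implementation must agree base-for-base over randomized exon structures,
strands and domain ranges.

Domain boundaries default to PfamScan alignment coordinates; an `envelope`
switch uses the wider envelope instead. Hits are filtered at e-value ≤ 0.01
(inclusive, so a hit printed as 0.01 is retained).

## Mutation mapping

COSMIC-style rows are classified by regex on the description text; only
nonsense, missense, coding-silent and complex events are mapped — intronic
and unknown events fall outside coding domains or lack usable detail.
Multi-base events are anchored at their first genomic base. Containment is
tested against the domain's *exonic blocks*, never the whole start–end
span: a position in an intron gap does not count, consistent with the
intronic exclusion. A record inside blocks of several families increments
each family once, but counts once in the "mapped" total; several isoform
mappings of one family count once per record (dedupe on record × family),
preventing isoform inflation. Percentages of mapped mutations are truncated
(not rounded) to two decimals, matching how such tables are conventionally
printed (1376/2085 → 65.99). Stabbing queries run on per-chromosome
interval trees; the test suite checks equivalence with an exhaustive scan.

## SMD statistic

For family *f* in cancer type *s*, with accumulated count *c* and
cumulative amino-acid length *L* over all occurrences of *f*:

    p = c / (3 L)        (mutations per coding nucleotide; `basis="aa"`
                          divides by L instead)
    z = p / sqrt(p (1 − p))

*p* is clamped into `[ε, 1−ε]` (ε = 1e-9, configurable) because *z* is
undefined at 0 and 1; clamps are logged and reported. The nucleotide basis
is the default because mutations are genomic events; the choice only
rescales *p* monotonically and so does not change rankings within a site.

Within each cancer type the z population is modelled as a two-group
mixture. The marginal density *f* is estimated by Poisson regression of
histogram counts (120 equal-width bins) on a cubic B-spline basis with 7
degrees of freedom. The empirical null *f₀ = N(δ, σ²)* is found by central
matching: a quadratic is fitted to the log smoothed counts over the bins
holding the central 50% of the data, giving σ from the curvature, δ from
the slope, and π₀ from the ratio of the implied null peak to the marginal,
capped at 1. Then

    fdr(z) = π₀ f₀(z) / f(z),   truncated into [0, 1],

and a family is called an SMD when `fdr(z) < 0.1` **and** `z ≥ δ`. The
second condition makes the call one-sided: the local fdr is symmetric, and
without it families far *below* the null centre — typically unmutated
families sitting at the lower clamp — would be "significant" despite being
mutation-deficient, which is not the hypothesis. The standalone `call_smds`
helper applies only the strict `fdr < threshold` filter; the model object
applies the one-sided rule. The 0.1 threshold balances discovery against
false positives and is configurable. Fewer than 200 scores (or a degenerate
sample, or a non-concave central fit) falls back to the theoretical N(0, 1)
null with π₀ = 1, with a warning — too few families cannot support an
empirical null.

Zero-count families stay in the z population by default (at the lower
clamp) so the null is anchored by unmutated and weakly mutated families; a
switch excludes them. Top-k ranking is ascending locfdr with ties broken by
higher count, then accession text. The family × cancer-type locfdr matrix
is emitted in sorted order with 1.0 sentinels; hierarchical clustering and
rendering are left to the caller.

## Synthetic worlds

`simulate_world` emulates the statistical structure the analysis assumes:
uniform background substitution with elevated rates inside planted driver
domains. Genes are laid end to end on 23 chromosomes; each transcript has
1–6 exons of 120–400 nt separated by introns of 200–2000 nt, a short 5′UTR,
a stop codon and a 3′UTR. Extra isoforms (mean 1.2 transcripts per gene)
are identical copies with distinct ids, and their duplicated Pfam hits
exercise the isoform dedupe. Domains of 25–60 aa are placed without overlap
(1–3 per transcript). Background families are drawn from a pool sized to
give each about two occurrences, as real Pfam families recur across genes;
planted families are placed on 8 distinct genes each. About 5% of hits are
decoys with e-value > 0.01 to exercise the filter.

Mutations are per-base Bernoulli draws over all coding bases:
`mutations_per_site` (default 100) independent sweeps — think tumour
samples — at `background_rate` (default 2 × 10⁻⁴) per base per sweep,
multiplied inside planted family blocks. Coding mutation types are sampled
as 70% missense, 10% nonsense, 10% coding-silent, 10% complex, and a
further 10% of all records are intronic/unknown to exercise the type
filter. The defaults (300 genes, ≈240 families per site, expected
background counts of a few mutations per family occurrence) match a
mid-sized cancer mutation set and give each site comfortably more than the
200 scores the empirical null requires. Everything is driven by one
`numpy` generator seeded from the config: the same seed yields
byte-identical files.

What the generator does *not* emulate: trinucleotide mutational signatures,
sample-level clonality and recurrence, overlapping genes, alternative
splicing beyond identical isoform copies, and realistic domain length or
family-size distributions. Passing tests therefore demonstrate the
pipeline's arithmetic and the estimator's calibration under the assumed
sampling model, not performance on real COSMIC data.

## Reference fixtures

Two hand-checkable transcripts encode the conversion edge cases. Fixture 1:
one exon, reverse strand; an 83-aa domain (aa 112–194) maps to a single
249-nt block read 73,700,972 → 73,700,724, so the inclusive span equals the
coding length. Fixture 2: six exons, forward strand; a 66-aa domain
(aa 10–75) starts in exon 1 at 23,980,225 and ends in exon 3 at 23,982,652;
its 198 coding nt are interrupted by introns of 638 and 1592 nt
(2230 total), endpoint difference 2427, inclusive span 2428. Details the
printed quantities do not constrain (peptide lengths 200 and 120 aa, sizes
of exons 4–6 and of the UTRs) are arbitrary but fixed; only the constrained
quantities are asserted.

## Numerical choices and limitations

- Central matching fits the quadratic to the *smoothed* log counts (the
  GLM fit), not raw log counts, avoiding log-of-zero in sparse bins.
- The marginal density is evaluated by clipping queries into the observed z
  range; far-tail queries reuse the boundary value, which is conservative
  for fdr (the marginal cannot vanish under the null density).
- σ estimation requires the central quadratic to be concave; otherwise the
  theoretical-null fallback triggers with a warning rather than producing a
  nonsensical spread.
- Discreteness: with small counts the z population is only
  quasi-continuous (counts are integers, lengths vary); the spline marginal
  absorbs this, but very sparse populations (most families at zero) defeat
  central matching — the estimator then refuses (fallback) rather than
  miscalibrate.
- The per-site problem sizes used in the test suite and examples
  (300-gene worlds, 4 sites, ~240 families, n = 5000 draws for the
  estimator checks) are the package's chosen desk-scale study conditions;
  genome-scale inventories are out of scope.
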