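# Methods

This note documents the models, conventions and numerical choices behind
`divscan`, in the spirit of the methods documentation of packages like
`msprime` or `statsmodels`: what is computed, under which assumptions,
and what the synthetic-data tests do and do not demonstrate.

## The analysis

`divscan` contrasts the genomic architecture of coding-sequence
divergence between two lineages anchored on one reference genome. The
canonical use case is a speciation continuum: an "early" comparison
(recently separated populations, most genes still identical) versus a
"late" comparison (long-separated sister species, nearly all genes
divergent). The pipeline stages are:

1. **classify** — transcripts are placed on the genome from tabular
   alignment hits and discriminated by position and occurrence:
   `scaffold_paralog` (hits on several scaffolds), `tandem_paralog`
   (several non-overlapping loci on one scaffold), `allelic` (several
   transcripts of one collection at reciprocally overlapping positions),
   `exon` (one locus split into co-linear segments, i.e. an
   intron-containing gene) and `uniq` (one contiguous locus). Only
   `uniq`/`exon` transcripts are paired across collections, one pair per
   locus; ambiguous loci are dropped and logged.
2. **cds** — six-frame translation selects the longest run of codons
   bounded by stop codons or the sequence ends (no start codon
   required); candidates with ambiguous bases or gaps, shorter than
   300 nt, or (optionally) without a protein annotation at e ≤ 1e-10
   are dropped with machine-readable reasons. Paired CDSs are trimmed
   to their common in-frame overlap using anchor coordinates rather
   than re-aligned — the pairs this pipeline retains are near-identical
   by construction, and pairs that cannot be brought into a common
   frame are dropped, not rescued.
3. **rates** — pairwise dN, dS, ω = dN/dS, κ and per-codon divergence
   t = 3(S·dS + N·dN)/(S+N) per gene (see below).
4. **seltest** — codon-bootstrap test of D = dN − dS > 0 with
   Benjamini–Hochberg FDR across genes; a gene is called positively
   selected when ω > 1 and q < α.
5. **scan** — genes ordered by anchor midpoint along scaffolds
   > 300 kb; per-scaffold divergence patterns, Fisher's dispersion
   index of inter-divergent-gene distances, per-scaffold Pearson
   correlation of t with ω, and a genome-wide OLS regression of dN
   on dS.

## Rate estimation

Both counting methods reduce an alignment to a codon-pair count vector
and evaluate dot products with precomputed tables (`divscan._codon`),
so single genes and bootstrap replicate batches share one vectorized
core.

**NG86** (equal-pathway counting). Synonymous sites per codon are
counted from single-nucleotide mutation opportunities; mutations that
would create a stop codon are not opportunities, and each codon is
renormalized to 3 sites so that S + N = 3L. This is the convention of
the PAML programs; biopython instead counts a stop-creating change
toward N, and the cross-check test converts between the two explicitly.
Differences between codons are averaged with equal weight over all
minimal mutational pathways, excluding pathways through stop codons
(all orderings are used in the rare case that every pathway is
blocked); codons differing at three positions average over the six
orderings. Jukes–Cantor correction maps pS = Sd/S and pN = Nd/N to
distances; when 4/3·p ≥ 1 the gene is flagged `saturated` and no finite
estimate is reported.

**YN00-style counting.** Codon usage is estimated from the pair by
position-specific nucleotide frequencies (F3x4, stops excluded and
renormalized). κ is estimated from sites that are fourfold-degenerate
(or nondegenerate) in both codons, via the Kimura two-parameter
solution on the transition/transversion proportions of each class,
combining the two classes weighted by their site counts; if neither
class is informative κ falls back to 1 and the gene is flagged.
Synonymous site fractions per codon weight each single-nucleotide
change by κ (transitions) and by the F3x4 frequency of the target
codon. Differences use the same equal-pathway counting as NG86 (the
equal-weighting configuration), split into transition and transversion
components, and the distance correction is a per-site-class K2P
correction (on PS, QS at synonymous sites and PN, QN at nonsynonymous
sites). This is a deliberate non-iterative transcription of the
counting scheme: it reproduces the method's two essential corrections
(κ and codon usage in the site counts) without the original's
fixed-point iteration, and its agreement with NG86 in the κ=1,
uniform-usage limit and its recovery of simulation truth are asserted
by tests rather than assumed.

**Edge rules for ω.** Genes with dN = dS = 0 get ω = 0 (flag
`identical`). Genes with dN > 0 but dS = 0 get S·dS reset to 1
(dS := 1/S, i.e. one synonymous change assumed missed by chance), flag
`dS_zero_reset`; these are excluded from estimator-recovery summaries.
Non-finite estimates are never written as numeric sentinels: the fields
are left empty and the gene carries `saturated`/`infinite_filtered`
flags.

**Standard errors** on dS and dN are delta-method approximations on the
difference proportions, reported for information only; the selection
test relies on the bootstrap instead.

**Saturation policy.** A gene whose synonymous sites are saturated has
divergence beyond any threshold used by the scan, so such genes count
as divergent for pattern classification and fall in the open top bin of
the divergence summary, while being excluded from means, correlations
and the regression (which require finite estimates). At late-stage
divergence a substantial fraction of genes saturate; this mirrors what
the original analysis reports for fast-evolving genes and is the reason
the late-stage per-scaffold t–ω correlation is frequently undefined
here.

## Selection test

Each replicate resamples the L codon columns with replacement — drawn
as a multinomial over the observed codon-column multiset, which is the
identical distribution and lets all replicates be evaluated in one
vectorized pass. D = dN − dS is recomputed per replicate with the same
method as the main run. The statistic is z = D_obs/sd(D_reps) (sample
sd, n−1) with a one-sided normal p-value; centering the numerator on
the replicate mean instead is available as an option and is numerically
near-identical. Replicates that saturate are excluded from the spread
and flagged. If the spread is zero the test is degenerate: p = 0 when
D_obs > 0, else p = 1 (identical genes land here with p = 1). FDR
control is Benjamini–Hochberg step-up (via statsmodels), with
Benjamini–Yekutieli behind a flag.

Calibration, measured by the acceptance suite at true ω = 1 (t = 0.2,
κ = 2, 300 codons, 200 replicates, 500 genes): the fraction of genes
with p < 0.05 is well under 0.10. Power at ω = 5 greatly exceeds the
null rate (paired comparison in the unit tests).

## Scaffold scan

Gene position is the anchor midpoint; distances are in bp. Pattern
classes: `A_none` (no gene with t above `t_div`, default 0.1),
`C_island` (a run of ≥ `min_run` = 3 consecutive divergent genes, or
more than `max_isolated` = 2 divergent genes), else `B_isolated`. The
run/isolated thresholds are the automated surrogate for a by-eye
clustering judgement and are configurable. Fisher's dispersion index is
the sample (n−1) variance of consecutive inter-divergent-gene distances
over their mean; it needs at least three divergent genes, scales
linearly with distance units, and its "≈1 means random" calibration
strictly applies to counts rather than distances — it is computed here
exactly as defined on distances, so treat it as a relative clustering
score. Scaffolds shorter than 300 kb (configurable; 400 kb is the other
documented choice) are excluded; Pearson r needs more than 5 genes with
finite t and ω and positive variance in both.

## The synthetic-data generator

The generator is the package's study system: it produces everything
the pipeline consumes with known per-gene truth.

**Codon process.** Continuous-time, single-nucleotide steps on the 61
sense codons: a change is weighted κ if a transition and ω if
nonsynonymous; changes creating stops have rate 0. The clock is scaled
so the expected number of substitutions per codon, averaged over a
uniform sense-codon composition, equals the branch length; each lineage
evolves t/2 from a uniform-codon ancestor (pairwise estimators see only
the total path). Composition drift away from uniform makes the realized
rate drift slightly at extreme ω or very long t; at the divergences
used here the realized mismatch density tracks t to within a few
percent (asserted at t = 0.1). No indels, no codon-frequency-biased
mutation, no within-population polymorphism — pairs only.

**Regimes.** `early`: 58% of genes strictly identical; divergent genes
draw t from 0.015 + Exponential(mean 0.025) substitutions/codon, so the
divergent mode sits near 0.025, the overall mean near 0.017, and a
small exponential tail exceeds t = 0.1; ω is a purifying-dominated
mixture (44% in (0,0.25), 36% in (0.25,0.5), 14% in (0.5,1), 6% above
1). The offset keeps "identical" a property of the truth rather than a
sampling accident (a gene with t ≥ 0.015 at 300 codons is virtually
never realized with zero differences). `late`: 0.4% identical, t from a
truncated Normal(1.8, 0.5) (so ~96% of genes exceed t = 0.75), ω
mixture with a 30% dN = 0 ("frozen") class and 2% above 1. κ = 2 in
both regimes. These marginals were set once from the two study
conditions the generator emulates and are not tuning knobs.

**Layout and complications.** Scaffolds of 400–600 kb carry 8 genes of
300 codons placed in non-overlapping slots; islands of divergence can
be placed explicitly as (scaffold, start gene, run length, t) entries.
A small fraction of genes (3% each by default) receive exactly one
complication — an extra hit on another scaffold, a second locus on the
same scaffold, an extra allelic transcript, or an intron-split anchor
(2–3 transcript-contiguous segments separated by 200–2000 bp on the
scaffold). Complications are mutually exclusive per gene so truth
labels stay unambiguous, and they are generated at the category
definitions' extremes, which is why classifier recovery on synthetic
bundles is exact; real hit tables with fuzzier boundaries would
exercise the `overlap_frac`/`gap_tolerance_bp` thresholds more than
these tests do. Transcripts are UTR + CDS + stop + UTR with an in-frame
stop terminating the 5' UTR, so the six-frame extractor recovers the
generated CDS exactly; real transcripts with long stop-free UTR runs
could in principle yield a longer ORF elsewhere.

**What passing tests show.** Exact category recovery, exact ortholog
pairing, unbiased recovery of (t, ω, κ) at moderate divergence, and the
early/late landscape contrast all hold on data generated under the
pipeline's own assumptions (no indels, congruent exon structure, clean
anchors). They do not demonstrate robustness to assembly artifacts,
alignment noise, or paralogy that evades positional discrimination.

## Determinism and problem sizes

Every stochastic step descends from one integer seed through
`numpy.random.SeedSequence` spawning (per-gene streams for the
generator, per-gene streams for the bootstrap), so a config + seed
reproduces byte-identical outputs; manifests record the seed and a
config hash. Default problem sizes in the acceptance runs — 2,000
genes for the early regime, 320 for the late regime, 500 genes for
recovery/calibration batches, 200 bootstrap replicates (1,000 in
production use) — were chosen as the smallest sizes at which the
binomial/Monte-Carlo noise of the reported fractions is comfortably
below the tolerances being checked.
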