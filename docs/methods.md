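# Methods

`trnactx` analyses the genomic context of tRNA genes in nematode-style
genomes: which tRNAs sit inside introns of protein-coding genes, whether the
pairing of a tRNA type (anticodon) with its host gene is conserved across
species, how RNA polymerase III occupancy and promoter-associated chromatin
marks differ between intronic and non-intronic tRNAs, and whether the genes
that host tRNAs are unusually uniform in their expression levels. This note
documents the models, conventions and numerical choices behind each stage,
and what the synthetic-data generator does and does not emulate.

## Coordinates and input formats

All coordinates are 0-based half-open internally (the UCSC convention of
genePred/BED/bedGraph). The tRNA tabular dialect follows tRNAscan-SE:
1-based inclusive coordinates with `begin > end` encoding the minus strand,
converted at the read boundary. Anticodons are upper-cased with U mapped to
T. Signal tracks are piecewise-constant bedGraph intervals; positions not
covered by any interval are *missing*, which is deliberately distinct from a
zero score — profile averages report a per-offset `n` so that the treatment
of unmeasured positions is always auditable.

## Intronic classification

Introns are the gaps between consecutive exons of a gene model, indexed
1..n−1 in transcription order (genomically reversed on the minus strand).
A tRNA is **intronic** when its interval is fully contained in a single
intron; a tRNA that overlaps a transcript without satisfying containment is
non-intronic with an `ambiguous_overlap` flag. A `transcript` containment
mode (containment anywhere in the transcript span) is available because the
two readings — "within introns" and "within transcripts" — give slightly
different sets; full-intron containment is the default as the stricter and
better-defined rule. When overlapping gene models both contain a tRNA the
host is the gene with the smallest containing intron, ties broken
lexicographically and flagged.

Non-intronic tRNAs get their nearest non-overlapping protein-coding gene on
each side. Sides are **tRNA-strand-relative** (upstream = the tRNA's 5′
side); distance is the gap between nearest boundaries, 0 when abutting;
genes whose transcript span overlaps the tRNA are never neighbors.

The observed intronic count is tested against a genomic-proportion null:
expected probability = merged intronic bp (union over transcripts, so
overlapping models are not double-counted) divided by total genome size
(sum of chromosome lengths from an explicit chrom-sizes input), using a
1-df chi-square goodness of fit.

## Anticodon–host pairing and conservation

Each intronic tRNA contributes the pair (anticodon, host gene); several
same-anticodon copies in one host collapse to a single pair, while distinct
anticodons in one host stay distinct pairs. Pseudo and functional tRNAs are
never mixed. For a target species, a reference pair (ac, g) is conserved iff
g has an ortholog g′ and (ac, g′) is a pair in the target; reference pairs
whose gene has no ortholog are removed from the denominator. Conservation is
directional (reference → target). Ortholog maps are explicit one-to-one
inputs; duplicated reference keys are input errors, because no many-to-many
resolution rule is defined here.

Two null pair classes mirror the same construction for non-intronic tRNAs
(nearest upstream / downstream neighbor) and a third uses pseudo tRNAs and
their hosts as a negative control.

### Distance-windowed conservation and extrapolation

To ask whether neighbor-pair conservation is merely a function of
tRNA-to-gene distance, non-intronic records are sorted by distance and
scanned with k windows of w records each (defaults w=40, k=20). The stride
is `step = round((N − w)/(k − 1))`, clipped to ≥1; at N=363 this gives
step 17 and a 57.5% overlap between adjacent windows. Windows always have
exactly w records; when rounding leaves a tail of the largest distances
uncovered, a warning reports how many records fell outside all windows.
Each window's conservation is computed exactly as above, restricted to its
records (each tRNA record is scored; a flag deduplicates to distinct pairs
within the window). An unweighted cubic least-squares fit of window
conservation against window median distance is evaluated at distance 0; its
uncertainty is the standard error of the mean prediction at x=0 from the
fit covariance with residual variance (df = n − 4). Windows have equal n by
construction, which is why the fit is unweighted.

### Pool similarity

Pseudo (or functional) tRNA pools of two species are compared as
per-anticodon gene-copy counts with Spearman correlation over the union of
anticodons, absent anticodons counted as 0 (an intersection-only mode
exists). The union-with-zeros default preserves "pool composition"
semantics: an anticodon absent from one pool is informative, not missing.

## Signal profiles

Every tRNA is anchored at its first mature nucleotide (gene start on +,
end−1 on −). Offsets are strand-relative: +x means x bases 3′ of the
anchor, so minus-strand rows run against genome order and mirrored loci on
opposite strands produce identical rows. Profile matrices cover
[−F, F) with F=1000 by default; per-offset means ignore missing cells and
report n. The per-tRNA Pol III occupancy proxy is the maximum of the
occupancy Q-value track over the strand-relative window [−100, +100) —
the upstream peak-assignment procedure of the original occupancy data is
not re-specified anywhere, so a peak-style window maximum is used and a
peak-table input can bypass the rule. Chromatin marks use the windows
[−500, −100) (H3K4me3, the promoter-proximal enrichment window) and
[−200, +200) (H3K27ac).

Group comparisons (intronic vs non-intronic occupancy; same-strand vs
opposite-strand intronic tRNAs) use a two-sided Wilcoxon rank-sum test.
Occupancy–mark correlations are Spearman over tRNAs with defined scores on
both sides.

## Expression breadth

For the set of tRNA-hosting genes, per-life-stage width is the sample
standard deviation of log10(FPKM+1) (IQR available). The null draws N=500
random gene sets of the same size, without replacement within a set, from
all genes with a defined value at that stage; the one-sided empirical
p-value is (r+1)/(N+1) with r the number of resamples at least as narrow as
observed — the floor at N=500 is 1/501 ≈ 0.002 and p is never 0. Host
genes missing a stage value are dropped for that stage and the effective
set size is used. One-sided is used because the hypothesis is specifically
"narrower". Per-stage RNGs are spawned from the master seed, so results are
bit-stable given the seed.

## Statistical primitives

* **Rank-sum**: mid-ranks; exact two-sided p by full enumeration of all
  C(n, n_a) labelings for pooled n ≤ 12 (ties handled by enumerating over
  the observed pooled multiset; two-sided = 2·min(tails), capped at 1);
  otherwise a normal approximation with tie-corrected variance and a 0.5
  continuity correction. The approximation agrees with enumeration to
  ≤0.02 on untied small samples; under heavy ties near p≈1 the two can
  diverge more, which is why the exact path is the small-n default.
* **Spearman**: mid-ranks, Pearson on ranks, two-sided p from the t
  approximation with n−2 df (appropriate for the n≈30–600 range used
  here; an exact mode is not provided). A zero-variance rank vector yields
  an explicitly `undefined` result. For |ρ|=1 the p-value is floored at
  the smallest positive float so p stays in (0, 1].
* **Chi-square GOF**: Σ(O−E)²/E with E=N·p, df = cells−1; E=0 is a
  degenerate-null error.
* **Polynomial prediction**: OLS on a Vandermonde design; prediction SE at
  x₀ from s²(XᵀX)⁻¹ with s² = RSS/(n−deg−1); rank deficiency is an error.
* **Empirical p**: (r+1)/(N+1), ties count as extreme.

No multiple-testing correction is applied anywhere; the stage p-values are
reported as-is, deliberately.

## Synthetic data: what is emulated, and what is not

The generator builds a reference species and configurable target species
with: multi-exon gene models packed left-to-right with random intergenic
gaps (no overlapping genes by default); functional and pseudo tRNA genes
with anticodons drawn from a fixed 46-anticodon alphabet; bedGraph
occupancy and two histone-mark tracks; one-to-one ortholog maps with a
retention rate; and a six-stage expression table. Every analysis target is
a planted parameter:

| parameter | default | rationale |
|---|---|---|
| functional / pseudo tRNA genes | 609 / 211 | the reference genome's counts |
| planted intronic fraction | 0.44 | the observed intronic share of coding tRNA genes |
| same-strand fraction of intronic | 0.5 | not printed numerically anywhere; agnostic default |
| per-target pair conservation | 0.52, 0.45, 0.38, 0.32, 0.05 | spans the observed 32–52% ingroup range plus a near-zero distant outgroup |
| ortholog retention | 0.9 | typical congeneric one-to-one ortholog coverage |
| occupancy model | lognormal, log-mean 2.0, log-sd 0.6, intronic shift −0.8, opposite-strand offset +0.4 | a clearly detectable but overlapping class shift on the −log10 Q-value scale |
| neighbor-distance mean | 1.5 kb | intergenic tRNA-to-gene distances at nematode gene density |
| windowed conservation decay | 0.5·exp(−d/2000 bp) | a nondegenerate falling curve for the distance-matched null |
| host expression sd shrink | 0.5 | a strong "narrow expression" effect for the breadth test |
| exons ~120–400 bp, introns ~400–1500 bp, gaps ~3.2 kb mean | — | sized so merged intronic bp ≈ 44% of the genome, i.e. the planted fraction sits at the genomic-proportion null, matching the study condition the chi-square probes |
| host pool 350 genes, anticodon reuse 0.75 | — | reproduces the observed compression of hundreds of intronic tRNAs onto ~200 distinct pairs over ~190 host genes |

Target species get their own independently drawn gene layouts; orthology is
positional renaming with dropout. A conserved pair is planted by placing a
same-anticodon tRNA in an intron of the ortholog host with the per-target
rate; neighbor-pair conservation decays with the reference distance; pseudo
pools track the reference pool loosely (Poisson around a damped copy
number, plus per-species log-normal jitter of anticodon weights), giving
moderate cross-species pool correlations with essentially zero conserved
pseudo pairs.

Not emulated: nucleotide sequence (the analysis is purely coordinate- and
score-based), chromatin autocorrelation and replicate noise structure,
alternative splicing (one exon chain per gene record), many-to-many
orthology, and realistic chromosome-scale organisation (features are packed
uniformly). The planted histone-mark amplitudes are deterministically
coupled to log-occupancy plus noise, so the synthetic occupancy–mark
Spearman correlations are stronger than those of real chromatin data;
passing recovery tests therefore demonstrates correctness of the
measurement machinery under the planted model, not the effect sizes to be
expected of real tracks.

Determinism: one `numpy` Generator seeded from the truth seed drives all
drawing in a fixed order; the same truth yields byte-identical bundles.

## Problem sizes used in checks

The bundled verification and the acceptance script run the default study
conditions (6 species, 1500 genes and 820 tRNA genes per species, 500
breadth resamples). Unit and property tests use smaller genomes (10–800
genes) chosen so that brute-force per-base oracles and 100-seed calibration
loops stay fast; the binomial tolerances quoted in the tests are exact 95%
intervals at the planted parameters, widened by one count only where
planting itself can fail (a full intron) or background tRNAs can create a
chance conserved pair.

## Known limitations

* The windowed stride rule can leave the largest-distance records outside
  all windows for some N; a warning reports the uncovered tail.
* Spearman p-values rely on the t approximation even for n near 3.
* The occupancy proxy (window max) differs from peak-table assignment when
  peaks are offset by more than 100 bp from the anchor.
* With `containment=transcript`, a tRNA inside an exon is "intronic" by
  the transcript reading and carries no intron index.
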