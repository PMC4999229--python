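# trnactx

Genomic-context analysis of tRNA genes: intronic classification,
cross-species conservation of anticodon–host-gene pairing, Pol III /
chromatin signal profiling, and host-gene expression-breadth testing.

## What this is for

In compact genomes such as those of *Caenorhabditis* nematodes, a large
fraction of tRNA genes sit inside introns of protein-coding genes. That
placement raises concrete, testable questions for anyone studying tRNA
regulation or genome organisation:

* Is the intronic fraction different from what gene structure alone would
  predict (the genomic proportion of intronic bp)?
* Is the *pairing* of a specific tRNA type (anticodon) with a specific host
  gene conserved across species — beyond what mere proximity to genes
  would give?
* Do intronic tRNAs differ from non-intronic ones in RNA polymerase III
  occupancy, and does the host's strand matter?
* Are tRNA-hosting genes unusual in their expression behaviour — e.g.
  narrower spread of expression levels than random gene sets?

`trnactx` implements this analysis pipeline end to end over standard
annotation formats (genePred/BED12 gene models, tRNAscan-SE-style tRNA
tables, bedGraph signal tracks, TSV ortholog maps and expression tables),
plus a synthetic-data generator that plants every effect the pipeline
measures, so the whole stack is testable without downloading anything.

## The core quantities

With a tRNA classified as intronic when its interval lies wholly inside one
intron of a gene model, the pipeline computes:

* **Intronic fraction vs genomic null** — a 1-df chi-square of the
  observed (intronic, non-intronic) counts against
  p = merged intronic bp / genome size.
* **Pairing conservation** — for reference pairs
  P = {(anticodon a, host gene g)} and an ortholog map o,
  conservation = |{(a,g) ∈ P : (a, o(g)) ∈ P′}| / |{(a,g) ∈ P : o(g) exists}|
  against a target species' pair set P′, computed for four pair classes:
  intronic hosts, upstream neighbors, downstream neighbors (the
  distance-based nulls over non-intronic tRNAs), and pseudo-tRNA hosts (a
  negative control).
* **Distance-windowed conservation** — neighbor-pair conservation in 20
  sliding windows of 40 distance-sorted records, with a cubic
  least-squares extrapolation of conservation to distance 0 (± the
  prediction standard error) for comparison with the intronic value.
* **Signal profiles and group tests** — strand-aware per-base profile
  matrices anchored at each tRNA's first mature nucleotide; a per-tRNA
  occupancy score (window max over [−100, +100)); Wilcoxon rank-sum
  comparisons (intronic vs non-intronic; same-strand vs opposite-strand)
  with exact enumeration at small n; Spearman correlations between
  occupancy and histone-mark window scores.
* **Expression breadth** — the sample sd of log10(FPKM+1) of the host-gene
  set per life stage, against N=500 random same-size gene sets, with
  one-sided empirical p = (r+1)/(N+1).

See `docs/methods.md` for conventions, defaults and limitations.

## Worked example

Generate a two-species synthetic dataset with planted effects and run the
main stages:

```python
from trnactx import (SyntheticTruth, generate_dataset, classify_trnas,
                     build_pairs, conservation_fraction,
                     intronic_fraction_test)

truth = SyntheticTruth(seed=42, n_species=2, n_genes=400,
                       n_trnas_functional=200, n_trnas_pseudo=80)
bundle = generate_dataset(truth, "demo", tracks_for="ref",
                          expression_for="ref")

ref = bundle.ref
assignments, summary = classify_trnas(ref.trnas, ref.genes)
c = summary["functional"]
print(f"functional tRNAs: {c.n_trnas}, intronic: {c.n_intronic} "
      f"({100 * c.fraction_intronic:.1f}%)")

chisq = intronic_fraction_test(summary, ref.genes,
                               sum(ref.chrom_sizes.values()))
print(f"chi-square vs genomic intron proportion: "
      f"stat={chisq.statistic:.3f}, p={chisq.p:.3f}")

pairs = build_pairs(assignments, ref.trnas)
target = bundle.targets[0]
t_assign, _ = classify_trnas(target.trnas, target.genes)
t_pairs = build_pairs(t_assign, target.trnas)
res = conservation_fraction(pairs, t_pairs,
                            bundle.ortholog_maps[target.name])
print(f"pairs: {res.n_pairs}, no ortholog: {res.n_no_ortholog}, "
      f"conserved: {res.n_conserved}/{res.n_evaluable} "
      f"({100 * res.fraction:.1f}%)")
```

Output:

```
functional tRNAs: 200, intronic: 98 (49.0%)
chi-square vs genomic intron proportion: stat=1.062, p=0.303
pairs: 90, no ortholog: 11, conserved: 46/79 (58.2%)
```

49% of the functional tRNAs were classified intronic — consistent with the
planted 44% at n=200 — and the chi-square is non-significant because the
generator sizes gene structure so that intronic bp matches the planted
fraction. Of the 90 distinct anticodon–host pairs, 11 lose their host to
ortholog dropout; 58% of the remaining 79 are conserved in the target
species (planted rate 0.52, within the binomial spread at n=79).

The same analyses are available from the shell:

```
trnactx simulate --seed 42 --out demo
trnactx classify --trnas demo/species_0/trnas.tsv \
    --genes demo/species_0/genes.genePred \
    --chrom-sizes demo/species_0/chrom.sizes --out demo_out
trnactx run --config config.yaml     # full pipeline, see docs/methods.md
```

Every run writes TSV tables (`assignments.tsv`, `conservation.tsv`,
`windows.tsv`, `extrapolation.tsv`, `profile_*.tsv`, `group_tests.tsv`,
`breadth.tsv`, `report.tsv`) with provenance headers; reruns with the same
config are byte-identical.

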