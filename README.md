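# cregatlas

Comparative-epigenomics pipeline for building a cross-species atlas of gene
regulatory elements (GREs) and identifying lineage-specific activity changes
in the primate brain.

## The problem

H3K27ac ChIP-seq marks active enhancers and promoters. Given peak calls and
read counts from four primate species — human, chimpanzee, rhesus macaque and
marmoset — across two brain tissues (cerebellum, prefrontal cortex), the goal
is to find **hominin-specific** regulatory changes: regions whose activity was
gained or lost on the branch leading to human and chimpanzee, while staying
stable in the two monkey species. Such regions are then characterized by cell
type (from single-cell open-chromatin sets), disease overlap (ASD/AD
deregulated regions), sequence signatures (conservation, hominin-branch
nucleotide changes), statistical interdependence of those annotations, and
chromatin contacts (4C-seq).

The pipeline implements the full analysis chain:

1. **Peak post-processing** — peaks extended to a minimum width of 2000 bp
   (center ± 1000 bp), stitched at ≥ 1 bp overlap, and required to be present
   in ≥ 2 biological replicates.
2. **Cross-species atlas** — reciprocal liftOver-style projection of every
   peak list onto the reference genome (minMatch = 0.1), exclusion of
   multi-mapping regions and regions changing > 50% in size, a merged
   candidate list re-projected reciprocally onto all genomes, a mappability
   filter (≥ 90% of bases outside assembly gaps on every genome), and
   atlas-wide removal of regions overlapping repeats (detected as
   multimap-only enrichment) in *any* species.
3. **Differential enrichment** — a simplified DESeq2-style engine
   (median-of-ratios size factors, trend-shrunk method-of-moments
   dispersions, NB Wald test on log2 fold change, BH-FDR per comparison,
   per-comparison exclusion of regions with all-zero counts in one species).
   A region is DE at |log2FC| ≥ 1 and FDR < 0.01.
4. **Consensus calls** — hominin gain/loss requires consistent DE in all
   four comparisons (human and chimp, each vs macaque and marmoset);
   species-specific calls require consistency against all three others.
5. **Annotation & statistics** — promoter/enhancer classification (TSS
   within 1000 bp), gene linkage via chromatin loops or nearest active TSS,
   single-cell-type assignment, Fisher exact enrichment against disease
   region sets, LLM3D-style log-linear interdependence on 2×2×2 tables,
   per-region sequential-ANOVA covariate variance partition, phastCons-style
   conservation over open-chromatin-masked bases, the hominin
   nucleotide-change percentage (human = chimp ≠ macaque, ≠ marmoset), and
   4C smoothing in running windows of 41 fragment ends.

A first-class synthetic-data module generates all inputs with planted truth
(NB counts with planted fold changes, chain maps with indels and planted
unmappable regions, duplicated repeat loci, cell-type/disease sets with
planted enrichment, alignments with planted hominin substitutions), so every
stage is testable end to end without external downloads.

## Worked example

```bash
python analysis/01_simulate_bundle.py   # write the synthetic study inputs
python analysis/02_run_pipeline.py      # atlas construction + all stages
python analysis/03_consensus_recovery.py
```

At the default study conditions (2000 regions, 4 species × 2 tissues × 3
replicates, NB dispersion 0.05, planted 4-fold hominin effects, 5%
unmappable and 5% repeat-confounded regions; seed 42) this prints:

```
merged candidate regions: 2000
atlas regions (mappable on all 4 genomes): 1807
  discarded (repeat): 101
  discarded (size_violation): 13
  discarded (unmappable): 79
planted-filter recovery:
       true_class  n_planted  n_predicted  tp  precision  recall
       unmappable         92           92  92        1.0     1.0
repeat_confounded        101          101 101        1.0     1.0

CB: 198 calls / 202 planted -> sensitivity 0.980, empirical FDR 0.000
PFC: 199 calls / 202 planted -> sensitivity 0.985, empirical FDR 0.000
```

i.e. the filters recover exactly the planted unmappable and repeat-confounded
regions (the 92 planted chain deletions surface as 79 `unmappable` + 13
`size_violation` ledger entries, depending on how much of each region's
flank still aligns), and the consensus recovers ~98% of planted hominin
changes with no false calls. `analysis/04` and `analysis/05` then show the
planted oligodendrocyte enrichment of gains (fraction 0.60 vs 0.10
background), the ASD-down enrichment (OR ≈ 9.5), the log-linear hierarchy
selecting a conditional-independence model while rejecting complete
independence (p ≈ 3e-45), and the sequence signatures (gains: 2.0% hominin
nucleotide changes and conservation 0.45, vs 0.5% and 0.60 for stable
regions).

The same pipeline is scriptable from a shell:

```bash
cregatlas simulate --out bundle/ --seed 42
cregatlas run-all --seed 42 --out results/run
cregatlas fourc --fragments bundle/fourc_fragments.tsv --window 41 --out smoothed.bedgraph
```

## Layout

```
src/cregatlas/     library: intervals, io, chains, atlas, diffexp,
                   annotate, enrich, seqscores, fourc, simulate,
                   evaluate, pipeline, cli
analysis/          numbered narrative drivers writing under results/
tests/             pytest suite (unit, property and acceptance tests)
scripts/           acceptance.py
docs/methods.md    models, parameters, numerical choices, limitations
```
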