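# Methods

This note documents the models and procedures implemented in `cregatlas`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study does and does not establish.

## Coordinates and interval algebra

All internal coordinates are 0-based half-open (BED convention); chain-format
quirks (reverse-strand query coordinates) are converted at the parser
boundary. Regulatory regions are unstranded; TSS strand is retained but
distances are measured to the TSS base itself. Merging stitches intervals
sharing ≥ 1 base (half-open adjacency shares zero bases and never merges).
Peak extension to the minimum width (default 2000 bp, center ± 1000 bp; for
odd widths the left half receives the extra base) clamps at chromosome
bounds rather than discarding or shifting, so a telomeric peak may remain
below the minimum width — extension is therefore idempotent only away from
chromosome edges, which is where essentially all regions live.

## Chain projection and the atlas filters

A chain map is a set of co-linear equal-width block runs. Projection takes
the `[min, max)` hull of the targets of all intersected blocks and requires
(i) a matched-base fraction ≥ `min_match` (default 0.1, the liftOver
`-minMatch` convention) and (ii) a single target locus — one chromosome and
orientation, with split targets bridged only within 10 kb (emulating
liftOver span semantics without re-implementing its internals). Reciprocal
mapping additionally requires the back-projection to overlap the source by
≥ 1 bp — the weakest criterion consistent with "reciprocal"; stricter
fractions are exposed as a parameter — and a relative size change ≤ 0.5
(strictly larger changes rejected). The mappability filter passes a region
iff ≥ 90% of its bases lie outside assembly gaps on *every* genome (the
boundary value passes). Repeats are defined operationally per species as
peaks enriched under multi-mapping but not unique mapping; one species
flagging a region removes it from the whole atlas. The atlas builder
guarantees the conservation identity |merged input| = |atlas| + Σ discards
by construction (asserted at run time), and the discard ledger partitions
every loss by reason.

## Differential enrichment and the consensus

The NB engine is deliberately a simplified DESeq2-style procedure, not a
bit-compatible clone; what the pipeline is *for* is the consensus
definition, and its acceptance standard is planted-effect recovery.

* **Size factors**: median-of-ratios to the per-region geometric mean over
  regions with all-positive counts. Note that scaling one sample by *c*
  scales its factor by *c* only relative to the other samples (the
  geometric-mean reference absorbs a common c^(1/m)); normalized ratios,
  fold changes and calls are exactly invariant, which is the property the
  pipeline relies on.
* **Dispersions** (NB variance μ + αμ²): per-region method of moments
  within each design group on normalized counts, df-weighted pooling,
  50/50 shrinkage toward a fitted α(μ) = a₀ + a₁/μ trend, floored at 1e-8;
  regions with no variance at all sit at the floor.
* **Wald test**: β = log2 of the ratio of normalized group means (a 0.5
  pseudo-mean added to both means when either is zero, keeping fold changes
  finite for zero-inflated regions that survive the zero exclusion);
  Var(ln mean) from the NB information, Var = (Σⱼ1/sⱼ)/(n²μ) + α/n per
  group; two-sided normal p. **Finite-sample behaviour**: at 3 vs 3
  replicates the plug-in dispersion makes the null p mildly
  anti-conservative — ECDF within ~2–3% of uniform, P(p < 0.01) ≈ 0.017 at
  the study conditions. t-reference and Satterthwaite-style corrections
  were evaluated and calibrated no better across conditions, so the simple
  normal reference is kept and the deviation documented; the
  four-comparison consensus conjunction absorbs it completely (null
  consensus calls are ~0 of 2000 regions, far under the 1% criterion).
* **Zero exclusion**: per comparison, regions with all-zero raw counts in
  every replicate of either species (within the tissue) are excluded from
  that comparison only.
* **Calls**: DE at |log2FC| ≥ 1 and BH-FDR < 0.01, computed within each
  pairwise comparison. A hominin gain (loss) requires up (down)
  significance with one consistent direction in all four comparisons of
  human and chimpanzee against macaque and marmoset; species-specific
  calls require consistency against all three other species. Direction
  conflicts yield no call. Tissues are analysed independently throughout.

## Enrichment statistics

* **Fisher**: two-sided exact p by the "at least as extreme probability"
  rule (hypergeometric probabilities ≤ observed, with the standard 1+1e-7
  relative tie tolerance); OR = ad/bc, infinite on a single zero in the
  denominator product. Verified against exact integer-arithmetic
  enumeration on all tables with total ≤ 50.
* **Log-linear interdependence** (2×2×2 tables): the full hierarchy —
  complete independence (df 4), three joint independences (df 3), three
  conditional independences (df 2), homogeneous association (df 1),
  saturated (df 0). Decomposable models use closed-form MLEs; homogeneous
  association uses iterative proportional fitting to the three two-way
  margins (tolerance 1e-12). Fit quality is the deviance
  G² = 2Σ obs·ln(obs/exp) against χ²(df); zero observed cells contribute
  zero and zero expected with positive observed gives G² = ∞ (impossible
  for margin-consistent MLEs). The selected model is the most parsimonious
  one with G² p ≥ 0.05, ties on df broken by larger p; the reported
  interdependence p is always that of complete independence, and the full
  fit table is emitted so other selection rules can be applied.
* **Covariate variance partition**: per-region OLS on rpkm-normalized
  counts (counts / (region kb × library millions)) with sequential
  (Type I) ANOVA in the declared covariate order — biological before
  technical by default, since Type I sums of squares are order-dependent.
  Implemented by blockwise Gram–Schmidt so thousands of regions share one
  orthogonalization; aliased columns are dropped and recorded. A region is
  flagged when any *nuisance* covariate reaches p < 0.01.

## Sequence scores

The hominin nucleotide-change percentage counts, among validly aligned
columns (non-gap in all four species; an optional mask can remove columns),
those where human = chimpanzee while differing from the macaque base and
from the marmoset base. The two monkeys need not agree with each other —
the literal reading of the definition — and a stricter mode requiring
macaque = marmoset is available. The denominator is valid columns, not
region width (parameterized via the mask). Conservation is the per-base
mean of a [0,1] track over region ∩ open-chromatin mask, missing when the
intersection is empty. Distribution comparisons use Welch's t (robust to
unequal variances; chosen over the equal-variance form and flagged as such).

## 4C smoothing

Contact profiles are smoothed by averaging counts in running windows of 41
fragment *ends* (index space, not genomic distance). Windows are centered —
the standard choice for 4C — and truncated at the profile edges so output
length equals input length; a strict mode emits NaN where the full window
does not fit, and a configurable viewpoint-exclusion radius (off by
default) masks self-ligation-dominated ends.

## The synthetic study

The generator's defaults are the study conditions the statistics assume:
2000 regions (~2 kb) on two 10 Mb chromosomes; four species × two tissues ×
three replicates; NB counts with baseline mean 100 (per-region log-normal
spread σ = 0.5), dispersion 0.05, library sizes log-normal (σ = 0.2) around
30 M reads with replicates in separate batches; planted hominin gains and
losses at 5% each with |log2FC| = 2 applied identically in both tissues;
5% unmappable regions (deleted from one non-reference chain) and 5%
repeat-confounded regions (duplicated in one non-reference species, absent
from its unique-mapping peaks); assembly gaps covering a binomially drawn
5% of bases; oligodendrocyte membership 0.6 in gains vs 0.1 background
(planted OR 13.5) and ASD-down membership 0.3 vs 0.05; hominin substitution
rates 0.02 (gains) vs 0.005 (background); conservation planted at 0.45
(gains) vs 0.60 (stable); 4C counts decaying exponentially (200 kb scale)
from the viewpoint with NB noise. One root seed feeds a named child stream
per generator (derived via a stable hash of the generator name), so adding
a generator never perturbs existing outputs and every artifact is
byte-reproducible.

Deliberate simplifications: gaps and duplicated loci are placed ≥ 3 kb from
regions, so the mappability filter is exercised by unit tests rather than
by the planted classes; indels avoid region bodies, so orthologous regions
stay findable except where deletion is planted; peaks exist for (almost)
every region in every species, with activity differences expressed in
counts rather than peak presence; alignments contain only hominin-branch
substitutions (no monkey-branch divergence, no indels). Passing tests
therefore demonstrate that the *methods* recover what they are defined to
recover under the assumed statistical model — not that real cross-species
ChIP-seq, with its mappability-activity confounding, assembly-quality
asymmetries and peak-calling noise, would behave as cleanly. The published
full-data counts (tens of thousands of atlas regions, ~2k lineage calls)
require reprocessing the deposited multi-species datasets and are outside
desk scale by design.

## Numerical and degenerate-input conventions

Boundary values follow the stated rules read literally: mappability keeps
exactly 90% annotated; the size filter rejects strictly > 50% change; DE
requires |β| ≥ 1 and q < 0.01. Equidistant gene-link ties break to the
lower-coordinate TSS; loop links beat proximity links and the largest
anchor overlap wins among loops. Empty universes, empty tables, even
smoothing windows, mixed-species merges and missing chain maps raise
errors naming the violated contract; config validation collects all
violations without throwing.
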