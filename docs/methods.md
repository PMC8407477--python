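# Methods

## Problem and model

Shotgun metagenomics usually stops at species-level profiles, but strains of
one species — here the gut commensal *Faecalibacterium prausnitzii* as the
motivating case — can behave very differently with respect to disease state.
`strainsift` estimates, for each strain genome in a reference panel, how
likely that strain is to be present in each sample, by re-assigning reads
that map ambiguously among closely related genomes.

The core procedure works per sample:

1. **Background filtering.** Reads with at least one *valid* alignment to any
   background (non-focal) genome are discarded. An alignment is valid when
   its mismatch count is strictly below 5 per 100 aligned bases
   (`n_mismatches / aligned_length < 0.05`).
2. **Exclusive mapping.** Every surviving read is aligned against each focal
   genome separately; all reads with a valid alignment to genome *G* are
   candidates for *G*. Within one genome, a read's candidate alignment is its
   best valid placement (fewest mismatches, ties to the leftmost start, then
   the plus strand).
3. **Competitive classification.** Let *m\** be the read's minimum mismatch
   count over all focal genomes. The read is **T1** for the unique genome
   achieving *m\** (retained), **T2** for genomes it aligns to less well
   (discarded), and **T3** for every genome in a tie at *m\**.
4. **Conditional T3 assignment.** A T3 alignment carrying at least one
   mismatch is rejected for *G* if any T1 alignment on *G* overlaps it
   (>= 1 shared base) with strictly fewer mismatches; otherwise it is
   assigned — possibly to several genomes at once, each with full weight.

Per strain and sample we then report **coverage** (fraction of genome
positions under >= 1 assigned base), **depth** (assigned bases / genome
length, averaged over all positions), and **abundance** (assigned reads /
total sample reads). Because tied near-identical strains each receive the
shared reads, estimated coverage is expected to sit slightly *above* the
truth when sibling strains co-occur; this is treated as signal (similarity to
a known strain), not error, and is asserted as a directional property in the
tests.

## Built-in mapper

External aligners can supply SAM (with NM or MD tags); for self-contained
runs the package ships an exact-seed, ungapped, end-to-end mapper. For read
length *L* and validity cutoff *f*, the largest admissible mismatch count is
*m* = ceil(*f·L*) − 1 (4 for 100 bp at *f* = 0.05). The mapper places *m* + 1
disjoint seed k-mers per strand, with effective seed length
min(k, floor(L/(m+1))) (k defaults to 21, so 20 for 100 bp reads). By
pigeonhole, any placement with <= *m* mismatches contains at least one exact
seed, so **every** valid placement on both strands is enumerated and verified
by an exact Hamming count — the property that makes the pipeline bit-identical
to an exhaustive brute-force scan, which the test suite checks on randomized
micro-instances. Gapped alignment, base qualities, and paired ends are out of
scope (the simulator introduces substitutions only).

## Synthetic communities

The simulator supplies the study conditions the pipeline is validated under:

- **Focal panel**: *n* genomes derived from one i.i.d.-uniform random
  ancestor by independent per-site substitution (default 10 kb, 2% per-site
  divergence, i.e. ~4% pairwise).
- **Background genomes**: independent random sequences, standing in for
  unrelated species.
- **Communities**: 1–10 focal strains and 1–100 background genomes per sample
  (capped by panel size), selected uniformly without replacement; read
  fractions drawn symmetric Dirichlet(α = 1) ("determined randomly" with no
  stated skew).
- **Reads**: 100 bp single-end, multinomial across genomes by read fraction,
  uniform start, either strand with probability 1/2. Substitution counts per
  read are Binomial(L, 0.01) capped at 5 — the cap is fixed by the study
  design; the binomial shape and the 1% default rate are this package's
  choice of a smooth, parameterizable model that respects the cap. Substituted
  positions are distinct and always change the base.

What the simulator does **not** emulate: indels and structural variation,
quality-score profiles and position-dependent error, paired-end inserts, GC
or coverage bias, and real strain phylogenies (a star phylogeny from one
ancestor rather than nested clades). Passing the recovery benchmark therefore
shows the *reassignment logic* is sound under controlled divergence, not that
every property of real gut metagenomes is captured.

## Recovery benchmark

`strainsift.benchmark.run_simulation_benchmark` simulates 30 samples of
100,000 reads over a 20-strain focal panel plus 10 background genomes, runs
the full pipeline, and computes Pearson correlations between estimated and
true coverage, depth, and abundance over all 600 (strain, sample) pairs
(absent strains contribute true zeros). These problem sizes are the package's
desk-scale standard conditions; `scripts/acceptance.py` reports the minimum
of the three correlations.

One property of this benchmark deserves emphasis. A single-ancestor panel at
2% per-site divergence puts *every* strain pair at roughly 4% pairwise
divergence — just inside the 5-mismatch validity horizon, the
maximal-sharing regime for the T3 rules. A strain absent from a sample still
accumulates coverage over every 100 bp window identical to a co-occurring
sibling (about 9–10% of positions per sibling pair at this divergence, so
substantially more with several siblings present). Depth and abundance
correlate with the truth near-perfectly here, while coverage — by design an
indicator of the *probability of presence* rather than a composition
estimate — correlates less tightly than it would on a panel with realistic
hierarchical structure, where most pairs are either far more divergent
(no sharing) or near-identical (sharing only when cluster mates co-occur).
The test suite asserts the exact correlations measured under these standard
conditions and flags coverage when it falls below the recovery bar.

## SNP arm

A minimal pileup caller mirrors the threshold semantics of the usual external
callers rather than their likelihood models: counting only bases with Phred
quality >= 15 (applied when the pileup is built), a site is called when depth
>= 10, the top non-reference base count is >= 4, and its frequency is >= 0.2
(all inclusive, all configurable). Users reproducing a dual-caller setup can
intersect two call sets on (genome, position, ref, alt). Per-sample SNP
density is calls per kilobase of *callable* sequence (positions with depth
>= 10) — the denominator is a package decision, as no standard formula
exists. Strains enter group comparisons only if they exceed 40% coverage
**and** 10× depth (both strict) in at least 20 samples of each group; group
differences use two-sided Mann-Whitney tests with Benjamini–Hochberg FDR
(a single-λ Storey estimator is available behind a flag). Outlier samples can
be downsampled without replacement to the pre-downsampling mean read count.

## Clustering and conserved genes

Strains are clustered by their coverage vectors across samples with
average-linkage agglomerative clustering under correlation distance
(1 − Pearson); *k* defaults to 5. Constant (e.g. absent-everywhere) coverage
vectors are placed at distance 0 from each other and 1 from variable vectors.
Agreement with an external labeling (e.g. a core-gene phylogeny clustering)
is measured with the adjusted Rand index.

Conserved genes: each reference CDS is aligned globally (match +1, mismatch
−1, linear gap −1) against every CDS of every annotated strain; scores are
normalized by the geometric mean of the two self-alignment scores (symmetric
and scale-stable; min/max/mean are available) and negatives clamp to 0. A CDS
is conserved iff its best hit scores strictly above 0.5 in every annotated
strain; unannotated strains are excluded with a warning. Gene-level cluster
divergence is summarized as mean intra- versus inter-cluster distance
(1 − score) over strain pairs.

## Classification

Feature matrices take estimated coverage, depth, abundance, or all three
(strain-major column order). SVM and random-forest models are evaluated with
stratified 5-fold cross-validation; within each training fold a randomized
search (30 iterations by default, inner 3-fold CV scored by AUC) explores
C ∈ [1e−2, 1e3] and γ ∈ [1e−4, 1e1] log-uniformly, rbf/linear kernels and
balanced/none class weights for the SVM, and 50–500 trees, depth 2–20 or
unbounded, feature/leaf/split settings and bootstrap on/off for the forest.
The reported statistic is the **median** per-fold AUC; everything is
deterministic given the seed. AUC is the rescaled Mann-Whitney U (ties count
half).

## Numerical and design notes

- Coordinates are 0-based half-open internally; 1-based only inside SAM/VCF/GFF.
- "Best" alignments are ordered by (mismatches, start, strand); all
  tie-breaks are deterministic, so the pipeline is a pure function of its
  inputs.
- The T3 overlap test uses the weakest literal reading (>= 1 shared base,
  one overlapping T1 witness suffices); both choices are configurable
  (`min_overlap`).
- The T3 sliding-window overlap check uses a mismatch sentinel of L + 1
  (never a saturating integer, which would not survive the float round trip
  inside the minimum filter).
- Degenerate inputs raise `ValueError` early: empty panels, zero-length
  alignments, zero callable territory, single-class labels, more clusters
  than strains.

## Reproducing at full scale

The real cohorts behind the motivating analysis are not shipped and are out
of desk-scale reach; the package asserts none of the numbers derived from
them. To rerun at full scale: download the liver-cirrhosis/healthy-control
cohort (ENA accession **ERP005860**, 123 LC + 114 HC samples) and the
Crohn's-disease cohort (SRA accession **SRP129027**), collect the 136
*F. prausnitzii* assemblies from NCBI as the focal panel and a
MetaPhlAn-derived reference set (without *F. prausnitzii*) as the background
set, align with your preferred external mapper, and feed the SAM/VCF files
through `strainsift assign`, `strainsift profile`, `strainsift snps`, and
`strainsift classify`. Quantities such as cohort AUCs, cross-cohort SNP
catalogues, and phylogeny-versus-coverage ARI values are only meaningful in
that full-scale setting.

## Known limitations

- Ungapped mapping: genomes with indel variation relative to the reads will
  lose alignments an affine-gap aligner would keep; supply external SAM in
  that case.
- The exact-placement guarantee assumes uniform read length per batch.
- The pileup caller has no genotype-likelihood model; it is a threshold
  mirror intended for intersection-style workflows.
- Storey's q-value uses a single-λ pi0 estimate, not the smoothed estimator.
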