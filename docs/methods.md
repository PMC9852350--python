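# Methods

This note documents the models and procedures implemented in
`xenotraffic`, the assumptions behind them, the defaults and why they
were chosen, and what the synthetic-data tests do and do not
demonstrate about real data.

## The detection model

The pipeline identifies transcripts that moved across a haustorial
junction between two plants of distantly related families.  It rests
on three observations:

1. A transcript transcribed in one organism but detected in the other
   must either be mobile or be an artifact (mis-assembly, conserved
   ortholog, index hopping).  Detection is a presence call: FPKM ≥ 0.3
   in at least one replicate of a tissue group.  The threshold is
   inclusive and deliberately low — mobile transcripts are diluted in
   the destination tissue, and the replicate-wise "any" rule favours
   sensitivity; specificity is recovered downstream by the homology
   stages.
2. Candidates are the unigenes present in both the parasite stem (CD)
   and the parasitized host root (HC).  The parasite-free host root
   (HA) separates candidates absent from the healthy host
   (HA-exclusive — predominantly parasite transcripts that moved
   CD→HC) from candidates also present there (HA-containing —
   predominantly host transcripts that moved HC→CD).  The Venn region
   is *not* the final verdict: a candidate's direction is decided by
   family-level homology, because presence patterns alone cannot
   separate a host transcript up-regulated on attachment from a
   parasite transcript that moved.
3. Family-of-origin assignment exploits the deep divergence between
   the two families.  Each candidate is searched against an
   Orobanchaceae-like and a Chenopodiaceae-like reference collection
   ("dual" search = each collection independently, any qualifying hit
   counts).  One-family evidence assigns the direction; both-family
   evidence marks a conserved ortholog that cannot be placed
   (ambiguous); no evidence leaves the candidate unassigned.
   Ambiguous and unassigned candidates are excluded from mobile
   totals.  Reciprocal-best-hit logic is intentionally *not* used: the
   ambiguous class is only expressible under any-hit semantics, and
   leaving dual-family unigenes unassigned-to-species is the
   scientifically conservative choice.

A consensus filter runs before the Venn partition: every unigene must
have sequence-level support in at least one species-level assembly
(union over reference sets), guarding against hybrid mis-assemblies.
Reordering it after the partition is possible in principle but not
exposed; with union semantics the retained candidate set is the same
either way.

## Homology backends

Evidence can come from pre-computed 12-column BLAST tabular files
(qualifying hit: E-value ≤ 10⁻¹⁰, inclusive) or from a built-in k-mer
backend suitable for desk-scale data:

* canonical (strand-minimum) k-mers, k = 21, 2-bit packed;
* containment = fraction of the query's distinct k-mers present in
  the reference index;
* a query "hits" a collection when containment ≥ 0.10.

Under the generator's substitution-only divergence model the expected
containment between relatives at per-site divergence *p* is (1−p)^k:
at k = 21 that is ≈ 0.34 at p = 0.05, ≈ 0.17 at p = 0.08, and
≈ 10⁻⁴ at p = 0.35, so the 0.10 floor separates within-family from
between-family relationships with a wide margin on both sides.  k must
be odd (no palindromic canonical ties) and large enough that random
21-mer collisions are negligible against reference indices of ~10⁷
k-mers (expected background containment < 10⁻⁴ per query).  The
backend estimates an identity for reporting as containment^(1/k).
No minimum alignment-length floor is applied beyond the k-mer length
itself.

## ORF screen

Six-frame scan for maximal ATG-initiated, stop-terminated ORFs
(standard code, stops TAA/TAG/TGA), default minimum 300 nt
(100 codons — a conventional coding heuristic; the source tool for
this step publishes no cutoff).  Codons containing N are treated as
neither start nor stop.  ORFs truncated by the transcript end are
excluded by default to avoid inflated calls on fragments; a flag
includes them, bracketing the plausible behaviours of ORF-finder
tools.  The screen *annotates* the run report; it does not filter
mobility calls unless strict mode is requested, since coding potential
is an assembly-quality cross-check, not a mobility criterion.

## Synthetic data generator

The generator emulates the study design end to end: two species with
`n_host_genes` = `n_parasite_genes` = 2,000 transcripts by default
(4,000 total), a conserved-ortholog fraction of 0.25, directional
mobile fractions 0.10 (CD→HC, of parasite genes) and 0.03 (HC→CD, of
host genes) drawn from the species-exclusive pools, and the 3/3/3/1
replicate design over CD/HC/HA/HI.

**Divergence geometry.** `within_family_divergence` (default 0.05) is
the expected *pairwise* per-site divergence between family members.
Conserved-ortholog neighbourhoods (host copy, parasite copy, each
family-reference cousin) descend from one ancestor with every branch
mutated at half that rate, so all pairwise distances in the
neighbourhood are ~0.05 and a conserved gene reliably hits both family
references.  Species-exclusive genes get an own-family cousin at the
full within-family rate and a distant homolog in the other family's
reference at `between_family_divergence` (default 0.40, far below any
callable containment).  Substitutions only, no indels — this keeps the
containment/identity relation analytic; indel evolution, isoforms and
chimeric assembly artifacts are out of scope.

**Coding structure.** A configurable fraction (default 0.8) of each
species' transcripts carries a planted ORF (ATG + non-stop codons +
stop, 300 nt) that is repaired after divergence mutation (start and
stop restored, interior stops reverted) so the planted signal survives
evolution.  Non-coding transcripts are post-processed to be genuinely
ORF-free: random kilobase-scale DNA contains a ≥ 300 nt spurious ORF
with probability ≈ 0.2, which would otherwise make the generator's
coding fraction unrecoverable; the ORF screen therefore measures
exactly the configured fraction on synthetic data.

**Abundance and counts.** True abundances are log-normal (meanlog 1.5,
sdlog 1.0 — a typical two-order-of-magnitude bulk RNA-seq dynamic
range).  A mobile transcript's destination abundance is
`transfer_dilution` × source abundance; the default 0.1 is a free
parameter, chosen as a clearly-detectable-but-strongly-diluted regime
(the phenomenon it models is reported qualitatively, not
quantitatively).  Mobile transcripts are present at the haustorial
interface with probability 0.99 (CD→HC) / 0.81 (HC→CD); non-mobile
transcripts of both species are always present there, since the
interface physically contains both organisms.  Expected counts are
abundance × length × depth with a *global* normalization constant, so
expected destination counts are exactly dilution × source counts;
replicate counts are negative-binomial with size parameter
`nb_dispersion` (default 10, moderate overdispersion; ∞ gives the
Poisson limit), at `library_size` = 3 × 10⁶ expected fragments per
library, equal across replicates by default.

**What the generator does not emulate.** Read-level error,
positional coverage bias, unequal library sizes, isoform structure,
index hopping between multiplexed libraries, and partial transcript
degradation in transit.  Passing recovery tests on synthetic data
therefore demonstrate the correctness of the classification logic
under the stated model, not the field error rate of the procedure on
real libraries, where mis-assembly and barcode leakage are the
dominant failure modes.

## Statistics

* **Abundance contrast** (mobile vs non-mobile source abundance):
  two-sided Mann–Whitney rank-sum on per-unigene mean source-group
  FPKM, exact enumeration below 10 per class, asymptotic with tie
  correction otherwise.  Both classes are restricted to unigenes
  detected in the source tissue so the non-mobile class is not padded
  with the other species' absent transcripts.  The distributions are
  summarized as log₁₀(FPKM + 0.01) quartiles; the 0.01 pseudocount is
  the smallest meaningful fraction of the 0.3 presence threshold.
* **Source–destination correlation**: Spearman's rho on mean FPKM
  pairs, plus Pearson's r on log₁₀(x + 0.01) for comparability with
  log-scale scatter plots.
* **Enrichment**: upper-tail hypergeometric per term
  (P[X ≥ k]; depletion is not tested), Benjamini–Hochberg adjustment
  across the terms of one analysis batch, enriched ⇔ adjusted
  p < 0.05.  The background is the expressed set of the source tissue.
* **Orthogroup loss**: conserved orthogroups are those present in
  ≥ 3 of 5 reference asterid species; the report gives the
  missing-in-focal set and the fraction of it shared with each
  comparator species (and their union), rendered to 2-decimal
  percents.

Rounding conventions are fixed so worked-example arithmetic is exact:
percentages and fold ratios to 2 decimals, the Venn outnumber ratio to
the nearest integer.

## Determinism and problem sizes

All randomness flows through explicit integer seeds
(`numpy.random.default_rng` with per-stage stream offsets); identical
configuration and seed produce byte-identical run reports.  The test
suite exercises the full pipeline at 4,000 genes × 10 seeds (the
default study conditions), brute-force oracle comparisons at 200
random kilobase sequences, and null calibrations at 200–500
simulations per statistic; the whole suite runs in under two minutes
on one CPU.

## Known limitations

* The k-mer backend is a surrogate for local alignment: it has no
  E-value theory, and its containment threshold was mapped to the
  E-value world only through the substitution-only divergence model.
* The unassigned ("neither") class is dropped from mobile totals by
  exactly the family-assignment cutoff; on real data the corresponding
  exclusion rule of any given study may differ, which shifts absolute
  counts but not the classification logic.
* FPKM uses the full transcript length, not an effective length; at
  typical transcript lengths the difference is a few percent and
  cancels within-pipeline, but absolute FPKM values are not
  RSEM-comparable.
* Single-replicate groups (HI) get presence calls from one library;
  those calls carry no replication support by design.
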