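# Methods

This note documents the models, rules, and numerical choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the method left room.

## Synthetic study generator

The generator produces a complete multi-individual venom-gland study with
ground truth for every downstream recovery test.

**Reference transcripts.**  Toxins are organized into gene families (the
default composition is 62 transcripts in 19 families, 16 of them snake
venom metalloproteinases, 15 serine proteinases, 11 C-type lectins, one
highly expressed phospholipase A2 and bradykinin-potentiating peptide,
plus the minor classes).  Each family descends from a random ancestor CDS;
members are mutated away from it at 0.25/site (start and stop codons
conserved), giving within-family identities around 60% — the regime in
which paralogs are distinguishable by exact-overlap assembly and by 80%
identity annotation, as real venom paralog families are.  Every transcript
carries 30-nt UTRs around an in-frame CDS.

**Individuals.**  Each individual receives a haplotype of every transcript,
mutated from the reference at `individual_divergence` (default 0.004/site,
i.e. ~0.8% between two individuals).  This default is set by two hard
constraints of the method itself: merged reads (~250–400 bp) must usually
survive the ≤3-mismatch mapping against a consensus representative from a
different individual, and 98% identity clustering must merge alleles of
one locus rather than split them.  Real samples differ by more than SNPs
(private transcripts, indel haplotypes, divergent UTRs); where an
experiment depends on that richer individual-specific k-mer content — the
contamination filter — the divergence knob is raised to 0.015/site as an
explicit stand-in (see below).

**Expression.**  Per-transcript abundances are lognormal (σ = 1.2 by
default) with a toxin multiplier (default 8×) reproducing the heavy-tailed,
toxin-dominated profile of venom glands; per-individual lognormal noise
(σ = 0.3) provides biological replication variance; planted fold changes
multiply abundance for the individuals carrying a chosen factor level.
Planted absences zero a transcript in an individual (never in all
individuals).  True expression is reported on the TPM scale.

**Reads.**  Expected fragment counts are `depth_per_transcript` (fragments
per kb of reference, per individual) apportioned by abundance × length, so
expectations sum exactly to the requested effort; realized counts are
Poisson.  Fragment lengths are Normal(400, 100) by default per the library
target; fragments may overhang transcript ends and are clipped, so
terminal bases are covered like interior ones (fragmentation of a full
molecule covers its ends).  Substitution errors are applied to the
fragment once; both 150-bp mates and the "ideally merged" fragment then
share them.  Qualities are two-state (38, or 2 with probability 0.002) —
enough to exercise the phred-5 trimmer, with no claim to Illumina error
profiles.  FASTQ output is phred+33.

**What the generator does not emulate:** indels, PCR duplicates, positional
quality decay, fragment-length bias, incomplete transcripts, UTR
annotation error, and expression correlation between paralogs.  Passing
recovery tests therefore demonstrate the correctness of the algorithms
under the stated statistical structure, not robustness to every real-data
pathology.

## Contamination filter

Demultiplex bleed-through deposits another sample's reads verbatim in a
library that shared the lane.  The filter censuses canonical 57-mers per
sample and, for each focal sample, marks a k-mer contaminant-indicative
when some other same-lane sample holds it with count ≥ 2 and
≥ 10 × (focal count + 1); a read is flagged when ≥ 25% of its valid
windows are indicative.  The enrichment form of the rule is this package's
operationalization (exposed in the API); the window fraction and the ≥
comparison follow the 25%-constructed reading.  Because a mis-assigned
cluster moves both mates together, injection and removal act on whole
pairs: flagging either mate drops both.  This matters — ~40% of
single-read misses carry no distinguishing window at all, while their
mates usually do.

Power analysis sets the validation conditions: a donor variant k-mer must
reach count ≥ 10–20 to clear the enrichment bar, i.e. ~30× raw coverage
(the experiment runs at 300 fragments/kb; real studies are >10× deeper
still), and a 150-bp read needs a distinguishing site ≥ ~23 bp from its
ends to pass the 25% window rule, which at 0.015/site divergence holds for
~95% of contaminant reads.  Exact idempotence is unattainable for an
enrichment rule (removal lowers focal counts and can newly flag borderline
reads); a second pass removes ≤ 0.1% in practice.

## Trimming and merging

Quality trimming keeps the prefix before the first base under phred 5.
Pair merging scans ungapped 3′ overlaps (≥ 10 bp, ≤ 10% mismatches),
scores candidates by matching bases, and resolves overlap disagreements by
the higher-quality call.  Only merged fragments continue into assembly and
quantification, as in the original workflow.

## Assembly

Seeds are drawn uniformly without replacement (1000 by default) and
extended in both directions: the contig's terminal overlap-mer (default
120 bp; tests scale it to 20 so toy reads stay printable) is looked up in
a both-orientation window index; reads whose overlapping bases agree with
the contig vote on the next base.  Each read is usable at a single
placement per contig — a candidate whose implied placement contradicts an
earlier one is ignored, which prevents a read's reverse complement from
re-entering through a short repeated window.  Extension stops on
no-overlap, ambiguity, or a repeated terminal window (cycle guard).

The default ambiguity rule is strict unanimity — any disagreement halts.
That is the conservative contract (and what the toy examples exercise),
but it cannot assemble through sequencing errors: at 0.1%/base and ~12×
candidate depth some candidate disagrees roughly every 80 bp.  The
integrated pipeline therefore extends along the plurality base when it
carries ≥ 75% of votes (`min_agreement = 0.75`) and relies on the
downstream coverage screens to remove the occasional mis-join — the same
division of labor the original assemble-then-screen workflow uses.
Contigs contained in a longer contig (either strand) are dropped, and
every contig can be re-validated independently by chaining zero-mismatch
read placements with the required overlap.

## Annotation and consensus

Identity is cd-hit-style: matching columns over the length of the shorter
sequence, with the shorter aligned to the best region of the longer (edlib
infix alignment, both strands; matches approximated as shorter-length
minus edit distance).  Greedy clustering visits sequences by decreasing
length (ties by sequence then id, so results are deterministic and
permutation-invariant); a sequence joins the first cluster whose
representative it matches at the threshold, else founds one; the founder,
being longest, stays representative.

Annotation assigns each contig its best reference match: at ≥ 80%
identity the contig inherits family, CDS placement (reference CDS located
in the contig by alignment, trimmed to a codon multiple), and signal
peptide; below, it lands in a manual-review queue with a longest-ORF CDS
(≥ 90 codons, either strand).  Identity here is nucleotide identity; a
protein-level option was considered and not needed, since the curated
reference is nucleotide FASTA.  The species consensus pools per-individual
sets, clusters at 98%, keeps representatives, and unions per-individual
provenance.

## Coverage screens

The chimera screen consumes zero-mismatch coverage of the assembling
individual's own merged reads (this follows the strictest alignment the
workflow defines, produced in the same step that purges mismatched reads).
Verdicts: any zero-depth CDS base removes the transcript; a >10-fold
max/min depth range removes it only when a two-segment changepoint
(moving-average smoothing, window 25; both segments ≥ 10% of the CDS)
splits the CDS into means differing >10-fold — the operationalization of
"multimodal coverage"; a >10-fold range without such a split is flagged
but kept.  Planted chimeras (5′ half of one parent fused to the 3′ half of
another, with reads simulated only from the parents) are caught either by
the zero-coverage rule (no error-free read spans the junction) or by the
segment test when the parents' depths differ.

Two absence rules coexist deliberately.  Toxin reporting: absent when
strictly more than 10% of the CDS has depth below 5× under ≤3-mismatch
alignment.  Shared-nontoxin selection (for phylogenetic loci): a locus is
kept only when every individual covers every site at least once.  Absence
calls are reporting-only; all transcripts remain in the differential
expression analysis.  At ~20× coverage the toxin rule recovers planted
absences with 100% sensitivity and ~98% specificity — the false calls come
from clusters of haplotype variants that locally defeat the ≤3-mismatch
cap, which is also the mechanism that produces conservative absence calls
on real data.

## Quantification

Reads map to every transcript reachable within 3 combined
mismatches/gaps (edlib, both strands), multi-mappers retained.  Abundances
come from a standard EM over candidate sets (E-step proportional to
abundance over effective length; M-step renormalizes; per-iteration
log-likelihood is non-decreasing), with effective length = CDS length (no
fragment-length correction — a deliberate simplification at this scale).
TPM columns sum to 10⁶ before zero handling.  Zeros are replaced
multiplicatively (δ = 0.65 × smallest nonzero in the column, nonzeros
rescaled to preserve the column total; 0.65 is common practice for the
replacement fraction).  clr subtracts the mean log.  Class-level matrices
sum transcript rows by family and conserve column totals.  Expression
clustering is average-linkage on Euclidean distances of ln-expression,
computed on label-sorted input for permutation invariance.

Differential expression consumes EM expected counts, not TPM: the
negative-binomial models require counts, and length normalization is
handled by the model offsets.  This is a documented divergence from a
literal "TPM counts" reading.

## Differential expression engine

One NB-GLM engine, two test flavors, emulating the require-both-engines
consensus practice: per contrast, the samples carrying the two levels (or
all samples, for the SVL slope) are subset; size factors are
median-of-ratios with geometric-mean anchoring; per-gene dispersions are
moment estimates on the residuals of the contrast design (so genuinely
differential genes do not inflate their own dispersion), shrunk 0.15/0.85
in log space toward an a₀ + a₁/μ trend fit by least squares.  The
shrinkage weight was calibrated on the null simulation to give nominal
test size (type-I 0.050–0.055 at α = 0.05 on 1,000 null genes over a
balanced 4 + 4 design; heavier gene weights are anticonservative, a median
trend fit under-shoots the skewed moment estimator).  The Wald statistic
is referred to the standard normal — a t reference with residual degrees
of freedom measured grossly conservative (type-I 0.004) — and the LRT
against the intercept-only model to χ²₁.  BH-FDR is applied within
contrast (a global mode is available); consensus significance requires
both q-values ≤ α.  Genes whose fit fails carry NaN p-values and never
count as significant.

Power note: a 4-fold effect is reliably detected by the consensus rule in
balanced 4 v 4 groups at dispersion 0.1, but not in 1 v 3 contrasts of the
real design at any depth — the calibration experiment therefore uses the
balanced design, and single-individual lineage contrasts in applications
should be read as descriptive.

## Phylogenetic signal

K = (MSE₀/MSE) / [(tr V − n/(1ᵀV⁻¹1))/(n−1)], with V the Brownian tip
covariance from branch lengths, the mean estimated by GLS, and MSE₀ the
mean squared deviation from that same GLS mean — the original definition,
verified to 10⁻⁶ against an independent R implementation (picante::Kcalc)
on a fixed tree.  V is built from patristic distances with midpoint
rooting computed in closed form from the tree diameter, which is exactly
deterministic (library midpoint rerooting proved hash-order dependent when
the midpoint ties at a node).  The permutation p-value is the add-one
estimator over uniform tip shuffles (999 by default; the trait is ln-TPM).
Mean K over 1,000 Brownian simulations on the eight-tip lineage tree sits
within (0.9, 1.1), the statistic's defining calibration.

## Proteomics

Per replicate, the conversion factor is the through-origin least-squares
slope of known standard amounts (25/250/2500 fmol) on observed normalized
spectral counts, b = Σcᵢsᵢ/Σsᵢ²; a replicate missing any standard is
unusable.  Concentrations are slope × count, averaged over the three
replicates.  Detection (≥ 1 replicate) and quantifiability (all 3) are
separate flags; quantitative analyses use the stricter one, and
systematically unreliable families (bradykinin-potentiating peptides,
myotoxins) are excluded by a configurable list.  Note the three-point fit
is dominated by the largest standard, so its relative error is on the
scale of the count noise cv (≈ cv, not cv/√n); recovery is exact at zero
noise.  Transcript–protein correlations (Spearman, Pearson, R²) are
computed on clr-transformed paired abundances of quantifiable,
non-excluded proteins.

## Pipeline and bookkeeping

`run_pipeline` executes decontaminate → trim → merge → assemble → annotate
→ chimera screen → per-individual dedupe → consensus → map/quantify →
absence calls → differential expression (transcript and class level) →
Blomberg K → proteomics → summary, all seeded from one configuration seed;
rerunning a configuration is byte-identical.  Consensus transcripts adopt
their annotation reference id (suffixed when duplicated); allelic
duplicates collapse onto one locus for transcript–protein pairing.
Summary percents are recomputed from their count numerators: absence
shares as integer or one-decimal percents rounded half away from zero, the
differential-expression share truncated to one decimal (4 of 62 prints as
6.4), matching how such figures are conventionally printed.

## Problem sizes

The validation experiments are desk-scale by design: 12–28 transcripts and
tens of thousands of reads per experiment at 20–90× coverage, versus
~2,000 transcripts and ~12 M read pairs per individual in a real study.
The statistical structure (family divergence, lognormal expression,
absence rates near 12%, 5% contamination, three spiked standards) matches
the study design; the sequencing effort is scaled to what the rules being
tested require, with the scaling rationale given per experiment above.

## Known limitations

* The assembler is exact-overlap only; indel sequencing errors or
  polymorphisms break contigs (out of scope by design).
* The contamination rule depends on sample distinguishability; samples
  with near-identical transcriptomes at low depth cannot be fully cleaned
  (the geometry is quantified above).
* The NB engine approximates, but does not numerically reproduce, the two
  published engines it stands in for; the consensus rule is preserved
  exactly.
* Proteomic inputs begin at normalized spectral counts; spectrum-level
  processing (search, FDR validation, protein inference) is upstream of
  this package.
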