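# Methods

`sipmosaic` implements the computational chain of a stable-isotope-probing
(SIP) metagenomics study of naphthalene degraders: attribution of a mosaic
catabolic operon to its two parental operons, recruitment of sequencing
reads to operon variants, 16S-based heavy-fraction enrichment calling,
in-silico degenerate-primer screening, and biosensor kinetics
normalization.  This note records the models, the parameters that matter,
and the design choices made where the problem was genuinely open.

## Pairwise alignment

All comparisons are pairwise nucleotide alignments with affine gap costs:
match +5, mismatch −4, and a length-*k* gap costing `gap_open + k ·
gap_extend` with defaults −10/−1.  Gaps are penalized strongly on purpose:
the operon variants being compared are collinear homologs, so most true
differences are substitutions, and a gap-happy alignment would smear
donor signals.  The dynamic programming is Biopython's exact affine-gap
Needleman–Wunsch (C implementation); this package owns the scoring
conventions, the identity definition and the projection logic, and always
takes the aligner's first reported alignment so results are deterministic.

Identity is defined as matching columns divided by **all** alignment
columns (gap columns count as non-matches).  This makes identity monotone
under added gaps.  For semi-global alignments (a read inside a longer
reference, reference overhangs free) identity is computed over the read's
aligned span only.

Read-scale alignment in the recruitment and 16S modules uses edlib's
bit-parallel semi-global mode, with identity recomputed from the extended
CIGAR under the same matches/columns definition.  An affine-gap DP over
every read × 10-kb reference pair would be orders of magnitude slower at
10⁴-read scale for no benefit at the identity resolution used here.  The
16S classifier additionally prefilters references with a k-bounded edit
distance (the identity floor implies a distance ceiling) and resolves the
exact identity only among hits within 2 edits of the best — a distance
gap larger than that cannot be overturned by the column normalization at
these read lengths.

## Site attribution

The query operon is aligned globally to each parent **independently**;
both alignments are projected onto query coordinates; each position is
labelled by the four-way rule: matches A only → `A_SPECIFIC`, matches B
only → `B_SPECIFIC`, both → `SHARED`, neither → `NOVEL`.  Two pairwise
alignments rather than a three-sequence alignment: deterministic,
O(n·m), and sufficient because the parents are collinear.  A parent gap
at a query position counts as "does not match" that parent — a base
absent from a parent is no evidence of homology with it.

Positions where the parents disagree are *informative sites*: the query
base identifies a donor there.  Segments are maximal same-donor runs of
≥ `min_run` informative sites (default 3); shorter runs are absorbed
into the flanking run with more informative sites (ties to the
preceding run).  Breakpoints are reported as the interval between the
last informative site of one segment and the first of the next, because
the true switch position is unidentifiable between informative sites.

Per-gene reports give the four-way percentage partition (sums to 100) and
both pairwise identities (`identity_to_A = %A-specific + %shared`, same
for B).  The categorical call tests, in order: `MOSAIC` (informative runs
of ≥ `min_run` sites from *both* donors inside the gene), `A_LIKE` /
`B_LIKE` (pairwise-identity margin ≥ `call_margin`, default 2 percentage
points), `NOVEL` (> 5% private sites), else `UNINFORMATIVE`.  MOSAIC is
tested before the identity margin deliberately: an unbalanced within-gene
recombinant (say an 80/20 donor split) has an identity margin far above
2 pp and would otherwise be misreported as single-donor, although it
demonstrably carries runs from both parents.

## Read recruitment and variant fractions

Each read is aligned semi-globally to every variant on both strands
(strand ties go to forward).  A read is **unrecruited** below
`recruit_min_identity` (default 0.80 — the homology floor standing in
for an operational definition of "operon-related reads", which upstream
tools leave unstated), **assigned** to the top variant if it beats the
runner-up by `assign_margin` (default 0.005, i.e. 0.5 pp), else
**ambiguous**.  Per-variant fractions are computed over confidently
assigned reads only; ambiguous and unrecruited counts are carried in
every report because the denominator choice is not neutral — variants
that share identical segments (a mosaic and its parents) make many reads
genuinely unassignable, and guessing them would manufacture precision.

Gene-linking reads (evidence that two genes sit on one molecule) are
reads assigned to a variant whose aligned span covers at least
`min_overlap` bases (default 20) inside both gene intervals.

## 16S classification and enrichment

A nearest-reference classifier against a small labelled 16S panel stands
in for database-scale profilers (it is documented as a stand-in, not a
reimplementation of them).  Default identity floor 0.97, the conventional
species-level 16S threshold; identity ties between different taxa are
left unclassified rather than broken arbitrarily.  Abundances are
percentages of classified reads, with the unclassified count reported
alongside (a total-read denominator would differ; the distinction is kept
visible in output metadata).

Enrichment across the gradient: `ratio = (heavy% + c) / (light% + c)`
with pseudocount c = 0.5 pp; a taxon is enriched iff ratio ≥ `min_ratio`
(default 5) and heavy% ≥ `min_heavy_abundance` (default 1%).  These are
declared heuristics: the underlying experimental readout is band
dominance on a gel, not a numeric rule.  Note an identifiability limit
that shaped the default simulation scenario: with leakage ℓ, a labelled
taxon's heavy/light ratio is approximately (1−ℓ)/S where S is the summed
community abundance of all labelled taxa, so when labelled taxa dominate
the community (S ≳ 0.2) no ratio threshold of 5 can fire.  Heavy-fraction
*dominance* (e.g. a 55%/1%/0.1% degrader pattern) is compatible with
small community abundances, and that is how the default SIP scenario is
built: labelled taxa at 5/1.5/1% of the community, dominating the heavy
pool at ~63/19/13% after renormalization.

## In-silico PCR

Primer sites are sought with IUPAC degeneracy-set matching and a uniform
per-position mismatch budget (default 0).  No 3′-anchoring or
thermodynamics: this is a sequence screen, not a chemistry model.  An
amplicon is a forward-primer site with a reverse-primer
reverse-complement site downstream within `max_product_len` (default
10 kb); both template orientations are scanned and minus-strand products
mapped back to input coordinates.  The read-set screen calls a primer
pair positive when ≥ `min_hit_reads` reads (default 5) contain a site
for either primer — single-primer evidence suffices because reads are
short fragments.

## Biosensor kinetics

Relative bioluminescence is raw luminescence divided by OD600 per well
and time point.  Replicate wells (4 by default) are averaged after
normalization, with the standard deviation carried.  Induction onset is
the earliest time where the induced trace reaches `fold_threshold`
(default 2) times the vehicle control at two consecutive samples; the
two-point requirement guards against single-sample spikes.  The
threshold is a declared operationalization of a qualitative "lights up
within minutes" readout.  No background subtraction is applied.

## The synthetic-data generator

The generator emulates the study's data shapes so every stage is testable
without downloads:

* **Parents**: equal-length collinear operons with the canonical *nag*
  gene order (*nagAa–nagG–nagH–nagAb–nagAc–nagAd–nagB–nagF–nagC–nagQ–
  nagE–nagD*); gene lengths are round stand-ins (1500, 1300, 500, 350,
  1350, 600, 800, 800, 800, 350, 950, 900 bp).  Parent B derives from
  parent A by independent per-gene substitutions (default divergence
  10%).  Equal-length, substitution-only parents keep truth donors in
  1:1 correspondence with mosaic coordinates; indel divergence between
  parents is an extension point, not modelled in v1.
* **Mosaic**: planned donor segments copied verbatim, then private
  mutations matching *neither* parent sprinkled at `novel_rate`
  (default 0.5%, consistent with sparse unassignable sites).
* **Reads**: lengths 30–530 bp (uniform by default), uniform start,
  uniform strand, substitution errors 0.5% and single-base indels 0.1%
  (pyrosequencing-like); homopolymer-aware error structure is *not*
  modelled.  Emitted lengths are clipped back into the length band when
  indels push them out.  An optional `min_informative` constraint
  resamples windows until they differ from every other variant in ≥ k
  positions — the machine form of "reads drawn from variant-specific
  regions".
* **SIP pools**: the light pool samples the whole community; each heavy
  read comes from the unlabelled background with probability `leakage`
  (default 5%, modelling carry-over of unlabelled DNA into heavy
  gradient fractions), otherwise from the labelled taxa renormalized.
  16S references are synthetic: one gene per taxon derived from a common
  ancestor at 5% divergence (≈10% pairwise).
* **Worked-example templates**: the gene-cluster record used for virtual
  amplification is a synthetic stand-in embedding the published cloning
  primers so that the product is 4,973 bp (the published cluster
  length); it is labelled synthetic everywhere and is not the deposited
  sequence.

Every generator is a pure function of its integer seed, with independent
child streams per output; truth files record donors, novel sites, read
origins and pool compositions, sufficient to recompute expected
downstream values without re-reading the FASTA output.

What passing tests on this generator do **not** show: robustness to
homopolymer indel error, chimeric reads, amplification bias, unequal
parent lengths, reference databases with thousands of taxa, or real 16S
secondary-structure-driven alignment difficulty.  The generator is a
study-condition emulator, not a sequencing simulator.

## Problem sizes and tolerances in the test suite

Recovery tests run at desk scale, chosen once: mosaic recovery uses 50
replicate three-segment mosaics on operons scaled to ~2 kb (gene lengths
× 0.2) at 10% divergence; mixture recovery uses 10,000 reads over three
4-kb variants at 10% pairwise divergence with the 64.3/18.0/17.7 mixture,
tolerance 3 binomial standard errors; SIP recovery uses 20 replicate
pools of 3,000 reads each.  The exhaustive alignment oracle enumerates
every alignment path for all sequence pairs over {A,C} up to length 4
(~900 pairs) and checks 300 random pairs of lengths 5–8 against an
independently written memoized affine recursion, since full enumeration
over all length-8 pairs (~2.6 × 10⁵ pairs × 2.7 × 10⁵ paths) is not a
meaningful target on any hardware.

## Known limitations

* Attribution assumes exactly two candidate parents; more parents, or
  phylogenetic recombination statistics (bootscan-style), are out of
  scope.
* The recruit threshold (0.80) is a stand-in for an unstated upstream
  definition of "operon-related"; absolute fractions depend on it and on
  the assigned-reads denominator.
* The enrichment rule is a heuristic with an explicit identifiability
  limit (see above); it reports carry-over-robust dominance, not
  isotopic incorporation per se.
* In-silico PCR ignores primer thermodynamics; a primer that matches at
  the sequence level may still fail in the machine, and vice versa for
  near-matches with favourable 3′ ends.
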