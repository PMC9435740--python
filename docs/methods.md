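# Methods

This note records the models, decision rules, parameter defaults and
numerical choices behind `primatesplice`, and what the synthetic fixture
does and does not establish about real data.

## Coordinates and domain objects

All internal coordinates are 0-based half-open; GTF I/O converts to and from
the 1-based inclusive file convention at the boundary, and round trips are
byte-stable for coordinates, strand and identifiers. A transcript is an
ordered chain of disjoint exons on one chromosome; introns are the gaps
between successive exons and must be at least 4 nt long so that the donor
and acceptor dinucleotides cannot overlap (`min_intron_length`,
configurable). Splice-site dinucleotides are always reported in
transcription orientation: on the minus strand the genomic last two intron
bases, reverse-complemented, are the donor. Transcript identity across
species is carried by shared keys in the orthology table (the same projected
model observed in five assemblies), not by per-species annotation ids.

## Structural classification

Categories are assigned by intron-chain comparison with a reference
annotation, ignoring 5′/3′ end positions (long-read end variability makes
end-aware matching unstable). Priority order: FSM (chain identity) > ISM
(consecutive sub-chain) > NIC (every donor and acceptor site individually
annotated, chain not matching) > FUSION (junctions contained in two or more
non-overlapping reference genes) > NNC (novel site, same-strand gene
overlap) > ANTISENSE > GENIC_INTRONIC > INTERGENIC. Fusion outranks NNC
because a read-through joining two genes is its own novelty class even when
its bridging junction is novel. Mono-exonic transcripts use overlap rules:
FSM when contained in a same-strand reference exon; otherwise the same-strand
genic catch-all is reported as GENIC_INTRONIC (exact sub-exon rules for
mono-exonic reads are genuinely underdetermined; this is the simplest
consistent extension), then antisense/intergenic. A junction is *known* iff
its exact intron interval occurs in a same-strand reference transcript.

## AS events

Events are detected between isoform pairs and deduplicated per gene by
(class, defining intervals). SE: an internal exon of one isoform whose
flanking junctions' outer splice sites form a single junction of the other.
RI: one isoform's exon spans exactly the two exons and intervening intron of
the other. A5SS/A3SS: two junctions share one boundary and differ at the
other, *with the additional requirement that the longer junction's free
boundary falls strictly inside the exon flanking the shorter junction* — the
literal share-one-boundary rule would also fire on the two flanking-junction
pairs of every SE configuration, which contradicts SE being its own class;
the containment requirement is the standard alternative-site definition.
MEX: two non-overlapping exons sharing the same flanking junction context,
each present in some isoform without the other, never co-occurring, and not
directly skippable across the shared context. 5′/3′ naming follows
transcription orientation, so flipping only the strand annotation swaps
A5SS and A3SS, while mirroring the locus *and* flipping the strand
reconstructs the same RNA and preserves every class; both symmetries are
asserted in the tests, alongside equality with a brute-force per-definition
oracle on randomized genes.

## Canonicity

Canonical = {GT-AG, GC-AG, AT-AC} in transcript orientation; anything else,
including pairs containing N (with a warning), is noncanonical. Orthologous
junctions are read from each assembly at their mapped coordinates; a change
flag requires at least two species present with differing labels, and
unmappable species are excluded rather than guessed. A species-specific
transcript is *canonicity-driven* when at least one of its distinguishing
junctions (junctions absent from every other species' expressed junction
set) is canonical in the expressing species and noncanonical in every other
species where it is present; *conserved canonicity* means every junction of
the transcript is canonical in all five species.

## Exon orthology and exonic parts

The pipeline consumes mapping tables (feature × species with MAPPED/UNMAPPED
status and alignment coverage in [0, 1]) rather than running a lift-over
tool; the decision rule is the implementable content. Conserved: mapped in
every other assembly. Species-specific: unmapped everywhere else *and*
coverage < 0.5 in all four other assemblies (strictly below; a single 0.5
leaves the exon unresolved). Anything else, including features with missing
coverage or multi-locus mappings, is unresolved. The rule is monotone:
lowering a coverage value can never turn a species-specific call into
conserved. Exonic parts — the DEU counting units — are the gene's exon union
split at every distinct exon boundary, each part carrying the set of
covering transcripts; flattening conserves total length, is idempotent, and
is checked against a per-base membership oracle. Part coordinates are kept
on an anchor frame (the generator emits colinear assemblies; with real
mapping tables the per-species projections attach through the same table).
UTR/CDS placement of an exon against the ORFs of its containing transcripts:
full_UTR (disjoint from every CDS), CDS_only (inside every CDS), else
partial_UTR.

## Presence, parsimony and species-specific transcripts

Strict presence: TPM > `presence_threshold` (default 0; 0.1 exposed in
config) in **all** replicates of a species. Lenient: in ≥ 2 replicates.
Absence: TPM ≤ `absence_threshold` (default 0) in all replicates. Any other
pattern is ambiguous and excluded from reconstruction and species-specific
calling — requiring consistent presence or absence across every biological
replicate is what separates expression evolution from inter-individual
variability. Species-specific = present in exactly one species, absent in
the other four.

Gains and losses are reconstructed per transcript on the fixed rooted
topology ((((H,C),G),O),M) by Sankoff dynamic programming over states {0,1}
with per-branch gain/loss costs (default 1/1; an asymmetric 2/1 scheme is
tested equally). All optimal internal labelings are enumerated (at most 16),
and an event not shared by every optimal labeling is reported on each
candidate branch with `ambiguous_direction=True` — notably the
macaque-versus-great-apes split, where a terminal gain and a stem loss tie.
The engine is generic over the tree (newick input via dendropy), but the
five-taxon default is the analysis frame.

The gene-level up-regulation confound check replaces a negative-binomial
Wald test with Welch's t on log2(TPM+1), focal replicates versus all other
samples, BH-adjusted across genes, flagging adjusted p < 0.1 with positive
log2 fold change. With three replicates per group the decision thresholds,
not the likelihood machinery, are the operative content; the generator keeps
gene totals constant under usage shifts precisely so that this check stays
negative on planted events.

## Usage dynamics

TMM normalization follows the trimmed-mean-of-M-values recipe: reference =
sample whose upper quartile of library-scaled nonzero counts is closest to
the mean upper quartile; M and A computed on doubly-positive genes; 30%
two-sided trim on M and 5% on A; factor = 2^(precision-weighted mean of
retained M) with binomial delta-method weights; factors rescaled to
geometric mean 1. An independent straight-line implementation in the test
suite must agree within 1e-9. Batch correction, when batch labels exist, is
per-batch median-centering of log2 expression — an additive location
correction only, documented as a deliberate simplification.

IU is a within-sample, within-gene fraction, so per-sample scaling cancels
in it; normalization matters for the expression filters and gene-level
checks. Genes with near-identical isoform pairs (equal intron counts, all
intron boundaries within `shift_max` = 30 nt, duplicates included) are
excluded from usage analyses as quantification-ambiguous.

DIU/DEU testing: for each feature and each of the ten species pairs, a
two-sided Welch t-test (seeded permutation test optional) on
logit-transformed usage, clipped to [ε, 1−ε] with ε = 0.01; BH adjustment
across features within each pair; FDR 0.05 default. Species-specific call
for S requires all four comparisons involving S significant with a
consistent sign and none of the six others significant. Expression filters:
gene TPM ≥ 1 in ≥ 2 samples per species, feature nonzero in ≥ 2 samples of
some species; groups with fewer than two usable replicates are skipped.

Dominance: transcripts ranked per species by mean IU across replicates (ties
broken by total expression, then lexicographic id). The shared-dominance
fraction is recomputed under increasing rank-1/rank-2 fold-change
thresholds, restricted to genes exceeding the threshold in every species;
on conserved synthetic data this curve is monotone non-decreasing. A
dominance *switch* is called when exactly one species deviates from the
other four **and** its dominance is decisive (rank-1/rank-2 fold change ≥
1.5): near-tied genes flip rank order by sampling noise, which says nothing
about evolution, and the decisiveness margin is the same robustness idea as
the fold-change curve.

## ORFs and peptides

ORF calling is the deterministic longest-ORF heuristic: longest sense-strand
ATG-initiated frame to an in-frame stop (or, flagged incomplete, to the last
complete codon), minimum 50 aa, ties 5′-most. Tryptic digestion cleaves
after K or R except before P, emitting all fragments with ≤ 2 missed
cleavages and length 7–40 (typical search-engine settings, configurable),
deduplicated per protein; a substring-enumeration oracle checks it
exhaustively. Peptide novelty is substring matching against the reference
proteome under I/L equivalence (mass-indistinguishable residues, matching
how search engines treat them; switchable off). Peptides matching multiple
proteins are kept and attributed to each parent rather than resolved.
Ordered protein-domain combinations are compared by exact tuple equality
against the reference combination set; the empty combination is known iff
an undomained reference ORF exists.

## Enrichment and gene classes

Fisher mode is the two-sided exact test by hypergeometric point-probability
summation (delegated to scipy, verified against exact integer combinatorics
to 1e-10 over all small tables); the odds ratio is (a·d)/(b·c) with zero
cells reported as 0/∞ plus a flag, never silently corrected. Backgrounds are
always explicit arguments. Hypergeometric mode reports the upper-tail
over-representation p and observed/expected fold change. BH adjustment
delegates to scipy's step-up implementation, verified against the direct
formula; Holm via statsmodels. All-pairs rank comparisons default to
Wilcoxon rank-sum with Holm adjustment; a DSCF mode (pairwise standardized
rank statistic referred to the studentized range) is available for
multi-class score comparisons.

Splicing-evolution gene classes combine species-specific transcript gains
with DIU and DEU up-calls per species: MULTI_SPECIES_UP (up events in ≥ 2
species — taking precedence over the single-species classes even when one
of the two species is human) > HUMAN_SPECIFIC_UP / NHP_SPECIFIC_UP >
OTHER_CHANGES (any non-up or group-level difference) > CONSERVED. The
classes partition the evaluated gene universe.

## Synthetic fixture: what it emulates, and what it does not

The generator derives five assemblies from one ancestral sequence per gene
neighborhood (kb-scale chromosomes, one per gene) by neutral substitutions
at rate 0.003, with splice-site dinucleotides locked so canonicity changes
only where planted. Design choices made once, on realism grounds:

* **Colinear genomes, plus strand only.** No indels, so orthologous
  coordinates coincide and the orthology table is exact; all simulated genes
  sit on the plus strand. Strand handling and reverse-complement symmetry
  are exercised by dedicated minus-strand unit and property tests instead of
  by the fixture. Consequently the fixture cannot detect coordinate-shift
  bugs specific to projected (non-colinear) assemblies.
* **Expression model.** Per sample, a gene total is drawn negative-binomial
  (log2 mean 11 ± 1 across genes, i.e. roughly 2000 counts; dispersion 0.1,
  a typical between-individual value for cell-line RNA-seq) and allocated to
  isoforms by a multinomial under the species' usage vector with logit-normal
  replicate jitter (σ = 0.15). Biological variability therefore acts mostly
  at the gene level while usage fractions stay comparatively stable, which
  is both realistic and what makes usage-based tests well calibrated; the
  generator does not model positional coverage, fragment-length bias, or
  mapping ambiguity, so passing recovery says nothing about quantifier
  error. TPM uses transcript length as effective length.
* **Planted events.** Transcript gains extend one exon 45 nt into its intron
  (past the 30-nt quantification-ambiguity window), creating a unique donor;
  the canonicity-driven subset carries GT at that donor only in the focal
  assembly and a noncanonical dinucleotide elsewhere. Exonizations insert a
  new 90-nt exon mid-intron, annotated only in the focal species, with
  simulated (drawn, not aligned) coverage in [0, 0.45) elsewhere and an Alu
  interval over a configurable fraction (default 0.8); a 5% background rate
  of ancient exonized Alus over conserved exons keeps the enrichment table
  finite. Gains and exonizations have usage 0.3 in the focal species and
  exactly 0 elsewhere (so strict absence holds by construction). DIU shifts
  move one isoform's usage from 0.3 to 0.7 in the focal species; DEU planting
  moves the inclusion isoform between 0.85 and 0.15; dominance switches swap
  a 0.75/0.25 pair. Gene totals stay constant under all usage planting.
* **Replicates.** The main design is 3 replicates per species; usage
  analyses (DIU/DEU/dominance) run on a second 6-replicate draw from the
  same reference, the problem size at which the planted shift sizes are the
  study conditions for those analyses.
* **Recovery scoring.** Sensitivity is per planted key. For the empirical
  FDR, a call is false only when its gene carries no planted perturbation
  for the called species: the planted classes are not independent (a
  focal-only transcript gain genuinely shifts isoform usage in its gene), so
  cross-class calls on perturbed genes are signal, not error.

Deterministic throughout: one seed fixes genomes, tables and expression;
identical configuration gives byte-identical fixture files. A pre-baked
5-gene smoke fixture under `tests/data/smoke/` exercises the file readers
and the CLI.

## Numerical details and degenerate inputs

Logit usage is clipped to [0.01, 0.99] before testing; zero-variance rows
yield NaN p-values (never significant). BH leaves NaNs in place. Sankoff
optimality comparisons use a 1e-9 tolerance. Genes whose total is zero in a
sample give missing IU for that sample; all-zero count columns are rejected
by TMM. Empty proteins digest to nothing; transcripts without a qualifying
ORF simply drop out of proteomic analyses. Deduplication keys and output
tables are sorted, so all outputs are order-independent.

## Known limitations

Real long-read artifact filtering (RT switching, coverage-based filters),
lift-over execution, NB-GLM usage machinery (DEXSeq/DRIMSeq), empirical-Bayes
batch correction, and MS spectrum-level evidence are all out of scope; where
the surrounding analyses needed a stand-in (Welch-on-logit usage tests,
median-centering batch correction, drawn alignment coverage) the replacement
is documented above and its decision thresholds are kept explicit. The
five-taxon tree is fixed by the study design; the parsimony engine itself is
tree-generic.
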