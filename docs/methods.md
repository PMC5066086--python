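# Methods

This note documents the models, conventions and design decisions behind
`bcrep`, in the spirit of a statistical-software methods appendix.  It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and regions

All V-gene coordinates use IMGT-style unique numbering with 1-based codons
laid out sequentially (the packaged toy germline has no numbering gaps):
FR1 ends at codon 26, CDR1 at 38, FR2 at 55, CDR2 at 65, FR3 at 104.  The
V core is therefore 312 nt, followed by a 6-nt 3' tail that reaches into
the CDR3.  The junction runs from the conserved Cys codon 104 to the
J-frame Trp (codon 118 analogue), inclusive; the CDR3 is the junction
minus both anchor codons.  All intervals are closed; nucleotide positions
within the V are 1-based.

**Mutation-analysis span.** Substitutions are called over codons 27–104
only.  FR1 is excluded because in the assay this pipeline models the
forward primers sit in FR1, so FR1 content is unreliable; the
CDR3/junction is excluded because N-region bases have no defined germline.
Consequently CDR means CDR1 ∪ CDR2 and FR means FR2 ∪ FR3 in every R/S and
selection statistic.  The denominator of the mutation frequency is the
number of *compared* germline positions (aligned, unambiguous on both
sides), not read length.

## The internal annotator

The annotator is deliberately simple: its purpose is to make the pipeline
runnable and testable end to end on synthetic data, not to compete with a
production aligner.  Candidate V and J genes are ranked by
global(gene)–local(read) edit distance (edlib "HW" mode); ties keep
database order, and only the first calls feed clonality.  The top V is
then realigned with Biopython's `PairwiseAligner` (match 2, mismatch −1,
gap open −6, extend −1) to obtain the per-position germline↔read map.
Reads whose V alignment needs internal gaps are flagged `has_indel` and
excluded from all mutation tallies; gaps confined to germline positions
past the V core (nt > 312) are treated as junction-attribution artifacts —
a trimmed 3' tail chance-matching N bases — and truncated rather than
flagged.

**Junction decomposition.** `v_del`/`j_del` are the germline bases missing
at the V 3' and J 5' ends of the alignment; interior bases are attributed
to a D gene by longest exact substring match (minimum 6 nt), whose trims
count toward `junction_deletions`; everything unattributable is N.  This
decomposition is inherently ambiguous: a trimmed germline base that
chance-matches an adjacent N base is re-attributed to the germline, so the
annotator's N count is a lower bound on the generative N count.  The
mode-equivalence test asserts exactly this one-sided relationship; all
analysis outputs that do not depend on the N/deletion split (mutations,
junctions, regions, clones, selection) are bit-identical between
FASTA-annotation mode and truth-annotation (AIRR) mode on error-free data.

## Filtering

The inclusion chain runs in a fixed order — productivity → completeness
(CDR1/FR2/CDR2/FR3 all present) → no ambiguous base in CDR1–CDR3 →
subclass defined — followed by duplicate collapse on the key *(exact
CDR1-start…CDR3-end nucleotide string, subclass)*.  The subclass is part
of the key so that identical variable sequences under different constant
genes survive as distinct transcripts; the cross-subclass overlap
statistic depends on this.  Keys observed fewer than 2 times are discarded
as presumptive sequencing errors (a single amplicon-PCR/sequencing error
virtually always creates a novel key).  Donor × class strata with fewer
than 45 unique transcripts are excluded from analysis.  Both thresholds
are configurable (`min_duplicate`, `min_unique`).

## Selection statistics

The per-transcript test asks whether `R_CDR` (replacement mutations in
CDR1+CDR2) is large given `M_v` (all mutations in the analysis span),
under X ~ Binomial(M_v, p) with `p` computed by enumerating all three
substitutions at every analysed germline position and counting the
fraction that are both replacement and in CDR.  The test is one-sided
(upper tail, P(X ≥ R_CDR)), uncorrected, with `p < 0.05` defining
"antigen-selected"; `M_v = 0` yields p-value 1.  Multiple mutations in one
codon are each classified independently against the *germline* codon (the
single-substitution convention); mutations to stop codons count as
replacement.  An optional hotspot weighting of the null (RGYW/WRCY and
WA/TW positions weighted ×k) is available but off by default.

The per-donor **selection strength** is the pseudocounted log-odds
contrast between the observed replacement count and its expectation under
the enumerated null, per region, with a 1,000-replicate nonparametric
bootstrap over transcripts for the CI.  It is antisymmetric in
(observed, expected) and zero at equality.  It is *not* a posterior — it
is a documented, clearly named summary whose sign and ordering reproduce
the qualitative contrast of interest (CDR strength above FR strength under
antigen selection).

## Clonality and lineage trees

Clone partition: group by (first V gene allele-collapsed, first J gene,
junction length), then single-linkage cluster with absolute junction
hamming distance ≤ 3 inclusive; ambiguous bases match anything (minimal
distance rule); distances are never normalized.  Clones may span isotype
classes and subclasses, so clonality is computed on the merged IGG+IGA set
per donor.

Lineage trees operate on mutation-presence sets.  Transcripts with
identical profiles merge into one node.  For ≤ 8 distinct profiles the
tree is the exact minimum-substitution (Steiner parsimony) solution: all
rooted binary topologies over the profiles are enumerated ((2k−3)!! of
them) and scored with Fitch's algorithm on bit-packed binary characters
(one per distinct mutation, O(1) per merge), with the germline fixed as an
all-absent root; ancestral states are then assigned top-down preferring
the parent state, zero-length edges collapsed, and surviving unobserved
states reported as inferred intermediates.  Homoplasy is representable but
penalized by the substitution count.  Above 8 profiles a greedy
agglomeration repeatedly joins the pair with the largest shared mutation
set under an inferred parent carrying the intersection; for laminar
(homoplasy-free) profile families — which the simulator produces by
construction — this is provably optimal, and the suite checks its
agreement with the exact search on ~100 simulated clones; on real data
with homoplasy it carries no optimality guarantee (documented
disclaimer, `LineageTree.exact` records which path ran).

## The simulator: what it emulates, and what it does not

The generator produces the statistical structure the analysis assumes,
with truth records for every read.  Defaults are the package's study
conditions and are not meant to be tuned per run:

| parameter | default | meaning / rationale |
|---|---|---|
| donors | 38 (2 cord blood, ages 0–74) | demo cohort spanning neonate → elderly |
| mutation rate | age ramp 0→7 % over ages 0–6, then plateau; CB 0.3 % | childhood accumulation of SHM with an adult plateau around 7 % |
| donor jitter | lognormal, σ = 0.12 | spreads adult donors over roughly 5.6–9.4 % |
| `gc_phase_fraction` | 0.55 | slight majority of mutations at G/C (BER phase) |
| `transition_prob` | 0.5 | about half of substitutions are transitions |
| `hotspot_bias` | 3.0 | RGYW/WRCY and WA/TW positions 3× more likely to mutate |
| `cdr_r_enrichment` / `fr_r_rejection` | 2.0 / 0.35 | antigen selection: replacement enrichment in CDR, purifying selection in FR; chosen analytically so region R/S ratios land in the empirically typical ranges (CDR ≈ 4–8, FR ≈ 1.6–2.7) |
| `within_clone_switch_prob` | 0.15 | member re-switches downstream-only; both pre- and post-switch transcripts are emitted (switching without new SHM) |
| subclass model | per-age-group table | IGG2/IGA2 share rises with age, IGG1 falls, IGG3 peaks in children, IGG4 rare |
| duplicate depth | Geometric(mean 3), min 1 | duplicated amplicons plus a 1/3 singleton fraction |
| `sequencing_error_rate` | 10⁻³ /base/copy | substitution errors creating singleton variants |
| junction model | geometric trims, Poisson(4) N per side | trimming/N-insertion at V(D)J joining; P nucleotides folded into N |
| clone sizes | Zipf(2.5), capped at 12 | heavy-tailed clonal expansions |
| `n_clones` | 70 per donor × class | sized so that, after duplicate-collapse losses, nearly all demo strata clear the 45-unique-transcript cutoff, as in a realistically sequenced cohort |

Mechanics worth knowing:

- **Two-phase SHM.** Each mutation first draws a phase (G/C with
  probability `gc_phase_fraction`, else A/T), then a position within the
  phase weighted by `hotspot_bias`, then a target base by
  `transition_prob`.  Candidates are rejected and redrawn (bounded budget)
  when the selection knobs say so or when they would create a stop codon —
  the latter emulates survivorship of expressed receptors and can be
  disabled (`allow_stop_mutations=True`) for exactly-neutral experiments.
  A saturated phase (very dense clones) falls back to the other phase so
  the drawn mutation count is always honored.
- **Lineages.** Each clone gets a trunk (40 % of the per-member expected
  count) shared by all members plus per-member private mutations at
  distinct positions, so profiles are laminar and homoplasy-free — which
  is what makes truth-based lineage assertions exact.
- **Frame discipline.** Toy D and J segments are frame-neutral, so only
  trims and insertions shift frame; N1 is adjusted by ≤ 2 nt to keep
  junctions in frame (recorded in truth), and junctions are redrawn when
  they contain an in-frame stop.

Not emulated: germinal-center dynamics and affinity maturation over time,
insertions/deletions from SHM, platform-specific error profiles
(homopolymer errors etc.), P-nucleotides as a separate entity, allelic
variation, and real IGHV motif composition — the toy germline is random
coding sequence, whose RGYW/WRCY density is lower than that of real,
hotspot-enriched V genes, so motif-targeting percentages on synthetic data
sit below values typical of biological repertoires.  Passing tests
therefore demonstrate the correctness of the machinery under the model's
assumptions, not biological fidelity of any particular percentage.

## Numerical and testing choices

- All randomness flows through one `numpy.random.Generator` seeded from the
  config; outputs are byte-identical for a fixed seed.
- Binomial tails come from `scipy.stats.binom.sf`; the suite checks them
  against exhaustive pmf summation to 10⁻¹² for `M_v ≤ 20`.
- Bootstrap CIs are percentile intervals (2.5/97.5) over transcript
  resamples; replicates with no mutations in the region are dropped.
- Deterministic tie-breaks everywhere: database order for equal alignment
  scores, lexicographic read-id order for duplicate representatives and
  clone ids, first-pair order in the greedy tree agglomeration.
- Test problem sizes are chosen to keep the whole suite within a few
  minutes while leaving comfortable statistical margins: e.g. mutation-rate
  recovery uses 500 independent transcripts × 234 nt (SE ≈ 0.08 pp against
  a ±0.3 pp assertion), and bootstrap-coverage checks use 100 cohorts of
  50 transcripts.

## Known limitations

- The annotator presumes substitution-only reads near full V length; it
  is not a general-purpose aligner and will mis-handle large indels or
  heavily truncated reads (they are dropped or flagged, never silently
  analysed).
- The N/deletion split of the junction is a parsimony convention, not a
  recoverable truth; only its one-sided bias is guaranteed.
- The greedy lineage heuristic is optimal only without homoplasy.
- The selection strength is a log-odds summary, not a posterior density;
  its CI reflects sampling of transcripts only, not uncertainty in the
  enumerated null.
- Cross-stratum statistics (age-group tables) are simple aggregates; no
  inferential statistics (ANOVA, correlation tests) are computed — the
  per-donor tables are exported for use in external statistics software.
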