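# bcrep — antigen-experienced B-cell receptor repertoire analysis

`bcrep` is a tested, reusable pipeline for analysing class-switched (IGG /
IGA) immunoglobulin heavy-chain transcript repertoires, the way such data
are analysed when asking how somatic hypermutation (SHM), antigen
selection, and class-switch recombination (CSR) behave across donors and
ages.  It is aimed at immunology and computational-biology groups who have
IGH amplicon reads (or externally annotated AIRR Rearrangement TSV) and
want the downstream statistics, plus a fully truth-tagged repertoire
simulator so every stage of the pipeline can be verified without touching
real data.

## What it computes

Given annotated rearrangements, the pipeline applies the classic
error-control strategy for amplicon SHM data — keep only productive,
complete, unambiguous, subclass-assigned reads whose exact CDR1–CDR3
nucleotide sequence occurs **≥ 2** times, and drop donor strata with fewer
than **45** unique transcripts — and then computes, per donor × isotype
class:

- **SHM profile** over IMGT codons 27–104 (FR1 excluded as primer
  territory, CDR3 excluded for lack of a germline): mutation frequency
  (% of compared bases), fraction of mutations at AID hotspots (the G of
  RGYW / C of WRCY) and polymerase-η motifs (WA/TW), the substitution
  spectrum split into transitions/transversions at A/T and G/C, and a 4×4
  germline→observed substitution matrix.
- **Replacement/silent statistics**: per-region R and S counts and the
  R/S ratios for CDR (CDR1+CDR2) and FR (FR2+FR3).
- **Antigen selection**: per transcript, the one-sided binomial tail
  probability of observing `R_CDR` replacement mutations in the CDRs among
  `M_v` total mutations, with the null probability obtained by exhaustive
  enumeration of all `3 × L` possible substitutions of the germline V
  (transcripts with `p < 0.05` are called antigen-selected); per donor, a
  log-odds selection strength per region,
  `log[(R+½)/(E_R+½)] − log[(N−R+½)/(N−E_R+½)]`, with a nonparametric
  bootstrap CI (a deliberately simple stand-in for a full Bayesian
  posterior treatment).
- **Clonality**: clones defined by shared first-called V gene, J gene and
  junction length with junction hamming distance ≤ 3 (single linkage,
  non-normalized, ambiguous bases match anything), plus maximal-clone-size
  and unique-clone summaries.
- **Lineage trees**: per clone, a minimal-substitution tree rooted at the
  unmutated germline; clones with ≤ 8 distinct mutation profiles get an
  exact Steiner-parsimony tree (exhaustive topology search with bit-packed
  Fitch scoring), larger clones a greedy shared-mutation agglomeration.
  Trees export to Newick with substitution counts as branch lengths.
- **Class-switch statistics**: subclass usage (IGG1–4, IGA1–2) per donor
  and age group, and the percentage of transcripts whose exact CDR1–CDR3
  sequence is observed under two different constant genes — evidence of
  switching without further hypermutation.

The **simulator** (`bcrep.simulate`) emits reads with known ground truth:
V(D)J recombination with junction trimming and N insertions, clonal
lineages with trunk + private mutations, a two-phase hotspot-biased SHM
model, region-dependent selection knobs, age-dependent downstream-only
class switching, duplicate read depth and sequencing-error singletons.

Annotation against the packaged **synthetic toy germline set** (10 V, 4 D,
4 J segments with IMGT-style anchors and 6 constant-region motifs) is
included so the pipeline runs end to end from FASTA; for real data you
would annotate externally (e.g. with IMGT/High-V-Quest) and load AIRR TSV.

## Worked example

```bash
python examples/02_shm_profile.py
```

prints (seed 11, one simulated 30-year-old donor):

```
transcripts analyzed : 49
pct_mutation         : 7.29%  (substitutions per compared germline base)
pct in RGYW/WRCY     : 16.5%  (AID hotspot targeting)
pct in WA/TW         : 31.8%  (pol-eta motifs)
pct at G/C           : 55.1%, of which transitions 53.4%
R/S ratio CDR        : 6.60
R/S ratio FR         : 1.49
```

The mutation frequency sits at the adult plateau (~7 %) configured in the
simulator's age model; slightly more than half the mutations fall at G/C
pairs, about half of those being transitions — the signature of the base
excision repair branch of SHM — and the CDR R/S ratio far exceeding the FR
ratio is the classic imprint of antigen selection.  The other examples
(`examples/01…05`) walk through filtering, selection testing, clonal
lineages and class-switch overlap the same way.

A thin CLI mirrors the stages: `bcrep simulate | annotate | filter |
analyze | report` (see `bcrep --help`).

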