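# Methods

This note documents the models and procedures implemented in `orloss`,
the defaults and why they were chosen, what the synthetic data do and do
not emulate, and the numerical conventions that make results
reproducible.

## Intact-OR identification

Vertebrate OR genes are single-exon, so candidacy is decided on the
nucleotide sequence alone. `find_orfs` scans all six frames (three
forward, three on the reverse complement) and reports every *maximal*
ATG-to-stop ORF — one whose start codon is the first ATG after the
preceding in-frame stop, so it cannot be extended 5′. Codons containing
N translate to X and never act as start or stop codons.

`filter_intact` applies two rules:

- **Length.** The ORF must be *longer than* 250 aa (strict: a 250-aa ORF
  is rejected). This threshold reflects the minimum plausible length of
  a seven-transmembrane receptor.
- **TM integrity.** The translation is globally aligned to an intact
  reference OR protein (affine gaps, open −10 / extend −1, BLOSUM62);
  any deletion run of ≥ 5 consecutive residues overlapping a
  transmembrane interval rejects the candidate, because a receptor
  missing part of a membrane-spanning helix cannot fold. Gaps of up to
  4 aa, and larger gaps confined to loops, are tolerated.

TM intervals are supplied with the reference panel (1-based inclusive
codon coordinates) rather than predicted; TM prediction is out of scope.
Alignment parameters are configurable — they are conventional defaults,
not values with independent support. An optional identity prefilter
(`min_identity`) is available but off by default; note that global
alignment of *unrelated* same-length coding sequences already yields
~60% column identity because gaps pair residues opportunistically, so
thresholds below that level only reject pathological inputs.

## One-to-one ortholog extraction

A clade of the (rooted) gene tree is a putative one-to-one ortholog
group when

1. its support is **strictly greater than 85** (0–100 scale; labels on a
   0–1 scale are interpreted as posterior probabilities and rescaled
   ×100 — the criterion is applied to whichever support the tree
   carries),
2. it contains **at most one gene per species**, and
3. it spans **at least 4 species**.

Only *maximal* qualifying clades are returned (a qualifying clade nested
in another is absorbed), which yields a unique, non-overlapping set;
groups are numbered by preorder appearance on the tree. Rooting uses the
outgroup when given, otherwise the midpoint. Internal node labels are
read as the support of the clade below the node (the common newick
convention).

The bundled tree builder is neighbour joining on p-distances
(gap/N sites pairwise-deleted; pairs with no comparable sites get the
saturation placeholder 0.75) with supports from site-resampling
bootstrap. It exists so synthetic end-to-end runs are self-contained; it
is not a substitute for ML or Bayesian inference on real data, where an
externally built tree should be supplied.

## Codon-aware pseudogene calling

`call_disruptions` globally aligns the query to the intact reference CDS
(affine gaps; match +2, mismatch −3, gap open −8, extend −2 — a gap of
length L costs open + (L−1)·extend) and projects the alignment onto
reference codons:

- every indel whose length is not a multiple of 3 is a **frameshift**;
- stop codons are read in the query's **running frame** (the frame
  implied by the cumulative indel offset), so stops induced downstream
  of a frameshift are found. A stop whose three bases map cleanly onto
  one reference codon in reference frame is a point **nonsense**
  mutation; any other stop is flagged `frame_induced` — reported, but
  distinguishable as a secondary consequence of the causal indel;
- in-frame indels are recorded but never set status by themselves.

A query is a **pseudogene** iff it carries ≥ 1 nonsense codon or ≥ 1
frameshifting indel. `first_disruption_fraction` is the reference codon
of the first disrupting event divided by the reference codon count
(terminal stop included); `classify_terminal_position` calls 5′ vs 3′
disruption at a configurable fraction (default 0.5 — the literature
notes "near the 5′ end" without a numeric definition, so the midpoint is
used and exposed as a parameter).

Two normalization steps make coordinates well-defined:

- **Left normalization.** When equal-scoring placements of an indel
  exist (repeats), the 5′-most placement on the reference is reported,
  as in VCF left alignment.
- **Complex-variant merging.** An insertion and a deletion within 9 nt
  of each other on the reference are re-expressed as their net edit (a
  block substitution when lengths are equal, otherwise one net indel).
  Parsimony alignment of clustered substitutions can otherwise fabricate
  compensating 1-nt indel pairs; merging them is the standard complex
  (MNP) representation and removes essentially all such artifacts while
  leaving genuinely separated compensating pairs (tens of codons apart)
  untouched.

Partial gene segments (e.g. 612–964-bp PCR amplicons) are handled
semiglobally: query end gaps are free and not reported as deletions, and
the reading frame is anchored to the reference codon grid at the first
aligned position. Queries below `min_identity` (default 50%) to the
reference are flagged low-confidence — their events are reported but
orthology is suspect.

Frame restoration (`frame_restored`) is set when frameshifting indels
are present but their net offset is ≡ 0 (mod 3), as with a 2-bp deletion
compensated by a 2-bp insertion.

## Shared disruptions and ancestral loss

Two disruptions in different species match when kind, indel length and
reference codon agree (codon tolerance configurable, default 0 — exact,
which left normalization against a common reference justifies;
`frame_induced` stops are excluded from matching since the causal indel
is matched instead). Maximal carrier sets are reported per signature.

Ancestral inference is Dollo-style: a shared disrupting signature is
assigned to the stem branch of the MRCA of its carriers (a complex loss
event is assumed to occur once); species-private events sit on terminal
branches. A congener alias map (`sequenced species → genome species`)
is applied before tree lookup, supporting designs where a sister species
is sequenced in place of the genome species.

A separate **weak-evidence rule** covers the pattern where all species
of a clade are pseudogenized and share a large in-frame deletion
(default ≥ 12 nt) while their frame-disrupting mutations are private:
the shared deletion suggests relaxed constraint before the split, but
the strict single-lesion logic does not apply. Such calls are labelled
`weak` and are never pooled with strict calls in the statistics.

Absence of data (a locus unrecoverable in a species) is reported as
`absent` and excluded from inference — missingness is not treated as
evidence of loss.

## Contingency statistics

Counting unit: (species, locus) sequence observations, not distinct
loci; `absent` entries are excluded (with a logged count). The
two-sided exact Fisher p sums hypergeometric probabilities ≤ that of
the observed table over the full support at fixed margins (the
minimum-likelihood rule, as in R's `fisher.test`), computed via
`lgamma` in log space with a 1e-7 relative slack for float ties; totals
within 1e-12 of 1 are returned as exactly 1.0. Degenerate margins give
p = 1.0 by convention with a warning. Two-sidedness is used because the
scientific claim is a *difference* in pseudogene fractions.

## Family and class assignment

Queries are assigned to the OR family of their best-scoring global
protein alignment against a user-supplied exemplar panel; ties break to
the lowest family id. Class is a pure function of family: 51–56 → Class
I (water-borne ligands), 1–14 → Class II (air-borne). This best-hit
scheme is a deliberate simplification of profile-HMM family scanning
and is not expected to reproduce HMM-based calls exactly.

## Synthetic data: what it emulates, and what it does not

`simulate_repertoire` evolves, per locus, an ancestral CDS (fixed ATG
start, random sense codons, TAA stop) along a species tree:

- **Substitutions** are uniform (Jukes–Cantor-like) at
  `substitution_rate` × branch length expected substitutions per site;
  proposals creating an unplanted stop in the lineage's current reading
  frame are resampled. The start codon, terminal stop and
  planted-lesion codons are protected so truth labels remain exactly
  derivable from the plan.
- **Planted disruptions** (nonsense, deletion L, insertion L) are placed
  on named branches in ancestral coordinates and inherited by all
  descendant leaves; descendant coordinates are derived by replaying
  events in branch order. Realized truth coordinates are left-normalized
  with the same convention as the caller.
- **Absence** is drawn independently per (species, locus) with a
  per-species probability, mimicking coverage-dependent recoverability
  differences between assemblies.

The default study conditions (`waterbird_scenario`) are 8 waterbird
species — two penguins sister to a fulmar, a four-species
ibis/egret/cormorant/pelican clade, and a loon outgroup on an
ultrametric tree of root-to-tip depth 1.25 —, 29 loci of 310 codons,
substitution rate 0.02/site/unit (≈ 2.5% query–reference divergence),
eight loci with penguin-stem disruption events (including a
compensating 2-bp deletion + 2-bp insertion pair, a 10-bp deletion with
shared upstream stops, and one locus with only a shared 12-bp in-frame
deletion plus private nonsense mutations — the weak-evidence case),
three private events in non-penguin species, and per-species absence
probabilities between 0.035 (high-coverage stand-in) and 0.41
(low-coverage stand-in).

Deliberately *not* modelled: realistic OR codon usage and composition,
selection (dN/dS), rate heterogeneity, gene conversion, duplication and
tandem clusters, alignment uncertainty from non-coding flanks, and
sequencing error. Passing tests on these data therefore demonstrate the
*structural* correctness of the inference chain (event recovery,
branch assignment, counting, exactness of the statistics) — not
robustness to every noise process in real genomes.

## Problem sizes and numerical choices

The test suite and the acceptance script run the simulator at its
default scale (8 species × 29 loci × 310 codons; 100 pipeline
replicates for the end-to-end study; ≥ 500 sequences at substitution
rate 0.05/site for the noise benchmark; 200 random trees for the
ortholog oracle), chosen so a complete run takes a few minutes on one
core. Determinism: a single integer seed drives every random stream;
identical configs and seeds give byte-identical outputs. Ties in
alignment are broken by left normalization (above); ties in family
assignment by lowest family id; group numbering follows preorder.

## Known limitations

- The NJ bootstrap builder is plumbing; real studies should import
  externally inferred trees with their own support values.
- Best-hit family assignment diverges from HMM-based assignment for
  queries roughly equidistant from several families.
- The identity prefilter/low-confidence threshold operates on gapped
  global alignment identity, whose floor for unrelated sequences is
  ~60%, not 25%.
- Exact shared-disruption matching (tolerance 0) assumes all species
  are called against the *same* reference; when mixing references,
  increase `tolerance` to absorb coordinate drift.
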