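# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `wyldomkit`. It is the package's own account of its science;
every number quoted here is computed by the test suite or the acceptance
script at run time.

## Sequence and alignment layer (`msa_core`)

**Pairwise identity.** Sequences are globally aligned with BLOSUM62, affine
gaps (open −11, extend −1) and free end gaps, via Biopython's pairwise
aligner. Identity is the number of identical aligned residue pairs divided
by the length of the *shorter* sequence — the convention of greedy
incremental clustering tools, which the clustering step mirrors. `X`
(unknown residue) never counts as a match.

**Greedy clustering.** Sequences are visited by descending length (ties by
id); each joins the first cluster whose representative (the founder, hence
the longest member) it matches at or above the identity threshold,
otherwise it founds a new cluster. The pipeline default of 0.70 is used to
deduplicate WYL seed alignments; the HTH wing models use 0.90 to keep the
two wing sub-types separated.

**Progressive aligner.** Guide tree: UPGMA (scipy average linkage) on
3-mer-profile distances — the k-tuple shortcut standard in progressive
aligners — rather than all-pairs DP identities, which keeps
maturation-scale re-alignments (hundreds of rows) affordable. Merges are
profile-profile Needleman-Wunsch with column score f_A^T·B62·f_B and the
same affine penalties; DP ties prefer diagonal, then vertical, making the
output deterministic for a given input order. Ungapping row k always
returns input k unchanged.

**Conservation.** Per column, gap-excluding residue frequencies give
H = −Σ f_a ln f_a and the score 1 − H/ln 20 (entropy with independent
counts). The named conservation tool offers several variants and the
original analysis does not say which was used, so the entropy variant is
the default and a BLOSUM62 sum-of-pairs variant (min-max scaled) is
provided as an option; neither is asserted to be the original's. Columns
with more than 50% gaps are flagged low-confidence; all-gap columns score
NaN.

## Profile-HMM engine (`phmm_engine`)

**Topology.** Plan7-style local multi-hit: flanking N and C states emitting
at background frequencies, a J loop allowing multiple domains per sequence,
core match/insert/delete states, uniform local entry (B→M_k = 1/M) and
free local exit (M_k→E with probability 1, the implicit-model convention of
the established tools). Loop/move probabilities are length-conditioned
(L/(L+3) multi-hit, L/(L+2) single-hit); E→J = E→C = 1/2 in multi-hit mode.
This is a semantic, not bit-exact, reimplementation of the established
search tools; bit scores are on the engine's own scale.

**Estimation.** Match columns are those with gap fraction strictly below
0.5. Match emissions are observed counts (uniform sequence weights) mixed
with the Robinson-Robinson background at a single pseudocount weight
(default 1.0) — a deliberate simplification of Dirichlet mixture priors;
its effect on the score scale is absorbed by the engine's own calibration.
Transitions come from the observed match/insert/delete paths with Laplace
smoothing (α = 0.1). Delete→insert transitions, absent from the topology,
are counted as delete extensions.

**Scoring.** Viterbi and Forward run in log2-odds space; insert and flank
emissions cancel against the background, and the final score subtracts a
geometric null length model. The in-row delete chain is computed by a
cumulative max (log-sum for Forward) over the delete-extension prefix sums,
which keeps the whole fill vectorized over model nodes. Both recursions are
verified against an independent brute-force path-enumeration oracle on
small models (tolerance 1e-9 bits).

**Domains and envelopes.** The optimal multi-hit path is segmented at local
entry/exit; a domain's envelope spans its emitted residues (the flanking
states define the boundary, so envelope and aligned span coincide in this
topology; the fields are kept separate because other envelope definitions
widen them). Two refinements matter in practice:

1. *Split merging.* A noisy stretch inside one domain occurrence can make
   the path exit and re-enter, splitting the occurrence into two segments
   whose model spans progress monotonically. Consecutive segments of the
   same model are merged when the later segment starts past the earlier
   one's last node minus a small tolerance (min(8, M/3) nodes). Genuine
   tandem copies restart near node 1 and never satisfy this.
2. *Scale-consistent rescoring.* Each envelope is rescored as its own
   sequence but with the flanking-state and null costs of the full-length
   context, plus the loop costs of the residues outside the envelope.
   Without this, short spurious envelopes escape most of the length
   correction that the calibration scores include, and their E-values are
   overconfident by several bits.

**Calibration and E-values.** A Gumbel law is fitted by maximum likelihood
(scipy) to multi-hit Viterbi scores of n random background sequences
(default n = 150–200, length 300–350; the engine requires n ≥ 100). The
E-value is N·P(S ≥ s) under the fitted law. One (μ, λ) pair serves both
full-sequence and per-domain E-values; because per-domain scores are
rescored on the same length scale (above), this single calibration is a
reasonable approximation, and the fitted tail is checked against held-out
random sequences in the tests.

**Thresholds.** Search defaults (E 1, domE 1, incE 0.01, incdomE 0.03) and
scan defaults (0.1, 0.1, 0.01, 0.03) follow the survey's settings. The
gathering thresholds 27.0 (WYL) and 30.0 (others) are carried as
conventions on the engine's own bit scale, not cross-tool equivalences;
recovery of planted domains, not score matching, is the correctness
criterion.

## Seed maturation (`hmm_maturation`)

The protocol that separates the WYL domain from its C-terminal extension:

1. Hits of the composite model (score > 30, independent E-value < 0.001)
   are split at 127 residues of envelope length; 250 are sampled from each
   stratum without replacement. A length of exactly 127 goes to the short
   stratum (the original protocol's "greater than"/"less than" wording
   leaves the tie unassigned; assigning it short affects only
   boundary-length sequences and is documented here).
2. Curation replaces the original manual step with a deterministic rule:
   rows whose gap fraction inside the conserved block (columns with ≥ 50%
   occupancy) exceeds 0.5, or that lack a residue in any tercile of the
   block, are dropped. The parameters are configurable to emulate stricter
   manual filtering.
3. Boundaries: the N-terminal boundary is the first column with ≥ 50%
   occupancy; the C-terminal boundary is the floor-median of the
   short-stratum hits' C-terminal columns. The crystal-structure input of
   the original boundary choice is not machine-readable here, so the
   short-hit median stands alone; an explicit boundary override is
   available.
4. Iteration: cluster the seed at the configured identity keeping
   representatives, build and calibrate, search the database keeping
   domains above the gathering threshold, re-align the hit envelopes with
   the internal aligner, trim to the ≥ 50%-occupancy span, repeat. The
   original protocol does not state how the full alignment was produced at
   each round; envelope re-alignment is this package's choice, and a
   model-based alignment would be the main alternative. With zero
   iterations (the WCX protocol) the model comes straight from the curated
   seed.

The wing split of the HTH seed is label-driven when labels exist (the
original split was by inspection); otherwise a complete-linkage clustering
of wing-region identities is cut into two groups.

All randomness flows from the config seed through a fixed derivation, so a
maturation run is byte-reproducible.

## Architecture classification (`architecture_classifier`)

Proteins are scanned against the model library; only included hits are
kept. Same-clan hits whose envelopes overlap by more than 50% of the
shorter envelope conflict; within each conflict component the kept subset
maximizes summed bit score (exact search up to 12 hits per component,
best-E-value greedy beyond), ties preferring lower total independent
E-value. Cross-clan overlaps are retained. Signatures are the clans of
resolved hits with independent E-value < 0.01, strictly N→C by envelope
start (ties by end, then model name); repeated clans are kept so natural
tandem fusions remain distinguishable. Classes are one per distinct
signature, sorted by descending size (ties by signature) and labeled A, B,
C, …; the display filter hides classes under 100 members from figures while
machine output always retains all of them. Proteins with empty signatures
form a reported unclassified set and are never merged into a class. Class
statistics use the numpy midpoint median and the sample standard deviation
(0 for singleton classes). Regions of ≥ 80 residues with no included hit
are reported for inspection rather than reclassified automatically, and
class merging (done by judgment in the original analysis) is exposed as an
explicit merge map, never automatic.

## Taxonomy statistics (`taxonomy_stats`)

The taxonomy is a flat TSV lineage table (no live taxonomy service, so
tests are deterministic). Two denominators are deliberately distinct:
`summarize_taxa` divides sequences by species *with hits* (the ring-plot
metric: radian = unique species, thickness = sequences per species), while
`per_organism_average` divides by *all* species of the taxon in the
collection, including zero-hit species, which therefore requires the
species universe as input. The 1.5% display filter operates on the species
fraction (matching the radian metric); a sequence-fraction alternative is a
flag, since the original caption does not say which total it means.
Non-bacterial sequences are excluded with a per-superkingdom report;
candidate-species judgment is out of automated scope.

## Synthetic collections (`synthetic_data`)

The generator emulates a reference-proteome collection: species grouped
into labeled phyla, each with background proteins (i.i.d. background
residues, 150–600 aa) and planted proteins built as linker + mutated domain
instances + linker. Defaults are the survey-like study conditions: four
phyla planted at the observed per-organism rates (5.2, 2.8, 2.0, 2.1), an
architecture menu of 60% HTH-WYL-WCX, 15% HTH-WYL, 10% fused tandem and
15% helicase-associated WYL, substitution rate 0.15 and indel rate 0.02.
Substitutions are drawn from BLOSUM62-derived conditional probabilities
rather than uniformly, so profile recovery at realistic noise is neither
trivial nor impossible; indels are geometric and never delete more than 10%
of an instance, keeping truth spans meaningful (a separate defect switch
plants C-terminal truncations to exercise curation). Per-species planted
counts are the integer part of the rate plus a Bernoulli remainder, so
integer rates are exact by construction. Composite mode plants a single
WYL-only (short mode, 90 aa) or fused WYL+WCX (long mode, 160 aa) region
with the split position recorded, which exercises the 127-residue split and
boundary recovery. Truth spans are 1-based inclusive, recorded after
mutation. Identical configurations give byte-identical outputs.

What the generator does **not** emulate: phylogenetic correlation between
sequences (no tree-based evolution), domain-length and linker-length
distributions of real proteomes, compositional bias, or homology between
families. Passing tests therefore demonstrate the pipeline's internal
correctness and its recovery power under controlled noise — not the
specific counts or proportions of any real proteome release, which depend
on the database snapshot and are out of scope.

## Problem sizes and numerical choices

The packaged experiments are sized for a desk-scale run: the survey
collection holds ~600 planted proteins plus one background protein per
species across 200 species; maturation replicates use 15 species with two
composite proteins each, 20 replicates; calibrations use 100–200 random
sequences. The enumeration oracle covers models up to M = 5 and sequences
up to length 8 on a reduced 4-letter alphabet (path counts grow
combinatorially beyond that). Tolerances: 1e-9 bits for DP-oracle
agreement; emission/transition normalization to 1e-9; exact equality for
hand-computed taxonomy aggregates and byte-level determinism checks.

## Known limitations

- Bit scores are not comparable with the external tools' scores; gathering
  thresholds are conventions on the engine's scale.
- The single Gumbel calibration is an approximation for per-domain
  E-values; a separate single-hit calibration would be slightly sharper.
- The envelope definition is path-based, narrower than posterior-mass
  envelopes; boundary errors of a few residues at high noise are expected.
- The progressive aligner is a guide-tree/profile merge without iterative
  refinement; deeply diverged families may misalign where a refining
  aligner would not.
- The unsupervised wing split assumes exactly two groups.
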