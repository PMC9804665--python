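# Methods

`famtrace` reconstructs the evolutionary history of protein families
across a eukaryote species tree from presence/absence evidence: which
species carry a detectable homolog, where on the tree each family was
gained, where it was subsequently lost, and where duplications occurred.
Because real multi-proteome surveys depend on dozens of external
databases, the package ships a fully seeded gene-family simulator that
reproduces the statistical structure of such a survey, so every stage
can be scored against known ground truth.

## Homology search

The search primitive is full Smith–Waterman local alignment (no seeding
heuristics) under BLOSUM62 with affine gap costs: a gap of length *L*
costs `gap_open + L * gap_extend`, defaults 11/1 — the de facto protein
search convention. The ambiguity letters B, Z and X (and other
non-canonical symbols) score 0 against everything. One numba kernel
serves both pairwise and profile search; a pairwise query is the
degenerate profile whose column *i* holds the substitution-matrix row of
query residue *i*.

Significance follows Karlin–Altschul statistics,
`E = K·m·n·exp(-λS)`, with *m* the query length and *n* the residues
searched. Gapped (λ, K) are not analytically derivable, so the package
estimates them by a seeded Gumbel fit to optimal-alignment scores of
random sequence pairs drawn from the Robinson–Robinson amino-acid
background (`fit_karlin_altschul`). The shipped defaults
(λ = 0.2883, K = 0.0592; 4000 pairs, m = n = 240, seed 0) sit close to
the values precomputed for the same scoring system by BLAST
(0.267, 0.041) and give a measured null false-hit rate of ≈ 0.045 per
query at the 0.05 cutoff. An empirical mode (exceedance rank among
seeded shuffles of the target, scaled by the number of targets) is
available per search for settings where no fitted constants exist.

Profiles are position-specific scoring matrices over an ungapped
center-star core: the member with the highest summed pairwise score
defines the columns, every other member contributes residues at the
columns its local alignment touches, counts receive +1 Laplace
pseudocounts, and log-odds against the background are scaled to
half-bits so the 11/1 gap costs remain commensurate. Each profile is
its own scoring system, so each carries its own (λ, K), fitted on 200
seeded random targets at construction time.

## The classification cascade

For each (family, species) pair the cascade emits one of three states,
mirroring the semantics of curated comparative-genomics surveys:

* **presence** — a candidate passed the full acceptance rule;
* **paralog** — forward evidence exists, but the best reverse hit is a
  different registered family member and the query is outside the
  reverse window (the "blue cell" state);
* **absence** — all strategies failed ("not found").

The acceptance rule for a forward hit (E ≤ 0.05) has three parts:

1. **Reverse validation.** The candidate is searched against the
   original query species' proteome augmented with the accepted-ortholog
   registry; it validates if the query or any previously accepted
   ortholog appears within the top *k* = 5 reverse hits passing the
   reverse cutoff (rank 5 inclusive; ranks counted after cutoff
   filtering with deterministic tie-breaks). The registry makes the
   role of "annotated orthologs from other species" deterministic and
   is what lets fallback strategies validate candidates that are too
   diverged to reach the original query directly.
2. **Length/architecture screen.** The candidate/query length ratio
   must fall in a configurable window (default [0.5, 2.0]), and once a
   family profile exists its core must align within the candidate above
   the profile cutoff — the stand-in for a conserved-domain comparison.
3. **Coverage screen.** The forward hit must cover ≥ 40% of the query.
   A reciprocal check alone cannot reject chance hits: the same chance
   alignment that produced the forward hit scores symmetrically in
   reverse, so a decoy that sneaks under the E-value cutoff
   "validates" automatically. Genuine homologs align most of the query
   ("similarity throughout the protein length"), chance HSPs do not.

Strategies escalate in order until one accepts: (1) the family's
primary query; (2) a *neighbour query* — the accepted ortholog from the
prior-positive species nearest (patristic distance) to the target; (3)
a PSSM over all recovered members. Species are visited in order of
increasing distance from the query species so the registry grows
outward. A species with no proteome raises a distinct error and is
recorded as `missing`, never silently as absence. Candidates within
10% of any threshold are flagged `review` in the evidence log.

Multiple accepted candidates in one species are all recorded; the count
is the species' paralog number. Every accepted distinct record id
counts as a copy (the package has no isoform concept).

## Matrix and lineage aggregation

Calls assemble losslessly into a families × species grid with per-cell
copy counts. A lineage is `present` for a family when any member
species is `+` (by default also `p`; configurable), `rescued` when all
core species are negative but a wider-sampling recheck of extra species
in the lineage found a positive, and `absent` otherwise. Rescue calls
attach as evidence only and never overwrite core cells.

## Origins, losses and duplications

Origins use Dollo parsimony: one gain, unlimited losses, no lateral
transfer. The gain is the LCA of all presence leaves; the losses are
the maximal presence-free subtrees strictly below it that contain at
least one observed absence. This minimises the loss count among all
single-gain scenarios: moving the gain rootward adds sister subtrees as
losses, and no gain below the LCA covers all presence leaves. `missing`
species are unobserved — they neither block a loss subtree nor create
one, so an all-missing clade never counts as a loss. A root gain is
labelled **Ancient**; otherwise the origin takes the most specific
clade label at or above the gain node (flagged when the gain node
itself is unlabeled). Families with two analogous machineries are run
separately; there is no joint model.

Duplications are placed by standard LCA reconciliation: each gene-tree
node maps to the LCA of its descendants' species; a node whose child
maps to the same species node is a duplication, assigned to the branch
above that node. With no gene loss this recovers simulated duplication
branches exactly; with loss it is a lower bound, as unobservable
duplications (one side extinct) leave no signal.

## The simulator

Families evolve down the species tree under a continuous-time
birth–death process: each extant copy duplicates at rate δ and dies at
rate μ per unit branch length, with exact exponential waiting times
(Gillespie), so per-branch survival `exp(-μt)` and expected copy number
`exp((δ-μ)t)` are available as closed-form test oracles. A loss kills
the whole descendant lineage — gene death, matching the Dollo
assumption downstream. Surviving copies speciate at every species-tree
node.

Sequences evolve under an F81-style amino-acid model: equal
exchangeabilities with Robinson–Robinson stationary frequencies. Its
transition kernel is closed-form — a site retains its state with
probability `exp(-βd)` and otherwise redraws from the stationary
distribution, with β normalised so branch lengths are expected
substitutions per site — which makes the expected p-distance
`(1 - exp(-βd))(1 - Σπ²)` exact. A named empirical rate matrix (LG,
WAG) would add realism the downstream stages never exploit, at the cost
of matrix-exponential oracles; the simulator's job is realistic
divergence, which the model provides.

Background proteomes are i.i.d. draws from the stationary composition
with log-normal lengths (median 220 aa, σ_log 0.3, minimum 30), so any
decoy scoring under the cutoff is by construction a calibration error.
Everything derives from one seed through spawned `SeedSequence`
streams; equal configurations reproduce byte-identical FASTA/TSV.

What the simulator does *not* emulate: indels (homologs differ by
substitutions only, so alignments are gap-poor relative to real
proteins), domain architecture and repeats, composition bias,
rate heterogeneity across sites, isoforms, annotation errors, and
assembly incompleteness. Passing recovery benchmarks therefore shows
the cascade's logic and calibration are sound under honest divergence,
not that the thresholds are optimal for any particular real proteome
set.

## Benchmark and problem sizes

The standard recovery benchmark is a 50-leaf Yule species tree scaled
to 0.6 expected substitutions/site mean root-to-tip, 8 lineage groups,
20 families at δ = μ = 0.2, 500 decoys per species, seed 1. Family
sequences are 200 aa. Acceptance checks: presence/absence precision
≥ 0.95 and recall ≥ 0.90 against ground truth, and ≥ 95% of families'
inferred gain nodes matching Dollo applied to the true pattern. The
strategy-monotonicity property (recall non-decreasing as fallbacks are
enabled) is checked at 16 species × 8 families × 150 decoys, and
byte-level determinism at 10 species × 5 families × 120 decoys — the
same code paths at sizes that keep the whole suite comfortably
re-runnable.

## Numerical and design notes

* Alignment scores are float32 inside the kernels; BLOSUM62 entries and
  gap costs are small integers, so all comparisons in traceback are
  exact (identical expressions recomputed in identical order).
* Hit ordering is fully deterministic: ascending E-value, then
  descending bit score, then lexicographic target id. Equal sequences
  therefore rank by id.
* The reverse-rank window is inclusive at rank 5 ("top five").
* Profiles rebuild only when the member set grows by ≥ 50%
  (center-star construction is quadratic in members); staleness only
  delays, never corrupts, since profiles are a sensitivity aid.
* Degenerate inputs: empty queries return empty hit lists; an empty
  proteome is an error; an all-absent pattern yields "no origin"
  rather than an exception; a trifurcating root is rejected as an
  unrooted tree.
* Known limitations: no translated (six-frame) rescue of unannotated
  loci, no isoform handling, no transfer-aware reconciliation, no
  probabilistic gain/loss model. Loss counts are reported without a
  threshold for doubting an ancient origin; interpretation of heavily
  patchy patterns is left to the user.
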