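# Methods

## The model

PDZ domains recognize the extreme C-terminus of their partner proteins.
The four terminal residues of the ligand (positions −3, −2, −1, 0, with 0
the very C-terminus) each insert into one pocket of the domain, and the
binding contribution of each position is treated as additive — the
standard independence assumption of linear-motif models. The package
turns *binary* domain–peptide interaction data into a *quantitative*
per-domain scoring model in two steps.

**Training: selectivity spaces.** Every curated domain is aligned into a
shared column space (a precomputed alignment, a profile-HMM via pyhmmer,
or — for equal-length inputs — the identity alignment), and the residues
lining each pocket are read off configurable alignment columns (a
`PocketDefinition`; pocket columns depend on the alignment, so the
default shipped with the synthetic generator is emitted alongside the
data rather than hard-coded). Pocket residues are encoded as
concatenated rows of a 20×10 amino-acid property table covering
hydrogen-bond donor count, polarity, volume, bulkiness, hydrophobicity,
isoelectric point, positive and negative formal charge, electron–ion
interaction potential, and free energy in water. The shipped default
table collects widely used published scales (Grantham polarity/volume,
Zimmerman bulkiness/hydrophobicity/pI, Fauchère-style donor and charge
counts, Cosic EIIP, Charton-style solution free energy); it is *a*
defensible instantiation of those ten properties, not a claim about any
particular prior study's exact numbers, and a user-supplied TSV table is
accepted everywhere. Each column is z-scored over the 20-letter alphabet
with the population (n) standard deviation — the alphabet is the entire
population, not a sample — so only the relative ordering of residues
within a property matters downstream.

For each pocket, the binary interaction records define 20 two-class
training sets: pockets of domains with at least one bound peptide
carrying amino acid *a* at that ligand position (positives) versus the
remainder. A Fisher's Linear Discriminant axis is trained per amino acid
using the closed form w ∝ S_W⁻¹(μ₊ − μ₋). Because positive sets can be
small, the within-class scatter is shrunk toward a scaled identity,
S_W + λ(tr S_W/d)I with λ = 10⁻³, before inversion; tests verify the
shrunken solution against an independent generalized-eigenproblem route.
Axes are unit-normalized and assembled into a d×20 projection matrix —
the pocket's *selectivity space*. Amino acids with no positive training
pocket get a zero axis and a flag; a space with more than 10 of 20
untrainable axes is rejected as non-discriminative. The Fisher score
reported per axis is the squared between-class mean separation along the
axis divided by the pooled within-class variance along it.

**Prediction: preference transfer and PWMs.** A query pocket is encoded,
projected, and its k nearest training pockets (Euclidean distance, ties
broken by domain identifier for reproducibility) contribute their
observed amino-acid preference multisets to a pooled profile. The
default k is 40, the setting appropriate to a training corpus of several
hundred pockets; analyses on the 30-domain synthetic world use k = 10 to
keep the same neighbor-to-pool ratio (pooling the entire training set
would erase the locality that the transfer relies on). Pool frequencies
are add-one smoothed over the alphabet and compared to per-position
background frequencies of proteome C-termini (also add-one smoothed):

    PWM(a, i) = log2(f_a,i / p_a,i) + k

The binding score of a peptide is the sum of PWM(S_i, i) over its last
four residues. The additive offset k is calibrated on the experimentally
confirmed training interactions: raw PWMs are built with k = 0, and k is
the smallest value at 10⁻³ resolution such that min(raw score) + 4k > 0,
i.e. every confirmed binder scores positive. The published corpus-scale
value of this constant is 1.921; it depends on the training corpus and
is reproduced here only as provenance. The "others" fallback used when a
loaded table lacks a row (published tables group non-preferred residues
as "others") is the per-position minimum of the table, which for tables
built here coincides with the pseudocount-implied contribution of
unobserved amino acids.

Per-cell versus per-score placement of k is not documented in prior
work; the per-cell additive choice implemented here makes the shift law
exact (adding δ to every cell adds 4δ to every score) and keeps loaded
published tables usable verbatim, since scoring is a pure lookup-sum.

**Evaluation.** Proteome ranking sorts scores descending with
percentile = 100·(1 − rank/N) and identifier tie-breaks. Domain-wise
leave-one-out holds out *all* interaction records of one domain (the
stricter of the two possible hold-out units), rebuilds the four spaces,
predicts the domain's PWM, and records the percentile of each known
ligand; the summary statistic is the fraction of known ligands at or
above the 90th percentile.

## Network analyses

PPI edge lists (already mapped to one identifier namespace by the
caller — the integrator never guesses synonyms) are deduplicated as
unordered pairs, evidence tags unioned, self-loops and edges without
direct experimental support dropped. Edges touching a PDZ protein become
candidate domain-mediated interactions annotated with the partner's
C-terminal tetrapeptide and predicted score. Two conjunctive filters
remove edges better explained otherwise: (1) a catalogued non-PDZ
domain–domain interaction across the pair *and* a PDZ score below
cutoff; (2) a known other peptide-binding-domain motif (SH3, WW, …)
*and* a PDZ score below cutoff, where the cutoff is the lowest score
among experimentally confirmed interactions. Both filters are idempotent
and keep unannotated proteins (with a warning) rather than guessing.

One-mode projections connect PDZ proteins sharing ≥1 ligand (PPN) or
ligands sharing ≥1 PDZ protein (PLN), weighted by shared-partner count
and verified against brute-force pairwise intersection in tests. The
paralog fraction of a side is the paralogous share of its
partner-sharing pairs; the two sides are compared with a Wilcoxon
rank-sum test over per-node paralog fractions (the sampling unit is a
deliberate design choice — the natural alternatives, pairs or nodes, are
not distinguished in prior descriptions; nodes avoid double-counting
pairs that share members). The exact null distribution is used when both
sides have ≤ 20 nodes, the normal approximation otherwise. A robustness
harness deletes a seeded random 20% of nodes or edges and re-runs the
comparison.

## Evolutionary analyses

Ortholog traces record, per species ordered by divergence time from
human, whether an ortholog exists and its C-terminal tetrapeptide ('−'
marks absence). An interaction is called *present* in a species when an
ortholog exists and its motif scores above threshold against the
domain's PWM; 0 is the natural threshold because k-calibration makes all
confirmed binders positive. A *gain* is called at the most distant
species that binds while every more-distant present species does not;
categories combine the origin group of the trace (premetazoan /
invertebrate) with the gain group. Traces that bind already in their
most distant species are "always-binder"; traces that never bind, or
whose binding pattern has no clean off→on transition, are "no-gain".
Rewired interactions per adjacent ladder interval are those absent in
the distal species and present in the proximal one; the rewiring rate
normalizes the count by divergence time and the two ortholog-opportunity
set sizes, rate = n_j / (t · p_all,i · p_pdz,j), implemented behind a
swappable formula hook because the composition of these variables admits
alternatives. Species divergence times are caller-supplied; an 8-rung
yeast-to-mouse ladder ships as the generator default.

## Enrichment

Annotation classes (e.g. 20 physiological disease classes) are tested
one at a time with exact hypergeometric tails over a finite background:
p_over = P(X ≥ k), p_under = P(X ≤ k). No multiple-testing correction is
applied — each class is an independent question — and the report flags
classes below the conventional 0.05 display threshold.

## The synthetic world

The generator emulates every input the pipeline consumes, with ground
truth emitted alongside. Domains fall into latent preference classes;
each class assigns one physicochemical residue group (hydrophobic,
polar, positive, negative, small) to each pocket, samples the pocket's
consensus residues from that group, and draws the class's primary
preferred ligand residues at that position from the *same* group — the
pocket-physicochemistry/preference correlation the selectivity spaces
exploit. Because real binding motifs are degenerate, class preference
sets are topped up round-robin until every ligand position tolerates at
least 11 distinct residues across classes; this breadth also guarantees
that at most a minority of selectivity axes are ever untrainable.

Defaults (the study conditions): 30 domains in 3 classes, 12 binder and
4 non-binder records per domain (about the per-domain density of real
training corpora), 5% label noise on binder residues, a 300-sequence
uniform background proteome plus 4 planted ligand proteins per class
whose C-termini realize the class preferences. Emulated C-termini are
length 10 with only the terminal four positions carrying signal,
matching the scoring window. The bipartite network links each domain's
protein to its class's planted ligands, classes double as paralog
families (so partner-sharing PDZ pairs are paralogous by construction
while ligand-side paralogy is sparse — the planted asymmetry), ortholog
traces plant motif-gain events concentrated at the
invertebrate→vertebrate boundary, and one annotation class is enriched
for network members. One master seed feeds named substreams
(`classes`, `domains`, `binders`, `proteome`, `network`, `orthologs`,
`annotations`) so components can be regenerated independently.

What the generator does *not* emulate — and what passing tests therefore
do not show about real data: realistic phylogenies or substitution
models (gains are planted switches, not evolved), sequence homology
structure within classes beyond pocket columns, assay-specific biases of
the underlying experiments (phage display versus protein arrays),
incomplete and noisy interactome coverage, and identifier-mapping
ambiguity. Corpus-scale figures (the 91% leave-one-out recovery on
hundreds of real ligands, the 1.921 offset, the 54.5%/33.6% paralog
fractions) require the original data and are treated as provenance, not
as reproduction targets.

## Numerical choices and degenerate inputs

Population z-scores at 10⁻⁹ tolerance; scatter shrinkage λ = 10⁻³·tr/d;
identical class means raise a degenerate-discriminant error; k
calibration at 10⁻³ resolution rounds up and bumps one step when the
minimum would land exactly at zero; all ranked outputs break ties by
identifier; add-one pseudocounts on both pool and background keep every
log-odds finite; empty proteomes, empty pools, empty confirmed sets and
all-absent traces are errors rather than silent defaults. Problem sizes
in the test suite and acceptance script (30-domain worlds, 100-replicate
ranking and rewiring runs, 25 random projection graphs, 10⁵ Monte-Carlo
draws) were chosen so the full pipeline re-runs in seconds while keeping
binomial error well below the decision margins.

## Known limitations

Positions are modeled independently (no pairwise coupling between ligand
positions); only C-terminal motifs are scored (internal PDZ-binding
motifs are out of scope); negatives are "everything not positive", so
untested domains are treated as non-preferring; ortholog inference and
identifier mapping are the caller's responsibility; and the default
property table is one reasonable instantiation of the ten indices, not
the only one.
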