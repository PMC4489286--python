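# Methods

This note documents the models and procedures implemented in `bgcmine`,
the defaults they ship with, and what the synthetic benchmarks do and do
not demonstrate.

## Profile-HMM scanning

Proteins are scored against profile HMMs in a Plan-7-style *local,
single-hit* mode. A hit path enters the profile at any match column
(uniform entry probability 1/L over the L columns), walks
match/insert/delete states with the profile's per-column transitions, and
exits from any match column (uniform 1/L). The bit score is the log2-odds
of the emitted subsequence under the hit path(s) versus the null model;
flanking residues are null-emitted under both hypotheses and cancel, which
makes the score exactly invariant under null flanks (a property test).
`viterbi` takes the best path, `forward` the log-sum over all single-hit
paths, so forward ≥ viterbi by construction. Residues outside the
20-letter alphabet are emitted by the null in every state (zero bits).
All dynamic programming is in log2 space; no probability-space underflow
handling is needed.

Multiple hits per protein are found greedily: the best Viterbi hit is
reported, its envelope excised, and the flanks re-scanned until nothing
reaches the reporting floor (0 bits). In `forward` mode the envelopes and
alignment maps still come from the Viterbi traceback; only the score is
recomputed. Hit filtering applies the per-profile gathering cutoff
(default 20 bits when a file carries none) and, among same-gene
same-profile hits overlapping by more than 50% of the shorter envelope,
keeps the best score (ties to the smaller start). The 50% policy is a
conventional choice and is configurable.

Profile files use a documented HMMER3-flavoured text subset (negative
natural-log probabilities, `*` for probability zero). A second writer
emits full HMMER3/f layout accepted by `hmmsearch`; the external-scanner
adapter runs that binary and parses its domain table. The table carries no
per-column alignment, so the adapter builds a linear consensus→residue
pairing over the aligned span — adequate for window arithmetic, not for
active-site extraction. E-values from these files are placeholders; the
internal scorer works on bit cutoffs only.

## Rule-based detection

A rule is `TYPE / CUTOFF (kb) / EXTENSION (kb) / CONDITION`, the condition
a boolean expression over profile names with `and`, `or`, `not`,
`minimum(n,[...])` and parentheses (precedence NOT > AND > OR). Genes
hitting any mentioned profile are grouped greedily left-to-right while the
gap between consecutive contributing genes (end of previous to start of
next — gene-boundary distance, robust to gene length) stays within the
cutoff. A group becomes a candidate iff the condition holds over *all*
profiles hit by its member genes; `not` is therefore a statement about the
local group, not the whole record. The core is the span of the member
genes; the cluster span adds the extension, clipped to the record.
Overlapping candidate spans merge: union span, types deduplicated in core
order and joined with `-` (hybrids), numbering reassigned left to right.
The engine is checked against an exhaustive all-maximal-intervals
evaluator on randomized layouts, and merging is idempotent and
permutation-invariant.

The shipped rule file covers a representative set of classes (t1pks,
transatpks, t2pks, t3pks, nrps, terpene, lantipeptide, bacteriocin,
siderophore, ectoine, arylpolyene, resorcinol, ladderane, PUFA) with a
20 kb cutoff and 5–20 kb extensions; it is data, and users supply their
own file for other class inventories.

## Probabilistic detection

The two-state HMM (cluster / background) runs over the record's domain
tokens: filtered hits sorted by gene start then envelope start, names
outside the model vocabulary mapped to `UNKNOWN` (present in both states
by construction). Posteriors come from forward–backward with per-position
scaling; a log-space reference implementation exists in the test suite and
an independent categorical-HMM library is used as a cross-check oracle.
Posteriors are smoothed with a centred moving average (window 5,
truncated at the edges; window 1 is the identity), and maximal runs with
smoothed P ≥ 0.6 spanning ≥ 5 tokens and ≥ 5 distinct genes become
regions. These four knobs are deliberately configuration, not constants —
they tune sensitivity versus specificity and are exposed on the CLI.
Regions are typed by marker-domain counts (saccharide markers take
precedence over fatty-acid markers; threshold 2 of either, all
configurable). Regions overlapping a rule-based cluster by ≥ 1 bp attach
their probability to it; the rest become standalone predictions.

The shipped model over the toy vocabulary is an illustrative payload;
training is out of scope, and a loader accepts user-trained models in the
documented JSON format.

## Dereplication

Queries are aligned to reference proteins with Biopython's
`PairwiseAligner` (local, BLOSUM62, gap open −11 / extend −1). Identity is
identical pairs over aligned columns; coverage is aligned columns over the
*shorter* sequence (symmetric). Hits need identity ≥ 30% and coverage
≥ 25% (inclusive; inherited thresholds, configurable), then the best
subject gene per (query gene, reference) is kept. Scores:

* `hit_gene_count` — distinct query genes with a kept hit;
* `synteny_score` — adjacent query pairs (i, i+1) whose subject genes are
  consecutive *in the same order* (j, j+1) in the reference with a
  consistent relative orientation (strand-product equality). The
  order-preserving definition is deliberate: a reference holding the same
  genes in order 1,3,2 conserves no adjacency;
* `core_bonus` — 3 if any hit query gene carries a core biosynthetic
  domain (ketosynthase, condensation, adenylation profiles by default).

Ranking is by total score, then percent of query genes hit, then
reference id; the query's own gene set inserted as a reference is maximal
by construction (a test). One engine serves known-cluster, genomic and
sub-cluster bundles, which differ only in payload and labels; known
references get repository hyperlinks.

## Active sites and key residues

Motifs anchor to profile *consensus columns*, not to a reference
sequence, so indels cannot shift them: the residue at each column is read
through the hit's alignment map (`-` for deleted columns). A motif is
either a full-string pattern (presence/absence of a catalytic residue) or
an ordered (pattern, label) outcome list with first-match-wins semantics
for multi-class calls (ketoreductase B-type/D- vs A-type/L-
stereochemistry from the LDD region, enoylreductase 2S/2R from its
tyrosine, carrier-protein β-branching from a tryptophan). Motifs marked
`required` flag their domain *scaffold-inactive* when the pattern fails;
structure prediction treats such domains as absent. The bundled motif XML
is editable data validated against a shipped schema; the residue choices
echo common literature assignments and are not hard-coded truths.

## NRPS/PKS structure

Domains are walked gene by gene in cluster order. Each KS (PKS) or C
(NRPS) opens an extension module; a leading AT/CAL (± carrier) or A
(± carrier) before the first KS/C is the loading module; TE/TD marks the
carrying module terminal (a boolean on the module — the spec-level
"termination" case folds into the closing extension module, as in the
two-module walkthrough test). Epimerization, methyltransferase,
branching, crotonase and pyran-synthase domains are recognized and
annotated but leave the scaffold untouched.

Monomers: the adenylation pocket code (8 residues at configured consensus
columns) is looked up in an editable table — exact string match, else
best row at ≥ 6/8 agreement (partial), else unknown. Acyltransferases
call malonyl vs methylmalonyl by motif, defaulting to malonyl (partial)
when nothing matches. In clusters typed `transatpks`, AT-less extension
modules are marked trans-AT and default to malonyl.

The scaffold assumes strict co-linearity (always stated in the output
assumptions). Each PKS extension contributes two backbone carbons; the
β-carbon inherited from the previous module is rendered per this module's
reduction state (keto C=O, hydroxyl C–OH, enoyl C=C, methylene CH2);
methylmalonyl adds an α-methyl. NRPS units join by amide bonds using
per-monomer side-chain fragments; unknown monomers become a generic
α-carbon wildcard so partial predictions still parse. The chain releases
as the free acid and is canonicalized with RDKit. An inactive KR
downgrades the whole module to keto even when DH/ER are present —
dehydration without a hydroxyl substrate is chemically moot — and this
assumption is flagged in the output. Stereochemistry labels are
annotations only and are never encoded as SMILES chirality: the claim is
a core scaffold, not a configured structure. Cyclization, tailoring and
type II/III PKS products are out of scope.

## Lanthipeptides

Candidate precursors are short ORFs (≤ 120 aa) in a lanthipeptide cluster
containing Ser/Thr and Cys. The leader/core split scans a prioritized,
editable cleavage-motif list (double-Gly first); cleavage falls
immediately after the first match of the highest-priority motif within
the N-terminal two thirds, with a halving fallback flagged `fallback`.
All core Ser/Thr are assumed dehydrated — an upper bound, since the rules
governing which residues escape are not settled; a flag exempts the
N-terminal residue. Bridges are min(#Cys, dehydrations). The finished
monoisotopic mass is the residue-table sum plus one water minus 18.010565
Da per dehydration (average masses behind a flag); the table is the
standard 6-decimal monoisotopic residue table, and the suite cross-checks
it against an independent mass-spectrometry library. Class assignment
(LanB+LanC → I, LanM → II) is metadata only.

## Synthetic data and what the tests show

The generator emits codon-encoded genes (fixed codon per amino acid, so
output is a pure function of the seed): background genes are random
50–90-mers, planted genes embed toy-profile consensus peptides with
optional per-column overrides (specificity codes, stereochemistry
residues, broken active sites), on random strands with Poisson intergenic
spacers (mean 150 bp). The toy profiles have strong consensus columns
(0.9 emission) and flat "variable" columns where product-determining
residues are read; variable columns are flanked by strong anchors so
local alignment never trims them. Planted genes score ≥ 20 bits above
cutoff; random background stays near 0 bits, so detection operates in a
deliberately high-signal regime. Consequently the end-to-end benchmarks
(20 genomes, 100% planted recovery, zero false calls) demonstrate the
correctness of the plumbing — coordinates, grouping, typing, merging,
reporting — **not** sensitivity on real genomes with marginal homology,
fragmented assemblies, or profile cross-talk. The algorithmic cores are
instead validated against exhaustive oracles (path enumeration for both
HMM layers, all-intervals search for the rule engine, a naive
re-implementation for comparison scoring) at 1e-9 tolerances.

## Numerical and determinism notes

The analysis path contains no sampling; the seed governs only fixture
generation, so identical inputs give byte-identical outputs (GenBank
dates are pinned for this reason). Distributions are validated to sum to
1 within 1e-9 and renormalized after text round-trips (serialization at
5 decimals keeps emissions within 1e-6). Ties break deterministically
everywhere: earlier envelope, lexicographically smaller name or id,
smaller coordinate. Problem sizes in the shipped benchmarks (records of
6–10 genes, 20-genome recovery runs, 200 random architectures, 10k-token
parameter-recovery simulations) were chosen to exercise every code path
while keeping the default suite quick to run.

## Known limitations

Circular records are read but cluster detection does not wrap the origin.
Gene calling is not performed (CDS features or protein FASTA are
required; table 11 translation with per-CDS override). The bundled
profiles, rules, motifs, code tables and reference bundles are toy or
illustrative payloads — the engines are the contribution, the payloads
are replaceable data. E-value statistics, fungal-specific handling,
cyclization/tailoring chemistry and bridge-topology prediction are out of
scope.
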