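# Methods

This note documents the models and procedures implemented in `motiftrace`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where the design was genuinely open.

## Species trees

A `Phylogeny` is rooted, strictly bifurcating (polytomies are rejected
with an explicit message), with named internal nodes and branch lengths
≥ 0. Branch lengths are treated as abstract evolutionary time: the
character model's gain/loss rates are per unit branch length, and the
sequence simulator's substitution rates are scaled independently —
nothing couples the two. Trees are not assumed ultrametric on input;
simulated pure-birth trees happen to be.

The simulator samples Yule trees: starting from the root split (two
lineages), the waiting time to the next split while k lineages exist is
Exponential(k·λ); after the n-th lineage appears one final
Exponential(n·λ) interval is appended. The expected root-to-tip height is
therefore Σ_{k=2}^{n} 1/(kλ), which the tests verify by Monte Carlo.

## Two-state character model and ancestral reconstruction

Motif presence evolves on the tree as a continuous-time Markov chain on
{0 = absent, 1 = present} with unequal rates: gain a (0→1) and loss b
(1→0), both per unit branch length. The transition matrix is the closed
form P01(t) = a/(a+b)·(1−e^{−(a+b)t}) (and symmetrically); a = b = 0 or
t = 0 gives the identity, so zero-length edges are legal.

*Likelihood.* Felsenstein pruning with per-node rescaling; verified
against exhaustive enumeration over all 2^(n−1) internal-state
assignments on trees of up to 6 leaves (agreement ≈ 1e−15) and against
the two-leaf closed form 0.5·(0.375² + 0.625²) = 0.265625. Impossible
configurations (mixed leaf states with a = b = 0) return −inf rather
than raising.

*Root prior.* Stationary (b/(a+b), a/(a+b)) by default; a flat 50/50
prior is available. The choice is exposed because the reference tooling
for this analysis does not document its prior.

*Rate fitting.* Maximum likelihood over (log a, log b), bounds
[1e−8, 1e3], from the best of a 5×5 log-spaced start grid
(1e−4 … 20) followed by L-BFGS-B. With a matrix of characters the rates
are shared and the summed log likelihood is optimised (used for
simulation calibration); per-motif fits are independent. When every leaf
shares one state the MLE is a boundary (the rate toward the absent state
collapses); this is flagged, not raised. Parameter recovery measured at
the reference conditions (64-taxon Yule tree, 300 characters,
a = 0.5, b = 0.2) is within ±25% for both rates, and the error shrinks
with character count.

*Marginals.* Exact per-node posteriors from a post-order (pruning) plus
pre-order (outside) sweep, verified against a clamping oracle (likelihood
with the target node fixed to each state) to 1e−10.

*Gain calls.* Nodes are hard-called present (P1 ≥ τ), absent
(P1 ≤ 1−τ) or uncertain, with τ = 0.92 by default. A **gain** is a
confidently present node whose parent is *below* τ; a present root counts
as a gain (acquisition at or before the root). A **loss** is a
confidently absent node with a confidently present parent. The
acquisition call is *once* for exactly one gain, *multiple* for two or
more, *none* when nothing is confidently present. The reported "scaled
likelihood of gain" is the marginal P1 at the gain node — for a
transition, the parent's marginal necessarily sits in mid-range (the
event falls somewhere on the connecting branch), so requiring the parent
to be *confidently absent* would suppress most true gains; the first
confident carrier is the natural event anchor, and simulation shows it
recovers the true gain node in ≈95% of single-gain characters at τ = 0.92.

## Orthology

Pairwise protein scores are exact Smith–Waterman local alignments with
BLOSUM62 and affine gaps; a gap of length k costs open + k·extend with
open = 11, extend = 1 (BLAST's defaults). Raw scores are used throughout
because the classification rules only compare scores. The local score is
floored at 0 (the empty alignment). Non-canonical residues score via the
matrix's X column. Scores are computed once per unordered pair
(symmetry).

Best hits are per (query, subject genome), ties broken lexicographically
by subject id — a deterministic rule where the underlying convention is
silent. Reciprocal best hits are orthologs; they are one-to-one unless a
within-genome paralog of either member scores strictly higher than the
pair (self-hits excluded). A score floor (default 0, i.e. keep all) is
exposed to mimic E-value cutoffs. The classification is verified against
a brute-force transcription of the rules on random score tables, and on
simulated proteomes without paralogs the recovered one-to-one pairs equal
the simulated ortholog map exactly.

## Markov clustering

The one-to-one graph is clustered with MCL: self-loops of weight 1 are
added (standard practice; prevents bipartite oscillation), the matrix is
column-normalised, and expansion (matrix power, default 2) alternates
with inflation (entrywise power, default 2.0, then renormalisation) and
pruning of entries below 1e−8 until the flow stabilises (tolerance 1e−8,
at most 200 iterations; non-convergence returns the current clustering
with a flag). Clusters come from the attractor structure: attractors are
nodes with positive return flow; each node joins the attractor receiving
its largest flow, and overlapping attractor systems merge via connected
components, so the result is a strict partition. Column stochasticity is
asserted to 1e−9 after every step. Planted-partition graphs
(4 blocks × 20 nodes, p_in = 0.9, p_out = 0.02) are recovered with
adjusted Rand index 1.0; disconnected components can never merge because
expansion cannot create flow between components.

The pipeline picks the focal family as the cluster covering the most
genomes, breaking ties by median protein length (ubiquitous housekeeping
families tie on coverage; the core + disordered-region family is the
longest), unless a member is named in the configuration.

## Disordered-region features

*Composition bias.* For each residue type and each window of length 5 to
500, the exact binomial tail P(X ≥ k) with n = window length and p = the
background frequency; windows at or below the threshold (default 1e−15)
are reported, overlapping same-residue windows resolved to the
lowest-probability one. A per-length count bound (binomial inverse
survival function) prunes the O(n·L) enumeration without changing the
result. Backgrounds default to the input set's global frequencies.
Signatures are single residues; joint signatures (RNQ-, AEPV-rich) arise
by merging overlapping segments downstream, which keeps the null model
exact. Multi-profile grouping of segments uses k-means on frequency
vectors with a fixed seed.

*Tandem repeats.* A region is a repeat of period p when seq[i] = seq[i+p]
across ≥ min_identity of its columns and it spans ≥ min_copies·p
residues; overlapping calls resolve to the most matching columns.
Defaults — period 3–10, ≥ 3 copies, identity ≥ 0.9 — were set by null
calibration: zero false calls in 100 i.i.d. 300-mers from each of the
globular, RNQ-rich and AEPV-rich backgrounds. Fractional copy numbers
are reported; the consensus unit is the per-column majority.

*Hydrophobic moment.* μ_H = |Σ_n H(r_n)·e^{i·n·δ}|/L with the Eisenberg
consensus scale and δ = 100° for α-helices; exact closed forms
(homopolymers, alternating sequences) validate it to 1e−12.

*Disorder heuristic.* index = 2.785·⟨H_norm⟩ − |⟨q⟩| − 1.151 over a
centred odd window (default 21), H_norm = (Kyte–Doolittle + 4.5)/9, q the
net charge; negative means predicted disordered. This is a simple
charge–hydropathy rule, labelled `disorder_heuristic` in every output; it
is not a trained disorder predictor and its calls should not be compared
with one.

## ZOOPS motif discovery

Generative model per sequence: with probability γ one motif instance is
emitted column-wise from the PWM at a uniformly chosen position; all
other residues are i.i.d. background. EM alternates the posterior over
{no site, site at j} with PWM/γ updates; the M-step adds a pseudocount
of 0.01 per residue per column (Dirichlet MAP), and the monotone quantity
asserted each iteration is the correspondingly penalised objective
(data log-likelihood ratio + Dirichlet log prior). Convergence at
relative change < 1e−6 or 200 iterations.

*Seeding.* Up to 60 subsequence seeds per width, evenly spaced over all
valid windows; each seeds a PWM with weight 0.8 on its own letters and is
scored by two preliminary EM sweeps before the best seed receives the
full EM. The high self-weight matters: softer seeds let EM reach a
merged optimum in which one PWM absorbs two dissimilar motifs as bimodal
columns — profitable under the raw ZOOPS likelihood whenever the
background is depleted in the motifs' letters — which destroys the
clade-specific presence signal the downstream reconstruction needs.

*Width selection.* Coarse widths (10, 13, 16, 19, 22, 25) followed by a
±1 hill climb that reuses the current best PWM (trimmed or padded by one
column) as an extra seed. Widths are compared by a BIC-penalised
log-likelihood ratio, LLR − ½·19·w·ln(expected sites): the raw LLR is
monotonically biased toward wide motifs because every extra column
overfits the site sample by ≈ (20−1)/2 nats, so unpenalised selection
returns the widest window containing the signal rather than the motif.

*Erasure and ranking.* After each motif, every non-overlapping window
scoring ≥ 60% of the maximum attainable log-odds is masked (erasing one
site per sequence lets repeat-derived low-complexity motifs be
rediscovered indefinitely); masked positions are excluded from later
counting, preserving coordinates. Discovery stops at 30 motifs, or when
the ranking score — information content (bits, relative entropy vs
background) × expected site count — falls below a floor (default 50), or
when fewer than 2 sites are expected. Motifs are ranked by that score.

*Annotation.* Log-odds scanning in bits; at most the single best window
per sequence, reported when it reaches min_bits (default 60% of the
motif's maximum score; ties go to the leftmost window). The presence
matrix keeps one strain per species (lexicographically first genome id).

## Synthetic evolution

The generator emulates the analysed family's architecture: a globular
core (default 529 residues, average bacterial composition) followed by a
disordered region (length ~ Normal(530, 80²), floor 60) built from
composition profiles — an RNQ-rich block (R 0.214, N 0.101, Q 0.091) then
an AEPV-rich block (A 0.208, E 0.138, P 0.106, V 0.127), with the
order-promoting residues W, F, Y, C, L, M, H down-weighted fivefold in
the remainder — plus REE×4 and AEVP×4 repeat tracks.

Substitution is per-site: on a branch of length t each site is resampled
from its block's profile with probability 1 − e^{−rt} (exactly the
multi-hit process, since every hit is an i.i.d. profile draw). The core
substitutes slowly (default 0.05/residue/unit); the disordered background
fast (default 1.0), so it saturates at tree scale and only the planted
motifs and the repeat tracks (held at the slow rate, emulating their
continual regeneration) stay conserved — the premise of the whole
analysis. Optional single-residue indels (default rate 0) are restricted
to the disordered region and shift all recorded truth coordinates.

Motif presence characters are simulated by exact Gillespie walks along
each branch (waiting time Exp(a) in state 0, Exp(b) in state 1; default
a = 0.3, b = 0.1, root absent); every flip is recorded. Where a leaf's
state is 1, one instance sampled from the motif's PWM (consensus weight
1 − noise, default noise 0.05) *replaces* the background residues at its
anchor, keeping region length independent of the character. Decoy
families (3 × 300 residues, slow-evolving) exercise the orthology and
clustering stages; paralogs are off by default, mirroring the near
absence of paralogy in the family analysed. Everything derives from one
seed and regenerates byte-identically.

`clade_gain_scenario` builds the reference end-to-end dataset: it samples
Yule trees (advancing deterministically from the given seed) until one
offers disjoint clades of ≥ 4 leaves with stem branches ≥ 0.4 that are
not root children, then plants one motif per clade. The stem-length
requirement is not cosmetic: a gain cannot localise onto a near-zero-length
stem (the likelihood happily moves it one node up and pays for a loss
elsewhere), and clades hanging directly off the root leave the root state
genuinely ambiguous — both situations yield honest "uncertain" outcomes
rather than recovery failures.

## What the tests do and do not show

The simulator reproduces the statistical structure the method assumes —
composition bias, fast ID background, conserved planted motifs, two-state
character evolution — but not everything real proteomes have: no
nucleotide-level evolution, no realistic indel length spectrum, no
among-site rate heterogeneity, no motif turnover in place (a motif is
either planted at its anchor or absent), no annotation noise, and decoys
are far fewer than a real proteome's thousands of proteins. Passing
tests therefore demonstrate correctness of the inference machinery and
its behaviour under the assumed model, not performance on real genome
databases. On real data the weakest links are the same ones visible in
the synthetic runs: low-complexity regions yield repeat-derived motifs
that are "acquired at the root", and closely related species contribute
weak clade-restricted background motifs.

## Problem sizes

Defaults in the tests and acceptance script: 16-taxon end-to-end runs
(proteomes of 4 proteins each), 32–64-taxon trees for character-level
recovery (200–300 characters), 60 × 300-residue sequence sets for motif
discovery, 200 random trees of ≤ 6 leaves for the likelihood oracles, and
1000 random score tables for the orthology rules. These sizes make every
ground-truth comparison exact or tightly bounded while keeping a full run
in minutes on one CPU.
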