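# Methods

`ugtsel` predicts the acceptor regioselectivity class of flavonoid
UDP-glycosyltransferases (UGTs) — e.g. whether an enzyme glucosylates the
3-O or the 7-O hydroxyl of a flavonoid — from primary sequence, using the
seven acceptor-pocket loop regions as the informative subsequences. This
note records the model, its assumptions, the parameters that matter, and
the places where a genuinely open design choice was settled.

## Residue model: side-chain graphs and seven indices

Each residue type is a rooted, labeled graph: the α-carbon is the root,
all side-chain atoms (hydrogens included) are nodes, covalent bonds are
edges weighted by idealized bond length in Å. The α-hydrogen is treated as
backbone and excluded; glycine's "side chain" is therefore a single
hydrogen, which makes most of its indices zero or minimal. Proline keeps
its second bond to the backbone nitrogen, so its graph is cyclic through
the root — the only cyclic case besides aromatic rings.

Seven indices are computed per residue:

| index | definition | units |
|---|---|---|
| reach | root eccentricity under bond-length weights | Å |
| branching_density | mean degree over nodes of degree ≥ 2 (0 if none) | – |
| forking_index | Σ over unit-hop distances d ≥ 1 of (internal nodes at d)/d, root excluded | – |
| net_partial_charge | Σ atomic partial charges | e |
| average_polarity | mean over bonds of \|Δq\| × length (unsigned bond dipole) | e·Å |
| hb_acceptor_index | Σ qualifying lone pairs × electronegativity × 1/(1+hops) | – |
| hb_donor_index | Σ donor H × heavy-atom electronegativity × 1/(1+hops to heavy atom) | – |

The hydrogen-bond distance weighting 1/(1+d) is a bounded decreasing
function of unit-hop distance from the root; it is a configurable hook
(`distance_weight=`) because nothing forces this particular form.
`average_polarity` uses the unsigned dipole: a signed mean would cancel
arbitrarily with bond orientation.

**Chemistry provenance.** The packaged tables
(`data/chemistry_atoms.tsv`, `data/chemistry_bonds.tsv`) are generated by
`scripts/make_chemistry.py`: Gasteiger–Marsili partial charges computed
with rdkit on the free amino acids in their standard pH-7 protonation
states (Lys⁺, Arg⁺, Asp⁻, Glu⁻, histidine as the neutral ε-tautomer),
Pauling electronegativities, and idealized covalent bond lengths from a
small lookup (C–C 1.54 Å, aromatic C–C 1.40 Å, carboxylate C–O 1.25 Å, …).
Lone pairs counted for hydrogen bonding: 2 per side-chain oxygen, 1 for
the pyridine-type His ND1, 2 for the Met thioether sulfur; the Cys S–H is
counted as a (weak) donor but not as an acceptor. Because the tables are
plain TSV package data, a different force field or protonation convention
can be swapped in without code changes — every index is recomputed from
the file.

A consequence worth knowing: with neutral His, the PCA component that
carries charge ranks R and K far above everything else, but His sits
mid-pack (7th). Analyses that expect H/K/R to cluster as "the positives"
presuppose a chemistry in which His is protonated.

## PCA refinement

The seven raw indices covary strongly (the size-like measures especially),
so the working residue encoding is correlation PCA: z-score each column
over the 20 residues (sd with ddof=1), eigendecompose the 7×7 correlation
matrix, and project. Eigenvalues sum to 7; components are ordered by
decreasing explained variance with a deterministic sign convention (the
largest-magnitude loading of each component is positive), so encodings are
bit-reproducible across runs and serializable (`PCAModel.save/load`).
Correlation rather than covariance PCA is a choice forced by units: Å,
elementary charge and dimensionless tallies are incommensurate. All 7
components are retained; the loop–index search restricts itself to
PC1–PC5 by default.

## Loop encoding and covering windows

Records carry seven loop intervals (labels a–g, 1-based inclusive,
ordered, non-overlapping). Two encodings:

* **Per-loop series** — each loop becomes a (length × 7) matrix of PC
  scores, one 1-D series per index. Positions named in a per-record
  exclusion list are dropped first; this is how the conserved first-loop
  histidine, identical in every sequence and hence uninformative, is
  removed — as data, not as a hard-coded rule. Ambiguity codes (X/B/Z…)
  encode as zero rows with a warning.
* **Flat vectors** — per loop, a *covering window* of one shared length
  (max loop length + 2×margin, default margin 2) is positioned on every
  record so that it contains that record's loop; window offsets are chosen
  by coordinate ascent on the gapless sum-of-pairs BLOSUM62 score (sweeps
  in record-ID order, ties to the smallest start, max 50 sweeps — a small
  exhaustive-search test pins the optimum). Windows that would overrun a
  sequence end are shifted inward when possible, otherwise padded with a
  neutral token encoding to zeros. Concatenating windows loop a→g,
  position left→right, index PC1→PC7 gives identical-length vectors; at a
  total window length of 86 positions this is the 86 × 7 = 602-input
  representation the network topology below assumes. (The one published
  worked example of a covering window — loop b of the grape enzyme VvGT,
  annotated S-44..S-56, covered by S-41..Q-61 — needs the real VvGT
  sequence and is therefore documented here rather than unit-tested.)

## Elastic distances

Three series distances, all with L1 local cost, numba-compiled:

* **DTW** — unconstrained dynamic time warping, symmetric step pattern
  (↑, →, ↗). With this step pattern DTW is symmetric in its arguments.
* **LCSS** — distance 1 − L/max(|x|,|y|), where L is the longest common
  subsequence under value tolerance ε and positional window δ. Default ε
  is half the pooled per-column sd of the score table; δ defaults to
  unconstrained.
* **MVM** — minimal-variance matching: cheapest monotone injective
  embedding of the shorter series into the longer. Order-asymmetry is
  resolved by always embedding the shorter series; equal lengths reduce to
  a plain L1 sum, so distance matrices are symmetric.

A protein-level distance is the sum of series distances over a chosen
loop subset × index subset. Restriction is exactly additive, which the
combinatorial search exploits: all 7 × 7 per-series pairwise distances are
cached once (`series_distance_cache`) and every combination is a sum over
that cache. No lower-bounding or windowing accelerations are used — loop
series are at most ~24 points long.

All three metrics are verified against explicit enumeration oracles
(warping paths, common-subsequence matchings, monotone embeddings) —
exhaustively over every series pair of lengths ≤ 6 on the {0,1,2} grid in
the acceptance suite, and property-based elsewhere.

## Classifiers

* **kNN** on a precomputed distance matrix; the query is never its own
  neighbor, distance ties break to the smallest record ID, and odd k with
  binary labels excludes vote ties, so results are fully deterministic.
* **Dissimilarity-space SVM** — a record's feature vector is its distances
  to the training records (the training set is the reference panel, so
  held-out records never appear as reference points), RBF kernel, C = 1,
  bandwidth γ = 1/(2·median²) of pairwise training feature distances
  (sklearn `SVC`). The reference-point kernel identity
  k_O(x,y) = ½(−d²(x,y)+d²(x,x_O)+d²(y,x_O)) is shipped only as a
  documented utility with a PSD check: DTW is non-metric, so that route
  cannot guarantee a valid kernel, which is why the feature-vector route
  is the default.
* **Crossvalidation** — leave-one-out, and leave-six-out with a seeded
  random partition (folds of 6, last fold smaller). Performance is
  reported as a *loss pattern* — the identity set of misclassified
  records, false positives starred — because with ~23 records the
  informative comparison is *which* records a method misses, not a rate.

`rank_distance_functions` evaluates the {DTW, LCSS, MVM} × {1,3,5-NN} ×
plan grid on the full loop/index sum, errors ascending, metric name as
tie-break.

## Bayesian neural network

One hidden layer, tanh units, logistic output for the binary class; the
working topology is 602–301–1 (181,805 parameters counting hidden and
output biases), but everything is size-agnostic and the tests run small
nets. Parameters are grouped four ways — input-to-hidden weights, hidden
biases, hidden-to-output weights, output bias — with zero-mean Gaussian
priors sharing one precision τ per group (σ = τ^(−1/2)). Trainable groups
put a Gamma hyperprior on τ, parameterized by shape control α and scale
control w:

P(τ) = (α/2w)^{α/2}/Γ(α/2) · τ^{α/2−1} e^{−τα/2w}

i.e. shape α/2 and rate α/(2w), mean w, variance 2w²/α — smaller α means a
vaguer hyperprior. Gaussian/Gamma conjugacy makes the precision update an
exact Gibbs draw: Gamma(α/2 + k/2, α/(2w) + ½Σwᵢ²). The output bias keeps
a fixed precision (σ = 1). Defaults α = 1, w = 1 per trainable group.

Training alternates (a) Hamiltonian weight updates — leapfrog trajectories
(default 20 steps of 0.05) with a Metropolis accept/reject; divergent
trajectories halve the step size with a warning — and (b) Gibbs precision
draws, in two phases: a short phase at fixed precisions to approach
equilibrium (default 100 iterations), then 1000 alternating iterations
keeping every 5th state after the first half. Weights start at zero
(momentum randomization breaks the symmetry). Prediction averages the
per-sample output probabilities and thresholds at 0.5. Diagnostics report
the acceptance rate, training mean squared error, and the ranges of
weights and group precisions across kept samples — the quantities one
watches to judge equilibration. With no data and fixed precisions the
sampler reproduces the prior Gaussians (KS-tested), and the gradient is
finite-difference-checked.

## Loop × index search and mode analysis

All (2⁷−1)(2⁵−1) = 3937 non-empty loop-subset × index-subset combinations
(indices PC1–PC5) are evaluated with leave-one-out 3NN. Note the count:
127 loop subsets × 31 index subsets. Aggregations:

* per-record miss frequencies (with the exact double-counting identity
  Σ_records counts = Σ_combos |loss|),
* the frequency spectrum of distinct loss patterns (frequency desc, size
  asc, lexicographic), and
* **mode analysis**: per loop subset, the modal loss pattern over its 31
  index choices. A loop subset *qualifies* when the modal loss has fewer
  than `max_loss` = 4 errors and the mode occurs in at least
  `min_frequency` = 10 of the 31 index subsets — a pronounced small mode,
  the signature of a loop subset that carries class signal robustly across
  index choices rather than by crossvalidation accident. Both thresholds
  are parameters; on synthetic data they should be scaled with the record
  count if it departs from 23.

## Alignment baseline

The comparison point is a distance from standard global pairwise alignment
scores: BLOSUM62, affine gaps (open 10, extend 0.5, Biopython
`PairwiseAligner`), distance = 1/score. Scopes: full sequence,
concatenated loops, or per-loop sum of reciprocal scores (the last is
loop-combination-specific and hence directly comparable with restricted
elastic classifiers). A progressive multiple-alignment pipeline is
deliberately not reimplemented; the baseline's role is comparative and the
scorer is disclosed in output metadata. Non-positive scores — common
between non-homologous random sequences — map to a sentinel distance of
10⁶ with a warning.

## Synthetic data: what it emulates, what it does not

`simulate` reproduces the study's *shape*: 23 records, lengths 446–511,
seven ordered loops with per-loop length ranges 3–6, 2–18, 7–24, 2–3, 1–4,
2–9, 2–9, and 10 positives. Class signal lives only in chosen loops
(default b and e): positive-class loop residues are rejection-sampled
against the shipped score table until their mean z-score over the signal
indices (default PC1–PC2) clears the effect size (default 1.0 pooled-sd
units), so the signal travels the full residue-graph → PCA → encoding
path. A per-residue substitution noise (default 0.05) is applied
afterwards. `simulate_warped` instead plants fixed per-class residue
templates in the signal loops and corrupts each record's copy with random
duplication/deletion indels to a random admissible length (plus extra
balanced indels at rate 0.4 and substitutions) — within-class variation
that is mostly temporal, the regime elastic distances exist for. The
ranking experiment uses it with signal in loops b, c, f (the loops with
wide length ranges, where warping can express itself) and noise 0.1.

What the generators do **not** emulate: real UGT residue composition, the
conserved PSPG motif, homology between records, or correlated loop
evolution. Background residues are uniform i.i.d., so full-length
alignment scores between records are frequently non-positive — a regime
real homologous UGTs are not in. Passing the planted-signal tests
therefore shows that the pipeline recovers loop-confined signal it was
pointed at under study-like geometry; it does not certify performance on
real, homologous, phylogenetically structured sequences.

## Numerical and degenerate-input choices

* `branching_density` of a graph with no internal node is 0.
* Zero-bond graphs have `average_polarity` 0.
* Zero-variance index columns reject PCA with a message.
* LCSS requires ε > 0; an unset ε with no per-index defaults is an error.
* MVM with the longer series first is an error at the operation level;
  the symmetrized wrapper orders by length.
* kNN requires odd k ≤ n−1; distance ties break to smallest record ID.
* Single-class SVM training sets are rejected.
* Empty posterior sample lists are rejected at prediction.
* A zero-iteration MCMC schedule returns exactly the initial state.
* Windows that cannot fit in-bounds pad with a neutral zero-scoring token.

## Problem sizes used in tests and the acceptance script

The shipped tests and `scripts/acceptance.py` run the study-scale search
(23 records, 3937 combinations) across 20 simulation seeds, the exhaustive
elastic-distance verification on the full {0,1,2} grid at lengths ≤ 6, and
BNN behavior on small topologies (2–3–1) where posterior behavior is
checkable; the 602–301–1 topology is exercised for its parameter-count
contract rather than trained, since nothing about the sampler changes with
size and a full-size chain adds hours without adding information.

## Known limitations

* The loop-interval annotations are inputs; no secondary-structure
  prediction is included, so the pipeline is only as good as its loop
  definitions.
* Gasteiger charges on free amino acids are a pragmatic stand-in for
  in-protein charge distributions; indices inherit their biases (see the
  His note above).
* The covering-window alignment is a greedy coordinate ascent; optimality
  is verified only on small exhaustive cases.
* The real 23-enzyme error sets are not reproducible here without the
  accession sequences and published loop intervals; the package supports
  that workflow (FASTA + loop TSV in, identical machinery) but ships no
  sequence data.
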