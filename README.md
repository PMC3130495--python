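# ugtsel

Predicting flavonoid UDP-glycosyltransferase (UGT) **acceptor
regioselectivity** from primary sequence.

Flavonoid UGTs attach a glucose to one specific hydroxyl of a flavonoid
acceptor — the 3-O position, the 7-O position, and so on — and which
position an enzyme prefers has resisted explanation by ordinary sequence
alignment: these enzymes share a fold and an acceptor pocket while their
sequences diverge widely, and sequence-similar enzymes can differ in
regioselectivity. The biochemical consensus is that the preference is
shaped by seven short, variable-length loop regions (labeled a–g) lining
the acceptor pocket. `ugtsel` is a toolkit for classifying UGTs by
regioselectivity from exactly those loops, for computational biologists
studying glycosyltransferase specificity or analogous fine functional
classification problems.

## The method

1. **Graph-derived residue indices.** Each residue type is modeled as a
   rooted graph (α-carbon root, side-chain atoms as nodes, bonds as
   length-weighted edges) from which seven indices are computed: reach,
   branching density, forking index, net partial charge, average bond
   polarity, and hydrogen-bond acceptor/donor tallies. The 20 × 7 table is
   orthogonalized by correlation PCA; residues are encoded as score
   vectors (PC1…PC7).
2. **Loops as time series.** A protein's loop *x* becomes a set of short
   1-D numeric series, one per index. Loop lengths vary from enzyme to
   enzyme (1–24 residues), which rules out fixed-dimension classifiers —
   so loops are compared with **elastic time-series distances**: dynamic
   time warping (DTW), longest common subsequence (LCSS), and
   minimal-variance matching (MVM). The distance between two proteins is
   the sum of series distances over any chosen subset of loops × indices:

   d(U, V) = Σ_{loop ∈ L} Σ_{index ∈ I} d_elastic(u_loop,index, v_loop,index)

3. **Classifiers.** k-nearest-neighbor on these distances;
   a dissimilarity-space SVM (feature vector = distances to the training
   records, RBF kernel); and a hierarchical Bayesian neural network on
   uniform-length "covering window" vectors (86 positions × 7 indices =
   602 inputs, one hidden layer of 301 tanh units, 181,805 parameters),
   trained by alternating Gibbs draws of grouped prior precisions from
   Gamma(α/2, α/2w) hyperpriors with Hamiltonian Monte Carlo weight
   updates. All evaluation is leave-one-out / leave-six-out
   crossvalidation, reported as *loss patterns* — the identity sets of
   misclassified records.
4. **Loop × index search.** Every non-empty loop subset × index subset
   combination — (2⁷−1)(2⁵−1) = 3937 of them — is evaluated with 3NN, and
   a *mode analysis* flags loop subsets whose 31 index choices agree on
   one small loss pattern: the signature of loops genuinely tied to the
   regioselectivity class.

Because the real study's sequences must be fetched by accession and its
loop intervals come from external structural annotation, the package ships
a first-class synthetic generator that reproduces the study's shape (23
records, lengths 446–511, the observed per-loop length ranges, 10/13 class
split) with class signal planted in chosen loops — so every claim above is
testable end to end. See `docs/methods.md` for the full model description.

## Worked example

Simulate a study-shaped dataset with class signal planted in loops **b**
and **e**, classify, and run the combinatorial search:

```sh
$ ugtsel simulate --out-dir demo --seed 7
wrote fixture to demo (23 records)

$ ugtsel classify --data-dir demo --out preds.tsv --metric dtw --model knn --k 3 --cv l1o
knn dtw l1o: 1 errors; missed: S09*

$ ugtsel search --data-dir demo --out-dir search
searched 3937 combos; 49 qualifying loop subset(s)

$ head -8 search/modes.tsv
# ugtsel 0.1.0 seed=None config=9807ca012650
loops	modal_pattern	modal_loss	mode_frequency	qualifies
a	S01, S03*, S04, S05, S10*, S11, S16, S18, S20	9	2	0
b	S03*, S10*	2	14	1
c	S01, S03*, S04, S06*, S07*, S08*, S12*, S13, S14*, S15, S16, S18, S20, S21*	14	2	0
d	S01, S05, S06*, S11, S14*, S20, S23*	7	1	0
e	S09*, S16, S23*	3	16	1
f	S02*, S03*, S06*, S10*, S12*, S13, S14*, S17*, S18, S19, S22*	11	2	0
```

Read the modes table per loop subset: loop **b** alone misclassifies only
two records (S03, S10) under 14 of its 31 index choices, and loop **e**
alone misses three under 16 of 31 — pronounced small modes, so both
qualify (`qualifies = 1`). The non-signal loops a, c, d, f miss 7–14
records with no stable mode. The search recovers exactly the loops the
signal was planted in; an asterisk marks a false positive. The full-sum
3NN classifier (`classify` above) misses a single record. Other
subcommands: `indices` (the 20 × 7 residue table), `encode` (flat
602-style vectors), `dist` (distance matrices with `--loops be
--indices 12345` style restriction), `baseline` (alignment-score
distances), `bnn-train`.

The same dataset format — FASTA plus loop/label TSVs — accepts real
sequences and loop annotations, so the identical machinery applies beyond
simulation.

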