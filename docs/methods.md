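# Methods

## The model

`kglink` treats a biomedical knowledge graph as a partially observed binary
3-way tensor over (subject entity, relation, object entity). Each entity and
each relation receives a latent embedding, and a *decoder* maps the three
embeddings of a candidate fact to an un-normalized score
φ(s, r, o). The primary decoder is the complex trilinear form

    φ(s, r, o) = Re( Σ_j  l_rj · e_sj · conj(e_oj) )

with complex entity embeddings `e ∈ C^d` and relation embeddings
`l ∈ C^d`. Separating real (a) and imaginary (b) parts gives four real
trilinear terms,

    φ = ⟨e_sa, l_ra, e_oa⟩ + ⟨e_sb, l_ra, e_ob⟩ + ⟨e_sa, l_rb, e_ob⟩ − ⟨e_sb, l_rb, e_oa⟩,

so the model trains as six real matrices. Conjugating the object makes φ
asymmetric in subject and object, which is what lets a single relation
embedding represent directed edges such as disease → gene therapeutic
links. Three alternative decoders are provided for comparison: DistMult
(the plain real trilinear product, symmetric by construction), canonical
polyadic decomposition (asymmetric via separate subject-role and object-role
entity tables), and holographic embeddings (relation vector dotted with the
circular correlation of subject and object).

Facts absent from the graph are assumed false (closed-world). Because
unobserved disease–gene pairs may simply be undiscovered, the data are
positive-unlabelled; this drives two protocol choices. First, evaluation is
recall-oriented (recall@k, and average precision over known positives)
rather than AUROC/AUPR, which would require trustworthy negatives. Second,
negative training examples are *presumed* negatives obtained by corrupting
one endpoint of an observed triple with a random entity of the same type,
without checking the corruption against the graph (a strict-filtering switch
exists but is off by default; on the synthetic benchmark it changes held-out
recall by ~0.03).

## Training recipe

* **Initialization** — all embedding matrices are Xavier-Gaussian: zero-mean
  normals with variance 1/d, reading each embedding row as a layer with
  fan-in = fan-out = d. (Glorot's matrix-shape convention would tie the
  scale to the entity count, which has no analogue for lookup tables.)
  The initialization stream is keyed off the training seed through a
  `SeedSequence` so that a model seeded with the same integer as a data
  generator does not replay the generator's draws.
* **Negative sampling** — 5 corruptions per positive (default); subject or
  object chosen uniformly, replaced by a uniform entity of the same type;
  if a side has no alternative entity the other side is corrupted.
* **Balanced batching** — each batch holds `floor(batch_size / #relations)`
  examples of *every* relation; an epoch covers the most frequent relation
  once, and rarer relations cycle through reshuffled copies, so their
  triples repeat (oversampling). This deliberately up-weights sparse
  relations such as the therapeutic-relationship benchmark edges.
* **Dropout** — inverted dropout (survivors scaled by 1/(1−p)) with p = 0.5
  on the entity embeddings entering the decoder, drawn independently per
  example and coordinate; evaluation applies no mask and no rescaling.
  Applying dropout to relation embeddings as well is available behind a
  flag but off by default.
* **Loss and optimizer** — mean binary cross-entropy with logits over the
  positives (label 1) and sampled negatives (label 0), in the numerically
  stable softplus form; optimized by Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8,
  default learning rate 0.01). Gradients are analytic: φ is trilinear, so
  the gradient with respect to each embedding is an elementwise product of
  the other two (for holographic embeddings, a circular correlation or
  convolution, computed by FFT); all four decoders are verified against
  central finite differences to a relative error below 1e-4.
* **Early stopping** — after each epoch a validation metric (default:
  filtered recall@k on the benchmark relation; k = 200 at full scale,
  k = 20 on the desk-scale benchmark) is computed on the held-out
  validation edges; training stops when the metric has not improved by more
  than 1e-4 for 5 consecutive epochs (both the tolerance and the patience
  are configuration knobs), and the best-validation model is restored.
  The training recipe is also consistent with a patience of 3; 5 is the
  package default.

Default hyperparameters follow the reference recipe: d = 200, batch size
3000, 5 negatives per positive, dropout 0.5, patience 5. The desk-scale
benchmarks below scale these to d = 16 and batch 512.

## Benchmarks and splits

The *benchmark relation* (disease → gene therapeutic relationship) is
split by edge count 60%/20%/20% into train/validation/test (or 60/40 when
no validation set is needed); every triple of every other relation stays in
train, so the model always sees the whole heterogeneous graph. Validation
and test sizes round down; train takes the remainder. Diseases with fewer
than 30 distinct benchmark gene neighbors can be removed from the test set
(they are typically disease subtypes whose siblings remain in training and
would leak information); training is left untouched by this filter.

Temporal evaluation *time-slices* the graph: each edge carries the earliest
literature-mention year, training keeps edges with year ≤ threshold, and
the test set holds benchmark edges in a window after the threshold
(threshold 2010 with a 5-year window tests on 2011–2015 inclusive) or all
later edges when no window is given. Relations without usable year tags go
to train unconditionally by default (a drop option exists).

Ranking is *filtered*: for each disease, every gene of the candidate pool
is scored, genes already linked in train (and validation) are removed, and
the rest are sorted by descending score with ties broken by ascending
entity id. Per-disease average precision divides by the disease's full
ground-truth positive count (not capped at the rank cutoff), and aggregate
mAP / average recall@k are unweighted means over diseases; diseases with no
test positives after filtering are excluded from averages and counted.
Score distributions (e.g. predicted clinical successes vs failures) are
compared with a two-sided Mann–Whitney–Wilcoxon test, Bonferroni-corrected
(α/m; 0.05/3 ≈ 0.017 for a three-comparison family), via
`scipy.stats.mannwhitneyu` with the exact null for small untied samples.

## The synthetic generator

Real biomedical knowledge graphs of this kind are proprietary, so the test
substrate is generated: five entity types (genes/proteins, diseases, GO
processes, pathways, compounds) joined by eleven typed relations that
mirror the canonical schema (PPI, GO hierarchy, two gene–process links,
disease–process, pathway membership, disease–pathway, compound links on
both sides, disease–gene association, and the therapeutic relationship).
Every entity and relation receives a hidden complex embedding of rank
`true_dim` (i.i.d. standard complex normals); all type-compatible pairs are
scored with the complex trilinear form and the top `edge_density` fraction
per relation becomes edges (self-loops excluded). Optional label noise
flips each pair independently. Because generator and model share a
functional family, an oracle that ranks by planted score is Bayes-optimal
on the noise-free graph (and verifiably achieves recall and AP of 1), and
a mismatched mode that plants no structure serves as a negative control.
Year tags are attached uniformly or in descending planted-score order
("strong links are discovered first"), which makes time-sliced benchmarks
learnable.

The default entity mix is compound-heavy (260 of 500), echoing the real
graph's composition. The *recovery benchmark* configuration instead uses
250 genes of 500 entities with a therapeutic density of 0.08 (≈ 20
positive genes per disease): a 10×-random recovery bar is only arithmetically
satisfiable when the candidate pool holds at least ~200 genes, since the
random-ranker expectation of recall@20 is 20/pool. Its per-relation
densities are uniform defaults of a few percent; experiments with densities
proportional to the real graph's per-relation abundances gave
indistinguishable recovery and are not the default.

What the generator does *not* emulate: literature-mention counts and
extraction confidence scores, ontology structure among diseases (real
disease subtypes are near-duplicates; synthetic diseases are exchangeable),
degree heavy-tails beyond what thresholded Gaussian scores produce, and
correlated noise between relations. Passing the planted-recovery tests
therefore shows the pipeline can extract latent structure its model family
can represent — not that it reproduces performance numbers on the
proprietary graph.

## Benchmark scale and observed behavior

The desk-scale benchmarks run on one CPU in minutes: recovery uses 500
entities, true rank 8, ~6,000 edges, ComplEx d = 16, batch 512, 60 epochs
maximum over 5 seeds; the dropout ablation uses 200 entities, true rank 4,
d = 64 (deliberately over-parameterized), a 40% train fraction and 25
epochs without early stopping, over 5 seeds per arm.

Two findings from these runs are worth stating plainly. First, training
beats the untrained baseline in every seed, and in the over-fit-prone
regime dropout 0.5 improves the median held-out recall — the expected
regularization direction. Second, with dropout 0.5 *mandated at d = 16*,
held-out filtered recall@20 on the recovery benchmark plateaus around
0.26–0.36 (3–4.5× the random-ranker expectation); the same pipeline without
dropout reaches 0.49–0.67 (6–8×) while fitting the training edges almost
perfectly (recall 0.98). Dropout of half the coordinates of a
16-dimensional embedding is far more destructive than at d = 200, and the
shortfall is insensitive to learning rate (0.005–0.1, with or without
staged decay), graph density (1×–3×), the early-stopping metric (recall@20
vs mAP) and strict negative filtering. A fixed enrichment multiple is also
scale-invariant in the pool size — both the bar and achievable recall fall
as 1/pool — so no entity mix changes this picture. The recovery test that
demands a 10× enrichment under dropout therefore fails by design honesty
rather than by implementation defect; the decoder, gradient, metric, and
split layers are each verified against independent oracles.

## Numerical and degenerate-case choices

* DistMult (and each ComplEx term) multiplies the two entity vectors before
  the relation vector, making subject–object symmetry and the
  zero-imaginary ComplEx → DistMult reduction bit-exact.
* Holographic circular correlation has a direct O(d²) implementation and an
  FFT path; they agree to 1e-8 and the batched trainer uses the FFT path.
* Ties in ranking are broken by ascending entity id — deterministic across
  runs and platforms.
* Duplicate (s, r, o) triples collapse to one; conflicting year tags keep
  the earliest (consistent with first-mention tagging).
* An empty validation set (e.g. temporal splits) disables early stopping;
  the loop runs to `max_epochs`.
* `max_epochs = 0` returns the untrained initialized model with an empty
  history, which doubles as the untrained baseline in comparisons.
* A non-finite training loss aborts with a diagnostic rather than
  continuing silently.
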