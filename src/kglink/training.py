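"""Embedding training: initialization, typed negative sampling,
relation-balanced batching, dropout, cross-entropy loss, Adam, early stopping.

The training recipe treats link prediction as binary classification of
triples.  Each observed (positive) triple is contrasted with a fixed number
of corrupted (negative) triples obtained by replacing one endpoint with a
random entity of the *same type*; under the closed-world assumption these
corruptions are presumed false without checking them against the graph.
Batches hold the same number of examples per relation, which oversamples
rare relations (notably the therapeutic-relationship benchmark edges) and
makes them weigh more in training.  All embedding matrices are updated by
Adam on the mean binary cross-entropy of decoder scores, with inverted
dropout on the entity embeddings entering the decoder.  Training stops when
the validation metric has not improved for a fixed number of epochs.

Gradients are computed analytically for each decoder (the score is trilinear
in its arguments, so per-argument gradients are elementwise products of the
other two) and verified against finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .decoders import DECODER_NAMES, EmbeddingSet, score_triples
from .kg import DataSplit, KnowledgeGraph, Triple


@dataclass
class TrainConfig:
    """Hyperparameters of the training recipe.

    Defaults follow the reference recipe: dimensionality 200, 5 negatives
    per positive, 3000-example batches, dropout 0.5 on entity embeddings,
    patience of 5 epochs on the validation metric.
    """

    embedding_dim: int = 200
    negatives_per_positive: int = 5
    batch_size: int = 3000
    dropout_p: float = 0.5
    learning_rate: float = 0.01
    patience_epochs: int = 5
    max_epochs: int = 100
    seed: int = 0
    decoder_name: str = "complex"
    score_normalization: str = "sigmoid"
    stop_tolerance: float = 1e-4
    validation_k: int = 200
    dropout_on_relations: bool = False
    strict_negative_filtering: bool = False

    def validate(self) -> None:
        if not (0.0 <= self.dropout_p < 1.0):
            raise ValueError("dropout_p must be in [0, 1)")
        for name in ("embedding_dim", "negatives_per_positive", "batch_size", "patience_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.decoder_name not in DECODER_NAMES:
            raise ValueError(f"unknown decoder {self.decoder_name!r}")
        if self.score_normalization not in ("sigmoid", "none"):
            raise ValueError("score_normalization must be 'sigmoid' or 'none'")


@dataclass
class TrainState:
    model: EmbeddingSet
    epoch: int
    validation_history: list[float]
    stopped_early: bool
    rng_state: object = None
    loss_history: list[float] = field(default_factory=list)


# -- initialization -------------------------------------------------------


def init_embeddings(n: int, k: int, d: int, decoder_name: str, seed: int) -> EmbeddingSet:
    """Xavier-Gaussian initialization of all embedding matrices.

    Each embedding row is treated as a d-unit layer (fan_in = fan_out = d),
    giving zero-mean Gaussians with variance 2/(d+d) = 1/d.  Matrices a
    decoder does not use are left all-zero.
    """
    if n <= 0 or k <= 0 or d <= 0:
        raise ValueError("entity count, relation count and dimension must be positive")
    if decoder_name not in DECODER_NAMES:
        raise ValueError(f"unknown decoder {decoder_name!r}")
    rng = np.random.default_rng(seed)
    std = math.sqrt(1.0 / d)

    def draw(rows: int) -> np.ndarray:
        return rng.normal(0.0, std, size=(rows, d))

    ent_a = draw(n)
    rel_a = draw(k)
    if decoder_name == "complex":
        ent_b = draw(n)
        rel_b = draw(k)
    else:
        ent_b = np.zeros((n, d))
        rel_b = np.zeros((k, d))
    obj_a = draw(n) if decoder_name == "cp" else None
    return EmbeddingSet(
        entity_real=ent_a,
        entity_imag=ent_b,
        relation_real=rel_a,
        relation_imag=rel_b,
        decoder_name=decoder_name,
        object_real=obj_a,
    )


# -- negative sampling ----------------------------------------------------


def sample_negatives(
    positive: Triple,
    kg: KnowledgeGraph,
    ratio: int,
    rng: np.random.Generator,
) -> list[Triple]:
    """Corrupt one endpoint of a positive triple with a same-type entity.

    For each of ``ratio`` negatives, the subject or object is chosen
    uniformly and replaced by a uniformly random entity of the replaced
    endpoint's type; the relation is kept.  Corruptions are not checked
    against known positives (closed-world assumption).  If the chosen side
    has no alternative entity of the required type the other side is
    corrupted; if neither side has one, the triple cannot be corrupted.
    """
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    rel = kg.relation_types[positive.relation]
    subj_pool = kg.entities_of_type(rel.subject_type)
    obj_pool = kg.entities_of_type(rel.object_type)
    if len(subj_pool) <= 1 and len(obj_pool) <= 1:
        raise ValueError(f"no entity pool can corrupt triple {positive}")
    out = []
    for _ in range(ratio):
        side = int(rng.integers(2))  # 0 = subject, 1 = object
        if side == 0 and len(subj_pool) <= 1:
            side = 1
        elif side == 1 and len(obj_pool) <= 1:
            side = 0
        if side == 0:
            repl = subj_pool[int(rng.integers(len(subj_pool)))]
            out.append(Triple(repl, positive.relation, positive.object))
        else:
            repl = obj_pool[int(rng.integers(len(obj_pool)))]
            out.append(Triple(positive.subject, positive.relation, repl))
    return out


# -- balanced batching ----------------------------------------------------


def _balanced_index_batches(
    by_relation: Sequence[np.ndarray], batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Batches of positions with equal per-relation counts.

    ``quota = floor(batch_size / #relations)`` examples per relation per
    batch; the epoch covers the most frequent relation once
    (``epoch_len = ceil(max_count / quota)`` batches), while rarer relations
    are oversampled by cycling shuffled copies, so their triples repeat.
    """
    n_rel = len(by_relation)
    if batch_size < n_rel:
        raise ValueError(f"batch_size {batch_size} < number of relations {n_rel}")
    quota = batch_size // n_rel
    max_count = max(len(a) for a in by_relation)
    epoch_len = math.ceil(max_count / quota)
    needed = epoch_len * quota

    streams = []
    for arr in by_relation:
        if len(arr) >= needed:
            streams.append(rng.permutation(arr)[:needed])
        else:
            reps = [rng.permutation(arr) for _ in range(math.ceil(needed / len(arr)))]
            streams.append(np.concatenate(reps)[:needed])

    batches = []
    for b in range(epoch_len):
        chunk = np.concatenate([s[b * quota : (b + 1) * quota] for s in streams])
        batches.append(rng.permutation(chunk))
    return batches


def make_balanced_batches(
    train: Sequence[Triple], batch_size: int, rng: np.random.Generator | int
) -> list[list[Triple]]:
    """Relation-balanced batches of training triples (see module docstring)."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    relations = sorted({t.relation for t in train})
    by_rel = []
    train = list(train)
    for r in relations:
        by_rel.append(np.array([i for i, t in enumerate(train) if t.relation == r], dtype=np.intp))
    batches = _balanced_index_batches(by_rel, batch_size, rng)
    return [[train[i] for i in batch] for batch in batches]


# -- dropout --------------------------------------------------------------


def apply_dropout(
    vectors: np.ndarray, p: float, rng: np.random.Generator, training_mode: bool = True
) -> np.ndarray:
    """Inverted dropout: zero each coordinate w.p. p, scale survivors by 1/(1-p).

    Identity when p == 0 or outside training mode, so evaluation never
    rescales.
    """
    if not (0.0 <= p < 1.0):
        raise ValueError("dropout probability must be in [0, 1)")
    vectors = np.asarray(vectors, float)
    if not training_mode or p == 0.0:
        return vectors
    mask = (rng.random(vectors.shape) >= p) / (1.0 - p)
    return vectors * mask


def _dropout_mask(shape, p: float, rng: np.random.Generator) -> np.ndarray:
    if p == 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= p) / (1.0 - p)


# -- loss -----------------------------------------------------------------


def _softplus(x: np.ndarray) -> np.ndarray:
    # log(1 + e^x), stable for large |x|
    return np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def loss(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Mean binary cross-entropy with logits: positives labeled 1, negatives 0.

    Uses the log-sum (softplus) form, so it stays finite for any finite
    scores.  All scores 0 gives ln 2.
    """
    pos_scores = np.atleast_1d(np.asarray(pos_scores, float))
    neg_scores = np.atleast_1d(np.asarray(neg_scores, float))
    if pos_scores.size == 0 or neg_scores.size == 0:
        raise ValueError("both positive and negative score lists must be nonempty")
    total = np.sum(_softplus(-pos_scores)) + np.sum(_softplus(neg_scores))
    return float(total / (pos_scores.size + neg_scores.size))


def normalize_score(phi: float | np.ndarray, mode: str = "sigmoid"):
    """Map a raw decoder score to [0, 1] via the logistic function (monotone),
    or pass it through unchanged with mode='none'."""
    if mode == "sigmoid":
        return _sigmoid(np.asarray(phi, float)) if np.ndim(phi) else float(_sigmoid(np.atleast_1d(float(phi)))[0])
    if mode == "none":
        return phi
    raise ValueError(f"unknown normalization mode {mode!r}")


# -- Adam -----------------------------------------------------------------


class _Adam:
    """Standard Adam (beta1=0.9, beta2=0.999, eps=1e-8) over named matrices."""

    def __init__(self, params: dict[str, np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for key, g in grads.items():
            m = self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            v = self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            self.params[key] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -- analytic gradients ---------------------------------------------------


def batch_loss_and_grads(
    model: EmbeddingSet,
    s_idx: np.ndarray,
    r_idx: np.ndarray,
    o_idx: np.ndarray,
    labels: np.ndarray,
    dropout_p: float = 0.0,
    rng: np.random.Generator | None = None,
    dropout_on_relations: bool = False,
) -> tuple[float, dict[str, np.ndarray]]:
    """Mean BCE loss and dense gradients w.r.t. every embedding matrix.

    The decoder score is trilinear, so dφ w.r.t. each gathered vector is an
    elementwise product of the other two; dropout masks (applied to the
    gathered entity rows) rescale the gradients on the way back.
    """
    rng = rng or np.random.default_rng()
    N = len(labels)
    name = model.decoder_name
    ra = model.relation_real[r_idx]
    rb = model.relation_imag[r_idx]

    if name == "cp":
        sa = model.entity_real[s_idx]
        oa = model.object_real[o_idx]
    else:
        sa = model.entity_real[s_idx]
        oa = model.entity_real[o_idx]
    sb = model.entity_imag[s_idx]
    ob = model.entity_imag[o_idx]

    # per-row masks on the entity vectors entering the decoder
    m_sa = _dropout_mask(sa.shape, dropout_p, rng)
    m_sb = _dropout_mask(sb.shape, dropout_p, rng)
    m_oa = _dropout_mask(oa.shape, dropout_p, rng)
    m_ob = _dropout_mask(ob.shape, dropout_p, rng)
    sa, sb, oa, ob = sa * m_sa, sb * m_sb, oa * m_oa, ob * m_ob
    if dropout_on_relations:
        m_ra = _dropout_mask(ra.shape, dropout_p, rng)
        m_rb = _dropout_mask(rb.shape, dropout_p, rng)
        ra, rb = ra * m_ra, rb * m_rb

    if name == "complex":
        phi = (
            np.sum(sa * ra * oa, -1) + np.sum(sb * ra * ob, -1)
            + np.sum(sa * rb * ob, -1) - np.sum(sb * rb * oa, -1)
        )
    elif name in ("distmult", "cp"):
        phi = np.sum(sa * ra * oa, -1)
    elif name == "hole":
        corr = np.real(np.fft.ifft(np.conj(np.fft.fft(sa, axis=-1)) * np.fft.fft(oa, axis=-1), axis=-1))
        phi = np.sum(ra * corr, -1)
    else:  # pragma: no cover
        raise ValueError(name)

    loss_val = float(
        (np.sum(_softplus(-phi[labels == 1])) + np.sum(_softplus(phi[labels == 0]))) / N
    )
    g = ((_sigmoid(phi) - labels) / N)[:, None]  # dL/dphi, column for broadcasting

    grads: dict[str, np.ndarray] = {}

    def scatter(shape, idx, rows):
        out = np.zeros(shape)
        np.add.at(out, idx, rows)
        return out

    if name == "complex":
        d_sa = g * (ra * oa + rb * ob) * m_sa
        d_sb = g * (ra * ob - rb * oa) * m_sb
        d_oa = g * (sa * ra - sb * rb) * m_oa
        d_ob = g * (sb * ra + sa * rb) * m_ob
        d_ra = g * (sa * oa + sb * ob)
        d_rb = g * (sa * ob - sb * oa)
        grads["entity_real"] = scatter(model.entity_real.shape, s_idx, d_sa)
        np.add.at(grads["entity_real"], o_idx, d_oa)
        grads["entity_imag"] = scatter(model.entity_imag.shape, s_idx, d_sb)
        np.add.at(grads["entity_imag"], o_idx, d_ob)
        grads["relation_real"] = scatter(model.relation_real.shape, r_idx, d_ra)
        grads["relation_imag"] = scatter(model.relation_imag.shape, r_idx, d_rb)
    elif name == "distmult":
        d_sa = g * ra * oa * m_sa
        d_oa = g * ra * sa * m_oa
        d_ra = g * sa * oa
        grads["entity_real"] = scatter(model.entity_real.shape, s_idx, d_sa)
        np.add.at(grads["entity_real"], o_idx, d_oa)
        grads["relation_real"] = scatter(model.relation_real.shape, r_idx, d_ra)
    elif name == "cp":
        d_u = g * ra * oa * m_sa
        d_w = g * ra * sa * m_oa
        d_ra = g * sa * oa
        grads["entity_real"] = scatter(model.entity_real.shape, s_idx, d_u)
        grads["object_real"] = scatter(model.object_real.shape, o_idx, d_w)
        grads["relation_real"] = scatter(model.relation_real.shape, r_idx, d_ra)
    elif name == "hole":
        Fs = np.fft.fft(sa, axis=-1)
        Fo = np.fft.fft(oa, axis=-1)
        Fr = np.fft.fft(g * ra, axis=-1)
        # dphi/ds = r (star) o ; dphi/do = circular convolution of r and s
        d_sa = np.real(np.fft.ifft(np.conj(Fr) * Fo, axis=-1)) * m_sa
        d_oa = np.real(np.fft.ifft(Fr * Fs, axis=-1)) * m_oa
        corr = np.real(np.fft.ifft(np.conj(Fs) * Fo, axis=-1))
        d_ra = g * corr
        grads["entity_real"] = scatter(model.entity_real.shape, s_idx, d_sa)
        np.add.at(grads["entity_real"], o_idx, d_oa)
        grads["relation_real"] = scatter(model.relation_real.shape, r_idx, d_ra)

    if dropout_on_relations and name == "complex":
        grads["relation_real"] *= 0  # recomputed below with masks
        np.add.at(grads["relation_real"], r_idx, d_ra * m_ra)
        grads["relation_imag"] *= 0
        np.add.at(grads["relation_imag"], r_idx, d_rb * m_rb)
    elif dropout_on_relations and name in ("distmult", "cp", "hole"):
        grads["relation_real"] *= 0
        np.add.at(grads["relation_real"], r_idx, d_ra * m_ra)

    return loss_val, grads


# -- the training loop ----------------------------------------------------


class _TypedSampler:
    """Vectorized typed corruption of index triples."""

    def __init__(self, kg: KnowledgeGraph, entity_ids: list[str], relation_names: list[str]):
        eidx = {e: i for i, e in enumerate(entity_ids)}
        types = sorted({t for t in kg.entity_types.values()})
        tidx = {t: i for i, t in enumerate(types)}
        self.pools = [
            np.array([eidx[e] for e in kg.entities_of_type(t)], dtype=np.intp) for t in types
        ]
        self.subj_type = np.array(
            [tidx[kg.relation_types[r].subject_type] for r in relation_names], dtype=np.intp
        )
        self.obj_type = np.array(
            [tidx[kg.relation_types[r].object_type] for r in relation_names], dtype=np.intp
        )

    def corrupt(
        self, s: np.ndarray, r: np.ndarray, o: np.ndarray, ratio: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        s = np.repeat(s, ratio)
        r = np.repeat(r, ratio)
        o = np.repeat(o, ratio)
        st = self.subj_type[r]
        ot = self.obj_type[r]
        pool_sizes = np.array([len(p) for p in self.pools])
        side = rng.integers(2, size=len(s))  # 0 subject, 1 object
        # fall back to the other side when the chosen pool has no alternative
        side = np.where((side == 0) & (pool_sizes[st] <= 1), 1, side)
        side = np.where((side == 1) & (pool_sizes[ot] <= 1), 0, side)
        if np.any((pool_sizes[st] <= 1) & (pool_sizes[ot] <= 1)):
            raise ValueError("a triple has no corruptible endpoint (both pools of size 1)")
        s = s.copy()
        o = o.copy()
        repl_type = np.where(side == 0, st, ot)
        for ti, pool in enumerate(self.pools):
            hit = repl_type == ti
            n_hit = int(hit.sum())
            if n_hit == 0:
                continue
            draws = pool[rng.integers(len(pool), size=n_hit)]
            subj_hit = hit & (side == 0)
            obj_hit = hit & (side == 1)
            s[subj_hit] = draws[(side[hit] == 0)]
            o[obj_hit] = draws[(side[hit] == 1)]
        return s, r, o


def default_validation_metric(k: int = 200) -> Callable:
    """Filtered average recall@k over validation diseases of the benchmark
    relation (train edges filtered from each prediction list)."""

    from .evaluate import evaluate_ranking  # local import to avoid a cycle

    def metric(model: EmbeddingSet, kg: KnowledgeGraph, split: DataSplit) -> float:
        report = evaluate_ranking(
            model, kg, split.valid, split.benchmark_relation,
            filter_triples=split.train, k_grid=(k,),
        )
        return report.aggregate_recall[k]

    return metric


def train(
    kg: KnowledgeGraph,
    split: DataSplit,
    config: TrainConfig,
    validation_metric: Callable | None = None,
    log: Callable[[str], None] | None = None,
) -> TrainState:
    """Learn an EmbeddingSet from a DataSplit.

    Runs epochs of relation-balanced batches; per batch draws typed
    negatives, applies dropout to the entity embeddings entering the
    decoder, and takes one Adam step on the mean binary cross-entropy.
    After each epoch the validation metric (default: filtered recall@k on
    the benchmark relation) is computed on ``split.valid``; training stops
    once the metric has not improved by more than ``stop_tolerance`` for
    ``patience_epochs`` consecutive epochs, and the best-metric model is
    restored.  With an empty validation set the loop simply runs
    ``max_epochs`` epochs.
    """
    config.validate()
    if len(split.train) == 0:
        raise ValueError("empty training set")

    entity_ids = sorted(kg.entity_types)
    relation_names = sorted(kg.relation_types)
    eidx = {e: i for i, e in enumerate(entity_ids)}
    ridx = {r: i for i, r in enumerate(relation_names)}

    # the init stream is keyed off config.seed so that a model initialized
    # with the same integer a data generator used does not replay the
    # generator's draws (which would correlate the init with the data)
    init_seed = int(np.random.SeedSequence([config.seed, 0x1217]).generate_state(1)[0] % (2**31))
    model = init_embeddings(
        len(entity_ids), len(relation_names), config.embedding_dim, config.decoder_name, init_seed
    )
    model.entity_ids = entity_ids
    model.relation_names = relation_names

    if config.max_epochs == 0:
        return TrainState(model, 0, [], stopped_early=False)

    s_all = np.array([eidx[t.subject] for t in split.train], dtype=np.intp)
    r_all = np.array([ridx[t.relation] for t in split.train], dtype=np.intp)
    o_all = np.array([eidx[t.object] for t in split.train], dtype=np.intp)
    train_rels = sorted({t.relation for t in split.train})
    by_rel = [np.flatnonzero(r_all == ridx[r]).astype(np.intp) for r in train_rels]

    known = {(int(a), int(b), int(c)) for a, b, c in zip(s_all, r_all, o_all)} if config.strict_negative_filtering else None

    sampler = _TypedSampler(kg, entity_ids, relation_names)
    rng = np.random.default_rng(config.seed)

    params = {"entity_real": model.entity_real, "relation_real": model.relation_real}
    if config.decoder_name == "complex":
        params["entity_imag"] = model.entity_imag
        params["relation_imag"] = model.relation_imag
    if config.decoder_name == "cp":
        params["object_real"] = model.object_real
    opt = _Adam(params, config.learning_rate)

    if validation_metric is None:
        validation_metric = default_validation_metric(config.validation_k)
    use_validation = len(split.valid) > 0

    history: list[float] = []
    losses: list[float] = []
    best_metric = -np.inf
    best_params = None
    best_epoch = 0
    epochs_since_improvement = 0
    stopped_early = False

    for epoch in range(1, config.max_epochs + 1):
        batches = _balanced_index_batches(by_rel, config.batch_size, rng)
        epoch_loss = 0.0
        for batch in batches:
            ps, pr, po = s_all[batch], r_all[batch], o_all[batch]
            ns, nr, no = sampler.corrupt(ps, pr, po, config.negatives_per_positive, rng)
            if known is not None:
                bad = np.array([(a, b, c) in known for a, b, c in zip(ns, nr, no)])
                keep = ~bad
                ns, nr, no = ns[keep], nr[keep], no[keep]
            s_b = np.concatenate([ps, ns])
            r_b = np.concatenate([pr, nr])
            o_b = np.concatenate([po, no])
            labels = np.concatenate([np.ones(len(ps)), np.zeros(len(ns))])
            loss_val, grads = batch_loss_and_grads(
                model, s_b, r_b, o_b, labels,
                dropout_p=config.dropout_p, rng=rng,
                dropout_on_relations=config.dropout_on_relations,
            )
            if not np.isfinite(loss_val):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate"
                )
            opt.step(grads)
            epoch_loss += loss_val
        epoch_loss /= len(batches)
        losses.append(epoch_loss)

        if use_validation:
            metric = float(validation_metric(model, kg, split))
        else:
            metric = float("nan")
        history.append(metric)
        if log is not None:
            log(f"epoch {epoch}\tloss {epoch_loss:.6f}\tval {metric:.6f}")

        if use_validation:
            if metric > best_metric + config.stop_tolerance:
                best_metric = metric
                best_epoch = epoch
                best_params = {k: v.copy() for k, v in params.items()}
                epochs_since_improvement = 0
            else:
                epochs_since_improvement += 1
                if epochs_since_improvement >= config.patience_epochs:
                    stopped_early = True
                    break

    if best_params is not None:
        for key, val in best_params.items():
            params[key][...] = val
    final_epoch = best_epoch if best_params is not None else len(history)
    return TrainState(
        model,
        epoch=final_epoch,
        validation_history=history,
        stopped_early=stopped_early,
        rng_state=rng.bit_generator.state,
        loss_history=losses,
    )
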