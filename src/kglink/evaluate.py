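"""Filtered ranking evaluation: per-disease recall@k curves, average
precision, mAP, and score-distribution comparison.

Evaluation follows the filtered-ranking protocol: for each disease, every
candidate gene is scored and the genes already linked to that disease in the
training (and validation) data are removed from the prediction list before
ranks are assigned, so known facts do not crowd out the held-out test genes.
Recall is the headline metric because the data are positive-unlabelled —
unobserved pairs may simply be undiscovered, so precision-style metrics
(AUROC, AUPR) would punish the model for predicting facts not yet known.

Metrics: for one disease with GTP ground-truth positive genes,
``recall@k = |positives in top k| / GTP`` and
``AP = (Σ_k P(k) · rel(k)) / GTP`` where rel(k) indicates a positive at rank
k and P(k) is the precision among the top k.  Aggregates are simple means
over diseases.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .decoders import EmbeddingSet, score_candidates
from .kg import KnowledgeGraph, Triple


@dataclass
class RankedList:
    """Ordered candidate objects for one (subject, relation) query.

    Candidates are sorted by descending score; ties broken by ascending
    entity id so output is deterministic.  ``filtered_out`` holds candidates
    removed because they form a known (train/validation) edge with this
    subject and relation.
    """

    subject: str
    relation: str
    candidates: list[str]
    scores: np.ndarray
    filtered_out: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        if len(self.candidates) != len(self.scores):
            raise ValueError("candidates and scores must be parallel")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing")
        if set(self.candidates) & self.filtered_out:
            raise ValueError("a filtered entity appears among the candidates")
        if len(set(self.candidates)) != len(self.candidates):
            raise ValueError("duplicate candidates")

    def top(self, k: int) -> list[str]:
        return self.candidates[:k]


def rank_objects(
    model: EmbeddingSet,
    subject: str,
    relation: str,
    candidate_pool: Iterable[str],
    filter_set: Iterable[Triple] = (),
) -> RankedList:
    """Score and rank candidate objects for (subject, relation, ·), removing
    candidates that form a triple of ``filter_set`` with this subject and
    relation."""
    pool = sorted(set(candidate_pool))
    if not pool:
        raise ValueError("candidate pool is empty")
    s = model.entity_index(subject)
    r = model.relation_index(relation)
    filtered = {
        t.object for t in filter_set if t.subject == subject and t.relation == relation
    } & set(pool)
    kept = [c for c in pool if c not in filtered]
    if not kept:
        return RankedList(subject, relation, [], np.array([]), filtered)
    idx = np.array([model.entity_index(c) for c in kept], dtype=np.intp)
    scores = score_candidates(model, s, r, idx)
    # descending score, ties broken by ascending entity id (kept is sorted)
    order = np.lexsort((np.arange(len(kept)), -scores))
    return RankedList(
        subject,
        relation,
        [kept[i] for i in order],
        scores[order],
        filtered,
    )


# -- metrics --------------------------------------------------------------


def recall_at_k(ranked: RankedList | Sequence[str], positives: set[str], k: int) -> float:
    """|positives ∩ top-k| / |positives|."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if not positives:
        raise ValueError("recall is undefined with no positives")
    top = ranked.top(k) if isinstance(ranked, RankedList) else list(ranked)[:k]
    return len(positives & set(top)) / len(positives)


def average_precision(
    ranked: RankedList | Sequence[str], positives: set[str], N: int | None = None
) -> float:
    """AP = (Σ_{k=1..N} P(k)·rel(k)) / GTP with GTP = |positives|.

    ``N`` is the rank cutoff (e.g. 500 for mAP@500); by default the full
    list is used.  GTP is the disease's total positive count, not capped at
    N, so a truncated list cannot inflate AP.
    """
    if not positives:
        raise ValueError("average precision is undefined with no positives")
    items = ranked.candidates if isinstance(ranked, RankedList) else list(ranked)
    if N is not None:
        if N < 1:
            raise ValueError("N must be >= 1")
        items = items[:N]
    hits = 0
    total = 0.0
    for rank, item in enumerate(items, start=1):
        if item in positives:
            hits += 1
            total += hits / rank
    return total / len(positives)


def mean_average_precision(per_disease_ap: Mapping[str, float]) -> float:
    """Unweighted mean of per-disease AP values."""
    if not per_disease_ap:
        raise ValueError("no diseases to average over")
    return float(np.mean(list(per_disease_ap.values())))


def recall_curve(
    per_disease: Mapping[str, tuple[RankedList | Sequence[str], set[str]]],
    k_grid: Sequence[int],
) -> dict[int, float]:
    """Average recall@k over diseases for each k of an ascending grid."""
    if not per_disease:
        raise ValueError("no diseases given")
    k_grid = list(k_grid)
    if k_grid != sorted(k_grid):
        raise ValueError("k_grid must be ascending")
    return {
        k: float(np.mean([recall_at_k(rl, pos, k) for rl, pos in per_disease.values()]))
        for k in k_grid
    }


# -- full evaluation ------------------------------------------------------


@dataclass
class EvalReport:
    """Per-disease and aggregate filtered-ranking results."""

    per_disease_ap: dict[str, float]
    per_disease_recall: dict[str, dict[int, float]]
    per_disease_gtp: dict[str, int]
    aggregate_map: float
    aggregate_recall: dict[int, float]
    k_grid: tuple[int, ...]
    n_diseases: int
    n_skipped_no_positives: int = 0
    ap_cutoff: int | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_diseases": self.n_diseases,
                "n_skipped_no_positives": self.n_skipped_no_positives,
                "k_grid": list(self.k_grid),
                "ap_cutoff": self.ap_cutoff,
                "mAP": self.aggregate_map,
                "avg_recall": {str(k): v for k, v in self.aggregate_recall.items()},
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        cols = ["disease_id", "GTP", "AP"] + [f"recall@{k}" for k in self.k_grid]
        lines = ["\t".join(cols)]
        for d in sorted(self.per_disease_ap):
            row = [d, str(self.per_disease_gtp[d]), f"{self.per_disease_ap[d]:.6f}"]
            row += [f"{self.per_disease_recall[d][k]:.6f}" for k in self.k_grid]
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"


def evaluate_ranking(
    model: EmbeddingSet,
    kg: KnowledgeGraph,
    test_triples: Sequence[Triple],
    relation: str,
    filter_triples: Sequence[Triple] = (),
    k_grid: Sequence[int] = (50, 100, 200, 500),
    ap_cutoff: int | None = None,
    diseases: Iterable[str] | None = None,
) -> EvalReport:
    """Filtered per-disease ranking over all candidate objects of the
    relation's object type.

    Diseases with zero test positives are excluded from the averages
    (recall is undefined there); the count of such exclusions is reported.
    """
    rel = kg.relation_types[relation]
    pool = kg.entities_of_type(rel.object_type)

    positives: dict[str, set[str]] = {}
    for t in test_triples:
        if t.relation == relation:
            positives.setdefault(t.subject, set()).add(t.object)
    subjects = sorted(positives) if diseases is None else sorted(set(diseases))
    skipped = sum(1 for s in subjects if not positives.get(s))
    subjects = [s for s in subjects if positives.get(s)]
    if not subjects:
        raise ValueError("no diseases with test positives to evaluate")

    per_ap: dict[str, float] = {}
    per_recall: dict[str, dict[int, float]] = {}
    per_gtp: dict[str, int] = {}
    for subj in subjects:
        ranked = rank_objects(model, subj, relation, pool, filter_triples)
        pos = positives[subj] - ranked.filtered_out
        if not pos:
            skipped += 1
            continue
        per_ap[subj] = average_precision(ranked, pos, ap_cutoff)
        per_recall[subj] = {k: recall_at_k(ranked, pos, k) for k in k_grid}
        per_gtp[subj] = len(pos)

    if not per_ap:
        raise ValueError("all diseases' positives were filtered out")
    agg_recall = {
        k: float(np.mean([per_recall[d][k] for d in per_ap])) for k in k_grid
    }
    return EvalReport(
        per_disease_ap=per_ap,
        per_disease_recall=per_recall,
        per_disease_gtp=per_gtp,
        aggregate_map=mean_average_precision(per_ap),
        aggregate_recall=agg_recall,
        k_grid=tuple(k_grid),
        n_diseases=len(per_ap),
        n_skipped_no_positives=skipped,
        ap_cutoff=ap_cutoff,
    )


# -- score-distribution comparison ----------------------------------------


@dataclass
class MwwResult:
    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    alpha_corrected: float
    significant: bool


def compare_score_distributions(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    n_comparisons: int = 1,
    alpha: float = 0.05,
) -> MwwResult:
    """Two-sided Mann-Whitney-Wilcoxon test with Bonferroni correction.

    ``alpha_corrected = alpha / n_comparisons`` (e.g. 0.05/3 ≈ 0.0167 for a
    family of three comparisons).  Medians of both samples are reported
    alongside U and p.  The exact null distribution is used for small
    samples without ties, the normal approximation otherwise.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    alpha_corrected = alpha / n_comparisons
    return MwwResult(
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        alpha_corrected=alpha_corrected,
        significant=bool(res.pvalue < alpha_corrected),
    )
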