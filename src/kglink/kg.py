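"""Typed knowledge-graph data model, edge-list I/O, benchmark splits, and
clinical-phase outcome labeling.

A knowledge graph here is a set of typed entities (genes/proteins, diseases,
biological processes, pathways, compounds by default) connected by directed,
labeled relations.  A fact is a ``(subject, relation, object)`` triple,
optionally tagged with the calendar year it first surfaced in the literature.
Facts absent from the graph are treated as false (closed-world assumption),
which is what makes link prediction on such graphs a positive-unlabelled
problem.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field, replace
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default entity-type vocabulary of the heterogeneous biomedical graph.
DEFAULT_ENTITY_TYPES = ("GeneProtein", "Disease", "GOProcess", "Pathway", "Compound")


class SchemaError(ValueError):
    """A triple or entity violates the graph's declared schema."""


class EdgeListParseError(ValueError):
    """A malformed row in an edge-list or dictionary file."""


@dataclass(frozen=True)
class Entity:
    id: str
    type_label: str


@dataclass(frozen=True)
class RelationType:
    """A directed, labeled relation with a fixed (subject, object) type signature."""

    name: str
    subject_type: str
    object_type: str
    directed: bool = True


@dataclass(frozen=True, order=True)
class Triple:
    """One directed fact ``(subject, relation, object)``, optionally year-tagged."""

    subject: str
    relation: str
    object: str
    year: int | None = None

    def key(self) -> tuple[str, str, str]:
        return (self.subject, self.relation, self.object)


def assign_edge_year(mention_years: Sequence[int]) -> int:
    """Year tag for an edge given the publication years of its mentions.

    The first literature mention of a relationship is taken as the moment the
    fact surfaced, so the edge is tagged with the earliest year of the list.
    """
    if len(mention_years) == 0:
        raise ValueError("cannot time-tag an edge with no mention years")
    for y in mention_years:
        if not (1000 <= int(y) <= 9999):
            raise ValueError(f"not a 4-digit calendar year: {y!r}")
    return int(min(mention_years))


class KnowledgeGraph:
    """Typed entities plus a deduplicated set of directed, labeled triples.

    Duplicate ``(s, r, o)`` triples collapse to one; when duplicates carry
    conflicting year tags the minimum (earliest mention) is kept.  Every
    triple must reference declared entities and satisfy its relation's type
    signature.
    """

    def __init__(
        self,
        entities: Iterable[Entity],
        relation_types: Iterable[RelationType],
        triples: Iterable[Triple] = (),
    ) -> None:
        self.entity_types: dict[str, str] = {}
        for e in entities:
            if e.id in self.entity_types:
                raise SchemaError(f"duplicate entity id: {e.id!r}")
            self.entity_types[e.id] = e.type_label
        self.relation_types: dict[str, RelationType] = {}
        for r in relation_types:
            if r.name in self.relation_types:
                raise SchemaError(f"duplicate relation name: {r.name!r}")
            self.relation_types[r.name] = r

        self._triples: dict[tuple[str, str, str], Triple] = {}
        n_dup = 0
        for t in triples:
            self._validate_triple(t)
            prev = self._triples.get(t.key())
            if prev is None:
                self._triples[t.key()] = t
            else:
                n_dup += 1
                years = [y for y in (prev.year, t.year) if y is not None]
                year = min(years) if years else None
                self._triples[t.key()] = replace(prev, year=year)
        if n_dup:
            logger.info("deduplicated %d duplicate triples", n_dup)

    # -- basic views ------------------------------------------------------

    @property
    def triples(self) -> list[Triple]:
        return list(self._triples.values())

    @property
    def n_entities(self) -> int:
        return len(self.entity_types)

    @property
    def n_relations(self) -> int:
        return len(self.relation_types)

    def __len__(self) -> int:
        return len(self._triples)

    def __contains__(self, key: tuple[str, str, str] | Triple) -> bool:
        if isinstance(key, Triple):
            key = key.key()
        return key in self._triples

    def entities_of_type(self, type_label: str) -> list[str]:
        """Sorted ids of all entities with the given type label."""
        return sorted(i for i, t in self.entity_types.items() if t == type_label)

    def triples_of_relation(self, relation: str) -> list[Triple]:
        if relation not in self.relation_types:
            raise SchemaError(f"unknown relation: {relation!r}")
        return [t for t in self._triples.values() if t.relation == relation]

    def _validate_triple(self, t: Triple) -> None:
        rel = self.relation_types.get(t.relation)
        if rel is None:
            raise SchemaError(f"triple references undeclared relation: {t}")
        for endpoint, want in ((t.subject, rel.subject_type), (t.object, rel.object_type)):
            have = self.entity_types.get(endpoint)
            if have is None:
                raise SchemaError(f"triple references undeclared entity {endpoint!r}: {t}")
            if have != want:
                raise SchemaError(
                    f"type signature violation for relation {rel.name!r}: "
                    f"{endpoint!r} is {have}, expected {want} ({t})"
                )
        if t.year is not None and not (1000 <= t.year <= 9999):
            raise SchemaError(f"year must be a 4-digit integer: {t}")


# -- edge-list I/O --------------------------------------------------------
#
# Edge-list TSV: subject_id <TAB> relation <TAB> object_id <TAB> year
# (year column optional, empty string when absent).  Entity dictionary TSV:
# entity_id <TAB> type_label.  Lines starting with '#' are comments.  Both
# files round-trip bit-exactly through write_edge_list/write_entity_dict.


def read_entity_dict(path: str | Path) -> list[Entity]:
    entities = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise EdgeListParseError(f"{path}:{lineno}: expected 'id<TAB>type_label', got {line!r}")
            entities.append(Entity(parts[0], parts[1]))
    return entities


def read_edge_list(
    path: str | Path,
    entity_dict: str | Path,
    relation_types: Iterable[RelationType] | None = None,
) -> KnowledgeGraph:
    """Load a knowledge graph from an edge-list TSV plus an entity dictionary.

    If ``relation_types`` is not given, each relation's type signature is
    inferred from its first triple and every later triple is validated
    against it.  Unknown entities and signature violations are rejected.
    """
    entities = read_entity_dict(entity_dict)
    entity_types = {e.id: e.type_label for e in entities}

    triples: list[Triple] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 3:
                parts.append("")
            if len(parts) != 4 or not all(parts[:3]):
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 'subject<TAB>relation<TAB>object[<TAB>year]', got {line!r}"
                )
            s, r, o, ystr = parts
            if ystr == "":
                year = None
            else:
                try:
                    year = int(ystr)
                except ValueError:
                    raise EdgeListParseError(f"{path}:{lineno}: bad year {ystr!r}") from None
            triples.append(Triple(s, r, o, year))

    if relation_types is None:
        seen: dict[str, RelationType] = {}
        for t in triples:
            if t.relation not in seen:
                st = entity_types.get(t.subject)
                ot = entity_types.get(t.object)
                if st is None or ot is None:
                    raise SchemaError(f"triple references undeclared entity: {t}")
                seen[t.relation] = RelationType(t.relation, st, ot)
        relation_types = seen.values()

    return KnowledgeGraph(entities, relation_types, triples)


def write_entity_dict(kg: KnowledgeGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# entity_id\ttype_label\n")
        for eid in sorted(kg.entity_types):
            fh.write(f"{eid}\t{kg.entity_types[eid]}\n")


def write_edge_list(kg: KnowledgeGraph, path: str | Path) -> None:
    """Write triples as TSV; ``read_edge_list`` round-trips the graph exactly."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# subject_id\trelation\tobject_id\tyear\n")
        for t in sorted(kg.triples):
            y = "" if t.year is None else str(t.year)
            fh.write(f"{t.subject}\t{t.relation}\t{t.object}\t{y}\n")


# -- benchmark splits -----------------------------------------------------


@dataclass
class DataSplit:
    """Disjoint train/valid/test triple sets.

    Validation and test contain only benchmark-relation triples; every
    non-benchmark triple stays in train, so the model always sees the full
    heterogeneous graph during training.
    """

    train: list[Triple]
    valid: list[Triple]
    test: list[Triple]
    benchmark_relation: str
    provenance: dict = field(default_factory=dict)

    def check_disjoint(self) -> None:
        a = {t.key() for t in self.train}
        b = {t.key() for t in self.valid}
        c = {t.key() for t in self.test}
        if a & b or b & c or a & c:
            raise ValueError("split sets are not pairwise disjoint")


def split_random(
    kg: KnowledgeGraph,
    benchmark_relation: str,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> DataSplit:
    """Random split of the benchmark relation by edge count.

    Benchmark triples are partitioned train/valid/test at the given
    fractions (the reference protocol: 60%-20%-20%, or 60%-40%-0% when only a
    train and test set are used).  Valid and test sizes are
    ``floor(fraction * count)``; train takes the remainder, so train is
    never starved by rounding.  All non-benchmark triples go to train.
    """
    if benchmark_relation not in kg.relation_types:
        raise SchemaError(f"benchmark relation {benchmark_relation!r} not in graph")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    bench = sorted(kg.triples_of_relation(benchmark_relation))
    rest = [t for t in kg.triples if t.relation != benchmark_relation]

    n = len(bench)
    n_valid = int(np.floor(fractions[1] * n))
    n_test = int(np.floor(fractions[2] * n))
    if n_valid + n_test > n:
        raise ValueError(f"only {n} benchmark triples for requested fractions {fractions}")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    valid = [bench[i] for i in order[:n_valid]]
    test = [bench[i] for i in order[n_valid : n_valid + n_test]]
    train = rest + [bench[i] for i in order[n_valid + n_test :]]
    return DataSplit(
        train,
        valid,
        test,
        benchmark_relation,
        provenance={"method": "random", "fractions": tuple(fractions), "seed": seed},
    )


def split_time(
    kg: KnowledgeGraph,
    benchmark_relation: str,
    year_threshold: int,
    window_years: int | None = None,
    relations_with_years: Iterable[str] | None = None,
    untagged: str = "train",
) -> DataSplit:
    """Temporal (time-sliced) train/test split.

    Training keeps every year-tagged triple with ``year <= year_threshold``;
    the test set holds benchmark triples with
    ``year_threshold < year <= year_threshold + window_years`` when a window
    is given (the time-bound protocol: threshold 2010 with a 5-year window
    tests on 2011-2015 inclusive), or every benchmark triple beyond the
    threshold otherwise.  Triples of relations outside
    ``relations_with_years`` carry no usable year and go to train
    (``untagged="train"``) or are dropped (``untagged="drop"``).  The
    validation set is empty: time-sliced evaluation is train/test only.
    """
    if untagged not in ("train", "drop"):
        raise ValueError(f"untagged must be 'train' or 'drop', got {untagged!r}")
    if benchmark_relation not in kg.relation_types:
        raise SchemaError(f"benchmark relation {benchmark_relation!r} not in graph")
    tagged_rels = set(relations_with_years) if relations_with_years is not None else {benchmark_relation}
    if benchmark_relation not in tagged_rels:
        raise ValueError("the benchmark relation must be year-tagged for a time split")

    missing = [t for t in kg.triples if t.relation in tagged_rels and t.year is None]
    if missing:
        raise SchemaError(
            f"{len(missing)} triples of year-tagged relations lack year tags, e.g. {missing[:3]}"
        )

    train: list[Triple] = []
    test: list[Triple] = []
    for t in kg.triples:
        if t.relation not in tagged_rels:
            if untagged == "train":
                train.append(t)
            continue
        if t.year <= year_threshold:
            train.append(t)
        elif t.relation == benchmark_relation:
            if window_years is None or t.year <= year_threshold + window_years:
                test.append(t)
    return DataSplit(
        train,
        [],
        test,
        benchmark_relation,
        provenance={
            "method": "time",
            "year_threshold": year_threshold,
            "window_years": window_years,
            "relations_with_years": sorted(tagged_rels),
            "untagged": untagged,
        },
    )


def filter_benchmark_diseases(
    kg: KnowledgeGraph, benchmark_relation: str, min_degree: int = 30
) -> set[str]:
    """Diseases with at least ``min_degree`` distinct benchmark gene neighbors.

    Low-degree diseases are typically subtypes whose siblings remain in
    training; evaluating on them inflates performance through information
    leakage, so the benchmark keeps only diseases with a gene-neighbor
    degree of ``min_degree`` (30 in the reference protocol) or more.
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    neighbors: dict[str, set[str]] = defaultdict(set)
    for t in kg.triples_of_relation(benchmark_relation):
        neighbors[t.subject].add(t.object)
    rel = kg.relation_types[benchmark_relation]
    all_subjects = kg.entities_of_type(rel.subject_type)
    return {d for d in all_subjects if len(neighbors.get(d, ())) >= min_degree}


# -- clinical-phase outcome labeling --------------------------------------


class Phase(IntEnum):
    """Ordered clinical development phases (highest reached by any compound)."""

    DISCOVERY = 0
    PHASE_I = 1
    PHASE_II = 2
    PHASE_III = 3
    PREREGISTRATION_OR_HIGHER = 4


_PHASE_ALIASES: Mapping[str, Phase] = {
    "discovery": Phase.DISCOVERY,
    "phase i": Phase.PHASE_I,
    "phase_i": Phase.PHASE_I,
    "phase ii": Phase.PHASE_II,
    "phase_ii": Phase.PHASE_II,
    "phase iii": Phase.PHASE_III,
    "phase_iii": Phase.PHASE_III,
    "pre-registration or higher": Phase.PREREGISTRATION_OR_HIGHER,
    "preregistration": Phase.PREREGISTRATION_OR_HIGHER,
    "preregistration_or_higher": Phase.PREREGISTRATION_OR_HIGHER,
}


def parse_phase(label: str) -> Phase:
    try:
        return _PHASE_ALIASES[label.strip().lower()]
    except KeyError:
        raise ValueError(f"unknown clinical phase label: {label!r}") from None


@dataclass(frozen=True)
class PhaseRecord:
    """Outcome of one compound's program for a gene-disease pair.

    ``discontinued`` marks a program stopped at ``phase`` (e.g. "Phase II
    discontinued"), which is distinct from an ongoing program at the same
    phase.  A bare "Discontinued" entry with no phase information maps to
    ``Phase.DISCOVERY`` with ``discontinued=True``.
    """

    gene: str
    disease: str
    compound: str
    phase: Phase
    discontinued: bool = False


def map_phase_to_outcome(records: Sequence[PhaseRecord]) -> str:
    """Aggregate per-compound phase records for one gene-disease pair.

    The pair is assigned the highest phase reached by any compound.  It is a
    clinical-trial *failure* iff that aggregate is a Phase II or Phase III
    discontinuation, a *success* iff the aggregate reaches Pre-registration
    or higher, and *unassigned* otherwise (Discovery, Phase I, and early
    discontinuations are ambiguous: programs stop for many reasons besides
    efficacy).  When several compounds tie at the highest phase, the pair
    counts as discontinued only if every one of them was discontinued — an
    ongoing program at that phase could still succeed.
    """
    if len(records) == 0:
        raise ValueError("no phase records for this gene-disease pair")
    pairs = {(r.gene, r.disease) for r in records}
    if len(pairs) != 1:
        raise ValueError(f"records span multiple gene-disease pairs: {sorted(pairs)}")

    top = max(r.phase for r in records)
    at_top = [r for r in records if r.phase == top]
    discontinued = all(r.discontinued for r in at_top)
    if top >= Phase.PREREGISTRATION_OR_HIGHER:
        return "success"
    if top in (Phase.PHASE_II, Phase.PHASE_III) and discontinued:
        return "failure"
    return "unassigned"


def read_phase_table(path: str | Path) -> dict[tuple[str, str], list[PhaseRecord]]:
    """Read a phase-record TSV (gene, disease, compound, phase, discontinued_flag)."""
    records: dict[tuple[str, str], list[PhaseRecord]] = defaultdict(list)
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected 5 tab-separated fields, got {line!r}"
                )
            gene, disease, compound, phase, disc = parts
            rec = PhaseRecord(gene, disease, compound, parse_phase(phase), disc.lower() in ("1", "true", "yes"))
            records[(gene, disease)].append(rec)
    return dict(records)
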