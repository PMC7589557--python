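"""Trilinear scoring functions (decoders) for knowledge-graph link prediction.

Each decoder maps the latent embeddings of a ``(subject, relation, object)``
triple to a real-valued, un-normalized likelihood φ(s, r, o).  Four standard
tensor-factorization decoders are provided:

* ``complex`` — the real part of the trilinear product of complex embeddings,
  ``φ = Re(Σ_j l_rj · e_sj · conj(e_oj))``.  Expanding real (a) and
  imaginary (b) parts gives four real trilinear terms,
  ``⟨sa,ra,oa⟩ + ⟨sb,ra,ob⟩ + ⟨sa,rb,ob⟩ − ⟨sb,rb,oa⟩``, so the model can be
  trained as six real embedding matrices.  The conjugation of the object
  makes the score asymmetric, letting one relation embed directed edges.
* ``distmult`` — the plain real trilinear product ``Σ_j l_rj e_sj e_oj``;
  symmetric in subject and object, hence a baseline.
* ``cp`` — canonical polyadic decomposition: the same trilinear product but
  with *separate* subject-role and object-role entity tables, which restores
  asymmetry.
* ``hole`` — holographic embeddings: the relation vector dotted with the
  circular correlation ``[s ⋆ o]_k = Σ_i s_i o_{(i+k) mod d}`` of subject and
  object; asymmetric because circular correlation is not commutative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DECODER_NAMES = ("complex", "distmult", "cp", "hole")


def _check_dims(*vecs: np.ndarray) -> int:
    d = None
    for v in vecs:
        v = np.asarray(v)
        if v.ndim != 1:
            raise ValueError(f"expected 1-D vectors, got shape {v.shape}")
        if d is None:
            d = v.shape[0]
        elif v.shape[0] != d:
            raise ValueError(f"dimension mismatch: {d} vs {v.shape[0]}")
    return d


def complex_score(
    e_s_real: np.ndarray,
    e_s_imag: np.ndarray,
    l_r_real: np.ndarray,
    l_r_imag: np.ndarray,
    e_o_real: np.ndarray,
    e_o_imag: np.ndarray,
) -> float:
    """φ(s,r,o) = ⟨sa,ra,oa⟩ + ⟨sb,ra,ob⟩ + ⟨sa,rb,ob⟩ − ⟨sb,rb,oa⟩.

    Equivalently ``Re(Σ_j l_rj e_sj conj(e_oj))`` with ``e = a + i·b``.
    """
    _check_dims(e_s_real, e_s_imag, l_r_real, l_r_imag, e_o_real, e_o_imag)
    sa, sb = np.asarray(e_s_real, float), np.asarray(e_s_imag, float)
    ra, rb = np.asarray(l_r_real, float), np.asarray(l_r_imag, float)
    oa, ob = np.asarray(e_o_real, float), np.asarray(e_o_imag, float)
    # entity vectors multiplied first so the zero-imaginary case reduces to
    # distmult_score bit-exactly
    return float(
        np.sum((sa * oa) * ra) + np.sum((sb * ob) * ra) + np.sum((sa * ob) * rb) - np.sum((sb * oa) * rb)
    )


def distmult_score(e_s: np.ndarray, l_r: np.ndarray, e_o: np.ndarray) -> float:
    """Symmetric real trilinear product Σ_j l_rj e_sj e_oj.

    The entity vectors are multiplied first, which makes the subject-object
    symmetry bit-exact (elementwise multiplication commutes exactly).
    """
    _check_dims(e_s, l_r, e_o)
    return float(np.sum((np.asarray(e_s, float) * np.asarray(e_o, float)) * np.asarray(l_r, float)))


def cp_score(u_s: np.ndarray, v_r: np.ndarray, w_o: np.ndarray) -> float:
    """Canonical polyadic score: trilinear product with distinct subject (u)
    and object (w) entity tables."""
    _check_dims(u_s, v_r, w_o)
    return float(np.sum(np.asarray(u_s, float) * np.asarray(v_r, float) * np.asarray(w_o, float)))


def circular_correlation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """[x ⋆ y]_k = Σ_i x_i y_{(i+k) mod d}, computed directly in O(d²)."""
    d = _check_dims(x, y)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    out = np.empty(d)
    for k in range(d):
        out[k] = np.sum(x * np.roll(y, -k))
    return out


def circular_correlation_fft(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Spectral fast path: x ⋆ y = ifft(conj(fft(x)) · fft(y))."""
    _check_dims(x, y)
    return np.real(np.fft.ifft(np.conj(np.fft.fft(x)) * np.fft.fft(y)))


def hole_score(e_s: np.ndarray, l_r: np.ndarray, e_o: np.ndarray, fast: bool = False) -> float:
    """Holographic score: l_r dotted with the circular correlation of s and o."""
    _check_dims(e_s, l_r, e_o)
    corr = circular_correlation_fft(e_s, e_o) if fast else circular_correlation(e_s, e_o)
    return float(np.dot(np.asarray(l_r, float), corr))


@dataclass
class EmbeddingSet:
    """Learned model state: entity and relation embedding matrices.

    Layout depends on the decoder:

    * ``complex`` uses all four core matrices (real + imaginary parts).
    * ``distmult`` and ``hole`` use only the real matrices; imaginary parts
      are kept as all-zero arrays so the container shape is uniform.
    * ``cp`` additionally carries separate object-role entity tables
      (``object_real``); subject-role vectors live in ``entity_real``.

    ``entity_ids`` / ``relation_names`` optionally map matrix rows back to
    graph identifiers (sorted order by convention) so that ranking can speak
    in entity ids.
    """

    entity_real: np.ndarray
    entity_imag: np.ndarray
    relation_real: np.ndarray
    relation_imag: np.ndarray
    decoder_name: str
    object_real: np.ndarray | None = None
    object_imag: np.ndarray | None = None
    entity_ids: list[str] | None = None
    relation_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.decoder_name not in DECODER_NAMES:
            raise ValueError(f"unknown decoder {self.decoder_name!r}; expected one of {DECODER_NAMES}")
        n, d = self.entity_real.shape
        k = self.relation_real.shape[0]
        for name, m, shape in (
            ("entity_imag", self.entity_imag, (n, d)),
            ("relation_real", self.relation_real, (k, d)),
            ("relation_imag", self.relation_imag, (k, d)),
        ):
            if m.shape != shape:
                raise ValueError(f"{name} has shape {m.shape}, expected {shape}")
        if self.decoder_name == "cp":
            if self.object_real is None or self.object_real.shape != (n, d):
                raise ValueError("cp decoder requires a separate object_real table of shape (n, d)")
        if self.entity_ids is not None and len(self.entity_ids) != n:
            raise ValueError("entity_ids length must equal entity count")
        if self.relation_names is not None and len(self.relation_names) != k:
            raise ValueError("relation_names length must equal relation count")

    @property
    def n(self) -> int:
        return self.entity_real.shape[0]

    @property
    def d(self) -> int:
        return self.entity_real.shape[1]

    @property
    def k(self) -> int:
        return self.relation_real.shape[0]

    # -- id <-> index -----------------------------------------------------

    def entity_index(self, entity_id: str) -> int:
        if self.entity_ids is None:
            raise ValueError("this EmbeddingSet carries no entity id mapping")
        try:
            return self._eidx[entity_id]
        except AttributeError:
            self._eidx = {e: i for i, e in enumerate(self.entity_ids)}
            return self._eidx[entity_id]

    def relation_index(self, relation_name: str) -> int:
        if self.relation_names is None:
            raise ValueError("this EmbeddingSet carries no relation name mapping")
        return self.relation_names.index(relation_name)

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        """Serialize to an NPZ container with named arrays."""
        arrays = {
            "entity_real": self.entity_real,
            "entity_imag": self.entity_imag,
            "relation_real": self.relation_real,
            "relation_imag": self.relation_imag,
            "decoder_name": np.array(self.decoder_name),
        }
        if self.object_real is not None:
            arrays["object_real"] = self.object_real
        if self.object_imag is not None:
            arrays["object_imag"] = self.object_imag
        if self.entity_ids is not None:
            arrays["entity_ids"] = np.array(self.entity_ids)
        if self.relation_names is not None:
            arrays["relation_names"] = np.array(self.relation_names)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "EmbeddingSet":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                entity_real=z["entity_real"],
                entity_imag=z["entity_imag"],
                relation_real=z["relation_real"],
                relation_imag=z["relation_imag"],
                decoder_name=str(z["decoder_name"]),
                object_real=z["object_real"] if "object_real" in z else None,
                object_imag=z["object_imag"] if "object_imag" in z else None,
                entity_ids=[str(x) for x in z["entity_ids"]] if "entity_ids" in z else None,
                relation_names=[str(x) for x in z["relation_names"]] if "relation_names" in z else None,
            )


def score_triples(
    model: EmbeddingSet,
    s_idx: np.ndarray,
    r_idx: np.ndarray,
    o_idx: np.ndarray,
    *,
    entity_real: np.ndarray | None = None,
    entity_imag: np.ndarray | None = None,
    object_real: np.ndarray | None = None,
) -> np.ndarray:
    """Vectorized φ for aligned index arrays of triples.

    The keyword overrides let the trainer substitute dropout-masked entity
    matrices without copying the model.
    """
    s_idx = np.asarray(s_idx)
    r_idx = np.asarray(r_idx)
    o_idx = np.asarray(o_idx)
    ent_a = model.entity_real if entity_real is None else entity_real
    ent_b = model.entity_imag if entity_imag is None else entity_imag
    if np.any(s_idx < 0) or np.any(s_idx >= model.n) or np.any(o_idx < 0) or np.any(o_idx >= model.n):
        raise IndexError("entity index out of range")
    if np.any(r_idx < 0) or np.any(r_idx >= model.k):
        raise IndexError("relation index out of range")

    name = model.decoder_name
    if name == "complex":
        sa, sb = ent_a[s_idx], ent_b[s_idx]
        ra, rb = model.relation_real[r_idx], model.relation_imag[r_idx]
        oa, ob = ent_a[o_idx], ent_b[o_idx]
        return (
            np.sum((sa * oa) * ra, axis=-1)
            + np.sum((sb * ob) * ra, axis=-1)
            + np.sum((sa * ob) * rb, axis=-1)
            - np.sum((sb * oa) * rb, axis=-1)
        )
    if name == "distmult":
        return np.sum((ent_a[s_idx] * ent_a[o_idx]) * model.relation_real[r_idx], axis=-1)
    if name == "cp":
        obj = model.object_real if object_real is None else object_real
        return np.sum(ent_a[s_idx] * model.relation_real[r_idx] * obj[o_idx], axis=-1)
    if name == "hole":
        # circular correlation via FFT, batched over triples
        s = ent_a[s_idx]
        o = ent_a[o_idx]
        corr = np.real(np.fft.ifft(np.conj(np.fft.fft(s, axis=-1)) * np.fft.fft(o, axis=-1), axis=-1))
        return np.sum(model.relation_real[r_idx] * corr, axis=-1)
    raise ValueError(f"unknown decoder {name!r}")


def score_candidates(
    model: EmbeddingSet,
    subject: int,
    relation: int,
    candidates: np.ndarray,
) -> np.ndarray:
    """Scores for (subject, relation, c) over a candidate object list, order
    preserved.  This is the batched prediction path used to rank all genes
    for one disease."""
    candidates = np.asarray(candidates)
    if candidates.size == 0:
        raise ValueError("candidate list is empty")
    s_idx = np.full(candidates.shape, subject, dtype=np.intp)
    r_idx = np.full(candidates.shape, relation, dtype=np.intp)
    return score_triples(model, s_idx, r_idx, candidates)
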