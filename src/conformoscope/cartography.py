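"""Structural cartography of a conformer ensemble.

An all-against-all similarity matrix over an ensemble of carrier models is
computed with a distance-matrix ("elastic") score: for every mapped residue
pair the score rewards agreement of the two intramolecular Calpha distance
matrices, weighted by a Gaussian envelope that de-emphasises long-range
pairs,

    S = sum_{i<j} (theta - |d_ij^A - d_ij^B| / d*_ij) * exp(-(d*_ij / L)^2),

with d*_ij the mean of the two distances, theta = 0.2 and L = 20 A by
default; the i = j terms contribute theta each. Because the score is
computed over a sequence-alignment correspondence (all compared proteins
are homologous conformers), no structural alignment search is needed.

The matrix is embedded in 2-D by correspondence analysis, each model is
assigned an outward-open / inward-open / intermediate state by comparing
its similarity to the two designated anchor structures, and the ensemble is
ordered along the OO -> IO transition by projecting embeddings onto the
anchor-to-anchor chord.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist

from .structure_io import StructureModel
from .superpose import ResidueMap, map_residues


@dataclasses.dataclass(frozen=True)
class ElasticScoreParams:
    theta: float = 0.2
    envelope_scale: float = 20.0
    max_pair_distance: Optional[float] = None

    def __post_init__(self) -> None:
        if self.theta <= 0 or self.envelope_scale <= 0:
            raise ValueError("theta and envelope_scale must be positive")


def elastic_similarity(
    a: StructureModel,
    b: StructureModel,
    residue_map: Optional[ResidueMap] = None,
    params: ElasticScoreParams = ElasticScoreParams(),
) -> float:
    """Elastic distance-matrix similarity over the mapped residues."""
    if residue_map is None:
        residue_map = map_residues(a, b)
    if len(residue_map) < 3:
        raise ValueError("need at least 3 mapped residue pairs")
    ca = a.coords[residue_map.a_indices]
    cb = b.coords[residue_map.b_indices]
    da = pdist(ca)
    db = pdist(cb)
    dstar = 0.5 * (da + db)
    keep = dstar > 0
    if params.max_pair_distance is not None:
        keep &= dstar <= params.max_pair_distance
    da, db, dstar = da[keep], db[keep], dstar[keep]
    weights = np.exp(-((dstar / params.envelope_scale) ** 2))
    terms = (params.theta - np.abs(da - db) / dstar) * weights
    return float(terms.sum() + params.theta * len(residue_map))


def self_similarity(n_mapped: int, coords: np.ndarray,
                    params: ElasticScoreParams = ElasticScoreParams()) -> float:
    """Maximum attainable score for a model of this size/geometry."""
    d = pdist(np.asarray(coords))
    d = d[d > 0]
    if params.max_pair_distance is not None:
        d = d[d <= params.max_pair_distance]
    w = np.exp(-((d / params.envelope_scale) ** 2))
    return float(params.theta * (w.sum() + n_mapped))


@dataclasses.dataclass
class ConformerMap:
    """All-against-all similarities plus embedding, state calls and ordering."""

    model_ids: list[str]
    similarity: np.ndarray
    anchors: tuple[str, str]  # (oo_id, io_id)
    embedding: Optional[np.ndarray] = None
    state_calls: dict[str, tuple[str, float]] = dataclasses.field(default_factory=dict)
    transition_order: list[str] = dataclasses.field(default_factory=list)

    def index_of(self, model_id: str) -> int:
        try:
            return self.model_ids.index(model_id)
        except ValueError:
            raise KeyError(f"model {model_id!r} not in map") from None

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("model_id\taxis1\taxis2\tstate\tmargin\n")
            for i, mid in enumerate(self.model_ids):
                e1, e2 = (self.embedding[i] if self.embedding is not None else (float("nan"),) * 2)
                state, margin = self.state_calls.get(mid, ("", float("nan")))
                fh.write(f"{mid}\t{e1:.5f}\t{e2:.5f}\t{state}\t{margin:.4f}\n")

    def similarity_to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("model_id\t" + "\t".join(self.model_ids) + "\n")
            for mid, row in zip(self.model_ids, self.similarity):
                fh.write(mid + "\t" + "\t".join(f"{v:.5f}" for v in row) + "\n")


def aaa_matrix(
    models: Sequence[StructureModel],
    anchors: tuple[str, str],
    params: ElasticScoreParams = ElasticScoreParams(),
    size_bins: int = 1,
) -> ConformerMap:
    """All-against-all normalised elastic similarities.

    Raw scores grow with the number of mapped residues, so they are
    standardised Z-like, ``(S - m(L)) / s(L)``, with the mean and spread
    fitted on the input pool itself, binned by aligned length when the pool
    spans a range of sizes (``size_bins > 1``).
    """
    if len(models) < 3:
        raise ValueError("need at least 3 models")
    ids = [m.model_id for m in models]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate model ids")
    for anchor in anchors:
        if anchor not in ids:
            raise ValueError(f"anchor {anchor!r} not among the models")
    n = len(models)
    raw = np.zeros((n, n))
    sizes = np.zeros((n, n))
    for i in range(n):
        raw[i, i] = self_similarity(len(models[i]), models[i].coords, params)
        sizes[i, i] = len(models[i])
        for j in range(i + 1, n):
            rmap = map_residues(models[i], models[j])
            if len(rmap) < 3:
                raise ValueError(f"models {ids[i]!r} and {ids[j]!r} share <3 mapped residues")
            raw[i, j] = raw[j, i] = elastic_similarity(models[i], models[j], rmap, params)
            sizes[i, j] = sizes[j, i] = len(rmap)

    off = ~np.eye(n, dtype=bool)
    if size_bins <= 1:
        m, s = raw[off].mean(), raw[off].std() or 1.0
        norm = (raw - m) / s
    else:
        edges = np.quantile(sizes[off], np.linspace(0, 1, size_bins + 1))
        norm = np.zeros_like(raw)
        which = np.clip(np.searchsorted(edges, sizes, side="right") - 1, 0, size_bins - 1)
        for b in range(size_bins):
            mask = which == b
            pool = raw[mask & off]
            if pool.size == 0:
                continue
            m, s = pool.mean(), pool.std() or 1.0
            norm[mask] = (raw[mask] - m) / s
    return ConformerMap(model_ids=list(ids), similarity=norm, anchors=anchors)


def _canonical_signs(coords: np.ndarray) -> np.ndarray:
    out = coords.copy()
    for k in range(out.shape[1]):
        col = out[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            out[:, k] = -col
    return out


def correspondence_embed(cmap: ConformerMap, n_axes: int = 2) -> np.ndarray:
    """2-D correspondence analysis of the min-shifted similarity matrix.

    Rows and columns are the same models, so the row principal coordinates
    are used as the embedding; axes are sign-canonicalised (the
    largest-magnitude coordinate on each axis is positive).
    """
    sim = cmap.similarity - cmap.similarity.min()
    total = sim.sum()
    if total <= 0:
        raise ValueError("similarity matrix is degenerate after min-shift")
    p = sim / total
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if np.any(r <= 0) or np.any(c <= 0):
        raise ValueError("zero-mass row/column in correspondence analysis")
    expected = np.outer(r, c)
    residuals = (p - expected) / np.sqrt(expected)
    u, svals, _ = np.linalg.svd(residuals)
    rank = int((svals > 1e-12).sum())
    if rank < n_axes:
        raise ValueError(
            f"similarity matrix has rank {rank} < {n_axes} after centering; "
            "consider classical MDS on the dissimilarities instead"
        )
    coords = (u[:, :n_axes] * svals[:n_axes]) / np.sqrt(r)[:, None]
    embedding = _canonical_signs(coords)
    cmap.embedding = embedding
    return embedding


def classical_mds(dissimilarity: np.ndarray, n_axes: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS; used as an independent cross-check."""
    d2 = np.asarray(dissimilarity, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:n_axes]
    coords = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return _canonical_signs(coords)


def assign_states(cmap: ConformerMap, delta: float = 1.0 / 3.0) -> dict[str, tuple[str, float]]:
    """Call OO / IO / intermediate per model from anchor similarities.

    The margin is ``(sim_to_OO - sim_to_IO) / (sim_to_OO + sim_to_IO)``
    after shifting similarities so that the smallest entry of the two
    anchor columns is zero (anchoring the calibration to the OO/IO pair
    itself keeps margins stable when noisy conformer pairs dominate the
    global matrix minimum). Calls are OO above ``+delta``, IO below
    ``-delta`` and intermediate within the band. Because the margin is
    close to affine in the transition coordinate (1 at the OO anchor, -1 at
    the IO anchor), the default band of one third makes the intermediate
    call coincide with the conventional thirds partition of the transition.
    """
    oo_id, io_id = cmap.anchors
    i_oo, i_io = cmap.index_of(oo_id), cmap.index_of(io_id)
    sim = cmap.similarity - cmap.similarity[:, [i_oo, i_io]].min()
    calls: dict[str, tuple[str, float]] = {}
    for i, mid in enumerate(cmap.model_ids):
        s_oo, s_io = sim[i, i_oo], sim[i, i_io]
        denom = s_oo + s_io
        margin = float((s_oo - s_io) / denom) if denom > 0 else 0.0
        if margin >= delta:
            state = "OO"
        elif margin <= -delta:
            state = "IO"
        else:
            state = "intermediate"
        calls[mid] = (state, margin)
    cmap.state_calls = calls
    return calls


def order_transition(cmap: ConformerMap) -> list[str]:
    """Order models along the OO -> IO chord of the embedding."""
    if cmap.embedding is None:
        correspondence_embed(cmap)
    if not cmap.state_calls:
        assign_states(cmap)
    oo_id, io_id = cmap.anchors
    e = cmap.embedding
    e_oo = e[cmap.index_of(oo_id)]
    e_io = e[cmap.index_of(io_id)]
    chord = e_io - e_oo
    norm2 = float(chord @ chord)
    if norm2 == 0:
        raise ValueError("anchors coincide in embedding space")
    sim = cmap.similarity - cmap.similarity.min()
    i_oo = cmap.index_of(oo_id)
    proj = ((e - e_oo) @ chord) / norm2
    order = sorted(
        range(len(cmap.model_ids)),
        key=lambda i: (round(float(proj[i]), 12), -sim[i, i_oo]),
    )
    cmap.transition_order = [cmap.model_ids[i] for i in order]
    return cmap.transition_order


def cartography(
    models: Sequence[StructureModel],
    anchors: tuple[str, str],
    params: ElasticScoreParams = ElasticScoreParams(),
    delta: float = 1.0 / 3.0,
) -> ConformerMap:
    """Full pipeline: matrix -> embedding -> state calls -> ordering."""
    cmap = aaa_matrix(models, anchors, params)
    correspondence_embed(cmap)
    assign_states(cmap, delta)
    order_transition(cmap)
    return cmap
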