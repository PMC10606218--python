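"""Synthetic rocking-bundle ensembles, mutant responses and grouped MSAs.

These generators stand in for structure-prediction output and curated
alignments, producing every input the pipeline consumes together with the
ground truth needed to score it:

* :func:`generate_ensemble` builds an idealised 11-helix transmembrane
  bundle in two anchor conformations. A "mobile" helix subset is rigidly
  rotated about the bundle axis (default 25 degrees) and translated 2 A
  along it, emulating the rocking-bundle/gating motion that switches an
  alternating-access carrier between outward-open (OO) and inward-open (IO)
  states. Conformers at intermediate ``t`` are linear Cartesian
  interpolations of the anchors plus optional Gaussian coordinate noise.
  The helix layout is built so that one residue community (helices h1-h5-h8)
  is fully connected by contacts only in the OO anchor and another
  (h6-h10-h11) only in the IO anchor, mirroring the mutually exclusive
  gating communities seen in carrier ensembles.
* :func:`simulate_mutant_response` maps mutation combinations to target
  conformations through a planted response table, standing in for structure
  prediction of mutants and enabling planted cooperative, antagonistic and
  suppressor relationships.
* :func:`generate_grouped_msa` emits group-structured alignments with
  planted type-ii rate shifts and group-selective columns.

All generators are seeded and bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Optional, Sequence

import numpy as np

from .clade_sites import GroupedMsa
from .structure_io import Segment, SegmentTable, StructureModel

AA20 = "ACDEFGHIKLMNPQRSTVWY"

HELIX_RISE = 1.5        # A per residue along the axis
HELIX_RADIUS = 2.3      # A, Calpha radius of an ideal alpha helix
HELIX_TURN = 100.0      # degrees per residue

# xy placement of the 11 helix axes (Angstroms). The four mobile helices
# (the rocking bundle h1-h2-h6 plus the outer-gate helix h10) form an inner
# arc; rotating the arc by +25 degrees about the bundle axis breaks the
# h1-h5 contact (present in the starting anchor only) and forms the
# h10-h11 contact (rotated anchor only), so the communities h1-h5-h8 and
# h6-h10-h11 are each fully connected in exactly one anchor.


def _polar(angle_deg: float, radius: float) -> tuple[float, float]:
    return (radius * math.cos(math.radians(angle_deg)),
            radius * math.sin(math.radians(angle_deg)))


_MOBILE_XY = {
    "h1": _polar(90.0, 9.8),
    "h2": _polar(185.0, 12.0),
    "h6": _polar(265.0, 9.8),
    "h10": _polar(303.0, 9.8),
}
# h5 sits in the path h1 retreats from (contact only before rotation); h11
# sits where h10 arrives (contact only after); h8 packs against h5 and h6
# against h10, completing the two planted communities. The remaining
# statics are placed where the global-fit residual field is small, so that
# a profile against either anchor shows deviation concentrated in the
# mobile bundle.
_STATIC_XY = {
    "h3": (0.0, 0.0),
    "h4": _polar(45.0, 24.0),
    "h5": (6.34, 11.20),
    "h7": _polar(10.0, 19.0),
    "h8": (9.78, 17.29),
    "h9": _polar(30.0, 17.0),
    "h11": (12.86, -0.55),
}
DEFAULT_MOBILE = tuple(sorted(_MOBILE_XY, key=lambda h: int(h[1:])))


@dataclasses.dataclass(frozen=True)
class EnsembleConfig:
    """Study conditions for the rocking-bundle ensemble generator."""

    n_helices: int = 11
    helix_length: int = 20
    mobile_subset: tuple[str, ...] = DEFAULT_MOBILE
    rotation_deg: float = 25.0
    translation_z: float = 2.0
    t_values: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
    noise_sigma: float = 0.0
    seed: int = 0
    contact_cutoff: float = 5.0
    planted_oo_community: tuple[str, ...] = ("h1", "h5", "h8")
    planted_io_community: tuple[str, ...] = ("h6", "h10", "h11")

    def __post_init__(self) -> None:
        if any(t < 0 or t > 1 for t in self.t_values):
            raise ValueError("t_values must lie in [0, 1]")
        if self.rotation_deg <= 0:
            raise ValueError("rotation_deg must be positive")

    @property
    def helix_names(self) -> tuple[str, ...]:
        return tuple(f"h{i}" for i in range(1, self.n_helices + 1))


@dataclasses.dataclass
class EnsembleTruth:
    """Ensemble plus the ground truth needed to score downstream modules."""

    config: EnsembleConfig
    models: list[StructureModel]
    anchor_oo: StructureModel
    anchor_io: StructureModel
    t_of: dict[str, float]
    state_of: dict[str, str]
    template_sequence: str
    segment_table: SegmentTable
    helix_residues: dict[str, tuple[int, ...]]
    oo_only_edges: frozenset[tuple[int, int]]
    io_only_edges: frozenset[tuple[int, int]]
    # co-moving segment groups in classify_switch's (segment, part) format
    switch_signature: tuple[tuple[tuple[str, str], ...], ...]

    @property
    def oo_community_residues(self) -> frozenset[int]:
        return frozenset(itertools.chain.from_iterable(self.oo_only_edges))

    @property
    def io_community_residues(self) -> frozenset[int]:
        return frozenset(itertools.chain.from_iterable(self.io_only_edges))

    def helix_of(self, residue: int) -> Optional[str]:
        for name, residues in self.helix_residues.items():
            if residue in residues:
                return name
        return None


def state_label(t: float) -> str:
    if t < 0.33:
        return "OO"
    if t > 0.67:
        return "IO"
    return "intermediate"


def _helix_coords(xy: tuple[float, float], length: int, phase_deg: float = 0.0,
                  z0: float = 0.0) -> np.ndarray:
    i = np.arange(length)
    ang = np.radians(phase_deg + i * HELIX_TURN)
    return np.stack(
        [xy[0] + HELIX_RADIUS * np.cos(ang), xy[1] + HELIX_RADIUS * np.sin(ang), z0 + i * HELIX_RISE],
        axis=1,
    )


def _rotate_xy(xy: tuple[float, float], deg: float) -> tuple[float, float]:
    a = math.radians(deg)
    return (xy[0] * math.cos(a) - xy[1] * math.sin(a),
            xy[0] * math.sin(a) + xy[1] * math.cos(a))


def _layout(cfg: EnsembleConfig) -> dict[str, tuple[float, float]]:
    names = cfg.helix_names
    if cfg.n_helices == 11:
        pos = dict(_MOBILE_XY)
        pos.update(_STATIC_XY)
        return pos
    # generic fallback: uniform ring (planted communities not guaranteed)
    radius = 9.0 / (2 * math.sin(math.pi / cfg.n_helices))
    return {
        h: (radius * math.cos(2 * math.pi * k / cfg.n_helices),
            radius * math.sin(2 * math.pi * k / cfg.n_helices))
        for k, h in enumerate(names)
    }


def _anchor_coords(cfg: EnsembleConfig, rotated: bool) -> np.ndarray:
    pos = _layout(cfg)
    a = math.radians(cfg.rotation_deg)
    rot_z = np.array([[math.cos(a), -math.sin(a), 0.0],
                      [math.sin(a), math.cos(a), 0.0],
                      [0.0, 0.0, 1.0]])
    blocks = []
    for h in cfg.helix_names:
        block = _helix_coords(pos[h], cfg.helix_length)
        if rotated and h in cfg.mobile_subset:
            # rigid-body motion of the whole mobile subset: rotation about
            # the bundle (z) axis plus a translation along it
            block = block @ rot_z.T + np.array([0.0, 0.0, cfg.translation_z])
        blocks.append(block)
    return np.concatenate(blocks, axis=0)


def _numbering(cfg: EnsembleConfig) -> tuple[tuple[int, ...], dict[str, tuple[int, ...]]]:
    numbers: list[int] = []
    helix_residues: dict[str, tuple[int, ...]] = {}
    pitch = cfg.helix_length + 5  # 5-residue numbering gap = unmodelled loop
    for k, h in enumerate(cfg.helix_names):
        start = k * pitch + 1
        res = tuple(range(start, start + cfg.helix_length))
        helix_residues[h] = res
        numbers.extend(res)
    return tuple(numbers), helix_residues


def _segments(cfg: EnsembleConfig, helix_residues: dict[str, tuple[int, ...]]) -> SegmentTable:
    segs = []
    for h, res in helix_residues.items():
        if h in ("h1", "h6"):  # split like the pseudo-symmetric gating helices
            mid = len(res) // 2
            segs.append(Segment(f"{h}a", res[0], res[mid - 1]))
            segs.append(Segment(f"{h}b", res[mid], res[-1]))
        else:
            segs.append(Segment(h, res[0], res[-1]))
    return SegmentTable(tuple(segs))


def _contact_edges(coords: np.ndarray, numbers: Sequence[int], cutoff: float) -> frozenset:
    d = np.linalg.norm(coords[:, None] - coords[None], axis=2)
    n = len(numbers)
    edges = set()
    for i in range(n):
        for j in range(i + 1, n):
            if abs(numbers[j] - numbers[i]) >= 3 and d[i, j] <= cutoff:
                edges.add((numbers[i], numbers[j]))
    return frozenset(edges)


def _helix_pairs(edges: frozenset, helix_residues: dict) -> set[tuple[str, str]]:
    lookup = {r: h for h, res in helix_residues.items() for r in res}
    return {
        tuple(sorted((lookup[i], lookup[j]), key=lambda h: int(h[1:])))
        for i, j in edges
        if lookup[i] != lookup[j]
    }


def _connected(triple: Sequence[str], pairs: set[tuple[str, str]]) -> bool:
    members = set(triple)
    reached = {next(iter(members))}
    frontier = True
    while frontier:
        frontier = False
        for a, b in pairs:
            if a in members and b in members:
                if (a in reached) ^ (b in reached):
                    reached.update((a, b))
                    frontier = True
    return reached == members


def generate_ensemble(cfg: EnsembleConfig = EnsembleConfig()) -> EnsembleTruth:
    """Build the conformer ensemble and its ground-truth table."""
    unknown = set(cfg.mobile_subset) - set(cfg.helix_names)
    if unknown:
        raise ValueError(f"mobile_subset contains unknown helices: {sorted(unknown)}")
    rng = np.random.default_rng(cfg.seed)
    numbers, helix_residues = _numbering(cfg)
    template = "".join(rng.choice(list(AA20), size=len(numbers)))
    coords_a = _anchor_coords(cfg, rotated=False)
    coords_b = _anchor_coords(cfg, rotated=True)

    edges_a = _contact_edges(coords_a, numbers, cfg.contact_cutoff)
    edges_b = _contact_edges(coords_b, numbers, cfg.contact_cutoff)
    oo_only = frozenset(edges_a - edges_b)
    io_only = frozenset(edges_b - edges_a)
    if cfg.n_helices == 11:
        pairs_a = _helix_pairs(edges_a, helix_residues)
        pairs_b = _helix_pairs(edges_b, helix_residues)
        ok = (_connected(cfg.planted_oo_community, pairs_a)
              and not _connected(cfg.planted_oo_community, pairs_b)
              and _connected(cfg.planted_io_community, pairs_b)
              and not _connected(cfg.planted_io_community, pairs_a))
        if not ok:
            raise RuntimeError(
                "planted communities not realised by the layout; "
                "adjust rotation_deg/mobile_subset"
            )

    def build(model_id: str, t: float, sigma: float) -> StructureModel:
        coords = (1.0 - t) * coords_a + t * coords_b
        if sigma > 0:
            coords = coords + rng.normal(0.0, sigma, coords.shape)
        return StructureModel(model_id, numbers, template, coords, source_tag="synthetic")

    anchor_oo = build("anchor_OO", 0.0, 0.0)
    anchor_io = build("anchor_IO", 1.0, 0.0)
    models, t_of, state_of = [], {}, {}
    for k, t in enumerate(cfg.t_values):
        mid = f"conf_{k:03d}"
        models.append(build(mid, float(t), cfg.noise_sigma))
        t_of[mid] = float(t)
        state_of[mid] = state_label(float(t))

    # switch signature for synthetic profiles: each mobile helix is one
    # co-moving group, in the (segment, part) format of classify_switch
    mobile_segments: list[tuple[tuple[str, str], ...]] = []
    seg_names = _segments(cfg, helix_residues).names
    for h in cfg.mobile_subset:
        parts = tuple((s, "all") for s in seg_names
                      if s == h or (s[:-1] == h and s[-1] in "ab"))
        mobile_segments.append(parts)
    signature = tuple(mobile_segments[:5])

    return EnsembleTruth(
        config=cfg,
        models=models,
        anchor_oo=anchor_oo,
        anchor_io=anchor_io,
        t_of=t_of,
        state_of=state_of,
        template_sequence=template,
        segment_table=_segments(cfg, helix_residues),
        helix_residues=helix_residues,
        oo_only_edges=oo_only,
        io_only_edges=io_only,
        switch_signature=signature,
    )


# ---------------------------------------------------------------------------
# mutant response simulation


@dataclasses.dataclass(frozen=True)
class ResponseTable:
    """Planted mutation -> conformation responses.

    ``singles`` maps a mutation label to the target interpolation coordinate
    ``t`` of the predicted mutant model; ``combos`` maps label sets to a
    ``t`` that overrides the singles (this is what plants cooperative,
    antagonistic and suppressor relationships). ``native_t`` is the
    conformation of the unmutated template (1.0 = the IO anchor, matching a
    wild-type inward-open template whose mutants may switch back to OO).
    ``extra_displacement`` optionally pushes single helices radially outward
    by a fixed amount (partial, local rearrangements).
    """

    singles: Mapping[str, float] = dataclasses.field(default_factory=dict)
    combos: Mapping[frozenset, float] = dataclasses.field(default_factory=dict)
    native_t: float = 1.0
    extra_displacement: Mapping[str, Mapping[str, float]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        for t in list(self.singles.values()) + list(self.combos.values()) + [self.native_t]:
            if not 0.0 <= t <= 1.0:
                raise ValueError("response t targets must lie in [0, 1]")

    def t_target(self, labels: Sequence[str]) -> float:
        key = frozenset(labels)
        if key in self.combos:
            return float(self.combos[key])
        if len(labels) == 1 and labels[0] in self.singles:
            return float(self.singles[labels[0]])
        if all(l in self.singles for l in labels) and labels:
            # independent effects: the strongest single dominates
            deltas = [abs(self.singles[l] - self.native_t) for l in labels]
            winner = list(labels)[int(np.argmax(deltas))]
            return float(self.singles[winner])
        return float(self.native_t)


def simulate_mutant_response(
    truth: EnsembleTruth,
    labels: Sequence[str],
    table: ResponseTable,
    mutant_sequence: Optional[str] = None,
    sigma: float = 0.0,
    seed: int = 0,
    model_id: Optional[str] = None,
) -> StructureModel:
    """Predicted structure of a mutant combination, per the response table."""
    cfg = truth.config
    t = table.t_target(list(labels))
    coords_a = truth.anchor_oo.coords
    coords_b = truth.anchor_io.coords
    coords = (1.0 - t) * coords_a + t * coords_b
    for label in labels:
        for helix, amount in table.extra_displacement.get(label, {}).items():
            res = truth.helix_residues[helix]
            idx = [truth.anchor_oo.index_of(r) for r in res]
            centre = coords[idx].mean(axis=0)
            direction = np.array([centre[0], centre[1], 0.0])
            norm = np.linalg.norm(direction)
            if norm > 0:
                coords[idx] += amount * direction / norm
    rng = np.random.default_rng(seed)
    if sigma > 0:
        coords = coords + rng.normal(0.0, sigma, coords.shape)
    return StructureModel(
        model_id or ("mut_" + "+".join(labels) if labels else "mut_wt"),
        truth.anchor_oo.numbers,
        mutant_sequence or truth.template_sequence,
        coords,
        source_tag="synthetic",
    )


# ---------------------------------------------------------------------------
# grouped MSAs


@dataclasses.dataclass(frozen=True)
class MsaTruth:
    type_ii_columns: tuple[int, ...]
    selective_columns: tuple[int, ...]
    selective_group: dict[int, str]


def generate_grouped_msa(
    n_groups: int = 3,
    n_per_group: int = 11,
    length: int = 400,
    planted_type_ii: Sequence[int] = (),
    planted_selective: Sequence[int] = (),
    dirichlet_concentration: float = 0.5,
    conservation: float = 0.95,
    seed: int = 0,
) -> tuple[GroupedMsa, MsaTruth]:
    """Group-structured MSA with planted rate shifts and selective sites.

    Background columns share one residue profile across all groups (drawn
    from a symmetric Dirichlet over the 20 amino acids). Type-ii columns fix
    residue X in the first group and a different residue Y in the second
    (the remaining groups keep X); selective columns give one group a
    private conserved residue while the others share a different one.
    """
    planted_type_ii = tuple(planted_type_ii)
    planted_selective = tuple(planted_selective)
    if set(planted_type_ii) & set(planted_selective):
        raise ValueError("planted column sets must be disjoint")
    for c in planted_type_ii + planted_selective:
        if not 0 <= c < length:
            raise ValueError(f"planted column {c} out of range [0, {length})")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA20))
    groups = [f"g{k}" for k in range(n_groups)]
    rows = {f"{g}_s{i:02d}": np.empty(length, dtype="<U1")
            for g in groups for i in range(n_per_group)}
    group_of = {name: name.split("_")[0] for name in rows}

    def conserved_column(primary: str) -> np.ndarray:
        others = letters[letters != primary]
        col = rng.choice(others, size=n_per_group)
        keep = rng.random(n_per_group) < conservation
        col[keep] = primary
        return col

    selective_group: dict[int, str] = {}
    for c in range(length):
        if c in planted_type_ii:
            x, y = rng.choice(letters, size=2, replace=False)
            for k, g in enumerate(groups):
                primary = y if k == 1 else x
                col = conserved_column(primary)
                for i, name in enumerate(n for n in rows if group_of[n] == g):
                    rows[name][c] = col[i]
        elif c in planted_selective:
            x, y = rng.choice(letters, size=2, replace=False)
            chosen = groups[len(selective_group) % n_groups]
            selective_group[c] = chosen
            for g in groups:
                col = conserved_column(x if g == chosen else y)
                for i, name in enumerate(n for n in rows if group_of[n] == g):
                    rows[name][c] = col[i]
        else:
            profile = rng.dirichlet(np.full(20, dirichlet_concentration))
            col = rng.choice(letters, size=n_groups * n_per_group, p=profile)
            for i, name in enumerate(rows):
                rows[name][c] = col[i]

    alignment = {name: "".join(col) for name, col in rows.items()}
    msa = GroupedMsa(alignment=alignment, groups=group_of)
    return msa, MsaTruth(planted_type_ii, planted_selective, selective_group)
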