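"""Residue correspondence, rigid superposition and per-residue RMSD profiles.

The central readout of the whole pipeline is the per-residue Calpha deviation
of a mobile model from a reference conformer under a single global
least-squares superposition. Conformational change shows up directly as
large local deviations of the segments that move between states; a windowed
or flexible fit would erase exactly that signal, so one global Kabsch fit on
all mapped residues is used throughout, weighting all residues equally.

Residue correspondence between models is established by global pairwise
sequence alignment (BLOSUM62, affine gaps 11/1), because author numbering is
not comparable across templates (reference structures may be N-terminally
truncated).
"""

from __future__ import annotations

import dataclasses
import json
import math
from pathlib import Path
from typing import Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation

from .structure_io import SegmentTable, StructureModel, sequence_of


@dataclasses.dataclass(frozen=True)
class ResidueMap:
    """Monotone residue correspondence between two models.

    ``pairs`` holds positional indices ``(index_in_a, index_in_b)``, strictly
    increasing in both coordinates. ``identity`` is the fraction of matching
    letters over aligned (non-gap) columns.
    """

    pairs: tuple[tuple[int, int], ...]
    identity: float

    def __post_init__(self) -> None:
        for (i0, j0), (i1, j1) in zip(self.pairs, self.pairs[1:]):
            if i1 <= i0 or j1 <= j0:
                raise ValueError("residue map must be strictly increasing in both models")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_indices(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    @property
    def b_indices(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)


def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def align_sequences(seq_a: str, seq_b: str) -> ResidueMap:
    """Globally align two sequences and return the column correspondence."""
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    alignment = _aligner().align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        for i, j in zip(range(a0, a1), range(b0, b1)):
            pairs.append((i, j))
            if seq_a[i] == seq_b[j]:
                matches += 1
    if not pairs:
        raise ValueError("alignment produced no aligned columns")
    return ResidueMap(tuple(pairs), matches / len(pairs))


def map_residues(a: StructureModel, b: StructureModel) -> ResidueMap:
    """Residue correspondence between two models via sequence alignment."""
    return align_sequences(sequence_of(a), sequence_of(b))


def kabsch_superpose(
    a_coords: np.ndarray, b_coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``b`` onto ``a``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``b @ rotation.T + translation`` minimises the RMSD to ``a``. The
    rotation is proper (determinant +1).
    """
    a = np.asarray(a_coords, dtype=float)
    b = np.asarray(b_coords, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"coordinate shapes differ or are not (n, 3): {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 3:
        raise ValueError("superposition needs at least 3 points")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    rot, rssd = Rotation.align_vectors(a - ca, b - cb)
    matrix = rot.as_matrix()
    translation = ca - matrix @ cb
    return matrix, translation, float(rssd / math.sqrt(n))


@dataclasses.dataclass(frozen=True)
class RmsdProfile:
    """Per-residue Calpha deviation of a mobile model from a reference.

    ``deviations`` is indexed like the mobile model's residues, with ``nan``
    for residues that have no counterpart in the reference (truncations
    yield missing values, never zeros).
    """

    reference_id: str
    mobile_id: str
    residue_numbers: tuple[int, ...]
    letters: str
    deviations: np.ndarray
    global_rmsd: float
    coverage: float
    segment_table: Optional[SegmentTable] = None

    def __post_init__(self) -> None:
        dev = np.asarray(self.deviations, dtype=float)
        object.__setattr__(self, "deviations", dev)
        if dev.shape != (len(self.residue_numbers),):
            raise ValueError("deviations must align with residue numbers")

    @property
    def mapped(self) -> np.ndarray:
        return ~np.isnan(self.deviations)

    def segment_mean(self, name: str, part: str = "all") -> float:
        """Mean deviation over mapped residues of a named segment (nan if none)."""
        if self.segment_table is None:
            raise ValueError("profile carries no segment table")
        wanted = set(self.segment_table.residues_of(name, part))
        mask = np.array([n in wanted for n in self.residue_numbers]) & self.mapped
        if not mask.any():
            return float("nan")
        return float(self.deviations[mask].mean())

    def to_tsv(self, path: str | Path) -> None:
        seg = self.segment_table
        with open(path, "w") as fh:
            fh.write("residue_number\tamino_acid\tsegment\tdeviation_A\n")
            for num, letter, dev in zip(self.residue_numbers, self.letters, self.deviations):
                name = seg.segment_of(num) if seg is not None else ""
                val = "" if math.isnan(dev) else f"{dev:.4f}"
                fh.write(f"{num}\t{letter}\t{name or ''}\t{val}\n")

    def summary(self) -> dict:
        return {
            "reference_id": self.reference_id,
            "mobile_id": self.mobile_id,
            "global_rmsd_A": round(self.global_rmsd, 4),
            "coverage": round(self.coverage, 4),
            "n_residues": len(self.residue_numbers),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2) + "\n")


def deviation_profile(
    mobile: StructureModel,
    reference: StructureModel,
    residue_map: Optional[ResidueMap] = None,
    segments: Optional[SegmentTable] = None,
    min_coverage: float = 0.5,
) -> RmsdProfile:
    """Per-residue Calpha deviation of ``mobile`` from ``reference``.

    A single global superposition is computed on all mapped Calpha pairs;
    the profile is then the per-residue Euclidean deviation in the mobile
    model's numbering. ``residue_map`` must map mobile -> reference (computed
    by sequence alignment if omitted).
    """
    if residue_map is None:
        residue_map = map_residues(mobile, reference)
    coverage = len(residue_map) / len(mobile)
    if coverage < min_coverage:
        raise ValueError(
            f"residue map covers only {coverage:.1%} of {mobile.model_id!r} "
            f"(minimum {min_coverage:.0%})"
        )
    mob = mobile.coords[residue_map.a_indices]
    ref = reference.coords[residue_map.b_indices]
    rotation, translation, rmsd = kabsch_superpose(ref, mob)
    moved = mob @ rotation.T + translation
    per_pair = np.linalg.norm(moved - ref, axis=1)
    deviations = np.full(len(mobile), np.nan)
    deviations[residue_map.a_indices] = per_pair
    return RmsdProfile(
        reference_id=reference.model_id,
        mobile_id=mobile.model_id,
        residue_numbers=mobile.numbers,
        letters=mobile.letters,
        deviations=deviations,
        global_rmsd=rmsd,
        coverage=coverage,
        segment_table=segments,
    )


def profile_distance(p: RmsdProfile, q: RmsdProfile) -> float:
    """Root-mean-square difference between two profiles on shared residues.

    Both profiles must be computed against the same reference; used to ask
    how similar two mutants' rearrangements are.
    """
    if p.reference_id != q.reference_id:
        raise ValueError(
            f"profiles have different references: {p.reference_id!r} vs {q.reference_id!r}"
        )
    dev_q = {n: d for n, d in zip(q.residue_numbers, q.deviations) if not math.isnan(d)}
    diffs = [
        d - dev_q[n]
        for n, d in zip(p.residue_numbers, p.deviations)
        if not math.isnan(d) and n in dev_q
    ]
    if not diffs:
        raise ValueError("profiles share no mapped residues")
    return float(np.sqrt(np.mean(np.square(diffs))))
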