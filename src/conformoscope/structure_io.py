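"""Reading and writing of single-chain Calpha traces and sequences.

Every downstream analysis in this package works on a :class:`StructureModel`,
a minimal carrier for one chain's Calpha trace: author residue numbers,
one-letter residue identities, coordinates in Angstroms and an optional
per-residue confidence (pLDDT-style, stored in the PDB B-factor column).

Only the first model / first chain of a PDB file is read; cross-model residue
correspondence is always established by sequence alignment (see
:mod:`conformoscope.superpose`), never by raw author numbering, because
reference structures may be truncated relative to the models compared
against them.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gemmi
import numpy as np

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


class StructureParseError(ValueError):
    """Raised when a structure file cannot be interpreted as a Calpha trace."""


@dataclasses.dataclass(frozen=True)
class StructureModel:
    """One single-chain Calpha trace.

    Parameters
    ----------
    model_id:
        Identifier used in reports and matrices.
    numbers:
        Author residue numbers, strictly increasing.
    letters:
        One-letter residue codes, same length as ``numbers``; non-standard
        residues are retained as ``'X'``.
    coords:
        ``(n, 3)`` Calpha coordinates in Angstroms.
    confidence:
        Optional per-residue score in ``[0, 100]`` (e.g. pLDDT).
    source_tag:
        Free-text provenance tag ("PDB", "AF2", "CFpdb", "CFnt", "aCF",
        "synthetic", ...).
    """

    model_id: str
    numbers: tuple[int, ...]
    letters: str
    coords: np.ndarray
    confidence: Optional[tuple[float, ...]] = None
    source_tag: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        object.__setattr__(self, "coords", coords)
        n = len(self.numbers)
        if n == 0:
            raise ValueError(f"model {self.model_id!r}: empty models are not allowed")
        if len(self.letters) != n or coords.shape != (n, 3):
            raise ValueError(
                f"model {self.model_id!r}: inconsistent lengths "
                f"(numbers {n}, letters {len(self.letters)}, coords {coords.shape})"
            )
        if not np.all(np.isfinite(coords)):
            raise ValueError(f"model {self.model_id!r}: non-finite coordinates")
        diffs = np.diff(self.numbers)
        if n > 1 and not np.all(diffs > 0):
            bad = self.numbers[int(np.argmin(diffs)) + 1]
            raise ValueError(
                f"model {self.model_id!r}: residue numbers not strictly "
                f"increasing at residue {bad}"
            )
        bad_letters = set(self.letters) - STANDARD_AA - {"X"}
        if bad_letters:
            raise ValueError(
                f"model {self.model_id!r}: invalid residue letters {sorted(bad_letters)}"
            )
        if self.confidence is not None and len(self.confidence) != n:
            raise ValueError(f"model {self.model_id!r}: confidence length mismatch")

    def __len__(self) -> int:
        return len(self.numbers)

    @property
    def sequence(self) -> str:
        return sequence_of(self)

    def index_of(self, number: int) -> int:
        """Positional index of an author residue number."""
        idx = {n: i for i, n in enumerate(self.numbers)}
        try:
            return idx[number]
        except KeyError:
            raise KeyError(f"residue {number} not in model {self.model_id!r}") from None


@dataclasses.dataclass(frozen=True)
class Segment:
    name: str
    start: int
    end: int
    cls: str = "helix"  # "helix" or "loop"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"segment {self.name}: start {self.start} > end {self.end}")
        if self.cls not in ("helix", "loop"):
            raise ValueError(f"segment {self.name}: class must be helix or loop")


@dataclasses.dataclass(frozen=True)
class SegmentTable:
    """Sorted, non-overlapping annotation of helix/loop segments.

    Segment names follow the transmembrane-helix convention of the LeuT fold
    ("h1a", "h1b", "h2", ..., "h11") with loops named "l1/2" etc.
    """

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.start))
        object.__setattr__(self, "segments", segs)
        names = [s.name for s in segs]
        if len(set(names)) != len(names):
            raise ValueError("segment names must be unique")
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(f"segments {a.name} and {b.name} overlap")

    def __iter__(self) -> Iterable[Segment]:
        return iter(self.segments)

    def segment_of(self, number: int) -> Optional[str]:
        for s in self.segments:
            if s.start <= number <= s.end:
                return s.name
        return None

    def residues_of(self, name: str, part: str = "all") -> range:
        """Residue-number range of a segment; ``part`` picks the N- or
        C-terminal half ("N" / "C") or the whole segment ("all")."""
        for s in self.segments:
            if s.name == name:
                mid = (s.start + s.end + 1) // 2
                if part == "N":
                    return range(s.start, mid)
                if part == "C":
                    return range(mid, s.end + 1)
                return range(s.start, s.end + 1)
        raise KeyError(f"no segment named {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.segments)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tstart\tend\tclass\n")
            for s in self.segments:
                fh.write(f"{s.name}\t{s.start}\t{s.end}\t{s.cls}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SegmentTable":
        segs = []
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("name"):
                raise ValueError(f"{path}: expected header 'name\\tstart\\tend\\tclass'")
            for line in fh:
                if not line.strip():
                    continue
                name, start, end, kind = line.rstrip("\n").split("\t")
                segs.append(Segment(name, int(start), int(end), kind))
        return cls(tuple(segs))


def _one_letter(resname: str) -> str:
    info = gemmi.find_tabulated_residue(resname)
    if info is not None and info.is_amino_acid() and info.is_standard():
        code = info.one_letter_code.upper()
        if code in STANDARD_AA:
            return code
    return "X"


def read_structure(path: str | Path, model_id: Optional[str] = None,
                   source_tag: str = "PDB") -> StructureModel:
    """Read the first model / first chain of a PDB file as a Calpha trace.

    Alternate locations are resolved to the highest-occupancy conformer
    (ties broken by file order); the B-factor column is captured as
    per-residue confidence. Raises :class:`StructureParseError` if the file
    contains no CA atoms.
    """
    path = Path(path)
    if model_id is None:
        model_id = path.stem
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or len(st[0]) == 0:
        raise StructureParseError(f"{path}: no models/chains found")
    chain = st[0][0]
    numbers: list[int] = []
    letters: list[str] = []
    coords: list[tuple[float, float, float]] = []
    conf: list[float] = []
    for res in chain:
        cas = [a for a in res if a.name == "CA"]
        if not cas:
            continue
        altlocs = [a.altloc for a in cas]
        if len(set(altlocs)) != len(altlocs):
            raise StructureParseError(
                f"{path}: duplicate CA records for residue {res.seqid.num}"
            )
        ca = max(cas, key=lambda a: a.occ)  # max is stable: first wins ties
        num = res.seqid.num
        if numbers and num <= numbers[-1]:
            raise StructureParseError(
                f"{path}: residue number {num} not strictly increasing "
                f"(after {numbers[-1]})"
            )
        numbers.append(num)
        letters.append(_one_letter(res.name))
        coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        conf.append(ca.b_iso)
    if not numbers:
        raise StructureParseError(f"{path}: no CA atom records")
    return StructureModel(
        model_id=model_id,
        numbers=tuple(numbers),
        letters="".join(letters),
        coords=np.array(coords, dtype=float),
        confidence=tuple(conf),
        source_tag=source_tag,
    )


_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_structure(model: StructureModel, path: str | Path) -> None:
    """Write a Calpha-only PDB file (fixed columns, coordinates to 3 decimals)."""
    if len(model) == 0:
        raise ValueError("cannot write an empty model")
    conf = model.confidence or tuple(0.0 for _ in model.numbers)
    with open(path, "w") as fh:
        for i, (num, letter, xyz, b) in enumerate(
            zip(model.numbers, model.letters, model.coords, conf), start=1
        ):
            fh.write(
                f"ATOM  {i:5d}  CA  {_THREE[letter]:<3s} A{num:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{b:6.2f}"
                f"          {'C':>2s}\n"
            )
        fh.write("TER\nEND\n")


def sequence_of(model: StructureModel) -> str:
    """One-letter sequence in residue order; numbering gaps add nothing."""
    if len(model) == 0:
        raise ValueError("empty model has no sequence")
    return model.letters


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a (possibly aligned) FASTA file into an ordered id -> sequence map."""
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: dict[str, str] | Sequence[tuple[str, str]],
                path: str | Path, width: int = 60) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
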