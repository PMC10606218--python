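"""Mutation parsing, synapomorphy registry, switch classification, epistasis.

The in-silico mutagenesis workflow targets the family synapomorphy of Slc11
carriers — the set of family-diagnostic residues produced by type-ii
evolutionary rate shifts on helices h1, h3, h6, h7, h10 and h11 — by
exchanging them for the corresponding outgroup residues and asking whether
the predicted mutant model abandons its native conformation.

The readout is the *broad-scale deviation* (BSD): under one global
superposition onto the native model, the fraction of in-scope residues
whose Calpha deviation exceeds a threshold (2 A default). A mutant is
called ``switched`` when the BSD is large and most of the co-moving
signature segments of the carrier transition are hit, ``silent`` when the
BSD is negligible, and ``partial`` otherwise. Non-additivity of mutation
combinations is scored as epistasis,

    epsilon = bsd(A+B) - bsd(A) - bsd(B),

classified cooperative / additive / antagonistic within a tolerance band.

This package does not run structure prediction: it emits mutant FASTA plus
a run manifest (the intended predictor settings are recorded verbatim as
metadata) and ingests the returned models.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np

from .structure_io import SegmentTable, StructureModel, write_fasta
from .superpose import RmsdProfile

MUTATION_RE = re.compile(r"^([A-Z])?(\d+)([A-Z])$")

#: Advanced structure-predictor settings used for the carrier models this
#: package was designed around; recorded in run manifests as metadata only.
ACF_SETTINGS = (
    "MSA meth Jack hammer, pairwise MSA option 75% coverage, 15% id, "
    "max_msa_clusters = 32, max_extra_msa = 64, no use of ptm sampling, "
    "num_ensembl 1, max_recycle 1, use is-training, num_sample 1, refine/Amber"
)


@dataclasses.dataclass(frozen=True)
class Mutation:
    wt_aa: str
    position: int  # author numbering of the template
    mutant_aa: str

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mutant_aa}"


@dataclasses.dataclass(frozen=True)
class MutationSet:
    label: str
    substitutions: tuple[Mutation, ...]
    template_id: str = ""

    def __post_init__(self) -> None:
        positions = [m.position for m in self.substitutions]
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.label}: duplicate positions in mutation set")

    def __len__(self) -> int:
        return len(self.substitutions)

    def union(self, other: "MutationSet", label: Optional[str] = None) -> "MutationSet":
        merged = {m.position: m for m in self.substitutions}
        for m in other.substitutions:
            if m.position in merged and merged[m.position] != m:
                raise ValueError(f"conflicting substitutions at position {m.position}")
            merged[m.position] = m
        subs = tuple(sorted(merged.values(), key=lambda m: m.position))
        return MutationSet(label or f"{self.label} {other.label}".strip(), subs, self.template_id)


@dataclasses.dataclass(frozen=True)
class Template:
    """A mutagenesis template: sequence plus author numbering."""

    template_id: str
    sequence: str
    numbers: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if not self.numbers:
            object.__setattr__(self, "numbers", tuple(range(1, len(self.sequence) + 1)))
        if len(self.numbers) != len(self.sequence):
            raise ValueError("numbering length must match sequence length")

    @classmethod
    def from_model(cls, model: StructureModel) -> "Template":
        return cls(model.model_id, model.letters, model.numbers)

    def letter_at(self, position: int) -> str:
        try:
            return self.sequence[self.numbers.index(position)]
        except ValueError:
            raise KeyError(f"position {position} not in template {self.template_id!r}") from None


class MutationParseError(ValueError):
    pass


def parse_mutation_spec(
    text: str,
    template: Template,
    aliases: Optional[Mapping[str, str]] = None,
    label: Optional[str] = None,
) -> MutationSet:
    """Parse substitution notation ("A131Y G135N") and registered aliases.

    Tokens are either ``<wt><position><mutant>`` (wild-type letter validated
    against the template), ``<position><mutant>`` (wild type read from the
    template, the field's shorthand as in "226T"), or alias names that
    expand recursively through the alias table.
    """
    aliases = aliases or {}
    subs: dict[int, Mutation] = {}

    def expand(token: str, seen: frozenset[str]) -> None:
        m = MUTATION_RE.match(token)
        if m:
            wt, pos, mut = m.group(1), int(m.group(2)), m.group(3)
            found = template.letter_at(pos)
            if wt is None:
                wt = found
            elif found != wt:
                raise MutationParseError(
                    f"wild-type mismatch at position {pos} of {template.template_id!r}: "
                    f"expected {wt}, found {found}"
                )
            if pos in subs and subs[pos].mutant_aa != mut:
                raise MutationParseError(f"conflicting substitutions at position {pos}")
            subs[pos] = Mutation(wt, pos, mut)
            return
        if token in aliases:
            if token in seen:
                raise MutationParseError(f"circular alias {token!r}")
            for sub_token in aliases[token].split():
                expand(sub_token, seen | {token})
            return
        raise MutationParseError(f"unknown mutation token or alias {token!r}")

    tokens = text.split()
    if not tokens:
        raise MutationParseError("empty mutation specification")
    for token in tokens:
        expand(token, frozenset())
    ordered = tuple(sorted(subs.values(), key=lambda m: m.position))
    return MutationSet(label or text, ordered, template.template_id)


def apply_mutations(template: Template, mset: MutationSet) -> str:
    """Mutant sequence with all substitutions applied (validated)."""
    seq = list(template.sequence)
    index = {n: i for i, n in enumerate(template.numbers)}
    for m in mset.substitutions:
        i = index.get(m.position)
        if i is None:
            raise KeyError(f"position {m.position} not in template {template.template_id!r}")
        if seq[i] != m.wt_aa:
            raise MutationParseError(
                f"wild-type mismatch at position {m.position}: expected {m.wt_aa}, found {seq[i]}"
            )
        seq[i] = m.mutant_aa
    return "".join(seq)


def emit_mutant_fasta(
    template: Template,
    msets: Sequence[MutationSet],
    fasta_path: str | Path,
    manifest_path: str | Path,
    predictor_settings: str = ACF_SETTINGS,
) -> None:
    """Write mutant sequences for external structure prediction + manifest."""
    records = []
    for mset in msets:
        header = f"{template.template_id}__{mset.label.replace(' ', '_') or 'wt'}"
        records.append((header, apply_mutations(template, mset)))
    write_fasta(records, fasta_path)
    with open(manifest_path, "w") as fh:
        fh.write("template_id\tlabel\tsubstitutions\tpredictor_settings\n")
        for mset in msets:
            subs = ";".join(str(m) for m in mset.substitutions)
            fh.write(f"{template.template_id}\t{mset.label}\t{subs}\t{predictor_settings}\n")


# ---------------------------------------------------------------------------
# synapomorphy registry


@dataclasses.dataclass(frozen=True)
class SynapomorphySite:
    segment: str
    position: int
    wt_aa: str
    outgroup_aa: str


@dataclasses.dataclass(frozen=True)
class SynapomorphyRegistry:
    """Family-diagnostic sites of one template, with outgroup residues."""

    template_id: str
    sites: tuple[SynapomorphySite, ...]

    def validate_against(self, segments: SegmentTable) -> None:
        for site in self.sites:
            seg = segments.segment_of(site.position)
            base = site.segment.rstrip("ab")
            if seg is None or seg.rstrip("ab") != base:
                raise ValueError(
                    f"site {site.position} annotated {site.segment} but lies in {seg}"
                )

    def mutation_spec(self, positions: Optional[Sequence[int]] = None) -> str:
        chosen = [s for s in self.sites if positions is None or s.position in positions]
        return " ".join(f"{s.wt_aa}{s.position}{s.outgroup_aa}" for s in chosen)

    def alias_table(self, h3_outgroup_g_positions: Sequence[int] = ()) -> dict[str, str]:
        """Standard combination aliases over this registry's numbering.

        The compound aliases follow the field's shorthand: YN (h3 pair),
        VY (h6 pair), VNT (VY + YN + the h6a A->T site), ANG (h10 triple),
        VN (VY + YN), Ttg (h6a/h7/h11 triple). When the positions of the
        four h3 sites that are invariant glycines in the orphan outgroup
        are supplied, the six-site compound h3 alias GYGNGG (YN plus those
        four G substitutions) is included.
        """
        by_seg: dict[str, list[SynapomorphySite]] = {}
        for s in self.sites:
            by_seg.setdefault(s.segment.rstrip("ab"), []).append(s)
        aliases: dict[str, str] = {}

        def spec(sites: Sequence[SynapomorphySite]) -> str:
            return " ".join(f"{s.wt_aa}{s.position}{s.outgroup_aa}" for s in sites)

        h3 = sorted(by_seg.get("h3", []), key=lambda s: s.position)
        if len(h3) >= 2:
            aliases["YN"] = spec(h3[:2])
        h6 = sorted(by_seg.get("h6", []), key=lambda s: s.position)
        if len(h6) >= 3:
            aliases["VY"] = spec(h6[1:3])
            aliases["VNT"] = f"VY YN {h6[0].wt_aa}{h6[0].position}{h6[0].outgroup_aa}"
        h10 = sorted(by_seg.get("h10", []), key=lambda s: s.position)
        if len(h10) >= 3:
            aliases["ANG"] = spec(h10)
        if "YN" in aliases and "VY" in aliases:
            aliases["VN"] = "VY YN"
        h7 = by_seg.get("h7", [])
        h11 = by_seg.get("h11", [])
        if h6 and h7 and h11:
            aliases["Ttg"] = spec([h6[0], h7[0], h11[0]])
        if "YN" in aliases and h3_outgroup_g_positions:
            gs = " ".join(f"{p}G" for p in sorted(h3_outgroup_g_positions))
            aliases["GYGNGG"] = f"YN {gs}"
        return aliases


#: Synapomorphic sites of the Q5HQ64 carrier template (h1 metal-binding
#: half-site, h3, h6 half-sites, h7, h10 and h11), each paired with the
#: corresponding orphan/NRMT outgroup residue.
Q5HQ64_REGISTRY = SynapomorphyRegistry(
    "Q5HQ64",
    (
        SynapomorphySite("h1", 54, "D", "G"),
        SynapomorphySite("h1", 57, "N", "T"),
        SynapomorphySite("h3", 131, "A", "Y"),
        SynapomorphySite("h3", 135, "G", "N"),
        SynapomorphySite("h6", 228, "A", "T"),
        SynapomorphySite("h6", 231, "M", "V"),
        SynapomorphySite("h6", 233, "H", "Y"),
        SynapomorphySite("h7", 277, "N", "T"),
        SynapomorphySite("h10", 393, "S", "A"),
        SynapomorphySite("h10", 397, "L", "N"),
        SynapomorphySite("h10", 398, "S", "G"),
        SynapomorphySite("h11", 442, "N", "G"),
    ),
)


# ---------------------------------------------------------------------------
# switch classification

#: Co-moving helix-segment groups of the carrier OO<->IO transition, each a
#: tuple of (segment_name, part) entries; a group is hit when any of its
#: member segments moves. These defaults name the blocks mobilised by the
#: carrier switch: h1b-h2N, h5-l5/6-h6a, l7/8-h8N, h9C-h10N and h11C.
SWITCH_SIGNATURE: tuple[tuple[tuple[str, str], ...], ...] = (
    (("h1b", "all"), ("l1/2", "all"), ("h2", "N")),
    (("h5", "all"), ("l5/6", "all"), ("h6a", "all")),
    (("l7/8", "all"), ("h8", "N")),
    (("h9", "C"), ("l9/10", "all"), ("h10", "N")),
    (("h11", "C"),),
)


@dataclasses.dataclass(frozen=True)
class SwitchThresholds:
    tau: float = 2.0                 # A, per-residue deviation threshold
    switch_threshold: float = 0.25   # BSD above which a model may be "switched"
    silent_threshold: float = 0.05   # BSD below which a model is "silent"
    min_signature_hits: int = 4
    signature: tuple[tuple[tuple[str, str], ...], ...] = SWITCH_SIGNATURE
    scope: str = "helix"             # "helix" restricts BSD to helix segments


@dataclasses.dataclass(frozen=True)
class SwitchCall:
    mutant_label: str
    bsd: float
    per_segment_mean: dict[str, float]
    signature_segments_hit: tuple[int, ...]  # indices into the signature
    verdict: str  # "switched" | "partial" | "silent"
    tau: float


@dataclasses.dataclass(frozen=True)
class EpistasisScore:
    pair: tuple[str, str]
    epsilon: float
    classification: str  # "cooperative" | "additive" | "antagonistic"
    band: float


def _scope_mask(profile: RmsdProfile, scope: str) -> np.ndarray:
    mask = profile.mapped.copy()
    if scope == "helix" and profile.segment_table is not None:
        helix_residues = set()
        for seg in profile.segment_table:
            if seg.cls == "helix":
                helix_residues.update(range(seg.start, seg.end + 1))
        in_scope = np.array([n in helix_residues for n in profile.residue_numbers])
        mask &= in_scope
    return mask


def broad_scale_deviation(profile: RmsdProfile, tau: float = 2.0,
                          scope: str = "helix") -> float:
    """Fraction of in-scope mapped residues deviating by more than ``tau``."""
    mask = _scope_mask(profile, scope)
    if not mask.any():
        raise ValueError("empty scope: no mapped residues to evaluate")
    return float((profile.deviations[mask] > tau).mean())


def classify_switch(
    profile: RmsdProfile,
    thresholds: SwitchThresholds = SwitchThresholds(),
    label: Optional[str] = None,
) -> SwitchCall:
    """Three-way verdict on a mutant profile vs its native reference."""
    if profile.segment_table is None:
        raise ValueError("classify_switch requires a segment table on the profile")
    bsd = broad_scale_deviation(profile, thresholds.tau, thresholds.scope)
    available = set(profile.segment_table.names)
    seg_means: dict[str, float] = {}
    hits: list[int] = []
    for gi, group in enumerate(thresholds.signature):
        group_hit = False
        for name, part in group:
            if name not in available:
                continue
            key = name if part == "all" else f"{name}{part}"
            mean = profile.segment_mean(name, part)
            seg_means[key] = mean
            if not np.isnan(mean) and mean > thresholds.tau:
                group_hit = True
        if group_hit:
            hits.append(gi)
    if bsd >= thresholds.switch_threshold and len(hits) >= thresholds.min_signature_hits:
        verdict = "switched"
    elif bsd < thresholds.silent_threshold:
        verdict = "silent"
    else:
        verdict = "partial"
    return SwitchCall(label or profile.mobile_id, bsd, seg_means, tuple(hits),
                      verdict, thresholds.tau)


def epistasis_score(
    call_a: SwitchCall,
    call_b: SwitchCall,
    call_ab: SwitchCall,
    band: float = 0.10,
) -> EpistasisScore:
    """Non-additivity of a mutation pair's broad-scale deviations."""
    epsilon = call_ab.bsd - call_a.bsd - call_b.bsd
    if epsilon > band:
        cls = "cooperative"
    elif epsilon < -band:
        cls = "antagonistic"
    else:
        cls = "additive"
    return EpistasisScore((call_a.mutant_label, call_b.mutant_label), float(epsilon), cls, band)


def suppressor_screen(
    switching_call: SwitchCall,
    combined_calls: Mapping[str, SwitchCall],
) -> list[tuple[str, float]]:
    """Rank candidate suppressors of an established conformation switch.

    ``combined_calls`` maps each candidate's label to the switch call of
    the (switching set + candidate) combination against the same native
    reference; suppression strength is the drop in BSD.
    """
    if switching_call.verdict != "switched":
        raise ValueError(
            f"background {switching_call.mutant_label!r} is not a switched mutant"
        )
    ranked = [
        (label, float(switching_call.bsd - call.bsd))
        for label, call in combined_calls.items()
    ]
    ranked.sort(key=lambda kv: (-kv[1], kv[0]))
    return ranked


def write_switch_report(calls: Sequence[SwitchCall], path: str | Path,
                        thresholds: SwitchThresholds = SwitchThresholds()) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tau_A={thresholds.tau} switch={thresholds.switch_threshold} "
                 f"silent={thresholds.silent_threshold} "
                 f"min_hits={thresholds.min_signature_hits}\n")
        fh.write("label\tbsd\tverdict\tsignature_groups_hit\n")
        for c in calls:
            fh.write(f"{c.mutant_label}\t{c.bsd:.4f}\t{c.verdict}\t"
                     f"{','.join(map(str, c.signature_segments_hit))}\n")
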