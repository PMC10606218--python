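"""Clade-level sequence analytics.

Four related questions about a family alignment are answered here:

* how similar are two sequences (percent identity under the package's
  declared global-alignment convention);
* does a sequence match a clade-diagnostic PROSITE-style pattern;
* which alignment columns show *type-ii evolutionary rate shifts* (residue X
  conserved in one clade, a different residue Y conserved in another —
  the raw material of a family synapomorphy) or *type-i* shifts (conserved
  in exactly one clade);
* which columns are *group-specific* under a dual scoring scheme: a
  sequence-harmony branch (Jensen-Shannon divergence between per-group
  residue profiles, z-scored so that group-distinct columns are strongly
  negative) and a relief branch (nearest-hit/nearest-miss column weighting
  over seeded subsamples, z-scored so group-distinct columns are strongly
  positive). A column is selected when it is extreme in both branches
  (defaults: z-weight > 6 and z-score < -10).

Both branch scores are standardised per column against a group-label
permutation null (sequences randomly reassigned to groups), so a column
whose residue usage ignores the grouping scores near zero while genuinely
group-distinct columns sit many null standard deviations away from it.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .superpose import align_sequences

GAP_CHARS = set("-.")

#: Diagnostic sequence pattern of the MCg1 clade of bacterial Slc11
#: (MntH C) transporters, in PROSITE-like notation.
MCG1_PATTERN = (
    "G[ASP]G[LAVSTIM][LM][VI]AVGY[MIV]DPGNWAT[DEASG]x(30,100)"
    "[IVL]A[CT][DA][LV]AE[VIL][IVLA]Gx(5,30)[GAVCSL][TAS][LFYIVC][AVGILST][MLVI]"
    "x(50,125)[IVM][LVI]GAT[LVI]MPHN[LI][YF]L[HQ][SGA]x(5,40)"
    "[FMLT][LVATIC][VILA]N[SAGL][ASG]x(2,50)[ACS]G[QLM][SN][SA][TA][VLI]T[GAS]"
)


def pairwise_identity(a: str, b: str) -> float:
    """Percent identity over aligned (non-gap) columns, to 0.1."""
    rmap = align_sequences(a, b)
    return round(100.0 * rmap.identity, 1)


# ---------------------------------------------------------------------------
# PROSITE-style patterns


@dataclasses.dataclass(frozen=True)
class PatternToken:
    kind: str                      # "literal" | "class" | "gap"
    letters: frozenset = frozenset()
    min_len: int = 1
    max_len: int = 1


@dataclasses.dataclass(frozen=True)
class SequencePattern:
    tokens: tuple[PatternToken, ...]
    source_text: str

    def render(self) -> str:
        out = []
        for tok in self.tokens:
            if tok.kind == "literal":
                out.append(next(iter(tok.letters)))
            elif tok.kind == "class":
                out.append("[" + "".join(sorted(tok.letters)) + "]")
            else:
                out.append(f"x({tok.min_len},{tok.max_len})")
        return "".join(out)


class PatternSyntaxError(ValueError):
    pass


def compile_pattern(text: str) -> SequencePattern:
    """Compile literals, ``[classes]`` and ``x(m,n)`` gaps into tokens."""
    tokens: list[PatternToken] = []
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace() or ch == "-":
            i += 1
        elif ch == "[":
            j = text.find("]", i)
            if j < 0:
                raise PatternSyntaxError(f"unbalanced '[' at position {i}")
            letters = text[i + 1:j]
            if not letters or not letters.isalpha():
                raise PatternSyntaxError(f"invalid class {text[i:j + 1]!r}")
            tokens.append(PatternToken("class", frozenset(letters.upper())))
            i = j + 1
        elif ch == "x":
            if i + 1 < n and text[i + 1] == "(":
                j = text.find(")", i)
                if j < 0:
                    raise PatternSyntaxError(f"unterminated gap at position {i}")
                body = text[i + 2:j]
                parts = body.split(",")
                try:
                    if len(parts) == 1:
                        lo = hi = int(parts[0])
                    elif len(parts) == 2:
                        lo, hi = int(parts[0]), int(parts[1])
                    else:
                        raise ValueError
                except ValueError:
                    raise PatternSyntaxError(f"invalid gap spec x({body})") from None
                if lo < 0 or lo > hi:
                    raise PatternSyntaxError(f"invalid gap range x({body})")
                tokens.append(PatternToken("gap", min_len=lo, max_len=hi))
                i = j + 1
            else:
                tokens.append(PatternToken("gap", min_len=1, max_len=1))
                i += 1
        elif ch.isalpha() and ch.isupper():
            tokens.append(PatternToken("literal", frozenset(ch)))
            i += 1
        else:
            raise PatternSyntaxError(f"unexpected character {ch!r} at position {i}")
    if not tokens:
        raise PatternSyntaxError("empty pattern")
    return SequencePattern(tuple(tokens), text)


@dataclasses.dataclass(frozen=True)
class PatternMatch:
    matched: bool
    start: Optional[int] = None          # 0-based, inclusive
    end: Optional[int] = None            # 0-based, exclusive
    spans: tuple[tuple[int, int], ...] = ()  # per literal/class token


def match_pattern(pattern: SequencePattern, seq: str) -> PatternMatch:
    """First match of a compiled pattern, by backtracking over gap ranges.

    Gap tokens are tried shortest-first, so the reported first match is the
    leftmost one with minimal gap stretches.
    """
    seq = seq.upper()
    tokens = pattern.tokens
    n = len(seq)

    def attempt(ti: int, pos: int, spans: list[tuple[int, int]]) -> Optional[int]:
        if ti == len(tokens):
            return pos
        tok = tokens[ti]
        if tok.kind == "gap":
            for glen in range(tok.min_len, tok.max_len + 1):
                if pos + glen > n:
                    break
                end = attempt(ti + 1, pos + glen, spans)
                if end is not None:
                    return end
            return None
        if pos >= n or seq[pos] not in tok.letters:
            return None
        spans.append((pos, pos + 1))
        end = attempt(ti + 1, pos + 1, spans)
        if end is None:
            spans.pop()
        return end

    min_total = sum(t.min_len if t.kind == "gap" else 1 for t in tokens)
    for start in range(0, n - min_total + 1):
        spans: list[tuple[int, int]] = []
        end = attempt(0, start, spans)
        if end is not None:
            return PatternMatch(True, start, end, tuple(spans))
    return PatternMatch(False)


# ---------------------------------------------------------------------------
# grouped alignments


@dataclasses.dataclass(frozen=True)
class GroupedMsa:
    """Equal-length gapped alignment rows with a row -> group labelling."""

    alignment: dict[str, str]
    groups: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError(f"alignment rows have unequal lengths: {sorted(lengths)}")
        missing = set(self.alignment) - set(self.groups)
        if missing:
            raise ValueError(f"rows without group label: {sorted(missing)[:5]}")

    @property
    def length(self) -> int:
        return len(next(iter(self.alignment.values())))

    @property
    def group_names(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.groups[name] for name in self.alignment)
        return tuple(seen)

    def rows_of(self, group: str) -> list[str]:
        names = [n for n in self.alignment if self.groups[n] == group]
        if not names:
            raise KeyError(f"no rows in group {group!r}")
        return [self.alignment[n] for n in names]

    def column(self, c: int, group: Optional[str] = None) -> str:
        rows = self.rows_of(group) if group else list(self.alignment.values())
        return "".join(r[c] for r in rows)

    def gap_fraction(self, c: int) -> float:
        col = self.column(c)
        return sum(ch in GAP_CHARS for ch in col) / len(col)

    @classmethod
    def from_files(cls, fasta_path, groups_path) -> "GroupedMsa":
        from .structure_io import read_fasta

        alignment = read_fasta(fasta_path)
        groups = {}
        with open(groups_path) as fh:
            for line in fh:
                if line.strip():
                    name, group = line.split()[:2]
                    groups[name] = group
        return cls(alignment, groups)


@dataclasses.dataclass(frozen=True)
class RateShift:
    column: int
    group_a_residue: str
    group_b_residue: str
    conservation_a: float
    conservation_b: float
    type: str  # "i" or "ii"


def _column_consensus(col: str) -> tuple[str, float]:
    residues = [c for c in col if c not in GAP_CHARS]
    if not residues:
        return "-", 0.0
    aa, count = Counter(residues).most_common(1)[0]
    return aa, count / len(col)


def type_ii_shifts(
    msa: GroupedMsa,
    groups: tuple[str, str],
    conservation_threshold: float = 0.9,
    include_type_i: bool = True,
) -> list[RateShift]:
    """Classify columns as type-i / type-ii rate shifts between two groups.

    Type ii: both groups conserved above the threshold at *different*
    residues. Type i: conserved in exactly one group. Columns with a gap
    majority are skipped.
    """
    ga, gb = groups
    for g in groups:
        msa.rows_of(g)
    shifts: list[RateShift] = []
    for c in range(msa.length):
        if msa.gap_fraction(c) > 0.5:
            continue
        aa_a, cons_a = _column_consensus(msa.column(c, ga))
        aa_b, cons_b = _column_consensus(msa.column(c, gb))
        conserved_a = cons_a >= conservation_threshold and aa_a != "-"
        conserved_b = cons_b >= conservation_threshold and aa_b != "-"
        if conserved_a and conserved_b and aa_a != aa_b:
            shifts.append(RateShift(c, aa_a, aa_b, cons_a, cons_b, "ii"))
        elif include_type_i and (conserved_a ^ conserved_b):
            shifts.append(RateShift(c, aa_a, aa_b, cons_a, cons_b, "i"))
    return shifts


def clade_consensus(msa: GroupedMsa, group: str) -> list[tuple[str, float]]:
    """Majority residue and its frequency per column ('-' on gap majority)."""
    out = []
    for c in range(msa.length):
        col = msa.column(c, group)
        gaps = sum(ch in GAP_CHARS for ch in col)
        if gaps > len(col) / 2:
            out.append(("-", gaps / len(col)))
        else:
            aa, freq = _column_consensus(col)
            out.append((aa, freq))
    return out


# ---------------------------------------------------------------------------
# group-specific site scoring

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AA20)}


@dataclasses.dataclass(frozen=True)
class SiteScore:
    column: int
    divergence: float       # generalised Jensen-Shannon divergence in [0, 1]
    z_score: float          # harmony branch; group-distinct => strongly negative
    relief_weight: float
    z_weight: float         # relief branch; group-distinct => strongly positive
    selected: bool


def _encode(msa: GroupedMsa) -> tuple[list[str], np.ndarray]:
    """Rows as an integer matrix; amino acids 0..19, everything else 20."""
    names = sorted(msa.alignment)
    x = np.full((len(names), msa.length), 20, dtype=np.int8)
    for r, name in enumerate(names):
        for c, ch in enumerate(msa.alignment[name]):
            x[r, c] = _AA_INDEX.get(ch, 20)
    return names, x


def _column_harmony(x: np.ndarray, group_idx: list[np.ndarray], pseudocount: float) -> np.ndarray:
    """Per-column 1 - generalised JS divergence between group profiles."""
    n_groups = len(group_idx)
    length = x.shape[1]
    profiles = np.empty((n_groups, length, 20))
    for k, idx in enumerate(group_idx):
        counts = np.full((length, 20), pseudocount)
        sub = x[idx]
        for a in range(20):
            counts[:, a] += (sub == a).sum(axis=0)
        profiles[k] = counts / counts.sum(axis=1, keepdims=True)

    def entropy(p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(p > 0, p * np.log2(p), 0.0)
        return -t.sum(axis=-1)

    mean_profile = profiles.mean(axis=0)
    jsd = entropy(mean_profile) - entropy(profiles).mean(axis=0)
    jsd = np.clip(jsd / math.log2(n_groups), 0.0, 1.0)
    return 1.0 - jsd


def _column_relief(x: np.ndarray, labels: np.ndarray, rng: np.random.Generator,
                   n_subsamples: int, distances: np.ndarray) -> np.ndarray:
    """Nearest-hit/nearest-miss column weights averaged over subsamples."""
    n, length = x.shape
    weights = np.zeros(length)
    n_terms = 0
    group_ids = np.unique(labels)
    for _ in range(n_subsamples):
        sampled: list[int] = []
        for g in group_ids:
            pool = np.flatnonzero(labels == g)
            k = max(2, len(pool) // 2)
            sampled.extend(rng.choice(pool, size=k, replace=False))
        sampled_arr = np.array(sampled)
        for r in sampled_arr:
            same = sampled_arr[(labels[sampled_arr] == labels[r]) & (sampled_arr != r)]
            other = sampled_arr[labels[sampled_arr] != labels[r]]
            if len(same) == 0 or len(other) == 0:
                continue
            hit = same[np.argmin(distances[r, same])]
            miss = other[np.argmin(distances[r, other])]
            weights += (x[r] != x[miss]).astype(float) - (x[r] != x[hit]).astype(float)
            n_terms += 1
    return weights / n_terms if n_terms else weights


def group_specific_sites(
    msa: GroupedMsa,
    n_subsamples: int = 100,
    seed: int = 0,
    z_weight_threshold: float = 6.0,
    z_score_threshold: float = -10.0,
    pseudocount: float = 0.5,
    max_gap_fraction: float = 0.5,
    n_null: int = 100,
    null_subsamples: int = 20,
) -> list[SiteScore]:
    """Score every column for group specificity (harmony + relief branches).

    Both branch scores are standardised per column against a group-label
    permutation null: the observed score is z-scored against the scores of
    ``n_null`` random reassignments of sequences to groups. A column whose
    residue usage ignores the grouping scores like its null and gets
    ``z ~ 0``; a genuinely group-distinct column sits far outside its null
    in both branches.
    """
    group_names = msa.group_names
    if len(group_names) < 2:
        raise ValueError("need at least 2 groups")
    for g in group_names:
        if len(msa.rows_of(g)) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 sequences")
    length = msa.length
    usable = np.array([msa.gap_fraction(c) <= max_gap_fraction for c in range(length)])

    names, x = _encode(msa)
    labels = np.array([group_names.index(msa.groups[n]) for n in names])
    group_idx = [np.flatnonzero(labels == k) for k in range(len(group_names))]
    # full-sequence mismatch distances drive nearest-hit/nearest-miss picks
    distances = (x[:, None, :] != x[None, :, :]).sum(axis=2)

    rng = np.random.default_rng(seed)
    harmony_obs = _column_harmony(x, group_idx, pseudocount)
    weight_obs = _column_relief(x, labels, rng, n_subsamples, distances)

    null_h = np.empty((n_null, length))
    null_w = np.empty((n_null, length))
    for p in range(n_null):
        perm = rng.permutation(labels)
        perm_idx = [np.flatnonzero(perm == k) for k in range(len(group_names))]
        null_h[p] = _column_harmony(x, perm_idx, pseudocount)
        null_w[p] = _column_relief(x, perm, rng, null_subsamples, distances)

    def null_z(observed: np.ndarray, null: np.ndarray) -> np.ndarray:
        mean = null.mean(axis=0)
        std = null.std(axis=0)
        delta = observed - mean
        floor = 1e-9
        z = np.where(std > floor, delta / np.maximum(std, floor), 0.0)
        # column constant under permutation: no evidence either way
        z[(std <= floor) & (np.abs(delta) <= floor)] = 0.0
        return z

    z_scores = null_z(harmony_obs, null_h)
    z_weights = null_z(weight_obs, null_w)

    out = []
    for c in range(length):
        selected = bool(
            usable[c]
            and z_weights[c] > z_weight_threshold
            and z_scores[c] < z_score_threshold
        )
        out.append(SiteScore(c, float(1.0 - harmony_obs[c]), float(z_scores[c]),
                             float(weight_obs[c]), float(z_weights[c]), selected))
    return out


def site_scores_table(scores: Sequence[SiteScore], msa: GroupedMsa) -> pd.DataFrame:
    consensus = {g: clade_consensus(msa, g) for g in msa.group_names}
    rows = []
    for s in scores:
        row = {"column": s.column, "divergence": s.divergence, "z_score": s.z_score,
               "relief_weight": s.relief_weight, "z_weight": s.z_weight,
               "selected": s.selected}
        for g in msa.group_names:
            row[f"consensus_{g}"] = consensus[g][s.column][0]
        rows.append(row)
    return pd.DataFrame(rows)


def write_site_scores(scores: Sequence[SiteScore], msa: GroupedMsa, path: str | Path) -> None:
    site_scores_table(scores, msa).to_csv(path, sep="\t", index=False)
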