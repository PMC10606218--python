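import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conformoscope.clade_sites import (
    AA20,
    GroupedMsa,
    MCG1_PATTERN,
    PatternSyntaxError,
    clade_consensus,
    compile_pattern,
    group_specific_sites,
    match_pattern,
    pairwise_identity,
    type_ii_shifts,
)
from conformoscope.synthetic import generate_grouped_msa


def pattern_to_regex(pattern):
    parts = []
    for tok in pattern.tokens:
        if tok.kind == "literal":
            parts.append(re.escape(next(iter(tok.letters))))
        elif tok.kind == "class":
            parts.append("[" + "".join(sorted(tok.letters)) + "]")
        else:
            parts.append(f".{{{tok.min_len},{tok.max_len}}}")
    return re.compile("".join(parts))


def minimal_expansion(pattern):
    out = []
    for tok in pattern.tokens:
        if tok.kind == "gap":
            out.append("A" * tok.min_len)
        else:
            out.append(sorted(tok.letters)[0])
    return "".join(out)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDEFGHIKL", "ACDEFGHIKL") == 100.0

    def test_single_substitution(self):
        assert pairwise_identity("ACDE", "ACDF") == 75.0

    def test_symmetric(self):
        a, b = "ACDEFGHIKLMNPQ", "ACDEFGHIKLMNPA"
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_gap_columns_excluded_from_denominator(self):
        # the declared convention counts matches over aligned (non-gap)
        # columns, so a pure truncation still scores 100
        assert pairwise_identity("ACDE", "ACD") == 100.0
        assert pairwise_identity("ACDE", "ACF") < 100.0


class TestPatternGrammar:
    def test_literal_and_class_tokens(self):
        p = compile_pattern("G[AS]G")
        assert [t.kind for t in p.tokens] == ["literal", "class", "literal"]

    def test_gap_token(self):
        p = compile_pattern("x(2,50)")
        assert p.tokens[0].kind == "gap"
        assert (p.tokens[0].min_len, p.tokens[0].max_len) == (2, 50)

    @pytest.mark.parametrize("bad", ["x(5,", "[ASD", "x(9,2)", "", "G[?]G"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(PatternSyntaxError):
            compile_pattern(bad)

    def test_render_round_trip(self):
        p = compile_pattern(MCG1_PATTERN)
        assert compile_pattern(p.render()).tokens == p.tokens


class TestPatternMatching:
    def test_simple_match_with_span(self):
        result = match_pattern(compile_pattern("G[AS]G"), "TGAGT")
        assert result.matched
        assert result.start == 1 and result.end == 4  # 0-based; residues 2-4

    def test_simple_non_match(self):
        assert not match_pattern(compile_pattern("G[AS]G"), "GTTG").matched

    def test_diagnostic_pattern_matches_own_expansion(self):
        p = compile_pattern(MCG1_PATTERN)
        seq = minimal_expansion(p)
        result = match_pattern(p, seq)
        assert result.matched and result.start == 0
        # violating a single literal breaks the match
        broken = seq.replace("DPGNWAT", "DPGNWAC", 1)
        assert not match_pattern(p, broken).matched

    def test_agrees_with_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        letters = list(AA20)
        agree = 0
        for _ in range(1000):
            toks = []
            for _ in range(rng.integers(2, 6)):
                r = rng.random()
                if r < 0.4:
                    toks.append(str(rng.choice(letters)))
                elif r < 0.7:
                    klass = rng.choice(letters, size=int(rng.integers(2, 5)), replace=False)
                    toks.append("[" + "".join(klass) + "]")
                else:
                    lo = int(rng.integers(0, 4))
                    toks.append(f"x({lo},{lo + int(rng.integers(0, 5))})")
            pattern = compile_pattern("".join(toks))
            seq = "".join(rng.choice(letters, size=int(rng.integers(10, 40))))
            mine = match_pattern(pattern, seq).matched
            oracle = pattern_to_regex(pattern).search(seq) is not None
            agree += mine == oracle
        assert agree == 1000

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seq=st.text(alphabet=AA20, min_size=0, max_size=30),
           gap_lo=st.integers(0, 3), gap_extra=st.integers(0, 4))
    def test_gap_semantics_match_regex(self, seq, gap_lo, gap_extra):
        text = f"A x({gap_lo},{gap_lo + gap_extra}) [GK]"
        pattern = compile_pattern(text)
        assert match_pattern(pattern, seq).matched == (
            pattern_to_regex(pattern).search(seq) is not None)


class TestRateShifts:
    def _msa(self, cols_a, cols_b):
        rows = {}
        for i, seq in enumerate(cols_a):
            rows[f"a{i}"] = seq
        for i, seq in enumerate(cols_b):
            rows[f"b{i}"] = seq
        groups = {k: k[0] for k in rows}
        return GroupedMsa(rows, groups)

    def test_clean_type_ii_column(self):
        msa = self._msa(["A"] * 4, ["Y"] * 4)
        shifts = type_ii_shifts(msa, ("a", "b"))
        assert len(shifts) == 1 and shifts[0].type == "ii"
        assert (shifts[0].group_a_residue, shifts[0].group_b_residue) == ("A", "Y")

    def test_type_i_column(self):
        msa = self._msa(["G"] * 4, ["G", "A", "Y", "W"])
        shifts = type_ii_shifts(msa, ("a", "b"))
        assert len(shifts) == 1 and shifts[0].type == "i"

    def test_count_invariant_under_group_swap(self):
        msa, _ = generate_grouped_msa(length=120, planted_type_ii=(5, 50, 90), seed=2)
        fwd = type_ii_shifts(msa, ("g0", "g1"))
        rev = type_ii_shifts(msa, ("g1", "g0"))
        assert len(fwd) == len(rev)
        assert sum(s.type == "ii" for s in fwd) == sum(s.type == "ii" for s in rev)

    def test_planted_shifts_recovered_without_noise(self):
        planted = tuple(range(10, 110, 10))
        msa, _ = generate_grouped_msa(length=200, planted_type_ii=planted,
                                      conservation=1.0, seed=3)
        recovered = {s.column for s in type_ii_shifts(msa, ("g0", "g1")) if s.type == "ii"}
        assert recovered == set(planted)

    def test_paired_h3_toy_alignment(self):
        # family rows conserve A/G at the two diagnostic h3 columns where the
        # outgroup conserves Y/N; both columns are recovered as type ii
        family = ["PQALTGWHKE"] * 5
        outgroup = ["PQYLTNWHKE"] * 5
        rows = {f"f{i}": family[i] for i in range(5)}
        rows.update({f"o{i}": outgroup[i] for i in range(5)})
        msa = GroupedMsa(rows, {k: ("slc11" if k[0] == "f" else "outG") for k in rows})
        shifts = [s for s in type_ii_shifts(msa, ("slc11", "outG")) if s.type == "ii"]
        assert [(s.column, s.group_a_residue, s.group_b_residue) for s in shifts] == [
            (2, "A", "Y"), (5, "G", "N")]


class TestConsensus:
    def test_single_sequence_group(self):
        msa = GroupedMsa({"a": "ACD", "b": "GGG"}, {"a": "x", "b": "y"})
        assert "".join(c for c, _ in clade_consensus(msa, "x")) == "ACD"

    def test_majority_with_frequency(self):
        msa = GroupedMsa({"a": "A", "b": "A", "c": "G"}, dict.fromkeys("abc", "x"))
        aa, freq = clade_consensus(msa, "x")[0]
        assert aa == "A" and freq == pytest.approx(2 / 3)

    def test_gap_majority_column(self):
        msa = GroupedMsa({"a": "-A", "b": "-A", "c": "CA"}, dict.fromkeys("abc", "x"))
        assert clade_consensus(msa, "x")[0][0] == "-"

    def test_planted_consensus_recovered(self):
        msa, _ = generate_grouped_msa(length=60, conservation=1.0, seed=9)
        cons = "".join(c for c, _ in clade_consensus(msa, "g0"))
        assert len(cons) == 60


class TestGroupSpecificSites:
    def test_identical_groups_not_selected(self):
        rows = {f"g{g}_s{i}": "ACDEFGHIKL" for g in range(2) for i in range(4)}
        msa = GroupedMsa(rows, {k: k.split("_")[0] for k in rows})
        scores = group_specific_sites(msa, n_subsamples=20, n_null=30, seed=0)
        assert not any(s.selected for s in scores)
        assert all(s.divergence == pytest.approx(0.0, abs=1e-12) for s in scores)

    def test_disjoint_conserved_column_is_extreme(self):
        rows = {f"g0_s{i}": "KKKKAAAA" for i in range(6)}
        rows.update({f"g1_s{i}": "EEEEAAAA" for i in range(6)})
        msa = GroupedMsa(rows, {k: k.split("_")[0] for k in rows})
        scores = group_specific_sites(msa, n_subsamples=50, n_null=100, seed=0)
        by_col = {s.column: s for s in scores}
        distinct = min(by_col[c].z_score for c in range(4))
        background = max(abs(by_col[c].z_score) for c in range(4, 8))
        assert distinct < -3
        assert background < 3
        assert all(by_col[c].z_weight > by_col[7].z_weight for c in range(4))

    def test_deterministic_given_seed(self):
        msa, _ = generate_grouped_msa(length=50, planted_selective=(5, 25), seed=4)
        a = group_specific_sites(msa, n_subsamples=10, n_null=20, seed=3)
        b = group_specific_sites(msa, n_subsamples=10, n_null=20, seed=3)
        assert [(s.z_score, s.z_weight) for s in a] == [(s.z_score, s.z_weight) for s in b]

    def test_selection_monotone_in_thresholds(self):
        msa, _ = generate_grouped_msa(length=80, planted_selective=(10, 40, 70), seed=5)
        loose = group_specific_sites(msa, seed=1, n_null=50,
                                     z_weight_threshold=2, z_score_threshold=-2)
        strict = group_specific_sites(msa, seed=1, n_null=50,
                                      z_weight_threshold=8, z_score_threshold=-15)
        assert {s.column for s in strict if s.selected} <= {s.column for s in loose if s.selected}

    def test_small_group_rejected(self):
        rows = {"g0_a": "ACD", "g0_b": "ACD", "g0_c": "ACD", "g1_a": "GGG", "g1_b": "GGG"}
        msa = GroupedMsa(rows, {k: k.split("_")[0] for k in rows})
        with pytest.raises(ValueError, match="fewer than 3"):
            group_specific_sites(msa)
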