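import dataclasses

import numpy as np
import pytest

from conformoscope.mutagenesis import (
    MutationParseError,
    Q5HQ64_REGISTRY,
    SwitchThresholds,
    Template,
    apply_mutations,
    broad_scale_deviation,
    classify_switch,
    emit_mutant_fasta,
    epistasis_score,
    parse_mutation_spec,
    suppressor_screen,
)
from conformoscope.superpose import deviation_profile
from conformoscope.synthetic import ResponseTable, simulate_mutant_response


class TestParsing:
    def test_explicit_pair(self, carrier_template):
        template, _ = carrier_template
        mset = parse_mutation_spec("A131Y G135N", template)
        assert [(m.wt_aa, m.position, m.mutant_aa) for m in mset.substitutions] == [
            ("A", 131, "Y"), ("G", 135, "N")]

    def test_wild_type_mismatch_names_position(self, carrier_template):
        template, _ = carrier_template
        with pytest.raises(MutationParseError, match="position 131.*expected V.*found A"):
            parse_mutation_spec("V131Y", template)

    def test_unknown_alias_rejected(self, carrier_template):
        template, aliases = carrier_template
        with pytest.raises(MutationParseError, match="unknown"):
            parse_mutation_spec("NOPE", template, aliases)

    def test_vnt_alias_is_vy_yn_plus_h6a(self, carrier_template):
        template, aliases = carrier_template
        vnt = parse_mutation_spec("VNT", template, aliases)
        expected = parse_mutation_spec("A131Y G135N A228T M231V H233Y", template)
        assert vnt.substitutions == expected.substitutions

    def test_position_only_shorthand(self, carrier_template):
        template, _ = carrier_template
        mset = parse_mutation_spec("228T", template)
        assert mset.substitutions[0].wt_aa == "A"
        assert mset.substitutions[0].position == 228

    def test_compound_h3_alias_expands_to_six(self, carrier_template):
        template, aliases = carrier_template
        mset = parse_mutation_spec("GYGNGG", template, aliases)
        assert len(mset.substitutions) == 6
        mutant = apply_mutations(template, mset)
        assert sum(a != b for a, b in zip(template.sequence, mutant)) == 6


class TestApply:
    def test_empty_set_identity(self, carrier_template):
        template, _ = carrier_template
        from conformoscope.mutagenesis import MutationSet
        assert apply_mutations(template, MutationSet("wt", ())) == template.sequence

    def test_pair_differs_at_two_positions(self, carrier_template):
        template, aliases = carrier_template
        mset = parse_mutation_spec("YN", template, aliases)
        mutant = apply_mutations(template, mset)
        diff = [i + 1 for i, (a, b) in enumerate(zip(template.sequence, mutant)) if a != b]
        assert diff == [131, 135]

    def test_fasta_and_manifest_emitted(self, carrier_template, tmp_path):
        template, aliases = carrier_template
        msets = [parse_mutation_spec("YN", template, aliases, label="YN")]
        emit_mutant_fasta(template, msets, tmp_path / "m.fasta", tmp_path / "manifest.tsv")
        fasta = (tmp_path / "m.fasta").read_text()
        assert fasta.startswith(">Q5HQ64-like__YN")
        manifest = (tmp_path / "manifest.tsv").read_text()
        assert "A131Y;G135N" in manifest
        assert "max_recycle 1" in manifest  # predictor settings metadata


class TestRegistry:
    def test_sites_lie_in_annotated_segments(self):
        from conformoscope.structure_io import Segment, SegmentTable
        segments = SegmentTable((
            Segment("h1", 45, 75), Segment("h3", 115, 143), Segment("h6", 215, 240),
            Segment("h7", 260, 285), Segment("h10", 380, 405), Segment("h11", 430, 455),
        ))
        Q5HQ64_REGISTRY.validate_against(segments)

    def test_mutation_spec_covers_all_sites(self, carrier_template):
        template, _ = carrier_template
        spec = Q5HQ64_REGISTRY.mutation_spec()
        mset = parse_mutation_spec(spec, template)
        assert len(mset.substitutions) == len(Q5HQ64_REGISTRY.sites)


class TestBsd:
    def test_wt_vs_wt_zero(self, truth):
        prof = deviation_profile(truth.anchor_io, truth.anchor_io,
                                 segments=truth.segment_table)
        assert broad_scale_deviation(prof) == 0.0

    def test_everything_displaced_is_one(self, truth):
        prof = deviation_profile(truth.anchor_io, truth.anchor_io,
                                 segments=truth.segment_table)
        shifted = dataclasses.replace(prof, deviations=prof.deviations + 3.0)
        assert broad_scale_deviation(shifted) == 1.0

    def test_monotone_in_tau(self, truth):
        prof = deviation_profile(truth.anchor_oo, truth.anchor_io,
                                 segments=truth.segment_table)
        taus = [0.5, 1.0, 2.0, 3.0, 5.0]
        values = [broad_scale_deviation(prof, tau) for tau in taus]
        assert values == sorted(values, reverse=True)

    def test_matches_generator_ground_truth(self, truth):
        # noiseless full switch: exactly the mobile residues move; the
        # expected fraction follows from the planted geometry
        prof = deviation_profile(truth.anchor_oo, truth.anchor_io,
                                 segments=truth.segment_table)
        bsd = broad_scale_deviation(prof, tau=2.0)
        n_mobile = sum(len(truth.helix_residues[h]) for h in truth.config.mobile_subset)
        planted_fraction = n_mobile / len(truth.anchor_oo)
        assert bsd >= planted_fraction - 0.05


class TestSwitchCalls:
    def test_wild_type_silent(self, truth):
        prof = deviation_profile(truth.anchor_io, truth.anchor_io,
                                 segments=truth.segment_table)
        call = classify_switch(prof, SwitchThresholds(signature=truth.switch_signature))
        assert call.verdict == "silent"

    def test_full_switch_hits_all_signature_groups(self, truth):
        prof = deviation_profile(truth.anchor_oo, truth.anchor_io,
                                 segments=truth.segment_table)
        call = classify_switch(prof, SwitchThresholds(signature=truth.switch_signature))
        assert call.verdict == "switched"
        assert len(call.signature_segments_hit) == len(truth.switch_signature)

    def test_single_helix_mover_is_partial(self, truth):
        table = ResponseTable(singles={"local": 1.0},
                              extra_displacement={"local": {"h9": 6.0}})
        mutant = simulate_mutant_response(truth, ["local"], table)
        prof = deviation_profile(mutant, truth.anchor_io, segments=truth.segment_table)
        call = classify_switch(prof, SwitchThresholds(signature=truth.switch_signature))
        assert call.verdict == "partial"
        assert len(call.signature_segments_hit) <= 1


class TestEpistasis:
    def test_cooperative_arithmetic(self):
        from conformoscope.mutagenesis import SwitchCall

        def call(label, bsd):
            return SwitchCall(label, bsd, {}, (), "silent", 2.0)

        score = epistasis_score(call("A", 0.0), call("B", 0.0), call("AB", 0.4))
        assert score.epsilon == pytest.approx(0.4)
        assert score.classification == "cooperative"
        score = epistasis_score(call("A", 0.3), call("B", 0.3), call("AB", 0.3))
        assert score.epsilon == pytest.approx(-0.3)
        assert score.classification == "antagonistic"
        score = epistasis_score(call("A", 0.2), call("B", 0.0), call("AB", 0.25))
        assert score.classification == "additive"

    def test_epsilon_with_empty_set_is_zero(self, truth):
        thr = SwitchThresholds(signature=truth.switch_signature)
        table = ResponseTable(singles={"a": 0.0}, native_t=1.0)

        def call(labels, seed):
            m = simulate_mutant_response(truth, labels, table, seed=seed)
            prof = deviation_profile(m, truth.anchor_io, segments=truth.segment_table)
            return classify_switch(prof, thr, label="+".join(labels) or "wt")

        a = call(["a"], 1)
        empty = call([], 2)
        combo = call(["a"], 3)  # a + nothing
        score = epistasis_score(a, empty, combo)
        assert score.epsilon == pytest.approx(0.0, abs=1e-9)
        assert score.classification == "additive"


class TestSuppressorScreen:
    def test_planted_suppressor_ranks_first(self, truth):
        thr = SwitchThresholds(signature=truth.switch_signature)
        table = ResponseTable(
            singles={"drv": 0.0, "sup": 1.0, "c1": 1.0, "c2": 1.0},
            combos={frozenset({"drv", "sup"}): 0.9},
            native_t=1.0,
        )

        def call(labels, seed):
            m = simulate_mutant_response(truth, labels, table, sigma=0.2, seed=seed)
            prof = deviation_profile(m, truth.anchor_io, segments=truth.segment_table)
            return classify_switch(prof, thr, label="+".join(labels))

        driver = call(["drv"], 1)
        combined = {c: call(["drv", c], 10 + k) for k, c in enumerate(["sup", "c1", "c2"])}
        ranked = suppressor_screen(driver, combined)
        assert ranked[0][0] == "sup"
        assert ranked[0][1] > 0.3

    def test_requires_switched_background(self, truth):
        thr = SwitchThresholds(signature=truth.switch_signature)
        prof = deviation_profile(truth.anchor_io, truth.anchor_io,
                                 segments=truth.segment_table)
        silent = classify_switch(prof, thr)
        with pytest.raises(ValueError, match="not a switched"):
            suppressor_screen(silent, {})
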