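import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from conformoscope.cartography import (
    ElasticScoreParams,
    aaa_matrix,
    assign_states,
    cartography,
    classical_mds,
    correspondence_embed,
    elastic_similarity,
    order_transition,
    self_similarity,
)
from conformoscope.structure_io import StructureModel
from conformoscope.superpose import map_residues
from conformoscope.synthetic import EnsembleConfig, generate_ensemble


def _model(model_id, coords, letters=None):
    coords = np.asarray(coords, dtype=float)
    return StructureModel(model_id, tuple(range(1, len(coords) + 1)),
                          letters or "ACDEFGHIKLMNPQRSTVWY"[: len(coords)], coords)


class TestElasticScore:
    def test_self_similarity_is_maximum(self):
        rng = np.random.default_rng(0)
        m = _model("m", rng.normal(size=(10, 3)) * 8)
        rmap = map_residues(m, m)
        s = elastic_similarity(m, m, rmap)
        assert s == pytest.approx(self_similarity(len(m), m.coords), rel=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        a = _model("a", rng.normal(size=(8, 3)) * 8)
        b = _model("b", a.coords + rng.normal(scale=1.0, size=(8, 3)))
        assert elastic_similarity(a, b) == pytest.approx(elastic_similarity(b, a))

    def test_matches_direct_summation_on_toy_pair(self):
        # 4 residues; one coordinate perturbed by 1 A
        ca = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4]], dtype=float)
        cb = ca.copy()
        cb[3, 2] = 5.0
        a, b = _model("a", ca), _model("b", cb)
        params = ElasticScoreParams()
        expected = 4 * params.theta
        for i in range(4):
            for j in range(i + 1, 4):
                da = np.linalg.norm(ca[i] - ca[j])
                db = np.linalg.norm(cb[i] - cb[j])
                ds = 0.5 * (da + db)
                expected += (params.theta - abs(da - db) / ds) * np.exp(-((ds / params.envelope_scale) ** 2))
        assert elastic_similarity(a, b, params=params) == pytest.approx(expected, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        a = _model("a", np.eye(3)[:2] * 4, "AC")
        b = _model("b", np.eye(3)[:2] * 4, "AC")
        with pytest.raises(ValueError, match="at least 3"):
            elastic_similarity(a, b)


class TestAaaMatrix:
    def test_identical_models_equal_offdiagonal(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(12, 3)) * 8
        models = [_model(f"m{i}", coords, "ACDEFGHIKLMN") for i in range(3)]
        cmap = aaa_matrix(models, ("m0", "m1"))
        off = cmap.similarity[~np.eye(3, dtype=bool)]
        np.testing.assert_allclose(off, off[0])

    def test_similarity_monotone_in_t(self, truth):
        pick = {m.model_id: m for m in truth.models}
        trio = [pick["conf_000"], pick["conf_005"], pick["conf_010"]]  # t=0,0.5,1
        cmap = aaa_matrix(trio, ("conf_000", "conf_010"))
        s = cmap.similarity
        assert s[0, 1] > s[0, 2]

    def test_diagonal_maximal_per_row(self, truth):
        models = [truth.anchor_oo, truth.anchor_io, *truth.models[:4]]
        cmap = aaa_matrix(models, ("anchor_OO", "anchor_IO"))
        for i in range(len(models)):
            assert cmap.similarity[i, i] == pytest.approx(cmap.similarity[i].max())

    def test_missing_anchor_rejected(self, truth):
        with pytest.raises(ValueError, match="anchor"):
            aaa_matrix(truth.models[:3], ("anchor_OO", "conf_000"))


class TestEmbedding:
    def test_two_planted_clusters_separate_on_axis1(self):
        cfg = EnsembleConfig(t_values=(0.0, 0.02, 0.05, 0.08, 0.92, 0.95, 0.98, 1.0))
        tr = generate_ensemble(cfg)
        cmap = cartography([tr.anchor_oo, tr.anchor_io, *tr.models],
                           ("anchor_OO", "anchor_IO"))
        from sklearn.metrics import silhouette_score
        labels = [0 if tr.t_of.get(m, 0.0 if m == "anchor_OO" else 1.0) < 0.5 else 1
                  for m in cmap.model_ids]
        assert silhouette_score(cmap.embedding[:, :1], labels) > 0.8

    def test_axis1_orders_noiseless_series(self, truth):
        cmap = cartography([truth.anchor_oo, truth.anchor_io, *truth.models],
                           ("anchor_OO", "anchor_IO"))
        axis1 = {m: cmap.embedding[i, 0] for i, m in enumerate(cmap.model_ids)}
        rho = spearmanr([truth.t_of[m] for m in truth.t_of],
                        [axis1[m] for m in truth.t_of]).statistic
        assert abs(rho) >= 0.99

    def test_agrees_with_classical_mds_ranks(self, truth):
        cmap = aaa_matrix([truth.anchor_oo, truth.anchor_io, *truth.models],
                          ("anchor_OO", "anchor_IO"))
        emb = correspondence_embed(cmap)
        mds = classical_mds(cmap.similarity.max() - cmap.similarity)
        rho = spearmanr(emb[:, 0], mds[:, 0]).statistic
        assert abs(rho) >= 0.95

    def test_sign_canonicalization_reproducible(self, truth):
        cmap = aaa_matrix([truth.anchor_oo, truth.anchor_io, *truth.models],
                          ("anchor_OO", "anchor_IO"))
        e1 = correspondence_embed(cmap)
        e2 = correspondence_embed(cmap)
        np.testing.assert_allclose(e1, e2)
        for k in range(e1.shape[1]):
            assert e1[np.argmax(np.abs(e1[:, k])), k] >= 0


class TestStateCalls:
    def test_anchors_called_correctly(self, truth):
        cmap = aaa_matrix([truth.anchor_oo, truth.anchor_io, *truth.models],
                          ("anchor_OO", "anchor_IO"))
        calls = assign_states(cmap)
        assert calls["anchor_OO"][0] == "OO"
        assert calls["anchor_IO"][0] == "IO"

    def test_midpoint_is_intermediate(self, truth):
        cmap = aaa_matrix([truth.anchor_oo, truth.anchor_io, *truth.models],
                          ("anchor_OO", "anchor_IO"))
        calls = assign_states(cmap)
        assert calls["conf_005"][0] == "intermediate"  # t = 0.5

    def test_antisymmetric_under_anchor_swap(self, truth):
        models = [truth.anchor_oo, truth.anchor_io, *truth.models]
        fwd = assign_states(aaa_matrix(models, ("anchor_OO", "anchor_IO")))
        rev = assign_states(aaa_matrix(models, ("anchor_IO", "anchor_OO")))
        swap = {"OO": "IO", "IO": "OO", "intermediate": "intermediate"}
        for mid, (state, _) in fwd.items():
            assert rev[mid][0] == swap[state]

    def test_margins_within_unit_interval(self, truth):
        cmap = aaa_matrix([truth.anchor_oo, truth.anchor_io, *truth.models],
                          ("anchor_OO", "anchor_IO"))
        for _, (_, margin) in assign_states(cmap).items():
            assert -1.0 <= margin <= 1.0


class TestTransitionOrder:
    def test_series_ordered_by_planted_t(self):
        cfg = EnsembleConfig(t_values=(0.05, 0.2, 0.35, 0.5, 0.65, 0.8, 0.95))
        tr = generate_ensemble(cfg)
        cmap = cartography([tr.anchor_oo, tr.anchor_io, *tr.models],
                           ("anchor_OO", "anchor_IO"))
        order = [m for m in cmap.transition_order if m in tr.t_of]
        ts = [tr.t_of[m] for m in order]
        assert ts == sorted(ts) or ts == sorted(ts, reverse=True)
        assert cmap.transition_order[0] == "anchor_OO"
        assert cmap.transition_order[-1] == "anchor_IO"
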