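"""Ground-truth recovery benchmarks on the synthetic study conditions.

Each function runs one end-to-end recovery experiment against the synthetic
generators' planted truth and returns the measured quantities. They are the
package's self-validation suite: the acceptance tests assert on their
outputs and the reproduction script reports them.

All experiments are fully seeded; the independent oracles used (rotation
grid search, regular-expression engine, classical MDS) never share code
with the implementation paths they check.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterable

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation
from scipy.stats import kstest, spearmanr

from .cartography import cartography
from .clade_sites import AA20, SequencePattern, compile_pattern, group_specific_sites, match_pattern
from .colocalization import colocalization_test
from .mutagenesis import (
    Q5HQ64_REGISTRY,
    SwitchThresholds,
    Template,
    apply_mutations,
    classify_switch,
    epistasis_score,
    parse_mutation_spec,
    suppressor_screen,
)
from .networks import build_psn, compare_state_networks, consensus_network, contact_norm_factors
from .superpose import deviation_profile, kabsch_superpose
from .synthetic import (
    EnsembleConfig,
    ResponseTable,
    generate_ensemble,
    generate_grouped_msa,
    simulate_mutant_response,
)


def _subseed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31 - 1))


# ---------------------------------------------------------------------------
# superposition


def grid_search_rmsd(a: np.ndarray, b: np.ndarray, coarse_deg: float = 15.0) -> float:
    """Brute-force superposition oracle: Euler-angle grid over proper
    rotations of the centred coordinates, polished by a simplex search."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    n = len(a)

    def rmsd_of(angles):
        r = Rotation.from_euler("zyz", angles, degrees=True).as_matrix()
        return np.sqrt(((b @ r.T - a) ** 2).sum() / n)

    grid = np.arange(0.0, 360.0, coarse_deg)
    tilt = np.arange(0.0, 180.0 + 1e-9, coarse_deg)
    best = min(itertools.product(grid, tilt, grid), key=rmsd_of)
    res = minimize(rmsd_of, best, method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


def superposition_oracle_check(seed: int, n_sets: int = 6) -> dict:
    """Max |Kabsch RMSD - grid-search RMSD| over random small point sets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_sets):
        n = int(rng.integers(4, 9))
        a = rng.normal(size=(n, 3)) * 3.0
        b = a + rng.normal(scale=0.4, size=a.shape)
        _, _, rmsd = kabsch_superpose(a, b)
        worst = max(worst, abs(rmsd - grid_search_rmsd(a, b)))
    return {"max_abs_diff_A": worst, "n": n_sets}


# ---------------------------------------------------------------------------
# cartography


def cartography_recovery(seed: int) -> dict:
    """State-call and ordering recovery on the rocking-bundle preset."""
    rng = np.random.default_rng(seed)

    truth = generate_ensemble(EnsembleConfig(seed=_subseed(rng)))
    cmap = cartography([truth.anchor_oo, truth.anchor_io, *truth.models],
                       ("anchor_OO", "anchor_IO"))
    axis1 = {m: cmap.embedding[i, 0] for i, m in enumerate(cmap.model_ids)}
    rho = spearmanr([truth.t_of[m] for m in truth.t_of],
                    [axis1[m] for m in truth.t_of]).statistic
    acc0 = float(np.mean([cmap.state_calls[m][0] == truth.state_of[m]
                          for m in truth.t_of]))

    ts = tuple(np.round(np.random.default_rng(_subseed(rng)).uniform(0, 1, 30), 3))
    noisy = generate_ensemble(EnsembleConfig(t_values=ts, noise_sigma=0.5,
                                             seed=_subseed(rng)))
    cmap_noisy = cartography([noisy.anchor_oo, noisy.anchor_io, *noisy.models],
                             ("anchor_OO", "anchor_IO"))
    acc5 = float(np.mean([cmap_noisy.state_calls[m][0] == noisy.state_of[m]
                          for m in noisy.t_of]))
    return {
        "spearman_abs": abs(float(rho)),
        "state_accuracy_sigma0": acc0,
        "state_accuracy_sigma05": acc5,
        "n_sigma0": len(truth.t_of),
        "n_sigma05": len(noisy.t_of),
    }


# ---------------------------------------------------------------------------
# networks


def network_recovery(seed: int) -> dict:
    """Recovery of the state-exclusive contact communities at sigma = 0."""
    truth = generate_ensemble(EnsembleConfig(seed=seed))
    norm = contact_norm_factors(truth.models)
    oo = [build_psn(m, norm_factors=norm) for m in truth.models
          if truth.state_of[m.model_id] == "OO"]
    io = [build_psn(m, norm_factors=norm) for m in truth.models
          if truth.state_of[m.model_id] == "IO"]
    comparison = compare_state_networks(consensus_network(oo), consensus_network(io),
                                        truth.segment_table)
    oo_nodes = set(itertools.chain.from_iterable(comparison.oo_only))
    io_nodes = set(itertools.chain.from_iterable(comparison.io_only))

    def jaccard(a: set, b: Iterable) -> float:
        b = set(b)
        return len(a & b) / len(a | b) if a | b else 0.0

    j_oo = jaccard(oo_nodes, truth.oo_community_residues)
    j_io = jaccard(io_nodes, truth.io_community_residues)
    # adjusted Rand index of the detected two-community partition against
    # the planted one, over the state-specific nodes
    nodes = sorted(oo_nodes | io_nodes)
    detected = [0 if n in oo_nodes else 1 for n in nodes]
    planted = [0 if n in truth.oo_community_residues else 1 for n in nodes]
    return {
        "jaccard_oo": j_oo,
        "jaccard_io": j_io,
        "ari": _adjusted_rand(planted, detected),
        "n_nodes": len(nodes),
    }


def _adjusted_rand(a: list[int], b: list[int]) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    from scipy.special import comb

    a_arr, b_arr = np.asarray(a), np.asarray(b)
    classes, clusters = np.unique(a_arr), np.unique(b_arr)
    table = np.array([[np.sum((a_arr == i) & (b_arr == j)) for j in clusters]
                      for i in classes])
    sum_comb = comb(table, 2).sum()
    sum_a = comb(table.sum(axis=1), 2).sum()
    sum_b = comb(table.sum(axis=0), 2).sum()
    total = comb(len(a), 2)
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


# ---------------------------------------------------------------------------
# switch / epistasis


def switch_epistasis_recovery(seed: int, sigma: float = 0.3) -> dict:
    """Verdict and epistasis-class recovery over 40 planted mutants."""
    rng = np.random.default_rng(seed)
    truth = generate_ensemble(EnsembleConfig(seed=_subseed(rng)))
    native = truth.anchor_io
    thresholds = SwitchThresholds(signature=truth.switch_signature)

    silent_singles = [f"s{i:02d}" for i in range(26)]
    singles = {label: 1.0 for label in silent_singles}
    singles.update({"a00": 0.0, "a01": 0.0, "w00": 0.0, "r00": 1.0, "r01": 1.0})
    coop_pairs = [("s00", "s01"), ("s02", "s03"), ("s04", "s05"),
                  ("s06", "s07"), ("s10", "s11")]
    combos = {frozenset(p): 0.0 for p in coop_pairs}
    combos[frozenset({"a00", "a01"})] = 1.0       # planted antagonism
    combos[frozenset({"w00", "r00"})] = 0.95      # planted suppressor
    combos[frozenset({"w00", "r01"})] = 0.0       # non-suppressor control
    table = ResponseTable(singles=singles, combos=combos, native_t=1.0)

    mutants: list[tuple[tuple[str, ...], str]] = []
    for label in silent_singles + ["r00", "r01"]:
        mutants.append(((label,), "silent"))
    mutants += [(("a00",), "switched"), (("a01",), "switched"), (("w00",), "switched")]
    mutants += [(pair, "switched") for pair in coop_pairs]
    mutants += [(("s08", "s09"), "silent")]       # additive (unlisted combo)
    mutants += [(("a00", "a01"), "silent"),
                (("w00", "r00"), "silent"),
                (("w00", "r01"), "switched")]
    assert len(mutants) == 40

    calls = {}
    for labels, _ in mutants:
        model = simulate_mutant_response(truth, list(labels), table, sigma=sigma,
                                         seed=_subseed(rng))
        prof = deviation_profile(model, native, segments=truth.segment_table)
        calls[labels] = classify_switch(prof, thresholds, label="+".join(labels))

    verdict_hits = sum(calls[labels].verdict == expected for labels, expected in mutants)

    epi_pairs = [(p, "cooperative") for p in coop_pairs]
    epi_pairs += [(("s08", "s09"), "additive"), (("a00", "a01"), "antagonistic")]
    epi_hits = 0
    for (a, b), expected in epi_pairs:
        score = epistasis_score(calls[(a,)], calls[(b,)], calls[(a, b)])
        epi_hits += score.classification == expected

    ranked = suppressor_screen(calls[("w00",)], {
        "r00": calls[("w00", "r00")],
        "r01": calls[("w00", "r01")],
    })
    return {
        "verdict_accuracy": verdict_hits / len(mutants),
        "epistasis_accuracy": epi_hits / len(epi_pairs),
        "combined_accuracy": (verdict_hits + epi_hits) / (len(mutants) + len(epi_pairs)),
        "suppressor_top_ranked": ranked[0][0] == "r00",
        "n_mutants": len(mutants),
    }


# ---------------------------------------------------------------------------
# pattern matching


def pattern_to_regex(pattern: SequencePattern) -> re.Pattern:
    parts = []
    for tok in pattern.tokens:
        if tok.kind == "literal":
            parts.append(re.escape(next(iter(tok.letters))))
        elif tok.kind == "class":
            parts.append("[" + "".join(sorted(tok.letters)) + "]")
        else:
            parts.append(f".{{{tok.min_len},{tok.max_len}}}")
    return re.compile("".join(parts))


def pattern_oracle_agreement(seed: int, n_trials: int = 1000) -> dict:
    """Fraction of random pattern/sequence trials agreeing with a regex
    oracle, plus constructive expansions of the clade-diagnostic pattern."""
    from .clade_sites import MCG1_PATTERN

    rng = np.random.default_rng(seed)
    letters = list(AA20)
    agree = 0
    for _ in range(n_trials):
        toks = []
        for _ in range(int(rng.integers(2, 6))):
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
        agree += mine == (pattern_to_regex(pattern).search(seq) is not None)

    mcg1 = compile_pattern(MCG1_PATTERN)
    expansion = "".join(
        "A" * tok.min_len if tok.kind == "gap" else sorted(tok.letters)[0]
        for tok in mcg1.tokens
    )
    expansion_hits = match_pattern(mcg1, expansion).matched
    broken = expansion.replace("DPGNWAT", "DPGNWAC", 1)
    expansion_hits &= not match_pattern(mcg1, broken).matched
    return {
        "oracle_agreement": agree / n_trials,
        "diagnostic_pattern_expansion_ok": bool(expansion_hits),
        "n": n_trials,
    }


# ---------------------------------------------------------------------------
# group-specific sites


def site_recovery(seed: int, n_columns: int = 400, n_planted: int = 45) -> dict:
    """Precision/recall of planted group-selective columns at the
    conventional dual thresholds (z-weight > 6, z-score < -10)."""
    rng = np.random.default_rng(seed)
    planted = tuple(sorted(rng.choice(n_columns, size=n_planted, replace=False)))
    msa, _ = generate_grouped_msa(length=n_columns, planted_selective=planted,
                                  seed=_subseed(rng))
    scores = group_specific_sites(msa, seed=_subseed(rng))
    picked = {s.column for s in scores if s.selected}
    tp = len(picked & set(planted))
    return {
        "precision": tp / len(picked) if picked else 0.0,
        "recall": tp / n_planted,
        "n_selected": len(picked),
        "n_planted": n_planted,
    }


# ---------------------------------------------------------------------------
# colocalization


def colocalization_calibration(seed: int, n_replicates: int = 200,
                               n_permutations: int = 199) -> dict:
    """KS uniformity p-value of permutation p-values under random site sets."""
    rng = np.random.default_rng(seed)
    truth = generate_ensemble(EnsembleConfig(seed=_subseed(rng)))
    model = truth.anchor_oo
    pvals = []
    for _ in range(n_replicates):
        sites = rng.choice(model.numbers, size=6, replace=False)
        res = colocalization_test(model, sites, n_permutations=n_permutations,
                                  seed=_subseed(rng))
        pvals.append(res.empirical_p)
    return {"ks_pvalue": float(kstest(pvals, "uniform").pvalue), "n": n_replicates}


def colocalization_planted(seed: int) -> dict:
    """p-value for the six planted sites split over two tight helix pairs."""
    truth = generate_ensemble(EnsembleConfig(seed=seed))
    sites = sorted(truth.oo_community_residues)[:3] + sorted(truth.io_community_residues)[:3]
    res = colocalization_test(truth.anchor_oo, sites, n_permutations=999, seed=seed)
    return {"p_value": res.empirical_p, "n_sites": len(sites)}


# ---------------------------------------------------------------------------
# compound h3 alias


def compound_h3_alias_count() -> dict:
    """Number of substitutions the six-site h3 alias expands to on a
    registry-conformant carrier template."""
    h3_gs = (127, 133, 138, 141)
    seq = ["L"] * 460
    for site in Q5HQ64_REGISTRY.sites:
        seq[site.position - 1] = site.wt_aa
    for pos in h3_gs:
        seq[pos - 1] = "S"
    template = Template("Q5HQ64-like", "".join(seq))
    aliases = Q5HQ64_REGISTRY.alias_table(h3_outgroup_g_positions=h3_gs)
    mset = parse_mutation_spec("GYGNGG", template, aliases)
    mutant = apply_mutations(template, mset)
    n_diff = sum(a != b for a, b in zip(template.sequence, mutant))
    return {"n_substitutions": len(mset.substitutions), "n_sequence_diffs": n_diff}
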