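"""Distances, the statistical-parsimony connection limit, network
construction and strain assignment."""

import itertools
import math

import numpy as np
import pytest

from wolbscan import (
    ConfigError,
    WolbscanError,
    assign_strains,
    build_network,
    hamming_matrix,
    haplotype_spectrum,
    parsimony_connection_limit,
    parsimony_probability,
)


class TestHamming:
    def test_identical_sequences(self):
        d = hamming_matrix({"a": "0101", "b": "0101"})
        assert d.steps[0, 1] == 0

    def test_by_inspection(self):
        d = hamming_matrix({"a": "0101", "b": "0110"})
        assert d.steps[0, 1] == 2
        assert d.p_distance[0, 1] == 0.5

    def test_matches_site_by_site_loop(self, rng):
        """Independent oracle: count differing sites with a plain loop."""
        strings = ["".join(rng.choice(list("01"), size=115))
                   for _ in range(12)]
        d = hamming_matrix(strings)
        for i in range(12):
            for j in range(12):
                brute = sum(a != b for a, b in zip(strings[i], strings[j]))
                assert d.steps[i, j] == brute

    def test_matrix_properties(self, rng):
        strings = ["".join(rng.choice(list("01"), size=40))
                   for _ in range(8)]
        d = hamming_matrix(strings)
        assert (d.steps == d.steps.T).all()
        assert (np.diag(d.steps) == 0).all()
        for i, j, k in itertools.permutations(range(8), 3):
            assert d.steps[i, k] <= d.steps[i, j] + d.steps[j, k]

    def test_unequal_lengths_rejected(self):
        with pytest.raises(WolbscanError, match="length"):
            hamming_matrix({"a": "010", "b": "0101"})


# --------------------------------------------------------------------------
# Independent transcriptions of the parsimony-probability model
# --------------------------------------------------------------------------

def oracle_probability_exact(j: int, m: int, qmax: int = 60) -> float:
    """Exact site-by-site dynamic program (no generating functions).

    States track (mutations left, differing sites so far, no-reversion
    flag); mutations are allocated site by site with binomial splits.
    Feasible only for small m.
    """
    pk = [0.0] * (qmax + 1)
    for k in range(qmax):
        pk[k + 1] = 1.0 - pk[k] / 3.0
    r = j / (1.0 + j)
    num = den = 0.0
    for q in range(j, qmax + 1):
        w = r ** q
        f = {(q, 0, True): 1.0}
        for s in range(m):
            left = m - s
            g = {}
            for (rem, d, ok), p in f.items():
                pr = 1.0 / left
                for k in range(rem + 1):
                    wk = math.comb(rem, k) * pr ** k * (1 - pr) ** (rem - k)
                    if wk < 1e-16:
                        continue
                    if pk[k] > 0:
                        key = (rem - k, d + 1, ok)
                        g[key] = g.get(key, 0.0) + p * wk * pk[k]
                    if pk[k] < 1:
                        key = (rem - k, d, ok and k == 0)
                        g[key] = g.get(key, 0.0) + p * wk * (1 - pk[k])
            f = g
        obs = sum(p for (rem, d, ok), p in f.items()
                  if rem == 0 and d == j)
        pars = sum(p for (rem, d, ok), p in f.items()
                   if rem == 0 and d == j and ok)
        num += w * pars
        den += w * obs
    return num / den


def oracle_probability_mc(j: int, m: int, n_draws: int = 400_000,
                          seed: int = 0) -> float:
    """Monte-Carlo transcription: simulate the generative model directly.

    Draw the true mutation count from the geometric prior, scatter
    mutations uniformly over sites with a symmetric 4-state jump chain,
    condition on j observed differences, and estimate the fraction of
    conditioned draws with no reverted site.
    """
    rng = np.random.default_rng(seed)
    r = j / (1.0 + j)
    q = j + rng.geometric(1.0 - r, size=n_draws) - 1  # support j, j+1, ...
    hits_ok = 0
    cond = 0
    for qi in np.unique(q):
        n_q = int((q == qi).sum())
        sites = rng.integers(0, m, size=(n_q, qi))
        # per draw: per-site hit counts -> state after k 4-state jumps
        for row in sites:
            counts = np.bincount(row, minlength=m)
            hit = counts > 0
            # differing prob after k hits follows p_{k+1} = 1 - p_k/3;
            # realise each site's final state by explicit jumps
            differs = np.zeros(m, dtype=bool)
            for s in np.nonzero(hit)[0]:
                state = 0
                for _ in range(counts[s]):
                    state = rng.integers(1, 4) if state == 0 else \
                        (0 if rng.integers(0, 3) == 0 else state)
                differs[s] = state != 0
            if differs.sum() == j:
                cond += 1
                if differs[hit].all():
                    hits_ok += 1
    return hits_ok / cond if cond else float("nan")


class TestParsimonyLimit:
    def test_probability_matches_exact_dp_at_small_m(self):
        for j, m in [(1, 8), (2, 10), (3, 12)]:
            assert parsimony_probability(j, m) == pytest.approx(
                oracle_probability_exact(j, m), abs=1e-7)

    def test_probability_matches_monte_carlo_at_survey_scale(self):
        # MC oracle is slow; sample a modest number of draws and allow
        # the corresponding binomial error.
        p = parsimony_probability(5, 115)
        mc = oracle_probability_mc(5, 115, n_draws=40_000, seed=3)
        assert p == pytest.approx(mc, abs=0.01)

    def test_limit_at_survey_scale(self):
        """At 115 sites the 95% limit connects pairs up to 5 steps and
        separates anything at 14+ steps (strain-scale divergence)."""
        limit = parsimony_connection_limit(115, 0.95)
        assert limit == 5
        assert parsimony_probability(5, 115) >= 0.95
        assert parsimony_probability(6, 115) < 0.95
        assert limit < 14

    def test_limit_monotone_in_confidence(self):
        limits = [parsimony_connection_limit(115, c)
                  for c in (0.5, 0.8, 0.9, 0.95, 0.99)]
        assert limits == sorted(limits, reverse=True)

    def test_vanishing_stringency_connects_everything(self):
        assert parsimony_connection_limit(20, 1e-9) == 20

    def test_probability_decreases_with_divergence(self):
        probs = [parsimony_probability(j, 115) for j in range(1, 20)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_longer_sequences_connect_more_steps(self):
        assert parsimony_connection_limit(600) > \
            parsimony_connection_limit(115)

    def test_bad_arguments(self):
        with pytest.raises(ConfigError):
            parsimony_connection_limit(0)
        with pytest.raises(ConfigError):
            parsimony_connection_limit(100, 1.0)


class TestBuildNetwork:
    def haps(self, **kw):
        base = "0" * 30
        def flip(s, idx):
            l = list(s)
            for i in idx:
                l[i] = "1" if l[i] == "0" else "0"
            return "".join(l)
        return {
            "h1": base,
            "h2": flip(base, [0]),
            "h3": flip(base, [0, 1, 2]),
            "h4": flip(base, range(5, 25)),
        }

    def test_components_split_at_limit(self):
        d = hamming_matrix(self.haps())
        net = build_network(d, limit=10)
        comp = net.component_of()
        assert comp["h1"] == comp["h2"] == comp["h3"]
        assert comp["h4"] != comp["h1"]
        assert len(net.components) == 2

    def test_brute_force_components(self, rng):
        strings = {f"h{i}": "".join(rng.choice(list("01"), size=25))
                   for i in range(10)}
        d = hamming_matrix(strings)
        limit = 6
        net = build_network(d, limit=limit)
        # brute-force reachability over threshold edges
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(strings)
        labels = d.labels
        for i in range(10):
            for j in range(i + 1, 10):
                if 0 < d.steps[i, j] <= limit:
                    g.add_edge(labels[i], labels[j])
        expected = {frozenset(c) for c in nx.connected_components(g)}
        assert set(net.components) == expected

    def test_single_haplotype(self):
        net = build_network(hamming_matrix({"h1": "0000"}), limit=3)
        assert len(net.components) == 1 and net.edges == []

    def test_all_within_limit_single_component(self):
        net = build_network(hamming_matrix(self.haps()), limit=30)
        assert len(net.components) == 1
        # minimum spanning structure has n-1 edges
        assert len(net.edges) == 3

    def test_every_edge_within_limit(self):
        net = build_network(hamming_matrix(self.haps()), limit=10)
        assert all(s <= 10 for _, _, s in net.edges)

    def test_inter_component_distance_exceeds_limit(self):
        d = hamming_matrix(self.haps())
        net = build_network(d, limit=10)
        comp = net.component_of()
        labels = d.labels
        for i in range(len(labels)):
            for j in range(i + 1, len(labels)):
                if comp[labels[i]] != comp[labels[j]]:
                    assert d.steps[i, j] > 10

    def test_components_invariant_to_input_order(self, rng):
        strings = {f"h{i}": "".join(rng.choice(list("01"), size=30))
                   for i in range(12)}
        ref = None
        keys = list(strings)
        for _ in range(10):
            rng.shuffle(keys)
            d = hamming_matrix({k: strings[k] for k in keys})
            comps = {frozenset(c)
                     for c in build_network(d, limit=8).components}
            if ref is None:
                ref = comps
            assert comps == ref

    def test_partitions_nest_as_limit_grows(self, rng):
        strings = {f"h{i}": "".join(rng.choice(list("01"), size=40))
                   for i in range(15)}
        d = hamming_matrix(strings)
        prev = None
        for limit in (2, 5, 10, 20, 40):
            comps = build_network(d, limit=limit).components
            if prev is not None:
                # every earlier component is contained in one new one
                for old in prev:
                    assert any(old <= new for new in comps)
            prev = comps

    def test_inferred_nodes_count(self):
        d = hamming_matrix({"a": "0000", "b": "0111"})
        net = build_network(d, limit=5)
        assert net.inferred_nodes == 2  # a 3-step edge renders 2 inferred


class TestAssignStrains:
    def build(self, sizes, sep=20):
        """Planted components with the given individual counts."""
        haps = {}
        ind_map = {}
        idx = 0
        base = ["0"] * 200
        for ci, size in enumerate(sizes):
            s = base.copy()
            for k in range(ci * sep, ci * sep + sep):
                s[k] = "1"
            hap = "".join(s)
            label = f"c{ci}"
            haps[label] = hap
            for _ in range(size):
                ind_map[f"ind{idx}"] = label
                idx += 1
        net = build_network(hamming_matrix(haps), limit=5)
        return net, ind_map

    def test_labels_by_decreasing_count(self):
        net, ind_map = self.build([103, 992, 172])
        asg = assign_strains(net, ind_map)
        assert asg.strain_counts == {"A": 992, "B": 172, "C": 103}

    def test_rare_flagging(self):
        net, ind_map = self.build([50, 1, 1, 30])
        asg = assign_strains(net, ind_map, min_major=11)
        assert asg.major == {"A": True, "B": True, "C": False, "D": False}
        assert len(asg.rare_strains()) == 2

    def test_single_component_single_strain(self):
        net, ind_map = self.build([7])
        asg = assign_strains(net, ind_map, min_major=5)
        assert asg.strains == ["A"] and asg.rare_strains() == []

    def test_unmapped_haplotype_is_an_error(self):
        net, ind_map = self.build([3])
        ind_map["extra"] = "nonexistent"
        with pytest.raises(WolbscanError, match="nonexistent"):
            assign_strains(net, ind_map)

    def test_spectrum_sums(self):
        net, ind_map = self.build([100, 3, 1, 1])
        asg = assign_strains(net, ind_map, min_major=2)
        spec = haplotype_spectrum(asg).set_index("strain")
        assert int(spec.n_individuals.sum()) == 105
        assert int(spec.loc["A"].n_haplotypes) == 1
        assert spec.loc["A"].multiplicities == "100"


class TestPlantedStrainRecovery:
    def test_planted_strains_recovered(self):
        """Generated strain structure is recovered exactly by the network
        at default parameters (ARI = 1 over infected individuals)."""
        from sklearn.metrics import adjusted_rand_score
        from wolbscan import SimulationConfig, simulate_truth
        for seed in range(5):
            cfg = SimulationConfig(n_localities=9,
                                   individuals_per_locality=15, seed=seed)
            truth = simulate_truth(cfg)
            inf = truth.individuals[truth.individuals.infected]
            haps = sorted(set(inf.haplotype))
            d = hamming_matrix({f"H{i}": h for i, h in enumerate(haps)})
            net = build_network(d)
            comp = net.component_of()
            label_of = {h: f"H{i}" for i, h in enumerate(haps)}
            inferred = [comp[label_of[h]] for h in inf.haplotype]
            assert adjusted_rand_score(inf.strain, inferred) == 1.0
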