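import math
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from starscan.genotype_io import GenotypeMatrix, PopulationAssignment
from starscan.preprocess import Window, assign_sites, make_windows
from starscan.sstar_core import (CandidateSiteSet, ScoreFunctionParams,
                                 candidate_sites, compute_sstar, pair_score,
                                 sstar_scan)

PARAMS = ScoreFunctionParams()


def brute_force_sstar(positions, genotypes, params=PARAMS):
    """Independent oracle: exhaustive maximization over all increasing chains."""
    k = len(positions)
    best, best_chain = 0.0, ()
    for r in range(2, k + 1):
        for chain in combinations(range(k), r):
            total = 0.0
            for a, b in zip(chain, chain[1:]):
                s = pair_score(positions[a], positions[b], genotypes[a],
                               genotypes[b], params)
                if s == -math.inf:
                    break
                total += s
            else:
                pos_chain = tuple(positions[i] for i in chain)
                if total > best or (total == best and best > 0
                                    and pos_chain < best_chain):
                    best, best_chain = total, pos_chain
    return best, best_chain


def candidate_set(positions, genotypes):
    positions = np.asarray(positions)
    w = Window("1", 0, int(positions.max()) + 1,
               np.arange(len(positions), dtype=np.intp))
    return CandidateSiteSet("tgt_0", w, w.site_indices, positions,
                            np.asarray(genotypes, dtype=np.int8))


class TestPairScore:
    def test_matching_pair_scores_distance_plus_bonus(self):
        assert pair_score(1000, 6000, 2, 2) == 10_000

    def test_close_identical_pair_forbidden(self):
        assert pair_score(100, 110, 1, 1) == 10 + 5000
        assert pair_score(100, 105, 1, 1) == -math.inf

    def test_small_genotype_mismatch_pays_penalty(self):
        assert pair_score(1000, 2000, 2, 1) == -10_000

    def test_large_genotype_distance_forbidden(self):
        params = ScoreFunctionParams(max_geno_dist=1)
        assert pair_score(1000, 2000, 0, 2, params) == -math.inf

    def test_non_increasing_positions_rejected(self):
        with pytest.raises(ValueError):
            pair_score(2000, 1000, 1, 1)


class TestComputeSstar:
    def test_two_matching_candidates(self):
        sc = compute_sstar(candidate_set([1000, 6000], [2, 2]))
        assert sc.sstar == 10_000
        assert sc.chain == (1000, 6000)

    def test_single_candidate_scores_zero(self):
        sc = compute_sstar(candidate_set([5000], [2]))
        assert sc.sstar == 0 and sc.chain == ()

    def test_three_candidates_skip_close_neighbor(self):
        # (100,105) is forbidden (d<10), so the best chain jumps 100 -> 9000
        sc = compute_sstar(candidate_set([100, 105, 9000], [2, 2, 2]))
        assert sc.sstar == 13_900
        assert sc.chain == (100, 9000)

    def test_all_negative_chains_floored_at_zero(self):
        sc = compute_sstar(candidate_set([100, 200], [2, 1]))
        assert sc.sstar == 0 and sc.chain == ()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            k = rng.integers(2, 11)
            pos = np.sort(rng.choice(50_000, size=k, replace=False)) + 1
            gen = rng.integers(1, 3, size=k)
            sc = compute_sstar(candidate_set(pos, gen))
            expected, chain = brute_force_sstar(list(pos), list(gen))
            assert sc.sstar == expected
            assert sc.chain == chain  # lexicographic tie-break matches too

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.data())
    def test_translation_invariance(self, data):
        k = data.draw(st.integers(2, 8))
        pos = sorted(data.draw(st.sets(st.integers(1, 30_000), min_size=k,
                                       max_size=k)))
        gen = data.draw(st.lists(st.integers(1, 2), min_size=k, max_size=k))
        shift = data.draw(st.integers(1, 10_000))
        base = compute_sstar(candidate_set(pos, gen)).sstar
        shifted = compute_sstar(
            candidate_set([p + shift for p in pos], gen)).sstar
        assert base == shifted

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_appending_matching_block_never_decreases_score(self, data):
        k = data.draw(st.integers(2, 6))
        pos = sorted(data.draw(st.sets(st.integers(1, 10_000), min_size=k,
                                       max_size=k)))
        gen = data.draw(st.lists(st.integers(1, 2), min_size=k, max_size=k))
        base = compute_sstar(candidate_set(pos, gen)).sstar
        # identical-code block far to the right, spaced >= min_bp_dist
        block_start = pos[-1] + 20_000
        nb = data.draw(st.integers(2, 4))
        pos2 = pos + [block_start + 100 * i for i in range(nb)]
        gen2 = gen + [2] * nb
        extended = compute_sstar(candidate_set(pos2, gen2)).sstar
        assert extended >= base

    def test_single_matching_pair_scale_property(self):
        for d in (10, 137, 5000, 49_999):
            sc = compute_sstar(candidate_set([1, 1 + d], [1, 1]))
            assert sc.sstar - PARAMS.match_bonus == d


class TestCandidateSites:
    def test_reference_carriers_disqualify(self):
        samples = ["ref_0", "ref_1", "tgt_0"]
        G = np.array([[0, 0, 1], [0, 0, 0], [1, 2, 2]], dtype=np.int8)
        gm = GenotypeMatrix(["1"] * 3, [100, 200, 300], ["A"] * 3, ["T"] * 3,
                            [True] * 3, samples, G)
        a = PopulationAssignment(["ref_0", "ref_1"], ["tgt_0"])
        w = assign_sites(make_windows(1000, 1000, 1000), gm)[0]
        c = candidate_sites(gm, a, w, "tgt_0")
        assert c.positions.tolist() == [100]

    def test_ref_max_daf_relaxes_the_rule(self):
        samples = ["ref_0", "ref_1", "tgt_0"]
        G = np.array([[1, 0, 2]], dtype=np.int8)
        gm = GenotypeMatrix(["1"], [100], ["A"], ["T"], [True], samples, G)
        a = PopulationAssignment(["ref_0", "ref_1"], ["tgt_0"])
        w = assign_sites(make_windows(1000, 1000, 1000), gm)[0]
        assert len(candidate_sites(gm, a, w, "tgt_0").positions) == 0
        assert len(candidate_sites(gm, a, w, "tgt_0",
                                   ref_max_daf=0.25).positions) == 1

    def test_non_target_individual_rejected(self, small_matrix):
        gm, a = small_matrix
        w = assign_sites(make_windows(10_000, 10_000, 10_000), gm)[0]
        with pytest.raises(ValueError, match="ref_0"):
            candidate_sites(gm, a, w, "ref_0")


class TestScan:
    def test_row_cardinality_and_determinism(self, small_matrix):
        gm, a = small_matrix
        ws = assign_sites(make_windows(10_000, 5_000, 2_500), gm)
        t1 = sstar_scan(gm, a, ws)
        t2 = sstar_scan(gm, a, ws)
        assert len(t1) == len(ws) * len(a.target_ids)
        assert t1.equals(t2)

    def test_all_zero_individual_scores_zero_everywhere(self):
        samples = ["ref_0", "tgt_0", "tgt_1"]
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, size=(20, 3)).astype(np.int8)
        G[:, 1] = 0
        gm = GenotypeMatrix(["1"] * 20, sorted(rng.choice(
            np.arange(1, 9999), 20, replace=False)), ["A"] * 20, ["T"] * 20,
            [True] * 20, samples, G)
        a = PopulationAssignment(["ref_0"], ["tgt_0", "tgt_1"])
        ws = assign_sites(make_windows(10_000, 5_000, 5_000), gm)
        t = sstar_scan(gm, a, ws)
        assert (t.loc[t["sample"] == "tgt_0", "sstar"] == 0).all()

    def test_individual_order_does_not_change_values(self, small_matrix):
        gm, a = small_matrix
        ws = assign_sites(make_windows(10_000, 5_000, 5_000), gm)
        t1 = sstar_scan(gm, a, ws)
        a_rev = PopulationAssignment(a.reference_ids,
                                     list(reversed(a.target_ids)), a.sources)
        t2 = sstar_scan(gm, a_rev, ws)
        key = ["chrom", "start", "sample"]
        merged = t1.merge(t2, on=key, suffixes=("_a", "_b"))
        assert (merged.sstar_a == merged.sstar_b).all()
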