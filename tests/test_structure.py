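import itertools

import numpy as np
import pandas as pd
import pytest

from unipargen import structure as st
from unipargen.io import StrPanel
from conftest import make_haplotypes
from _oracles import amova_oracle_one_level, amova_oracle_two_level


def _random_instance(rng, two_level=False, max_n=12):
    """Random small AMOVA instance on a continuous squared-distance matrix."""
    if two_level:
        n_grps = rng.integers(2, 4)
        pops, grps = [], []
        for g in range(n_grps):
            for p in range(rng.integers(1, 3)):
                size = rng.integers(2, 4)
                pops += [f"g{g}p{p}"] * size
                grps += [f"g{g}"] * size
        pops, grps = pops[:max_n], grps[:max_n]
    else:
        n_pops = rng.integers(2, 5)
        pops = []
        for p in range(n_pops):
            pops += [f"p{p}"] * rng.integers(2, 4)
        pops, grps = pops[:max_n], None
    # drop truncated singleton populations
    keep = [i for i in range(len(pops)) if pops.count(pops[i]) >= 2]
    pops = [pops[i] for i in keep]
    grps = [grps[i] for i in keep] if grps else None
    n = len(pops)
    pts = rng.normal(size=(n, 3))
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=2)
    return d2, pops, grps


class TestAmovaOracleEquivalence:
    def test_one_level_matches_brute_force(self, rng):
        for _ in range(50):
            d2, pops, _ = _random_instance(rng)
            res = st.amova(d2, pops, n_perm=0)
            sa, sc, phi = amova_oracle_one_level(d2, pops)
            assert res.sigma_b == pytest.approx(sa, abs=1e-9)
            assert res.sigma_c == pytest.approx(sc, abs=1e-9)
            assert res.phi_st == pytest.approx(phi, abs=1e-9)

    def test_two_level_matches_brute_force(self, rng):
        done = 0
        while done < 50:
            d2, pops, grps = _random_instance(rng, two_level=True)
            if len(set(grps)) < 2 or len(set(pops)) <= len(set(grps)):
                continue
            res = st.amova(d2, pops, grps, n_perm=0)
            sa, sb, sc = amova_oracle_two_level(d2, list(pops), list(grps))
            assert res.sigma_a == pytest.approx(sa, abs=1e-9)
            assert res.sigma_b == pytest.approx(sb, abs=1e-9)
            assert res.sigma_c == pytest.approx(sc, abs=1e-9)
            done += 1

    def test_two_population_amova_equals_pairwise_phi_st(self, rng):
        seqs_a = ["AAAAAA", "AAAAAT", "AAAATT"]
        seqs_b = ["TTTTAA", "TTTTAT", "TTTTTT"]
        phi_mat = st.pairwise_phi_st({"A": seqs_a, "B": seqs_b})
        d2 = st.sequence_distance_matrix(seqs_a + seqs_b)
        res = st.amova(d2, ["A"] * 3 + ["B"] * 3, n_perm=0)
        assert phi_mat.loc["A", "B"] == pytest.approx(res.phi_st, abs=0)


class TestPhiSt:
    def test_identical_populations_give_zero(self):
        seqs = ["ACGTAC", "ACGTAT"]
        mat = st.pairwise_phi_st({"A": seqs, "B": list(seqs)})
        assert mat.loc["A", "B"] == pytest.approx(0.0, abs=1e-9)

    def test_fixed_difference_gives_one(self):
        mat = st.pairwise_phi_st(
            {"A": ["AAAAA", "AAAAA"], "B": ["TTTTA", "TTTTA"]}
        )
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_small_population_rejected_by_name(self):
        with pytest.raises(ValueError, match="B"):
            st.pairwise_phi_st({"A": ["AAAA", "AAAT"], "B": ["AAAA"]})

    def test_label_permutation_permutes_matrix(self, rng):
        pops = {
            "A": ["AAAAAA", "AAAAAT"],
            "B": ["TTAAAA", "TTAAAT"],
            "C": ["TTTTAA", "TTTTAT"],
        }
        mat = st.pairwise_phi_st(pops)
        renamed = {"C": pops["A"], "A": pops["B"], "B": pops["C"]}
        mat2 = st.pairwise_phi_st(renamed)
        assert mat.loc["A", "B"] == pytest.approx(mat2.loc["C", "A"])
        assert mat.loc["B", "C"] == pytest.approx(mat2.loc["A", "B"])


class TestRst:
    def test_fixed_difference_gives_one(self):
        pops = {
            "A": make_haplotypes([(10,), (10,)], ids=["a1", "a2"]),
            "B": make_haplotypes([(12,), (12,)], ids=["b1", "b2"]),
        }
        mat = st.pairwise_r_st(pops)
        assert mat.loc["A", "B"] == pytest.approx(1.0)

    def test_identical_populations_give_zero(self):
        panel = StrPanel(("L0", "L1"))
        pops = {
            "A": make_haplotypes([(10, 11), (11, 12)], panel=panel, ids=["a1", "a2"]),
            "B": make_haplotypes([(10, 11), (11, 12)], panel=panel, ids=["b1", "b2"]),
        }
        assert st.pairwise_r_st(pops).loc["A", "B"] == pytest.approx(0.0, abs=1e-9)

    def test_matches_brute_force_on_two_locus_case(self, rng):
        rows = rng.integers(8, 14, size=(6, 2))
        haps = make_haplotypes(rows)
        pops = {"A": haps[:3], "B": haps[3:]}
        mat = st.pairwise_r_st(pops)
        d2 = st.str_squared_distance_matrix(rows.astype(float))
        sa, sc, phi = amova_oracle_one_level(d2, ["A"] * 3 + ["B"] * 3)
        assert mat.loc["A", "B"] == pytest.approx(phi, abs=1e-9)


class TestAmovaDegenerateAndPermutation:
    def test_all_identical_samples_report_zero(self):
        d2 = np.zeros((6, 6))
        res = st.amova(d2, ["A"] * 3 + ["B"] * 3, n_perm=49, seed=1)
        assert res.sigma_b == 0.0 and res.sigma_c == 0.0
        assert res.phi_st == 0.0

    def test_p_value_bounds_and_permutation_count(self, rng):
        d2, pops, _ = _random_instance(rng)
        res = st.amova(d2, pops, n_perm=99, seed=3)
        p = res.p_values["phi_st"]
        assert 1.0 / 100 <= p <= 1.0
        assert res.n_permutations == 99

    def test_strong_structure_gets_small_p(self):
        seqs_a = ["AAAAAAAA", "AAAAAAAT", "AAAAAATT", "AAAAATTT", "AAAAAAAA"]
        seqs_b = ["TTTTTTTT", "TTTTTTTA", "TTTTTTAA", "TTTTTAAA", "TTTTTTTT"]
        d2 = st.sequence_distance_matrix(seqs_a + seqs_b)
        res = st.amova(d2, ["A"] * 5 + ["B"] * 5, n_perm=199, seed=5)
        assert res.p_values["phi_st"] <= 0.05

    def test_two_level_flags_single_population_groups(self, rng):
        d2 = st.str_squared_distance_matrix(rng.integers(8, 14, size=(8, 2)).astype(float))
        pops = ["p0"] * 2 + ["p1"] * 2 + ["p2"] * 2 + ["p3"] * 2
        grps = ["g0"] * 4 + ["g1"] * 2 + ["g2"] * 2
        res = st.amova(d2, pops, grps, n_perm=9, seed=1)
        assert set(res.single_population_groups) == {"g1", "g2"}

    def test_percentages_sum_to_100(self, rng):
        for _ in range(10):
            d2, pops, grps = _random_instance(rng, two_level=True)
            if len(set(grps)) < 2 or len(set(pops)) <= len(set(grps)):
                continue
            res = st.amova(d2, pops, grps, n_perm=0)
            assert sum(res.percentages) == pytest.approx(100.0, abs=1e-9)


class TestMigrationTrend:
    def test_phi_st_decreases_with_migration(self):
        """Island-model simulations: phi-st falls monotonically as the
        migration rate rises (panmixia limit ~0, isolation limit high)."""
        from unipargen.simulate import SimConfig, sim_mtdna
        from unipargen.structure import sequence_distance_matrix

        means = []
        for m, label in [(1e-5, "low"), (1e-3, "mid"), (0.3, "high")]:
            vals = []
            for rep in range(8):
                cfg = SimConfig(
                    seed=1000 + rep, n_pops=2, n_per_pop=6, theta=5.0,
                    migration_rate=m,
                )
                records, meta, _ = sim_mtdna(cfg)
                seqs = [r[1] for r in records]
                pops = [meta[r[0]].population for r in records]
                d2 = sequence_distance_matrix(seqs)
                res = st.amova(d2, pops, n_perm=0)
                vals.append(res.phi_st_raw)
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
        assert means[0] > 0.5
        assert means[2] < 0.2


class TestSharedHaplotypes:
    def test_counts_and_diagonal(self):
        mat = st.shared_haplotypes(
            {"A": ["h1", "h2", "h2"], "B": ["h2", "h3"], "C": ["h4"]}
        )
        assert mat.loc["A", "B"] == 1
        assert mat.loc["A", "C"] == 0
        assert mat.loc["A", "A"] == 2
        assert mat.loc["C", "C"] == 1
        pd.testing.assert_frame_equal(mat, mat.T)
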