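import numpy as np
import pytest

from unipargen import clusters as dc
from unipargen.io import SampleMeta
from unipargen.simulate import SimConfig, sim_ystr
from conftest import make_haplotypes


def _with_meta(rows, pops_countries, ids=None):
    metas = [
        SampleMeta(ids[i] if ids else f"s{i}", p, c, f"F_{p}", "Y")
        for i, (p, c) in enumerate(pops_countries)
    ]
    return make_haplotypes(rows, ids=ids, metas=metas)


class TestRankingAndCores:
    def test_rank_counts_and_tie_break(self):
        haps = make_haplotypes([(10, 10), (10, 10), (11, 11), (12, 9), (12, 9)])
        ranked = dc.rank_haplotypes(haps)
        assert ranked["count"].tolist() == [2, 2, 1]
        # ties broken lexicographically by allele vector
        assert ranked["haplotype"].tolist()[0] == (10, 10)
        assert ranked["count"].sum() == 5

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            dc.rank_haplotypes([])

    def test_select_cores_threshold(self):
        haps = make_haplotypes([(10,)] * 9 + [(11,)] * 8 + [(12,)])
        ranked = dc.rank_haplotypes(haps)
        assert [c for c, _ in dc.select_cores(ranked, 9)] == [(10,)]
        assert dc.select_cores(ranked, 10) == []

    def test_derived_min_count_at_one_percent(self):
        # ceil(0.01 * 775) = 8: a count-8 haplotype qualifies
        assert dc.derive_min_count(775) == 8
        haps = make_haplotypes([(10,)] * 8 + [(i + 20,) for i in range(767)])
        ranked = dc.rank_haplotypes(haps)
        cores = dc.select_cores(ranked, dc.derive_min_count(len(haps)))
        assert ((10,), 8) in cores

    def test_unique_haplotypes_never_cores(self):
        haps = make_haplotypes([(10,), (11,), (12,)])
        ranked = dc.rank_haplotypes(haps)
        with pytest.raises(ValueError):
            dc.select_cores(ranked, 1)
        assert dc.select_cores(ranked, 2) == []


class TestClusterBuilding:
    def test_threshold_membership(self):
        rows = [(10,), (11,), (12,), (15,)]
        haps = make_haplotypes(rows)
        clusters, unassigned = dc.build_clusters([((10,), 5)], haps, d_max=3)
        assert clusters[0].n == 3
        assert [h.alleles for h in unassigned] == [(15,)]

    def test_tie_goes_to_higher_count_core(self):
        haps = make_haplotypes([(11,)])
        clusters, _ = dc.build_clusters([((12,), 9), ((10,), 12)], haps, d_max=2)
        assert clusters[1].core == (10,)
        assert clusters[1].n == 1 and clusters[0].n == 0

    def test_d_max_zero_keeps_exact_matches_only(self):
        haps = make_haplotypes([(10,), (10,), (11,)])
        clusters, unassigned = dc.build_clusters([((10,), 2)], haps, d_max=0)
        assert clusters[0].n == 2 and len(unassigned) == 1

    def test_duplicate_cores_rejected(self):
        with pytest.raises(ValueError):
            dc.build_clusters([((10,), 3), ((10,), 2)], [], d_max=1)

    def test_conservation_partition(self, rng):
        rows = [tuple(int(x) for x in rng.integers(8, 14, size=3)) for _ in range(40)]
        haps = make_haplotypes(rows)
        ranked = dc.rank_haplotypes(haps)
        cores = dc.select_cores(ranked, 2)
        clusters, unassigned = dc.build_clusters(cores, haps, d_max=2)
        assert sum(c.n for c in clusters) + len(unassigned) == len(haps)
        ids = [h.sample_id for c in clusters for h in c.members]
        assert len(ids) == len(set(ids))  # disjoint


class TestGeographyProfile:
    def test_population_frequency_fraction_of_sampled(self):
        # 7 of 10 sampled chromosomes of one population fall in the cluster
        rows = [(10,)] * 7 + [(20,)] * 3
        pool = _with_meta(rows, [("Tsachila", "Ecuador")] * 10)
        cluster = dc.DescentCluster(core=(10,), core_count=7, members=pool[:7])
        dc.profile_geography(cluster, pool)
        assert cluster.per_population_frequency["Tsachila"] == pytest.approx(0.70)

    def test_variance_identifies_origin(self):
        rows = [(10,), (12,), (11,), (11,)]
        pool = _with_meta(
            rows,
            [("X", "A"), ("X", "A"), ("Y", "B"), ("Y", "B")],
        )
        cluster = dc.DescentCluster(core=(11,), core_count=2, members=pool)
        dc.profile_geography(cluster, pool, min_members=2)
        assert cluster.per_country_variance["A"] == pytest.approx(2.0)
        assert cluster.per_country_variance["B"] == pytest.approx(0.0)
        assert cluster.inferred_origin == ("A",)

    def test_all_identical_members_tie_policy(self):
        rows = [(11,)] * 4
        pool = _with_meta(rows, [("X", "A"), ("X", "A"), ("Y", "B"), ("Y", "B")])
        cluster = dc.DescentCluster(core=(11,), core_count=4, members=pool)
        dc.profile_geography(cluster, pool, min_members=2)
        assert cluster.inferred_origin == ("A", "B")

    def test_too_few_members_means_undetermined(self):
        pool = _with_meta([(11,), (12,)], [("X", "A"), ("Y", "B")])
        cluster = dc.DescentCluster(core=(11,), core_count=2, members=pool)
        dc.profile_geography(cluster, pool, min_members=3)
        assert cluster.inferred_origin == ()


class TestTmrca:
    def test_members_equal_core_date_to_zero(self):
        cluster = dc.DescentCluster(
            core=(10, 10), core_count=2, members=make_haplotypes([(10, 10), (10, 10)])
        )
        t, ci = dc.tmrca_asd(cluster, dc.TmrcaConfig(seed=0))
        assert t == 0.0 and ci == (0.0, 0.0)

    def test_hand_computed_two_member_case(self):
        # two members one step off the core at one locus of 14:
        # ASD = 1/14; generations = (1/14)/0.022 = 3.2468; years = 97.4
        rows = [tuple([11] + [10] * 13), tuple([10] * 13 + [11])]
        cluster = dc.DescentCluster(
            core=tuple([10] * 14), core_count=2, members=make_haplotypes(rows)
        )
        t, _ = dc.tmrca_asd(cluster, dc.TmrcaConfig(mu=0.022, generation_years=30.0, seed=0))
        assert t == pytest.approx((1 / 14) / 0.022 * 30.0, rel=1e-12)
        assert t == pytest.approx(97.4, abs=0.1)

    def test_estimator_unbiased_on_star_genealogies(self):
        """Star genealogy, n=50, L=14: relative bias of the ASD clock < 5%."""
        mu, true_years = 0.022, 600.0
        estimates = []
        for rep in range(300):
            cfg = SimConfig(
                seed=50_000 + rep, L_loci=14, mu_str=mu, genealogy="star",
                tmrca_true_years=true_years,
            )
            haps, truth = sim_ystr(cfg, n=50)
            cluster = dc.DescentCluster(core=truth["founder"], core_count=1, members=haps)
            t, _ = dc.tmrca_asd(
                cluster, dc.TmrcaConfig(mu=mu, n_bootstrap=10, seed=rep)
            )
            estimates.append(t)
        assert abs(np.mean(estimates) - true_years) / true_years < 0.05

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            dc.TmrcaConfig(mu=0.0)
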