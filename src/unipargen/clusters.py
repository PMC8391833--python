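"""Y-STR descent clusters and ASD-based TMRCA estimation.

The procedure mirrors how male lineage-expansion signals are screened in
pooled Y-STR databases: pool all complete haplotypes, rank distinct
haplotypes by frequency, keep the frequent ones (unique haplotypes can
never seed a cluster) as "core" haplotypes, grow a descent cluster (DC)
around each core from all chromosomes within a small number of mutational
steps, profile each cluster's geography (per-population / per-country
frequencies and per-country allele-size variance, whose maximum marks the
inferred origin), and date the cluster by the average squared distance
(ASD) between members and the core: under the stepwise mutation model on a
star genealogy E[ASD] = mu * T per locus, so T = ASD / mu generations.
Confidence intervals come from a percentile bootstrap over cluster members.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SampleMeta, StrHaplotype


@dataclasses.dataclass
class TmrcaConfig:
    """Dating parameters: mutation rate per locus per generation, years per
    generation, and the bootstrap settings for the CI."""

    mu: float = 0.022
    generation_years: float = 30.0
    n_bootstrap: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mu <= 0:
            raise ValueError("mu must be > 0")
        if self.generation_years <= 0:
            raise ValueError("generation_years must be > 0")


@dataclasses.dataclass
class DescentCluster:
    core: tuple[int, ...]
    core_count: int
    members: list[StrHaplotype]
    per_population_frequency: dict[str, float] = dataclasses.field(default_factory=dict)
    per_country_frequency: dict[str, float] = dataclasses.field(default_factory=dict)
    per_country_variance: dict[str, float] = dataclasses.field(default_factory=dict)
    inferred_origin: tuple[str, ...] = ()
    tmrca_years: float | None = None
    tmrca_ci: tuple[float, float] | None = None
    alpha: float | None = None

    @property
    def n(self) -> int:
        return len(self.members)


def rank_haplotypes(pooled: Sequence[StrHaplotype]) -> pd.DataFrame:
    """Distinct haplotypes with counts, descending; ties broken by allele
    vector (lexicographic)."""
    if not pooled:
        raise ValueError("empty haplotype pool")
    counts = Counter(h.alleles for h in pooled)
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {"haplotype": [k for k, _ in items], "count": [c for _, c in items]}
    )


def derive_min_count(n_total: int, fraction: float = 0.01) -> int:
    """Core threshold as ceil(fraction * N), never below 2 (unique
    haplotypes are not cores)."""
    return max(2, math.ceil(fraction * n_total))


def select_cores(
    ranked: pd.DataFrame, min_count: int
) -> list[tuple[tuple[int, ...], int]]:
    """Haplotypes with count >= min_count, in rank order."""
    if min_count < 2:
        raise ValueError("min_count must be >= 2 (unique haplotypes are never cores)")
    return [
        (tuple(row.haplotype), int(row.count))
        for row in ranked.itertuples(index=False)
        if row.count >= min_count
    ]


def _step_distance(a: Sequence[int], b: Sequence[int]) -> int:
    return int(sum(abs(x - y) for x, y in zip(a, b)))


def build_clusters(
    cores: Sequence[tuple[tuple[int, ...], int]],
    pooled: Sequence[StrHaplotype],
    d_max: int = 2,
) -> tuple[list[DescentCluster], list[StrHaplotype]]:
    """Assign every pooled chromosome to the nearest core within ``d_max``
    mutational steps; ties go to the higher-count core, then to rank order.
    Returns (clusters, unassigned). Clusters are disjoint and conserve the
    pool: sum of cluster sizes + unassigned = pool size.
    """
    if d_max < 0:
        raise ValueError("d_max must be >= 0")
    seen = set()
    for core, _c in cores:
        if core in seen:
            raise ValueError(f"duplicate core {core}")
        seen.add(core)
    members: list[list[StrHaplotype]] = [[] for _ in cores]
    unassigned: list[StrHaplotype] = []
    for h in pooled:
        best: tuple[int, int, int] | None = None  # (distance, -count, rank)
        for rank, (core, count) in enumerate(cores):
            d = _step_distance(h.alleles, core)
            if d <= d_max:
                key = (d, -count, rank)
                if best is None or key < best:
                    best = key
        if best is None:
            unassigned.append(h)
        else:
            members[best[2]].append(h)
    clusters = [
        DescentCluster(core=core, core_count=count, members=mem)
        for (core, count), mem in zip(cores, members)
    ]
    return clusters, unassigned


def _meta_of(h: StrHaplotype, meta: Mapping[str, SampleMeta] | None) -> SampleMeta:
    m = h.meta if h.meta is not None else (meta or {}).get(h.sample_id)
    if m is None:
        raise ValueError(f"no metadata for sample {h.sample_id!r}")
    return m


def profile_geography(
    cluster: DescentCluster,
    pooled: Sequence[StrHaplotype],
    meta: Mapping[str, SampleMeta] | None = None,
    min_members: int = 3,
) -> DescentCluster:
    """Fill in geographic frequencies, per-country variance and origin.

    Frequencies divide cluster members from a population (or country) by
    the total chromosomes sampled from it. The per-country allele-size
    variance (mean over loci, unbiased) is computed for countries with at
    least ``min_members`` members; the inferred origin is the country (or
    countries, on ties) with the maximum variance — a geographically older
    presence accumulates more variance around the founder haplotype.
    """
    pop_totals = Counter()
    country_totals = Counter()
    for h in pooled:
        m = _meta_of(h, meta)
        pop_totals[m.population] += 1
        country_totals[m.country] += 1
    pop_in = Counter()
    country_in: dict[str, list[StrHaplotype]] = {}
    for h in cluster.members:
        m = _meta_of(h, meta)
        pop_in[m.population] += 1
        country_in.setdefault(m.country, []).append(h)
    cluster.per_population_frequency = {
        p: pop_in[p] / pop_totals[p] for p in pop_in
    }
    cluster.per_country_frequency = {
        c: len(v) / country_totals[c] for c, v in country_in.items()
    }
    variances = {}
    for c, hs in country_in.items():
        if len(hs) >= min_members:
            mat = np.array([h.alleles for h in hs], dtype=float)
            variances[c] = float(np.mean(np.var(mat, axis=0, ddof=1)))
    cluster.per_country_variance = variances
    if not variances:
        cluster.inferred_origin = ()
    else:
        vmax = max(variances.values())
        cluster.inferred_origin = tuple(
            sorted(c for c, v in variances.items() if v >= vmax - 1e-15)
        )
    return cluster


def tmrca_asd(
    cluster: DescentCluster, config: TmrcaConfig
) -> tuple[float, tuple[float, float]]:
    """ASD TMRCA of a cluster in years, with a percentile bootstrap CI.

    ASD = mean over members of the mean squared repeat difference from the
    core over loci; TMRCA = ASD / mu generations, times generation_years.
    """
    if cluster.n < 2:
        raise ValueError("TMRCA needs a cluster with n >= 2")
    core = np.asarray(cluster.core, dtype=float)
    mat = np.array([h.alleles for h in cluster.members], dtype=float)
    per_member = np.mean((mat - core) ** 2, axis=1)  # mean over loci
    asd = float(np.mean(per_member))
    scale = config.generation_years / config.mu
    tmrca = asd * scale
    rng = np.random.default_rng(config.seed)
    n = per_member.size
    boots = np.mean(
        per_member[rng.integers(0, n, size=(config.n_bootstrap, n))], axis=1
    )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    ci = (float(lo) * scale, float(hi) * scale)
    cluster.tmrca_years = tmrca
    cluster.tmrca_ci = ci
    return tmrca, ci


def find_descent_clusters(
    pooled: Sequence[StrHaplotype],
    meta: Mapping[str, SampleMeta] | None = None,
    min_count: int | None = None,
    core_fraction: float = 0.01,
    d_max: int = 2,
    min_members: int = 3,
    tmrca_config: TmrcaConfig | None = None,
) -> tuple[list[DescentCluster], list[StrHaplotype]]:
    """End-to-end screening: rank, select cores, grow clusters, profile
    geography and date every cluster with n >= 2. Clusters are returned
    largest first."""
    ranked = rank_haplotypes(pooled)
    if min_count is None:
        min_count = derive_min_count(len(pooled), core_fraction)
    cores = select_cores(ranked, min_count)
    clusters, unassigned = build_clusters(cores, pooled, d_max)
    cfg = tmrca_config or TmrcaConfig()
    for cl in clusters:
        profile_geography(cl, pooled, meta, min_members)
        if cl.n >= 2:
            tmrca_asd(cl, cfg)
    clusters.sort(key=lambda c: (-c.n, -c.core_count, c.core))
    return clusters, unassigned


def cluster_table(
    clusters: Sequence[DescentCluster], sampling_year: int = 2000
) -> pd.DataFrame:
    """Report table: N, countries, populations, max frequency/variance,
    TMRCA with CI, and the calendar period (sampling_year - TMRCA)."""
    rows = []
    for i, c in enumerate(clusters, start=1):
        max_freq_c = max(c.per_country_frequency.items(), key=lambda kv: kv[1], default=(None, None))
        max_var = max(c.per_country_variance.items(), key=lambda kv: kv[1], default=(None, None))
        rows.append(
            {
                "cluster": f"DC{i}",
                "core": "-".join(map(str, c.core)),
                "N": c.n,
                "countries": ",".join(sorted(c.per_country_frequency)),
                "populations": ",".join(sorted(c.per_population_frequency)),
                "max_country_frequency": max_freq_c[1],
                "max_country_frequency_where": max_freq_c[0],
                "max_variance": max_var[1],
                "max_variance_where": max_var[0],
                "inferred_origin": ",".join(c.inferred_origin),
                "tmrca_years": c.tmrca_years,
                "tmrca_ci_low": None if c.tmrca_ci is None else c.tmrca_ci[0],
                "tmrca_ci_high": None if c.tmrca_ci is None else c.tmrca_ci[1],
                "period": None if c.tmrca_years is None else sampling_year - c.tmrca_years,
            }
        )
    return pd.DataFrame(rows)


def membership_table(
    clusters: Sequence[DescentCluster],
    unassigned: Sequence[StrHaplotype],
    meta: Mapping[str, SampleMeta] | None = None,
) -> pd.DataFrame:
    rows = []
    for i, c in enumerate(clusters, start=1):
        for h in c.members:
            m = _meta_of(h, meta)
            rows.append(
                {
                    "sample_id": h.sample_id,
                    "cluster": f"DC{i}",
                    "population": m.population,
                    "country": m.country,
                    "steps_from_core": _step_distance(h.alleles, c.core),
                }
            )
    for h in unassigned:
        m = _meta_of(h, meta)
        rows.append(
            {
                "sample_id": h.sample_id,
                "cluster": "unassigned",
                "population": m.population,
                "country": m.country,
                "steps_from_core": None,
            }
        )
    return pd.DataFrame(rows)
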