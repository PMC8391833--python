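"""Synthetic-data generators with known ground truth.

Three generators cover the pipeline's inputs end to end:

* :func:`sim_mtdna` — whole mitochondrial genomes under an n-island
  neutral coalescent (msprime genealogies) with a finite-sites,
  transition-biased (ti:tv 20:1) mutation model on the 16,569-position
  reference, emitted as reference + mutations so the typing module can
  round-trip them. Under this model the expected mean number of pairwise
  differences within a deme-free population equals theta = 2 * Ne * mu.
* :func:`sim_ystr` — Y-STR haplotypes under the symmetric single-step
  mutation model on coalescent (optionally exponentially growing) or star
  genealogies; on a star of depth T generations the per-locus expected
  squared distance from the founder is mu * T.
* :func:`sim_descent_scenario` — a pooled multi-country Y-STR database
  with one implanted descent cluster of known membership, founder,
  source country and TMRCA (founder expands in the source country; one
  migrant sub-founder expands recently in a second country, so frequency
  peaks in the spread country while allele-size variance peaks at the
  source).

* :func:`sim_haplogroup_genomes` — genomes built by spiking haplogroup
  motif variants onto the reference plus a few private mutations, for
  classifier validation.

All generators are fully deterministic given ``SimConfig.seed``.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import msprime
import numpy as np

from .io import SampleMeta, StrHaplotype, StrPanel
from .mtdna import (
    HOTSPOT_SUBSTITUTION_SITES,
    MotifPanel,
    MtVariant,
    apply_variants,
    load_reference,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclasses.dataclass
class SimConfig:
    """Full parameterization of the synthetic-data generators."""

    seed: int
    n_per_pop: int = 20
    n_pops: int = 1
    theta: float = 5.0
    migration_rate: float = 0.01
    Ne: float = 1000.0
    L_loci: int = 14
    mu_str: float = 0.0022
    genealogy: str = "coalescent"  # "coalescent" | "star"
    tmrca_true_years: float = 571.0
    generation_years: float = 30.0
    growth_alpha: float = 0.0
    ti_tv_ratio: float = 20.0
    country_map: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for name in ("theta", "migration_rate", "Ne", "mu_str", "growth_alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _msprime_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(1, 2**31 - 1))


def ancestral_str_alleles(L: int) -> tuple[int, ...]:
    """Ancestral repeat counts: 10 plus a small locus-dependent offset."""
    return tuple(10 + (i % 5) for i in range(L))


def _mutate_base(base: str, rng: np.random.Generator, ti_tv: float) -> str:
    if rng.random() < ti_tv / (ti_tv + 1.0):
        return _TS_PARTNER[base]
    return _TV_PARTNERS[base][rng.integers(0, 2)]


def sim_mtdna(config: SimConfig):
    """Simulate structured mtDNA genomes.

    Returns ``(records, meta, truth)`` where records are ``(id, sequence)``
    pairs, meta maps sample_id to :class:`SampleMeta`, and truth holds the
    tskit tree sequence, the per-sample substitution dicts and the
    placed-mutation list.
    """
    if config.theta <= 0:
        raise ValueError("theta must be > 0")
    rng = np.random.default_rng(config.seed)
    reference = load_reference()
    L = len(reference)
    if config.n_pops > 1:
        demography = msprime.Demography.island_model(
            [config.Ne] * config.n_pops, migration_rate=config.migration_rate
        )
        samples = {f"pop_{i}": config.n_per_pop for i in range(config.n_pops)}
        ts = msprime.sim_ancestry(
            samples=samples,
            demography=demography,
            ploidy=1,
            random_seed=_msprime_seed(rng),
        )
    else:
        ts = msprime.sim_ancestry(
            samples=config.n_per_pop,
            population_size=config.Ne,
            ploidy=1,
            random_seed=_msprime_seed(rng),
        )
    mu_genome = config.theta / (2.0 * config.Ne)  # per genome per generation
    tree = ts.first()
    states: dict[int, dict[int, str]] = {}
    mutations: list[tuple[int, int, str, str]] = []  # (node, pos, from, to)

    # depth-first, carrying sparse substitution state
    stack = [(root, {}) for root in tree.roots]
    while stack:
        node, state = stack.pop()
        states[node] = state
        for child in tree.children(node):
            t = tree.time(node) - tree.time(child)
            child_state = dict(state)
            k = rng.poisson(mu_genome * t)
            for _ in range(k):
                pos = int(rng.integers(1, L + 1))
                cur = child_state.get(pos, reference[pos - 1])
                new = _mutate_base(cur, rng, config.ti_tv_ratio)
                if new == reference[pos - 1]:
                    child_state.pop(pos, None)  # back mutation to reference
                else:
                    child_state[pos] = new
                mutations.append((child, pos, cur, new))
            stack.append((child, child_state))

    records: list[tuple[str, str]] = []
    meta: dict[str, SampleMeta] = {}
    sample_states: dict[str, dict[int, str]] = {}
    ref_list = list(reference)
    for i, node in enumerate(ts.samples()):
        pop_idx = ts.node(node).population
        pop = f"pop_{pop_idx}"
        country = (config.country_map or {}).get(pop, f"Country{pop_idx}")
        sid = f"mt{i:03d}"
        sub = states[node]
        seq = ref_list.copy()
        for pos, base in sub.items():
            seq[pos - 1] = base
        records.append((sid, "".join(seq)))
        meta[sid] = SampleMeta(sid, pop, country, f"Family{pop_idx}", "mtDNA")
        sample_states[sid] = sub
    truth = {
        "tree_sequence": ts,
        "sample_states": sample_states,
        "mutations": mutations,
        "reference": reference,
    }
    return records, meta, truth


def sim_haplogroup_genomes(
    panel: MotifPanel,
    n: int,
    seed: int,
    max_private: int = 10,
    reference: str | None = None,
):
    """Genomes carrying a full haplogroup motif plus up to ``max_private``
    random non-motif, non-hotspot private substitutions.

    Returns ``(records, true_labels)``.
    """
    rng = np.random.default_rng(seed)
    reference = reference or load_reference()
    L = len(reference)
    motif_positions = {
        p
        for sites in panel.motifs.values()
        for s in sites
        for p in range(s.position, s.end + 1)
    }
    labels = panel.labels
    records = []
    truth = {}
    for i in range(n):
        label = labels[i % len(labels)]
        variants = list(panel.motifs[label])
        k = int(rng.integers(0, max_private + 1))
        used = set(motif_positions)
        for _ in range(k):
            while True:
                pos = int(rng.integers(1, L + 1))
                if pos not in used and pos not in HOTSPOT_SUBSTITUTION_SITES:
                    break
            used.add(pos)
            ref_b = reference[pos - 1]
            alt = _mutate_base(ref_b, rng, 20.0)
            kind = "transition" if alt == _TS_PARTNER[ref_b] else "transversion"
            variants.append(MtVariant(pos, ref_b, alt, kind))
        sid = f"hg{i:03d}"
        records.append((sid, apply_variants(reference, variants)))
        truth[sid] = label
    return records, truth


def _smm_step(rng: np.random.Generator, mu: float, t: float) -> int:
    """Net allele displacement after Poisson(mu*t) symmetric unit steps."""
    k = rng.poisson(mu * t)
    if k == 0:
        return 0
    return int(2 * rng.binomial(k, 0.5) - k)


def _mutate_alleles(
    alleles: np.ndarray, rng: np.random.Generator, mu: float, t: float
) -> np.ndarray:
    out = alleles.copy()
    for i in range(out.size):
        out[i] += _smm_step(rng, mu, t)
    return out


def default_panel(L: int) -> StrPanel:
    return StrPanel(tuple(f"DYS{i+1:02d}" for i in range(L)))


def sim_ystr(
    config: SimConfig,
    n: int | None = None,
    founder: Sequence[int] | None = None,
    id_prefix: str = "y",
):
    """Simulate Y-STR haplotypes under the stepwise mutation model.

    Star genealogies hang ``n`` lineages of depth ``tmrca_true_years``
    directly off the founder haplotype; coalescent genealogies come from
    msprime (with optional exponential growth ``growth_alpha``). Returns
    ``(haplotypes, truth)`` with the founder and the genealogy's TMRCA in
    generations in ``truth``.
    """
    if config.L_loci < 1:
        raise ValueError("L_loci must be >= 1")
    rng = np.random.default_rng(config.seed)
    panel = default_panel(config.L_loci)
    base = np.asarray(
        founder if founder is not None else ancestral_str_alleles(config.L_loci),
        dtype=int,
    )
    n = n if n is not None else config.n_per_pop
    haplos: list[StrHaplotype] = []
    if config.genealogy == "star":
        t = config.tmrca_true_years / config.generation_years
        for i in range(n):
            alleles = _mutate_alleles(base, rng, config.mu_str, t)
            haplos.append(StrHaplotype(f"{id_prefix}{i:03d}", tuple(int(a) for a in alleles), panel))
        truth = {"founder": tuple(int(a) for a in base), "tmrca_generations": t}
        return haplos, truth
    demography = msprime.Demography()
    demography.add_population(
        name="pop0", initial_size=config.Ne, growth_rate=config.growth_alpha
    )
    ts = msprime.sim_ancestry(
        samples={"pop0": n},
        demography=demography,
        ploidy=1,
        random_seed=_msprime_seed(rng),
    )
    tree = ts.first()
    states: dict[int, np.ndarray] = {}
    stack = [(root, base) for root in tree.roots]
    while stack:
        node, alleles = stack.pop()
        states[node] = alleles
        for child in tree.children(node):
            t = tree.time(node) - tree.time(child)
            stack.append((child, _mutate_alleles(alleles, rng, config.mu_str, t)))
    for i, node in enumerate(ts.samples()):
        haplos.append(
            StrHaplotype(
                f"{id_prefix}{i:03d}", tuple(int(a) for a in states[node]), panel
            )
        )
    truth = {
        "founder": tuple(int(a) for a in base),
        "tmrca_generations": max(tree.time(r) for r in tree.roots),
        "tree_sequence": ts,
    }
    return haplos, truth


@dataclasses.dataclass
class DescentScenarioConfig:
    """An implanted male lineage expansion in a multi-country Y-STR pool.

    The founder lives in ``source_country`` at depth ``tmrca_true_years``;
    ``n_spread`` of its descendants stem from a single migrant sub-founder
    that arrived in ``spread_country`` ``migration_years`` ago, the other
    ``n_source`` descend independently from the founder. Background
    chromosomes come from independent per-country coalescents.
    """

    seed: int
    L_loci: int = 14
    mu_str: float = 0.0022
    generation_years: float = 30.0
    tmrca_true_years: float = 571.0
    source_country: str = "Peru"
    spread_country: str = "Ecuador"
    migration_years: float = 60.0
    n_source: int = 6
    n_spread: int = 12
    # per-country pools mix several populations; the large haploid size keeps
    # background haplotype sharing at the ~1% level seen in pooled databases
    background_Ne: float = 5000.0
    background_per_country: int = 100
    background_pops: dict[str, tuple[str, ...]] = dataclasses.field(
        default_factory=lambda: {
            "Ecuador": ("Tsachila", "Kichwa"),
            "Peru": ("Chachapoya", "InkaD"),
            "Colombia": ("Pasto",),
        }
    )
    spread_population: str = "Tsachila"

    @property
    def n_descendants(self) -> int:
        return self.n_source + self.n_spread


def sim_descent_scenario(config: DescentScenarioConfig):
    """Build the pooled database with one implanted descent cluster.

    Returns ``(pooled, meta, truth)``; truth records the implanted member
    ids, the founder and sub-founder haplotypes, the true TMRCA (years)
    and the source country.
    """
    rng = np.random.default_rng(config.seed)
    panel = default_panel(config.L_loci)
    pooled: list[StrHaplotype] = []
    meta: dict[str, SampleMeta] = {}

    for country, pops in config.background_pops.items():
        sub = SimConfig(
            seed=int(rng.integers(0, 2**31 - 1)),
            L_loci=config.L_loci,
            mu_str=config.mu_str,
            Ne=config.background_Ne,
            generation_years=config.generation_years,
        )
        haplos, _ = sim_ystr(
            sub, n=config.background_per_country, id_prefix=f"bg_{country}_"
        )
        for i, h in enumerate(haplos):
            pop = pops[i % len(pops)]
            m = SampleMeta(h.sample_id, pop, country, f"Fam_{pop}", "Y")
            meta[h.sample_id] = m
            pooled.append(StrHaplotype(h.sample_id, h.alleles, panel, m))

    # implanted cluster: founder at full depth in the source country
    t_total = config.tmrca_true_years / config.generation_years
    t_mig = config.migration_years / config.generation_years
    founder = np.asarray(ancestral_str_alleles(config.L_loci), dtype=int)
    # decouple the founder from the background ancestral haplotype
    founder = _mutate_alleles(founder, rng, config.mu_str, 50.0 * t_total)
    member_ids = []
    src_pops = config.background_pops[config.source_country]
    for i in range(config.n_source):
        alleles = _mutate_alleles(founder, rng, config.mu_str, t_total)
        sid = f"dc_src{i:02d}"
        pop = src_pops[i % len(src_pops)]
        m = SampleMeta(sid, pop, config.source_country, f"Fam_{pop}", "Y")
        meta[sid] = m
        pooled.append(StrHaplotype(sid, tuple(int(a) for a in alleles), panel, m))
        member_ids.append(sid)
    # one lineage migrates and expands recently in the spread country; the
    # migrant carries the founder haplotype, so the implanted cluster has a
    # single modal core (the founder) rather than two competing cores
    subfounder = founder.copy()
    for i in range(config.n_spread):
        alleles = _mutate_alleles(subfounder, rng, config.mu_str, t_mig)
        sid = f"dc_spr{i:02d}"
        m = SampleMeta(
            sid, config.spread_population, config.spread_country,
            f"Fam_{config.spread_population}", "Y",
        )
        meta[sid] = m
        pooled.append(StrHaplotype(sid, tuple(int(a) for a in alleles), panel, m))
        member_ids.append(sid)

    truth = {
        "member_ids": member_ids,
        "founder": tuple(int(a) for a in founder),
        "subfounder": tuple(int(a) for a in subfounder),
        "tmrca_true_years": config.tmrca_true_years,
        "source_country": config.source_country,
        "spread_country": config.spread_country,
    }
    return pooled, meta, truth
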