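"""Population-structure statistics: phi-st / Rst matrices, hierarchical
AMOVA with permutation tests, and shared-haplotype counts.

AMOVA partitions the total molecular variance, computed from a matrix of
squared inter-individual distances, into among-group, among-population
(within group) and within-population components via the standard
sums-of-squares decomposition. For sequences the squared distance is the
number of pairwise nucleotide differences (giving phi-st); for STRs it is
the summed squared allele-size difference over loci (giving Slatkin's Rst).

Raw variance components may be negative; Phi statistics are reported from
components floored at zero (keeping them in [0, 1]) while the raw values
are carried alongside for audit.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .diversity import pairwise_differences
from .io import StrHaplotype


def sequence_distance_matrix(sequences: Sequence[str]) -> np.ndarray:
    """Pairwise nucleotide differences (pairwise deletion of gap/N sites)."""
    n = len(sequences)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = pairwise_differences(sequences[i], sequences[j])[0]
    return d


def str_squared_distance_matrix(allele_matrix: np.ndarray) -> np.ndarray:
    """Summed squared allele-size differences over loci (Rst metric)."""
    a = np.asarray(allele_matrix, dtype=float)
    diff = a[:, None, :] - a[None, :, :]
    return np.sum(diff**2, axis=2)


def str_step_distance_matrix(allele_matrix: np.ndarray) -> np.ndarray:
    """Summed absolute repeat differences (mutational steps) over loci."""
    a = np.asarray(allele_matrix, dtype=float)
    return np.sum(np.abs(a[:, None, :] - a[None, :, :]), axis=2)


@dataclasses.dataclass
class AmovaResult:
    """Variance components and Phi statistics of a (possibly nested) AMOVA."""

    sigma_a: float  # among groups (0.0 in a one-level design)
    sigma_b: float  # among populations within groups (= among populations)
    sigma_c: float  # within populations
    percentages: tuple[float, float, float]
    phi_st: float
    phi_sc: float | None
    phi_ct: float | None
    phi_st_raw: float
    p_values: dict[str, float] = dataclasses.field(default_factory=dict)
    n_permutations: int = 0
    single_population_groups: tuple[str, ...] = ()


def _within_ss(d2: np.ndarray, labels: np.ndarray) -> float:
    ss = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        ss += d2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def _one_level_components(d2: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(sigma_among, sigma_within) for populations within the total."""
    n_tot = labels.size
    uniq, counts = np.unique(labels, return_counts=True)
    n_pops = uniq.size
    ss_total = d2.sum() / (2.0 * n_tot)
    ss_within = _within_ss(d2, labels)
    ss_among = ss_total - ss_within
    sigma_c = ss_within / (n_tot - n_pops)
    n_c = (n_tot - np.sum(counts**2) / n_tot) / (n_pops - 1)
    sigma_a = (ss_among / (n_pops - 1) - sigma_c) / n_c
    return float(sigma_a), float(sigma_c)


def _phi(num: float, den: float) -> float:
    return 0.0 if den <= 0 else num / den


def _two_level_components(
    d2: np.ndarray, pop: np.ndarray, grp: np.ndarray
) -> tuple[float, float, float]:
    """(sigma_a, sigma_b, sigma_c) for groups / populations / individuals."""
    n_tot = pop.size
    pops, pop_counts = np.unique(pop, return_counts=True)
    n_pops = pops.size
    grps = np.unique(grp)
    n_grps = grps.size
    ss_total = d2.sum() / (2.0 * n_tot)
    ss_wp = _within_ss(d2, pop)
    ss_wg = _within_ss(d2, grp)
    ss_ap_wg = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    pop_of = {}
    grp_sizes = {}
    for g in grps:
        grp_sizes[g] = int(np.sum(grp == g))
    sum_np2_over_ng = 0.0
    for p in pops:
        idx = np.flatnonzero(pop == p)
        g = grp[idx[0]]
        pop_of[p] = g
        sum_np2_over_ng += idx.size**2 / grp_sizes[g]
    sum_np2_over_n = float(np.sum(pop_counts**2)) / n_tot
    sum_ng2_over_n = float(sum(s**2 for s in grp_sizes.values())) / n_tot

    n1 = (n_tot - sum_np2_over_ng) / (n_pops - n_grps)
    n2 = (sum_np2_over_ng - sum_np2_over_n) / (n_grps - 1)
    n3 = (n_tot - sum_ng2_over_n) / (n_grps - 1)

    sigma_c = ss_wp / (n_tot - n_pops)
    sigma_b = (ss_ap_wg / (n_pops - n_grps) - sigma_c) / n1
    sigma_a = (ss_ag / (n_grps - 1) - sigma_c - n2 * sigma_b) / n3
    return float(sigma_a), float(sigma_b), float(sigma_c)


def amova(
    d2: np.ndarray,
    pop_labels: Sequence[Hashable],
    group_labels: Sequence[Hashable] | None = None,
    n_perm: int = 999,
    seed: int | None = None,
) -> AmovaResult:
    """AMOVA on a squared-distance matrix.

    ``pop_labels`` assigns each sample (matrix row) to a population;
    ``group_labels``, if given, assigns each sample to a higher-level group
    (language family or country) for the two-level nested design. Permutation
    p-values use the +1 correction: Phi_ST permutes samples among
    populations, Phi_SC samples among populations within groups, Phi_CT
    whole populations among groups.
    """
    d2 = np.asarray(d2, dtype=float)
    pop = np.asarray(pop_labels)
    n = pop.size
    if d2.shape != (n, n):
        raise ValueError("distance matrix does not match label length")
    uniq, counts = np.unique(pop, return_counts=True)
    if uniq.size < 2:
        raise ValueError("AMOVA needs at least two populations")
    if group_labels is not None and len(set(group_labels)) >= uniq.size:
        raise ValueError(
            "two-level AMOVA needs fewer groups than populations "
            "(every group holds a single population)"
        )
    small = uniq[counts < 2]
    if small.size:
        raise ValueError(f"population {small[0]!r} has fewer than 2 samples")
    rng = np.random.default_rng(seed)

    if group_labels is None:
        sigma_a, sigma_c = _one_level_components(d2, pop)
        total_raw = sigma_a + sigma_c
        phi_raw = _phi(sigma_a, total_raw)
        fa, fc = max(sigma_a, 0.0), max(sigma_c, 0.0)
        phi = _phi(fa, fa + fc)
        pct = (
            (0.0, 100.0 * sigma_a / total_raw, 100.0 * sigma_c / total_raw)
            if total_raw != 0
            else (0.0, 0.0, 100.0)
        )
        p_values = {}
        if n_perm:
            obs = phi_raw
            count = 0
            for _ in range(n_perm):
                perm = rng.permutation(pop)
                sa, sc = _one_level_components(d2, perm)
                if _phi(sa, sa + sc) >= obs - 1e-12:
                    count += 1
            p_values["phi_st"] = (count + 1) / (n_perm + 1)
        return AmovaResult(
            sigma_a=0.0,
            sigma_b=sigma_a,
            sigma_c=sigma_c,
            percentages=pct,
            phi_st=phi,
            phi_sc=None,
            phi_ct=None,
            phi_st_raw=phi_raw,
            p_values=p_values,
            n_permutations=n_perm,
        )

    grp = np.asarray(group_labels)
    if grp.size != n:
        raise ValueError("group labels do not match sample count")
    # each population must sit in exactly one group
    single_pop_groups = []
    pops_per_group: dict[Hashable, set] = {}
    for p in uniq:
        gset = set(grp[pop == p].tolist())
        if len(gset) != 1:
            raise ValueError(f"population {p!r} spans multiple groups")
        pops_per_group.setdefault(next(iter(gset)), set()).add(p)
    if len(pops_per_group) < 2:
        raise ValueError("two-level AMOVA needs at least two groups")
    for g, ps in pops_per_group.items():
        if len(ps) == 1:
            single_pop_groups.append(str(g))

    sigma_a, sigma_b, sigma_c = _two_level_components(d2, pop, grp)
    total_raw = sigma_a + sigma_b + sigma_c
    phi_st_raw = _phi(sigma_a + sigma_b, total_raw)
    fa, fb, fc = max(sigma_a, 0.0), max(sigma_b, 0.0), max(sigma_c, 0.0)
    ftot = fa + fb + fc
    phi_st = _phi(fa + fb, ftot)
    phi_sc = _phi(fb, fb + fc)
    phi_ct = _phi(fa, ftot)
    pct = (
        tuple(100.0 * s / total_raw for s in (sigma_a, sigma_b, sigma_c))
        if total_raw != 0
        else (0.0, 0.0, 100.0)
    )

    p_values = {}
    if n_perm:
        group_of_pop = {p: grp[pop == p][0] for p in uniq}
        obs_st = phi_st_raw
        obs_sc = _phi(sigma_b, sigma_b + sigma_c)
        obs_ct = _phi(sigma_a, total_raw)
        c_st = c_sc = c_ct = 0
        pop_list = list(uniq)
        for _ in range(n_perm):
            # Phi_ST: samples among populations without regard to groups;
            # each permuted sample inherits the group of its new population
            perm_pop = rng.permutation(pop)
            grp_of_perm = np.asarray([group_of_pop[p] for p in perm_pop])
            sa1, sb1, sc1 = _two_level_components(d2, perm_pop, grp_of_perm)
            if _phi(sa1 + sb1, sa1 + sb1 + sc1) >= obs_st - 1e-12:
                c_st += 1
            # Phi_SC: samples among populations within groups
            perm2 = pop.copy()
            for g in pops_per_group:
                idx = np.flatnonzero(grp == g)
                perm2[idx] = rng.permutation(pop[idx])
            sa2, sb2, sc2 = _two_level_components(d2, perm2, grp)
            if _phi(sb2, sb2 + sc2) >= obs_sc - 1e-12:
                c_sc += 1
            # Phi_CT: whole populations among groups
            perm_groups = rng.permutation([group_of_pop[p] for p in pop_list])
            gmap = dict(zip(pop_list, perm_groups))
            grp_perm = np.asarray([gmap[p] for p in pop])
            sa3, sb3, sc3 = _two_level_components(d2, pop, grp_perm)
            if _phi(sa3, sa3 + sb3 + sc3) >= obs_ct - 1e-12:
                c_ct += 1
        p_values = {
            "phi_st": (c_st + 1) / (n_perm + 1),
            "phi_sc": (c_sc + 1) / (n_perm + 1),
            "phi_ct": (c_ct + 1) / (n_perm + 1),
        }

    return AmovaResult(
        sigma_a=sigma_a,
        sigma_b=sigma_b,
        sigma_c=sigma_c,
        percentages=pct,
        phi_st=phi_st,
        phi_sc=phi_sc,
        phi_ct=phi_ct,
        phi_st_raw=phi_st_raw,
        p_values=p_values,
        n_permutations=n_perm,
        single_population_groups=tuple(single_pop_groups),
    )


def _pairwise_fixation(
    pop_data: Mapping[str, np.ndarray], d2_fn
) -> pd.DataFrame:
    pops = sorted(pop_data)
    for p in pops:
        if len(pop_data[p]) < 2:
            raise ValueError(f"population {p!r} has fewer than 2 samples")
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    for p1, p2 in itertools.combinations(pops, 2):
        combined = list(pop_data[p1]) + list(pop_data[p2])
        labels = [p1] * len(pop_data[p1]) + [p2] * len(pop_data[p2])
        d2 = d2_fn(combined)
        sigma_a, sigma_c = _one_level_components(d2, np.asarray(labels))
        fa, fc = max(sigma_a, 0.0), max(sigma_c, 0.0)
        mat.loc[p1, p2] = mat.loc[p2, p1] = _phi(fa, fa + fc)
    return mat


def pairwise_phi_st(pop_sequences: Mapping[str, Sequence[str]]) -> pd.DataFrame:
    """Pairwise phi-st between populations of aligned sequences.

    Each entry is the among-population variance fraction of a two-population
    AMOVA with components floored at zero, so identical populations score 0
    rather than a negative sampling artifact; raw (possibly negative)
    components are available through :func:`amova`.
    """
    return _pairwise_fixation(
        {p: list(v) for p, v in pop_sequences.items()},
        lambda seqs: sequence_distance_matrix(seqs),
    )


def pairwise_r_st(pop_haplotypes: Mapping[str, Sequence[StrHaplotype]]) -> pd.DataFrame:
    """Pairwise Slatkin's Rst between populations of STR haplotypes."""
    return _pairwise_fixation(
        {p: list(v) for p, v in pop_haplotypes.items()},
        lambda haps: str_squared_distance_matrix(
            np.array([h.alleles for h in haps], dtype=float)
        ),
    )


def shared_haplotypes(
    pop_haplotypes: Mapping[str, Iterable[Hashable]]
) -> pd.DataFrame:
    """Counts of distinct haplotypes shared between population pairs.

    The diagonal holds the number of distinct haplotypes per population.
    """
    pops = sorted(pop_haplotypes)
    sets = {p: set(pop_haplotypes[p]) for p in pops}
    mat = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for p1 in pops:
        mat.loc[p1, p1] = len(sets[p1])
        for p2 in pops:
            if p1 < p2:
                shared = len(sets[p1] & sets[p2])
                mat.loc[p1, p2] = mat.loc[p2, p1] = shared
    return mat


def amova_table(result: AmovaResult) -> pd.DataFrame:
    """One row per stratum: component, percentage, Phi, p-value."""
    rows = [
        {
            "stratum": "among_groups",
            "sigma2": result.sigma_a,
            "percent": result.percentages[0],
            "phi": result.phi_ct,
            "p": result.p_values.get("phi_ct"),
        },
        {
            "stratum": "among_populations",
            "sigma2": result.sigma_b,
            "percent": result.percentages[1],
            "phi": result.phi_sc if result.phi_sc is not None else result.phi_st,
            "p": result.p_values.get("phi_sc", result.p_values.get("phi_st")),
        },
        {
            "stratum": "within_populations",
            "sigma2": result.sigma_c,
            "percent": result.percentages[2],
            "phi": result.phi_st,
            "p": result.p_values.get("phi_st"),
        },
    ]
    return pd.DataFrame(rows)


def haplotype_counts(items: Iterable[Hashable]) -> Counter:
    return Counter(items)
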