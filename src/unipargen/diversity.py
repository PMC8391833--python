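"""Molecular diversity indices for sequence and Y-STR data.

Haplotype diversity uses Nei's unbiased estimator
``H = n (1 - sum p_i^2) / (n - 1)`` with Nei's sampling variance for the
standard error. Sequence diversity reports the mean number of pairwise
differences (MPD) and the per-site nucleotide diversity; STR reports add
the mean unbiased allele-size variance over loci.
"""

from __future__ import annotations

import dataclasses
import itertools
from collections import Counter
from typing import Sequence

import numpy as np
import pandas as pd

from .io import StrHaplotype

_VALID = frozenset("ACGT")


@dataclasses.dataclass
class DiversityReport:
    n: int
    k: int
    haplotype_diversity: float
    haplotype_diversity_se: float
    mean_pairwise_differences: float
    nucleotide_diversity: float | None = None
    mean_allele_size_variance: float | None = None


def haplotype_diversity(haplotype_counts: Sequence[int]) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard error.

    ``haplotype_counts`` are the multiplicities of each distinct haplotype.
    """
    counts = np.asarray([c for c in haplotype_counts if c > 0], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("haplotype diversity requires n >= 2")
    p = counts / n
    sum2 = float(np.sum(p**2))
    sum3 = float(np.sum(p**3))
    h = n / (n - 1.0) * (1.0 - sum2)
    # Nei (1987) eq. 8.12
    var = (
        2.0
        / (n * (n - 1.0))
        * (2.0 * (n - 2.0) * (sum3 - sum2**2) + sum2 - sum2**2)
    )
    return float(h), float(np.sqrt(max(var, 0.0)))


_VALID_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _as_bytes(s: str) -> np.ndarray:
    return np.frombuffer(s.encode("ascii"), dtype=np.uint8)


def pairwise_differences(a: str, b: str) -> tuple[int, int]:
    """(differences, effective length) with pairwise deletion of sites where
    either sequence is not a plain base (gap or N)."""
    if len(a) != len(b):
        raise ValueError("sequences have unequal lengths")
    xa, xb = _as_bytes(a), _as_bytes(b)
    valid = np.isin(xa, _VALID_BYTES) & np.isin(xb, _VALID_BYTES)
    eff = int(valid.sum())
    diff = int(np.count_nonzero((xa != xb) & valid))
    return diff, eff


def sequence_diversity(sequences: Sequence[str]) -> DiversityReport:
    """Diversity indices for equal-length aligned sequences."""
    n = len(sequences)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
    counts = Counter(sequences)
    h, se = haplotype_diversity(list(counts.values()))
    diffs = []
    pis = []
    for a, b in itertools.combinations(sequences, 2):
        d, eff = pairwise_differences(a, b)
        diffs.append(d)
        pis.append(d / eff if eff else 0.0)
    return DiversityReport(
        n=n,
        k=len(counts),
        haplotype_diversity=h,
        haplotype_diversity_se=se,
        mean_pairwise_differences=float(np.mean(diffs)),
        nucleotide_diversity=float(np.mean(pis)),
    )


def allele_size_variance(alleles: Sequence[int]) -> float:
    """Unbiased variance of repeat counts at one locus."""
    arr = np.asarray(alleles, dtype=float)
    if arr.size < 2:
        return 0.0
    return float(np.var(arr, ddof=1))


def mean_allele_size_variance(allele_matrix: np.ndarray) -> float:
    """Mean over loci of the unbiased allele-size variance (rows = samples)."""
    arr = np.asarray(allele_matrix, dtype=float)
    if arr.shape[0] < 2:
        return 0.0
    return float(np.mean(np.var(arr, axis=0, ddof=1)))


def str_diversity(haplotypes: Sequence[StrHaplotype]) -> DiversityReport:
    """Diversity indices for Y-STR haplotypes on a shared panel.

    Haplotype identity requires equality at every panel locus.
    """
    n = len(haplotypes)
    if n < 2:
        raise ValueError("need at least 2 haplotypes")
    panels = {h.panel.locus_names for h in haplotypes}
    if len(panels) != 1:
        raise ValueError("mixed locus panels")
    counts = Counter(h.alleles for h in haplotypes)
    h_div, se = haplotype_diversity(list(counts.values()))
    mat = np.array([h.alleles for h in haplotypes], dtype=float)
    mpd = float(
        np.mean(
            [
                np.sum(np.abs(mat[i] - mat[j]))
                for i, j in itertools.combinations(range(n), 2)
            ]
        )
    )
    return DiversityReport(
        n=n,
        k=len(counts),
        haplotype_diversity=h_div,
        haplotype_diversity_se=se,
        mean_pairwise_differences=mpd,
        mean_allele_size_variance=mean_allele_size_variance(mat),
    )


def diversity_table(per_population: dict[str, DiversityReport]) -> pd.DataFrame:
    """One row per population, mirroring the usual appendix-table layout."""
    rows = []
    for pop, rep in sorted(per_population.items()):
        rows.append(
            {
                "population": pop,
                "n": rep.n,
                "k": rep.k,
                "HD": rep.haplotype_diversity,
                "HD_se": rep.haplotype_diversity_se,
                "MPD": rep.mean_pairwise_differences,
                "pi": rep.nucleotide_diversity,
                "allele_size_variance": rep.mean_allele_size_variance,
            }
        )
    return pd.DataFrame(rows)
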