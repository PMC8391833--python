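"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's vectorized implementations: sums of
squares are accumulated with explicit pair loops and the variance-component
coefficients are written out directly from the nested ANOVA definitions.
"""

from __future__ import annotations

import itertools


def amova_oracle_one_level(d2, pops):
    """(sigma_among, sigma_within, phi_st) from explicit pair sums."""
    n = len(pops)
    labels = sorted(set(pops))
    ss_total = 0.0
    for i, j in itertools.combinations(range(n), 2):
        ss_total += d2[i][j]
    ss_total /= n
    ss_within = 0.0
    sizes = {}
    for lab in labels:
        idx = [i for i in range(n) if pops[i] == lab]
        sizes[lab] = len(idx)
        acc = 0.0
        for i, j in itertools.combinations(idx, 2):
            acc += d2[i][j]
        ss_within += acc / len(idx)
    ss_among = ss_total - ss_within
    p = len(labels)
    ms_within = ss_within / (n - p)
    n_c = (n - sum(s**2 for s in sizes.values()) / n) / (p - 1)
    sigma_a = (ss_among / (p - 1) - ms_within) / n_c
    sigma_c = ms_within
    fa, fc = max(sigma_a, 0.0), max(sigma_c, 0.0)
    phi = 0.0 if fa + fc <= 0 else fa / (fa + fc)
    return sigma_a, sigma_c, phi


def amova_oracle_two_level(d2, pops, grps):
    """(sigma_a, sigma_b, sigma_c) for groups / pops-in-groups / within."""
    n = len(pops)
    pop_labels = sorted(set(pops))
    grp_labels = sorted(set(grps))

    def pair_sum(idx):
        acc = 0.0
        for i, j in itertools.combinations(idx, 2):
            acc += d2[i][j]
        return acc

    ss_total = pair_sum(range(n)) / n
    ss_wp = 0.0
    for lab in pop_labels:
        idx = [i for i in range(n) if pops[i] == lab]
        ss_wp += pair_sum(idx) / len(idx)
    ss_wg = 0.0
    for lab in grp_labels:
        idx = [i for i in range(n) if grps[i] == lab]
        ss_wg += pair_sum(idx) / len(idx)
    ss_ap = ss_wg - ss_wp
    ss_ag = ss_total - ss_wg

    n_pops = len(pop_labels)
    n_grps = len(grp_labels)
    grp_size = {g: sum(1 for x in grps if x == g) for g in grp_labels}
    pop_size = {p: sum(1 for x in pops if x == p) for p in pop_labels}
    grp_of = {}
    for p in pop_labels:
        i = pops.index(p)
        grp_of[p] = grps[i]

    a = sum(pop_size[p] ** 2 / grp_size[grp_of[p]] for p in pop_labels)
    b = sum(pop_size[p] ** 2 for p in pop_labels) / n
    c = sum(grp_size[g] ** 2 for g in grp_labels) / n
    n1 = (n - a) / (n_pops - n_grps)
    n2 = (a - b) / (n_grps - 1)
    n3 = (n - c) / (n_grps - 1)

    sigma_c = ss_wp / (n - n_pops)
    sigma_b = (ss_ap / (n_pops - n_grps) - sigma_c) / n1
    sigma_a = (ss_ag / (n_grps - 1) - sigma_c - n2 * sigma_b) / n3
    return sigma_a, sigma_b, sigma_c
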