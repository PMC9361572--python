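"""Independent brute-force oracle for the NG86 estimator.

Deliberately naive: the genetic code is spelled out from biopython's
standard table at call time, every neighbour mutation and every
mutational pathway is enumerated inline, and nothing is cached or
shared with the package implementation.  Used only to cross-check the
optimized path on small random pairs.
"""

import math
from itertools import permutations

from Bio.Data import CodonTable

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_CODE = dict(_TABLE.forward_table)
_STOPS = set(_TABLE.stop_codons)


def oracle_sites(codon):
    s = 0.0
    n = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            mut = codon[:pos] + base + codon[pos + 1 :]
            if mut not in _STOPS and _CODE[mut] == _CODE[codon]:
                s += 1 / 3
            else:
                n += 1 / 3
    return s, n


def oracle_differences(ca, cb):
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    paths = []
    blocked = []
    for order in permutations(positions):
        cur = ca
        syn = nonsyn = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                hit_stop = True
                nonsyn += 1
            elif cur in _STOPS:
                nonsyn += 1
            elif _CODE[nxt] == _CODE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if hit_stop else paths).append((syn, nonsyn))
    use = paths if paths else paths + blocked
    sd = sum(p[0] for p in use) / len(use)
    nd = sum(p[1] for p in use) / len(use)
    return sd, nd


def oracle_kaks(seq_a, seq_b):
    """Naive NG86 ks/ka for two equal-length in-frame sense sequences."""
    assert len(seq_a) == len(seq_b) and len(seq_a) % 3 == 0
    s_total = 0.0
    sd = nd = 0.0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i : i + 3], seq_b[i : i + 3]
        sa, _ = oracle_sites(ca)
        sb, _ = oracle_sites(cb)
        s_total += (sa + sb) / 2
        d_s, d_n = oracle_differences(ca, cb)
        sd += d_s
        nd += d_n
    n_total = len(seq_a) - s_total
    out = {}
    for key, diffs, sites in (("ks", sd, s_total), ("ka", nd, n_total)):
        p = diffs / sites
        out[key] = (
            math.nan if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
        )
    out["S"], out["N"], out["Sd"], out["Nd"] = s_total, n_total, sd, nd
    return out
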