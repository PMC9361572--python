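"""Pairwise Ka/Ks estimation by the Nei–Gojobori (1986) counting method.

The estimator works codon by codon on a pre-aligned, in-frame pair of
coding sequences:

* every sense codon contributes fractional synonymous (s) and
  nonsynonymous (n) site counts, s + n = 3, from enumerating its nine
  single-nucleotide neighbours against the standard genetic code
  (mutations creating stop codons count as nonsynonymous);
* codon differences are decomposed over all mutational pathways between
  the two codons, averaging synonymous/nonsynonymous step counts, with
  pathways passing through stop codons excluded from the average;
* the observed proportions pS = Sd/S and pN = Nd/N are corrected for
  multiple hits with the Jukes–Cantor formula
  d = -(3/4) ln(1 - 4p/3), which saturates at p >= 3/4.

Only the standard nuclear genetic code is supported; the code table is
a module constant so the hook is visible, but alternative codes are
rejected rather than silently mis-handled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

from .io_formats import SequenceRecord

_STANDARD = CodonTable.unambiguous_dna_by_id[1]

#: codon -> one-letter amino acid, sense codons of the standard code only
GENETIC_CODE: dict[str, str] = dict(_STANDARD.forward_table)
#: the three standard stop codons
STOP_CODONS: frozenset[str] = frozenset(_STANDARD.stop_codons)

NUCLEOTIDES = "ACGT"

#: below this many retained codons the estimate is flagged, not refused
MIN_CODONS = 30

#: observed difference proportion at which Jukes-Cantor diverges
SATURATION_P = 0.75


@dataclass(frozen=True)
class AlignedCodonPair:
    """Two in-frame coding sequences, cleaned and ready for counting."""

    pair_id: str
    seq_a: str
    seq_b: str
    excluded_codons: int = 0

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(f"{self.pair_id}: unequal sequence lengths")
        if len(self.seq_a) % 3 != 0:
            raise ValueError(f"{self.pair_id}: length not divisible by 3")

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3

    def codon_columns(self):
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass(frozen=True)
class SiteCounts:
    """Fractional synonymous (S) and nonsynonymous (N) site counts."""

    S: float
    N: float


@dataclass(frozen=True)
class DiffCounts:
    """Pathway-averaged synonymous (Sd) and nonsynonymous (Nd) differences."""

    Sd: float
    Nd: float


@dataclass(frozen=True)
class KaKsResult:
    """Full per-pair output of the NG86 estimator.

    ``ks``/``ka`` are NaN when the corresponding observed proportion is
    at or beyond the Jukes-Cantor saturation point (flags set), and
    ``omega`` is NaN whenever ``ks`` is NaN or zero.
    """

    pair_id: str
    n_codons: int
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    ks: float
    ka: float
    omega: float
    saturated_s: bool
    saturated_n: bool
    too_short: bool


def _check_sense(codon: str) -> None:
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} is not a sense codon")
    if codon not in GENETIC_CODE:
        raise ValueError(f"invalid or ambiguous codon {codon!r}")


@lru_cache(maxsize=None)
def count_codon_sites(codon: str) -> SiteCounts:
    """Fractional synonymous/nonsynonymous site counts for one sense codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 of a
    site: synonymous if it codes the same amino acid, otherwise (stop
    codons included) nonsynonymous.  s + n = 3 exactly.
    """
    _check_sense(codon)
    aa = GENETIC_CODE[codon]
    s = 0.0
    for pos in range(3):
        for base in NUCLEOTIDES:
            if base == codon[pos]:
                continue
            mutant = codon[:pos] + base + codon[pos + 1 :]
            if mutant not in STOP_CODONS and GENETIC_CODE[mutant] == aa:
                s += 1.0 / 3.0
    return SiteCounts(S=s, N=3.0 - s)


def _step_type(cur: str, nxt: str) -> int:
    """1 if the single-nucleotide step cur->nxt is synonymous, else 0.

    Any step into or out of a stop codon is treated as nonsynonymous
    (only reachable in the all-pathways-blocked fallback).
    """
    if cur in STOP_CODONS or nxt in STOP_CODONS:
        return 0
    return 1 if GENETIC_CODE[cur] == GENETIC_CODE[nxt] else 0


@lru_cache(maxsize=None)
def count_codon_differences(codon_a: str, codon_b: str) -> DiffCounts:
    """Pathway-averaged difference counts between two sense codons.

    With k differing positions, all k! orderings of the single-base
    changes are enumerated; each pathway's synonymous/nonsynonymous step
    counts are averaged.  Pathways passing through a stop codon are
    excluded; if every pathway is blocked, all pathways are used with
    stop-involving steps counted as nonsynonymous.  Sd + Nd = k.
    """
    _check_sense(codon_a)
    _check_sense(codon_b)
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    k = len(diff_pos)
    if k == 0:
        return DiffCounts(0.0, 0.0)

    clean: list[tuple[int, int]] = []  # (syn, nonsyn) per stop-free pathway
    blocked: list[tuple[int, int]] = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                through_stop = True
            if _step_type(cur, nxt):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        (blocked if through_stop else clean).append((syn, nonsyn))

    pathways = clean if clean else clean + blocked
    sd = sum(p[0] for p in pathways) / len(pathways)
    nd = sum(p[1] for p in pathways) / len(pathways)
    return DiffCounts(Sd=sd, Nd=nd)


def jukes_cantor(p: float) -> float:
    """Jukes-Cantor multiple-hit correction d = -(3/4) ln(1 - 4p/3).

    Returns NaN for p >= 0.75 (saturation); raises for negative p.
    """
    if p < 0:
        raise ValueError(f"proportion of differences must be >= 0, got {p}")
    if p >= SATURATION_P:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def preprocess_pair(rec_a: SequenceRecord, rec_b: SequenceRecord) -> AlignedCodonPair:
    """Clean an aligned sequence pair into an :class:`AlignedCodonPair`.

    Codon columns containing a gap, ``N`` or any non-ACGT symbol in
    either sequence are dropped (complete deletion at codon
    granularity) and counted in ``excluded_codons``.  A terminal stop
    codon column is stripped; an internal stop in a retained column is
    an error naming the codon index.
    """
    a = rec_a.seq.upper().replace("U", "T")
    b = rec_b.seq.upper().replace("U", "T")
    if len(a) != len(b):
        raise ValueError(
            f"{rec_a.id}/{rec_b.id}: aligned lengths differ ({len(a)} vs {len(b)})"
        )
    if len(a) % 3 != 0:
        raise ValueError(f"{rec_a.id}/{rec_b.id}: aligned length not divisible by 3")

    n_cols = len(a) // 3
    columns = [(a[3 * i : 3 * i + 3], b[3 * i : 3 * i + 3]) for i in range(n_cols)]
    # strip one terminal stop column if either sequence ends in a stop
    if columns and (columns[-1][0] in STOP_CODONS or columns[-1][1] in STOP_CODONS):
        columns = columns[:-1]

    kept_a: list[str] = []
    kept_b: list[str] = []
    excluded = 0
    for idx, (ca, cb) in enumerate(columns):
        if any(ch not in NUCLEOTIDES for ch in ca + cb):
            excluded += 1
            continue
        for name, codon in ((rec_a.id, ca), (rec_b.id, cb)):
            if codon in STOP_CODONS:
                raise ValueError(
                    f"internal stop codon {codon} in {name} at codon index {idx}"
                )
        kept_a.append(ca)
        kept_b.append(cb)

    pair_id = f"{rec_a.id}-{rec_b.id}"
    if not kept_a:
        raise ValueError(f"{pair_id}: no codon columns retained")
    return AlignedCodonPair(pair_id, "".join(kept_a), "".join(kept_b), excluded)


def compute_kaks(pair: AlignedCodonPair) -> KaKsResult:
    """NG86 Ka/Ks for one aligned codon pair.

    S and N are averaged over the two sequences, Sd and Nd summed over
    codon columns, then pS = Sd/S and pN = Nd/N are Jukes-Cantor
    corrected into ks and ka.  omega = ka/ks (NaN when ks is NaN or 0).
    """
    if pair.n_codons == 0:
        raise ValueError(f"{pair.pair_id}: zero retained codons")
    s_a = s_b = 0.0
    sd = nd = 0.0
    for ca, cb in pair.codon_columns():
        s_a += count_codon_sites(ca).S
        s_b += count_codon_sites(cb).S
        diff = count_codon_differences(ca, cb)
        sd += diff.Sd
        nd += diff.Nd
    total = 3.0 * pair.n_codons
    S = (s_a + s_b) / 2.0
    N = total - S

    pS = sd / S if S > 0 else math.nan
    pN = nd / N if N > 0 else math.nan
    saturated_s = (not math.isnan(pS)) and pS >= SATURATION_P
    saturated_n = (not math.isnan(pN)) and pN >= SATURATION_P
    ks = math.nan if math.isnan(pS) else jukes_cantor(pS)
    ka = math.nan if math.isnan(pN) else jukes_cantor(pN)
    omega = math.nan if (math.isnan(ks) or ks == 0.0) else ka / ks

    return KaKsResult(
        pair_id=pair.pair_id,
        n_codons=pair.n_codons,
        S=S,
        N=N,
        Sd=sd,
        Nd=nd,
        pS=pS,
        pN=pN,
        ks=ks,
        ka=ka,
        omega=omega,
        saturated_s=saturated_s,
        saturated_n=saturated_n,
        too_short=pair.n_codons < MIN_CODONS,
    )


def compute_kaks_for_pairs(
    pair_list, sequences: list[SequenceRecord]
) -> list[KaKsResult]:
    """Run the estimator over every pair in a :class:`GenePairList`."""
    by_id = {r.id: r for r in sequences}
    results = []
    for a, b, _relation in pair_list.pairs:
        for g in (a, b):
            if g not in by_id:
                raise KeyError(f"no sequence for gene {g!r}")
        results.append(compute_kaks(preprocess_pair(by_id[a], by_id[b])))
    return results
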