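"""Duplicate-gene type classification in the MCScanX style.

Every family gene receives exactly one of five labels, by precedence:

1. ``wgd_segmental`` — the gene sits in a collinear (syntenic) pair;
2. ``tandem``        — it has a homolog at the adjacent gene-order rank
                       on the same chromosome;
3. ``proximal``      — a homolog within a small rank window (default 10)
                       on the same chromosome;
4. ``dispersed``     — any other homolog;
5. ``singleton``     — no homolog at all.

Gene-order ranks are genome-wide (all supplied loci, not just family
genes), so tandem/proximal distances reflect true chromosomal
adjacency.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .io_formats import GeneLocus, GenePairList, assign_ranks


class DupClass(str, Enum):
    WGD_SEGMENTAL = "wgd_segmental"
    TANDEM = "tandem"
    PROXIMAL = "proximal"
    DISPERSED = "dispersed"
    SINGLETON = "singleton"

    def __str__(self) -> str:  # keeps TSV output plain
        return self.value


@dataclass(frozen=True)
class Evidence:
    """Which rule fired for a gene and the partner that triggered it."""

    rule: str
    partner: str | None


@dataclass
class ClassificationResult:
    labels: dict[str, DupClass]
    evidence: dict[str, Evidence]
    proximal_window: int

    def counts(self) -> dict[DupClass, int]:
        out = {c: 0 for c in DupClass}
        for label in self.labels.values():
            out[label] += 1
        return out


def classify_genes(
    family_genes,
    homolog_pairs: GenePairList,
    collinear_pairs: GenePairList,
    loci: list[GeneLocus],
    proximal_window: int = 10,
) -> ClassificationResult:
    """Classify each family gene into one of the five duplication types.

    ``homolog_pairs`` should contain all homologous relations among the
    genes of interest (collinear pairs may be repeated there);
    ``collinear_pairs`` carries only the syntenic-block pairs.  Every
    family gene and every pair member must have a locus.
    """
    if proximal_window < 2:
        raise ValueError(f"proximal_window must be >= 2, got {proximal_window}")
    family = list(dict.fromkeys(family_genes))
    if not family:
        raise ValueError("empty family gene list")

    if any(loc.rank is None for loc in loci):
        assign_ranks(loci)
    locus_by_id = {loc.gene_id: loc for loc in loci}
    for g in family:
        if g not in locus_by_id:
            raise KeyError(f"family gene {g!r} has no locus")
    for g in sorted(homolog_pairs.gene_ids() | collinear_pairs.gene_ids()):
        if g not in locus_by_id:
            raise KeyError(f"paired gene {g!r} has no locus")

    collinear_adj = collinear_pairs.partners()
    homolog_adj = homolog_pairs.partners()

    labels: dict[str, DupClass] = {}
    evidence: dict[str, Evidence] = {}
    for g in family:
        loc = locus_by_id[g]
        if g in collinear_adj:
            labels[g] = DupClass.WGD_SEGMENTAL
            evidence[g] = Evidence("collinear_pair", collinear_adj[g][0])
            continue
        partners = homolog_adj.get(g, [])
        same_chrom = [
            (abs(locus_by_id[p].rank - loc.rank), p)
            for p in partners
            if locus_by_id[p].chrom == loc.chrom
        ]
        adjacent = sorted(p for d, p in same_chrom if d == 1)
        nearby = sorted((d, p) for d, p in same_chrom if 1 < d <= proximal_window)
        if adjacent:
            labels[g] = DupClass.TANDEM
            evidence[g] = Evidence("adjacent_rank", adjacent[0])
        elif nearby:
            labels[g] = DupClass.PROXIMAL
            evidence[g] = Evidence(f"rank_within_{proximal_window}", nearby[0][1])
        elif partners:
            labels[g] = DupClass.DISPERSED
            evidence[g] = Evidence("distant_homolog", partners[0])
        else:
            labels[g] = DupClass.SINGLETON
            evidence[g] = Evidence("no_homolog", None)
    return ClassificationResult(labels, evidence, proximal_window)


def summarize_contribution(result: ClassificationResult):
    """Per-class counts and percentages (2 d.p.), as a DataFrame.

    Percentage = 100 * count / total over the classified family; all
    five classes are reported, zero counts included.
    """
    import pandas as pd

    if not result.labels:
        raise ValueError("empty classification result")
    total = len(result.labels)
    counts = result.counts()
    rows = [
        {
            "dup_class": c.value,
            "count": counts[c],
            "percentage": round(100.0 * counts[c] / total, 2),
        }
        for c in DupClass
    ]
    return pd.DataFrame(rows)
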