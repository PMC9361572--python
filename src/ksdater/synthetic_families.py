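"""Synthetic stand-in gene families with realistic type composition.

The real per-gene locus and homology tables behind the published
BZR1-family duplication-type summaries are not redistributable, so
these builders construct small synthetic genomes whose classified type
composition matches the published per-genome percentages: a nine-gene
celery-like family with five WGD/segmental members (55.56%) and a
ten-gene coriander-like family with six (60.00%).  They are synthetic
constructions for worked examples and summary checks, not the real
gene coordinates.
"""

from __future__ import annotations

from .io_formats import GeneLocus, GenePairList, assign_ranks, make_pair_list

_SPACING = 1000
_LENGTH = 600


def _locus(gene_id: str, chrom: str, slot: int) -> GeneLocus:
    start = slot * _SPACING
    return GeneLocus(gene_id, chrom, start, start + _LENGTH, "+")


def synthetic_celery_family() -> tuple[list[str], GenePairList, GenePairList, list[GeneLocus]]:
    """Nine family genes: 5 WGD/segmental, 2 proximal, 2 dispersed.

    Returns (family_genes, homolog_pairs, collinear_pairs, loci); loci
    include non-family background genes so gene-order ranks are
    genome-wide.
    """
    family = [f"cel{i}" for i in range(1, 10)]
    # five genes in collinear pairs across chr1/chr2
    collinear = [("cel1", "cel6"), ("cel2", "cel7"), ("cel3", "cel6")]
    # one proximal pair (2 intervening background genes) and one dispersed
    homologs = collinear + [("cel4", "cel5"), ("cel8", "cel9")]
    loci = [
        _locus("cel1", "chr1", 0),
        _locus("cel2", "chr1", 2),
        _locus("cel3", "chr1", 4),
        _locus("bg1", "chr1", 5),
        _locus("bg2", "chr1", 6),
        _locus("cel4", "chr1", 8),
        _locus("bg3", "chr1", 9),
        _locus("bg4", "chr1", 10),
        _locus("cel5", "chr1", 11),  # proximal: 3 ranks from cel4
        _locus("cel6", "chr2", 0),
        _locus("cel7", "chr2", 2),
        _locus("cel8", "chr2", 5),
        _locus("cel9", "chr3", 3),  # dispersed partner on another chromosome
        _locus("bg5", "chr3", 0),
    ]
    return (
        family,
        make_pair_list(homologs, "homolog"),
        make_pair_list(collinear, "collinear"),
        assign_ranks(loci),
    )


def synthetic_coriander_family() -> tuple[list[str], GenePairList, GenePairList, list[GeneLocus]]:
    """Ten family genes: 6 WGD/segmental, 2 tandem, 2 dispersed."""
    family = [f"cor{i}" for i in range(1, 11)]
    collinear = [("cor1", "cor6"), ("cor2", "cor7"), ("cor3", "cor8")]
    homologs = collinear + [("cor4", "cor5"), ("cor9", "cor10")]
    loci = [
        _locus("cor1", "chr1", 0),
        _locus("cor2", "chr1", 2),
        _locus("cor3", "chr1", 4),
        _locus("cor4", "chr1", 6),
        _locus("cor5", "chr1", 7),  # tandem: adjacent ranks
        _locus("cor6", "chr2", 0),
        _locus("cor7", "chr2", 2),
        _locus("cor8", "chr2", 4),
        _locus("cor9", "chr2", 7),
        _locus("cor10", "chr3", 1),  # dispersed partner
        _locus("bg1", "chr1", 1),
        _locus("bg2", "chr2", 6),
    ]
    return (
        family,
        make_pair_list(homologs, "homolog"),
        make_pair_list(collinear, "collinear"),
        assign_ranks(loci),
    )


#: the four collinear celery paralog pairs with their published Ks values
CELERY_PARALOG_KS = (
    ("AgBZR1.1-AgBZR1.8", 0.6081),
    ("AgBZR1.3-AgBZR1.5", 0.6067),
    ("AgBZR1.2-AgBZR1.3", 0.9464),
    ("AgBZR1.2-AgBZR1.5", 0.9687),
)

#: extreme ortholog Ks values behind the published divergence-time range
#: endpoints (minimum Ks of celery-coriander and celery-Arabidopsis pairs)
ORTHOLOG_KS_EXTREMES = {
    ("celery", "coriander"): 0.1103,
    ("celery", "arabidopsis"): 1.3407,
}
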