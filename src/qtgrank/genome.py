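"""Interval queries against a genome annotation.

QTL membership uses inclusive interval overlap: a gene belongs to a
marker-bounded region if any part of its body overlaps
``[left_marker_pos, right_marker_pos]`` (coordinates 1-based inclusive).
"""

from __future__ import annotations

import math

from .types import GenomeAnnotation, QTLRegion

__all__ = ["genes_in_qtl", "flanking_genes"]


def genes_in_qtl(annotation: GenomeAnnotation, region: QTLRegion) -> list[str]:
    """Gene ids on the region's chromosome overlapping the marker interval.

    Returned in start order.  Raises ``KeyError`` for an unknown chromosome.
    """
    tree = annotation.interval_tree(region.chromosome)
    # internal tree is half-open, so close the right end
    hits = tree.overlap(region.left_marker_pos, region.right_marker_pos + 1)
    models = [annotation.gene(iv.data) for iv in hits]
    models.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return [g.gene_id for g in models]


def flanking_genes(annotation: GenomeAnnotation, gene_id: str, k: int) -> list[str]:
    """The ``k`` genes nearest to *gene_id* in gene order on its chromosome.

    Takes ceil(k/2) upstream and floor(k/2) downstream neighbours, borrowing
    from the other side near chromosome ends so the total is
    ``min(k, available)``.  The query gene itself is excluded.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    gene = annotation.gene(gene_id)
    chrom_genes = annotation.genes_on(gene.chromosome)
    ids = [g.gene_id for g in chrom_genes]
    pos = ids.index(gene_id)
    avail_up, avail_down = pos, len(ids) - 1 - pos
    take_up = min(avail_up, math.ceil(k / 2))
    take_down = min(avail_down, k // 2)
    leftover = k - take_up - take_down
    if leftover > 0:
        extra_down = min(avail_down - take_down, leftover)
        take_down += extra_down
        leftover -= extra_down
    if leftover > 0:
        take_up += min(avail_up - take_up, leftover)
    return ids[pos - take_up : pos] + ids[pos + 1 : pos + 1 + take_down]
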