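"""Gene-model annotation and the enrichment / orientation statistics.

Insertion calls are annotated against canonical transcripts (the longest
transcript among those sharing the maximal CDS length), assigned a region
(5' UTR, CDS, 3' UTR, intron, intergenic) and an orientation relative to
the host transcript, and the resulting counts feed exact binomial and
Fisher tests.  Sample relatedness is summarised by hierarchical
clustering of germline presence/absence profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "Transcript",
    "canonical_transcripts",
    "annotate_region",
    "region_bp_fractions",
    "region_binomial_test",
    "orientation_binomial_test",
    "fisher_or_test",
    "cluster_samples",
]

LONG_GENE_BP = 100_000

_REGION_RANK = {"CDS": 0, "5UTR": 1, "3UTR": 1, "intron": 2}


@dataclass(frozen=True)
class Transcript:
    """A transcript model (0-based half-open intervals)."""

    gene: str
    tx_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError("CDS outside transcript bounds")
        prev_end = self.tx_start - 1
        for s, e in self.exons:
            if s >= e or s < self.tx_start or e > self.tx_end or s <= prev_end:
                raise ValueError("exons must be disjoint, sorted, within tx bounds")
            prev_end = e

    @property
    def cds_len(self) -> int:
        return sum(min(e, self.cds_end) - max(s, self.cds_start)
                   for s, e in self.exons if e > self.cds_start and s < self.cds_end)

    @property
    def span(self) -> int:
        return self.tx_end - self.tx_start

    @property
    def length_class(self) -> str:
        return "long" if self.span > LONG_GENE_BP else "short"

    def region_at(self, pos: int) -> Optional[str]:
        """Region of a 0-based position, or None when outside the transcript."""
        if not (self.tx_start <= pos < self.tx_end):
            return None
        in_exon = any(s <= pos < e for s, e in self.exons)
        if not in_exon:
            return "intron"
        if self.cds_start <= pos < self.cds_end:
            return "CDS"
        # UTR side depends on strand
        before_cds = pos < self.cds_start
        if self.strand == "+":
            return "5UTR" if before_cds else "3UTR"
        return "3UTR" if before_cds else "5UTR"


def canonical_transcripts(models: Iterable[Transcript]) -> dict[str, Transcript]:
    """Pick one canonical transcript per gene.

    The canonical transcript is the longest transcript among those with
    the longest coding sequence.
    """
    canon: dict[str, Transcript] = {}
    for tx in models:
        cur = canon.get(tx.gene)
        if cur is None or (tx.cds_len, tx.span) > (cur.cds_len, cur.span):
            canon[tx.gene] = tx
    return canon


def annotate_region(chrom: str, pos: int, strand: str,
                    canon: Mapping[str, Transcript]) -> tuple[str, Optional[str], str]:
    """Annotate a 0-based insertion position.

    Returns ``(region, gene, orientation)`` where region is one of
    5UTR / CDS / 3UTR / intron / intergenic and orientation is ``sense``,
    ``antisense`` or ``NA`` (intergenic).  When canonical transcripts of
    several genes overlap the site, the gene giving the most exonic region
    wins (CDS > UTR > intron).
    """
    best: tuple[int, str, Transcript] | None = None
    for tx in canon.values():
        if tx.chrom != chrom:
            continue
        region = tx.region_at(pos)
        if region is None:
            continue
        key = (_REGION_RANK[region], region, tx)
        if best is None or key[0] < best[0]:
            best = key
    if best is None:
        return "intergenic", None, "NA"
    _, region, tx = best
    orientation = "sense" if strand == tx.strand else "antisense"
    return region, tx.gene, orientation


def region_bp_fractions(contig_sizes: Mapping[str, int],
                        canon: Mapping[str, Transcript]) -> dict[str, float]:
    """Exact base-pair share of each region class over the supplied genome.

    Overlaps between canonical transcripts are resolved by the same
    CDS > UTR > intron precedence used in :func:`annotate_region`.
    """
    total = sum(contig_sizes.values())
    counts = {"5UTR": 0, "CDS": 0, "3UTR": 0, "intron": 0, "intergenic": 0}
    for chrom, size in contig_sizes.items():
        txs = [t for t in canon.values() if t.chrom == chrom]
        if not txs:
            counts["intergenic"] += size
            continue
        best = np.full(size, 99, dtype=np.int8)  # 99 = intergenic
        codes = {"CDS": 0, "5UTR": 1, "3UTR": 2, "intron": 3}
        rank = {"CDS": 0, "5UTR": 1, "3UTR": 1, "intron": 2}
        for tx in txs:
            for region, segs in _region_segments(tx).items():
                for s, e in segs:
                    code, r = codes[region], rank[region]
                    cur = best[s:e]
                    lab = np.where(cur == 99, 3, np.where(cur == 0, 0, np.where(cur == 3, 2, 1)))
                    upd = (r < lab) | (cur == 99)
                    cur[upd] = code
        for region, code in codes.items():
            counts[region] += int((best == code).sum())
        counts["intergenic"] += int((best == 99).sum())
    return {k: v / total for k, v in counts.items()}


def _region_segments(tx: Transcript) -> dict[str, list[tuple[int, int]]]:
    segs: dict[str, list[tuple[int, int]]] = {"5UTR": [], "CDS": [], "3UTR": [], "intron": []}
    prev_end = None
    for s, e in tx.exons:
        if prev_end is not None and s > prev_end:
            segs["intron"].append((prev_end, s))
        prev_end = e
        cuts = [(s, min(e, tx.cds_start)), (max(s, tx.cds_start), min(e, tx.cds_end)),
                (max(s, tx.cds_end), e)]
        labels_plus = ["5UTR", "CDS", "3UTR"]
        labels_minus = ["3UTR", "CDS", "5UTR"]
        labels = labels_plus if tx.strand == "+" else labels_minus
        for (a, b), lab in zip(cuts, labels):
            if b > a:
                segs[lab].append((a, b))
    return segs


def region_binomial_test(k: int, n: int, expected_fraction: float):
    """Two-sided exact binomial test of a region count against its
    genome-wide base-pair share."""
    if n == 0:
        raise ValueError("no insertions to test")
    if not 0.0 < expected_fraction < 1.0:
        raise ValueError("expected fraction must be in (0, 1)")
    res = stats.binomtest(k, n, expected_fraction, alternative="two-sided")
    return {"proportion": k / n, "expected": expected_fraction, "p_value": res.pvalue}


def orientation_binomial_test(sense: int, total: int):
    """Two-sided exact binomial test of the sense proportion against 50%."""
    if total <= 0:
        raise ValueError("no transcript-overlapping insertions")
    res = stats.binomtest(sense, total, 0.5, alternative="two-sided")
    return {"proportion": sense / total, "p_value": res.pvalue}


def fisher_or_test(table: Sequence[Sequence[int]], ci: bool = True):
    """Fisher's exact test on a 2x2 table.

    Returns the conditional maximum-likelihood odds ratio with its exact
    95% CI and the two-sided p-value computed by the probability-mass
    method (sum of hypergeometric probabilities <= that of the observed
    table).  ``ci=False`` skips the (comparatively slow) interval
    inversion when only the point estimate and p-value are needed.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("odds ratio undefined: table has an all-zero margin")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    orres = stats.contingency.odds_ratio(t, kind="conditional")
    interval = None
    if ci:
        c = orres.confidence_interval(confidence_level=0.95)
        interval = (c.low, c.high)
    return {"odds_ratio": orres.statistic, "ci": interval, "p_value": p}


def cluster_samples(presence: pd.DataFrame,
                    locus_categories: Optional[Mapping[str, str]] = None,
                    kr_weight: float = 0.0):
    """Cluster samples on germline presence/absence profiles.

    ``presence`` is a samples x loci {0,1} matrix.  Distances are Jaccard
    on the polymorphic (KNR + UNK) loci; near-universal KR loci carry no
    information about individual identity and are down-weighted to
    ``kr_weight`` (dropped entirely by default).  Average linkage.
    Returns the linkage matrix, each sample's nearest-neighbour partner,
    a Newick string of the dendrogram and a list of outlier samples with
    empty profiles.
    """
    if presence.shape[0] < 2:
        raise ValueError("need at least two samples")
    mat = presence.to_numpy(dtype=float)
    if locus_categories is not None:
        w = np.array([kr_weight if locus_categories.get(c) == "KR" else 1.0
                      for c in presence.columns])
        mat = mat * w
        mat = mat[:, w > 0]
    outliers = [s for s, row in zip(presence.index, mat) if row.sum() == 0]
    dist = pdist(mat, metric="jaccard")
    dist = np.nan_to_num(dist, nan=1.0)  # two empty profiles
    link = hierarchy.linkage(dist, method="average")
    dm = squareform(dist)
    np.fill_diagonal(dm, np.inf)
    partners = {s: presence.index[int(np.argmin(dm[i]))]
                for i, s in enumerate(presence.index)}
    newick = _to_newick(hierarchy.to_tree(link), list(presence.index))
    return {"linkage": link, "partners": partners, "newick": newick, "outliers": outliers}


def _to_newick(node, labels: list[str]) -> str:
    def rec(n) -> str:
        if n.is_leaf():
            return f"{labels[n.id]}:{n.dist:.6g}"
        return f"({rec(n.left)},{rec(n.right)}):{n.dist:.6g}"
    return f"({rec(node.left)},{rec(node.right)});" if not node.is_leaf() else f"({labels[node.id]});"
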