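"""Strand-specific peak calling over flank alignments.

A peak is triggered wherever per-base depth exceeds 1; the peak extent is
the maximal depth >= 1 region containing the trigger, and adjacent peaks
closer than the merge gap (default 100 bp, end-exclusive) are merged.
Each peak is annotated with the six features the classifier consumes:
RPM, width, signal count, per-signal duplicate depth, best repeat-
annotation overlap and its width.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["Peak", "PeakFeatures", "call_peaks", "compute_features", "join_peaks"]


@dataclass
class PeakFeatures:
    rpm: float
    width: int
    signal_count: int
    signal_depths: list[int]
    signal_starts: list[int]
    overlap_annotation: str = ""
    overlap_family: str = ""
    overlap_width: int = 0


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    strand: Optional[str]  # None for unstranded (reference-insertion) peaks
    read_idx: np.ndarray   # positional indices into the alignment table
    features: Optional[PeakFeatures] = None

    @property
    def n_reads(self) -> int:
        return len(self.read_idx)

    def insertion_point(self) -> int:
        """1-based flank coordinate nearest the L1 junction."""
        if self.strand == "-":
            return self.end
        return self.start + 1


def _call_group(starts: np.ndarray, ends: np.ndarray, idx: np.ndarray,
                chrom: str, strand: Optional[str], merge_gap: int,
                trigger_depth: int) -> list[Peak]:
    """Sweep-line peak calling on one (chrom, strand) group."""
    order = np.argsort(starts, kind="stable")
    starts, ends, idx = starts[order], ends[order], idx[order]
    events = np.concatenate([np.stack([starts, np.ones_like(starts)], axis=1),
                             np.stack([ends, -np.ones_like(ends)], axis=1)])
    events = events[np.lexsort((events[:, 1], events[:, 0]))]
    # covered intervals (depth >= 1) and their max depth
    regions: list[tuple[int, int, int]] = []
    depth = 0
    region_start = 0
    max_depth = 0
    for pos, delta in events:
        if depth == 0 and delta > 0:
            region_start, max_depth = int(pos), 0
        depth += int(delta)
        max_depth = max(max_depth, depth)
        if depth == 0:
            regions.append((region_start, int(pos), max_depth))
    # keep triggered regions, then merge across small gaps
    trig = [(s, e) for s, e, d in regions if d >= trigger_depth]
    merged: list[list[int]] = []
    for s, e in trig:
        if merged and s - merged[-1][1] <= merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    peaks = []
    for s, e in merged:
        member = (starts < e) & (ends > s)
        peaks.append(Peak(chrom=chrom, start=s, end=e, strand=strand,
                          read_idx=idx[member]))
    return peaks


def call_peaks(alignments: pd.DataFrame, strand_specific: bool = True,
               merge_gap: int = 100, trigger_depth: int = 2) -> list[Peak]:
    """Call peaks from an alignment table (columns chrom/start/end/strand).

    Depth is evaluated per base; a singleton read (depth 1 everywhere)
    never seeds a peak.  With ``strand_specific`` the reads are
    partitioned by strand before calling.
    """
    if alignments.empty:
        return []
    peaks: list[Peak] = []
    keys = ["chrom", "strand"] if strand_specific else ["chrom"]
    for key, grp in alignments.groupby(keys, sort=True):
        chrom = key[0] if isinstance(key, tuple) else key
        strand = key[1] if strand_specific else None
        peaks.extend(_call_group(grp["start"].to_numpy(), grp["end"].to_numpy(),
                                 grp.index.to_numpy(), chrom, strand,
                                 merge_gap, trigger_depth))
    return peaks


def compute_features(peak: Peak, alignments: pd.DataFrame,
                     library_mapped_reads: int,
                     annotation: Optional[pd.DataFrame] = None) -> PeakFeatures:
    """Annotate one peak with the six classifier features.

    Signals are groups of reads sharing a start position (one sampled
    cell); their depth is the PCR-duplicate count.  The 1-bp start-shift
    tolerance is applied later, by the classifier, not here.
    """
    if library_mapped_reads <= 0:
        raise ValueError("library_mapped_reads must be > 0")
    reads = alignments.loc[peak.read_idx]
    rpm = 1e6 * len(reads) / library_mapped_reads
    # width: bases with depth >= 1 inside the peak
    starts = reads["start"].to_numpy().clip(min=peak.start)
    ends = reads["end"].to_numpy().clip(max=peak.end)
    events = sorted([(s, 1) for s in starts] + [(e, -1) for e in ends])
    width = 0
    depth = 0
    last = None
    for pos, delta in events:
        if depth > 0 and last is not None:
            width += pos - last
        depth += delta
        last = pos
    sig = reads.groupby("start_position")["dup_group"].count().sort_index()
    features = PeakFeatures(
        rpm=rpm, width=int(width), signal_count=len(sig),
        signal_depths=[int(v) for v in sig.values],
        signal_starts=[int(v) for v in sig.index])
    if annotation is not None and len(annotation):
        ann = annotation[(annotation.chrom == peak.chrom)
                         & (annotation.start < peak.end)
                         & (annotation.end > peak.start)]
        if len(ann):
            ov = np.minimum(ann.end, peak.end) - np.maximum(ann.start, peak.start)
            best = int(np.argmax(ov.to_numpy()))
            features.overlap_annotation = str(ann.iloc[best]["name"])
            features.overlap_family = str(ann.iloc[best].get("family", ""))
            features.overlap_width = int(ov.to_numpy()[best])
    return features


def join_peaks(per_sample: dict[str, Sequence[Peak]],
               merge_gap: int = 100) -> pd.DataFrame:
    """Join peaks across samples into a merged, strand-specific locus
    reference with a per-sample presence/absence matrix.

    Returns a DataFrame indexed by joined-locus label
    (``chrom:start-end:strand``, 1-based inclusive) with one {0,1} column
    per sample; the result is invariant to sample input order.
    """
    rows = []
    for sample, peaks in per_sample.items():
        for p in peaks:
            rows.append((p.chrom, p.strand or ".", p.start, p.end, sample))
    samples = sorted(per_sample)
    if not rows:
        return pd.DataFrame(columns=samples)
    tab = pd.DataFrame(rows, columns=["chrom", "strand", "start", "end", "sample"])
    loci = []
    for (chrom, strand), grp in tab.groupby(["chrom", "strand"], sort=True):
        grp = grp.sort_values("start")
        cur_start, cur_end, members = None, None, []
        for _, row in grp.iterrows():
            if cur_end is None or row.start - cur_end > merge_gap:
                if cur_end is not None:
                    loci.append((chrom, strand, cur_start, cur_end, members))
                cur_start, cur_end, members = row.start, row.end, []
            cur_end = max(cur_end, row.end)
            members.append(row["sample"])
        if cur_end is not None:
            loci.append((chrom, strand, cur_start, cur_end, members))
    data = {}
    for chrom, strand, start, end, members in loci:
        label = f"{chrom}:{start + 1}-{end}:{strand}"
        data[label] = {s: int(s in members) for s in samples}
    out = pd.DataFrame.from_dict(data, orient="index", columns=samples).fillna(0).astype(int)
    return out.sort_index()
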