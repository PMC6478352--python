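"""Error-filter chain and five-way insertion classification.

Reads surviving the structure parse are screened by alignment-level
filters (improper alignment, poly-A chimera, aligner inconsistency,
local structural variation), then peaks are routed:

* peaks over annotated reference L1Hs -> known-reference (KR) criteria;
* peaks over older young subfamilies (L1PA2-4) -> rejected;
* peaks over the known non-reference catalogue -> KNR criteria;
* remaining peaks -> unknown-germline (UNK) criteria, and those that fall
  short are evaluated as putative somatic insertions, which must carry a
  PCR duplicate and be private to one individual; clonal somatic calls
  additionally need two or more duplicate-supported start positions
  (after merging starts that differ by a 1-bp shift).

Every input peak ends in exactly one category and the per-filter ledger
sums back to the input count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .config import FilterConfig
from .consensus import revcomp
from .peakcall import Peak, PeakFeatures, call_peaks, compute_features
from .simdata import SyntheticGenome

logger = logging.getLogger(__name__)

__all__ = [
    "InsertionCall",
    "improper_alignment_filter",
    "is_polyA_chimera",
    "chimera_polyA_filter",
    "misalignment_filter",
    "local_sv_filter",
    "merge_shifted_signals",
    "classify_kr",
    "classify_knr",
    "classify_unk",
    "classify_somatic",
    "classify_unassembled",
    "run_cascade",
    "CascadeResult",
]

CATEGORIES = ("KR", "KNR", "UNK", "somatic", "clonal_somatic", "rejected")


@dataclass
class InsertionCall:
    chrom: str
    position: int  # 1-based insertion point (flank coordinate nearest the junction)
    strand: Optional[str]
    category: str
    features: Optional[PeakFeatures]
    sample: str
    individual: str
    rejection_reasons: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category}")
        if (self.category == "rejected") != bool(self.rejection_reasons):
            raise ValueError("rejected calls and only rejected calls carry reasons")

    @property
    def locus(self) -> tuple[str, int, Optional[str]]:
        return self.chrom, self.position, self.strand


# ---------------------------------------------------------------- read-level


def improper_alignment_filter(aligned_len: int, mismatches: int,
                              cfg: FilterConfig = FilterConfig()) -> bool:
    """Pass iff the flank aligns over >= 30 bp with <= 3 mismatches."""
    return aligned_len >= cfg.improper.min_align_bp and mismatches <= cfg.improper.max_mismatch


def is_polyA_chimera(overlap: int, a_frac: float,
                     cfg: FilterConfig = FilterConfig()) -> bool:
    """The printed poly-A chimera rule on (segment overlap, A-fraction).

    Chimeric iff the retrotransposon and genomic segments overlap > 10 bp
    with A% >= 50%, or overlap 6-10 bp with A% < 50%.
    """
    c = cfg.chimera
    if overlap > c.long_overlap_bp and a_frac >= c.a_frac:
        return True
    if c.short_overlap_lo <= overlap <= c.long_overlap_bp and a_frac < c.a_frac:
        return True
    return False


def chimera_polyA_filter(l1_span: Optional[tuple[int, int]],
                         flank_span: Optional[tuple[int, int]],
                         sequence: str,
                         cfg: FilterConfig = FilterConfig()) -> tuple[bool, bool]:
    """Evaluate the chimera rule on a contig's best segment placements.

    Spans are half-open on the contig (flank-first orientation, where the
    poly-A tail reads as poly-T; the A-fraction is therefore the T
    fraction of the overlap on the stored strand, i.e. A on the
    retrotransposon-sense strand).  Returns ``(passes, evaluable)``;
    contigs missing a segment pass with ``evaluable=False``.
    """
    if not l1_span or not flank_span:
        return True, False
    lo = max(l1_span[0], flank_span[0])
    hi = min(l1_span[1], flank_span[1])
    overlap = max(0, hi - lo)
    if overlap == 0:
        return True, True
    region = sequence[lo:hi]
    a_frac = region.count("T") / len(region)
    return not is_polyA_chimera(overlap, a_frac, cfg), True


def misalignment_filter(chrom: str, start: int, strand: str,
                        alt_chrom: Optional[str], alt_start: Optional[int],
                        alt_strand: Optional[str],
                        cfg: FilterConfig = FilterConfig()) -> tuple[bool, bool]:
    """Pass iff the two independent placements agree (same chromosome and
    strand, starts within the 1-bp shift tolerance).

    Returns ``(passes, verified)``; a missing secondary placement passes
    unverified.
    """
    if alt_chrom is None or alt_chrom == "" or alt_start is None or pd.isna(alt_start):
        return True, False
    ok = (alt_chrom == chrom and alt_strand == strand
          and abs(int(alt_start) - start) <= cfg.shift_tolerance_bp)
    return ok, True


def local_sv_filter(sequence: str, chrom: str, start: int, end: int, strand: str,
                    genome: SyntheticGenome,
                    cfg: FilterConfig = FilterConfig()) -> bool:
    """Reject contigs explained by reference sequence near the flank.

    The window spans the flank alignment plus ``local_sv_window_bp``
    beyond the junction (where a genuine non-reference insertion has no
    reference counterpart, but a nearby reference L1 or local
    rearrangement does).  The full contig is aligned into the window with
    infix edit-distance alignment on both orientations; a near-full-length
    contiguous match (edit distance <= ``local_sv_max_dist_frac`` of the
    contig length) fails the filter.  An all-N window passes.
    """
    w = cfg.local_sv_window_bp
    if strand == "+":
        window = genome.fetch(chrom, start - w, end)
    else:
        window = genome.fetch(chrom, start, end + w)
    if not window or set(window) <= {"N"}:
        return True
    budget = int(cfg.local_sv_max_dist_frac * len(sequence))
    for query in (sequence, revcomp(sequence)):
        res = edlib.align(query, window, mode="HW", task="distance", k=budget)
        if res["editDistance"] != -1:
            return False
    return True


# ---------------------------------------------------------------- peak-level


def merge_shifted_signals(starts: Sequence[int], depths: Sequence[int],
                          tol: int = 1) -> tuple[list[int], list[int]]:
    """Merge unique start positions that differ by at most ``tol`` bp.

    The higher-depth start represents a merged pair (ties: smaller
    coordinate).  Greedy, deepest-first.
    """
    order = sorted(range(len(starts)), key=lambda i: (-depths[i], starts[i]))
    merged: dict[int, int] = {}
    for i in order:
        s, d = starts[i], depths[i]
        for rep in merged:
            if abs(rep - s) <= tol:
                merged[rep] += d
                break
        else:
            merged[s] = d
    reps = sorted(merged)
    return reps, [merged[r] for r in reps]


def _not_excluded(chrom: str, cfg: FilterConfig) -> bool:
    return chrom not in cfg.exclude_chroms


def classify_kr(peak: Peak, cfg: FilterConfig) -> Optional[str]:
    """KR criteria: annotated-L1Hs overlap > 200 bp, RPM > 40, not on an
    excluded chromosome.  Strict inequalities.  Returns the failing
    criterion or None."""
    f = peak.features
    if f.overlap_family != "L1Hs":
        return "kr_no_l1hs_overlap"
    if not f.rpm > cfg.kr.rpm_min:
        return "kr_rpm"
    if not f.overlap_width > cfg.kr.overlap_min_bp:
        return "kr_overlap_width"
    if not _not_excluded(peak.chrom, cfg):
        return "chrY"
    return None


def classify_knr(peak: Peak, cfg: FilterConfig) -> Optional[str]:
    """KNR criteria (inclusive): signals >= 30, RPM >= 100, >= 3 signals
    of depth >= 5, not on an excluded chromosome."""
    f = peak.features
    if f.signal_count < cfg.knr.signal_min:
        return "knr_signal_count"
    if f.rpm < cfg.knr.rpm_min:
        return "knr_rpm"
    if sum(d >= cfg.knr.deep_signal_depth for d in f.signal_depths) < cfg.knr.deep_signals_min:
        return "knr_deep_signals"
    if not _not_excluded(peak.chrom, cfg):
        return "chrY"
    return None


def classify_unk(peak: Peak, cfg: FilterConfig) -> Optional[str]:
    """UNK criteria (inclusive): signals >= 10, >= 3 signals of depth >= 5,
    not on an excluded chromosome."""
    f = peak.features
    if f.signal_count < cfg.unk.signal_min:
        return "unk_signal_count"
    if sum(d >= cfg.unk.deep_signal_depth for d in f.signal_depths) < cfg.unk.deep_signals_min:
        return "unk_deep_signals"
    if not _not_excluded(peak.chrom, cfg):
        return "chrY"
    return None


def classify_somatic(peak: Peak, shared_individuals: int,
                     cfg: FilterConfig) -> tuple[str, Optional[str]]:
    """Somatic evaluation of a peak that fell through the germline rules.

    Requires at least one duplicate-supported signal (depth >= 2) and a
    locus private to one individual.  Clonal somatic calls carry >= 2
    duplicate-supported signals at distinct start positions after the
    1-bp shift merge.  Returns (category, rejection_reason).
    """
    f = peak.features
    if not _not_excluded(peak.chrom, cfg):
        return "rejected", "chrY"
    _, depths = merge_shifted_signals(f.signal_starts, f.signal_depths,
                                      cfg.shift_tolerance_bp)
    dup_signals = sum(d >= 2 for d in depths)
    if dup_signals < 1:
        return "rejected", "no_pcr_duplicate"
    if shared_individuals >= 2:
        return "rejected", "observed_in_common"
    return ("clonal_somatic" if dup_signals >= 2 else "somatic"), None


# ---------------------------------------------------------------- cascade


@dataclass
class CascadeResult:
    calls: list[InsertionCall]
    ledger: dict[str, int]
    peaks: dict[str, list[Peak]]

    def calls_by_category(self) -> dict[str, list[InsertionCall]]:
        out: dict[str, list[InsertionCall]] = {c: [] for c in CATEGORIES}
        for c in self.calls:
            out[c.category].append(c)
        return out


def _overlaps_annotation(reads: pd.DataFrame, annotation: pd.DataFrame,
                         families: Iterable[str]) -> pd.Series:
    """Vectorised read-vs-annotation overlap mask."""
    mask = np.zeros(len(reads), dtype=bool)
    ann = annotation[annotation.family.isin(list(families))]
    starts = reads["start"].to_numpy()
    ends = reads["end"].to_numpy()
    chroms = reads["chrom"].to_numpy()
    for chrom, grp in ann.groupby("chrom"):
        on_chrom = chroms == chrom
        if not on_chrom.any():
            continue
        a_start = grp["start"].to_numpy()[:, None]
        a_end = grp["end"].to_numpy()[:, None]
        hit = ((a_start < ends[None, :]) & (a_end > starts[None, :])).any(axis=0)
        mask |= on_chrom & hit
    return pd.Series(mask, index=reads.index)


def _peak_in_db(peak: Peak, db: pd.DataFrame) -> bool:
    if db is None or db.empty:
        return False
    hit = db[(db.chrom == peak.chrom) & (db.start < peak.end) & (db.end > peak.start)]
    if "strand" in db.columns and peak.strand is not None and len(hit):
        hit = hit[hit.strand == peak.strand]
    return len(hit) > 0


def run_cascade(parsed: pd.DataFrame, genome: SyntheticGenome,
                knr_db: Optional[pd.DataFrame], cfg: FilterConfig,
                sample: str, individual: str,
                shared_locus_individuals: Optional[Mapping[tuple, set]] = None,
                merge_gap: Optional[int] = None) -> CascadeResult:
    """Run the full error-filter chain and classification for one library.

    ``parsed`` is the output of :func:`hatseq.readproc.parse_contigs`
    (alignment columns plus sequence-filter flags).
    ``shared_locus_individuals`` maps joined loci (chrom, strand) interval
    keys to the set of individuals carrying a candidate there, for the
    observed-in-common filter; with None every locus counts as private.
    """
    ledger: dict[str, int] = {"input_reads": len(parsed)}
    df = parsed.reset_index(drop=True)
    total_mapped = max(1, len(df))

    # --- read-level sequence filters (flags set by parse_contigs)
    def flagged(fl: str, *names: str) -> bool:
        have = set(str(fl).split(";")) if fl else set()
        return any(n in have for n in names)

    reasons = []
    for _, row in df.iterrows():
        if flagged(row.get("flags", ""), "no_primer", "too_short"):
            reasons.append("no_primer")
        elif flagged(row.get("flags", ""), "l1_identity"):
            reasons.append("l1_identity")
        elif flagged(row.get("flags", ""), "no_diagnostic_G", "motif_not_covered"):
            reasons.append("diagnostic_motif")
        elif not improper_alignment_filter(int(row.aligned_len), int(row.mismatches), cfg):
            reasons.append("improper_alignment")
        else:
            reasons.append("")
    df["reject"] = reasons
    for name in ("no_primer", "l1_identity", "diagnostic_motif", "improper_alignment"):
        ledger[name] = int((df["reject"] == name).sum())
    survivors = df[df["reject"] == ""].copy()

    # --- route reads over annotated young L1 to the reference path
    on_ref = _overlaps_annotation(survivors, genome.repeats, ("L1Hs",)) \
        if len(survivors) else pd.Series(dtype=bool)
    kr_reads = survivors[on_ref].copy() if len(survivors) else survivors
    nonref = survivors[~on_ref].copy() if len(survivors) else survivors

    # --- non-reference read filters
    def nonref_reject(row) -> str:
        ok, _ = misalignment_filter(row.chrom, int(row.start), row.strand,
                                    row.get("alt_chrom"), row.get("alt_start"),
                                    row.get("alt_strand"), cfg)
        if not ok:
            return "misaligned"
        l1_span = (int(row.l1_off), int(row.l1_off) + int(row.l1_len)) \
            if not pd.isna(row.get("l1_off")) else None
        fl_span = (int(row.flank_off), int(row.flank_off) + int(row.flank_len)) \
            if not pd.isna(row.get("flank_off")) else None
        ok, _ = chimera_polyA_filter(l1_span, fl_span, row.sequence, cfg)
        if not ok:
            return "chimera_polyA"
        if not local_sv_filter(row.sequence, row.chrom, int(row.start), int(row.end),
                               row.strand, genome, cfg):
            return "local_SV"
        return ""

    if len(nonref):
        nonref["reject"] = nonref.apply(nonref_reject, axis=1)
    for name in ("misaligned", "chimera_polyA", "local_SV"):
        ledger[name] = int((nonref["reject"] == name).sum()) if len(nonref) else 0
    nonref_clean = nonref[nonref["reject"] == ""] if len(nonref) else nonref

    gap = cfg.merge_gap_bp if merge_gap is None else merge_gap
    calls: list[InsertionCall] = []
    peaks_out: dict[str, list[Peak]] = {c: [] for c in CATEGORIES}

    def emit(peak: Peak, category: str, reason: Optional[str] = None,
             flags: Optional[list[str]] = None) -> None:
        call = InsertionCall(
            chrom=peak.chrom, position=peak.insertion_point(), strand=peak.strand,
            category=category, features=peak.features, sample=sample,
            individual=individual,
            rejection_reasons=[reason] if reason else [], flags=flags or [])
        calls.append(call)
        peaks_out[category].append(peak)

    # --- KR path: unstranded peaks over reference copies
    for peak in call_peaks(kr_reads, strand_specific=False, merge_gap=gap):
        peak.features = compute_features(peak, kr_reads, total_mapped, genome.repeats)
        fail = classify_kr(peak, cfg)
        if fail is None:
            emit(peak, "KR")
        else:
            emit(peak, "rejected", fail)

    # --- non-reference path: strand-specific peaks
    shared = shared_locus_individuals or {}
    for peak in call_peaks(nonref_clean, strand_specific=True, merge_gap=gap):
        peak.features = compute_features(peak, nonref_clean, total_mapped, genome.repeats)
        if peak.features.overlap_family in ("L1PA2", "L1PA3", "L1PA4"):
            emit(peak, "rejected", "subfamily")
            continue
        if _peak_in_db(peak, knr_db):
            fail = classify_knr(peak, cfg)
            if fail is None:
                emit(peak, "KNR")
            else:
                emit(peak, "rejected", fail)
            continue
        if classify_unk(peak, cfg) is None:
            emit(peak, "UNK")
            continue
        n_ind = _shared_count(peak, shared, gap)
        category, reason = classify_somatic(peak, n_ind, cfg)
        emit(peak, category, reason)

    for cat in CATEGORIES:
        ledger[f"calls_{cat}"] = sum(1 for c in calls if c.category == cat)
    ledger["unpeaked_reads"] = (len(kr_reads) + len(nonref_clean)
                                - sum(p.n_reads for ps in peaks_out.values() for p in ps))
    return CascadeResult(calls=calls, ledger=ledger, peaks=peaks_out)


def _shared_count(peak: Peak, shared: Mapping[tuple, set], gap: int) -> int:
    """Number of individuals with a candidate at this joined locus."""
    best: set = set()
    for (chrom, strand, start, end), individuals in shared.items():
        if chrom == peak.chrom and strand == peak.strand \
                and start - gap <= peak.end and peak.start <= end + gap:
            best |= set(individuals)
    return len(best)


def classify_unassembled(records: pd.DataFrame, genome: SyntheticGenome,
                         cfg: FilterConfig, annotation: Optional[pd.DataFrame] = None
                         ) -> list[InsertionCall]:
    """Reduced-filter calling on read pairs that failed contig merging.

    The poly-A chimera and local-SV filters need the merged junction
    sequence and are not applicable; candidates therefore require >= 3
    supporting signals and are always flagged ``low_confidence``.
    Candidates overlapping repeat annotation are additionally flagged
    ``repeat_overlap``.
    """
    df = records.reset_index(drop=True).copy()
    keep = []
    for _, row in df.iterrows():
        if not improper_alignment_filter(int(row.aligned_len), int(row.mismatches), cfg):
            continue
        ok, _ = misalignment_filter(row.chrom, int(row.start), row.strand,
                                    row.get("alt_chrom"), row.get("alt_start"),
                                    row.get("alt_strand"), cfg)
        if ok:
            keep.append(row)
    if not keep:
        return []
    kept = pd.DataFrame(keep).reset_index(drop=True)
    calls = []
    for peak in call_peaks(kept, strand_specific=True, merge_gap=cfg.merge_gap_bp,
                           trigger_depth=1):
        peak.features = compute_features(peak, kept, max(1, len(records)),
                                         annotation if annotation is not None
                                         else genome.repeats)
        starts, depths = merge_shifted_signals(peak.features.signal_starts,
                                               peak.features.signal_depths,
                                               cfg.shift_tolerance_bp)
        if len(starts) < cfg.unassembled_signal_min:
            continue
        flags = ["low_confidence"]
        if peak.features.overlap_width > 0:
            flags.append("repeat_overlap")
        calls.append(InsertionCall(
            chrom=peak.chrom, position=peak.insertion_point(), strand=peak.strand,
            category="somatic", features=peak.features,
            sample=str(kept.iloc[0]["sample"]) if "sample" in kept.columns else "",
            individual=str(kept.iloc[0]["individual"]) if "individual" in kept.columns else "",
            flags=flags))
    return calls
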