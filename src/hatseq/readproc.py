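"""Read-structure parsing for HAT-seq contigs.

A merged contig is stored flank-first:

    [3' genomic flank][poly-T][reverse-complemented L1Hs 3' end][phase bases]

which is the reverse complement of the sequencing orientation of Read 2
(phase bases, primer 28-mer, L1Hs 3' end, poly-A, flank).  The functions
here locate the primer and its 2/4/6-nt phase offset, measure identity to
the L1Hs 3'-end consensus, test the subfamily-diagnostic G, trim the
poly-T tract off the flank, and score the poly-T (= poly-A) tail length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .consensus import ANCHOR5, L1Consensus, revcomp

__all__ = [
    "PhaseResult",
    "detect_phase_and_trim",
    "l1_identity_filter",
    "diagnostic_motif_filter",
    "polyT_trim",
    "polyT_length",
    "polyA_size_from_fragment",
    "parse_contigs",
]

PHASES = (2, 4, 6)


@dataclass(frozen=True)
class PhaseResult:
    phase: Optional[int]
    remainder: Optional[str]
    reason: Optional[str] = None

    @property
    def ok(self) -> bool:
        return self.reason is None


def detect_phase_and_trim(read2: str, primer28: str) -> PhaseResult:
    """Locate the exact 28-mer primer at offset 2, 4, or 6 of Read 2.

    Returns the phase and the sequence after the primer, or a rejection
    (``no_primer`` / ``too_short``).  Matching is exact: a single
    substitution anywhere in the 28-mer rejects the read.
    """
    if not read2:
        raise ValueError("empty read")
    n = len(primer28)
    too_short = True
    for phase in PHASES:
        if len(read2) < phase + n:
            continue
        too_short = False
        if read2[phase : phase + n] == primer28:
            return PhaseResult(phase, read2[phase + n :])
    return PhaseResult(None, None, "too_short" if too_short else "no_primer")


def l1_identity_filter(remainder: str, consensus_tail: str,
                       max_mismatches: int = 4) -> tuple[bool, float]:
    """End-anchored ungapped comparison of the post-primer remainder
    against the consensus 3' end.

    The compared span is the leading portion of ``remainder`` up to the
    consensus-tail length; a read passes when it has at most
    ``max_mismatches`` substitutions there (>= 95% identity on a 100-mer).
    Returns ``(passes, identity_fraction)``.
    """
    if not remainder:
        return False, 0.0
    span = min(len(remainder), len(consensus_tail))
    if span == 0:
        return False, 0.0
    mism = sum(a != b for a, b in zip(remainder[:span], consensus_tail[:span]))
    identity = 1.0 - mism / span
    return mism <= max_mismatches, identity


def diagnostic_motif_filter(remainder: str, consensus: L1Consensus) -> tuple[bool, Optional[str]]:
    """Check that the base mapped to the consensus diagnostic position is G.

    ``remainder`` is the Read-2 sequence after the primer, aligned
    end-anchored to the consensus tail.  Reads whose L1 segment ends before
    the diagnostic position fail with ``motif_not_covered``.
    """
    pos = consensus.diagnostic_offset_in_tail
    if pos >= len(remainder):
        return False, "motif_not_covered"
    if remainder[pos] != "G":
        return False, "no_diagnostic_G"
    return True, None


def _tract_span(seq: str) -> Optional[tuple[int, int]]:
    """Maximal poly-T tract ending at the right edge of ``seq``.

    Scans leftward admitting non-T bases while the local T fraction over a
    4-base window stays >= 0.75, then snaps the left boundary to the
    leftmost T.  Returns the half-open tract span, or None when the tract
    contains no 8-T seed.
    """
    n = len(seq)
    i = n - 1
    window: list[str] = []
    while i >= 0:
        window = (window + [seq[i]])[-4:] if len(window) >= 4 else window + [seq[i]]
        window = window[-4:]
        if seq[i] != "T" and window.count("T") / len(window) < 0.75:
            break
        i -= 1
    start = i + 1
    while start < n and seq[start] != "T":
        start += 1
    if "T" * 8 not in seq[start:]:
        return None
    return start, n


def polyT_trim(seq: str) -> tuple[str, bool]:
    """Trim the poly-T tract adjoining the L1 side off a flank+poly-T string.

    The tract needs an 8-T seed; after the seed it is extended through
    isolated non-T bases while the T fraction over a trailing 4-base window
    stays >= 0.75 (real tails carry sporadic substitutions).  Returns the
    genomic-flank subsequence and a flag that is True when no tract was
    found (input returned unchanged, ``no_polyT``).
    """
    span = _tract_span(seq)
    if span is None:
        return seq, True
    return seq[: span[0]], False


def polyT_length(seq: str, anchor5: str = ANCHOR5,
                 anchor_pos: Optional[int] = None) -> tuple[Optional[int], Optional[str]]:
    """Score the poly-T tail length upstream of the ATTAT anchor.

    The anchor is the first ``anchor5`` occurrence scanning from the L1Hs
    junction outward (the rightmost occurrence on a flank-first contig);
    ``anchor_pos`` overrides the search when the L1 segment placement is
    known.  From the base preceding the anchor the scan walks toward the
    contig start scoring +1 per T and -2 per non-T; the reported length is
    the distance to the furthest T reached before the running score first
    drops below 0 (an X-drop-style extension that reproduces the run
    length exactly on pure poly-T; a reported tract cannot begin on a
    mismatch).
    """
    if anchor_pos is None:
        anchor_pos = seq.rfind(anchor5)
        if anchor_pos < 0:
            return None, "no_anchor"
    elif seq[anchor_pos : anchor_pos + len(anchor5)] != anchor5:
        return None, "no_anchor"
    score = 0
    best = 0
    for k, i in enumerate(range(anchor_pos - 1, -1, -1), start=1):
        score += 1 if seq[i] == "T" else -2
        if score < 0:
            break  # X-drop termination
        if seq[i] == "T":  # a tract cannot begin on a mismatch
            best = k
    return best, None


def polyA_size_from_fragment(measured: int, known_excl_tail: int) -> int:
    """Poly-A tail length from a sized amplicon.

    ``measured - known_excl_tail - 1``; the extra base subtracted is the 3'
    terminal dA added by Taq polymerase.
    """
    if measured < known_excl_tail + 1:
        raise ValueError("inconsistent_sizing: measured product shorter than tail-less amplicon")
    return measured - known_excl_tail - 1


def parse_contigs(df: pd.DataFrame, consensus: L1Consensus,
                  max_mismatches: int = 4) -> pd.DataFrame:
    """Run the read-level structure parse over a table of contigs.

    Expects a ``sequence`` column holding flank-first contigs.  Adds
    ``phase``, ``l1_identity``, ``polyT_len`` and accumulates failures in a
    semicolon-joined ``flags`` column (``no_primer``, ``l1_identity``,
    ``no_diagnostic_G`` / ``motif_not_covered``, ``no_polyT``,
    ``no_anchor``).  The three sequence filters are pure predicates, so
    their order does not affect which reads survive.
    """
    out = df.copy()
    phases: list[Optional[int]] = []
    idents: list[float] = []
    tail_lens: list[Optional[int]] = []
    flags: list[str] = []
    l1_offs = out["l1_off"] if "l1_off" in out.columns else pd.Series([None] * len(out))
    for seq, old, l1_off in zip(out["sequence"], out.get("flags", [""] * len(out)), l1_offs):
        fl = [f for f in str(old).split(";") if f] if old else []
        read2 = revcomp(seq)
        pr = detect_phase_and_trim(read2, consensus.primer28)
        identity = 0.0
        tail_len: Optional[int] = None
        if not pr.ok:
            fl.append(pr.reason or "no_primer")
        else:
            ok, identity = l1_identity_filter(pr.remainder, consensus.tail, max_mismatches)
            if not ok:
                fl.append("l1_identity")
            ok, reason = diagnostic_motif_filter(pr.remainder, consensus)
            if not ok:
                fl.append(reason or "no_diagnostic_G")
        anchor_pos = None
        if l1_off is not None and not pd.isna(l1_off):
            cand = int(l1_off)
            if seq[cand : cand + len(consensus.anchor5)] == consensus.anchor5:
                anchor_pos = cand
        tail_len, reason = polyT_length(seq, consensus.anchor5, anchor_pos)
        if reason:
            fl.append(reason)
        phases.append(pr.phase)
        idents.append(identity)
        tail_lens.append(tail_len)
        flags.append(";".join(fl))
    out["phase"] = phases
    out["l1_identity"] = idents
    out["polyT_len"] = tail_lens
    out["flags"] = flags
    return out
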