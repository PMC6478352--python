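"""The L1Hs 3'-end consensus used for read-structure parsing.

HAT-seq amplicons are primed from the diagnostic "AC" motif near the 3'
end of the human-specific LINE-1 consensus, so every informative read
carries (i) the 28-mer priming sequence, (ii) the remainder of the L1Hs
3' end including the subfamily-diagnostic G, and (iii) the poly-A tail
followed by 3' flanking genomic sequence.  This module bundles a 400-bp
synthetic consensus with the same structural landmarks (the real Repbase
coordinate of the diagnostic G, 6012, is mapped onto the bundled sequence
via :attr:`L1Consensus.diagnostic_offset`) so the whole pipeline is
exercisable without distributing Repbase material.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

__all__ = ["PRIMER28", "ANCHOR5", "L1Consensus", "load_default_consensus", "revcomp"]

#: 3' consensus sequence of the phase-shifted L1Hs primer (P7_Ns_L1Hs).
PRIMER28 = "GGGAGATATACCTAATGCTAGATGACAC"

#: 5-mer anchoring the poly-T tract on merged contigs (reverse complement
#: of the ATAAT terminating the L1Hs 3' UTR).
ANCHOR5 = "ATTAT"

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse-complement a DNA string (N-safe)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class L1Consensus:
    """L1Hs 3'-end consensus plus the landmarks the read filters need.

    Parameters
    ----------
    sequence:
        The consensus 3'-end sequence, 5'->3' in L1 orientation.
    primer_offset:
        0-based offset of the 28-mer primer within ``sequence``.
    diagnostic_offset:
        0-based offset of the subfamily-diagnostic G within ``sequence``.
    """

    sequence: str
    primer_offset: int
    diagnostic_offset: int
    primer28: str = PRIMER28
    anchor5: str = ANCHOR5

    def __post_init__(self) -> None:
        if self.sequence[self.primer_offset : self.primer_offset + len(self.primer28)] != self.primer28:
            raise ValueError("primer28 not found at primer_offset")
        if not (0 <= self.diagnostic_offset < len(self.sequence)):
            raise ValueError("diagnostic_offset outside consensus")
        if self.sequence[self.diagnostic_offset] != "G":
            raise ValueError("base at diagnostic_offset is not G")

    @property
    def tail(self) -> str:
        """Consensus downstream of the primer -- the span Read 2 covers."""
        return self.sequence[self.primer_offset + len(self.primer28) :]

    @property
    def diagnostic_offset_in_tail(self) -> int:
        return self.diagnostic_offset - self.primer_offset - len(self.primer28)


def load_default_consensus() -> L1Consensus:
    """Load the bundled 400-bp synthetic L1Hs 3'-end consensus."""
    text = resources.files("hatseq.data").joinpath("l1hs_3prime_synthetic.fa").read_text()
    seq = "".join(line.strip() for line in text.splitlines() if not line.startswith(">"))
    return L1Consensus(sequence=seq, primer_offset=300, diagnostic_offset=380)
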