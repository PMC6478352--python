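"""Pipeline configuration.

Every threshold used by the error filters and the five-way insertion
classifier lives here, at the published defaults, so that tests and
sensitivity analyses can vary them without touching the decision logic.
Configurations round-trip losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Any

import yaml

__all__ = ["KRConfig", "KNRConfig", "UNKConfig", "ChimeraConfig", "ImproperConfig",
           "FilterConfig", "MotifControlConfig"]


@dataclass(frozen=True)
class KRConfig:
    """Known-reference call criteria (strict inequalities)."""
    rpm_min: float = 40.0          # RPM must exceed this
    overlap_min_bp: int = 200      # overlap with annotated L1Hs must exceed this


@dataclass(frozen=True)
class KNRConfig:
    """Known non-reference call criteria (inclusive inequalities)."""
    signal_min: int = 30
    rpm_min: float = 100.0
    deep_signals_min: int = 3
    deep_signal_depth: int = 5


@dataclass(frozen=True)
class UNKConfig:
    """Unknown-germline call criteria (inclusive inequalities)."""
    signal_min: int = 10
    deep_signals_min: int = 3
    deep_signal_depth: int = 5


@dataclass(frozen=True)
class ChimeraConfig:
    """Poly-A chimera rule: reject when the retrotransposon and genomic
    segments overlap > ``long_overlap_bp`` with A-fraction >= ``a_frac``,
    or overlap ``short_overlap_lo``..``long_overlap_bp`` with A-fraction
    < ``a_frac``."""
    long_overlap_bp: int = 10
    short_overlap_lo: int = 6
    a_frac: float = 0.5


@dataclass(frozen=True)
class ImproperConfig:
    min_align_bp: int = 30
    max_mismatch: int = 3


@dataclass(frozen=True)
class FilterConfig:
    kr: KRConfig = field(default_factory=KRConfig)
    knr: KNRConfig = field(default_factory=KNRConfig)
    unk: UNKConfig = field(default_factory=UNKConfig)
    chimera: ChimeraConfig = field(default_factory=ChimeraConfig)
    improper: ImproperConfig = field(default_factory=ImproperConfig)
    exclude_chroms: tuple[str, ...] = ("chrY",)
    shift_tolerance_bp: int = 1
    local_sv_window_bp: int = 2000
    # fraction-of-contig-length edit-distance budget for the local-SV check
    local_sv_max_dist_frac: float = 0.08
    merge_gap_bp: int = 100
    identity_max_mismatches: int = 4     # "> 4 mismatches" to the L1Hs 3' end fails
    unassembled_signal_min: int = 3

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "FilterConfig":
        raw: dict[str, Any] = yaml.safe_load(text) or {}
        nested = {"kr": KRConfig, "knr": KNRConfig, "unk": UNKConfig,
                  "chimera": ChimeraConfig, "improper": ImproperConfig}
        kwargs: dict[str, Any] = {}
        for key, value in raw.items():
            if key in nested:
                kwargs[key] = nested[key](**value)
            elif key == "exclude_chroms":
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def with_overrides(self, **kwargs: Any) -> "FilterConfig":
        return replace(self, **kwargs)


#: The seven L1 endonuclease cleavage motifs of TPRT-mediated integration.
EN_MOTIFS = ("TTAAAA", "TTAAGA", "TTAGAA", "TTGAAA", "TTAAAG", "CTAAAA", "TCAAAA")


@dataclass(frozen=True)
class MotifControlConfig:
    """Parameters of the EN-motif distance analysis and its random control."""
    motifs: tuple[str, ...] = EN_MOTIFS
    window_bp: int = 2000
    n_random: int = 100_000
    mappability_floor: float = 0.25
    low_map_fraction_max: float = 0.20
    n_fraction_max: float = 0.90

    def __post_init__(self) -> None:
        for m in self.motifs:
            if len(m) != 6 or set(m) - set("ACGT"):
                raise ValueError(f"not a hexamer over ACGT: {m}")
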