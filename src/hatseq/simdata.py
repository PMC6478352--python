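"""Synthetic genomes, spike-in designs and HAT-seq-structured read fixtures.

The generator emulates the laboratory design end to end: a toy reference
with planted young-LINE-1 repeats and gene models; donor-specific
germline insertions (the ACC1/ACC2 spike-in scheme, where heterozygous
insertions diluted into carrier-free DNA behave like somatic insertions
of known cell fraction); Poisson sampling of insertion copies at the
~3,000-cell library input; per-cell fragmentation start positions with
geometric PCR-duplicate multiplicities; and the artifact classes the
error filters are built to reject (poly-A chimeras, misaligned reads and
reads derived from a nearby reference L1).  Every emitted record carries
a ground-truth identifier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .consensus import L1Consensus, load_default_consensus, revcomp
from .genomic_stats import Transcript

__all__ = [
    "SpikeInDesign",
    "SyntheticGenome",
    "GroundTruth",
    "GermlineSite",
    "SomaticSite",
    "ArtifactSite",
    "LibraryParams",
    "build_genome",
    "sample_insertions",
    "plan_truth",
    "generate_contigs",
]

logger = logging.getLogger(__name__)

YOUNG_FAMILIES = ("L1Hs", "L1PA2", "L1PA3", "L1PA4")
#: reference L1Hs copies are planted with a short genomic A-tail
REFERENCE_TAIL = 20


@dataclass(frozen=True)
class SpikeInDesign:
    """Dilution-series parameters for the positive-control model.

    ``lambda`` per site is ``input_cells * dilution_fraction *
    copies_per_cell`` -- e.g. 3,000 cells at 1% dilution and one copy per
    cell gives 30 copies of each donor-specific insertion.
    """

    n_sites: int
    copies_per_cell: float = 1.0
    input_cells: int = 3000
    dilution_fraction: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 0:
            raise ValueError("n_sites must be >= 0")
        if not 0.0 <= self.dilution_fraction <= 1.0:
            raise ValueError("dilution_fraction must be in [0, 1]")
        if self.input_cells < 0 or self.copies_per_cell < 0:
            raise ValueError("negative design parameter")

    @property
    def lam(self) -> float:
        return self.input_cells * self.dilution_fraction * self.copies_per_cell


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    repeats: pd.DataFrame  # chrom, start, end, strand, family, name
    gene_models: list[Transcript]
    mappability: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def contig_sizes(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        return seq[max(0, start) : min(len(seq), end)]


@dataclass(frozen=True)
class GermlineSite:
    site_id: str
    chrom: str
    pos: int  # 0-based junction coordinate
    strand: str
    zygosity: str  # het | hom
    category: str  # KR | KNR | UNK


@dataclass(frozen=True)
class SomaticSite:
    site_id: str
    chrom: str
    pos: int
    strand: str
    cell_fraction: float
    n_cells: int  # cells carrying the insertion that were sampled


@dataclass(frozen=True)
class ArtifactSite:
    site_id: str
    chrom: str
    pos: int
    strand: str
    artifact_type: str  # chimera_polyA | misaligned | local_SV
    params: tuple = ()


@dataclass
class GroundTruth:
    germline_sites: list[GermlineSite] = field(default_factory=list)
    somatic_sites: list[SomaticSite] = field(default_factory=list)
    artifact_sites: list[ArtifactSite] = field(default_factory=list)

    def manifest(self) -> str:
        return json.dumps({
            "germline": [asdict(s) for s in self.germline_sites],
            "somatic": [asdict(s) for s in self.somatic_sites],
            "artifact": [asdict(s) for s in self.artifact_sites],
        }, indent=1)


@dataclass(frozen=True)
class LibraryParams:
    """Sequencing-library emulation parameters.

    ``het_signals`` is the mean number of sampled cells (unique
    fragmentation starts) observed per heterozygous germline insertion;
    homozygous sites get twice that.  ``dup_mean`` is the mean PCR
    duplicate count per signal (geometric, so a signal has >= 2 reads with
    probability 1 - 1/dup_mean).
    """

    frag_min: int = 30
    frag_max: int = 150
    het_signals: float = 60.0
    dup_mean: float = 4.0
    tail_mode: int = 25


def sample_insertions(design: SpikeInDesign, seed: Optional[int] = None):
    """Draw per-site sampled copy counts, independently Poisson(lambda).

    Returns ``(counts, sampled_idx)`` where ``sampled_idx`` are the sites
    with at least one sampled copy.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    counts = rng.poisson(design.lam, size=design.n_sites)
    return counts, np.flatnonzero(counts >= 1)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def build_genome(contig_sizes: Mapping[str, int], n_l1hs: int = 5,
                 n_older: int = 0, n_genes: int = 2, seed: int = 0,
                 consensus: Optional[L1Consensus] = None,
                 long_gene: bool = False) -> SyntheticGenome:
    """Build a deterministic toy genome with planted repeats and genes.

    L1Hs copies are planted as the full 3'-end consensus followed by a
    short genomic A-tail (so reads derived from reference copies are
    reproducible artifacts); older-subfamily copies (L1PA2-4) are the
    consensus mutated at 8%.  Repeats and genes are placed without
    overlap; a configuration that cannot fit raises ``ValueError``.
    """
    if any(size < 10_000 for size in contig_sizes.values()):
        raise ValueError("contigs must be >= 10 kb")
    consensus = consensus or load_default_consensus()
    rng = np.random.default_rng(seed)
    sequences = {c: _random_seq(rng, n) for c, n in contig_sizes.items()}
    chroms = list(contig_sizes)

    unit = len(consensus.sequence) + REFERENCE_TAIL
    margin = 2500
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}

    def place(chrom_len_needed: int) -> tuple[str, int]:
        for _ in range(2000):
            chrom = chroms[rng.integers(len(chroms))]
            size = contig_sizes[chrom]
            if size - 2 * margin - chrom_len_needed <= 0:
                continue
            start = int(rng.integers(margin, size - margin - chrom_len_needed))
            if all(start + chrom_len_needed + 800 <= s or e + 800 <= start
                   for s, e in taken[chrom]):
                taken[chrom].append((start, start + chrom_len_needed))
                return chrom, start
        raise ValueError("requested features cannot fit without overlap")

    repeats = []
    families = ["L1Hs"] * n_l1hs + [YOUNG_FAMILIES[1 + i % 3] for i in range(n_older)]
    for i, family in enumerate(families):
        chrom, start = place(unit)
        strand = "+" if rng.random() < 0.5 else "-"
        core = consensus.sequence if family == "L1Hs" else _mutate(rng, consensus.sequence, 0.08)
        insert = core + "A" * REFERENCE_TAIL
        if strand == "-":
            insert = revcomp(insert)
        seq = sequences[chrom]
        sequences[chrom] = seq[:start] + insert + seq[start + unit:]
        core_span = (start, start + len(core)) if strand == "+" else \
                    (start + REFERENCE_TAIL, start + unit)
        repeats.append((chrom, core_span[0], core_span[1], strand, family, f"{family}_{i}"))
    repeats_df = pd.DataFrame(repeats, columns=["chrom", "start", "end", "strand",
                                                "family", "name"])

    gene_models: list[Transcript] = []
    for g in range(n_genes):
        span = int(rng.integers(3000, 8000))
        if long_gene and g == 0 and min(contig_sizes.values()) > 120_000 + 2 * margin:
            span = 120_000
        chrom, start = place(span)
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(2, 5))
        cuts = np.sort(rng.choice(np.arange(200, span - 200), size=2 * n_exons, replace=False))
        exons = tuple((start + int(cuts[2 * k]), start + int(cuts[2 * k + 1]))
                      for k in range(n_exons))
        cds_start = exons[0][0] + (exons[0][1] - exons[0][0]) // 2
        cds_end = exons[-1][0] + (exons[-1][1] - exons[-1][0]) // 2
        gene_models.append(Transcript(
            gene=f"gene{g}", tx_id=f"tx{g}", chrom=chrom, strand=strand,
            tx_start=start, tx_end=start + span,
            cds_start=cds_start, cds_end=cds_end, exons=exons))

    mappability = {c: np.ones(n, dtype=np.float32) for c, n in contig_sizes.items()}
    return SyntheticGenome(sequences=sequences, repeats=repeats_df,
                           gene_models=gene_models, mappability=mappability)


def plan_truth(genome: SyntheticGenome, n_kr: int = 0, n_knr: int = 0,
               n_unk: int = 0, n_somatic: int = 0, n_chimera: int = 0,
               n_misaligned: int = 0, n_local_sv: int = 0,
               somatic_cells: int | Sequence[int] = 1,
               seed: int = 0, prefix: str = "s",
               avoid: Sequence[tuple[str, int]] = ()) -> tuple[GroundTruth, pd.DataFrame]:
    """Choose ground-truth loci on a genome.

    KR sites sit at the 3' junction of planted L1Hs copies; KNR, UNK and
    somatic sites are placed in repeat-free sequence; local-SV artifacts
    sit at reference-L1Hs junctions *without* a planted insertion, so the
    full contig is explained by nearby reference sequence.  Returns the
    truth plus a BED-like KNR database table (emulating a catalogue of
    known polymorphic insertions).
    """
    rng = np.random.default_rng(seed)
    truth = GroundTruth()
    l1hs = genome.repeats[genome.repeats.family == "L1Hs"].reset_index(drop=True)
    if n_kr + n_local_sv > len(l1hs):
        raise ValueError("not enough planted L1Hs copies for KR + local_SV sites")
    order = rng.permutation(len(l1hs))

    def junction(row) -> tuple[str, int, str]:
        # 3' junction past the genomic A-tail of the reference copy
        if row.strand == "+":
            return row.chrom, int(row.end) + REFERENCE_TAIL, "+"
        return row.chrom, int(row.start) - REFERENCE_TAIL, "-"

    k = 0
    for i in range(n_kr):
        chrom, pos, strand = junction(l1hs.iloc[order[k]]); k += 1
        truth.germline_sites.append(GermlineSite(f"{prefix}_kr{i}", chrom, pos, strand,
                                                 "het" if i % 3 else "hom", "KR"))
    for i in range(n_local_sv):
        chrom, pos, strand = junction(l1hs.iloc[order[k]]); k += 1
        truth.artifact_sites.append(ArtifactSite(f"{prefix}_sv{i}", chrom, pos, strand,
                                                 "local_SV"))

    used: list[tuple[str, int]] = list(avoid)

    def clean_locus() -> tuple[str, int, str]:
        chroms = list(genome.sequences)
        for _ in range(4000):
            chrom = chroms[rng.integers(len(chroms))]
            size = len(genome.sequences[chrom])
            pos = int(rng.integers(2500, size - 2500))
            rep = genome.repeats[genome.repeats.chrom == chrom]
            if ((rep.start - 2500 < pos) & (pos < rep.end + 2500)).any():
                continue
            if any(c == chrom and abs(pos - p) < 1200 for c, p in used):
                continue
            used.append((chrom, pos))
            return chrom, pos, "+" if rng.random() < 0.5 else "-"
        raise ValueError("could not place a clean locus")

    knr_rows = []
    for i in range(n_knr):
        chrom, pos, strand = clean_locus()
        truth.germline_sites.append(GermlineSite(f"{prefix}_knr{i}", chrom, pos, strand,
                                                 "het" if i % 4 else "hom", "KNR"))
        knr_rows.append((chrom, max(0, pos - 50), pos + 50, f"{prefix}_knr{i}", 0, strand))
    for i in range(n_unk):
        chrom, pos, strand = clean_locus()
        truth.germline_sites.append(GermlineSite(f"{prefix}_unk{i}", chrom, pos, strand,
                                                 "het", "UNK"))
    cells = ([somatic_cells] * n_somatic if isinstance(somatic_cells, (int, np.integer))
             else list(somatic_cells))
    for i in range(n_somatic):
        chrom, pos, strand = clean_locus()
        n_cells = int(cells[i])
        truth.somatic_sites.append(SomaticSite(f"{prefix}_som{i}", chrom, pos, strand,
                                               cell_fraction=max(n_cells, 1) / 3000.0,
                                               n_cells=n_cells))
    for i in range(n_chimera):
        chrom, pos, strand = clean_locus()
        # overlap (bp) and A-fraction straddle the chimera-filter boundary
        overlap, a_frac = [(12, 0.6), (8, 0.4), (11, 0.5), (6, 0.4)][i % 4]
        truth.artifact_sites.append(ArtifactSite(f"{prefix}_chi{i}", chrom, pos, strand,
                                                 "chimera_polyA", (overlap, a_frac)))
    for i in range(n_misaligned):
        chrom, pos, strand = clean_locus()
        truth.artifact_sites.append(ArtifactSite(f"{prefix}_mis{i}", chrom, pos, strand,
                                                 "misaligned"))
    knr_db = pd.DataFrame(knr_rows, columns=["chrom", "start", "end", "name",
                                             "score", "strand"])
    return truth, knr_db


def simulate_cohort(genome: SyntheticGenome, n_individuals: int = 5,
                    tissues: Sequence[str] = ("neuron", "heart"),
                    n_knr_shared: int = 4, n_knr_private: int = 4,
                    n_unk_private: int = 2, n_kr: int = 2,
                    n_somatic: int = 2, somatic_cells: int = 2,
                    params: LibraryParams = LibraryParams(),
                    seed: int = 0):
    """Simulate a multi-individual cohort.

    Each individual carries the cohort-shared KNR insertions plus an
    individual-specific polymorphic (KNR + UNK) profile; both tissue
    samples of an individual share its germline profile, while somatic
    sites are private to a single sample.  Returns ``(samples, knr_db)``
    where ``samples`` maps sample name to a dict with the contig table,
    individual, tissue and ground truth.
    """
    rng = np.random.default_rng(seed)
    shared_truth, shared_db = plan_truth(genome, n_kr=n_kr, n_knr=n_knr_shared,
                                         seed=seed, prefix="shared")
    taken = [(s.chrom, s.pos) for s in shared_truth.germline_sites]
    dbs = [shared_db]
    samples: dict[str, dict] = {}
    for i in range(n_individuals):
        ind = f"I{i + 1}"
        priv, priv_db = plan_truth(genome, n_knr=n_knr_private, n_unk=n_unk_private,
                                   seed=seed + 1000 + i, prefix=ind, avoid=taken)
        taken += [(s.chrom, s.pos) for s in priv.germline_sites]
        dbs.append(priv_db)
        germline = shared_truth.germline_sites + priv.germline_sites
        for t, tissue in enumerate(tissues):
            name = f"{ind}_{tissue}"
            som, _ = plan_truth(genome, n_somatic=n_somatic,
                                somatic_cells=somatic_cells,
                                seed=seed + 5000 + 10 * i + t, prefix=name,
                                avoid=taken)
            taken += [(s.chrom, s.pos) for s in som.somatic_sites]
            truth = GroundTruth(germline_sites=list(germline),
                                somatic_sites=som.somatic_sites)
            contigs = generate_contigs(genome, truth, params=params, sample=name,
                                       individual=ind,
                                       seed=int(rng.integers(2**31)))
            samples[name] = {"contigs": contigs, "individual": ind,
                             "tissue": tissue, "truth": truth}
    knr_db = pd.concat(dbs, ignore_index=True)
    return samples, knr_db


def _tail_len(rng: np.random.Generator, params: LibraryParams) -> int:
    # binomial around the modal tail length; sd ~2.7 bp
    return int(params.tail_mode - 15 + rng.binomial(30, 0.5))


def _flank_seq(genome: SyntheticGenome, chrom: str, pos: int, strand: str,
               length: int) -> Optional[str]:
    """Junction-proximal flank, oriented so its last base abuts the tail."""
    size = len(genome.sequences[chrom])
    if strand == "+":
        if pos + length > size:
            return None
        return revcomp(genome.fetch(chrom, pos, pos + length))
    if pos - length < 0:
        return None
    return genome.fetch(chrom, pos - length, pos)


def _interval(pos: int, strand: str, frag: int) -> tuple[int, int, int]:
    """Alignment interval and outermost (signal) coordinate."""
    if strand == "+":
        return pos, pos + frag, pos + frag
    return pos - frag, pos, pos - frag


def generate_contigs(genome: SyntheticGenome, truth: GroundTruth,
                     consensus: Optional[L1Consensus] = None,
                     params: LibraryParams = LibraryParams(),
                     sample: str = "S1", individual: str = "I1",
                     seed: int = 0) -> pd.DataFrame:
    """Emit the merged-contig table for one library.

    Each record is one sequenced contig: flank-first sequence, its flank
    alignment (chrom/start/end/strand, 0-based half-open), an independent
    secondary placement (emulating a second aligner), the on-contig spans
    of the genomic and retrotransposon segments, a duplicate-group key and
    the ground-truth id.  Reads from one simulated cell share one
    fragmentation start; PCR duplicates replicate the record verbatim.
    Sites whose flank would run past the contig end are skipped.
    """
    consensus = consensus or load_default_consensus()
    rng = np.random.default_rng(seed)
    tail_block = revcomp(consensus.tail)  # 3'-end segment without primer, reverse

    rows: list[dict] = []

    def phase_suffix() -> tuple[str, int]:
        phase = int(rng.choice([2, 4, 6]))
        return _random_seq(rng, phase), phase

    def emit_signal(site_id: str, chrom: str, pos: int, strand: str,
                    tail: int, kr: bool, signal_idx: int) -> None:
        frag = int(rng.integers(params.frag_min, params.frag_max + 1))
        flank = _flank_seq(genome, chrom, pos, strand, frag)
        if flank is None:
            logger.warning("flank for %s extends past contig end; site skipped", site_id)
            return
        suffix, phase = phase_suffix()
        seq = flank + "T" * tail + tail_block + revcomp(consensus.primer28) + revcomp(suffix)
        l1_off = len(flank) + tail
        start, end, outer = _interval(pos, strand, frag)
        if kr:
            # uniquely mapped read pairs span ~240 bp into the reference copy
            if strand == "+":
                start = pos - REFERENCE_TAIL - 240
            else:
                end = pos + REFERENCE_TAIL + 240
        ndup = int(rng.geometric(1.0 / params.dup_mean))
        group = f"{site_id}.{sample}.{signal_idx}"
        for d in range(ndup):
            rows.append(dict(
                contig_id=f"{group}.{d}", truth_id=site_id, sample=sample,
                individual=individual, sequence=seq, chrom=chrom,
                start=start, end=end, strand=strand, mapq=60, mismatches=0,
                aligned_len=end - start, dup_group=group, start_position=outer,
                l1_off=l1_off, l1_len=len(seq) - l1_off,
                flank_off=0, flank_len=len(flank),
                alt_chrom=chrom, alt_start=start, alt_strand=strand, phase=phase))

    for site in truth.germline_sites:
        tail = _tail_len(rng, params)
        mean = params.het_signals * (2.0 if site.zygosity == "hom" else 1.0)
        n_signals = max(1, int(rng.poisson(mean)))
        for j in range(n_signals):
            emit_signal(site.site_id, site.chrom, site.pos, site.strand, tail,
                        kr=(site.category == "KR"), signal_idx=j)

    for site in truth.somatic_sites:
        tail = _tail_len(rng, params)
        for j in range(site.n_cells):
            emit_signal(site.site_id, site.chrom, site.pos, site.strand, tail,
                        kr=False, signal_idx=j)

    for art in truth.artifact_sites:
        _emit_artifact(rows, art, genome, consensus, params, rng, sample, individual)

    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["chrom", "start", "contig_id"], kind="stable").reset_index(drop=True)
    return df


def _emit_artifact(rows: list, art: ArtifactSite, genome: SyntheticGenome,
                   consensus: L1Consensus, params: LibraryParams,
                   rng: np.random.Generator, sample: str, individual: str) -> None:
    tail_block = revcomp(consensus.tail)
    l1_block = tail_block + revcomp(consensus.primer28)

    def base_row(seq, chrom, start, end, strand, outer, l1_off, flank_len, group, d,
                 alt=None):
        alt_chrom, alt_start, alt_strand = alt or (chrom, start, strand)
        rows.append(dict(
            contig_id=f"{group}.{d}", truth_id=art.site_id, sample=sample,
            individual=individual, sequence=seq, chrom=chrom, start=start, end=end,
            strand=strand, mapq=60, mismatches=0, aligned_len=end - start,
            dup_group=group, start_position=outer, l1_off=l1_off,
            l1_len=len(seq) - l1_off, flank_off=0, flank_len=flank_len,
            alt_chrom=alt_chrom, alt_start=alt_start, alt_strand=alt_strand,
            phase=int(rng.choice([2, 4, 6]))))

    n_signals = 2  # duplicate-supported so only the targeted filter rejects it
    for j in range(n_signals):
        frag = int(rng.integers(params.frag_min, params.frag_max + 1))
        flank = _flank_seq(genome, art.chrom, art.pos, art.strand, frag)
        if flank is None:
            continue
        suffix = _random_seq(rng, int(rng.choice([2, 4, 6])))
        start, end, outer = _interval(art.pos, art.strand, frag)
        group = f"{art.site_id}.{sample}.{j}"
        for d in range(2):
            if art.artifact_type == "chimera_polyA":
                overlap, a_frac = art.params
                n_t = round(overlap * a_frac)
                bridge = ("T" * n_t + "".join(rng.choice(list("CG"), size=overlap - n_t)))
                bridge = "".join(rng.permutation(list(bridge)))
                seq = flank[:-overlap] + bridge + l1_block + revcomp(suffix)
                # flank and L1 best placements overlap by `overlap` on the contig
                base_row(seq, art.chrom, start, end, art.strand, outer,
                         l1_off=len(flank) - overlap, flank_len=len(flank),
                         group=group, d=d)
            elif art.artifact_type == "misaligned":
                tail = _tail_len(rng, params)
                seq = flank + "T" * tail + l1_block + revcomp(suffix)
                other = [c for c in genome.sequences if c != art.chrom]
                alt = ((other[0] if other else art.chrom),
                       start + 5000, art.strand)
                base_row(seq, art.chrom, start, end, art.strand, outer,
                         l1_off=len(flank) + tail, flank_len=len(flank),
                         group=group, d=d, alt=alt)
            else:  # local_SV: contig fully explained by nearby reference copy
                tail = REFERENCE_TAIL
                seq = flank + "T" * tail + l1_block + revcomp(suffix)
                base_row(seq, art.chrom, start, end, art.strand, outer,
                         l1_off=len(flank) + tail, flank_len=len(flank),
                         group=group, d=d)
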