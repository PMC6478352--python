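"""End-to-end orchestration: parse -> filter/classify -> annotate -> quantify.

The cohort runner makes two classification passes: the first collects
putative somatic loci per individual, the second applies the
observed-in-common filter against that cross-individual index (recurrent
somatic insertions in unrelated individuals are far less likely than
recurrent artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .classify import CascadeResult, run_cascade
from .config import FilterConfig, MotifControlConfig
from .consensus import L1Consensus, load_default_consensus
from .genomic_stats import (annotate_region, canonical_transcripts, cluster_samples,
                            orientation_binomial_test, region_binomial_test,
                            region_bp_fractions)
from .peakcall import join_peaks
from .quant import SampleLibrary, group_rates, somatic_rate_per_cell
from .readproc import parse_contigs
from .simdata import SyntheticGenome
from .tprt import en_motif_distance, polyA_length_distribution

__all__ = ["SampleInput", "run_sample", "run_cohort"]

GERMLINE = ("KR", "KNR", "UNK")
SOMATIC = ("somatic", "clonal_somatic")


@dataclass
class SampleInput:
    sample: str
    individual: str
    tissue_class: str  # brain | non_brain
    contigs: pd.DataFrame
    cohort: str = ""


def _candidate_loci(result: CascadeResult) -> list[tuple[str, str, int, int]]:
    loci = []
    for cat in ("somatic", "clonal_somatic"):
        for p in result.peaks[cat]:
            loci.append((p.chrom, p.strand, p.start, p.end))
    # rejected-for-duplicates candidates still mark a locus as seen
    for p, call in zip(result.peaks["rejected"],
                       [c for c in result.calls if c.category == "rejected"]):
        if call.rejection_reasons == ["no_pcr_duplicate"]:
            loci.append((p.chrom, p.strand, p.start, p.end))
    return loci


def run_sample(inp: SampleInput, genome: SyntheticGenome,
               knr_db: Optional[pd.DataFrame],
               consensus: Optional[L1Consensus] = None,
               cfg: FilterConfig = FilterConfig(),
               shared_index: Optional[Mapping[tuple, set]] = None) -> dict:
    """Classify one library and annotate its calls with TPRT hallmarks."""
    consensus = consensus or load_default_consensus()
    parsed = parse_contigs(inp.contigs, consensus, cfg.identity_max_mismatches)
    result = run_cascade(parsed, genome, knr_db, cfg, inp.sample, inp.individual,
                         shared_locus_individuals=shared_index)
    annotations = []
    for call in result.calls:
        if call.category == "rejected":
            continue
        dist, flags = en_motif_distance(call.chrom, call.position - 1,
                                        call.strand or "+", genome)
        annotations.append({"chrom": call.chrom, "position": call.position,
                            "category": call.category, "en_distance": dist,
                            "en_flags": ";".join(flags)})
    tails = polyA_length_distribution(parsed["polyT_len"].dropna().astype(int))
    lib = _sample_library(inp, result)
    return {"parsed": parsed, "result": result, "library": lib,
            "tprt": pd.DataFrame(annotations), "tails": tails}


def _sample_library(inp: SampleInput, result: CascadeResult) -> SampleLibrary:
    reads = {cat: sum(p.n_reads for p in result.peaks[cat])
             for cat in ("KR", "KNR", "UNK")}
    reads_somatic = sum(p.n_reads for cat in SOMATIC for p in result.peaks[cat])
    return SampleLibrary(
        sample=inp.sample, individual=inp.individual, tissue_class=inp.tissue_class,
        reads_somatic=reads_somatic, reads_knr=reads["KNR"], reads_kr=reads["KR"],
        reads_unk=reads["UNK"],
        knr_count=len(result.peaks["KNR"]))


def run_cohort(inputs: list[SampleInput], genome: SyntheticGenome,
               knr_db: Optional[pd.DataFrame],
               consensus: Optional[L1Consensus] = None,
               cfg: FilterConfig = FilterConfig()) -> dict:
    """Run the full pipeline over a cohort of libraries.

    Returns per-sample results plus the cohort report: germline
    presence/absence matrix and clustering, per-cell somatic rates with
    the paired brain vs non-brain test, and orientation/region
    statistics over the pooled calls.
    """
    if len({i.sample for i in inputs}) != len(inputs):
        raise ValueError("duplicate sample ids in manifest")
    consensus = consensus or load_default_consensus()

    # pass 1: collect candidate somatic loci per individual
    shared: dict[tuple, set] = {}
    first = {}
    for inp in inputs:
        res = run_sample(inp, genome, knr_db, consensus, cfg)
        first[inp.sample] = res
        for locus in _candidate_loci(res["result"]):
            shared.setdefault(locus, set()).add(inp.individual)

    # pass 2: apply the observed-in-common filter
    samples = {}
    for inp in inputs:
        samples[inp.sample] = run_sample(inp, genome, knr_db, consensus, cfg,
                                         shared_index=shared)

    # germline presence matrix + clustering
    germline_peaks = {s: [p for cat in GERMLINE for p in r["result"].peaks[cat]]
                      for s, r in samples.items()}
    presence = join_peaks(germline_peaks, merge_gap=cfg.merge_gap_bp)
    clustering = None
    if presence.shape[1] >= 2 and len(presence):
        cats = _locus_categories(presence, samples, cfg.merge_gap_bp)
        clustering = cluster_samples(presence.T, locus_categories=cats)

    # per-cell rates; the individual's KNR count is shared by its samples
    knr_by_ind: dict[str, int] = {}
    for inp in inputs:
        lib = samples[inp.sample]["library"]
        knr_by_ind[inp.individual] = max(knr_by_ind.get(inp.individual, 0), lib.knr_count)
    rate_rows = []
    for inp in inputs:
        lib = samples[inp.sample]["library"]
        lib.knr_count = knr_by_ind[inp.individual]
        if lib.reads_knr > 0:
            rate_rows.append({"individual": inp.individual, "cohort": inp.cohort,
                              "tissue_class": inp.tissue_class, "sample": inp.sample,
                              "rate": somatic_rate_per_cell(lib)})
    rates = pd.DataFrame(rate_rows)
    rate_report = group_rates(rates, cohort_col="cohort" if any(i.cohort for i in inputs) else None) \
        if len(rates) else None

    stats_report = _cohort_stats(samples, genome)
    return {"samples": samples, "presence": presence, "clustering": clustering,
            "rates": rates, "rate_report": rate_report, "stats": stats_report}


def _locus_categories(presence: pd.DataFrame, samples: dict, gap: int) -> dict[str, str]:
    cats: dict[str, str] = {}
    for label in presence.index:
        loc, strand = label.rsplit(":", 1)
        chrom, span = loc.rsplit(":", 1)
        start = int(span.split("-")[0]) - 1
        end = int(span.split("-")[1])
        for r in samples.values():
            for cat in GERMLINE:
                for p in r["result"].peaks[cat]:
                    if (p.chrom == chrom and (p.strand or ".") == strand
                            and p.start < end and p.end > start):
                        cats[label] = cat
                        break
    return cats


def _cohort_stats(samples: dict, genome: SyntheticGenome) -> dict:
    canon = canonical_transcripts(genome.gene_models)
    fractions = region_bp_fractions(genome.contig_sizes, canon)
    germ_sense = germ_total = 0
    som_regions: list[str] = []
    for r in samples.values():
        for call in r["result"].calls:
            if call.category == "rejected":
                continue
            region, gene, orientation = annotate_region(
                call.chrom, call.position - 1, call.strand or "+", canon)
            if call.category in GERMLINE and orientation != "NA":
                germ_total += 1
                germ_sense += orientation == "sense"
            if call.category in SOMATIC:
                som_regions.append(region)
    out: dict = {"region_fractions": fractions}
    if germ_total:
        out["germline_orientation"] = orientation_binomial_test(germ_sense, germ_total)
    if som_regions:
        n = len(som_regions)
        k_intron = sum(r == "intron" for r in som_regions)
        if 0 < fractions["intron"] < 1:
            out["somatic_intron_test"] = region_binomial_test(k_intron, n, fractions["intron"])
    return out
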