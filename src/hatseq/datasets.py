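"""Published study inputs bundled with the package.

The cohort overview table summarises the twenty postmortem libraries
(five Rett syndrome patients and five matched healthy controls, one
prefrontal-cortex neuron and one non-brain sample each): somatic
insertion counts, estimated somatic insertion rates per cell, and
germline KR/KNR/UNK counts per individual.  The spike-in constants
describe the two-donor dilution-series benchmark used to calibrate
sensitivity and precision.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_cohort_overview", "cohort_rate_table", "SPIKE_IN", "ORIENTATION"]

#: Dilution-series benchmark: 64 donor-specific heterozygous insertions
#: spiked at 1% / 0.1% / 0.01% into 3,000 cells of carrier-free DNA, with
#: the number of insertions surviving all error filters at each dilution,
#: and the cohort-level candidate total with the per-library
#: false-positive ceiling observed in the benchmark.
SPIKE_IN = {
    "n_sites": 64,
    "input_cells": 3000,
    "copies_per_cell": 1.0,
    "dilutions": (0.01, 0.001, 0.0001),
    "identified": (49, 17, 5),
    "somatic_total": 9181,
    "n_libraries": 20,
    "fp_per_library_bound": 183,
    "clonal_signal_min": 3,
}

#: Germline transcript-overlap orientation counts: sense insertions over
#: all transcript-overlapping germline insertions.
ORIENTATION = {"sense": 633, "total": 1544}


def load_cohort_overview() -> pd.DataFrame:
    """Per-individual cohort summary table."""
    with resources.files("hatseq.data").joinpath("cohort_overview.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype={"individual": str, "matched_id": str})


def cohort_rate_table() -> pd.DataFrame:
    """Long-format per-sample rate table for :func:`hatseq.quant.group_rates`."""
    wide = load_cohort_overview()
    rows = []
    for _, r in wide.iterrows():
        rows.append({"individual": r.individual, "cohort": r.cohort,
                     "tissue_class": "brain", "rate": r.rate_neuron})
        rows.append({"individual": r.individual, "cohort": r.cohort,
                     "tissue_class": "non_brain", "rate": r.rate_nonbrain})
    return pd.DataFrame(rows)
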