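"""End-to-end typing pipeline: demux -> locus assignment -> align -> call.

Thin composition of the library modules, used by the command-line
interface and by whole-stack tests.  No algorithmic content lives here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .align_ingest import (
    AssignedRead,
    CoverageSummary,
    depth_of_coverage,
    misalignment_filter,
    plumbing_align,
)
from .allele_db import AlleleDictionary, FrequencyTable
from .caller import HLACall, call_samples, calls_to_frame
from .demux import BarcodeManifest, DemuxReport, PrimerManifest, RawRead, assign_locus, demultiplex
from .phasing import DEFAULT_P_ERR


@dataclass
class PipelineResult:
    calls: list[HLACall]
    pair_scores: pd.DataFrame
    coverage: CoverageSummary
    demux_report: DemuxReport
    n_locus_assigned: int
    n_aligned: int
    n_filtered_out: int
    kept_reads: list[AssignedRead]

    def calls_frame(self) -> pd.DataFrame:
        return calls_to_frame(self.calls)


def run_typing(
    reads: Iterable[RawRead],
    barcodes: BarcodeManifest,
    primers: PrimerManifest,
    dictionary: AlleleDictionary,
    frequencies: FrequencyTable | None = None,
    population: str | None = None,
    p_err: float = DEFAULT_P_ERR,
    primer_mismatch: int = 1,
    barcode_mismatch: int = 0,
    **call_kwargs,
) -> PipelineResult:
    """Type every sample in a pooled FASTQ-style read stream."""
    by_sample, report = demultiplex(reads, barcodes, max_mismatch=barcode_mismatch)
    aligned: list[AssignedRead] = []
    n_assigned = 0
    for sample in sorted(by_sample):
        for read in by_sample[sample]:
            hit = assign_locus(read, primers, max_mismatch=primer_mismatch)
            if hit is None:
                continue
            n_assigned += 1
            placed = plumbing_align(
                hit.read, hit.locus, dictionary,
                sample=sample, exon=hit.exon, strand=hit.strand,
            )
            if placed is not None:
                aligned.append(placed)
    kept, removed = misalignment_filter(aligned, dictionary)
    samples = sorted(barcodes.barcodes)
    coverage = depth_of_coverage(kept, dictionary, samples=samples)
    calls, pair_scores = call_samples(
        kept, dictionary,
        frequencies=frequencies, population=population,
        samples=samples, p_err=p_err, **call_kwargs,
    )
    return PipelineResult(
        calls=calls,
        pair_scores=pair_scores,
        coverage=coverage,
        demux_report=report,
        n_locus_assigned=n_assigned,
        n_aligned=len(aligned),
        n_filtered_out=removed,
        kept_reads=kept,
    )


def type_simulated(dataset, **kwargs) -> PipelineResult:
    """Run the full pipeline on a :class:`~hlacall.simulator.SimulatedDataset`."""
    return run_typing(
        dataset.reads,
        dataset.barcodes,
        dataset.primers,
        dataset.dictionary,
        frequencies=kwargs.pop("frequencies", dataset.frequencies),
        population=kwargs.pop("population", dataset.population),
        **kwargs,
    )
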