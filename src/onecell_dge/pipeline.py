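"""End-to-end convenience: demultiplex → align → count in one call.

Glue for test-scale and simulated data; each step is the corresponding
module operation and can be run separately on real data (where an external
transcript aligner replaces :func:`~onecell_dge.counting.toy_align`).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .barcodes import IndexSet
from .counting import (TranscriptGeneMap, UMICountMatrix, build_matrix,
                       parse_alignments, toy_align, unify_umis)
from .readproc import DemuxReport, demultiplex

__all__ = ["run_pipeline", "count_sample"]


def count_sample(sam_path: str | Path, t2g: TranscriptGeneMap,
                 total_reads: int | None = None,
                 multimap_policy: str = "discard",
                 seed: int = 0) -> tuple[pd.Series, dict[str, int], pd.DataFrame]:
    """Parse one sample's SAM and unify UMIs.

    Returns ``(unified counts, tallies, assignments)``; ``total_reads``
    overrides the SAM-derived read total (use the demultiplexed read count
    when the aligner drops records).
    """
    assignments, tallies = parse_alignments(sam_path, t2g, multimap_policy)
    if total_reads is not None:
        tallies["total_reads"] = int(total_reads)
    counts, _ = unify_umis(assignments, seed=seed)
    return counts, tallies, assignments


def run_pipeline(read1_fastq: str | Path, index_fastq: str | Path,
                 index_set: IndexSet, reference_fasta: str | Path,
                 t2g: TranscriptGeneMap, work_dir: str | Path,
                 k: int = 31, seed: int = 0,
                 multimap_policy: str = "discard",
                 demux_kwargs: dict | None = None,
                 ) -> tuple[UMICountMatrix, DemuxReport, dict[str, pd.DataFrame]]:
    """Demultiplex, align each sample with the toy aligner, and count.

    Returns the UMI count matrix, the demultiplexing report, and the
    per-sample gene-assignment tables (inputs for saturation analysis).
    """
    work = Path(work_dir)
    demux_dir = work / "demux"
    report = demultiplex(read1_fastq, index_fastq, index_set, demux_dir,
                         **(demux_kwargs or {}))
    per_sample = {}
    assignments = {}
    for sample in index_set.sample_ids:
        fq = demux_dir / f"{sample}.fastq"
        if not fq.exists():
            fq = demux_dir / f"{sample}.fastq.gz"
        if not fq.exists():
            continue
        sam = work / f"{sample}.sam"
        toy_align(fq, reference_fasta, sam, k=k)
        counts, tallies, asn = count_sample(
            sam, t2g, total_reads=report.assigned.get(sample),
            multimap_policy=multimap_policy, seed=seed)
        per_sample[sample] = (counts, tallies)
        assignments[sample] = asn
    if not per_sample:
        raise ValueError("no sample produced any reads")
    matrix = build_matrix(per_sample, t2g.genes)
    return matrix, report, assignments
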