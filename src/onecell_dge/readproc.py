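"""Index-read parsing, UMI embedding, read trimming, and demultiplexing.

The sequencer emits two positionally paired FASTQ streams: read1 (the cDNA
fragment) and a 20-nt index read laid out as 8 nt of multiplex index,
10 nt of UMI, and 2 tail bases that are discarded.  This module trims the
index read to 18 nt, splits it into index and UMI, embeds the UMI into the
read1 name (so it survives the SAM round trip), decodes the index with
single-substitution error correction, quality-trims read1, and writes one
FASTQ per sample.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .barcodes import IndexDecoder, IndexSet

__all__ = [
    "UMI_SEPARATOR",
    "trim_index_read",
    "split_index_umi",
    "embed_umi_in_name",
    "extract_umi_from_name",
    "quality_trim",
    "trim_adapter",
    "demultiplex",
    "DemuxReport",
    "read_fastq",
    "write_fastq_record",
]

UMI_SEPARATOR = "_UMI:"

INDEX_READ_LEN = 18  # after 3'-tail trimming
DEFAULT_INDEX_LEN = 8
DEFAULT_UMI_LEN = 10


# ---------------------------------------------------------------------------
# FASTQ plumbing
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield ``(title, sequence, quality)`` from a FASTQ file (.gz ok)."""
    with _open_text(path) as fh:
        yield from FastqGeneralIterator(fh)


def write_fastq_record(fh: IO[str], title: str, seq: str, qual: str) -> None:
    fh.write(f"@{title}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Index-read handling
# ---------------------------------------------------------------------------

def trim_index_read(index_seq: str, index_qual: str | None = None,
                    keep: int = INDEX_READ_LEN) -> tuple[str, str | None]:
    """Trim the 3' tail of the index read down to ``keep`` bases.

    A 20-nt index read loses its final 2 bases; an 18-nt read is returned
    unchanged.  Shorter reads are an error.
    """
    if len(index_seq) < keep:
        raise ValueError(
            f"index read of length {len(index_seq)} is shorter than {keep}")
    if index_qual is not None and len(index_qual) != len(index_seq):
        raise ValueError("index quality string length mismatch")
    return index_seq[:keep], (index_qual[:keep] if index_qual is not None else None)


def split_index_umi(trimmed: str, layout: str = "index_first",
                    index_len: int = DEFAULT_INDEX_LEN,
                    umi_len: int = DEFAULT_UMI_LEN) -> tuple[str, str]:
    """Partition a trimmed index read into ``(index, umi)`` per the layout."""
    if index_len + umi_len != len(trimmed):
        raise ValueError(
            f"index_len + umi_len = {index_len + umi_len} != read length {len(trimmed)}")
    if layout == "index_first":
        return trimmed[:index_len], trimmed[index_len:]
    if layout == "umi_first":
        return trimmed[umi_len:], trimmed[:umi_len]
    raise ValueError(f"unknown layout {layout!r}")


def embed_umi_in_name(read_id: str, umi: str) -> str:
    """Append the UMI to the read name with a SAM-safe separator.

    Only the token before the first whitespace is kept (SAM QNAMEs cannot
    contain whitespace, and aligners drop FASTQ description fields anyway).
    """
    token = read_id.split()[0]
    if UMI_SEPARATOR in token:
        raise ValueError(f"read id {token!r} already carries a UMI token")
    return f"{token}{UMI_SEPARATOR}{umi}"


def extract_umi_from_name(name: str) -> tuple[str, str]:
    """Inverse of :func:`embed_umi_in_name`; raises if the token is absent."""
    token = name.split()[0]
    if UMI_SEPARATOR not in token:
        raise ValueError(f"no UMI token in read name {name!r}")
    read_id, umi = token.rsplit(UMI_SEPARATOR, 1)
    return read_id, umi


# ---------------------------------------------------------------------------
# Read1 trimming
# ---------------------------------------------------------------------------

def quality_trim(seq: str, qual: str, trailing_q: int = 20, window: int = 4,
                 window_q: float = 15, minlen: int = 30) -> tuple[str, str] | None:
    """Quality-trim a read; returns ``None`` when it falls below ``minlen``.

    Three stages, applied in order: (1) strip 3' bases whose quality is
    below ``trailing_q``; (2) scan 5'→3' with a window of ``window`` bases
    and truncate at the start of the first window whose mean quality is
    below ``window_q``; (3) drop the read if fewer than ``minlen`` bases
    remain.
    """
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    phred = [ord(c) - 33 for c in qual]
    if any(q < 0 or q > 93 for q in phred):
        raise ValueError("quality string is not Phred+33")
    end = len(seq)
    while end > 0 and phred[end - 1] < trailing_q:
        end -= 1
    if window > 0 and end >= window:
        thresh = window_q * window
        for start in range(0, end - window + 1):
            if sum(phred[start:start + window]) < thresh:
                end = start
                break
    if end < minlen:
        return None
    return seq[:end], qual[:end]


def trim_adapter(seq: str, qual: str, adapter: str,
                 min_overlap: int = 7) -> tuple[str, str]:
    """Clip a 3' adapter: full internal occurrence, or a terminal prefix.

    The read is truncated at the first full occurrence of the adapter, or
    failing that at a 3'-terminal match to an adapter prefix of at least
    ``min_overlap`` bases.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    cut = seq.find(adapter)
    if cut < 0:
        for k in range(min(len(adapter) - 1, len(seq)), min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
    if cut < 0:
        return seq, qual
    return seq[:cut], qual[:cut]


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

@dataclass
class DemuxReport:
    """Accounting of a demultiplexing run.

    ``assigned`` counts every pair decoded to a sample, including reads that
    the quality filter later drops (tracked per sample in
    ``dropped_quality``); ``written`` is what actually reached the output
    FASTQ.  Conservation: ``sum(assigned) + unassigned == total_pairs``.
    """

    total_pairs: int = 0
    assigned: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0
    dropped_quality: dict[str, int] = field(default_factory=dict)
    umi_with_n: int = 0

    @property
    def assigned_total(self) -> int:
        return sum(self.assigned.values())

    @property
    def assigned_fraction(self) -> float:
        return self.assigned_total / self.total_pairs if self.total_pairs else 0.0

    @property
    def written(self) -> dict[str, int]:
        return {s: self.assigned[s] - self.dropped_quality.get(s, 0)
                for s in self.assigned}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "total_pairs": self.total_pairs,
                "assigned": self.assigned,
                "unassigned": self.unassigned,
                "assigned_fraction": self.assigned_fraction,
                "dropped_quality": self.dropped_quality,
                "umi_with_n": self.umi_with_n,
            }, fh, indent=2)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tassigned\tdropped_quality\twritten\n")
            for s in self.assigned:
                fh.write(f"{s}\t{self.assigned[s]}\t"
                         f"{self.dropped_quality.get(s, 0)}\t{self.written[s]}\n")
            fh.write(f"unassigned\t{self.unassigned}\t0\t0\n")


def demultiplex(read1_fastq: str | Path, index_fastq: str | Path,
                index_set: IndexSet, out_dir: str | Path,
                layout: str = "index_first",
                index_len: int = DEFAULT_INDEX_LEN,
                umi_len: int = DEFAULT_UMI_LEN,
                effective_index_len: int | None = None,
                max_correct: int = 1,
                adapter: str | None = None,
                trailing_q: int = 20, window: int = 4, window_q: float = 15,
                minlen: int = 30,
                gzip_out: bool = False) -> DemuxReport:
    """Demultiplex paired read1/index FASTQ into per-sample FASTQ files.

    Each pair is decoded from the first ``effective_index_len`` bases of the
    index field (default: the full index), its UMI embedded into the read1
    name, read1 adapter- and quality-trimmed, and written to
    ``<out_dir>/<sample_id>.fastq[.gz]``.  Pairing is positional; read ids
    are cross-checked on the first whitespace token.

    Reads whose UMI contains N are kept (counted in the report); the
    counting stage discards them at unification.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    decode_set = index_set
    if effective_index_len is not None and effective_index_len != index_set.length:
        decode_set = index_set.truncated(effective_index_len)
    decoder = IndexDecoder(decode_set, max_correct=max_correct)
    eff_len = decode_set.length

    report = DemuxReport(assigned={s: 0 for s in index_set.sample_ids},
                         dropped_quality={})
    suffix = ".fastq.gz" if gzip_out else ".fastq"
    handles: dict[str, IO[str]] = {}
    try:
        from itertools import zip_longest
        r1_iter = read_fastq(read1_fastq)
        ix_iter = read_fastq(index_fastq)
        for r1, ix in zip_longest(r1_iter, ix_iter):
            if r1 is None or ix is None:
                raise ValueError("read1 and index FASTQ have unequal record counts")
            title1, seq1, qual1 = r1
            title_ix, seq_ix, _ = ix
            id1 = title1.split()[0]
            if id1 != title_ix.split()[0]:
                raise ValueError(
                    f"read id mismatch between mates: {id1!r} vs "
                    f"{title_ix.split()[0]!r}")
            report.total_pairs += 1
            trimmed, _ = trim_index_read(seq_ix)
            index_field, umi = split_index_umi(trimmed, layout, index_len, umi_len)
            sample = decoder(index_field[:eff_len])
            if sample is None:
                report.unassigned += 1
                continue
            report.assigned[sample] += 1
            if "N" in umi:
                report.umi_with_n += 1
            name = embed_umi_in_name(id1, umi)
            if adapter:
                seq1, qual1 = trim_adapter(seq1, qual1, adapter)
            kept = quality_trim(seq1, qual1, trailing_q, window, window_q, minlen)
            if kept is None:
                report.dropped_quality[sample] = report.dropped_quality.get(sample, 0) + 1
                continue
            fh = handles.get(sample)
            if fh is None:
                fh = _open_text(out_dir / f"{sample}{suffix}", "wt")
                handles[sample] = fh
            write_fastq_record(fh, name, *kept)
    finally:
        for fh in handles.values():
            fh.close()
    return report
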