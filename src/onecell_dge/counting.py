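"""Gene assignment of transcript alignments and UMI unification.

The central computation of digital gene expression tag counting: reads
aligned to a transcript reference are resolved to gene loci through a
transcript→gene map, and all mapped reads sharing a gene locus and a UMI
are unified into a single molecule count.  Reads on different genes are
never merged, even with identical UMIs.  The unification key is
(gene, UMI) only — the mapping position is recorded but does not enter the
key — and UMIs are compared exactly (no error-tolerant merging).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

from .readproc import extract_umi_from_name

__all__ = [
    "TranscriptGeneMap",
    "UMICountMatrix",
    "parse_alignments",
    "unify_umis",
    "build_matrix",
    "toy_align",
]

ASSIGNMENT_COLUMNS = ["read_id", "umi", "gene_id", "transcript_id", "position"]


class TranscriptGeneMap:
    """Many-to-one transcript→gene map with an explicit gene universe."""

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise ValueError("empty transcript-to-gene map")
        self._map = dict(mapping)
        self.genes = sorted(set(self._map.values()))

    def __getitem__(self, transcript_id: str) -> str:
        return self._map[transcript_id]

    def __contains__(self, transcript_id: str) -> bool:
        return transcript_id in self._map

    def __len__(self) -> int:
        return len(self._map)

    @property
    def transcripts(self) -> list[str]:
        return sorted(self._map)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TranscriptGeneMap":
        """Read ``transcript_id<TAB>gene_id`` rows (# comments ignored)."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tid, gid = line.split("\t")[:2]
                if tid in mapping and mapping[tid] != gid:
                    raise ValueError(f"transcript {tid!r} maps to two genes")
                mapping[tid] = gid
        return cls(mapping)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for tid in sorted(self._map):
                fh.write(f"{tid}\t{self._map[tid]}\n")


@dataclass
class UMICountMatrix:
    """Genes × samples UMI count matrix plus per-sample sequencing statistics.

    ``stats`` rows are samples with columns ``total_reads``, ``mapped_reads``,
    ``mapping_rate``, ``umi_counts`` (column sum of the matrix),
    ``umi_unified_rate`` = (mapped − UMI)/mapped, and ``detected_genes``.
    """

    counts: pd.DataFrame
    stats: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        for s in self.counts.columns:
            if self.stats.loc[s, "umi_counts"] > self.stats.loc[s, "mapped_reads"]:
                raise ValueError(f"umi_counts > mapped_reads for sample {s!r}")

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def to_tsv(self, path: str | Path, stats_path: str | Path | None = None) -> None:
        self.counts.to_csv(path, sep="\t", index_label="gene_id")
        if stats_path is not None:
            self.stats.to_csv(stats_path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 stats_path: str | Path | None = None) -> "UMICountMatrix":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        if stats_path is not None:
            stats = pd.read_csv(stats_path, sep="\t", index_col=0)
        else:
            stats = _stats_from_counts(counts)
        return cls(counts=counts, stats=stats)

    def to_mtx(self, directory: str | Path) -> None:
        """MatrixMarket triple: matrix.mtx, genes.tsv, samples.tsv."""
        from scipy.io import mmwrite
        from scipy.sparse import csr_matrix
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(directory / "matrix.mtx", csr_matrix(self.counts.values))
        (directory / "genes.tsv").write_text("\n".join(self.genes) + "\n")
        (directory / "samples.tsv").write_text("\n".join(self.samples) + "\n")


def _stats_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    umi = counts.sum(axis=0)
    return pd.DataFrame({
        "total_reads": np.nan, "mapped_reads": umi, "mapping_rate": np.nan,
        "umi_counts": umi, "umi_unified_rate": 0.0,
        "detected_genes": (counts > 0).sum(axis=0),
    })


# ---------------------------------------------------------------------------
# SAM → gene assignments
# ---------------------------------------------------------------------------

def parse_alignments(sam_path: str | Path, t2g: TranscriptGeneMap,
                     multimap_policy: str = "discard",
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Resolve SAM alignments against a transcript reference to gene loci.

    Returns ``(assignments, tallies)``.  ``assignments`` has one row per
    read that resolved to exactly one gene (columns: read_id, umi, gene_id,
    transcript_id, position, 1-based leftmost).  Reads hitting transcripts
    of more than one gene follow ``multimap_policy``:

    - ``discard`` (default): contribute to no gene, tallied as
      ``discarded_multigene`` — conservative, since probabilistic
      multi-mapping resolution is out of scope;
    - ``first``: the primary (or first-seen) alignment's gene wins;
    - ``all``: one assignment per distinct gene (inflates counts; for
      diagnostics only).

    Multiple transcripts of one gene collapse to a single assignment (the
    first-seen transcript/position is kept).  Unmapped records are tallied
    but yield nothing.
    """
    if multimap_policy not in ("discard", "first", "all"):
        raise ValueError(f"unknown multimap_policy {multimap_policy!r}")
    per_read: dict[str, dict[str, tuple[str, int]]] = {}
    first_gene: dict[str, tuple[str, str, int]] = {}
    umis: dict[str, str] = {}
    tallies = {"records": 0, "unmapped": 0, "mapped_reads": 0,
               "assigned_reads": 0, "discarded_multigene": 0}
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        for rec in sam:
            tallies["records"] += 1
            qname = rec.query_name
            if rec.is_unmapped:
                tallies["unmapped"] += 1
                continue
            tid = rec.reference_name
            if tid not in t2g:
                raise KeyError(f"reference {tid!r} absent from transcript-gene map")
            read_id, umi = extract_umi_from_name(qname)
            gid = t2g[tid]
            genes = per_read.setdefault(qname, {})
            if gid not in genes:
                genes[gid] = (tid, rec.reference_start + 1)
            if qname not in first_gene and not rec.is_secondary:
                first_gene[qname] = (gid, tid, rec.reference_start + 1)
            umis[qname] = umi
    rows = []
    for qname, genes in per_read.items():
        read_id, _ = extract_umi_from_name(qname)
        umi = umis[qname]
        if len(genes) == 1:
            gid, (tid, pos) = next(iter(genes.items()))
            rows.append((read_id, umi, gid, tid, pos))
            tallies["assigned_reads"] += 1
        elif multimap_policy == "discard":
            tallies["discarded_multigene"] += 1
        elif multimap_policy == "first":
            gid, tid, pos = first_gene.get(qname) or (None, None, None)
            if gid is None:  # only secondary records seen; fall back to any
                gid, (tid, pos) = next(iter(genes.items()))
            rows.append((read_id, umi, gid, tid, pos))
            tallies["assigned_reads"] += 1
        else:  # all
            for gid, (tid, pos) in genes.items():
                rows.append((read_id, umi, gid, tid, pos))
            tallies["assigned_reads"] += 1
    tallies["mapped_reads"] = len(per_read)
    assignments = pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)
    return assignments, tallies


# ---------------------------------------------------------------------------
# UMI unification
# ---------------------------------------------------------------------------

def unify_umis(assignments: pd.DataFrame, seed: int = 0,
               ) -> tuple[pd.Series, pd.DataFrame]:
    """Collapse one sample's gene assignments into per-gene UMI counts.

    ``count(gene)`` is the number of distinct UMIs observed on that gene.
    One representative read per (gene, UMI) group is selected uniformly at
    random with the given seed — mirroring "pick one read per duplicate
    group" — but the choice never affects the counts.  UMIs containing N
    are discarded (they cannot be grouped unambiguously).

    Returns ``(counts, representatives)`` where ``counts`` is a gene→int
    Series and ``representatives`` has one row per (gene, UMI) group.
    """
    if assignments.empty:
        return (pd.Series(dtype=int),
                pd.DataFrame(columns=ASSIGNMENT_COLUMNS))
    clean = assignments[~assignments["umi"].str.contains("N", regex=False)]
    if clean.empty:
        return (pd.Series(dtype=int),
                pd.DataFrame(columns=ASSIGNMENT_COLUMNS))
    rng = np.random.default_rng(seed)
    # shuffle once, then take the first row of each (gene, umi) group:
    # a uniform random representative independent of input order
    perm = rng.permutation(len(clean))
    shuffled = clean.iloc[perm]
    representatives = shuffled.drop_duplicates(subset=["gene_id", "umi"])
    counts = representatives.groupby("gene_id").size().sort_index()
    counts.name = "umi_count"
    return counts, representatives.reset_index(drop=True)


def build_matrix(per_sample: Mapping[str, tuple[pd.Series, dict[str, int]]],
                 gene_universe: Iterable[str]) -> UMICountMatrix:
    """Assemble per-sample unified counts into a genes × samples matrix.

    ``per_sample`` maps sample id → (unified counts, tallies dict with
    ``total_reads`` and ``mapped_reads``).  Missing (gene, sample) cells
    are 0.
    """
    genes = sorted(gene_universe)
    samples = list(per_sample)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    counts = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    stats_rows = []
    for sample, (unified, tallies) in per_sample.items():
        unknown = set(unified.index) - set(genes)
        if unknown:
            raise ValueError(f"counts for genes outside the universe: {sorted(unknown)[:5]}")
        counts.loc[unified.index, sample] = unified.astype(int)
        mapped = int(tallies.get("mapped_reads", 0))
        total = int(tallies.get("total_reads", tallies.get("records", mapped)))
        umi_total = int(unified.sum())
        stats_rows.append({
            "sample_id": sample,
            "total_reads": total,
            "mapped_reads": mapped,
            "mapping_rate": mapped / total if total else 0.0,
            "umi_counts": umi_total,
            "umi_unified_rate": (mapped - umi_total) / mapped if mapped else 0.0,
            "detected_genes": int((counts[sample] > 0).sum()),
        })
    stats = pd.DataFrame(stats_rows).set_index("sample_id")
    return UMICountMatrix(counts=counts, stats=stats)


# ---------------------------------------------------------------------------
# Toy aligner (test-scale exact k-mer seed aligner)
# ---------------------------------------------------------------------------

def _read_fasta(path: str | Path) -> list[tuple[str, str]]:
    from Bio import SeqIO
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def toy_align(reads: Iterable[tuple[str, str, str]] | str | Path,
              reference_fasta: str | Path, out_sam: str | Path,
              k: int = 31) -> dict[str, int]:
    """Exact first-k-mer seed aligner producing valid SAM.

    A read aligns to every transcript that contains its first ``k``-mer
    exactly, at the leftmost occurrence; otherwise it is reported unmapped.
    Additional hits beyond the first are written as secondary records.
    This is a deterministic small-scale aligner for simulated data, not a
    general-purpose mapper.

    ``reads`` is either a FASTQ path or an iterable of (title, seq, qual).
    Returns a tally dict (reads, mapped, unmapped).
    """
    from .readproc import read_fastq
    transcripts = _read_fasta(reference_fasta)
    if len({tid for tid, _ in transcripts}) != len(transcripts):
        raise ValueError("duplicate transcript ids in reference")
    index: dict[str, list[tuple[int, int]]] = {}
    lengths = []
    for ti, (tid, seq) in enumerate(transcripts):
        lengths.append(len(seq))
        seen: set[str] = set()
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            if kmer in seen:
                continue  # leftmost occurrence per transcript only
            seen.add(kmer)
            index.setdefault(kmer, []).append((ti, pos))
    if isinstance(reads, (str, Path)):
        reads = read_fastq(reads)
    tally = {"reads": 0, "mapped": 0, "unmapped": 0}
    with open(out_sam, "w") as out:
        out.write("@HD\tVN:1.6\tSO:unknown\n")
        for (tid, _), L in zip(transcripts, lengths):
            out.write(f"@SQ\tSN:{tid}\tLN:{L}\n")
        out.write("@PG\tID:toy_align\tPN:toy_align\n")
        for title, seq, qual in reads:
            tally["reads"] += 1
            qname = title.split()[0]
            hits = index.get(seq[:k]) if len(seq) >= k else None
            if not hits:
                tally["unmapped"] += 1
                out.write(f"{qname}\t4\t*\t0\t0\t*\t*\t0\t0\t{seq}\t{qual}\n")
                continue
            tally["mapped"] += 1
            for j, (ti, pos) in enumerate(hits):
                flag = 0 if j == 0 else 256
                ref_id, ref_len = transcripts[ti][0], lengths[ti]
                match = min(len(seq), ref_len - pos)
                cigar = f"{match}M" + (f"{len(seq) - match}S" if match < len(seq) else "")
                out.write(f"{qname}\t{flag}\t{ref_id}\t{pos + 1}\t255\t{cigar}"
                          f"\t*\t0\t0\t{seq}\t{qual}\n")
    return tally
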