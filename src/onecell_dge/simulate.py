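"""Synthetic read simulator with ground truth for the whole pipeline.

Generates a transcript reference, per-cell expression, captured molecules
carrying UMIs, PCR duplicate reads, sequencing errors, and ERCC-style
spike-ins, and writes the matching read1/index FASTQ pair plus truth
tables, so that demultiplexing, alignment, UMI counting, saturation, QC
and the statistics modules are all testable end-to-end with known truth.

Model
-----
* per-gene expression level ``λ_g ~ LogNormal(μ, σ)`` drawn once; per cell
  the true molecule count is Poisson(λ_g), of which
  ``Binomial(molecules, capture_rate)`` are captured into cDNA;
* every captured molecule receives a uniform random UMI (4^10 space) and
  emits ``Geometric(p_dup)`` reads on {1, 2, ...} (mean 1/p_dup), so
  p_dup = 1 means exactly one read per molecule and smaller p_dup means
  heavier PCR duplication;
* read1 is an 80-nt fragment at a uniform start within the transcript;
  the index read is 8 nt of sample index + 10 nt of UMI + 2 random tail
  bases (20 nt), with independent per-base substitution error rates for
  the read1, index and UMI segments;
* spike-in species follow a 2-fold concentration ladder and bypass the
  expression model (molecules ~ Poisson(concentration × spike_scale),
  thinned by the capture rate).

Defaults emulate a shallow single-cell tag-counting experiment: 10 cells,
200 genes, roughly 5000 captured molecules per cell, error-free reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .barcodes import IndexSet, design_indexes
from .readproc import write_fastq_record

__all__ = ["SimConfig", "Reference", "TruthTable", "make_reference",
           "simulate_cells", "ground_truth_compare"]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the package's study conditions."""

    n_genes: int = 200
    transcripts_per_gene: int = 1
    transcript_length: int = 500
    n_cells: int = 10
    expression_mu: float = np.log(25.0)  # per-gene LogNormal location
    expression_sigma: float = 1.0
    capture_rate: float = 0.6
    umi_length: int = 10
    index_length: int = 8
    p_dup: float = 0.3                  # Geometric read count, mean 1/p_dup
    read_length: int = 80
    error_rate_read1: float = 0.0
    error_rate_index: float = 0.0
    error_rate_umi: float = 0.0
    n_spikes: int = 8
    spike_base_conc: float = 1.0        # ladder: base × 2^k, k = 0..n_spikes-1
    spike_scale: float = 0.2            # molecules per unit concentration per cell
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("capture_rate", "p_dup", "error_rate_read1",
                     "error_rate_index", "error_rate_umi"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.p_dup == 0:
            raise ValueError("p_dup must be positive (mean reads per molecule 1/p_dup)")
        if self.transcript_length < self.read_length:
            raise ValueError("transcripts must be at least one read long")

    def to_flat_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for k, v in asdict(self).items():
                fh.write(f"{k}\t{v}\n")

    @classmethod
    def from_flat_file(cls, path: str | Path) -> "SimConfig":
        kw = {}
        fields = {f.name: f.type for f in cls.__dataclass_fields__.values()}  # noqa
        import dataclasses
        types = {f.name: f for f in dataclasses.fields(cls)}
        for line in open(path):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            k, v = line.split("\t")[:2]
            if k not in types:
                raise KeyError(f"unknown simulation parameter {k!r}")
            caster = int if types[k].type == "int" else float
            kw[k] = caster(float(v))
        return cls(**kw)


@dataclass
class Reference:
    """Simulated transcriptome: sequences, transcript→gene map, spike ladder."""

    transcripts: list[tuple[str, str]]           # (transcript_id, sequence)
    t2g: dict[str, str]
    spike_concs: dict[str, float]                # ERCC-style ids → concentration

    @property
    def genes(self) -> list[str]:
        return sorted(set(self.t2g.values()))

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {"fasta": out / "reference.fasta", "t2g": out / "t2g.tsv",
                 "spikes": out / "spikes.tsv"}
        with open(paths["fasta"], "w") as fh:
            for tid, seq in self.transcripts:
                fh.write(f">{tid}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
        with open(paths["t2g"], "w") as fh:
            for tid in sorted(self.t2g):
                fh.write(f"{tid}\t{self.t2g[tid]}\n")
        with open(paths["spikes"], "w") as fh:
            for sid in sorted(self.spike_concs):
                fh.write(f"{sid}\t{self.spike_concs[sid]}\n")
        return paths


@dataclass
class TruthTable:
    """Ground truth of one simulation run.

    ``per_cell_gene`` rows: cell, gene, true_molecules, captured_molecules,
    distinct_umi_pairs (distinct (gene, UMI) pairs after collisions — the
    quantity UMI counting should recover exactly in the error-free regime).
    ``per_read`` rows: read_id, cell, gene, molecule_id.
    """

    per_cell_gene: pd.DataFrame
    per_read: pd.DataFrame
    index_set: IndexSet = field(repr=False, default=None)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.per_cell_gene.to_csv(out / "truth_cells.tsv", sep="\t", index=False)
        self.per_read.to_csv(out / "truth_reads.tsv", sep="\t", index=False)

    def distinct_pairs_matrix(self) -> pd.DataFrame:
        """Genes × cells table of true distinct (gene, UMI) pair counts."""
        return (self.per_cell_gene
                .pivot_table(index="gene", columns="cell",
                             values="distinct_umi_pairs", fill_value=0,
                             aggfunc="sum")
                .astype(int))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def make_reference(config: SimConfig, seed: int | None = None) -> Reference:
    """Deterministically generate transcripts, the gene map, and spike ladder."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    transcripts = []
    t2g = {}
    width = len(str(config.n_genes * config.transcripts_per_gene))
    gwidth = len(str(config.n_genes))
    k = 0
    for g in range(config.n_genes):
        gid = f"gene{g + 1:0{gwidth}d}"
        for _ in range(config.transcripts_per_gene):
            k += 1
            tid = f"tx{k:0{width}d}"
            transcripts.append((tid, _random_dna(rng, config.transcript_length)))
            t2g[tid] = gid
    spikes = {}
    for s in range(config.n_spikes):
        sid = f"ERCC-{s + 1:04d}"
        spikes[sid] = config.spike_base_conc * 2.0 ** s
        transcripts.append((sid, _random_dna(rng, config.transcript_length)))
        t2g[sid] = sid  # spike species are their own gene locus
    return Reference(transcripts=transcripts, t2g=t2g, spike_concs=spikes)


def simulate_cells(config: SimConfig, reference: Reference,
                   out_dir: str | Path,
                   index_set: IndexSet | None = None,
                   seed: int | None = None) -> tuple[dict[str, Path], TruthTable]:
    """Simulate reads for every cell and write the paired FASTQ plus truth.

    Returns ``(paths, truth)`` with ``paths`` holding ``read1`` and
    ``index`` FASTQ files.  Cells are named ``cell01 …`` and assigned the
    first ``n_cells`` indexes of ``index_set`` (a fresh error-correcting
    design by default).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if index_set is None:
        index_set = design_indexes(cfg.n_cells, length=cfg.index_length,
                                   sample_prefix="cell")
    if len(index_set) < cfg.n_cells:
        raise ValueError("index set smaller than the number of cells")
    cells = index_set.sample_ids[:cfg.n_cells]
    cell_index = dict(index_set.entries[:cfg.n_cells])

    tx_by_gene: dict[str, list[tuple[str, str]]] = {}
    for tid, seq in reference.transcripts:
        tx_by_gene.setdefault(reference.t2g[tid], []).append((tid, seq))
    genes = [g for g in reference.genes if not g.startswith("ERCC-")]
    spike_ids = sorted(reference.spike_concs)

    lam = np.exp(rng.normal(cfg.expression_mu, cfg.expression_sigma,
                            size=len(genes)))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"read1": out / "read1.fastq", "index": out / "index.fastq"}
    truth_cells = []
    truth_reads = []
    read_no = 0
    mol_no = 0
    q1 = "I" * cfg.read_length
    qx = "I" * 20
    with open(paths["read1"], "w") as f1, open(paths["index"], "w") as fx:
        for cell in cells:
            idx_seq = cell_index[cell]
            true_mols = rng.poisson(lam)
            spike_mols = rng.poisson(np.array([reference.spike_concs[s]
                                               for s in spike_ids])
                                     * cfg.spike_scale)
            for gene, n_true, is_spike in (
                    [(g, int(m), False) for g, m in zip(genes, true_mols)]
                    + [(s, int(m), True) for s, m in zip(spike_ids, spike_mols)]):
                captured = (int(rng.binomial(n_true, cfg.capture_rate))
                            if n_true else 0)
                umis = ["".join(_BASES[rng.integers(0, 4, cfg.umi_length)])
                        for _ in range(captured)]
                for umi in umis:
                    mol_no += 1
                    tid, seq = tx_by_gene[gene][rng.integers(0, len(tx_by_gene[gene]))]
                    n_reads = int(rng.geometric(cfg.p_dup))
                    for _ in range(n_reads):
                        read_no += 1
                        rid = f"r{read_no:08d}"
                        start = int(rng.integers(0, len(seq) - cfg.read_length + 1))
                        r1 = _substitute(rng, seq[start:start + cfg.read_length],
                                         cfg.error_rate_read1)
                        ix = (_substitute(rng, idx_seq, cfg.error_rate_index)
                              + _substitute(rng, umi, cfg.error_rate_umi)
                              + _random_dna(rng, 2))
                        write_fastq_record(f1, rid, r1, q1)
                        write_fastq_record(fx, rid, ix, qx)
                        truth_reads.append((rid, cell, gene, mol_no))
                truth_cells.append({
                    "cell": cell, "gene": gene,
                    "true_molecules": n_true,
                    "captured_molecules": captured,
                    "distinct_umi_pairs": len(set(umis)),
                    "is_spike": is_spike,
                })
    truth = TruthTable(
        per_cell_gene=pd.DataFrame(truth_cells),
        per_read=pd.DataFrame(truth_reads,
                              columns=["read_id", "cell", "gene", "molecule_id"]),
        index_set=index_set,
    )
    return paths, truth


def ground_truth_compare(matrix, truth: TruthTable) -> pd.DataFrame:
    """Per-cell recovery of the truth's distinct (gene, UMI) pair counts.

    Returns per cell: ``exact_match_fraction`` (genes whose UMI count equals
    the truth exactly) and ``max_abs_deviation``.  In the error-free regime
    the deviation is required to be zero everywhere.
    """
    counts = matrix.counts if hasattr(matrix, "counts") else matrix
    want = truth.distinct_pairs_matrix()
    missing = set(want.columns) - set(counts.columns)
    if missing:
        raise ValueError(f"cells missing from the matrix: {sorted(missing)}")
    rows = []
    for cell in want.columns:
        obs = counts[cell].reindex(want.index).fillna(0).astype(int)
        diff = (obs - want[cell]).abs()
        rows.append({"cell": cell,
                     "exact_match_fraction": float((diff == 0).mean()),
                     "max_abs_deviation": int(diff.max())})
    return pd.DataFrame(rows).set_index("cell")
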