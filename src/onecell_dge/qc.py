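"""Per-sample quality control: screening, replicate concordance, spike-ins.

The screen follows the configuration of SinQC-style single-cell QC —
maximum false-positive rate, TPM expression cutoff, and Spearman/Pearson
test p-value thresholds — with an explicitly simplified, documented rule
(the original program's internal algorithm is not reimplemented): a sample
fails when even its most-correlated partner shows no significant rank or
linear correlation, with the number of failures capped so the expected
false-positive rate under an exchangeable null stays at or below
``max_fpr``.  All correlations and fits use log2(x + 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "QCConfig",
    "SpikeInTable",
    "tpm",
    "qc_screen",
    "replicate_concordance",
    "spikein_linearity",
]

DEFAULT_GENE_LENGTH = 1000.0  # 3'-anchored tag counts are only weakly length-dependent


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the QC screen (defaults mirror the standard settings)."""

    max_fpr: float = 0.05
    tpm_cutoff: float = 1.0
    spearman_p: float = 0.001
    pearson_p: float = 0.001

    def __post_init__(self) -> None:
        for name in ("max_fpr", "spearman_p", "pearson_p"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.tpm_cutoff < 0:
            raise ValueError("tpm_cutoff must be >= 0")


@dataclass
class SpikeInTable:
    """Spike species → nominal concentration (any consistent unit), > 0."""

    concentrations: dict[str, float]
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.concentrations:
            raise ValueError("empty spike-in table")
        if any(c <= 0 for c in self.concentrations.values()):
            raise ValueError("spike concentrations must be positive")
        if self.dilution_factor <= 0:
            raise ValueError("dilution factor must be positive")

    @property
    def effective(self) -> pd.Series:
        s = pd.Series(self.concentrations, dtype=float) / self.dilution_factor
        s.index.name = "spike_id"
        return s

    @classmethod
    def from_tsv(cls, path, dilution_factor: float = 1.0) -> "SpikeInTable":
        conc: dict[str, float] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                sid, c = line.split("\t")[:2]
                conc[sid] = float(c)
        return cls(conc, dilution_factor)


# ---------------------------------------------------------------------------
# TPM
# ---------------------------------------------------------------------------

def tpm(counts: pd.DataFrame,
        lengths: Mapping[str, float] | pd.Series | None = None,
        default_length: float = DEFAULT_GENE_LENGTH) -> pd.DataFrame:
    """Transcripts-per-million from a genes × samples count table.

    Per sample: ``rate_g = count_g / length_g``; ``TPM_g = 1e6 rate_g / Σ rate``.
    Genes without a length annotation get ``default_length`` (tag counts are
    3'-anchored, so length normalisation is a mild correction here).
    Columns sum to 1e6 except for all-zero samples, which stay zero.
    """
    if lengths is None:
        lens = pd.Series(default_length, index=counts.index, dtype=float)
    else:
        lens = pd.Series(lengths, dtype=float).reindex(counts.index)
        lens = lens.fillna(default_length)
    bad = lens[(lens <= 0) & (counts.sum(axis=1) > 0)]
    if len(bad):
        raise ValueError(f"non-positive length for expressed genes: {list(bad.index)[:5]}")
    rate = counts.div(lens, axis=0)
    total = rate.sum(axis=0)
    out = rate.div(total.replace(0, np.nan), axis=1) * 1e6
    return out.fillna(0.0)


# ---------------------------------------------------------------------------
# QC screen
# ---------------------------------------------------------------------------

def _pairwise_best(log_expr: pd.DataFrame) -> pd.DataFrame:
    """Best-partner Spearman and Pearson statistics per sample.

    Correlations are computed on all genes over the full table (genes never
    expressed anywhere are dropped); ranks once, then a correlation matrix,
    so the scan is O(samples² · genes) in vectorised form.
    """
    expressed = log_expr.loc[log_expr.sum(axis=1) > 0]
    X = expressed.values
    n_genes, n_samples = X.shape
    with np.errstate(invalid="ignore"):
        pear = np.corrcoef(X.T)
        ranks = sps.rankdata(X, axis=0)
        spear = np.corrcoef(ranks.T)
    np.fill_diagonal(pear, -np.inf)
    np.fill_diagonal(spear, -np.inf)

    def t_pvalue(r: float, n: int) -> float:
        r = min(max(r, -1.0), 1.0)
        if n < 3 or abs(r) == 1.0:
            return 0.0 if abs(r) == 1.0 else 1.0
        t = r * np.sqrt((n - 2) / (1 - r * r))
        return 2 * sps.t.sf(abs(t), n - 2)

    rows = []
    for i, sample in enumerate(log_expr.columns):
        j_s = int(np.argmax(spear[i]))
        j_p = int(np.argmax(pear[i]))
        rho, r = spear[i, j_s], pear[i, j_p]
        rows.append({
            "sample_id": sample,
            "best_spearman_partner": log_expr.columns[j_s],
            "best_spearman_rho": rho,
            "spearman_p": t_pvalue(rho, n_genes),
            "best_pearson_partner": log_expr.columns[j_p],
            "best_pearson_r": r,
            "pearson_p": t_pvalue(r, n_genes),
        })
    return pd.DataFrame(rows).set_index("sample_id")


def qc_screen(matrix, config: QCConfig | None = None,
              lengths: Mapping[str, float] | None = None) -> pd.DataFrame:
    """Screen samples for failure, SinQC-configuration style (simplified rule).

    ``matrix`` is a :class:`~onecell_dge.counting.UMICountMatrix` or a plain
    genes × samples count DataFrame.  Per sample the table reports detected
    genes at TPM ≥ cutoff, mapping rate (NaN when unknown), best-partner
    Spearman/Pearson statistics, a ``low_complexity`` warning flag (detected
    genes in the lower ``max_fpr`` tail), and ``status`` PASS/FAIL.

    Failure rule: a sample is a candidate when BOTH best-partner correlation
    tests are non-significant at the configured thresholds; at most
    ``floor(max_fpr · n)`` candidates fail, worst best-partner ρ first — the
    cap bounds the expected false-positive rate under a rank-exchangeable
    null.  Technical metrics warn but never fail a sample on their own.
    """
    config = config or QCConfig()
    counts = matrix.counts if hasattr(matrix, "counts") else matrix
    stats = matrix.stats if hasattr(matrix, "stats") else None
    n = counts.shape[1]
    if n < 3:
        raise ValueError("QC screen needs at least 3 samples")

    expr = tpm(counts, lengths)
    log_expr = np.log2(expr + 1.0)
    best = _pairwise_best(log_expr)

    out = best.copy()
    out.insert(0, "detected_genes",
               (expr >= config.tpm_cutoff).sum(axis=0).astype(int))
    out.insert(1, "mapping_rate",
               stats["mapping_rate"].reindex(out.index) if stats is not None else np.nan)

    k_tail = max(1, int(np.floor(config.max_fpr * n)))
    tail_rank = out["detected_genes"].rank(method="min")
    out["low_complexity"] = tail_rank <= k_tail

    candidate = ((out["spearman_p"] >= config.spearman_p)
                 & (out["pearson_p"] >= config.pearson_p))
    max_fail = int(np.floor(config.max_fpr * n))
    fail = pd.Series(False, index=out.index)
    if candidate.any() and max_fail > 0:
        worst = (out.loc[candidate, "best_spearman_rho"]
                 .sort_values().index[:max_fail])
        fail.loc[worst] = True
    out["status"] = np.where(fail, "FAIL", "PASS")
    out.attrs["config"] = {
        "MAX FPR": config.max_fpr, "TPM Cutoff": config.tpm_cutoff,
        "Spearman's test P-value": f"<{config.spearman_p}",
        "Pearson's test P-value": f"<{config.pearson_p}",
    }
    return out


# ---------------------------------------------------------------------------
# Replicate concordance and spike-in linearity
# ---------------------------------------------------------------------------

def replicate_concordance(counts_a: pd.Series, counts_b: pd.Series) -> float:
    """R² between two replicate count vectors on log2(count + 1).

    Ordinary least squares of b on a over genes detected in either
    replicate.  Scaling one replicate by a constant leaves R² at 1 (affine
    in log space).
    """
    a, b = counts_a.align(counts_b, join="inner")
    detected = (a > 0) | (b > 0)
    if detected.sum() < 3:
        raise ValueError("fewer than 3 genes detected in either replicate")
    x = np.log2(a[detected].astype(float) + 1)
    y = np.log2(b[detected].astype(float) + 1)
    fit = sps.linregress(x, y)
    return float(fit.rvalue ** 2)


def spikein_linearity(matrix, spikes: SpikeInTable,
                      spike_prefix: str = "ERCC-") -> pd.DataFrame:
    """Per-sample dose-response fit of UMI counts against spike concentrations.

    Least squares of log2(UMI + 1) on log2(nominal concentration) over the
    spike rows (``ERCC-*`` naming auto-detected, restricted to species in
    the table).  Drop-out spikes (count 0) are retained as pseudocount
    points in the primary fit; the ``*_excl`` columns report the variant
    with zero-count species excluded.  Counts proportional to concentration
    give slope 1 and R² = 1; global library-size scaling moves only the
    intercept.
    """
    counts = matrix.counts if hasattr(matrix, "counts") else matrix
    conc = spikes.effective
    spike_rows = [g for g in counts.index if g.startswith(spike_prefix) and g in conc.index]
    if not spike_rows:
        raise ValueError("no spike rows present in the matrix")
    sub = counts.loc[spike_rows].astype(float)
    if (sub.sum(axis=1) > 0).sum() == 0:
        raise ValueError("no spike detected")
    x_all = np.log2(conc[spike_rows].values)
    rows = []
    for sample in sub.columns:
        y = np.log2(sub[sample].values + 1.0)
        detected = sub[sample].values > 0
        if detected.sum() < 3:
            raise ValueError(
                f"fewer than 3 spike species detected in sample {sample!r}")
        fit = sps.linregress(x_all, y)
        fit_x = sps.linregress(x_all[detected], y[detected])
        rows.append({
            "sample_id": sample,
            "slope": fit.slope, "intercept": fit.intercept,
            "r2": fit.rvalue ** 2, "n_spikes": len(spike_rows),
            "slope_excl": fit_x.slope, "intercept_excl": fit_x.intercept,
            "r2_excl": fit_x.rvalue ** 2, "n_detected": int(detected.sum()),
        })
    return pd.DataFrame(rows).set_index("sample_id")
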