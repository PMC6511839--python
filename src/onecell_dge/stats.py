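"""Downstream statistics on UMI count matrices.

Implements the normalisation and testing chain used for two-group
differential expression on tag counts:

* TMM (trimmed mean of M-values) scaling factors;
* the iDEGES loop — iteratively exclude putative DEGs and renormalise, so
  that asymmetric differential expression does not bias the factors;
* a two-group exact test under a negative binomial model with a common
  dispersion, conditioning on each gene's total count;
* Benjamini–Hochberg q-values and DEG calling/ranking;
* Hoeffding's D independence statistic (×30 scaling, population maximum 1)
  with permutation or asymptotic p-values;
* Spearman/Pearson correlation tests.

The exact test deliberately uses a user-supplied common dispersion rather
than tagwise/trended empirical-Bayes estimation; with dispersion 0 it
degenerates to the conditional binomial (Poisson) split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NormalizationResult",
    "DEResult",
    "DependenceTestResult",
    "tmm_factors",
    "nb_exact_test",
    "bh_fdr",
    "ideges_normalize",
    "call_degs",
    "hoeffding_d",
    "correlation_tests",
]

DEFAULT_DISPERSION = 0.1


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def _tmm_pair(obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
              logratio_trim: float, sum_trim: float, min_count: int) -> float:
    keep = (obs >= min_count) & (ref >= min_count)
    o, r = obs[keep].astype(float), ref[keep].astype(float)
    if o.size == 0:
        return 1.0
    po, pr = o / lib_obs, r / lib_ref
    M = np.log2(po / pr)
    A = 0.5 * np.log2(po * pr)
    w = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = M.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    rank_m = sps.rankdata(M)
    rank_a = sps.rankdata(A)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not sel.any() or w[sel].sum() == 0:
        return 1.0
    f = np.sum(M[sel] / w[sel]) / np.sum(1.0 / w[sel])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: pd.DataFrame, ref_sample: str = "auto",
                logratio_trim: float = 0.3, sum_trim: float = 0.05,
                min_count: int = 1) -> pd.Series:
    """Trimmed-mean-of-M scaling factors, rescaled to geometric mean 1.

    For each sample against the reference, M (log ratio of library-size-
    normalised counts) and A (mean log abundance) are computed over genes
    with at least ``min_count`` in both columns; M values are trimmed by
    ``logratio_trim`` per tail and A values by ``sum_trim`` per tail; the
    factor is 2 to the inverse-asymptotic-variance-weighted mean of the
    surviving M values.  ``ref_sample="auto"`` picks the sample whose
    75th count percentile (as a fraction of library size) is closest to the
    mean across samples.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero samples: {bad}")
    if ref_sample == "auto":
        uq = counts.apply(lambda c: np.percentile(c[c > 0], 75) if (c > 0).any() else 0.0)
        uq = uq / lib
        ref_sample = (uq - uq.mean()).abs().idxmin()
    elif ref_sample not in counts.columns:
        raise KeyError(f"reference sample {ref_sample!r} not in matrix")
    ref = counts[ref_sample].values
    factors = {}
    for s in counts.columns:
        if s == ref_sample:
            factors[s] = 1.0
        else:
            factors[s] = _tmm_pair(counts[s].values, ref, lib[s], lib[ref_sample],
                                   logratio_trim, sum_trim, min_count)
    f = pd.Series(factors)[counts.columns]
    f /= np.exp(np.mean(np.log(f)))
    f.name = "tmm_factor"
    return f


# ---------------------------------------------------------------------------
# Exact NB test
# ---------------------------------------------------------------------------

def _exact_p_one(sum_a: int, sum_b: int, n_a: int, n_b: int,
                 dispersion: float) -> float:
    s = sum_a + sum_b
    if s == 0:
        return 1.0
    k = np.arange(s + 1)
    if dispersion == 0:
        logp = sps.binom.logpmf(k, s, n_a / (n_a + n_b))
    else:
        r_a, r_b = n_a / dispersion, n_b / dispersion
        logp = (gammaln(k + r_a) - gammaln(k + 1)
                + gammaln(s - k + r_b) - gammaln(s - k + 1))
        logp -= logp.max()
        logp -= np.log(np.exp(logp).sum())
    p_obs = logp[sum_a]
    # two-sided by minimum likelihood: include all outcomes no more probable
    # than the observed one (tie mass included, with a tolerance for rounding)
    mask = logp <= p_obs + 1e-10
    return float(min(1.0, np.exp(logp[mask]).sum() / np.exp(logp).sum()))


def nb_exact_test(counts_a: pd.DataFrame | np.ndarray,
                  counts_b: pd.DataFrame | np.ndarray,
                  dispersion: float = DEFAULT_DISPERSION,
                  lib_sizes_a: np.ndarray | None = None,
                  lib_sizes_b: np.ndarray | None = None) -> np.ndarray:
    """Two-group exact test p-values under NB with a common dispersion.

    Per gene, counts are moment-match scaled to a common effective library
    size (the geometric mean over all samples) and rounded; the test then
    conditions on the gene's total pseudo-count and sums the probability of
    every split no more likely than the observed one (minimum-likelihood
    two-sided).  ``dispersion = 0`` gives the conditional binomial split.

    ``counts_*`` are genes × samples; returns one p-value per gene.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    A = np.asarray(counts_a, dtype=float)
    B = np.asarray(counts_b, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise ValueError("gene universes differ between groups")
    n_a, n_b = A.shape[1], B.shape[1]
    if lib_sizes_a is None:
        lib_sizes_a = A.sum(axis=0)
    if lib_sizes_b is None:
        lib_sizes_b = B.sum(axis=0)
    libs = np.concatenate([np.asarray(lib_sizes_a, float),
                           np.asarray(lib_sizes_b, float)])
    if (libs <= 0).any():
        raise ValueError("non-positive effective library size")
    common = np.exp(np.mean(np.log(libs)))
    Ap = np.rint(A * (common / libs[:n_a])).astype(np.int64)
    Bp = np.rint(B * (common / libs[n_a:])).astype(np.int64)
    sum_a = Ap.sum(axis=1)
    sum_b = Bp.sum(axis=1)
    return np.array([_exact_p_one(int(a), int(b), n_a, n_b, dispersion)
                     for a, b in zip(sum_a, sum_b)])


def bh_fdr(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# iDEGES
# ---------------------------------------------------------------------------

@dataclass
class NormalizationResult:
    """Final per-sample scaling factors and the iDEGES exclusion history."""

    factors: pd.Series
    iterations: int
    excluded: list[pd.Index] = field(default_factory=list)
    floor_pdeg: float = 0.05
    fdr_inner: float = 0.1

    def effective_lib_sizes(self, counts: pd.DataFrame) -> pd.Series:
        return counts.sum(axis=0) * self.factors


def _subset_factors(counts: pd.DataFrame, keep: pd.Index | np.ndarray,
                    **tmm_kw) -> pd.Series:
    """TMM on a gene subset, expressed against full library sizes."""
    sub = counts.loc[keep]
    f_sub = tmm_factors(sub, **tmm_kw)
    eff = f_sub * sub.sum(axis=0) / counts.sum(axis=0)
    eff /= np.exp(np.mean(np.log(eff)))
    return eff


def ideges_normalize(counts: pd.DataFrame, groups: pd.Series | dict,
                     iterations: int = 3, fdr_inner: float = 0.1,
                     floor_pdeg: float = 0.05,
                     dispersion: float = DEFAULT_DISPERSION) -> NormalizationResult:
    """Iterative DEG-exclusion normalisation (TMM → test → exclude → TMM).

    Each of ``iterations`` passes: (1) scaling factors on the current gene
    set; (2) exact test of all genes with those factors; (3) mark putative
    DEGs at q < ``fdr_inner`` — but if fewer than ``floor_pdeg`` of genes
    qualify, mark the top ``floor_pdeg`` fraction by p-value instead;
    (4) recompute factors on the complement.  With ``iterations = 0`` the
    result is plain TMM.
    """
    groups = pd.Series(groups)
    labels = groups.unique()
    if len(labels) != 2:
        raise ValueError("iDEGES requires exactly two groups")
    cols_a = groups.index[groups == labels[0]]
    cols_b = groups.index[groups == labels[1]]
    factors = tmm_factors(counts)
    excluded: list[pd.Index] = []
    testable = counts.index[counts.sum(axis=1) > 0]
    for _ in range(iterations):
        lib = counts.sum(axis=0) * factors
        p = nb_exact_test(counts.loc[testable, cols_a], counts.loc[testable, cols_b],
                          dispersion=dispersion,
                          lib_sizes_a=lib[cols_a].values,
                          lib_sizes_b=lib[cols_b].values)
        q = bh_fdr(p)
        deg_mask = q < fdr_inner
        floor_n = int(np.ceil(floor_pdeg * len(testable)))
        if deg_mask.sum() < floor_n:
            order = np.argsort(p, kind="stable")[:floor_n]
            deg_mask = np.zeros(len(testable), dtype=bool)
            deg_mask[order] = True
        deg = testable[deg_mask]
        keep = counts.index.difference(deg)
        factors = _subset_factors(counts, keep)
        excluded.append(deg)
    return NormalizationResult(factors=factors, iterations=iterations,
                               excluded=excluded, floor_pdeg=floor_pdeg,
                               fdr_inner=fdr_inner)


# ---------------------------------------------------------------------------
# DEG calling
# ---------------------------------------------------------------------------

@dataclass
class DEResult:
    """Per-gene differential expression table and group-direction tallies."""

    table: pd.DataFrame
    fdr: float
    n_total: int
    n_up: dict[str, int]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


def call_degs(counts: pd.DataFrame, groups: pd.Series | dict,
              norm: NormalizationResult | None = None, fdr: float = 0.01,
              dispersion: float = DEFAULT_DISPERSION,
              prior: float = 0.5) -> DEResult:
    """Call differentially expressed genes at q < ``fdr``.

    Tests every gene with the normalised effective library sizes, adjusts
    p-values by Benjamini–Hochberg, and reports per gene the m-value
    (log2 fold change of normalised abundance, second group over first),
    a-value (mean log2 abundance), p, q, and a significance rank ordered by
    (q, p, −|m|, gene id).  All-zero genes are reported NA and never
    tested.  Direction tallies count significant genes by the sign of m.
    """
    groups = pd.Series(groups)
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise ValueError("two groups required")
    if norm is None:
        norm = NormalizationResult(factors=tmm_factors(counts), iterations=0)
    cols_a = groups.index[groups == labels[0]]
    cols_b = groups.index[groups == labels[1]]
    lib = norm.effective_lib_sizes(counts)
    testable = counts.index[counts.sum(axis=1) > 0]
    p = nb_exact_test(counts.loc[testable, cols_a], counts.loc[testable, cols_b],
                      dispersion=dispersion,
                      lib_sizes_a=lib[cols_a].values, lib_sizes_b=lib[cols_b].values)
    q = bh_fdr(p)
    cpm = counts.div(lib / 1e6, axis=1)
    mu_a = cpm.loc[testable, cols_a].mean(axis=1) + prior
    mu_b = cpm.loc[testable, cols_b].mean(axis=1) + prior
    m = np.log2(mu_b / mu_a)
    a = 0.5 * np.log2(mu_b * mu_a)
    table = pd.DataFrame(index=counts.index, columns=["m_value", "a_value",
                                                      "p_value", "q_value"],
                         dtype=float)
    table.loc[testable, "m_value"] = m
    table.loc[testable, "a_value"] = a
    table.loc[testable, "p_value"] = p
    table.loc[testable, "q_value"] = q
    order = table.loc[testable].copy()
    order["absm"] = -order["m_value"].abs()
    order = order.sort_values(["q_value", "p_value", "absm"],
                              kind="stable").index
    # stable sort on gene-id-presorted rows makes remaining ties deterministic
    rank = pd.Series(np.nan, index=counts.index)
    rank.loc[order] = np.arange(1, len(order) + 1)
    table["rank"] = rank
    sig = table.loc[testable][table.loc[testable, "q_value"] < fdr]
    n_up = {
        str(labels[1]): int((sig["m_value"] > 0).sum()),
        str(labels[0]): int((sig["m_value"] < 0).sum()),
    }
    return DEResult(table=table, fdr=fdr, n_total=len(sig), n_up=n_up)


# ---------------------------------------------------------------------------
# Hoeffding's D
# ---------------------------------------------------------------------------

@dataclass
class DependenceTestResult:
    D: float
    p_value: float
    n: int
    method: str


def _comparison_matrices(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    less = (v[None, :] < v[:, None]).astype(float)
    equal = (v[None, :] == v[:, None]).astype(float)
    np.fill_diagonal(equal, 0.0)
    return less, equal


def _hoeffding_from_matrices(xl, xe, yl, ye, R, S, n) -> float:
    # bivariate rank with tie weights: strictly-below pairs count 1,
    # one-coordinate ties 1/2, both-coordinate ties 1/4
    Q = 1.0 + (xl * yl + 0.5 * (xe * yl + xl * ye) + 0.25 * (xe * ye)).sum(axis=1)
    D1 = np.sum((Q - 1) * (Q - 2))
    D2 = np.sum((R - 1) * (R - 2) * (S - 1) * (S - 2))
    D3 = np.sum((R - 2) * (S - 2) * (Q - 1))
    denom = n * (n - 1) * (n - 2) * (n - 3) * (n - 4)
    return 30.0 * ((n - 2) * (n - 3) * D1 + D2 - 2 * (n - 2) * D3) / denom


def _bkr_asymptotic_p(nd30: float, jmax: int = 50) -> float:
    """Upper-tail probability of the limiting law of n·D/30 under independence.

    The limit is a centred weighted sum of chi-square(1) variables with
    weights 1/(π⁴ j² k²); the tail is evaluated by Gil-Pelaez inversion of
    the characteristic function.
    """
    j = np.arange(1, jmax + 1)
    lam = 1.0 / (np.pi ** 4 * np.outer(j ** 2, j ** 2)).ravel()

    def cf(t: np.ndarray) -> np.ndarray:
        t = np.atleast_1d(t)[:, None]
        return np.exp((-0.5 * np.log(1 - 2j * t * lam[None, :])
                       - 1j * t * lam[None, :]).sum(axis=1))

    from scipy.integrate import quad
    f = lambda t: np.imag(np.exp(-1j * t * nd30) * cf(t))[0] / t
    acc = 0.0
    for a, b in zip(np.linspace(1e-8, 2000, 81)[:-1], np.linspace(1e-8, 2000, 81)[1:]):
        val, _ = quad(f, a, b, limit=200)
        acc += val
    p = 0.5 + acc / np.pi
    return float(min(max(p, 0.0), 1.0))


def hoeffding_d(x, y, p_via: str = "permutation", n_perm: int = 10000,
                seed: int | None = None) -> DependenceTestResult:
    """Hoeffding's D statistic of independence with a p-value.

    D uses the classical rank formula
    ``D = 30 (A − 2(n−2)B + (n−2)(n−3)C) / (n(n−1)(n−2)(n−3)(n−4))``
    on midranks and tie-weighted bivariate ranks, scaled so the population
    maximum is 1 (range about [−0.5, 1]); the statistic is invariant under
    strictly monotone transforms of either margin.  The permutation
    p-value shuffles y (add-one estimator); the asymptotic p-value uses
    the large-sample null law of n·D/30.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y differ in length")
    if n < 5:
        raise ValueError("Hoeffding's D needs n >= 5")
    R = sps.rankdata(x)
    S = sps.rankdata(y)
    xl, xe = _comparison_matrices(x)
    yl, ye = _comparison_matrices(y)
    D = _hoeffding_from_matrices(xl, xe, yl, ye, R, S, n)
    if p_via == "permutation":
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Dp = _hoeffding_from_matrices(xl, xe, yl[np.ix_(perm, perm)],
                                          ye[np.ix_(perm, perm)], R, S[perm], n)
            if Dp >= D - 1e-12:
                exceed += 1
        p = (exceed + 1) / (n_perm + 1)
    elif p_via == "asymptotic":
        p = _bkr_asymptotic_p(n * D / 30.0)
    else:
        raise ValueError(f"unknown p_via {p_via!r}")
    return DependenceTestResult(D=float(D), p_value=float(p), n=n, method=p_via)


def correlation_tests(x, y) -> dict[str, float]:
    """Spearman ρ and Pearson r with p-values (midranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    rho, p_rho = sps.spearmanr(x, y)
    r, p_r = sps.pearsonr(x, y)
    return {"spearman_rho": float(rho), "spearman_p": float(p_rho),
            "pearson_r": float(r), "pearson_p": float(p_r)}
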