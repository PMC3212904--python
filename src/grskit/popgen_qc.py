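"""Genotype QC: Hardy-Weinberg equilibrium tests and pairwise LD via EM.

HWE is a 1-df Pearson chi-square of observed genotype counts against the
p^2 / 2pq / q^2 expectation, with the allele frequency estimated from the
same counts. Pairwise linkage disequilibrium between two unphased biallelic
SNPs is summarised by Lewontin's D' and r^2 after maximising the two-locus
haplotype-frequency likelihood with an EM algorithm: every genotype pair
except the double heterozygote determines its two haplotypes; the double
heterozygote's cis/trans phase is split each E-step in proportion to the
current haplotype-frequency estimates. Both statistics are conventionally
computed among controls (the QC stratum); pooled samples are an option.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_data import GenotypeMatrix, PhenotypeVector, split_by_status


@dataclass
class HWEResult:
    n_AA: int
    n_Aa: int
    n_aa: int
    chi2: float
    df: int
    p_value: float


@dataclass
class LDResult:
    snp_a: str
    snp_b: str
    D: float
    d_prime: float
    r2: float
    em_iterations: int
    loglik: float
    haplotype_freqs: np.ndarray = field(default=None, repr=False)  # (AB, Ab, aB, ab)
    loglik_trace: list = field(default_factory=list, repr=False)
    boundary: bool = False  # Dmax == 0: d_prime defined as 0


# ---------------------------------------------------------------------------
# Hardy-Weinberg equilibrium
# ---------------------------------------------------------------------------

def hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> HWEResult:
    """Pearson chi-square HWE test from genotype counts (1 df).

    ``n_AA`` counts homozygotes for the allele whose frequency is estimated
    as p-hat; the labels are symmetric. Monomorphic input returns chi2=0,
    p=1 (nothing to test).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return HWEResult(n_AA, n_Aa, n_aa, 0.0, 1, 1.0)
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return HWEResult(n_AA, n_Aa, n_aa, chi2, 1, float(stats.chi2.sf(chi2, 1)))


def hwe_table(gm: GenotypeMatrix, ph: PhenotypeVector | None = None,
              stratum: str = "control") -> pd.DataFrame:
    """Per-SNP HWE results, computed among controls by default."""
    sub = _stratum_matrix(gm, ph, stratum)
    rows = []
    for snp in sub.snp_ids:
        dos, miss = sub.column(snp)
        d = dos[~miss]
        res = hwe_chi2(int((d == 2).sum()), int((d == 1).sum()),
                       int((d == 0).sum()))
        rows.append({"snp_id": snp, "n_AA": res.n_AA, "n_Aa": res.n_Aa,
                     "n_aa": res.n_aa, "chi2": res.chi2, "p_value": res.p_value})
    return pd.DataFrame(rows)


def _stratum_matrix(gm: GenotypeMatrix, ph: PhenotypeVector | None,
                    stratum: str) -> GenotypeMatrix:
    if stratum == "pooled" or ph is None:
        return gm
    cases, controls = split_by_status(gm, ph)
    if stratum == "control":
        return controls
    if stratum == "case":
        return cases
    raise ValueError(f"unknown stratum {stratum!r}")


# ---------------------------------------------------------------------------
# two-locus EM and LD statistics
# ---------------------------------------------------------------------------

def _genotype_cross_table(dosage_a: np.ndarray, dosage_b: np.ndarray,
                          missing_a: np.ndarray | None = None,
                          missing_b: np.ndarray | None = None) -> np.ndarray:
    """3x3 joint genotype counts over jointly observed samples."""
    a = np.asarray(dosage_a)
    b = np.asarray(dosage_b)
    ok = np.ones(a.shape[0], dtype=bool)
    if missing_a is not None:
        ok &= ~np.asarray(missing_a)
    if missing_b is not None:
        ok &= ~np.asarray(missing_b)
    table = np.zeros((3, 3), dtype=float)
    np.add.at(table, (a[ok], b[ok]), 1.0)
    return table


def _genotype_probs(h: np.ndarray) -> np.ndarray:
    """P(genotype pair) under random union of haplotypes h = (AB, Ab, aB, ab)."""
    hAB, hAb, haB, hab = h
    P = np.empty((3, 3))
    P[2, 2] = hAB ** 2
    P[2, 1] = 2 * hAB * hAb
    P[2, 0] = hAb ** 2
    P[1, 2] = 2 * hAB * haB
    P[1, 1] = 2 * (hAB * hab + hAb * haB)
    P[1, 0] = 2 * hAb * hab
    P[0, 2] = haB ** 2
    P[0, 1] = 2 * haB * hab
    P[0, 0] = hab ** 2
    return P


def table_loglik(table: np.ndarray, h: np.ndarray) -> float:
    """Observed-data multinomial log-likelihood of a 3x3 genotype table."""
    P = _genotype_probs(np.asarray(h, dtype=float))
    with np.errstate(divide="ignore"):
        logP = np.where(table > 0, np.log(np.maximum(P, 1e-300)), 0.0)
    return float((table * logP).sum())


def em_haplotype_freqs(table: np.ndarray, tol: float = 1e-10,
                       max_iter: int = 1000
                       ) -> tuple[np.ndarray, int, list[float]]:
    """EM for two-locus haplotype frequencies from a 3x3 genotype table.

    Initialised at linkage equilibrium; converges when the largest haplotype
    frequency change falls below ``tol``. Returns (freqs, iterations,
    log-likelihood trace); the trace is non-decreasing.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    # allele-1 ("A"/"B") marginal frequencies are phase-free
    ga = table.sum(axis=1)
    gb = table.sum(axis=0)
    pA = (2 * ga[2] + ga[1]) / (2 * n)
    pB = (2 * gb[2] + gb[1]) / (2 * n)
    h = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])

    # fixed haplotype counts contributed by unambiguous genotype cells
    # cell (i, j) -> haplotype count vector (AB, Ab, aB, ab)
    fixed = np.zeros(4)
    contrib = {(2, 2): (2, 0, 0, 0), (2, 1): (1, 1, 0, 0), (2, 0): (0, 2, 0, 0),
               (1, 2): (1, 0, 1, 0), (1, 0): (0, 1, 0, 1),
               (0, 2): (0, 0, 2, 0), (0, 1): (0, 0, 1, 1), (0, 0): (0, 0, 0, 2)}
    for (i, j), vec in contrib.items():
        fixed += table[i, j] * np.asarray(vec, dtype=float)
    n_dh = table[1, 1]

    trace = [table_loglik(table, h)]
    iterations = 0
    for iterations in range(1, max_iter + 1):
        cis = h[0] * h[3]
        trans = h[1] * h[2]
        w = cis / (cis + trans) if cis + trans > 0 else 0.5
        counts = fixed + n_dh * np.array([w, 1 - w, 1 - w, w])
        h_new = counts / (2 * n)
        delta = np.abs(h_new - h).max()
        h = h_new
        trace.append(table_loglik(table, h))
        if delta < tol:
            break
    return h, iterations, trace


def ld_from_haplotypes(h: np.ndarray) -> tuple[float, float, float, bool]:
    """(D, D', r^2, boundary_flag) from haplotype frequencies (AB, Ab, aB, ab)."""
    hAB, hAb, haB, hab = h
    pA = hAB + hAb
    pB = hAB + haB
    qA, qB = 1 - pA, 1 - pB
    D = hAB - pA * pB
    if D >= 0:
        dmax = min(pA * qB, qA * pB)
    else:
        dmax = min(pA * pB, qA * qB)
    boundary = dmax <= 0
    d_prime = 0.0 if boundary else D / dmax
    denom = pA * qA * pB * qB
    r2 = 0.0 if denom <= 0 else D * D / denom
    return float(D), float(d_prime), float(r2), boundary


def ld_em(dosage_a: np.ndarray, dosage_b: np.ndarray,
          missing_a: np.ndarray | None = None,
          missing_b: np.ndarray | None = None,
          snp_a: str = "A", snp_b: str = "B") -> LDResult:
    """Lewontin's D' and r^2 between two unphased SNPs via EM.

    Raises if either SNP is monomorphic among jointly observed samples or
    fewer than two samples are jointly observed (LD undefined).
    """
    table = _genotype_cross_table(dosage_a, dosage_b, missing_a, missing_b)
    n = table.sum()
    if n < 2:
        raise ValueError(f"{snp_a}/{snp_b}: fewer than 2 jointly observed samples")
    ga, gb = table.sum(axis=1), table.sum(axis=0)
    pA = (2 * ga[2] + ga[1]) / (2 * n)
    pB = (2 * gb[2] + gb[1]) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise ValueError(f"{snp_a}/{snp_b}: LD undefined for monomorphic SNP")
    h, iterations, trace = em_haplotype_freqs(table)
    D, d_prime, r2, boundary = ld_from_haplotypes(h)
    if boundary:
        import logging
        logging.getLogger("grskit").warning(
            "%s/%s: Dmax = 0, D' reported as 0", snp_a, snp_b)
    return LDResult(snp_a, snp_b, D, d_prime, r2, iterations, trace[-1],
                    haplotype_freqs=h, loglik_trace=trace, boundary=boundary)


def ld_table(gm: GenotypeMatrix, ph: PhenotypeVector | None = None,
             stratum: str = "control",
             pairs: list[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Long-format pairwise LD table (all pairs by default, controls only)."""
    sub = _stratum_matrix(gm, ph, stratum)
    snps = sub.snp_ids
    if pairs is None:
        pairs = [(snps[i], snps[j]) for i in range(len(snps))
                 for j in range(i + 1, len(snps))]
    rows = []
    for sa, sb in pairs:
        da, ma = sub.column(sa)
        db, mb = sub.column(sb)
        try:
            res = ld_em(da, db, ma, mb, sa, sb)
        except ValueError:
            rows.append({"snp_a": sa, "snp_b": sb, "D": np.nan,
                         "d_prime": np.nan, "r2": np.nan})
            continue
        rows.append({"snp_a": sa, "snp_b": sb, "D": res.D,
                     "d_prime": res.d_prime, "r2": res.r2})
    return pd.DataFrame(rows)
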