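"""Case-control association statistics.

Univariate effects are odds ratios from 2x2 tables with Wald machinery:
OR = ad/bc, SE(ln OR) = sqrt(1/a + 1/b + 1/c + 1/d), 95% CI =
exp(ln OR +/- 1.96 SE), two-sided normal p. When any cell is zero the
Haldane-Anscombe 0.5 correction is applied to all four cells and the result
is flagged. Allelic tests treat the 2n alleles as independent observations;
carriage and compound tests are carrier-level 2x2 tables.

Multivariate effects come from a Bernoulli logistic model maximised by
Newton-Raphson/IRLS with step-halving; Wald standard errors are taken from
the inverse observed information. Perfect separation is detected (diverging
coefficient) and flagged rather than silently reported. Analytic power for
the allelic test uses the standard two-proportion normal approximation on
allele frequencies, with a Monte-Carlo mode that simulates stratum genotype
draws under the log-additive model.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .core_data import GenotypeMatrix, PhenotypeVector, TwoByTwo, split_by_status
from .synthetic_cohort import calibrate_intercept, expected_genotype_freq_in_stratum, CohortSimConfig
from .core_data import VariantSpec

logger = logging.getLogger("grskit")

Z975 = stats.norm.ppf(0.975)


@dataclass
class AssociationResult:
    label: str
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    coding: str
    table: TwoByTwo | None = None
    haldane: bool = False  # 0.5 cell correction applied (zero-cell / "ND" analogue)

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class LogisticFit:
    coefficients: np.ndarray
    standard_errors: np.ndarray
    converged: bool
    iterations: int
    loglik: float
    term_names: list[str] = field(default_factory=list)
    loglik_trace: list = field(default_factory=list, repr=False)
    separated: bool = False


# ---------------------------------------------------------------------------
# 2x2 machinery
# ---------------------------------------------------------------------------

def wald_or(t: TwoByTwo, label: str = "", coding: str = "allelic",
            alpha: float = 0.05) -> AssociationResult:
    """Odds ratio with Wald CI and p from a 2x2 table (Haldane on zero cells)."""
    if t.a + t.b == 0 or t.c + t.d == 0:
        raise ValueError("empty case or control margin")
    haldane = t.has_zero_cell
    a, b, c, d = (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5) if haldane \
        else (t.a, t.b, t.c, t.d)
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - alpha / 2)
    ln_or = math.log(or_point)
    ci = (math.exp(ln_or - z * se), math.exp(ln_or + z * se))
    p = 2.0 * stats.norm.sf(abs(ln_or) / se)
    return AssociationResult(label, or_point, ci[0], ci[1], min(p, 1.0),
                             coding, table=t, haldane=haldane)


def allelic_test(t: TwoByTwo, label: str = "") -> AssociationResult:
    """Allelic OR: exposed/unexposed are risk/non-risk allele counts."""
    return wald_or(t, label=label, coding="allelic")


def allelic_table(gm: GenotypeMatrix, ph: PhenotypeVector, snp_id: str
                  ) -> TwoByTwo:
    """Allele-count 2x2 for one SNP (2n denominators, pairwise deletion)."""
    cases, controls = split_by_status(gm, ph)
    counts = []
    for sub in (cases, controls):
        dos, miss = sub.column(snp_id)
        n_obs = int((~miss).sum())
        risk = int(dos[~miss].sum())
        counts.append((risk, 2 * n_obs - risk))
    (a, b), (c, d) = counts
    return TwoByTwo(a, b, c, d)


def _carrier_two_by_two(gm: GenotypeMatrix, ph: PhenotypeVector,
                        snp_ids: list[str], threshold: int) -> TwoByTwo:
    cols = [gm.variant_index(s) for s in snp_ids]
    dos = gm.dosage[:, cols]
    miss = gm.missing_mask[:, cols]
    all_missing = miss.all(axis=1)
    if all_missing.any():
        logger.warning("%d samples missing at all listed SNPs excluded",
                       int(all_missing.sum()))
    total = np.where(miss, 0, dos).sum(axis=1)
    exposed = total >= threshold
    status = dict(zip(ph.sample_ids, ph.is_case))
    is_case = np.array([status[s] for s in gm.sample_ids])
    keep = ~all_missing
    a = int((exposed & is_case & keep).sum())
    b = int((~exposed & is_case & keep).sum())
    c = int((exposed & ~is_case & keep).sum())
    d = int((~exposed & ~is_case & keep).sum())
    return TwoByTwo(a, b, c, d)


def carriage_test(gm: GenotypeMatrix, ph: PhenotypeVector,
                  snp_ids: list[str], label: str = "carriage"
                  ) -> AssociationResult:
    """Carrier OR: exposure is >= 1 risk allele across the listed SNPs."""
    t = _carrier_two_by_two(gm, ph, snp_ids, threshold=1)
    return wald_or(t, label=label, coding="carriage")


def compound_test(gm: GenotypeMatrix, ph: PhenotypeVector,
                  snp_ids: list[str], label: str = "compound"
                  ) -> AssociationResult:
    """Compound het/homozygote OR: >= 2 risk alleles across the listed SNPs."""
    t = _carrier_two_by_two(gm, ph, snp_ids, threshold=2)
    return wald_or(t, label=label, coding="compound")


def univariate_table(gm: GenotypeMatrix, ph: PhenotypeVector) -> pd.DataFrame:
    """Per-SNP risk-allele frequencies and allelic ORs (long TSV-ready table)."""
    rows = []
    for v in gm.variants:
        t = allelic_table(gm, ph, v.snp_id)
        res = allelic_test(t, label=v.snp_id)
        rows.append({
            "snp_id": v.snp_id, "gene": v.gene,
            "case_raf": t.a / (t.a + t.b) if t.a + t.b else np.nan,
            "control_raf": t.c / (t.c + t.d) if t.c + t.d else np.nan,
            "or": res.or_point, "ci_low": res.ci_low, "ci_high": res.ci_high,
            "p_value": res.p_value, "haldane": res.haldane})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic regression (IRLS)
# ---------------------------------------------------------------------------

def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # log sigma(eta)*y + log(1-sigma(eta))*(1-y), numerically stable
    return float(-(np.logaddexp(0.0, -eta) * y
                   + np.logaddexp(0.0, eta) * (1 - y)).sum())


def logistic_fit(design: np.ndarray, outcome: np.ndarray,
                 max_iter: int = 100, tol: float = 1e-8,
                 term_names: list[str] | None = None) -> LogisticFit:
    """Maximum-likelihood logistic regression via Newton-Raphson / IRLS.

    ``design`` must include its own intercept column and be full rank;
    rank deficiency raises an error naming the offending columns. Steps are
    halved whenever the log-likelihood would decrease; convergence is max
    score-equation residual < tol. Perfect separation (a coefficient walking
    past |beta| = 15 while the likelihood still climbs) is flagged with
    ``converged=False, separated=True`` and a warning, mirroring the
    not-determinable cells of sparse genotype strata.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    n, k = X.shape
    names = term_names or [f"x{j}" for j in range(k)]
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        _, r, piv = _qr_pivot(X)
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")

    beta = np.zeros(k)
    ll = _bernoulli_loglik(y, X @ beta)
    trace = [ll]
    converged = False
    separated = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = X @ beta
        p = expit(eta)
        score = X.T @ (y - p)
        if np.abs(score).max() < tol:
            converged = True
            break
        w = np.clip(p * (1 - p), 1e-12, None)
        H = (X * w[:, None]).T @ X
        step = np.linalg.solve(H, score)
        new_beta = beta + step
        new_ll = _bernoulli_loglik(y, X @ new_beta)
        halvings = 0
        while new_ll < ll - 1e-12 and halvings < 40:
            step /= 2.0
            new_beta = beta + step
            new_ll = _bernoulli_loglik(y, X @ new_beta)
            halvings += 1
        beta, ll = new_beta, new_ll
        trace.append(ll)
        if np.abs(beta).max() > 15.0:
            separated = True
            logger.warning("possible perfect separation: |beta| > 15 "
                           "(term %s); fit flagged not converged",
                           names[int(np.abs(beta).argmax())])
            break

    p = expit(X @ beta)
    w = np.clip(p * (1 - p), 1e-12, None)
    H = (X * w[:, None]).T @ X
    cov = np.linalg.inv(H)
    se = np.sqrt(np.diag(cov))
    return LogisticFit(beta, se, converged and not separated, it, ll,
                       term_names=names, loglik_trace=trace,
                       separated=separated)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr
    return qr(X, mode="economic", pivoting=True)


def design_log_additive(gm: GenotypeMatrix, snp_ids: list[str]
                        ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """(design, term names, kept-row mask): intercept + per-SNP dosage.

    Complete-case: samples missing any listed genotype are dropped (warned).
    """
    cols = [gm.variant_index(s) for s in snp_ids]
    keep = ~gm.missing_mask[:, cols].any(axis=1)
    if not keep.all():
        logger.warning("dropping %d samples with missing genotypes from fit",
                       int((~keep).sum()))
    X = np.column_stack([np.ones(int(keep.sum()))]
                        + [gm.dosage[keep, j].astype(float) for j in cols])
    return X, ["intercept"] + list(snp_ids), keep


def design_genotype(gm: GenotypeMatrix, snp_ids: list[str]
                    ) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Intercept + per-SNP indicator pair (1 copy, 2 copies)."""
    cols = [gm.variant_index(s) for s in snp_ids]
    keep = ~gm.missing_mask[:, cols].any(axis=1)
    if not keep.all():
        logger.warning("dropping %d samples with missing genotypes from fit",
                       int((~keep).sum()))
    parts = [np.ones(int(keep.sum()))]
    names = ["intercept"]
    for s, j in zip(snp_ids, cols):
        d = gm.dosage[keep, j]
        parts += [(d == 1).astype(float), (d == 2).astype(float)]
        names += [f"{s}:1copy", f"{s}:2copy"]
    return np.column_stack(parts), names, keep


def multivariate_fit(gm: GenotypeMatrix, ph: PhenotypeVector,
                     snp_ids: list[str], coding: str = "log_additive"
                     ) -> tuple[LogisticFit, pd.DataFrame]:
    """Joint logistic fit over a SNP panel; per-term ORs with Wald CIs."""
    if coding == "log_additive":
        X, names, keep = design_log_additive(gm, snp_ids)
    elif coding == "genotype":
        X, names, keep = design_genotype(gm, snp_ids)
    else:
        raise ValueError(f"unknown coding {coding!r}")
    status = dict(zip(ph.sample_ids, ph.is_case))
    y = np.array([status[s] for s in gm.sample_ids])[keep].astype(float)
    fit = logistic_fit(X, y, term_names=names)
    rows = []
    for name, b, s in zip(names, fit.coefficients, fit.standard_errors):
        if name == "intercept":
            continue
        rows.append({"term": name, "or": math.exp(b),
                     "ci_low": math.exp(b - Z975 * s),
                     "ci_high": math.exp(b + Z975 * s),
                     "p_value": 2 * stats.norm.sf(abs(b) / s),
                     "coding": coding, "converged": fit.converged})
    return fit, pd.DataFrame(rows)


def backward_prune(gm: GenotypeMatrix, ph: PhenotypeVector,
                   snp_ids: list[str], alpha: float = 0.05,
                   coding: str = "log_additive"
                   ) -> tuple[list[str], pd.DataFrame]:
    """Backward elimination at Wald p >= alpha (non-canonical convenience).

    Starts from the full joint fit and iteratively removes the least
    significant SNP until every remaining term has p < alpha. This is one
    reasonable selection path, not a canonical one; use the full fit when in
    doubt.
    """
    current = list(snp_ids)
    while len(current) > 1:
        _, table = multivariate_fit(gm, ph, current, coding=coding)
        worst = table.loc[table["p_value"].idxmax()]
        if worst["p_value"] < alpha:
            break
        current.remove(worst["term"])
    _, table = multivariate_fit(gm, ph, current, coding=coding)
    return current, table


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------

def power_allelic(n_case: int, n_control: int, control_raf: float,
                  odds_ratio: float, alpha: float = 0.05) -> float:
    """Analytic power of the two-sided allelic test (normal approximation).

    The case risk-allele frequency is obtained from the control frequency and
    the OR on the odds scale; power = Phi(|p1 - p0| / SE_alt - z_{1-alpha/2})
    with SE_alt = sqrt(p1 q1 / (2 n_case) + p0 q0 / (2 n_control)), plus the
    (negligible at real effect sizes) opposite-tail term so the null value is
    exactly alpha.
    """
    if not 0.0 < control_raf < 1.0:
        raise ValueError("control_raf must lie in (0, 1)")
    p0 = control_raf
    odds1 = odds_ratio * p0 / (1 - p0)
    p1 = odds1 / (1 + odds1)
    se = math.sqrt(p1 * (1 - p1) / (2 * n_case) + p0 * (1 - p0) / (2 * n_control))
    z = stats.norm.ppf(1 - alpha / 2)
    delta = abs(p1 - p0) / se
    return float(stats.norm.cdf(delta - z) + stats.norm.cdf(-delta - z))


def power_allelic_mc(n_case: int, n_control: int, control_raf: float,
                     odds_ratio: float, alpha: float = 0.05,
                     prevalence: float = 0.005, n_replicates: int = 2000,
                     seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo power of the allelic test under the log-additive model.

    Case/control genotypes are drawn from the analytic stratum genotype
    distribution — exactly the conditional law a retrospective rejection
    sampler induces for a single SNP — so this is the simulation-based
    counterpart of :func:`power_allelic`. Returns (power, MC standard error).
    """
    spec = VariantSpec(snp_id="snp", control_raf=control_raf)
    config = CohortSimConfig(variants=[spec],
                             per_allele_or={"snp": odds_ratio},
                             n_case=n_case, n_control=n_control,
                             prevalence=prevalence, seed=seed)
    b0 = calibrate_intercept(config)
    g_case = expected_genotype_freq_in_stratum(control_raf, odds_ratio, b0, "case")
    g_ctrl = expected_genotype_freq_in_stratum(control_raf, odds_ratio, b0, "control")
    rng = np.random.default_rng(seed)
    rejections = 0
    case_counts = rng.multinomial(n_case, g_case, size=n_replicates)
    ctrl_counts = rng.multinomial(n_control, g_ctrl, size=n_replicates)
    for cc, kc in zip(case_counts, ctrl_counts):
        a = int(cc[1] + 2 * cc[2])
        c = int(kc[1] + 2 * kc[2])
        t = TwoByTwo(a, 2 * n_case - a, c, 2 * n_control - c)
        if wald_or(t, alpha=alpha).p_value < alpha:
            rejections += 1
    power = rejections / n_replicates
    se = math.sqrt(max(power * (1 - power), 1e-12) / n_replicates)
    return power, se
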