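"""Genetic risk scores and threshold-classifier evaluation.

Two profiles are built over a risk-oriented SNP panel: the allele-count score
(sum of 0/1/2 risk-allele dosages) and the weighted score (dosage times a
per-SNP weight, by convention the multivariate log-additive OR of the
risk-oriented allele). Missing genotypes are mean-imputed as twice the pooled
risk-allele frequency so the cohort size stays fixed; affected samples are
flagged. Each cutoff t defines the classifier "score >= t is a case", whose
sensitivity, specificity, PPV, NPV, accuracy and 2x2 odds ratio are tabulated
across a cutoff sweep; the ROC over all distinct cutoffs has trapezoidal AUC,
identical to the Mann-Whitney statistic with ties counted one half.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import AssociationResult, wald_or
from .core_data import GenotypeMatrix, PhenotypeVector, TwoByTwo

logger = logging.getLogger("grskit")


@dataclass
class ScoreProfile:
    sample_ids: list[str]
    score: np.ndarray
    score_type: str                     # "count" | "weighted"
    panel: list[str]
    weights: np.ndarray
    imputed: np.ndarray = None          # bool: any imputed dosage per sample

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=float)
        if self.imputed is None:
            self.imputed = np.zeros(len(self.sample_ids), dtype=bool)
        hi = 2.0 * np.asarray(self.weights).sum()
        if self.score.min() < -1e-9 or self.score.max() > hi + 1e-9:
            raise ValueError("score outside [0, 2 * sum(weights)]")


@dataclass
class ThresholdEvaluation:
    cutoff: float
    n_case_ge: int
    n_control_ge: int
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    haldane: bool = False


@dataclass
class RocCurve:
    points: np.ndarray   # (k, 2) of (1 - specificity, sensitivity)
    auc: float


# ---------------------------------------------------------------------------
# score construction
# ---------------------------------------------------------------------------

def _panel_dosage(gm: GenotypeMatrix, panel: list[str]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Panel dosages with missing cells mean-imputed (2 * pooled RAF)."""
    if not panel:
        raise ValueError("empty score panel")
    cols = [gm.variant_index(s) for s in panel]
    dos = gm.dosage[:, cols].astype(float)
    miss = gm.missing_mask[:, cols]
    for j in range(len(cols)):
        mj = miss[:, j]
        if mj.any():
            obs = dos[~mj, j]
            if obs.size == 0:
                raise ValueError(f"{panel[j]}: all genotypes missing")
            dos[mj, j] = obs.mean()  # = 2 * pooled risk-allele frequency
    imputed = miss.any(axis=1)
    if imputed.any():
        logger.warning("mean-imputed missing genotypes for %d samples",
                       int(imputed.sum()))
    return dos, imputed


def count_score(gm: GenotypeMatrix, panel: list[str]) -> ScoreProfile:
    """Allele-count risk score: sum of risk-oriented dosages over the panel."""
    dos, imputed = _panel_dosage(gm, panel)
    weights = np.ones(len(panel))
    return ScoreProfile(list(gm.sample_ids), dos.sum(axis=1), "count",
                        list(panel), weights, imputed)


def weighted_score(gm: GenotypeMatrix, panel: list[str],
                   weights: dict[str, float] | None = None) -> ScoreProfile:
    """Weighted risk score: sum of weight_i * dosage_i over the panel.

    Defaults to each VariantSpec's ``weight`` (the multivariate log-additive
    OR of the risk-oriented allele, reciprocal for flipped protective SNPs);
    a {snp_id: weight} mapping overrides it.
    """
    dos, imputed = _panel_dosage(gm, panel)
    if weights is None:
        w = np.array([gm.variants[gm.variant_index(s)].weight for s in panel])
    else:
        missing = [s for s in panel if s not in weights]
        if missing:
            raise ValueError(f"missing weight for {', '.join(missing)}")
        w = np.array([weights[s] for s in panel])
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return ScoreProfile(list(gm.sample_ids), dos @ w, "weighted",
                        list(panel), w, imputed)


def split_scores(profile: ScoreProfile, ph: PhenotypeVector
                 ) -> tuple[np.ndarray, np.ndarray]:
    """(case scores, control scores) aligned through sample ids."""
    status = dict(zip(ph.sample_ids, ph.is_case))
    is_case = np.array([status[s] for s in profile.sample_ids])
    return profile.score[is_case], profile.score[~is_case]


# ---------------------------------------------------------------------------
# threshold evaluation
# ---------------------------------------------------------------------------

def classification_metrics(n_case_ge: int, n_cases: int, n_control_ge: int,
                           n_controls: int, cutoff: float = float("nan")
                           ) -> ThresholdEvaluation:
    """Full classification record for one "score >= cutoff" rule.

    Percentages: sensitivity = 100 a/n_cases with a = cases at/above cutoff;
    specificity = 100 (n_controls - c)/n_controls; accuracy is the
    prevalence-weighted mean of the two; PPV/NPV condition on the predicted
    class. The OR is the Wald 2x2 estimate on (a, n_cases - a, c,
    n_controls - c).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("need at least one case and one control")
    if not (0 <= n_case_ge <= n_cases and 0 <= n_control_ge <= n_controls):
        raise ValueError("counts at/above cutoff exceed group totals")
    t = TwoByTwo(n_case_ge, n_cases - n_case_ge,
                 n_control_ge, n_controls - n_control_ge)
    res = wald_or(t, coding="threshold")
    sens = 100.0 * n_case_ge / n_cases
    spec = 100.0 * (n_controls - n_control_ge) / n_controls
    acc = (sens * n_cases + spec * n_controls) / (n_cases + n_controls)
    pred_pos = n_case_ge + n_control_ge
    pred_neg = (n_cases - n_case_ge) + (n_controls - n_control_ge)
    ppv = 100.0 * n_case_ge / pred_pos if pred_pos else float("nan")
    npv = 100.0 * (n_controls - n_control_ge) / pred_neg if pred_neg else float("nan")
    return ThresholdEvaluation(cutoff, n_case_ge, n_control_ge,
                               res.or_point, res.ci_low, res.ci_high,
                               res.p_value, sens, spec, ppv, npv, acc,
                               haldane=res.haldane)


def threshold_sweep(case_scores: np.ndarray, control_scores: np.ndarray,
                    cutoffs: np.ndarray | None = None
                    ) -> list[ThresholdEvaluation]:
    """Evaluate the ">= t" classifier over a cutoff grid.

    Defaults to all distinct observed scores. Cutoff semantics are inclusive.
    """
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValueError("need nonempty case and control score vectors")
    if cutoffs is None:
        cutoffs = np.unique(np.concatenate([case_scores, control_scores]))
    out = []
    for t in np.asarray(cutoffs, dtype=float):
        out.append(classification_metrics(
            int((case_scores >= t).sum()), case_scores.size,
            int((control_scores >= t).sum()), control_scores.size, cutoff=t))
    return out


def sweep_table(evals: list[ThresholdEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cutoff": e.cutoff, "n_case_ge": e.n_case_ge,
        "n_control_ge": e.n_control_ge, "or": e.or_point,
        "ci_low": e.ci_low, "ci_high": e.ci_high, "p_value": e.p_value,
        "sensitivity": e.sensitivity, "specificity": e.specificity,
        "ppv": e.ppv, "npv": e.npv, "accuracy": e.accuracy,
        "haldane": e.haldane} for e in evals])


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def roc(case_scores: np.ndarray, control_scores: np.ndarray) -> RocCurve:
    """ROC over all distinct cutoffs with trapezoidal AUC.

    The trapezoid rule across tie groups makes the AUC equal to the
    Mann-Whitney probability P(case > control) + 0.5 P(tie). Constant scores
    in both groups give AUC 0.5 with a warning.
    """
    case_scores = np.asarray(case_scores, dtype=float)
    control_scores = np.asarray(control_scores, dtype=float)
    if case_scores.size == 0 or control_scores.size == 0:
        raise ValueError("need nonempty case and control score vectors")
    allv = np.unique(np.concatenate([case_scores, control_scores]))
    if allv.size == 1:
        logger.warning("constant scores in both groups; AUC defined as 0.5")
        return RocCurve(np.array([[0.0, 0.0], [1.0, 1.0]]), 0.5)
    # descending cutoffs: (1-spec, sens) walks from (0,0) to (1,1)
    pts = [(0.0, 0.0)]
    for t in allv[::-1]:
        sens = float((case_scores >= t).mean())
        fpr = float((control_scores >= t).mean())
        pts.append((fpr, sens))
    points = np.array(pts)
    auc = float(np.trapezoid(points[:, 1], points[:, 0]))
    return RocCurve(points, auc)


def score_distribution(profile: ScoreProfile, ph: PhenotypeVector,
                       bins: np.ndarray) -> pd.DataFrame:
    """Per-group percentage of samples per score bin (histogram analogue).

    ``bins`` are histogram edges covering the score range; percentages sum to
    100 within each group.
    """
    bins = np.asarray(bins, dtype=float)
    case, ctrl = split_scores(profile, ph)
    lo, hi = bins[0], bins[-1]
    for name, v in (("case", case), ("control", ctrl)):
        if v.size and (v.min() < lo or v.max() > hi):
            raise ValueError(f"bins do not cover the {name} score range")
    rows = []
    c_hist, _ = np.histogram(case, bins=bins)
    k_hist, _ = np.histogram(ctrl, bins=bins)
    for i in range(len(bins) - 1):
        rows.append({"bin_low": bins[i], "bin_high": bins[i + 1],
                     "case_pct": 100.0 * c_hist[i] / case.size,
                     "control_pct": 100.0 * k_hist[i] / ctrl.size})
    return pd.DataFrame(rows)
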