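"""Retrospective case-control cohort simulator.

The generative model mirrors the design the analysis assumes: genotypes are
drawn for a source population in Hardy-Weinberg equilibrium (optionally with
pairwise LD, specified as Lewontin's D' targets that may chain into small
haplotype blocks), disease is assigned under a prospective log-additive
logistic model

    P(case | c) = logistic(b0 + sum_i ln(OR_i) * c_i),

with the intercept b0 calibrated so the population prevalence matches the
configured target, and individuals are then ascertained retrospectively by
rejection sampling until the case and control quotas are filled. Because the
draw is honestly prospective, the conditional genotype law within each
stratum (available analytically from :func:`expected_genotype_freq_in_stratum`
by Bayes inversion) is an independent oracle for the simulator.

One master integer seed drives a single numpy Generator; identical seeds give
byte-identical output within this implementation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit

from . import panel as _panel_mod
from .core_data import GenotypeMatrix, PhenotypeVector, VariantSpec

_ATOM_CAP = 200_000  # max support size kept during score-PMF convolution


@dataclass
class HaplotypePair:
    """Two-locus haplotype frequencies (AB, Ab, aB, ab)."""

    freq_AB: float
    freq_Ab: float
    freq_aB: float
    freq_ab: float

    def __post_init__(self) -> None:
        freqs = self.as_array()
        if (freqs < -1e-12).any():
            raise ValueError("negative haplotype frequency")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("haplotype frequencies must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.freq_AB, self.freq_Ab, self.freq_aB, self.freq_ab])

    @property
    def p_a(self) -> float:
        return self.freq_AB + self.freq_Ab

    @property
    def p_b(self) -> float:
        return self.freq_AB + self.freq_aB


@dataclass
class CohortSimConfig:
    """Generative-model parameters for one simulated case-control cohort."""

    variants: list[VariantSpec]            # control_raf used as population freq
    per_allele_or: dict[str, float]
    n_case: int
    n_control: int
    prevalence: float = 0.005
    ld_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    seed: int = 0
    max_total_draws: int = 50_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        known = {v.snp_id for v in self.variants}
        for v in self.variants:
            if v.snp_id not in self.per_allele_or:
                raise ValueError(f"no per-allele OR for {v.snp_id}")
            if not self.per_allele_or[v.snp_id] > 0:
                raise ValueError(f"{v.snp_id}: per-allele OR must be positive")
            if math.isnan(v.control_raf):
                raise ValueError(f"{v.snp_id}: population frequency required")
        for a, b, dp in self.ld_pairs:
            if a not in known or b not in known:
                raise ValueError(f"LD pair ({a}, {b}) names an unknown SNP")
            if not -1.0 <= dp <= 1.0:
                raise ValueError("target D' must lie in [-1, 1]")
        _build_blocks(self)  # validates the forest structure eagerly


def make_haplotype_pair(raf_a: float, raf_b: float, d_prime: float
                        ) -> HaplotypePair:
    """Haplotype frequencies realising a target D' at given allele frequencies.

    D = d_prime * Dmax with Dmax = min(pA*qB, qA*pB) for d_prime >= 0 and
    min(pA*pB, qA*qB) for d_prime < 0, so any d_prime in [-1, 1] yields a
    valid (nonnegative) table.
    """
    if not (0.0 < raf_a < 1.0 and 0.0 < raf_b < 1.0):
        raise ValueError("allele frequencies must lie in (0, 1)")
    qa, qb = 1.0 - raf_a, 1.0 - raf_b
    dmax = min(raf_a * qb, qa * raf_b) if d_prime >= 0 else min(raf_a * raf_b, qa * qb)
    D = d_prime * dmax
    freqs = np.array([raf_a * raf_b + D, raf_a * qb - D,
                      qa * raf_b - D, qa * qb + D])
    if (freqs < -1e-12).any():
        raise ValueError(
            f"invalid D'={d_prime} at frequencies ({raf_a}, {raf_b})")
    return HaplotypePair(*np.clip(freqs, 0.0, 1.0))


# ---------------------------------------------------------------------------
# LD blocks: forests of pairwise D' constraints
# ---------------------------------------------------------------------------

@dataclass
class _Block:
    """One independent haplotype block: columns, states and probabilities."""

    columns: list[int]           # indices into config.variants
    hap_alleles: np.ndarray      # (n_states, k) 0/1 alleles per haplotype
    hap_probs: np.ndarray        # (n_states,)


def _build_blocks(config: CohortSimConfig) -> list[_Block]:
    """Group SNPs into independent blocks; LD edges must form a forest."""
    idx = {v.snp_id: j for j, v in enumerate(config.variants)}
    parent = list(range(len(config.variants)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    adj: dict[int, list[tuple[int, float]]] = {}
    for a, b, dp in config.ld_pairs:
        ia, ib = idx[a], idx[b]
        ra, rb = find(ia), find(ib)
        if ra == rb:
            raise ValueError("ld_pairs contain a cycle; chains/trees only")
        parent[ra] = rb
        adj.setdefault(ia, []).append((ib, dp))
        adj.setdefault(ib, []).append((ia, dp))

    groups: dict[int, list[int]] = {}
    for j in range(len(config.variants)):
        groups.setdefault(find(j), []).append(j)

    blocks = []
    for members in groups.values():
        blocks.append(_enumerate_block(config, sorted(members), adj))
    return blocks


def _enumerate_block(config: CohortSimConfig, members: list[int],
                     adj: dict[int, list[tuple[int, float]]]) -> _Block:
    """Haplotype state space for one tree-shaped block, exact enumeration."""
    freqs = {j: config.variants[j].control_raf for j in members}
    if len(members) == 1:
        j = members[0]
        return _Block([j], np.array([[0], [1]]),
                      np.array([1.0 - freqs[j], freqs[j]]))

    pos = {j: k for k, j in enumerate(members)}
    root = members[0]
    # BFS tree order
    order, seen, stack = [], {root}, [root]
    edges = []  # (parent, child, d_prime)
    while stack:
        u = stack.pop(0)
        order.append(u)
        for v, dp in adj.get(u, []):
            if v not in seen:
                seen.add(v)
                edges.append((u, v, dp))
                stack.append(v)

    n_states = 2 ** len(members)
    alleles = ((np.arange(n_states)[:, None] >> np.arange(len(members))) & 1
               ).astype(np.int8)
    probs = np.where(alleles[:, pos[root]] == 1, freqs[root], 1 - freqs[root]
                     ).astype(float)
    for u, v, dp in edges:
        hp = make_haplotype_pair(freqs[u], freqs[v], dp)
        # conditional P(child allele | parent allele) on one haplotype
        p1 = freqs[u]
        cond = np.array([[hp.freq_ab / (1 - p1), hp.freq_aB / (1 - p1)],
                         [hp.freq_Ab / p1, hp.freq_AB / p1]])
        probs *= cond[alleles[:, pos[u]], alleles[:, pos[v]]]
    return _Block(members, alleles, probs)


# ---------------------------------------------------------------------------
# intercept calibration
# ---------------------------------------------------------------------------

def _convolve(atom_sets: list[tuple[np.ndarray, np.ndarray]],
              cap: int = _ATOM_CAP) -> tuple[np.ndarray, np.ndarray]:
    """Convolve discrete PMFs, merging equal atoms; snap to a grid on overflow."""
    scores = np.array([0.0])
    probs = np.array([1.0])
    for s, p in atom_sets:
        new_s = (scores[:, None] + s[None, :]).ravel()
        new_p = (probs[:, None] * p[None, :]).ravel()
        if new_s.size > cap:
            span = new_s.max() - new_s.min()
            step = max(span / cap, 1e-12)
            new_s = np.round(new_s / step) * step
        uniq, inv = np.unique(new_s, return_inverse=True)
        scores = uniq
        probs = np.bincount(inv, weights=new_p)
    return scores, probs


def _score_pmf(config: CohortSimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact (up to atom capping) PMF of the genetic score sum ln(OR_i)*c_i."""
    lnor = np.array([math.log(config.per_allele_or[v.snp_id])
                     for v in config.variants])
    atom_sets = []
    for block in _build_blocks(config):
        hap_scores = block.hap_alleles @ lnor[block.columns]
        # genotype = two independent haplotypes
        s, p = _convolve([(hap_scores, block.hap_probs)] * 2, cap=_ATOM_CAP)
        atom_sets.append((s, p))
    return _convolve(atom_sets)


def calibrate_intercept(config: CohortSimConfig) -> float:
    """Logistic intercept b0 matching the target prevalence.

    Solves E[ logistic(b0 + S) ] = prevalence over the genotype-score
    distribution S by bisection (Brent) on a guaranteed bracket.
    """
    scores, probs = _score_pmf(config)

    def gap(b0: float) -> float:
        return float(probs @ expit(b0 + scores)) - config.prevalence

    base = float(logit(config.prevalence))
    lo = base - float(scores.max()) - 1.0
    hi = base - float(scores.min()) + 1.0
    for _ in range(10):
        if gap(lo) < 0 < gap(hi):
            return float(brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16))
        lo -= 10.0
        hi += 10.0
    raise RuntimeError("could not bracket the prevalence equation")


def expected_genotype_freq_in_stratum(raf: float, odds_ratio: float,
                                      intercept: float, stratum: str
                                      ) -> np.ndarray:
    """Genotype probabilities (c = 0, 1, 2) within cases or controls.

    Bayes inversion of the single-SNP logistic model over an HWE population:
    P(c | status) is proportional to P(status | c) * P(c).
    """
    if stratum not in ("case", "control"):
        raise ValueError("stratum must be 'case' or 'control'")
    if not 0.0 <= raf <= 1.0:
        raise ValueError("raf outside [0, 1]")
    q = 1.0 - raf
    g = np.array([q * q, 2 * raf * q, raf * raf])
    pen = expit(intercept + np.log(odds_ratio) * np.arange(3))
    w = g * (pen if stratum == "case" else 1.0 - pen)
    return w / w.sum()


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(config: CohortSimConfig, return_diagnostics: bool = False
                    ) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Draw a case-control cohort by retrospective (rejection) ascertainment.

    Individuals are generated prospectively (HWE / LD-block genotypes, then
    Bernoulli disease under the calibrated logistic model) and retained in
    draw order until both quotas are met. Fixed seed gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    b0 = calibrate_intercept(config)
    lnor = np.array([math.log(config.per_allele_or[v.snp_id])
                     for v in config.variants])
    blocks = _build_blocks(config)
    m = len(config.variants)

    expected = max(config.n_case / config.prevalence,
                   config.n_control / (1.0 - config.prevalence))
    if expected > config.max_total_draws:
        raise RuntimeError(
            f"expected {expected:.0f} draws to fill quotas exceeds the cap "
            f"{config.max_total_draws} (prevalence {config.prevalence})")

    need_case, need_ctrl = config.n_case, config.n_control
    kept_dos: list[np.ndarray] = []
    kept_case: list[np.ndarray] = []
    total_draws = 0
    total_cases = 0
    batch = int(min(max(expected * 1.2, 1000), 2_000_000))
    while need_case > 0 or need_ctrl > 0:
        if total_draws >= config.max_total_draws:
            raise RuntimeError(
                f"draw cap {config.max_total_draws} reached with quotas "
                f"unfilled ({need_case} cases / {need_ctrl} controls short)")
        dosage = np.empty((batch, m), dtype=np.int8)
        for blk in blocks:
            h1 = rng.choice(len(blk.hap_probs), size=batch, p=blk.hap_probs)
            h2 = rng.choice(len(blk.hap_probs), size=batch, p=blk.hap_probs)
            dosage[:, blk.columns] = blk.hap_alleles[h1] + blk.hap_alleles[h2]
        p = expit(b0 + dosage @ lnor)
        is_case = rng.random(batch) < p
        total_draws += batch
        total_cases += int(is_case.sum())
        take = np.where(is_case,
                        np.cumsum(is_case) <= need_case,
                        np.cumsum(~is_case) <= need_ctrl)
        kept_dos.append(dosage[take])
        kept_case.append(is_case[take])
        need_case -= int((is_case & take).sum())
        need_ctrl -= int((~is_case & take).sum())

    dosage = np.concatenate(kept_dos)
    is_case = np.concatenate(kept_case)
    sample_ids = [f"S{i + 1:05d}" for i in range(dosage.shape[0])]
    gm = GenotypeMatrix(sample_ids, list(config.variants), dosage,
                        np.zeros_like(dosage, dtype=bool))
    ph = PhenotypeVector(sample_ids, is_case)
    if return_diagnostics:
        diag = {"intercept": b0, "total_draws": total_draws,
                "total_cases_drawn": total_cases,
                "observed_prevalence": total_cases / total_draws}
        return gm, ph, diag
    return gm, ph


def make_reference_cohort(seed: int, n_case: int | None = None,
                          n_control: int | None = None,
                          prevalence: float = 0.005, with_ld: bool = True
                          ) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Synthetic 22-SNP cohort emulating the bundled AJ Crohn's disease panel.

    Uses the panel's control risk-allele frequencies as population
    frequencies and the univariate per-allele ORs as effect sizes, with the
    reported strong LD pairs, at the reference sample sizes (369 cases / 503
    controls) unless overridden.
    """
    config = CohortSimConfig(
        variants=_panel_mod.full_panel(),
        per_allele_or=_panel_mod.univariate_ors(),
        n_case=_panel_mod.N_CASE if n_case is None else n_case,
        n_control=_panel_mod.N_CONTROL if n_control is None else n_control,
        prevalence=prevalence,
        ld_pairs=list(_panel_mod.LD_PAIRS) if with_ld else [],
        seed=seed)
    return simulate_cohort(config)
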