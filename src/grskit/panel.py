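"""Bundled 22-SNP Crohn's disease susceptibility panel (Ashkenazi Jewish reference).

Risk-allele frequencies in 503 AJ controls and 369 AJ CD cases, per-allele
univariate odds ratios, multivariate log-additive odds ratios for the seven
SNPs that remain independently associated, pairwise linkage disequilibrium
targets, and the per-cutoff classification counts of the published threshold
table. These constants parameterise the synthetic-cohort generator and serve
as worked-example inputs; they are reference values, not computed output.
"""

from __future__ import annotations

from .core_data import VariantSpec

# gene, snp_id, control risk-allele freq, case risk-allele freq, univariate OR
PANEL_ROWS = [
    ("NOD2", "rs2066844", 0.02, 0.04, 1.85),
    ("NOD2", "rs2066845", 0.04, 0.11, 3.23),
    ("NOD2", "rs2066847", 0.02, 0.11, 5.18),
    ("NOD2", "rs17221417", 0.22, 0.38, 2.13),
    ("NOD2", "rs2076756", 0.22, 0.39, 2.26),
    ("IL23R", "rs11209026", 0.07, 0.02, 0.27),
    ("IL23R", "rs7517847", 0.38, 0.25, 0.55),
    ("IL23R", "rs11805303", 0.35, 0.41, 1.32),
    ("IRGM", "rs13361189", 0.16, 0.21, 1.47),
    ("IRGM", "rs11747270", 0.15, 0.21, 1.48),
    ("IRGM", "rs1000113", 0.15, 0.21, 1.49),
    ("PTGER4", "rs1373692", 0.61, 0.67, 1.29),
    ("PTGER4", "rs1992660", 0.60, 0.65, 1.21),
    ("PTGER4", "rs4613763", 0.07, 0.08, 1.05),
    ("ATG16L1", "rs2241880", 0.59, 0.63, 1.18),
    ("ATG16L1", "rs10210302", 0.59, 0.62, 1.14),
    ("NKX2-3", "rs11190140", 0.45, 0.43, 0.92),
    ("IL12B", "rs6887695", 0.32, 0.32, 1.03),
    ("IL12B", "rs10045431", 0.71, 0.69, 0.94),
    ("PTPN2", "rs2542151", 0.10, 0.12, 1.20),
    ("TNFSF15", "rs4263839", 0.76, 0.75, 0.95),
    ("STAT3", "rs744166", 0.61, 0.62, 0.99),
]

#: The three NOD2 coding variants (R702W, G908R, L1007fs).
NOD2_CODING_SNPS = ["rs2066844", "rs2066845", "rs2066847"]

#: Multivariate log-additive per-allele ORs for the seven independently
#: associated SNPs, on the minor-allele scale as published (IL23R entries < 1
#: are protective and get flipped to the major allele downstream).
MULTIVARIATE_LOG_ADDITIVE_OR = {
    "rs2066844": 2.01,
    "rs2066845": 3.30,
    "rs2066847": 5.24,
    "rs11209026": 0.43,
    "rs7517847": 0.59,
    "rs13361189": 1.64,
    "rs1373692": 1.37,
}

#: Pairwise LD (D') among panel SNPs, reported in the reference cohort.
#: Forms a forest (chains allowed, no cycles) for the haplotype simulator.
LD_PAIRS = [
    ("rs17221417", "rs2066845", 0.99),
    ("rs2076756", "rs2066847", 0.97),
    ("rs11805303", "rs11209026", 1.00),
    ("rs7517847", "rs11209026", 0.86),
    ("rs13361189", "rs11747270", 0.99),
    ("rs11747270", "rs1000113", 0.99),
    ("rs1373692", "rs1992660", 0.96),
    ("rs2241880", "rs10210302", 0.99),
]

#: Reference cohort sample sizes.
N_CASE = 369
N_CONTROL = 503

# Published per-cutoff classification counts for the 7-SNP risk scores:
# (cutoff, cases at/above, controls at/above, published OR).
# The last three weighted rows' published ORs are not the cross-products of
# their own counts; recompute_threshold_table flags them.
THRESHOLD_COUNTS_COUNT_SCORE = [
    (3, 366, 489, 3.49),
    (4, 354, 425, 4.33),
    (5, 316, 310, 3.71),
    (6, 214, 152, 3.19),
    (7, 107, 39, 4.86),
    (8, 27, 3, 13.16),
]
THRESHOLD_COUNTS_WEIGHTED_SCORE = [
    (2, 368, 498, 3.69),
    (3, 361, 470, 3.17),
    (4, 331, 377, 2.91),
    (5, 287, 259, 3.30),
    (6, 216, 138, 3.73),
    (7, 174, 88, 4.21),
    (8, 124, 42, 5.56),
    (9, 108, 27, 7.69),
    (10, 73, 20, 9.45),
    (11, 53, 13, 14.2),
]


def full_panel() -> list[VariantSpec]:
    """All 22 panel SNPs as printed (minor-allele oriented, weight 1)."""
    return [
        VariantSpec(snp_id=s, gene=g, risk_allele="G", is_flipped=False,
                    control_raf=c, case_raf=a, weight=1.0)
        for g, s, c, a, _ in PANEL_ROWS
    ]


def univariate_ors() -> dict[str, float]:
    """Per-allele univariate OR for each panel SNP, printed orientation."""
    return {s: o for _, s, _, _, o in PANEL_ROWS}


def significant_panel(weights: str = "or") -> list[VariantSpec]:
    """The seven-SNP score panel, risk-oriented.

    Protective SNPs (IL23R rs11209026 and rs7517847) are flipped so the
    declared risk allele is the major allele: their frequency becomes 1 - f
    and their weight the reciprocal of the published multivariate OR, making
    every panel allele risk-increasing.

    Parameters
    ----------
    weights : {"or", "log_or", "unit"}
        Weight convention: multivariate log-additive OR (default, the
        published weighted-score convention), its natural log, or 1.
    """
    if weights not in ("or", "log_or", "unit"):
        raise ValueError(f"unknown weight convention {weights!r}")
    import math

    rows = {r[1]: r for r in PANEL_ROWS}
    specs = []
    for snp, or_ in MULTIVARIATE_LOG_ADDITIVE_OR.items():
        gene, _, craf, araf, _ = rows[snp]
        flipped = or_ < 1.0
        if flipped:
            or_, craf = 1.0 / or_, 1.0 - craf
            araf = 1.0 - araf
        if weights == "or":
            w = or_
        elif weights == "log_or":
            w = math.log(or_)
        else:
            w = 1.0
        specs.append(VariantSpec(snp_id=snp, gene=gene, risk_allele="G",
                                 is_flipped=flipped, control_raf=craf,
                                 case_raf=araf, weight=w))
    return specs
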