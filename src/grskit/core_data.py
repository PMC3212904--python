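"""Domain containers and I/O for case-control genotype data.

Genotypes are held as risk-allele dosages: 0 for common-allele homozygotes,
1 for heterozygotes, 2 for risk-allele homozygotes, with a parallel missing
mask. A variant whose risk-oriented allele is the major/reference allele
(protective variants flipped to point in the risk direction) carries
``is_flipped=True`` and its VCF ALT count c is recoded as 2 - c on read.

File formats: VCF 4.x (GT field only) read through pysam; an internal
tab-separated genotype table (header of SNP ids, one row per sample, cells in
{0,1,2,NA}); a phenotype table (sample_id, status with 1=case / 0=control);
and a variant-specification table (TSV or JSON). Sample and variant order is
preserved everywhere — nothing is sorted.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("grskit")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class VariantSpec:
    """One panel SNP: identity, risk-oriented allele, frequencies, weight.

    ``control_raf``/``case_raf`` are risk-allele frequencies (the frequency of
    the risk-oriented allele, i.e. already on the flipped scale when
    ``is_flipped``). ``weight`` is the risk-score weight (1 for count scores).
    """

    snp_id: str
    gene: str = ""
    risk_allele: str = "G"
    is_flipped: bool = False
    control_raf: float = math.nan
    case_raf: float = math.nan
    weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("control_raf", "case_raf"):
            v = getattr(self, name)
            if v is not None and not math.isnan(v) and not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.snp_id}: {name}={v} outside [0, 1]")
        if not self.weight > 0:
            raise ValueError(f"{self.snp_id}: weight must be positive")


@dataclass
class PhenotypeVector:
    """Case/control status for an ordered set of samples."""

    sample_ids: list[str]
    is_case: np.ndarray  # bool, aligned with sample_ids

    def __post_init__(self) -> None:
        self.is_case = np.asarray(self.is_case, dtype=bool)
        if len(self.sample_ids) != self.is_case.shape[0]:
            raise ValueError("sample_ids and status lengths differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids in phenotype vector")

    @property
    def n_case(self) -> int:
        return int(self.is_case.sum())

    @property
    def n_control(self) -> int:
        return int((~self.is_case).sum())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({"sample_id": self.sample_ids,
                      "status": self.is_case.astype(int)}
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PhenotypeVector":
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
        if not {"sample_id", "status"} <= set(df.columns):
            raise ValueError("phenotype table needs sample_id and status columns")
        return cls(list(df["sample_id"]), df["status"].to_numpy(dtype=int) == 1)


@dataclass
class GenotypeMatrix:
    """Samples x variants risk-allele dosage table with a missing-data mask."""

    sample_ids: list[str]
    variants: list[VariantSpec]
    dosage: np.ndarray        # int8 (n_samples, n_variants); 0 where missing
    missing_mask: np.ndarray  # bool, True where genotype unobserved

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, m = len(self.sample_ids), len(self.variants)
        if self.dosage.shape != (n, m) or self.missing_mask.shape != (n, m):
            raise ValueError("dosage/missing_mask shape inconsistent with ids")
        ids = [v.snp_id for v in self.variants]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate snp_ids in panel")
        observed = self.dosage[~self.missing_mask]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosages must lie in {0, 1, 2}")

    # -- indexing helpers ---------------------------------------------------

    @property
    def snp_ids(self) -> list[str]:
        return [v.snp_id for v in self.variants]

    def variant_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def column(self, snp_id: str) -> tuple[np.ndarray, np.ndarray]:
        """(dosage, missing_mask) for one SNP, in sample order."""
        j = self.variant_index(snp_id)
        return self.dosage[:, j], self.missing_mask[:, j]

    def subset_samples(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        ids = [s for s, k in zip(self.sample_ids, keep) if k]
        return GenotypeMatrix(ids, self.variants,
                              self.dosage[keep], self.missing_mask[keep])

    def flip_variant(self, snp_id: str) -> "GenotypeMatrix":
        """Re-orient one variant to the opposite allele (involution)."""
        j = self.variant_index(snp_id)
        dos = self.dosage.copy()
        dos[:, j] = np.where(self.missing_mask[:, j], 0, 2 - dos[:, j])
        variants = list(self.variants)
        v = variants[j]
        variants[j] = dataclasses.replace(
            v, is_flipped=not v.is_flipped,
            control_raf=1.0 - v.control_raf if not math.isnan(v.control_raf) else v.control_raf,
            case_raf=1.0 - v.case_raf if not math.isnan(v.case_raf) else v.case_raf)
        return GenotypeMatrix(self.sample_ids, variants, dos, self.missing_mask)

    # -- internal TSV dialect ------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        cells = self.dosage.astype(object)
        cells[self.missing_mask] = "NA"
        df = pd.DataFrame(cells, columns=self.snp_ids)
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path,
                 variants: list[VariantSpec] | None = None) -> "GenotypeMatrix":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        sample_ids = list(df["sample_id"])
        snp_ids = [c for c in df.columns if c != "sample_id"]
        if variants is None:
            variants = [VariantSpec(snp_id=s) for s in snp_ids]
        else:
            by_id = {v.snp_id: v for v in variants}
            variants = [by_id[s] for s in snp_ids]
        raw = df[snp_ids].to_numpy()
        missing = raw == "NA"
        dosage = np.where(missing, "0", raw).astype(np.int8)
        return cls(sample_ids, variants, dosage, missing)


@dataclass
class TwoByTwo:
    """Exposed/unexposed by case/control counts — the atom of OR estimation.

    a: exposed cases, b: unexposed cases, c: exposed controls, d: unexposed
    controls.
    """

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be nonnegative")

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


# ---------------------------------------------------------------------------
# variant-spec tables
# ---------------------------------------------------------------------------

def read_variant_specs(path: str | Path) -> list[VariantSpec]:
    """Read a variant-specification table (TSV or JSON list of records)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path, sep="\t").to_dict("records")
    fields = {f.name for f in dataclasses.fields(VariantSpec)}
    specs = []
    for rec in records:
        rec = {k: v for k, v in rec.items() if k in fields}
        if "is_flipped" in rec:
            rec["is_flipped"] = bool(rec["is_flipped"]) and str(rec["is_flipped"]).lower() not in ("false", "0")
        specs.append(VariantSpec(**rec))
    if len({s.snp_id for s in specs}) != len(specs):
        raise ValueError("duplicate snp_ids in variant-spec table")
    return specs


def write_variant_specs(specs: list[VariantSpec], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in specs]).to_csv(
        path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------

def read_genotypes(vcf_source: str | Path, phenotype_table: str | Path,
                   variant_specs: list[VariantSpec] | str | Path,
                   ) -> tuple[GenotypeMatrix, PhenotypeVector]:
    """Load dosages from a VCF and align them with a phenotype table.

    Only the GT field is consulted. Dosage counts copies of each spec's
    risk-oriented allele: when the risk allele is the ALT allele the ALT count
    is used directly; when it is the REF allele (``is_flipped`` orientation)
    the count is recoded 2 - c. Sites in the VCF that are not listed in the
    specs are ignored; VCF samples absent from the phenotype table are dropped
    with a warning; a spec SNP absent from the VCF, a multiallelic or
    non-diploid call, or a risk allele matching neither REF nor ALT is a hard
    error. Missing calls (./.) set the missing mask.
    """
    import pysam

    if not isinstance(variant_specs, list):
        variant_specs = read_variant_specs(variant_specs)
    ph = PhenotypeVector.from_tsv(phenotype_table)

    spec_by_id = {v.snp_id: v for v in variant_specs}
    found: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    with pysam.VariantFile(str(vcf_source)) as vf:
        vcf_samples = list(vf.header.samples)
        sample_set = set(vcf_samples)
        missing_ph = [s for s in ph.sample_ids if s not in sample_set]
        if missing_ph:
            raise ValueError(
                f"{len(missing_ph)} phenotype samples absent from VCF "
                f"(first: {missing_ph[0]!r})")
        extra = [s for s in vcf_samples if s not in set(ph.sample_ids)]
        if extra:
            logger.warning("dropping %d VCF samples absent from phenotype table",
                           len(extra))
        for rec in vf:
            if rec.id not in spec_by_id:
                continue
            spec = spec_by_id[rec.id]
            alts = rec.alts or ()
            if len(alts) != 1:
                raise ValueError(f"{rec.id}: site is not biallelic")
            if spec.risk_allele == alts[0]:
                flip = False
            elif spec.risk_allele == rec.ref:
                flip = True
            else:
                raise ValueError(
                    f"{rec.id}: risk allele {spec.risk_allele!r} is neither "
                    f"REF ({rec.ref}) nor ALT ({alts[0]})")
            dos = np.zeros(len(vcf_samples), dtype=np.int8)
            miss = np.zeros(len(vcf_samples), dtype=bool)
            for i, s in enumerate(vcf_samples):
                gt = rec.samples[s].get("GT")
                if gt is None or all(g is None for g in gt):
                    miss[i] = True
                    continue
                if len(gt) != 2 or any(g is None for g in gt):
                    raise ValueError(f"{rec.id}: non-diploid GT for sample {s}")
                c = int(gt[0] > 0) + int(gt[1] > 0)
                dos[i] = 2 - c if flip else c
            found[rec.id] = (dos, miss)

    absent = [s for s in spec_by_id if s not in found]
    if absent:
        raise ValueError(f"variant(s) absent from VCF: {', '.join(absent)}")

    order = {s: i for i, s in enumerate(vcf_samples)}
    row = np.array([order[s] for s in ph.sample_ids])
    dosage = np.column_stack([found[v.snp_id][0][row] for v in variant_specs])
    missing = np.column_stack([found[v.snp_id][1][row] for v in variant_specs])
    gm = GenotypeMatrix(list(ph.sample_ids), list(variant_specs), dosage, missing)
    return gm, ph


def write_vcf(gm: GenotypeMatrix, path: str | Path,
              contig: str = "1", start_pos: int = 1000) -> None:
    """Write a minimal GT-only VCF for a genotype matrix (synthetic contig).

    Each variant gets a dummy position; the risk-oriented allele is written as
    ALT (or as REF for flipped variants) against a fixed other allele so that
    :func:`read_genotypes` round-trips dosages exactly.
    """
    lines = ["##fileformat=VCFv4.2",
             f"##contig=<ID={contig}>",
             '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
             + "\t".join(gm.sample_ids)]
    other = {"A": "G", "C": "G", "G": "A", "T": "A"}
    for j, v in enumerate(gm.variants):
        oth = other.get(v.risk_allele, "A")
        ref, alt = (v.risk_allele, oth) if v.is_flipped else (oth, v.risk_allele)
        alt_count = 2 - gm.dosage[:, j] if v.is_flipped else gm.dosage[:, j]
        gts = []
        for i in range(len(gm.sample_ids)):
            if gm.missing_mask[i, j]:
                gts.append("./.")
            else:
                c = int(alt_count[i])
                gts.append(("0/0", "0/1", "1/1")[c])
        lines.append("\t".join(
            [contig, str(start_pos * (j + 1)), v.snp_id, ref, alt, ".", "PASS",
             ".", "GT"] + gts))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# basic operations
# ---------------------------------------------------------------------------

def split_by_status(gm: GenotypeMatrix, ph: PhenotypeVector
                    ) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Partition a genotype matrix into (cases, controls), order preserved."""
    status = dict(zip(ph.sample_ids, ph.is_case))
    unknown = [s for s in gm.sample_ids if s not in status]
    if unknown:
        raise ValueError(f"sample(s) without phenotype: {', '.join(unknown[:5])}")
    is_case = np.array([status[s] for s in gm.sample_ids], dtype=bool)
    return gm.subset_samples(is_case), gm.subset_samples(~is_case)


def allele_frequency(gm: GenotypeMatrix, snp_id: str) -> float:
    """Risk-allele frequency at one SNP: sum(dosage) / (2 * observed n)."""
    dos, miss = gm.column(snp_id)
    n_obs = int((~miss).sum())
    if n_obs == 0:
        raise ValueError(f"{snp_id}: all genotypes missing")
    return float(dos[~miss].sum()) / (2.0 * n_obs)
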