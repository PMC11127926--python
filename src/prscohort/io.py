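"""Readers and writers for the pipeline's external formats.

Three file families are handled here: tab-separated PRS weight tables
(one weighted effect-allele variant per row), VCF genotypes (read through
cyvcf2, with genotype-quality masking and imputation-quality filtering
applied at read time), and tab-separated per-sample phenotype tables.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PRSModelVariant",
    "PRSModel",
    "GenotypeMatrix",
    "CohortTable",
    "VcfReadLog",
    "read_prs_model",
    "write_prs_model",
    "read_genotypes_vcf",
    "write_genotypes_vcf",
    "read_cohort_table",
    "write_cohort_table",
]

COHORT_LABELS = ("case", "control")
VITAL_LABELS = ("alive", "deceased", "missing")

#: Autosome names accepted when sex chromosomes are excluded.
_SEX_CHROMS = {"X", "Y", "chrX", "chrY", "23", "24", "MT", "chrM", "M"}


@dataclass(frozen=True)
class PRSModelVariant:
    """One weighted variant of a PRS model.

    ``weight`` is the per-effect-allele log-odds-scale weight; the score
    contribution of a sample is ``weight * effect_allele_count``.
    """

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    weight: float

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"effect and other allele identical at {self.chrom}:{self.pos}"
            )
        if not np.isfinite(self.weight):
            raise ValueError(f"non-finite weight at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.effect_allele, self.other_allele)


@dataclass
class PRSModel:
    """An ordered collection of weighted variants for one disease."""

    disease_name: str
    variants: list[PRSModelVariant]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"PRS model {self.disease_name!r} has no variants")
        keys = [v.key for v in self.variants]
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate variant key in model: {dup}")

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def weights(self) -> np.ndarray:
        return np.array([v.weight for v in self.variants], dtype=float)


@dataclass
class VcfReadLog:
    """Bookkeeping produced by :func:`read_genotypes_vcf`."""

    n_records: int = 0
    n_genotypes_masked_gq: int = 0
    n_dropped_r2: int = 0
    n_dropped_filter: int = 0
    n_dropped_multiallelic: int = 0
    n_dropped_sex_chrom: int = 0
    n_split_multiallelic: int = 0


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-allele dosages with missingness.

    ``dosage`` is a float array; entries are 0, 1, 2 or NaN (missing).
    ``r2`` holds per-variant imputation quality where annotated (NaN =
    directly genotyped / unannotated).
    """

    sample_ids: list[str]
    variant_keys: list[tuple]  # (chrom, pos, ref, alt)
    dosage: np.ndarray
    r2: np.ndarray | None = None
    filter_pass: np.ndarray | None = None
    log: VcfReadLog = field(default_factory=VcfReadLog)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.variant_keys)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variant_keys)} variants"
            )
        if len(set(self.variant_keys)) != len(self.variant_keys):
            raise ValueError("duplicate variant keys in genotype matrix")
        finite = self.dosage[~np.isnan(self.dosage)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage values must be 0/1/2/NaN, found {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variant_keys)

    def take_variants(self, idx) -> "GenotypeMatrix":
        """Restrict to variants at integer positions ``idx`` (order kept)."""
        idx = np.asarray(idx, dtype=int)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            variant_keys=[self.variant_keys[i] for i in idx],
            dosage=self.dosage[:, idx].copy(),
            r2=None if self.r2 is None else self.r2[idx].copy(),
            filter_pass=None
            if self.filter_pass is None
            else self.filter_pass[idx].copy(),
            log=dataclasses.replace(self.log),
        )

    def take_samples(self, sample_ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            sample_ids=list(sample_ids),
            variant_keys=list(self.variant_keys),
            dosage=self.dosage[idx, :].copy(),
            r2=None if self.r2 is None else self.r2.copy(),
            filter_pass=None if self.filter_pass is None else self.filter_pass.copy(),
            log=dataclasses.replace(self.log),
        )


# ---------------------------------------------------------------------------
# PRS model tables


_CANONICAL_COLS = ["chrom", "pos", "effect_allele", "other_allele", "weight"]


def read_prs_model(path, disease_name: str | None = None) -> PRSModel:
    """Read a tab-separated PRS weight table.

    The canonical dialect has header columns ``chrom, pos, effect_allele,
    other_allele, weight``. A common "score file" dialect with columns
    ``id, effect_allele, other_allele, weight`` (``id`` = ``chrom:pos``)
    is accepted as well.

    Raises
    ------
    ValueError
        On a duplicate variant key (the key is named) or a non-numeric
        weight (the 1-based data row number is named).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns)
    if set(_CANONICAL_COLS) <= set(cols):
        chroms = df["chrom"].astype(str)
        poss = df["pos"]
    elif {"id", "effect_allele", "other_allele", "weight"} <= set(cols):
        parts = df["id"].str.split(":", n=1, expand=True)
        if parts.shape[1] != 2 or parts.isna().any().any():
            raise ValueError(f"{path}: 'id' column must be chrom:pos")
        chroms, poss = parts[0], parts[1]
    else:
        raise ValueError(
            f"{path}: expected columns {_CANONICAL_COLS} or id-keyed dialect, got {cols}"
        )

    variants: list[PRSModelVariant] = []
    seen: set[tuple] = set()
    for row_no, (c, p, ea, oa, w) in enumerate(
        zip(chroms, poss, df["effect_allele"], df["other_allele"], df["weight"]),
        start=1,
    ):
        try:
            weight = float(w)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: non-numeric weight {w!r} at data row {row_no}")
        v = PRSModelVariant(str(c), int(p), str(ea), str(oa), weight)
        if v.key in seen:
            raise ValueError(f"{path}: duplicate variant key {v.key}")
        seen.add(v.key)
        variants.append(v)
    return PRSModel(disease_name or path.stem, variants)


def write_prs_model(model: PRSModel, path) -> None:
    df = pd.DataFrame(
        [(v.chrom, v.pos, v.effect_allele, v.other_allele, v.weight) for v in model.variants],
        columns=_CANONICAL_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF genotypes


def read_genotypes_vcf(
    path,
    min_gq: float = 20.0,
    min_r2: float = 0.8,
    r2_field: str = "R2",
    drop_sex_chromosomes: bool = True,
    split_multiallelic: bool = False,
    apply_filter: bool = True,
) -> GenotypeMatrix:
    """Read diploid genotypes from a VCF into a dosage matrix.

    Quality handling mirrors the upstream joint-genotyping conventions:
    genotypes with ``GQ <= min_gq`` are set missing (records without a GQ
    annotation are left untouched — a filter cannot be applied to absent
    data); variants carrying an imputation-quality annotation
    (INFO ``r2_field``, with ``INFO`` accepted as an alias) with value
    ``<= min_r2`` are excluded, while unannotated variants are treated as
    directly genotyped and retained; records failing FILTER are excluded.
    Multiallelic records are rejected and counted unless
    ``split_multiallelic`` enables a naive per-ALT split.
    """
    from cyvcf2 import VCF

    path = str(path)
    if not Path(path).exists():
        raise FileNotFoundError(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare exceptions on bad files
        raise ValueError(f"unreadable VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ValueError(f"{path}: VCF has no samples / no GT field")

    log = VcfReadLog()
    keys: list[tuple] = []
    rows: list[np.ndarray] = []
    r2s: list[float] = []
    r2_aliases = (r2_field, "INFO") if r2_field != "INFO" else ("INFO",)

    for rec in vcf:
        log.n_records += 1
        if drop_sex_chromosomes and rec.CHROM in _SEX_CHROMS:
            log.n_dropped_sex_chrom += 1
            continue
        if apply_filter and rec.FILTER is not None:  # None == PASS in cyvcf2
            log.n_dropped_filter += 1
            continue
        r2 = np.nan
        for alias in r2_aliases:
            val = rec.INFO.get(alias)
            if val is not None:
                r2 = float(val)
                break
        if not np.isnan(r2) and r2 <= min_r2:
            log.n_dropped_r2 += 1
            continue

        gts = np.array(rec.genotypes, dtype=object)
        alleles = np.array([[g[0], g[1]] for g in gts], dtype=float)
        alleles[alleles < 0] = np.nan
        gq = rec.gt_quals  # -1 where absent
        has_gq = gq is not None and np.any(np.asarray(gq) >= 0)

        n_alt = len(rec.ALT)
        if n_alt > 1 and not split_multiallelic:
            log.n_dropped_multiallelic += 1
            continue
        alt_indices = range(1, n_alt + 1)
        if n_alt > 1:
            log.n_split_multiallelic += 1
        for ai, alt in zip(alt_indices, rec.ALT):
            dos = np.nansum(alleles == ai, axis=1).astype(float)
            dos[np.isnan(alleles).any(axis=1)] = np.nan
            if has_gq:
                mask = (np.asarray(gq, dtype=float) >= 0) & (
                    np.asarray(gq, dtype=float) <= min_gq
                )
                log.n_genotypes_masked_gq += int(np.sum(mask & ~np.isnan(dos)))
                dos[mask] = np.nan
            keys.append((rec.CHROM, rec.POS, rec.REF, alt))
            rows.append(dos)
            r2s.append(r2)

    dosage = (
        np.column_stack(rows) if rows else np.empty((len(sample_ids), 0), dtype=float)
    )
    return GenotypeMatrix(
        sample_ids=sample_ids,
        variant_keys=keys,
        dosage=dosage,
        r2=np.asarray(r2s, dtype=float),
        log=log,
    )


def write_genotypes_vcf(matrix: GenotypeMatrix, path, gq: np.ndarray | None = None) -> None:
    """Write a minimal VCF 4.2 with GT (and R2 INFO where present).

    The emitted file round-trips through :func:`read_genotypes_vcf`
    (dosages and missingness preserved exactly). Heterozygotes are
    written unphased as ``0/1``; missing dosages as ``./.``. An optional
    samples x variants ``gq`` array adds a per-genotype GQ field.
    """
    if matrix.n_variants == 0:
        raise ValueError("refusing to write a VCF with no variants")
    if gq is not None:
        gq = np.asarray(gq)
        if gq.shape != matrix.dosage.shape:
            raise ValueError("gq array shape does not match dosage matrix")
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation R-squared">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if gq is not None:
            fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        for chrom in dict.fromkeys(k[0] for k in matrix.variant_keys):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        fmt = "GT" if gq is None else "GT:GQ"
        for j, (chrom, pos, ref, alt) in enumerate(matrix.variant_keys):
            r2 = np.nan if matrix.r2 is None else matrix.r2[j]
            info = "." if np.isnan(r2) else f"R2={r2:g}"
            cells = []
            for i, d in enumerate(matrix.dosage[:, j]):
                cell = "./." if np.isnan(d) else gt_map[d]
                if gq is not None:
                    cell += f":{int(gq[i, j])}"
                cells.append(cell)
            fh.write(
                f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t{info}\t{fmt}\t"
                + "\t".join(cells)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Phenotype tables


_PHENO_COLS = [
    "sample_id",
    "cohort",
    "organ_site",
    "sex",
    "age",
    "vital_status",
    "survival_years",
]


@dataclass
class CohortTable:
    """Per-sample phenotype records backed by a pandas DataFrame.

    Required columns: sample_id, cohort (case/control), organ_site, sex,
    age, vital_status (alive/deceased/missing), survival_years. Extra
    columns (e.g. a treatment label) pass through untouched.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _PHENO_COLS if c not in self.df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns {missing}")
        df = self.df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        bad = set(df["cohort"]) - set(COHORT_LABELS)
        if bad:
            raise ValueError(f"unknown cohort label(s) {sorted(bad)}")
        df["vital_status"] = df["vital_status"].fillna("missing")
        bad = set(df["vital_status"]) - set(VITAL_LABELS)
        if bad:
            raise ValueError(f"unknown vital status label(s) {sorted(bad)}")
        df["survival_years"] = pd.to_numeric(df["survival_years"], errors="coerce")
        if (df["survival_years"].dropna() < 0).any():
            raise ValueError("negative survival_years")
        known = df["vital_status"] != "missing"
        if df.loc[known, "survival_years"].isna().any():
            raise ValueError("survival_years required when vital_status is known")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def subset(self, sample_ids) -> "CohortTable":
        sub = self.df.set_index("sample_id").loc[list(sample_ids)].reset_index()
        return CohortTable(sub)


def read_cohort_table(path) -> CohortTable:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return CohortTable(df)


def write_cohort_table(table: CohortTable, path) -> None:
    table.df.to_csv(path, sep="\t", index=False)
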