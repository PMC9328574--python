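"""Genotype, annotation and phenotype I/O.

Genotypes are modelled as allele-dosage matrices (samples x variants, values in
{0, 1, 2}, NaN for missing) read from either a PLINK BED/BIM/FAM triple or a
VCF. Variants are grouped into gene regions from a BED or GFF3 annotation;
region intervals are handled 1-based and closed on both ends (the GFF3
convention), with BED's 0-based half-open coordinates converted at parse time.

The PLINK binary triple is a fixed 2-bit-per-genotype format; a minimal
reader/writer for it lives here. VCF parsing goes through cyvcf2.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Variant",
    "GenotypeMatrix",
    "GeneRegion",
    "Phenotype",
    "GenotypeFormatError",
    "EmptyInputError",
    "read_genotypes",
    "write_plink",
    "write_vcf",
    "read_regions",
    "group_variants",
    "impute_missing",
    "filter_variants",
    "read_phenotype",
    "write_phenotype",
    "write_importance_table",
    "read_importance_table",
]


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed under the named standard."""


class EmptyInputError(ValueError):
    """Raised when a parsed input contains zero samples or zero variants."""


@dataclass(frozen=True)
class Variant:
    id: str
    chrom: str
    pos: int
    ref: str = "A"
    alt: str = "G"


@dataclass
class GenotypeMatrix:
    """Dosage matrix with sample/variant metadata.

    ``dosages`` is ``float64`` with NaN marking missing genotypes; observed
    entries are allele counts in {0, 1, 2} (alt-allele dosage).
    """

    samples: list[str]
    variants: list[Variant]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError(f"{len(self.samples)} samples but {n} dosage rows")
        if m != len(self.variants):
            raise ValueError(f"{len(self.variants)} variants but {m} dosage columns")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_frequencies(self) -> np.ndarray:
        """Alt-allele frequency per variant from observed (non-missing) entries."""
        return np.nanmean(self.dosages, axis=0) / 2.0


@dataclass(frozen=True)
class GeneRegion:
    """A named variant group: ordered column indices into a GenotypeMatrix."""

    gene_id: str
    variant_indices: np.ndarray

    def __post_init__(self) -> None:
        idx = np.asarray(self.variant_indices, dtype=int)
        if idx.size == 0:
            raise ValueError(f"region {self.gene_id}: empty variant index list")
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"region {self.gene_id}: indices must be strictly increasing")
        object.__setattr__(self, "variant_indices", idx)

    @property
    def n_k(self) -> int:
        return len(self.variant_indices)

    def dosage_block(self, genotypes: GenotypeMatrix) -> np.ndarray:
        return genotypes.dosages[:, self.variant_indices]


@dataclass
class Phenotype:
    values: np.ndarray
    outcome_type: str  # "continuous" | "binary"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.outcome_type not in ("continuous", "binary"):
            raise ValueError(f"unknown outcome_type {self.outcome_type!r}")
        if self.outcome_type == "binary":
            vals = self.values[~np.isnan(self.values)]
            if not np.all(np.isin(vals, [0.0, 1.0])):
                raise ValueError("binary phenotype values must be in {0, 1}")

    @property
    def n(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# PLINK BED/BIM/FAM
# ---------------------------------------------------------------------------

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.00 SNP-major
# 2-bit codes, counting ALT (the BIM A1 allele): 00=hom A1, 10=het, 11=hom A2, 01=missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def _plink_paths(path: str | Path) -> tuple[Path, Path, Path]:
    p = Path(path)
    stem = p.with_suffix("") if p.suffix == ".bed" else p
    return stem.with_suffix(".bed"), stem.with_suffix(".bim"), stem.with_suffix(".fam")


def _read_plink(path: str | Path) -> GenotypeMatrix:
    bed, bim, fam = _plink_paths(path)
    for f in (bed, bim, fam):
        if not f.exists():
            raise GenotypeFormatError(f"missing PLINK file: {f}")
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    samples = fam_df[1].tolist()
    bim_df = pd.read_csv(bim, sep=r"\s+", header=None, dtype=str)
    variants = [
        Variant(id=r[1], chrom=str(r[0]), pos=int(r[3]), ref=r[5], alt=r[4])
        for r in bim_df.itertuples(index=False)
    ]
    n, m = len(samples), len(variants)
    if n == 0 or m == 0:
        raise EmptyInputError(f"{path}: zero samples or zero variants")
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise GenotypeFormatError(f"{bed}: bad magic bytes (not SNP-major PLINK v1 BED)")
    bytes_per_variant = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_variant * m:
        raise GenotypeFormatError(f"{bed}: unexpected length for {n} samples x {m} variants")
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (blocks[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write a PLINK BED/BIM/FAM triple (SNP-major, v1)."""
    bed, bim, fam = _plink_paths(prefix)
    with open(fam, "w") as fh:
        for s in genotypes.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    with open(bim, "w") as fh:
        for v in genotypes.variants:
            fh.write(f"{v.chrom}\t{v.id}\t0\t{v.pos}\t{v.alt}\t{v.ref}\n")
    n = genotypes.n_samples
    dos = genotypes.dosages
    dosage_to_code = {2.0: 0, 1.0: 2, 0.0: 3}
    with open(bed, "wb") as fh:
        fh.write(_PLINK_MAGIC)
        for j in range(genotypes.n_variants):
            codes = np.full(((n + 3) // 4) * 4, 0, dtype=np.uint8)
            for i in range(n):
                x = dos[i, j]
                codes[i] = 1 if np.isnan(x) else dosage_to_code[float(x)]
            packed = (
                codes[0::4] | (codes[1::4] << 2) | (codes[2::4] << 4) | (codes[3::4] << 6)
            )
            fh.write(packed.astype(np.uint8).tobytes())


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _read_vcf(path: str | Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise GenotypeFormatError("cyvcf2 is required to read VCF files") from exc
    if not os.path.exists(path):
        raise GenotypeFormatError(f"no such file: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise GenotypeFormatError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        alt = rec.ALT[0] if rec.ALT else "."
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variants.append(Variant(id=vid, chrom=str(rec.CHROM), pos=rec.POS, ref=rec.REF, alt=alt))
        # gt_types: 0=HOM_REF, 1=HET, 2=UNKNOWN, 3=HOM_ALT
        gt = rec.gt_types.astype(float)
        dos = np.choose(gt.astype(int), [0.0, 1.0, np.nan, 2.0])
        rows.append(dos)
    if not samples or not rows:
        raise EmptyInputError(f"{path}: zero samples or zero variants")
    return GenotypeMatrix(samples=samples, variants=variants, dosages=np.array(rows).T)


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with hard GT calls."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(v.chrom for v in genotypes.variants):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, v in enumerate(genotypes.variants):
            calls = [
                "./." if np.isnan(x) else gt_map[float(x)] for x in genotypes.dosages[:, j]
            ]
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from PLINK (``bed``) or VCF (``vcf``); inferred from suffix if None."""
    if format is None:
        s = str(path)
        if s.endswith(".bed") or os.path.exists(s + ".bed"):
            format = "bed"
        elif s.endswith((".vcf", ".vcf.gz")):
            format = "vcf"
        else:
            raise GenotypeFormatError(f"cannot infer genotype format for {path}")
    if format == "bed":
        return _read_plink(path)
    if format == "vcf":
        return _read_vcf(path)
    raise GenotypeFormatError(f"unknown genotype format {format!r}")


# ---------------------------------------------------------------------------
# Region annotation and variant grouping
# ---------------------------------------------------------------------------


def _gff3_attr(attrs: str, keys: Iterable[str]) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for k in keys:
        if k in fields:
            return fields[k]
    return None


def read_regions(path: str | Path) -> pd.DataFrame:
    """Parse a BED or GFF3 region annotation.

    Returns a DataFrame with columns ``gene_id, chrom, start, end`` where
    start/end are 1-based and closed on both ends. BED rows (0-based,
    half-open) are converted; GFF3 rows are taken as-is, keeping ``gene``
    features if any are present.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#") or not line.strip():
                    continue
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 9:
                    raise ValueError(f"{path}: malformed GFF3 line: {line.strip()!r}")
                gid = _gff3_attr(parts[8], ("ID", "Name", "gene_id"))
                rows.append(
                    {
                        "gene_id": gid or f"{parts[0]}:{parts[3]}-{parts[4]}",
                        "chrom": parts[0],
                        "start": int(parts[3]),
                        "end": int(parts[4]),
                        "type": parts[2],
                    }
                )
        df = pd.DataFrame(rows)
        if (df["type"] == "gene").any():
            df = df[df["type"] == "gene"].reset_index(drop=True)
        return df[["gene_id", "chrom", "start", "end"]]
    # BED: chrom, start(0-based), end(exclusive), name
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns")
    out = pd.DataFrame(
        {
            "gene_id": df[3].astype(str)
            if df.shape[1] > 3
            else [f"region{i}" for i in range(len(df))],
            "chrom": df[0].astype(str),
            "start": df[1].astype(int) + 1,
            "end": df[2].astype(int),
        }
    )
    return out


def group_variants(genotypes: GenotypeMatrix, annotation: pd.DataFrame) -> list[GeneRegion]:
    """Assign variants to gene regions by closed-interval membership.

    A variant inside multiple regions goes to the first region in annotation
    order (a warning is logged); variants in no region are dropped, as are
    regions with no assigned variants.
    """
    required = {"gene_id", "chrom", "start", "end"}
    if not required.issubset(annotation.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    chroms = np.array([v.chrom for v in genotypes.variants])
    pos = np.array([v.pos for v in genotypes.variants])
    assigned = np.zeros(len(pos), dtype=bool)
    regions: list[GeneRegion] = []
    for row in annotation.itertuples(index=False):
        inside = (chroms == str(row.chrom)) & (pos >= int(row.start)) & (pos <= int(row.end))
        overlap = inside & assigned
        if overlap.any():
            logger.warning(
                "%d variant(s) in %s already assigned to an earlier region; keeping first assignment",
                int(overlap.sum()),
                row.gene_id,
            )
        take = np.flatnonzero(inside & ~assigned)
        if take.size == 0:
            continue
        assigned[take] = True
        regions.append(GeneRegion(gene_id=str(row.gene_id), variant_indices=take))
    return regions


# ---------------------------------------------------------------------------
# Imputation and filters
# ---------------------------------------------------------------------------


def impute_missing(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the per-variant mean of observed dosages."""
    dos = genotypes.dosages
    if not np.isnan(dos).any():
        return genotypes
    all_missing = np.all(np.isnan(dos), axis=0)
    if all_missing.any():
        bad = genotypes.variants[int(np.flatnonzero(all_missing)[0])].id
        raise ValueError(f"variant {bad}: all genotypes missing, cannot impute")
    col_means = np.nanmean(dos, axis=0)
    out = dos.copy()
    rows, cols = np.where(np.isnan(out))
    out[rows, cols] = col_means[cols]
    return GenotypeMatrix(
        samples=list(genotypes.samples), variants=list(genotypes.variants), dosages=out
    )


def filter_variants(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.0,
    max_missing_rate: float = 1.0,
) -> GenotypeMatrix:
    """Drop variants with MAF below ``maf_min`` or missing rate above the cap."""
    freq = genotypes.allele_frequencies()
    maf = np.minimum(freq, 1 - freq)
    miss = np.isnan(genotypes.dosages).mean(axis=0)
    keep = np.flatnonzero((maf >= maf_min) & (miss <= max_missing_rate))
    if keep.size == 0:
        raise EmptyInputError("no variants pass the filters")
    return GenotypeMatrix(
        samples=list(genotypes.samples),
        variants=[genotypes.variants[j] for j in keep],
        dosages=genotypes.dosages[:, keep].copy(),
    )


# ---------------------------------------------------------------------------
# Phenotype and result tables
# ---------------------------------------------------------------------------


def read_phenotype(path: str | Path, samples: Sequence[str] | None = None) -> Phenotype:
    """Read a ``sample_id<TAB>phenotype`` table; align to ``samples`` if given."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "phenotype" not in df.columns:
        raise ValueError(f"{path}: expected header 'sample_id\\tphenotype'")
    if samples is not None:
        df = df.set_index("sample_id")
        missing = [s for s in samples if s not in df.index]
        if missing:
            raise ValueError(f"{path}: no phenotype for samples {missing[:5]}")
        values = df.loc[list(samples), "phenotype"].to_numpy(dtype=float)
    else:
        values = df["phenotype"].to_numpy(dtype=float)
    observed = values[~np.isnan(values)]
    outcome_type = "binary" if np.all(np.isin(observed, [0.0, 1.0])) else "continuous"
    return Phenotype(values=values, outcome_type=outcome_type)


def write_phenotype(phenotype: Phenotype, samples: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\n")
        for s, v in zip(samples, phenotype.values):
            fh.write(f"{s}\t{float(v)!r}\n")


def write_importance_table(results: Sequence, path: str | Path) -> None:
    """Write per-gene screening results as a TSV (gene order preserved)."""
    if not results:
        raise ValueError("no results to write")
    with open(path, "w") as fh:
        fh.write("gene_id\tn_variants\tdelta\tse\tz\tp\n")
        for r in results:
            fh.write(
                f"{r.gene_id}\t{r.n_variants}\t{float(r.delta)!r}\t{float(r.se)!r}\t{float(r.z)!r}\t{float(r.p)!r}\n"
            )


def read_importance_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
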