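"""File formats: IBD segment tables, genotypes, phenotype/covariate tables
and eigenvec-style component files.

IBD segment files are flat delimited text.  Because detection tools differ
in column layout, parsing is driven by an :class:`IBDDialect` that maps the
six semantic roles (two sample ids, chromosome, physical start/end, genetic
length) onto column indices.  Two presets are built in: ``"ilash"`` for the
11-column iLASH output and ``"generic6"`` for the six roles in order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "IBDDialect",
    "SampleTable",
    "GenotypeMatrix",
    "DIALECT_PRESETS",
    "read_ibd_segments",
    "read_genotypes",
    "write_genotypes_vcf",
    "write_components",
    "read_components",
    "read_pheno_table",
    "write_pheno_table",
    "read_labels",
    "write_labels",
]

_ROLES = ("id_a", "id_b", "chromosome", "start_bp", "end_bp", "length_cM")


@dataclass(frozen=True)
class IBDDialect:
    """Column layout of an IBD segment file.

    ``column_map`` assigns a 0-based column index to each of the six roles;
    ``delimiter=None`` splits on any whitespace.
    """

    column_map: Dict[str, int]
    delimiter: Optional[str] = "\t"
    has_header: bool = False
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        missing = set(_ROLES) - set(self.column_map)
        if missing:
            raise ValueError(f"dialect missing roles: {sorted(missing)}")
        idx = [self.column_map[r] for r in _ROLES]
        if len(set(idx)) != len(idx):
            raise ValueError("dialect maps two roles to the same column")
        if min(idx) < 0:
            raise ValueError("column indices must be non-negative")

    @property
    def max_column(self) -> int:
        return max(self.column_map[r] for r in _ROLES)


#: iLASH writes family/individual id pairs for both haplotypes plus SNP
#: names; only the individual ids, coordinates and the cM length matter here.
DIALECT_PRESETS: Dict[str, IBDDialect] = {
    "ilash": IBDDialect(
        column_map={
            "id_a": 1,
            "id_b": 3,
            "chromosome": 4,
            "start_bp": 5,
            "end_bp": 6,
            "length_cM": 9,
        },
        delimiter="\t",
        has_header=False,
        preset_name="ilash",
    ),
    "generic6": IBDDialect(
        column_map={r: i for i, r in enumerate(_ROLES)},
        delimiter=None,
        has_header=False,
        preset_name="generic6",
    ),
}


class SampleTable:
    """Ordered, unique sample identifiers with an id -> row index."""

    __slots__ = ("sample_ids", "index")

    def __init__(self, sample_ids: Sequence[str]):
        ids = list(sample_ids)
        self.index: Dict[str, int] = {s: i for i, s in enumerate(ids)}
        if len(self.index) != len(ids):
            raise ValueError("sample ids are not unique")
        self.sample_ids: List[str] = ids

    def __len__(self) -> int:
        return len(self.sample_ids)

    def __contains__(self, sid: str) -> bool:
        return sid in self.index

    def __getitem__(self, i: int) -> str:
        return self.sample_ids[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleTable) and other.sample_ids == self.sample_ids

    def __repr__(self) -> str:
        return f"SampleTable(n={len(self)})"


@dataclass
class GenotypeMatrix:
    """Biallelic autosomal genotypes as alternate-allele dosages.

    ``dosages`` is samples x variants int8 with -1 for missing.  Variant
    metadata lives in a DataFrame with columns chromosome/position/ref/alt/id
    (positions 1-based).  Allele frequencies are computed over non-missing
    entries and cached.
    """

    samples: SampleTable
    variants: pd.DataFrame
    dosages: np.ndarray
    _freqs: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if n != len(self.samples):
            raise ValueError("dosage rows do not match sample count")
        if m != len(self.variants):
            raise ValueError("dosage columns do not match variant count")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def _count_alleles(self):
        """Per-variant (alt count, non-missing 2n), chunked to bound temps."""
        d = self.dosages
        m = d.shape[1]
        alt = np.empty(m, dtype=np.int64)
        nonmiss = np.empty(m, dtype=np.int64)
        for s in range(0, m, 16384):
            blk = d[:, s : s + 16384]
            miss = blk < 0
            alt[s : s + blk.shape[1]] = np.where(miss, 0, blk).sum(
                axis=0, dtype=np.int64
            )
            nonmiss[s : s + blk.shape[1]] = blk.shape[0] - miss.sum(axis=0)
        return alt, 2 * nonmiss

    @property
    def allele_freqs(self) -> np.ndarray:
        """Alternate-allele frequency per variant over non-missing genotypes."""
        if self._freqs is None:
            alt, denom = self._count_alleles()
            with np.errstate(invalid="ignore"):
                self._freqs = np.where(denom > 0, alt / np.maximum(denom, 1), np.nan)
        return self._freqs

    @property
    def minor_allele_freqs(self) -> np.ndarray:
        p = self.allele_freqs
        return np.minimum(p, 1.0 - p)

    @property
    def minor_allele_counts(self) -> np.ndarray:
        alt, tot = self._count_alleles()
        return np.minimum(alt, tot - alt)

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[np.where(mask)[0]].reset_index(drop=True)
            if mask.dtype == bool
            else self.variants.iloc[mask].reset_index(drop=True),
            dosages=self.dosages[:, mask],
        )


def _parse_chromosome(token: str) -> Optional[int]:
    t = token.lower().removeprefix("chr")
    try:
        c = int(t)
    except ValueError:
        return None
    return c if 1 <= c <= 22 else None


def read_ibd_segments(
    path: Union[str, Path],
    dialect: Union[str, IBDDialect] = "generic6",
) -> Iterator["IBDSegment"]:
    """Stream IBD segments from a delimited text file.

    Self-pairs (``id_a == id_b``) and non-autosomal rows are skipped with a
    logged count; malformed coordinates or negative lengths raise with the
    offending row number.
    """
    from .ibd_graph import IBDSegment  # local import avoids a module cycle

    if isinstance(dialect, str):
        try:
            dialect = DIALECT_PRESETS[dialect]
        except KeyError:
            raise ValueError(
                f"unknown dialect preset {dialect!r}; "
                f"available: {sorted(DIALECT_PRESETS)}"
            ) from None
    cm = dialect.column_map
    need = dialect.max_column + 1
    n_self = n_nonauto = n_rows = 0
    with open(path, "rt") as fh:
        for lineno, line in enumerate(fh, start=1):
            if dialect.has_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split(dialect.delimiter)
            if len(fields) < need:
                raise ValueError(
                    f"{path}:{lineno}: expected at least {need} columns, "
                    f"got {len(fields)}"
                )
            id_a = fields[cm["id_a"]]
            id_b = fields[cm["id_b"]]
            if id_a == id_b:
                n_self += 1
                continue
            chrom = _parse_chromosome(fields[cm["chromosome"]])
            if chrom is None:
                n_nonauto += 1
                continue
            try:
                start = int(float(fields[cm["start_bp"]]))
                end = int(float(fields[cm["end_bp"]]))
                length = float(fields[cm["length_cM"]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field: {exc}")
            if length < 0 or not math.isfinite(length):
                raise ValueError(f"{path}:{lineno}: invalid length_cM {length}")
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end_bp {end} <= start_bp {start}")
            n_rows += 1
            yield IBDSegment(id_a, id_b, chrom, start, end, length)
    if n_self or n_nonauto:
        logger.info(
            "read_ibd_segments(%s): %d segments, skipped %d self-pairs, "
            "%d non-autosomal rows",
            path,
            n_rows,
            n_self,
            n_nonauto,
        )


# ---------------------------------------------------------------------------
# genotypes


def _infer_format(path: Path) -> str:
    s = path.name.lower()
    if s.endswith((".vcf", ".vcf.gz", ".vcf.bgz")):
        return "vcf"
    if s.endswith(".bed"):
        return "plink_bed"
    raise ValueError(f"cannot infer genotype format from {path.name!r}")


def read_genotypes(
    path: Union[str, Path], format: Optional[str] = None
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or PLINK .bed/.bim/.fam.

    Only biallelic autosomal SNPs are retained (multi-allelic records and
    indels are dropped with a logged count).  Dosages count the alternate
    allele; missing genotypes stay missing (-1) and are imputed downstream,
    not here.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "plink_bed":
        return _read_plink_bed(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = SampleTable(list(vcf.samples))
    cols: List[np.ndarray] = []
    meta: List[Tuple[int, int, str, str, str]] = []
    n_dropped = 0
    for v in vcf:
        chrom = _parse_chromosome(v.CHROM)
        if chrom is None or len(v.ALT) != 1 or not v.is_snp:
            n_dropped += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = v.gt_types.astype(np.int8)
        g[g == 3] = -1
        cols.append(g)
        meta.append((chrom, v.POS, v.REF, v.ALT[0], v.ID or f"{v.CHROM}:{v.POS}"))
    vcf.close()
    if n_dropped:
        logger.info("read_genotypes(%s): dropped %d non-SNP/multi-allelic/"
                    "non-autosomal records", path, n_dropped)
    dosages = (
        np.stack(cols, axis=1) if cols else np.empty((len(samples), 0), dtype=np.int8)
    )
    variants = pd.DataFrame(
        meta, columns=["chromosome", "position", "ref", "alt", "id"]
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


# 2-bit PLINK codes per genotype: 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Dosage counts A1 (the first allele column of the .bim file).
_PLINK_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)
_PLINK_LUT = np.zeros((256, 4), dtype=np.int8)
for _byte in range(256):
    for _k in range(4):
        _PLINK_LUT[_byte, _k] = _PLINK_DECODE[(_byte >> (2 * _k)) & 0b11]


def _read_plink_bed(path: Path) -> GenotypeMatrix:
    stem = path.with_suffix("")
    bim = stem.with_suffix(".bim")
    fam = stem.with_suffix(".fam")
    for companion in (bim, fam):
        if not companion.exists():
            raise FileNotFoundError(f"missing PLINK companion file {companion}")
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chromosome", "id", "cm", "position", "a1", "a2"],
        dtype={"chromosome": str, "id": str, "a1": str, "a2": str},
    )
    samples = SampleTable(fam_df[1].tolist())
    n, m = len(samples), len(bim_df)

    raw = np.fromfile(path, dtype=np.uint8)
    if raw[:3].tobytes() != b"\x6c\x1b\x01":
        raise ValueError(f"{path} is not a SNP-major PLINK .bed file")
    bpr = (n + 3) // 4  # bytes per variant row
    body = raw[3:]
    if body.size != bpr * m:
        raise ValueError(
            f"{path}: payload size {body.size} inconsistent with "
            f"{n} samples x {m} variants"
        )
    decoded = _PLINK_LUT[body.reshape(m, bpr)].reshape(m, bpr * 4)[:, :n]

    chrom = bim_df["chromosome"].map(_parse_chromosome)
    snp = (bim_df["a1"].str.len() == 1) & (bim_df["a2"].str.len() == 1)
    keep = chrom.notna() & snp
    if (~keep).any():
        logger.info(
            "read_genotypes(%s): dropped %d non-SNP/non-autosomal variants",
            path,
            int((~keep).sum()),
        )
    decoded = decoded[keep.to_numpy()]
    bim_df = bim_df[keep].reset_index(drop=True)
    variants = pd.DataFrame(
        {
            "chromosome": bim_df["chromosome"].map(_parse_chromosome).astype(int),
            "position": bim_df["position"].astype(int),
            "ref": bim_df["a2"],
            "alt": bim_df["a1"],
            "id": bim_df["id"],
        }
    )
    return GenotypeMatrix(
        samples=samples, variants=variants, dosages=decoded.T.copy()
    )


def write_genotypes_vcf(g: GenotypeMatrix, path: Union[str, Path]) -> None:
    """Write a minimal uncompressed VCF 4.2 with GT fields only."""
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=spc\n")
        for c in sorted(g.variants["chromosome"].unique()):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.samples.sample_ids)
            + "\n"
        )
        V = g.variants
        for j in range(g.n_variants):
            row = V.iloc[j]
            gts = "\t".join(gt_codes[int(x)] for x in g.dosages[:, j])
            fh.write(
                f"{row.chromosome}\t{row.position}\t{row.id}\t{row.ref}\t"
                f"{row.alt}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# component / phenotype / label tables (PLINK-convention FID IID ...)


def write_components(
    path: Union[str, Path],
    samples: SampleTable,
    vectors: np.ndarray,
    label_prefix: str = "SPC",
) -> None:
    """Write an eigenvec-style file: FID IID <prefix>1 ... <prefix>k.

    FID is duplicated from IID; values carry >= 10 significant digits so
    that a read-back is lossless to well below solver tolerance.
    """
    vectors = np.asarray(vectors)
    if vectors.ndim == 1:
        vectors = vectors[:, None]
    if vectors.shape[0] != len(samples):
        raise ValueError(
            f"component rows ({vectors.shape[0]}) != sample count ({len(samples)})"
        )
    with open(path, "wt") as fh:
        for i, sid in enumerate(samples.sample_ids):
            vals = " ".join(f"{x:.12g}" for x in vectors[i])
            fh.write(f"{sid} {sid} {vals}".rstrip() + "\n")


def read_components(path: Union[str, Path]) -> Tuple[SampleTable, np.ndarray]:
    """Read an eigenvec-style file back into (samples, n x k array)."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype={0: str, 1: str})
    samples = SampleTable(df[1].tolist())
    mat = df.iloc[:, 2:].to_numpy(dtype=float)
    return samples, mat


def write_pheno_table(
    path: Union[str, Path],
    samples: SampleTable,
    values: np.ndarray,
    name: str = "pheno",
) -> None:
    """Write a whitespace-delimited FID IID <name> phenotype file."""
    values = np.asarray(values, dtype=float)
    if values.shape[0] != len(samples):
        raise ValueError("phenotype length != sample count")
    with open(path, "wt") as fh:
        fh.write(f"FID IID {name}\n")
        for sid, v in zip(samples.sample_ids, values):
            fh.write(f"{sid} {sid} {v:.12g}\n")


def read_pheno_table(path: Union[str, Path]) -> pd.DataFrame:
    """Read FID IID value... into a DataFrame indexed by IID."""
    with open(path, "rt") as fh:
        first = fh.readline().split()
    header = 0 if first[:2] in (["FID", "IID"], ["#FID", "IID"]) else None
    df = pd.read_csv(path, sep=r"\s+", header=header, dtype={0: str, 1: str})
    if header is None:
        df.columns = ["FID", "IID"] + [f"V{i}" for i in range(1, df.shape[1] - 1)]
    else:
        df.columns = ["FID", "IID"] + list(df.columns[2:])
    return df.set_index("IID")


def write_labels(
    path: Union[str, Path], samples: SampleTable, labels: np.ndarray
) -> None:
    """Write per-sample deme coordinates: sample_id, row, col (TSV)."""
    labels = np.asarray(labels, dtype=int)
    pd.DataFrame(
        {"sample_id": samples.sample_ids, "row": labels[:, 0], "col": labels[:, 1]}
    ).to_csv(path, sep="\t", index=False)


def read_labels(path: Union[str, Path]) -> Tuple[SampleTable, np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleTable(df["sample_id"].tolist()), df[["row", "col"]].to_numpy(int)
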