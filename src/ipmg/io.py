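"""Readers and writers for every external format used by the pipeline.

Expression tables, clinical tables, leukocyte/purity fractions and genotype
dosages travel as TSV; somatic mutations as a MAF-dialect TSV; pathways as
GMT; coding sequences as FASTA records carrying one flanking base on each
side of the CDS. All downstream stages receive data only through the types
defined here and never read files directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("ipmg")

# canonical variant-class vocabulary used by the mutation-correction stage
VARIANT_CLASSES = ("missense", "nonsense", "silent", "frameshift", "splice_site", "other")

_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "silent": "silent",
    "synonymous": "silent",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift": "frameshift",
    "splice_site": "splice_site",
    "splice_region": "splice_site",
}

#: variant classes that zero the protein-activity score
LOSS_OF_FUNCTION_CLASSES = frozenset({"frameshift", "splice_site"})


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric table with a processing-stage tag.

    ``values`` is a float DataFrame indexed by gene id with sample-id
    columns; NaN marks missing cells until the imputation stage.
    """

    values: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id: {dup!r}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise ValueError(f"duplicate sample id: {dup!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def with_values(self, values: pd.DataFrame, stage: str) -> "ExpressionMatrix":
        return replace(self, values=values, stage=stage)


@dataclass
class MutationTable:
    """Per-sample somatic mutation records.

    ``records`` columns: gene, sample, variant_class, ref, alt, cds_pos
    (1-based within the coding frame; <=0 when unknown), context (the
    5'-ref-3' trinucleotide, empty when unresolvable).
    """

    records: pd.DataFrame
    n_dropped: int = 0
    n_unknown_class: int = 0

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class PathwayDB:
    """Named gene sets; member lists are deduplicated and order-preserving."""

    sets: dict[str, list[str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def filter_names(self, keywords: tuple[str, ...] = ("cancer", "disease")) -> "PathwayDB":
        """Drop sets whose name contains any keyword (case-insensitive)."""
        lowered = tuple(k.lower() for k in keywords)
        kept = {
            name: genes
            for name, genes in self.sets.items()
            if not any(k in name.lower() for k in lowered)
        }
        return PathwayDB(kept)


# ---------------------------------------------------------------------------
# expression

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV; empty cells and 'NA' become NaN.

    Duplicate gene or sample ids and non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        raw = df[col].replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})
        try:
            out[col] = raw.astype(float)
        except ValueError as exc:
            bad = raw[pd.to_numeric(raw, errors="coerce").isna() & raw.notna()]
            gene = bad.index[0] if len(bad) else "?"
            raise ValueError(
                f"non-numeric expression value at gene {gene!r}, sample {col!r}"
            ) from exc
    return ExpressionMatrix(out, stage="raw")


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


# ---------------------------------------------------------------------------
# clinical / fractions

REQUIRED_CLINICAL = ("sample_id", "cancer_type", "treatment_class", "time_days", "event")
TREATMENT_CLASSES = ("immunotherapy", "non_immunotherapy")


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the clinical table; validates ids, times and treatment classes."""
    clin = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cancer_type": str})
    missing = [c for c in REQUIRED_CLINICAL if c not in clin.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if clin["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in clinical table")
    if (clin["time_days"] < 0).any():
        raise ValueError("negative survival time in clinical table")
    if clin["cancer_type"].isna().any():
        raise ValueError("sample without cancer_type in clinical table")
    bad = set(clin["treatment_class"]) - set(TREATMENT_CLASSES)
    if bad:
        raise ValueError(f"unknown treatment_class values: {sorted(bad)}")
    clin["event"] = clin["event"].astype(int)
    return clin.reset_index(drop=True)


def write_clinical(clin: pd.DataFrame, path: str | Path) -> None:
    clin.to_csv(path, sep="\t", index=False)


def read_fractions(path: str | Path) -> pd.DataFrame:
    """Per-sample leukocyte fraction and tumor purity, indexed by sample_id."""
    fr = pd.read_csv(path, sep="\t", dtype={"sample_id": str}).set_index("sample_id")
    for col in ("leukocyte_fraction", "tumor_purity"):
        if col not in fr.columns:
            raise ValueError(f"fraction table missing column {col!r}")
        vals = fr[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{col} outside [0, 1]")
    return fr


def write_fractions(fr: pd.DataFrame, path: str | Path) -> None:
    fr.to_csv(path, sep="\t", index=True, index_label="sample_id")


# ---------------------------------------------------------------------------
# mutations (MAF dialect)

MAF_COLUMNS = ("gene", "sample", "variant_classification", "ref", "alt")


def read_maf(path: str | Path, cds: dict[str, str] | None = None) -> MutationTable:
    """Read a MAF-dialect TSV into a :class:`MutationTable`.

    Variant classifications are mapped onto the canonical vocabulary;
    unknown labels become "other" (with a warning count), rows with
    ref == alt are rejected. When a row lacks an explicit trinucleotide
    ``context`` it is reconstructed from ``cds`` (flanked CDS sequences,
    see :func:`read_cds`) via the 1-based ``cds_pos`` column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"MAF missing columns: {missing}")

    n_dropped = int((df["ref"] == df["alt"]).sum())
    if n_dropped:
        logger.warning("read_maf: dropped %d records with ref == alt", n_dropped)
    df = df[df["ref"] != df["alt"]].copy()

    cls = df["variant_classification"].str.lower().map(_MAF_CLASS_MAP)
    n_unknown = int(cls.isna().sum())
    if n_unknown:
        logger.warning("read_maf: %d records with unknown variant class -> 'other'", n_unknown)
    df["variant_class"] = cls.fillna("other")

    if "cds_pos" in df.columns:
        pos = pd.to_numeric(df["cds_pos"], errors="coerce").fillna(0).astype(int)
    else:
        pos = pd.Series(0, index=df.index)
    df["cds_pos"] = pos

    if "context" not in df.columns:
        df["context"] = ""
    if cds is not None:
        need = (df["context"] == "") & (df["cds_pos"] > 0)
        df.loc[need, "context"] = [
            trinucleotide_context(cds.get(g, ""), p)
            for g, p in zip(df.loc[need, "gene"], df.loc[need, "cds_pos"])
        ]

    records = df[["gene", "sample", "variant_class", "ref", "alt", "cds_pos", "context"]]
    return MutationTable(records.reset_index(drop=True), n_dropped=n_dropped,
                         n_unknown_class=n_unknown)


def write_maf(muts: MutationTable, path: str | Path) -> None:
    df = muts.records.rename(columns={"variant_class": "variant_classification"})
    df.to_csv(path, sep="\t", index=False)


def trinucleotide_context(flanked_cds: str, cds_pos: int) -> str:
    """5'-ref-3' context of a 1-based CDS position from a flanked sequence.

    ``flanked_cds`` carries exactly one extra base on each side of the CDS,
    so CDS position ``p`` sits at string index ``p`` and its flanks at
    ``p - 1`` and ``p + 1``. Returns "" when out of range.
    """
    i = cds_pos  # 1-based CDS position == 0-based index into flanked string
    if not flanked_cds or i < 1 or i + 1 >= len(flanked_cds):
        return ""
    return flanked_cds[i - 1 : i + 2]


# ---------------------------------------------------------------------------
# gene sets

def read_gmt(path: str | Path, filter_keywords: tuple[str, ...] | None = None) -> PathwayDB:
    """Read a GMT file; dedup members, drop sets with < 2 members.

    ``filter_keywords`` removes sets whose name contains any keyword
    (case-insensitive); pass ``("cancer", "disease")`` for the default
    disease-pathway removal, or None to keep everything.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            genes = list(dict.fromkeys(g for g in parts[2:] if g))
            if len(genes) < 2:
                logger.warning("read_gmt: set %s has < 2 members after dedup; excluded", name)
                continue
            sets[name] = genes
    db = PathwayDB(sets)
    if filter_keywords:
        db = db.filter_names(filter_keywords)
    return db


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in db.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# coding sequences

def read_cds(path: str | Path) -> dict[str, str]:
    """Read flanked CDS FASTA: each record is 5'flank + CDS + 3'flank.

    Record length must therefore be ``3k + 2``. Returns gene -> sequence
    (uppercase).
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if (len(seq) - 2) % 3 != 0:
            raise ValueError(f"CDS for {rec.id} has length {len(seq) - 2} not divisible by 3")
        out[rec.id] = seq
    return out


def write_cds(cds: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=gene, description="flanked_cds") for gene, seq in cds.items()]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# genotypes

@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage matrix with SNP and gene coordinates.

    ``dosages``: DataFrame indexed by sample_id, SNP-id columns, values in
    {0, 1, 2}. ``snp_coords``/``gene_coords``: BED-like frames with columns
    chrom, start, end indexed by SNP/gene id (half-open, 0-based).
    """

    dosages: pd.DataFrame
    snp_coords: pd.DataFrame
    gene_coords: pd.DataFrame

    def maf(self) -> pd.Series:
        """Minor allele frequency per SNP: allele count / (2n), folded to <= 0.5."""
        p = self.dosages.sum(axis=0) / (2.0 * len(self.dosages))
        return np.minimum(p, 1.0 - p)


def read_genotypes(dosage_path: str | Path, snp_bed: str | Path,
                   gene_bed: str | Path) -> GenotypeMatrix:
    dos = pd.read_csv(dosage_path, sep="\t", index_col=0)
    bad = ~dos.isin([0, 1, 2]).all(axis=None)
    if bad:
        raise ValueError("genotype dosages must be 0/1/2")
    cols = ["chrom", "start", "end", "name"]
    snps = pd.read_csv(snp_bed, sep="\t", header=None, names=cols).set_index("name")
    genes = pd.read_csv(gene_bed, sep="\t", header=None, names=cols).set_index("name")
    return GenotypeMatrix(dos.astype(np.int8), snps, genes)


def write_genotypes(geno: GenotypeMatrix, dosage_path: str | Path,
                    snp_bed: str | Path, gene_bed: str | Path) -> None:
    geno.dosages.to_csv(dosage_path, sep="\t", index_label="sample_id")
    for frame, path in ((geno.snp_coords, snp_bed), (geno.gene_coords, gene_bed)):
        frame.reset_index()[["chrom", "start", "end", "name"]].to_csv(
            path, sep="\t", header=False, index=False
        )
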