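"""Readers, writers and the shared genotype container.

The pipeline works on biallelic SNP dosages (count of ALT alleles per
diploid genotype: 0, 1, 2, or missing).  All coordinates — VCF positions,
GFF3 gene spans and QTL intervals — are 1-based and inclusive at both
ends, matching the source formats.

Formats handled here: VCF 4.x (GT subfield only), GFF3 gene annotation,
and tab-separated phenotype / QTL report tables.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cyvcf2 import VCF
from gffutils.iterators import DataIterator

#: Sentinel for a missing dosage.  Never 0 — 0 is a legal dosage.
MISSING = -1

_VALID_DOSAGES = frozenset((-1, 0, 1, 2))


class VCFFormatError(ValueError):
    """Raised for malformed VCF input (bad header, non-diploid GT)."""


class SchemaError(ValueError):
    """Raised when a delimited table does not match its declared schema."""


@dataclass(frozen=True)
class SiteRecord:
    """One biallelic site: chromosome, 1-based position, alleles, quality."""

    chrom: str
    pos: int
    ref: str
    alt: str
    qual: float = 0.0

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"REF and ALT must differ at {self.chrom}:{self.pos}")
        if self.qual < 0:
            raise ValueError(f"negative QUAL at {self.chrom}:{self.pos}")


class GenotypeMatrix:
    """Samples x biallelic sites ALT-allele dosage matrix.

    Parameters
    ----------
    sample_ids
        Unique sample names, one per dosage row.
    sites
        Ordered :class:`SiteRecord` list, one per dosage column.  Within
        each chromosome, positions must be strictly increasing.
    dosage
        ``(n_samples, n_sites)`` integer array with values in
        ``{0, 1, 2, MISSING}``.  Heterozygotes are unphased: 0/1 and 1/0
        both code as dosage 1.
    """

    def __init__(self, sample_ids, sites, dosage, validate=True):
        self.sample_ids = list(sample_ids)
        self.sites = list(sites)
        self.dosage = np.asarray(dosage, dtype=np.int16)
        if validate:
            self._validate()

    def _validate(self):
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if self.dosage.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.sites)} sites"
            )
        if self.dosage.size and not np.isin(self.dosage, (-1, 0, 1, 2)).all():
            bad = np.unique(self.dosage[~np.isin(self.dosage, (-1, 0, 1, 2))])
            raise ValueError(f"illegal dosage values {bad.tolist()}")
        last: dict[str, int] = {}
        for s in self.sites:
            if s.chrom in last and s.pos <= last[s.chrom]:
                raise ValueError(
                    f"positions not strictly increasing on {s.chrom} at {s.pos}"
                )
            last[s.chrom] = s.pos

    # -- basic geometry ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def chroms(self) -> np.ndarray:
        return np.array([s.chrom for s in self.sites], dtype=object)

    def quals(self) -> np.ndarray:
        return np.array([s.qual for s in self.sites], dtype=float)

    def called_mask(self) -> np.ndarray:
        """Boolean mask of non-missing genotypes."""
        return self.dosage != MISSING

    # -- subsetting ----------------------------------------------------
    def take_sites(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        sites = [self.sites[i] for i in index]
        return GenotypeMatrix(self.sample_ids, sites, self.dosage[:, index],
                              validate=False)

    def take_samples(self, which) -> "GenotypeMatrix":
        """Subset samples by integer index or by id."""
        which = list(which)
        if which and isinstance(which[0], str):
            lookup = {s: i for i, s in enumerate(self.sample_ids)}
            missing = [s for s in which if s not in lookup]
            if missing:
                raise KeyError(f"unknown sample ids: {missing}")
            idx = [lookup[s] for s in which]
        else:
            idx = which
        ids = [self.sample_ids[i] for i in idx]
        return GenotypeMatrix(ids, self.sites, self.dosage[idx, :])

    def site_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chroms(),
                "pos": self.positions(),
                "ref": [s.ref for s in self.sites],
                "alt": [s.alt for s in self.sites],
                "qual": self.quals(),
            }
        )

    def __repr__(self):
        return f"GenotypeMatrix({self.n_samples} samples x {self.n_sites} sites)"


def read_vcf(path, min_qual: float = 0.0, require_biallelic: bool = True
             ) -> GenotypeMatrix:
    """Read diploid GT calls from a VCF 4.x file.

    Sites failing the QUAL threshold are dropped; with
    ``require_biallelic`` (the default) multi-allelic and non-SNP records
    are dropped rather than split, so site counts stay interpretable.
    Skip counts are attached to the returned matrix as ``.read_log``.

    ``./.`` (and half-calls) become :data:`MISSING`; phased ``|`` and
    unphased ``/`` separators are both accepted, and the dosage is simply
    the ALT-allele count.
    """
    try:
        vcf = VCF(str(path), gts012=True)
    except Exception as exc:  # cyvcf2 raises plain OSError on bad headers
        raise VCFFormatError(f"cannot parse VCF header of {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    n_header = 0
    with open(path, "rb") as fh:
        for line in fh:
            if not line.startswith(b"#"):
                break
            n_header += 1
    log = {"n_records": 0, "dropped_multiallelic_or_non_snp": 0,
           "dropped_low_qual": 0}
    sites: list[SiteRecord] = []
    cols: list[np.ndarray] = []
    for i, var in enumerate(vcf):
        log["n_records"] += 1
        line_no = n_header + i + 1
        if var.ploidy != 2:
            raise VCFFormatError(
                f"non-diploid genotype at line {line_no} "
                f"({var.CHROM}:{var.POS})"
            )
        alts = [a for a in var.ALT if a not in (".", "")]
        if require_biallelic and (
            len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1
        ):
            log["dropped_multiallelic_or_non_snp"] += 1
            continue
        qual = float(var.QUAL) if var.QUAL is not None else 0.0
        if qual < min_qual:
            log["dropped_low_qual"] += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int16)
        gt[gt == 3] = MISSING  # gts012: 3 == unknown
        sites.append(SiteRecord(var.CHROM, var.POS, var.REF, alts[0], qual))
        cols.append(gt)
    dosage = (np.column_stack(cols) if cols
              else np.empty((len(sample_ids), 0), dtype=np.int16))
    gm = GenotypeMatrix(sample_ids, sites, dosage)
    gm.read_log = log
    return gm


_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal GT-only VCF 4.2 file.

    ``read_vcf(write_vcf(gm))`` reproduces sample ids, site records and
    dosages exactly (QUAL is serialised with 6 significant digits).
    """
    seen = []
    for s in gm.sites:
        if s.chrom not in seen:
            seen.append(s.chrom)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ricepop\n")
        for chrom in seen:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.sample_ids) + "\n")
        for j, s in enumerate(gm.sites):
            gts = "\t".join(_GT_CODE[int(g)] for g in gm.dosage[:, j])
            fh.write(f"{s.chrom}\t{s.pos}\t.\t{s.ref}\t{s.alt}\t{s.qual:.6g}"
                     f"\t.\t.\tGT\t{gts}\n")


@dataclass
class GeneAnnotation:
    """Gene records (1-based inclusive coordinates) from a GFF3 file."""

    genes: pd.DataFrame  # gene_id, chrom, start, end, strand

    def __post_init__(self):
        required = {"gene_id", "chrom", "start", "end", "strand"}
        if not required.issubset(self.genes.columns):
            raise SchemaError(f"gene table must have columns {sorted(required)}")
        if self.genes["gene_id"].duplicated().any():
            dup = self.genes.loc[self.genes["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene id: {dup.iloc[0]!r}")
        if (self.genes["start"] > self.genes["end"]).any():
            raise ValueError("gene with start > end")

    def __len__(self):
        return len(self.genes)


def read_gff_genes(path) -> GeneAnnotation:
    """Load features of type ``gene`` from a GFF3 file.

    Records without an ``ID`` attribute are skipped with a warning;
    coordinates are kept 1-based inclusive, exactly as in the file.
    """
    rows = []
    for feat in DataIterator(str(path)):
        if feat.featuretype != "gene":
            continue
        ids = feat.attributes.get("ID")
        if not ids:
            warnings.warn(
                f"gene record without ID at {feat.seqid}:{feat.start} skipped"
            )
            continue
        rows.append((ids[0], feat.seqid, int(feat.start), int(feat.end),
                     feat.strand))
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end",
                                        "strand"])
    return GeneAnnotation(genes)


@dataclass
class TraitTable:
    """Numeric phenotype values, one row per sample, missing allowed."""

    data: pd.DataFrame  # index: sample ids; columns: trait names

    def __post_init__(self):
        if self.data.index.duplicated().any():
            raise SchemaError("phenotype table has duplicated sample ids")
        non_numeric = [c for c in self.data.columns
                       if not pd.api.types.is_numeric_dtype(self.data[c])]
        if non_numeric:
            raise SchemaError(f"non-numeric trait columns: {non_numeric}")

    @property
    def traits(self) -> list[str]:
        return list(self.data.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def values_for(self, trait: str, sample_ids=None) -> np.ndarray:
        col = self.data[trait]
        if sample_ids is not None:
            col = col.reindex(sample_ids)
        return col.to_numpy(dtype=float)


_QTL_COLUMNS = ["name", "trait", "chrom", "panels", "start", "end",
                "n_sig_snps", "min_p", "n_genes"]


@dataclass
class QTLReportTable:
    """Per-QTL report rows (one interval per QTL, 1-based inclusive)."""

    data: pd.DataFrame
    min_sig_log10p: float | None = None

    def __post_init__(self):
        missing = [c for c in _QTL_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(
                f"QTL table missing required columns {missing}; "
                f"expected {_QTL_COLUMNS}"
            )
        d = self.data
        if (d["start"] >= d["end"]).any():
            raise ValueError("QTL with start >= end")
        if (d["n_sig_snps"] < 2).any():
            bad = d.loc[d["n_sig_snps"] < 2, "name"].tolist()
            raise ValueError(
                f"QTLs must contain >= 2 significant SNPs; violated by {bad}"
            )
        if (d["min_p"] <= 0).any() or (d["min_p"] > 1).any():
            raise ValueError("min_p outside (0, 1]")
        if self.min_sig_log10p is not None:
            logs = -np.log10(d["min_p"].to_numpy(dtype=float))
            if (logs < self.min_sig_log10p).any():
                bad = d.loc[logs < self.min_sig_log10p, "name"].tolist()
                raise ValueError(
                    f"QTL min p above significance threshold "
                    f"1e-{self.min_sig_log10p}: {bad}"
                )

    def __len__(self):
        return len(self.data)

    def panel_sets(self) -> pd.Series:
        return self.data["panels"].map(
            lambda s: frozenset(p.strip() for p in str(s).split(",")))


def read_table(path, schema: str, min_sig_log10p: float | None = None):
    """Read a tab-separated table as either a phenotype or QTL report.

    Parameters
    ----------
    schema
        ``"phenotype"`` — first column is the sample id, remaining
        columns are numeric traits (blank cells become missing).
        ``"qtl_report"`` — per-QTL rows with columns
        ``name trait chrom panels start end n_sig_snps min_p n_genes``.
    min_sig_log10p
        Optional significance floor for the QTL schema: every row's
        ``-log10(min_p)`` must reach it.  Off by default because published
        QTL tables commonly print peak p-values on a different scale than
        the genome-wide threshold.
    """
    df = pd.read_csv(path, sep="\t")
    if schema == "phenotype":
        if df.shape[1] < 2:
            raise SchemaError("phenotype table needs a sample column and "
                              "at least one trait column")
        df = df.set_index(df.columns[0])
        try:
            df = df.apply(pd.to_numeric)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"non-numeric trait value: {exc}") from exc
        return TraitTable(df)
    if schema == "qtl_report":
        df["chrom"] = df.get("chrom", pd.Series(dtype=object)).astype(str)
        return QTLReportTable(df, min_sig_log10p=min_sig_log10p)
    raise ValueError(f"unknown schema {schema!r}")


def bundled_qtl_table() -> QTLReportTable:
    """The packaged example QTL report from a rice diversity-panel GWAS.

    21 QTLs over 10 chromosomes aggregating 643 significant
    SNP-trait associations from a full panel and Indica / Japonica
    subpanels; used by the report-aggregation machinery and as a worked
    example.
    """
    ref = importlib.resources.files("ricepop") / "data" / "qtl_rice_panel.tsv"
    with importlib.resources.as_file(ref) as p:
        return read_table(p, schema="qtl_report")
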