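"""On-disk formats and the internal genotype data model.

Coordinates are 1-based inclusive throughout, matching VCF.  Missing
dosages are represented by ``numpy.nan`` — an out-of-band sentinel, never
a numeric code.  Dosage is the expected effect-allele count in [0, 2].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: folded-frequency threshold below which a palindromic (A/T or C/G)
#: allele pair may be resolved by comparing frequencies
AMBIGUOUS_FREQ_THRESHOLD = 0.40


class GenotypeParseError(ValueError):
    """Raised for malformed or unsupported genotype input."""


@dataclass
class VariantRecord:
    """One variant: location, alleles, per-population frequency, per-stratum INFO."""

    id: str
    chrom: str
    pos: int  # 1-based
    effect_allele: str
    other_allele: str
    freq: dict[str, float] = field(default_factory=dict)  # population -> effect-allele freq
    info: dict[str, float] = field(default_factory=dict)  # stratum -> imputation INFO

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.id}: effect and other allele are identical")
        for v in self.info.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.id}: INFO {v} outside [0,1]")

    def maf(self, population: str) -> float:
        """Minor-allele frequency (folded, always <= 0.5) in one population."""
        f = self.freq[population]
        return min(f, 1.0 - f)

    def is_palindromic(self) -> bool:
        return COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class DosageMatrix:
    """Dense samples x variants effect-allele dosage matrix, NaN = missing."""

    samples: list[str]
    variants: list[str]
    data: np.ndarray  # (n_samples, n_variants), float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage matrix shape {self.data.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        self._vidx = {v: j for j, v in enumerate(self.variants)}
        self._sidx = {s: i for i, s in enumerate(self.samples)}
        if len(self._vidx) != len(self.variants):
            raise ValueError("duplicated variant id in dosage matrix")
        with np.errstate(invalid="ignore"):
            bad = np.nansum((self.data < 0) | (self.data > 2))
        if bad:
            raise ValueError(f"{bad} dosage values outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def column(self, variant_id: str) -> np.ndarray:
        return self.data[:, self._vidx[variant_id]]

    def variant_index(self, variant_id: str) -> int:
        return self._vidx[variant_id]

    def sample_index(self, sample_ids) -> np.ndarray:
        return np.array([self._sidx[s] for s in sample_ids], dtype=int)

    def subset_samples(self, sample_ids) -> "DosageMatrix":
        idx = self.sample_index(sample_ids)
        return DosageMatrix(list(sample_ids), list(self.variants), self.data[idx])

    def callrate(self) -> np.ndarray:
        """Per-variant fraction of non-missing samples."""
        return 1.0 - np.mean(np.isnan(self.data), axis=0)

    def allele_freq(self) -> np.ndarray:
        """Per-variant effect-allele frequency over non-missing samples."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.data, axis=0) / 2.0


@dataclass
class LocusCatalogEntry:
    """One known risk locus: region anchor, reported risk allele and OR."""

    region_id: str
    index_variant: str
    risk_allele: str
    reported_or: float
    chrom: str
    start: int
    end: int
    source_population: str = "EUR"
    risk_allele_freq: float | None = None  # reported frequency, used for palindromic SNPs

    def __post_init__(self) -> None:
        if self.reported_or <= 0:
            raise ValueError(f"{self.region_id}: reported OR must be positive")
        if self.start >= self.end:
            raise ValueError(f"{self.region_id}: window start must precede end")


CATALOG_COLUMNS = [
    "region_id",
    "index_variant",
    "risk_allele",
    "reported_or",
    "chrom",
    "start",
    "end",
    "source_population",
    "risk_allele_freq",
]


def write_catalog(entries: list[LocusCatalogEntry], path) -> None:
    rows = []
    for e in entries:
        rows.append(
            {
                "region_id": e.region_id,
                "index_variant": e.index_variant,
                "risk_allele": e.risk_allele,
                "reported_or": e.reported_or,
                "chrom": e.chrom,
                "start": e.start,
                "end": e.end,
                "source_population": e.source_population,
                "risk_allele_freq": "" if e.risk_allele_freq is None else e.risk_allele_freq,
            }
        )
    pd.DataFrame(rows, columns=CATALOG_COLUMNS).to_csv(path, sep="\t", index=False)


def read_catalog(path) -> list[LocusCatalogEntry]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = set(CATALOG_COLUMNS) - set(df.columns)
    if missing:
        raise GenotypeParseError(f"catalog missing columns: {sorted(missing)}")
    entries = []
    for _, r in df.iterrows():
        raf = r["risk_allele_freq"]
        entries.append(
            LocusCatalogEntry(
                region_id=str(r["region_id"]),
                index_variant=str(r["index_variant"]),
                risk_allele=str(r["risk_allele"]),
                reported_or=float(r["reported_or"]),
                chrom=str(r["chrom"]),
                start=int(r["start"]),
                end=int(r["end"]),
                source_population=str(r["source_population"]),
                risk_allele_freq=None if pd.isna(raf) or raf == "" else float(raf),
            )
        )
    return entries


def align_to_catalog(
    variant: VariantRecord,
    entry: LocusCatalogEntry,
    data_freq: float | None = None,
) -> int | str:
    """Orientation of a variant's effect allele relative to the reported risk allele.

    Returns +1 when the effect allele is the risk allele, -1 when it is the
    other allele (downstream effect signs must be flipped), or the string
    ``"ambiguous"`` when the strand cannot be resolved.  Strand-complement
    matching is attempted for non-palindromic pairs.  Palindromic (A/T, C/G)
    pairs are resolved by frequency only when both the observed effect-allele
    frequency and the reported risk-allele frequency are folded below 0.40;
    otherwise the call is ambiguous.

    Parameters
    ----------
    data_freq : observed effect-allele frequency used for the palindromic
        rule; defaults to the mean of the variant's per-population
        frequencies when available.
    """
    if variant.id != entry.index_variant:
        raise ValueError(
            f"variant {variant.id} does not match catalog index {entry.index_variant}"
        )
    eff, oth, risk = variant.effect_allele, variant.other_allele, entry.risk_allele

    if variant.is_palindromic():
        if data_freq is None:
            data_freq = (
                float(np.mean(list(variant.freq.values()))) if variant.freq else None
            )
        raf = entry.risk_allele_freq
        if data_freq is None or raf is None:
            return "ambiguous"
        if (
            min(data_freq, 1 - data_freq) >= AMBIGUOUS_FREQ_THRESHOLD
            or min(raf, 1 - raf) >= AMBIGUOUS_FREQ_THRESHOLD
        ):
            return "ambiguous"
        if risk not in (eff, oth, COMPLEMENT.get(eff), COMPLEMENT.get(oth)):
            raise ValueError(f"{variant.id}: no allele correspondence with risk {risk}")
        # both alleles resolvable by which side of 0.5 they sit on
        return +1 if (data_freq < 0.5) == (raf < 0.5) else -1

    if risk == eff:
        return +1
    if risk == oth:
        return -1
    if COMPLEMENT.get(risk) == eff:
        return +1
    if COMPLEMENT.get(risk) == oth:
        return -1
    raise ValueError(
        f"{variant.id}: risk allele {risk} matches neither {eff}/{oth} nor complements"
    )


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation quality score">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect-allele dosage">
"""


def write_vcf(variants: list[VariantRecord], dosages: DosageMatrix, path) -> None:
    """Write hard-call GT plus DS dosage; INFO carries the mean imputation score.

    Per-stratum INFO scores do not fit a single VCF INFO float; the mean is
    written here and the full variant x stratum table travels in a sidecar
    TSV (see :func:`write_info_table`).
    """
    order = [dosages.variant_index(v.id) for v in variants]
    contigs = list(dict.fromkeys(v.chrom for v in variants))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(dosages.samples) + "\n")
        for v, j in zip(variants, order):
            col = dosages.data[:, j]
            mean_info = float(np.mean(list(v.info.values()))) if v.info else 1.0
            cells = []
            for d in col:
                if math.isnan(d):
                    cells.append("./.:.")
                else:
                    hard = int(round(d))
                    gt = ["0/0", "0/1", "1/1"][hard]
                    cells.append(f"{gt}:{d:.4f}")
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.id}\t{v.other_allele}\t{v.effect_allele}"
                f"\t.\t.\tINFO={mean_info:.4f}\tGT:DS\t" + "\t".join(cells) + "\n"
            )


def write_info_table(variants: list[VariantRecord], path) -> None:
    strata = sorted({s for v in variants for s in v.info})
    rows = [{"variant": v.id, **{s: v.info.get(s, np.nan) for s in strata}} for v in variants]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_info_table(path) -> dict[str, dict[str, float]]:
    df = pd.read_csv(path, sep="\t", index_col="variant")
    return {vid: {s: float(x) for s, x in row.items()} for vid, row in df.iterrows()}


def read_genotypes(path, fmt: str = "vcf") -> tuple[list[VariantRecord], DosageMatrix]:
    """Read a genotype file into variant records and a dosage matrix.

    For VCF input the dosage is taken from the DS FORMAT field when present
    and otherwise from GT allele counts.  Multi-allelic sites and duplicated
    variant ids are rejected.
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown genotype format: {fmt!r}")


def _read_vcf(path) -> tuple[list[VariantRecord], DosageMatrix]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    columns: list[np.ndarray] = []
    seen: set[str] = set()
    for lineno, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise GenotypeParseError(
                f"{path} record {lineno} ({rec.ID}): multi-allelic site not supported"
            )
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        if vid in seen:
            raise GenotypeParseError(f"{path} record {lineno}: duplicated variant id {vid}")
        seen.add(vid)
        try:
            ds = rec.format("DS")
        except KeyError:  # DS absent from the FORMAT header entirely
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(-1)
            col = np.where((col < 0) | (col > 2), np.nan, col)
        else:
            gts = rec.genotype.array()  # (n, ploidy+1), -1 = missing allele
            alleles = gts[:, :-1]
            col = np.where(
                (alleles < 0).any(axis=1), np.nan, alleles.clip(min=0).sum(axis=1)
            ).astype(float)
        info_score = rec.INFO.get("INFO")
        variants.append(
            VariantRecord(
                id=vid,
                chrom=str(rec.CHROM),
                pos=int(rec.POS),
                effect_allele=rec.ALT[0],
                other_allele=rec.REF,
                info={} if info_score is None else {"all": float(info_score)},
            )
        )
        columns.append(col)
    data = np.column_stack(columns) if columns else np.empty((len(samples), 0))
    return variants, DosageMatrix(samples, [v.id for v in variants], data)


def _read_tsv(path) -> tuple[list[VariantRecord], DosageMatrix]:
    """Plain dosage table: variant metadata columns then one column per sample."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "effect_allele", "other_allele"]
    missing = set(meta_cols) - set(df.columns)
    if missing:
        raise GenotypeParseError(f"dosage TSV missing columns: {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise GenotypeParseError(f"duplicated variant id {dup}")
    samples = [c for c in df.columns if c not in meta_cols]
    variants = [
        VariantRecord(
            id=str(r["id"]),
            chrom=str(r["chrom"]),
            pos=int(r["pos"]),
            effect_allele=str(r["effect_allele"]),
            other_allele=str(r["other_allele"]),
        )
        for _, r in df.iterrows()
    ]
    data = df[samples].to_numpy(dtype=float).T  # samples x variants
    return variants, DosageMatrix(samples, [v.id for v in variants], data)


SAMPLE_COLUMNS = [
    "sample",
    "population",
    "stratum",
    "sex",
    "age",
    "bmi",
    "case",
    "has_claims",
    "prior_condition",
]


def write_samples(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise GenotypeParseError(f"sample table missing columns: {sorted(missing)}")
    return df


def read_cohort_dir(indir) -> dict:
    """Load a written cohort directory back into analysis-ready objects.

    Reconstructs per-population effect-allele frequencies from the dosage
    data and per-stratum INFO scores from the sidecar table.  Returns a
    dict with ``variants``, ``dosages``, ``samples``, ``catalog``,
    ``truth`` and ``region_variants`` (region id -> ordered variant ids).
    """
    from pathlib import Path

    indir = Path(indir)
    variants, dosages = read_genotypes(indir / "genotypes.vcf", "vcf")
    samples = read_samples(indir / "samples.tsv")
    catalog = read_catalog(indir / "catalog.tsv")
    truth = pd.read_csv(indir / "truth.tsv", sep="\t")
    info = read_info_table(indir / "info_scores.tsv")
    for v in variants:
        v.info = info.get(v.id, v.info)
    for pop, g in samples.groupby("population"):
        idx = dosages.sample_index(g["sample"])
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(dosages.data[idx], axis=0) / 2.0
        for v, f in zip(variants, freqs):
            v.freq[pop] = float(f)
    region_variants: dict[str, list[str]] = {}
    for _, row in truth.iterrows():
        region_variants.setdefault(row["region_id"], []).append(row["variant"])
    return {
        "variants": variants,
        "dosages": dosages,
        "samples": samples,
        "catalog": catalog,
        "truth": truth,
        "region_variants": region_variants,
    }
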