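"""Data model and I/O for multi-environment trial (MET) analysis.

Containers are thin wrappers around pandas DataFrames with validation. An
*environment* is the combination of year, location and sowing period; trials
(each with its own experimental design) are nested within environments.

Sowing periods follow the southern-hemisphere wheat calendar: PRE (sown
before May 15), OPT (sown between May 15 and June 15, both inclusive) and
POS (sown after June 15).
"""

from __future__ import annotations

import datetime as _dt
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOWING_PERIODS = ("PRE", "OPT", "POS")

#: month-day cutoffs delimiting the optimal sowing window (inclusive)
OPT_WINDOW_START = (5, 15)
OPT_WINDOW_END = (6, 15)

PHENO_REQUIRED = [
    "genotype", "year", "location", "trial", "replicate",
    "sowing_date", "yield",
]
PHENO_OPTIONAL = ["block", "heading_date", "harvest_date"]

WEATHER_VARS = ["prec", "tmax", "tmin", "tmean", "rh", "sr", "ws", "et", "cc"]


class SchemaError(ValueError):
    """Input table does not match the expected schema."""


class DuplicateKeyError(ValueError):
    """Duplicate (genotype, trial, replicate, block) plot keys."""


def sowing_period(date: _dt.date) -> str:
    """Classify a sowing date into PRE / OPT / POS.

    OPT is inclusive of both the May 15 and June 15 boundary dates.
    """
    md = (date.month, date.day)
    if md < OPT_WINDOW_START:
        return "PRE"
    if md <= OPT_WINDOW_END:
        return "OPT"
    return "POS"


def environment_label(year: int, location: str, period: str) -> str:
    return f"{int(year)}_{location}_{period}"


@dataclass(frozen=True)
class Environment:
    """Identity of an environment: (year, location, sowing period)."""

    year: int
    location: str
    sowing_period: str

    def __post_init__(self):
        if self.sowing_period not in SOWING_PERIODS:
            raise ValueError(f"unknown sowing period {self.sowing_period!r}")

    def __str__(self) -> str:
        return environment_label(self.year, self.location, self.sowing_period)


class PhenotypeTable:
    """Plot-level phenotype records.

    One row per (genotype, trial, replicate[, block]) with yield (kg/ha),
    sowing/heading/harvest dates and the derived environment label.
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        for col in PHENO_OPTIONAL:
            if col not in df.columns:
                df[col] = np.nan
        if validate:
            missing = [c for c in PHENO_REQUIRED if c not in df.columns]
            if missing:
                raise SchemaError(f"missing required columns: {missing}")
        if "sowing_period" not in df.columns:
            df["sowing_period"] = [
                sowing_period(d) for d in pd.to_datetime(df["sowing_date"]).dt.date
            ]
        if "environment" not in df.columns:
            df["environment"] = [
                environment_label(y, l, s)
                for y, l, s in zip(df["year"], df["location"], df["sowing_period"])
            ]
        if validate and len(df):
            self._check_keys(df)
            env_per_trial = df.groupby("trial")["environment"].nunique()
            bad = env_per_trial[env_per_trial > 1]
            if len(bad):
                raise SchemaError(
                    f"trials mapping to multiple environments: {list(bad.index)}"
                )
        self.df = df.reset_index(drop=True)

    @staticmethod
    def _check_keys(df: pd.DataFrame) -> None:
        key = df[["genotype", "trial", "replicate", "block"]].astype(str)
        dup = key[key.duplicated()]
        if len(dup):
            raise DuplicateKeyError(
                "duplicate plot keys: "
                + "; ".join(map(str, dup.head(5).itertuples(index=False, name=None)))
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def environments(self) -> list[str]:
        return sorted(self.df["environment"].unique())

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].astype(str).unique())

    def environment_of_trial(self) -> pd.Series:
        return self.df.groupby("trial")["environment"].first()


@dataclass
class MarkerSet:
    """Biallelic marker dosages (count of the alternate allele).

    ``dosage`` is an (n_genotypes, n_loci) float array with NaN for missing
    calls; entries are in [0, 2] after imputation.
    """

    dosage: np.ndarray
    genotypes: list[str]
    loci: pd.DataFrame  # columns: chrom, pos, ref, alt

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.genotypes = [str(g) for g in self.genotypes]
        if self.dosage.shape != (len(self.genotypes), len(self.loci)):
            raise ValueError("dosage shape inconsistent with indices")
        if len(set(self.genotypes)) != len(self.genotypes):
            raise ValueError("duplicate genotype ids")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosage).sum())

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus, ignoring missing calls."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosage, axis=0) / 2.0


class WeatherTable:
    """Daily weather, one row per (environment, date).

    Columns: prec (mm), tmax/tmin/tmean (degC), rh (%), sr (MJ m-2 d-1),
    ws (m s-1), et (mm), cc (%).
    """

    def __init__(self, df: pd.DataFrame, validate: bool = True):
        df = df.copy()
        df["date"] = pd.to_datetime(df["date"])
        if validate:
            missing = [c for c in ["environment", "date", *WEATHER_VARS]
                       if c not in df.columns]
            if missing:
                raise SchemaError(f"missing weather columns: {missing}")
            if df.duplicated(["environment", "date"]).any():
                raise SchemaError("duplicate (environment, date) rows")
            bad = (df["tmin"] > df["tmean"]) | (df["tmean"] > df["tmax"])
            if bad.any():
                raise SchemaError(
                    f"{int(bad.sum())} rows violate tmin <= tmean <= tmax"
                )
        self.df = df.sort_values(["environment", "date"]).reset_index(drop=True)

    def slice(self, environment: str) -> pd.DataFrame:
        out = self.df[self.df["environment"] == environment]
        if not len(out):
            raise KeyError(f"no weather for environment {environment!r}")
        return out


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_phenotypes(path) -> PhenotypeTable:
    """Read a comma-delimited plot-level phenotype file.

    Required header columns: genotype, year, location, trial, replicate,
    sowing_date, yield. Dates must be ISO-8601; unparseable dates raise a
    row-level error listing offending rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in PHENO_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {missing}")
    for col in ("sowing_date", "heading_date", "harvest_date"):
        if col in df.columns:
            parsed = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
            bad = df.index[parsed.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: unparseable {col} on rows {list(bad[:10])}"
                )
            df[col] = parsed
    return PhenotypeTable(df)


def write_phenotypes(pheno: PhenotypeTable, path, metadata: dict | None = None):
    pheno.df.to_csv(path, index=False)
    _write_sidecar(path, metadata)


def read_weather(path) -> WeatherTable:
    return WeatherTable(pd.read_csv(path))


def write_weather(weather: WeatherTable, path, metadata: dict | None = None):
    weather.df.to_csv(path, index=False)
    _write_sidecar(path, metadata)


def _write_sidecar(path, metadata: dict | None):
    import json

    meta = {"writer": "phenogp", **(metadata or {})}
    with open(f"{path}.meta.json", "w") as fh:
        json.dump(meta, fh, indent=1, default=str)


def read_markers(path, fmt: str | None = None) -> MarkerSet:
    """Read markers from a VCF (biallelic SNPs, GT field) or a tab-delimited
    dosage matrix (genotypes in rows, loci in columns, NA for missing).

    Multiallelic VCF records are skipped with a warning and counted.
    """
    path = str(path)
    if fmt is None:
        fmt = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "matrix"
    if fmt == "vcf":
        return _read_vcf(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    loci = pd.DataFrame({
        "chrom": "NA", "pos": np.arange(1, df.shape[1] + 1),
        "ref": "A", "alt": "B", "id": df.columns,
    })
    return MarkerSet(df.to_numpy(dtype=float), list(df.index.astype(str)), loci)


def _read_vcf(path: str) -> MarkerSet:
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    rows, recs, skipped = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        gt = np.asarray(var.gt_types, dtype=float)  # 0,1,2; 3 = missing
        gt[gt == 3] = np.nan
        rows.append(gt)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if skipped:
        warnings.warn(f"skipped {skipped} multiallelic records")
    if not rows:
        raise ValueError(f"{path}: no biallelic records")
    loci = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt"])
    ms = MarkerSet(np.asarray(rows).T, samples, loci)
    ms.n_skipped_multiallelic = skipped
    return ms


def write_markers(markers: MarkerSet, path, metadata: dict | None = None):
    """Write markers as a tab-delimited dosage matrix."""
    df = pd.DataFrame(markers.dosage, index=markers.genotypes)
    df.columns = [f"locus{i+1}" for i in range(df.shape[1])]
    df.to_csv(path, sep="\t", na_rep="NA")
    _write_sidecar(path, metadata)


def check_genotype_overlap(markers: MarkerSet, pheno: PhenotypeTable) -> set[str]:
    shared = set(markers.genotypes) & set(pheno.genotypes)
    if not shared:
        raise ValueError("no genotype ids shared between markers and phenotypes")
    return shared


# ---------------------------------------------------------------------------
# QC filters
# ---------------------------------------------------------------------------

@dataclass
class MarkerQCReport:
    n_input: int
    n_removed_maf: int
    n_removed_het: int
    n_removed_miss: int
    n_retained: int
    n_imputed: int


def qc_markers(
    markers: MarkerSet,
    maf_min: float = 0.05,
    het_max: float = 0.10,
    miss_max: float = 0.80,
    impute: bool = True,
) -> tuple[MarkerSet, MarkerQCReport]:
    """Remove loci failing MAF / heterozygosity / missingness rules, then
    impute remaining missing calls with the per-locus mean dosage.

    A locus is removed if minor-allele frequency < ``maf_min``, if the
    fraction of heterozygous calls > ``het_max``, or if the fraction of
    missing calls > ``miss_max``. Filtering precedes imputation.
    """
    for name, v in [("maf_min", maf_min), ("het_max", het_max),
                    ("miss_max", miss_max)]:
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must be in [0,1], got {v}")
    D = markers.dosage
    n = D.shape[0]
    miss_frac = np.isnan(D).mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(D, axis=0) / 2.0
        het = np.nanmean(D == 1, axis=0)
    maf = np.minimum(p, 1 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)
    fail_maf = maf < maf_min
    fail_het = het > het_max
    fail_miss = miss_frac > miss_max
    keep = ~(fail_maf | fail_het | fail_miss)
    report = MarkerQCReport(
        n_input=D.shape[1],
        n_removed_maf=int(fail_maf.sum()),
        n_removed_het=int(fail_het.sum()),
        n_removed_miss=int(fail_miss.sum()),
        n_retained=int(keep.sum()),
        n_imputed=0,
    )
    if not keep.any():
        raise ValueError(
            f"all loci removed by QC (maf {report.n_removed_maf}, "
            f"het {report.n_removed_het}, miss {report.n_removed_miss})"
        )
    D2 = D[:, keep].copy()
    if impute:
        nan_mask = np.isnan(D2)
        report.n_imputed = int(nan_mask.sum())
        if report.n_imputed:
            col_mean = np.nanmean(D2, axis=0)
            D2[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    out = MarkerSet(D2, markers.genotypes, markers.loci.loc[keep].reset_index(drop=True))
    return out, report


def filter_environments(pheno: PhenotypeTable, min_genotypes: int = 25) -> PhenotypeTable:
    """Drop environments with fewer than ``min_genotypes`` distinct genotypes
    (strictly-less-than rule; an environment with exactly the threshold count
    is retained)."""
    if min_genotypes < 1:
        raise ValueError("min_genotypes must be >= 1")
    counts = pheno.df.groupby("environment")["genotype"].nunique()
    keep = counts[counts >= min_genotypes].index
    for env in counts.index.difference(keep):
        logger.info("dropping environment %s (%d genotypes < %d)",
                    env, counts[env], min_genotypes)
    if not len(keep):
        raise ValueError("no environments survive the genotype-count filter")
    out = pheno.df[pheno.df["environment"].isin(keep)]
    return PhenotypeTable(out, validate=False)


def connectivity_summary(pheno: PhenotypeTable) -> dict[str, pd.DataFrame]:
    """Counts of genotypes shared between pairs of sites and pairs of years.

    A *site* is a location x sowing-period combination. Diagonals hold the
    number of distinct genotypes per site / year.
    """
    if not len(pheno.df):
        raise ValueError("empty phenotype table")
    df = pheno.df
    site = df["location"].astype(str) + "_" + df["sowing_period"].astype(str)
    out = {}
    for name, labels in [("site", site), ("year", df["year"].astype(str))]:
        sets = {lv: set(df.loc[labels == lv, "genotype"]) for lv in sorted(labels.unique())}
        lv = list(sets)
        mat = pd.DataFrame(
            [[len(sets[a] & sets[b]) for b in lv] for a in lv],
            index=lv, columns=lv, dtype=int,
        )
        out[name] = mat
    return out
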