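"""Core domain types and file readers/writers shared by all pipeline stages.

Data model
----------
* :class:`GenotypeMatrix` — accessions × SNPs minor-allele dosage matrix with
  entries in {0, 1, 2} (``MISSING`` = −1 in memory, ``"NA"`` on disk).
* :class:`ClimateWindow` — 6 climate factors × 25 days relative to planting,
  days −4 … +20 inclusive (5 days before planting through 20 days after).
* :class:`PhenotypeTable` — (accession, environment, days-to-flowering)
  records.
* :class:`ClassScheme` — ordered flowering-time classes defined by inclusive
  upper bounds ("class maxima"); a phenotype of exactly the bound value
  belongs to that class.

All on-disk formats are UTF-8 CSV with a header row; readers are
gzip-transparent. Genotypes may alternatively come from a minimal biallelic
VCF (GT field mapped to dosage).
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = -1

#: Fixed climate-factor order: day length D (h), minimum temperature Tn (°C),
#: maximum temperature Tx (°C), precipitation R (mm), relative humidity H (%),
#: solar radiation S (MJ/m²).
CLIMATE_FACTORS = (
    "day_length",
    "temp_min",
    "temp_max",
    "precipitation",
    "humidity",
    "solar_radiation",
)

#: Day offsets of the climate window relative to planting (day 0): the window
#: covers the 5 days before planting (−4 … 0) and the 20 days after (+1 … +20),
#: 25 days total.
WINDOW_DAYS = tuple(range(-4, 21))

#: Inclusive upper bounds of the 15 flowering-time classes used for the mung
#: bean dataset (days to flowering ranges 25–120).
DEFAULT_CLASS_MAXIMA = (35, 40, 42, 44, 45, 47, 49, 51, 54, 59, 65, 75, 91, 110, 120)


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


@dataclass(frozen=True)
class SNPRecord:
    """Marker metadata: chromosome (number or scaffold name), 1-based bp
    position, and major/minor alleles."""

    chromosome: str
    position: int
    major_allele: str
    minor_allele: str

    def __post_init__(self):
        if self.position <= 0:
            raise ValueError(f"SNP position must be positive, got {self.position}")
        for allele in (self.major_allele, self.minor_allele):
            if allele not in {"A", "C", "G", "T"}:
                raise ValueError(f"allele must be one of A/C/G/T, got {allele!r}")


@dataclass
class GenotypeMatrix:
    """Biallelic SNP dosages for n accessions × m SNPs.

    ``values[i, j]`` is the minor-allele count of SNP j in accession i
    (0, 1, 2, or ``MISSING``).
    """

    values: np.ndarray
    accession_ids: list[str]
    snp_ids: list[str]
    snp_meta: list[SNPRecord] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be a 2-D matrix")
        n, m = self.values.shape
        if n < 2 or m < 1:
            raise ValueError(f"need at least 2 accessions and 1 SNP, got {n}×{m}")
        if len(self.accession_ids) != n:
            raise ValueError("accession_ids length must match row count")
        if len(set(self.accession_ids)) != n:
            raise ValueError("accession ids must be unique")
        if len(self.snp_ids) != m:
            raise ValueError("snp_ids length must match column count")
        if self.snp_meta is not None and len(self.snp_meta) != m:
            raise ValueError("snp_meta length must match column count")
        bad = ~np.isin(self.values, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype value {self.values[i, j]} at accession "
                f"{self.accession_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )

    @property
    def n_accessions(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def has_missing(self) -> bool:
        return bool((self.values == MISSING).any())

    def impute(self) -> "GenotypeMatrix":
        """Replace missing calls by the per-SNP mode (most frequent dosage).

        Ties break toward the lower dosage. A SNP that is entirely missing
        imputes to 0.
        """
        values = self.values.copy()
        for j in range(values.shape[1]):
            col = values[:, j]
            miss = col == MISSING
            if not miss.any():
                continue
            obs = col[~miss]
            if obs.size == 0:
                fill = 0
            else:
                counts = np.bincount(obs, minlength=3)
                fill = int(np.argmax(counts))  # argmax takes the first max: lower dosage
            col[miss] = fill
        return GenotypeMatrix(values, list(self.accession_ids), list(self.snp_ids), self.snp_meta)


@dataclass
class ClimateWindow:
    """Daily climate values for the 25-day window around planting.

    ``values`` is 6×25: rows follow :data:`CLIMATE_FACTORS`, columns the days
    −4 … +20 relative to planting (planting at day 0, column 4).
    """

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (6, 25):
            raise ValueError(f"climate window must be 6×25, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("climate window contains non-finite values")

    def factor(self, name: str) -> np.ndarray:
        return self.values[CLIMATE_FACTORS.index(name)]


@dataclass
class PhenotypeTable:
    """Days-to-flowering records, one per (accession, environment) pair."""

    records: pd.DataFrame  # columns: accession_id, environment_id, days_to_flower

    def __post_init__(self):
        df = pd.DataFrame(self.records)
        required = ["accession_id", "environment_id", "days_to_flower"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        df = df[required].copy()
        df["days_to_flower"] = df["days_to_flower"].astype(int)
        if (df["days_to_flower"] < 1).any():
            raise ValueError("days_to_flower must be ≥ 1")
        if df.duplicated(["accession_id", "environment_id"]).any():
            dup = df[df.duplicated(["accession_id", "environment_id"])].iloc[0]
            raise ValueError(
                f"duplicate (accession, environment) pair: "
                f"({dup.accession_id!r}, {dup.environment_id!r})"
            )
        self.records = df

    def __len__(self) -> int:
        return len(self.records)

    @property
    def days(self) -> np.ndarray:
        return self.records["days_to_flower"].to_numpy()


@dataclass(frozen=True)
class ClassScheme:
    """Ordered phenotype classes defined by strictly increasing inclusive
    upper bounds; class i holds values in (bounds[i−1], bounds[i]]."""

    upper_bounds: tuple[int, ...] = DEFAULT_CLASS_MAXIMA

    def __post_init__(self):
        bounds = tuple(int(b) for b in self.upper_bounds)
        if len(bounds) < 1:
            raise ValueError("need at least one class bound")
        if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
            raise ValueError("class bounds must be strictly increasing")
        object.__setattr__(self, "upper_bounds", bounds)

    @property
    def n_classes(self) -> int:
        return len(self.upper_bounds)

    def class_maximum(self, index: int) -> int:
        return self.upper_bounds[index]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(list(self.upper_bounds)))

    @classmethod
    def from_json(cls, path) -> "ClassScheme":
        return cls(tuple(json.loads(Path(path).read_text())))


def bin_phenotype(days, scheme: ClassScheme = ClassScheme()):
    """Map days-to-flowering to class indices: the smallest class whose
    inclusive upper bound is ≥ ``days``.

    Accepts a scalar or an array; raises if any value exceeds the last bound
    or is < 1.
    """
    arr = np.atleast_1d(np.asarray(days, dtype=int))
    bounds = np.asarray(scheme.upper_bounds)
    if (arr < 1).any():
        raise ValueError("days_to_flower must be ≥ 1")
    if (arr > bounds[-1]).any():
        bad = arr[arr > bounds[-1]][0]
        raise ValueError(f"days value {bad} exceeds the last class bound {bounds[-1]}")
    idx = np.searchsorted(bounds, arr, side="left")
    return int(idx[0]) if np.isscalar(days) or np.ndim(days) == 0 else idx


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_genotype(path, meta_path=None) -> GenotypeMatrix:
    """Read a genotype CSV: header of SNP ids (first column ``accession_id``),
    one row per accession, entries 0/1/2 or NA.

    ``meta_path`` optionally points to a marker-metadata CSV with columns
    snp_id, chromosome, position, major_allele, minor_allele.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, dtype=str)
    if df.columns[0] != "accession_id":
        raise ValueError("first genotype column must be 'accession_id'")
    snp_ids = list(df.columns[1:])
    accession_ids = df["accession_id"].tolist()
    if len(set(accession_ids)) != len(accession_ids):
        dup = pd.Series(accession_ids)
        dup = dup[dup.duplicated()].iloc[0]
        raise ValueError(f"duplicate accession id {dup!r}")
    raw = df.iloc[:, 1:].to_numpy()
    values = np.empty(raw.shape, dtype=np.int64)
    valid = {"0": 0, "1": 1, "2": 2, "NA": MISSING, "": MISSING}
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell == "nan":
                cell = "NA"
            if cell not in valid:
                raise ValueError(
                    f"invalid genotype value {cell!r} at row {accession_ids[i]!r}, "
                    f"column {snp_ids[j]!r}"
                )
            values[i, j] = valid[cell]
    meta = None
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, dtype={"chromosome": str})
        meta = [
            SNPRecord(str(r.chromosome), int(r.position), r.major_allele, r.minor_allele)
            for r in mdf.itertuples()
        ]
    return GenotypeMatrix(values, accession_ids, snp_ids, meta)


def write_genotype(G: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(
        np.where(G.values == MISSING, "NA", G.values.astype(str)),
        columns=G.snp_ids,
    )
    df.insert(0, "accession_id", G.accession_ids)
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, index=False)


def read_genotype_vcf(path) -> GenotypeMatrix:
    """Read genotypes from a minimal VCF: biallelic sites only, GT mapped to
    ALT-allele dosage (0/1/2), missing GT → ``MISSING``.

    Only the GT subfield is consulted; phasing separators (| or /) are
    accepted. Multi-allelic sites raise.
    """
    samples: list[str] = []
    snp_ids: list[str] = []
    meta: list[SNPRecord] = []
    rows: list[list[int]] = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            chrom, pos, vid, ref, alt = fields[0], int(fields[1]), fields[2], fields[3], fields[4]
            if "," in alt:
                raise ValueError(f"multi-allelic site at {chrom}:{pos} not supported")
            fmt = fields[8].split(":")
            try:
                gt_idx = fmt.index("GT")
            except ValueError:
                raise ValueError(f"no GT field at {chrom}:{pos}") from None
            dosages = []
            for cell in fields[9:]:
                gt = cell.split(":")[gt_idx].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    dosages.append(MISSING)
                else:
                    dosages.append(sum(int(a) for a in alleles))
            snp_ids.append(vid if vid != "." else f"{chrom}_{pos}")
            if ref in "ACGT" and alt in "ACGT":
                meta.append(SNPRecord(chrom, pos, ref, alt))
            rows.append(dosages)
    if not rows:
        raise ValueError("VCF contains no variant records")
    values = np.array(rows, dtype=np.int64).T  # sites × samples → samples × sites
    return GenotypeMatrix(values, samples, snp_ids, meta if len(meta) == len(snp_ids) else None)


def read_climate(path, planting_date) -> ClimateWindow:
    """Slice a daily climate CSV to the 25-day window around ``planting_date``.

    The CSV needs an ISO ``date`` column plus the six factor columns of
    :data:`CLIMATE_FACTORS`. Raises if any of the 25 days is absent.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, parse_dates=["date"])
    unknown = [c for c in df.columns if c not in CLIMATE_FACTORS + ("date",)]
    if unknown:
        raise ValueError(f"unknown climate columns: {unknown}")
    missing_cols = [c for c in CLIMATE_FACTORS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing climate factor columns: {missing_cols}")
    planting = pd.Timestamp(planting_date)
    wanted = [planting + pd.Timedelta(days=d) for d in WINDOW_DAYS]
    df = df.set_index("date")
    absent = [str(d.date()) for d in wanted if d not in df.index]
    if absent:
        raise ValueError(f"climate series missing required dates: {absent}")
    window = df.loc[wanted, list(CLIMATE_FACTORS)].to_numpy().T
    return ClimateWindow(window)


def write_climate(window: ClimateWindow, path, planting_date) -> None:
    planting = pd.Timestamp(planting_date)
    dates = [planting + pd.Timedelta(days=d) for d in WINDOW_DAYS]
    df = pd.DataFrame(window.values.T, columns=list(CLIMATE_FACTORS))
    df.insert(0, "date", [d.date().isoformat() for d in dates])
    with _open_text(path, "wt") as fh:
        df.to_csv(fh, index=False)


def read_phenotype(path) -> PhenotypeTable:
    with _open_text(path) as fh:
        df = pd.read_csv(fh, dtype={"accession_id": str, "environment_id": str})
    return PhenotypeTable(df)


def write_phenotype(table: PhenotypeTable, path) -> None:
    with _open_text(path, "wt") as fh:
        table.records.to_csv(fh, index=False)
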