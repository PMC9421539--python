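"""Genotype and metadata I/O.

Reads and writes the text formats the dating workflow touches: EIGENSTRAT
(.geno/.snp/.ind) genotype triplets, PLINK text (.ped/.map) as a secondary
reader, and delimited per-sample metadata tables (date mean/SD in years
before present, dating-method label, country, coordinates, family ID).

Genotype calls are stored as the count of the .snp file's *first-listed*
allele (0, 1 or 2); the dating method only consumes allele frequencies and
their trends, so the choice of counted allele is internally consistent and
immaterial downstream. Missing calls use :data:`MISSING` (-1) in memory and
the character ``9`` on disk. Physical positions are 1-based, following the
.snp convention. Coordinates are decimal degrees (WGS84 assumed); invalid
coordinates are flagged by validation, never auto-corrected.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "MODERN_DATE_BP",
    "DatingMethod",
    "GenotypeMatrix",
    "SampleRecord",
    "FormatError",
    "ConsistencyError",
    "SchemaError",
    "DEFAULT_METHOD_MAP",
    "read_eigenstrat",
    "write_eigenstrat",
    "read_plink_text",
    "read_metadata",
    "write_metadata",
    "records_to_frame",
]

#: In-memory marker for a missing genotype call.
MISSING: int = -1

#: Conventional age (years BP) assigned to modern samples.
MODERN_DATE_BP: float = 10.0


class FormatError(ValueError):
    """A file violates its format (ragged lines, illegal characters...)."""


class ConsistencyError(ValueError):
    """Companion files disagree (row counts, id counts...)."""


class SchemaError(ValueError):
    """A table is missing mandatory columns."""


class DatingMethod(str, enum.Enum):
    """How a sample's date was obtained."""

    RADIOCARBON_DIRECT = "radiocarbon_direct"
    ARCHAEOLOGICAL_CONTEXT = "archaeological_context"
    MODERN = "modern"
    OTHER = "other"


#: Default mapping from annotation strings to :class:`DatingMethod`.
#: AADR-style labels appear with both en-dash and hyphen variants.
DEFAULT_METHOD_MAP: dict[str, DatingMethod] = {
    "Direct: IntCal20": DatingMethod.RADIOCARBON_DIRECT,
    "radiocarbon_direct": DatingMethod.RADIOCARBON_DIRECT,
    "Context: Archaeological–Period": DatingMethod.ARCHAEOLOGICAL_CONTEXT,
    "Context: Archaeological-Period": DatingMethod.ARCHAEOLOGICAL_CONTEXT,
    "archaeological_context": DatingMethod.ARCHAEOLOGICAL_CONTEXT,
    "Modern": DatingMethod.MODERN,
    "modern": DatingMethod.MODERN,
    "other": DatingMethod.OTHER,
}


@dataclass
class SampleRecord:
    """Per-sample metadata.

    ``date_mean``/``date_sd`` are in years before present (present = 1950).
    Modern samples carry the conventional date of 10 BP with SD 0.
    """

    sample_id: str
    date_mean: float
    date_sd: float
    dating_method: DatingMethod
    country: str = ""
    latitude: float | None = None
    longitude: float | None = None
    family_id: str | None = None

    @property
    def is_ancient(self) -> bool:
        return self.dating_method is not DatingMethod.MODERN

    def has_valid_coordinates(self) -> bool:
        if self.latitude is None or self.longitude is None:
            return False
        return -90.0 <= self.latitude <= 90.0 and -180.0 <= self.longitude <= 180.0

    def validate(self) -> None:
        if self.date_sd < 0:
            raise ValueError(f"{self.sample_id}: negative date_sd")
        if self.dating_method is DatingMethod.MODERN:
            if self.date_mean != MODERN_DATE_BP or self.date_sd != 0:
                raise ValueError(
                    f"{self.sample_id}: modern samples must have "
                    f"date_mean={MODERN_DATE_BP}, date_sd=0"
                )
        if self.latitude is not None and not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"{self.sample_id}: latitude out of range")
        if self.longitude is not None and not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"{self.sample_id}: longitude out of range")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs allele-count matrix with an explicit missingness marker.

    ``calls[i, j]`` is the number of copies (0/1/2) of ``counted_allele[j]``
    carried by sample ``i``, or :data:`MISSING`.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray  # (n_samples, n_snps) int8, MISSING for no-call
    counted_allele: np.ndarray = field(default=None)  # type: ignore[assignment]
    other_allele: np.ndarray = field(default=None)  # type: ignore[assignment]
    chromosome: np.ndarray = field(default=None)  # type: ignore[assignment]
    position: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        m = len(self.snp_ids)
        if self.counted_allele is None:
            self.counted_allele = np.array(["A"] * m)
        if self.other_allele is None:
            self.other_allele = np.array(["G"] * m)
        if self.chromosome is None:
            self.chromosome = np.array(["1"] * m)
        if self.position is None:
            self.position = np.arange(1, m + 1, dtype=np.int64)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def validate(self) -> None:
        if self.calls.shape != (self.n_samples, self.n_snps):
            raise ConsistencyError(
                f"calls shape {self.calls.shape} does not match "
                f"{self.n_samples} samples x {self.n_snps} SNPs"
            )
        if len(set(self.sample_ids)) != self.n_samples:
            raise ConsistencyError("duplicate sample ids")
        if len(set(self.snp_ids)) != self.n_snps:
            raise ConsistencyError("duplicate SNP ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"illegal call {self.calls[i, j]} at sample "
                f"{self.sample_ids[i]}, SNP {self.snp_ids[j]}"
            )

    def subset_snps(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            snp_ids=[self.snp_ids[j] for j in index],
            calls=self.calls[:, index].copy(),
            counted_allele=self.counted_allele[index].copy(),
            other_allele=self.other_allele[index].copy(),
            chromosome=self.chromosome[index].copy(),
            position=self.position[index].copy(),
        )

    def subset_samples(self, index: Sequence[int] | np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in index],
            snp_ids=list(self.snp_ids),
            calls=self.calls[index].copy(),
            counted_allele=self.counted_allele.copy(),
            other_allele=self.other_allele.copy(),
            chromosome=self.chromosome.copy(),
            position=self.position.copy(),
        )


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

_GENO_CODE = {"0": 0, "1": 1, "2": 2, "9": MISSING}
_GENO_CHAR = {0: "0", 1: "1", 2: "2", MISSING: "9"}


def read_eigenstrat(
    geno_path: str | Path, snp_path: str | Path, ind_path: str | Path
) -> tuple[GenotypeMatrix, list[SampleRecord]]:
    """Read an EIGENSTRAT triplet.

    The .geno file has one line per SNP and one character per individual;
    the matrix is transposed to samples x SNPs on read, with ``9`` mapped to
    :data:`MISSING`. Returns the matrix and metadata *stubs* (ids and the
    .ind group label only; dates come from :func:`read_metadata`).
    """
    snp_rows = _read_snp(snp_path)
    ind_rows = _read_ind(ind_path)

    n_snps, n_ind = len(snp_rows), len(ind_rows)
    calls = np.full((n_ind, n_snps), MISSING, dtype=np.int8)
    with open(geno_path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno > n_snps:
                raise ConsistencyError(
                    f"{geno_path}: more genotype lines than .snp rows ({n_snps})"
                )
            if len(line) != n_ind:
                raise FormatError(
                    f"{geno_path}: line {lineno} has {len(line)} characters, "
                    f"expected {n_ind}"
                )
            try:
                calls[:, lineno - 1] = [_GENO_CODE[c] for c in line]
            except KeyError as exc:
                raise FormatError(
                    f"{geno_path}: illegal character {exc.args[0]!r} "
                    f"on line {lineno}"
                ) from None
        if lineno != n_snps:
            raise ConsistencyError(
                f"{geno_path}: {lineno} genotype lines but {n_snps} .snp rows"
            )

    matrix = GenotypeMatrix(
        sample_ids=[r[0] for r in ind_rows],
        snp_ids=[r[0] for r in snp_rows],
        calls=calls,
        counted_allele=np.array([r[3] for r in snp_rows]),
        other_allele=np.array([r[4] for r in snp_rows]),
        chromosome=np.array([r[1] for r in snp_rows]),
        position=np.array([r[2] for r in snp_rows], dtype=np.int64),
    )
    matrix.validate()
    stubs = [
        SampleRecord(
            sample_id=r[0],
            date_mean=float("nan"),
            date_sd=0.0,
            dating_method=DatingMethod.OTHER,
            country=r[2],
        )
        for r in ind_rows
    ]
    return matrix, stubs


def _read_snp(path: str | Path) -> list[tuple[str, str, int, str, str]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise FormatError(f"{path}: line {lineno} has {len(parts)} fields, expected 6")
            snp_id, chrom, _gpos, ppos, a1, a2 = parts[:6]
            rows.append((snp_id, chrom, int(ppos), a1, a2))
    return rows


def _read_ind(path: str | Path) -> list[tuple[str, str, str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            sample_id = parts[0]
            sex = parts[1] if len(parts) > 1 else "U"
            group = parts[2] if len(parts) > 2 else ""
            rows.append((sample_id, sex, group))
    return rows


def write_eigenstrat(
    matrix: GenotypeMatrix,
    records: Sequence[SampleRecord] | None,
    prefix: str | Path,
) -> tuple[Path, Path, Path]:
    """Write ``prefix``.geno/.snp/.ind; bit-exact inverse of the reader."""
    matrix.validate()
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno_path = prefix.with_suffix(".geno")
    snp_path = prefix.with_suffix(".snp")
    ind_path = prefix.with_suffix(".ind")

    by_id = {r.sample_id: r for r in records} if records else {}
    try:
        with open(geno_path, "w") as fh:
            for j in range(matrix.n_snps):
                fh.write("".join(_GENO_CHAR[int(c)] for c in matrix.calls[:, j]))
                fh.write("\n")
        with open(snp_path, "w") as fh:
            for j, sid in enumerate(matrix.snp_ids):
                fh.write(
                    f"{sid}\t{matrix.chromosome[j]}\t0.0\t{matrix.position[j]}"
                    f"\t{matrix.counted_allele[j]}\t{matrix.other_allele[j]}\n"
                )
        with open(ind_path, "w") as fh:
            for sid in matrix.sample_ids:
                rec = by_id.get(sid)
                group = rec.country if rec and rec.country else "Unknown"
                fh.write(f"{sid}\tU\t{group}\n")
    except OSError as exc:
        raise OSError(f"failed writing EIGENSTRAT files at {prefix}: {exc}") from exc
    return geno_path, snp_path, ind_path


# ---------------------------------------------------------------------------
# PLINK text (secondary reader)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    """Read PLINK .ped/.map text files.

    Counts the first allele observed per SNP column so calls stay on the
    0/1/2 scale; ``0 0`` genotypes map to missing.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 4:
                raise FormatError(f"{map_path}: line {lineno}: expected 4 fields")
            map_rows.append((parts[1], parts[0], int(parts[3])))
    n_snps = len(map_rows)

    sample_ids: list[str] = []
    rows: list[list[int]] = []
    counted: list[str | None] = [None] * n_snps
    other: list[str | None] = [None] * n_snps
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise FormatError(
                    f"{ped_path}: line {lineno} has {len(parts)} fields, "
                    f"expected {6 + 2 * n_snps}"
                )
            sample_ids.append(parts[1])
            row = []
            for j in range(n_snps):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                if a == "0" or b == "0":
                    row.append(MISSING)
                    continue
                for allele in (a, b):
                    if counted[j] is None:
                        counted[j] = allele
                    elif other[j] is None and allele != counted[j]:
                        other[j] = allele
                row.append(int(a == counted[j]) + int(b == counted[j]))
            rows.append(row)

    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        snp_ids=[r[0] for r in map_rows],
        calls=np.asarray(rows, dtype=np.int8).reshape(len(sample_ids), n_snps),
        counted_allele=np.array([c or "A" for c in counted]),
        other_allele=np.array([o or "G" for o in other]),
        chromosome=np.array([r[1] for r in map_rows]),
        position=np.array([r[2] for r in map_rows], dtype=np.int64),
    )
    matrix.validate()
    return matrix


# ---------------------------------------------------------------------------
# Metadata tables
# ---------------------------------------------------------------------------

_MANDATORY = ("sample_id", "date_mean", "date_sd", "dating_method")


def read_metadata(
    table_path: str | Path,
    method_map: Mapping[str, DatingMethod] | None = None,
    sep: str | None = None,
) -> list[SampleRecord]:
    """Read a delimited metadata table into :class:`SampleRecord` rows.

    Dating-method strings are mapped through ``method_map`` (default
    :data:`DEFAULT_METHOD_MAP`); unmappable strings become ``other`` rather
    than being dropped — filtering is the preprocessing stage's job.
    Delimiter is sniffed from the header (tab preferred) when ``sep`` is None.
    """
    method_map = dict(DEFAULT_METHOD_MAP if method_map is None else method_map)
    path = Path(table_path)
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    missing_cols = [c for c in _MANDATORY if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing mandatory columns {missing_cols}")

    records: list[SampleRecord] = []
    for idx, row in df.iterrows():
        for col in ("date_mean", "date_sd"):
            try:
                float(row[col])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {idx}: non-numeric {col} {row[col]!r}"
                ) from None
        raw_method = str(row["dating_method"])
        method = method_map.get(raw_method, DatingMethod.OTHER)
        if not isinstance(method, DatingMethod):
            method = DatingMethod(method)
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                date_mean=float(row["date_mean"]),
                date_sd=float(row["date_sd"]),
                dating_method=method,
                country=str(row.get("country", "")) if pd.notna(row.get("country", "")) else "",
                latitude=_opt_float(row.get("latitude")),
                longitude=_opt_float(row.get("longitude")),
                family_id=_opt_str(row.get("family_id")),
            )
        )
    return records


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value)
    return s if s and s.lower() != "nan" else None


def records_to_frame(records: Iterable[SampleRecord]) -> pd.DataFrame:
    rows = [
        {
            "sample_id": r.sample_id,
            "date_mean": r.date_mean,
            "date_sd": r.date_sd,
            "dating_method": r.dating_method.value,
            "country": r.country,
            "latitude": r.latitude,
            "longitude": r.longitude,
            "family_id": r.family_id,
            "is_ancient": r.is_ancient,
        }
        for r in records
    ]
    return pd.DataFrame(rows)


def write_metadata(records: Iterable[SampleRecord], path: str | Path, sep: str = "\t") -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = records_to_frame(records).drop(columns=["is_ancient"])
    df.to_csv(path, sep=sep, index=False)
    return path
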