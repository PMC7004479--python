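"""Domain types and file I/O for the decomplexing-venomics pipeline.

The pipeline moves through five kinds of data:

* a 215 nm RP-HPLC absorbance trace (:class:`Chromatogram`) plus manually
  collected fraction windows (:class:`FractionBoundarySet`), from which the
  chromatographic share ``f_i`` of each fraction is integrated;
* peptide-spectrum matches (:class:`PsmRecord`) per fraction, with the search
  scores, scored peak intensity (SPI) and spectral intensity used for
  filtering and label-free quantification;
* an accession -> toxin-family map (:class:`FamilyMap`) over the controlled
  vocabulary of snake-venom protein families;
* per-protein whole-venom relative abundances (:class:`AbundanceTable`,
  percent of total venom protein, plus an unidentified bucket);
* indirect-ELISA plate readings at 492 nm (:class:`ElisaPlate`).

All on-disk formats are plain CSV/TSV with documented headers; every reader
validates the type invariants and raises a row-addressable error.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    MalformedRecord,
    MalformedTrace,
    SchemaError,
    VocabularyError,
)

#: Controlled vocabulary of toxin-family labels.
FAMILY_VOCABULARY = frozenset(
    {
        "KSPI",     # Kunitz-type serine protease inhibitor
        "PLA2",     # phospholipase A2
        "snaclec",  # snake venom C-type lectin/lectin-like protein
        "SVSP",     # snake venom serine protease
        "SVMP",     # snake venom metalloproteinase
        "LAAO",     # L-amino acid oxidase
        "svVEGF",   # snake venom vascular endothelial growth factor
        "svNGF",    # snake venom nerve growth factor
        "5NUC",     # 5'-nucleotidase
        "PDE",      # phosphodiesterase
        "DIS",      # disintegrin
        "OTHER",
    }
)

CHROMATOGRAM_COLUMNS = ("time_min", "absorbance_mau")
PSM_COLUMNS = (
    "fraction_id",
    "accession",
    "protein_name",
    "species",
    "peptide",
    "protein_score",
    "peptide_score",
    "spi",
    "intensity",
    "is_decoy",
)
BOUNDARY_COLUMNS = ("fraction_id", "start_min", "end_min", "collected")
ELISA_COLUMNS = ("fraction_id", "antivenom", "replicate", "a492", "is_blank", "is_control")


# ---------------------------------------------------------------------------
# Chromatography types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromatogram:
    """A timed absorbance trace (215 nm), time in minutes, absorbance in mAU.

    ``meta`` optionally carries the flow rate (mL/min) and the mobile-phase
    gradient program as ``[((t0, t1), pct_b), ...]`` segments.
    """

    time: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "absorbance", a)
        if t.ndim != 1 or a.shape != t.shape:
            raise MalformedTrace("time and absorbance must be 1-D arrays of equal length")
        if t.size < 2:
            raise MalformedTrace(f"trace needs at least 2 points, got {t.size}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(a)):
            raise MalformedTrace("trace contains non-finite values")
        if not np.all(np.diff(t) > 0):
            bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise MalformedTrace(f"time must be strictly increasing (violated at row {bad})")

    def __len__(self) -> int:
        return int(self.time.size)

    def with_absorbance(self, absorbance: np.ndarray) -> "Chromatogram":
        return replace(self, absorbance=np.asarray(absorbance, dtype=float))


@dataclass(frozen=True)
class FractionBoundary:
    fraction_id: str
    start: float
    end: float
    collected: bool = True


@dataclass(frozen=True)
class FractionBoundarySet:
    """Sorted, non-overlapping half-open fraction windows ``[start, end)`` in minutes."""

    entries: tuple[FractionBoundary, ...]

    def __post_init__(self) -> None:
        entries = tuple(sorted(self.entries, key=lambda b: b.start))
        object.__setattr__(self, "entries", entries)
        for b in entries:
            if not (b.end > b.start):
                raise MalformedRecord(f"fraction {b.fraction_id}: end must exceed start")
        for prev, nxt in zip(entries, entries[1:]):
            if nxt.start < prev.end - 1e-12:
                raise MalformedRecord(
                    f"fractions {prev.fraction_id} and {nxt.fraction_id} overlap"
                )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def collected(self) -> tuple[FractionBoundary, ...]:
        return tuple(b for b in self.entries if b.collected)


class FractionShareTable(dict):
    """fraction_id -> share f_i of total integrated area (proportions, sum 1)."""

    def validate(self) -> "FractionShareTable":
        for fid, f in self.items():
            if f < 0:
                raise MalformedRecord(f"fraction {fid}: negative share {f}")
        if self and abs(sum(self.values()) - 1.0) > 1e-9:
            raise MalformedRecord(f"fraction shares sum to {sum(self.values())}, expected 1")
        return self


# ---------------------------------------------------------------------------
# PSM types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match.

    ``spi`` is the scored peak intensity in percent (0-100); ``intensity`` is
    the spectral intensity in arbitrary units used for MSI quantification.
    """

    fraction_id: str
    accession: str
    protein_name: str
    species: str
    peptide: str
    protein_score: float
    peptide_score: float
    spi: float
    intensity: float
    is_decoy: bool

    def __post_init__(self) -> None:
        if not self.accession:
            raise MalformedRecord("accession must be nonempty")
        if not (0.0 <= self.spi <= 100.0):
            raise MalformedRecord(f"spi {self.spi} outside [0, 100]")
        if self.intensity < 0:
            raise MalformedRecord(f"negative intensity {self.intensity}")


@dataclass(frozen=True)
class FilterThresholds:
    """Validation filter cascade: all three score filters are strict ``>``."""

    min_protein_score: float = 20.0
    min_peptide_score: float = 10.0
    min_spi: float = 70.0
    max_fdr: float = 0.01

    def __post_init__(self) -> None:
        for name in ("min_protein_score", "min_peptide_score", "min_spi"):
            if not np.isfinite(getattr(self, name)):
                raise MalformedRecord(f"{name} must be finite")
        if not (0.0 < self.max_fdr < 1.0):
            raise MalformedRecord(f"max_fdr {self.max_fdr} outside (0, 1)")


# ---------------------------------------------------------------------------
# Family map and abundance tables
# ---------------------------------------------------------------------------

class FamilyMap(dict):
    """accession -> toxin-family label over :data:`FAMILY_VOCABULARY`."""

    def __init__(self, mapping: Mapping[str, str] | Iterable[tuple[str, str]] = ()):
        super().__init__(mapping)
        for acc, fam in self.items():
            if fam not in FAMILY_VOCABULARY:
                raise VocabularyError(
                    f"family {fam!r} for accession {acc!r} not in controlled vocabulary"
                )

    def family_of(self, accession: str, warn_unmapped: bool = True) -> str:
        """Look up an accession; unmapped accessions fall back to OTHER."""
        try:
            return self[accession]
        except KeyError:
            if warn_unmapped:
                warnings.warn(f"accession {accession!r} not in family map; using OTHER")
            return "OTHER"


@dataclass
class AbundanceTable:
    """Per-protein whole-venom relative abundances (% of total venom protein).

    ``proteins`` has columns (accession, protein_name, family, fraction_id,
    abundance_pct); ``unidentified_pct`` is the summed share of collected
    fractions in which no protein was identified.  ``meta`` may carry the
    per-fraction breakdown of the unidentified bucket.
    """

    venom_id: str
    proteins: pd.DataFrame
    unidentified_pct: float = 0.0
    meta: dict = field(default_factory=dict)

    _COLUMNS = ("accession", "protein_name", "family", "fraction_id", "abundance_pct")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.proteins.columns)
        if missing:
            raise SchemaError(f"abundance table missing columns {sorted(missing)}")
        if (self.proteins["abundance_pct"] < 0).any():
            raise MalformedRecord("negative abundance")
        if self.unidentified_pct < 0:
            raise MalformedRecord("negative unidentified share")

    @property
    def total_pct(self) -> float:
        return float(self.proteins["abundance_pct"].sum() + self.unidentified_pct)

    def check_conservation(self, tol: float = 1e-6) -> None:
        if abs(self.total_pct - 100.0) > tol:
            raise MalformedRecord(
                f"{self.venom_id}: abundances + unidentified sum to {self.total_pct}, "
                f"expected 100 within {tol}"
            )


# ---------------------------------------------------------------------------
# ELISA plate
# ---------------------------------------------------------------------------

@dataclass
class ElisaPlate:
    """Indirect-ELISA wells: replicate A492 per (antigen fraction, antivenom).

    ``meta`` carries the antivenom dilution (default 1:2700) and the antigen
    coat mass in ng (default 10).
    """

    wells: pd.DataFrame
    meta: dict = field(default_factory=lambda: {"dilution": "1:2700", "coat_ng": 10.0})

    def __post_init__(self) -> None:
        missing = set(ELISA_COLUMNS) - set(self.wells.columns)
        if missing:
            raise SchemaError(f"ELISA table missing columns {sorted(missing)}")
        if (self.wells["a492"] < 0).any():
            row = int(self.wells.index[self.wells["a492"] < 0][0])
            raise MalformedRecord(f"row {row}: negative A492")
        if not bool(self.wells["is_blank"].any()):
            raise MalformedRecord("plate has no blank well")
        sample = self.wells[~self.wells["is_blank"]]
        counts = sample.groupby(["fraction_id", "antivenom"]).size()
        low = counts[counts < 2]
        if len(low):
            fid, av = low.index[0]
            raise MalformedRecord(f"cell ({fid}, {av}) has {int(low.iloc[0])} replicate(s), need >= 2")


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def read_chromatogram(path: str | Path) -> Chromatogram:
    """Read a two-column (time_min, absorbance_mau) CSV trace."""
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise MalformedTrace(f"{path}: empty file") from exc
    _require_columns(df, CHROMATOGRAM_COLUMNS, str(path))
    if len(df) < 2:
        raise MalformedTrace(f"{path}: trace needs at least 2 rows, got {len(df)}")
    return Chromatogram(df["time_min"].to_numpy(float), df["absorbance_mau"].to_numpy(float))


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    pd.DataFrame({"time_min": chrom.time, "absorbance_mau": chrom.absorbance}).to_csv(
        path, index=False
    )


def read_boundaries(path: str | Path) -> FractionBoundarySet:
    """Read a fraction-boundary TSV (fraction_id, start_min, end_min, collected)."""
    df = pd.read_csv(path, sep="\t")
    _require_columns(df, BOUNDARY_COLUMNS, str(path))
    entries = tuple(
        FractionBoundary(str(r.fraction_id), float(r.start_min), float(r.end_min), bool(r.collected))
        for r in df.itertuples()
    )
    return FractionBoundarySet(entries)


def write_boundaries(bounds: FractionBoundarySet, path: str | Path) -> None:
    pd.DataFrame(
        {
            "fraction_id": [b.fraction_id for b in bounds],
            "start_min": [b.start for b in bounds],
            "end_min": [b.end for b in bounds],
            "collected": [int(b.collected) for b in bounds],
        }
    ).to_csv(path, sep="\t", index=False)


def read_psm_table(path: str | Path, decoy_prefix: str | None = None) -> list[PsmRecord]:
    """Read a PSM TSV with the nine documented columns plus the decoy flag.

    ``decoy_prefix`` (commonly ``"DECOY_"``) additionally marks any accession
    carrying that prefix as a decoy, for tables that encode decoys by
    accession convention instead of (or as well as) the 0/1 flag column.
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    _require_columns(df, PSM_COLUMNS, str(path))
    records: list[PsmRecord] = []
    for i, r in enumerate(df.itertuples(), start=2):  # header is line 1
        is_decoy = bool(r.is_decoy)
        acc = str(r.accession)
        if decoy_prefix and acc.startswith(decoy_prefix):
            is_decoy = True
        try:
            records.append(
                PsmRecord(
                    fraction_id=str(r.fraction_id),
                    accession=acc,
                    protein_name=str(r.protein_name),
                    species=str(r.species),
                    peptide=str(r.peptide),
                    protein_score=float(r.protein_score),
                    peptide_score=float(r.peptide_score),
                    spi=float(r.spi),
                    intensity=float(r.intensity),
                    is_decoy=is_decoy,
                )
            )
        except MalformedRecord as exc:
            raise MalformedRecord(f"{path} line {i}: {exc}") from exc
    return records


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    rows = [
        {
            "fraction_id": p.fraction_id,
            "accession": p.accession,
            "protein_name": p.protein_name,
            "species": p.species,
            "peptide": p.peptide,
            "protein_score": p.protein_score,
            "peptide_score": p.peptide_score,
            "spi": p.spi,
            "intensity": p.intensity,
            "is_decoy": int(p.is_decoy),
        }
        for p in psms
    ]
    pd.DataFrame(rows, columns=list(PSM_COLUMNS)).to_csv(path, sep="\t", index=False)


def read_family_map(path: str | Path) -> FamilyMap:
    """Read an accession -> family TSV; unknown family labels raise VocabularyError."""
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    _require_columns(df, ("accession", "family"), str(path))
    return FamilyMap({str(r.accession): str(r.family) for r in df.itertuples()})


def write_family_map(fmap: FamilyMap, path: str | Path) -> None:
    pd.DataFrame(sorted(fmap.items()), columns=["accession", "family"]).to_csv(
        path, sep="\t", index=False
    )


def read_elisa_plate(path: str | Path, meta: dict | None = None) -> ElisaPlate:
    """Read a long-format ELISA CSV (fraction_id, antivenom, replicate, a492, is_blank, is_control)."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no wells")
    _require_columns(df, ELISA_COLUMNS, str(path))
    df = df.assign(
        fraction_id=df["fraction_id"].astype(str),
        antivenom=df["antivenom"].astype(str),
        is_blank=df["is_blank"].astype(bool),
        is_control=df["is_control"].astype(bool),
        a492=df["a492"].astype(float),
    )
    kwargs = {"meta": meta} if meta is not None else {}
    return ElisaPlate(df, **kwargs)


def write_elisa_plate(plate: ElisaPlate, path: str | Path) -> None:
    out = plate.wells.copy()
    out["is_blank"] = out["is_blank"].astype(int)
    out["is_control"] = out["is_control"].astype(int)
    out.to_csv(path, index=False)


def read_abundance_table(path: str | Path, venom_id: str | None = None) -> AbundanceTable:
    """Read a per-protein abundance TSV written by :func:`write_abundance_table`.

    The ``__unidentified__`` accession row, if present, is split off into the
    unidentified bucket.
    """
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    _require_columns(df, AbundanceTable._COLUMNS, str(path))
    mask = df["accession"] == "__unidentified__"
    unident = float(df.loc[mask, "abundance_pct"].sum())
    proteins = df.loc[~mask].reset_index(drop=True)
    proteins = proteins.assign(abundance_pct=proteins["abundance_pct"].astype(float))
    vid = venom_id if venom_id is not None else str(Path(path).stem)
    return AbundanceTable(venom_id=vid, proteins=proteins, unidentified_pct=unident)


def write_abundance_table(
    table: AbundanceTable,
    proteins_path: str | Path,
    families_path: str | Path | None = None,
) -> None:
    """Write the per-protein sheet (with an unidentified row) and, optionally,
    the per-family aggregate sheet.

    Abundances are carried internally as exact floats; the on-disk rendering
    uses enough digits to round-trip losslessly.
    """
    out = table.proteins.loc[:, list(AbundanceTable._COLUMNS)].copy()
    bucket = pd.DataFrame(
        [
            {
                "accession": "__unidentified__",
                "protein_name": "(Unidentified)",
                "family": "OTHER",
                "fraction_id": ";".join(table.meta.get("unidentified_fractions", [])),
                "abundance_pct": table.unidentified_pct,
            }
        ]
    )
    out = pd.concat([out, bucket], ignore_index=True)
    out.to_csv(proteins_path, sep="\t", index=False, float_format="%.10g")
    if families_path is not None:
        from .quantification import aggregate_families  # local import: avoid cycle

        fam = aggregate_families(table, FamilyMap(dict(zip(table.proteins["accession"],
                                                           table.proteins["family"]))))
        fam.to_csv(families_path, sep="\t", index=False, float_format="%.10g")


def write_comparison(comparison: "pd.DataFrame | dict", path: str | Path, **extra) -> None:
    """Serialise a venom comparison (per-family table + counts) to JSON."""
    if isinstance(comparison, pd.DataFrame):
        payload = {"families": comparison.to_dict(orient="records")}
    else:
        payload = dict(comparison)
    payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def format_percent(x: float) -> str:
    """Render a proportion-derived percentage with 2 decimals (table convention)."""
    return f"{x:.2f}"
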