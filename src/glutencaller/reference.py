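"""Embedded reference library of wheat HMW-GS alleles and cultivar tables.

The library bundles, as plain TSV fixtures:

* the 22 named HMW-GS subunits (alleles) of the Glu-A1/Glu-B1/Glu-D1 loci,
  with cysteine counts, gene accessions and gene-predicted mature-protein
  masses where public sequences exist;
* the locus haplotypes (tightly linked x+y pairs) observed in the curated
  cultivar panels, e.g. "13+16" or "5+10";
* a standards panel of 24 internationally used cultivars with replicate-mean
  measured masses (alkylated, i.e. 4-vp adducted) per expressed subunit;
* a validation panel of 38 Korean cultivars in the same layout;
* the per-observation comparison table of adduct-corrected measured masses
  against gene-predicted masses.

1Bx7 is special: one legacy subunit name covers three distinguishable gene
variants. "group 1" is the lower-mass class (~82,400 Da corrected), "group 2"
the higher-mass class (~83,000 Da, carrying an 18 bp coding insertion), and
"7OE" the overexpression variant that is mass-identical to group 2 but
carries a gene duplication detectable only by PCR. The library stores them
as three records sharing the display name "7" ("7OE" for the duplication
variant).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import SchemaError, UnknownAlleleError, ValidationError
from .masses import round_half_away, vp_shift

LOCI = ("Glu-A1", "Glu-B1", "Glu-D1")

#: Acquisition mass range of the instrument protocol, Da.
ACQUISITION_RANGE = (60_000.0, 110_000.0)

#: Tightly linked Glu-B1 pairs used to disambiguate near-isobaric subunits.
LINKED_PAIRS = {"1Bx13": "1By16", "1Bx14": "1By15",
                "1Bx17": "1By18", "1Bx20": "1By20"}

@dataclass(frozen=True)
class MassStats:
    mean: int
    min: float
    max: float
    n: int


@dataclass(frozen=True)
class AlleleRecord:
    """One HMW-GS subunit (or one 1Bx7 variant)."""

    name: str                 # canonical subunit name, e.g. "1By8*"
    locus: str                # Glu-A1 | Glu-B1 | Glu-D1
    subunit_type: str         # "x" | "y"
    cysteine_count: int
    display: str              # short form used in composition strings
    variant: str | None = None          # group1 | group2 | OE for 1Bx7
    predicted_mature_mass: float | None = None
    accession: str | None = None
    notes: str = ""
    #: (cultivar, alkylated measured mass in Da) observations, standards only
    reference_masses: tuple[tuple[str, float], ...] = ()

    @property
    def key(self) -> str:
        return f"{self.name}:{self.variant}" if self.variant else self.name

    @property
    def corrected_reference_masses(self) -> tuple[float, ...]:
        """Reference masses with the 4-vp adduct removed (float, unfloored)."""
        shift = vp_shift(self.cysteine_count)
        return tuple(m - shift for _, m in self.reference_masses)


@dataclass(frozen=True)
class LocusHaplotype:
    """A tightly linked x(+y) allele pair inherited as a unit."""

    locus: str
    label: str                    # display label, e.g. "7+9" or "N"
    x_key: str | None = None      # allele key ("1Bx7" means any non-OE variant)
    y_key: str | None = None
    #: haplotypes excluded from the mass-only search (7OE+8* is mass-identical
    #: to 7+8*; it is selected after the search from PCR evidence)
    searchable: bool = True

    @property
    def members(self) -> tuple[str | None, str | None]:
        return (self.x_key, self.y_key)


@dataclass
class ReferenceLibrary:
    alleles: dict[str, AlleleRecord]
    haplotypes: list[LocusHaplotype]
    standards: pd.DataFrame
    korean: pd.DataFrame
    predicted: pd.DataFrame

    # -- lookup -----------------------------------------------------------

    def records_for(self, allele: str) -> list[AlleleRecord]:
        """All records for a subunit name or exact variant key.

        ``"1Bx7"`` returns the three variant records; ``"1Bx7:group1"`` or
        any plain name returns a single record.
        """
        if allele in self.alleles:
            return [self.alleles[allele]]
        recs = [r for r in self.alleles.values() if r.name == allele]
        if not recs:
            raise UnknownAlleleError(allele)
        return recs

    def haplotypes_for(self, locus: str) -> list[LocusHaplotype]:
        return [h for h in self.haplotypes if h.locus == locus]

    @property
    def subunit_names(self) -> list[str]:
        """The distinct named subunits; the overexpression variant counts as
        its own name ("1Bx7OE") alongside plain "1Bx7"."""
        seen: dict[str, None] = {}
        for rec in self.alleles.values():
            name = "1Bx7OE" if (rec.name, rec.variant) == ("1Bx7", "OE") else rec.name
            seen.setdefault(name, None)
        return list(seen)

    # -- statistics -------------------------------------------------------

    def mass_stats(self, allele: str) -> MassStats:
        obs = [m for rec in self.records_for(allele)
               for _, m in rec.reference_masses]
        if not obs:
            raise ValidationError(f"no reference masses for {allele}")
        mean = int(round_half_away(sum(obs) / len(obs), 0))
        return MassStats(mean=mean, min=min(obs), max=max(obs), n=len(obs))

    def window(self, allele: str, tol: float) -> tuple[float, float]:
        if tol < 0:
            raise ValidationError("tolerance must be >= 0")
        stats = self.mass_stats(allele)
        return (stats.min - tol, stats.max + tol)

    def corrected_stats(self, allele: str) -> MassStats:
        """Like :meth:`mass_stats` but on adduct-corrected masses."""
        obs = [m for rec in self.records_for(allele)
               for m in rec.corrected_reference_masses]
        if not obs:
            raise ValidationError(f"no reference masses for {allele}")
        mean = int(round_half_away(sum(obs) / len(obs), 0))
        return MassStats(mean=mean, min=min(obs), max=max(obs), n=len(obs))

    def corrected_window(self, allele: str, tol: float) -> tuple[float, float]:
        if tol < 0:
            raise ValidationError("tolerance must be >= 0")
        s = self.corrected_stats(allele)
        return (s.min - tol, s.max + tol)

    # -- composition parsing ----------------------------------------------

    def haplotype_by_label(self, locus: str, label: str) -> LocusHaplotype:
        label = label.replace(" ", "")
        for hap in self.haplotypes_for(locus):
            if hap.label == label:
                return hap
        raise UnknownAlleleError(f"{locus} haplotype {label!r}")

    def row_peaks(self, row: Mapping) -> list[float]:
        """Measured masses of one cultivar-table row, sorted ascending."""
        cols = ("a1x_mass", "b1x_mass", "b1y_mass", "d1x_mass", "d1y_mass")
        return sorted(float(row[c]) for c in cols if pd.notna(row[c]))

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Write the five fixture tables back out (round-trips with
        :func:`load_library`)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        frames = {
            "alleles.tsv": self._alleles_frame(),
            "haplotypes.tsv": self._haplotypes_frame(),
            "standards_table2.tsv": self.standards,
            "korean_table4.tsv": self.korean,
            "predicted_table3.tsv": self.predicted,
        }
        for name, frame in frames.items():
            frame.to_csv(directory / name, sep="\t", index=False)

    def _alleles_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.alleles.values():
            rows.append({
                "name": rec.name, "variant": rec.variant or "",
                "locus": rec.locus, "subunit_type": rec.subunit_type,
                "cysteine_count": rec.cysteine_count, "display": rec.display,
                "predicted_mass": rec.predicted_mature_mass,
                "accession": rec.accession or "", "notes": rec.notes,
            })
        return pd.DataFrame(rows)

    def _haplotypes_frame(self) -> pd.DataFrame:
        rows = [{"locus": h.locus, "label": h.label,
                 "x_allele": h.x_key or "", "y_allele": h.y_key or "",
                 "searchable": "true" if h.searchable else "false"}
                for h in self.haplotypes]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# loading


def _read_tsv(directory: Path | None, name: str) -> pd.DataFrame:
    try:
        if directory is None:
            ref = resources.files("glutencaller.data").joinpath(name)
            with resources.as_file(ref) as path:
                return pd.read_csv(path, sep="\t", dtype=str,
                                   keep_default_na=False, na_values=[""])
        return pd.read_csv(Path(directory) / name, sep="\t", dtype=str,
                           keep_default_na=False, na_values=[""])
    except FileNotFoundError:
        raise SchemaError("missing fixture", file=name) from None
    except pd.errors.ParserError as exc:
        raise SchemaError(f"unparseable fixture: {exc}", file=name) from None


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError("missing columns", file=name, column=missing)


def _float_cell(df_name, value, row, col, optional=False):
    if pd.isna(value):
        if optional:
            return None
        raise SchemaError("missing value", file=df_name, row=row, column=col)
    try:
        return float(value)
    except (TypeError, ValueError):
        raise SchemaError(f"non-numeric value {value!r}",
                          file=df_name, row=row, column=col) from None


def _slot_allele_key(locus: str, slot: str, part: str,
                     bx7_group: str | None) -> str:
    """Map one composition-label part to a canonical allele key."""
    if locus == "Glu-A1":
        return f"1Ax{part}"
    prefix = {"Glu-B1": "1B", "Glu-D1": "1D"}[locus] + slot
    if locus == "Glu-B1" and slot == "x" and part in ("7", "7OE"):
        if part == "7OE":
            return "1Bx7:OE"
        if bx7_group in ("group1", "group2"):
            return f"1Bx7:{bx7_group}"
        return "1Bx7"
    return prefix + part


def parse_haplotype_label(locus: str, label: str,
                          bx7_group: str | None = None
                          ) -> tuple[str | None, str | None]:
    """Split a composition label like ``"7+9"`` into (x key, y key)."""
    label = label.replace(" ", "")
    if locus == "Glu-A1":
        if label == "N":
            return (None, None)
        return (_slot_allele_key(locus, "x", label, None), None)
    if "+" in label:
        x_part, y_part = label.split("+", 1)
    else:
        x_part, y_part = label, None
    x_key = _slot_allele_key(locus, "x", x_part, bx7_group)
    y_key = (_slot_allele_key(locus, "y", y_part, None)
             if y_part is not None else None)
    return (x_key, y_key)


def _build_alleles(alleles_df: pd.DataFrame) -> dict[str, AlleleRecord]:
    name = "alleles.tsv"
    _require_columns(alleles_df, ["name", "variant", "locus", "subunit_type",
                                  "cysteine_count", "display",
                                  "predicted_mass", "accession"], name)
    records: dict[str, AlleleRecord] = {}
    for i, row in alleles_df.iterrows():
        cys = row["cysteine_count"]
        try:
            cys = int(cys)
        except (TypeError, ValueError):
            raise SchemaError(f"non-integer cysteine count {cys!r}",
                              file=name, row=i, column="cysteine_count") from None
        predicted = _float_cell(name, row["predicted_mass"], i,
                                "predicted_mass", optional=True)
        rec = AlleleRecord(
            name=row["name"],
            locus=row["locus"],
            subunit_type=row["subunit_type"],
            cysteine_count=cys,
            display=row["display"],
            variant=None if pd.isna(row["variant"]) else row["variant"],
            predicted_mature_mass=predicted,
            accession=None if pd.isna(row["accession"]) else row["accession"],
            notes="" if pd.isna(row.get("notes")) else row.get("notes"),
        )
        if rec.key in records:
            raise SchemaError("duplicate allele", file=name, row=i, column="name")
        records[rec.key] = rec
    return records


def _attach_reference_masses(records: dict[str, AlleleRecord],
                             standards: pd.DataFrame) -> None:
    obs: dict[str, list[tuple[str, float]]] = {k: [] for k in records}
    slots = (("Glu-A1", "glu_a1", "a1x_mass", None),
             ("Glu-B1", "glu_b1", "b1x_mass", "b1y_mass"),
             ("Glu-D1", "glu_d1", "d1x_mass", "d1y_mass"))
    for i, row in standards.iterrows():
        group = row.get("bx7_group")
        group = None if pd.isna(group) else group
        for locus, comp_col, x_col, y_col in slots:
            x_key, y_key = parse_haplotype_label(locus, row[comp_col], group)
            for key, col in ((x_key, x_col), (y_key, y_col)):
                if key is None:
                    continue
                mass = _float_cell("standards_table2.tsv", row[col], i, col)
                if key not in obs:
                    raise SchemaError(f"unknown allele {key!r} in composition",
                                      file="standards_table2.tsv", row=i,
                                      column=comp_col)
                obs[key].append((row["cultivar"], mass))
    for key, masses in obs.items():
        records[key] = replace(records[key], reference_masses=tuple(masses))


def _build_haplotypes(df: pd.DataFrame) -> list[LocusHaplotype]:
    _require_columns(df, ["locus", "label", "x_allele", "y_allele",
                          "searchable"], "haplotypes.tsv")
    haps = []
    for i, row in df.iterrows():
        haps.append(LocusHaplotype(
            locus=row["locus"],
            label=row["label"],
            x_key=None if pd.isna(row["x_allele"]) else row["x_allele"],
            y_key=None if pd.isna(row["y_allele"]) else row["y_allele"],
            searchable=str(row["searchable"]).lower() != "false",
        ))
    return haps


def _coerce_cultivar_table(df: pd.DataFrame, name: str) -> pd.DataFrame:
    cols = ["cultivar", "glu_a1", "glu_b1", "glu_d1"]
    mass_cols = ["a1x_mass", "b1x_mass", "b1y_mass", "d1x_mass", "d1y_mass"]
    rsd_cols = ["a1x_rsd", "b1x_rsd", "b1y_rsd", "d1x_rsd", "d1y_rsd"]
    _require_columns(df, cols + mass_cols + rsd_cols, name)
    df = df.copy()
    for col in mass_cols + rsd_cols:
        for i, value in df[col].items():
            _float_cell(name, value, i, col, optional=True)
        df[col] = pd.to_numeric(df[col])
    return df


def validate_library(lib: ReferenceLibrary) -> None:
    """Enforce the structural invariants of the curated data."""
    for rec in lib.alleles.values():
        expected = {"1Dx5": 5, "1Bx20": 2}.get(
            rec.name, 7 if rec.subunit_type == "y" else 4)
        if rec.cysteine_count != expected:
            raise SchemaError(
                f"{rec.key}: cysteine count {rec.cysteine_count}, "
                f"expected {expected}", file="alleles.tsv")
        for cultivar, mass in rec.reference_masses:
            if not ACQUISITION_RANGE[0] <= mass <= ACQUISITION_RANGE[1]:
                raise SchemaError(
                    f"{rec.key}: mass {mass} ({cultivar}) outside "
                    f"acquisition range", file="standards_table2.tsv")
    for hap in lib.haplotypes:
        for key in hap.members:
            if key is None:
                continue
            base = key.split(":", 1)[0]
            if base not in {r.name for r in lib.alleles.values()}:
                raise SchemaError(f"haplotype {hap.label}: unknown member "
                                  f"{key}", file="haplotypes.tsv")
        if hap.locus == "Glu-A1" and hap.y_key is not None:
            raise SchemaError("Glu-A1 haplotype with a y member",
                              file="haplotypes.tsv")
        if hap.locus == "Glu-B1" and hap.x_key is None:
            raise SchemaError("Glu-B1 haplotype without an x member",
                              file="haplotypes.tsv")
        if hap.locus == "Glu-D1" and (hap.x_key is None or hap.y_key is None):
            raise SchemaError("Glu-D1 haplotype missing a member",
                              file="haplotypes.tsv")
        if hap.locus == "Glu-B1" and hap.x_key in LINKED_PAIRS:
            if hap.y_key != LINKED_PAIRS[hap.x_key]:
                raise SchemaError(
                    f"{hap.x_key} paired with {hap.y_key}, expected "
                    f"{LINKED_PAIRS[hap.x_key]}", file="haplotypes.tsv")
    if len(lib.standards) != 24:
        raise SchemaError(f"expected 24 standard cultivars, found "
                          f"{len(lib.standards)}", file="standards_table2.tsv")
    if len(lib.korean) != 38:
        raise SchemaError(f"expected 38 Korean cultivars, found "
                          f"{len(lib.korean)}", file="korean_table4.tsv")
    if len(lib.subunit_names) != 22:
        raise SchemaError(f"expected 22 subunit names, found "
                          f"{len(lib.subunit_names)}", file="alleles.tsv")


def load_library(directory: str | Path | None = None) -> ReferenceLibrary:
    """Load the packaged reference library (or one from ``directory``).

    Deterministic; raises :class:`SchemaError` naming file/row/column when a
    fixture is malformed, and validates all structural invariants.
    """
    directory = None if directory is None else Path(directory)
    alleles_df = _read_tsv(directory, "alleles.tsv")
    haplotypes_df = _read_tsv(directory, "haplotypes.tsv")
    standards = _coerce_cultivar_table(
        _read_tsv(directory, "standards_table2.tsv"), "standards_table2.tsv")
    korean = _coerce_cultivar_table(
        _read_tsv(directory, "korean_table4.tsv"), "korean_table4.tsv")
    predicted = _read_tsv(directory, "predicted_table3.tsv")
    _require_columns(predicted, ["allele", "variant", "accession",
                                 "predicted_mass", "cultivar",
                                 "corrected_mass", "difference", "error_pct"],
                     "predicted_table3.tsv")
    for col in ("predicted_mass", "corrected_mass", "difference", "error_pct"):
        predicted = predicted.copy()
        predicted[col] = pd.to_numeric(predicted[col])

    records = _build_alleles(alleles_df)
    _attach_reference_masses(records, standards)
    lib = ReferenceLibrary(
        alleles=records,
        haplotypes=_build_haplotypes(haplotypes_df),
        standards=standards,
        korean=korean,
        predicted=predicted,
    )
    validate_library(lib)
    return lib


# module-level convenience wrappers matching the operation names used in docs

def allele_mass_stats(library: ReferenceLibrary, allele: str) -> MassStats:
    """Mean (integer Da), min, max and count of the standards-panel measured
    masses for one subunit."""
    return library.mass_stats(allele)


def allele_window(library: ReferenceLibrary, allele: str,
                  tol: float) -> tuple[float, float]:
    """``[min - tol, max + tol]`` interval of the standards-panel measured
    masses for one subunit."""
    return library.window(allele, tol)
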