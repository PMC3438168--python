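"""Domain types for a local flora and its identification substrates.

Two parallel data substrates describe a flora:

* a :class:`CharacterMatrix` — taxa scored against categorical
  morpho-anatomical characters, each character tagged with the organ it is
  observed on (whole plant, leaf, flower, fruit) and whether it is seasonal;
* a :class:`BarcodeLibrary` — aligned reference sequences for one or more
  plastid markers (rbcL, matK, trnH-psbA by default), one flagged reference
  individual per species plus optional extra individuals for intraspecific
  variability surveys.

Readers and writers use plain-text formats: TSV for the matrix (with a
sidecar character-definition table) and one FASTA file per marker with
pipe-delimited ``voucher|taxon|marker[|role]`` headers.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Reserved token for an unscored matrix cell.
UNKNOWN = "?"

#: Allowed organ tags for characters.
ORGANS = frozenset({"whole-plant", "leaf", "flower", "fruit", "other"})

#: Default declared marker set (extensible per library).
DEFAULT_MARKERS = ("rbcL", "matK", "trnH-psbA")

#: Default FASTA header grammar: voucher|taxon|marker with optional role.
DEFAULT_HEADER_PATTERN = (
    r"^(?P<voucher>[^|]+)\|(?P<taxon>[^|]+)\|(?P<marker>[^|]+)"
    r"(?:\|(?P<role>ref|extra))?$"
)


class FloraValidationError(ValueError):
    """A domain invariant was violated while building or reading data."""


def round_half_up(value: float | Decimal, ndigits: int = 1) -> float:
    """Round with ties away from zero (half-up), as used for all reported %."""
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value) if not isinstance(value, Decimal) else value)
                 .quantize(quantum, rounding=ROUND_HALF_UP))


def percentage(count: int, total: int) -> float:
    """100 * count / total, half-up to one decimal (e.g. 304/343 -> 88.6)."""
    if total <= 0:
        raise FloraValidationError("percentage needs a positive denominator")
    return float((Decimal(100 * count) / Decimal(total))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Taxon:
    """A terminal taxon of the flora (species or infraspecific entity)."""

    taxon_id: str
    name: str
    genus: str
    group_id: str | None = None  # congeneric stress-group label, e.g. "Gr5"

    def __post_init__(self) -> None:
        if not self.taxon_id:
            raise FloraValidationError("taxon_id must be non-empty")
        if not self.genus:
            raise FloraValidationError(f"taxon {self.taxon_id!r}: genus must be non-empty")


@dataclass(frozen=True)
class CharacterDefinition:
    """A categorical character with its observable states and organ tag.

    ``seasonal`` marks characters only observable in specific life stages
    (e.g. petal colour outside the flowering period).
    """

    char_id: str
    prompt: str
    states: tuple[str, ...]
    organ: str
    seasonal: bool = False

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise FloraValidationError(f"character {self.char_id!r}: needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise FloraValidationError(f"character {self.char_id!r}: duplicate state labels")
        if UNKNOWN in self.states:
            raise FloraValidationError(f"character {self.char_id!r}: {UNKNOWN!r} is reserved")
        if self.organ not in ORGANS:
            raise FloraValidationError(
                f"character {self.char_id!r}: organ {self.organ!r} not in {sorted(ORGANS)}")


class CharacterMatrix:
    """Taxa x categorical characters, the substrate of the digital key.

    Cells hold a declared state label or :data:`UNKNOWN`. Missing cells are
    normalised to UNKNOWN at construction; scored states are validated
    against the character definitions.
    """

    def __init__(
        self,
        taxa: Sequence[Taxon],
        characters: Sequence[CharacterDefinition],
        scores: Mapping[tuple[str, str], str],
    ) -> None:
        ids = [t.taxon_id for t in taxa]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise FloraValidationError(f"duplicate taxon_id(s): {dupes}")
        cids = [c.char_id for c in characters]
        if len(set(cids)) != len(cids):
            raise FloraValidationError("duplicate char_id(s) in character list")
        self.taxa: tuple[Taxon, ...] = tuple(taxa)
        self.characters: tuple[CharacterDefinition, ...] = tuple(characters)
        self._by_taxon = {t.taxon_id: t for t in self.taxa}
        self._by_char = {c.char_id: c for c in self.characters}
        self.scores: dict[tuple[str, str], str] = {}
        for t in self.taxa:
            for c in self.characters:
                state = scores.get((t.taxon_id, c.char_id), UNKNOWN)
                if state != UNKNOWN and state not in c.states:
                    raise FloraValidationError(
                        f"taxon {t.taxon_id!r}, character {c.char_id!r}: "
                        f"state {state!r} is not one of {c.states}")
                self.scores[(t.taxon_id, c.char_id)] = state

    # -- accessors ---------------------------------------------------------
    @property
    def taxon_ids(self) -> tuple[str, ...]:
        return tuple(t.taxon_id for t in self.taxa)

    @property
    def char_ids(self) -> tuple[str, ...]:
        return tuple(c.char_id for c in self.characters)

    def taxon(self, taxon_id: str) -> Taxon:
        try:
            return self._by_taxon[taxon_id]
        except KeyError:
            raise FloraValidationError(f"unknown taxon {taxon_id!r}") from None

    def character(self, char_id: str) -> CharacterDefinition:
        try:
            return self._by_char[char_id]
        except KeyError:
            raise FloraValidationError(f"unknown character {char_id!r}") from None

    def has_taxon(self, taxon_id: str) -> bool:
        return taxon_id in self._by_taxon

    def state(self, taxon_id: str, char_id: str) -> str:
        return self.scores[(taxon_id, char_id)]

    def n_unknown(self) -> int:
        return sum(1 for v in self.scores.values() if v == UNKNOWN)

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a taxa-rows x characters-columns DataFrame of state labels."""
        data = {c.char_id: [self.scores[(t.taxon_id, c.char_id)] for t in self.taxa]
                for c in self.characters}
        return pd.DataFrame(data, index=pd.Index(self.taxon_ids, name="taxon_id"))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (self.taxa == other.taxa and self.characters == other.characters
                and self.scores == other.scores)

    def __repr__(self) -> str:
        return (f"CharacterMatrix({len(self.taxa)} taxa x "
                f"{len(self.characters)} characters)")


@dataclass(frozen=True)
class SpecimenProfile:
    """The character states observable on one collected specimen.

    ``unavailable_organs`` lists organ tags absent from the specimen (for
    example ``{"flower"}`` for a plant collected out of its flowering
    period); no observed character may belong to an unavailable organ.
    """

    observed: Mapping[str, str]
    unavailable_organs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "observed", dict(self.observed))
        object.__setattr__(self, "unavailable_organs", frozenset(self.unavailable_organs))
        bad = self.unavailable_organs - ORGANS
        if bad:
            raise FloraValidationError(f"unknown organ tag(s): {sorted(bad)}")

    def validate_against(self, characters: Iterable[CharacterDefinition]) -> None:
        by_id = {c.char_id: c for c in characters}
        for cid in self.observed:
            c = by_id.get(cid)
            if c is not None and c.organ in self.unavailable_organs:
                raise FloraValidationError(
                    f"observed character {cid!r} belongs to unavailable organ {c.organ!r}")


@dataclass(frozen=True)
class BarcodeRecord:
    """One aligned sequence for (taxon, marker), backed by a voucher.

    ``is_reference`` flags the single individual per species that enters
    discrimination analyses; extra individuals feed intraspecific surveys.
    """

    taxon_id: str
    marker: str
    voucher: str
    sequence: str
    is_reference: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FloraValidationError(
                f"record {self.voucher!r} ({self.taxon_id}/{self.marker}): empty sequence")


class BarcodeLibrary:
    """Per-marker aligned sequence sets keyed by taxon and voucher.

    Invariants enforced at construction: within a marker all sequences share
    the aligned length; at most one reference record per (taxon, marker).
    ``taxon_universe`` optionally declares the full set of taxa attempted
    (the denominator of completeness reports).
    """

    def __init__(
        self,
        records: Iterable[BarcodeRecord],
        markers: Sequence[str] = DEFAULT_MARKERS,
        taxon_universe: Sequence[str] | None = None,
    ) -> None:
        self.markers: tuple[str, ...] = tuple(markers)
        self.records: tuple[BarcodeRecord, ...] = tuple(records)
        self._lengths: dict[str, int] = {}
        refs: set[tuple[str, str]] = set()
        for rec in self.records:
            if rec.marker not in self.markers:
                raise FloraValidationError(
                    f"record {rec.voucher!r}: marker {rec.marker!r} not in declared "
                    f"set {self.markers}")
            length = self._lengths.setdefault(rec.marker, len(rec.sequence))
            if len(rec.sequence) != length:
                raise FloraValidationError(
                    f"marker {rec.marker!r}: record {rec.voucher!r} "
                    f"({rec.taxon_id}) has aligned length {len(rec.sequence)}, "
                    f"expected {length}")
            if rec.is_reference:
                key = (rec.taxon_id, rec.marker)
                if key in refs:
                    raise FloraValidationError(
                        f"duplicate reference record for taxon {rec.taxon_id!r}, "
                        f"marker {rec.marker!r}")
                refs.add(key)
        self._reference = {(r.taxon_id, r.marker): r for r in self.records if r.is_reference}
        if taxon_universe is not None:
            self.taxon_universe: tuple[str, ...] | None = tuple(taxon_universe)
        else:
            self.taxon_universe = None

    def alignment_length(self, marker: str) -> int:
        try:
            return self._lengths[marker]
        except KeyError:
            raise FloraValidationError(f"no records for marker {marker!r}") from None

    def records_for(self, marker: str, reference_only: bool = False) -> tuple[BarcodeRecord, ...]:
        return tuple(r for r in self.records
                     if r.marker == marker and (r.is_reference or not reference_only))

    def reference_record(self, taxon_id: str, marker: str) -> BarcodeRecord | None:
        return self._reference.get((taxon_id, marker))

    def taxa_with(self, marker: str) -> tuple[str, ...]:
        """Taxa possessing a reference record for ``marker`` (sorted)."""
        return tuple(sorted({t for (t, m) in self._reference if m == marker}))

    def taxa_with_all(self, markers: Sequence[str]) -> tuple[str, ...]:
        present = [set(self.taxa_with(m)) for m in markers]
        return tuple(sorted(set.intersection(*present))) if present else ()

    def sequenced_taxa(self) -> tuple[str, ...]:
        return tuple(sorted({r.taxon_id for r in self.records}))

    def individuals_for(self, taxon_id: str, marker: str) -> tuple[BarcodeRecord, ...]:
        """All records (reference + extras) for a taxon/marker, voucher-sorted."""
        return tuple(sorted((r for r in self.records
                             if r.taxon_id == taxon_id and r.marker == marker),
                            key=lambda r: r.voucher))

    def __len__(self) -> int:
        return len(self.records)

    def __repr__(self) -> str:
        return f"BarcodeLibrary({len(self.records)} records, markers={self.markers})"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_character_matrix(matrix_path: str | Path,
                          characters_path: str | Path) -> CharacterMatrix:
    """Read a taxa x characters TSV plus its character-definition sidecar.

    The matrix table has columns ``taxon_id, name, genus, group_id`` followed
    by one column per char_id; cells hold state labels or ``?`` for UNKNOWN.
    The sidecar declares ``char_id, prompt, organ, seasonal, states`` with
    states pipe-delimited.
    """
    chars_df = pd.read_csv(characters_path, sep="\t", dtype=str, keep_default_na=False)
    characters = [
        CharacterDefinition(
            char_id=row["char_id"],
            prompt=row["prompt"],
            states=tuple(row["states"].split("|")),
            organ=row["organ"],
            seasonal=row["seasonal"].strip().lower() in {"1", "true", "yes"},
        )
        for _, row in chars_df.iterrows()
    ]
    mat_df = pd.read_csv(matrix_path, sep="\t", dtype=str, keep_default_na=False)
    meta_cols = ["taxon_id", "name", "genus", "group_id"]
    missing = [c for c in meta_cols[:3] if c not in mat_df.columns]
    if missing:
        raise FloraValidationError(f"matrix table lacks column(s) {missing}")
    taxa = [
        Taxon(taxon_id=row["taxon_id"], name=row["name"], genus=row["genus"],
              group_id=(row.get("group_id") or None) if "group_id" in mat_df.columns else None)
        for _, row in mat_df.iterrows()
    ]
    char_cols = [c for c in mat_df.columns if c not in meta_cols]
    declared = {c.char_id for c in characters}
    undeclared = [c for c in char_cols if c not in declared]
    if undeclared:
        raise FloraValidationError(f"matrix columns without definitions: {undeclared}")
    scores: dict[tuple[str, str], str] = {}
    for _, row in mat_df.iterrows():
        for cid in char_cols:
            scores[(row["taxon_id"], cid)] = row[cid] if row[cid] != "" else UNKNOWN
    return CharacterMatrix(taxa, characters, scores)


def write_character_matrix(matrix: CharacterMatrix,
                           matrix_path: str | Path,
                           characters_path: str | Path) -> None:
    """Write the matrix and its character-definition sidecar as TSV."""
    chars_df = pd.DataFrame(
        {
            "char_id": [c.char_id for c in matrix.characters],
            "prompt": [c.prompt for c in matrix.characters],
            "organ": [c.organ for c in matrix.characters],
            "seasonal": ["true" if c.seasonal else "false" for c in matrix.characters],
            "states": ["|".join(c.states) for c in matrix.characters],
        }
    )
    chars_df.to_csv(characters_path, sep="\t", index=False)
    rows = []
    for t in matrix.taxa:
        row: dict[str, str] = {
            "taxon_id": t.taxon_id, "name": t.name, "genus": t.genus,
            "group_id": t.group_id or "",
        }
        for c in matrix.characters:
            row[c.char_id] = matrix.state(t.taxon_id, c.char_id)
        rows.append(row)
    pd.DataFrame(rows).to_csv(matrix_path, sep="\t", index=False)


class HeaderParseError(FloraValidationError):
    """A FASTA header did not match the configured grammar."""


def read_barcode_fasta(
    paths: Sequence[str | Path] | str | Path,
    markers: Sequence[str] = DEFAULT_MARKERS,
    header_pattern: str = DEFAULT_HEADER_PATTERN,
    taxon_universe: Sequence[str] | None = None,
) -> BarcodeLibrary:
    """Read FASTA file(s) with ``voucher|taxon|marker[|role]`` headers.

    Lowercase bases are normalised to uppercase; gaps and ambiguity codes are
    preserved verbatim. When several records share (taxon, marker) and carry
    no role field, the record with the lexicographically smallest voucher is
    the reference individual.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    pattern = re.compile(header_pattern)
    parsed: list[tuple[str, str, str, str | None, str]] = []
    for path in paths:
        for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
            m = pattern.match(rec.description)
            if not m:
                raise HeaderParseError(
                    f"{path}: record {i}: header {rec.description!r} does not match "
                    f"pattern {header_pattern!r}")
            parsed.append((m.group("voucher"), m.group("taxon"), m.group("marker"),
                           m.groupdict().get("role"), str(rec.seq).upper()))
    # resolve reference roles: explicit flag wins, else smallest voucher
    explicit = {(t, mk) for (_, t, mk, role, _) in parsed if role == "ref"}
    first_voucher: dict[tuple[str, str], str] = {}
    for voucher, taxon, marker, role, _ in parsed:
        key = (taxon, marker)
        if key not in explicit and (key not in first_voucher or voucher < first_voucher[key]):
            first_voucher[key] = voucher
    records = []
    for voucher, taxon, marker, role, seq in parsed:
        if role is not None:
            is_ref = role == "ref"
        else:
            is_ref = first_voucher.get((taxon, marker)) == voucher
        records.append(BarcodeRecord(taxon_id=taxon, marker=marker, voucher=voucher,
                                     sequence=seq, is_reference=is_ref))
    return BarcodeLibrary(records, markers=markers, taxon_universe=taxon_universe)


def write_barcode_fasta(library: BarcodeLibrary, out_dir: str | Path) -> list[Path]:
    """Write one FASTA per marker; records sorted by (taxon_id, voucher).

    Marker names containing path-hostile characters are sanitised for the
    filename only; headers keep the verbatim marker name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if not library.records:
        logger.warning("write_barcode_fasta: empty library, nothing written")
        return written
    for marker in library.markers:
        recs = sorted(library.records_for(marker), key=lambda r: (r.taxon_id, r.voucher))
        if not recs:
            continue
        fname = re.sub(r"[^A-Za-z0-9._-]", "_", marker) + ".fasta"
        path = out_dir / fname
        seq_records = [
            SeqRecord(
                Seq(r.sequence),
                id=f"{r.voucher}|{r.taxon_id}|{r.marker}|{'ref' if r.is_reference else 'extra'}",
                description="",
            )
            for r in recs
        ]
        SeqIO.write(seq_records, str(path), "fasta")
        written.append(path)
    return written


@dataclass(frozen=True)
class CompletenessReport:
    """Counts/percentages of taxa with >=1, >=2 and all declared markers."""

    n_taxa: int
    n_markers: int
    count_at_least_1: int
    count_at_least_2: int
    count_all: int
    pct_at_least_1: float
    pct_at_least_2: float
    pct_all: float


def library_completeness_report(
    library: BarcodeLibrary,
    taxon_universe: Sequence[str] | None = None,
) -> CompletenessReport:
    """Marker-coverage completeness of the library over its taxon universe.

    Percentages are 100 * count / universe size, half-up to one decimal
    (so 304/343 reports 88.6 and 300/343 reports 87.5).
    """
    universe = tuple(taxon_universe) if taxon_universe is not None else library.taxon_universe
    if universe is None:
        universe = library.sequenced_taxa()
    if not universe:
        raise FloraValidationError("completeness report needs a non-empty taxon universe")
    per_taxon = {t: 0 for t in universe}
    for t in universe:
        per_taxon[t] = sum(1 for m in library.markers
                           if library.reference_record(t, m) is not None)
    n = len(universe)
    c1 = sum(1 for v in per_taxon.values() if v >= 1)
    c2 = sum(1 for v in per_taxon.values() if v >= 2)
    call = sum(1 for v in per_taxon.values() if v >= len(library.markers))
    return CompletenessReport(
        n_taxa=n, n_markers=len(library.markers),
        count_at_least_1=c1, count_at_least_2=c2, count_all=call,
        pct_at_least_1=percentage(c1, n),
        pct_at_least_2=percentage(c2, n),
        pct_all=percentage(call, n),
    )


@dataclass(frozen=True)
class LibraryMatrixReport:
    """Cross-check of taxon ids between matrix and library (report-only)."""

    sequence_only: tuple[str, ...]   # in library but not in matrix
    morphology_only: tuple[str, ...]  # in matrix but lacking any sequence

    @property
    def consistent(self) -> bool:
        return not self.sequence_only and not self.morphology_only


def validate_library(library: BarcodeLibrary, matrix: CharacterMatrix) -> LibraryMatrixReport:
    """List taxa present on only one side of the morphology/molecular divide."""
    lib_taxa = set(library.sequenced_taxa())
    mat_taxa = set(matrix.taxon_ids)
    return LibraryMatrixReport(
        sequence_only=tuple(sorted(lib_taxa - mat_taxa)),
        morphology_only=tuple(sorted(mat_taxa - lib_taxa)),
    )
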