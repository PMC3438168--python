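"""Scenario analysis and the integrated barcode-filter identification.

A *scenario* is a stalled morphological identification: a multi-entry query
narrows the flora to a candidate group (GP), after which the dichotomous
key cannot continue because the next characters sit on an organ the
specimen lacks. For each marker (or concatenated combination) the pipeline
reports, over the candidates: N (taxa with a sequence), the MOTU count
under complete sequence identity, and the discriminatory efficiency
100 * MOTU / N — the percentage of candidates resolvable to a unique taxon
by that marker.

The integrated identifier runs the two data sources in sequence: a query
sequence is matched to a MOTU (exact identity first, nearest reference by
K2P within a threshold as fallback); if the MOTU holds several taxa, a
residual morphological key restricted to the observable characters settles
the remainder.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .barcode_analysis import (
    DistanceSignal,
    cluster_motus,
    concatenate_markers,
    k2p_distance,
)
from .flora_model import (
    BarcodeLibrary,
    CharacterMatrix,
    FloraValidationError,
    SpecimenProfile,
)
from .key_engine import (
    Filter,
    IdentificationResult,
    Outcome,
    build_dichotomous_key,
    identify_stepwise,
    multi_entry_filter,
    residual_key_for,
)

logger = logging.getLogger(__name__)

#: Nearest-reference fallback threshold: the intraspecific K2P ceiling
#: (within-species distances stay consistently below 2%).
DEFAULT_ASSIGNMENT_THRESHOLD = 0.02


@dataclass(frozen=True)
class Scenario:
    """A stalled-identification scenario: filter + missing organs."""

    label: str
    query: Filter
    unavailable_organs: frozenset[str]
    narrative: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "unavailable_organs", frozenset(self.unavailable_organs))

    def validate_against(self, matrix: CharacterMatrix) -> None:
        """Filter characters must not sit on unavailable organs."""
        for cid in self.query.constraints:
            organ = matrix.character(cid).organ
            if organ in self.unavailable_organs:
                raise FloraValidationError(
                    f"scenario {self.label!r}: filter character {cid!r} belongs to "
                    f"unavailable organ {organ!r}")


@dataclass(frozen=True)
class MarkerPerformance:
    """One Table-row cell group: N, MOTU and efficiency for a marker/combo."""

    marker: str
    n_sequences: int
    motu_count: int
    efficiency: float


@dataclass(frozen=True)
class ScenarioResult:
    """Candidates after morphological filtering plus per-marker performance."""

    label: str
    candidates: tuple[str, ...]
    performances: tuple[MarkerPerformance, ...]

    @property
    def group_size(self) -> int:
        return len(self.candidates)

    def performance(self, marker: str) -> MarkerPerformance:
        for p in self.performances:
            if p.marker == marker:
                return p
        raise KeyError(marker)


def discrimination_efficiency(n_sequences: int, n_motus: int) -> float:
    """100 * MOTU / N, half-up to one decimal.

    This is the percentage of candidate taxa a marker resolves: each
    singleton MOTU is one correctly identified species, and a k-taxon MOTU
    contributes one resolvable entity out of k. E.g. (41, 38) -> 92.7 and
    (101, 96) -> 95.0.
    """
    if n_sequences == 0:
        raise FloraValidationError("efficiency undefined for zero sequences")
    if not 0 < n_motus <= n_sequences:
        raise FloraValidationError(
            f"MOTU count {n_motus} must be in (0, {n_sequences}]")
    return float((Decimal(100 * n_motus) / Decimal(n_sequences))
                 .quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def run_scenario(
    matrix: CharacterMatrix,
    library: BarcodeLibrary,
    scenario: Scenario,
    markers: Sequence[str] | None = None,
    combinations: Sequence[Sequence[str]] = (),
) -> ScenarioResult:
    """Filter the flora, then score each marker/combination on the candidates.

    Single markers restrict to candidates carrying a reference sequence
    (N <= GP); combinations restrict to candidates carrying *all* component
    markers, which is why combination columns report smaller N.
    """
    scenario.validate_against(matrix)
    candidates = multi_entry_filter(matrix, scenario.query)
    if not candidates:
        raise FloraValidationError(
            f"scenario {scenario.label!r}: the multi-entry filter matched no taxa")
    if markers is None:
        markers = library.markers
    performances: list[MarkerPerformance] = []
    for m in markers:
        part = cluster_motus(library, m, candidates)
        n = len(part.taxa)
        if n == 0:
            logger.warning("scenario %s: marker %s has no sequenced candidates, skipped",
                           scenario.label, m)
            continue
        performances.append(MarkerPerformance(
            marker=m, n_sequences=n, motu_count=part.motu_count,
            efficiency=discrimination_efficiency(n, part.motu_count)))
    for combo in combinations:
        try:
            restricted, part = concatenate_markers(library, combo, candidates)
        except FloraValidationError:
            logger.warning("scenario %s: combination %s has no candidates with all "
                           "markers, skipped", scenario.label, "+".join(combo))
            continue
        n = len(restricted)
        performances.append(MarkerPerformance(
            marker="+".join(combo), n_sequences=n, motu_count=part.motu_count,
            efficiency=discrimination_efficiency(n, part.motu_count)))
    return ScenarioResult(label=scenario.label, candidates=candidates,
                          performances=tuple(performances))


def table3_report(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Scenario-by-marker performance table (one row per scenario).

    Columns: ``S``, ``GP``, then ``<marker>:N``, ``<marker>:MOTU``,
    ``<marker>:%`` for every marker/combination present in any result.
    A marker absent from a scenario renders as an absent (NA) cell, not
    zero.
    """
    if not results:
        raise FloraValidationError("table3_report needs at least one result")
    marker_order: list[str] = []
    for r in results:
        for p in r.performances:
            if p.marker not in marker_order:
                marker_order.append(p.marker)
    rows = []
    for r in results:
        row: dict[str, object] = {"S": r.label, "GP": r.group_size}
        for m in marker_order:
            try:
                p = r.performance(m)
            except KeyError:
                continue
            row[f"{m}:N"] = p.n_sequences
            row[f"{m}:MOTU"] = p.motu_count
            row[f"{m}:%"] = p.efficiency
        rows.append(row)
    cols = ["S", "GP"] + [f"{m}:{x}" for m in marker_order for x in ("N", "MOTU", "%")]
    return pd.DataFrame(rows, columns=cols)


def write_table3(df: pd.DataFrame, path: str | Path) -> None:
    """TSV with one-decimal percentages; absent cells written empty."""
    out = df.copy()
    for col in out.columns:
        if col.endswith(":%"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{v:.1f}")
        elif col.endswith(":N") or col.endswith(":MOTU"):
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else str(int(v)))
    out.to_csv(path, sep="\t", index=False)


def read_table3(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"S": str})
    return df


def results_from_frame(df: pd.DataFrame) -> list[ScenarioResult]:
    """Rebuild ScenarioResult rows (minus candidate lists) from a report
    frame, for round-trip checks."""
    markers = sorted({c[:-2] for c in df.columns if c.endswith(":N")})
    out = []
    for _, row in df.iterrows():
        perfs = []
        for m in markers:
            if pd.isna(row.get(f"{m}:N")):
                continue
            perfs.append(MarkerPerformance(
                marker=m, n_sequences=int(row[f"{m}:N"]),
                motu_count=int(row[f"{m}:MOTU"]),
                efficiency=float(row[f"{m}:%"])))
        perfs.sort(key=lambda p: p.marker)
        out.append(ScenarioResult(label=str(row["S"]),
                                  candidates=tuple(f"_gp{i}" for i in range(int(row["GP"]))),
                                  performances=tuple(perfs)))
    return out


# ---------------------------------------------------------------------------
# Built-in scenarios
# ---------------------------------------------------------------------------

#: Canonical constraint names -> (char_id, state) for the synthetic flora.
DEFAULT_SCENARIO_VOCABULARY: dict[str, tuple[str, str]] = {
    "herb or small shrub": ("stature", "herb_or_small_shrub"),
    "tree or shrub >50cm": ("stature", "woody_gt_50cm"),
    "not a woody climber": ("woody_climber", "no"),
    "green with chlorophyll": ("chlorophyll", "present"),
    "without spines": ("spines", "absent"),
    "terrestrial": ("habitat", "terrestrial"),
    "with leaves": ("leaves_present", "yes"),
    "leaves opposite": ("leaf_arrangement", "opposite"),
    "leaves not opposite": ("leaf_arrangement", "alternate"),
    "leaves simple": ("leaf_type", "simple"),
    "leaves entire": ("leaf_margin", "entire"),
    "leaves not whorled": ("leaf_whorled", "no"),
    "deciduous": ("phenology", "deciduous"),
    "fruit dry": ("fruit_type", "dry"),
}

_SCENARIO_CONSTRAINTS: dict[str, tuple[tuple[str, ...], frozenset[str], str]] = {
    # label -> (constraint names, unavailable organs, narrative)
    "A": (("herb or small shrub", "green with chlorophyll", "without spines",
           "terrestrial", "leaves opposite", "leaves simple", "leaves not whorled"),
          frozenset({"flower"}),
          "Herbaceous specimen with opposite, simple, non-whorled leaves, "
          "collected out of its flowering period."),
    "B": (("herb or small shrub", "green with chlorophyll", "without spines",
           "terrestrial", "with leaves", "leaves not opposite", "leaves entire",
           "leaves not whorled"),
          frozenset({"flower"}),
          "Herbaceous specimen with alternate, entire, non-whorled leaves, "
          "collected out of its flowering period."),
    "C": (("tree or shrub >50cm", "not a woody climber", "deciduous",
           "terrestrial", "fruit dry"),
          frozenset({"leaf"}),
          "Deciduous tree collected in late autumn, with dry fruits but "
          "missing leaves."),
}


def define_scenario_library(
    vocabulary: Mapping[str, tuple[str, str]] | None = None,
) -> dict[str, Scenario]:
    """The three built-in scenarios (A: 7 constraints, B: 8, C: 5).

    ``vocabulary`` maps canonical constraint names to (char_id, state)
    pairs of the target matrix; the default targets the synthetic flora.
    Raises listing any unmapped constraint name.
    """
    vocab = dict(vocabulary) if vocabulary is not None else dict(DEFAULT_SCENARIO_VOCABULARY)
    scenarios: dict[str, Scenario] = {}
    for label, (names, organs, narrative) in _SCENARIO_CONSTRAINTS.items():
        missing = [n for n in names if n not in vocab]
        if missing:
            raise FloraValidationError(
                f"scenario {label}: unmapped constraint name(s): {missing}")
        constraints = dict(vocab[n] for n in names)
        scenarios[label] = Scenario(label=label, query=Filter(constraints),
                                    unavailable_organs=organs, narrative=narrative)
    return scenarios


# ---------------------------------------------------------------------------
# Integrated identification
# ---------------------------------------------------------------------------

def _assign_query(library: BarcodeLibrary, marker: str, query_seq: str,
                  threshold: float) -> frozenset[str]:
    """Taxa of the MOTU the query falls in (empty set if no match).

    Exact identity with a reference sequence wins; otherwise the nearest
    reference by K2P is accepted when within ``threshold``.
    """
    if marker not in library.markers:
        raise FloraValidationError(f"query marker {marker!r} not in library")
    query = query_seq.upper()
    length = library.alignment_length(marker)
    if len(query) != length:
        raise FloraValidationError(
            f"query for {marker!r} has length {len(query)}, expected aligned "
            f"length {length}")
    part = cluster_motus(library, marker)
    for block in part.blocks:
        ref = library.reference_record(min(block), marker)
        if ref.sequence.upper() == query:
            return block
    best_d, best_block = None, None
    for block in part.blocks:
        ref = library.reference_record(min(block), marker)
        try:
            d = k2p_distance(query, ref.sequence)
        except DistanceSignal:
            continue
        if best_d is None or d < best_d:
            best_d, best_block = d, block
    if best_d is not None and best_d <= threshold:
        return best_block
    return frozenset()


def integrated_identify(
    matrix: CharacterMatrix,
    library: BarcodeLibrary,
    specimen: SpecimenProfile,
    query_sequences: Mapping[str, str] | None = None,
    threshold: float = DEFAULT_ASSIGNMENT_THRESHOLD,
) -> IdentificationResult:
    """Two-stage identification: barcode filter, then residual key.

    Stage 1 assigns each provided query sequence to a MOTU (exact identity,
    else nearest reference within ``threshold``); the candidate set is the
    intersection of MOTU memberships across markers (union fallback with a
    warning when the intersection is empty). Stage 2 resolves multi-taxon
    candidate sets with a dichotomous key over the characters observable on
    the specimen. With no query sequences the call degrades to
    morphology-only stepwise identification over the whole flora.
    """
    query_sequences = dict(query_sequences or {})
    if not query_sequences:
        # Full key (all characters): the session stalls at the first
        # unobservable character instead of quietly losing resolution.
        key = build_dichotomous_key(matrix, matrix.taxon_ids)
        return identify_stepwise(key, specimen)
    per_marker: list[frozenset[str]] = []
    for marker, seq in query_sequences.items():
        per_marker.append(_assign_query(library, marker, seq, threshold))
    matched = [s for s in per_marker if s]
    if not matched:
        return IdentificationResult(outcome=Outcome.NO_MATCH)
    candidates = frozenset.intersection(*matched)
    if not candidates:
        logger.warning("integrated_identify: marker assignments disagree; "
                       "falling back to their union")
        candidates = frozenset.union(*matched)
    if len(candidates) == 1:
        (taxon,) = candidates
        return IdentificationResult(outcome=Outcome.SUCCESS, taxon=taxon,
                                    candidates=(taxon,))
    key = residual_key_for(matrix, sorted(candidates), specimen)
    return identify_stepwise(key, specimen)
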