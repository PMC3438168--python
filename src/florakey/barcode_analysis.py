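"""Distance and clustering analysis of an aligned DNA-barcode library.

Implements the Kimura two-parameter (K2P) distance with pairwise deletion,
MOTU clustering by complete sequence identity, marker concatenation with
partition refinement, and the intraspecific / congeneric-group summaries
used to characterise marker performance.

The K2P distance corrects separately for transitions (purine<->purine,
pyrimidine<->pyrimidine) and transversions::

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

with P and Q the transition and transversion proportions over the aligned
columns where both sequences carry an unambiguous base (A/C/G/T). Columns
with a gap or ambiguity code in either sequence are deleted pairwise.
Saturation (a non-positive log argument) and zero comparable columns are
explicit signals, never silent NaNs inside means.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .flora_model import BarcodeLibrary, CharacterMatrix, FloraValidationError, round_half_up

logger = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase
#: purine flag per code (A=0, G=2 are purines; C=1, T=3 pyrimidines)
_IS_PURINE = np.array([True, False, True, False], dtype=bool)


class DistanceSignal(ArithmeticError):
    """Base for non-numeric distance outcomes."""


class SaturatedDistance(DistanceSignal):
    """K2P log argument non-positive: divergence beyond the model's range."""


class NoOverlap(DistanceSignal):
    """No aligned column where both sequences carry an unambiguous base."""


@dataclass(frozen=True)
class SiteComparison:
    """Counts of comparable, transition and transversion sites for one pair."""

    compared_sites: int
    transitions: int
    transversions: int

    def __post_init__(self) -> None:
        if self.transitions + self.transversions > self.compared_sites:
            raise ValueError("transitions + transversions exceed compared sites")

    @property
    def P(self) -> float:
        return self.transitions / self.compared_sites if self.compared_sites else 0.0

    @property
    def Q(self) -> float:
        return self.transversions / self.compared_sites if self.compared_sites else 0.0


def encode_sequence(seq: str) -> np.ndarray:
    """Byte-encode an aligned sequence; non-ACGT characters map to 255."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def compare_sites(seq_a: str, seq_b: str) -> SiteComparison:
    """Count comparable sites, transitions and transversions (pairwise deletion)."""
    if len(seq_a) != len(seq_b):
        raise FloraValidationError(
            f"aligned lengths differ: {len(seq_a)} vs {len(seq_b)}")
    a = encode_sequence(seq_a)
    b = encode_sequence(seq_b)
    valid = (a != 255) & (b != 255)
    diff = valid & (a != b)
    ts = diff & (_IS_PURINE[a & 3] == _IS_PURINE[b & 3])
    n_diff = int(diff.sum())
    n_ts = int(ts.sum())
    return SiteComparison(compared_sites=int(valid.sum()),
                          transitions=n_ts, transversions=n_diff - n_ts)


def k2p_from_counts(compared_sites: int, transitions: int, transversions: int) -> float:
    """K2P distance from site counts; raises on saturation or no overlap."""
    if compared_sites == 0:
        raise NoOverlap("no comparable aligned columns")
    P = transitions / compared_sites
    Q = transversions / compared_sites
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistance(f"K2P undefined for P={P:.4f}, Q={Q:.4f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(seq_a: str, seq_b: str) -> float:
    """Pairwise K2P distance (substitutions/site) between aligned sequences.

    Raises :class:`SaturatedDistance` when the log argument is non-positive
    and :class:`NoOverlap` when no column is comparable.
    """
    c = compare_sites(seq_a, seq_b)
    return k2p_from_counts(c.compared_sites, c.transitions, c.transversions)


@dataclass
class DistanceMatrix:
    """Symmetric per-marker K2P matrix with explicit inapplicable cells.

    ``values`` holds NaN wherever ``flags`` records SATURATED/NO_OVERLAP;
    means always exclude flagged cells and expose the exclusion count.
    ``excluded_taxa`` lists subset members dropped for lacking a reference
    record (mirrors per-marker N below group size in real libraries).
    """

    marker: str
    taxon_ids: tuple[str, ...]
    values: np.ndarray
    flags: dict[tuple[str, str], str] = field(default_factory=dict)
    excluded_taxa: tuple[str, ...] = ()

    def distance(self, taxon_a: str, taxon_b: str) -> float:
        i = self.taxon_ids.index(taxon_a)
        j = self.taxon_ids.index(taxon_b)
        return float(self.values[i, j])

    def pair_values(self) -> np.ndarray:
        """Upper-triangle distances, flagged cells removed."""
        iu = np.triu_indices(len(self.taxon_ids), k=1)
        vals = self.values[iu]
        return vals[~np.isnan(vals)]

    @property
    def n_flagged(self) -> int:
        return len(self.flags)

    def mean(self) -> float:
        """Mean pairwise distance over unflagged pairs (substitutions/site)."""
        vals = self.pair_values()
        if vals.size == 0:
            raise NoOverlap(f"marker {self.marker!r}: no unflagged pairs to average")
        return float(vals.mean())

    def mean_percent(self) -> float:
        """Mean pairwise K2P x100, half-up to one decimal (reporting scale)."""
        return round_half_up(self.mean() * 100.0, 1)

    def max(self) -> float:
        vals = self.pair_values()
        if vals.size == 0:
            raise NoOverlap(f"marker {self.marker!r}: no unflagged pairs")
        return float(vals.max())


def pairwise_distance_matrix(
    library: BarcodeLibrary,
    marker: str,
    taxa_subset: Sequence[str] | None = None,
) -> DistanceMatrix:
    """All-pairs K2P over the reference sequences of a marker.

    Subset members lacking a reference record are dropped with a logged
    exclusion rather than raising. Row-vectorised over the alignment.
    """
    if taxa_subset is None:
        taxa = list(library.taxa_with(marker))
        excluded: list[str] = []
    else:
        taxa, excluded = [], []
        for t in taxa_subset:
            (taxa if library.reference_record(t, marker) else excluded).append(t)
        if excluded:
            logger.info("marker %s: %d taxa excluded (no reference record): %s",
                        marker, len(excluded), excluded)
    n = len(taxa)
    codes = np.empty((n, library.alignment_length(marker)), dtype=np.uint8) if n else \
        np.empty((0, 0), dtype=np.uint8)
    for i, t in enumerate(taxa):
        codes[i] = encode_sequence(library.reference_record(t, marker).sequence)
    valid = codes != 255
    purine = _IS_PURINE[codes & 3]
    values = np.zeros((n, n), dtype=float)
    flags: dict[tuple[str, str], str] = {}
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        diff = both & (codes[i] != codes[i + 1:])
        ts = diff & (purine[i] == purine[i + 1:])
        L = both.sum(axis=1).astype(float)
        n_ts = ts.sum(axis=1)
        n_tv = diff.sum(axis=1) - n_ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(L > 0, n_ts / L, 0.0)
            Q = np.where(L > 0, n_tv / L, 0.0)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            d = np.where((w1 > 0) & (w2 > 0), -0.5 * np.log(w1 * np.sqrt(np.abs(w2))), np.nan)
        for k, j in enumerate(range(i + 1, n)):
            if L[k] == 0:
                flags[(taxa[i], taxa[j])] = "NO_OVERLAP"
                values[i, j] = values[j, i] = np.nan
            elif math.isnan(d[k]):
                flags[(taxa[i], taxa[j])] = "SATURATED"
                values[i, j] = values[j, i] = np.nan
            else:
                values[i, j] = values[j, i] = d[k]
    return DistanceMatrix(marker=marker, taxon_ids=tuple(taxa), values=values,
                          flags=flags, excluded_taxa=tuple(excluded))


@dataclass(frozen=True)
class MOTUPartition:
    """Equivalence classes of taxa under complete sequence identity.

    ``marker`` names the single marker or the '+'-joined combination the
    partition was computed on; blocks are disjoint and cover all analysed
    taxa.
    """

    marker: str
    blocks: tuple[frozenset[str], ...]
    excluded_taxa: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b in self.blocks:
            if seen & b:
                raise FloraValidationError("MOTU blocks are not disjoint")
            seen |= b

    @property
    def motu_count(self) -> int:
        return len(self.blocks)

    @property
    def taxa(self) -> frozenset[str]:
        return frozenset().union(*self.blocks) if self.blocks else frozenset()

    def block_of(self, taxon_id: str) -> frozenset[str]:
        for b in self.blocks:
            if taxon_id in b:
                return b
        raise KeyError(taxon_id)

    def refines(self, other: "MOTUPartition") -> bool:
        """True if every block here is contained in a block of ``other``
        (compared on the shared taxon set)."""
        shared = self.taxa & other.taxa
        for b in self.blocks:
            bs = b & shared
            if not bs:
                continue
            if not any(bs <= ob for ob in other.blocks):
                return False
        return True


def _identity_partition(marker_label: str, seq_by_taxon: Mapping[str, str],
                        excluded: Sequence[str]) -> MOTUPartition:
    groups: dict[str, set[str]] = {}
    for taxon, seq in seq_by_taxon.items():
        groups.setdefault(seq.upper(), set()).add(taxon)
    blocks = tuple(sorted((frozenset(g) for g in groups.values()),
                          key=lambda b: min(b)))
    return MOTUPartition(marker=marker_label, blocks=blocks, excluded_taxa=tuple(excluded))


def cluster_motus(
    library: BarcodeLibrary,
    marker: str,
    taxa_subset: Sequence[str] | None = None,
) -> MOTUPartition:
    """Group taxa whose aligned reference sequences are completely identical.

    Identity is exact string equality after case normalisation; gap
    characters and ambiguity codes compare verbatim (indels are diagnostic,
    N != A). Taxa showing complete identity are non-identifiable with the
    marker under examination — they share a MOTU.
    """
    taxa = taxa_subset if taxa_subset is not None else library.taxa_with(marker)
    seqs: dict[str, str] = {}
    excluded: list[str] = []
    for t in taxa:
        rec = library.reference_record(t, marker)
        if rec is None:
            excluded.append(t)
        else:
            seqs[t] = rec.sequence
    if excluded:
        logger.info("cluster_motus %s: excluded %d taxa without records", marker, len(excluded))
    return _identity_partition(marker, seqs, excluded)


def concatenate_markers(
    library: BarcodeLibrary,
    markers: Sequence[str],
    taxa_subset: Sequence[str] | None = None,
) -> tuple[tuple[str, ...], MOTUPartition]:
    """MOTUs on the concatenation of >=2 markers, in fixed marker order.

    Restricted to taxa possessing ALL requested markers (this is why
    combination columns report smaller N); the resulting partition refines
    each single-marker partition on the shared taxon set.
    """
    if len(markers) < 2:
        raise FloraValidationError("concatenation needs >=2 markers")
    base = taxa_subset if taxa_subset is not None else library.sequenced_taxa()
    restricted, excluded = [], []
    for t in base:
        if all(library.reference_record(t, m) is not None for m in markers):
            restricted.append(t)
        else:
            excluded.append(t)
    if not restricted:
        raise FloraValidationError(
            f"no taxon carries all markers {tuple(markers)}")
    seqs = {t: "".join(library.reference_record(t, m).sequence for m in markers)
            for t in restricted}
    label = "+".join(markers)
    return tuple(restricted), _identity_partition(label, seqs, excluded)


def intraspecific_summary(
    library: BarcodeLibrary,
    taxa: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Within-species K2P mean and standard error, per species and marker.

    Uses all individuals (reference + extras). Species with fewer than two
    individuals for a marker are skipped with a log entry; saturated or
    non-overlapping pairs are excluded and counted.

    Returns a DataFrame with columns ``taxon_id, marker, n_individuals,
    n_pairs, mean_k2p, se_k2p, n_excluded_pairs``.
    """
    if taxa is None:
        taxa = library.sequenced_taxa()
    rows = []
    for t in taxa:
        for marker in library.markers:
            individuals = library.individuals_for(t, marker)
            if len(individuals) < 2:
                if individuals:
                    logger.info("intraspecific_summary: %s/%s has <2 individuals, skipped",
                                t, marker)
                continue
            dists, n_bad = [], 0
            for ra, rb in itertools.combinations(individuals, 2):
                try:
                    dists.append(k2p_distance(ra.sequence, rb.sequence))
                except DistanceSignal:
                    n_bad += 1
            if not dists:
                continue
            arr = np.asarray(dists)
            se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else 0.0
            rows.append({"taxon_id": t, "marker": marker,
                         "n_individuals": len(individuals), "n_pairs": arr.size,
                         "mean_k2p": float(arr.mean()), "se_k2p": se,
                         "n_excluded_pairs": n_bad})
    return pd.DataFrame(rows, columns=["taxon_id", "marker", "n_individuals",
                                       "n_pairs", "mean_k2p", "se_k2p",
                                       "n_excluded_pairs"])


def congeneric_group_report(
    library: BarcodeLibrary,
    matrix: CharacterMatrix,
    groups: Mapping[str, Sequence[str]] | None = None,
    include_max: bool = False,
) -> pd.DataFrame:
    """Per congeneric group and marker: N, MOTU count and mean K2P%.

    ``groups`` maps group label -> taxon ids; when omitted, groups are taken
    from the matrix's taxon ``group_id`` labels. Distance cells are NaN
    (inapplicable) when fewer than two group members are sequenced for the
    marker. The parenthesised distance is the mean intragroup K2P by
    default; ``include_max`` adds the maximum as a separate column.
    """
    if groups is None:
        collected: dict[str, list[str]] = {}
        for t in matrix.taxa:
            if t.group_id:
                collected.setdefault(t.group_id, []).append(t.taxon_id)
        groups = collected
    rows = []
    for label in sorted(groups):
        members = list(groups[label])
        for marker in library.markers:
            part = cluster_motus(library, marker, members)
            n = len(part.taxa)
            row: dict[str, object] = {"group": label, "marker": marker,
                                      "n_taxa": len(members), "n_sequenced": n,
                                      "motu_count": part.motu_count if n else 0}
            if n >= 2:
                dm = pairwise_distance_matrix(library, marker, sorted(part.taxa))
                try:
                    row["mean_k2p_pct"] = dm.mean_percent()
                    if include_max:
                        row["max_k2p_pct"] = round_half_up(dm.max() * 100.0, 1)
                except NoOverlap:
                    row["mean_k2p_pct"] = float("nan")
            else:
                row["mean_k2p_pct"] = float("nan")
                if include_max:
                    row["max_k2p_pct"] = float("nan")
            rows.append(row)
    cols = ["group", "marker", "n_taxa", "n_sequenced", "motu_count", "mean_k2p_pct"]
    if include_max:
        cols.append("max_k2p_pct")
    return pd.DataFrame(rows, columns=cols)
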