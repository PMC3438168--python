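"""Synthetic local flora: character matrix + barcode library + truth ledger.

Emulates the statistical structure of a strongly heterogeneous local flora
(one or a few species per genus, ~300-350 taxa): a two-level tree (genus
radiation, then species), three plastid-like markers of contrasting
variability evolved under the two-parameter (K80) substitution model whose
distance the analysis layer estimates, shared gap blocks standing in for
spacer indels, intraspecific variability kept below a 2% K2P ceiling, and
*planted* congeneric species pairs with completely identical sequences per
marker — the only cross-taxon identical sequences, so expected MOTU counts
are exact (n_species - n_planted_pairs).

The character matrix carries genus-level characters (growth form, leaf
arrangement, phenology, ...) shared within each genus, and species-level
characters (flower, fruit, leaf shape) assigned by a mixed-radix encoding
of the species index so that, with all organs available, every species pair
differs in at least one character. Flower characters occupy the least
significant digits: congeners therefore tend to differ *only* in flower
characters, which is exactly what makes a key stall on a specimen collected
out of its flowering period.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .flora_model import (
    UNKNOWN,
    BarcodeLibrary,
    BarcodeRecord,
    CharacterDefinition,
    CharacterMatrix,
    FloraValidationError,
    SpecimenProfile,
    Taxon,
    read_barcode_fasta,
    read_character_matrix,
    write_barcode_fasta,
    write_character_matrix,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class ConfigError(FloraValidationError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class MarkerSpec:
    """Evolutionary profile of one synthetic marker.

    ``interspecific_scale`` is the expected K2P distance (substitutions per
    site) between species of different genera — the dominant pair class in
    a genus-heterogeneous flora, hence approximately the flora-wide mean.
    ``intraspecific_mean`` is the expected branch length from a species'
    reference to an extra individual. ``indel_rate`` is the expected gapped
    fraction of the alignment (spacer-like markers only).
    """

    length: int
    interspecific_scale: float
    kappa: float = 3.0
    indel_rate: float = 0.0
    intraspecific_mean: float = 0.004

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigError("marker length must be positive")
        if self.kappa <= 0:
            raise ConfigError("kappa must be > 0")
        if not 0 <= self.indel_rate < 0.5:
            raise ConfigError("indel_rate must be in [0, 0.5)")


#: Default markers: low variability (rbcL-like, flora mean K2P 10.8%), high
#: (matK-like, 27.9%), highest plus indels (trnH-psbA-like spacer).
DEFAULT_MARKER_SPECS: dict[str, MarkerSpec] = {
    "rbcL": MarkerSpec(length=552, interspecific_scale=0.108, kappa=3.0,
                       intraspecific_mean=0.0005),
    "matK": MarkerSpec(length=840, interspecific_scale=0.279, kappa=3.0,
                       intraspecific_mean=0.004),
    "trnH-psbA": MarkerSpec(length=450, interspecific_scale=0.35, kappa=3.0,
                            indel_rate=0.04, intraspecific_mean=0.004),
}


@dataclass(frozen=True)
class IdenticalPairDirective:
    """Plant a congeneric pair with identical sequences for some markers.

    The first two species of genus ``genus_index`` share, for each listed
    marker, a completely identical aligned sequence.
    """

    genus_index: int
    markers: tuple[str, ...]


@dataclass(frozen=True)
class FloraConfig:
    """Stated world of the synthetic flora.

    Defaults emulate the target structure: ~115 genera of 1-5 species
    (~345 taxa), three markers of contrasting variability, intraspecific
    K2P below the 2% ceiling, three individuals per species for 50 species
    in the intraspecific survey, and a handful of genera whose genus-level
    character states are pinned to the built-in scenario profiles so each
    scenario is instantiable.
    """

    n_genera: int = 115
    species_per_genus: int | tuple[int, int] = (1, 5)
    marker_specs: Mapping[str, MarkerSpec] = field(
        default_factory=lambda: dict(DEFAULT_MARKER_SPECS))
    intraspecific_ceiling: float = 0.02
    identical_pairs: tuple[IdenticalPairDirective, ...] = ()
    morph_identical_pairs: tuple[int, ...] = ()
    n_species_intraspecific: int = 50
    n_individuals_intraspecific: int = 3
    scenario_seed_genera: int = 2
    unknown_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genera <= 0:
            raise ConfigError("n_genera must be positive")
        for name, spec in self.marker_specs.items():
            if not 0 <= self.intraspecific_ceiling < spec.interspecific_scale:
                raise ConfigError(
                    f"marker {name!r}: intraspecific ceiling must sit below the "
                    f"interspecific scale")
        for d in self.identical_pairs:
            unknown = set(d.markers) - set(self.marker_specs)
            if unknown:
                raise ConfigError(f"identical-pair directive names unknown markers {unknown}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "FloraConfig":
        d = dict(d)
        if "marker_specs" in d:
            d["marker_specs"] = {k: MarkerSpec(**v) for k, v in d["marker_specs"].items()}
        if "identical_pairs" in d:
            d["identical_pairs"] = tuple(
                IdenticalPairDirective(genus_index=p["genus_index"],
                                       markers=tuple(p["markers"]))
                for p in d["identical_pairs"])
        if "species_per_genus" in d and isinstance(d["species_per_genus"], list):
            d["species_per_genus"] = tuple(d["species_per_genus"])
        if "morph_identical_pairs" in d:
            d["morph_identical_pairs"] = tuple(d["morph_identical_pairs"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Generator ledger used as a test oracle.

    Branch lengths are stored as marker-independent *fractions* of the
    interspecific scale (the tree shape is shared across markers; each
    marker multiplies by its own rate scale). ``planted_pairs`` lists, per
    marker, the taxon-id pairs with identical sequences — by construction
    the only cross-taxon identities.
    """

    genus_of: dict[str, str]
    genus_branch_frac: dict[str, float]
    species_branch_frac: dict[str, float]
    marker_scales: dict[str, float]
    planted_pairs: dict[str, list[tuple[str, str]]]
    morph_identical: list[tuple[str, str]]
    newick: str

    def true_distance(self, marker: str, taxon_a: str, taxon_b: str) -> float:
        """Expected model distance (substitutions/site) between two taxa."""
        for pair in self.planted_pairs.get(marker, []):
            if set(pair) == {taxon_a, taxon_b}:
                return 0.0
        scale = self.marker_scales[marker]
        ga, gb = self.genus_of[taxon_a], self.genus_of[taxon_b]
        if taxon_a == taxon_b:
            return 0.0
        if ga == gb:
            frac = self.species_branch_frac[taxon_a] + self.species_branch_frac[taxon_b]
        else:
            frac = (self.species_branch_frac[taxon_a] + self.species_branch_frac[taxon_b]
                    + self.genus_branch_frac[ga] + self.genus_branch_frac[gb])
        return frac * scale

    def expected_motu_count(self, marker: str, taxa: Sequence[str] | None = None) -> int:
        """n_species - n_planted_pairs, optionally restricted to a subset."""
        universe = set(taxa) if taxa is not None else set(self.genus_of)
        pairs = [p for p in self.planted_pairs.get(marker, [])
                 if p[0] in universe and p[1] in universe]
        return len(universe) - len(pairs)

    def to_json(self, **kwargs) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        d["planted_pairs"] = {m: [tuple(p) for p in ps]
                              for m, ps in d["planted_pairs"].items()}
        d["morph_identical"] = [tuple(p) for p in d["morph_identical"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# K80 sequence evolution
# ---------------------------------------------------------------------------

def _k80_site_probs(branch_length: float, kappa: float) -> tuple[float, float, float]:
    """(p_same, p_transition, p_each_transversion) after ``branch_length``
    expected substitutions/site under K80 with ts/tv rate ratio kappa."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * branch_length)
    e2 = np.exp(-2.0 * (alpha + beta) * branch_length)
    p_tv_each = 0.25 - 0.25 * e1
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_same = 1.0 - p_ts - 2.0 * p_tv_each
    return float(p_same), float(p_ts), float(p_tv_each)


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform-random base-code array (0..3 for A,C,G,T)."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def evolve_sequences(root: np.ndarray | str, branch_length: float, kappa: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence along one branch under the K80 model.

    Per-site independent substitution; transitions (A<->G, C<->T) occur at
    ``kappa`` times the rate of each transversion. Branch length is in
    expected substitutions/site, so the matching two-parameter distance
    estimator recovers it in expectation. Accepts a code array or an ACGT
    string; returns a code array.
    """
    if branch_length < 0:
        raise ConfigError("branch length must be >= 0")
    if isinstance(root, str):
        codes = np.frombuffer(root.encode("ascii"), dtype=np.uint8)
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(b"ACGT"):
            lut[b] = i
        root = lut[codes]
    seq = np.asarray(root, dtype=np.uint8)
    if branch_length == 0:
        return seq.copy()
    p_same, p_ts, p_tv = _k80_site_probs(branch_length, kappa)
    u = rng.random(seq.size)
    pick_tv2 = rng.random(seq.size) < 0.5
    out = seq.copy()
    ts_mask = (u >= p_same) & (u < p_same + p_ts)
    tv_mask = u >= p_same + p_ts
    out[ts_mask] = seq[ts_mask] ^ 2            # A<->G, C<->T
    tv1 = tv_mask & ~pick_tv2
    tv2 = tv_mask & pick_tv2
    out[tv1] = seq[tv1] ^ 1
    out[tv2] = seq[tv2] ^ 3
    return out


def decode(codes: np.ndarray) -> str:
    """Base-code array back to an ACGT string (255 renders as '-')."""
    table = np.full(256, ord("-"), dtype=np.uint8)
    table[:4] = _BASES
    return table[codes].tobytes().decode("ascii")


def _apply_gap_blocks(seq: str, rng: np.random.Generator, indel_rate: float,
                      block_range: tuple[int, int] = (3, 12)) -> str:
    """Overwrite random column blocks with '-', keeping alignment length.

    The expected gapped fraction approximates ``indel_rate``; blocks mimic
    shared-column spacer indels without altering the alignment frame.
    """
    if indel_rate <= 0:
        return seq
    L = len(seq)
    mean_block = (block_range[0] + block_range[1]) / 2.0
    n_blocks = rng.poisson(L * indel_rate / mean_block)
    chars = list(seq)
    for _ in range(n_blocks):
        size = int(rng.integers(block_range[0], block_range[1] + 1))
        start = int(rng.integers(0, max(1, L - size)))
        chars[start:start + size] = ["-"] * size
    return "".join(chars)


# ---------------------------------------------------------------------------
# Character-matrix construction
# ---------------------------------------------------------------------------

# Genus-level characters: (char_id, prompt, organ, states, weights).
# Weights set the fraction of genera sharing the first state, so scenario
# filters retain a realistic slice of the flora.
GENUS_CHARACTERS: tuple[tuple[str, str, str, tuple[str, ...], tuple[float, ...]], ...] = (
    ("stature", "Growth form", "whole-plant",
     ("herb_or_small_shrub", "woody_gt_50cm"), (0.55, 0.45)),
    ("woody_climber", "Woody climber", "whole-plant", ("no", "yes"), (0.9, 0.1)),
    ("chlorophyll", "Green, with chlorophyll", "whole-plant",
     ("present", "absent"), (0.97, 0.03)),
    ("spines", "Spines", "whole-plant", ("absent", "present"), (0.85, 0.15)),
    ("latex", "Laticiferous", "whole-plant", ("absent", "present"), (0.85, 0.15)),
    ("habitat", "Habitat", "whole-plant", ("terrestrial", "aquatic"), (0.92, 0.08)),
    ("phenology", "Phenology", "whole-plant", ("deciduous", "evergreen"), (0.7, 0.3)),
    ("leaves_present", "Leaves present", "leaf", ("yes", "no"), (0.98, 0.02)),
    ("leaf_arrangement", "Leaf arrangement", "leaf",
     ("opposite", "alternate"), (0.45, 0.55)),
    ("leaf_whorled", "Leaves whorled", "leaf", ("no", "yes"), (0.9, 0.1)),
    ("leaf_type", "Leaf type", "leaf", ("simple", "compound"), (0.85, 0.15)),
    ("leaf_margin", "Leaf margin", "leaf", ("entire", "toothed"), (0.6, 0.4)),
    ("fruit_type", "Fruit type", "fruit", ("dry", "fleshy"), (0.6, 0.4)),
)

# Species-level characters, least-significant digit first; flower characters
# lead so congeners differ chiefly in flower states.
SPECIES_CHARACTERS: tuple[tuple[str, str, str, bool, tuple[str, ...]], ...] = (
    ("petal_color", "Petal colour", "flower", True,
     ("white", "yellow", "pink", "purple", "blue", "red")),
    ("corolla_shape", "Corolla shape", "flower", True,
     ("tubular", "campanulate", "rotate", "papilionaceous")),
    ("fruit_surface", "Fruit surface", "fruit", False,
     ("glabrous", "hairy", "winged")),
    ("leaf_shape", "Leaf shape", "leaf", False,
     ("ovate", "lanceolate", "lobed", "cordate", "linear")),
    ("stamen_count", "Stamen number", "flower", True,
     ("two", "five", "ten", "many")),
)

# Genus-level state profiles pinned for the built-in scenarios (A, B, C).
SCENARIO_GENUS_PROFILES: dict[str, dict[str, str]] = {
    "A": {"stature": "herb_or_small_shrub", "chlorophyll": "present",
          "spines": "absent", "habitat": "terrestrial",
          "leaf_arrangement": "opposite", "leaf_type": "simple",
          "leaf_whorled": "no", "leaves_present": "yes", "latex": "absent"},
    "B": {"stature": "herb_or_small_shrub", "chlorophyll": "present",
          "spines": "absent", "habitat": "terrestrial",
          "leaves_present": "yes", "leaf_arrangement": "alternate",
          "leaf_margin": "entire", "leaf_whorled": "no", "latex": "absent"},
    "C": {"stature": "woody_gt_50cm", "woody_climber": "no",
          "phenology": "deciduous", "habitat": "terrestrial",
          "fruit_type": "dry"},
}


def default_character_definitions() -> list[CharacterDefinition]:
    defs = [CharacterDefinition(cid, prompt, states, organ)
            for cid, prompt, organ, states, _ in GENUS_CHARACTERS]
    defs += [CharacterDefinition(cid, prompt, states, organ, seasonal=seasonal)
             for cid, prompt, organ, seasonal, states in SPECIES_CHARACTERS]
    return defs


def _species_digit_states(index: int) -> dict[str, str]:
    """Mixed-radix encoding of a global species index over the
    species-level characters (capacity 6*4*3*5*4 = 1440)."""
    out = {}
    k = index
    for cid, _, _, _, states in SPECIES_CHARACTERS:
        out[cid] = states[k % len(states)]
        k //= len(states)
    if k:
        raise ConfigError("flora exceeds the species-character capacity (1440)")
    return out


# ---------------------------------------------------------------------------
# Flora simulation
# ---------------------------------------------------------------------------

def simulate_flora(config: FloraConfig) -> tuple[CharacterMatrix, BarcodeLibrary, SyntheticTruth]:
    """Generate (matrix, library, truth) deterministically from the config.

    Guarantees realised by construction and post-checks:

    * same seed => byte-identical outputs;
    * planted identical pairs are the *only* cross-taxon identical
      sequences per marker (collisions are re-drawn, capped);
    * with all organs available the dichotomous key separates every pair
      not listed in ``morph_identical_pairs`` (mixed-radix uniqueness);
    * the first ``scenario_seed_genera`` genera per scenario profile carry
      the scenario's filter states, so scenarios A/B/C are instantiable.
    """
    rng = np.random.default_rng(config.seed)
    markers = tuple(config.marker_specs)

    # -- genus/species skeleton -------------------------------------------
    if isinstance(config.species_per_genus, int):
        sizes = np.full(config.n_genera, config.species_per_genus, dtype=int)
    else:
        lo, hi = config.species_per_genus
        sizes = rng.integers(lo, hi + 1, size=config.n_genera)
    for d in config.identical_pairs:
        if not 0 <= d.genus_index < config.n_genera:
            raise ConfigError(f"identical-pair genus index {d.genus_index} out of range")
        if sizes[d.genus_index] < 2:
            raise ConfigError(
                f"identical-pair directive targets genus {d.genus_index} "
                f"with <2 species")
    for g in config.morph_identical_pairs:
        if not 0 <= g < config.n_genera or sizes[g] < 2:
            raise ConfigError(f"morph-identical directive targets unsuitable genus {g}")

    genus_names = [f"Genus{g:03d}" for g in range(config.n_genera)]
    taxa: list[Taxon] = []
    genus_of: dict[str, str] = {}
    species_by_genus: dict[str, list[str]] = {g: [] for g in genus_names}
    planted_genera = {d.genus_index: f"Gr{k + 1}"
                      for k, d in enumerate(config.identical_pairs)}
    idx = 0
    for g, gname in enumerate(genus_names):
        for s in range(int(sizes[g])):
            tid = f"tx{idx:04d}"
            taxa.append(Taxon(taxon_id=tid, name=f"{gname} sp{s + 1:02d}",
                              genus=gname, group_id=planted_genera.get(g)))
            genus_of[tid] = gname
            species_by_genus[gname].append(tid)
            idx += 1
    n_species = idx

    # -- character matrix ---------------------------------------------------
    characters = default_character_definitions()
    genus_states: dict[str, dict[str, str]] = {}
    k_seed = config.scenario_seed_genera
    for g, gname in enumerate(genus_names):
        states: dict[str, str] = {}
        profile: dict[str, str] | None = None
        if g < k_seed:
            profile = SCENARIO_GENUS_PROFILES["A"]
        elif g < 2 * k_seed:
            profile = SCENARIO_GENUS_PROFILES["B"]
        elif g < 3 * k_seed:
            profile = SCENARIO_GENUS_PROFILES["C"]
        for cid, _, _, state_set, weights in GENUS_CHARACTERS:
            pick = state_set[rng.choice(len(state_set), p=np.asarray(weights))]
            states[cid] = pick
        if profile:
            states.update(profile)
        genus_states[gname] = states

    scores: dict[tuple[str, str], str] = {}
    morph_identical: list[tuple[str, str]] = []
    species_digits = {t.taxon_id: _species_digit_states(i) for i, t in enumerate(taxa)}
    for g in config.morph_identical_pairs:
        a, b = species_by_genus[genus_names[g]][:2]
        species_digits[b] = dict(species_digits[a])
        morph_identical.append((a, b))
    for t in taxa:
        for cid, state in genus_states[t.genus].items():
            scores[(t.taxon_id, cid)] = state
        for cid, state in species_digits[t.taxon_id].items():
            scores[(t.taxon_id, cid)] = state
    if config.unknown_rate > 0:
        for key in list(scores):
            if rng.random() < config.unknown_rate:
                scores[key] = UNKNOWN
    matrix = CharacterMatrix(taxa, characters, scores)

    # -- tree shape (shared across markers) ---------------------------------
    genus_branch_frac = {g: float(rng.uniform(0.35, 0.55)) for g in genus_names}
    species_branch_frac = {t.taxon_id: float(rng.uniform(0.02, 0.08)) for t in taxa}
    newick_parts = []
    for gname in genus_names:
        tips = ",".join(f"{tid}:{species_branch_frac[tid]:.6f}"
                        for tid in species_by_genus[gname])
        newick_parts.append(f"({tips}){gname}:{genus_branch_frac[gname]:.6f}")
    newick = f"({','.join(newick_parts)})root;"

    # -- sequences -----------------------------------------------------------
    planted_pairs: dict[str, list[tuple[str, str]]] = {m: [] for m in markers}
    planted_members: dict[str, dict[str, str]] = {m: {} for m in markers}
    for d in config.identical_pairs:
        gname = genus_names[d.genus_index]
        a, b = species_by_genus[gname][:2]
        for m in d.markers:
            planted_pairs[m].append((a, b))
            planted_members[m][a] = b
            planted_members[m][b] = a

    records: list[BarcodeRecord] = []
    voucher_counter = 0

    def next_voucher() -> str:
        nonlocal voucher_counter
        voucher_counter += 1
        return f"MIB:ZPL:{voucher_counter:05d}"

    ref_seqs: dict[str, dict[str, str]] = {}
    for m in markers:
        spec = config.marker_specs[m]
        scale = spec.interspecific_scale
        root = random_sequence(spec.length, rng)
        seqs: dict[str, str] = {}
        for gname in genus_names:
            anc = evolve_sequences(root, genus_branch_frac[gname] * scale,
                                   spec.kappa, rng)
            for tid in species_by_genus[gname]:
                tip = evolve_sequences(anc, species_branch_frac[tid] * scale,
                                       spec.kappa, rng)
                seq = decode(tip)
                seqs[tid] = _apply_gap_blocks(seq, rng, spec.indel_rate)
        # realise planted identical pairs exactly
        for a, b in planted_pairs[m]:
            seqs[b] = seqs[a]
        # reject unplanned collisions: re-draw the later, non-planted member
        for attempt in range(60):
            by_seq: dict[str, list[str]] = {}
            for tid, s in seqs.items():
                by_seq.setdefault(s, []).append(tid)
            offenders: list[str] = []
            for s, members in by_seq.items():
                members = sorted(members)
                planted = planted_members[m]
                allowed = set()
                if len(members) >= 2:
                    for tid in members:
                        if planted.get(tid) in members:
                            allowed.add(tid)
                    extra = [tid for tid in members if tid not in allowed]
                    keep_one = 0 if not allowed else None
                    for j, tid in enumerate(extra):
                        if keep_one is not None and j == keep_one:
                            continue
                        offenders.append(tid)
            if not offenders:
                break
            for tid in offenders:
                gname = genus_of[tid]
                anc = evolve_sequences(root, genus_branch_frac[gname] * scale,
                                       spec.kappa, rng)
                tip = evolve_sequences(anc, species_branch_frac[tid] * scale,
                                       spec.kappa, rng)
                seqs[tid] = _apply_gap_blocks(decode(tip), rng, spec.indel_rate)
        else:
            raise ConfigError(
                f"marker {m!r}: could not resolve sequence collisions after 60 redraws")
        ref_seqs[m] = seqs

    for t in taxa:  # taxon-major voucher order, mirroring field collection
        for m in markers:
            records.append(BarcodeRecord(taxon_id=t.taxon_id, marker=m,
                                         voucher=next_voucher(),
                                         sequence=ref_seqs[m][t.taxon_id],
                                         is_reference=True))

    # -- intraspecific survey individuals -----------------------------------
    n_survey = min(config.n_species_intraspecific, n_species)
    survey_idx = sorted(rng.choice(n_species, size=n_survey, replace=False).tolist())
    for i in survey_idx:
        tid = taxa[i].taxon_id
        for m in markers:
            spec = config.marker_specs[m]
            ref = ref_seqs[m][tid]
            gap_positions = [j for j, ch in enumerate(ref) if ch == "-"]
            base = ref.replace("-", "")
            for _ in range(config.n_individuals_intraspecific):
                b = float(rng.uniform(0, 2 * spec.intraspecific_mean))
                evolved = decode(evolve_sequences(base, b, spec.kappa, rng))
                chars = list(evolved)
                for j in gap_positions:  # re-insert the species' gap columns
                    chars.insert(j, "-")
                records.append(BarcodeRecord(taxon_id=tid, marker=m,
                                             voucher=next_voucher(),
                                             sequence="".join(chars),
                                             is_reference=False))

    library = BarcodeLibrary(records, markers=markers,
                             taxon_universe=[t.taxon_id for t in taxa])
    truth = SyntheticTruth(
        genus_of=genus_of,
        genus_branch_frac=genus_branch_frac,
        species_branch_frac=species_branch_frac,
        marker_scales={m: config.marker_specs[m].interspecific_scale for m in markers},
        planted_pairs=planted_pairs,
        morph_identical=morph_identical,
        newick=newick,
    )
    return matrix, library, truth


def make_specimen(matrix: CharacterMatrix, taxon_id: str,
                  unavailable_organs: Sequence[str] = ()) -> SpecimenProfile:
    """A specimen of ``taxon_id`` missing the given organs.

    The profile carries the taxon's scored states for every character whose
    organ is available; characters of unavailable organs (and UNKNOWN
    cells) are absent from the profile.
    """
    matrix.taxon(taxon_id)  # raises for unknown taxon
    unavailable = frozenset(unavailable_organs)
    observed = {
        c.char_id: matrix.state(taxon_id, c.char_id)
        for c in matrix.characters
        if c.organ not in unavailable and matrix.state(taxon_id, c.char_id) != UNKNOWN
    }
    return SpecimenProfile(observed=observed, unavailable_organs=unavailable)


# ---------------------------------------------------------------------------
# On-disk flora bundle
# ---------------------------------------------------------------------------

def write_flora(matrix: CharacterMatrix, library: BarcodeLibrary,
                truth: SyntheticTruth | None, out_dir: str | Path) -> None:
    """Write matrix.tsv + characters.tsv + per-marker FASTA (+ truth.json)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_character_matrix(matrix, out / "matrix.tsv", out / "characters.tsv")
    write_barcode_fasta(library, out)
    if truth is not None:
        (out / "truth.json").write_text(truth.to_json(indent=1))


def read_flora(in_dir: str | Path,
               markers: Sequence[str] = tuple(DEFAULT_MARKER_SPECS),
               ) -> tuple[CharacterMatrix, BarcodeLibrary, SyntheticTruth | None]:
    """Read a flora bundle written by :func:`write_flora`."""
    src = Path(in_dir)
    matrix = read_character_matrix(src / "matrix.tsv", src / "characters.tsv")
    fastas = sorted(src.glob("*.fasta"))
    library = read_barcode_fasta(fastas, markers=markers,
                                 taxon_universe=matrix.taxon_ids)
    truth = None
    truth_path = src / "truth.json"
    if truth_path.exists():
        truth = SyntheticTruth.from_json(truth_path.read_text())
    return matrix, library, truth
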