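import pytest
from hypothesis import HealthCheck, settings

import florakey as fk

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def tiny_matrix() -> fk.CharacterMatrix:
    """5 taxa x 3 characters, 2 UNKNOWN cells."""
    taxa = [
        fk.Taxon("ac", "Acer campestre", "Acer", "Gr1"),
        fk.Taxon("ap", "Acer pseudoplatanus", "Acer", "Gr1"),
        fk.Taxon("sv", "Senecio vulgaris", "Senecio", "Gr6"),
        fk.Taxon("si", "Senecio inaequidens", "Senecio", "Gr6"),
        fk.Taxon("qp", "Quercus petraea", "Quercus"),
    ]
    chars = [
        fk.CharacterDefinition("leaves", "Leaf arrangement",
                               ("opposite", "alternate", "whorled"), "leaf"),
        fk.CharacterDefinition("petals", "Petal colour",
                               ("yellow", "white"), "flower", seasonal=True),
        fk.CharacterDefinition("habit", "Growth form", ("herb", "tree"), "whole-plant"),
    ]
    scores = {
        ("ac", "leaves"): "opposite", ("ac", "petals"): "yellow", ("ac", "habit"): "tree",
        ("ap", "leaves"): "opposite", ("ap", "petals"): "white", ("ap", "habit"): "tree",
        ("sv", "leaves"): "alternate", ("sv", "petals"): "yellow", ("sv", "habit"): "herb",
        ("si", "leaves"): fk.UNKNOWN, ("si", "petals"): "yellow", ("si", "habit"): "herb",
        ("qp", "leaves"): "alternate", ("qp", "petals"): fk.UNKNOWN, ("qp", "habit"): "tree",
    }
    return fk.CharacterMatrix(taxa, chars, scores)


@pytest.fixture(scope="session")
def tiny_library() -> fk.BarcodeLibrary:
    """4 taxa x 2 markers with one identical rbcL pair (ac == ap)."""
    records = [
        fk.BarcodeRecord("ac", "rbcL", "MIB:ZPL:0001", "ACGTACGTAC"),
        fk.BarcodeRecord("ap", "rbcL", "MIB:ZPL:0002", "ACGTACGTAC"),
        fk.BarcodeRecord("sv", "rbcL", "MIB:ZPL:0003", "ACGTACGTAA"),
        fk.BarcodeRecord("si", "rbcL", "MIB:ZPL:0004", "ACGAACGTAA"),
        fk.BarcodeRecord("ac", "matK", "MIB:ZPL:0001", "GGGTTTCC"),
        fk.BarcodeRecord("ap", "matK", "MIB:ZPL:0002", "GGGTTTCA"),
        fk.BarcodeRecord("sv", "matK", "MIB:ZPL:0003", "GGATTTCC"),
        fk.BarcodeRecord("si", "matK", "MIB:ZPL:0004", "GGATTACC"),
    ]
    return fk.BarcodeLibrary(records, markers=("rbcL", "matK"),
                             taxon_universe=["ac", "ap", "sv", "si", "qp"])


@pytest.fixture(scope="session")
def small_flora():
    """8 genera x 4 species, planted rbcL pair in genus 4, matK pair in
    genus 5; first genera pinned to the scenario profiles."""
    cfg = fk.FloraConfig(
        n_genera=8,
        species_per_genus=4,
        n_species_intraspecific=6,
        identical_pairs=(
            fk.IdenticalPairDirective(4, ("rbcL",)),
            fk.IdenticalPairDirective(5, ("matK",)),
        ),
        scenario_seed_genera=1,
        seed=11,
    )
    return fk.simulate_flora(cfg)
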