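"""K2P distance, MOTU clustering, concatenation and group summaries.

The K2P implementation is checked against an independent brute-force
oracle (character-by-character counting + closed form evaluated separately)
and, on clean sequences, against R ape's dist.dna(model="K80").
"""

import itertools
import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import florakey as fk
from florakey.barcode_analysis import NoOverlap, SaturatedDistance, k2p_from_counts

PURINES = {"A", "G"}
BASES = "ACGT"


def brute_force_k2p(a: str, b: str) -> float:
    """Independent oracle: per-character loop, no shared code with the
    implementation's vectorised path."""
    assert len(a) == len(b)
    L = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in BASES or y not in BASES:
            continue
        L += 1
        if x == y:
            continue
        if (x in PURINES) == (y in PURINES):
            ts += 1
        else:
            tv += 1
    if L == 0:
        raise NoOverlap("oracle: no overlap")
    P, Q = ts / L, tv / L
    arg = (1 - 2 * P - Q) * math.sqrt(1 - 2 * Q)
    if arg <= 0:
        raise SaturatedDistance("oracle: saturated")
    return -0.5 * math.log(arg)


def random_pair(rng, with_noise=True):
    L = int(rng.integers(200, 1501))
    alphabet = list("ACGT") + (list("-NRYWS") if with_noise else [])
    probs = None
    if with_noise:
        probs = [0.22, 0.22, 0.22, 0.22, 0.05, 0.03, 0.01, 0.01, 0.01, 0.01]
    a = "".join(rng.choice(alphabet, size=L, p=probs))
    b = list(a)
    for i in range(L):
        if rng.random() < 0.08:
            b[i] = alphabet[int(rng.integers(0, len(alphabet)))]
    return a, "".join(b)


class TestK2PDistance:
    def test_identical_sequences_zero(self):
        assert fk.k2p_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_example(self):
        # L=100, 10 transitions, 5 transversions
        assert k2p_from_counts(100, 10, 5) == pytest.approx(0.1701811651403471, abs=1e-12)

    def test_saturation_signalled(self):
        with pytest.raises(SaturatedDistance):
            k2p_from_counts(100, 50, 25)  # P=0.5, Q=0.25

    def test_no_overlap_signalled(self):
        with pytest.raises(NoOverlap):
            fk.k2p_distance("----", "AC--")

    def test_pairwise_deletion_ignores_gap_and_ambiguity_columns(self):
        # the N and gap columns must not count; the single transition must
        assert fk.k2p_distance("ANG-T", "GNGAT") == pytest.approx(
            brute_force_k2p("ANG-T", "GNGAT"))

    def test_symmetry_and_oracle_on_random_pairs(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b = random_pair(rng)
            try:
                expected = brute_force_k2p(a, b)
            except (NoOverlap, SaturatedDistance) as sig:
                with pytest.raises(type(sig)):
                    fk.k2p_distance(a, b)
                continue
            assert fk.k2p_distance(a, b) == pytest.approx(expected, abs=1e-10)
            assert fk.k2p_distance(b, a) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_P_and_Q(self):
        base = k2p_from_counts(1000, 100, 50)
        assert k2p_from_counts(1000, 101, 50) > base
        assert k2p_from_counts(1000, 100, 51) > base

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
    def test_matches_ape_reference_on_clean_pairs(self, tmp_path):
        """Cross-check against ape::dist.dna(model='K80') on gap-free pairs."""
        rng = np.random.default_rng(17)
        pairs = [random_pair(rng, with_noise=False) for _ in range(10)]
        fasta = tmp_path / "pairs.fasta"
        lines = []
        for i, (a, b) in enumerate(pairs):
            lines += [f">p{i}a", a, f">p{i}b", b]
        fasta.write_text("\n".join(lines) + "\n")
        script = tmp_path / "k2p.R"
        script.write_text(
            'suppressMessages(library(ape))\n'
            f'seqs <- read.FASTA("{fasta}")\n'
            'for (i in seq(1, length(seqs), by=2)) {\n'
            '  d <- dist.dna(seqs[c(i, i+1)], model="K80", pairwise.deletion=TRUE)\n'
            '  cat(sprintf("%.12f\\n", as.numeric(d)))\n'
            '}\n')
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        ref = [float(x) for x in out.stdout.split()]
        # pairs have different lengths; compare each pair independently
        for (a, b), expected in zip(pairs, ref):
            assert fk.k2p_distance(a[:len(b)], b) == pytest.approx(expected, abs=1e-9)


class TestDistanceMatrix:
    def test_identical_pair_zero_matrix(self):
        lib = fk.BarcodeLibrary([fk.BarcodeRecord("a", "rbcL", "v1", "ACGT"),
                                 fk.BarcodeRecord("b", "rbcL", "v2", "ACGT")],
                                markers=("rbcL",))
        dm = fk.pairwise_distance_matrix(lib, "rbcL")
        assert dm.values.tolist() == [[0.0, 0.0], [0.0, 0.0]]
        assert dm.mean() == 0.0

    def test_entries_equal_per_pair_oracle(self, small_flora):
        _, library, _ = small_flora
        taxa = library.taxa_with("matK")[:6]
        dm = fk.pairwise_distance_matrix(library, "matK", taxa)
        for ta, tb in itertools.combinations(taxa, 2):
            a = library.reference_record(ta, "matK").sequence
            b = library.reference_record(tb, "matK").sequence
            assert dm.distance(ta, tb) == pytest.approx(brute_force_k2p(a, b), abs=1e-10)

    def test_missing_record_excluded_not_fatal(self, tiny_library):
        dm = fk.pairwise_distance_matrix(tiny_library, "rbcL",
                                         ["ac", "ap", "sv", "si", "qp"])
        assert dm.excluded_taxa == ("qp",)
        assert len(dm.taxon_ids) == 4

    def test_symmetry_zero_diagonal(self, small_flora):
        _, library, _ = small_flora
        dm = fk.pairwise_distance_matrix(library, "rbcL")
        assert np.allclose(dm.values, dm.values.T, equal_nan=True)
        assert np.all(np.diag(dm.values) == 0.0)


class TestMOTUClustering:
    def test_one_identical_pair(self, tiny_library):
        part = fk.cluster_motus(tiny_library, "rbcL")
        assert part.motu_count == 3
        assert frozenset({"ac", "ap"}) in part.blocks

    def test_all_distinct(self, tiny_library):
        part = fk.cluster_motus(tiny_library, "matK")
        assert part.motu_count == 4

    def test_n_copies_single_motu(self):
        lib = fk.BarcodeLibrary(
            [fk.BarcodeRecord(f"t{i}", "rbcL", f"v{i}", "AC-GT") for i in range(5)],
            markers=("rbcL",))
        part = fk.cluster_motus(lib, "rbcL")
        assert part.motu_count == 1

    def test_gaps_and_ambiguity_are_diagnostic(self):
        lib = fk.BarcodeLibrary(
            [fk.BarcodeRecord("a", "m", "v1", "AC-GT"),
             fk.BarcodeRecord("b", "m", "v2", "ACNGT"),
             fk.BarcodeRecord("c", "m", "v3", "ACAGT")],
            markers=("m",))
        assert fk.cluster_motus(lib, "m").motu_count == 3

    def test_identity_case_insensitive(self):
        # reader normalises case, but clustering itself must too
        lib = fk.BarcodeLibrary([fk.BarcodeRecord("a", "m", "v1", "acgt"),
                                 fk.BarcodeRecord("b", "m", "v2", "ACGT")],
                                markers=("m",))
        assert fk.cluster_motus(lib, "m").motu_count == 1

    def test_blocks_partition_taxa(self, small_flora):
        _, library, _ = small_flora
        part = fk.cluster_motus(library, "rbcL")
        union = [t for b in part.blocks for t in b]
        assert sorted(union) == sorted(set(union)) == sorted(part.taxa)


class TestConcatenation:
    def test_partition_refinement_on_fixture(self, tiny_library):
        # ac/ap identical on rbcL but distinct on matK -> separated
        taxa, part = fk.concatenate_markers(tiny_library, ("rbcL", "matK"))
        assert part.motu_count == 4
        single = fk.cluster_motus(tiny_library, "rbcL")
        assert part.refines(single)

    def test_restricts_to_taxa_with_all_markers(self):
        recs = [fk.BarcodeRecord("a", "m1", "v1", "AAAA"),
                fk.BarcodeRecord("b", "m1", "v2", "AAAT"),
                fk.BarcodeRecord("a", "m2", "v1", "CC"),
                # b lacks m2
                ]
        lib = fk.BarcodeLibrary(recs, markers=("m1", "m2"))
        taxa, part = fk.concatenate_markers(lib, ("m1", "m2"))
        assert taxa == ("a",)
        assert part.excluded_taxa == ("b",)

    def test_needs_two_markers(self, tiny_library):
        with pytest.raises(fk.FloraValidationError):
            fk.concatenate_markers(tiny_library, ("rbcL",))

    @given(st.data())
    @settings(max_examples=100)
    def test_refinement_law_random_libraries(self, data):
        """Combined-marker MOTUs refine each single-marker partition and the
        MOTU count never decreases when a marker is added."""
        n = data.draw(st.integers(2, 8), label="n_taxa")
        seqs1 = data.draw(st.lists(st.text("ACGT-", min_size=3, max_size=3),
                                   min_size=n, max_size=n), label="m1")
        seqs2 = data.draw(st.lists(st.text("ACGT-", min_size=4, max_size=4),
                                   min_size=n, max_size=n), label="m2")
        recs = []
        for i in range(n):
            recs.append(fk.BarcodeRecord(f"t{i}", "m1", f"v{i}", seqs1[i]))
            recs.append(fk.BarcodeRecord(f"t{i}", "m2", f"w{i}", seqs2[i]))
        lib = fk.BarcodeLibrary(recs, markers=("m1", "m2"))
        _, combined = fk.concatenate_markers(lib, ("m1", "m2"))
        for m in ("m1", "m2"):
            single = fk.cluster_motus(lib, m)
            assert combined.refines(single)
            assert combined.motu_count >= single.motu_count


class TestIntraspecificSummary:
    def test_identical_individuals_zero(self):
        recs = [fk.BarcodeRecord("sp", "m", "v1", "ACGTACGT", True),
                fk.BarcodeRecord("sp", "m", "v2", "ACGTACGT", False),
                fk.BarcodeRecord("sp", "m", "v3", "ACGTACGT", False)]
        lib = fk.BarcodeLibrary(recs, markers=("m",))
        df = fk.intraspecific_summary(lib)
        assert len(df) == 1
        assert df.iloc[0]["mean_k2p"] == 0.0
        assert df.iloc[0]["se_k2p"] == 0.0
        assert df.iloc[0]["n_pairs"] == 3

    def test_single_individual_skipped(self, tiny_library):
        df = fk.intraspecific_summary(tiny_library)
        assert df.empty

    def test_per_marker_rows_independent(self, small_flora):
        _, library, _ = small_flora
        df = fk.intraspecific_summary(library)
        assert set(df["marker"]) == set(library.markers)
        # 6 surveyed species x 3 markers
        assert len(df) == 18


class TestCongenericGroups:
    def test_planted_pair_group(self, small_flora):
        matrix, library, truth = small_flora
        df = fk.congeneric_group_report(library, matrix)
        gr1 = df[(df["group"] == "Gr1") & (df["marker"] == "rbcL")].iloc[0]
        assert gr1["n_sequenced"] == 4
        assert gr1["motu_count"] == 3  # planted identical pair collapses one
        gr1_matk = df[(df["group"] == "Gr1") & (df["marker"] == "matK")].iloc[0]
        assert gr1_matk["motu_count"] == 4

    def test_all_identical_group(self):
        taxa = [fk.Taxon(f"t{i}", f"T {i}", "G", "Gr1") for i in range(3)]
        chars = [fk.CharacterDefinition("c", "p", ("x", "y"), "leaf")]
        mat = fk.CharacterMatrix(taxa, chars, {(f"t{i}", "c"): "x" for i in range(3)})
        lib = fk.BarcodeLibrary([fk.BarcodeRecord(f"t{i}", "m", f"v{i}", "ACGT")
                                 for i in range(3)], markers=("m",))
        df = fk.congeneric_group_report(lib, mat)
        row = df.iloc[0]
        assert row["motu_count"] == 1
        assert row["mean_k2p_pct"] == 0.0

    def test_rows_equal_independent_calls(self, small_flora):
        matrix, library, _ = small_flora
        df = fk.congeneric_group_report(library, matrix)
        for _, row in df.iterrows():
            members = [t.taxon_id for t in matrix.taxa if t.group_id == row["group"]]
            part = fk.cluster_motus(library, row["marker"], members)
            assert row["motu_count"] == part.motu_count

    def test_undersequenced_group_inapplicable(self):
        taxa = [fk.Taxon("t0", "T", "G", "Gr1"), fk.Taxon("t1", "U", "G", "Gr1")]
        chars = [fk.CharacterDefinition("c", "p", ("x", "y"), "leaf")]
        mat = fk.CharacterMatrix(taxa, chars, {("t0", "c"): "x", ("t1", "c"): "y"})
        lib = fk.BarcodeLibrary([fk.BarcodeRecord("t0", "m", "v0", "ACGT")],
                                markers=("m",))
        df = fk.congeneric_group_report(lib, mat)
        assert math.isnan(df.iloc[0]["mean_k2p_pct"])
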