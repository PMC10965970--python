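import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bridgehead.alignment_io import (
    AlignmentError,
    AlignmentParseError,
    MetadataError,
    build_coordinate_map,
    collapse_haplotypes,
    excise_reference_interval,
    find_tandem_repeats,
    read_alignment,
    write_alignment,
)
from tests.conftest import make_alignment, write_fasta, write_metadata


class TestReadAlignment:
    def test_minimal_parse(self, tmp_path):
        write_fasta(tmp_path / "a.fasta", {"s1": "ACGTNACGT-", "s2": "acguTACGTA"})
        write_metadata(tmp_path / "m.tsv", {"s1": "Japan", "s2": "USA"})
        aln = read_alignment(tmp_path / "a.fasta", tmp_path / "m.tsv")
        assert aln.n_sequences == 2 and aln.n_columns == 10
        # uppercased, U mapped to T
        assert aln.sequence("s2") == "ACGTTACGTA"
        assert aln.regions == {"s1": "Japan", "s2": "USA"}

    def test_comma_delimited_metadata(self, tmp_path):
        write_fasta(tmp_path / "a.fasta", {"s1": "ACGT"})
        write_metadata(tmp_path / "m.csv", {"s1": "Azores"}, sep=",")
        assert read_alignment(tmp_path / "a.fasta", tmp_path / "m.csv").regions["s1"] == "Azores"

    def test_unequal_lengths_rejected(self, tmp_path):
        write_fasta(tmp_path / "a.fasta", {"s1": "ACGTACGTAC", "s2": "ACGTACGTA"})
        write_metadata(tmp_path / "m.tsv", {"s1": "Japan", "s2": "Japan"})
        with pytest.raises(AlignmentError):
            read_alignment(tmp_path / "a.fasta", tmp_path / "m.tsv")

    def test_missing_metadata_row_rejected(self, tmp_path):
        write_fasta(tmp_path / "a.fasta", {"s1": "ACGT", "s2": "ACGT"})
        write_metadata(tmp_path / "m.tsv", {"s1": "Japan"})
        with pytest.raises(MetadataError, match="s2"):
            read_alignment(tmp_path / "a.fasta", tmp_path / "m.tsv")

    def test_bad_character_names_sequence_and_column(self, tmp_path):
        write_fasta(tmp_path / "a.fasta", {"s1": "ACGT", "s2": "ACXT"})
        write_metadata(tmp_path / "m.tsv", {"s1": "Japan", "s2": "Japan"})
        with pytest.raises(AlignmentParseError, match=r"s2.*column 3"):
            read_alignment(tmp_path / "a.fasta", tmp_path / "m.tsv")

    def test_round_trip_identity(self, tmp_path, toy_alignment):
        write_alignment(toy_alignment, tmp_path / "out.fasta", tmp_path / "out.tsv")
        back = read_alignment(tmp_path / "out.fasta", tmp_path / "out.tsv")
        assert back.sequence_ids == toy_alignment.sequence_ids
        assert (back.sites == toy_alignment.sites).all()
        assert back.regions == toy_alignment.regions


class TestCoordinateMap:
    def test_single_gap(self):
        aln = make_alignment({"ref": "AC-GT", "x": "ACAGT"})
        cmap = build_coordinate_map(aln, "ref")
        assert [cmap.column_of_position(p) for p in (1, 2, 3, 4)] == [1, 2, 4, 5]

    def test_gap_free_is_identity(self):
        aln = make_alignment({"ref": "ACGT" * 5})
        cmap = build_coordinate_map(aln, "ref")
        assert all(cmap.column_of_position(p) == p for p in range(1, 21))

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT-"), size=200))
        if "-" not in seq:
            seq = seq[:10] + "-" + seq[11:]
        aln = make_alignment({"ref": seq})
        cmap = build_coordinate_map(aln, "ref")
        pos = 0
        for col, ch in enumerate(seq, start=1):  # independent linear scan
            if ch != "-":
                pos += 1
                assert cmap.column_of_position(pos) == col
        assert cmap.reference_length == pos

    def test_unknown_reference(self, toy_alignment):
        with pytest.raises(KeyError):
            build_coordinate_map(toy_alignment, "nope")


class TestExcision:
    def test_full_excision_leaves_nothing(self, toy_alignment):
        out = excise_reference_interval(toy_alignment, "s1", 1, 10)
        assert out.n_columns == 0 and out.n_sequences == 4

    def test_control_region_arithmetic(self):
        # gap-free reference of length 18,406; removing 14,740..17,118
        # (2,379 columns) leaves 16,027
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=18_406))
        aln = make_alignment({"ref": seq})
        out = excise_reference_interval(aln, "ref", 14_740, 17_118)
        assert out.n_columns == 16_027

    def test_gap_only_columns_inside_interval_removed(self):
        # ref positions 2..3 span columns 2..4 (incl. the gap column 3)
        aln = make_alignment({"ref": "AC-GT", "x": "ACAGT"})
        out = excise_reference_interval(aln, "ref", 2, 3)
        assert out.n_columns == 2
        assert out.sequence("ref") == "AT" and out.sequence("x") == "AT"

    def test_interval_outside_reference(self, toy_alignment):
        with pytest.raises(IndexError):
            excise_reference_interval(toy_alignment, "s1", 5, 11)

    def test_idempotent_on_disjoint_second_call(self):
        aln = make_alignment({"ref": "ACGTACGT"})
        once = excise_reference_interval(aln, "ref", 3, 5)
        assert once.sequence("ref") == "ACCGT"
        again = excise_reference_interval(once, "ref", 1, 2)
        assert again.sequence("ref") == "CGT"


class TestHaplotypes:
    def test_identical_rows_collapse_to_one(self):
        aln = make_alignment({f"s{i}": "ACGTACGT" for i in range(22)})
        table = collapse_haplotypes(aln)
        assert table.n_haplotypes == 1 and table.counts == [22]

    def test_all_distinct(self):
        aln = make_alignment({"a": "AAAA", "b": "AAAC", "c": "AAAG"})
        table = collapse_haplotypes(aln)
        assert table.counts == [1, 1, 1]

    def test_sorted_by_count_then_first_seen(self):
        aln = make_alignment(
            {"a": "AAAA", "b": "CCCC", "c": "CCCC", "d": "GGGG", "e": "AAAA", "f": "TTTT"}
        )
        table = collapse_haplotypes(aln)
        assert table.counts == [2, 2, 1, 1]
        assert table.members[0] == ["a", "e"] and table.members[1] == ["b", "c"]

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        rows = {
            f"s{i}": "".join(rng.choice(list("ACGT"), size=6)) for i in range(30)
        }
        aln = make_alignment(rows)
        table = collapse_haplotypes(aln)
        assert sum(table.counts) == 30
        regained = sorted(x for m in table.members for x in m)
        assert regained == sorted(rows)
        # region occupancy sums match counts
        assert all(sum(rc.values()) == c for rc, c in zip(table.region_counts, table.counts))


def brute_force_tandem_arrays(seq: str, unit_min: int, unit_max: int, max_mm: int):
    """Exhaustive (start, unit, copies) enumeration used as an oracle.

    Returns all maximal arrays of >= 2 copies, each copy within max_mm of the
    array's majority consensus.
    """
    s = np.frombuffer(seq.encode(), dtype="S1")
    found = []
    for u in range(unit_min, min(unit_max, len(s) // 2) + 1):
        for start in range(0, len(s) - 2 * u + 1):
            for k in range(2, (len(s) - start) // u + 1):
                blocks = s[start : start + k * u].reshape(k, u)
                cons = blocks[0].copy()
                for j in range(u):
                    vals, cnt = np.unique(blocks[:, j], return_counts=True)
                    if cnt.max() > (blocks[:, j] == cons[j]).sum():
                        cons[j] = vals[np.argmax(cnt)]
                if ((blocks != cons).sum(axis=1) <= max_mm).all():
                    found.append((start + 1, u, k))
    # keep only maximal (not extensible to k+1 at the same start/unit and not a
    # suffix of an array starting a unit earlier)
    maximal = [
        (st, u, k)
        for st, u, k in found
        if (st, u, k + 1) not in found and (st - u, u, k + 1) not in found
    ]
    return set(maximal)


class TestTandemRepeats:
    def test_exact_repeats(self):
        seq = "ACGTA" * 5
        anns = find_tandem_repeats(seq, unit_min=2, unit_max=10, max_mismatch_per_copy=0)
        best = max(anns, key=lambda a: a.copy_number)
        assert (best.unit_length, best.copy_number, best.start, best.end) == (5, 5, 1, 25)
        assert best.max_unit_divergence == 0

    def test_random_sequence_with_no_repeat_is_empty(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=200))
        oracle = brute_force_tandem_arrays(seq, 20, 40, 0)
        assert oracle == set()  # oracle confirms no unit >= 20 bp repeats twice
        assert find_tandem_repeats(seq, unit_min=20, unit_max=40, max_mismatch_per_copy=0) == []

    def test_matches_brute_force_on_planted_arrays(self):
        rng = np.random.default_rng(5)
        unit = "".join(rng.choice(list("ACGT"), size=17))
        copies = [list(unit) for _ in range(6)]
        copies[2][4] = "A" if unit[4] != "A" else "C"  # one divergent copy
        flank1 = "".join(rng.choice(list("ACGT"), size=40))
        flank2 = "".join(rng.choice(list("ACGT"), size=40))
        seq = flank1 + "".join("".join(c) for c in copies) + flank2
        anns = find_tandem_repeats(seq, unit_min=12, unit_max=25, max_mismatch_per_copy=2)
        assert len(anns) == 1
        a = anns[0]
        # the planted array is covered (a phase-shifted maximal array with the
        # same unit length and copy number is an equally valid report)
        assert a.unit_length == 17 and a.copy_number >= 6
        assert a.start <= 41 and a.end >= 40 + 17 * 6 - 2
        assert a.max_unit_divergence <= 2
        assert (a.start, a.unit_length, a.copy_number) in brute_force_tandem_arrays(
            seq, 12, 25, 2
        )

    def test_control_region_like_structure(self):
        # synthetic control region emulating the reference mitogenome's
        # repeat organisation: 25 copies of an 81 bp unit (some copies with
        # 1 substitution) followed by a 38 bp partial copy
        rng = np.random.default_rng(7)
        unit = "".join(rng.choice(list("ACGT"), size=81))
        copies = []
        for i in range(25):
            c = list(unit)
            if i in (3, 11, 19):
                c[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[c[i]]
            copies.append("".join(c))
        seq = "".join(copies) + unit[:38]
        anns = find_tandem_repeats(seq, unit_min=60, unit_max=100, max_mismatch_per_copy=2)
        assert len(anns) == 1
        a = anns[0]
        assert a.unit_length == 81 and a.copy_number == 25
        assert a.partial_length == 38
        assert a.max_unit_divergence <= 1

    def test_rejects_gapped_or_empty(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("")
        with pytest.raises(ValueError):
            find_tandem_repeats("ACG-ACG-")

    @settings(max_examples=10, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_equivalence_on_short_sequences(self, seed):
        rng = np.random.default_rng(seed)
        unit_len = int(rng.integers(5, 12))
        n_copies = int(rng.integers(2, 6))
        unit = "".join(rng.choice(list("ACGT"), size=unit_len))
        seq = (
            "".join(rng.choice(list("ACGT"), size=30))
            + unit * n_copies
            + "".join(rng.choice(list("ACGT"), size=30))
        )
        anns = find_tandem_repeats(seq, unit_min=5, unit_max=15, max_mismatch_per_copy=0)
        oracle = brute_force_tandem_arrays(seq, 5, 15, 0)
        # every reported array is a maximal oracle array
        for a in anns:
            assert (a.start, a.unit_length, a.copy_number) in oracle
        # the planted array is recovered (possibly phase-shifted or with a
        # longer span if the flanks extend it by chance)
        assert any(
            a.unit_length == unit_len and a.copy_number >= n_copies for a in anns
        )
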