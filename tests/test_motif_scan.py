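"""IUPAC scanning against a regex oracle; clubbing and CRE summaries."""

import re

import numpy as np
import pytest

from pp2anet.config_io import IUPAC_TO_BASES, Motif, PromoterSet, ValidationError
from pp2anet.motif_scan import (
    MotifFrequencyMatrix,
    MotifLibrary,
    builtin_motif_library,
    club_hits,
    reverse_complement_pattern,
    scan_promoters,
    scan_sequence,
    summarize_common_unique,
)
from pp2anet.synthetic_data import MotifPlanting, generate_promoters


def regex_starts(seq, pattern):
    """Independent oracle: overlapping regex over IUPAC character classes.

    A sequence N is allowed only where the pattern itself says N.
    """
    classes = []
    for p in pattern:
        allowed = "".join(sorted(IUPAC_TO_BASES[p]))
        classes.append(f"[{allowed}N]" if p == "N" else f"[{allowed}]")
    rx = re.compile("(?=(" + "".join(classes) + "))")
    return [m.start() + 1 for m in rx.finditer(seq)]


def oracle_hits(seq, motif, strands):
    hits = {(s, "+") for s in regex_starts(seq, motif.pattern)}
    if strands == "both":
        rc = reverse_complement_pattern(motif.pattern)
        if rc != motif.pattern:
            hits |= {(s, "-") for s in regex_starts(seq, rc)}
    return hits


class TestBuiltinLibrary:
    def test_sixteen_validated_motifs_with_known_entries(self):
        lib = builtin_motif_library()
        assert len(lib) == 16
        assert lib["ARR1AT"].pattern == "NGATT"
        assert lib["CAATBOX1"].pattern == "CAAT"
        assert lib["GT1CONSENSUS"].pattern == "GRWAAW"
        # construction validates all patterns as IUPAC
        assert all(set(m.pattern) <= set(IUPAC_TO_BASES) for m in lib)


class TestScanSequence:
    @pytest.mark.parametrize(
        "pattern,seq,expected_starts",
        [
            ("CAAT", "GGCAATGG", [3]),
            ("CANNTG", "CATTTG", [1]),
            ("NGATT", "TGATTGATT", [1, 5]),
        ],
    )
    def test_forward_examples(self, pattern, seq, expected_starts):
        hits = scan_sequence(seq, Motif("m", pattern), strands="forward")
        assert [h.start for h in hits] == expected_starts

    def test_self_complementary_pattern_reported_once(self):
        hits = scan_sequence("ACACGTGA", Motif("m", "CACGTG"), strands="both")
        assert len(hits) == 1
        assert hits[0].start == 2 and hits[0].strand == "+"

    def test_minus_strand_match_reports_supplied_window(self):
        # revcomp of TGAC is GTCA; a GTCA window is a minus-strand W-box site
        hits = scan_sequence("AAGTCAAA", Motif("WRKY71OS", "TGAC"), strands="both")
        minus = [h for h in hits if h.strand == "-"]
        assert [(h.start, h.matched) for h in minus] == [(3, "GTCA")]
        rc = reverse_complement_pattern("GTCA")  # == revcomp of matched window
        assert rc == "TGAC"

    def test_sequence_n_matches_only_pattern_n(self):
        # unknown base in the sequence never satisfies a concrete pattern base
        assert scan_sequence("CANT", Motif("m", "CAAT"), strands="forward") == []
        # but a sequence N is fine where the pattern itself is N
        hits = scan_sequence("CANNTG", Motif("m", "CANNTG"), strands="forward")
        assert [h.start for h in hits] == [1]

    def test_pattern_longer_than_sequence_yields_nothing(self):
        assert scan_sequence("ACG", Motif("m", "CANNTG")) == []

    def test_scanner_equals_regex_oracle_on_random_sequences(self):
        rng = np.random.default_rng(17)
        lib = builtin_motif_library()
        for _ in range(40):
            n = int(rng.integers(10, 200))
            seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24] * 4 + [0.04]))
            for motif in lib:
                for strands in ("forward", "both"):
                    ours = {
                        (h.start, h.strand)
                        for h in scan_sequence(seq, motif, strands=strands)
                    }
                    assert ours == oracle_hits(seq, motif, strands)

    def test_reverse_complement_symmetry_of_total_counts(self):
        comp = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}
        rng = np.random.default_rng(19)
        lib = builtin_motif_library()
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGT"), size=150))
            rc_seq = "".join(comp[c] for c in reversed(seq))
            for motif in lib:
                a = len(scan_sequence(seq, motif, strands="both"))
                b = len(scan_sequence(rc_seq, motif, strands="both"))
                assert a == b


class TestClubbing:
    PATTERNS = {"CAATBOX1": "CAAT", "CACTFTPPCA1": "CACGTG"}

    def test_same_motif_same_strand_collapse_to_one_group(self):
        hits = scan_sequence(
            "CAAT" + "G" * 30 + "CAAT" + "G" * 30 + "CAAT",
            Motif("CAATBOX1", "CAAT"),
            strands="forward",
            gene_id="g1",
        )
        (group,) = club_hits(hits, self.PATTERNS)
        assert group.frequency == 3
        assert group.starts == (1, 35, 69)

    def test_strand_distinguishes_sites(self):
        from pp2anet.motif_scan import MotifHit

        hits = [
            MotifHit("g1", "CACTFTPPCA1", 5, "+", "CACGTG"),
            MotifHit("g1", "CACTFTPPCA1", 200, "-", "CACGTG"),
        ]
        groups = club_hits(hits, self.PATTERNS)
        assert sorted((g.strand, g.frequency) for g in groups) == [("+", 1), ("-", 1)]

    def test_empty_hit_list(self):
        assert club_hits([], self.PATTERNS) == []

    def test_hits_from_multiple_genes_rejected(self):
        from pp2anet.motif_scan import MotifHit

        hits = [
            MotifHit("g1", "CAATBOX1", 1, "+", "CAAT"),
            MotifHit("g2", "CAATBOX1", 1, "+", "CAAT"),
        ]
        with pytest.raises(ValidationError, match="single gene"):
            club_hits(hits, self.PATTERNS)


class TestScanPromoters:
    def test_empty_promoter_set(self):
        hits, matrix = scan_promoters(
            PromoterSet({}), builtin_motif_library(), strands="both"
        )
        assert hits == [] and matrix.grand_total() == 0

    def test_planted_truth_recovered_exactly(self):
        lib = builtin_motif_library()
        plantings = [
            MotifPlanting("g1", lib["CAATBOX1"], 4),
            MotifPlanting("g1", lib["WRKY71OS"], 2),
            MotifPlanting("g2", lib["TAAAGSTKST1"], 3),
        ]
        proms, truth = generate_promoters(
            ["g1", "g2"], length=1000, plantings=plantings,
            avoid_background=True, seed=33,
        )
        sub_lib = MotifLibrary(
            (lib["CAATBOX1"], lib["WRKY71OS"], lib["TAAAGSTKST1"])
        )
        _, matrix = scan_promoters(proms, sub_lib, strands="both")
        assert {k: v for k, v in matrix.counts.items() if v} == dict(
            truth.planted_motif_counts
        )

    def test_matrix_equals_group_by_recount_of_hits(self):
        rng = np.random.default_rng(41)
        proms = PromoterSet(
            {
                f"g{i}": "".join(rng.choice(list("ACGT"), size=300))
                for i in range(4)
            }
        )
        lib = builtin_motif_library()
        hits, matrix = scan_promoters(proms, lib, strands="both")
        recount: dict = {}
        for h in hits:
            key = (h.gene_id, h.motif)
            recount[key] = recount.get(key, 0) + 1
        assert {k: v for k, v in matrix.counts.items() if v} == recount
        assert matrix.grand_total() == len(hits)


class TestSummaries:
    def make_matrix(self, counts, genes, motifs):
        return MotifFrequencyMatrix(
            genes=tuple(genes), motifs=tuple(motifs), counts=dict(counts)
        )

    def test_single_gene_motif_with_two_sites_is_common_not_unique(self):
        matrix = self.make_matrix({("g1", "CAATBOX1"): 2}, ["g1"], ["CAATBOX1"])
        summary = summarize_common_unique(matrix)
        assert summary.common == {"CAATBOX1"}
        assert summary.unique == {}

    def test_single_total_occurrence_is_unique_not_common(self):
        matrix = self.make_matrix(
            {("g1", "X"): 1}, ["g1", "g2", "g3"], ["X"]
        )
        summary = summarize_common_unique(matrix)
        assert summary.unique == {"X": "g1"}
        assert summary.common == frozenset()

    def test_random_matrix_matches_definition_replay(self):
        rng = np.random.default_rng(55)
        genes = [f"g{i}" for i in range(5)]
        motifs = [f"m{i}" for i in range(8)]
        counts = {
            (g, m): int(rng.integers(0, 3)) for g in genes for m in motifs
        }
        matrix = self.make_matrix(
            {k: v for k, v in counts.items() if v}, genes, motifs
        )
        summary = summarize_common_unique(matrix)
        expected_common = {
            m for m in motifs if all(counts[(g, m)] >= 1 for g in genes)
        }
        expected_unique = {
            m for m in motifs if sum(counts[(g, m)] for g in genes) == 1
        }
        assert summary.common == expected_common
        assert set(summary.unique) == expected_unique
        # with >= 2 genes analysed, common and unique never overlap
        assert not (summary.common & set(summary.unique))
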