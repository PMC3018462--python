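"""Exact probe matching and the bidirectional common/unique partition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import naive_match_counts, random_dna
from saspipe._util import revcomp
from saspipe.mapping import SequenceIndex, classify_common_unique, match_probeset
from saspipe.simulate import PlatformDesign, ProbeSet, TranscriptRecord


def _record(tid, seq, gid=None, orientation="sense"):
    return TranscriptRecord(tid, gid, orientation, seq, "chr1", 0, len(seq), "+")


def _platform(name, entries, probes_per=None):
    """entries: list of (probeset_id, transcript_id, sequence, probes)."""
    p = PlatformDesign(name)
    for pid, tid, seq, probes in entries:
        p.probesets[pid] = ProbeSet(pid, name, probes, tid, None, "sense")
        if seq is not None:
            p.transcripts[tid] = _record(tid, seq)
    return p


class TestSequenceIndex:
    def test_forward_hit(self):
        idx = SequenceIndex({"s1": "AAACCCGG"})
        assert idx.find("AACC") == {("s1", "forward")}

    def test_palindrome_hits_both_strands(self):
        idx = SequenceIndex({"s1": "ACGTACGT"})
        assert idx.find("ACGT") == {("s1", "forward"), ("s1", "reverse")}

    def test_reverse_strand_hit(self):
        idx = SequenceIndex({"s1": "AAACCCTTT"})
        probe = revcomp("ACCCT")
        assert idx.find(probe) == {("s1", "reverse")}

    def test_absent_kmer_empty(self):
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": random_dna(rng, 200) for i in range(5)}
        idx = SequenceIndex(seqs)
        probe = random_dna(rng, 25)
        # brute-force scan as the oracle
        expected = naive_match_counts([probe], seqs)
        assert (idx.find(probe) == set()) == (expected == {})

    def test_empty_sequence_set_rejected(self):
        with pytest.raises(ValueError):
            SequenceIndex({})

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.data())
    def test_index_agrees_with_naive_scan(self, data):
        dna = st.text(alphabet="ACGT", min_size=30, max_size=120)
        seqs = {f"s{i}": data.draw(dna) for i in range(data.draw(st.integers(1, 5)))}
        probe = data.draw(st.text(alphabet="ACGT", min_size=4, max_size=12))
        idx = SequenceIndex(seqs)
        hits = {sid for sid, _ in idx.find(probe)}
        expected = set(naive_match_counts([probe], seqs))
        assert hits == expected


class TestMatchProbeset:
    def _probeset(self, probes):
        return ProbeSet("ps1", "x", probes, "t", None, "sense")

    def test_all_probes_in_one_target(self):
        rng = np.random.default_rng(1)
        target = random_dna(rng, 500)
        probes = [target[i * 30 : i * 30 + 25] for i in range(11)]
        mr = match_probeset(self._probeset(probes), SequenceIndex({"T": target}))
        assert mr.best_target_id == "T"
        assert mr.n_probes_matched_to_best == 11

    def test_six_in_target_five_scattered(self):
        rng = np.random.default_rng(2)
        target = random_dna(rng, 400)
        others = {f"o{i}": random_dna(rng, 400) for i in range(5)}
        probes = [target[i * 40 : i * 40 + 25] for i in range(6)]
        probes += [others[f"o{i}"][10:35] for i in range(5)]
        mr = match_probeset(self._probeset(probes), SequenceIndex({"T": target, **others}))
        assert mr.best_target_id == "T"
        assert mr.n_probes_matched_to_best == 6

    def test_split_five_five_never_pools(self):
        # probes split across two sequences never combine into one count
        rng = np.random.default_rng(3)
        t1, t2 = random_dna(rng, 300), random_dna(rng, 300)
        probes = [t1[i * 30 : i * 30 + 25] for i in range(5)]
        probes += [t2[i * 30 : i * 30 + 25] for i in range(5)]
        mr = match_probeset(self._probeset(probes), SequenceIndex({"T1": t1, "T2": t2}))
        assert mr.n_probes_matched_to_best == 5

    def test_tie_breaks_to_smallest_target_id(self):
        seq = "ACGTACGTACGTACGTACGT"
        mr = match_probeset(
            self._probeset(["ACGTACGT"]), SequenceIndex({"B": seq, "A": seq})
        )
        assert mr.best_target_id == "A"

    def test_no_hits(self):
        mr = match_probeset(self._probeset(["AAAAA"]), SequenceIndex({"T": "CCCCCCCC"}))
        assert mr.best_target_id is None
        assert mr.n_probes_matched_to_best == 0

    def test_strand_symmetry_counts_invariant(self):
        rng = np.random.default_rng(4)
        seqs = {f"s{i}": random_dna(rng, 300) for i in range(4)}
        probes = [seqs["s0"][i * 20 : i * 20 + 25] for i in range(8)]
        ps = self._probeset(probes)
        mr_fwd = match_probeset(ps, SequenceIndex(seqs))
        mr_rev = match_probeset(ps, SequenceIndex({k: revcomp(v) for k, v in seqs.items()}))
        assert mr_fwd.counts == mr_rev.counts
        assert mr_fwd.strand_of_best != mr_rev.strand_of_best


def _probes_from(seq, n, step=30, k=25):
    return [seq[i * step : i * step + k] for i in range(n)]


class TestClassifyCommonUnique:
    def test_identical_platforms_all_common(self):
        rng = np.random.default_rng(5)
        entries = []
        for i in range(4):
            seq = random_dna(rng, 400)
            entries.append((f"ps{i}", f"t{i}", seq, _probes_from(seq, 11)))
        pa = _platform("a", entries)
        pb = _platform("b", [(pid + "_b", tid, seq, pr) for pid, tid, seq, pr in entries])
        part = classify_common_unique(pa, pb)
        assert part.classes["a"]["unique"] == set()
        assert part.classes["b"]["unique"] == set()

    def test_disjoint_content_all_unique(self):
        rng = np.random.default_rng(6)
        ea = [("pa", "ta", random_dna(rng, 400), None)]
        ea[0] = (ea[0][0], ea[0][1], ea[0][2], _probes_from(ea[0][2], 11))
        sb = random_dna(rng, 400)
        eb = [("pb", "tb", sb, _probes_from(sb, 11))]
        part = classify_common_unique(_platform("a", ea), _platform("b", eb))
        assert part.classes["a"]["common"] == set()
        assert part.classes["b"]["common"] == set()

    def test_partition_law(self, small_world):
        _, _, _, generic, dsa = small_world
        part = classify_common_unique(generic, dsa)
        for platform in (generic, dsa):
            cls = part.classes[platform.name]
            assert cls["common"] | cls["unique"] == set(platform.probesets)
            assert cls["common"] & cls["unique"] == set()

    def test_recovers_ground_truth_exactly(self, small_world):
        _, _, truth, generic, dsa = small_world
        part = classify_common_unique(generic, dsa)
        recovered = part.classes["generic"]["common"] | part.classes["dsa"]["common"]
        assert recovered == truth.common_probesets

    def test_boundary_monotonicity(self):
        """Breaking the 6th matching probe flips common -> unique; adding a
        matching probe never flips common -> unique."""
        rng = np.random.default_rng(7)
        seq = random_dna(rng, 500)
        six = _probes_from(seq, 6, step=50)
        filler = [random_dna(rng, 25) for _ in range(5)]
        other = random_dna(rng, 500)

        def build(probes):
            pa = _platform("a", [("pa", "ta", seq, _probes_from(seq, 11, step=40))])
            pb = _platform("b", [("pb", "tb", other, probes)])
            return classify_common_unique(pa, pb)

        part = build(six + filler)
        assert "pb" in part.classes["b"]["common"]
        broken = ["T" * 25] + six[1:] + filler  # homopolymer absent from seq
        part2 = build(broken)
        assert "pb" in part2.classes["b"]["unique"]
        part3 = build(six + [seq[401:426]] + filler[:4])
        assert "pb" in part3.classes["b"]["common"]

    def test_fewer_than_six_probes_cannot_qualify_as_query(self):
        # 5/5 probes of pb occur in pa's sequence, but 5 < 6 so the rule
        # cannot fire; pb's own (distinct) sequence draws no reverse match
        rng = np.random.default_rng(8)
        seq = random_dna(rng, 300)
        other = random_dna(rng, 300)
        pa = _platform("a", [("pa", "ta", seq, _probes_from(seq, 11, step=20))])
        pb = _platform("b", [("pb", "tb", other, _probes_from(seq, 5, step=20))])
        part = classify_common_unique(pa, pb)
        assert "pb" in part.classes["b"]["unique"]
        assert "pa" in part.classes["a"]["unique"]

    def test_sequence_level_marking_in_pass_two(self):
        # a B probeset too short to qualify as a query still becomes common
        # when the other platform's probeset matches its full-length sequence
        rng = np.random.default_rng(12)
        seq = random_dna(rng, 300)
        pa = _platform("a", [("pa", "ta", seq, _probes_from(seq, 11, step=20))])
        pb = _platform("b", [("pb", "tb", seq, _probes_from(seq, 5, step=20))])
        part = classify_common_unique(pa, pb)
        assert "pa" in part.classes["a"]["common"]
        assert "pb" in part.classes["b"]["common"]

    def test_missing_sequence_record_excluded_not_dropped(self):
        rng = np.random.default_rng(9)
        seq = random_dna(rng, 300)
        pa = _platform("a", [("pa", "ta", seq, _probes_from(seq, 11, step=20))])
        pb = _platform("b", [("pb", "tb", seq, _probes_from(seq, 11, step=20))])
        del pb.transcripts["tb"]  # orphan probeset
        part = classify_common_unique(pa, pb)
        assert part.classes["b"]["excluded"] == {"pb"}
        assert part.summary()["b"]["excluded"] == 1

    def test_match_counts_equal_naive_scan_on_random_instances(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            n_seq = int(rng.integers(1, 8))
            seqs = {f"s{i}": random_dna(rng, int(rng.integers(60, 300))) for i in range(n_seq)}
            donor = seqs[f"s{int(rng.integers(0, n_seq))}"]
            probes = []
            for _ in range(int(rng.integers(1, 12))):
                if rng.random() < 0.6 and len(donor) > 30:
                    start = int(rng.integers(0, len(donor) - 25))
                    p = donor[start : start + 25]
                else:
                    p = random_dna(rng, 25)
                if rng.random() < 0.3:
                    p = revcomp(p)
                probes.append(p)
            ps = ProbeSet("q", "x", probes, "t", None, "sense")
            mr = match_probeset(ps, SequenceIndex(seqs))
            assert mr.counts == naive_match_counts(probes, seqs)
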