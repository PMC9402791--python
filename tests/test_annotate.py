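"""V/J assignment, CDR3 extraction, junction decomposition, repertoire building."""

import numpy as np
import pytest

from trirep.annotate import (
    Clonotype,
    Rejection,
    Repertoire,
    annotate_reads,
    assign_vj,
    build_repertoire,
    decompose_junction,
    extract_cdr3,
    read_airr,
    write_airr,
)
from trirep.merge import MergedRead, revcomp
from trirep.simulate import make_clonotype

BASES = "ACGT"


def _read(seq: str, rid: str = "r") -> MergedRead:
    return MergedRead(rid, seq, "I" * len(seq), 0, 0)


def exhaustive_best_segment(seq: str, segments):
    """Oracle: score every segment on every diagonal, ungapped."""
    best = None
    for seg in segments:
        s = seg.sequence
        for d in range(-len(s) + 1, len(seq)):
            a, b = max(0, d), min(len(seq), d + len(s))
            if b <= a:
                continue
            m = sum(seq[i] == s[i - d] for i in range(a, b))
            score = 2 * m - (b - a)
            if best is None or score > best[1]:
                best = (seg.segment_id, score)
    return best


class TestAssignVJ:
    def test_constructed_read_assigns_correct_segments(self, library):
        v = library["TRBV3"]
        j = library["TRBJ2"]
        seq = v.sequence[:-4] + "GGCAT" + j.sequence[2:]
        hit = assign_vj(_read(seq), library)
        assert not isinstance(hit, Rejection)
        ann, canon = hit
        assert (ann.v_id, ann.j_id) == ("TRBV3", "TRBJ2")
        # cross-check V against an exhaustive all-segment, all-diagonal scan
        oracle_v = exhaustive_best_segment(seq, library.of_class("V", True))
        assert ann.v_id == oracle_v[0]

    def test_random_sequence_unassigned(self, rng):
        seq = "".join(BASES[i] for i in rng.integers(0, 4, 150))
        from trirep.germline import builtin_library

        res = assign_vj(_read(seq), builtin_library())
        assert isinstance(res, Rejection) and res.reason == "unassigned"

    def test_reverse_complement_canonicalized(self, library):
        v, j = library["TRBV5"], library["TRBJ4"]
        seq = v.sequence + "GGTACA" + j.sequence[3:]
        fwd = assign_vj(_read(seq), library)
        rev = assign_vj(_read(revcomp(seq)), library)
        assert not isinstance(fwd, Rejection) and not isinstance(rev, Rejection)
        ann_f, canon_f = fwd
        ann_r, canon_r = rev
        assert canon_r == canon_f
        assert (ann_r.v_id, ann_r.j_id) == (ann_f.v_id, ann_f.j_id)
        assert ann_r.strand == "-"


class TestExtractCDR3:
    def test_zero_noise_junctions_match_truth(self, library, small_truth, small_clean_run):
        result, _ = small_clean_run
        assert result.unfiltered.junctions == small_truth.junctions

    def test_stop_codon_rejected(self, library):
        v, j = library["TRBV1"], library["TRBJ1"]
        ct = make_clonotype(v, j, 0, 0, "TAA")  # in-frame stop inside junction
        assert not ct.productive
        hit = assign_vj(_read(ct.full_nt), library)
        ann, canon = hit
        res = extract_cdr3(canon, ann, library)
        assert isinstance(res, Rejection) and res.reason == "stop-codon"

    def test_mutated_v_anchor_rejected(self, library):
        v, j = library["TRBV1"], library["TRBJ1"]
        ct = make_clonotype(v, j, 0, 0, "GGG")
        seq = bytearray(ct.full_nt.encode())
        pos = v.anchor_offset + 1  # break the Cys codon (TGT/TGC -> TAT/TAC = Tyr)
        seq[pos] = ord("A")
        hit = assign_vj(_read(seq.decode()), library)
        assert not isinstance(hit, Rejection)
        ann, canon = hit
        res = extract_cdr3(canon, ann, library)
        assert isinstance(res, Rejection) and res.reason == "no-V-anchor"

    def test_out_of_frame_junction_rejected(self, library):
        v, j = library["TRBV2"], library["TRBJ3"]
        ct = make_clonotype(v, j, 0, 0, "GG")  # 2 nt insert breaks the frame
        hit = assign_vj(_read(ct.full_nt), library)
        ann, canon = hit
        res = extract_cdr3(canon, ann, library)
        assert isinstance(res, Rejection) and res.reason == "out-of-frame"


class TestDecomposeJunction:
    def test_recovers_homology_free_decomposition(self, library, rng):
        """Exact (v_trim, j_trim, n_len) recovery when the insert shares no
        terminal bases with the trimmed germline ends."""
        vs = library.of_class("V", True)
        js = library.of_class("J", True)
        checked = 0
        for _ in range(300):
            v = vs[rng.integers(len(vs))]
            j = js[rng.integers(len(js))]
            vt, jt = int(rng.integers(0, 7)), int(rng.integers(0, 7))
            nl = int(rng.integers(1, 10))
            n = "".join(BASES[i] for i in rng.integers(0, 4, nl))
            # homology-free: insert must not extend either germline end
            if vt and n[0] == v.sequence[len(v.sequence) - vt]:
                continue
            if jt and n[-1] == j.sequence[jt - 1]:
                continue
            ct = make_clonotype(v, j, vt, jt, n)
            got = decompose_junction(ct.junction_nt, v.segment_id, j.segment_id, library)
            assert got == (vt, jt, nl)
            checked += 1
        assert checked > 100

    def test_untrimmed_empty_insert(self, library):
        v, j = library["TRBV1"], library["TRBJ1"]
        ct = make_clonotype(v, j, 0, 0, "")
        assert decompose_junction(ct.junction_nt, v.segment_id, j.segment_id, library) == (0, 0, 0)

    def test_greedy_bias_attributes_homology_to_germline(self, library):
        v, j = library["TRBV1"], library["TRBJ1"]
        true_vt = 3
        # insert starts with exactly the base the trim removed
        n = v.sequence[len(v.sequence) - true_vt] + "GG"
        ct = make_clonotype(v, j, true_vt, 0, n)
        vt, jt, nl = decompose_junction(ct.junction_nt, v.segment_id, j.segment_id, library)
        assert vt <= true_vt
        assert nl <= len(n)


class TestBuildRepertoire:
    def test_frequencies(self):
        recs = [("TGTAAATTT", "V1", "J1", 5), ("TGTCCCTTT", "V2", "J1", 3)]
        rep = build_repertoire(recs)
        by_j = {c.junction_nt: c for c in rep.clonotypes}
        assert by_j["TGTAAATTT"].frequency == pytest.approx(0.625)
        assert by_j["TGTCCCTTT"].frequency == pytest.approx(0.375)
        assert rep.total_reads_assigned == 8

    def test_plurality_v_call_with_lexicographic_tie(self):
        recs = [
            ("TGTAAATTT", "V2", "J1", 3),
            ("TGTAAATTT", "V1", "J1", 3),
            ("TGTAAATTT", "V3", "J1", 2),
        ]
        rep = build_repertoire(recs)
        (c,) = rep.clonotypes
        assert c.v_id == "V1"  # tie between V1 and V2 breaks lexicographically
        assert c.copies == 8

    def test_empty(self):
        rep = build_repertoire([])
        assert len(rep) == 0 and rep.total_reads_assigned == 0

    def test_frequency_conservation_and_anchor_convention(self, small_noisy_run):
        result, _ = small_noisy_run
        for rep in (result.unfiltered, result.repertoire):
            total = sum(c.frequency for c in rep.clonotypes)
            assert total == pytest.approx(1.0, abs=1e-9)
            for c in rep.clonotypes:
                assert c.junction_aa[0] == "C" and c.junction_aa[-1] in "FW"
                assert "*" not in c.junction_aa

    def test_error_reads_create_false_clonotypes_without_filtering(
        self, small_truth, small_noisy_run
    ):
        """The asymmetry that motivates the filter cascade: noise leaves
        recall at 1 but drops unfiltered precision below 1."""
        result, _ = small_noisy_run
        truth = small_truth.junctions
        unf = result.unfiltered.junctions
        assert len(unf & truth) == len(truth)  # recall 1.0
        assert len(unf - truth) > 0  # precision < 1.0


class TestAirrIO:
    def test_round_trip(self, small_clean_run, tmp_path):
        result, _ = small_clean_run
        path = tmp_path / "rep.tsv"
        write_airr(result.repertoire, path)
        back = read_airr(path)
        assert back.junctions == result.repertoire.junctions
        orig = {c.junction_nt: c for c in result.repertoire.clonotypes}
        for c in back.clonotypes:
            o = orig[c.junction_nt]
            assert (c.v_id, c.j_id) == (o.v_id, o.j_id)
            assert c.copies == pytest.approx(o.copies)
            assert c.frequency == pytest.approx(o.frequency)
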