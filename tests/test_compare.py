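"""Multi-repertoire sharing, exclusivity, public/private and turnover analyses."""

import pytest
from hypothesis import given, settings, strategies as st

from trirep.annotate import Clonotype, Repertoire
from trirep.compare import (
    build_sharing_report,
    exclusive_variants,
    pairwise_overlap,
    public_private,
    trilineage_common,
    turnover,
)

# short junction-like tokens drawn from a tiny pool to force overlaps
TOKENS = [f"TGT{a}{b}TTT" for a in "ACGT" for b in "ACGT"]
token_sets = st.sets(st.sampled_from(TOKENS), min_size=0, max_size=12)


def rep_from(juncs, donor="d", lineage="s"):
    clonos = [Clonotype(j, "", "V1", "J1", 1) for j in sorted(juncs)]
    rep = Repertoire(donor, lineage, clonos, len(clonos))
    rep.renormalize()
    return rep


class TestPairwiseOverlap:
    def test_identical(self):
        r = rep_from(TOKENS[:8])
        shared, pa, pb = pairwise_overlap(r, rep_from(TOKENS[:8]))
        assert len(shared) == 8 and pa == pb == 100.0

    def test_disjoint(self):
        shared, pa, pb = pairwise_overlap(rep_from(TOKENS[:4]), rep_from(TOKENS[4:8]))
        assert shared == set() and pa == pb == 0.0

    def test_empty_defined_as_zero(self):
        _, pa, pb = pairwise_overlap(rep_from([]), rep_from(TOKENS[:3]))
        assert pa == 0.0 and pb == 0.0

    def test_designed_sharing_recovered(self, library):
        from trirep.simulate import share_clonotypes, simulate_repertoire

        reps = [simulate_repertoire(library, 100, seed=s) for s in (61, 62)]
        reps = share_clonotypes(reps, pairwise={(0, 1): 10}, seed=63)
        shared, pa, _ = pairwise_overlap(reps[0].to_repertoire(), reps[1].to_repertoire())
        assert len(shared) == 10 and pa == pytest.approx(10.0)

    @given(token_sets, token_sets)
    @settings(max_examples=100, deadline=None)
    def test_matches_naive_oracle(self, sa, sb):
        shared, pa, pb = pairwise_overlap(rep_from(sa), rep_from(sb))
        naive_shared = {x for x in sa if x in sb}
        assert shared == naive_shared
        assert pa == (100.0 * len(naive_shared) / len(sa) if sa else 0.0)
        assert pb == (100.0 * len(naive_shared) / len(sb) if sb else 0.0)


class TestExclusiveVariants:
    def test_all_disjoint_all_exclusive(self):
        samples = {
            ("I", "CD15"): rep_from(TOKENS[:3]),
            ("I", "CD14"): rep_from(TOKENS[3:6]),
            ("II", "CD15"): rep_from(TOKENS[6:9]),
        }
        out = exclusive_variants(samples)
        assert all(len(v) == 3 for v in out.values())

    def test_shared_variant_excluded_everywhere(self):
        samples = {
            ("I", "CD15"): rep_from(TOKENS[:3]),
            ("I", "CD14"): rep_from(TOKENS[2:5]),
        }
        out = exclusive_variants(samples)
        assert TOKENS[2] not in out[("I", "CD15")]
        assert TOKENS[2] not in out[("I", "CD14")]

    def test_needs_two_samples(self):
        with pytest.raises(ValueError):
            exclusive_variants({("I", "CD3"): rep_from(TOKENS[:2])})

    @given(st.lists(token_sets, min_size=2, max_size=5))
    @settings(max_examples=60, deadline=None)
    def test_set_identity_holds(self, sets):
        samples = {("D", f"L{i}"): rep_from(s) for i, s in enumerate(sets)}
        out = exclusive_variants(samples)
        for i, s in enumerate(sets):
            key = ("D", f"L{i}")
            others = set().union(*(x for j, x in enumerate(sets) if j != i))
            # naive: exclusive + shared-with-at-least-one-other partitions the set
            assert out[key] == s - others
            assert len(out[key]) + len(s & others) == len(s)


class TestTrilineageCommon:
    def test_identical_is_100(self):
        r = rep_from(TOKENS[:5])
        common, frac = trilineage_common(r, rep_from(TOKENS[:5]), rep_from(TOKENS[:5]))
        assert len(common) == 5 and frac == 100.0

    def test_empty_intersection(self):
        common, frac = trilineage_common(
            rep_from(TOKENS[:2]), rep_from(TOKENS[2:4]), rep_from(TOKENS[4:6])
        )
        assert common == set() and frac == 0.0

    def test_designed_fraction(self, library):
        from trirep.simulate import share_clonotypes, simulate_repertoire

        reps = [simulate_repertoire(library, 100, seed=s) for s in (71, 72, 73)]
        reps = share_clonotypes(
            reps,
            pairwise={(0, 1): 4, (0, 2): 4, (1, 2): 4},
            triples={(0, 1, 2): 4},
            seed=74,
        )
        obs = [r.to_repertoire() for r in reps]
        common, frac = trilineage_common(*obs)
        union = reps[0].junctions | reps[1].junctions | reps[2].junctions
        assert len(common) == 4
        assert frac == pytest.approx(100.0 * 4 / len(union))

    def test_common_contained_in_every_pairwise(self, library):
        from trirep.simulate import share_clonotypes, simulate_repertoire

        reps = [simulate_repertoire(library, 60, seed=s) for s in (81, 82, 83)]
        reps = share_clonotypes(
            reps, pairwise={(0, 1): 6, (0, 2): 5, (1, 2): 3},
            triples={(0, 1, 2): 2}, seed=84,
        )
        obs = [r.to_repertoire() for r in reps]
        common, _ = trilineage_common(*obs)
        for a in range(3):
            for b in range(a + 1, 3):
                shared, _, _ = pairwise_overlap(obs[a], obs[b])
                assert common <= shared


class TestPublicPrivate:
    def test_single_public_variant(self):
        donors = {f"D{i}": rep_from({TOKENS[0]} | set(TOKENS[1 + 2 * i : 3 + 2 * i]))
                  for i in range(5)}
        public, pct, private = public_private(donors)
        assert public == {TOKENS[0]}

    def test_disjoint_donors_all_private(self):
        donors = {"A": rep_from(TOKENS[:3]), "B": rep_from(TOKENS[3:6])}
        public, pct, private = public_private(donors)
        assert public == set()
        assert pct == {"A": 100.0, "B": 100.0}

    @given(st.lists(token_sets, min_size=2, max_size=5))
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_oracle(self, sets):
        donors = {f"D{i}": rep_from(s) for i, s in enumerate(sets)}
        public, pct, private = public_private(donors)
        naive_public = set(TOKENS)
        for s in sets:
            naive_public &= s
        assert public == naive_public
        for i, s in enumerate(sets):
            others = set().union(*(x for j, x in enumerate(sets) if j != i))
            assert private[f"D{i}"] == s - others
            expect = 100.0 * len(s - others) / len(s) if s else 0.0
            assert pct[f"D{i}"] == pytest.approx(expect)


class TestTurnover:
    def test_identical(self):
        r = rep_from(TOKENS[:6])
        retained, lost, gained = turnover(r, rep_from(TOKENS[:6]))
        assert retained == 100.0 and lost == set() and gained == set()

    def test_disjoint(self):
        retained, lost, gained = turnover(rep_from(TOKENS[:3]), rep_from(TOKENS[3:6]))
        assert retained == 0.0
        assert lost == set(TOKENS[:3]) and gained == set(TOKENS[3:6])

    def test_designed_differentiation(self):
        before = set(TOKENS[:10])
        after = set(TOKENS[7:13])  # keeps 3 of 6, gains 3 new
        retained, lost, gained = turnover(rep_from(before), rep_from(after))
        assert retained == pytest.approx(100.0 * 3 / 6)
        assert lost == before - after and gained == after - before

    def test_empty_after_errors(self):
        with pytest.raises(ValueError):
            turnover(rep_from(TOKENS[:2]), rep_from([]))


class TestSharingReport:
    def test_report_consistency(self, library):
        from trirep.simulate import share_clonotypes, simulate_repertoire

        reps, keys = [], []
        s = 90
        for d in ("I", "II"):
            for lin in ("CD15", "CD14", "CD3"):
                s += 1
                reps.append(simulate_repertoire(library, 50, seed=s, donor_id=d, lineage=lin))
                keys.append((d, lin))
        reps = share_clonotypes(reps, pairwise={(0, 2): 5, (1, 2): 3}, seed=99)
        samples = {k: r.to_repertoire() for k, r in zip(keys, reps)}
        report = build_sharing_report(samples)
        assert report.shared_counts.loc["I/CD15", "I/CD3"] == 5
        assert report.shared_counts.loc["I/CD14", "I/CD3"] == 3
        # symmetric counts, diagonal = repertoire sizes
        import numpy as np

        m = report.shared_counts.values
        assert (m == m.T).all()
        for i, k in enumerate(keys):
            assert m[i, i] == len(samples[k])
        text = report.to_json()
        assert "shared_counts" in text
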