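"""Demultiplexing, quality trimming, dereplication and chimera flagging."""

import numpy as np
import pytest

from itseval.core import (FusionPrimer, PipelineConfig, Read,
                          reverse_complement)
from itseval.primers import ITS4, ITS86F
from itseval.readpipe import (DemuxRule, UniqueSeq, _edit_matrix,
                              demultiplex, dereplicate, flag_chimeras,
                              quality_trim)
from itseval.simulate import ADAPTOR_A, ADAPTOR_B, make_mids

from conftest import random_dna


def _samples(n=2, seed=5):
    mids = make_mids(n, seed=seed)
    return [(f"S{i + 1:02d}",
             FusionPrimer(ADAPTOR_A, mid, ITS86F),
             FusionPrimer(ADAPTOR_B, mid, ITS4))
            for i, mid in enumerate(mids)]


def _read(insert: str, sample, rid="r1", mutate_front=None, mutate_back=None,
          drop_back=False):
    _, fwd, rev = sample
    front = fwd.full_sequence
    back = reverse_complement(rev.full_sequence)
    if mutate_front:
        front = "".join(
            ("G" if c != "G" else "T") if i in mutate_front else c
            for i, c in enumerate(front))
    if mutate_back:
        # mutate within the reverse MID/primer as seen on the read's 3' end
        back = "".join(
            ("G" if c != "G" else "T") if i in mutate_back else c
            for i, c in enumerate(back))
    bases = front + insert + ("" if drop_back else back)
    return Read(id=rid, bases=bases)


class TestDemux:
    def test_clean_run_fully_and_correctly_assigned(self, clean_run):
        refs, samples, reads, truth = clean_run
        res = demultiplex(reads, samples)
        assert len(res.unassigned) == 0
        assert len(res.assigned) == len(reads)
        got = {r.id: r for r in res.assigned}
        by_id = truth.set_index("read_id")
        for rid, read in got.items():
            row = by_id.loc[rid]
            assert read.sample_id == row["sample"]
            # decorations fully clipped: the read is exactly the true insert
            assert read.bases == refs.insert(row["taxon"], ITS86F, ITS4)

    def test_one_mid_error_tolerated_two_rejected(self, rng):
        samples = _samples()
        insert = random_dna(rng, 250)
        a = len(ADAPTOR_A)
        one = _read(insert, samples[0], mutate_front=[a])          # MID pos 0
        two = _read(insert, samples[0], mutate_front=[a, a + 1])
        res = demultiplex([one, two], samples)
        assert [r.id for r in res.assigned] == ["r1"]
        assert res.assigned[0].sample_id == "S01"
        assert len(res.unassigned) == 1
        assert res.log[0]["mid_errors_fwd"] == 1

    def test_two_primer_errors_tolerated_three_rejected(self, rng):
        samples = _samples()
        insert = random_dna(rng, 250)
        p0 = len(ADAPTOR_A) + 10  # first base of the forward primer
        ok = _read(insert, samples[0], mutate_front=[p0, p0 + 3])
        bad = _read(insert, samples[0], mutate_front=[p0, p0 + 3, p0 + 6])
        res = demultiplex([ok, bad], samples)
        assert len(res.assigned) == 1
        assert res.log[0]["primer_errors_fwd"] == 2

    def test_missing_reverse_end_unassigned(self, rng):
        samples = _samples()
        read = _read(random_dna(rng, 250), samples[0], drop_back=True)
        res = demultiplex([read], samples)
        assert res.assigned == [] and len(res.unassigned) == 1

    def test_reverse_mid_also_checked(self, rng):
        samples = _samples()
        insert = random_dna(rng, 250)
        # reverse MID occupies positions [adaptor, adaptor+10) of the
        # reverse decoration, i.e. the last (adaptor+10) bases of the read
        # reverse-complemented; mutate two bases inside it
        _, fwd, rev = samples[0]
        back = reverse_complement(rev.full_sequence)
        mid_zone = range(len(rev.primer), len(rev.primer) + 10)
        read = _read(insert, samples[0],
                     mutate_back=[mid_zone[0], mid_zone[1]])
        res = demultiplex([read], samples)
        assert res.assigned == []

    def test_duplicate_sample_id_rejected(self):
        samples = _samples()
        dup = [samples[0], ("S01", samples[1][1], samples[1][2])]
        with pytest.raises(ValueError, match="duplicate"):
            demultiplex([], dup)

    def test_close_mids_warn(self, rng):
        s = _samples(1)[0]
        near = s[1].mid[:-1] + ("G" if s[1].mid[-1] != "G" else "T")
        other = ("S02", FusionPrimer(ADAPTOR_A, near, ITS86F),
                 FusionPrimer(ADAPTOR_B, near, ITS4))
        with pytest.warns(UserWarning, match="substitutions apart"):
            demultiplex([], [s, other])


class TestQualityTrim:
    CFG = PipelineConfig()

    def _mk(self, bases, quals=None):
        return Read("r", bases, quals=quals)

    def test_flat_high_quality_untouched(self, rng):
        r = self._mk(random_dna(rng, 300), [35] * 300)
        (out,) = quality_trim([r], self.CFG)
        assert len(out) == 300

    def test_window_mean_just_below_threshold_truncates(self, rng):
        # windows are 50 bases; the first window reaching into the low-quality
        # tail has mean (49*35 + 34)/50 = 34.98 < 35 and starts at base 201
        quals = [35] * 250 + [34] * 50
        r = self._mk(random_dna(rng, 300), quals)
        (out,) = quality_trim([r], self.CFG)
        assert len(out) == 201

    def test_window_mean_at_threshold_kept(self, rng):
        # one base of 36 among 34s lifts nothing: use 49*35+36 = mean 35.02
        quals = [35] * 250 + [36] + [35] * 49
        r = self._mk(random_dna(rng, 300), quals)
        (out,) = quality_trim([r], self.CFG)
        assert len(out) == 300

    def test_truncation_can_drop_read_below_min_len(self, rng):
        quals = [35] * 150 + [2] * 150  # first bad window starts inside 150
        r = self._mk(random_dna(rng, 300), quals)
        assert quality_trim([r], self.CFG) == []

    def test_ambiguous_base_discards(self, rng):
        seq = random_dna(rng, 150) + "N" + random_dna(rng, 149)
        assert quality_trim([self._mk(seq, [40] * 300)], self.CFG) == []

    def test_ambiguous_base_beyond_truncation_is_harmless(self, rng):
        seq = random_dna(rng, 250) + "N" + random_dna(rng, 49)
        quals = [35] * 250 + [30] * 50  # truncated at 201, before the N
        (out,) = quality_trim([self._mk(seq, quals)], self.CFG)
        assert len(out) == 201 and "N" not in out.bases

    def test_homopolymer_boundary(self, rng):
        flank = "ACGT" * 62  # 248 bases, no long runs
        ok = flank + "G" * 8
        bad = flank + "G" * 9
        out = quality_trim([self._mk(ok, [40] * len(ok)),
                            self._mk(bad, [40] * len(bad))], self.CFG)
        assert [r.bases for r in out] == [ok]

    def test_length_boundaries(self, rng):
        reads = [self._mk(random_dna(rng, n), [40] * n)
                 for n in (199, 200, 600, 601)]
        out = quality_trim(reads, self.CFG)
        assert sorted(len(r) for r in out) == [200, 600]

    def test_idempotent(self, rng):
        reads = []
        for i in range(30):
            n = int(rng.integers(150, 700))
            quals = list(rng.integers(20, 41, n))
            reads.append(Read(f"r{i}", random_dna(rng, n), quals=quals))
        once = quality_trim(reads, self.CFG)
        twice = quality_trim(once, self.CFG)
        assert [(r.id, r.bases, r.quals) for r in twice] == \
            [(r.id, r.bases, r.quals) for r in once]

    def test_missing_quals_warns_once(self, rng):
        reads = [self._mk(random_dna(rng, 300)) for _ in range(3)]
        with pytest.warns(UserWarning, match="no quality") as rec:
            out = quality_trim(reads, self.CFG)
        assert len(out) == 3
        assert sum("no quality" in str(w.message) for w in rec) == 1


class TestDereplicate:
    def test_counts_order_and_provenance(self):
        reads = ([Read(f"a{i}", "AAACCC", sample_id="s1") for i in range(3)]
                 + [Read("b1", "GGGTTT", sample_id="s1"),
                    Read("b2", "GGGTTT", sample_id="s2"),
                    Read("c1", "CCCAAA", sample_id="s2")])
        uniques = dereplicate(reads)
        assert [(u.sequence, u.abundance) for u in uniques] == [
            ("AAACCC", 3), ("GGGTTT", 2), ("CCCAAA", 1)]
        assert uniques[0].sample_counts == {"s1": 3}
        assert uniques[1].sample_counts == {"s1": 1, "s2": 1}
        assert uniques[0].member_ids == ["a0", "a1", "a2"]

    def test_abundance_ties_break_lexicographically(self):
        reads = [Read("x", "TTTT"), Read("y", "AAAA")]
        uniques = dereplicate(reads)
        assert [u.sequence for u in uniques] == ["AAAA", "TTTT"]


def _edit_oracle(a, b, free_b_start=False):
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        D[i][0] = i
    if not free_b_start:
        for j in range(1, m + 1):
            D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = min(D[i - 1][j] + 1, D[i][j - 1] + 1,
                          D[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
    return D


class TestEditMatrix:
    @pytest.mark.parametrize("free", [False, True])
    def test_matches_scalar_oracle(self, rng, free):
        for _ in range(40):
            a = random_dna(rng, int(rng.integers(0, 25)))
            b = random_dna(rng, int(rng.integers(0, 25)))
            got = _edit_matrix(a, b, free_b_start=free)
            assert got.tolist() == _edit_oracle(a, b, free_b_start=free)


class TestChimeras:
    def _uniques(self, rng, n_parent=20, n_query=2, cross=0.5, mutate_q=0):
        a = random_dna(rng, 320)
        b = random_dna(rng, 340)
        k_a, k_b = int(len(a) * cross), int(len(b) * cross)
        q = a[:k_a] + b[k_b:]
        if mutate_q:
            pos = rng.choice(len(q), size=mutate_q, replace=False)
            q = "".join(("G" if c != "G" else "T") if i in set(pos) else c
                        for i, c in enumerate(q))
        return (UniqueSeq(a, n_parent), UniqueSeq(b, n_parent),
                UniqueSeq(q, n_query))

    def test_constructed_chimera_flagged(self, rng):
        pa, pb, q = self._uniques(rng)
        clean, flagged = flag_chimeras([pa, pb, q])
        assert [u.sequence for u in flagged] == [q.sequence]
        assert {u.sequence for u in clean} == {pa.sequence, pb.sequence}

    def test_chimera_with_sequencing_errors_still_flagged(self, rng):
        pa, pb, q = self._uniques(rng, mutate_q=3)
        _, flagged = flag_chimeras([pa, pb, q])
        assert [u.sequence for u in flagged] == [q.sequence]

    def test_truncated_parent_copy_not_flagged(self, rng):
        a = random_dna(rng, 320)
        b = random_dna(rng, 340)
        trunc = UniqueSeq(a[:220], 2)
        clean, flagged = flag_chimeras(
            [UniqueSeq(a, 20), UniqueSeq(b, 20), trunc])
        assert flagged == []

    def test_unrelated_sequence_not_flagged(self, rng):
        parents = [UniqueSeq(random_dna(rng, 320), 20) for _ in range(2)]
        stranger = UniqueSeq(random_dna(rng, 300), 2)
        _, flagged = flag_chimeras(parents + [stranger])
        assert flagged == []

    def test_abundance_fold_gate(self, rng):
        pa, pb, q = self._uniques(rng, n_parent=20, n_query=15)
        # parents are not >= 2x the query's abundance: no candidates
        _, flagged = flag_chimeras([pa, pb, q], min_parent_fold=2.0)
        assert flagged == []

    def test_conservation(self, rng):
        uniques = [UniqueSeq(random_dna(rng, 250), int(rng.integers(1, 30)))
                   for _ in range(8)]
        clean, flagged = flag_chimeras(uniques)
        assert len(clean) + len(flagged) == len(uniques)
        assert ({u.sequence for u in clean} | {u.sequence for u in flagged}
                == {u.sequence for u in uniques})
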