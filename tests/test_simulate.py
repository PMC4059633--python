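"""The synthetic-data generator: reference operons, reads and Ct series."""

import numpy as np
import pandas as pd
import pytest

from itseval.core import reverse_complement
from itseval.insilico import best_hit, virtual_pcr
from itseval.primers import ITS1F, ITS2, ITS3, ITS4, ITS86F, PRIMER_PAIRS
from itseval.simulate import (ADAPTOR_A, ADAPTOR_B, CommunityConfig,
                              CtSimConfig, ReadSimConfig, make_fusion_samples,
                              make_mids, make_reference_set, simulate_ct,
                              simulate_reads)


class TestReferenceSet:
    def test_operon_carries_all_primer_sites(self):
        refs = make_reference_set(CommunityConfig(n_taxa=3, seed=0))
        for taxon in refs.taxa:
            seq = refs.sequences[taxon]
            sites = refs.sites[taxon]
            assert seq[slice(*sites["ITS1F"])] == ITS1F.sequence
            assert seq[slice(*sites["ITS86F"])] == ITS86F.sequence
            assert seq[slice(*sites["ITS4"])] == \
                reverse_complement(ITS4.sequence)
            # ITS2 and ITS3 share one 5.8S locus (exact reverse complements)
            assert sites["ITS2"] == sites["ITS3"]
            assert seq[slice(*sites["ITS3"])] == ITS3.sequence
            assert seq[slice(*sites["ITS2"])] == \
                reverse_complement(ITS2.sequence)

    def test_best_hits_score_zero_on_clean_operons(self):
        refs = make_reference_set(CommunityConfig(n_taxa=3, seed=1))
        for taxon in refs.taxa:
            seq = refs.sequences[taxon]
            for p in (ITS1F, ITS2, ITS3, ITS4, ITS86F):
                assert best_hit(p, seq).score == 0.0

    def test_planted_mismatch_recovered_by_scorer(self):
        # one non-3' substitution in the ITS86F site of taxon 0
        pos = 3
        base = "G" if ITS86F.sequence[3] != "G" else "T"
        cfg = CommunityConfig(
            n_taxa=2, seed=2,
            primer_site_mismatches={0: {"ITS86F": [(pos, base)]}})
        refs = make_reference_set(cfg)
        h0 = best_hit(ITS86F, refs.sequences[refs.taxa[0]])
        h1 = best_hit(ITS86F, refs.sequences[refs.taxa[1]])
        assert h0.score == pytest.approx(0.4)
        assert h1.score == 0.0
        assert refs.truth.loc[0, "expected_score_ITS86F"] == pytest.approx(0.4)
        assert refs.truth.loc[1, "expected_score_ITS86F"] == 0.0

    def test_planted_terminal_mismatch_truth_is_400(self):
        p = len(ITS4.sequence) - 1
        base = "G" if ITS4.sequence[p] != "G" else "T"
        cfg = CommunityConfig(n_taxa=1, seed=3,
                              primer_site_mismatches={0: {"ITS4": [(p, base)]}})
        refs = make_reference_set(cfg)
        assert refs.truth.loc[0, "expected_score_ITS4"] == pytest.approx(4.0)

    def test_virtual_pcr_matches_declared_insert(self):
        refs = make_reference_set(CommunityConfig(n_taxa=2, seed=4))
        for pair_name, (fwd, rev) in PRIMER_PAIRS.items():
            for taxon in refs.taxa:
                amps = virtual_pcr(fwd, rev, refs.sequences[taxon])
                assert len(amps) == 1, (pair_name, taxon)
                assert amps[0].sequence == refs.insert(taxon, fwd, rev)

    def test_abundance_models(self):
        logser = make_reference_set(CommunityConfig(n_taxa=10, seed=5))
        assert logser.abundances.sum() == pytest.approx(1.0)
        assert (np.diff(logser.abundances) < 0).all()
        uni = CommunityConfig(n_taxa=4, abundance_model="uniform").abundances()
        assert np.allclose(uni, 0.25)
        with pytest.raises(ValueError):
            CommunityConfig(n_taxa=3, abundance_model=[0.5, 0.5]).abundances()

    def test_deterministic_given_seed(self):
        a = make_reference_set(CommunityConfig(n_taxa=4, seed=9))
        b = make_reference_set(CommunityConfig(n_taxa=4, seed=9))
        assert a.sequences == b.sequences

    def test_invalid_mismatch_specs_rejected(self):
        with pytest.raises(ValueError, match="outside primer"):
            make_reference_set(CommunityConfig(
                n_taxa=1, primer_site_mismatches={0: {"ITS4": [(99, "A")]}}))
        same = ITS4.sequence[0]
        with pytest.raises(ValueError, match="equals the primer base"):
            make_reference_set(CommunityConfig(
                n_taxa=1, primer_site_mismatches={0: {"ITS4": [(0, same)]}}))


class TestMids:
    def test_separation_and_length(self):
        mids = make_mids(12, seed=0)
        assert len(mids) == 12
        assert all(len(m) == 10 for m in mids)
        for i, a in enumerate(mids):
            for b in mids[i + 1:]:
                assert sum(x != y for x, y in zip(a, b)) >= 3

    def test_fusion_samples_layout(self):
        fwd, rev = PRIMER_PAIRS["ITS86F/ITS4"]
        samples = make_fusion_samples(3, fwd, rev, seed=1)
        assert [s[0] for s in samples] == ["S01", "S02", "S03"]
        for _, f, r in samples:
            assert f.adaptor == ADAPTOR_A and r.adaptor == ADAPTOR_B
            assert f.mid == r.mid
            assert f.primer is fwd and r.primer is rev


class TestSimulateReads:
    def test_clean_reads_have_exact_layout(self, clean_run):
        refs, samples, reads, truth = clean_run
        by_sid = {s[0]: s for s in samples}
        by_id = truth.set_index("read_id")
        for read in reads[:100]:
            row = by_id.loc[read.id]
            _, fwd_fp, rev_fp = by_sid[row["sample"]]
            insert = refs.insert(row["taxon"], fwd_fp.primer, rev_fp.primer)
            expected = (fwd_fp.full_sequence + insert
                        + reverse_complement(rev_fp.full_sequence))
            assert read.bases == expected
            assert len(read.quals) == len(read.bases)

    def test_truth_row_per_read(self, clean_run):
        _, _, reads, truth = clean_run
        assert len(truth) == len(reads)
        assert set(truth["read_id"]) == {r.id for r in reads}
        assert not truth["is_chimera"].any()
        assert not truth["is_dimer"].any()

    def test_abundances_roughly_respected(self, clean_run):
        refs, _, _, truth = clean_run
        freqs = truth["taxon"].value_counts(normalize=True)
        for taxon, expected in zip(refs.taxa, refs.abundances):
            assert freqs.get(taxon, 0.0) == pytest.approx(expected, abs=0.08)

    def test_dimers_lack_reverse_decorations(self):
        refs = make_reference_set(CommunityConfig(n_taxa=3, seed=6))
        fwd, rev = PRIMER_PAIRS["ITS86F/ITS4"]
        samples = make_fusion_samples(2, fwd, rev, seed=7)
        cfg = ReadSimConfig(reads_per_sample=50, n_samples=2, dimer_rate=1.0,
                            chimera_rate=0.0, seed=8)
        reads, truth = simulate_reads(refs, samples, cfg)
        assert truth["is_dimer"].all()
        lengths = np.array([len(r) for r in reads])
        assert abs(lengths.mean() - 116) < 15
        tail = reverse_complement(ADAPTOR_B)[-10:]
        assert not any(r.bases.endswith(tail) for r in reads)

    def test_chimeras_are_two_parent_crossovers(self):
        refs = make_reference_set(CommunityConfig(n_taxa=4, seed=10))
        fwd, rev = PRIMER_PAIRS["ITS86F/ITS4"]
        samples = make_fusion_samples(1, fwd, rev, seed=11)
        cfg = ReadSimConfig(reads_per_sample=30, n_samples=1, dimer_rate=0.0,
                            chimera_rate=1.0, sub_rate=0.0,
                            homopolymer_err_rate=0.0, ambig_rate=0.0, seed=12)
        reads, truth = simulate_reads(refs, samples, cfg)
        assert truth["is_chimera"].all()
        _, fwd_fp, rev_fp = samples[0]
        inserts = {t: refs.insert(t, fwd, rev) for t in refs.taxa}
        for read, (_, row) in zip(reads, truth.iterrows()):
            ta, tb = row["taxon"].split("|")
            core = read.bases[len(fwd_fp.full_sequence):
                              len(read.bases) - len(rev_fp.full_sequence)]
            # starts as one parent, ends as the other
            assert core[:40] == inserts[ta][:40]
            assert core[-40:] == inserts[tb][-40:]
            assert core != inserts[ta] and core != inserts[tb]

    def test_substitution_rate_calibrated(self):
        refs = make_reference_set(CommunityConfig(n_taxa=2, seed=13))
        fwd, rev = PRIMER_PAIRS["ITS86F/ITS4"]
        samples = make_fusion_samples(1, fwd, rev, seed=14)
        cfg = ReadSimConfig(reads_per_sample=200, n_samples=1, sub_rate=0.01,
                            homopolymer_err_rate=0.0, ambig_rate=0.0,
                            chimera_rate=0.0, dimer_rate=0.0, seed=15)
        reads, truth = simulate_reads(refs, samples, cfg)
        _, fwd_fp, rev_fp = samples[0]
        diffs = total = 0
        for read, (_, row) in zip(reads, truth.iterrows()):
            insert = refs.insert(row["taxon"], fwd, rev)
            core = read.bases[len(fwd_fp.full_sequence):
                              len(read.bases) - len(rev_fp.full_sequence)]
            assert len(core) == len(insert)  # no indels in this config
            diffs += sum(a != b for a, b in zip(core, insert))
            total += len(insert)
        assert diffs / total == pytest.approx(0.01, rel=0.35)

    def test_quality_model(self):
        refs = make_reference_set(CommunityConfig(n_taxa=2, seed=16))
        fwd, rev = PRIMER_PAIRS["ITS86F/ITS4"]
        samples = make_fusion_samples(1, fwd, rev, seed=17)
        cfg = ReadSimConfig(reads_per_sample=20, n_samples=1, dimer_rate=0.0,
                            chimera_rate=0.0, qual_start=38.0, qual_slope=0.01,
                            qual_jitter=0.0, seed=18)
        reads, _ = simulate_reads(refs, samples, cfg)
        for r in reads[:5]:
            q = np.array(r.quals)
            assert q[0] == 38
            assert q[-1] <= q[0]
            assert (q >= 2).all() and (q <= 40).all()

    def test_sample_count_mismatch_rejected(self):
        refs = make_reference_set(CommunityConfig(n_taxa=2, seed=19))
        fwd, rev = PRIMER_PAIRS["ITS86F/ITS4"]
        samples = make_fusion_samples(2, fwd, rev, seed=20)
        with pytest.raises(ValueError):
            simulate_reads(refs, samples,
                           ReadSimConfig(n_samples=3, reads_per_sample=5))


class TestSimulateCt:
    def test_noiseless_series_follows_model(self):
        cfg = CtSimConfig(true_efficiency=100.0, ct0=20.0, noise_sd=0.0)
        series = simulate_ct(cfg)
        cts = [ct for _, ct in series.points]
        # 2-fold dilutions at 100% efficiency: Ct rises by exactly 1
        assert cts == pytest.approx([20, 21, 22, 23, 24, 25, 26])

    def test_seeded_noise_reproducible(self):
        a = simulate_ct(CtSimConfig(noise_sd=0.2, seed=5))
        b = simulate_ct(CtSimConfig(noise_sd=0.2, seed=5))
        assert a.points == b.points

    def test_validation(self):
        with pytest.raises(ValueError):
            CtSimConfig(true_efficiency=0.0)
        with pytest.raises(ValueError):
            CtSimConfig(noise_sd=-1.0)
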