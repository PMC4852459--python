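"""Codon alignment construction and pairwise dN/dS estimators."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nlrevo._codons import SENSE_CODONS, SN_SITES
from nlrevo.codondiv import (
    CodonAlignment,
    TranslationMismatch,
    backtranslate,
    domain_slice,
    group_median_matrix,
    myn_pair,
    ng86_pair,
    pairwise_divergences,
)

codon_strings = st.lists(
    st.sampled_from(SENSE_CODONS), min_size=1, max_size=25
).map("".join)


class TestNG86:
    def test_identical_rows(self):
        r = ng86_pair("ATGAAATTT", "ATGAAATTT")
        assert r.dN == 0 and r.dS == 0 and r.Sd == 0 and r.Nd == 0
        assert r.valid

    def test_synonymous_third_position(self):
        # TTT->TTC is synonymous; hand-counted sites: S = 5/3, N = 22/3
        r = ng86_pair("TTTAAAGGG", "TTCAAAGGG")
        assert r.S_sites == pytest.approx(5 / 3)
        assert r.N_sites == pytest.approx(22 / 3)
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.dS == pytest.approx(-0.75 * math.log(0.2), abs=1e-4)
        assert r.dN == 0

    def test_nonsynonymous_change_with_invalid_ratio(self):
        # AAA->AGA (K->R): dS = 0, so omega is an invalid ratio (NaN)
        r = ng86_pair("ATGAAA", "ATGAGA")
        assert r.S_sites == pytest.approx(0.5)
        assert r.N_sites == pytest.approx(5.5)
        assert (r.Sd, r.Nd) == (0.0, 1.0)
        assert r.dN == pytest.approx(0.2082, abs=1e-4)
        assert r.dS == 0
        assert math.isnan(r.omega)

    def test_site_conservation_all_sense_codons(self):
        # stop-neighbour convention keeps S + N = 3 for every codon
        for codon in SENSE_CODONS:
            s, n = SN_SITES[codon]
            assert s + n == pytest.approx(3.0)

    @given(a=codon_strings, b=codon_strings)
    def test_symmetry(self, a, b):
        n = min(len(a), len(b)) // 3 * 3
        a, b = a[:n], b[:n]
        if not n:
            return
        ra, rb = ng86_pair(a, b), ng86_pair(b, a)
        assert ra == rb

    def test_sites_sum_to_three_per_codon(self):
        r = ng86_pair("ATGAAATTTCCC", "ATGAGATTCCCA")
        assert r.S_sites + r.N_sites == pytest.approx(3 * r.n_codons)

    def test_gap_codons_excluded(self):
        full = ng86_pair("TTTAAAGGG", "TTCAAAGGG")
        gapped = ng86_pair("TTT---GGG", "TTCAAAGGG")
        assert gapped.n_codons == 2
        assert gapped.Sd == full.Sd  # the TTT/TTC difference is still seen

    def test_frame_and_empty_errors(self):
        with pytest.raises(ValueError):
            ng86_pair("ATGA", "ATGA")
        with pytest.raises(ValueError):
            ng86_pair("---", "ATG")

    def test_matches_biopython_on_low_divergence_pairs(self):
        # independent oracle: Bio.codonalign NG86 (same published estimator)
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        rng = np.random.default_rng(3)
        for _ in range(5):
            codons = [SENSE_CODONS[i] for i in rng.integers(0, 61, size=60)]
            other = list(codons)
            for pos in rng.choice(60, size=10, replace=False):
                # single-position change, keeping the codon sense
                for _ in range(50):
                    c = list(other[pos])
                    c[rng.integers(3)] = "ACGT"[rng.integers(4)]
                    cand = "".join(c)
                    if cand in SN_SITES and cand != codons[pos]:
                        other[pos] = cand
                        break
            a, b = "".join(codons), "".join(other)
            dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            mine = ng86_pair(a, b)
            assert mine.dN == pytest.approx(dn, abs=1e-9)
            assert mine.dS == pytest.approx(ds, abs=1e-9)


# fixture pair for the YN00 oracle: 150 codons, 25 codons differing at one
# position each; expected values frozen from an independent reference
# implementation (Bio.codonalign YN00), which is also re-run at test time.
_YN_A = (
    "GGAACTAACGTTCACATTATGAGAGTTACGGGTGTTTTAGAGACCGCCCGTAAGAACACCATCATGGAAGCG"
    "AACGATATAGTCGGCGTAGAGCGGATGCTAGCCCACTCCTGGAAATACTCCAGGGTACGTCCCCACAGCATC"
    "TACCCCACGACCCGAACGCCGTGCCCGGCGCAATCCAAGGTGCTCGAGACTTTGCGAACCGATCAGTCTGGA"
    "GCTTGTTGGCCTGCAATAGTCACAAAGGGGATGTATCAGACCTGCATGTGGACGCGACACCTCGGATCTCCT"
    "AGGCCTCCGATCGGGCACGTATTGGGTGGCACAGCGGGAAGGGAGGTGATTAGGCTCCGACACTTGGGAGTA"
    "GATATGGGTCCATCTTATTATAATATGTCGAAGTCCCCACGCCACACAATCTTCTTTGCATGTGTCCCAATC"
    "GGCCTTCGCTGTTTCGGC"
)
_YN_B = (
    "GGAACTAACGTTCACATTATGAGAGTTACGGGTGTTCTAGAGACCGCCCTTAAGAACACCATCATGGAACCG"
    "AACGATATAGTCTGCGTAGAGCGGATGCTAGCCCAGTCATGGAAATTCCCCAGGGTACGTCCCCACAGCATC"
    "AACCCCACGACCCGAACGCCGTGCACGGCGCAATCCAAGGTGCTCGCGACTTTGCGAACAGATCAGTCTGGA"
    "GCTTGTTGGCCTACAATAGTCACAAAGGGGATGTATCAGACCTGCATGTGGACGCGACACGTCGGATCTCCT"
    "AGGCCTACGATCGGGCACGTGTTGGGTGGCACAGCGGGGAGAGAGGTGATTAGGCTCCGACACTGGGGAGTA"
    "GATATGGGTCCATCTTATTCTAATATGTCGGAGTCCCCACGCCACACAATCTTGTTTGCATGTGTCCCAAAC"
    "GGCCTTCGGTGCTTCGGC"
)
_YN_EXPECTED = {"dN": 0.0518910833, "dS": 0.0765268867}


class TestMYN:
    def test_identical_rows(self):
        r = myn_pair("ATGAAATTTCCCGGG", "ATGAAATTTCCCGGG")
        assert r.dN == 0 and r.dS == 0 and r.valid

    def test_frozen_reference_fixture(self):
        r = myn_pair(_YN_A, _YN_B)
        assert r.valid
        assert r.dN == pytest.approx(_YN_EXPECTED["dN"], abs=1e-3)
        assert r.dS == pytest.approx(_YN_EXPECTED["dS"], abs=1e-3)

    def test_against_live_reference(self):
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        dn, ds = cal_dn_ds(CodonSeq(_YN_A), CodonSeq(_YN_B), method="YN00")
        r = myn_pair(_YN_A, _YN_B)
        assert r.dN == pytest.approx(dn, abs=1e-3)
        assert r.dS == pytest.approx(ds, abs=1e-3)

    def test_consistent_with_ng86_at_low_divergence(self, small_dataset):
        ids = small_dataset.gene_ids
        a = small_dataset.sequences[ids[0]]
        b = small_dataset.sequences[ids[1]]
        ng, yn = ng86_pair(a, b), myn_pair(a, b)
        assert yn.valid
        if ng.dS > 0.02:
            assert yn.dS == pytest.approx(ng.dS, rel=0.15)


class TestBacktranslate:
    def test_gap_becomes_gap_codon(self):
        aln = backtranslate([("x", "M-A")], {"x": "ATGGCT"})
        assert aln.rows == ["ATG---GCT"]

    def test_trailing_stop_dropped(self):
        aln = backtranslate([("x", "MA")], {"x": "ATGGCTTAA"})
        assert aln.rows == ["ATGGCT"]

    def test_mismatch_reports_id_and_residue(self):
        with pytest.raises(TranslationMismatch, match=r"x: residue 2"):
            backtranslate([("x", "MV")], {"x": "ATGGCT"})

    def test_missing_cds(self):
        with pytest.raises(KeyError):
            backtranslate([("x", "MA")], {})


class TestDomainSlice:
    @pytest.fixture()
    def aln(self):
        rows = ["ATGAAATTTCCCGGGTTACATGAATGGCAT"] * 2  # 10 codons
        return CodonAlignment(
            ids=["a", "b"], rows=rows,
            partitions={"nacht": (1, 6), "b30.2": (7, 10)},
        )

    def test_slice_lengths(self, aln):
        assert all(len(r) == 18 for r in domain_slice(aln, "nacht").rows)

    def test_slices_concatenate_to_original(self, aln):
        parts = [domain_slice(aln, d).rows for d in ("nacht", "b30.2")]
        rebuilt = ["".join(p) for p in zip(*parts)]
        assert rebuilt == aln.rows

    def test_unknown_domain(self, aln):
        with pytest.raises(KeyError):
            domain_slice(aln, "lrr")

    def test_empty_interval(self, aln):
        aln.partitions["empty"] = (5, 4)
        with pytest.raises(ValueError):
            domain_slice(aln, "empty")


class TestGroupMedians:
    def test_identical_sequences_zero_medians(self):
        aln = CodonAlignment(ids=list("abcd"), rows=["ATGAAATTT"] * 4)
        gm = group_median_matrix(aln, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"})
        assert (gm.median_dS.values == 0).all()
        assert (gm.median_dN.values == 0).all()
        assert gm.n_pairs.loc["g1", "g1"] == 1  # |g|(|g|-1)/2

    def test_matches_brute_force_over_pairs(self):
        rows = ["ATGAAATTTCCC", "ATGAGATTTCCC", "ATGAAATTCCCA", "TTGAAATTTCCG"]
        ids = list("abcd")
        groups = {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}
        gm = group_median_matrix(CodonAlignment(ids=ids, rows=rows), groups)
        # brute force the six pairs with the pairwise estimator directly
        by_cell = {}
        for i in range(4):
            for j in range(i + 1, 4):
                cell = tuple(sorted((groups[ids[i]], groups[ids[j]])))
                by_cell.setdefault(cell, []).append(ng86_pair(rows[i], rows[j]))
        for (ga, gb), vals in by_cell.items():
            ok = [v for v in vals if v.valid]  # medians are over valid pairs
            assert gm.n_dropped.loc[ga, gb] == len(vals) - len(ok)
            if not ok:
                assert math.isnan(gm.median_dS.loc[ga, gb])
                continue
            assert gm.median_dS.loc[ga, gb] == pytest.approx(
                float(np.median([v.dS for v in ok]))
            )
            assert gm.median_dN.loc[ga, gb] == pytest.approx(
                float(np.median([v.dN for v in ok]))
            )

    def test_singleton_group_flagged_not_raised(self):
        aln = CodonAlignment(ids=list("abc"), rows=["ATGAAATTT"] * 3)
        gm = group_median_matrix(aln, {"a": "g1", "b": "g1", "c": "g2"})
        assert math.isnan(gm.median_dS.loc["g2", "g2"])
        assert gm.n_pairs.loc["g2", "g2"] == 0

    def test_pairwise_table_covers_all_pairs(self, small_dataset):
        ids = small_dataset.gene_ids
        aln = CodonAlignment(
            ids=ids, rows=[small_dataset.sequences[g] for g in ids]
        )
        t = pairwise_divergences(aln, small_dataset.group_map)
        n = len(ids)
        assert len(t) == n * (n - 1) // 2
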