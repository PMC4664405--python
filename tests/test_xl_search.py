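"""Candidate enumeration, spectrum scoring, and target-decoy search."""

import itertools

import numpy as np
import pytest

from xlmap.digestion import DecoyMode, DigestParams, build_database, digest
from xlmap.peptide_chem import (
    BS3_XLINK_DELTA,
    MASS,
    CrossLinkedPair,
    Peptide,
    Provenance,
    fragment_ions,
    pair_mass,
    peptide_mass,
    precursor_mz,
)
from xlmap.synthetic_data import SpectrumSimConfig, make_xl_spectra
from xlmap.xl_search import (
    PSM,
    MatchScores,
    SearchParams,
    SpectrumRecord,
    assumed_charges,
    candidate_pairs,
    decoy_fdr,
    eligible_link_sites,
    match_spectrum,
    read_mgf,
    run_search,
    write_mgf,
)


def toy_peptides():
    # all internal peptides (start > 1): only lysines are link sites
    seqs = [
        ("p1", "AAKGGR", 10, 15),
        ("p2", "TETTGEKGK", 10, 18),
        ("p3", "LLKVVR", 10, 15),
        ("p4", "GGGGGGR", 10, 16),  # no link site
    ]
    return [Peptide(s, provenance=Provenance(pid, a, b)) for pid, s, a, b in seqs]


class TestLinkSites:
    def test_internal_lysine_eligible_terminal_not(self):
        p = Peptide("TETTGEKGK", provenance=Provenance("b", 553, 561))
        assert eligible_link_sites(p, protein_length=600) == [7]

    def test_cterminal_lysine_eligible_at_protein_cterm(self):
        p = Peptide("TETTGEKGK", provenance=Provenance("b", 553, 561))
        assert eligible_link_sites(p, protein_length=561) == [7, 9]

    def test_protein_nterm_alpha_amine_eligible(self):
        p = Peptide("MAATTR", provenance=Provenance("a", 1, 6))
        assert eligible_link_sites(p, protein_length=100) == [1]


class TestCandidatePairs:
    def test_planted_mass_matches_exactly_one_pair(self):
        peps = toy_peptides()
        target = CrossLinkedPair(peps[0], peps[2], 3, 3)
        cands = candidate_pairs(peps, pair_mass(target), tol_ppm=10)
        assert len(cands) == 1
        assert cands[0].id_string() == target.id_string()

    def test_vanishing_tolerance_excludes_perturbed_mass(self):
        peps = toy_peptides()
        target = CrossLinkedPair(peps[0], peps[2], 3, 3)
        assert candidate_pairs(peps, pair_mass(target) + 0.5, tol_ppm=0.001) == []

    def test_count_matches_brute_force_on_random_databases(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWYK"))  # K enriched
        for trial in range(5):
            peps = []
            for i in range(rng.integers(5, 30)):
                seq = "".join(rng.choice(letters, size=rng.integers(4, 12)))
                peps.append(Peptide(seq, provenance=Provenance(f"p{i}", 10, 9 + len(seq))))
            masses = [peptide_mass(p) for p in peps]
            precursor = masses[0] + masses[-1] + BS3_XLINK_DELTA
            tol = precursor * 50e-6
            expected = 0
            for i, j in itertools.combinations_with_replacement(range(len(peps)), 2):
                if abs(masses[i] + masses[j] + BS3_XLINK_DELTA - precursor) <= tol:
                    si = eligible_link_sites(peps[i])
                    sj = eligible_link_sites(peps[j])
                    expected += len(si) * len(sj)
            got = candidate_pairs(peps, precursor, tol_ppm=50)
            assert len(got) == expected


class TestAssumedCharges:
    params = SearchParams()

    def make(self, declared):
        return SpectrumRecord("s", 500.0, declared, np.array([100.0]), np.array([1.0]))

    def test_declared_singly_charged(self):
        assert assumed_charges(self.make(1), self.params) == [1]

    def test_unknown_charge_searched_as_2_and_3(self):
        assert assumed_charges(self.make(None), self.params) == [2, 3]

    def test_declared_charge_wins(self):
        assert assumed_charges(self.make(4), self.params) == [4]


class TestMatchSpectrum:
    def test_perfect_spectrum_matches_every_ion(self, fig_pair):
        z = 3
        ions = fragment_ions(fig_pair, max_fragment_charge=2)
        mz = np.array([f.mz for f in ions])
        s = SpectrumRecord(
            "perfect", precursor_mz(pair_mass(fig_pair), z), z, mz, np.ones(mz.size)
        )
        sc = match_spectrum(s, fig_pair, z, SearchParams(seed=1))
        assert sc.score == len(ions)
        # binomial tail at full score is its maximum for this N
        worse = match_spectrum(
            SpectrumRecord("half", s.precursor_mz, z, mz[::2], np.ones(mz[::2].size)),
            fig_pair, z, SearchParams(seed=1),
        )
        assert sc.pp >= worse.pp

    def test_empty_peak_list_scores_zero(self, fig_pair):
        s = SpectrumRecord("empty", 891.68, 4, np.array([]), np.array([]))
        assert match_spectrum(s, fig_pair, 4, SearchParams(seed=1)) == MatchScores(0, 0.0, 0.0)

    def test_null_pvalues_not_anticonservative(self, fig_pair, rng):
        """On uniform-random peak lists the binomial-tail p-value should be
        stochastically no smaller than uniform: P(p <= 0.05) <= ~5%."""
        params = SearchParams(seed=2, n_permutations=10)
        z = 3
        hits = 0
        n_sim = 500
        for _ in range(n_sim):
            mz = np.sort(rng.uniform(300, 1650, size=60))
            s = SpectrumRecord("null", precursor_mz(pair_mass(fig_pair), z), z,
                               mz, rng.uniform(1, 100, size=60))
            sc = match_spectrum(s, fig_pair, z, params)
            if 10.0 ** (-sc.pp) <= 0.05:
                hits += 1
        # binomial(500, 0.05) upper band: mean 25, 3 sigma ~ 14.6
        assert hits <= 40


class TestRunSearch:
    def _planted_inputs(self, n_pairs=10, coverage=1.0, seed=5):
        from xlmap.peptide_chem import with_cam

        rng = np.random.default_rng(seed)
        # no P (would suppress the flanking tryptic cleavage when leading)
        letters = "ACDEFGHILMNQSTVWY"
        proteins = []
        pairs = []
        for i in range(n_pairs):
            core_a = "".join(rng.choice(list(letters), size=8))
            core_b = "".join(rng.choice(list(letters), size=6))
            seq_a = core_a[:4] + "K" + core_a[4:] + "R"
            seq_b = core_b[:3] + "K" + core_b[3:] + "R"
            prot_a = ("A%02d" % i, seq_a + "GGGGGG")
            prot_b = ("B%02d" % i, "MK" + seq_b + "GGGGGG")
            proteins += [prot_a, prot_b]
            pa = with_cam(seq_a, Provenance(prot_a[0], 1, len(seq_a)))
            pb = with_cam(seq_b, Provenance(prot_b[0], 3, 2 + len(seq_b)))
            pairs.append(CrossLinkedPair(pa, pb, 5, 4))
        spectra, truth = make_xl_spectra(
            SpectrumSimConfig(coverage=coverage, n_noise_peaks=20), pairs, seed=seed
        )
        db = build_database(proteins, DecoyMode("reversed"))
        params = SearchParams(seed=seed, n_permutations=50)
        return pairs, spectra, truth, db, params

    def test_planted_pairs_all_recovered(self):
        pairs, spectra, truth, db, params = self._planted_inputs()
        psms, report = run_search(spectra, db, params)
        assert len(psms) == len(pairs)
        by_spectrum = {p.spectrum_id: p for p in psms}
        for row, pair in zip(truth.itertuples(index=False), pairs):
            psm = by_spectrum[row.spectrum_id]
            assert psm.pair.id_string() == pair.id_string()
            assert not psm.is_decoy

    def test_zero_coverage_yields_no_psms_but_is_counted(self):
        _, spectra, _, db, params = self._planted_inputs(n_pairs=3, coverage=0.0)
        psms, report = run_search(spectra, db, params)
        assert psms == []
        assert report["n_below_threshold_or_unmatched"] == 3

    def test_result_independent_of_spectrum_order(self):
        _, spectra, _, db, params = self._planted_inputs(n_pairs=4)
        psms_fwd, _ = run_search(spectra, db, params)
        psms_rev, _ = run_search(list(reversed(spectra)), db, params)
        key = lambda ps: sorted((p.spectrum_id, p.pair.id_string(), p.scores.score) for p in ps)
        assert key(psms_fwd) == key(psms_rev)

    def test_fig_pair_outranks_reversed_decoys(self, fig_pair):
        spectra, _ = make_xl_spectra(SpectrumSimConfig(n_noise_peaks=10), [fig_pair], seed=9)
        targets = [
            ("SGC_ALPHA", "MGGKR" + "YCLFGNNVTLANKFESCSVPR" + "AAAAAAR"),
            ("SGC_BETA", "MAAAK" + "TETTGEKGK" + "GGGGGGR"),
        ]
        db = build_database(targets, DecoyMode("reversed"))
        psms, _ = run_search(spectra, db, SearchParams(seed=9, n_permutations=50))
        assert len(psms) == 1
        assert not psms[0].is_decoy
        assert psms[0].pair.peptide_a.sequence in ("YCLFGNNVTLANKFESCSVPR", "TETTGEKGK")


class TestDecoyFdr:
    def _psm(self, score, decoy, i):
        pep = Peptide("AAKAAR", provenance=Provenance("DECOY_p" if decoy else "p", 1, 6))
        pair = CrossLinkedPair(pep, pep, 3, 3)
        return PSM(f"s{i}", pair, 2, MatchScores(score, float(score), 0.0), decoy)

    def test_monotone_counts_and_fdr(self):
        psms = [self._psm(s, d, i) for i, (s, d) in enumerate(
            [(1, True), (2, False), (3, False), (3, True), (5, False), (8, False)]
        )]
        table = decoy_fdr(psms)
        assert list(table["score_cutoff"]) == sorted(table["score_cutoff"])
        assert all(np.diff(table["n_target"]) <= 0)
        assert all(np.diff(table["n_decoy"]) <= 0)

    def test_no_decoys_flagged_zero_fdr(self):
        psms = [self._psm(s, False, i) for i, s in enumerate([2, 4, 6])]
        table = decoy_fdr(psms)
        assert (table["fdr"] == 0).all()
        assert (table["flag"] == "no_decoy_psms").all()

    def test_all_decoys_flagged_undefined(self):
        psms = [self._psm(s, True, i) for i, s in enumerate([2, 4])]
        table = decoy_fdr(psms)
        assert table["fdr"].isna().all()
        assert (table["flag"] == "no_target_psms").all()

    def test_matched_score_distributions_give_fdr_near_one(self, rng):
        psms = []
        i = 0
        for _ in range(300):
            s = int(rng.integers(1, 20))
            psms.append(self._psm(s, False, i)); i += 1
            s = int(rng.integers(1, 20))
            psms.append(self._psm(s, True, i)); i += 1
        table = decoy_fdr(psms)
        lowest = table.iloc[0]
        assert lowest["fdr"] == pytest.approx(1.0, abs=0.2)


class TestMgfIO:
    def test_round_trip(self, tmp_path):
        s = SpectrumRecord(
            "spec one", 891.68, 4,
            np.array([100.0, 200.5, 300.25]), np.array([10.0, 5.0, 1.0]),
        )
        path = tmp_path / "t.mgf"
        write_mgf(path, [s])
        back = read_mgf(path)
        assert len(back) == 1
        assert back[0].spectrum_id == "spec one"
        assert back[0].declared_charge == 4
        np.testing.assert_allclose(back[0].mz, s.mz)
        np.testing.assert_allclose(back[0].intensity, s.intensity)
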