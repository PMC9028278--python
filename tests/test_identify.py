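"""Target lists, marker screening, candidate scoring and the full pipeline."""

import numpy as np
import pytest

from cyclospot import (
    FragmentConfig,
    IdentifyConfig,
    Run,
    ScoreWeights,
    Spectrum,
    SynthConfig,
    build_target_list,
    enumerate_openings,
    generate,
    generate_fragments,
    identify,
    score_candidate,
    screen_marker,
    subtract,
)
from cyclospot.chem import DIAG_ION_MZ, PCA_RESIDUAL, WATER, mz
from cyclospot.cyclic import CyclicPeptide
from cyclospot.fragments import doublet_for_residue
from cyclospot.spectra import TARGETED


def _msms(mzs, intensities, precursor=None, time=1.0):
    return Spectrum(
        scan_id="s",
        time=time,
        ms_level=2,
        scan_function=TARGETED,
        precursor_mz=precursor,
        isolation_width=1.0,
        mz=np.asarray(mzs, dtype=float),
        intensity=np.asarray(intensities, dtype=float),
    )


class TestTargetList:
    def test_derivatized_minus_hydrolyzed_is_pca_residual(self, jb1):
        tl = build_target_list(jb1, max_charge=3)
        for z in (1, 2, 3):
            hyd = next(e for e in tl.entries if e.species == "hydrolyzed" and e.charge == z)
            der = next(e for e in tl.entries if e.species == "derivatized" and e.charge == z)
            par = next(e for e in tl.entries if e.species == "parent" and e.charge == z)
            assert der.mz - hyd.mz == pytest.approx(PCA_RESIDUAL / z, abs=1e-9)
            assert hyd.mz - par.mz == pytest.approx(WATER / z, abs=1e-9)
        hyd1 = next(e for e in tl.entries if e.species == "hydrolyzed" and e.charge == 1)
        der1 = next(e for e in tl.entries if e.species == "derivatized" and e.charge == 1)
        assert round(der1.mz - hyd1.mz, 4) == 89.0265
        par1 = next(e for e in tl.entries if e.species == "parent" and e.charge == 1)
        assert round(hyd1.mz - par1.mz, 4) == 18.0106

    def test_tsv_export(self, jb1, tmp_path):
        tl = build_target_list(jb1, max_charge=2)
        path = str(tmp_path / "targets.tsv")
        tl.to_tsv(path)
        lines = open(path).read().strip().splitlines()
        assert lines[0] == "mass\tmz\tz\tspecies"
        assert len(lines) == 1 + 6


class TestScreenMarker:
    def test_planted_apexes_recovered_after_subtraction(self, jb1):
        a, c, truth = generate(
            SynthConfig(parent=jb1, true_opening_sites=((11, 1.0), (5, 0.8)), seed=9)
        )
        peaks = screen_marker(subtract(a, c))
        assert len(peaks) == 2
        apexes = sorted(p.apex_time for p in peaks)
        planted = sorted(p.rt_apexes[0] for p in truth.planted)
        for got, want in zip(apexes, planted):
            assert abs(got - want) <= 0.075  # within 1.5 duty cycles

    def test_self_subtracted_control_is_empty(self, jb1_synth_pair):
        _, control, _, _ = jb1_synth_pair
        assert screen_marker(subtract(control, control)) == []

    def test_unsubtracted_run_shows_matrix_conjugates_too(self, jb1_synth_pair):
        """Without subtraction the matrix 2PCA conjugates add marker peaks —
        the reason screening runs on subtracted data."""
        analyte, control, truth, _ = jb1_synth_pair
        n_analyte_species = len(truth.planted)
        n_matrix_pca = sum(sp.has_pca for sp in truth.matrix)
        assert n_matrix_pca > 0
        raw = screen_marker(analyte)
        subtracted = screen_marker(subtract(analyte, control))
        assert len(raw) > len(subtracted)
        assert len(subtracted) == n_analyte_species


class TestScoreCandidate:
    def test_true_thr_opening_beats_decoy_thr(self, somatostatin):
        """Both Thr openings share the doublet; only the true one matches the
        y ladder (the duplicate-residue disambiguation)."""
        true_cand = next(
            c for c in enumerate_openings(somatostatin) if c.opening_site == 10
        )
        decoy = next(
            c for c in enumerate_openings(somatostatin) if c.opening_site == 12
        )
        frags = generate_fragments(true_cand, FragmentConfig(max_charge=1))
        b1, a1 = doublet_for_residue("T")
        peaks = sorted(
            [f.mz for f in frags if f.kind in ("y", "b") and f.h_offset == 0]
            + [b1, a1]
        )
        spectrum = _msms(peaks, np.full(len(peaks), 100.0))
        s_true = score_candidate(spectrum, true_cand)
        s_decoy = score_candidate(spectrum, decoy)
        assert s_true.doublet_matched and s_decoy.doublet_matched
        assert s_true.y_coverage > s_decoy.y_coverage
        assert s_true.score > s_decoy.score

    def test_empty_spectrum_scores_zero(self, jb1):
        cand = enumerate_openings(jb1)[0]
        s = score_candidate(_msms([], []), cand)
        assert s.score == 0.0
        assert not s.doublet_matched
        assert s.n_matched_peaks == 0

    def test_lone_doublet_member_not_credited(self, jb1):
        cand = next(c for c in enumerate_openings(jb1) if c.n_term_residue == "S")
        b1, _ = doublet_for_residue("S")
        s = score_candidate(_msms([b1], [100.0]), cand)
        assert not s.doublet_matched

    def test_doublet_requires_consistent_h_offset(self, jb1):
        from cyclospot.chem import H_ATOM

        cand = next(c for c in enumerate_openings(jb1) if c.n_term_residue == "S")
        b1, a1 = doublet_for_residue("S")
        # b at offset 0, a at offset -1: inconsistent, no credit
        s = score_candidate(
            _msms(sorted([b1, a1 - H_ATOM]), [100.0, 100.0]),
            cand,
            match_ppm=5.0,
        )
        assert not s.doublet_matched
        # both at -1: credited with the offset recorded
        s2 = score_candidate(
            _msms(sorted([b1 - H_ATOM, a1 - H_ATOM]), [100.0, 100.0]),
            cand,
            match_ppm=5.0,
        )
        assert s2.doublet_matched and s2.doublet_h_offset == -1

    def test_isobaric_internal_alone_flags_ambiguity(self, jb1):
        cand = next(c for c in enumerate_openings(jb1) if c.n_term_residue == "S")
        frags = generate_fragments(cand, FragmentConfig(max_charge=1))
        plk = next(f for f in frags if f.label == "internal PLK")
        s = score_candidate(_msms([plk.mz], [100.0]), cand)
        assert not s.doublet_matched
        assert any(
            {"internal PLK", "internal LKP"} <= set(g)
            for g in s.internal_ambiguity_flags
        )

    def test_adding_matched_peak_never_lowers_score(self, jb1):
        cand = next(c for c in enumerate_openings(jb1) if c.n_term_residue == "S")
        frags = generate_fragments(cand, FragmentConfig(max_charge=1))
        mzs: list[float] = []
        prev = -1.0
        for f in frags[:40]:
            mzs.append(f.mz)
            spectrum = _msms(sorted(set(mzs)), np.full(len(set(mzs)), 50.0))
            score = score_candidate(spectrum, cand).score
            assert score >= prev - 1e-12
            prev = score

    def test_permutation_soundness_random_rings(self, rng):
        """For a spectrum built from opening k, candidate k never scores
        below any other rotation (20 random cyclic sequences)."""
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for trial in range(20):
            seq = "".join(rng.choice(residues, size=rng.integers(5, 11)))
            parent = CyclicPeptide(f"r{trial}", seq)
            cands = enumerate_openings(parent)
            k = int(rng.integers(len(cands)))
            true_cand = cands[k]
            frags = generate_fragments(true_cand, FragmentConfig(max_charge=1))
            b1, a1 = doublet_for_residue(true_cand.n_term_residue)
            mzs = sorted(
                {f.mz for f in frags if f.kind in ("y", "b") and f.h_offset == 0}
                | {b1, a1}
            )
            spectrum = _msms(mzs, np.full(len(mzs), 100.0))
            scores = {c.opening_site: score_candidate(spectrum, c).score for c in cands}
            assert scores[true_cand.opening_site] == max(scores.values())


class TestIdentifyPipeline:
    def test_recovers_planted_ser_opening(self, jb1, jb1_synth_pair):
        analyte, control, truth, _ = jb1_synth_pair
        result = identify(analyte, control, jb1)
        assert result.status == "identified"
        assert result.verdict.candidate.opening_site == truth.planted[0].opening_site
        assert result.verdict.candidate.n_term_residue == "S"
        assert result.verdict.doublet_matched

    def test_two_openings_reported_as_separate_peaks_with_verdicts(self, jb1):
        a, c, truth = generate(
            SynthConfig(parent=jb1, true_opening_sites=((11, 1.0), (5, 0.8)), seed=9)
        )
        result = identify(a, c, jb1)
        assert len(result.marker_peaks) == 2
        sites = {
            p.best.candidate.opening_site
            for p in result.peak_assignments
            if p.best is not None
        }
        assert sites == {11, 5}

    def test_control_against_itself_gives_no_evidence(self, jb1, jb1_synth_pair):
        _, control, _, _ = jb1_synth_pair
        result = identify(control, control, jb1)
        assert result.status == "no evidence"
        assert result.verdict is None
        assert result.marker_peaks == []

    def test_deterministic_report(self, jb1, jb1_synth_pair):
        analyte, control, _, _ = jb1_synth_pair
        r1 = identify(analyte, control, jb1)
        r2 = identify(analyte, control, jb1)
        assert r1.to_json() == r2.to_json()
        assert r1.to_text() == r2.to_text()

    def test_marker_peak_without_msms_reported_unassigned(self, jb1):
        """A 2PCA species seen in AIF but never targeted is flagged, not
        sequenced — the secondary-metabolite situation."""
        a, c, truth = generate(
            SynthConfig(parent=jb1, true_opening_sites=((11, 1.0),), seed=4)
        )
        stripped = Run(
            spectra=[s for s in a.spectra if s.scan_function != TARGETED],
            metadata=a.metadata,
        )
        result = identify(stripped, c, jb1)
        assert result.status == "no evidence"
        assert len(result.peak_assignments) == 1
        assert result.peak_assignments[0].status == "unassigned 2PCA species"
        obs = result.peak_assignments[0].observed_precursor_mz
        assert obs == pytest.approx(truth.planted[0].precursor_mz, rel=1e-4)
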