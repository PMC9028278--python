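"""Soft-spot identification: targets, marker screening, scoring, ranking.

The workflow mirrors manual interpretation of 2PCA-derivatized ring-opened
cyclic peptides and makes each evidence channel explicit:

1. Build an inclusion list for the parent, the hydrolyzed parent
   ([M + H2O]) and its 2PCA conjugate ([M + H2O + C6H3N]).
2. Background-subtract the analyte run and screen the subtracted AIF scans
   for the imidazolidinone marker ion (m/z 107.0609) to find retention
   times carrying analyte-specific 2PCA conjugates.
3. Score every ring-opening candidate against the targeted MS/MS spectra
   whose precursor matches the inclusion list: the diagnostic a1/b1 doublet
   names the N-terminal residue, and the y-ion ladder (insensitive to the
   N-terminal tag) disambiguates duplicate residues.
4. Rank candidates; marker peaks without a matching precursor are reported
   as unassigned 2PCA species (e.g. secondary metabolites).

Scores are a weighted sum of evidence channels. The weights are plumbing,
not chemistry: they encode "doublet and y-coverage dominate" and are fully
configurable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .chem import DIAG_ION_MZ, PCA_RESIDUAL, WATER, mz
from .cyclic import CyclicPeptide, LinearCandidate, enumerate_openings
from .fragments import (
    FragmentConfig,
    TheoreticalFragment,
    generate_fragments,
    isobaric_internal_groups,
)
from .spectra import AIF, FULL, TARGETED, ChromPeak, Run, Spectrum, extract_xic, find_peaks
from .subtract import SubtractionConfig, subtract

__all__ = [
    "TargetEntry",
    "TargetList",
    "build_target_list",
    "screen_marker",
    "ScoreWeights",
    "CandidateScore",
    "score_candidate",
    "IdentifyConfig",
    "SoftSpotResult",
    "identify",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TargetEntry:
    species: str  # "parent" | "hydrolyzed" | "derivatized"
    charge: int
    neutral_mass: float
    mz: float


@dataclass(frozen=True)
class TargetList:
    """Inclusion list for targeted MS/MS of one parent."""

    parent: CyclicPeptide
    entries: tuple[TargetEntry, ...]

    def for_species(self, species: str) -> list[TargetEntry]:
        return [e for e in self.entries if e.species == species]

    def to_tsv(self, path: str) -> None:
        """Vendor-editor-compatible TSV (mass, mz, z, species)."""
        with open(path, "w") as fh:
            fh.write("mass\tmz\tz\tspecies\n")
            for e in self.entries:
                fh.write(f"{e.neutral_mass:.4f}\t{e.mz:.4f}\t{e.charge}\t{e.species}\n")


def build_target_list(parent: CyclicPeptide, max_charge: int = 3) -> TargetList:
    """Targets at charges 1..max_charge for parent, parent + H2O, and
    parent + H2O + 2PCA residual."""
    ring = parent.ring_mass
    species = (
        ("parent", ring),
        ("hydrolyzed", ring + WATER),
        ("derivatized", ring + WATER + PCA_RESIDUAL),
    )
    entries = tuple(
        TargetEntry(species=name, charge=z, neutral_mass=m, mz=mz(m, z))
        for name, m in species
        for z in range(1, max_charge + 1)
    )
    return TargetList(parent=parent, entries=entries)


def screen_marker(
    run: Run,
    ppm_tol: float = 5.0,
    min_intensity: float = 1.0,
    min_points: int = 3,
) -> list[ChromPeak]:
    """Chromatographic peaks of the m/z 107.0609 marker ion in AIF scans.

    On a background-subtracted run, each peak marks a retention time at
    which an analyte-specific 2PCA conjugate (soft-spot product or
    secondary metabolite) elutes.
    """
    xic = extract_xic(run, DIAG_ION_MZ, ppm_tol, scan_function=AIF)
    return find_peaks(xic, min_intensity=min_intensity, min_points=min_points)


@dataclass(frozen=True)
class ScoreWeights:
    """Relative weight of each evidence channel (sums need not be 1)."""

    doublet: float = 0.4
    y_coverage: float = 0.4
    b_coverage: float = 0.1
    marker: float = 0.05
    matched_intensity: float = 0.05


@dataclass(frozen=True)
class CandidateScore:
    """Evidence collected for one ring-opening candidate in one spectrum."""

    candidate: LinearCandidate
    doublet_matched: bool
    doublet_mz: Optional[float]
    doublet_h_offset: Optional[int]
    marker_matched: bool
    y_coverage: float
    b_coverage: float
    n_matched_peaks: int
    matched_intensity_fraction: float
    internal_ambiguity_flags: tuple[tuple[str, ...], ...]
    score: float

    def summary(self) -> dict:
        return {
            "opening_site": self.candidate.opening_site,
            "n_term_residue": self.candidate.n_term_residue,
            "sequence": self.candidate.sequence,
            "score": round(self.score, 4),
            "doublet_matched": self.doublet_matched,
            "doublet_mz": None if self.doublet_mz is None else round(self.doublet_mz, 4),
            "doublet_h_offset": self.doublet_h_offset,
            "marker_matched": self.marker_matched,
            "y_coverage": round(self.y_coverage, 4),
            "b_coverage": round(self.b_coverage, 4),
            "n_matched_peaks": self.n_matched_peaks,
            "matched_intensity_fraction": round(self.matched_intensity_fraction, 4),
            "internal_ambiguity_flags": [list(g) for g in self.internal_ambiguity_flags],
        }


def _match_positions(spectrum: Spectrum, target: float, ppm: float) -> slice:
    half = target * ppm * 1e-6
    i0 = int(np.searchsorted(spectrum.mz, target - half, side="left"))
    i1 = int(np.searchsorted(spectrum.mz, target + half, side="right"))
    return slice(i0, i1)


def score_candidate(
    spectrum: Spectrum,
    candidate: LinearCandidate,
    frag_config: FragmentConfig = FragmentConfig(),
    match_ppm: float = 10.0,
    weights: ScoreWeights = ScoreWeights(),
) -> CandidateScore:
    """Score one candidate against one MS/MS spectrum.

    The doublet counts only when BOTH members match at the same
    hydrogen-transfer offset (its diagnostic power is the 27.9949 Da
    spacing); a lone member contributes to peak counts but not to
    ``doublet_matched``. Coverages count distinct ladder ordinals matched
    at any charge/offset over the n-1 possible. An empty spectrum scores 0.
    """
    frags = generate_fragments(candidate, frag_config)
    n = len(candidate.sequence)
    matched_frags: list[TheoreticalFragment] = []
    matched_peak_idx: set[int] = set()
    doublet_hits: dict[int, set[str]] = {}
    doublet_mz_by_offset: dict[int, float] = {}
    marker_matched = False
    y_hit: set[int] = set()
    b_hit: set[int] = set()

    if len(spectrum) > 0:
        for f in frags:
            sl = _match_positions(spectrum, f.mz, match_ppm)
            if sl.start == sl.stop:
                continue
            matched_frags.append(f)
            matched_peak_idx.update(range(sl.start, sl.stop))
            if f.kind in ("doublet_b", "doublet_a"):
                doublet_hits.setdefault(f.h_offset, set()).add(f.kind)
                if f.kind == "doublet_b":
                    doublet_mz_by_offset[f.h_offset] = f.mz
            elif f.kind == "marker":
                marker_matched = True
            elif f.kind == "y":
                y_hit.add(f.span[1] - f.span[0])
            elif f.kind == "b":
                b_hit.add(f.span[1] - f.span[0])

    complete_offsets = sorted(k for k, kinds in doublet_hits.items() if len(kinds) == 2)
    doublet_matched = bool(complete_offsets)
    # prefer the canonical (0) offset when several are complete
    doublet_offset = None
    if doublet_matched:
        doublet_offset = 0 if 0 in complete_offsets else complete_offsets[0]

    denom = max(n - 1, 1)
    y_cov = len(y_hit) / denom
    b_cov = len(b_hit) / denom
    total_intensity = float(spectrum.intensity.sum()) if len(spectrum) else 0.0
    mif = (
        float(spectrum.intensity[sorted(matched_peak_idx)].sum()) / total_intensity
        if total_intensity > 0
        else 0.0
    )

    ambiguity: list[tuple[str, ...]] = []
    matched_labels = {f.label for f in matched_frags}
    for group in isobaric_internal_groups(frags, ppm_tol=match_ppm):
        if any(g.label in matched_labels for g in group):
            ambiguity.append(tuple(sorted({g.label for g in group})))

    score = (
        weights.doublet * doublet_matched
        + weights.y_coverage * y_cov
        + weights.b_coverage * b_cov
        + weights.marker * marker_matched
        + weights.matched_intensity * mif
    )
    return CandidateScore(
        candidate=candidate,
        doublet_matched=doublet_matched,
        doublet_mz=doublet_mz_by_offset.get(doublet_offset) if doublet_matched else None,
        doublet_h_offset=doublet_offset,
        marker_matched=marker_matched,
        y_coverage=y_cov,
        b_coverage=b_cov,
        n_matched_peaks=len(matched_peak_idx),
        matched_intensity_fraction=mif,
        internal_ambiguity_flags=tuple(ambiguity),
        score=score,
    )


@dataclass(frozen=True)
class IdentifyConfig:
    """End-to-end pipeline configuration with the study defaults:
    ±0.2 min / ±10 ppm / scaling factor 2 subtraction, ±5 ppm marker XIC,
    ±10 ppm MS/MS peak matching."""

    subtraction: SubtractionConfig = SubtractionConfig()
    fragment: FragmentConfig = FragmentConfig()
    match_ppm: float = 10.0
    precursor_ppm: float = 10.0
    marker_ppm: float = 5.0
    marker_min_intensity: float = 1.0
    marker_min_points: int = 3
    max_charge: int = 3
    weights: ScoreWeights = ScoreWeights()
    ambiguity_margin: float = 0.1
    rt_gate: bool = False
    pseudo_linear: bool = True


def _rank_key(cs: CandidateScore):
    return (
        -cs.score,
        not cs.doublet_matched,
        -cs.y_coverage,
        cs.candidate.opening_site,
    )


@dataclass
class PeakAssignment:
    """Per-marker-peak verdict (one elution may be one metabolite)."""

    peak: ChromPeak
    best: Optional[CandidateScore]
    status: str  # "identified" | "ambiguous" | "unassigned 2PCA species"
    observed_precursor_mz: Optional[float] = None


@dataclass
class SoftSpotResult:
    """Ranked soft-spot candidates with all collected evidence."""

    parent: CyclicPeptide
    target_list: TargetList
    ranking: list[CandidateScore]
    status: str  # "identified" | "ambiguous" | "no evidence"
    verdict: Optional[CandidateScore]
    tied: list[CandidateScore]
    marker_peaks: list[ChromPeak]
    peak_assignments: list[PeakAssignment]
    n_spectra_scored: int

    def to_dict(self) -> dict:
        return {
            "parent": {
                "name": self.parent.name,
                "sequence": self.parent.sequence,
                "topology": self.parent.topology,
            },
            "status": self.status,
            "verdict": None if self.verdict is None else self.verdict.summary(),
            "tied": [t.summary() for t in self.tied],
            "ranking": [r.summary() for r in self.ranking],
            "marker_peaks": [
                {
                    "apex_time_min": round(p.apex_time, 4),
                    "apex_intensity": p.apex_intensity,
                    "start_time_min": round(p.start_time, 4),
                    "end_time_min": round(p.end_time, 4),
                }
                for p in self.marker_peaks
            ],
            "peak_assignments": [
                {
                    "apex_time_min": round(a.peak.apex_time, 4),
                    "status": a.status,
                    "opening_site": None if a.best is None else a.best.candidate.opening_site,
                    "observed_precursor_mz": a.observed_precursor_mz,
                }
                for a in self.peak_assignments
            ],
            "n_spectra_scored": self.n_spectra_scored,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [
            f"Soft-spot report for {self.parent.name} "
            f"({self.parent.sequence}, {self.parent.topology})",
            f"status: {self.status}",
        ]
        if self.verdict is not None:
            c = self.verdict.candidate
            lines.append(
                f"verdict: ring opening at residue {c.opening_site} "
                f"({c.n_term_residue}); linearized sequence {c.sequence}"
            )
        lines.append(f"marker peaks (m/z {DIAG_ION_MZ:.4f}): {len(self.marker_peaks)}")
        for a in self.peak_assignments:
            extra = (
                f" opening at {a.best.candidate.opening_site}"
                if a.best is not None
                else (
                    f" observed precursor m/z {a.observed_precursor_mz:.4f}"
                    if a.observed_precursor_mz is not None
                    else ""
                )
            )
            lines.append(f"  RT {a.peak.apex_time:.2f} min: {a.status}{extra}")
        lines.append("ranking:")
        for r in self.ranking:
            c = r.candidate
            lines.append(
                f"  site {c.opening_site:>2} ({c.n_term_residue}) "
                f"score {r.score:.3f} doublet={'Y' if r.doublet_matched else 'n'} "
                f"y-cov {r.y_coverage:.2f} b-cov {r.b_coverage:.2f}"
            )
        return "\n".join(lines) + "\n"


def _precursor_matches(spectrum: Spectrum, entries: list[TargetEntry], ppm: float) -> bool:
    if spectrum.precursor_mz is None:
        return False
    for e in entries:
        if abs(spectrum.precursor_mz - e.mz) / e.mz * 1e6 <= ppm:
            return True
    return False


def identify(
    analyte: Run,
    control: Run,
    parent: CyclicPeptide,
    config: IdentifyConfig = IdentifyConfig(),
) -> SoftSpotResult:
    """Full pipeline: subtract, screen the marker, score, rank.

    Targeted MS/MS spectra whose precursor matches the derivatized target
    (any charge, within ``precursor_ppm``) are scored against every
    ring-opening candidate; per candidate the best score across spectra is
    kept. Marker peaks whose retention window contains no matching MS/MS
    spectrum are reported as unassigned 2PCA species with the most intense
    co-eluting MS1 peak as the observed precursor.
    """
    subtracted = subtract(analyte, control, config.subtraction)
    marker_peaks = screen_marker(
        subtracted,
        ppm_tol=config.marker_ppm,
        min_intensity=config.marker_min_intensity,
        min_points=config.marker_min_points,
    )
    target_list = build_target_list(parent, max_charge=config.max_charge)
    derivatized = target_list.for_species("derivatized")

    msms = [
        s
        for s in analyte.select(TARGETED)
        if _precursor_matches(s, derivatized, config.precursor_ppm)
    ]
    if config.rt_gate and marker_peaks:
        msms = [
            s
            for s in msms
            if any(p.start_time <= s.time <= p.end_time for p in marker_peaks)
        ]

    candidates = enumerate_openings(parent, pseudo_linear=config.pseudo_linear)
    best: dict[int, CandidateScore] = {}
    per_spectrum: list[tuple[Spectrum, list[CandidateScore]]] = []
    for s in msms:
        scores = [
            score_candidate(s, c, config.fragment, config.match_ppm, config.weights)
            for c in candidates
        ]
        per_spectrum.append((s, scores))
        for cs in scores:
            site = cs.candidate.opening_site
            if site not in best or cs.score > best[site].score:
                best[site] = cs

    ranking = sorted(best.values(), key=_rank_key)

    if not ranking or all(r.score == 0 for r in ranking):
        status = "no evidence"
        verdict = None
        tied: list[CandidateScore] = []
        if not msms:
            logger.info("no MS/MS spectra matched the target list")
    elif len(ranking) == 1 or ranking[0].score - ranking[1].score > config.ambiguity_margin:
        status = "identified"
        verdict = ranking[0]
        tied = []
    else:
        status = "ambiguous"
        verdict = None
        tied = [
            r for r in ranking if ranking[0].score - r.score <= config.ambiguity_margin
        ]

    # per-marker-peak assignment
    assignments: list[PeakAssignment] = []
    for p in marker_peaks:
        in_peak = [
            (s, scores)
            for s, scores in per_spectrum
            if p.start_time <= s.time <= p.end_time
        ]
        if in_peak:
            peak_best_by_site: dict[int, CandidateScore] = {}
            for _, scores in in_peak:
                for cs in scores:
                    site = cs.candidate.opening_site
                    if site not in peak_best_by_site or cs.score > peak_best_by_site[site].score:
                        peak_best_by_site[site] = cs
            runner = sorted(peak_best_by_site.values(), key=_rank_key)
            peak_best = runner[0]
            margin_ok = (
                len(runner) < 2
                or runner[0].score - runner[1].score > config.ambiguity_margin
            )
            assignments.append(
                PeakAssignment(
                    peak=p,
                    best=peak_best,
                    status="identified" if margin_ok and peak_best.score > 0 else "ambiguous",
                )
            )
        else:
            assignments.append(
                PeakAssignment(
                    peak=p,
                    best=None,
                    status="unassigned 2PCA species",
                    observed_precursor_mz=_coeluting_base_peak(subtracted, p),
                )
            )

    return SoftSpotResult(
        parent=parent,
        target_list=target_list,
        ranking=ranking,
        status=status,
        verdict=verdict,
        tied=tied,
        marker_peaks=marker_peaks,
        peak_assignments=assignments,
        n_spectra_scored=len(msms),
    )


def _coeluting_base_peak(run: Run, peak: ChromPeak) -> Optional[float]:
    """Most intense MS1 peak in the scan nearest the marker-peak apex."""
    ms1 = run.select(FULL)
    if not ms1:
        return None
    nearest = min(ms1, key=lambda s: abs(s.time - peak.apex_time))
    if len(nearest) == 0:
        return None
    return float(nearest.mz[int(np.argmax(nearest.intensity))])
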