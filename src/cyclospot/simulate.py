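"""Synthetic LC-MS/MS run generator with ground truth.

Emulates the data shape of an in-vitro cyclic-peptide stability incubation
analyzed by the three-scan method (MS1 survey + AIF + targeted MS/MS):

* a matrix-only control run containing shared background ions — random
  tryptic-like species with Gaussian elution profiles, a configurable
  fraction of which carry 2PCA and therefore emit the m/z 107.0609 marker
  ion in AIF scans;
* an analyte run containing the *same* matrix ions (identical m/z, RT and
  intensity, so subtraction can remove them exactly) plus planted
  hydrolyzed + 2PCA ring-opened species: MS1 precursor peaks, AIF marker +
  high-mass fragments, and targeted MS/MS spectra near the apex holding the
  diagnostic doublet, partial b/y ladders, internal fragments, and noise.

All m/z values are perturbed by magnitude-bounded Gaussian jitter
(sigma = mz_jitter_ppm / 3, truncated at ±mz_jitter_ppm) so a stated jitter
bound guarantees containment in matching windows of that width. Everything
is driven by a seeded PRNG: a fixed seed gives byte-identical mzML output.

What this emulator does NOT model: isotope envelopes, profile peak shapes,
RT drift between runs, detector saturation — conclusions from synthetic
recovery therefore bear on the algorithmic pipeline, not on instrument
physics.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from .chem import DIAG_ION_MZ, PCA_RESIDUAL, mz
from .cyclic import CyclicPeptide, enumerate_openings
from .fragments import FragmentConfig, generate_fragments
from .spectra import AIF, FULL, TARGETED, Run, Spectrum, write_run

__all__ = ["SynthConfig", "PlantedSpecies", "GroundTruth", "generate", "write_fixture"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic incubation pair.

    Defaults follow the emulated acquisition: a 6-min window of a
    0.05-min MS1+AIF duty cycle, 50 matrix ions of which 20% carry 2PCA,
    3 ppm mass jitter, 0.05-min (sigma) chromatographic peaks. The marker
    ion is planted at ~8% of the precursor intensity, matching its low
    relative abundance in real spectra.
    """

    parent: CyclicPeptide
    true_opening_sites: tuple[tuple[int, float], ...]  # (site, relative abundance)
    precursor_charge: int = 2
    matrix_ion_count: int = 50
    matrix_pca_fraction: float = 0.2
    rt_range: tuple[float, float] = (0.0, 6.0)
    cycle_time: float = 0.05
    peak_width_sigma: float = 0.05
    split_peak_isomers: bool = False
    split_rt_offset: float = 0.5  # isomer peaks are chromatographically resolved
    split_minor_fraction: float = 0.4
    noise_peak_count: int = 20
    analyte_intensity: float = 1.0e6
    matrix_intensity_range: tuple[float, float] = (1.0e4, 1.0e6)
    marker_fraction: float = 0.08
    fragment_intensity_range: tuple[float, float] = (0.05, 0.6)
    y_completeness: float = 0.9
    b_completeness: float = 0.5
    doublet_h_offset: int = -1
    n_msms_scans: int = 3
    mz_jitter_ppm: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        n = len(self.parent.sequence)
        for site, abund in self.true_opening_sites:
            if not any(
                c.opening_site == site for c in enumerate_openings(self.parent)
            ):
                raise ValueError(
                    f"opening site {site} is not a valid opening of "
                    f"{self.parent.name} (n={n}, topology={self.parent.topology})"
                )
            if abund <= 0:
                raise ValueError("relative abundances must be positive")


@dataclass(frozen=True)
class PlantedSpecies:
    """Ground truth for one planted analyte species."""

    opening_site: int
    sequence: str
    rt_apexes: tuple[float, ...]
    precursor_mz: float
    precursor_charge: int
    apex_intensity: float
    fragment_mzs: tuple[float, ...]
    msms_scan_ids: tuple[str, ...]


@dataclass(frozen=True)
class MatrixSpecies:
    mz: float
    rt: float
    intensity: float
    has_pca: bool
    fragment_mzs: tuple[float, ...]


@dataclass(frozen=True)
class GroundTruth:
    planted: tuple[PlantedSpecies, ...]
    matrix: tuple[MatrixSpecies, ...]
    seed: int

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(asdict(self), indent=indent, sort_keys=True)


def _gaussian(t: np.ndarray, apex: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - apex) / sigma) ** 2)


class _Jitter:
    """Magnitude-bounded Gaussian ppm jitter (sigma = ppm/3, clipped)."""

    def __init__(self, rng: np.random.Generator, ppm: float):
        self.rng = rng
        self.ppm = ppm

    def __call__(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.ppm <= 0:
            return values.copy()
        dev = self.rng.normal(0.0, self.ppm / 3.0, size=values.shape)
        dev = np.clip(dev, -self.ppm, self.ppm)
        return values * (1.0 + dev * 1e-6)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, size=None):
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=size))


# intensity below which a Gaussian tail is not sampled into a scan
_PROFILE_FLOOR = 1.0


def generate(config: SynthConfig) -> tuple[Run, Run, GroundTruth]:
    """Build (analyte run, control run, ground truth) from the config.

    The matrix portion of every scan is generated once and shared verbatim
    by both runs; analyte species and per-run noise come from independent
    seeded streams, so matrix ions subtract out exactly while analyte ions
    and noise are run-specific.
    """
    rng_matrix = np.random.default_rng(config.seed)
    rng_analyte = np.random.default_rng(config.seed + 10_000)
    rng_noise_a = np.random.default_rng(config.seed + 20_000)
    rng_noise_c = np.random.default_rng(config.seed + 30_000)

    t0, t1 = config.rt_range
    scan_times = np.arange(t0, t1 + 1e-9, config.cycle_time)
    margin = 3 * config.peak_width_sigma
    usable = t1 - t0 - 2 * margin

    # planted analyte retention times, spread across the run
    planted_rts: list[float] = []
    for i in range(len(config.true_opening_sites)):
        rt = t0 + margin + usable * (i + 1) / (len(config.true_opening_sites) + 1)
        rt += float(rng_analyte.uniform(-0.2, 0.2)) * min(1.0, usable / 4)
        planted_rts.append(rt)

    # 2PCA-bearing matrix conjugates are kept chromatographically resolved
    # from the analyte species: a matrix marker co-eluting within the
    # subtraction window would (correctly) also cancel the analyte's marker,
    # and the emulated study conditions presume resolved conjugates.
    pca_exclusion = 0.2 + 4 * config.peak_width_sigma

    # ---- matrix species (shared) ------------------------------------------
    matrix: list[MatrixSpecies] = []
    for _ in range(config.matrix_ion_count):
        m = rng_matrix.uniform(400.0, 1400.0)
        has_pca = rng_matrix.random() < config.matrix_pca_fraction
        rt = float(rng_matrix.uniform(t0 + margin, t1 - margin))
        if has_pca:
            for _attempt in range(100):
                if all(abs(rt - p) > pca_exclusion for p in planted_rts):
                    break
                rt = float(rng_matrix.uniform(t0 + margin, t1 - margin))
        inten = float(
            _log_uniform(rng_matrix, *config.matrix_intensity_range)
        )
        frag_mzs = tuple(np.sort(rng_matrix.uniform(150.0, m, size=3)))
        matrix.append(
            MatrixSpecies(
                mz=float(m), rt=float(rt), intensity=inten, has_pca=has_pca,
                fragment_mzs=frag_mzs,
            )
        )

    jitter_matrix = _Jitter(rng_matrix, config.mz_jitter_ppm)

    # matrix peak content per scan index, shared between runs
    matrix_ms1: list[tuple[np.ndarray, np.ndarray]] = []
    matrix_aif: list[tuple[np.ndarray, np.ndarray]] = []
    for t in scan_times:
        ms1_mz, ms1_int, aif_mz, aif_int = [], [], [], []
        for sp in matrix:
            h = sp.intensity * float(_gaussian(np.array([t]), sp.rt, config.peak_width_sigma)[0])
            if h < _PROFILE_FLOOR:
                continue
            ms1_mz.append(sp.mz)
            ms1_int.append(h)
            for fm in sp.fragment_mzs:
                aif_mz.append(fm)
                aif_int.append(h * 0.3)
            if sp.has_pca:
                aif_mz.append(DIAG_ION_MZ)
                aif_int.append(h * config.marker_fraction)
        matrix_ms1.append(
            (jitter_matrix(np.array(ms1_mz)), np.array(ms1_int, dtype=float))
        )
        matrix_aif.append(
            (jitter_matrix(np.array(aif_mz)), np.array(aif_int, dtype=float))
        )

    # ---- planted analyte species ------------------------------------------
    candidates = {c.opening_site: c for c in enumerate_openings(config.parent)}
    frag_config = FragmentConfig(
        ion_types=frozenset({"b", "y", "internal_b"}),
        max_charge=1,
        h_transfer_variants=(0,),
    )
    planted_specs = []
    for i, (site, abund) in enumerate(config.true_opening_sites):
        cand = candidates[site]
        rt = planted_rts[i]
        apex = config.analyte_intensity * abund
        prec_mz = mz(cand.neutral_mass + PCA_RESIDUAL, config.precursor_charge)

        frags = generate_fragments(cand, frag_config)
        y_frags = [f for f in frags if f.kind == "y"]
        b_frags = [f for f in frags if f.kind == "b" and f.h_offset == 0]
        internals = [f for f in frags if f.kind == "internal_b"]
        n_y = max(1, int(round(config.y_completeness * len(y_frags))))
        n_b = max(1, int(round(config.b_completeness * len(b_frags))))
        keep_y = [y_frags[j] for j in sorted(rng_analyte.choice(len(y_frags), size=min(n_y, len(y_frags)), replace=False))] if y_frags else []
        keep_b = [b_frags[j] for j in sorted(rng_analyte.choice(len(b_frags), size=min(n_b, len(b_frags)), replace=False))] if b_frags else []
        # a few length-3 internal fragments (proline-like favored spans)
        tri = [f for f in internals if f.span[1] - f.span[0] == 3]
        keep_int = [tri[j] for j in sorted(rng_analyte.choice(len(tri), size=min(2, len(tri)), replace=False))] if tri else []

        from .fragments import doublet_for_residue
        from .chem import H_ATOM

        b1, a1 = doublet_for_residue(cand.n_term_residue)
        k = config.doublet_h_offset
        doublet_mzs = [b1 + k * H_ATOM, a1 + k * H_ATOM]

        frag_mzs = [f.mz for f in keep_y + keep_b + keep_int] + doublet_mzs
        frag_rel = _log_uniform(
            rng_analyte,
            *config.fragment_intensity_range,
            size=len(frag_mzs),
        )
        # lysine in the ring sequesters charge at its epsilon-amine and
        # strengthens the y series
        if "K" in cand.sequence[1:]:
            for j in range(len(keep_y)):
                frag_rel[j] = min(1.0, frag_rel[j] * 2.0)
        rts = [rt]
        heights = [apex]
        if config.split_peak_isomers:
            rts.append(rt + config.split_rt_offset)
            heights.append(apex * config.split_minor_fraction)
        planted_specs.append(
            {
                "cand": cand,
                "rts": rts,
                "heights": heights,
                "prec_mz": prec_mz,
                "frag_mzs": np.array(frag_mzs),
                "frag_rel": np.asarray(frag_rel),
                "high_mass": np.array([m for m in frag_mzs if m >= 300.0]),
            }
        )

    jitter_analyte = _Jitter(rng_analyte, config.mz_jitter_ppm)

    def noise(rng: np.random.Generator, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
        nmz = rng.uniform(lo, hi, size=config.noise_peak_count)
        nint = _log_uniform(rng, 1e2, 1e4, size=config.noise_peak_count)
        return nmz, nint

    # ---- assemble runs -----------------------------------------------------
    def build_run(is_analyte: bool, rng_noise: np.random.Generator) -> tuple[Run, dict]:
        spectra: list[Spectrum] = []
        scan_no = 0
        msms_ids: dict[int, list[str]] = {i: [] for i in range(len(planted_specs))}

        def profile_height(spec: dict, t: float) -> float:
            return sum(
                h * float(np.exp(-0.5 * ((t - r) / config.peak_width_sigma) ** 2))
                for r, h in zip(spec["rts"], spec["heights"])
            )

        for idx, t in enumerate(scan_times):
            scan_no += 1
            ms1_mz, ms1_int = matrix_ms1[idx]
            aif_mz, aif_int = matrix_aif[idx]
            ms1_mz = list(ms1_mz)
            ms1_int = list(ms1_int)
            aif_mz = list(aif_mz)
            aif_int = list(aif_int)
            if is_analyte:
                for spec in planted_specs:
                    h = profile_height(spec, t)
                    if h < _PROFILE_FLOOR:
                        continue
                    ms1_mz.extend(jitter_analyte(np.array([spec["prec_mz"]])))
                    ms1_int.append(h)
                    if len(spec["high_mass"]):
                        aif_mz.extend(jitter_analyte(spec["high_mass"]))
                        aif_int.extend(h * 0.3 * np.ones(len(spec["high_mass"])))
                    aif_mz.extend(jitter_analyte(np.array([DIAG_ION_MZ])))
                    aif_int.append(h * config.marker_fraction)
            nmz, nint = noise(rng_noise, 400.0, 2000.0)
            spectra.append(
                Spectrum(
                    scan_id=f"scan={scan_no}",
                    time=float(t),
                    ms_level=1,
                    scan_function=FULL,
                    mz=np.concatenate([np.asarray(ms1_mz, dtype=float), nmz]),
                    intensity=np.concatenate([np.asarray(ms1_int, dtype=float), nint]),
                )
            )
            scan_no += 1
            nmz, nint = noise(rng_noise, 100.0, 1500.0)
            spectra.append(
                Spectrum(
                    scan_id=f"scan={scan_no}",
                    time=float(t) + config.cycle_time * 0.4,
                    ms_level=2,
                    scan_function=AIF,
                    isolation_width=1400.0,
                    mz=np.concatenate([np.asarray(aif_mz, dtype=float), nmz]),
                    intensity=np.concatenate([np.asarray(aif_int, dtype=float), nint]),
                )
            )

        if is_analyte:
            for i, spec in enumerate(planted_specs):
                apex_rt = spec["rts"][0]
                near = np.argsort(np.abs(scan_times - apex_rt))[: config.n_msms_scans]
                for j, idx in enumerate(sorted(near)):
                    scan_no += 1
                    t = float(scan_times[idx]) + config.cycle_time * 0.7
                    h = profile_height(spec, float(scan_times[idx]))
                    nmz, nint = noise(rng_noise, 100.0, spec["prec_mz"] + 50)
                    sid = f"scan={scan_no}"
                    msms_ids[i].append(sid)
                    spectra.append(
                        Spectrum(
                            scan_id=sid,
                            time=t,
                            ms_level=2,
                            scan_function=TARGETED,
                            precursor_mz=spec["prec_mz"],
                            isolation_width=1.0,
                            mz=np.concatenate([jitter_analyte(spec["frag_mzs"]), nmz]),
                            intensity=np.concatenate(
                                [np.maximum(h, _PROFILE_FLOOR) * spec["frag_rel"], nint]
                            ),
                        )
                    )
        run = Run(
            spectra=spectra,
            metadata={"id": "analyte" if is_analyte else "control"},
        )
        return run, msms_ids

    analyte_run, msms_ids = build_run(True, rng_noise_a)
    control_run, _ = build_run(False, rng_noise_c)

    truth = GroundTruth(
        planted=tuple(
            PlantedSpecies(
                opening_site=spec["cand"].opening_site,
                sequence=spec["cand"].sequence,
                rt_apexes=tuple(float(r) for r in spec["rts"]),
                precursor_mz=float(spec["prec_mz"]),
                precursor_charge=config.precursor_charge,
                apex_intensity=float(spec["heights"][0]),
                fragment_mzs=tuple(float(m) for m in spec["frag_mzs"]),
                msms_scan_ids=tuple(msms_ids[i]),
            )
            for i, spec in enumerate(planted_specs)
        ),
        matrix=tuple(matrix),
        seed=config.seed,
    )
    return analyte_run, control_run, truth


def write_fixture(config: SynthConfig, out_dir: str) -> dict[str, str]:
    """Generate and write analyte.mzML, control.mzML and truth.json."""
    import os

    analyte, control, truth = generate(config)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "analyte": os.path.join(out_dir, "analyte.mzML"),
        "control": os.path.join(out_dir, "control.mzML"),
        "truth": os.path.join(out_dir, "truth.json"),
    }
    write_run(analyte, paths["analyte"])
    write_run(control, paths["control"])
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return paths
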