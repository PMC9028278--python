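"""Dynamic control-scan background subtraction for AIF / MS1 data.

Analyte incubations and matrix-only (or other-peptide) control incubations
share the matrix-derived ions; the analyte-specific hydrolyzed + 2PCA
species appear only in the analyte run. For each analyte scan, control scans
inside a retention-time window (default ±0.2 min) are pooled; each analyte
peak is matched against every control peak within a ppm tolerance (default
±10 ppm), the highest matched control intensity is scaled (default ×2) and
subtracted. Peaks that do not survive are dropped (or clamped to zero).

Subtraction is applied per scan function: each analyte scan is only compared
with control scans of the same function.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass

import numpy as np

from .spectra import Run, Spectrum

__all__ = ["SubtractionConfig", "subtract", "cross_peptide_controls"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubtractionConfig:
    """Knobs of the control-scan subtraction.

    time_window : minutes, half-width of the control-scan window (±).
    ppm_tol     : half-width of the m/z match window, on the analyte peak.
    scaling_factor : multiplier applied to the best matched control
        intensity before subtraction; >= 1 removes shared background
        completely even with modest run-to-run intensity drift.
    drop_nonpositive : remove peaks with non-positive residual intensity
        instead of keeping them as zeros.
    """

    time_window: float = 0.2
    ppm_tol: float = 10.0
    scaling_factor: float = 2.0
    drop_nonpositive: bool = True

    def __post_init__(self) -> None:
        if self.time_window <= 0:
            raise ValueError("time_window must be positive")
        if self.ppm_tol <= 0:
            raise ValueError("ppm_tol must be positive")
        if self.scaling_factor < 0:
            raise ValueError("scaling_factor must be non-negative")


def _subtract_spectrum(
    s: Spectrum,
    control_mz: np.ndarray,
    control_intensity: np.ndarray,
    config: SubtractionConfig,
) -> Spectrum:
    if len(s) == 0 or len(control_mz) == 0:
        matched_max = np.zeros(len(s))
    else:
        half = s.mz * config.ppm_tol * 1e-6
        lo = np.searchsorted(control_mz, s.mz - half, side="left")
        hi = np.searchsorted(control_mz, s.mz + half, side="right")
        matched_max = np.zeros(len(s))
        # max of an arbitrary slice; loop only over peaks with matches
        for i in np.nonzero(hi > lo)[0]:
            matched_max[i] = control_intensity[lo[i] : hi[i]].max()
    new_intensity = s.intensity - config.scaling_factor * matched_max
    if config.drop_nonpositive:
        keep = new_intensity > 0
        mz_out, int_out = s.mz[keep], new_intensity[keep]
    else:
        mz_out, int_out = s.mz, np.maximum(new_intensity, 0.0)
    return Spectrum(
        scan_id=s.scan_id,
        time=s.time,
        ms_level=s.ms_level,
        scan_function=s.scan_function,
        mz=mz_out,
        intensity=int_out,
        precursor_mz=s.precursor_mz,
        isolation_width=s.isolation_width,
    )


def subtract(analyte: Run, control: Run, config: SubtractionConfig = SubtractionConfig()) -> Run:
    """Background-subtract an analyte run against a control run.

    Loops over every analyte scan; control scans of the same scan function
    within ``±time_window`` minutes are pooled and each analyte peak is
    reduced by ``scaling_factor`` times the highest matched control
    intensity (within ``ppm_tol``). Scan times, ids and ordering are
    preserved. An empty control run returns the analyte unchanged with a
    logged warning.
    """
    if len(control) == 0:
        logger.warning("empty control run: returning analyte unchanged")
        return Run(spectra=list(analyte.spectra), metadata=dict(analyte.metadata))

    by_function: dict[str, list[Spectrum]] = {}
    for c in control.spectra:
        by_function.setdefault(c.scan_function, []).append(c)
    times_by_function = {
        fn: [c.time for c in scans] for fn, scans in by_function.items()
    }

    out: list[Spectrum] = []
    for s in analyte.spectra:
        scans = by_function.get(s.scan_function, [])
        times = times_by_function.get(s.scan_function, [])
        i0 = bisect.bisect_left(times, s.time - config.time_window)
        i1 = bisect.bisect_right(times, s.time + config.time_window)
        window = scans[i0:i1]
        if window:
            cmz = np.concatenate([c.mz for c in window])
            cint = np.concatenate([c.intensity for c in window])
            order = np.argsort(cmz, kind="stable")
            cmz, cint = cmz[order], cint[order]
        else:
            cmz = np.empty(0)
            cint = np.empty(0)
        out.append(_subtract_spectrum(s, cmz, cint, config))
    return Run(spectra=out, metadata={**analyte.metadata, "background_subtracted": True})


def cross_peptide_controls(runs: list[Run], index_of_analyte: int) -> Run:
    """Control run for one analyte built from the *other* peptides' runs.

    When no matrix-only incubation exists, runs of samples incubated with
    different cyclic peptides cover the matrix ions: everything shared with
    them is background. The other runs' spectra are merged in time order.
    """
    if len(runs) < 2:
        raise ValueError("cross-peptide controls require at least two runs")
    if not (0 <= index_of_analyte < len(runs)):
        raise ValueError(f"index_of_analyte {index_of_analyte} out of range")
    spectra: list[Spectrum] = []
    for i, r in enumerate(runs):
        if i != index_of_analyte:
            spectra.extend(r.spectra)
    return Run(spectra=spectra, metadata={"control_of": index_of_analyte})
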