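"""Isotopic-chromatogram ("evidence") construction.

For a glycopeptide precursor, the intensity of each theoretical isotopologue
is picked per MS1 scan inside a ppm tolerance window, and the chromatogram is
extended left and right from the trigger scan until the summed-isotope profile
drops below 10% of the apex of the extending profile. The area under the
monoisotopic trace (trapezoidal, in intensity·minutes) is the default
glycopeptide intensity.
"""

from __future__ import annotations

import numpy as np

from .model import Evidence, IsotopePattern, Run, Scan

APEX_FRACTION = 0.10  # stop extending when the profile falls below 10% of apex


def pick_peak(scan: Scan, target_mz: float, tol_ppm: float = 20.0) -> float:
    """Intensity of the most intense peak within ±tol_ppm of target_mz.

    Absence of a peak is a 0, not an error. Ties in intensity are broken by
    the smaller |Δm/z|.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    lo = target_mz * (1.0 - tol_ppm * 1e-6)
    hi = target_mz * (1.0 + tol_ppm * 1e-6)
    i0, i1 = np.searchsorted(scan.mz, [lo, hi])
    if i0 == i1:
        return 0.0
    window = scan.intensity[i0:i1]
    best = np.flatnonzero(window == window.max())
    if len(best) > 1:
        dmz = np.abs(scan.mz[i0:i1][best] - target_mz)
        return float(window[best[np.argmin(dmz)]])
    return float(window[best[0]])


def _scan_envelope(
    scan: Scan, pattern: IsotopePattern, tol_ppm: float
) -> np.ndarray:
    return np.array([pick_peak(scan, mz, tol_ppm) for mz in pattern.mz])


def build_evidence(
    run: Run,
    pattern: IsotopePattern,
    trigger_scan: int,
    tol_ppm: float = 20.0,
    ref: str = "",
) -> Evidence | None:
    """Build the evidence around an MS1 trigger scan, or None if no signal.

    ``trigger_scan`` indexes ``run.ms1_scans``. The summed-isotope profile is
    extended in each direction while it stays at or above 10% of the running
    apex (the apex of the extending profile, updated as scans are added). A
    scan with no in-window peak contributes 0 and terminates extension on that
    side.
    """
    ms1 = run.ms1_scans
    if not ms1:
        return None
    trigger_scan = int(np.clip(trigger_scan, 0, len(ms1) - 1))

    envelopes: dict[int, np.ndarray] = {}

    def summed(i: int) -> float:
        if i not in envelopes:
            envelopes[i] = _scan_envelope(ms1[i], pattern, tol_ppm)
        return float(envelopes[i].sum())

    trigger_intensity = summed(trigger_scan)
    if trigger_intensity <= 0:
        neighbors = [
            summed(j)
            for j in (trigger_scan - 1, trigger_scan + 1)
            if 0 <= j < len(ms1)
        ]
        if not any(v > 0 for v in neighbors):
            return None

    apex = trigger_intensity
    left = right = trigger_scan
    # extend right, then left, keeping a running apex of the summed profile
    for direction in (+1, -1):
        i = trigger_scan
        while True:
            j = i + direction
            if j < 0 or j >= len(ms1):
                break
            value = summed(j)
            if value < APEX_FRACTION * max(apex, 1e-300) or value == 0.0:
                break
            apex = max(apex, value)
            i = j
        if direction > 0:
            right = i
        else:
            left = i

    indices = range(left, right + 1)
    rt = np.array([ms1[i].rt for i in indices])
    intensities = np.column_stack([envelopes[i] for i in indices])
    profile = intensities.sum(axis=0)
    apex_scan = int(np.argmax(profile))
    # the integration grid extends one scan past the retained range on each
    # side, so the trapezoid captures the descent to the 10% boundary
    grid_lo = max(left - 1, 0)
    grid_hi = min(right + 1, len(ms1) - 1)
    for j in (grid_lo, grid_hi):
        if j not in envelopes:
            envelopes[j] = _scan_envelope(ms1[j], pattern, tol_ppm)
    grid_idx = range(grid_lo, grid_hi + 1)
    grid_rt = np.array([ms1[i].rt for i in grid_idx])
    grid_mono = np.array([envelopes[i][0] for i in grid_idx])
    mono_area = float(np.trapezoid(grid_mono, grid_rt))
    return Evidence(
        ref=ref,
        rt=rt,
        intensities=intensities,
        apex_scan=apex_scan,
        trigger_scan=trigger_scan - left,
        mono_area=mono_area,
        pattern=pattern,
        area_grid_rt=grid_rt,
        area_grid_mono=grid_mono,
    )


def evidence_intensity(e: Evidence, mode: str = "mono") -> float:
    """Quantified intensity of an evidence.

    Default is the area under the monoisotopic trace; ``mode='sum'`` instead
    integrates the summed-isotope profile.
    """
    if mode == "mono":
        return e.mono_area
    if mode == "sum":
        return float(np.trapezoid(e.intensities.sum(axis=0), e.rt))
    raise ValueError(f"unknown intensity mode {mode!r}")
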