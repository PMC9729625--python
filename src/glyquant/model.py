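"""Core in-memory data model shared across the pipeline.

The central objects are the glycopeptide spectrum match (:class:`GPSM`), the
centroided :class:`Scan`/:class:`Run` pair, the per-isotopologue extracted-ion
chromatogram bundle (:class:`Evidence`) and the quantitation records that the
merge step aggregates into the ``.list`` output tables.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .constants import PROTON_MASS


@dataclass
class GPSM:
    """One identified glycopeptide spectrum match."""

    run_id: str
    spectrum_ref: str
    peptide: str
    modifications: list[tuple[int, str, float]]  # (1-based position, name, Da)
    glycan_composition: dict[str, int]
    glycosite: int
    charge: int
    precursor_mz: float
    precursor_mass: float
    rt: float  # minutes
    protein: str
    glycan_structure: str | None = None
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if self.charge < 1:
            raise ValueError(f"charge must be >= 1, got {self.charge}")
        counts = self.glycan_composition
        if any(v < 0 for v in counts.values()) or not any(counts.values()):
            raise ValueError(f"invalid glycan composition {counts}")
        if self.precursor_mz and self.precursor_mass:
            implied = (self.precursor_mz - PROTON_MASS) * self.charge
            tol = 50e-6 * self.precursor_mass
            if abs(implied - self.precursor_mass) > max(tol, 0.5):
                # decoys carry a deliberate +10 Da offset between mass and m/z
                # only when constructed inconsistently; enforce for targets
                if not self.is_decoy:
                    raise ValueError(
                        f"precursor m/z {self.precursor_mz} inconsistent with "
                        f"mass {self.precursor_mass} at charge {self.charge}"
                    )

    @property
    def glycopeptide_key(self) -> tuple:
        """Identity used for cross-run matching: sequence, mods, glycan, charge."""
        comp = tuple(sorted((k, v) for k, v in self.glycan_composition.items() if v))
        mods = tuple(sorted(self.modifications))
        return (self.peptide, mods, comp, self.charge)


@dataclass
class Scan:
    scan_id: str
    ms_level: int
    rt: float  # minutes
    mz: np.ndarray
    intensity: np.ndarray
    precursor: tuple[float, int, str] | None = None  # (mz, charge, parent MS1 id)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise ValueError(f"scan {self.scan_id}: m/z not strictly ascending")
        if np.any(self.intensity < 0):
            raise ValueError(f"scan {self.scan_id}: negative intensity")


@dataclass
class Run:
    run_id: str
    scans: list[Scan]

    def __post_init__(self) -> None:
        self.scans = sorted(self.scans, key=lambda s: s.rt)
        self._ms1 = [s for s in self.scans if s.ms_level == 1]
        self._ms1_rts = [s.rt for s in self._ms1]

    @property
    def ms1_scans(self) -> list[Scan]:
        return self._ms1

    @property
    def ms1_rts(self) -> list[float]:
        return self._ms1_rts

    def ms1_index_at_or_before(self, rt: float) -> int:
        """Index (into ms1_scans) of the last MS1 scan with scan RT <= rt."""
        i = bisect.bisect_right(self._ms1_rts, rt) - 1
        return max(i, 0)

    def nearest_ms1_index(self, rt: float) -> int:
        i = bisect.bisect_left(self._ms1_rts, rt)
        if i == 0:
            return 0
        if i >= len(self._ms1_rts):
            return len(self._ms1_rts) - 1
        return i if self._ms1_rts[i] - rt < rt - self._ms1_rts[i - 1] else i - 1


@dataclass
class IsotopePattern:
    """Theoretical or experimental isotopologue envelope at a given charge."""

    mz: np.ndarray  # ascending, Da/e
    abundance: np.ndarray  # max-normalized to 1
    charge: int

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.abundance = np.asarray(self.abundance, dtype=float)


@dataclass
class Evidence:
    """Per-isotopologue chromatograms over a contiguous MS1 scan range."""

    ref: str
    rt: np.ndarray  # minutes, strictly increasing
    intensities: np.ndarray  # [n_isotopes, n_scans]
    apex_scan: int  # index into rt
    trigger_scan: int  # index into rt
    mono_area: float  # intensity * minutes
    pattern: IsotopePattern | None = None
    #: integration grid: the retained scans plus the first sub-threshold scan
    #: on each side, so the trapezoid captures the descent to the boundary
    area_grid_rt: np.ndarray | None = None
    area_grid_mono: np.ndarray | None = None

    @property
    def rt_start(self) -> float:
        return float(self.rt[0])

    @property
    def rt_end(self) -> float:
        return float(self.rt[-1])

    @property
    def apex_rt(self) -> float:
        return float(self.rt[self.apex_scan])

    @property
    def mono_trace(self) -> np.ndarray:
        return self.intensities[0]

    def apex_envelope(self) -> np.ndarray:
        """Experimental isotope envelope at the apex scan."""
        return self.intensities[:, self.apex_scan].copy()


@dataclass
class GMMParams:
    """Two-component Gaussian mixture; component 0 is the false-positive set."""

    pi0: float
    pi1: float
    mu0: float
    mu1: float
    sigma0: float
    sigma1: float

    def __post_init__(self) -> None:
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-9:
            raise ValueError("mixture probabilities must sum to 1")
        if self.sigma0 <= 0 or self.sigma1 <= 0:
            raise ValueError("component standard deviations must be positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.pi0, self.pi1, self.mu0, self.mu1, self.sigma0, self.sigma1]
        )


@dataclass
class QuantRecord:
    """Quantified intensity for one GPSM in one run/channel."""

    gpsm: GPSM
    run_id: str
    channel: str
    intensity: float
    origin: str = "identified"  # identified | mbr | mir
    score: float | None = None
    accepted: bool = True

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError("intensity must be >= 0")
        if self.origin == "mbr" and (self.score is None):
            raise ValueError("MBR records must carry a match score")


@dataclass
class MatchResult:
    """Outcome of matching one glycopeptide into one target run."""

    glycopeptide_key: tuple
    source_run: str
    target_run: str
    reference: Evidence
    best_candidate: Evidence | None
    score: float
    is_decoy: bool = False
    accepted: bool = False

    @property
    def intensity(self) -> float:
        return self.best_candidate.mono_area if self.best_candidate else 0.0


@dataclass
class QuantMatrix:
    """Flat record store plus the run/channel column order for outputs."""

    records: list[QuantRecord] = field(default_factory=list)
    columns: list[str] = field(default_factory=list)

    def add(self, record: QuantRecord) -> None:
        self.records.append(record)
        if record.channel not in self.columns:
            self.columns.append(record.channel)
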