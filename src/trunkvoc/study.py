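"""Study data model: enclosure samples, treatment phases, and feature tables.

The study design is a three-tree, three-phase trunk-volatile monitoring
experiment: a non-infested control (``ApC``), a beetle-infested maple
(``ApI``) and a non-infested neighbor (``ApN``), each sampled in duplicate
on repeated days across an acclimation phase, an abiotic-stress phase
(pruning and relocation into quarantine) and a long biotic-stress phase.
Background (ambient-air) samples are taken at each location to separate
trunk volatiles from ubiquitous ambient compounds.

Tables are plain CSV (UTF-8, header row, decimal point).  A compound that
was not detected in a sample is a *missing row* in the peaks table, never an
area of zero — detection frequencies and censoring downstream rely on this.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

__all__ = [
    "SampleRecord",
    "PhaseDefinition",
    "FeatureObservation",
    "DEFAULT_PHASES",
    "assign_phase",
    "load_tables",
    "samples_to_frame",
    "observations_to_frame",
    "write_tables",
]

#: Columns required in the sample-design table.
DESIGN_COLUMNS = [
    "sample_id",
    "tree_id",
    "day",
    "replicate",
    "bark_area_dm2",
    "duration_h",
    "flow_ml_min",
    "is_background",
    "location",
]

#: Columns required in the peaks (feature-observation) table.
PEAKS_COLUMNS = ["sample_id", "feature_id", "rt_min", "area", "match_score"]


@dataclass(frozen=True)
class SampleRecord:
    """One enclosure sampling event.

    Parameters
    ----------
    sample_id : str
        Opaque unique identifier.
    tree_id : str
        Tree label (``"ApC"``, ``"ApI"``, ``"ApN"``) or ``"BG"`` for
        background samples.
    day : int
        Days since tree arrival (day 0 = arrival).
    replicate : int
        Duplicate index within a day, 1-based; consecutive duplicates count
        as two samples in grouped statistics.
    bark_area_dm2 : float
        Enclosed bark surface in dm² (ignored for backgrounds).
    duration_h : float
        Sampling time in hours.
    flow_ml_min : float
        Pump flow in mL·min⁻¹.
    is_background : bool
        True for ambient-air samples.
    location : str
        ``"outside"`` or ``"inside_quarantine"``.
    """

    sample_id: str
    tree_id: str
    day: int
    replicate: int
    bark_area_dm2: float
    duration_h: float
    flow_ml_min: float = 30.0
    is_background: bool = False
    location: str = "outside"

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValueError(f"sample {self.sample_id}: day must be >= 0")
        if self.replicate < 1:
            raise ValueError(f"sample {self.sample_id}: replicate must be >= 1")
        if self.duration_h <= 0:
            raise ValueError(f"sample {self.sample_id}: duration must be > 0")
        if not self.is_background and not self.bark_area_dm2 > 0:
            raise ValueError(
                f"sample {self.sample_id}: bark_area_dm2 must be > 0 "
                "for trunk samples"
            )


@dataclass(frozen=True)
class PhaseDefinition:
    """A treatment phase as a closed integer day interval."""

    phase_id: int
    label: str
    day_start: int
    day_end: int

    def __contains__(self, day: int) -> bool:
        return self.day_start <= day <= self.day_end


#: Default phases: acclimation, abiotic stress, biotic stress.
DEFAULT_PHASES = (
    PhaseDefinition(1, "acclimation", 0, 8),
    PhaseDefinition(2, "abiotic_stress", 9, 19),
    PhaseDefinition(3, "biotic_stress", 20, 188),
)


@dataclass(frozen=True)
class FeatureObservation:
    """A detected deconvoluted component in one sample.

    ``area`` is the summed ion intensity of the deconvoluted component
    (dimensionless counts); absence is encoded by not having a row at all.
    """

    sample_id: str
    feature_id: str
    rt_min: float
    area: float
    match_score: float | None = None

    def __post_init__(self) -> None:
        if not self.rt_min > 0:
            raise ValueError(f"{self.feature_id}: retention time must be > 0")
        if not self.area > 0:
            raise ValueError(
                f"{self.feature_id} in {self.sample_id}: area must be > 0 "
                "(absence is a missing row, not zero)"
            )


def _check_phases(phases: tuple[PhaseDefinition, ...] | list[PhaseDefinition]) -> None:
    ordered = sorted(phases, key=lambda p: p.day_start)
    for a, b in zip(ordered, ordered[1:]):
        if a.day_end >= b.day_start:
            raise ValueError(
                f"phases {a.phase_id} and {b.phase_id} overlap or are unordered"
            )


def assign_phase(day: int, phases=DEFAULT_PHASES) -> int:
    """Return the phase_id of the unique phase whose interval contains *day*.

    Raises
    ------
    ValueError
        If *day* lies outside every phase interval (sample outside the
        study window) or the phases overlap.
    """
    _check_phases(phases)
    for phase in phases:
        if day in phase:
            return phase.phase_id
    raise ValueError(f"day {day} is outside every defined phase interval")


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory column(s) {missing}")


def load_tables(
    design_path, peaks_path
) -> tuple[list[SampleRecord], list[FeatureObservation]]:
    """Load the design and peaks CSVs into typed records.

    Every observation's ``sample_id`` must resolve to a design row; an
    unresolvable id is a hard error naming the offending row.
    """
    design = pd.read_csv(design_path)
    _require_columns(design, DESIGN_COLUMNS, design_path)
    peaks = pd.read_csv(peaks_path)
    _require_columns(peaks, [c for c in PEAKS_COLUMNS if c != "match_score"], peaks_path)

    samples = []
    for row in design.itertuples(index=False):
        bark = row.bark_area_dm2
        is_bg = bool(row.is_background)
        samples.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                tree_id=str(row.tree_id),
                day=int(row.day),
                replicate=int(row.replicate),
                bark_area_dm2=float(bark) if pd.notna(bark) else float("nan"),
                duration_h=float(row.duration_h),
                flow_ml_min=float(row.flow_ml_min),
                is_background=is_bg,
                location=str(row.location),
            )
        )

    known = {s.sample_id for s in samples}
    observations = []
    for i, row in enumerate(peaks.itertuples(index=False)):
        sid = str(row.sample_id)
        if sid not in known:
            raise ValueError(
                f"{peaks_path} row {i}: sample_id {sid!r} does not resolve "
                "to any design record"
            )
        score = getattr(row, "match_score", None)
        observations.append(
            FeatureObservation(
                sample_id=sid,
                feature_id=str(row.feature_id),
                rt_min=float(row.rt_min),
                area=float(row.area),
                match_score=float(score) if score is not None and pd.notna(score) else None,
            )
        )
    return samples, observations


def samples_to_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "tree_id": s.tree_id,
                "day": s.day,
                "replicate": s.replicate,
                "bark_area_dm2": s.bark_area_dm2,
                "duration_h": s.duration_h,
                "flow_ml_min": s.flow_ml_min,
                "is_background": s.is_background,
                "location": s.location,
            }
            for s in samples
        ],
        columns=DESIGN_COLUMNS,
    )


def observations_to_frame(observations: list[FeatureObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": o.sample_id,
                "feature_id": o.feature_id,
                "rt_min": o.rt_min,
                "area": o.area,
                "match_score": o.match_score,
            }
            for o in observations
        ],
        columns=PEAKS_COLUMNS,
    )


def write_tables(
    samples: list[SampleRecord],
    observations: list[FeatureObservation],
    design_path,
    peaks_path,
) -> None:
    """Write the design/peaks tables; round-trips with :func:`load_tables`."""
    samples_to_frame(samples).to_csv(design_path, index=False)
    observations_to_frame(observations).to_csv(peaks_path, index=False)
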