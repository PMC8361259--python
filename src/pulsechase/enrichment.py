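"""Corrected DNA deuterium enrichment from GC-MS isotopomer peak areas.

In a 6,6-2H2-glucose pulse-chase study the DNA of cells that divided while
labeled glucose was available carries deuterium.  The GC-MS readout is a pair
of peak areas per sample: the unlabeled (M+0) and doubly labeled (M+2) ion of
the derivatized DNA adenosine (m/z 435/437) or of plasma glucose (m/z
328/330).  This module turns those raw area pairs into the quantity plotted
in the kinetic figures:

1. tracer-to-tracee ratio  TTR = area(m+2) / area(m)
2. calibration against a standard curve of known enrichment
3. subtraction of the subject's own pre-label natural background
4. normalization by label availability: the mean plasma glucose enrichment
   p_bar of the subject's finger-prick samples, scaled by the de novo
   synthesis / base-salvage fraction b = 0.65

The normalized value net / (b * p_bar) estimates the fraction of cells whose
DNA was synthesized during the labeling window (precursor-product scaling).
Negative net enrichments are preserved, never clipped, and flagged via
``below_detection``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MassSpecReading",
    "CalibrationCurve",
    "CorrectionConstants",
    "EnrichmentPoint",
    "PrecursorExposure",
    "EnrichmentError",
    "UnusableReadingError",
    "DegenerateDesignError",
    "InvalidCurveError",
    "MissingBaselineError",
    "MissingPrecursorError",
    "CannotNormalizeError",
    "compute_ttr",
    "fit_calibration",
    "ttr_to_enrichment",
    "subtract_background",
    "summarize_precursor",
    "normalize_enrichment",
    "enrichment_pipeline",
    "read_readings_csv",
    "read_standards_csv",
    "write_enrichment_csv",
    "READINGS_COLUMNS",
    "DNA_CHANNEL",
    "GLUCOSE_CHANNEL",
]

DNA_CHANNEL = "dna_adenosine_435_437"
GLUCOSE_CHANNEL = "glucose_328_330"

COMPARTMENTS = ("blood", "sputum", "plasma")
CELL_TYPES = ("eosinophil", "basophil", "progenitor", "none")

#: exact column order of the measurement CSV dialect
READINGS_COLUMNS = [
    "sample_id",
    "subject_id",
    "phase",
    "study_day",
    "compartment",
    "cell_type",
    "channel_set",
    "area_m0",
    "area_m2",
]


class EnrichmentError(ValueError):
    """Base class for enrichment-processing failures."""


class UnusableReadingError(EnrichmentError):
    """Zero or missing unlabeled peak area: TTR undefined (distinct from TTR=0)."""


class DegenerateDesignError(EnrichmentError):
    """Calibration standards do not span two distinct known enrichments."""


class InvalidCurveError(EnrichmentError):
    """Calibration curve with non-positive slope cannot be inverted."""


class MissingBaselineError(EnrichmentError):
    """No pre-label baseline sample for a subject/phase."""


class MissingPrecursorError(EnrichmentError):
    """No plasma glucose enrichment available for a subject/phase."""


class CannotNormalizeError(EnrichmentError):
    """Mean precursor enrichment is zero; precursor-product scaling undefined."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MassSpecReading:
    """One GC-MS peak-area pair for one sample and channel set.

    ``study_day`` is phase-local: real days since the current phase's label
    intake (label day = 0).  Pre-label baseline samples carry a negative
    study_day.  Plasma glucose readings use ``compartment='plasma'`` and
    ``cell_type='none'``.
    """

    sample_id: str
    subject_id: str
    study_day: float
    phase: int
    compartment: str
    cell_type: str
    area_m0: float
    area_m2: float
    channel_set: str = DNA_CHANNEL

    def __post_init__(self) -> None:
        if self.phase not in (1, 2):
            raise ValueError(f"phase must be 1 or 2, got {self.phase!r}")
        if self.compartment not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"unknown cell_type {self.cell_type!r}")
        if self.channel_set not in (DNA_CHANNEL, GLUCOSE_CHANNEL):
            raise ValueError(f"unknown channel_set {self.channel_set!r}")
        if self.area_m0 < 0 or self.area_m2 < 0:
            raise ValueError("peak areas must be nonnegative")
        if self.channel_set == GLUCOSE_CHANNEL and (
            self.compartment != "plasma" or self.cell_type != "none"
        ):
            raise ValueError(
                "glucose channel readings must be plasma with cell_type='none'"
            )


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line mapping known enrichment to measured TTR."""

    slope: float
    intercept: float
    n_standards: int
    residual_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise InvalidCurveError(
                f"calibration slope must be positive, got {self.slope}"
            )
        if self.n_standards < 2:
            raise DegenerateDesignError("calibration needs at least 2 standards")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be nonnegative")


@dataclass(frozen=True)
class CorrectionConstants:
    """Correction constants of the enrichment pipeline.

    ``de_novo_fraction_b`` is the fraction of nucleotides built by de novo
    synthesis (label-incorporating) rather than base salvage; 0.65 for
    adenosine in this protocol.  ``detection_threshold`` is the smallest net
    enrichment considered distinguishable from background.
    """

    de_novo_fraction_b: float = 0.65
    detection_threshold: float = 0.0005

    def __post_init__(self) -> None:
        if not (0.0 < self.de_novo_fraction_b <= 1.0):
            raise ValueError("de_novo_fraction_b must lie in (0, 1]")
        if self.detection_threshold < 0:
            raise ValueError("detection_threshold must be nonnegative")


@dataclass
class EnrichmentPoint:
    """Corrected enrichment for one subject/day/compartment/cell type."""

    subject_id: str
    phase: int
    study_day: float
    compartment: str
    cell_type: str
    raw_enrichment: float
    net_enrichment: float
    normalized_enrichment: float
    below_detection: bool

    def __post_init__(self) -> None:
        if not math.isfinite(self.normalized_enrichment):
            raise ValueError("normalized_enrichment must be finite")


@dataclass
class PrecursorExposure:
    """Plasma glucose label availability for one subject and phase."""

    subject_id: str
    phase: int
    enrichments: list[float]
    sample_times_min: list[float] = field(default_factory=lambda: [35.0, 185.0, 305.0])
    mean_enrichment: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.enrichments) == 0:
            raise MissingPrecursorError(
                f"no plasma enrichment for subject {self.subject_id} phase {self.phase}"
            )
        self.mean_enrichment = float(np.mean(self.enrichments))
        if not (-0.01 <= self.mean_enrichment <= 1.0):
            raise ValueError(
                f"mean precursor enrichment {self.mean_enrichment} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def compute_ttr(reading: MassSpecReading) -> float:
    """Tracer-to-tracee ratio TTR = (m+2)/m of one reading.

    Raises :class:`UnusableReadingError` when the unlabeled peak is zero or
    missing -- an unusable reading, not a reading with TTR 0.
    """
    m0 = reading.area_m0
    if m0 is None or not math.isfinite(m0) or m0 == 0:
        raise UnusableReadingError(
            f"zero unlabeled peak in sample {reading.sample_id!r}"
        )
    return reading.area_m2 / m0


def fit_calibration(
    standards: Sequence[tuple[float, float]],
) -> CalibrationCurve:
    """Ordinary least-squares standard curve measured_ttr = slope*known + intercept."""
    if len(standards) < 2:
        raise DegenerateDesignError("need at least 2 calibration standards")
    x = np.asarray([s[0] for s in standards], dtype=float)
    y = np.asarray([s[1] for s in standards], dtype=float)
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all known enrichments identical")
    # closed-form simple OLS
    xbar, ybar = x.mean(), y.mean()
    sxx = float(np.sum((x - xbar) ** 2))
    sxy = float(np.sum((x - xbar) * (y - ybar)))
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (slope * x + intercept)
    n = len(x)
    residual_sd = float(np.sqrt(np.sum(resid**2) / (n - 2))) if n > 2 else 0.0
    return CalibrationCurve(
        slope=slope, intercept=intercept, n_standards=n, residual_sd=residual_sd
    )


def ttr_to_enrichment(ttr: float, curve: CalibrationCurve) -> float:
    """Invert the standard curve: enrichment = (ttr - intercept) / slope.

    May return a slightly negative value for noisy readings near background;
    values are never clipped silently.
    """
    if curve.slope <= 0:
        raise InvalidCurveError("calibration slope must be positive")
    return (ttr - curve.intercept) / curve.slope


def subtract_background(enrichment: float, baseline_enrichment: float) -> float:
    """Net enrichment after subtracting the subject's pre-label background."""
    if not (math.isfinite(enrichment) and math.isfinite(baseline_enrichment)):
        raise ValueError("enrichment and baseline must be finite")
    return enrichment - baseline_enrichment


def summarize_precursor(
    samples: Sequence[float],
    *,
    subject_id: str = "",
    phase: int = 1,
    sample_times_min: Sequence[float] | None = None,
) -> PrecursorExposure:
    """Mean plasma glucose enrichment p_bar over the finger-prick samples."""
    if sample_times_min is None:
        sample_times_min = [35.0, 185.0, 305.0][: max(len(samples), 1)]
    return PrecursorExposure(
        subject_id=subject_id,
        phase=phase,
        enrichments=[float(v) for v in samples],
        sample_times_min=[float(t) for t in sample_times_min],
    )


def normalize_enrichment(
    net: float,
    exposure: PrecursorExposure | float,
    constants: CorrectionConstants = CorrectionConstants(),
) -> float:
    """Precursor-product normalization: net / (b * p_bar).

    The result estimates the fraction of cells whose DNA was synthesized
    during the labeling window, correcting for label availability in plasma
    and for the de novo / base-salvage fraction b.
    """
    p_bar = (
        exposure.mean_enrichment
        if isinstance(exposure, PrecursorExposure)
        else float(exposure)
    )
    if p_bar <= 0:
        raise CannotNormalizeError(
            f"mean precursor enrichment must be positive, got {p_bar}"
        )
    return net / (constants.de_novo_fraction_b * p_bar)


# ---------------------------------------------------------------------------
# table-level pipeline
# ---------------------------------------------------------------------------


def _to_dataframe(readings: Iterable[MassSpecReading] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(readings, pd.DataFrame):
        missing = [c for c in READINGS_COLUMNS if c not in readings.columns]
        if missing:
            raise EnrichmentError(f"readings table missing columns: {missing}")
        return readings.copy()
    rows = [vars(r) for r in readings]
    return pd.DataFrame(rows, columns=READINGS_COLUMNS)


def _row_enrichment(row: pd.Series, curve: CalibrationCurve) -> float:
    reading = MassSpecReading(
        sample_id=str(row["sample_id"]),
        subject_id=str(row["subject_id"]),
        study_day=float(row["study_day"]),
        phase=int(row["phase"]),
        compartment=str(row["compartment"]),
        cell_type=str(row["cell_type"]),
        area_m0=float(row["area_m0"]),
        area_m2=float(row["area_m2"]),
        channel_set=str(row["channel_set"]),
    )
    return ttr_to_enrichment(compute_ttr(reading), curve)


def enrichment_pipeline(
    readings: Iterable[MassSpecReading] | pd.DataFrame,
    standards: Mapping[str, Sequence[tuple[float, float]] | CalibrationCurve],
    constants: CorrectionConstants = CorrectionConstants(),
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Run the full correction pipeline over a measurement table.

    Parameters
    ----------
    readings
        Measurement table (rows of :class:`MassSpecReading` or an equivalent
        DataFrame).  Per subject and phase it must contain at least one
        pre-label (study_day < 0) blood DNA baseline and at least one
        during-label plasma glucose reading.
    standards
        Per-channel calibration: mapping from channel_set to either a list of
        (known_enrichment, measured_ttr) standards or a fitted curve.
    constants
        De novo fraction b and detection threshold.

    Returns
    -------
    points, errors
        ``points``: one row per DNA reading with raw, net and normalized
        enrichment and the ``below_detection`` flag.  ``errors``: list of
        (sample_id-or-scope, message); a bad row or subject never aborts the
        rest of the table.
    """
    df = _to_dataframe(readings)
    curves: dict[str, CalibrationCurve] = {}
    for channel, spec in standards.items():
        curves[channel] = (
            spec if isinstance(spec, CalibrationCurve) else fit_calibration(spec)
        )

    points: list[EnrichmentPoint] = []
    errors: list[tuple[str, str]] = []

    for (subject, phase), grp in df.groupby(["subject_id", "phase"], sort=True):
        phase = int(phase)
        try:
            exposure = _subject_precursor(
                grp, curves, subject=str(subject), phase=phase
            )
        except EnrichmentError as exc:
            errors.append((f"{subject}/phase{phase}", str(exc)))
            continue

        dna = grp[grp["channel_set"] == DNA_CHANNEL]
        baselines = dna[(dna["study_day"] < 0) & (dna["compartment"] == "blood")]
        if DNA_CHANNEL not in curves:
            errors.append((f"{subject}/phase{phase}", "no DNA calibration curve"))
            continue
        dna_curve = curves[DNA_CHANNEL]

        baseline_by_cell: dict[str, float] = {}
        baseline_vals: list[float] = []
        for _, row in baselines.iterrows():
            try:
                val = _row_enrichment(row, dna_curve)
            except EnrichmentError as exc:
                errors.append((str(row["sample_id"]), str(exc)))
                continue
            baseline_by_cell[str(row["cell_type"])] = val
            baseline_vals.append(val)
        if not baseline_vals:
            errors.append(
                (
                    f"{subject}/phase{phase}",
                    f"no usable pre-label blood DNA baseline for subject "
                    f"{subject!r} phase {phase}",
                )
            )
            continue
        baseline_any = float(np.mean(baseline_vals))

        for _, row in dna[dna["study_day"] >= 0].iterrows():
            try:
                raw = _row_enrichment(row, dna_curve)
                base = baseline_by_cell.get(str(row["cell_type"]), baseline_any)
                net = subtract_background(raw, base)
                norm = normalize_enrichment(net, exposure, constants)
            except EnrichmentError as exc:
                errors.append((str(row["sample_id"]), str(exc)))
                continue
            points.append(
                EnrichmentPoint(
                    subject_id=str(subject),
                    phase=phase,
                    study_day=float(row["study_day"]),
                    compartment=str(row["compartment"]),
                    cell_type=str(row["cell_type"]),
                    raw_enrichment=raw,
                    net_enrichment=net,
                    normalized_enrichment=norm,
                    below_detection=bool(net < constants.detection_threshold),
                )
            )

    out = pd.DataFrame(
        [vars(p) for p in points],
        columns=[
            "subject_id",
            "phase",
            "study_day",
            "compartment",
            "cell_type",
            "raw_enrichment",
            "net_enrichment",
            "normalized_enrichment",
            "below_detection",
        ],
    )
    return out, errors


def _subject_precursor(
    grp: pd.DataFrame,
    curves: Mapping[str, CalibrationCurve],
    *,
    subject: str,
    phase: int,
) -> PrecursorExposure:
    """Plasma glucose exposure for one subject/phase group of readings."""
    plasma = grp[grp["channel_set"] == GLUCOSE_CHANNEL]
    if GLUCOSE_CHANNEL not in curves:
        raise MissingPrecursorError("no glucose calibration curve")
    curve = curves[GLUCOSE_CHANNEL]
    base_rows = plasma[plasma["study_day"] < 0]
    base = 0.0
    if len(base_rows):
        base = float(
            np.mean([_row_enrichment(r, curve) for _, r in base_rows.iterrows()])
        )
    during = plasma[plasma["study_day"] >= 0]
    if during.empty:
        raise MissingPrecursorError(
            f"no during-label plasma reading for subject {subject!r} phase {phase}"
        )
    vals = [
        subtract_background(_row_enrichment(r, curve), base)
        for _, r in during.iterrows()
    ]
    return PrecursorExposure(subject_id=subject, phase=phase, enrichments=vals)


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_readings_csv(path) -> pd.DataFrame:
    """Read the measurement CSV dialect (comma, header, UTF-8)."""
    df = pd.read_csv(path, dtype={"sample_id": str, "subject_id": str})
    missing = [c for c in READINGS_COLUMNS if c not in df.columns]
    if missing:
        raise EnrichmentError(f"readings CSV missing columns: {missing}")
    return df


def read_standards_csv(path) -> list[tuple[float, float]]:
    """Read a standards CSV with columns known_enrichment, measured_ttr."""
    df = pd.read_csv(path)
    for col in ("known_enrichment", "measured_ttr"):
        if col not in df.columns:
            raise EnrichmentError(f"standards CSV missing column {col!r}")
    return list(zip(df["known_enrichment"].astype(float), df["measured_ttr"].astype(float)))


def write_enrichment_csv(points: pd.DataFrame, path) -> None:
    """Write the EnrichmentPoint table with >= 9 significant digits."""
    points.to_csv(path, index=False, float_format="%.10g")
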