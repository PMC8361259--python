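"""Synthetic two-arm, two-phase deuterium pulse-chase trial generator.

Emulates the study design: 20 patients with eosinophilic asthma randomized
1:1 to mepolizumab (100 mg s.c. every 28 days, first dose 4 days after the
first label intake) or placebo; oral 6,6-2H2-glucose labeling at day 0 and
day 84 (12 half-hourly doses, 1 g/kg total); per subject 10 blood samples
(2 pre-label baselines + 8 post-label, staggered across subjects), 3 sputum
samples and 3 finger-prick plasma samples per labeling at 35/185/305 min.

The generator drives the conveyor-belt forward model per subject and phase,
converts the true enrichment curves into raw GC-MS peak-area pairs (the
inverse of the measurement pipeline), and adds multiplicative measurement
noise.  A truth sidecar (true enrichments and per-subject kinetic
parameters) is emitted separately and is never read by the analysis path.

Treatment effects follow the trial's reported directions: eosinophil
production collapses toward a residual floor within days of dosing,
short-term (phase 1) blood downlabeling is slower, long-term (phase 2)
kinetics are restored, and airway influx is reduced.  Basophils are
unaffected by treatment.  Effect magnitudes are configurable scenario
parameters, not measured rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .conveyor import (
    BASOPHIL_DEFAULTS,
    EOSINOPHIL_DEFAULTS,
    KineticParameters,
    LabelAvailability,
    SimulationGrid,
    simulate_conveyor,
)
from .enrichment import (
    DNA_CHANNEL,
    GLUCOSE_CHANNEL,
    READINGS_COLUMNS,
    CorrectionConstants,
    MassSpecReading,
)

__all__ = [
    "TrialDesign",
    "SubjectProfile",
    "TreatmentScenario",
    "MeasurementTable",
    "NATURAL_BACKGROUND_TTR",
    "SPUTUM_EOS_CUTOFF_PERCENT",
    "default_design",
    "identity_standards",
    "effective_params",
    "generate_subject",
    "emit_ms_readings",
    "generate_trial",
]

#: natural-abundance TTR of the M+2 channel, per derivative (measurement
#: background; subtracted via the subject's own baseline in the pipeline)
NATURAL_BACKGROUND_TTR = {DNA_CHANNEL: 0.006, GLUCOSE_CHANNEL: 0.004}

#: sputum eosinophil percentage defining the eosinophilic-asthma cutoff
SPUTUM_EOS_CUTOFF_PERCENT = 3.0

_POOL_UP = [2, 4, 5, 6, 7]  # uplabeling-window candidate days
_POOL_DOWN = [8, 10, 12, 14]  # early downlabeling days
_POOL_LATE = [18, 22, 27, 32, 42]  # late downlabeling / post-detection days


@dataclass
class TrialDesign:
    """Arms, labeling/dosing schedule and per-subject sampling days.

    ``blood_days[i][phase]`` / ``sputum_days[i][phase]`` are phase-local
    sampling days for subject position ``i`` (shared between the matched
    subjects of the two arms, mirroring the trial's largely-similar time
    points across groups).  Each subject has 10 blood samples in total:
    one pre-label baseline plus four post-label days per phase.
    """

    n_per_arm: int = 10
    arms: tuple[str, str] = ("placebo", "mepolizumab")
    label_days: list[int] = field(default_factory=lambda: [0, 84])
    dose_days: list[int] = field(default_factory=lambda: [4, 32, 60, 88])
    blood_days: dict[int, dict[int, list[int]]] = field(default_factory=dict)
    sputum_days: dict[int, dict[int, list[int]]] = field(default_factory=dict)
    plasma_times_min: list[float] = field(default_factory=lambda: [35.0, 185.0, 305.0])
    baseline_blood_day: float = -0.1
    baseline_plasma_day: float = -0.02

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if self.dose_days[0] - self.label_days[0] != 4:
            raise ValueError("first dose must fall 4 days after the first label")

    def first_dose_offset(self, phase: int) -> float:
        """Days from this phase's label intake to the *first-ever* dose."""
        return self.dose_days[0] - self.label_days[phase - 1]


def default_design(seed: int = 0, n_per_arm: int = 10) -> TrialDesign:
    """Default two-phase design with seed-staggered sampling days.

    Exact per-subject day assignments are not part of the published design
    ("time points varied between volunteers"); they are drawn here
    deterministically from ``seed``, stratified so each subject contributes
    to both the uplabeling and downlabeling windows and the pool
    {2,4,5,6,7,8,10,12,14,18,22,27,32,42} is covered across subjects.
    """
    rng = np.random.default_rng(seed)
    blood: dict[int, dict[int, list[int]]] = {}
    sputum: dict[int, dict[int, list[int]]] = {}
    for phase in (1, 2):
        up = [int(v) for v in rng.permutation(_POOL_UP)]
        down = [int(v) for v in rng.permutation(_POOL_DOWN)]
        late = [int(v) for v in rng.permutation(_POOL_LATE)]
        for i in range(n_per_arm):
            days = sorted(
                {
                    up[(2 * i) % len(up)],
                    up[(2 * i + 1) % len(up)],
                    down[i % len(down)],
                    late[i % len(late)],
                }
            )
            # collisions in the cyclic picks are topped up from the down pool
            j = 0
            while len(days) < 4:
                cand = down[(i + 1 + j) % len(down)]
                if cand not in days:
                    days.append(cand)
                    days.sort()
                j += 1
            blood.setdefault(i, {})[phase] = days
            # sputum is induced on blood-draw days (paired samples): two
            # visits in phase 1 (one early, one late), one in phase 2
            if phase == 1:
                sputum.setdefault(i, {})[phase] = sorted(
                    {days[i % 2], days[2 + (i // 2) % 2]}
                )
            else:
                sputum.setdefault(i, {})[phase] = [days[i % 4]]
    return TrialDesign(n_per_arm=n_per_arm, blood_days=blood, sputum_days=sputum)


@dataclass
class SubjectProfile:
    """One synthetic patient."""

    subject_id: str
    arm: str
    position: int  # matched index within the arm, keys the sampling days
    body_weight_kg: float = 75.0
    baseline_eos_count: float = 0.49  # 1e6/mL
    baseline_baso_count: float = 0.035  # 1e6/mL
    plasma_amplitude: float = 0.05  # p_bar
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_eos_count < 0.25:
            raise ValueError(
                "baseline eosinophil count below the 0.25e6/mL inclusion floor"
            )
        if self.baseline_baso_count <= 0 or self.body_weight_kg <= 0:
            raise ValueError("counts and weight must be positive")


#: arm-specific baseline count medians (1e6/mL)
BASELINE_COUNT_MEDIANS = {
    "placebo": {"eosinophil": 0.49, "basophil": 0.035},
    "mepolizumab": {"eosinophil": 0.40, "basophil": 0.046},
}


@dataclass(frozen=True)
class TreatmentScenario:
    """Configurable anti-IL-5 effect magnitudes and measurement noise.

    The trial reports directions (count collapse within 2 days, slower
    phase-1 downlabeling, restored phase-2 kinetics), not rates; these
    defaults realize those directions with magnitudes the n=10 statistics
    detect.  ``between_subject_cv`` is lognormal inter-subject variability
    applied to the kinetic parameters.
    """

    production_floor: float = 0.1
    production_decay_time: float = 1.0  # days
    phase1_blood_halflife_multiplier: float = 1.8
    phase2_blood_halflife_multiplier: float = 1.0
    airway_influx_multiplier: float = 0.3
    count_noise_cv: float = 0.25
    ms_area_noise_cv: float = 0.02
    between_subject_cv: float = 0.10
    sputum_eos_percent_baseline: float = 8.0

    def __post_init__(self) -> None:
        if not (0.0 < self.production_floor <= 1.0):
            raise ValueError("production_floor must lie in (0, 1]")
        if self.production_decay_time <= 0:
            raise ValueError("production_decay_time must be positive")
        for name in (
            "phase1_blood_halflife_multiplier",
            "phase2_blood_halflife_multiplier",
            "airway_influx_multiplier",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("count_noise_cv", "ms_area_noise_cv", "between_subject_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class MeasurementTable:
    """Full synthetic trial output plus the analysis-blind truth sidecar."""

    readings: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    truth_params: pd.DataFrame
    mfi: pd.DataFrame | None = None


def identity_standards(channel_set: str) -> list[tuple[float, float]]:
    """Standards realizing the generator's calibration: slope 1, natural-background intercept."""
    bg = NATURAL_BACKGROUND_TTR[channel_set]
    return [(e, bg + e) for e in (0.0, 0.01, 0.02, 0.04, 0.08)]


def effective_params(
    base: KineticParameters,
    scenario: TreatmentScenario,
    arm: str,
    phase: int,
    t: float,
) -> KineticParameters:
    """Kinetic parameters in effect ``t`` days after the first dose.

    Placebo (or any untreated state, t < 0) returns ``base`` unchanged.
    Under mepolizumab the production scale relaxes from 1 toward
    ``production_floor`` with time constant ``production_decay_time``, the
    blood half-life is multiplied by the phase-specific multiplier and the
    airway influx by ``airway_influx_multiplier``.
    """
    if arm != "mepolizumab" or t < 0:
        return base
    floor = scenario.production_floor
    ps = floor + (1.0 - floor) * math.exp(-t / scenario.production_decay_time)
    mult = (
        scenario.phase1_blood_halflife_multiplier
        if phase == 1
        else scenario.phase2_blood_halflife_multiplier
    )
    return replace(
        base,
        production_scale=base.production_scale * ps,
        blood_half_life=base.blood_half_life * mult,
        airway_influx_fraction=base.airway_influx_fraction
        * scenario.airway_influx_multiplier,
    )


def emit_ms_readings(
    true_enrichment: float,
    p_bar: float,
    constants: CorrectionConstants,
    total_area: float,
    noise_cv: float,
    rng: np.random.Generator | int,
    *,
    sample_id: str,
    subject_id: str,
    study_day: float,
    phase: int,
    compartment: str,
    cell_type: str,
    channel_set: str = DNA_CHANNEL,
) -> MassSpecReading:
    """Construct a raw peak-area pair whose noise-free analysis recovers the truth.

    For the DNA channel ``true_enrichment`` is the precursor-normalized
    enrichment, so the emitted net TTR excess is ``true_enrichment * b *
    p_bar`` on top of the natural background; the plasma glucose channel
    carries its enrichment directly.  With the identity calibration
    (:func:`identity_standards`) and the subject's own baseline rows, the
    pipeline inverts this construction exactly at zero noise.  Multiplicative
    Gaussian noise with coefficient of variation ``noise_cv`` is applied to
    each peak area independently.
    """
    if true_enrichment < 0:
        raise ValueError("true_enrichment must be nonnegative")
    if true_enrichment > 1:
        raise ValueError("true_enrichment must be <= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    bg = NATURAL_BACKGROUND_TTR[channel_set]
    if channel_set == DNA_CHANNEL:
        net = true_enrichment * constants.de_novo_fraction_b * p_bar
    else:
        net = true_enrichment
    ttr = bg + net
    area_m0 = total_area / (1.0 + ttr)
    area_m2 = ttr * area_m0
    if noise_cv > 0:
        area_m0 *= max(1.0 + noise_cv * rng.standard_normal(), 1e-6)
        area_m2 *= max(1.0 + noise_cv * rng.standard_normal(), 1e-6)
    return MassSpecReading(
        sample_id=sample_id,
        subject_id=subject_id,
        study_day=study_day,
        phase=phase,
        compartment=compartment,
        cell_type=cell_type,
        area_m0=area_m0,
        area_m2=area_m2,
        channel_set=channel_set,
    )


def _subject_kinetics(
    base: KineticParameters, cv: float, rng: np.random.Generator
) -> KineticParameters:
    """Subject-specific kinetic parameters: lognormal scatter around the base."""
    if cv <= 0:
        # keep the stream position identical regardless of cv
        rng.standard_normal(3)
        return base
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    f = np.exp(sigma * rng.standard_normal(3))
    return replace(
        base,
        delay_shift=base.delay_shift * float(f[0]),
        delay_mean_extra=base.delay_mean_extra * float(f[1]),
        blood_half_life=base.blood_half_life * float(f[2]),
    )


def _lognormal_noise(value: float, cv: float, rng: np.random.Generator) -> float:
    """Lognormal draw with median ``value`` (exact truth at cv = 0)."""
    if cv <= 0:
        return value
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return value * math.exp(sigma * rng.standard_normal())


def generate_subject(
    profile: SubjectProfile,
    design: TrialDesign,
    base_params: Mapping[str, KineticParameters],
    scenario: TreatmentScenario,
    grid: SimulationGrid = SimulationGrid(),
    constants: CorrectionConstants = CorrectionConstants(),
    *,
    cell_types: tuple[str, ...] = ("eosinophil", "basophil"),
    include_sputum: bool = True,
    total_area: float = 2.0e5,
) -> dict[str, list]:
    """Simulate one subject's truth curves and sample noisy measurements.

    Reproducible from ``profile.seed``.  Returns lists of reading rows,
    count rows and truth rows.  The treatment scenario acts on the
    eosinophil lineage only; basophils are placebo-like in either arm.
    """
    rng = np.random.default_rng(profile.seed)
    avail = LabelAvailability(amplitude=profile.plasma_amplitude)
    treated_arm = profile.arm == "mepolizumab"

    subject_params = {
        ct: _subject_kinetics(base_params[ct], scenario.between_subject_cv, rng)
        for ct in cell_types
    }
    baseline_counts = {
        "eosinophil": profile.baseline_eos_count,
        "basophil": profile.baseline_baso_count,
    }

    readings: list[dict] = []
    counts: list[dict] = []
    truth: list[dict] = []
    params_rows: list[dict] = []

    def emit(true_e, day, phase, compartment, cell_type, channel, tag):
        r = emit_ms_readings(
            true_e,
            profile.plasma_amplitude,
            constants,
            total_area,
            scenario.ms_area_noise_cv,
            rng,
            sample_id=f"{profile.subject_id}-p{phase}-{tag}",
            subject_id=profile.subject_id,
            study_day=day,
            phase=phase,
            compartment=compartment,
            cell_type=cell_type,
            channel_set=channel,
        )
        readings.append(vars(r))

    for phase in (1, 2):
        dose_offset = design.first_dose_offset(phase)
        curves: dict[tuple[str, str], object] = {}
        for ct in cell_types:
            p = subject_params[ct]
            treated = treated_arm and ct == "eosinophil"
            if treated:
                eff_inf = effective_params(p, scenario, profile.arm, phase, 1e9)

                def ps_fn(t, _p=p):
                    td = np.asarray(t, dtype=float) - dose_offset
                    floor = scenario.production_floor
                    out = floor + (1.0 - floor) * np.exp(
                        -np.maximum(td, 0.0) / scenario.production_decay_time
                    )
                    return np.where(td < 0, 1.0, out) * _p.production_scale

                mult = (
                    scenario.phase1_blood_halflife_multiplier
                    if phase == 1
                    else scenario.phase2_blood_halflife_multiplier
                )

                hl_fn = None
                if mult != 1.0:

                    def hl_fn(t, _p=p, _m=mult):
                        td = np.asarray(t, dtype=float) - dose_offset
                        return np.where(td < 0, _p.blood_half_life, _p.blood_half_life * _m)

                sim_params = replace(
                    p, airway_influx_fraction=eff_inf.airway_influx_fraction
                )
                sol = simulate_conveyor(
                    sim_params, avail, grid, production_scale_fn=ps_fn, half_life_fn=hl_fn
                )
            else:
                sol = simulate_conveyor(p, avail, grid)
            curves[("blood", ct)] = sol.blood
            if ct == "eosinophil":
                curves[("sputum", ct)] = sol.airway
            params_rows.append(
                {
                    "subject_id": profile.subject_id,
                    "phase": phase,
                    "cell_type": ct,
                    "delay_shift": p.delay_shift,
                    "delay_mean_extra": p.delay_mean_extra,
                    "blood_half_life": p.blood_half_life,
                    "treated": treated,
                }
            )

        # --- plasma glucose: baseline + three during-label finger pricks
        emit(0.0, design.baseline_plasma_day, phase, "plasma", "none",
             GLUCOSE_CHANNEL, "plasma-base")
        for j, tmin in enumerate(design.plasma_times_min):
            emit(profile.plasma_amplitude, tmin / 1440.0, phase, "plasma", "none",
                 GLUCOSE_CHANNEL, f"plasma-{j}")

        # --- blood DNA: baseline + staggered post-label days, both cell types
        blood_days = design.blood_days.get(profile.position, {}).get(phase, [])
        for ct in cell_types:
            emit(0.0, design.baseline_blood_day, phase, "blood", ct,
                 DNA_CHANNEL, f"dna-base-{ct[:3]}")
        for day in blood_days:
            for ct in cell_types:
                true_e = float(curves[("blood", ct)].at(day))
                emit(true_e, float(day), phase, "blood", ct, DNA_CHANNEL,
                     f"dna-d{day}-{ct[:3]}")
                truth.append(
                    {
                        "subject_id": profile.subject_id,
                        "arm": profile.arm,
                        "phase": phase,
                        "study_day": float(day),
                        "compartment": "blood",
                        "cell_type": ct,
                        "true_normalized_enrichment": true_e,
                    }
                )

        # --- sputum DNA (eosinophils only)
        if include_sputum and "eosinophil" in cell_types:
            for day in design.sputum_days.get(profile.position, {}).get(phase, []):
                true_e = float(curves[("sputum", "eosinophil")].at(day))
                emit(true_e, float(day), phase, "sputum", "eosinophil", DNA_CHANNEL,
                     f"dna-s{day}-eos")
                truth.append(
                    {
                        "subject_id": profile.subject_id,
                        "arm": profile.arm,
                        "phase": phase,
                        "study_day": float(day),
                        "compartment": "sputum",
                        "cell_type": "eosinophil",
                        "true_normalized_enrichment": true_e,
                    }
                )

        # --- absolute counts at every blood visit (quasi-steady count model:
        # the rapid post-dose count collapse is margination/clearance-driven
        # and tracks the effective production scale, not the delayed conveyor)
        for day in [design.baseline_blood_day] + [float(d) for d in blood_days]:
            td = day - dose_offset
            for ct in cell_types:
                factor = 1.0
                if treated_arm and ct == "eosinophil" and td >= 0:
                    floor = scenario.production_floor
                    factor = floor + (1.0 - floor) * math.exp(
                        -td / scenario.production_decay_time
                    )
                val = _lognormal_noise(
                    baseline_counts[ct] * factor, scenario.count_noise_cv, rng
                )
                counts.append(
                    {
                        "subject_id": profile.subject_id,
                        "arm": profile.arm,
                        "phase": phase,
                        "study_day": day,
                        "compartment": "blood",
                        "cell_type": ct,
                        "value": val,
                        "units": "1e6/mL",
                    }
                )
        if include_sputum:
            for day in design.sputum_days.get(profile.position, {}).get(phase, []):
                td = day - dose_offset
                factor = 1.0
                if treated_arm and td >= 0:
                    floor = scenario.production_floor
                    factor = floor + (1.0 - floor) * math.exp(
                        -td / scenario.production_decay_time
                    )
                val = _lognormal_noise(
                    scenario.sputum_eos_percent_baseline * factor,
                    scenario.count_noise_cv,
                    rng,
                )
                counts.append(
                    {
                        "subject_id": profile.subject_id,
                        "arm": profile.arm,
                        "phase": phase,
                        "study_day": float(day),
                        "compartment": "sputum",
                        "cell_type": "eosinophil",
                        "value": val,
                        "units": "percent_of_granulocytes",
                    }
                )

    return {
        "readings": readings,
        "counts": counts,
        "truth": truth,
        "truth_params": params_rows,
    }


def generate_trial(
    design: TrialDesign,
    base_params: Mapping[str, KineticParameters] | None = None,
    scenario: TreatmentScenario = TreatmentScenario(),
    master_seed: int = 0,
    grid: SimulationGrid = SimulationGrid(),
    constants: CorrectionConstants = CorrectionConstants(),
    *,
    cell_types: tuple[str, ...] = ("eosinophil", "basophil"),
    include_sputum: bool = True,
    include_mfi: bool = False,
) -> MeasurementTable:
    """Generate the full two-arm, two-phase measurement table.

    Subject seeds and profiles are derived deterministically from
    ``master_seed``: the same seed reproduces the table bit for bit.
    """
    if base_params is None:
        base_params = {
            "eosinophil": EOSINOPHIL_DEFAULTS,
            "basophil": BASOPHIL_DEFAULTS,
        }
    master = np.random.default_rng(master_seed)
    readings: list[dict] = []
    counts: list[dict] = []
    truth: list[dict] = []
    params_rows: list[dict] = []
    mfi_rows: list[dict] = []

    for arm in design.arms:
        prefix = "P" if arm == "placebo" else "M"
        for i in range(design.n_per_arm):
            medians = BASELINE_COUNT_MEDIANS[arm]
            eos = 0.0
            for _ in range(200):  # inclusion floor 0.25e6/mL enforced at generation
                eos = _lognormal_noise(medians["eosinophil"], 0.6, master)
                if eos >= 0.25:
                    break
            eos = max(eos, 0.25)
            profile = SubjectProfile(
                subject_id=f"{prefix}{i + 1:02d}",
                arm=arm,
                position=i,
                body_weight_kg=float(
                    np.clip(75.0 * math.exp(0.15 * master.standard_normal()), 45, 140)
                ),
                baseline_eos_count=eos,
                baseline_baso_count=_lognormal_noise(medians["basophil"], 0.5, master),
                plasma_amplitude=float(
                    np.clip(_lognormal_noise(0.05, 0.1, master), 0.01, 0.2)
                ),
                seed=int(master.integers(0, 2**31 - 1)),
            )
            sub = generate_subject(
                profile,
                design,
                base_params,
                scenario,
                grid,
                constants,
                cell_types=cell_types,
                include_sputum=include_sputum,
            )
            readings.extend(sub["readings"])
            counts.extend(sub["counts"])
            truth.extend(sub["truth"])
            params_rows.extend(sub["truth_params"])
            if include_mfi:
                # arm-level distribution draws only, for exercising rank tests
                rng = np.random.default_rng(profile.seed + 1)
                il5ra = 1000.0 * (0.45 if arm == "mepolizumab" else 1.0)
                for ct in cell_types:
                    mfi_rows.append(
                        {
                            "subject_id": profile.subject_id,
                            "arm": arm,
                            "cell_type": ct,
                            "marker": "IL5RA",
                            "mfi": _lognormal_noise(il5ra, 0.3, rng),
                        }
                    )

    return MeasurementTable(
        readings=pd.DataFrame(readings, columns=READINGS_COLUMNS),
        counts=pd.DataFrame(counts),
        truth=pd.DataFrame(truth),
        truth_params=pd.DataFrame(params_rows),
        mfi=pd.DataFrame(mfi_rows) if include_mfi else None,
    )
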