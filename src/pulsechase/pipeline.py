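"""Run orchestration: simulate -> enrich -> analyze -> report.

A :class:`RunConfig` (YAML round-trippable, dotted-key overridable) fully
determines a run together with its master seed; every command writes a
machine-readable provenance record next to its outputs.  Results go to
files; logging goes to stderr.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import conveyor, enrichment, stats, synthesis

__all__ = [
    "RunConfig",
    "SchemaError",
    "DataError",
    "cmd_simulate",
    "cmd_enrich",
    "cmd_analyze",
    "cmd_report",
]

log = logging.getLogger("pulsechase")

EXIT_SCHEMA = 2
EXIT_DATA = 3


class SchemaError(ValueError):
    """Input file does not match the expected schema (exit code 2)."""


class DataError(ValueError):
    """Input data are missing or unusable (exit code 3)."""


def _scenario_defaults() -> dict:
    return dataclasses.asdict(synthesis.TreatmentScenario())


def _kinetics_defaults() -> dict:
    return {
        ct: dataclasses.asdict(conveyor.default_parameters(ct))
        for ct in ("eosinophil", "basophil")
    }


@dataclass
class RunConfig:
    """Complete configuration of a pipeline run.

    Defaults reproduce the documented study conditions; any field can be
    overridden via a config file or ``--override section.key=value``.
    """

    master_seed: int = 0
    out_dir: str = "pulsechase_run"
    log_level: str = "INFO"
    constants: dict = field(
        default_factory=lambda: {
            "de_novo_fraction_b": 0.65,
            "detection_threshold": 0.0005,
        }
    )
    design: dict = field(default_factory=lambda: {"n_per_arm": 10})
    scenario: dict = field(default_factory=_scenario_defaults)
    kinetics: dict = field(default_factory=_kinetics_defaults)
    grid: dict = field(default_factory=lambda: {"dt": 0.1, "horizon": 60.0})
    windows: dict = field(
        default_factory=lambda: {"up": [0.0, 7.0], "down": [8.0, 22.0]}
    )

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls()
        known = {f.name for f in dataclasses.fields(cls)}
        for key, value in d.items():
            if key not in known:
                raise SchemaError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                merged = dict(current)
                for k, v in value.items():
                    if isinstance(merged.get(k), dict) and isinstance(v, dict):
                        merged[k] = {**merged[k], **v}
                    else:
                        merged[k] = v
                setattr(cfg, key, merged)
            else:
                setattr(cfg, key, value)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        p = Path(path)
        if not p.exists():
            raise DataError(f"config file not found: {p}")
        return cls.from_dict(yaml.safe_load(p.read_text()) or {})

    def apply_override(self, spec: str) -> None:
        """Apply a ``section.key=value`` (or ``key=value``) override."""
        if "=" not in spec:
            raise SchemaError(f"override must be key=value, got {spec!r}")
        key, raw = spec.split("=", 1)
        value = yaml.safe_load(raw)
        parts = key.strip().split(".")
        if len(parts) == 1:
            if not hasattr(self, parts[0]):
                raise SchemaError(f"unknown config key {parts[0]!r}")
            setattr(self, parts[0], value)
            return
        target: Any = getattr(self, parts[0], None)
        if not isinstance(target, dict):
            raise SchemaError(f"unknown config section {parts[0]!r}")
        for p in parts[1:-1]:
            if p not in target or not isinstance(target[p], dict):
                raise SchemaError(f"unknown config key {key!r}")
            target = target[p]
        target[parts[-1]] = value

    # -- typed accessors ---------------------------------------------------
    def correction_constants(self) -> enrichment.CorrectionConstants:
        return enrichment.CorrectionConstants(**self.constants)

    def treatment_scenario(self) -> synthesis.TreatmentScenario:
        return synthesis.TreatmentScenario(**self.scenario)

    def simulation_grid(self) -> conveyor.SimulationGrid:
        return conveyor.SimulationGrid(**self.grid)

    def kinetic_parameters(self) -> dict[str, conveyor.KineticParameters]:
        return {
            ct: conveyor.KineticParameters(**params)
            for ct, params in self.kinetics.items()
        }

    def phase_windows(self) -> stats.PhaseWindows:
        return stats.PhaseWindows(
            up=tuple(self.windows["up"]), down=tuple(self.windows["down"])
        )


def _package_version() -> str:
    try:
        from importlib.metadata import version

        return version("pulsechase")
    except Exception:  # pragma: no cover
        return "unknown"


def _write_provenance(cfg: RunConfig, out: Path, command: str) -> None:
    record = {
        "command": command,
        "master_seed": cfg.master_seed,
        "package_version": _package_version(),
        "config": cfg.to_dict(),
    }
    (out / f"provenance_{command}.json").write_text(json.dumps(record, indent=2))


def _out_dir(cfg: RunConfig) -> Path:
    out = Path(cfg.out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise DataError(f"cannot create output directory {out}: {exc}") from exc
    return out


def _require(path: Path) -> Path:
    if not path.exists():
        raise DataError(f"missing input file: {path}")
    return path


# ---------------------------------------------------------------------------
# commands
# ---------------------------------------------------------------------------


def cmd_simulate(cfg: RunConfig) -> dict[str, Path]:
    """Generate the synthetic trial and write measurement + sidecar files."""
    out = _out_dir(cfg)
    design = synthesis.default_design(
        seed=cfg.master_seed, n_per_arm=int(cfg.design.get("n_per_arm", 10))
    )
    table = synthesis.generate_trial(
        design,
        cfg.kinetic_parameters(),
        cfg.treatment_scenario(),
        master_seed=cfg.master_seed,
        grid=cfg.simulation_grid(),
        constants=cfg.correction_constants(),
    )
    paths = {
        "measurements": out / "measurements.csv",
        "counts": out / "counts.csv",
        "truth": out / "truth.csv",
        "truth_params": out / "truth_params.csv",
        "standards_dna": out / "standards_dna.csv",
        "standards_glucose": out / "standards_glucose.csv",
        "design": out / "design.yaml",
    }
    table.readings.to_csv(paths["measurements"], index=False, float_format="%.10g")
    table.counts.to_csv(paths["counts"], index=False, float_format="%.10g")
    table.truth.to_csv(paths["truth"], index=False, float_format="%.10g")
    table.truth_params.to_csv(paths["truth_params"], index=False, float_format="%.10g")
    for channel, key in (
        (enrichment.DNA_CHANNEL, "standards_dna"),
        (enrichment.GLUCOSE_CHANNEL, "standards_glucose"),
    ):
        pd.DataFrame(
            synthesis.identity_standards(channel),
            columns=["known_enrichment", "measured_ttr"],
        ).to_csv(paths[key], index=False, float_format="%.10g")
    design_doc = {
        "n_per_arm": design.n_per_arm,
        "arms": list(design.arms),
        "label_days": design.label_days,
        "dose_days": design.dose_days,
        "plasma_times_min": design.plasma_times_min,
        "blood_days": design.blood_days,
        "sputum_days": design.sputum_days,
    }
    paths["design"].write_text(yaml.safe_dump(design_doc, sort_keys=True))
    _write_provenance(cfg, out, "simulate")
    log.info("simulated %d readings for %d subjects (seed %d)",
             len(table.readings), 2 * design.n_per_arm, cfg.master_seed)
    return paths


def cmd_enrich(cfg: RunConfig) -> dict[str, Path]:
    """Run the enrichment correction pipeline over the measurement table."""
    out = _out_dir(cfg)
    readings = enrichment.read_readings_csv(_require(out / "measurements.csv"))
    standards = {
        enrichment.DNA_CHANNEL: enrichment.read_standards_csv(
            _require(out / "standards_dna.csv")
        ),
        enrichment.GLUCOSE_CHANNEL: enrichment.read_standards_csv(
            _require(out / "standards_glucose.csv")
        ),
    }
    if len(readings) == 0:
        raise DataError("measurements file contains no rows")
    points, errors = enrichment.enrichment_pipeline(
        readings, standards, cfg.correction_constants()
    )
    for scope, message in errors:
        log.warning("enrichment error [%s]: %s", scope, message)
    n_dna = int((readings["channel_set"] == enrichment.DNA_CHANNEL).sum())
    if n_dna and len(points) < 0.5 * (
        n_dna - int(
            (
                (readings["channel_set"] == enrichment.DNA_CHANNEL)
                & (readings["study_day"] < 0)
            ).sum()
        )
    ):
        raise DataError(
            f"more than half of the DNA readings failed ({len(errors)} errors)"
        )
    path = out / "enrichment.csv"
    enrichment.write_enrichment_csv(points, path)
    _write_provenance(cfg, out, "enrich")
    log.info("wrote %d enrichment points (%d row errors)", len(points), len(errors))
    return {"enrichment": path}


def _arm_map(counts: pd.DataFrame) -> dict[str, str]:
    return dict(zip(counts["subject_id"].astype(str), counts["arm"].astype(str)))


_REGRESSION_TARGETS = [
    ("blood", "eosinophil"),
    ("sputum", "eosinophil"),
    ("blood", "basophil"),
]


def cmd_analyze(cfg: RunConfig) -> dict[str, Path]:
    """Group comparisons: ANCOVA per window, rank tests, dilution ratios."""
    out = _out_dir(cfg)
    enr = pd.read_csv(_require(out / "enrichment.csv"))
    counts = pd.read_csv(_require(out / "counts.csv"))
    for frame, cols, name in (
        (enr, ["subject_id", "phase", "study_day", "compartment", "cell_type",
               "normalized_enrichment"], "enrichment"),
        (counts, ["subject_id", "arm", "phase", "study_day", "compartment",
                  "cell_type", "value"], "counts"),
    ):
        missing = [c for c in cols if c not in frame.columns]
        if missing:
            raise SchemaError(f"{name} file missing columns: {missing}")
    arm_of = _arm_map(counts)
    enr = enr.assign(arm=enr["subject_id"].astype(str).map(arm_of))
    if enr["arm"].isna().any():
        raise DataError("subjects in enrichment.csv without an arm in counts.csv")
    windows = cfg.phase_windows()
    threshold = cfg.correction_constants().detection_threshold
    arms = ("placebo", "mepolizumab")

    rows: list[dict] = []

    def add(test, phase, compartment, cell_type, window, statistic, p, method,
            n, flags=""):
        rows.append(
            {
                "test": test,
                "phase": phase,
                "compartment": compartment,
                "cell_type": cell_type,
                "window_or_day": window,
                "groups": "placebo_vs_mepolizumab",
                "statistic": statistic,
                "p_value": p,
                "method": method,
                "n": n,
                "flags": flags,
            }
        )

    # --- phase-wise regression comparisons
    for compartment, cell_type in _REGRESSION_TARGETS:
        sub = enr[(enr["compartment"] == compartment) & (enr["cell_type"] == cell_type)]
        for phase in sorted(sub["phase"].unique()):
            grp = sub[sub["phase"] == phase]
            pts = {
                arm: list(
                    zip(
                        grp.loc[grp["arm"] == arm, "study_day"],
                        grp.loc[grp["arm"] == arm, "normalized_enrichment"],
                    )
                )
                for arm in arms
            }
            comparison = stats.compare_phase_regressions(
                pts[arms[0]], pts[arms[1]], windows
            )
            for label in ("up", "down"):
                wc = getattr(comparison, label)
                if wc is None:
                    add(
                        "ancova_slope", phase, compartment, cell_type, label,
                        float("nan"), float("nan"), "not_computable", 0,
                        comparison.not_computable.get(label, ""),
                    )
                    continue
                add("ancova_slope", phase, compartment, cell_type, label,
                    wc.f_slope, wc.p_slope, "ancova_f", wc.n_a + wc.n_b,
                    ";".join(wc.flags))
                add("ancova_elevation", phase, compartment, cell_type, label,
                    wc.f_elev, wc.p_elev, "ancova_f", wc.n_a + wc.n_b,
                    ";".join(wc.flags))

    # --- per-day count rank tests (blood compartment)
    blood_counts = counts[counts["compartment"] == "blood"]
    for (phase, cell_type, day), grp in blood_counts.groupby(
        ["phase", "cell_type", "study_day"]
    ):
        x = grp.loc[grp["arm"] == arms[0], "value"].to_numpy()
        y = grp.loc[grp["arm"] == arms[1], "value"].to_numpy()
        if len(x) == 0 or len(y) == 0:
            continue
        res = stats.rank_sum_test(x, y)
        add("mann_whitney_count", phase, "blood", cell_type, f"day {day:g}",
            res.statistic, res.p_value, res.method, len(x) + len(y),
            ";".join(res.flags))

    # --- paired blood-vs-sputum signed-rank tests on enrichment
    eos = enr[enr["cell_type"] == "eosinophil"]
    for (arm, phase), grp in eos.groupby(["arm", "phase"]):
        blood = grp[grp["compartment"] == "blood"].set_index(
            ["subject_id", "study_day"]
        )["normalized_enrichment"]
        sputum = grp[grp["compartment"] == "sputum"].set_index(
            ["subject_id", "study_day"]
        )["normalized_enrichment"]
        common = blood.index.intersection(sputum.index)
        if len(common) == 0:
            continue
        pairs = [(float(blood[i]), float(sputum[i])) for i in common]
        res = stats.signed_rank_test(pairs)
        rows.append(
            {
                "test": "wilcoxon_blood_vs_sputum",
                "phase": phase,
                "compartment": "blood_vs_sputum",
                "cell_type": "eosinophil",
                "window_or_day": "paired_days",
                "groups": arm,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "n": len(pairs),
                "flags": ";".join(res.flags),
            }
        )

    # --- per-day group medians / IQR (figure-ready) and dilution ratios
    med_rows: list[dict] = []
    for (phase, compartment, cell_type, arm, day), grp in enr.groupby(
        ["phase", "compartment", "cell_type", "arm", "study_day"]
    ):
        v = grp["normalized_enrichment"].to_numpy()
        med_rows.append(
            {
                "phase": phase,
                "compartment": compartment,
                "cell_type": cell_type,
                "arm": arm,
                "study_day": day,
                "n": len(v),
                "median": float(np.median(v)),
                "q1": float(np.percentile(v, 25)),
                "q3": float(np.percentile(v, 75)),
            }
        )
    medians = pd.DataFrame(med_rows)

    dil_rows: list[dict] = []
    for (arm, compartment), grp in medians[
        (medians["cell_type"] == "eosinophil") & (medians["phase"] == 1)
    ].groupby(["arm", "compartment"]):
        series = list(zip(grp["study_day"], grp["median"]))
        try:
            dil = stats.dilution_ratio(series, ref_day=7.0,
                                       detection_threshold=threshold)
        except stats.NotComputableError as exc:
            dil_rows.append(
                {"arm": arm, "compartment": compartment, "study_day": float("nan"),
                 "ratio": float("nan"), "note": str(exc)}
            )
            continue
        for d, r in zip(dil.days, dil.ratios):
            dil_rows.append(
                {"arm": arm, "compartment": compartment, "study_day": d,
                 "ratio": r, "note": ""}
            )

    paths = {
        "results": out / "results.tsv",
        "medians": out / "medians.csv",
        "dilution": out / "dilution_ratios.csv",
    }
    pd.DataFrame(rows).to_csv(paths["results"], sep="\t", index=False,
                              float_format="%.10g")
    medians.to_csv(paths["medians"], index=False, float_format="%.10g")
    pd.DataFrame(dil_rows).to_csv(paths["dilution"], index=False,
                                  float_format="%.10g")
    _write_provenance(cfg, out, "analyze")
    log.info("analysis wrote %d test rows", len(rows))
    return paths


def cmd_report(cfg: RunConfig) -> Path:
    """Human-readable summary of detection days, slopes, p-values, ratios."""
    out = _out_dir(cfg)
    results = pd.read_csv(_require(out / "results.tsv"), sep="\t")
    medians = pd.read_csv(_require(out / "medians.csv"))
    dilution = pd.read_csv(_require(out / "dilution_ratios.csv"))
    threshold = cfg.correction_constants().detection_threshold

    lines = ["# Pulse-chase analysis report", ""]
    lines.append("## Label detection windows (group medians vs. threshold "
                 f"{threshold:g})")
    for (phase, compartment, cell_type, arm), grp in medians.groupby(
        ["phase", "compartment", "cell_type", "arm"]
    ):
        post = grp[grp["study_day"] >= 0].sort_values("study_day")
        detected = post[post["median"] >= threshold]["study_day"]
        if len(detected):
            lines.append(
                f"- phase {phase} {compartment} {cell_type} ({arm}): label "
                f"detected from day {detected.min():g} to day {detected.max():g}"
            )
        else:
            lines.append(
                f"- phase {phase} {compartment} {cell_type} ({arm}): "
                "never above the detection threshold"
            )
    lines.append("")
    lines.append("## Regression comparisons (placebo vs mepolizumab)")
    reg = results[results["test"].isin(["ancova_slope", "ancova_elevation"])]
    for _, r in reg.iterrows():
        lines.append(
            f"- {r['test']} phase {r['phase']} {r['compartment']} "
            f"{r['cell_type']} [{r['window_or_day']}]: F = {r['statistic']:.4g}, "
            f"p = {r['p_value']:.4g} ({r['method']}, n = {r['n']})"
        )
    lines.append("")
    lines.append("## Per-day count comparisons (Mann-Whitney)")
    mw = results[results["test"] == "mann_whitney_count"]
    for _, r in mw.iterrows():
        lines.append(
            f"- phase {r['phase']} {r['cell_type']} {r['window_or_day']}: "
            f"U = {r['statistic']:g}, p = {r['p_value']:.4g} ({r['method']})"
        )
    lines.append("")
    lines.append("## Paired blood vs sputum (Wilcoxon signed-rank)")
    wx = results[results["test"] == "wilcoxon_blood_vs_sputum"]
    for _, r in wx.iterrows():
        lines.append(
            f"- phase {r['phase']} {r['groups']}: W+ = {r['statistic']:g}, "
            f"p = {r['p_value']:.4g} ({r['method']}, n = {r['n']})"
        )
    lines.append("")
    lines.append("## Dilution ratios (reference day 7)")
    for (arm, compartment), grp in dilution.groupby(["arm", "compartment"]):
        noted = grp[grp["note"].notna() & (grp["note"] != "")]
        if len(noted):
            lines.append(f"- {arm} {compartment}: {noted.iloc[0]['note']}")
            continue
        pts = ", ".join(
            f"day {d:g}: {r:.3f}"
            for d, r in zip(grp["study_day"], grp["ratio"])
        )
        lines.append(f"- {arm} {compartment}: {pts}")
    lines.append("")

    path = out / "report.md"
    path.write_text("\n".join(lines))
    _write_provenance(cfg, out, "report")
    return path
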