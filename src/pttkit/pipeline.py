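"""End-to-end orchestration: simulate → extract → estimate → evaluate.

One :func:`run_pipeline` call covers the three entry points:

* ``simulate`` — draw a synthetic cohort, synthesize one RV/LV curve pair
  per patient (transport delay set to the patient's drawn PTT), measure
  peak-to-peak PTT from the curves, and run the full diagnostic evaluation
  on the *measured* values.
* ``curves`` — measure PTT from existing curve CSV files.
* ``cohort`` — run the diagnostic evaluation on an existing cohort CSV.

All randomness is funneled through the single run seed; rerunning with the
same config reproduces every output file byte for byte (no timestamps are
written).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .curves import read_curves_csv, write_curves_csv
from .ptt import PeakConfig, compute_ptt
from .synthetic import (
    BolusParams,
    CohortParams,
    PatientRecord,
    cohort_to_dataframe,
    read_cohort_csv,
    simulate_cohort,
    simulate_curve_pair,
    write_cohort_csv,
)

__all__ = ["RunConfig", "RunReport", "PipelineError", "run_pipeline", "evaluate_cohort"]

logger = logging.getLogger(__name__)

MODES = ("simulate", "curves", "cohort")
SCORES = ("ptt_s", "nptt")
OUTCOMES = ("dd_relevant", "mvr_relevant", "dd_or_mvr")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (seed mandatory)."""

    mode: str
    seed: int
    out_dir: Path
    peak: PeakConfig = field(default_factory=PeakConfig)
    cohort: CohortParams | None = None
    bolus: BolusParams | None = None
    curves_csv: tuple[str, ...] = ()
    cohort_csv: str | None = None
    edges: tuple[float, float] = (8.0, 12.0)
    n_boot: int = 2000
    alpha: float = 0.05
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        if self.mode == "curves" and not self.curves_csv:
            raise ValueError("curves mode needs at least one curves_csv path")
        if self.mode == "cohort" and not self.cohort_csv:
            raise ValueError("cohort mode needs a cohort_csv path")
        for p in (*self.curves_csv, *( [self.cohort_csv] if self.cohort_csv else [] )):
            if not Path(p).exists():
                raise ValueError(f"input path does not exist: {p}")

    @classmethod
    def from_json(cls, path, **overrides) -> "RunConfig":
        """Build a config from a JSON file; file values take precedence
        over keyword fallbacks."""
        with open(path) as fh:
            data = json.load(fh)
        merged = {**overrides, **data}
        if "peak" in merged and isinstance(merged["peak"], dict):
            merged["peak"] = PeakConfig(**merged["peak"])
        if "cohort" in merged and isinstance(merged["cohort"], dict):
            merged["cohort"] = CohortParams(**merged["cohort"])
        if "bolus" in merged and isinstance(merged["bolus"], dict):
            merged["bolus"] = BolusParams(**merged["bolus"])
        if "curves_csv" in merged:
            merged["curves_csv"] = tuple(merged["curves_csv"])
        if "edges" in merged:
            merged["edges"] = tuple(merged["edges"])
        return cls(**merged)

    def to_canonical_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        d["edges"] = list(self.edges)
        d["curves_csv"] = list(self.curves_csv)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_canonical_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass(frozen=True)
class RunReport:
    """Files written by a run plus an in-memory summary."""

    files: dict
    summary: dict
    config_hash: str


def _write_json(path: Path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def evaluate_cohort(
    records, edges=(8.0, 12.0), n_boot: int = 2000, alpha: float = 0.05, seed: int = 0
) -> dict:
    """Full diagnostic evaluation of a cohort.

    For each score (PTT, nPTT) and each outcome (relevant DD, relevant MVR,
    their union): AUC with stratified-bootstrap CI and rank-sum p-value,
    and thresholds reaching 70% specificity and 70% sensitivity.  Plus the
    PTT stratification table over ``edges`` for the union outcome, and the
    nPTT quartile table.
    """
    df = records if isinstance(records, pd.DataFrame) else cohort_to_dataframe(list(records))
    out: dict = {"aucs": {}, "thresholds": {}}
    for score in SCORES:
        scores = df[score].to_numpy(float)
        for outcome in OUTCOMES:
            labels = dx._outcome_column(df, outcome)
            key = f"{score}:{outcome}"
            if labels.all() or not labels.any():
                logger.warning("outcome %s has a single class; skipping AUC", outcome)
                continue
            out["aucs"][key] = dx.evaluate_auc(
                scores, labels, n_boot=n_boot, alpha=alpha, seed=seed
            )
            thr_sp, m_sp = dx.threshold_at_specificity(scores, labels, 0.70)
            thr_se, m_se = dx.threshold_at_sensitivity(scores, labels, 0.70)
            out["thresholds"][key] = {
                "at_specificity_0.70": m_sp.to_dict(),
                "at_sensitivity_0.70": m_se.to_dict(),
            }
    out["stratum_table"] = dx.stratify_by_ptt(df, edges=edges, outcome="dd_or_mvr")
    out["quartiles"] = dx.quartile_table(df, variable="nptt")
    return out


def _write_evaluation(out_dir: Path, ev: dict, files: dict) -> dict:
    results = {
        "aucs": {k: v.to_dict() for k, v in ev["aucs"].items()},
        "thresholds": ev["thresholds"],
        "stratum_table": {
            "edges": list(ev["stratum_table"].edges),
            "n": list(ev["stratum_table"].n),
            "n_positive": list(ev["stratum_table"].n_positive),
            "pct_positive": list(ev["stratum_table"].pct_positive),
            "pooled_pct_above_first_edge": ev["stratum_table"].pooled_percent_above_first_edge(),
        },
        "quartile_boundaries": list(ev["quartiles"].boundaries),
        "quartile_sizes": list(ev["quartiles"].sizes),
    }
    _write_json(out_dir / "results.json", results)
    ev["stratum_table"].to_dataframe().to_csv(out_dir / "stratum_table.csv", index=False)
    ev["quartiles"].summary.to_csv(out_dir / "quartile_table.csv", index=False)
    files["results"] = out_dir / "results.json"
    files["stratum_table"] = out_dir / "stratum_table.csv"
    files["quartile_table"] = out_dir / "quartile_table.csv"
    return results


def _measure_pair(rv, lv, peak_cfg: PeakConfig):
    return compute_ptt(rv, lv, rr_s=None, config=peak_cfg)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute one configured run; see module docstring for the modes."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict = {}
    summary: dict = {"mode": config.mode, "seed": config.seed}

    try:
        if config.mode == "simulate":
            _run_simulate(config, out_dir, files, summary)
        elif config.mode == "curves":
            _run_curves(config, out_dir, files, summary)
        else:
            _run_cohort(config, out_dir, files, summary)
    except PipelineError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise PipelineError(config.mode, exc) from exc

    manifest = {
        "config": config.to_canonical_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": sorted(str(Path(p).relative_to(out_dir)) for p in files.values()),
    }
    _write_json(out_dir / "manifest.json", manifest)
    files["manifest"] = out_dir / "manifest.json"
    return RunReport(files=files, summary=summary, config_hash=config.config_hash())


def _stage(stage: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineError):
                raise PipelineError(stage, exc) from exc
            return False

    return _Ctx()


def _run_simulate(config: RunConfig, out_dir: Path, files: dict, summary: dict) -> None:
    cohort_params = config.cohort or CohortParams(seed=config.seed)
    if cohort_params.seed != config.seed:
        cohort_params = replace(cohort_params, seed=config.seed)
    bolus_template = config.bolus or BolusParams()

    with _stage("simulate-cohort"):
        records = simulate_cohort(cohort_params)
        write_cohort_csv(records, out_dir / "cohort_true.csv")
        files["cohort_true"] = out_dir / "cohort_true.csv"

    curves_dir = out_dir / "curves"
    curves_dir.mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)
    child_seeds = rng.integers(0, 2**31 - 1, size=len(records))

    measured_rows = []
    with _stage("simulate-curves"):
        for rec, child_seed in zip(records, child_seeds):
            params = replace(bolus_template, transport_delay=rec.ptt_s,
                             rr_mean=rec.rr_s, seed=int(child_seed))
            rv, lv, truth = simulate_curve_pair(params)
            write_curves_csv(rv, lv, curves_dir / f"{rec.patient_id}.csv")
            m = _measure_pair(rv, lv, config.peak)
            measured_rows.append(
                {"patient_id": rec.patient_id, **m.to_dict(),
                 "ptt_true": truth["ptt_true"],
                 "dd_grade": rec.dd_grade, "mvr_grade": rec.mvr_grade,
                 "dd_relevant": rec.dd_relevant, "mvr_relevant": rec.mvr_relevant}
            )
        files["curves_dir"] = curves_dir

    with _stage("measure"):
        measured = pd.DataFrame(measured_rows)
        measured.to_csv(out_dir / "measurements.csv", index=False)
        files["measurements"] = out_dir / "measurements.csv"

    with _stage("evaluate"):
        cohort_measured = measured.rename(columns={})[
            ["patient_id", "ptt_s", "nptt", "rr_s", "dd_grade", "mvr_grade",
             "dd_relevant", "mvr_relevant"]
        ]
        cohort_measured.to_csv(out_dir / "cohort_measured.csv", index=False)
        files["cohort_measured"] = out_dir / "cohort_measured.csv"
        ev = evaluate_cohort(cohort_measured, edges=config.edges,
                             n_boot=config.n_boot, alpha=config.alpha, seed=config.seed)
        summary["results"] = _write_evaluation(out_dir, ev, files)
        summary["n_patients"] = len(records)

    if config.make_plots:
        with _stage("plots"):
            from .plots import plot_roc

            df = cohort_measured
            labels = df["dd_relevant"].to_numpy(bool) | df["mvr_relevant"].to_numpy(bool)
            plot_roc(df["ptt_s"].to_numpy(float), labels, out_dir / "roc_ptt_dd_or_mvr.png")
            files["roc_plot"] = out_dir / "roc_ptt_dd_or_mvr.png"


def _run_curves(config: RunConfig, out_dir: Path, files: dict, summary: dict) -> None:
    rows = []
    with _stage("measure"):
        for path in config.curves_csv:
            rv, lv = read_curves_csv(path)
            m = _measure_pair(rv, lv, config.peak)
            rows.append({"source": str(path), **m.to_dict()})
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / "measurements.csv", index=False)
        files["measurements"] = out_dir / "measurements.csv"
    summary["measurements"] = rows


def _run_cohort(config: RunConfig, out_dir: Path, files: dict, summary: dict) -> None:
    with _stage("read-cohort"):
        records = read_cohort_csv(config.cohort_csv)
    with _stage("evaluate"):
        ev = evaluate_cohort(records, edges=config.edges, n_boot=config.n_boot,
                             alpha=config.alpha, seed=config.seed)
        summary["results"] = _write_evaluation(out_dir, ev, files)
        summary["n_patients"] = len(records)
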