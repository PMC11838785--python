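"""End-to-end experiment driver: config handling, run orchestration, export.

``run_experiment`` trains the full model, runs the 272-trial factorial
(and optionally the r_lex sweep), and writes auditable artifacts: a trials
CSV, a summary JSON, an optional sweep CSV, and a log recording the seed,
every effective parameter, the decay-schedule endpoints, and a hash of the
configuration.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path

import pandas as pd

from .errors import DataError, ParameterError
from .routing import sweep_rlex
from .stroop import StroopModel, TrialResult, rt_contrast_test, summarize

__all__ = ["ExperimentConfig", "export_activation_movie", "run_experiment"]

# CSV dialect is fixed (comma, dot decimal, header row, UTF-8) so that
# byte-identical reruns are meaningful.
_CSV_KW = dict(index=False, encoding="utf-8")


@dataclasses.dataclass
class ExperimentConfig:
    """All tunable parameters of the experiment, with task defaults.

    The semantic map uses softmax temperature 0.7 and the lexical map 0.5;
    activation persistence alpha = 0.8 and lateral gain beta = 0.1; the
    semantic-to-lexical transfer gain (r_sem) is 0.05 and the distractor
    strength r_lex is 0.45; the response criterion is 1 bit of readout
    entropy with a 500-step cap.
    """

    rows: int = 20
    cols: int = 20
    sem_temperature: float = 0.7
    lex_temperature: float = 0.5
    temperature_end: float = 0.05
    alpha: float = 0.8
    beta: float = 0.1
    sigma_start: float = 2.0
    sigma_end: float = 0.25
    eta_start: float = 0.2
    eta_end: float = 0.05
    epochs: int = 1000
    settle_steps: int = 30
    assoc_epochs: int = 10
    theta: float = 0.1
    gamma: float = 0.05
    r_lex: float = 0.45
    entropy_threshold: float = 1.0
    max_steps: int = 500
    seed: int = 0

    def validate(self) -> "ExperimentConfig":
        bad = []
        positive = ("rows", "cols", "sem_temperature", "lex_temperature",
                    "temperature_end",
                    "sigma_start", "sigma_end", "eta_start", "eta_end",
                    "epochs", "settle_steps", "assoc_epochs", "theta",
                    "entropy_threshold", "max_steps")
        for name in positive:
            if getattr(self, name) <= 0:
                bad.append(name)
        if not (0 < self.alpha <= 1):
            bad.append("alpha")
        if self.beta < 0:
            bad.append("beta")
        if not (0 <= self.r_lex <= 1):
            bad.append("r_lex")
        if self.gamma <= 0:
            bad.append("gamma")
        if self.sigma_end > self.sigma_start:
            bad.append("sigma_end")
        if self.eta_end > self.eta_start:
            bad.append("eta_end")
        if bad:
            raise ParameterError(f"invalid config fields: {', '.join(sorted(set(bad)))}")
        return self

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {', '.join(sorted(unknown))}")
        return cls(**raw).validate()

    def to_json(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def build_model(self) -> StroopModel:
        self.validate()
        return StroopModel(**dataclasses.asdict(self))


def _trials_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        {"condition": [r.spec.condition for r in results],
         "target": [r.spec.target for r in results],
         "distractor": [r.spec.distractor or "" for r in results],
         "output": [r.output or "" for r in results],
         "correct": [r.correct for r in results],
         "steps": [r.steps for r in results],
         "converged": [r.converged for r in results]})


def _summary_payload(results, config: ExperimentConfig) -> dict:
    summary = summarize(results)
    payload = {"config_digest": config.digest(), "seed": config.seed,
               "n_trials": len(results),
               "overall_accuracy": summary["overall"], "conditions": {}}
    for cond, s in summary.items():
        if cond == "overall":
            continue
        payload["conditions"][cond] = {
            "n_trials": s.n_trials, "n_correct": s.n_correct,
            "accuracy": s.accuracy,
            "mean_rt": None if math.isnan(s.mean_rt) else s.mean_rt,
            "se_rt": None if math.isnan(s.se_rt) else s.se_rt}
    return payload


def run_experiment(config: ExperimentConfig, outdir, sweep: bool = False,
                   contrasts: bool = True, model: StroopModel | None = None):
    """Train, run the factorial, optionally sweep, and write artifacts.

    Writes ``trials.csv``, ``summary.json``, ``log.json``, optionally
    ``sweep.csv`` and ``contrasts.json`` under ``outdir``.  A pre-fitted
    ``model`` can be supplied to skip training (its parameters must come
    from the same config).  Returns the fitted model.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if model is None:
        model = config.build_model().fit()
    results = model.run_factorial()
    _trials_frame(results).to_csv(outdir / "trials.csv", **_CSV_KW)
    payload = _summary_payload(results, config)
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)

    if contrasts:
        contrast = rt_contrast_test(results, seed=config.seed)
        with open(outdir / "contrasts.json", "w", encoding="utf-8") as fh:
            json.dump(contrast, fh, indent=2, sort_keys=True)

    selected = None
    if sweep:
        points, selected = sweep_rlex(model, r_sem=config.gamma)
        pd.DataFrame([dataclasses.asdict(p) for p in points]).to_csv(
            outdir / "sweep.csv", **_CSV_KW)

    log = {"config": dataclasses.asdict(config),
           "config_digest": config.digest(), "seed": config.seed,
           "eta_schedule": [config.eta_start, config.eta_end],
           "sigma_schedule": [config.sigma_start, config.sigma_end],
           "entropy_threshold": config.entropy_threshold,
           "selected_r_lex": selected}
    with open(outdir / "log.json", "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=2, sort_keys=True)
    return model


def export_activation_movie(trial: TrialResult, outdir):
    """Write per-step activation grids for a snapshot-recorded trial.

    Produces ``semantic_activation.csv`` and ``lexical_activation.csv``
    under ``outdir``; each row is one time step (column ``t``, then one
    column per map unit), plus the lexical entropy trace in
    ``entropy.csv``.  Raises :class:`DataError` if the trial was run
    without snapshot recording.
    """
    if trial.snapshots is None:
        raise DataError("trial was run without snapshot recording; "
                        "re-run with record_snapshots=True")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, idx in (("semantic", 1), ("lexical", 2)):
        rows = [{"t": snap[0],
                 **{f"u{i}": v for i, v in enumerate(snap[idx])}}
                for snap in trial.snapshots]
        pd.DataFrame(rows).to_csv(outdir / f"{name}_activation.csv", **_CSV_KW)
    pd.DataFrame({"t": range(1, len(trial.entropy_trace) + 1),
                  "entropy_bits": trial.entropy_trace}).to_csv(
        outdir / "entropy.csv", **_CSV_KW)
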