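"""End-to-end pipeline: simulate -> detect -> filter -> classify -> quantify.

``run_pipeline`` executes the configured stages, persists every
intermediate artifact under an output directory and returns the bundle of
results.  Re-running with the same configuration and seed reproduces the
artifacts bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .background import knn_background_filter
from .classify import SplitSpec, assemble_datasets, predict, save_model, train_model
from .config import PipelineConfig
from .hydrolysate import confident_calls, normalize_abundance, positional_trend
from .params import DEFAULT_PARAMS, get_params
from .quantify import signal_frequency
from .signals import detect_events, events_to_frame
from .simulate import (
    HydrolysateSpec,
    PeptideSpec,
    TraceConfig,
    hydrolysate_concentrations,
    simulate_blank,
    simulate_trace,
)

__all__ = ["run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is part of the message."""


def _trace_config(cfg: PipelineConfig, duration: float, seed: int) -> TraceConfig:
    s = cfg.simulate
    return TraceConfig(
        sampling_rate=s.sampling_rate,
        baseline_current=s.baseline_current,
        noise_sd=s.noise_sd,
        duration=duration,
        copper_occupancy=s.copper_occupancy,
        seed=seed,
    )


def _detect(cfg: PipelineConfig, trace, experiment_id: str) -> pd.DataFrame:
    events, baseline, _ = detect_events(
        trace,
        penalty=cfg.detect.penalty,
        min_blockade=cfg.detect.min_blockade,
        min_dwell_ms=cfg.detect.min_dwell_ms,
        experiment_id=experiment_id,
    )
    return events_to_frame(events, trace.sampling_rate)


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.write(out / "config.json")
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(64)]
    seed_iter = iter(seeds)
    metrics: dict = {"seed": config.seed, "stages": []}
    artifacts: dict = {"out_dir": out}

    def stage(name):
        metrics["stages"].append(name)
        return name

    try:
        # ------------------------------------------------ training data
        stage("simulate")
        train_events = []
        for cls, conc in sorted(config.simulate.analytes.items()):
            if conc <= 0:
                continue
            p = get_params(cls)
            for e in range(config.simulate.train_experiments_per_class):
                tc = _trace_config(
                    config, config.simulate.train_duration_s, next(seed_iter)
                )
                trace, _ = simulate_trace([(p, conc)], tc)
                df = _detect(config, trace, experiment_id=f"{cls}-train{e}")
                df = df[df["n_sublevels"] == 1]  # state-1 signals only
                df["label"] = cls
                train_events.append(df)
        labeled = (
            pd.concat(train_events, ignore_index=True)
            if train_events
            else pd.DataFrame()
        )
        if len(labeled):
            cio.write_events(labeled, out / "training_events.tsv")

        # ------------------------------------------------ blank control
        blank_tc = _trace_config(config, config.simulate.duration_s, next(seed_iter))
        blank_trace, blank_log = simulate_blank(
            blank_tc, artifact_rate=config.simulate.artifact_rate_per_min
        )
        cio.write_trace(blank_trace, out / "blank_trace.tsv")
        blank_events = _detect(config, blank_trace, experiment_id="blank")
        cio.write_events(blank_events, out / "blank_events.tsv")

        # ------------------------------------------------ sample trace
        sample_tc = _trace_config(config, config.simulate.duration_s, next(seed_iter))
        analytes = [
            (get_params(c), v) for c, v in sorted(config.simulate.analytes.items()) if v > 0
        ]
        sample_trace, sample_log = simulate_trace(analytes, sample_tc)
        cio.write_trace(sample_trace, out / "sample_trace.tsv")
        cio.write_events(sample_log, out / "sample_truth.tsv")

        stage("detect")
        sample_events = _detect(config, sample_trace, experiment_id="sample")
        cio.write_events(sample_events, out / "sample_events.tsv")

        stage("filter")
        if config.filter.enabled and len(sample_events) and len(blank_events):
            filtered, report = knn_background_filter(
                sample_events, blank_events, k=config.filter.k, seed=next(seed_iter)
            )
            (out / "filter_report.json").write_text(json.dumps(report))
        else:
            filtered = sample_events
            next(seed_iter)
        cio.write_events(filtered, out / "filtered_events.tsv")

        # ------------------------------------------------ classification
        stage("classify")
        calls = pd.DataFrame(columns=["call", "p_max"])
        model = None
        if len(labeled) and labeled["label"].nunique() >= 2:
            train, test, validation = assemble_datasets(
                labeled,
                SplitSpec(
                    per_class_target=config.classify.per_class_target,
                    seed=next(seed_iter),
                ),
            )
            model = train_model(
                train,
                algorithm=config.classify.algorithm,
                cv_folds=config.classify.cv_folds,
                seed=next(seed_iter),
            )
            save_model(model, out / "model.joblib")
            metrics["cv_accuracy_mean"] = float(np.mean(model.cv_scores))
            if len(filtered):
                pred = predict(model, filtered)
                calls = pd.concat(
                    [filtered[["experiment_id", "onset_s"]].reset_index(drop=True),
                     pred.reset_index(drop=True)],
                    axis=1,
                )
        cio.write_events(calls, out / "calls.tsv")

        # ------------------------------------------------ quantification
        stage("quantify")
        duration_min = config.simulate.duration_s / 60.0
        conf = calls[calls["p_max"] > config.classify.probability_threshold] if len(calls) else calls
        freq = {}
        for cls in sorted(config.simulate.analytes):
            freq[cls] = signal_frequency(len(conf[conf["call"] == cls]) if len(conf) else 0, duration_min)
        metrics["signal_frequency_per_min"] = freq
        metrics["n_detected_events"] = int(len(sample_events))
        metrics["n_filtered_events"] = int(len(filtered))
        metrics["n_confident_calls"] = int(len(conf))
        metrics["n_true_events"] = int(len(sample_log))

        # ------------------------------------------------ hydrolysate
        if config.hydrolysate is not None and model is not None:
            stage("hydrolysate")
            h = config.hydrolysate
            pep = PeptideSpec(
                sequence=h.peptide,
                enzyme=h.enzyme,
                cleavage_rate=h.cleavage_rate_per_min,
                digestion_time=h.digestion_time_min,
            )
            spec = HydrolysateSpec(pep, peptide_concentration=h.peptide_concentration_uM)
            conc = hydrolysate_concentrations(spec)
            tc = _trace_config(config, config.simulate.duration_s, next(seed_iter))
            trace_h, _ = simulate_trace([(get_params(c), v) for c, v in sorted(conc.items())], tc)
            ev_h = _detect(config, trace_h, experiment_id="hydrolysate")
            pred_h = predict(model, ev_h) if len(ev_h) else pd.DataFrame(columns=["call", "p_max"])
            counts = confident_calls(pred_h, p_min=config.classify.probability_threshold) if len(pred_h) else pd.Series(dtype=int)
            if len(counts):
                profile = normalize_abundance(counts, DEFAULT_PARAMS)
                rho, pval = positional_trend(h.peptide, pep.terminus, profile)
                metrics["hydrolysate"] = {
                    "abundance_percent": profile.percent,
                    "trend_rho": rho,
                    "trend_p": pval,
                }

        (out / "metrics.json").write_text(json.dumps(metrics, indent=2))
        artifacts["metrics"] = metrics
        artifacts["calls"] = calls
        artifacts["model"] = model
        return artifacts
    except Exception as exc:
        failed = metrics["stages"][-1] if metrics["stages"] else "setup"
        raise StageError(f"pipeline stage '{failed}' failed: {exc}") from exc
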