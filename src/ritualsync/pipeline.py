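"""End-to-end orchestration: simulate/load -> preprocess -> embed ->
calibrate -> CRQA/DCRP -> surrogates -> network -> inference -> report.

Everything is reproducible from (config, seed): the same RunConfig produces
byte-identical output CSVs. Every number in the emitted model tables can be
recomputed from the emitted pair-metrics CSV alone.
"""

from __future__ import annotations

import json
import logging
import shutil
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import dataio, inference, network, preprocess, recurrence, surrogate
from .embedding import embed, select_embedding_params, unify_pair_params
from .synthetic import RitualConfig, SessionData, generate_session

logger = logging.getLogger(__name__)

SIGNALS = ("posture", "hr")


@dataclass
class RunConfig:
    """All analysis knobs for one pipeline run."""

    mode: str = "simulate"  # "simulate" | "load"
    ritual: RitualConfig = field(default_factory=RitualConfig)
    input_dir: Optional[str] = None
    out_dir: Optional[str] = None
    band_halfwidth_s: int = 15
    min_line: int = 2
    target_band: tuple = (2.0, 5.0)
    target_point: float = 3.5
    n_surrogates: int = 10
    adjacency_threshold_m: float = 2.0
    max_lag: int = 20
    max_dim: int = 10
    seed: int = 1
    trim: Optional[tuple] = None  # (start_s, end_s) analysis window when loading
    questionnaire_path: Optional[str] = None

    def __post_init__(self) -> None:
        lo, hi = self.target_band
        if not (0 < lo < hi <= 100):
            raise ValueError("target_band must satisfy 0 < lo < hi <= 100")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.mode not in ("simulate", "load"):
            raise ValueError("mode must be 'simulate' or 'load'")


@dataclass
class PipelineResult:
    """In-memory report bundle; the CSV emission mirrors these tables."""

    session: SessionData
    pair_metrics: pd.DataFrame
    dcrp: pd.DataFrame
    series_params: pd.DataFrame
    radii: dict
    model_tables: dict
    lag_tests: dict
    spacing: Optional[tuple]
    questionnaire: Optional[list]
    manifest: dict


@contextmanager
def _stage(name: str):
    logger.info("stage: %s", name)
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc


def _signal_series(participant, signal: str):
    return participant.posture if signal == "posture" else participant.hr


def _preprocess_session(session: SessionData) -> dict:
    """Imputed + z-scored value arrays keyed by (signal, participant id)."""
    clean = {}
    for signal in SIGNALS:
        for p in session.participants:
            clean[(signal, p.id)] = preprocess.preprocess_series(_signal_series(p, signal)).values
    return clean


def analyze_session(
    session: SessionData,
    config: RunConfig,
    questionnaire: Optional[pd.DataFrame] = None,
) -> PipelineResult:
    """Run the full analysis on an in-memory session."""
    with _stage("preprocess"):
        clean = _preprocess_session(session)

    with _stage("embedding parameters"):
        params = {
            key: select_embedding_params(values, config.max_lag, config.max_dim)
            for key, values in clean.items()
        }
        series_params = pd.DataFrame(
            [
                {"id": pid, "signal": sig, "delay": p.delay, "dimension": p.dimension}
                for (sig, pid), p in params.items()
            ]
        ).sort_values(["signal", "id"], kind="stable").reset_index(drop=True)

    with _stage("proximity network"):
        meta = session.metadata
        graph = network.build_graph(session.proximity, meta, config.adjacency_threshold_m)
        pairs = network.categorize_pairs(graph, meta, session.proximity)

    with _stage("pair embedding"):
        pair_params = {}
        trajectories = {sig: {} for sig in SIGNALS}
        for rec in pairs:
            for sig in SIGNALS:
                up = unify_pair_params(params[(sig, rec.id_a)], params[(sig, rec.id_b)])
                pair_params[(sig, rec.pair_id)] = up
                trajectories[sig][rec.pair_id] = (
                    embed(clean[(sig, rec.id_a)], up),
                    embed(clean[(sig, rec.id_b)], up),
                )

    with _stage("radius calibration"):
        radii = {
            sig: recurrence.calibrate_global_radius(
                [trajectories[sig][r.pair_id] for r in pairs],
                target_band=config.target_band,
                target_point=config.target_point,
            )
            for sig in SIGNALS
        }

    metric_rows = []
    dcrp_rows = []
    with _stage("true-pair CRQA"):
        for rec in pairs:
            for sig in SIGNALS:
                ta, tb = trajectories[sig][rec.pair_id]
                crp = recurrence.quantify(
                    recurrence.cross_recurrence_matrix(ta, tb, radii[sig]), config.min_line
                )
                profile = recurrence.diagonal_profile(crp, config.band_halfwidth_s)
                metric_rows.append(
                    {
                        "pair_id": rec.pair_id,
                        "id_a": rec.id_a,
                        "id_b": rec.id_b,
                        "signal": sig,
                        "category": rec.category,
                        "node_distance": rec.node_distance,
                        "type": "true",
                        "replicate": 0,
                        "rec_pct": crp.rec_rate_pct,
                        "det_pct": crp.determinism_pct,
                        "peak_lag_s": profile.peak_lag / session.participants[0].posture.sample_hz,
                    }
                )
                for lag, rp in zip(profile.lags, profile.rec_pct_by_lag):
                    dcrp_rows.append(
                        {"pair_id": rec.pair_id, "signal": sig, "lag_s": int(lag), "rec_pct": rp}
                    )

    with _stage("surrogate CRQA"):
        clean_session = _as_clean_session(session, clean)
        for replicate, surro in enumerate(
            surrogate.make_surrogate_session(clean_session, config.n_surrogates, config.seed), start=1
        ):
            svalues = {
                (sig, p.id): _signal_series(p, sig).values
                for p in surro.participants
                for sig in SIGNALS
            }
            for rec in pairs:
                for sig in SIGNALS:
                    up = pair_params[(sig, rec.pair_id)]
                    crp = recurrence.quantify(
                        recurrence.cross_recurrence_matrix(
                            embed(svalues[(sig, rec.id_a)], up),
                            embed(svalues[(sig, rec.id_b)], up),
                            radii[sig],
                        ),
                        config.min_line,
                    )
                    metric_rows.append(
                        {
                            "pair_id": rec.pair_id,
                            "id_a": rec.id_a,
                            "id_b": rec.id_b,
                            "signal": sig,
                            "category": rec.category,
                            "node_distance": rec.node_distance,
                            "type": "surrogate",
                            "replicate": replicate,
                            "rec_pct": crp.rec_rate_pct,
                            "det_pct": crp.determinism_pct,
                            "peak_lag_s": np.nan,
                        }
                    )

    pair_metrics = pd.DataFrame(metric_rows)
    dcrp = pd.DataFrame(dcrp_rows)

    with _stage("inference"):
        model_tables = {}
        for sig in SIGNALS:
            for outcome in ("rec", "det"):
                model_tables[f"category:{sig}:{outcome}"] = inference.fit_category_model(
                    pair_metrics, outcome, sig
                )
                model_tables[f"surrogate_contrast:{sig}:{outcome}"] = (
                    inference.fit_surrogate_contrast_model(pair_metrics, outcome, sig)
                )
                model_tables[f"network:{sig}:{outcome}"] = inference.fit_network_model(
                    pair_metrics, outcome, sig, with_random_pair=False
                )
                model_tables[f"network_mixed:{sig}:{outcome}"] = inference.fit_network_model(
                    pair_metrics, outcome, sig, with_random_pair=True
                )

        lag_tests = {}
        true_rows = pair_metrics[pair_metrics["type"] == "true"]
        for sig in SIGNALS:
            imam_lags = true_rows[
                (true_rows["signal"] == sig) & (true_rows["id_a"] == "imam")
            ]["peak_lag_s"]
            if len(imam_lags) >= 2:
                lag_tests[sig] = inference.lag_t_test(imam_lags)

        spacing = None
        groups = [g for g in meta.loc[meta["role"] == "worshipper", "group"].unique()]
        if len(groups) == 2:
            nn_a = network.nearest_neighbour_distances(session.proximity, meta, groups[0])
            nn_b = network.nearest_neighbour_distances(session.proximity, meta, groups[1])
            spacing = inference.spacing_comparison(nn_a, nn_b)

        questionnaire_summary = (
            inference.summarize_questionnaire(questionnaire) if questionnaire is not None else None
        )

    manifest = {
        "seed": config.seed,
        "n_participants": len(session.participants),
        "n_pairs": len(pairs),
        "n_surrogates": config.n_surrogates,
        "radii": radii,
        "target_band": list(config.target_band),
        "target_point": config.target_point,
        "band_halfwidth_s": config.band_halfwidth_s,
        "min_line": config.min_line,
        "adjacency_threshold_m": config.adjacency_threshold_m,
        "mean_rec_pct": {
            sig: float(
                pair_metrics[
                    (pair_metrics["signal"] == sig) & (pair_metrics["type"] == "true")
                ]["rec_pct"].mean()
            )
            for sig in SIGNALS
        },
    }
    return PipelineResult(
        session=session,
        pair_metrics=pair_metrics,
        dcrp=dcrp,
        series_params=series_params,
        radii=radii,
        model_tables=model_tables,
        lag_tests=lag_tests,
        spacing=spacing,
        questionnaire=questionnaire_summary,
        manifest=manifest,
    )


def _as_clean_session(session: SessionData, clean: dict) -> SessionData:
    """Session whose series are the imputed + z-scored versions (no missing)."""
    from .synthetic import ParticipantRecord  # local import to avoid cycle noise

    participants = []
    for p in session.participants:
        participants.append(
            ParticipantRecord(
                id=p.id,
                role=p.role,
                group=p.group,
                grid_position=p.grid_position,
                posture=p.posture.copy_with(clean[("posture", p.id)], np.zeros(len(p.posture), bool)),
                hr=p.hr.copy_with(clean[("hr", p.id)], np.zeros(len(p.hr), bool)),
            )
        )
    return SessionData(participants=participants, proximity=session.proximity,
                       config_used=session.config_used)


def _write_bundle(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.pair_metrics.to_csv(out_dir / "pair_metrics.csv", index=False)
    result.dcrp.to_csv(out_dir / "dcrp.csv", index=False)
    result.series_params.to_csv(out_dir / "series_params.csv", index=False)
    for name, table in sorted(result.model_tables.items()):
        fname = "models_" + name.replace(":", "_") + ".csv"
        table.to_csv(out_dir / fname, index=False)
    if result.lag_tests:
        pd.DataFrame(
            [
                {"signal": sig, "t": r.t, "df": r.df, "p": r.p, "mean": r.mean, "sd": r.sd,
                 "degenerate": r.degenerate}
                for sig, r in sorted(result.lag_tests.items())
            ]
        ).to_csv(out_dir / "lag_tests.csv", index=False)
    if result.spacing is not None:
        pd.DataFrame([{"U": result.spacing[0], "p": result.spacing[1]}]).to_csv(
            out_dir / "spacing.csv", index=False
        )
    if result.questionnaire is not None:
        pd.DataFrame(
            [
                {"question": q.question, "n_yes": q.n_yes, "n_total": q.n_total, "pct_yes": q.pct_yes}
                for q in result.questionnaire
            ]
        ).to_csv(out_dir / "questionnaire.csv", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(result.manifest, indent=1, sort_keys=True))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Full run per the configured mode; writes the report bundle if out_dir set.

    A failure in any stage aborts with a stage-tagged message and removes
    any partially written outputs.
    """
    with _stage("input"):
        if config.mode == "simulate":
            ritual = config.ritual
            if ritual.seed != config.seed:
                ritual = RitualConfig.from_dict({**ritual.to_dict(), "seed": config.seed})
            session = generate_session(ritual)
        else:
            if not config.input_dir:
                raise ValueError("mode='load' requires input_dir")
            session = dataio.read_session(config.input_dir, trim=config.trim)
        questionnaire = None
        if config.questionnaire_path:
            questionnaire = pd.read_csv(config.questionnaire_path, index_col=0)

    out_dir = Path(config.out_dir) if config.out_dir else None
    created_out = out_dir is not None and not out_dir.exists()
    try:
        result = analyze_session(session, config, questionnaire)
        if out_dir is not None:
            with _stage("report emission"):
                _write_bundle(result, out_dir)
    except Exception:
        if out_dir is not None and out_dir.exists() and created_out:
            shutil.rmtree(out_dir, ignore_errors=True)
        raise
    return result
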