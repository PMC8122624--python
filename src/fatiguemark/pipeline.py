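"""End-to-end orchestration: simulate/load → ICA clean → epoch → features
→ nested-CV evaluation, with a manifest and summary tables.

A run directory contains ``manifest.json`` (config hash, package versions,
seeds, per-stage log counts), per-session feature tables (CSV + registry
sidecar), per-session/per-condition evaluation reports (JSON), and the
``summary/`` tables produced by :func:`summarize`.  Every number in a
summary traces back to a report file listed in the manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .biomarkers import FeatureConfig, FeatureTable, extract_features
from .classify import (
    EvalReport,
    ModelConfig,
    all_positive_baseline,
    nested_cv_evaluate,
    point_biserial_r2,
    single_channel_evaluation,
)
from .core import ValidationError, extract_epochs
from .ica import remove_eye_components
from .io import read_session, write_events_tsv, write_session
from .synthetic import EffectSizes, GeneratorConfig, generate_cohort

logger = logging.getLogger(__name__)

CONDITIONS = ("spectral", "HOST", "combined")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    #: synthetic-cohort parameters (used when no session paths are given)
    simulate: dict = field(default_factory=lambda: {"n_sessions": 2, "regime": "balanced"})
    #: list of {"signal": path, "events": path} for pre-recorded sessions
    sessions: list = field(default_factory=list)
    ica_enabled: bool = True
    ica_threshold: float = 0.1
    ica_fit_stride: int = 4
    period: str = "delay"
    window_s: float = 1.0
    features: dict = field(default_factory=dict)
    model: dict = field(default_factory=dict)
    conditions: tuple[str, ...] = ("combined",)
    k_max: int = 5
    screen_top_m: int | None = 30
    run_single_channel: bool = False
    save_signals: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        if "conditions" in raw:
            raw["conditions"] = tuple(raw["conditions"])
        cfg = cls(**raw)
        for cond in cfg.conditions:
            if cond not in CONDITIONS:
                raise ValidationError(f"unknown condition {cond!r}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["conditions"] = list(self.conditions)
        return d

    def generator_config(self) -> GeneratorConfig:
        sim = dict(self.simulate)
        sim.pop("n_sessions", None)
        sim.pop("regime", None)
        es = sim.pop("effect_sizes", None)
        kwargs = dict(sim)
        if es is not None:
            kwargs["effect_sizes"] = EffectSizes(**es)
        kwargs.setdefault("seed", self.seed)
        return GeneratorConfig(**kwargs)

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(**self.features)

    def model_config(self) -> ModelConfig:
        m = dict(self.model)
        m.setdefault("seed", self.seed)
        return ModelConfig(**m)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.sessions:
        out = []
        for entry in cfg.sessions:
            sig, ev = Path(entry["signal"]), Path(entry["events"])
            if not sig.exists():
                raise ValidationError(f"missing signal file: {sig}")
            if not ev.exists():
                raise ValidationError(f"missing events file: {ev}")
            session, events = read_session(sig, ev)
            out.append((session, events, None))
        return out, False
    sim = cfg.simulate
    cohort = generate_cohort(
        cfg.generator_config(),
        n_sessions=int(sim.get("n_sessions", 2)),
        regime=str(sim.get("regime", "balanced")),
    )
    return cohort, True


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute the full pipeline and return the run directory."""
    out = Path(out_dir)
    (out / "features").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "versions": _versions(),
        "stages": [],
        "log": {},
    }
    stage = "simulate/load"
    try:
        cohort, simulated = _load_or_simulate(config)
        manifest["stages"].append(stage)
        manifest["log"]["n_sessions"] = len(cohort)

        if simulated and config.save_signals:
            (out / "sessions").mkdir(exist_ok=True)
            for session, events, truth in cohort:
                write_session(session, out / "sessions" / f"{session.session_id}.h5")
                write_events_tsv(events, out / "sessions" / f"{session.session_id}.events.tsv")

        fcfg = config.feature_config()
        mcfg = config.model_config()
        ica_log, report_index = [], []
        for si, (session, events, truth) in enumerate(cohort):
            sid = session.session_id
            stage = f"preprocess[{sid}]"
            if config.ica_enabled:
                session, ica_rep = remove_eye_components(
                    session,
                    threshold=config.ica_threshold,
                    seed=config.seed,
                    fit_stride=config.ica_fit_stride,
                )
                ica_log.append(
                    {"session": sid, "removed": list(ica_rep.removed_component_indices)}
                )
            stage = f"features[{sid}]"
            epochs = extract_epochs(session, events, config.period, config.window_s)
            table = extract_features(epochs, fcfg)
            table.to_csv(out / "features" / f"{sid}.csv")
            stage = f"evaluate[{sid}]"
            for cond in config.conditions:
                rep = nested_cv_evaluate(
                    table,
                    config=mcfg,
                    condition=cond,
                    k_max=config.k_max,
                    screen_top_m=config.screen_top_m,
                    seed=config.seed + si,
                )
                rep.period = config.period
                rep.window_s = config.window_s
                path = out / "reports" / f"{sid}.{cond}.json"
                path.write_text(rep.to_json())
                report_index.append(
                    {"session": sid, "condition": cond, "path": str(path.relative_to(out))}
                )
            if config.run_single_channel:
                stage = f"single_channel[{sid}]"
                per_ch = single_channel_evaluation(table, config=mcfg, seed=config.seed)
                path = out / "reports" / f"{sid}.single_channel.json"
                path.write_text(json.dumps(per_ch, indent=1, sort_keys=True))
                report_index.append(
                    {"session": sid, "condition": "single_channel",
                     "path": str(path.relative_to(out))}
                )
        manifest["log"]["ica"] = ica_log
        manifest["reports"] = report_index
        manifest["stages"].append("evaluate")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage}: {err}") from err
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _versions() -> dict:
    import scipy
    import sklearn
    import xgboost

    return {
        "fatiguemark": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
        "xgboost": xgboost.__version__,
        "pandas": pd.__version__,
    }


# ---------------------------------------------------------------------------
# summaries


def summarize(run_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Build summary tables from a completed run directory.

    * ``selection_frequency``: per feature family, the fraction of sessions
      in which the wrapper selected it at least once (selections repeated
      within a session count once);
    * ``top_features``: the highest point-biserial R² column per family
      and session;
    * ``conditions``: pooled metrics per session and condition;
    * ``per_channel`` when single-electrode models were run.

    Raises if the run is missing its manifest or reports.  Writes CSVs to
    ``<run_dir>/summary`` and returns the tables.
    """
    run = Path(run_dir)
    manifest_path = run / "manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"incomplete run: {manifest_path} missing")
    manifest = json.loads(manifest_path.read_text())
    missing = [r["path"] for r in manifest.get("reports", []) if not (run / r["path"]).exists()]
    if missing:
        raise ValidationError(f"incomplete run: missing reports {missing}")
    out_dir = run / "summary"
    out_dir.mkdir(exist_ok=True)
    tables: dict[str, pd.DataFrame] = {}

    cond_rows, sel_by_session, per_channel_rows = [], {}, []
    for entry in manifest.get("reports", []):
        payload = json.loads((run / entry["path"]).read_text())
        if entry["condition"] == "single_channel":
            for ch, f1 in payload.items():
                per_channel_rows.append(
                    {"session": entry["session"], "channel": ch, "f1": f1}
                )
            continue
        cond_rows.append(
            {
                "session": entry["session"],
                "condition": entry["condition"],
                **{f"pooled_{k}": v for k, v in payload["pooled"].items()},
                "baseline_f1": payload["baseline_f1"],
            }
        )
        fams = set()
        feat_csv = run / "features" / f"{entry['session']}.csv"
        registry = json.loads(Path(str(feat_csv) + ".registry.json").read_text())
        for fold_sel in payload["selected_per_fold"]:
            for col in fold_sel:
                fams.add(registry[col]["family"])
        sel_by_session.setdefault(entry["session"], set()).update(fams)

    if cond_rows:
        tables["conditions"] = pd.DataFrame(cond_rows)
    if sel_by_session:
        all_fams = sorted(set().union(*sel_by_session.values()))
        n_sessions = len(sel_by_session)
        tables["selection_frequency"] = pd.DataFrame(
            [
                {
                    "family": fam,
                    "n_sessions_selected": sum(fam in s for s in sel_by_session.values()),
                    "frequency": sum(fam in s for s in sel_by_session.values()) / n_sessions,
                }
                for fam in all_fams
            ]
        )
    if per_channel_rows:
        tables["per_channel"] = pd.DataFrame(per_channel_rows)

    top_rows = []
    for feat_csv in sorted((run / "features").glob("*.csv")):
        table = FeatureTable.from_csv(feat_csv)
        X = table.values.to_numpy(dtype=np.float64)
        med = np.nanmedian(X, axis=0)
        bad = ~np.isfinite(X)
        X[bad] = np.broadcast_to(np.where(np.isfinite(med), med, 0.0), X.shape)[bad]
        r2 = point_biserial_r2(X, table.labels)
        by_family: dict[str, tuple[str, float]] = {}
        for col, val in zip(table.feature_names, r2):
            fam = table.family_of(col)
            if fam not in by_family or val > by_family[fam][1]:
                by_family[fam] = (col, float(val))
        for fam, (col, val) in sorted(by_family.items()):
            top_rows.append(
                {"session": feat_csv.stem, "family": fam, "feature": col, "r2": val}
            )
    if top_rows:
        tables["top_features"] = pd.DataFrame(top_rows)

    if not tables:
        logger.warning("summarize: no sessions found in %s; writing empty tables", run)
        tables["conditions"] = pd.DataFrame(
            columns=["session", "condition", "pooled_f1", "baseline_f1"]
        )
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    return tables
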