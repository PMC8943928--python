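"""End-to-end orchestration: simulate → preprocess → extract → analyze.

The pipeline is deterministic: identical configuration and seed produce
byte-identical outputs, and a machine-readable run log (package and
library versions, seed, configuration hash) accompanies every result
directory.  Missing or undefined values are carried through explicitly
as empty CSV cells, never imputed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import ValidationError
from .features import PARAMETERS, FeatureConfig, extract_profile
from .frailty import CRITERIA, FriedCriteria, assess
from .preprocess import PreprocessConfig, preprocess, read_recording_csv
from . import stats as st
from . import synthetic as syn


@dataclass
class RunConfig:
    """Everything one full run depends on."""

    input_dir: str | Path | None = None
    out_dir: str | Path = "adlkin-out"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_perm: int = 10_000
    alpha: float = 0.05
    entry_p: float = 0.05
    removal_p: float = 0.10
    seed: int = 0
    simulate: bool = False
    n_per_group: dict[str, int] = field(default_factory=lambda: {"R": 8, "P": 13, "F": 6})
    sim_config: str | Path | None = None
    keep_going: bool = False


def _config_digest(cfg: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def extract_features_table(
    manifest: pd.DataFrame,
    data_dir: Path,
    pre_cfg: PreprocessConfig,
    feat_cfg: FeatureConfig,
    keep_going: bool = False,
    log: list[str] | None = None,
) -> pd.DataFrame:
    """Preprocess every recording in the manifest and extract features."""
    if manifest.duplicated(["participant_id", "task"]).any():
        raise ValidationError("duplicate participant×task recordings in manifest")
    rows = []
    for rec in manifest.itertuples():
        try:
            raw = read_recording_csv(
                data_dir / rec.file, participant_id=rec.participant_id, task=rec.task
            )
            sig = preprocess(raw, pre_cfg)
            prof = extract_profile(sig, feat_cfg)
            rows.append(
                {"participant_id": rec.participant_id, "task": rec.task, **prof.as_dict()}
            )
        except Exception as exc:
            msg = f"recording {rec.participant_id}/{rec.task}: {exc}"
            if not keep_going:
                raise
            warnings.warn(msg, stacklevel=2)
            if log is not None:
                log.append(msg)
    return pd.DataFrame(rows)


def frailty_from_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Recompute score and category from the five criterion columns."""
    out = manifest.drop_duplicates("participant_id").copy()
    scores, cats = [], []
    for rec in out.itertuples():
        crit = FriedCriteria(**{name: bool(getattr(rec, name)) for name in CRITERIA})
        a = assess(crit)
        scores.append(a.score)
        cats.append(a.category)
    out["fried_score"] = scores
    out["category"] = cats
    bad = out[out["group"] != out["category"]]
    if not bad.empty:
        raise ValidationError(
            f"manifest group inconsistent with criteria for {bad['participant_id'].tolist()}"
        )
    return out[["participant_id", "group", *CRITERIA, "fried_score", "category"]]


def _comparisons_frame(table: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for scope in st.SCOPES:
        for gc in st.compare_groups(table, scope):
            row = {
                "scope": scope,
                "parameter": gc.parameter,
                "F": gc.F,
                "df_between": gc.df[0],
                "df_within": gc.df[1],
                "p": gc.p,
                "eta2p": gc.eta2p,
            }
            for pair, p_adj, d in gc.posthoc:
                row[f"p_{pair}"] = p_adj
                row[f"d_{pair}"] = d
            rows.append(row)
    return pd.DataFrame(rows)


def _report_text(
    table: pd.DataFrame,
    comparisons: pd.DataFrame,
    correlations: pd.DataFrame,
    models: dict[str, st.RegressionModel],
    mv: dict[str, tuple[float, float]],
) -> str:
    lines = ["adlkin analysis report", "=" * 60, ""]
    counts = table["group"].value_counts()
    lines.append(
        "cohort: "
        + ", ".join(f"{g}={int(counts.get(g, 0))}" for g in st.GROUP_ORDER)
        + f" (total {len(table)})"
    )
    lines.append("")
    for scope in st.SCOPES:
        lines.append(f"--- group means (SD) by parameter, scope: {scope} ---")
        header = f"{'param':8s}" + "".join(f"{g:>16s}" for g in st.GROUP_ORDER) + f"{'p':>10s}{'eta2p':>8s}"
        lines.append(header)
        sub = comparisons[comparisons["scope"] == scope].set_index("parameter")
        for param in PARAMETERS:
            col = st.scope_column(param, scope)
            cells = []
            for g in st.GROUP_ORDER:
                vals = table.loc[table["group"] == g, col].dropna()
                cells.append(f"{vals.mean():8.2f} ({vals.std(ddof=1):5.2f})")
            p, e = sub.loc[param, "p"], sub.loc[param, "eta2p"]
            star = "*" if p < 0.05 else " "
            lines.append(f"{param:8s}" + "".join(f"{c:>16s}" for c in cells) + f"{p:>9.3f}{star}{e:>8.2f}")
        stat, p = mv[scope]
        lines.append(f"multivariate permutation test: statistic={stat:.2f}, p={p:.4f}")
        lines.append("")
    lines.append("--- inter-task correlations (TEA vs GARDEN) ---")
    for rec in correlations.itertuples():
        lines.append(f"{rec.parameter:8s} r={rec.r:6.2f}  p={rec.p:.3f}  n={rec.n}")
    lines.append("")
    for scope, model in models.items():
        lines.append(f"--- stepwise MLR of frailty score, scope: {scope} ---")
        if not model.selected:
            lines.append("no predictor met the entry criterion (R2 = 0)")
        else:
            lines.append(
                f"R2={model.R2:.3f} (adj {model.R2_adj:.3f}), model p={model.model_p:.4f}"
            )
            for name in model.selected:
                lines.append(
                    f"  {name:8s} beta_std={model.beta_std[name]:7.3f}  VIF={model.vif[name]:.2f}"
                )
        lines.append("")
    return "\n".join(lines)


def analyze(
    features: pd.DataFrame,
    manifest: pd.DataFrame,
    out_dir: Path,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Run the full statistics stage and write result files."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frail = frailty_from_manifest(manifest)
    table = st.build_cohort_table(features, frail)
    table = st.task_average(table)
    table.to_csv(out_dir / "cohort_table.csv", index=False)

    comparisons = _comparisons_frame(table)
    comparisons.to_csv(out_dir / "group_comparisons.csv", index=False)

    correlations = pd.DataFrame(
        [dataclasses.asdict(st.inter_task_correlation(table, p)) for p in PARAMETERS]
    )
    correlations.to_csv(out_dir / "correlations.csv", index=False)

    mv = {}
    models = {}
    for i, scope in enumerate(st.SCOPES):
        cols = [st.scope_column(p, scope) for p in PARAMETERS]
        mv[scope] = st.multivariate_group_test(
            table, columns=cols, n_perm=n_perm, seed=seed + i
        )
        model = st.stepwise_mlr(table, scope=scope)
        models[scope] = model
        pd.DataFrame(
            {
                "predictor": model.selected,
                "beta_std": [model.beta_std[c] for c in model.selected],
                "vif": [model.vif[c] for c in model.selected],
                "R2": model.R2,
                "R2_adj": model.R2_adj,
                "model_p": model.model_p,
            }
        ).to_csv(out_dir / f"regression_{scope}.csv", index=False)

    report = _report_text(table, comparisons, correlations, models, mv)
    (out_dir / "report.txt").write_text(report)
    return {
        "table": table,
        "comparisons": comparisons,
        "correlations": correlations,
        "models": models,
        "multivariate": mv,
        "report": report,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Full chain; returns the analysis results dictionary."""
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []

    if cfg.simulate:
        sim = syn.load_config(cfg.sim_config) if cfg.sim_config else syn.default_config()
        sim = syn.with_seed(sim, cfg.seed)
        data_dir = out_dir / "data"
        cohort = syn.simulate_cohort(sim, cfg.n_per_group)
        manifest = syn.write_cohort(cohort, data_dir)
        syn.save_config(sim, out_dir / "simulation_config.yaml")
    else:
        if cfg.input_dir is None:
            raise ValidationError("input_dir is required unless simulate is set")
        data_dir = Path(cfg.input_dir)
        manifest_path = data_dir / "manifest.csv"
        if not manifest_path.exists():
            raise ValidationError(f"no manifest.csv in {data_dir}")
        manifest = pd.read_csv(manifest_path)

    features = extract_features_table(
        manifest, data_dir, cfg.preprocess, cfg.features, cfg.keep_going, log
    )
    features.to_csv(out_dir / "features.csv", index=False)

    results = analyze(features, manifest, out_dir, n_perm=cfg.n_perm, seed=cfg.seed)

    run_log = {
        "adlkin_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": cfg.seed,
        "config_sha256": _config_digest(cfg),
        "n_recordings": int(len(features)),
        "errors": log,
    }
    (out_dir / "run_log.json").write_text(json.dumps(run_log, indent=2))
    return results
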