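"""Pipeline orchestration and reporting surfaces.

`run_pipeline` drives preprocess → extract → screen → integrate → model →
report from a single declarative config; `cohort_summary` reproduces the
demographics-table arithmetic (counts and truncated percentages per
stratum).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from .model import (
    FeatureTable,
    crossval_auc,
    impute_censored,
    integrate_blocks,
    make_outcome,
    train_test_eval,
    transcriptome_screen,
)
from .stats import (
    SurvivalRecord,
    kaplan_meier,
    logrank_test,
    median_split,
    univariate_screen,
)
from .synthetic import CohortConfig, SyntheticCohort, generate_cohort
from .volume import normalize_intensity, read_mask, read_volume, resample_isotropic

__all__ = ["PipelineConfig", "cohort_summary", "run_pipeline", "truncate_percent"]

log = logging.getLogger("radiosurv")

DAYS_PER_YEAR = 365.25


def truncate_percent(count: int, total: int) -> float:
    """Percentage of ``count`` in ``total``, truncated (not rounded) to two
    decimals — e.g. 129/132 = 97.727... → 97.72."""
    if total <= 0:
        raise ValueError("total must be positive")
    return math.floor(count / total * 100 * 100) / 100


def cohort_summary(clinical: pd.DataFrame) -> pd.DataFrame:
    """Demographics table: count and truncated percentage per stratum.

    Expects the standard clinical columns (age, sex, kps, therapy_type,
    os_days, event); optional columns (mgmt, idh1, radiation, chemotherapy)
    are summarized verbatim when present, including 'NA'/'Unknown' strata.
    """
    required = {"age", "os_days", "event"}
    missing = required - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    n = len(clinical)
    rows: list[tuple[str, str, int, float]] = []

    def add(variable: str, stratum: str, count: int) -> None:
        rows.append((variable, stratum, count, truncate_percent(count, n)))

    age = clinical["age"].to_numpy(dtype=float)
    add("age", "<=65", int((age <= 65).sum()))
    add("age", ">65", int((age > 65).sum()))

    if "sex" in clinical:
        for s, c in clinical["sex"].value_counts().sort_index().items():
            add("sex", str(s), int(c))
    if "kps" in clinical:
        kps = pd.to_numeric(clinical["kps"], errors="coerce")
        add("kps", "<70", int((kps < 70).sum()))
        add("kps", ">=70", int((kps >= 70).sum()))
        unknown = int(kps.isna().sum())
        if unknown:
            add("kps", "Unknown", unknown)
    for col in ("mgmt", "idh1", "therapy_type", "radiation", "chemotherapy",
                "extent_of_surgery"):
        if col in clinical:
            for s, c in clinical[col].astype(str).value_counts().sort_index().items():
                add(col, s, int(c))

    years = clinical["os_days"].to_numpy(dtype=float) / DAYS_PER_YEAR
    event = clinical["event"].to_numpy(dtype=int)
    bands = [("<1y", years < 1), ("1-4y", (years >= 1) & (years <= 4)),
             (">4y", years > 4)]
    for name, sel in bands:
        cens = int(((event == 0) & sel).sum())
        rows.append(
            ("survival", f"{name} (censored {cens})", int(sel.sum()),
             truncate_percent(int(sel.sum()), n))
        )
    return pd.DataFrame(rows, columns=["variable", "stratum", "count", "percent"])


@dataclass
class PipelineConfig:
    """Declarative end-to-end pipeline configuration.

    Exactly one data source: a synthetic ``cohort`` config, or ``data_dir``
    holding volumes/, masks/ and the CSV tables.
    """

    cohort: CohortConfig | None = None
    data_dir: str | None = None
    blocks: tuple[str, ...] = ("radiomic", "clinical", "genomic",
                               "transcriptomic", "protein")
    mode: str = "cv"  # cv | holdout | uncensored-only
    n_trees: int = 500
    n_folds: int = 10
    test_size: float | int = 0.5
    seed: int = 0
    outdir: str = "pipeline_out"
    compute_importance: bool = False
    expression_alpha: float = 0.05
    n_gray_levels: int = 32

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.data_dir is None):
            raise ValueError("exactly one data source: cohort config or data_dir")
        if self.mode not in ("cv", "holdout", "uncensored-only"):
            raise ValueError(f"unknown mode '{self.mode}'")


def _load_from_dir(data_dir: Path, n_gray_levels: int):
    clinical = pd.read_csv(data_dir / "clinical.csv", index_col="patient_id")
    tables = {}
    for name in ("mutations", "expression", "proteins"):
        p = data_dir / f"{name}.csv"
        tables[name] = pd.read_csv(p, index_col="patient_id") if p.exists() else None
    rows, kept, dropped = {}, [], []
    for pid in clinical.index:
        vpath = data_dir / "volumes" / f"{pid}.nii.gz"
        mpath = data_dir / "masks" / f"{pid}.nii.gz"
        if not (vpath.exists() and mpath.exists()):
            dropped.append(pid)
            continue
        vol = read_volume(vpath)
        mask = read_mask(mpath, paired_volume=vol)
        vol = normalize_intensity(resample_isotropic(vol))
        mask = resample_isotropic(mask)
        rows[pid] = feat.extract_all(vol, mask, n_gray_levels)
        kept.append(pid)
    for pid in dropped:
        log.warning("patient %s dropped: missing volume or mask", pid)
    log.info("feature extraction: %d used, %d dropped", len(kept), len(dropped))
    radiomics = pd.DataFrame.from_dict(rows, orient="index")
    radiomics.index.name = "patient_id"
    clinical = clinical.loc[kept]
    for name, df in tables.items():
        if df is not None:
            tables[name] = df.loc[df.index.intersection(kept)]
    return clinical, radiomics, tables


def _records_from_clinical(clinical: pd.DataFrame) -> list[SurvivalRecord]:
    return [
        SurvivalRecord(float(t), int(e))
        for t, e in zip(clinical["os_days"], clinical["event"])
    ]


def _round_floats(obj, ndigits=8):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis and write a self-describing report bundle.

    Stages: data acquisition (synthetic or on-disk) → preprocessing and
    45-feature extraction → univariate median-split screen with Holm
    correction → transcriptome screen → block integration → random-forest
    model (CV, holdout, or uncensored-only) → demographics + KM export +
    JSON report. Reruns with the same config produce byte-identical JSON.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    embedded = asdict(config)
    embedded.pop("outdir")  # not part of the analysis; keeps reruns comparable
    report: dict = {
        "config": _round_floats(embedded),
        "seed": config.seed,
        "stages": {},
    }

    # --- stage 1: data ---
    if config.cohort is not None:
        log.info("stage data: generating synthetic cohort (n=%d)",
                 config.cohort.n_patients)
        cohort: SyntheticCohort = generate_cohort(config.cohort)
        clinical = cohort.clinical
        radiomics = cohort.radiomics
        tables = {"mutations": cohort.mutations,
                  "expression": cohort.expression,
                  "proteins": cohort.proteins}
        report["config"]["cohort_digest"] = config.cohort.digest()
    else:
        log.info("stage data: loading from %s", config.data_dir)
        clinical, radiomics, tables = _load_from_dir(
            Path(config.data_dir), config.n_gray_levels
        )
    report["stages"]["data"] = {"n_patients": int(len(clinical))}

    records = _records_from_clinical(clinical)
    if config.mode == "uncensored-only":
        keep = clinical["event"] == 1
        n_drop = int((~keep).sum())
        log.info("uncensored-only mode: dropping %d censored patients", n_drop)
        clinical = clinical[keep]
        if radiomics is not None:
            radiomics = radiomics.loc[clinical.index]
        for k, df in tables.items():
            if df is not None:
                tables[k] = df.loc[df.index.intersection(clinical.index)]
        records = _records_from_clinical(clinical)
        imputed = np.array([r.time for r in records])
        report["stages"]["censoring"] = {"dropped_censored": n_drop}
    else:
        imputed = impute_censored(records)
        report["stages"]["censoring"] = {
            "imputed": int(sum(1 for r in records if r.event == 0))
        }

    # --- stage 2: demographics ---
    demo = cohort_summary(clinical)
    demo.to_csv(outdir / "demographics.csv", index=False)
    report["stages"]["demographics"] = {"n_strata": int(len(demo))}

    # --- stage 3: univariate radiomic screen ---
    if radiomics is not None and "radiomic" in config.blocks:
        screen = univariate_screen(radiomics, records)
        screen.to_csv(outdir / "univariate_screen.csv")
        sig = screen[screen["p_adjusted"] < 0.05].index.tolist()
        report["stages"]["screen"] = {
            "n_features": int(len(screen)),
            "significant_after_holm": sorted(sig),
        }

    # --- stage 4: transcriptome screen + block assembly ---
    block_kwargs: dict = {}
    if "radiomic" in config.blocks and radiomics is not None:
        block_kwargs["radiomics"] = radiomics
    if "clinical" in config.blocks:
        block_kwargs["clinical"] = clinical[["age", "therapy_type"]]
    if "genomic" in config.blocks and tables.get("mutations") is not None:
        block_kwargs["genomics"] = tables["mutations"]
    if "transcriptomic" in config.blocks and tables.get("expression") is not None:
        genes = transcriptome_screen(
            tables["expression"], records, alpha=config.expression_alpha
        )
        report["stages"]["transcriptome_screen"] = {"n_selected": len(genes)}
        if genes:
            block_kwargs["transcriptomics"] = tables["expression"][genes]
    if "protein" in config.blocks and tables.get("proteins") is not None:
        block_kwargs["proteins"] = tables["proteins"]
    table = integrate_blocks(**block_kwargs)
    log.info("integrated table: %d patients x %d features",
             table.n_patients, table.data.shape[1])
    report["stages"]["integrate"] = {
        "n_patients": table.n_patients,
        "n_features": int(table.data.shape[1]),
        "blocks": {b: len(table.columns_of(b)) for b in
                   sorted(set(table.blocks.values()))},
    }

    # --- stage 5: outcome labels + model ---
    labels = make_outcome(records)
    report["stages"]["outcome"] = {
        "cutoff_days": float(labels.cutoff_days),
        "n_long": int(labels.labels.sum()),
        "n_short": int((1 - labels.labels).sum()),
    }
    if config.mode in ("cv", "uncensored-only"):
        res = crossval_auc(
            table, labels, n_trees=config.n_trees, k=config.n_folds,
            seed=config.seed, compute_importance=config.compute_importance,
        )
        pred = res.predicted_groups
        model_rep = {
            "fold_aucs": [float(a) for a in res.fold_aucs],
            "mean_auc": res.mean_auc,
            "pooled_auc": res.pooled_auc,
        }
    else:
        res = train_test_eval(
            table, labels, records=records, test_size=config.test_size,
            n_trees=config.n_trees, seed=config.seed,
            compute_importance=config.compute_importance,
        )
        pred = res.predicted_groups
        model_rep = {"test_auc": res.mean_auc}
        for k in ("logrank_p", "logrank_statistic"):
            if k in res.extras:
                model_rep[k] = float(res.extras[k])

    # KM + log-rank of predicted short/long groups (scored patients only)
    scored = ~np.isnan(res.out_of_fold_scores)
    rec_scored = [r for r, s in zip(records, scored) if s]
    pred_scored = pred[scored]
    if len(set(pred_scored)) == 2:
        lr = logrank_test(
            [r for r, p in zip(rec_scored, pred_scored) if p == 0],
            [r for r, p in zip(rec_scored, pred_scored) if p == 1],
        )
        model_rep["predicted_groups_logrank_p"] = float(lr.p_value)
        km_rows = []
        for grp in (0, 1):
            curve = kaplan_meier(
                [r for r, p in zip(rec_scored, pred_scored) if p == grp]
            )
            for t, s, ar in zip(curve.event_times, curve.survival_probs,
                                curve.at_risk):
                km_rows.append((grp, float(t), float(s), int(ar)))
        pd.DataFrame(
            km_rows, columns=["predicted_group", "time", "survival", "at_risk"]
        ).to_csv(outdir / "km_predicted_groups.csv", index=False)
    if res.importances is not None:
        imp = res.importances.sort_values(ascending=False)
        imp.to_csv(outdir / "importances.csv", header=["importance"])
        model_rep["top_features"] = [
            [str(k), float(v)] for k, v in imp.head(10).items()
        ]
    report["stages"]["model"] = model_rep
    report["feature_roster_version"] = "45-feature-v1"

    payload = json.dumps(_round_floats(report), indent=2, sort_keys=True)
    (outdir / "report.json").write_text(payload)
    log.info("report written to %s", outdir / "report.json")
    return report
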