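"""End-to-end orchestration: simulate -> extract -> agreement -> screen -> model.

A run is fully described by a :class:`RunConfig`; all randomness flows
from its single seed and every stage output is a pure function of
(inputs, config, seed), so re-running a serialized config reproduces the
numeric outputs bit-for-bit.  Outputs mirror the usual reporting layout
of texture-analysis studies: an interobserver-agreement table (ICC per
feature), a univariate comparison table, a per-feature ROC table for the
significant features, and per-scope stepwise-model reports, all gathered
in ``report.json`` next to the stage CSVs and a ``run.log``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from texturestager import image_io, modeling, stats, texture
from texturestager.synthetic import CohortSpec, generate_cohort, write_cohort

logger = logging.getLogger("texturestager")

#: Caveats attached to every report.
STANDING_WARNINGS = (
    "no multiple-testing correction is applied across features",
    "model ROC metrics are in-sample (fit and evaluated on the same cohort)",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one input source is used: ``cohort`` (a synthetic-cohort
    spec, generated into the output directory) or ``manifest``/``labels``
    paths.  ``n_levels`` is the gray-level count for quantization — the
    256-level (8 bits/pixel) convention is available, but the default of
    32 keeps co-occurrence matrices well populated on small ROIs.
    """

    out_dir: str
    cohort: CohortSpec | None = None
    manifest: str | None = None
    labels: str | None = None
    n_levels: int = 32
    alpha: float = 0.05
    entry_p: float = 0.05
    removal_p: float = 0.10
    scopes: tuple[str, ...] = ("sagittal", "axial", "combined")
    reader_policy: str = "first-reader"  # or "mean-of-readers"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.manifest is None):
            raise ValueError("provide exactly one of cohort spec or manifest path")
        if self.reader_policy not in ("first-reader", "mean-of-readers"):
            raise ValueError(f"unknown reader_policy {self.reader_policy!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scopes"] = list(self.scopes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("cohort") is not None:
            d["cohort"] = CohortSpec(**d["cohort"])
        if "scopes" in d and d["scopes"] is not None:
            d["scopes"] = tuple(d["scopes"])
        return cls(**d)


def _setup_logging(out_dir: Path) -> logging.FileHandler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def _univariate_stage(table: pd.DataFrame, alpha: float):
    y = table["class_label"].to_numpy(dtype=int)
    results, rows = [], []
    for col in image_io.feature_columns(table):
        res = stats.compare_groups(table[col].to_numpy(), y, alpha=alpha, feature_name=col)
        r_s = stats.spearman_with_class(table[col].to_numpy(), y)
        results.append(res)
        (c0, s0), (c1, s1) = res.group_summaries[0], res.group_summaries[1]
        rows.append(
            {
                "feature": col, "test": res.test_used, "p_value": res.p_value,
                "significant": res.significant,
                "neg_center": c0, "neg_spread": s0,
                "pos_center": c1, "pos_spread": s1,
                "spearman_r": r_s,
            }
        )
    return results, pd.DataFrame(rows)


def _roc_stage(table: pd.DataFrame, univariate) -> pd.DataFrame:
    y = table["class_label"].to_numpy(dtype=int)
    rows = []
    for res in univariate:
        if not res.significant:
            continue
        roc = modeling.roc_analysis(table[res.feature_name].to_numpy(), y)
        rows.append(
            {
                "feature": res.feature_name, "auc": roc.auc,
                "ci_low": roc.ci_low, "ci_high": roc.ci_high,
                "sensitivity_pct": roc.sensitivity, "specificity_pct": roc.specificity,
                "cutoff": roc.cutoff_label,
            }
        )
    return pd.DataFrame(rows)


def _model_to_dict(rep: modeling.ScopeReport) -> dict:
    out = {"scope": rep.scope, "candidates": rep.candidates, "skipped": rep.skipped}
    if rep.skipped:
        out["reason"] = rep.reason
        return out
    m = rep.model
    out["selected_features"] = m.selected_features
    out["intercept"] = m.intercept
    out["terms"] = [
        {
            "feature": f,
            "coefficient": m.coefficients[f],
            "odds_ratio": m.odds_ratios[f],
            "ci_95": [m.ci_low[f], m.ci_high[f]],
            "p_value": m.p_values[f],
        }
        for f in m.selected_features
    ]
    out["hosmer_lemeshow_p"] = m.hl_p
    out["separation_flags"] = m.separation_flags
    if rep.roc is not None:
        out["roc"] = {
            "auc": rep.roc.auc,
            "ci_95": [rep.roc.ci_low, rep.roc.ci_high],
            "sensitivity_pct": rep.roc.sensitivity,
            "specificity_pct": rep.roc.specificity,
            "accuracy_pct": rep.roc.accuracy,
            "cutoff": rep.roc.cutoff_label,
        }
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and return the path of ``report.json``.

    Stage order: cohort simulation (or manifest loading), feature
    extraction for both readers, interobserver ICC, reader-policy
    reduction, univariate screening, per-feature ROC, stepwise models
    per scope.  Any stage failure leaves partial outputs plus a FAILED
    marker file naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out_dir)
    stage = "configure"
    try:
        (out_dir / "config.json").write_text(
            json.dumps(config.to_dict(), indent=2, sort_keys=True)
        )

        stage = "simulate"
        if config.cohort is not None:
            spec = dataclasses.replace(config.cohort, seed=config.seed)
            logger.info("generating synthetic cohort: %s", spec)
            manifest_path = write_cohort(generate_cohort(spec), out_dir / "cohort")
            labels_path = manifest_path.parent / "labels.csv"
        else:
            manifest_path, labels_path = Path(config.manifest), Path(config.labels)

        stage = "extract"
        samples = image_io.load_manifest(manifest_path, labels_path)
        logger.info("loaded %d ROI samples", len(samples))
        tables = {}
        for reader in (1, 2):
            if any(s.reader == reader for s in samples):
                tables[reader] = texture.compute_feature_table(
                    samples, n_levels=config.n_levels, reader=reader
                )
        table = tables[1]
        image_io.write_feature_table(table, out_dir / "features.csv")
        if 2 in tables:
            image_io.write_feature_table(tables[2], out_dir / "features_reader2.csv")

        stage = "agreement"
        icc_rows = []
        if 2 in tables:
            t2 = tables[2].set_index("subject_id").loc[table["subject_id"]]
            for col in image_io.feature_columns(table):
                a = stats.icc_two_readers(
                    table[col].to_numpy(), t2[col].to_numpy(), feature_name=col
                )
                icc_rows.append({"feature": col, "icc": a.icc, "band": a.band})
            pd.DataFrame(icc_rows).to_csv(out_dir / "icc.csv", index=False)
            if config.reader_policy == "mean-of-readers":
                merged = table.copy()
                for col in image_io.feature_columns(table):
                    merged[col] = (table[col].to_numpy() + t2[col].to_numpy()) / 2.0
                table = merged
        elif config.reader_policy == "mean-of-readers":
            logger.warning("mean-of-readers requested but only one reader present")

        stage = "univariate"
        if table["class_label"].isna().any():
            raise ValueError("univariate stage needs class labels for every subject")
        univariate, uni_df = _univariate_stage(table, config.alpha)
        uni_df.to_csv(out_dir / "univariate.csv", index=False)

        stage = "roc"
        roc_df = _roc_stage(table, univariate)
        roc_df.to_csv(out_dir / "roc.csv", index=False)

        stage = "model"
        y = table["class_label"].to_numpy(dtype=int)
        feats = table[image_io.feature_columns(table)]
        suite = modeling.run_model_suite(
            feats, y, univariate, scopes=config.scopes,
            entry_p=config.entry_p, removal_p=config.removal_p,
        )

        stage = "report"
        report = {
            "config": config.to_dict(),
            "versions": {
                "python": sys.version.split()[0],
                "numpy": np.__version__,
                "pandas": pd.__version__,
            },
            "n_subjects": int(len(table)),
            "warnings": list(STANDING_WARNINGS),
            "interobserver_icc": icc_rows,
            "univariate": uni_df.to_dict(orient="records"),
            "per_feature_roc": roc_df.to_dict(orient="records"),
            "models": {scope: _model_to_dict(rep) for scope, rep in suite.items()},
        }
        report_path = out_dir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True))
        logger.info("report written to %s", report_path)
        return report_path
    except Exception as exc:
        (out_dir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
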