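"""End-to-end study pipeline.

Per participant: pick the first of their candidate photographs passing
QC, standardise it against the in-frame white square, compute the EI
map and the mean palpebral/forniceal EI. Participants are then split
into training and validation sets by alternation in input order (first
participant to training), an ROC analysis on the training set selects
the EI cut-off maximising sensitivity + specificity, and both sets are
evaluated against laboratory haemoglobin (< 110 g/L = anaemic) with
exact CIs and Fisher's exact test. Regressions of EI on haemoglobin are
reported for the whole cohort and for the blood-sampling-delay
subgroups (photograph within 4 h of sampling vs more than 12 h apart;
the (4, 12] band is reported but belongs to neither subgroup).

Every participant appears exactly once in the report: analysed, or
excluded with a machine-readable reason. Reports are a pure function of
(config, inputs): rerunning produces byte-identical JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as dx
from .calibration import QCConfig, QCReport, calibrate, qc_assess
from .data_model import CohortTable, RGBImage, SceneAnnotation
from .erythema import classify_anaemia, ei_map, measure_annotation
from .errors import ValidationError
from .io import read_annotations, read_cohort, read_image, write_annotations, write_cohort, write_image
from .synthetic import CohortSimConfig, ColourModel, simulate_cohort

__all__ = [
    "StudyConfig",
    "SelectionResult",
    "select_image",
    "run_study",
    "simulate_and_run",
    "write_simulated_inputs",
]

log = logging.getLogger("conjscreen.pipeline")


@dataclass
class StudyConfig:
    images_dir: str | Path | None = None
    rois_path: str | Path | None = None
    cohort_path: str | Path | None = None
    out_dir: str | Path | None = None
    mode: str = "real"                 # "real" or "imagej8"
    anaemia_cutoff: float = 110.0
    ei_threshold: float | None = None  # fixed cut-off; skips ROC fitting
    split: str = "alternate"           # or "all-training"
    qc: QCConfig = field(default_factory=QCConfig)
    sim: CohortSimConfig | None = None
    model: ColourModel = field(default_factory=ColourModel)
    hb_bands: tuple[float, ...] = (90.0, 110.0, 130.0)  # inner band edges
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.anaemia_cutoff <= 0:
            raise ValidationError("anaemia_cutoff must be positive")
        if self.mode not in ("real", "imagej8"):
            raise ValidationError(f"unknown mode {self.mode!r}")
        if self.split not in ("alternate", "all-training"):
            raise ValidationError(f"unknown split {self.split!r}")


@dataclass
class SelectionResult:
    index: int | None                 # None = no candidate passed QC
    reports: list[QCReport]

    @property
    def passed(self) -> bool:
        return self.index is not None


def select_image(
    candidates: list[tuple[RGBImage, SceneAnnotation]],
    qc_config: QCConfig | None = None,
) -> SelectionResult:
    """First-pass rule: return the index of the first candidate whose QC
    report passes, with all reports for the record."""
    if not candidates:
        raise ValidationError("no candidate images supplied")
    reports = []
    for i, (image, annotation) in enumerate(candidates):
        report = qc_assess(image, annotation, qc_config)
        reports.append(report)
        if report.passed:
            return SelectionResult(index=i, reports=reports)
    return SelectionResult(index=None, reports=reports)


def _round(x, nd=6):
    if x is None:
        return None
    if isinstance(x, float):
        if np.isnan(x):
            return None
        if np.isinf(x):
            return "inf" if x > 0 else "-inf"
        return round(x, nd)
    return x


def _fit_to_dict(fit: dx.RegressionFit | None) -> dict | None:
    if fit is None:
        return None
    return {
        "slope": _round(fit.slope),
        "intercept": _round(fit.intercept),
        "slope_se": _round(fit.slope_se),
        "r_squared": _round(fit.r_squared),
        "p_zero_slope": _round(fit.p_zero_slope),
        "n": fit.n,
    }


def _summary_to_dict(s: dx.DiagnosticSummary) -> dict:
    return {
        "tp": s.table.tp, "fn": s.table.fn, "fp": s.table.fp, "tn": s.table.tn,
        "sensitivity": _round(s.sensitivity),
        "sensitivity_ci": [_round(v) for v in s.sensitivity_ci],
        "specificity": _round(s.specificity),
        "specificity_ci": [_round(v) for v in s.specificity_ci],
        "ppv": _round(s.ppv),
        "ppv_ci": [_round(v) for v in s.ppv_ci],
        "npv": _round(s.npv),
        "npv_ci": [_round(v) for v in s.npv_ci],
        "accuracy": _round(s.accuracy),
        "accuracy_ci": [_round(v) for v in s.accuracy_ci],
        "positive_lr": _round(s.positive_lr),
        "fisher_p": _round(s.fisher_p),
        "ci_level": s.ci_level,
    }


def _evaluate_set(df: pd.DataFrame, threshold: float, cutoff: float) -> dict:
    pred = classify_anaemia(df["palpebral_ei"].to_numpy(), threshold)
    truth = df["haemoglobin"].to_numpy() < cutoff
    table = dx.build_contingency(pred, truth)
    return _summary_to_dict(dx.diagnostic_summary(table))


def run_study(config: StudyConfig) -> dict:
    """Run the full analysis; returns the report as a plain dict (also
    written to ``out_dir`` as JSON + CSV tables when set)."""
    if not (config.images_dir and config.rois_path and config.cohort_path):
        raise ValidationError("images_dir, rois_path and cohort_path are required")
    images_dir = Path(config.images_dir)
    cohort = read_cohort(config.cohort_path)
    annotations = read_annotations(config.rois_path)

    # image_id convention: "<participant_id>_<k>"; candidates ordered by k
    by_participant: dict[str, list[SceneAnnotation]] = {}
    for ann in annotations:
        pid = ann.image_id.rsplit("_", 1)[0]
        by_participant.setdefault(pid, []).append(ann)
    for anns in by_participant.values():
        anns.sort(key=lambda a: a.image_id)

    rows = []
    exclusions = []
    qc_outcomes = {}
    for record in cohort:
        if not record.eligible:
            exclusions.append(
                {"id": record.id, "reason": "time_window",
                 "detail": f"delay {record.delay_hours:.1f} h > 36 h"}
            )
            continue
        anns = by_participant.get(record.id, [])
        candidates = []
        for ann in anns:
            path = images_dir / f"{ann.image_id}.png"
            if not path.exists():
                path = images_dir / f"{ann.image_id}.tiff"
            if not path.exists():
                continue
            candidates.append((read_image(path), ann))
        if not candidates:
            exclusions.append(
                {"id": record.id, "reason": "no_images", "detail": ""}
            )
            continue
        selection = select_image(candidates, config.qc)
        qc_outcomes[record.id] = [
            {"image_id": candidates[i][1].image_id,
             "passed": r.passed,
             "failing": r.failing_flags(),
             "metrics": {k: _round(v) for k, v in r.metrics.items()}}
            for i, r in enumerate(selection.reports)
        ]
        if not selection.passed:
            flags = sorted({f for r in selection.reports for f in r.failing_flags()})
            exclusions.append(
                {"id": record.id, "reason": "qc_failed", "detail": ",".join(flags)}
            )
            log.info("participant %s excluded: QC failed (%s)", record.id, flags)
            continue
        image, annotation = candidates[selection.index]
        std_image, calib = calibrate(image, annotation.white_patch, mode=config.mode)
        measurement = measure_annotation(ei_map(std_image, config.mode), annotation)
        if measurement.palpebral_ei is None:
            exclusions.append(
                {"id": record.id, "reason": "missing_palpebral_roi", "detail": ""}
            )
            continue
        log.info(
            "participant %s: image %s, palpebral EI %.2f",
            record.id, annotation.image_id, measurement.palpebral_ei,
        )
        rows.append(
            {
                "id": record.id,
                "image_id": annotation.image_id,
                "haemoglobin": record.haemoglobin,
                "anaemic": record.haemoglobin < config.anaemia_cutoff,
                "delay_hours": record.delay_hours,
                "palpebral_ei": measurement.palpebral_ei,
                "palpebral_n": measurement.palpebral_n,
                "forniceal_ei": measurement.forniceal_ei,
                "forniceal_n": measurement.forniceal_n,
                "clipped_fraction": calib.clipped_fraction,
            }
        )

    if not rows:
        raise ValidationError("no participant passed eligibility and QC")
    df = pd.DataFrame(rows)

    # --- association statistics -------------------------------------------
    stats_block: dict = {}
    both = df.dropna(subset=["forniceal_ei"])
    if len(both) >= 2:
        try:
            t, p = dx.paired_t(both["palpebral_ei"], both["forniceal_ei"])
            stats_block["paired_t_palpebral_vs_forniceal"] = {
                "t": _round(t), "p": _round(p), "n": len(both)
            }
        except ValidationError:
            pass
    for name, values in [
        ("haemoglobin", df["haemoglobin"]),
        ("palpebral_ei", df["palpebral_ei"]),
        ("forniceal_ei", both["forniceal_ei"]),
    ]:
        if len(values) >= 20:
            k2, p = dx.normality_test(values.to_numpy())
            stats_block.setdefault("normality", {})[name] = {
                "k2": _round(k2), "p": _round(p)
            }

    regressions = {
        "palpebral": _fit_to_dict(
            dx.linear_fit(df["haemoglobin"], df["palpebral_ei"])
        )
    }
    if len(both) >= 3 and both["haemoglobin"].nunique() > 1:
        regressions["forniceal"] = _fit_to_dict(
            dx.linear_fit(both["haemoglobin"], both["forniceal_ei"])
        )
    for name, sub in [
        ("delay_le_4h", df[df["delay_hours"] <= 4.0]),
        ("delay_gt_12h", df[df["delay_hours"] > 12.0]),
    ]:
        if len(sub) >= 3 and sub["haemoglobin"].nunique() > 1:
            regressions[name] = _fit_to_dict(
                dx.linear_fit(sub["haemoglobin"], sub["palpebral_ei"])
            )
    delay_bands = {
        "le_4h": int((df["delay_hours"] <= 4.0).sum()),
        "between_4_and_12h": int(
            ((df["delay_hours"] > 4.0) & (df["delay_hours"] <= 12.0)).sum()
        ),
        "gt_12h": int((df["delay_hours"] > 12.0).sum()),
    }

    # one-way ANOVA of palpebral EI across haemoglobin bands
    edges = (-np.inf, *config.hb_bands, np.inf)
    groups = {}
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = df[(df["haemoglobin"] >= lo) & (df["haemoglobin"] < hi)]
        if len(sel) >= 2:
            groups[f"[{lo:g},{hi:g})"] = sel["palpebral_ei"].to_numpy()
    anova_block = None
    if len(groups) >= 2:
        res = dx.one_way_anova_bonferroni(groups)
        anova_block = {
            "F": _round(res.effects["group"].F),
            "df": res.effects["group"].df,
            "p": _round(res.effects["group"].p),
            "pairwise": [
                {"a": c.group_a, "b": c.group_b,
                 "difference": _round(c.difference),
                 "p_adjusted": _round(c.p_adjusted)}
                for c in res.pairwise
            ],
        }

    # --- split, threshold, evaluation -------------------------------------
    if config.split == "alternate":
        train_df = df.iloc[0::2]
        valid_df = df.iloc[1::2]
    else:
        train_df = df
        valid_df = df.iloc[0:0]

    threshold_block: dict = {}
    if config.ei_threshold is not None:
        threshold = float(config.ei_threshold)
        threshold_block = {"source": "fixed", "threshold": _round(threshold)}
    else:
        truth = train_df["haemoglobin"].to_numpy() < config.anaemia_cutoff
        if truth.sum() < 2 or (~truth).sum() < 2:
            raise ValidationError(
                "threshold fitting needs >= 2 training participants per class"
            )
        curve = dx.roc_curve(train_df["palpebral_ei"].to_numpy(), truth)
        chosen = dx.youden_threshold(curve)
        lo, hi = dx.auc_ci(curve.auc, curve.n_pos, curve.n_neg)
        threshold = chosen.threshold
        threshold_block = {
            "source": "youden_on_training",
            "threshold": _round(threshold),
            "training_sensitivity": _round(chosen.sensitivity),
            "training_specificity": _round(chosen.specificity),
            "auc": _round(curve.auc),
            "auc_ci": [_round(lo), _round(hi)],
            "n_pos": curve.n_pos,
            "n_neg": curve.n_neg,
        }

    evaluation = {"training": _evaluate_set(train_df, threshold, config.anaemia_cutoff)}
    if len(valid_df) and valid_df["anaemic"].nunique() > 1:
        evaluation["validation"] = _evaluate_set(
            valid_df, threshold, config.anaemia_cutoff
        )

    report = {
        "config": {
            "mode": config.mode,
            "anaemia_cutoff_g_per_L": config.anaemia_cutoff,
            "split": config.split,
            "seed": config.seed,
        },
        "counts": {
            "cohort": len(cohort),
            "analysed": len(df),
            "excluded": len(exclusions),
            "training": len(train_df),
            "validation": len(valid_df),
            "anaemic_analysed": int(df["anaemic"].sum()),
            "delay_bands": delay_bands,
        },
        "qc": qc_outcomes,
        "exclusions": exclusions,
        "measurements": df.round(6).to_dict(orient="records"),
        "statistics": stats_block,
        "regressions": regressions,
        "hb_band_anova": anova_block,
        "threshold": threshold_block,
        "evaluation": evaluation,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        df.to_csv(out / "measurements.csv", index=False)
        pd.DataFrame(exclusions).to_csv(out / "exclusions.csv", index=False)
        _write_table1(evaluation, out / "table1.csv")
    return report


def _write_table1(evaluation: dict, path: Path) -> None:
    """CSV in the layout of a diagnostic-characteristics table: one
    column per evaluated set, one row per statistic."""
    rows = [
        "positive_predictive_value", "negative_predictive_value",
        "positive_likelihood_ratio", "sensitivity", "specificity",
        "accuracy", "fisher_p",
    ]
    keymap = {
        "positive_predictive_value": "ppv",
        "negative_predictive_value": "npv",
        "positive_likelihood_ratio": "positive_lr",
        "sensitivity": "sensitivity",
        "specificity": "specificity",
        "accuracy": "accuracy",
        "fisher_p": "fisher_p",
    }
    data = {"statistic": rows}
    for name, summary in evaluation.items():
        data[name] = [summary[keymap[r]] for r in rows]
    pd.DataFrame(data).to_csv(path, index=False)


def write_simulated_inputs(sim, out_dir: str | Path) -> tuple[Path, Path, Path]:
    """Write a simulated cohort through the public file interfaces
    (PNG scenes, ROI JSON, cohort CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    images_dir = out / "images"
    images_dir.mkdir(exist_ok=True)
    annotations = []
    for scene in sim.scenes:
        if scene.image is None:
            raise ValidationError("simulation was run with render_scenes=False")
        write_image(scene.image, images_dir / f"{scene.image.id}.png")
        annotations.append(scene.annotation)
    rois_path = out / "rois.json"
    cohort_path = out / "cohort.csv"
    write_annotations(annotations, rois_path)
    write_cohort(sim.cohort, cohort_path)
    return images_dir, rois_path, cohort_path


def simulate_and_run(config: StudyConfig) -> dict:
    """Generate a synthetic cohort, write it to disk through the public
    file formats, then run the full study pipeline on the files."""
    if config.sim is None:
        raise ValidationError("config.sim (generator settings) is required")
    if not config.out_dir:
        raise ValidationError("out_dir is required for simulate_and_run")
    sim = simulate_cohort(config.sim, config.model)
    images_dir, rois_path, cohort_path = write_simulated_inputs(
        sim, Path(config.out_dir) / "sim_inputs"
    )
    run_config = dataclasses.replace(
        config, images_dir=images_dir, rois_path=rois_path, cohort_path=cohort_path
    )
    return run_study(run_config)
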