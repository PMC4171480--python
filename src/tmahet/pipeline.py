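"""End-to-end orchestration: images -> QC -> features -> survival models.

A single config drives the stages in order.  Images failing quality
control are excluded from feature extraction and every downstream
analysis; a case stays informative while at least one of its images
passes.  Per-stage counts (images in/passed/failed, informative cases)
are logged and echoed into the run report so the cohort accounting is
reproducible from the outputs alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tmahet import cutpoint as cutpoint_mod
from tmahet import features as features_mod
from tmahet import qc as qc_mod
from tmahet import rsf as rsf_mod
from tmahet import segment as segment_mod
from tmahet import synth as synth_mod

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Stage parameter blocks plus run-level settings.

    Input is either a synthetic cohort (``synth`` block) or a manifest
    CSV of image paths (``manifest_path`` + ``survival_path``).
    ``qc_mode``: ``"none"`` (all images pass), ``"manual"`` (manifest
    ``qc_label`` column, values pass/fail) or ``"classifier"``
    (logistic QC model trained on the manifest's labelled images,
    applied to the rest).  Unknown config keys are rejected.
    """

    seed: int = 0
    output_dir: str = "tmahet_run"
    qc_mode: str = "none"
    synth: synth_mod.SyntheticCohortSpec | None = None
    manifest_path: str | None = None
    survival_path: str | None = None
    dapi_channel: str = "DAPI"
    cd99_channel: str = "CD99"
    segment: dict = field(default_factory=dict)
    feature_cols: list[str] | None = None
    cutpoint_centiles: list[int] = field(default_factory=lambda: list(range(10, 100, 10)))
    run_cutpoint: bool = True
    rsf: dict = field(default_factory=lambda: {"n_trees": 200})
    run_rsf: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if isinstance(d.get("synth"), dict):
            sd = dict(d["synth"])
            if isinstance(sd.get("image_spec"), dict):
                sd["image_spec"] = synth_mod.SyntheticImageSpec(
                    **{
                        k: tuple(v) if isinstance(v, list) else v
                        for k, v in sd["image_spec"].items()
                    }
                )
            for k in ("images_per_patient", "subpop_beta"):
                if k in sd:
                    sd[k] = tuple(sd[k])
            d["synth"] = synth_mod.SyntheticCohortSpec(**sd)
        return cls(**d)

    def to_jsonable(self) -> dict:
        def enc(v):
            if dataclasses.is_dataclass(v) and not isinstance(v, type):
                return {k: enc(x) for k, x in dataclasses.asdict(v).items()}
            if isinstance(v, tuple):
                return list(v)
            return v

        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


class PipelineStageError(RuntimeError):
    """A stage failed; the message names the stage."""


def qc_filter(
    manifest: pd.DataFrame, qc_pass: pd.Series, mode: str = "manual"
) -> tuple[pd.DataFrame, dict]:
    """Apply per-image QC results; keep cases with >= 1 passing image.

    ``qc_pass`` is indexed by image_id (boolean).  Returns the filtered
    manifest and an accounting summary: image and case counts with the
    eliminated percentage (rounded to integer, exact fraction
    alongside).  A missing QC record for any image is an error.
    """
    missing = set(manifest["image_id"]) - set(qc_pass.index)
    if missing:
        raise PipelineStageError(f"qc: missing QC records for {sorted(missing)[:5]}")
    passed = manifest["image_id"].map(qc_pass).astype(bool)
    kept = manifest[passed].reset_index(drop=True)
    cases = manifest["patient_id"].nunique()
    informative = kept["patient_id"].nunique()
    eliminated = cases - informative
    summary = {
        "qc_mode": mode,
        "images_in": int(len(manifest)),
        "images_passed": int(passed.sum()),
        "images_failed": int((~passed).sum()),
        "cases_imaged": int(cases),
        "cases_informative": int(informative),
        "cases_eliminated": int(eliminated),
        "eliminated_fraction": eliminated / cases if cases else 0.0,
        "eliminated_percent": int(round(100 * eliminated / cases)) if cases else 0,
    }
    log.info(
        "QC: %d/%d images passed; %d/%d cases informative (%d%% eliminated)",
        summary["images_passed"],
        summary["images_in"],
        informative,
        cases,
        summary["eliminated_percent"],
    )
    return kept, summary


def _qc_pass_series(cfg, manifest, images) -> pd.Series:
    if cfg.qc_mode == "none":
        return pd.Series(True, index=manifest["image_id"])
    if cfg.qc_mode == "manual":
        if "qc_label" not in manifest:
            raise PipelineStageError("qc: manual mode needs a qc_label column")
        return pd.Series(
            (manifest["qc_label"].astype(str) == "pass").to_numpy(),
            index=manifest["image_id"],
        )
    if cfg.qc_mode == "classifier":
        if "qc_label" not in manifest or manifest["qc_label"].isna().all():
            raise PipelineStageError("qc: classifier mode needs labelled images")
        feats = qc_mod.qc_feature_table(
            {iid: images[iid][cfg.dapi_channel] for iid in manifest["image_id"]}
        )
        labelled = manifest.dropna(subset=["qc_label"])
        y = labelled["qc_label"].map({"pass": "good", "fail": "poor"})
        clf = qc_mod.train_qc_classifier(
            feats.loc[labelled["image_id"]], y, feature_subset="all12"
        )
        p_poor = clf.predict_proba(feats[clf.feature_columns_].to_numpy())[:, 1]
        return pd.Series(p_poor < 0.5, index=feats.index)
    raise PipelineStageError(f"qc: unknown qc_mode {cfg.qc_mode!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; write outputs under ``config.output_dir``.

    Returns the run report (also written as ``report.json``).  A stage
    failure raises :class:`PipelineStageError` naming the stage;
    outputs of completed stages are retained.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_jsonable(), indent=2))
    report: dict = {"seed": config.seed}

    # ---- input stage -----------------------------------------------------
    try:
        if config.synth is not None:
            cohort = synth_mod.generate_cohort(config.synth)
            images = cohort.images
            manifest = cohort.manifest
            survival = cohort.survival
        elif config.manifest_path and config.survival_path:
            manifest = pd.read_csv(config.manifest_path)
            survival = pd.read_csv(config.survival_path)
            images = {}
            for row in manifest.itertuples():
                img = synth_mod.read_image(row.image_path)
                img.image_id = row.image_id
                img.patient_id = row.patient_id
                images[row.image_id] = img
        else:
            raise ValueError("config needs either a synth block or manifest paths")
    except Exception as exc:
        raise PipelineStageError(f"input: {exc}") from exc
    manifest.to_csv(out / "manifest.csv", index=False)
    survival.to_csv(out / "survival.csv", index=False)

    # ---- QC stage --------------------------------------------------------
    try:
        qc_pass = _qc_pass_series(config, manifest, images)
        kept, qc_summary = qc_filter(manifest, qc_pass, config.qc_mode)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(f"qc: {exc}") from exc
    report["qc"] = qc_summary
    pd.DataFrame(
        {"image_id": qc_pass.index, "qc_pass": qc_pass.to_numpy()}
    ).to_csv(out / "qc_results.csv", index=False)

    # ---- segmentation + cell features ------------------------------------
    try:
        cell_tables = []
        for row in kept.itertuples():
            img = images[row.image_id]
            seg = segment_mod.segment_cells(
                img,
                dapi_channel=config.dapi_channel,
                cd99_channel=config.cd99_channel,
                **config.segment,
            )
            cell_tables.append(features_mod.extract_cell_features(img, seg))
        cells = (
            pd.concat(cell_tables, ignore_index=True)
            if cell_tables
            else pd.DataFrame()
        )
    except Exception as exc:
        raise PipelineStageError(f"segment: {exc}") from exc
    cells.to_csv(out / "cells.csv", index=False)
    report["segmentation"] = {
        "images_segmented": len(cell_tables),
        "cells_total": int(len(cells)),
    }

    # ---- patient features -------------------------------------------------
    try:
        if config.feature_cols is None:
            feature_cols = [
                c for c in cells.columns if c.endswith(("_log2_nc_mean", "_log2_nc_total"))
            ]
        else:
            feature_cols = config.feature_cols
        pdf = features_mod.patient_distribution_features(cells, feature_cols)
        matrix = pdf.flat()
    except Exception as exc:
        raise PipelineStageError(f"features: {exc}") from exc
    matrix.to_csv(out / "patient_features.csv")
    report["features"] = {
        "patients": int(len(matrix)),
        "features_per_patient": int(matrix.shape[1]),
    }

    surv = survival.set_index("patient_id").loc[matrix.index]
    time = surv["time_days"].to_numpy()
    event = surv["event"].to_numpy()

    # ---- cut-point stage ---------------------------------------------------
    if config.run_cutpoint and "cd99_log2_nc_mean" in cells:
        try:
            grid = cutpoint_mod.threshold_grid_cox(
                cells,
                survival,
                cd99_centiles=np.asarray(config.cutpoint_centiles),
                ki67_centiles=np.asarray(config.cutpoint_centiles),
            )
            grid.table.to_csv(out / "cutpoint_grid.csv", index=False)
            opt = grid.optimal
            report["cutpoint"] = {
                "min_p": float(opt["p"]),
                "optimal_centile_cd99": int(opt["centile_cd99"]),
                "optimal_centile_ki67": int(opt["centile_ki67"]),
            }
        except Exception as exc:
            raise PipelineStageError(f"cutpoint: {exc}") from exc

    # ---- RSF stage ---------------------------------------------------------
    if config.run_rsf:
        try:
            # a stratum with no cells encodes as zero density, not NaN
            X = matrix.fillna(0.0)
            report["rsf"] = {"n_patients": int(len(X))}
            params = rsf_mod.RSFParams(seed=config.seed, **config.rsf)
            if len(X) >= 20 and event.sum() >= 5:
                model = rsf_mod.fit_rsf(X, time, event, params)
                mort, curves = rsf_mod.predict(model, X)
                pd.DataFrame(
                    {"patient_id": X.index, "predicted_mortality": mort}
                ).to_csv(out / "rsf_mortality.csv", index=False)
                curves.to_csv(out / "rsf_survival_curves.csv")
                report["rsf"]["oob_error"] = model.oob_error
            else:
                report["rsf"]["skipped"] = (
                    "fewer than 20 patients or 5 events after QC"
                )
        except Exception as exc:
            raise PipelineStageError(f"rsf: {exc}") from exc

    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report
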