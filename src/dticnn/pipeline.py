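"""End-to-end orchestration: simulate -> prepare -> evaluate -> analyze.

Every stage logs its seed and wall time; the run directory receives all
artifacts plus a machine-readable ``results.json``.  Identical
(config, seed) gives identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import nibabel as nib
import numpy as np

from . import evaluation as ev
from . import features as ft
from . import model as pcnn
from . import prep
from . import roi as roi_mod
from .config import RunConfig

log = logging.getLogger("dticnn")


def run_pipeline(config: RunConfig) -> dict:
    from .synthetic import generate_cohort  # local import keeps CLI startup light

    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config_hash": _config_hash(config)}

    try:
        # -- simulate ------------------------------------------------------
        t0 = time.time()
        log.info("simulate: seed=%d", config.cohort.seed)
        records, atlas, manifest = generate_cohort(config.cohort, out / "cohort")
        summary.setdefault("stages", {})["simulate"] = {"wall_time_s": round(time.time() - t0, 2)}

        # -- prepare -------------------------------------------------------
        t0 = time.time()
        store = prep.build_record_store(manifest, config.prep_target_shape, out / "store.h5")
        summary["stages"]["prepare"] = {"wall_time_s": round(time.time() - t0, 2)}

        # -- evaluate ------------------------------------------------------
        t0 = time.time()
        plan_seed = config.stage_seed("folds")
        log.info("evaluate: fold seed=%d", plan_seed)
        plan = ev.make_fold_plan(store.subject_ids, plan_seed)
        (out / "fold_plan.json").write_text(plan.to_json())
        cv = ev.run_nested_cv(store, config.model, plan)
        summary["pcnn"] = cv.summary()
        if cv.best_model is not None:
            pcnn.save_checkpoint(cv.best_model, out / "best_model.npz")
        if config.run_svm:
            svm = ev.svm_baseline(store, plan)
            summary["svm"] = svm.summary()
        summary["stages"]["evaluate"] = {"wall_time_s": round(time.time() - t0, 2)}

        # -- features ------------------------------------------------------
        if config.run_features and cv.best_model is not None:
            t0 = time.time()
            table = ft.feature_group_analysis(cv.best_model, store, config.features_alpha)
            table.to_csv(out / "feature_stats.csv", index=False)
            summary["features"] = {
                "n_sig_mean": int(table["sig_mean"].sum()),
                "n_sig_entropy": int(table["sig_H"].sum()),
                "entropy_larger_group": "A" if (table["H_A"] > table["H_B"]).mean() > 0.5 else "B",
            }
            summary["stages"]["features"] = {"wall_time_s": round(time.time() - t0, 2)}

        # -- roi -----------------------------------------------------------
        if config.run_roi:
            t0 = time.time()
            raw_store = prep.build_record_store(
                manifest, config.cohort.volume_shape, out / "store_raw.h5"
            )
            results = roi_mod.map_all_rois(raw_store, atlas, config.roi_model, plan)
            acc_map = roi_mod.build_accuracy_map(atlas, results)
            nib.save(nib.Nifti1Image(acc_map.astype(np.float32), np.eye(4)), str(out / "roi_accuracy_map.nii.gz"))
            ranks = roi_mod.rank_rois(results, config.roi_top_k)
            for tissue, tbl in ranks.items():
                tbl.to_csv(out / f"roi_top_{tissue}.csv", index=False)
            summary["roi"] = {
                "per_roi": {
                    str(r.roi_id): {"name": r.roi_name, "tissue": r.tissue, "mean_accuracy": r.mean_accuracy}
                    for r in results
                },
                "top_gray": ranks["gray"].to_dict("records"),
                "top_white": ranks["white"].to_dict("records"),
            }
            summary["stages"]["roi"] = {"wall_time_s": round(time.time() - t0, 2)}
    except Exception as exc:
        summary["error"] = f"{type(exc).__name__}: {exc}"
        (out / "results.json").write_text(json.dumps(summary, indent=2))
        raise

    (out / "results.json").write_text(json.dumps(summary, indent=2))
    return summary


def _config_hash(config: RunConfig) -> str:
    fields = {k: v for k, v in vars(config).items() if k != "out"}
    fields["cohort"] = repr(config.cohort)
    blob = repr(sorted(fields.items(), key=lambda kv: kv[0])).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
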