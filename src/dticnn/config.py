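"""Run configuration: one YAML file drives the whole pipeline.

Per-stage seeds are derived as sha256(global_seed, stage) so stages are
decoupled but the run is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import DomainError
from .model import TrainingConfig
from .synthetic import CohortSpec, GroupEffect, derive_seed


@dataclass
class RunConfig:
    seed: int
    out: Path
    cohort: CohortSpec
    prep_target_shape: tuple
    model: TrainingConfig
    roi_model: TrainingConfig
    features_alpha: float = 0.05
    roi_top_k: int = 5
    run_svm: bool = True
    run_roi: bool = True
    run_features: bool = True

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, stage)


def _effects_from_cfg(items) -> list:
    effects = []
    for it in items or []:
        effects.append(
            GroupEffect(
                kind=it["kind"],
                target_roi_ids=frozenset(it.get("target_roi_ids", [])),
                magnitude=float(it.get("magnitude", 0.0)),
                direction=int(it.get("direction", +1)),
            )
        )
    return effects


def load_run_config(path, seed: int | None = None, out=None) -> RunConfig:
    """Parse and validate a YAML run configuration (fails fast)."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise DomainError(f"config root must be a mapping; got {type(raw).__name__}")
    unknown = set(raw) - {"seed", "out", "cohort", "prep", "model", "evaluation", "features", "roi"}
    if unknown:
        raise DomainError(f"unknown config sections: {sorted(unknown)}")
    try:
        run_seed = int(seed if seed is not None else raw.get("seed", 0))
        cohort_raw = dict(raw.get("cohort") or {})
        cohort_raw.setdefault("seed", derive_seed(run_seed, "cohort"))
        cohort_raw["effects"] = _effects_from_cfg(cohort_raw.get("effects"))
        cohort = CohortSpec(**cohort_raw)

        prep_raw = dict(raw.get("prep") or {})
        target_shape = tuple(prep_raw.get("target_shape", cohort.volume_shape))

        model_raw = dict(raw.get("model") or {})
        model_raw.setdefault("seed", derive_seed(run_seed, "model"))
        model_cfg = TrainingConfig(**model_raw)

        roi_raw = dict(raw.get("roi") or {})
        top_k = int(roi_raw.pop("top_k", 5))
        run_roi = bool(roi_raw.pop("enabled", True))
        roi_model_raw = {**model_raw, **{k: v for k, v in roi_raw.items() if k != "enabled"}}
        roi_cfg = TrainingConfig(**roi_model_raw)

        feat_raw = dict(raw.get("features") or {})
        ev_raw = dict(raw.get("evaluation") or {})
    except (TypeError, KeyError, ValueError) as exc:
        raise DomainError(f"invalid configuration: {exc}") from exc
    return RunConfig(
        seed=run_seed,
        out=Path(out if out is not None else raw.get("out", "run")),
        cohort=cohort,
        prep_target_shape=target_shape,
        model=model_cfg,
        roi_model=roi_cfg,
        features_alpha=float(feat_raw.get("alpha", 0.05)),
        roi_top_k=top_k,
        run_svm=bool(ev_raw.get("svm", True)),
        run_roi=run_roi,
        run_features=bool(feat_raw.get("enabled", True)),
    )
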