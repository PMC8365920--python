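"""Model configuration loading and muscle/skeleton construction."""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import yaml

from .body import MusclePaths, SkeletonParams
from .muscle import MUSCLES_PER_LEG, MuscleParams

DEFAULT_CONFIG_RESOURCE = "default_model.yaml"


def load_model_config(path: str | Path | None = None) -> dict:
    """Load a model config file; the packaged default when path is None."""
    if path is None:
        ref = resources.files("planargait").joinpath(
            f"data/{DEFAULT_CONFIG_RESOURCE}")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if cfg.get("schema") != "planargait-model-v1":
        raise ValueError("unrecognized model config schema")
    missing = {"segments", "joints", "contact", "muscles"} - set(cfg)
    if missing:
        raise ValueError(f"model config missing sections: {sorted(missing)}")
    return cfg


def config_hash(cfg: dict) -> str:
    """Short stable hash of a config dict, for log provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def build_muscles(cfg: dict, sides: tuple[str, ...] = ("R", "L"),
                  names: tuple[str, ...] = MUSCLES_PER_LEG
                  ) -> list[MuscleParams]:
    """Instantiate per-side MuscleParams in canonical order (right leg
    first, then left, each in HAB..TA order)."""
    out = []
    for side in sides:
        for name in names:
            mc = cfg["muscles"][name]
            out.append(MuscleParams(
                name=f"{name}_{side}",
                f_max=float(mc["f_max"]),
                l_opt=float(mc["l_opt"]),
                l_slack=float(mc["l_slack"]),
                v_max=float(mc.get("v_max", 10.0)),
                tau_act=float(mc.get("tau_act", 0.015)),
                tau_deact=float(mc.get("tau_deact", 0.05)),
                fv_ecc_plateau=float(mc.get("fv_ecc_plateau", 1.5)),
            ))
    return out


def build_model(cfg: dict | None = None
                ) -> tuple[SkeletonParams, list[MuscleParams], MusclePaths]:
    """Skeleton, 22 muscles, and path model from a config dict."""
    if cfg is None:
        cfg = load_model_config()
    skel = SkeletonParams.from_config(cfg)
    muscles = build_muscles(cfg)
    paths = MusclePaths.from_config(cfg, muscles)
    return skel, muscles, paths
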