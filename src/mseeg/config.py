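"""YAML round-trip for the full pipeline configuration.

One file carries every default — synthesis parameters, frame length and
overlap, wavelet, feature settings, m-ACO and GOA hyperparameters, fold
count and seeds — so any run is reproducible from the file alone.
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .classify import GoaConfig
from .evaluate import EvalConfig
from .features import FeatureConfig
from .selection import MacoConfig
from .synthetic import SyntheticSpec

__all__ = ["load_config", "save_config", "default_config"]

_SECTIONS = {
    "synthetic": SyntheticSpec,
    "features": FeatureConfig,
    "maco": MacoConfig,
    "goa": GoaConfig,
}


def default_config() -> dict:
    """Nested dict of every tunable with its default value."""
    eval_cfg = EvalConfig()
    top = {
        f.name: getattr(eval_cfg, f.name)
        for f in fields(EvalConfig)
        if f.name not in ("features", "maco", "goa")
    }
    out = {"evaluate": top, "synthetic": asdict(SyntheticSpec())}
    out["features"] = asdict(FeatureConfig())
    out["maco"] = asdict(MacoConfig())
    out["goa"] = asdict(GoaConfig())
    return out


def save_config(path, config: dict | None = None) -> None:
    with open(Path(path), "w") as fh:
        yaml.safe_dump(config or default_config(), fh, sort_keys=False)


def _build(cls, data: dict):
    names = {f.name for f in fields(cls)}
    kwargs = {k: v for k, v in (data or {}).items() if k in names}
    # YAML stores tuples as lists; dataclasses that expect tuples convert them
    for f in fields(cls):
        if f.name in kwargs and isinstance(kwargs[f.name], list):
            inner = kwargs[f.name]
            kwargs[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in inner
            )
    return cls(**kwargs)


def load_config(path) -> tuple[EvalConfig, SyntheticSpec]:
    """Build an :class:`EvalConfig` and a :class:`SyntheticSpec` from YAML."""
    with open(Path(path)) as fh:
        data = yaml.safe_load(fh) or {}
    eval_kwargs = dict(data.get("evaluate", {}))
    eval_cfg = _build(EvalConfig, eval_kwargs)
    eval_cfg.features = _build(FeatureConfig, data.get("features", {}))
    eval_cfg.maco = _build(MacoConfig, data.get("maco", {}))
    eval_cfg.goa = _build(GoaConfig, data.get("goa", {}))
    spec = _build(SyntheticSpec, data.get("synthetic", {}))
    return eval_cfg, spec
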