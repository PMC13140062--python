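"""Flat key-value configuration.

All numeric knobs of the pipeline (BOILED-Egg ellipse constants, rule-of-five
cutoffs, the Active/Inactive probability threshold, the risk-band boundaries
and output rounding) live in ``data/defaults.yaml`` so every choice is
auditable and overridable from a user config file.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import yaml

from .errors import ValidationError


def default_config() -> dict:
    """Return a fresh copy of the packaged default settings."""
    text = resources.files("herbcyp.data").joinpath("defaults.yaml").read_text("utf-8")
    return yaml.safe_load(text)


def load_config(path: str | None = None) -> dict:
    """Merge a user YAML config (flat key: value mapping) over the defaults."""
    cfg = default_config()
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValidationError(f"config file {path!r} is not a key-value mapping")
        unknown = sorted(set(user) - set(cfg))
        if unknown:
            raise ValidationError([f"unknown config key: {k}" for k in unknown])
        cfg.update(user)
    _check(cfg)
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration, for run logs."""
    blob = "\n".join(f"{k}={cfg[k]!r}" for k in sorted(cfg))
    return hashlib.sha256(blob.encode("utf-8")).hexdigest()[:12]


def _check(cfg: dict) -> None:
    problems = []
    t = cfg["activity_threshold_percent"]
    if not 0 < t < 100:
        problems.append(f"activity_threshold_percent must lie in (0, 100), got {t}")
    lo, hi = cfg["risk_moderate_mean_percent"], cfg["risk_high_mean_percent"]
    if not lo < hi:
        problems.append(f"risk band boundaries must be ordered: {lo} !< {hi}")
    if problems:
        raise ValidationError(problems)
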