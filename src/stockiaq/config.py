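"""YAML-backed run configuration.

A single YAML file can override any pipeline or generator default; absent
keys fall back to the package defaults, so an empty (or missing) file is a
valid configuration.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .assembly import DEFAULT_PIPELINE_CONFIG


def load_config(path: str | Path | None = None) -> dict:
    """Load a pipeline configuration, merging over the defaults."""
    cfg = {k: v for k, v in DEFAULT_PIPELINE_CONFIG.items()}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("configuration must be a YAML mapping")
        cfg.update(loaded)
    return cfg
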