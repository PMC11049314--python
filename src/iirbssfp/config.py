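"""YAML/JSON configuration loading for sequence and tissue parameters."""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .params import ParameterError, SequenceParams, SinglePoolTissue, TwoPoolTissue

__all__ = ["read_config", "load_sequence", "load_tissues"]


def read_config(path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def load_sequence(path) -> SequenceParams:
    """Sequence settings from the ``sequence:`` section (or the whole file)."""
    cfg = read_config(path)
    return SequenceParams(**cfg.get("sequence", cfg))


def load_tissues(path) -> dict:
    """Named tissues from the ``tissues:`` section.

    Entries with an ``mf`` key become two-pool tissues, the rest single-pool.
    """
    cfg = read_config(path)
    tissues = cfg.get("tissues")
    if tissues is None:
        raise ParameterError(f"{path}: no 'tissues' section")
    out = {}
    for name, kw in tissues.items():
        cls = TwoPoolTissue if "mf" in kw else SinglePoolTissue
        out[name] = cls(**kw)
    return out
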