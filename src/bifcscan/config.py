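"""YAML configuration for simulations.

Schema::

    sort:
      n_cells: 100000
      n_reads_per_condition: 1000000
      bifc_top_fraction: 0.05
      ...                      # any SortSpec field
    effects:
      neutral:     {proportion: 0.8}
      aggregating: {proportion: 0.1, expr: 0.7, agg: 5.0}
      interface:   {proportion: 0.1, dimer: 0.2}
    signal:
      alpha: 1.0
      beta: 0.5
      gamma: 1.0
      cv_noise: 0.5

Parameter values in ``effects`` may be scalars or two-element lists
interpreted as uniform (low, high) ranges.
"""

from __future__ import annotations

import yaml

from .core import SortSpec, ValidationError
from .simulate import DEFAULT_EFFECTS, EffectClass

SIGNAL_DEFAULTS = {"alpha": 1.0, "beta": 0.5, "gamma": 1.0, "cv_noise": 0.5}


def _maybe_range(value):
    if isinstance(value, (list, tuple)):
        if len(value) != 2:
            raise ValidationError(f"parameter range must have two elements, got {value}")
        return (float(value[0]), float(value[1]))
    return float(value)


def load_config(path) -> tuple[SortSpec, dict[str, EffectClass], dict[str, float]]:
    """Load (SortSpec, effect classes, signal weights) from a YAML file;
    omitted sections fall back to package defaults."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    sort = SortSpec(**(cfg.get("sort") or {}))
    effects = dict(DEFAULT_EFFECTS)
    for name, fields in (cfg.get("effects") or {}).items():
        fields = dict(fields or {})
        proportion = float(fields.pop("proportion", 0.0))
        params = {k: _maybe_range(v) for k, v in fields.items()}
        unknown = set(params) - {"expr", "dimer", "agg", "clust"}
        if unknown:
            raise ValidationError(f"unknown effect parameters for class {name!r}: {sorted(unknown)}")
        effects[name] = EffectClass(name, proportion=proportion, **params)
    signal = dict(SIGNAL_DEFAULTS)
    signal.update({k: float(v) for k, v in (cfg.get("signal") or {}).items()})
    unknown = set(signal) - set(SIGNAL_DEFAULTS)
    if unknown:
        raise ValidationError(f"unknown signal parameters: {sorted(unknown)}")
    return sort, effects, signal
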