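"""Default configuration and YAML loading.

Values here are the single source for PSI grids and priors, fit floors,
and generator defaults, so nothing is hard-coded at call sites.
"""

from __future__ import annotations

import copy
import json
import hashlib
from pathlib import Path

import yaml

DEFAULT_CONFIG: dict = {
    "psi": {
        # (kappa, alpha) grid with the asynchronous contamination link
        "kappa_min": 0.5,
        "kappa_max": 200.0,
        "n_kappa": 40,
        "alpha_min": 0.5,
        "alpha_max": 1.0,
        "n_alpha": 20,
        # candidate foil offsets |delta|: dense grid on (0, pi]
        "n_stimulus": 180,
        "prior": "uniform",
        "n_trials": 80,
    },
    "fit": {
        "min_analogue_trials": 10,
        "min_afc_trials": 20,
        "min_delta_levels": 5,
    },
    "design": {
        "set_sizes": [1, 4],
        "timings": ["synchronous", "asynchronous"],
        "delays_ms": [0, 1000],
        "chroma_radii": [25, 50],
        "wheel_radii_dva": [3.0, 10.0],
        "n_analogue_per_cond": 50,
        "n_afc_per_cond": 80,
        "n_locations": 8,
        "location_ring_radius_dva": 6.0,
        "stimulus_duration_ms": 500,
    },
    # generating parameters for synthetic observers, keyed by
    # "timing/set_size/delay_ms"; values chosen as plausible for colour
    # report (precision: sync > async, set size 1 > 4, no delay > delay)
    "observer": {
        "kappa_by_condition": {
            "synchronous/1/0": 50.0,
            "asynchronous/1/0": 12.0,
            "asynchronous/4/0": 6.0,
            "synchronous/1/1000": 50.0,
            "asynchronous/1/1000": 10.0,
            "asynchronous/4/1000": 5.0,
        },
        "alpha_by_condition": {
            "synchronous/1/0": 0.99,
            "asynchronous/1/0": 0.97,
            "asynchronous/4/0": 0.85,
            "synchronous/1/1000": 0.99,
            "asynchronous/1/1000": 0.95,
            "asynchronous/4/1000": 0.80,
        },
        "sigma_t_sync": 0.15,
        "sigma_motor": 0.0,
    },
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config, deep-merged over the defaults."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    _merge(cfg, user)
    return cfg


def _merge(base: dict, extra: dict) -> None:
    for key, val in extra.items():
        if isinstance(val, dict) and isinstance(base.get(key), dict):
            _merge(base[key], val)
        else:
            base[key] = val


def config_hash(cfg: dict) -> str:
    """Stable short hash of a config for provenance records."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
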