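"""Perturbation-sweep experiments: generate, perturb, score, tabulate.

The experiment grid is a mapping (read from YAML by the command-line layer):

.. code-block:: yaml

    network:
      n_neurons: 50
      seeds: [0, 1, 2]
    max_distance: 300
    models:
      delete: {fractions: [0.1, 0.3, 0.6]}
      insert: {p_max: [0.05, 0.2, 0.6], d1: 500, d2: 1500}
      split:  {p_max: [0.05, 0.3, 0.9], d1: 300, d2: 800}
      merge:  {p_max: [0.001, 0.004, 0.02], d1: 200, d2: 600}

Every (seed, model, intensity) cell yields one reconstruction, scored by
global NRI (with its precision and recall), the adapted Rand index and the
NVI; the result is a tidy frame with one row per run per metric.
"""

from __future__ import annotations

import copy

import pandas as pd

from .matching import DEFAULT_MAX_DISTANCE
from .perturb import Kernel, PerturbConfig, apply_perturbation
from .pipeline import evaluate
from .synth_network import default_config, derive_graph, generate_network

__all__ = ["DEFAULT_EXPERIMENT", "run_experiment"]

DEFAULT_EXPERIMENT: dict = {
    "network": {"n_neurons": 50, "seeds": [0, 1, 2]},
    "max_distance": DEFAULT_MAX_DISTANCE,
    "models": {
        "delete": {"fractions": [0.1, 0.3, 0.6]},
        "insert": {"p_max": [0.05, 0.2, 0.6], "d1": 500.0, "d2": 1500.0},
        "split": {"p_max": [0.05, 0.3, 0.9], "d1": 300.0, "d2": 800.0},
        "merge": {"p_max": [0.001, 0.004, 0.02], "d1": 200.0, "d2": 600.0},
    },
}


def _configs_for(model: str, grid: dict, seed: int) -> list[tuple[float, PerturbConfig]]:
    out: list[tuple[float, PerturbConfig]] = []
    if model == "delete":
        for f in grid["fractions"]:
            out.append((f, PerturbConfig("delete", fraction=f, seed=seed)))
    else:
        for p in grid["p_max"]:
            kernel = Kernel(p_max=p, d1=grid["d1"], d2=grid["d2"])
            out.append((p, PerturbConfig(model, kernel=kernel, seed=seed)))
    return out


def run_experiment(config: dict | None = None) -> pd.DataFrame:
    """Run the full grid; returns a tidy frame with columns
    (network_seed, model, intensity, metric, value).

    A failed run is recorded with metric ``"error"`` and NaN value and the
    sweep continues.
    """
    cfg = copy.deepcopy(DEFAULT_EXPERIMENT)
    if config:
        for key, value in config.items():
            if isinstance(value, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(value)
            else:
                cfg[key] = value
    max_distance = cfg["max_distance"]
    rows: list[dict] = []
    for net_seed in cfg["network"]["seeds"]:
        net_cfg = default_config(n_neurons=cfg["network"]["n_neurons"], seed=net_seed)
        morph = generate_network(net_cfg)
        gt = derive_graph(morph)
        for model in sorted(cfg["models"]):
            # decorrelate the perturbation stream from the generator stream
            perturb_seed = net_seed * 1009 + 17
            for intensity, pconfig in _configs_for(model, cfg["models"][model], perturb_seed):
                base = {
                    "network_seed": net_seed,
                    "model": model,
                    "intensity": intensity,
                }
                try:
                    recon_morph = apply_perturbation(morph, pconfig)
                    recon = derive_graph(recon_morph)
                    recon.role = "reconstruction"
                    result = evaluate(gt, recon, max_distance=max_distance)
                except Exception:  # noqa: BLE001 — record, keep sweeping
                    rows.append({**base, "metric": "error", "value": float("nan")})
                    continue
                g = result.global_result
                for metric, value in (
                    ("nri", g.score),
                    ("precision", g.precision),
                    ("recall", g.recall),
                    ("adapted_rand", result.adapted_rand),
                    ("nvi", result.nvi),
                ):
                    rows.append({**base, "metric": metric, "value": value})
    return pd.DataFrame(rows, columns=["network_seed", "model", "intensity", "metric", "value"])
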