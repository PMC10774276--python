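"""Run configuration: YAML files merged over package defaults.

A config file has up to three sections — ``dataset``, ``partition`` and
``federation`` — each overriding the defaults below.  Every generation
and training parameter of a run is reachable from here.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from .data import LabeledDataset, FederatedPartition, make_blobs, partition_clients
from .federation import FederationConfig

__all__ = ["DEFAULT_CONFIG", "load_config", "build_dataset", "build_partition", "build_federation_config"]

DEFAULT_CONFIG: dict = {
    "dataset": {
        "C": 10,
        "per_class": 100,
        "d": 8,
        "separation": 8.0,
        "noise_sd": 1.0,
        "csv": None,  # path to a user-supplied feature/label CSV
    },
    "partition": {
        "K": 10,
        "classes_per_client": 1,
        "val_fraction": 0.2,
        "proxy_fraction": 0.15,
        "test_fraction": 0.15,
    },
    "federation": {
        "T": 10,
        "label_mode": "soft",
        "tau_client": 0.25,
        "tau_server": 2.0,
        "local_epochs": 5,
        "distill_epochs": 5,
        "pretrain_epochs": 30,
        "proxy_batch": 100,
        "learning_rate": 0.05,
        "batch_size": 32,
        "hidden": [32],
        "kulsif_beta": 1e-3,
        "kulsif_bandwidth": "median-heuristic",
        "reference_margin": 0.05,
    },
}


def load_config(path: str | Path | None = None) -> dict:
    """Package defaults, with the YAML file's sections merged on top."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        for section, values in user.items():
            if section not in cfg:
                raise KeyError(f"unknown config section {section!r}")
            cfg[section].update(values)
    return cfg


def build_dataset(cfg: dict, seed: int) -> LabeledDataset:
    d = cfg["dataset"]
    if d.get("csv"):
        from .data import load_csv

        return load_csv(d["csv"], C=d["C"])
    return make_blobs(
        C=d["C"],
        per_class=d["per_class"],
        d=d["d"],
        separation=d["separation"],
        noise_sd=d["noise_sd"],
        seed=seed,
    )


def build_partition(ds: LabeledDataset, cfg: dict, seed: int) -> FederatedPartition:
    p = cfg["partition"]
    return partition_clients(
        ds,
        K=p["K"],
        classes_per_client=p["classes_per_client"],
        val_fraction=p["val_fraction"],
        proxy_fraction=p["proxy_fraction"],
        test_fraction=p["test_fraction"],
        seed=seed + 1,
    )


def build_federation_config(cfg: dict, seed: int) -> FederationConfig:
    f = dict(cfg["federation"])
    f["hidden"] = tuple(f["hidden"])
    return FederationConfig(
        K=cfg["partition"]["K"], C=cfg["dataset"]["C"], seed=seed, **f
    )
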