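"""Checkpoint and config (de)serialisation.

Checkpoints are JSON: portable, diffable, and adequate for the network sizes
involved.  A pre-trained checkpoint stores generator+critic weights and the
growth stage; a class-GAN-pair checkpoint stores the per-class generators
plus the fitted real-data transformer so generated rows can be mapped back
to the original feature scale.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .gan_core import GanHyperparams, NetworkSchedule, build_critic, build_generator
from .preprocessing import FittedTransformer
from .training import ClassGANPair, PhaseConfig, PretrainedGAN, TrainingConfig

__all__ = ["save_pretrained", "load_pretrained", "save_pair", "load_pair",
           "training_config_to_dict", "training_config_from_dict"]


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _net_meta(net):
    return {"n_features": net.n_features,
            "hidden_sizes": list(net.schedule.hidden_sizes),
            "dropout_prob": net.dropout.p,
            "state": _jsonify(net.state())}


def _rebuild(meta, builder):
    schedule = NetworkSchedule(tuple(meta["hidden_sizes"]),
                               active_stage=int(meta["state"]["stage"]))
    hyper = GanHyperparams(dropout_prob=meta["dropout_prob"])
    net = builder(meta["n_features"], schedule, hyper, np.random.default_rng(0))
    net.load_state(meta["state"])
    return net


def save_pretrained(pretrained: PretrainedGAN, path) -> None:
    payload = {"kind": "pretrained",
               "generator": _net_meta(pretrained.generator),
               "critic": _net_meta(pretrained.critic)}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_pretrained(path) -> PretrainedGAN:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "pretrained":
        raise ValueError("not a pre-trained GAN checkpoint")
    return PretrainedGAN(_rebuild(payload["generator"], build_generator),
                         _rebuild(payload["critic"], build_critic), [])


def save_pair(pair: ClassGANPair, path) -> None:
    payload = {"kind": "pair",
               "minor_label": pair.minor_label,
               "major_label": pair.major_label,
               "generators": {str(lbl): _net_meta(g)
                              for lbl, g in pair.generators.items()},
               "transformer": (None if pair.transformer is None
                               else _jsonify(pair.transformer.to_dict()))}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_pair(path) -> ClassGANPair:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("kind") != "pair":
        raise ValueError("not a class-GAN-pair checkpoint")
    generators = {int(lbl): _rebuild(meta, build_generator)
                  for lbl, meta in payload["generators"].items()}
    transformer = (None if payload["transformer"] is None
                   else FittedTransformer.from_dict(payload["transformer"]))
    return ClassGANPair(generators, transformer, {},
                        payload["minor_label"], payload["major_label"])


def training_config_to_dict(config: TrainingConfig) -> dict:
    return {"pretrain": dataclasses.asdict(config.pretrain),
            "retrain": dataclasses.asdict(config.retrain),
            "batch_size_minor": config.batch_size_minor,
            "batch_size_major": config.batch_size_major}


def training_config_from_dict(payload: dict) -> TrainingConfig:
    def phase(d):
        d = dict(d)
        for key in ("lr_1", "lr_2"):
            if key in d:
                d[key] = tuple(d[key])
        return PhaseConfig(**d)

    kwargs = {}
    if "pretrain" in payload:
        kwargs["pretrain"] = phase(payload["pretrain"])
    if "retrain" in payload:
        kwargs["retrain"] = phase(payload["retrain"])
    for key in ("batch_size_minor", "batch_size_major"):
        if key in payload:
            kwargs[key] = payload[key]
    return TrainingConfig(**kwargs)
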