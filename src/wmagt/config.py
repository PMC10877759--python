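"""YAML configuration round-trip for the model, training and graph settings."""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import yaml

from .encoders import EncoderConfig
from .interaction_ncf import DecoderConfig, ModelConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_config", "save_config"]


class RunConfig:
    """Bundle of everything a run needs: model, training, graph k."""

    def __init__(self, model: ModelConfig | None = None,
                 train: TrainConfig | None = None, knn_k: int = 15):
        self.model = model or ModelConfig()
        self.train = train or TrainConfig()
        self.knn_k = knn_k

    def to_dict(self) -> dict:
        d = asdict(self.model)
        d["encoder"] = asdict(self.model.encoder)
        d["decoder"] = asdict(self.model.decoder)
        return {
            "knn_k": self.knn_k,
            "encoder": d.pop("encoder"),
            "decoder": d.pop("decoder"),
            "model": d,
            "training": asdict(self.train),
        }


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    enc = EncoderConfig(**raw.get("encoder", {}))
    dec_raw = raw.get("decoder", {})
    if "hidden_dims" in dec_raw:
        dec_raw = {**dec_raw, "hidden_dims": tuple(dec_raw["hidden_dims"])}
    dec = DecoderConfig(**dec_raw)
    model = ModelConfig(encoder=enc, decoder=dec, **raw.get("model", {}))
    tr_raw = raw.get("training", {})
    if "loss_weights" in tr_raw:
        tr_raw = {**tr_raw, "loss_weights": tuple(tr_raw["loss_weights"])}
    return RunConfig(model=model, train=TrainConfig(**tr_raw),
                     knn_k=raw.get("knn_k", 15))


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=False, default_flow_style=None))
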