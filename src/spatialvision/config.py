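"""Load and save model parameter configurations.

A config file is a YAML mapping with one block per colour channel plus an
optional ``transducer`` block, e.g.::

    channels:
      Achr: {t0: 0.0051, E2: 6.22, alpha: 5.26, f0: 4.51, f1: 0.32, g: 2.5}
      BY:   {t0: 0.0051, E2: 6.22, alpha: 5.26, f0: 0.7517, f1: 0.32, g: 1.0}
      RG:   {t0: 0.0082, E2: 1.82, alpha: 2.53, f0: 5.37, f1: 0.94, g: 2.0}
    transducer: {Rmax: 30, p: 2, q: 0.4, d_exp: 2, M: 4, w_x: 1, attention_factor: 1.0}

Omitted channels or keys fall back to the compiled-in defaults.
"""

from __future__ import annotations

from dataclasses import asdict, replace
from pathlib import Path

import yaml

from .csf_core import DEFAULT_PARAMS, ChannelId, ChannelParams
from .response_model import TransducerParams

_KEYMAP = {"t0": "t0", "E2": "E2_ecc", "alpha": "alpha",
           "f0": "f0", "f1": "f1", "g": "gain_g"}


class ModelConfig:
    """Full parameterization: per-channel CSF params plus transducer params."""

    def __init__(self, channels: dict[ChannelId, ChannelParams] | None = None,
                 transducer: TransducerParams | None = None):
        self.channels = dict(DEFAULT_PARAMS) if channels is None else dict(channels)
        self.transducer = TransducerParams() if transducer is None else transducer

    @classmethod
    def from_yaml(cls, path) -> "ModelConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        channels = dict(DEFAULT_PARAMS)
        for name, block in (raw.get("channels") or {}).items():
            ch = ChannelId(name)
            kwargs = {_KEYMAP[k]: float(v) for k, v in block.items()}
            channels[ch] = replace(channels[ch], **kwargs)
        tr = TransducerParams(**{k: float(v) for k, v in
                                 (raw.get("transducer") or {}).items()})
        return cls(channels, tr)

    def to_yaml(self, path) -> None:
        inv = {v: k for k, v in _KEYMAP.items()}
        out = {
            "channels": {
                ch.value: {inv[k]: v for k, v in asdict(p).items()}
                for ch, p in self.channels.items()
            },
            "transducer": asdict(self.transducer),
        }
        Path(path).write_text(yaml.safe_dump(out, sort_keys=False))
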