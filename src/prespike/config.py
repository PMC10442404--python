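"""Run configuration: defaults, YAML round-trip, and run manifests.

The simulator is fully determined by five hyperparameters — the timestep
``h``, membrane time constant ``tau_m``, spiking threshold ``v_th``,
learning rate ``eta`` and input time constant ``tau_x`` — plus the protocol
selection.  The shipped defaults were calibrated once against the two-input
protocol's weight-space structure (the no-spike / single-spike / multi-spike
partition falls inside w in [0, 0.06] with ``v_th = 1``) and its anticipation
timeline; they are configuration, not constants of nature, and every CLI
entry point accepts overrides.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .neuron import NeuronParams
from .plasticity import PlasticityParams

__all__ = [
    "DEFAULT_V_TH",
    "DEFAULT_TAU_M",
    "DEFAULT_TAU_X",
    "DEFAULT_ETA_SCALED",
    "DEFAULT_ETA_ONLINE",
    "default_neuron_params",
    "RunConfig",
    "write_manifest",
]

DEFAULT_V_TH = 1.0        # dimensionless; lone-spike EPSP at w=0.037 reaches it
DEFAULT_TAU_M = 10.0      # ms
DEFAULT_TAU_X = 2.0       # ms
DEFAULT_H = 0.05          # ms

#: per-step learning rate of the multiplicatively scaled online rule
DEFAULT_ETA_SCALED = 1e-3
#: per-step learning rate of the plain (unscaled) online rule, used by the
#: recurrent-network experiments
DEFAULT_ETA_ONLINE = 1e-7


def default_neuron_params(tau_m: float = DEFAULT_TAU_M) -> NeuronParams:
    return NeuronParams(h=DEFAULT_H, tau_m=tau_m, v_th=DEFAULT_V_TH)


@dataclass
class RunConfig:
    """One protocol run: physics + plasticity + protocol + seed + output dir."""

    protocol: str = "two-input"
    neuron: dict = field(default_factory=dict)      # h, tau_m, v_th
    plasticity: dict = field(default_factory=dict)  # eta, mode, ...
    params: dict = field(default_factory=dict)      # protocol-specific
    seed: int = 0
    outdir: str = "prespike-out"

    def neuron_params(self) -> NeuronParams:
        base = dict(h=DEFAULT_H, tau_m=DEFAULT_TAU_M, v_th=DEFAULT_V_TH)
        base.update(self.neuron)
        return NeuronParams(**base)

    def plasticity_params(self) -> PlasticityParams:
        base = dict(eta=DEFAULT_ETA_SCALED, mode="online_scaled")
        base.update(self.plasticity)
        return PlasticityParams(**base)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    def merged(self, **overrides) -> "RunConfig":
        """New config with non-None overrides applied on top."""
        data = asdict(self)
        for key, value in overrides.items():
            if value is None:
                continue
            if key in ("neuron", "plasticity", "params"):
                data[key] = {**data[key], **value}
            else:
                data[key] = value
        return RunConfig(**data)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def write_manifest(config: RunConfig, outdir) -> Path:
    """Write a JSON run manifest (config, hash, seed, versions) and return its path."""
    import prespike

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    payload = asdict(config)
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=_json_default).encode()
    ).hexdigest()
    manifest = {
        "config": payload,
        "config_sha256": digest,
        "seed": config.seed,
        "versions": {
            "prespike": prespike.__version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=_json_default))
    return path
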