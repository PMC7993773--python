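"""File I/O: amplitude tables, run configs, and fit-result serialization.

Amplitude tables are columnar delimited text (CSV): rows are trials, columns
are stimulus positions with a header naming the pulse index, one file per
protocol.  Configs are YAML (JSON is valid YAML and accepted too); times may
be given in seconds or with an explicit ``ms`` suffix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .inference import FitResult
from .kernels import Kernel
from .spiketrains import ProtocolSpec
from .srp import SRPParameters
from .tm import TMParameters

__all__ = [
    "read_amplitudes",
    "write_amplitudes",
    "load_config",
    "dump_config",
    "save_fit_result",
    "load_fit_parameters",
    "parse_time",
]


def read_amplitudes(path) -> np.ndarray:
    """Read a trials x pulses amplitude table from delimited text."""
    df = pd.read_csv(path)
    return df.to_numpy(dtype=float)


def write_amplitudes(matrix: np.ndarray, path) -> None:
    m = np.atleast_2d(np.asarray(matrix, dtype=float))
    df = pd.DataFrame(m, columns=[f"pulse_{j + 1}" for j in range(m.shape[1])])
    df.to_csv(path, index=False)


def parse_time(value) -> float:
    """A time value in seconds; strings with an ``ms`` suffix are converted."""
    if isinstance(value, str):
        v = value.strip().lower()
        if v.endswith("ms"):
            return float(v[:-2]) / 1000.0
        if v.endswith("s"):
            v = v[:-1]
        return float(v)
    return float(value)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping")
    return cfg


def dump_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def protocols_from_config(section) -> dict[str, ProtocolSpec]:
    """Parse the ``protocols`` config section: label -> list of [n, Hz] pairs."""
    out = {}
    for label, segments in section.items():
        out[label] = ProtocolSpec.from_config(segments, label=label)
    return out


def srp_params_from_config(section: dict) -> SRPParameters:
    return SRPParameters.from_dict(section)


def save_fit_result(result: FitResult, path, extra: dict | None = None) -> None:
    d = result.to_dict()
    if extra:
        d.update(extra)
    Path(path).write_text(json.dumps(d, indent=2) + "\n")


def load_fit_parameters(path):
    """Load fitted parameters back from a fit JSON (SRP or TM)."""
    d = json.loads(Path(path).read_text())
    if d.get("model") == "tm":
        return TMParameters.from_dict(d["parameters"])
    return SRPParameters.from_dict(d["parameters"])
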