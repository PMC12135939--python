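"""Ground-truth records serialized alongside every simulated dataset."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruth"]


def _plain(obj):
    """Recursively convert numpy scalars/arrays to JSON-native types."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


@dataclass(frozen=True)
class GroundTruth:
    """True generator parameters and latent state for one simulated dataset.

    ``kind`` names the generator ('counts', 'image', 'landmarks',
    'variants'); ``data`` holds only JSON-native values so the record
    round-trips losslessly through :meth:`to_json` / :meth:`from_json`.
    """

    kind: str
    data: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "data", _plain(self.data))

    def __getitem__(self, key):
        return self.data[key]

    def to_json(self, path=None) -> str:
        text = json.dumps({"kind": self.kind, "data": self.data},
                          indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "GroundTruth":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        return cls(kind=payload["kind"], data=payload["data"])
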