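"""Single-file checkpoints: an npz archive carrying a JSON config entry.

The config travels inside the archive under the reserved key ``__config__``
(JSON encoded as bytes), so a checkpoint is self-describing: the reader can
rebuild the module before loading weights.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

FORMAT_VERSION = 1

__all__ = ["save_checkpoint", "load_checkpoint", "FORMAT_VERSION"]


def save_checkpoint(path, state: dict[str, np.ndarray], config: dict) -> None:
    header = dict(config)
    header["__format_version__"] = FORMAT_VERSION
    payload = np.frombuffer(json.dumps(header).encode("utf-8"), dtype=np.uint8)
    arrays = {"__config__": payload}
    for k, v in state.items():
        arrays["w::" + k] = v
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> tuple[dict[str, np.ndarray], dict]:
    with np.load(path) as z:
        config = json.loads(bytes(z["__config__"].tobytes()).decode("utf-8"))
        state = {k[3:]: z[k] for k in z.files if k.startswith("w::")}
    version = config.pop("__format_version__", None)
    if version != FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint version {version!r}")
    return state, config
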