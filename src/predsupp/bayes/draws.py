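"""Container for named posterior draws organized by chain."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd


@dataclass
class PosteriorDraws:
    """Named parameter samples with shape (chains, draws, *param_shape).

    ``log_likelihood`` (chains, draws, observations) is present when the
    model declares a pointwise likelihood, enabling WAIC.  ``unconstrained``
    holds the raw sampler coordinates and is kept for diagnostics.
    """

    params: dict[str, np.ndarray]
    chains: int
    draws: int
    warmup: int
    seed: int
    log_likelihood: Optional[np.ndarray] = None
    unconstrained: Optional[np.ndarray] = None
    divergences: Optional[np.ndarray] = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, arr in self.params.items():
            if arr.shape[:2] != (self.chains, self.draws):
                raise ValueError(
                    f"parameter {name!r} has shape {arr.shape}, expected leading "
                    f"({self.chains}, {self.draws})"
                )

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated: shape (chains*draws, *param_shape)."""
        arr = self.params[name]
        return arr.reshape(-1, *arr.shape[2:])

    def by_chain(self, name: str) -> np.ndarray:
        return self.params[name]

    def scalar_components(self) -> dict[str, np.ndarray]:
        """Flatten every parameter to scalar series of shape (chains, draws)."""
        out: dict[str, np.ndarray] = {}
        for name, arr in self.params.items():
            if arr.ndim == 2:
                out[name] = arr
            else:
                flat = arr.reshape(self.chains, self.draws, -1)
                for j in range(flat.shape[-1]):
                    idx = np.unravel_index(j, arr.shape[2:])
                    label = name + "[" + ",".join(str(i) for i in idx) + "]"
                    out[label] = flat[..., j]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Wide table with chain/draw indices — the serialization format."""
        comps = self.scalar_components()
        chains_idx = np.repeat(np.arange(self.chains), self.draws)
        draws_idx = np.tile(np.arange(self.draws), self.chains)
        data = {"chain": chains_idx, "draw": draws_idx}
        for name, arr in comps.items():
            data[name] = arr.reshape(-1)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
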