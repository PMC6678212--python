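"""Adsorption time-series container shared by the engines and the analysis."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class AdsorptionCurve:
    """Number of NP-bound proteins versus time.

    Attributes
    ----------
    times : (n,) float array — time grid (units set by the producer;
        engines record μs, synthetic series use the τ of the generator)
    total : (n,) float array — total bound count per frame
    per_type : dict label -> (n,) array, optional per-type split
    """

    times: np.ndarray
    total: np.ndarray
    per_type: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.total = np.asarray(self.total, dtype=float)
        if self.times.shape != self.total.shape:
            raise ValueError("times and counts must have the same length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.total < 0):
            raise ValueError("bound counts cannot be negative")

    def __len__(self) -> int:
        return len(self.times)

    def plateau(self, tail_fraction: float = 0.2) -> float:
        """Mean count over the final `tail_fraction` of the series."""
        if len(self) == 0:
            raise ValueError("empty curve")
        k = max(1, int(round(tail_fraction * len(self))))
        return float(self.total[-k:].mean())

    def plateau_per_type(self, tail_fraction: float = 0.2) -> dict:
        k = max(1, int(round(tail_fraction * len(self))))
        return {lab: float(np.asarray(c)[-k:].mean())
                for lab, c in self.per_type.items()}

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.times, "n_bound": self.total}
        for lab, c in self.per_type.items():
            data[f"n_bound_{lab}"] = np.asarray(c)
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AdsorptionCurve":
        df = pd.read_csv(path)
        per_type = {c.removeprefix("n_bound_"): df[c].to_numpy()
                    for c in df.columns if c.startswith("n_bound_")}
        return cls(times=df["time"].to_numpy(),
                   total=df["n_bound"].to_numpy(), per_type=per_type)

    def plot(self, ax=None):
        """Plot total (and per-type) bound counts versus time."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.times, self.total, label="total", color="k")
        for lab, c in self.per_type.items():
            ax.plot(self.times, c, label=lab)
        ax.set_xlabel("time")
        ax.set_ylabel("proteins bound")
        ax.legend()
        return ax
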