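"""Beat record: time series of one converged cardiac cycle."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class BeatRecord:
    """Time series of pressures, flows and volumes over one cardiac cycle.

    Channels are named ``"p_lv"``, ``"q_cor_lad_in"``, ``"v_lad_subendo_art"``
    etc.; ``events`` holds valve transition times within the beat (seconds
    from beat start), e.g. ``"aortic_open"``, ``"mitral_close"``.
    """

    dt: float
    channels: dict[str, np.ndarray]
    events: dict[str, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @property
    def period(self) -> float:
        return self.n * self.dt

    def __getitem__(self, channel: str) -> np.ndarray:
        try:
            return self.channels[channel]
        except KeyError:
            raise KeyError(
                f"beat record has no channel {channel!r}; available: "
                f"{sorted(self.channels)[:8]}..."
            ) from None

    def mean(self, channel: str) -> float:
        return float(np.mean(self[channel]))

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format (t, channel, value) table of the whole beat."""
        t = self.time
        frames = [
            pd.DataFrame({"t": t, "channel": name, "value": series})
            for name, series in sorted(self.channels.items())
        ]
        return pd.concat(frames, ignore_index=True)

    def window_mask(self, t_start: float, t_end: float) -> np.ndarray:
        """Boolean mask for the (wrapping) time window [t_start, t_end)."""
        t = self.time
        if t_end >= t_start:
            return (t >= t_start) & (t < t_end)
        return (t >= t_start) | (t < t_end)
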