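"""Spike rasters: spike times grouped by source (electrode or neuron).

The :class:`SpikeRaster` is the common currency of the whole pipeline —
the synthetic generator, the spike detector and the circuit simulator all
produce one, and every downstream statistic consumes one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["SpikeRaster"]

#: minimum admissible same-source inter-spike interval after dedup (seconds)
DEDUP_ISI = 0.002


@dataclass
class SpikeRaster:
    """Spike times per source over a recording of known duration.

    Parameters
    ----------
    spike_times
        One sorted float array of spike times (seconds) per source.
    source_ids
        Label per source, same length/order as ``spike_times``.
    duration
        Recording length in seconds; all spike times lie in ``[0, duration]``.
    provenance
        One of ``"recorded"``, ``"simulated"``, ``"synthetic"``.
    """

    spike_times: list[np.ndarray]
    source_ids: list
    duration: float
    provenance: str = "synthetic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        if len(self.spike_times) != len(self.source_ids):
            raise ValueError("spike_times and source_ids lengths differ")
        self.spike_times = [np.asarray(t, dtype=float) for t in self.spike_times]
        for sid, t in zip(self.source_ids, self.spike_times):
            if t.size and (t.min() < 0 or t.max() > self.duration):
                raise ValueError(f"source {sid}: spike times outside [0, duration]")
            if np.any(np.diff(t) < 0):
                raise ValueError(f"source {sid}: spike times not sorted")

    # -- basic properties -------------------------------------------------
    @property
    def n_sources(self) -> int:
        return len(self.source_ids)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.spike_times))

    def rates(self) -> np.ndarray:
        """Per-source firing rate in Hz (spike count / duration)."""
        return np.array([t.size / self.duration for t in self.spike_times])

    def pooled(self) -> np.ndarray:
        """All spike times pooled across sources, sorted ascending."""
        if not self.spike_times:
            return np.empty(0)
        return np.sort(np.concatenate(self.spike_times))

    def __getitem__(self, source_id) -> np.ndarray:
        return self.spike_times[self.source_ids.index(source_id)]

    # -- transforms -------------------------------------------------------
    def window(self, t0: float, t1: float, rezero: bool = True) -> "SpikeRaster":
        """Restrict to spikes in ``[t0, t1)``; optionally shift times to 0."""
        if not 0 <= t0 < t1 <= self.duration + 1e-9:
            raise ValueError(f"window [{t0}, {t1}) outside [0, {self.duration}]")
        off = t0 if rezero else 0.0
        trains = [t[(t >= t0) & (t < t1)] - off for t in self.spike_times]
        dur = (t1 - t0) if rezero else self.duration
        return SpikeRaster(trains, list(self.source_ids), dur,
                           self.provenance, dict(self.meta))

    def subset(self, ids: Iterable) -> "SpikeRaster":
        ids = list(ids)
        trains = [self[sid] for sid in ids]
        return SpikeRaster(trains, ids, self.duration, self.provenance,
                           dict(self.meta))

    def dedup(self, min_isi: float = DEDUP_ISI) -> "SpikeRaster":
        """Drop same-source spikes closer than ``min_isi`` to the kept one."""
        out = []
        for t in self.spike_times:
            if t.size < 2:
                out.append(t.copy())
                continue
            keep = [t[0]]
            for x in t[1:]:
                if x - keep[-1] > min_isi:
                    keep.append(x)
            out.append(np.array(keep))
        return SpikeRaster(out, list(self.source_ids), self.duration,
                           self.provenance, dict(self.meta))

    # -- I/O --------------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        rows = [(sid, t) for sid, tt in zip(self.source_ids, self.spike_times)
                for t in tt]
        return pd.DataFrame(rows, columns=["source_id", "time_s"])

    def save(self, path: str | Path) -> None:
        """Write as delimited text: one row per spike, ``source_id\ttime_s``.

        A ``# duration_s=...`` comment line carries the recording length.
        """
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# duration_s={self.duration!r} provenance={self.provenance}\n")
            fh.write("source_id\ttime_s\n")
            for sid, tt in zip(self.source_ids, self.spike_times):
                for t in tt:
                    fh.write(f"{sid}\t{t:.7f}\n")

    @classmethod
    def load(cls, path: str | Path, duration: float | None = None,
             provenance: str = "recorded") -> "SpikeRaster":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline()
            if first.startswith("#"):
                for tok in first[1:].split():
                    k, _, v = tok.partition("=")
                    if k == "duration_s":
                        duration = float(v)
                    elif k == "provenance":
                        provenance = v
                df = pd.read_csv(fh, sep="\t")
            else:
                fh.seek(0)
                df = pd.read_csv(fh, sep="\t")
        if duration is None:
            duration = float(df["time_s"].max()) if len(df) else 1.0
        groups = {sid: np.sort(g["time_s"].to_numpy())
                  for sid, g in df.groupby("source_id", sort=True)}
        ids = sorted(groups)
        return cls([groups[i] for i in ids], ids, duration, provenance)

    @classmethod
    def from_events(cls, sources: Sequence, times: Sequence[float],
                    source_ids: Sequence, duration: float,
                    provenance: str = "simulated") -> "SpikeRaster":
        """Build from parallel (source, time) event arrays."""
        sources = np.asarray(sources)
        times = np.asarray(times, dtype=float)
        trains = []
        for sid in source_ids:
            t = times[sources == sid]
            trains.append(np.sort(t))
        return cls(trains, list(source_ids), duration, provenance)
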