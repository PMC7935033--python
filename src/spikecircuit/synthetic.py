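"""Synthetic MEA-like data with known ground truth.

Two generators:

* :func:`generate_raster` — spike rasters with controlled rate, burst
  structure and planted pairwise correlation / community structure
  (shared-mother-train construction).
* :func:`generate_trace` — raw multichannel voltage traces (spike waveform
  templates embedded in Gaussian noise, optional 60 Hz mains hum) with the
  planted spike times retained, so the detection chain can be scored
  against ground truth.

Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .raster import SpikeRaster, DEDUP_ISI

__all__ = [
    "BurstSpec", "CorrelationSpec", "RasterSpec", "TraceSpec", "Trace",
    "generate_raster", "generate_trace", "default_spike_template",
    "save_trace", "load_trace",
]


@dataclass(frozen=True)
class BurstSpec:
    """Compound burst events unioned with the Poisson background."""
    burst_rate: float          # bursts per second per source
    spikes_per_burst: int
    intra_burst_isi: float     # seconds

    def validate(self) -> None:
        if self.burst_rate < 0:
            raise ValueError(f"burst_rate must be >= 0, got {self.burst_rate}")
        if self.spikes_per_burst < 1:
            raise ValueError("spikes_per_burst must be >= 1")
        if self.intra_burst_isi <= 0:
            raise ValueError("intra_burst_isi must be > 0")


@dataclass(frozen=True)
class CorrelationSpec:
    """Planted pairwise correlation via a shared mother train per group.

    Each group has one hidden mother Poisson train; every member copies each
    mother spike with probability ``sharing_prob`` (jittered by a centred
    Gaussian of SD ``jitter``) and tops up with an independent Poisson train
    of rate ``(1 - sharing_prob) * base_rate`` so the marginal rate is
    unchanged.
    """
    group_of_source: tuple     # group label per source, len == n_sources
    sharing_prob: float
    jitter: float = 0.001      # seconds

    def validate(self, n_sources: int) -> None:
        if len(self.group_of_source) != n_sources:
            raise ValueError("group_of_source length must equal n_sources")
        if not 0.0 <= self.sharing_prob <= 1.0:
            raise ValueError(
                f"sharing_prob must be in [0, 1], got {self.sharing_prob}")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")


@dataclass(frozen=True)
class RasterSpec:
    n_sources: int
    duration: float            # seconds
    base_rate: float           # Hz per source
    burst_spec: BurstSpec | None = None
    correlation_spec: CorrelationSpec | None = None
    refractory: float = DEDUP_ISI   # absolute refractory imposed on output
    seed: int = 0

    def validate(self) -> None:
        if self.n_sources < 1:
            raise ValueError(f"n_sources must be >= 1, got {self.n_sources}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.base_rate < 0:
            raise ValueError(f"base_rate must be >= 0, got {self.base_rate}")
        if self.burst_spec is not None:
            self.burst_spec.validate()
        if self.correlation_spec is not None:
            self.correlation_spec.validate(self.n_sources)


def _poisson_train(rng: np.random.Generator, rate: float,
                   duration: float) -> np.ndarray:
    n = rng.poisson(rate * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


def _enforce_refractory(t: np.ndarray, refractory: float) -> np.ndarray:
    if t.size < 2 or refractory <= 0:
        return t
    keep = [t[0]]
    for x in t[1:]:
        if x - keep[-1] >= refractory:
            keep.append(x)
    return np.array(keep)


def generate_raster(spec: RasterSpec) -> SpikeRaster:
    """Generate a spike raster with the planted structure of ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cs = spec.correlation_spec

    mothers: dict = {}
    if cs is not None:
        for g in dict.fromkeys(cs.group_of_source):  # stable order
            mothers[g] = _poisson_train(rng, spec.base_rate, spec.duration)

    trains = []
    for i in range(spec.n_sources):
        if cs is None:
            t = _poisson_train(rng, spec.base_rate, spec.duration)
        else:
            mother = mothers[cs.group_of_source[i]]
            take = rng.uniform(size=mother.size) < cs.sharing_prob
            shared = mother[take]
            if cs.jitter > 0 and shared.size:
                shared = shared + rng.normal(0.0, cs.jitter, size=shared.size)
            own = _poisson_train(
                rng, spec.base_rate * (1.0 - cs.sharing_prob), spec.duration)
            t = np.concatenate([shared, own])
        if spec.burst_spec is not None:
            bs = spec.burst_spec
            starts = _poisson_train(rng, bs.burst_rate, spec.duration)
            if starts.size:
                offs = np.arange(bs.spikes_per_burst) * bs.intra_burst_isi
                t = np.concatenate([t, (starts[:, None] + offs[None, :]).ravel()])
        t = np.sort(t)
        t = t[(t >= 0) & (t <= spec.duration)]
        trains.append(_enforce_refractory(t, spec.refractory))

    return SpikeRaster(trains, list(range(spec.n_sources)), spec.duration,
                       provenance="synthetic", meta={"seed": spec.seed})


# ---------------------------------------------------------------------------
# raw voltage traces
# ---------------------------------------------------------------------------

def default_spike_template(sampling_rate: float = 20_000.0) -> np.ndarray:
    """A biphasic extracellular-like waveform, ~1.5 ms, peak amplitude -1.

    The dominant deflection is negative, as for extracellular somatic
    spikes; the template is scaled by ``TraceSpec.amplitude``.
    """
    n = int(round(1.5e-3 * sampling_rate))
    t = np.arange(n) / sampling_rate
    w = -np.exp(-((t - 0.3e-3) / 0.12e-3) ** 2) \
        + 0.35 * np.exp(-((t - 0.75e-3) / 0.3e-3) ** 2)
    return w / np.abs(w).max()   # peak magnitude 1, dominant phase negative


@dataclass(frozen=True)
class TraceSpec:
    true_spike_times: tuple    # one tuple/array of seconds per channel
    duration: float            # seconds
    sampling_rate: float = 20_000.0
    noise_sd: float = 5e-6     # volts
    amplitude: float = 50e-6   # volts, scales the (peak-1) template
    spike_template: np.ndarray | None = None
    mains_hum: float = 0.0     # 60 Hz amplitude in volts
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError(
                f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        tmpl = self.template()
        if tmpl.size >= int(self.duration * self.sampling_rate):
            raise ValueError("spike template longer than the trace")

    def template(self) -> np.ndarray:
        if self.spike_template is not None:
            return np.asarray(self.spike_template, dtype=float)
        return default_spike_template(self.sampling_rate)


@dataclass
class Trace:
    """Multichannel voltage trace with optional planted ground truth."""
    data: np.ndarray           # (n_channels, n_samples), volts
    sampling_rate: float
    true_spike_times: list[np.ndarray] | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.sampling_rate


def generate_trace(spec: TraceSpec) -> Trace:
    """Gaussian noise + spike templates at the planted times (+ 60 Hz hum)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_samples = int(round(spec.duration * spec.sampling_rate))
    tmpl = spec.template() * spec.amplitude
    # the detector timestamps the absolute-maximum sample of an excursion
    peak_off = int(np.argmax(np.abs(tmpl)))

    chans = []
    truth = []
    for times in spec.true_spike_times:
        x = rng.normal(0.0, spec.noise_sd, size=n_samples)
        if spec.mains_hum > 0:
            t = np.arange(n_samples) / spec.sampling_rate
            x += spec.mains_hum * np.sin(2 * np.pi * 60.0 * t)
        kept = []
        for ts in np.asarray(times, dtype=float):
            i0 = int(round(ts * spec.sampling_rate)) - peak_off
            if i0 < 0 or i0 + tmpl.size > n_samples:
                continue
            x[i0:i0 + tmpl.size] += tmpl
            kept.append((i0 + peak_off) / spec.sampling_rate)
        chans.append(x)
        truth.append(np.array(kept))

    return Trace(np.vstack(chans) if chans else np.empty((0, n_samples)),
                 spec.sampling_rate, truth, meta={"seed": spec.seed})


# ---------------------------------------------------------------------------
# trace container I/O: plain-text header + little-endian float32 payload
# ---------------------------------------------------------------------------

_MAGIC = "SPIKECIRCUIT-TRACE v1"


def save_trace(trace: Trace, path: str | Path) -> None:
    """Binary container with a plain-text header.

    Header lines (ASCII, ``key=value``) terminated by ``#end``; payload is
    C-order float32 little-endian, shape (n_channels, n_samples).
    """
    path = Path(path)
    hdr = (f"{_MAGIC}\n"
           f"n_channels={trace.data.shape[0]}\n"
           f"n_samples={trace.data.shape[1]}\n"
           f"sampling_rate_hz={trace.sampling_rate!r}\n"
           f"#end\n")
    with open(path, "wb") as fh:
        fh.write(hdr.encode("ascii"))
        fh.write(np.ascontiguousarray(trace.data, dtype="<f4").tobytes())


def load_trace(path: str | Path) -> Trace:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii").strip()
        if magic != _MAGIC:
            raise ValueError(f"not a trace container: {path}")
        fields = {}
        while True:
            line = fh.readline().decode("ascii").strip()
            if line == "#end":
                break
            k, _, v = line.partition("=")
            fields[k] = v
        nc = int(fields["n_channels"])
        ns = int(fields["n_samples"])
        fs = float(fields["sampling_rate_hz"])
        data = np.frombuffer(fh.read(nc * ns * 4), dtype="<f4")
    return Trace(data.reshape(nc, ns).astype(float), fs)
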