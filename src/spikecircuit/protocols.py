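"""In-silico experiment orchestration.

Two experiments:

* :func:`run_condition_suite` — replicate simulations of control and
  perturbed networks, each analyzed with the same spike-train /
  connectivity / graph pipeline as MEA recordings, reported normalized to
  the control-condition mean.
* :func:`run_entrainment` — the stabilize / control / train / test
  protocol: after the control phase the external current of 1% of the
  excitatory neurons (the input population) is doubled; the readout is the
  signal fidelity (output-population rate over input-population rate) and
  the per-population fold changes, plus pre/post functional-network
  reorganization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import spike_metrics as sm
from .connectivity import build_network, FunctionalNetwork
from .graph_metrics import network_metrics, NetworkMetricsResult
from .raster import SpikeRaster
from .simulator import (SimulationConfig, apply_cypin_condition,
                        replicate_seeds, simulate_raw, run_simulation)

__all__ = [
    "ProtocolResult", "ConditionSummary", "PhasePlan",
    "run_entrainment", "run_condition_suite", "normalize_to_baseline",
    "analyze_raster", "INPUT_FRACTION", "STIM_FACTOR",
]

INPUT_FRACTION = 0.01   # fraction of excitatory neurons stimulated
STIM_FACTOR = 2.0       # external current multiplier during train/test
LOCAL_EFF_EXCLUDE = 0.001


@dataclass(frozen=True)
class PhasePlan:
    """Durations (s) of the four protocol phases."""
    stabilize: float = 10.0
    control: float = 300.0
    training: float = 300.0
    testing: float = 300.0

    @property
    def total(self) -> float:
        return self.stabilize + self.control + self.training + self.testing

    @property
    def train_start(self) -> float:
        return self.stabilize + self.control

    def bounds(self) -> dict[str, tuple[float, float]]:
        t0 = 0.0
        out = {}
        for name, d in [("stabilize", self.stabilize),
                        ("control", self.control),
                        ("training", self.training),
                        ("testing", self.testing)]:
            out[name] = (t0, t0 + d)
            t0 += d
        return out


@dataclass
class ProtocolResult:
    condition: str
    phases: PhasePlan
    input_ids: np.ndarray
    output_ids: np.ndarray
    # population-pooled firing rates (Hz per neuron) per phase
    input_rates: dict[str, float]
    output_rates: dict[str, float]
    input_fold: float            # testing vs control, input population
    output_fold: float
    fidelity_pre: float          # output/input rate ratio, control phase
    fidelity_post: float         # output/input rate ratio, testing phase
    pre_network: FunctionalNetwork | None = None
    post_network: FunctionalNetwork | None = None
    pre_metrics: NetworkMetricsResult | None = None
    post_metrics: NetworkMetricsResult | None = None
    raster: SpikeRaster | None = None
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "condition": self.condition,
            "fidelity_pre": self.fidelity_pre,
            "fidelity_post": self.fidelity_post,
            "input_fold": self.input_fold,
            "output_fold": self.output_fold,
            **{f"input_rate_{k}": v for k, v in self.input_rates.items()},
            **{f"output_rate_{k}": v for k, v in self.output_rates.items()},
        }])


def _population_rate(raster: SpikeRaster, ids: np.ndarray) -> float:
    """Pooled population rate: total spikes / (n neurons x duration)."""
    sub = raster.subset(list(ids))
    return sub.n_spikes / (len(ids) * raster.duration)


def run_entrainment(config: SimulationConfig, condition: str = "control",
                    seed: int | None = None,
                    phases: PhasePlan | None = None,
                    stim_factor: float = STIM_FACTOR,
                    input_fraction: float = INPUT_FRACTION,
                    compute_networks: bool = True,
                    per_neuron_folds: bool = False,
                    keep_raster: bool = False) -> ProtocolResult:
    """Run the stabilize/control/train/test protocol for one condition.

    The input population is a uniform-random draw of
    ``round(input_fraction * n_exc)`` excitatory neurons under the run
    seed; the output population is every other excitatory neuron.  From the
    start of training onward the inputs' external current (bias and noise)
    is multiplied by ``stim_factor``.  Fold changes compare the testing
    phase against the same population's control-phase rate; fidelity is the
    output/input rate ratio within one phase.  ``per_neuron_folds`` averages
    per-neuron fold changes instead of pooling the population rates.
    """
    cfg = apply_cypin_condition(config, condition)
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    if phases is None:
        phases = PhasePlan(stabilize=cfg.stabilization)

    rng = np.random.default_rng(cfg.seed + 0x5EED)
    n_inputs = max(1, round(input_fraction * cfg.n_exc))
    input_ids = np.sort(rng.choice(cfg.n_exc, size=n_inputs, replace=False))
    output_ids = np.setdiff1d(np.arange(cfg.n_exc), input_ids)

    raster = simulate_raw(cfg, phases.total,
                          stim_start=phases.train_start,
                          stim_ids=input_ids, stim_factor=stim_factor)

    bounds = phases.bounds()
    phase_rasters = {name: raster.window(a, b, rezero=True)
                     for name, (a, b) in bounds.items() if name != "stabilize"}

    in_rates = {k: _population_rate(r, input_ids)
                for k, r in phase_rasters.items()}
    out_rates = {k: _population_rate(r, output_ids)
                 for k, r in phase_rasters.items()}

    def _fold(ids: np.ndarray) -> float:
        if per_neuron_folds:
            rc = phase_rasters["control"].subset(list(ids)).rates()
            rt = phase_rasters["testing"].subset(list(ids)).rates()
            ok = rc > 0
            return float(np.mean(rt[ok] / rc[ok])) if ok.any() else math.nan
        a = _population_rate(phase_rasters["testing"], ids)
        b = _population_rate(phase_rasters["control"], ids)
        return a / b if b > 0 else math.nan

    fid_pre = (out_rates["control"] / in_rates["control"]
               if in_rates["control"] > 0 else math.nan)
    fid_post = (out_rates["testing"] / in_rates["testing"]
                if in_rates["testing"] > 0 else math.nan)

    result = ProtocolResult(
        condition=condition, phases=phases, input_ids=input_ids,
        output_ids=output_ids, input_rates=in_rates, output_rates=out_rates,
        input_fold=_fold(input_ids), output_fold=_fold(output_ids),
        fidelity_pre=fid_pre, fidelity_post=fid_post,
        raster=raster if keep_raster else None,
        meta={**raster.meta, "stim_factor": stim_factor,
              "input_ids": input_ids.tolist()},
    )

    if compute_networks:
        pre = build_network(phase_rasters["control"])
        post = build_network(phase_rasters["testing"])
        result.pre_network = pre
        result.post_network = post
        result.pre_metrics = network_metrics(pre.weights, seed=cfg.seed)
        result.post_metrics = network_metrics(post.weights, seed=cfg.seed + 1)
    return result


# ---------------------------------------------------------------------------
# condition suite (replicates, normalized to control)
# ---------------------------------------------------------------------------

@dataclass
class ConditionSummary:
    condition: str
    replicates: pd.DataFrame           # one row per replicate, raw metrics
    normalized_mean: pd.Series | None  # replicate mean / control mean
    normalized_sem: pd.Series | None

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"normalized_mean": self.normalized_mean,
                           "normalized_sem": self.normalized_sem})
        df.insert(0, "condition", self.condition)
        return df


def analyze_raster(raster: SpikeRaster, fano_bin: float = 1.0,
                   compute_network: bool = True,
                   louvain_repeats: int = 100,
                   seed: int = 0) -> dict:
    """The MEA analysis pipeline applied to one raster.

    Per-source metrics (rate, ISI, CV, FF) are averaged over the active
    sources (rate >= the 75th percentile of the per-source rate
    distribution, pooled within this recording); the burst rate uses the
    population network-burst rule (>= 50 spikes in 50 ms).  Optionally adds
    the functional-network measures.
    """
    rates = raster.rates()
    active = sm.active_sources(rates)
    per = [sm.train_metrics(raster.spike_times[i], raster.duration, fano_bin)
           for i in active]
    bursts = sm.detect_network_bursts(raster)
    ibi = sm.interburst_intervals(bursts)

    def _nanmean(xs):
        xs = [x for x in xs if not math.isnan(x)]
        return float(np.mean(xs)) if xs else math.nan

    out = {
        "spike_rate": float(np.mean([m.spike_rate for m in per])),
        "mean_isi": _nanmean([m.mean_isi for m in per]),
        "cv_isi": _nanmean([m.cv_isi for m in per]),
        "fano_factor": _nanmean([m.fano_factor for m in per]),
        "burst_rate": len(bursts) / raster.duration,
        "mean_ibi": float(np.mean(ibi)) if ibi.size else math.nan,
        "n_active": int(active.size),
    }
    if compute_network:
        net = build_network(raster)
        gm = network_metrics(net.weights, n_repeats=louvain_repeats,
                             seed=seed)
        out.update(global_efficiency=gm.global_efficiency,
                   mean_local_efficiency=gm.mean_local_efficiency,
                   n_communities=gm.n_communities, Q=gm.Q)
    return out


def run_condition_suite(config: SimulationConfig,
                        conditions: list[str] = ("control", "cypin_oe_1",
                                                 "cypin_oe_2"),
                        n_replicates: int | None = None,
                        seed: int | None = None,
                        compute_networks: bool = True,
                        louvain_repeats: int = 100
                        ) -> dict[str, ConditionSummary]:
    """Replicate simulations per condition, normalized to the control mean.

    Every replicate runs the full simulate-then-analyze path (network-burst
    rule for in-silico data); each condition's replicate-mean metrics are
    divided by the control-condition mean, so the control row is 1 by
    construction.
    """
    conditions = list(conditions)
    if "control" not in conditions:
        raise ValueError("conditions must include 'control'")
    n_rep = n_replicates if n_replicates is not None else config.n_replicates
    master = seed if seed is not None else config.seed
    seeds = replicate_seeds(master, n_rep)

    raw: dict[str, pd.DataFrame] = {}
    for cond in conditions:
        rows = []
        for r, s in enumerate(seeds):
            cfg = apply_cypin_condition(config, cond)
            cfg = replace(cfg, seed=s)
            raster = run_simulation(cfg)
            row = analyze_raster(raster, compute_network=compute_networks,
                                 louvain_repeats=louvain_repeats, seed=s)
            row["replicate"] = r
            rows.append(row)
        raw[cond] = pd.DataFrame(rows).set_index("replicate")

    metric_cols = [c for c in raw["control"].columns
                   if c not in ("n_active",)]
    ctrl_mean = raw["control"][metric_cols].mean()

    out = {}
    for cond in conditions:
        vals = raw[cond][metric_cols]
        norm = vals / ctrl_mean
        out[cond] = ConditionSummary(
            condition=cond,
            replicates=raw[cond],
            normalized_mean=norm.mean(),
            normalized_sem=norm.sem() if len(norm) > 1 else norm.mean() * 0,
        )
    return out


def normalize_to_baseline(values, baseline_values,
                          exclude_below: float = 0.0) -> np.ndarray:
    """Elementwise fold change vs baseline with a small-baseline guard.

    Pairs whose baseline is below ``exclude_below`` are dropped (the rule
    used for local efficiency, where near-zero baselines make the ratio
    aberrant; pass ``exclude_below=0.001`` for that metric).  Raises if
    every pair is excluded.
    """
    v = np.asarray(values, dtype=float)
    b = np.asarray(baseline_values, dtype=float)
    if v.shape != b.shape:
        raise ValueError("values and baseline must have equal length")
    keep = b >= max(exclude_below, np.finfo(float).tiny)
    if not keep.any():
        raise ValueError("all pairs excluded: no baseline above threshold")
    return v[keep] / b[keep]
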