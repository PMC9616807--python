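"""Experiment drivers and the recording-analysis pipeline.

``analyze_recording`` takes spike events with per-condition time windows
(e.g. interleaved natural / artificial stimulation trials), smooths them
into rates, concatenates the windows of each condition and runs the
sequentiality pipeline, optionally on early/late halves as well.
``compare_conditions`` applies the paired statistics used for cohorts of
subjects: a two-tailed paired t-test on log seq (excluding subjects with
zero/undefined seq in either condition, for the log to be defined) or a
Wilcoxon signed-rank test on the raw values without exclusions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

from . import __version__ as _version
from .seqcore import (SequentialityAnalysis, UndefinedSequentiality,
                      DEFAULT_MAX_LAG, DEFAULT_LAG_STEP, DEFAULT_N_EPOCHS,
                      DEFAULT_MULTIPLIER)
from .timeseries import TimeSeries, spikes_to_rate


@dataclass
class ConditionResult:
    """Per-subject, per-condition sequentiality measurement."""

    subject: str
    condition: str
    seq: float                    # NaN when undefined
    seq_raw: float = None
    n_channels: int = 0
    duration_ms: float = 0.0
    n_components: int = 0
    undefined_reason: str = None

    @property
    def defined(self) -> bool:
        return self.seq is not None and np.isfinite(self.seq)


def _measure(ts: TimeSeries, params: dict, subject: str,
             condition: str) -> ConditionResult:
    est = SequentialityAnalysis(
        max_lag=params.get("max_lag", DEFAULT_MAX_LAG),
        lag_step=params.get("lag_step", DEFAULT_LAG_STEP),
        n_epochs=params.get("n_epochs", DEFAULT_N_EPOCHS),
        multiplier=params.get("multiplier", DEFAULT_MULTIPLIER),
        dt=ts.dt)
    try:
        est.fit(ts)
    except ValueError as err:
        return ConditionResult(subject=subject, condition=condition,
                               seq=float("nan"), n_channels=ts.n_units,
                               duration_ms=ts.duration,
                               undefined_reason=str(err))
    reason = None
    if not np.isfinite(est.seq_):
        reason = "no component of either parity survives the noise floor"
    return ConditionResult(subject=subject, condition=condition,
                           seq=est.seq_, seq_raw=est.seq_raw_,
                           n_channels=ts.n_units, duration_ms=ts.duration,
                           n_components=est.n_surviving_,
                           undefined_reason=reason)


def analyze_recording(events, condition_windows: dict, unit_ids=None,
                      subject: str = "subject", params: dict = None,
                      split_halves: bool = False) -> dict:
    """Per-condition sequentiality of a spike recording.

    Parameters
    ----------
    events : iterable of (time_ms, unit_id)
    condition_windows : dict
        Maps condition label to a list of (t0_ms, t1_ms) trial windows.
        Trials of a condition are concatenated before epoching; covariances
        are never computed across the gaps between conditions (each window's
        rates are smoothed within the full recording, then excised).
    params : dict
        ``max_lag``/``lag_step``/``n_epochs``/``multiplier``/``dt``/
        ``kernel_width``; defaults are the package defaults (+/-200 ms,
        2 ms, M=10, 7 sigma, dt=2 ms bins, 10 ms smoothing).
    split_halves : bool
        Also analyse the first and second halves of each condition's
        concatenated time (labels ``<cond>_early`` / ``<cond>_late``).

    Returns
    -------
    dict mapping condition label to :class:`ConditionResult`.
    """
    params = dict(params or {})
    dt = params.get("dt", 2.0)
    kernel_width = params.get("kernel_width", 10.0)
    events = [(float(t), str(u)) for t, u in events]
    t_end = max((t for t, _ in events), default=0.0) + dt
    for wins in condition_windows.values():
        for t0, t1 in wins:
            if t1 <= t0:
                raise ValueError("condition windows must have t1 > t0")
            t_end = max(t_end, t1)
    for t, _ in events:
        if not any(t0 <= t < t1 for wins in condition_windows.values()
                   for t0, t1 in wins):
            raise ValueError(f"event at {t} ms falls outside every declared window")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = spikes_to_rate(events, dt=dt, kernel_width=kernel_width,
                              unit_ids=unit_ids, t_stop=t_end)

    out = {}
    for cond, wins in condition_windows.items():
        segs = []
        for t0, t1 in sorted(wins):
            i0, i1 = int(round(t0 / dt)), int(round(t1 / dt))
            segs.append(full.values[:, i0:i1])
        vals = np.concatenate(segs, axis=1)
        ts = TimeSeries(vals, dt=dt, unit_ids=full.unit_ids)
        out[cond] = _measure(ts, params, subject, cond)
        if split_halves:
            half = vals.shape[1] // 2
            for label, sl in (("early", slice(0, half)),
                              ("late", slice(half, 2 * half))):
                tsh = TimeSeries(vals[:, sl], dt=dt, unit_ids=full.unit_ids)
                out[f"{cond}_{label}"] = _measure(tsh, params, subject,
                                                  f"{cond}_{label}")
    return out


@dataclass
class PairedComparison:
    statistic: float
    p_value: float
    n_included: int
    n_total: int
    excluded: list = field(default_factory=list)
    test: str = "paired_t_on_log"


def compare_conditions(results_a, results_b,
                       test: str = "paired_t_on_log") -> PairedComparison:
    """Paired cohort statistics across subjects.

    ``paired_t_on_log``: two-tailed paired t-test on log seq; subjects with
    zero or undefined seq in either condition are excluded (and reported),
    since the log is undefined for them.  ``wilcoxon_raw``: Wilcoxon
    signed-rank on the raw seq values with no exclusions (undefined treated
    as 0).
    """
    if len(results_a) != len(results_b):
        raise ValueError("paired comparisons need equal-length cohorts")
    n_total = len(results_a)
    for a, b in zip(results_a, results_b):
        if a.subject != b.subject:
            raise ValueError(f"pairing mismatch: {a.subject} vs {b.subject}")

    if test == "paired_t_on_log":
        xs, ys, excluded = [], [], []
        for a, b in zip(results_a, results_b):
            if a.defined and b.defined and a.seq > 0 and b.seq > 0:
                xs.append(np.log(a.seq))
                ys.append(np.log(b.seq))
            else:
                excluded.append((a.subject,
                                 "zero or undefined sequentiality in at "
                                 "least one condition"))
        if len(xs) < 3:
            raise ValueError(
                f"only {len(xs)} usable pairs after exclusions "
                f"({n_total - len(xs)} excluded): {excluded}")
        if np.allclose(xs, ys):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.ttest_rel(xs, ys)
        return PairedComparison(statistic=float(stat), p_value=float(p),
                                n_included=len(xs), n_total=n_total,
                                excluded=excluded, test=test)
    if test == "wilcoxon_raw":
        xs = [a.seq if a.defined else 0.0 for a in results_a]
        ys = [b.seq if b.defined else 0.0 for b in results_b]
        d = np.asarray(xs) - np.asarray(ys)
        if np.allclose(d, 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = stats.wilcoxon(xs, ys)
        return PairedComparison(statistic=float(stat), p_value=float(p),
                                n_included=n_total, n_total=n_total, test=test)
    raise ValueError(f"unknown test {test!r}")


# ------------------------------------------------------------- experiment run
def run_experiment(config: dict, out_dir=None) -> dict:
    """Drive a scenario end to end: generate, simulate, measure, report.

    ``config`` keys: ``scenario`` (name), ``N``, ``seed``, optional
    ``measure`` overrides (max_lag, lag_step, n_epochs, multiplier) and
    scenario ``overrides``.  Returns a report dict (also written as JSON
    with a parameter manifest when ``out_dir`` is given); the report
    carries the input-side and output-side sequentiality.
    """
    from . import netsim, synthdata

    for key in ("scenario",):
        if key not in config:
            raise ValueError(f"config is missing required key {key!r}")
    name = config["scenario"]
    N = int(config.get("N", 50))
    seed = int(config.get("seed", 0))
    measure = dict(config.get("measure", {}))
    bundle = synthdata.scenario(name, N=N, seed=seed,
                                **dict(config.get("overrides", {})))

    v, rates, xi = netsim.run_network(bundle.W, bundle.input_model,
                                      bundle.config, seed=seed)
    res_out = _measure(v, measure, subject=name, condition="output")
    res_in = _measure(xi, measure, subject=name, condition="input")
    report = {
        "manifest": {
            "version": _version, "scenario": name, "N": N, "seed": seed,
            "T": bundle.config.T, "dt": bundle.config.dt,
            "tau": bundle.config.tau, "tau_in": bundle.input_model.tau_in,
            "mu": bundle.input_model.mu,
            "nonlinearity": bundle.config.nonlinearity,
            "measure": measure,
        },
        "input": asdict(res_in),
        "output": asdict(res_out),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        v.to_csv(out_dir / "membrane.csv")
        np.savetxt(out_dir / "weights.txt", bundle.W.W,
                   header=f"scenario={name} N={N} seed={seed}")
    return report
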