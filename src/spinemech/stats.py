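"""Summary statistics and report generation for tension-probe data.

Histograms, skewness, totals, below-threshold fractions and crossing-time
extraction for the per-probe tension-force norms recorded during a run.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats as _sps

from .engine import NOT_REACHED, ObservableSeries


@dataclass
class TensionSummary:
    bin_edges: np.ndarray          # pN
    counts: np.ndarray
    skewness: float                # adjusted Fisher-Pearson
    total: float                   # pN
    threshold: float               # pN
    frac_below: float
    max_probe: int
    max_value: float               # pN

    def to_dict(self) -> dict:
        return {"bin_edges": self.bin_edges.tolist(),
                "counts": self.counts.tolist(),
                "skewness": self.skewness, "total": self.total,
                "threshold": self.threshold, "frac_below": self.frac_below,
                "max_probe": self.max_probe, "max_value": self.max_value}


def tension_summary(probe_norms, bin_width: float = 0.2,
                    threshold: float = 0.6) -> TensionSummary:
    """Histogram/skewness/total/threshold-fraction summary of probe norms."""
    x = np.asarray(probe_norms, dtype=float)
    if x.size == 0:
        raise ValueError("probe_norms must be non-empty")
    hi = max(float(x.max()), bin_width)
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    if x.size > 2 and x.std() > 1e-12 * max(1.0, abs(x.mean())):
        skew = float(_sps.skew(x, bias=False))
    else:
        skew = 0.0      # degenerate (constant) sample
    return TensionSummary(
        bin_edges=edges, counts=counts,
        skewness=skew,
        total=float(x.sum()), threshold=threshold,
        frac_below=float((x < threshold).mean()),
        max_probe=int(np.argmax(x)), max_value=float(x.max()))


def volume_crossing(series: ObservableSeries, v_target: float) -> float:
    """First time the recorded volume reaches ``v_target`` (linear
    interpolation between steps); ``inf`` when never reached."""
    v = series.volume_arr
    t = series.t_arr
    if v.size == 0:
        raise ValueError("empty series")
    hit = np.nonzero(v >= v_target)[0]
    if len(hit) == 0:
        return NOT_REACHED
    i = hit[0]
    if i == 0:
        return float(t[0])
    f = (v_target - v[i - 1]) / (v[i] - v[i - 1])
    return float(t[i - 1] + f * (t[i] - t[i - 1]))


def make_report(run_dir: str | Path) -> dict:
    """Collect the per-scenario CSV outputs under ``run_dir`` into one
    human-readable table + machine-readable JSON (written alongside)."""
    import pandas as pd

    run_dir = Path(run_dir)
    rows = {}
    missing = []
    for csv in sorted(run_dir.glob("*.csv")):
        if csv.name.endswith(".probes.csv"):
            continue
        df = pd.read_csv(csv)
        name = csv.stem
        entry = {"steps": len(df), "t_end": float(df["t"].iloc[-1]),
                 "volume_end": float(df["volume"].iloc[-1]),
                 "area_end": float(df["area"].iloc[-1])}
        if "psd_area" in df:
            entry["psd_area_end"] = float(df["psd_area"].iloc[-1])
            if df["psd_area"].iloc[-1] > 0 and df["volume"].iloc[-1] > 0:
                entry["psd_area_over_volume"] = (
                    entry["psd_area_end"] / entry["volume_end"])
        probes = csv.with_suffix(".probes.csv")
        if probes.exists():
            norms = np.loadtxt(probes, delimiter=",")
            ts = tension_summary(norms[-1])
            entry["tension_total_end"] = ts.total
            entry["tension_skewness_end"] = ts.skewness
            entry["tension_frac_below_0.6"] = ts.frac_below
        rows[name] = entry
    if not rows:
        missing.append(str(run_dir / "*.csv"))
    report = {"runs": rows, "missing": missing,
              "skewness_estimator": "adjusted Fisher-Pearson (bias-corrected)"}
    out = run_dir / "report.json"
    out.write_text(json.dumps(report, indent=2))
    return report
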