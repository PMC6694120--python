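"""Raw flow-cytometry event processing.

Turns per-cell event tables (FSC/SSC scatter, FITC-A reporter signal, PE-A
correlated signal, acquisition timestamps) into per-sample expression
summaries, cell densities from the event rate, and per-genotype Malthusian
growth rates.

The processing chain per sample is::

    events -> gate_events -> correct_saturation -> summarize_sample

and per genotype (paired glucose / 12 h-galactose samples)::

    growth_rate(density_glu, density_gal)  ->  mu [1/h], generations

All expression statistics are computed on a pseudo-log scale,
``log10(raw + 1000) - 3``, which maps raw 0 A.U. to 0 and tolerates the
negative raw values that cytometers emit for dim cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "SampleSummary",
    "pseudolog",
    "pseudolog_inverse",
    "gate_events",
    "correct_saturation",
    "summarize_sample",
    "growth_rate",
    "default_bin_edges",
    "on_cutoff_from_controls",
]

#: Default pseudo-log histogram range; covers raw ~0 to ~3e6 A.U.
PSEUDOLOG_RANGE = (-0.5, 3.5)
N_BINS = 60

EVENT_COLUMNS = ["FSC-A", "SSC-A", "FITC-A", "PE-A", "time_ms"]


@dataclass
class EventTable:
    """Per-cell cytometer measurements for one sample.

    ``data`` holds one row per event with columns FSC-A, SSC-A, FITC-A,
    PE-A (arbitrary units) and time_ms (acquisition timestamp,
    nondecreasing).  ``sampling_rate`` is the aspiration rate in ul/s and
    links event rate to cell density.
    """

    data: pd.DataFrame
    sample_id: str = ""
    sampling_rate: float = 0.5  # ul / s

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        missing = [c for c in EVENT_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"event table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    def replace_data(self, data: pd.DataFrame) -> "EventTable":
        return EventTable(data=data, sample_id=self.sample_id,
                          sampling_rate=self.sampling_rate)


@dataclass
class SampleSummary:
    """Distribution and density summary of one gated sample."""

    sample_id: str
    condition: str
    fracON: float
    mean_yfp: float  # mean pseudo-log FITC-A of gated cells
    density: float  # cells / ul, from the event-rate fit
    density_vector: np.ndarray  # 60 normalized bin densities
    n_gated: int
    n_events: int
    censored: bool = False
    genotype_id: str = ""
    replicate: int = 0
    extra: dict = field(default_factory=dict)


def pseudolog(raw):
    """Pseudo-log transform of raw fluorescence: log10(raw + 1000) - 3.

    Strictly increasing on raw > -1000; raw 0 maps to 0 and raw 99000 to 2.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= -1000):
        raise ValueError("pseudolog undefined for raw <= -1000 A.U.")
    return np.log10(raw + 1000.0) - 3.0


def pseudolog_inverse(value):
    """Inverse of :func:`pseudolog`: 10**(value + 3) - 1000."""
    value = np.asarray(value, dtype=float)
    return np.power(10.0, value + 3.0) - 1000.0


def default_bin_edges(n_bins: int = N_BINS,
                      lo: float = PSEUDOLOG_RANGE[0],
                      hi: float = PSEUDOLOG_RANGE[1]) -> np.ndarray:
    """Equally spaced pseudo-log bin edges (n_bins + 1 values)."""
    return np.linspace(lo, hi, n_bins + 1)


def gate_events(events: EventTable,
                rect_quantile: float = 0.95,
                centroid_exclusion: float = 0.40,
                min_events: int = 100,
                grid: int = 64) -> tuple[EventTable, dict]:
    """Two-stage scatter gate on FSC-A x SSC-A.

    Stage 1 keeps events inside the central ``rect_quantile`` box per axis
    (e.g. 0.95 trims 2.5% from each tail of FSC and of SSC independently).
    Stage 2 standardizes both axes, locates the highest-density point with
    a ``grid`` x ``grid`` 2-D histogram, and keeps the
    ``1 - centroid_exclusion`` fraction of stage-1 survivors nearest that
    centroid (Euclidean distance on the standardized axes).  Ties at the
    distance threshold are kept, so a fully degenerate cloud (all events
    identical) passes through unchanged.

    Returns the gated table plus an info dict; samples retaining fewer than
    ``min_events`` events are flagged censored rather than dropped.
    """
    if not 0.0 < rect_quantile <= 1.0:
        raise ValueError("rect_quantile must be in (0, 1]")
    if not 0.0 <= centroid_exclusion < 1.0:
        raise ValueError("centroid_exclusion must be in [0, 1)")
    df = events.data
    if len(df) == 0:
        raise ValueError("cannot gate an empty event table")

    fsc = df["FSC-A"].to_numpy(float)
    ssc = df["SSC-A"].to_numpy(float)
    tail = (1.0 - rect_quantile) / 2.0
    keep = np.ones(len(df), dtype=bool)
    if tail > 0:
        for axis in (fsc, ssc):
            lo, hi = np.quantile(axis, [tail, 1.0 - tail])
            keep &= (axis >= lo) & (axis <= hi)

    if centroid_exclusion > 0 and keep.sum() > 1:
        x, y = fsc[keep], ssc[keep]
        xs = np.std(x) or 1.0
        ys = np.std(y) or 1.0
        xz, yz = (x - x.mean()) / xs, (y - y.mean()) / ys
        hist, xe, ye = np.histogram2d(xz, yz, bins=grid)
        i, j = np.unravel_index(np.argmax(hist), hist.shape)
        cx = 0.5 * (xe[i] + xe[i + 1])
        cy = 0.5 * (ye[j] + ye[j + 1])
        d = np.hypot(xz - cx, yz - cy)
        thr = np.quantile(d, 1.0 - centroid_exclusion)
        sub = d <= thr
        idx = np.flatnonzero(keep)
        keep = np.zeros(len(df), dtype=bool)
        keep[idx[sub]] = True

    gated = events.replace_data(df.loc[keep].reset_index(drop=True))
    info = {
        "n_input": len(df),
        "n_retained": int(keep.sum()),
        "censored": bool(keep.sum() < min_events),
    }
    return gated, info


def correct_saturation(events: EventTable,
                       ceiling: float = 2 ** 18 - 1,
                       min_fit_events: int = 30) -> tuple[EventTable, dict]:
    """Reconstruct FITC-A readings clipped at the detector ceiling.

    Fits ordinary least squares of log(FITC-A) on log(PE-A) over
    non-saturated events with positive signal in both channels, then
    replaces each saturated event's FITC-A by the fit's prediction from its
    PE-A.  With no saturated events the table is returned unchanged; a
    degenerate fit (zero PE variance, or too few usable events) leaves
    saturated values at the ceiling and sets ``info['flagged']``.
    """
    df = events.data
    fitc = df["FITC-A"].to_numpy(float)
    pe = df["PE-A"].to_numpy(float)
    saturated = fitc >= ceiling
    info = {"n_saturated": int(saturated.sum()), "flagged": False,
            "slope": np.nan, "intercept": np.nan}
    if not saturated.any():
        return events, info

    usable = (~saturated) & (fitc > 0) & (pe > 0)
    if usable.sum() < min_fit_events:
        if (~saturated).sum() < min_fit_events:
            raise ValueError(
                f"need >= {min_fit_events} non-saturated events to fit the "
                f"FITC~PE recovery model, have {int((~saturated).sum())}")
        info["flagged"] = True
        return events, info

    lx = np.log(pe[usable])
    ly = np.log(fitc[usable])
    if np.ptp(lx) == 0.0:
        info["flagged"] = True
        return events, info
    slope, intercept = np.polyfit(lx, ly, 1)
    info["slope"], info["intercept"] = float(slope), float(intercept)

    out = fitc.copy()
    pred_ok = saturated & (pe > 0)
    out[pred_ok] = np.exp(intercept + slope * np.log(pe[pred_ok]))
    new = df.copy()
    new["FITC-A"] = out
    return events.replace_data(new), info


def _event_rate_per_ms(time_ms: np.ndarray) -> float:
    """Events/ms as the OLS slope of cumulative event count vs time."""
    n = len(time_ms)
    if n < 2 or np.ptp(time_ms) == 0:
        return np.nan
    counts = np.arange(1, n + 1, dtype=float)
    slope, _ = np.polyfit(time_ms.astype(float), counts, 1)
    return float(slope)


def summarize_sample(events: EventTable,
                     on_cutoff: float,
                     bin_edges: np.ndarray | None = None,
                     rate_events: EventTable | None = None) -> SampleSummary:
    """Summarize a gated, saturation-corrected sample.

    fracON is the proportion of cells above ``on_cutoff`` on the pseudo-log
    scale; the 60-bin density vector is normalized so sum x binwidth = 1.
    Cell density (cells/ul) is the cumulative-count-vs-time OLS slope
    (events/ms) x 1000 / sampling_rate; pass ``rate_events`` to estimate
    the rate from the pre-gate table while summarizing expression on the
    gated one.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    bin_edges = np.asarray(bin_edges, dtype=float)
    df = events.data
    n = len(df)
    if n == 0:
        return SampleSummary(
            sample_id=events.sample_id, condition="", fracON=np.nan,
            mean_yfp=np.nan, density=np.nan,
            density_vector=np.full(len(bin_edges) - 1, np.nan),
            n_gated=0, n_events=0, censored=True)

    p = pseudolog(df["FITC-A"].to_numpy(float))
    frac_on = float(np.mean(p > on_cutoff))
    mean_yfp = float(np.mean(p))

    clipped = np.clip(p, bin_edges[0], bin_edges[-1])
    counts, _ = np.histogram(clipped, bins=bin_edges)
    width = bin_edges[1] - bin_edges[0]
    dens = counts / (counts.sum() * width)

    src = rate_events if rate_events is not None else events
    rate = _event_rate_per_ms(src.data["time_ms"].to_numpy())
    density = rate * 1000.0 / src.sampling_rate if np.isfinite(rate) else np.nan

    return SampleSummary(
        sample_id=events.sample_id, condition="", fracON=frac_on,
        mean_yfp=mean_yfp, density=float(density), density_vector=dens,
        n_gated=n, n_events=len(src.data))


def growth_rate(density_glu: float, density_gal: float,
                dilution: float = 150.0 / 9.0,
                hours: float = 12.0) -> tuple[float, float]:
    """Malthusian growth rate and generations from a density pair.

    The galactose culture was inoculated from the saturated glucose culture
    at 9 parts in 150, so the inoculum density is ``density_glu / dilution``
    with ``dilution = 150/9``.  Returns::

        mu          = ln(density_gal / inoculum) / hours   [1/h]
        generations = log2(density_gal / inoculum)

    Nonpositive densities yield (nan, nan); callers flag such samples.
    """
    if not (density_glu > 0 and density_gal > 0):
        return (np.nan, np.nan)
    inoculum = density_glu / dilution
    ratio = density_gal / inoculum
    return (float(np.log(ratio) / hours), float(np.log2(ratio)))


def on_cutoff_from_controls(control_pseudolog: Sequence[np.ndarray] | np.ndarray,
                            quantile: float = 0.999) -> float:
    """ON/OFF cutoff from autofluorescent-control samples.

    Pools the controls' pseudo-log signals and returns their ``quantile``
    (default 99.9th percentile): cells above it are called ON.
    """
    if isinstance(control_pseudolog, np.ndarray):
        pooled = control_pseudolog.ravel()
    else:
        pooled = np.concatenate([np.asarray(a).ravel()
                                 for a in control_pseudolog])
    if pooled.size == 0:
        raise ValueError("no control events supplied")
    return float(np.quantile(pooled, quantile))
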