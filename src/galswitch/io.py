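"""Plain-text interchange: delimited event tables, layouts, stage TSVs.

Every stage artifact is tab-separated text so any stage can be re-run
from disk and diffed.  Event tables use the five-column dialect
(FSC-A, SSC-A, FITC-A, PE-A, time_ms); sample metadata lives in the
layout table, one row per sample.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd

from .cytometry import EVENT_COLUMNS, EventTable

LAYOUT_COLUMNS = ["sample_id", "genotype_id", "condition",
                  "sampling_rate_ul_per_s", "replicate", "censored", "file"]


def write_event_table(events: EventTable, path: str | Path,
                      compress: bool = False) -> Path:
    path = Path(path)
    if compress and not str(path).endswith(".gz"):
        path = path.with_suffix(path.suffix + ".gz")
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        events.data[EVENT_COLUMNS].to_csv(fh, sep="\t", index=False,
                                          float_format="%.4f")
    return path


def read_event_table(path: str | Path, sample_id: str = "",
                     sampling_rate: float = 0.5) -> EventTable:
    df = pd.read_csv(path, sep="\t")
    return EventTable(data=df, sample_id=sample_id or Path(path).stem,
                      sampling_rate=sampling_rate)


def write_layout(layout: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    layout.to_csv(path, sep="\t", index=False)
    return path


def read_layout(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def profile_columns(n_bins: int = 60) -> list[str]:
    return ([f"glu_{i:02d}" for i in range(n_bins)]
            + [f"gal_{i:02d}" for i in range(n_bins)])


def profiles_to_frame(profiles: dict[str, np.ndarray],
                      n_bins: int = 60) -> pd.DataFrame:
    cols = profile_columns(n_bins)
    df = pd.DataFrame.from_dict(profiles, orient="index", columns=cols)
    df.index.name = "genotype_id"
    return df
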