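"""File I/O and run configuration.

Scans are plain CSV/TSV numeric matrices (rows = regions by default, with a
``transpose`` flag for the columns-as-regions dialect), metadata is a CSV
with subject_id / condition / optional dose, and results are written as a
tidy CSV (one row per subject x condition x metric) stamped with the
parameter values, seeds, and a config hash so identical runs are
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import MetricParams
from .signal_prep import RoiTimeSeries

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "read_timeseries", "read_metadata", "write_results",
           "read_results"]


@dataclass
class RunConfig:
    """Parameters and seeds governing a full pipeline run."""

    params: MetricParams = field(default_factory=MetricParams)
    cohort_seed: int = 0
    transpose: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        th = self.params.thresholds
        if any(not 0 < t < 100 for t in th) or any(
            b <= a for a, b in zip(th, th[1:])
        ):
            raise ValueError("thresholds must be strictly increasing within (0, 100)")

    def config_hash(self) -> str:
        payload = json.dumps(
            {"params": asdict(self.params), "cohort_seed": self.cohort_seed,
             "transpose": self.transpose},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _read_numeric(path: Path) -> pd.DataFrame:
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    try:
        df = pd.read_csv(path, sep=sep, header=None, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file") from None
    # tolerate a header row / index column of labels
    if df.iloc[0].apply(lambda v: isinstance(v, str)).any():
        df = pd.read_csv(path, sep=sep, header=0, float_precision="round_trip")
    if df.shape[1] and df.iloc[:, 0].apply(lambda v: isinstance(v, str)).all():
        df = df.set_index(df.columns[0])
    return df


def read_timeseries(
    path: str | Path, transpose: bool = False, sampling_interval: float = 2.0
) -> RoiTimeSeries:
    """Read a region x time matrix from CSV/TSV.

    ``transpose=True`` reads the columns-as-regions dialect. Missing or
    non-numeric cells are rejected with the offending position named.
    """
    path = Path(path)
    df = _read_numeric(path)
    arr = df.to_numpy()
    numeric = pd.DataFrame(arr).apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = ~np.isfinite(numeric)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: missing or non-numeric value at row {i}, column {j}"
        )
    if transpose:
        numeric = numeric.T
    region_ids = [str(r) for r in df.index] if not transpose else []
    ts = RoiTimeSeries(
        values=numeric,
        region_ids=region_ids if len(region_ids) == numeric.shape[0] else [],
        sampling_interval=sampling_interval,
    )
    logger.info("read %s: %d regions x %d timepoints", path, ts.n_regions,
                ts.n_timepoints)
    return ts


def read_metadata(
    path: str | Path, conditions: list[str] | None = None
) -> pd.DataFrame:
    """Read and validate the subject metadata table.

    Requires subject_id and condition columns; dose is optional (NaN for
    awake scans is accepted — those scans are excluded from dose analyses).
    Duplicate (subject, condition) rows and unknown condition labels are
    rejected.
    """
    df = pd.read_csv(path)
    required = {"subject_id", "condition"}
    if not required.issubset(df.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    dupes = df.duplicated(subset=["subject_id", "condition"])
    if dupes.any():
        raise ValueError(f"duplicate (subject, condition) rows: {dupes.sum()}")
    if conditions is not None:
        unknown = set(df["condition"]) - set(conditions)
        if unknown:
            raise ValueError(f"unknown condition label(s): {sorted(unknown)}")
        df["condition"] = pd.Categorical(df["condition"], categories=conditions,
                                         ordered=True)
    if "dose" not in df.columns:
        df["dose"] = np.nan
    return df


def write_results(
    profiles: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write profiles as a tidy CSV: one row per (subject, condition, metric).

    Every row carries the metric parameters, seeds, and the config hash, so
    a result file is self-describing and runs are byte-reproducible.
    """
    config = config or RunConfig()
    from .cohort import METRICS  # local import to avoid cycle at module load

    id_cols = [c for c in ("subject_id", "condition", "dose") if c in profiles.columns]
    value_cols = [c for c in METRICS if c in profiles.columns]
    tidy = profiles.melt(
        id_vars=id_cols, value_vars=value_cols, var_name="metric", value_name="value"
    )
    p = config.params
    tidy["m"] = p.m
    tidy["r_coef"] = p.r_coef
    tidy["k_max"] = str(p.k_max)
    tidy["variance_threshold"] = p.variance_threshold
    tidy["thresholds"] = "|".join(str(t) for t in p.thresholds)
    tidy["surrogate_seed"] = p.surrogate_seed
    tidy["cohort_seed"] = config.cohort_seed
    tidy["config_hash"] = config.config_hash()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tidy.to_csv(path, index=False, float_format="%.17g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a tidy results CSV back into a wide profile table."""
    tidy = pd.read_csv(path, float_precision="round_trip")
    if tidy.empty:
        return tidy
    id_cols = [c for c in ("subject_id", "condition", "dose") if c in tidy.columns]
    wide = tidy.pivot_table(
        index=id_cols, columns="metric", values="value", aggfunc="first"
    ).reset_index()
    wide.columns.name = None
    return wide
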