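"""On-disk formats: long trace TSV, signal-matrix TSV + JSON sidecar,
sample-metadata TSV, and the validated run configuration.

TSV (tab-separated, ``NA`` for missing, ``.`` decimal) is the lingua franca;
structured reports are JSON.  Schema violations raise :class:`SchemaError`
naming the offending record.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

from .errors import SchemaError
from .peaks import QuantConfig, SignalMatrix, Trace, TraceSet
from .synthetic_data import GRADES, TUMOR_TYPES, CohortConfig

__all__ = [
    "read_trace_table", "write_trace_table",
    "read_signal_matrix", "write_signal_matrix",
    "read_metadata", "write_metadata",
    "RunConfig",
]

TRACE_COLUMNS = ["sample_id", "antibody_id", "strip_index", "mw_kda", "intensity_rfu"]
PRESERVATIONS = ("fresh_frozen", "FFPE")


def write_trace_table(traces: TraceSet | Sequence[Trace], path: str | Path) -> None:
    """Long-format TSV: one row per (sample, antibody, strip)."""
    frames = []
    for t in traces:
        n = len(t)
        frames.append(pd.DataFrame({
            "sample_id": t.sample_id, "antibody_id": t.antibody_id,
            "strip_index": np.arange(n), "mw_kda": t.mw_axis,
            "intensity_rfu": t.intensities}))
    df = pd.concat(frames, ignore_index=True) if frames else \
        pd.DataFrame(columns=TRACE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_trace_table(path: str | Path) -> TraceSet:
    """Parse and validate a long-format trace TSV into grouped traces."""
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    if df.empty:
        warnings.warn(f"{path}: empty trace table")
        return TraceSet([])
    if (df["intensity_rfu"] < 0).any():
        bad = df.index[df["intensity_rfu"] < 0][0]
        raise SchemaError(f"{path}: negative intensity at data line {bad + 2} "
                          f"({df.loc[bad, 'sample_id']}, {df.loc[bad, 'antibody_id']})")
    traces = []
    for (sample, antibody), grp in df.groupby(["sample_id", "antibody_id"], sort=False):
        strips = grp["strip_index"].to_numpy()
        n = strips.max() + 1 if len(strips) else 0
        if len(np.unique(strips)) != len(strips):
            raise SchemaError(f"{path}: duplicate strip in group ({sample}, {antibody})")
        if not np.array_equal(np.sort(strips), np.arange(n)) or len(strips) != n:
            raise SchemaError(f"{path}: incomplete strips (got {len(strips)}) "
                              f"in group ({sample}, {antibody})")
        grp = grp.sort_values("strip_index")
        traces.append(Trace(str(sample), str(antibody),
                            grp["intensity_rfu"].to_numpy(dtype=float),
                            grp["mw_kda"].to_numpy(dtype=float)))
    return TraceSet(traces)


def write_signal_matrix(matrix: SignalMatrix, path: str | Path) -> None:
    """Rows = signals, columns = samples, missing = ``NA``; sidecar JSON
    (``<path>.meta.json``) carries per-signal metadata and the log2 flag."""
    path = Path(path)
    if "NA" in matrix.values.columns:
        raise SchemaError("a sample named 'NA' is ambiguous with the missing marker")
    matrix.values.to_csv(path, sep="\t", na_rep="NA")
    meta = {
        "log2": bool(matrix.log2),
        "detection_floor": None if np.isnan(matrix.detection_floor)
        else float(matrix.detection_floor),
        "signals": matrix.signal_info.reset_index().to_dict(orient="records"),
    }
    Path(f"{path}.meta.json").write_text(json.dumps(meta, indent=1))


def read_signal_matrix(path: str | Path) -> SignalMatrix:
    path = Path(path)
    values = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"],
                         keep_default_na=False)
    values = values.astype(float)
    sidecar = Path(f"{path}.meta.json")
    if not sidecar.exists():
        raise SchemaError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    info = pd.DataFrame(meta["signals"]).set_index("signal_id") if meta["signals"] \
        else pd.DataFrame(index=pd.Index([], name="signal_id"))
    if sorted(info.index) != sorted(values.index):
        raise SchemaError(f"{path}: sidecar signal ids do not match matrix rows")
    floor = meta.get("detection_floor")
    return SignalMatrix(values, info.loc[values.index], log2=bool(meta["log2"]),
                        detection_floor=float("nan") if floor is None else float(floor))


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_metadata(path: str | Path, tumor_types: Sequence[str] = TUMOR_TYPES
                  ) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    for col in ("sample_id", "tumor_type", "preservation"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col}")
    bad = df[~df["tumor_type"].isin(tumor_types)]
    if len(bad):
        raise SchemaError(f"{path}: unknown tumor types {sorted(set(bad['tumor_type']))}")
    bad = df[~df["preservation"].isin(PRESERVATIONS)]
    if len(bad):
        raise SchemaError(f"{path}: unknown preservation "
                          f"{sorted(set(bad['preservation']))}")
    if "grade" in df.columns:
        known = df["grade"].dropna()
        bad_g = sorted(set(known) - set(GRADES))
        if bad_g:
            raise SchemaError(f"{path}: unknown grades {bad_g}")
    if "tumor_cell_content" in df.columns:
        tcc = df["tumor_cell_content"].dropna()
        if ((tcc < 0) | (tcc > 100)).any():
            raise SchemaError(f"{path}: tumor_cell_content outside [0, 100]")
    return df


class SimulateSettings(BaseModel):
    """Mirrors :class:`~digiwest.synthetic_data.CohortConfig` (seed comes
    from the run level)."""

    model_config = ConfigDict(extra="forbid")
    n_per_type: int = 5
    n_antibodies: int = 300
    fraction_concordant: float = 1.0 / 3.0
    trace_length: int = 96
    mw_min: float = 10.0
    mw_max: float = 250.0
    peak_width: float = 1.5
    baseline_level: float = 20.0
    noise_sd: float = 4.0
    detection_floor: float = 50.0
    hnsc_crossreaction: bool = True

    def to_cohort_config(self, seed: int) -> CohortConfig:
        return CohortConfig(
            n_per_type=self.n_per_type, n_antibodies=self.n_antibodies,
            fraction_concordant=self.fraction_concordant,
            trace_length=self.trace_length, mw_range=(self.mw_min, self.mw_max),
            peak_width=self.peak_width, baseline_level=self.baseline_level,
            noise_sd=self.noise_sd, detection_floor=self.detection_floor,
            hnsc_crossreaction=self.hnsc_crossreaction, seed=seed)


class QuantifySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    min_snr: float = 3.0
    min_prominence: float = 5.0
    min_separation: int = 3
    shift_tolerance: float = 0.20
    detection_floor: float = 50.0
    group_window: int = 5

    def to_quant_config(self) -> QuantConfig:
        return QuantConfig(**self.model_dump())


class SelectSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    alpha: float = 0.05
    min_detected: int = 4
    min_pairs: int = 3


class StatsSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    bh_scope: str = "per_pair"
    alpha: float = 0.05
    welch: bool = False


class ClassifySettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    C_grid: tuple[float, ...] = (1.0, 10.0, 100.0, 1000.0)
    sigma_grid: tuple[float, ...] = Field(
        default_factory=lambda: tuple(0.01 * 10.0 ** k for k in range(-3, 4)))
    outer_folds: int = 5
    outer_repeats: int = 10
    inner_folds: int = 4
    inner_repeats: int = 5
    standardize: bool = True
    probability: str = "pairwise"


class RunConfig(BaseModel):
    """Schema-validated configuration of a full pipeline run.

    Unknown keys are rejected; every stage tunable has the study's stated
    value as default where one is stated.
    """

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    log2_floor: float = 1.0
    simulate: SimulateSettings = Field(default_factory=SimulateSettings)
    quantify: QuantifySettings = Field(default_factory=QuantifySettings)
    select: SelectSettings = Field(default_factory=SelectSettings)
    stats: StatsSettings = Field(default_factory=StatsSettings)
    classify: ClassifySettings = Field(default_factory=ClassifySettings)
    write_traces: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))
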