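"""Seeded generator of DigiWest-like cohorts with planted ground truth.

The generator emulates the study design the downstream analysis assumes:
25 paired fresh-frozen (FF) / FFPE primary tumors (five each of HNSC, LUSC,
LUAD, COAD, PAAD), an independent 25-sample FFPE validation cohort, and an
antibody panel of which only a subset behaves concordantly between the two
preservation conditions.

Latent abundance model (log2 units of peak height) for sample s, antibody a:

    log2 A(s, a) = base_a + g(s) * effect_a[type(s)] + u_s + eps(s, a)

with a per-sample loading effect u_s ~ N(0, tau^2), per-cell noise
eps ~ N(0, omega^2), and a grade factor g(s) that damps class effects in
poorly differentiated tumors.  Concordant antibodies carry the same latent
abundance into FFPE (plus a small extra noise term); FFPE amplitudes are then
multiplicatively attenuated per antibody, which lowers both mean intensity
and detection frequency.  Non-concordant antibodies redraw their FFPE
abundance from an independent latent stream, planting a ~0 FF/FFPE
correlation.  A configurable secondary-antibody cross-reaction adds a band
at 47-53 kDa in HNSC samples only, stronger in FF than FFPE.

All randomness flows from one integer seed, expanded into stable
per-(purpose, sample, antibody) substreams, so generation order never
changes the output.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .peaks import Trace, TraceSet, calibrate_mw

__all__ = [
    "TUMOR_TYPES",
    "GRADES",
    "AntibodyTemplate",
    "CohortConfig",
    "GroundTruth",
    "generate_panel",
    "generate_trace",
    "generate_cohort",
    "generate_validation_cohort",
]

TUMOR_TYPES: tuple[str, ...] = ("HNSC", "LUSC", "LUAD", "COAD", "PAAD")
GRADES: tuple[str, ...] = ("G1", "G2", "G2-3", "G3")

#: class-effect damping per histological grade (poorly differentiated tumors
#: lose part of their type-specific profile)
GRADE_EFFECT = {"G1": 1.0, "G2": 1.0, "G2-3": 0.8, "G3": 0.6}


@dataclass(frozen=True)
class AntibodyTemplate:
    """Generative stand-in for one antibody of the panel."""

    antibody_id: str
    expected_mw: float
    is_phospho: bool
    class_effect: Mapping[str, float]
    concordant: bool
    ffpe_attenuation: float
    shift_factor: float = 1.0
    extra_peaks: tuple[tuple[float, float], ...] = ()
    crossreact: bool = False
    crossreact_mw: float = float("nan")
    base_log2: float = 5.5

    def __post_init__(self) -> None:
        if self.expected_mw <= 0:
            raise ConfigurationError("expected_mw must be positive")
        if not (0.0 < self.ffpe_attenuation <= 1.0):
            raise ConfigurationError("ffpe_attenuation must be in (0, 1]")
        if self.shift_factor <= 0:
            raise ConfigurationError("shift_factor must be positive")

    @property
    def shift_flag(self) -> bool:
        return abs(self.shift_factor - 1.0) > 0.20


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters of the generator.

    Defaults reproduce the paired 5x5 design and the qualitative FFPE
    regime (lower intensities, fewer detected samples) the selection stage
    is built to screen for.
    """

    n_per_type: int = 5
    tumor_types: tuple[str, ...] = TUMOR_TYPES
    n_antibodies: int = 300
    fraction_concordant: float = 1.0 / 3.0
    trace_length: int = 96
    mw_range: tuple[float, float] = (10.0, 250.0)
    peak_width: float = 1.5          # Gaussian sd, strips
    baseline_level: float = 20.0     # RFU
    noise_sd: float = 4.0            # RFU
    detection_floor: float = 50.0    # RFU*strips
    hnsc_crossreaction: bool = True
    seed: int = 0
    # latent-abundance model
    base_log2_mean: float = 5.85
    base_log2_sd: float = 0.7
    tau: float = 0.5                 # per-sample loading effect, log2 sd
    omega: float = 0.9               # per-cell noise, log2 sd
    marker_fraction: float = 0.7     # concordant antibodies carrying a class effect
    effect_low: float = 1.0          # planted class effect range, log2
    effect_high: float = 2.5
    atten_log2_low: float = 0.3      # FFPE attenuation = 2**-U(low, high)
    atten_log2_high: float = 1.7
    ffpe_extra_sd: float = 0.25      # extra FFPE noise on concordant antibodies, log2
    shift_fraction: float = 0.05     # antibodies with a >20% displaced band
    extra_peak_fraction: float = 0.2
    n_crossreact: int = 3
    crossreact_height_ff: float = 150.0
    crossreact_height_ffpe: float = 60.0

    def __post_init__(self) -> None:
        if self.n_per_type < 2:
            raise ConfigurationError("n_per_type must be >= 2")
        if self.trace_length < 8:
            raise ConfigurationError("trace_length must be >= 8")
        lo, hi = self.mw_range
        if not 0 < lo < hi:
            raise ConfigurationError("mw_range must satisfy 0 < min < max")
        for name in ("peak_width", "baseline_level", "noise_sd", "detection_floor",
                     "base_log2_sd", "tau", "omega"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.fraction_concordant <= 1.0:
            raise ConfigurationError("fraction_concordant must be in [0, 1]")
        if self.n_antibodies < 1:
            raise ConfigurationError("n_antibodies must be >= 1")

    def mw_axis(self) -> np.ndarray:
        """Strip -> kDa axis, decreasing with strip index (gel-top convention)."""
        lo, hi = self.mw_range
        return calibrate_mw(self.trace_length, [(0, hi), (self.trace_length - 1, lo)])


@dataclass
class GroundTruth:
    """Planted facts about a generated cohort, keyed to its templates."""

    antibodies: pd.DataFrame          # one row per antibody
    samples: pd.DataFrame             # the paired-cohort metadata
    templates: tuple[AntibodyTemplate, ...]
    config: CohortConfig


def _substream(seed: int, *keys) -> np.random.Generator:
    """Stable per-key RNG stream: identical regardless of generation order."""
    digest = hashlib.sha256("|".join(str(k) for k in keys).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *words]))


def generate_panel(config: CohortConfig) -> tuple[AntibodyTemplate, ...]:
    """Draw the antibody templates (shared by the paired and validation cohorts)."""
    rng = _substream(config.seed, "panel")
    n = config.n_antibodies
    n_conc = int(round(config.fraction_concordant * n))
    conc_idx = set(rng.choice(n, size=n_conc, replace=False).tolist())
    lo, hi = config.mw_range
    # keep expected MW away from the axis edges so displaced bands stay on-axis
    mw_lo, mw_hi = lo * 1.5, hi * 0.72
    types = config.tumor_types
    templates: list[AntibodyTemplate] = []
    cross_idx: set[int] = set()
    if config.hnsc_crossreaction and config.n_crossreact > 0 and "HNSC" in types:
        cross_idx = set(rng.choice(n, size=min(config.n_crossreact, n),
                                   replace=False).tolist())
    for i in range(n):
        expected_mw = float(10 ** rng.uniform(np.log10(mw_lo), np.log10(mw_hi)))
        concordant = i in conc_idx
        effect: dict[str, float] = {t: 0.0 for t in types}
        if concordant and rng.random() < config.marker_fraction:
            marked = types[rng.integers(len(types))]
            effect[marked] = float(rng.uniform(config.effect_low, config.effect_high))
        attenuation = float(2.0 ** -rng.uniform(config.atten_log2_low,
                                                config.atten_log2_high))
        shift_factor = 1.0
        if rng.random() < config.shift_fraction:
            shift_factor = float(rng.choice([0.7, 1.35]))
        extra: tuple[tuple[float, float], ...] = ()
        if rng.random() < config.extra_peak_fraction:
            factor = float(rng.choice([0.55, 1.6]))
            mw2 = float(np.clip(expected_mw * factor, lo * 1.05, hi * 0.95))
            extra = ((mw2, float(rng.uniform(0.3, 0.7))),)
        templates.append(AntibodyTemplate(
            antibody_id=f"AB{i + 1:04d}",
            expected_mw=expected_mw,
            is_phospho=bool(rng.random() < 0.15),
            class_effect=effect,
            concordant=concordant,
            ffpe_attenuation=attenuation,
            shift_factor=shift_factor,
            extra_peaks=extra,
            crossreact=i in cross_idx,
            crossreact_mw=float(rng.uniform(47.0, 53.0)) if i in cross_idx else float("nan"),
            base_log2=float(rng.normal(config.base_log2_mean, config.base_log2_sd)),
        ))
    return tuple(templates)


def _nearest_strip(mw_axis: np.ndarray, target_mw: float) -> int:
    log_axis = np.log10(mw_axis)
    return int(np.argmin(np.abs(log_axis - np.log10(target_mw))))


def generate_trace(template: AntibodyTemplate, abundance: float, preservation: str,
                   config: CohortConfig, rng: np.random.Generator,
                   extra_bands: Sequence[tuple[float, float]] = ()) -> Trace:
    """One 96-point trace: baseline + Gaussian band(s) + noise, clipped at 0.

    ``abundance`` is log2 of the FF peak height; FFPE amplitudes are
    multiplied by the template's attenuation factor.  ``extra_bands`` are
    additive (mw, height) artifacts, e.g. the HNSC cross-reaction.
    """
    if preservation not in ("fresh_frozen", "FFPE"):
        raise ValueError(f"unknown preservation {preservation!r}")
    if not np.isfinite(abundance):
        raise ValueError("abundance must be finite")
    mw_axis = config.mw_axis()
    lo, hi = min(mw_axis[0], mw_axis[-1]), max(mw_axis[0], mw_axis[-1])
    target = template.expected_mw * template.shift_factor
    if not lo <= target <= hi:
        raise ConfigurationError(
            f"{template.antibody_id}: band at {target:.1f} kDa outside axis "
            f"[{lo:.1f}, {hi:.1f}]")
    amp = 2.0 ** float(abundance)
    if preservation == "FFPE":
        amp *= template.ffpe_attenuation
    strips = np.arange(config.trace_length, dtype=float)
    y = np.full(config.trace_length, config.baseline_level, dtype=float)

    def add_band(mw: float, height: float) -> None:
        c = _nearest_strip(mw_axis, mw)
        y_band = height * np.exp(-0.5 * ((strips - c) / config.peak_width) ** 2)
        np.add(y, y_band, out=y)

    add_band(target, amp)
    for mw2, rel in template.extra_peaks:
        add_band(mw2, amp * rel)
    for mw2, height in extra_bands:
        add_band(mw2, height)
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=config.trace_length)
    np.clip(y, 0.0, None, out=y)
    return Trace(sample_id="", antibody_id=template.antibody_id,
                 intensities=y, mw_axis=mw_axis)


def _paired_metadata(config: CohortConfig) -> pd.DataFrame:
    rng = _substream(config.seed, "samples")
    types = [t for t in config.tumor_types for _ in range(config.n_per_type)]
    n = len(types)
    grades = _grade_multiset(n, {"G1": 0.04, "G2": 0.72, "G2-3": 0.08, "G3": 0.16})
    grades = list(rng.permutation(grades))
    rows = []
    for i, t in enumerate(types):
        pair = f"P{i + 1:02d}"
        tcc_ff = float(np.round(rng.uniform(40, 100)))
        tcc_ffpe = float(np.round(rng.uniform(40, 96)))
        for pres, tcc in (("fresh_frozen", tcc_ff), ("FFPE", tcc_ffpe)):
            rows.append({"sample_id": f"{pair}-{'FF' if pres == 'fresh_frozen' else 'FFPE'}",
                         "tumor_type": t, "preservation": pres, "grade": grades[i],
                         "tumor_cell_content": tcc, "pair_id": pair})
    return pd.DataFrame(rows)


def _grade_multiset(n: int, probs: Mapping[str, float]) -> list[str]:
    counts = {g: int(round(p * n)) for g, p in probs.items()}
    while sum(counts.values()) > n:
        counts["G2"] -= 1
    counts["G2"] += n - sum(counts.values())
    return [g for g in GRADES for _ in range(counts.get(g, 0))]


def _latent_ff(config: CohortConfig, templates, meta_row) -> dict[str, float]:
    """Per-antibody latent FF log2 abundance for one sample."""
    u = float(_substream(config.seed, "loading", meta_row.sample_id).normal(0.0, config.tau))
    g = GRADE_EFFECT[meta_row.grade]
    out = {}
    for tpl in templates:
        eps = float(_substream(config.seed, "eps", meta_row.pair_id,
                               tpl.antibody_id).normal(0.0, config.omega))
        out[tpl.antibody_id] = (tpl.base_log2
                                + g * tpl.class_effect.get(meta_row.tumor_type, 0.0)
                                + u + eps)
    return out


def generate_cohort(config: CohortConfig
                    ) -> tuple[TraceSet, TraceSet, pd.DataFrame, GroundTruth]:
    """The paired FF/FFPE cohort with bijective pairing and planted truth."""
    templates = generate_panel(config)
    meta = _paired_metadata(config)
    truth = GroundTruth(
        antibodies=pd.DataFrame([{
            "antibody_id": t.antibody_id, "expected_mw": t.expected_mw,
            "is_phospho": t.is_phospho, "concordant": t.concordant,
            "shift_flag": t.shift_flag, "crossreact": t.crossreact,
            "ffpe_attenuation": t.ffpe_attenuation,
            "effect_type": max(t.class_effect, key=t.class_effect.get)
            if any(t.class_effect.values()) else "",
            "effect_size": max(t.class_effect.values()),
        } for t in templates]),
        samples=meta.copy(), templates=templates, config=config)

    ff_traces: list[Trace] = []
    ffpe_traces: list[Trace] = []
    ff_meta = meta[meta.preservation == "fresh_frozen"]
    ffpe_meta = meta[meta.preservation == "FFPE"].set_index("pair_id")
    for row in ff_meta.itertuples():
        latent = _latent_ff(config, templates, row)
        ffpe_row = ffpe_meta.loc[row.pair_id]
        u_alt = float(_substream(config.seed, "loading-ffpe",
                                 str(ffpe_row.sample_id)).normal(0.0, config.tau))
        g = GRADE_EFFECT[row.grade]
        for tpl in templates:
            a_ff = latent[tpl.antibody_id]
            if tpl.concordant:
                extra = float(_substream(config.seed, "ffpe-extra", row.pair_id,
                                         tpl.antibody_id).normal(0.0, config.ffpe_extra_sd))
                a_ffpe = a_ff + extra
            else:
                eps2 = float(_substream(config.seed, "eps-ffpe", row.pair_id,
                                        tpl.antibody_id).normal(0.0, config.omega))
                a_ffpe = (tpl.base_log2
                          + g * tpl.class_effect.get(row.tumor_type, 0.0)
                          + u_alt + eps2)
            bands_ff: list[tuple[float, float]] = []
            bands_ffpe: list[tuple[float, float]] = []
            if tpl.crossreact and row.tumor_type == "HNSC":
                bands_ff.append((tpl.crossreact_mw, config.crossreact_height_ff))
                bands_ffpe.append((tpl.crossreact_mw, config.crossreact_height_ffpe))
            t_ff = generate_trace(tpl, a_ff, "fresh_frozen", config,
                                  _substream(config.seed, "trace", row.sample_id,
                                             tpl.antibody_id), bands_ff)
            t_ff.sample_id = row.sample_id
            t_ffpe = generate_trace(tpl, a_ffpe, "FFPE", config,
                                    _substream(config.seed, "trace",
                                               str(ffpe_row.sample_id),
                                               tpl.antibody_id), bands_ffpe)
            t_ffpe.sample_id = str(ffpe_row.sample_id)
            ff_traces.append(t_ff)
            ffpe_traces.append(t_ffpe)
    return (TraceSet(ff_traces, "fresh_frozen"), TraceSet(ffpe_traces, "FFPE"),
            meta, truth)


def generate_validation_cohort(config: CohortConfig, truth: GroundTruth
                               ) -> tuple[TraceSet, pd.DataFrame]:
    """An independent FFPE cohort over the same antibody panel.

    Sample identifiers are disjoint from the paired cohort; the class-effect
    structure (templates) is reused, abundances and noise are fresh draws.
    """
    if len(truth.templates) != config.n_antibodies:
        raise ConfigurationError(
            f"antibody panel mismatch: truth has {len(truth.templates)} templates, "
            f"config expects {config.n_antibodies}")
    rng = _substream(config.seed, "val-samples")
    types = [t for t in config.tumor_types for _ in range(config.n_per_type)]
    n = len(types)
    grades = list(rng.permutation(_grade_multiset(n, {"G2": 0.72, "G3": 0.28})))
    rows = []
    for i, t in enumerate(types):
        rows.append({"sample_id": f"V{i + 1:02d}-FFPE", "tumor_type": t,
                     "preservation": "FFPE", "grade": grades[i],
                     "tumor_cell_content": float(np.round(rng.uniform(40, 96))),
                     "pair_id": ""})
    meta = pd.DataFrame(rows)
    traces: list[Trace] = []
    for row in meta.itertuples():
        u = float(_substream(config.seed, "val-loading", row.sample_id).normal(0.0, config.tau))
        g = GRADE_EFFECT[row.grade]
        for tpl in truth.templates:
            eps = float(_substream(config.seed, "val-eps", row.sample_id,
                                   tpl.antibody_id).normal(0.0, config.omega))
            a = (tpl.base_log2 + g * tpl.class_effect.get(row.tumor_type, 0.0) + u + eps)
            bands = []
            if tpl.crossreact and row.tumor_type == "HNSC":
                bands.append((tpl.crossreact_mw, config.crossreact_height_ffpe))
            tr = generate_trace(tpl, a, "FFPE", config,
                                _substream(config.seed, "val-trace", row.sample_id,
                                           tpl.antibody_id), bands)
            tr.sample_id = row.sample_id
            traces.append(tr)
    return TraceSet(traces, "FFPE"), meta
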