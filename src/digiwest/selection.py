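"""Antibody selection: detection filter, FF/FFPE concordance, final panel.

An antibody earns its place in the classification panel by (1) being
detectable in at least ``min_detected`` samples or in all samples of one
tumor type, (2) showing a significant Pearson correlation between its log2
signals in paired fresh-frozen and FFPE samples after Benjamini-Hochberg
correction, and (3) surviving quality exclusions: a-priori manual excludes
(e.g. antibodies confounded by a secondary-antibody cross-reaction band),
bands displaced >20 % from the expected molecular weight, and unclear
peaks.  When an antibody yields several signals, only the one with the
highest correlation coefficient is retained.

Correlations use complete pairs only (samples detected in both
preservations); Pearson's r is undefined on missing values and
complete-pairs is the natural reading of signals "detected in both".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from statsmodels.stats.multitest import multipletests

from .peaks import SignalMatrix

__all__ = [
    "CorrelationResult",
    "SelectionResult",
    "detection_filter",
    "correlate_ff_ffpe",
    "bh_adjust",
    "select_panel",
    "run_selection",
    "correlations_to_frame",
]

DISPOSITIONS = ("kept", "not_detected", "not_significant", "shifted",
                "unclear_peak", "manual_exclude")


@dataclass(frozen=True)
class CorrelationResult:
    """Per-signal FF/FFPE Pearson concordance over complete pairs."""

    antibody_id: str
    signal_id: str
    r: float
    n_pairs: int
    p: float
    p_bh: float
    significant: bool


@dataclass
class SelectionResult:
    """Stage counts, per-antibody dispositions and the final panel."""

    stage_counts: dict[str, int]
    dispositions: dict[str, str]
    panel: list[tuple[str, str]]      # (antibody_id, signal_id)
    correlations: list[CorrelationResult] = field(default_factory=list)

    def __post_init__(self) -> None:
        bad = set(self.dispositions.values()) - set(DISPOSITIONS)
        if bad:
            raise ValueError(f"unknown dispositions: {sorted(bad)}")

    @property
    def kept_antibodies(self) -> list[str]:
        return [a for a, _ in self.panel]


def detection_filter(matrix: SignalMatrix, metadata: pd.DataFrame,
                     min_detected: int = 4) -> list[str]:
    """Antibodies detectable in >= ``min_detected`` samples of one tumor type,
    or in every sample of that type."""
    if matrix.values.empty:
        warnings.warn("empty signal matrix: detection filter keeps nothing")
        return []
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in matrix.sample_ids if s not in meta.index]
    if missing:
        raise KeyError(f"samples without metadata: {missing}")
    groups = meta.loc[matrix.sample_ids, "tumor_type"]
    det = matrix.antibody_detection()
    kept = []
    for ab, row in det.iterrows():
        for t, cols in groups.groupby(groups).groups.items():
            n_det = int(row[cols].sum())
            if n_det >= min_detected or n_det == len(cols):
                kept.append(ab)
                break
    return kept


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    NaN entries are excluded from the family size m and returned as NaN.
    """
    p = np.asarray(pvalues, dtype=float)
    mask = ~np.isnan(p)
    if np.any((p[mask] < 0) | (p[mask] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    out = np.full_like(p, np.nan)
    if mask.sum():
        out[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return out


def correlate_ff_ffpe(ff: SignalMatrix, ffpe: SignalMatrix,
                      pairing: Mapping[str, str], min_pairs: int = 3,
                      alpha: float = 0.05) -> list[CorrelationResult]:
    """Per-signal Pearson r between paired log2 FF and FFPE values.

    ``pairing`` maps FF sample ids to their FFPE partners and must be
    bijective.  Signals with fewer than ``min_pairs`` complete pairs (or
    zero variance) get undefined r and are excluded from BH testing.
    """
    if not ff.log2 or not ffpe.log2:
        raise ValueError("correlate_ff_ffpe expects log2-transformed matrices")
    ff_samples = [s for s in ff.sample_ids if s in pairing]
    if not ff_samples:
        raise ValueError("no shared samples between matrices under the pairing")
    if len(set(pairing.values())) != len(pairing):
        raise ValueError("pairing must be bijective")
    ffpe_partner = [pairing[s] for s in ff_samples]
    missing = [s for s in ffpe_partner if s not in ffpe.values.columns]
    if missing:
        raise ValueError(f"FFPE partners missing from matrix: {missing}")

    shared_signals = [s for s in ff.signal_ids if s in set(ffpe.signal_ids)]
    results: list[dict] = []
    for sig in shared_signals:
        x = ff.values.loc[sig, ff_samples].to_numpy(dtype=float)
        y = ffpe.values.loc[sig, ffpe_partner].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        n = int(ok.sum())
        r = p = np.nan
        if n >= min_pairs and np.std(x[ok]) > 0 and np.std(y[ok]) > 0:
            r, p = pearsonr(x[ok], y[ok])
        results.append({"antibody_id": str(ff.signal_info.loc[sig, "antibody_id"]),
                        "signal_id": sig, "r": float(r), "n_pairs": n, "p": float(p)})
    p_bh = bh_adjust([rec["p"] for rec in results])
    return [CorrelationResult(**rec, p_bh=float(q),
                              significant=bool(q < alpha) if not np.isnan(q) else False)
            for rec, q in zip(results, p_bh)]


def correlations_to_frame(correlations: Iterable[CorrelationResult]) -> pd.DataFrame:
    """Tabular (volcano-plot ready) view: r and -log10 p-BH per signal."""
    df = pd.DataFrame([c.__dict__ for c in correlations])
    if not df.empty:
        df["neg_log10_p_bh"] = -np.log10(df["p_bh"])
    return df


def select_panel(correlations: Sequence[CorrelationResult],
                 matched: pd.DataFrame,
                 manual_excludes: Sequence[str] = (),
                 unclear: Sequence[str] = (),
                 alpha: float = 0.05) -> SelectionResult:
    """Apply the exclusion cascade and retain one best signal per antibody.

    Order: manual excludes -> BH significance -> highest-r signal per
    antibody (ties: smaller relative shift, then signal id) -> drop
    shift-flagged -> drop unclear-peak antibodies.  ``matched`` is the
    per-signal metadata table (``signal_info``) carrying ``shift_flag`` and
    ``relative_shift``.
    """
    known = set(matched.index)
    missing = [c.signal_id for c in correlations if c.signal_id not in known]
    if missing:
        raise KeyError(f"correlations without matched-signal records: {missing}")
    manual = set(manual_excludes)
    unclear_set = set(unclear)
    antibodies = sorted({c.antibody_id for c in correlations})
    dispositions: dict[str, str] = {}
    panel: list[tuple[str, str]] = []
    by_ab: dict[str, list[CorrelationResult]] = {}
    for c in correlations:
        by_ab.setdefault(c.antibody_id, []).append(c)
    for ab in antibodies:
        if ab in manual:
            dispositions[ab] = "manual_exclude"
            continue
        sig = [c for c in by_ab[ab] if c.significant]
        if not sig:
            dispositions[ab] = "not_significant"
            continue
        best = min(sig, key=lambda c: (-c.r,
                                       float(matched.loc[c.signal_id, "relative_shift"]),
                                       c.signal_id))
        if bool(matched.loc[best.signal_id, "shift_flag"]):
            dispositions[ab] = "shifted"
            continue
        if ab in unclear_set:
            dispositions[ab] = "unclear_peak"
            continue
        dispositions[ab] = "kept"
        panel.append((ab, best.signal_id))
    n_sig = len({c.antibody_id for c in correlations if c.significant})
    counts = {"tested": len(antibodies),
              "correlated_significant": n_sig,
              "post_exclusion": len(panel)}
    return SelectionResult(counts, dispositions, panel, list(correlations))


def run_selection(ff: SignalMatrix, ffpe: SignalMatrix, metadata: pd.DataFrame,
                  manual_excludes: Sequence[str] = (), unclear: Sequence[str] = (),
                  alpha: float = 0.05, min_detected: int = 4,
                  min_pairs: int = 3) -> SelectionResult:
    """Full pipeline: detection filter -> correlation -> panel selection.

    ``ff`` and ``ffpe`` must already be log2-transformed; the pairing is
    derived from the metadata's ``pair_id`` column.  Antibodies failing the
    FFPE detection filter are recorded as ``not_detected``.
    """
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    detected = set(detection_filter(ffpe, meta.reset_index(), min_detected=min_detected))
    all_abs = sorted(set(ff.signal_info["antibody_id"]) |
                     set(ffpe.signal_info["antibody_id"]))
    pairing = {}
    for pair, grp in meta.groupby("pair_id"):
        if not pair:
            continue
        by_pres = grp.groupby("preservation").groups
        if "fresh_frozen" in by_pres and "FFPE" in by_pres:
            pairing[str(by_pres["fresh_frozen"][0])] = str(by_pres["FFPE"][0])
    keep_sig_ff = [s for s in ff.signal_ids
                   if ff.signal_info.loc[s, "antibody_id"] in detected]
    keep_sig_ffpe = [s for s in ffpe.signal_ids
                     if ffpe.signal_info.loc[s, "antibody_id"] in detected]
    correlations = correlate_ff_ffpe(ff.subset_signals(keep_sig_ff),
                                     ffpe.subset_signals(keep_sig_ffpe),
                                     pairing, min_pairs=min_pairs, alpha=alpha)
    matched = pd.concat([ff.signal_info, ffpe.signal_info])
    matched = matched[~matched.index.duplicated(keep="first")]
    result = select_panel(correlations, matched, manual_excludes, unclear, alpha)
    for ab in all_abs:
        if ab not in detected:
            result.dispositions[ab] = "not_detected"
        elif ab not in result.dispositions:
            # detected but no signal shared between preservations: untestable
            result.dispositions[ab] = "not_significant"
    result.stage_counts = {"initial": len(all_abs), "detected": len(detected),
                           **result.stage_counts}
    return result
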