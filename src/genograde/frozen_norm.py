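"""Chip-level QC flagging and frozen single-sample normalization.

The normalization scheme stores the parameters of an RMA-style fit on a
reference batch of arrays (a mean quantile profile plus per-probe additive
effects from median polish) and applies them to new arrays *without
re-estimation*.  This gives the single-sample contract: the normalized
value of an array depends only on that array and the stored model, so a
sample processed alone equals the same sample processed in a batch,
bit-exactly, and the output is invariant under any strictly increasing
distortion of the raw intensities (only ranks enter the model).

Full convolution background correction of classic RMA is intentionally
omitted; a caller-supplied ``background`` hook on :func:`apply_frozen` /
:func:`fit_reference` can reinstate one.  Quartiles for QC fences use the
linear-interpolation convention (numpy default, "type 7") for cross-platform
determinism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import NormalizationError

__all__ = [
    "QCMetrics",
    "QC_METRIC_FIELDS",
    "qc_flag_outliers",
    "qc_exclude",
    "ReferenceNormModel",
    "fit_reference",
    "apply_frozen",
    "apply_frozen_matrix",
]

QC_METRIC_FIELDS = (
    "avg_noise",
    "avg_background",
    "percent_present",
    "scale_factor",
    "degradation_slope",
    "gapdh_ratio",
    "actin_ratio",
)


@dataclass(frozen=True)
class QCMetrics:
    """Per-array hybridization quality-control metrics (consumed, not computed)."""

    array_id: str
    avg_noise: float
    avg_background: float
    percent_present: float
    scale_factor: float
    degradation_slope: float
    gapdh_ratio: float
    actin_ratio: float

    def __post_init__(self):
        if not 0.0 <= self.percent_present <= 100.0:
            raise NormalizationError(
                f"array {self.array_id}: percent_present must be in [0, 100]"
            )


def qc_flag_outliers(metrics: Sequence[QCMetrics]) -> pd.DataFrame:
    """Flag, per metric, values outside the Tukey fences Q1/Q3 -+ 1.5 IQR.

    Quartiles use linear interpolation (type 7).  Requires at least four
    arrays for the quartiles to be meaningful; with fewer, supply external
    fences instead.
    """
    if len(metrics) < 4:
        raise NormalizationError(
            "qc_flag_outliers needs >= 4 arrays; supply external fences for "
            "smaller batches"
        )
    ids = [m.array_id for m in metrics]
    flags = {}
    for name in QC_METRIC_FIELDS:
        x = np.asarray([getattr(m, name) for m in metrics], dtype=float)
        q1, q3 = np.quantile(x, [0.25, 0.75], method="linear")
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        flags[name] = (x < lo) | (x > hi)
    return pd.DataFrame(flags, index=pd.Index(ids, name="array_id"))


_EXCLUSION_RULES = (
    ("rule 1: average noise and average background flagged",
     lambda f: f["avg_noise"] and f["avg_background"]),
    ("rule 2: scale factor and percent present flagged",
     lambda f: f["scale_factor"] and f["percent_present"]),
    ("rule 3: degradation slope flagged",
     lambda f: f["degradation_slope"]),
    ("rule 4: GAPDH and beta-actin ratios flagged",
     lambda f: f["gapdh_ratio"] and f["actin_ratio"]),
)


def qc_exclude(flags: Mapping[str, bool]):
    """Decide keep/exclude for one array from its per-metric outlier flags.

    Exclusion rules (first match wins): (1) noise AND background, (2) scale
    factor AND percent present, (3) degradation slope alone, (4) GAPDH AND
    beta-actin.  Returns ``("exclude", reason)`` or ``("keep", None)``.
    """
    missing = [k for k in QC_METRIC_FIELDS if k not in flags]
    if missing:
        raise NormalizationError(f"missing QC flags: {missing}")
    for reason, rule in _EXCLUSION_RULES:
        if rule(flags):
            return "exclude", reason
    return "keep", None


@dataclass
class ReferenceNormModel:
    """Frozen normalization parameters estimated once from a reference batch.

    quantile_profile
        Nondecreasing reference intensity vector, one entry per probe rank.
    probe_effects
        Additive per-probe effect on the log2 scale (probe affinity), with
        median zero within each probeset (median-polish convention).
    probe_map
        probe id -> probeset id.
    """

    quantile_profile: np.ndarray
    probe_effects: pd.Series
    probe_map: pd.Series
    model_id: str = "unnamed"

    def __post_init__(self):
        self.quantile_profile = np.asarray(self.quantile_profile, dtype=float)
        if np.any(np.diff(self.quantile_profile) < 0):
            raise NormalizationError("quantile_profile must be nondecreasing")
        if len(self.quantile_profile) != len(self.probe_map):
            raise NormalizationError(
                "quantile_profile length must equal the number of probes"
            )
        missing = self.probe_map.index.difference(self.probe_effects.index)
        if len(missing):
            raise NormalizationError(
                f"probes without stored effects: {list(missing[:5])}"
            )

    def to_json(self, path) -> None:
        payload = {
            "model_id": self.model_id,
            "quantile_profile": self.quantile_profile.tolist(),
            "probe_effects": self.probe_effects.to_dict(),
            "probe_map": self.probe_map.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "ReferenceNormModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            quantile_profile=np.asarray(payload["quantile_profile"], dtype=float),
            probe_effects=pd.Series(payload["probe_effects"], dtype=float),
            probe_map=pd.Series(payload["probe_map"], dtype=str),
            model_id=payload.get("model_id", "unnamed"),
        )


def median_polish_row_effects(matrix: np.ndarray, max_iter: int = 20,
                              tol: float = 1e-12) -> np.ndarray:
    """Row effects from Tukey median polish, recentred to median zero.

    Rows are probes, columns arrays.  Only the row effects are needed for
    the frozen model; overall and column effects are discarded.
    """
    resid = np.asarray(matrix, dtype=float).copy()
    row_eff = np.zeros(resid.shape[0])
    for _ in range(max_iter):
        rmed = np.median(resid, axis=1)
        row_eff += rmed
        resid -= rmed[:, None]
        cmed = np.median(resid, axis=0)
        resid -= cmed[None, :]
        if np.max(np.abs(rmed)) < tol and np.max(np.abs(cmed)) < tol:
            break
    return row_eff - np.median(row_eff)


def _check_probe_map(probe_ids: pd.Index, probe_map: Mapping) -> pd.Series:
    pm = pd.Series(dict(probe_map) if not isinstance(probe_map, pd.Series) else probe_map,
                   dtype=str)
    missing = probe_ids.difference(pm.index)
    if len(missing):
        raise NormalizationError(
            f"probes absent from probe_map: {sorted(missing)[:10]}"
        )
    return pm.reindex(probe_ids)


def fit_reference(
    probe_matrix: pd.DataFrame,
    probe_map: Mapping,
    model_id: str = "reference",
    background: Optional[Callable[[pd.DataFrame], pd.DataFrame]] = None,
) -> ReferenceNormModel:
    """Fit the frozen model from a reference batch (probes x arrays, raw scale).

    The quantile profile is the mean over arrays of the per-array sorted
    intensities; probe effects come from a within-probeset median polish of
    the log2 quantile-normalized matrix.
    """
    if background is not None:
        probe_matrix = background(probe_matrix)
    x = probe_matrix.to_numpy(dtype=float)
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise NormalizationError("raw intensities must be finite and > 0")
    pm = _check_probe_map(probe_matrix.index, probe_map)

    n = x.shape[0]
    profile = np.sort(x, axis=0).mean(axis=1)

    # quantile-normalize each array onto the profile (mid-ranks, interpolated)
    grid = np.arange(1, n + 1, dtype=float)
    qn = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")
        qn[:, j] = np.interp(ranks, grid, profile)
    logm = pd.DataFrame(np.log2(qn), index=probe_matrix.index,
                        columns=probe_matrix.columns)

    effects = pd.Series(0.0, index=probe_matrix.index)
    for _, idx in logm.groupby(pm).groups.items():
        effects.loc[idx] = median_polish_row_effects(logm.loc[idx].to_numpy())
    return ReferenceNormModel(profile, effects, pm, model_id=model_id)


def apply_frozen(
    raw_array: pd.Series,
    model: ReferenceNormModel,
    background: Optional[Callable[[pd.Series], pd.Series]] = None,
) -> pd.Series:
    """Normalize one array against the frozen model; returns probeset log2 values.

    Steps: (i) map each probe intensity onto the stored quantile profile at
    its mid-rank, (ii) log2, (iii) subtract the stored probe effect,
    (iv) summarize each probeset by the median of its corrected probes.
    """
    if background is not None:
        raw_array = background(raw_array)
    model_probes = model.probe_map.index
    extra = raw_array.index.difference(model_probes)
    missing = model_probes.difference(raw_array.index)
    if len(extra) or len(missing):
        raise NormalizationError(
            f"probe ids do not match the model: missing {sorted(missing)[:5]}, "
            f"unknown {sorted(extra)[:5]}"
        )
    x = raw_array.reindex(model_probes).to_numpy(dtype=float)
    if np.any(~np.isfinite(x)):
        raise NormalizationError("raw intensities must be finite")
    n = len(x)
    ranks = rankdata(x, method="average")
    mapped = np.interp(ranks, np.arange(1, n + 1, dtype=float),
                       model.quantile_profile)
    corrected = np.log2(mapped) - model.probe_effects.reindex(model_probes).to_numpy()
    out = pd.Series(corrected, index=model_probes).groupby(model.probe_map).median()
    out.index.name = "probeset_id"
    return out


def apply_frozen_matrix(raw_matrix: pd.DataFrame, model: ReferenceNormModel,
                        background=None) -> pd.DataFrame:
    """Normalize several arrays column by column (single-sample contract)."""
    cols = {
        c: apply_frozen(raw_matrix[c], model, background=background)
        for c in raw_matrix.columns
    }
    return pd.DataFrame(cols)
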