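"""Genomic Grade Index scoring, standardization and equivocal-zone grading.

The raw score of a sample is the sum of log2 expression over the
probesets up-regulated in grade-3 tumours minus the sum over those
up-regulated in grade-1 tumours.  Scores are standardized against a
reference set of histological grade 1 and grade 3 tumours so that the
reference class means land exactly at -1 and +1:

    GGI = scale * (raw - offset),  offset = (m1 + m3) / 2,  scale = 2 / (m3 - m1)

where m1 and m3 are the reference class means of the raw score.  The
genomic-grade cut-off sits at 0; around it an *equivocal zone* is built
from class-conditional Gaussians with means fixed at -1/+1 and class SDs
estimated from the standardized reference: the upper band edge is the
smallest g >= 0 at which the likelihood of the grade-3 class outweighs
the grade-1 class by the required odds (default 3:1, equal priors), the
lower edge symmetrically.  Samples inside the band are called equivocal
rather than forced into a grade.
"""

from __future__ import annotations

import enum
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import CalibrationError, GradingError

__all__ = [
    "SignatureDefinition",
    "GGCalibration",
    "GenomicGrade",
    "GradeCall",
    "raw_score",
    "raw_scores",
    "calibrate",
    "standardize",
    "equivocal_band",
    "band_from_sds",
    "build_calibration",
    "classify",
    "score_cohort",
    "read_signature",
    "write_signature",
]


@dataclass(frozen=True)
class SignatureDefinition:
    """Probeset sets up-regulated in grade-3 and grade-1 tumours."""

    up_in_g3: frozenset
    up_in_g1: frozenset
    name: str = "signature"

    def __post_init__(self):
        object.__setattr__(self, "up_in_g3", frozenset(self.up_in_g3))
        object.__setattr__(self, "up_in_g1", frozenset(self.up_in_g1))
        if not self.up_in_g3 or not self.up_in_g1:
            raise GradingError("both signature sets must be nonempty")
        overlap = self.up_in_g3 & self.up_in_g1
        if overlap:
            raise GradingError(f"signature sets overlap: {sorted(overlap)[:5]}")

    @property
    def probesets(self) -> frozenset:
        return self.up_in_g3 | self.up_in_g1


def read_signature(path, name: Optional[str] = None) -> SignatureDefinition:
    """Read a two-column TSV (probeset_id, direction in {up_g3, up_g1})."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["probeset_id", "direction"]:
        raise GradingError("signature file must have columns probeset_id, direction")
    bad = set(df["direction"]) - {"up_g3", "up_g1"}
    if bad:
        raise GradingError(f"unknown direction value(s): {sorted(bad)}")
    return SignatureDefinition(
        up_in_g3=frozenset(df.loc[df["direction"] == "up_g3", "probeset_id"]),
        up_in_g1=frozenset(df.loc[df["direction"] == "up_g1", "probeset_id"]),
        name=name or str(path),
    )


def write_signature(signature: SignatureDefinition, path) -> None:
    rows = [(p, "up_g3") for p in sorted(signature.up_in_g3)]
    rows += [(p, "up_g1") for p in sorted(signature.up_in_g1)]
    pd.DataFrame(rows, columns=["probeset_id", "direction"]).to_csv(
        path, sep="\t", index=False
    )


class GenomicGrade(str, enum.Enum):
    GG1 = "GG1"
    EQ = "EQ"
    GG3 = "GG3"


@dataclass(frozen=True)
class GradeCall:
    sample_id: str
    ggi: float  # standardized score
    grade: GenomicGrade


@dataclass
class GGCalibration:
    """The decision machinery of the signature: standardization + band."""

    scale: float
    offset: float
    band_low: float
    band_high: float
    odds_threshold: float = 3.0
    ref_summary: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.scale > 0:
            raise CalibrationError(f"scale must be > 0, got {self.scale}")
        if not (self.band_low <= 0.0 <= self.band_high):
            raise CalibrationError("band must satisfy band_low <= 0 <= band_high")
        if self.odds_threshold < 1:
            raise CalibrationError("odds_threshold must be >= 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "scale": self.scale,
                    "offset": self.offset,
                    "band_low": self.band_low,
                    "band_high": self.band_high,
                    "odds_threshold": self.odds_threshold,
                    "ref_summary": self.ref_summary,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GGCalibration":
        with open(path) as fh:
            return cls(**json.load(fh))


def raw_score(expr: Mapping[str, float], signature: SignatureDefinition) -> float:
    """Sum of grade-3-up probeset values minus sum of grade-1-up values."""
    if isinstance(expr, pd.Series):
        expr = expr.to_dict()
    missing = sorted(p for p in signature.probesets if p not in expr)
    if missing:
        raise GradingError(f"signature probesets missing from expression: {missing[:10]}")
    return float(
        sum(expr[p] for p in signature.up_in_g3)
        - sum(expr[p] for p in signature.up_in_g1)
    )


def raw_scores(expr_matrix: pd.DataFrame, signature: SignatureDefinition) -> pd.Series:
    """Vectorized raw score, one per sample column."""
    missing = sorted(signature.probesets - set(expr_matrix.index))
    if missing:
        raise GradingError(f"signature probesets missing from expression: {missing[:10]}")
    up3 = expr_matrix.loc[sorted(signature.up_in_g3)].sum(axis=0)
    up1 = expr_matrix.loc[sorted(signature.up_in_g1)].sum(axis=0)
    s = up3 - up1
    s.name = "raw_score"
    return s


def _class_means(scores: np.ndarray, labels: np.ndarray):
    m1 = scores[labels == 1].mean() if np.any(labels == 1) else np.nan
    m3 = scores[labels == 3].mean() if np.any(labels == 3) else np.nan
    return m1, m3


def calibrate(raw_scores, hg_labels):
    """Closed-form scale/offset so reference class means map to -1 and +1.

    ``hg_labels`` holds 1 or 3 per reference sample.  Returns
    ``(scale, offset)`` with offset the midpoint of the class means and
    scale 2 / (m3 - m1).
    """
    scores = np.asarray(raw_scores, dtype=float)
    labels = np.asarray(hg_labels)
    bad = set(np.unique(labels)) - {1, 3}
    if bad:
        raise CalibrationError(f"reference labels must be 1 or 3, got {sorted(bad)}")
    if not (np.any(labels == 1) and np.any(labels == 3)):
        raise CalibrationError("both reference classes must be nonempty")
    m1, m3 = _class_means(scores, labels)
    if not m3 > m1:
        raise CalibrationError(
            f"grade-3 mean ({m3:g}) must exceed grade-1 mean ({m1:g}); "
            "the signature is not oriented"
        )
    offset = (m1 + m3) / 2.0
    scale = 2.0 / (m3 - m1)
    return scale, offset


def standardize(raw, scale: float, offset: float):
    """GGI = scale * (raw - offset)."""
    if isinstance(raw, pd.Series):
        return scale * (raw - offset)
    return scale * (np.asarray(raw, dtype=float) - offset)


def band_from_sds(sd1: float, sd3: float, odds_threshold: float = 3.0):
    """Equivocal band edges from class-conditional Gaussians N(-1, sd1), N(+1, sd3).

    band_high is the smallest g >= 0 where the grade-3 : grade-1 likelihood
    ratio (equal priors) reaches the odds threshold; band_low the analogue
    below 0 with the reciprocal ratio.  Root bracketing to ~1e-12.
    """
    for name, sd in (("sd1", sd1), ("sd3", sd3)):
        if not (np.isfinite(sd) and sd > 0):
            raise GradingError(f"{name} must be finite and > 0, got {sd}")
    if odds_threshold < 1:
        raise GradingError("odds_threshold must be >= 1")
    log_odds = math.log(odds_threshold)

    def llr(g):  # log density ratio grade3 / grade1
        return (
            -((g - 1.0) ** 2) / (2.0 * sd3**2)
            + ((g + 1.0) ** 2) / (2.0 * sd1**2)
            + math.log(sd1 / sd3)
        )

    def first_crossing(f, target):
        # smallest |g| >= 0 with f(g) >= target, scanning outward from 0
        if f(0.0) >= target:
            return 0.0
        # equal-SD crossing sits at sd^2 log(odds)/2; cover it with margin
        smax = max(sd1, sd3)
        hi = max(3.0, 1.0 + 6.0 * smax, smax**2 * (log_odds + 1.0))
        grid = np.linspace(0.0, hi, 4001)
        vals = np.array([f(g) for g in grid])
        above = np.nonzero(vals >= target)[0]
        if not len(above):
            raise GradingError("odds threshold never reached; band undefined")
        k = above[0]
        return brentq(lambda g: f(g) - target, grid[k - 1], grid[k], xtol=1e-12)

    band_high = first_crossing(llr, log_odds)
    band_low = -first_crossing(lambda g: -llr(-g), log_odds)
    if band_high > 3.0 or band_low < -3.0:
        warnings.warn("equivocal band extends beyond [-3, 3]", stacklevel=2)
    return band_low, band_high


def _fixed_mean_sd(x: np.ndarray, mu: float) -> float:
    # spread about the calibrated class mean, n-1 denominator
    if len(x) < 2:
        raise GradingError("each reference class needs >= 2 samples")
    return float(np.sqrt(np.sum((x - mu) ** 2) / (len(x) - 1)))


def equivocal_band(standardized_ref_scores, hg_labels, odds_threshold: float = 3.0):
    """Estimate class SDs from the standardized reference and build the band."""
    scores = np.asarray(standardized_ref_scores, dtype=float)
    labels = np.asarray(hg_labels)
    sd1 = _fixed_mean_sd(scores[labels == 1], -1.0)
    sd3 = _fixed_mean_sd(scores[labels == 3], +1.0)
    if not (np.isfinite(sd1) and np.isfinite(sd3)):
        raise GradingError("non-finite reference class SDs")
    return band_from_sds(sd1, sd3, odds_threshold)


def build_calibration(raw_ref_scores, hg_labels,
                      odds_threshold: float = 3.0) -> GGCalibration:
    """Calibrate scale/offset and the equivocal band from one reference set."""
    scale, offset = calibrate(raw_ref_scores, hg_labels)
    std = standardize(np.asarray(raw_ref_scores, dtype=float), scale, offset)
    labels = np.asarray(hg_labels)
    band_low, band_high = equivocal_band(std, labels, odds_threshold)
    summary = {
        "n_g1": int(np.sum(labels == 1)),
        "n_g3": int(np.sum(labels == 3)),
        "sd_g1": _fixed_mean_sd(std[labels == 1], -1.0),
        "sd_g3": _fixed_mean_sd(std[labels == 3], +1.0),
        "mean_g1": float(std[labels == 1].mean()),
        "mean_g3": float(std[labels == 3].mean()),
    }
    return GGCalibration(scale, offset, band_low, band_high, odds_threshold, summary)


def classify(ggi: float, calib: GGCalibration, sample_id: str = "") -> GradeCall:
    """GG1 below the band, GG3 above it, equivocal inside (inclusive)."""
    if not np.isfinite(ggi):
        raise GradingError(f"non-finite GGI for sample {sample_id!r}")
    if ggi < calib.band_low:
        grade = GenomicGrade.GG1
    elif ggi > calib.band_high:
        grade = GenomicGrade.GG3
    else:
        grade = GenomicGrade.EQ
    return GradeCall(sample_id=sample_id, ggi=float(ggi), grade=grade)


def score_cohort(expr_matrix: pd.DataFrame, signature: SignatureDefinition,
                 calib: GGCalibration) -> list:
    """Raw score, standardize and classify every sample column, order preserved."""
    raw = raw_scores(expr_matrix, signature)
    std = standardize(raw, calib.scale, calib.offset)
    return [classify(std[c], calib, sample_id=str(c)) for c in expr_matrix.columns]
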