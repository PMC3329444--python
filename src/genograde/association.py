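"""Cross-tabulations, concordance/reclassification summaries and independence tests.

Concordance between genomic and histological grade is reported per
histological class over *non-equivocal* calls only: for HG-1 it is
n(GG1, HG1) / [n(GG1, HG1) + n(GG3, HG1)], symmetrically for HG-3.
Equivocal calls are excluded from the denominator because they are, by
design, refusals to grade rather than misgrades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AssociationError

__all__ = [
    "CrossTab",
    "cross_tab",
    "composite_labels",
    "concordance_non_equivocal",
    "reclassification_summary",
    "chi_square_test",
    "fisher_exact",
]


@dataclass
class CrossTab:
    """A labelled contingency table of nonnegative integer counts."""

    row_labels: tuple
    col_labels: tuple
    counts: np.ndarray
    n_excluded: int = 0

    def __post_init__(self):
        self.row_labels = tuple(str(r) for r in self.row_labels)
        self.col_labels = tuple(str(c) for c in self.col_labels)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise AssociationError("counts shape does not match labels")
        if np.any(self.counts < 0):
            raise AssociationError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, row, col) -> int:
        return int(self.counts[self.row_labels.index(str(row)),
                               self.col_labels.index(str(col))])

    def row_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=1), index=list(self.row_labels))

    def col_sums(self) -> pd.Series:
        return pd.Series(self.counts.sum(axis=0), index=list(self.col_labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.row_labels),
                            columns=list(self.col_labels))

    def transpose(self) -> "CrossTab":
        return CrossTab(self.col_labels, self.row_labels, self.counts.T,
                        self.n_excluded)


def _as_series(x, name):
    s = pd.Series(x)
    if s.index.has_duplicates:
        raise AssociationError(f"duplicate sample ids in {name}")
    return s


def cross_tab(a, b, row_order: Optional[Sequence] = None,
              col_order: Optional[Sequence] = None) -> CrossTab:
    """Tabulate two categorical per-sample vectors paired by sample id.

    Samples missing either value are excluded and tallied in
    ``CrossTab.n_excluded``.  Inputs must cover the same sample ids.
    """
    sa, sb = _as_series(a, "a"), _as_series(b, "b")
    if set(sa.index) != set(sb.index):
        raise AssociationError("sample ids of the two vectors do not match")
    sb = sb.reindex(sa.index)
    sa_str = sa.map(lambda v: None if pd.isna(v) else str(getattr(v, "value", v)))
    sb_str = sb.map(lambda v: None if pd.isna(v) else str(getattr(v, "value", v)))
    ok = sa_str.notna() & sb_str.notna()
    n_excluded = int((~ok).sum())
    sa_str, sb_str = sa_str[ok], sb_str[ok]

    rows = tuple(row_order) if row_order is not None else tuple(sorted(set(sa_str)))
    cols = tuple(col_order) if col_order is not None else tuple(sorted(set(sb_str)))
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    ri = {r: i for i, r in enumerate(str(r) for r in rows)}
    ci = {c: j for j, c in enumerate(str(c) for c in cols)}
    for va, vb in zip(sa_str, sb_str):
        counts[ri[va], ci[vb]] += 1
    return CrossTab(rows, cols, counts, n_excluded=n_excluded)


def composite_labels(*series, sep: str = "/") -> pd.Series:
    """Join several categorical vectors into one composite label per sample."""
    parts = [_as_series(s, f"series {i}") for i, s in enumerate(series)]
    idx = parts[0].index
    for p in parts[1:]:
        if set(p.index) != set(idx):
            raise AssociationError("sample ids of composite inputs do not match")
    out = {}
    for k in idx:
        vals = [p.loc[k] for p in parts]
        out[k] = (
            None if any(pd.isna(v) for v in vals)
            else sep.join(str(getattr(v, "value", v)) for v in vals)
        )
    return pd.Series(out)


def _orient_gg_rows(tab: CrossTab) -> CrossTab:
    if {"GG1", "GG3"} <= set(tab.row_labels):
        return tab
    if {"GG1", "GG3"} <= set(tab.col_labels):
        return tab.transpose()
    raise AssociationError("table has no GG1/GG3 labels on either axis")


def concordance_non_equivocal(tab: CrossTab, hg1_label="1", hg3_label="3") -> dict:
    """Per-HG-class agreement fractions over non-equivocal genomic-grade calls.

    Returns ``{"HG1": frac, "HG3": frac}``; a zero denominator yields NaN
    with a warning.
    """
    t = _orient_gg_rows(tab)
    out = {}
    for key, hg, gg_match, gg_other in (
        ("HG1", str(hg1_label), "GG1", "GG3"),
        ("HG3", str(hg3_label), "GG3", "GG1"),
    ):
        agree = t.count(gg_match, hg)
        disagree = t.count(gg_other, hg)
        denom = agree + disagree
        if denom == 0:
            warnings.warn(f"no non-equivocal calls in class {key}", stacklevel=2)
            out[key] = math.nan
        else:
            out[key] = agree / denom
    return out


def reclassification_summary(tab: CrossTab, hg2_label="2") -> dict:
    """Fractions of HG-2 tumours reclassified as GG1 / EQ / GG3 (sum to 1)."""
    t = _orient_gg_rows(tab)
    if str(hg2_label) not in t.col_labels:
        raise AssociationError(f"no column {hg2_label!r} in table")
    counts = {g: t.count(g, hg2_label) for g in ("GG1", "EQ", "GG3")}
    total = sum(counts.values())
    if total == 0:
        warnings.warn("no HG-2 samples", stacklevel=2)
        return {g: math.nan for g in counts}
    return {g: c / total for g, c in counts.items()}


def chi_square_test(tab: CrossTab, correction: bool = False):
    """Pearson chi-square test of independence; no continuity correction by default.

    Returns ``(statistic, df, p)``.  A zero row or column margin is an error.
    """
    counts = tab.counts
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise AssociationError("chi-square needs at least a 2x2 table")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise AssociationError("table has a zero margin")
    res = stats.chi2_contingency(counts, correction=correction)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def fisher_exact(tab: CrossTab) -> float:
    """Two-sided Fisher exact p for a 2x2 table (hypergeometric tail sum)."""
    if tab.counts.shape != (2, 2):
        raise AssociationError("Fisher exact test needs a 2x2 table")
    return float(stats.fisher_exact(tab.counts, alternative="two-sided")[1])
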