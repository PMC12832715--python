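"""Variable-wise completeness auditing and missingness-randomness testing.

Two kinds of information loss are kept separate throughout:

* **missing** — structurally empty / NA content;
* **undetermined** — present-but-sentinel content (e.g. comuna ``99999`` =
  ignored, ``88888`` = foreign national).

Variables whose completeness falls below a threshold (default 99.95%) are
flagged for a chi-square goodness-of-fit test of whether the incomplete
content is distributed proportionally to group sizes (i.e. at random).
Per-group (O-E)^2/E contributions are reported so the "favored" groups are
identifiable.  Variables whose missingness masks coincide exactly carry no
information to test against each other and are reported untestable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VariableCompleteness",
    "CompletenessReport",
    "GofResult",
    "audit",
    "gof_missing_randomness",
]

DEFAULT_THRESHOLD = 99.95


class AuditError(ValueError):
    pass


@dataclass(frozen=True)
class VariableCompleteness:
    variable: str
    n_total: int
    n_missing: int
    n_undetermined: int
    pct_complete: float
    flagged: bool


@dataclass
class CompletenessReport:
    variables: list = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD
    #: groups of >=2 variables whose missingness masks are identical; no
    #: randomness test can distinguish them.
    collinear_missing: list = field(default_factory=list)

    @property
    def flagged(self) -> list:
        return [v for v in self.variables if v.flagged]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(v) for v in self.variables])


def _missing_mask(series: pd.Series) -> pd.Series:
    as_str = series.astype("string")
    return series.isna() | (as_str.str.strip().fillna("") == "")


def audit(
    table: pd.DataFrame,
    sentinel_config: Mapping[str, Sequence[str]] | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> CompletenessReport:
    """Audit every column of ``table`` for missing and undetermined content.

    ``sentinel_config`` maps column names to the literal values that mean
    "undetermined" for that column; naming a column absent from the table is
    an error (it usually signals a schema mismatch upstream).
    """
    sentinel_config = dict(sentinel_config or {})
    unknown = set(sentinel_config) - set(table.columns)
    if unknown:
        raise AuditError(f"sentinel_config names unknown variables: {sorted(unknown)}")

    report = CompletenessReport(threshold=threshold)
    masks: dict[str, np.ndarray] = {}
    n = len(table)
    for col in table.columns:
        miss = _missing_mask(table[col])
        sentinels = set(map(str, sentinel_config.get(col, ())))
        if sentinels:
            undet = table[col].astype("string").str.strip().isin(sentinels) & ~miss
        else:
            undet = pd.Series(False, index=table.index)
        n_missing = int(miss.sum())
        n_undet = int(undet.sum())
        pct = 100.0 if n == 0 else 100.0 * (n - n_missing - n_undet) / n
        report.variables.append(
            VariableCompleteness(
                variable=col,
                n_total=n,
                n_missing=n_missing,
                n_undetermined=n_undet,
                pct_complete=pct,
                flagged=pct < threshold,
            )
        )
        if n_missing > 0:
            masks[col] = miss.to_numpy()

    # detect perfectly matched missingness across variables
    grouped: dict[bytes, list[str]] = {}
    for col, mask in masks.items():
        grouped.setdefault(mask.tobytes(), []).append(col)
    report.collinear_missing = [cols for cols in grouped.values() if len(cols) > 1]
    return report


@dataclass
class GofResult:
    chi2: float
    df: int
    p_value: float
    #: one row per group: (label, observed, expected, contribution)
    groups: list

    def __post_init__(self):
        total = sum(g[3] for g in self.groups)
        assert abs(total - self.chi2) <= 1e-9 * max(1.0, self.chi2)

    def top_groups(self, k: int = 2) -> list:
        """Groups sorted by their chi-square contribution, largest first."""
        return sorted(self.groups, key=lambda g: g[3], reverse=True)[:k]


def gof_missing_randomness(
    missing_by_group: Mapping[str, float],
    total_by_group: Mapping[str, float],
) -> GofResult:
    """Pearson goodness-of-fit test of missing counts against the
    proportional-to-size null.

    Expected missingness in group g is ``sum(missing) * total_g /
    sum(total)``; the statistic is the usual sum of (O-E)^2/E with
    ``df = groups - 1`` and an upper-tail chi-square p-value.
    """
    labels = list(total_by_group)
    if len(labels) < 2:
        raise AuditError("goodness-of-fit needs at least 2 groups")
    if set(missing_by_group) - set(labels):
        raise AuditError("missing_by_group names groups absent from total_by_group")
    totals = np.array([float(total_by_group[g]) for g in labels])
    observed = np.array([float(missing_by_group.get(g, 0.0)) for g in labels])
    grand_total = totals.sum()
    if grand_total <= 0:
        raise AuditError("total_by_group sums to zero")
    expected = observed.sum() * totals / grand_total
    bad = (expected == 0) & (observed > 0)
    if bad.any():
        names = [labels[i] for i in np.flatnonzero(bad)]
        raise AuditError(
            f"expected count 0 with nonzero observed in groups {names}; merge groups before testing"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (observed - expected) ** 2 / np.where(expected > 0, expected, 1.0), 0.0)
    chi2 = float(contrib.sum())
    df = len(labels) - 1
    p = float(stats.chi2.sf(chi2, df)) if chi2 > 0 else 1.0
    groups = [
        (labels[i], float(observed[i]), float(expected[i]), float(contrib[i]))
        for i in range(len(labels))
    ]
    return GofResult(chi2=chi2, df=df, p_value=p, groups=groups)
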