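"""Case-control exposure analysis: overlay residences on class rasters,
contingency tables, Pearson chi-square, and suppression-aware frequency
reports.

Chi-square applies the Yates continuity correction automatically on 2x2
tables (and never on larger ones).  Frequency reports suppress cells whose
absolute frequency is strictly below the disclosure threshold (3 by
default, a statistical-secrecy rule for small counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, InvalidArgumentError
from .geo_core import Raster, ResidenceRecord, residence_xy, sample_raster

CLASS_NAMES = {1: "low", 2: "moderate", 3: "high"}


@dataclass
class ContingencyTable:
    """Exposure-class x group counts; rows ordered low -> high.

    ``exclusions`` lists residence ids that landed on nodata cells (they are
    reported, never silently dropped).
    """

    counts: pd.DataFrame          # index = class codes, columns = [case, control]
    exclusions: list[str] = field(default_factory=list)

    @property
    def row_margins(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.values.sum())


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    correction: str  # "none" or "yates"


def contingency_from_counts(rows: Sequence[Sequence[int]],
                            row_labels: Sequence[int] | None = None) -> ContingencyTable:
    """Build a table directly from (case, control) count rows, ordered
    low -> high exposure."""
    arr = np.asarray(rows, dtype=int)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InvalidArgumentError("rows must be (n_classes, 2) case/control counts")
    if (arr < 0).any():
        raise InvalidArgumentError("counts must be non-negative")
    labels = list(row_labels) if row_labels is not None else list(range(1, len(arr) + 1))
    df = pd.DataFrame(arr, index=labels, columns=["case", "control"])
    return ContingencyTable(counts=df)


def build_contingency(residences: Sequence[ResidenceRecord],
                      class_raster: Raster,
                      classes: Sequence[int] = (1, 2, 3)) -> ContingencyTable:
    """Counts of case/control residences by sampled exposure class.

    Every class in ``classes`` appears as a row even when empty; residences
    on nodata cells go to the exclusions list.
    """
    counts = pd.DataFrame(0, index=list(classes), columns=["case", "control"])
    exclusions: list[str] = []
    if residences:
        xy = residence_xy(residences)
        ids = [r.id for r in residences]
        vals, nodata = sample_raster(class_raster, xy, ids=ids, return_nodata_mask=True)
        for rec, v, bad in zip(residences, vals, nodata):
            if bad:
                exclusions.append(rec.id)
                continue
            v = int(v)
            if v not in counts.index:
                counts.loc[v] = 0
            counts.loc[v, rec.group] += 1
        counts = counts.sort_index()
    return ContingencyTable(counts=counts, exclusions=exclusions)


def pearson_chi2(t: ContingencyTable, correction: str = "auto") -> ChiSquareResult:
    """Pearson chi-square of independence.

    ``correction="auto"`` applies Yates continuity correction exactly when
    the table (after dropping zero-margin rows absent from both groups) is
    2x2; "none"/"yates" force the choice.
    """
    obs = t.counts.values
    obs = obs[obs.sum(axis=1) > 0]  # empty exposure classes carry no information
    if obs.shape[0] < 2:
        raise DegenerateTableError(
            f"fewer than 2 exposure classes with positive margin (rows: {obs.shape[0]})")
    if (obs.sum(axis=0) == 0).any():
        which = t.counts.columns[np.flatnonzero(t.counts.values.sum(axis=0) == 0)]
        raise DegenerateTableError(f"zero column margin for {list(which)}")
    if correction == "auto":
        use_yates = obs.shape == (2, 2)
    elif correction in ("none", "yates"):
        use_yates = correction == "yates"
    else:
        raise InvalidArgumentError(f"unknown correction {correction!r}")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=use_yates)
    return ChiSquareResult(statistic=float(stat), df=int(df), p=float(p),
                           correction="yates" if use_yates else "none")


SUPPRESSED = "<suppressed>"


def frequency_report(tables: dict[str, ContingencyTable],
                     suppression_threshold: int = 3,
                     chi2: bool = True) -> pd.DataFrame:
    """Long-form frequency report, one row per (variable, class, group).

    Percentages are of the group column total (1 decimal).  Cells with
    absolute frequency strictly below the threshold are suppressed — both
    count and percentage — while group totals stay intact.  The variable's
    chi-square p is attached to its first row.
    """
    if suppression_threshold < 0:
        raise InvalidArgumentError("suppression threshold must be >= 0")
    rows = []
    for name, table in tables.items():
        totals = table.col_margins
        p_val: float | None = None
        if chi2:
            try:
                p_val = pearson_chi2(table).p
            except DegenerateTableError:
                p_val = None
        first = True
        for cls in table.counts.index:
            row: dict = {"variable": name,
                         "class": CLASS_NAMES.get(int(cls), str(cls))}
            for grp in ("case", "control"):
                cnt = int(table.counts.loc[cls, grp])
                pct = 100.0 * cnt / totals[grp] if totals[grp] else 0.0
                if cnt < suppression_threshold:
                    row[f"{grp}_n"], row[f"{grp}_pct"] = SUPPRESSED, SUPPRESSED
                else:
                    row[f"{grp}_n"], row[f"{grp}_pct"] = cnt, round(pct, 1)
            row["p"] = round(p_val, 3) if (first and p_val is not None) else None
            first = False
            rows.append(row)
    return pd.DataFrame(rows)


def format_report(report: pd.DataFrame) -> str:
    """Plain-text rendering of the frequency report."""
    lines = [f"{'variable':28s} {'class':10s} {'case n':>10s} {'case %':>8s} "
             f"{'ctrl n':>10s} {'ctrl %':>8s} {'p':>7s}"]
    for _, r in report.iterrows():
        p = "" if r["p"] is None or (isinstance(r["p"], float) and np.isnan(r["p"])) \
            else f"{r['p']:.3f}"
        lines.append(f"{r['variable']:28s} {r['class']:10s} {str(r['case_n']):>10s} "
                     f"{str(r['case_pct']):>8s} {str(r['control_n']):>10s} "
                     f"{str(r['control_pct']):>8s} {p:>7s}")
    return "\n".join(lines)
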