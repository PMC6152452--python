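"""Genotyping-success contingency analysis by hair-sample source and year.

Hair from creosote-treated power poles degrades badly (shed guard hair,
sunlight exposure) while rubbing-tree hair genotypes well; these tables
quantify that, with success defined as a consensus genotype scored at eight
or more of the ten loci.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .consensus import filter_by_locus_coverage
from .model import Dataset, HAIR_SOURCES, NONINVASIVE_SOURCES

SUCCESS, FAILURE = "success", "failure"


def contingency_table(columns: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Build a success/failure table from ``{column: (n_success, n_failure)}``."""
    df = pd.DataFrame(columns, index=[SUCCESS, FAILURE])
    if (df.values < 0).any():
        raise ValueError("counts must be non-negative")
    return df


def tabulate_success(
    dataset: Dataset, by: str = "source", min_loci: int = 8
) -> pd.DataFrame:
    """Success/failure counts of hair samples grouped by ``source`` or ``year``.

    Success means the sample's consensus scored at least ``min_loci`` loci.
    The by-source analysis is restricted to noninvasively collected hair
    (tissue and capture hair excluded); the by-year analysis covers all hair
    samples (tissue excluded), matching how such studies report the two.
    """
    if not dataset.samples:
        raise ValueError("empty dataset")
    if by not in ("source", "year"):
        raise ValueError("by must be 'source' or 'year'")
    include = NONINVASIVE_SOURCES if by == "source" else HAIR_SOURCES
    retained, _ = filter_by_locus_coverage(dataset, min_loci=min_loci)
    retained_ids = {s.sample_id for s in retained}
    counts: dict[str, list[int]] = {}
    for rec in dataset.samples:
        if rec.source not in include:
            continue
        key = rec.source.value if by == "source" else str(rec.year)
        cell = counts.setdefault(key, [0, 0])
        cell[0 if rec.sample_id in retained_ids else 1] += 1
    ordered = dict(sorted(counts.items()))
    return contingency_table({k: (v[0], v[1]) for k, v in ordered.items()})


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    low_expected_cells: list[tuple[str, str]]


def chi_square_independence(table: pd.DataFrame) -> ChiSquareResult:
    """Pearson chi-square of independence, no continuity correction.

    Cells with expected count below 5 are reported (``low_expected_cells``)
    as a warning rather than an error, since pooled field tables routinely
    have sparse columns.
    """
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need >= 2 rows and >= 2 columns")
    values = table.values
    if (values.sum(axis=0) == 0).any() or (values.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    stat, p, df, expected = stats.chi2_contingency(values, correction=False)
    low = [
        (str(table.index[i]), str(table.columns[j]))
        for i in range(table.shape[0])
        for j in range(table.shape[1])
        if expected[i, j] < 5
    ]
    if low:
        warnings.warn(f"expected count < 5 in cells {low}", stacklevel=2)
    return ChiSquareResult(float(stat), int(df), float(p), low)


def success_rates(table: pd.DataFrame) -> pd.Series:
    """Per-column success percentage, rounded to 2 decimals; NaN where the
    column total is zero (flagged undefined)."""
    totals = table.sum(axis=0)
    rates = 100.0 * table.loc[SUCCESS] / totals
    rates[totals == 0] = float("nan")
    return rates.round(2)


def pool_columns(
    table: pd.DataFrame, groups: dict[str, Sequence[str]]
) -> pd.DataFrame:
    """Pool columns into named groups; columns not mentioned are dropped.

    E.g. ``{"trees": ["tree", "barbed_wire"], "poles": ["pole"]}`` gives the
    2x2 comparison of rubbing-tree-derived hair against power poles.
    """
    data = {
        name: tuple(table[list(cols)].sum(axis=1)) for name, cols in groups.items()
    }
    return contingency_table(data)
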