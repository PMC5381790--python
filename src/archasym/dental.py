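"""Dental-formula parsing, symmetry classification and count statistics.

Cyprinid pharyngeal dentition is written as a four-number formula
``minor_L,major_L-major_R,minor_R`` (e.g. ``1,5-5,1``): teeth on the minor
and major rows of the left hemi-arch, then major and minor rows of the
right hemi-arch.  A formula is *symmetric* when left and right row counts
match.  The module also provides Simpson's diversity of formula counts,
grouped frequency tables and a 2x2 Pearson chi-square test.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DentalFormula",
    "parse_formula",
    "simpson_diversity",
    "frequency_table",
    "chisq_2x2",
]

# side separator may be hyphen, en-dash or em-dash
_FORMULA_RE = re.compile(r"^\s*(\d+)\s*,\s*(\d+)\s*[-–—]\s*(\d+)\s*,\s*(\d+)\s*$")

_MAX_TEETH = 10  # sanity bound; cyprinid rows never approach this


@dataclass(frozen=True)
class DentalFormula:
    """Functional tooth counts on the four pharyngeal rows."""

    minor_l: int
    major_l: int
    major_r: int
    minor_r: int

    def __post_init__(self) -> None:
        for name in ("minor_l", "major_l", "major_r", "minor_r"):
            v = getattr(self, name)
            if not (0 <= v <= _MAX_TEETH):
                raise ValueError(f"{name}={v} outside the plausible range 0..{_MAX_TEETH}")

    @property
    def symmetric(self) -> bool:
        return self.minor_l == self.minor_r and self.major_l == self.major_r

    def __str__(self) -> str:
        # canonical form uses the en-dash between sides
        return f"{self.minor_l},{self.major_l}–{self.major_r},{self.minor_r}"


def parse_formula(text: str) -> DentalFormula:
    """Parse a dental formula string ``a,b-c,d``.

    The separator between sides may be "-", "–" or "—"; counts read in
    left-to-right anatomical order (minor L, major L, major R, minor R).
    """
    m = _FORMULA_RE.match(text)
    if m is None:
        raise ValueError(f"malformed dental formula: {text!r}")
    return DentalFormula(*(int(g) for g in m.groups()))


def simpson_diversity(counts, *, finite_sample: bool = False) -> float:
    """Simpson's diversity index ``D = 1 - sum(p_i^2)`` of category counts.

    Parameters
    ----------
    counts
        Mapping category -> count, or a sequence of counts.
    finite_sample
        Use the finite-sample variant ``1 - sum n_i(n_i-1) / (N(N-1))``
        instead of the plug-in proportions.

    Returns
    -------
    float in ``[0, 1)``: the probability that two randomly drawn
    individuals belong to different categories.
    """
    if isinstance(counts, Mapping):
        vals = np.asarray(list(counts.values()), dtype=float)
    else:
        vals = np.asarray(list(counts), dtype=float)
    if vals.size == 0 or np.any(vals < 0):
        raise ValueError("counts must be a non-empty collection of nonnegative numbers")
    total = vals.sum()
    if total <= 0:
        raise ValueError("total count must be positive")
    if finite_sample:
        if total < 2:
            raise ValueError("finite-sample variant needs a total count of at least 2")
        return float(1.0 - np.sum(vals * (vals - 1.0)) / (total * (total - 1.0)))
    p = vals / total
    return float(1.0 - np.sum(p**2))


def frequency_table(records, by: Sequence[str] | str | None = None) -> pd.DataFrame:
    """Counts and within-group proportions of dental formulae.

    Parameters
    ----------
    records
        DataFrame (or iterable of dicts) with a ``formula`` column and any
        of ``site``, ``lineage``, ``biotype``.
    by
        Grouping column name(s); ``None`` pools everything.

    Returns
    -------
    Tidy DataFrame with columns ``by... , formula, count, proportion``;
    proportions sum to 1 within each group.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no records")
    if "formula" not in df.columns:
        raise ValueError("records need a 'formula' column")
    if by is None:
        by_cols: list[str] = []
    elif isinstance(by, str):
        by_cols = [by]
    else:
        by_cols = list(by)

    counts = (
        df.groupby(by_cols + ["formula"], dropna=False, observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    if by_cols:
        totals = counts.groupby(by_cols, observed=True)["count"].transform("sum")
    else:
        totals = counts["count"].sum()
    counts["proportion"] = counts["count"] / totals
    return counts


def chisq_2x2(table, continuity_correction: bool = False) -> dict:
    """Pearson chi-square test on a 2x2 contingency table.

    No continuity correction by default.  Returns ``{"chi2", "df", "P"}``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("counts must be nonnegative")
    if np.any(t.sum(axis=0) <= 0) or np.any(t.sum(axis=1) <= 0):
        raise ValueError("all row and column margins must be positive")
    res = stats.chi2_contingency(t, correction=continuity_correction)
    return {"chi2": float(res.statistic), "df": int(res.dof), "P": float(res.pvalue)}
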