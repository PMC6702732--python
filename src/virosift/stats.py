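"""Two-proportion count tests on library-size-normalized small-RNA counts.

Compares the number of reads mapped to a locus between two conditions as a 2x2
chi-squared test on [mapped, library - mapped] x [A, B], with Yates continuity
correction by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


@dataclass(frozen=True)
class CountTest:
    locus_id: str
    mapped_a: int
    library_a: int
    mapped_b: int
    library_b: int
    statistic: float
    df: int
    p_value: float
    percent_a: float
    percent_b: float


def normalized_percent(mapped: int, library: int) -> float:
    """Mapped reads as a percentage of the library size."""
    if library <= 0:
        raise ValueError("library size must be positive")
    if mapped < 0 or mapped > library:
        raise ValueError("mapped count must lie in [0, library]")
    return mapped / library * 100.0


def proportion_chisq(
    mapped_a: int,
    library_a: int,
    mapped_b: int,
    library_b: int,
    continuity_correction: bool = True,
    locus_id: str = "",
) -> CountTest:
    """2x2 chi-squared on [mapped, library-mapped] x [condition A, B], df=1.

    With ``continuity_correction`` the Yates correction is applied (|O-E|
    reduced by 0.5, floored at 0). A table with a zero row or column margin has
    no testable association; it returns statistic 0 with a warning.
    """
    for mapped, library in ((mapped_a, library_a), (mapped_b, library_b)):
        if library <= 0:
            raise ValueError("library size must be positive")
        if mapped < 0 or mapped > library:
            raise ValueError("mapped count must lie in [0, library]")
    table = np.array(
        [[mapped_a, library_a - mapped_a], [mapped_b, library_b - mapped_b]], dtype=np.int64
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin): statistic set to 0", stacklevel=2)
        stat, p = 0.0, 1.0
    else:
        stat, p, _, _ = chi2_contingency(table, correction=continuity_correction)[:4]
    return CountTest(
        locus_id=locus_id,
        mapped_a=mapped_a,
        library_a=library_a,
        mapped_b=mapped_b,
        library_b=library_b,
        statistic=float(stat),
        df=1,
        p_value=float(p),
        percent_a=normalized_percent(mapped_a, library_a),
        percent_b=normalized_percent(mapped_b, library_b),
    )


def proportion_chisq_table(
    counts: pd.DataFrame, continuity_correction: bool = True
) -> pd.DataFrame:
    """Run the test for every row (locus, mapped_a, library_a, mapped_b, library_b)."""
    required = {"locus", "mapped_a", "library_a", "mapped_b", "library_b"}
    if not required.issubset(counts.columns):
        raise ValueError(f"expected columns {sorted(required)}")
    rows = []
    for rec in counts.itertuples(index=False):
        t = proportion_chisq(
            int(rec.mapped_a),
            int(rec.library_a),
            int(rec.mapped_b),
            int(rec.library_b),
            continuity_correction=continuity_correction,
            locus_id=str(rec.locus),
        )
        rows.append(
            {
                "locus": t.locus_id,
                "statistic": t.statistic,
                "df": t.df,
                "p_value": t.p_value,
                "percent_a": t.percent_a,
                "percent_b": t.percent_b,
            }
        )
    return pd.DataFrame(rows)
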