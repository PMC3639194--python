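"""Chi-square differential abundance between paired count libraries.

Each feature (tag or family) is tested with a Pearson chi-square on the
2x2 table [[a, N_A - a], [b, N_B - b]] (feature vs rest, per library),
without continuity correction by default.  When any expected cell is below
5 the test falls back to Fisher's exact test and the result is labeled
accordingly.  P-values are Benjamini-Hochberg adjusted across the features
of a library pair.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError


class ChisqResult(NamedTuple):
    chi2: float
    p: float
    method: str  # "chi-square" | "fisher"


def chisq_2x2(
    a: int, a_rest: int, b: int, b_rest: int, *, correction: bool = False
) -> ChisqResult:
    """Pearson chi-square (df=1) on [[a, a_rest], [b, b_rest]].

    Falls back to Fisher's exact test when any expected cell is < 5
    (``chi2`` is NaN in that case).  Raises ``ValueError`` on a zero grand
    total or an empty row.
    """
    cells = (a, a_rest, b, b_rest)
    if any(c < 0 for c in cells):
        raise ValueError("cell counts must be non-negative")
    if a + a_rest == 0 or b + b_rest == 0:
        raise ValueError("both row totals must be positive")
    table = np.array([[a, a_rest], [b, b_rest]], dtype=np.int64)
    n = table.sum()
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    if expected.min() < 5:
        _, p = stats.fisher_exact(table)
        return ChisqResult(float("nan"), float(p), "fisher")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return ChisqResult(float(chi2), float(p), "chi-square")


@dataclass
class DEResult:
    feature: str
    pair: tuple[str, str]
    a: int
    b: int
    n_a: int
    n_b: int
    cpm_a: float
    cpm_b: float
    log2fc: float
    chi2: float
    p: float
    p_adj: float
    method: str
    significant: bool


def _log2fc(a: int, b: int, n_a: int, n_b: int) -> float:
    cpm_a = a / n_a * 1e6
    cpm_b = b / n_b * 1e6
    if a == 0 or b == 0:
        # pseudocount on the normalized scale only, never in the test
        return math.log2((cpm_b + 0.5) / (cpm_a + 0.5))
    return math.log2(cpm_b / cpm_a)


def call_differential(
    counts: Mapping[str, tuple[int, int]] | pd.DataFrame,
    pair: tuple[str, str],
    *,
    totals: tuple[int, int] | None = None,
    alpha: float = 0.01,
    min_abs_log2fc: float = 1.0,
    correction: bool = False,
) -> list[DEResult]:
    """Test every feature with a + b > 0 between the two libraries.

    ``counts`` is either ``{feature: (a, b)}`` or a DataFrame with the two
    library columns.  ``totals`` are the library sequencing totals
    (defaulting to the column sums).  ``significant`` means BH-adjusted
    p < ``alpha`` and |log2fc| >= ``min_abs_log2fc``.
    """
    lib_a, lib_b = pair
    if isinstance(counts, pd.DataFrame):
        for lib in pair:
            if lib not in counts.columns:
                raise ConfigurationError(f"unknown library {lib!r}")
        items = [(str(f), (int(r[lib_a]), int(r[lib_b]))) for f, r in counts.iterrows()]
    else:
        items = [(f, (int(ab[0]), int(ab[1]))) for f, ab in counts.items()]

    if totals is None:
        n_a = sum(ab[0] for _, ab in items)
        n_b = sum(ab[1] for _, ab in items)
    else:
        n_a, n_b = totals
    if n_a <= 0 or n_b <= 0:
        raise ValueError("library totals must be positive")

    tested = [(f, ab) for f, ab in items if ab[0] + ab[1] > 0]
    results: list[DEResult] = []
    for feature, (a, b) in tested:
        chi2, p, method = chisq_2x2(a, n_a - a, b, n_b - b, correction=correction)
        results.append(
            DEResult(
                feature=feature,
                pair=pair,
                a=a,
                b=b,
                n_a=n_a,
                n_b=n_b,
                cpm_a=a / n_a * 1e6,
                cpm_b=b / n_b * 1e6,
                log2fc=_log2fc(a, b, n_a, n_b),
                chi2=chi2,
                p=p,
                p_adj=p,
                method=method,
                significant=False,
            )
        )
    if results:
        p_adj = stats.false_discovery_control([r.p for r in results], method="bh")
        for r, q in zip(results, p_adj):
            r.p_adj = float(q)
            r.significant = bool(r.p_adj < alpha and abs(r.log2fc) >= min_abs_log2fc)
    return results


def results_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "feature": r.feature,
                "a": r.a,
                "b": r.b,
                "cpm_a": r.cpm_a,
                "cpm_b": r.cpm_b,
                "log2fc": r.log2fc,
                "chi2": r.chi2,
                "p": r.p,
                "p_adj": r.p_adj,
                "method": r.method,
                "significant": r.significant,
            }
            for r in results
        ]
    )
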