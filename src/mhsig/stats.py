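"""Inferential statistics used in the study: Yates-corrected
chi-squared on 2x2 tables, the unpaired two-tailed t-test, and a
correlation contrast that looks for gene pairs co-expressed only within
a cell-state subset.

Test statistics are computed from their textbook formulas; tail
probabilities come from scipy's chi2 and t distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    df: float


def chi2_yates(table: Sequence[Sequence[float]]) -> TestResult:
    """Chi-squared test of independence on a 2x2 table with Yates'
    continuity correction.

    statistic = sum over cells of (|O - E| - 0.5)^2 / E, with the
    correction term floored at zero when |O - E| < 0.5; p is the upper
    tail of the chi-squared distribution with 1 df.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("cell counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = t.sum()
    if n <= 0 or (rows == 0).any() or (cols == 0).any():
        raise ValueError("degenerate table: zero margin")
    expected = np.outer(rows, cols) / n
    corrected = np.clip(np.abs(t - expected) - 0.5, 0.0, None)
    stat = float((corrected**2 / expected).sum())
    return TestResult(statistic=stat, p_value=float(sps.chi2.sf(stat, 1)), df=1)


def t_test_unpaired(
    x: Sequence[float],
    y: Sequence[float],
    welch: bool = False,
) -> TestResult:
    """Unpaired two-tailed t-test; Student's pooled-variance form by
    default, Welch's unequal-variance form behind a flag.

    Two groups with zero variance and equal means yield p = 1 by
    convention (no evidence of a difference).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    mx, my = x.mean(), y.mean()
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        if mx == my:
            return TestResult(statistic=0.0, p_value=1.0, df=nx + ny - 2)
        return TestResult(statistic=math.copysign(math.inf, mx - my),
                          p_value=0.0, df=nx + ny - 2)
    if welch:
        se2x, se2y = vx / nx, vy / ny
        se = math.sqrt(se2x + se2y)
        df = (se2x + se2y) ** 2 / (
            se2x**2 / (nx - 1) + se2y**2 / (ny - 1)
        )
    else:
        pooled = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = math.sqrt(pooled * (1 / nx + 1 / ny))
        df = nx + ny - 2
    stat = (mx - my) / se
    return TestResult(
        statistic=float(stat),
        p_value=float(2 * sps.t.sf(abs(stat), df)),
        df=float(df),
    )


@dataclass
class GeneContrast:
    gene: str
    r_subset: float | None
    r_all: float | None
    flagged: bool


def _pearson(a: np.ndarray, b: np.ndarray) -> float | None:
    # undefined (not 0) for constant vectors
    if a.std() == 0 or b.std() == 0:
        return None
    return float(np.corrcoef(a, b)[0, 1])


def correlation_contrast(
    expr: "np.ndarray | object",
    anchor_gene: str,
    test_genes: Sequence[str],
    subset_mask: Sequence[bool],
    gene_names: Sequence[str] | None = None,
    r_hi: float = 0.45,
    r_lo: float = 0.1,
) -> list[GeneContrast]:
    """Contrast Pearson correlations inside a metacell subset vs all
    metacells.

    ``expr`` is a genes x metacells matrix (numpy array with
    ``gene_names``, or a pandas DataFrame indexed by gene).  A test gene
    is flagged when it correlates with the anchor within the subset
    (r_subset >= r_hi) but negligibly or negatively across all metacells
    (r_all <= r_lo) — the pattern of subset-restricted co-expression.

    The default r_hi of 0.45 corresponds to a correlation p-value of
    about 1e-3 at 50 metacells, a proxy for "significant within the
    subset" that keeps a null gene's false-flag rate near 1e-3; r_lo
    treats correlations at or below 0.1 as negligible.
    """
    import pandas as pd

    if isinstance(expr, pd.DataFrame):
        frame = expr
    else:
        if gene_names is None:
            raise ValueError("gene_names required for array input")
        frame = pd.DataFrame(np.asarray(expr), index=list(gene_names))
    mask = np.asarray(subset_mask, dtype=bool)
    if mask.shape[0] != frame.shape[1]:
        raise ValueError("subset mask length must equal the metacell count")
    if not mask.any() or mask.all():
        raise ValueError("subset must be non-empty and a proper subset")
    if anchor_gene not in frame.index:
        raise KeyError(f"anchor gene {anchor_gene!r} absent from the matrix")
    anchor = frame.loc[anchor_gene].to_numpy(dtype=float)
    out: list[GeneContrast] = []
    for gene in test_genes:
        if gene not in frame.index:
            raise KeyError(f"test gene {gene!r} absent from the matrix")
        v = frame.loc[gene].to_numpy(dtype=float)
        r_sub = _pearson(anchor[mask], v[mask])
        r_all = _pearson(anchor, v)
        flagged = (
            r_sub is not None and r_all is not None
            and r_sub >= r_hi and r_all <= r_lo
        )
        out.append(GeneContrast(gene=gene, r_subset=r_sub, r_all=r_all,
                                flagged=flagged))
    return out
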