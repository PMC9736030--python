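"""Expression-threshold filters and transforms over an FPKM matrix.

The matrix is a pandas DataFrame with gene rows and sample columns.
Thresholds follow the family-analysis conventions: FPKM >= 1 for
"expressed", FPKM >= 20 for "highly expressed".  The differential call
is a configurable fold-change rule with an FPKM floor and pseudo-count
(the source analysis never states its criterion; this default is an
artifact convention).
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

EXPRESSED_THRESHOLD = 1.0
HIGH_THRESHOLD = 20.0
DEFAULT_MIN_FC = 2.0
DEFAULT_MIN_FPKM = 1.0
PSEUDO_FPKM = 0.01


def validate_matrix(matrix: pd.DataFrame) -> None:
    if matrix.empty:
        raise ValueError("expression matrix is empty")
    if (matrix.values < 0).any():
        raise ValueError("expression matrix contains negative values")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    if matrix.columns.duplicated().any():
        raise ValueError("duplicate sample ids in expression matrix")


def average_replicates(matrix: pd.DataFrame, replicate_map: dict[str, str]) -> pd.DataFrame:
    """Mean-collapse replicate columns; ``replicate_map`` maps sample -> tissue."""
    grouped = matrix.T.groupby([replicate_map[c] for c in matrix.columns]).mean().T
    return grouped


def expressed_genes(
    matrix: pd.DataFrame, threshold: float = EXPRESSED_THRESHOLD
) -> dict[str, set[str]]:
    """Genes expressed in at least one tissue, and in all tissues."""
    validate_matrix(matrix)
    any_tissue = set(matrix.index[matrix.max(axis=1) >= threshold])
    all_tissues = set(matrix.index[matrix.min(axis=1) >= threshold])
    return {"any_tissue": any_tissue, "all_tissues": all_tissues}


def highly_expressed(
    matrix: pd.DataFrame, threshold: float = HIGH_THRESHOLD
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Per-tissue highly-expressed and tissue-preferential gene sets.

    A gene is highly expressed in tissue t iff FPKM(g, t) >= threshold,
    and t-preferential iff additionally t attains the row maximum (ties
    yield all argmax tissues).
    """
    validate_matrix(matrix)
    high: dict[str, set[str]] = {t: set() for t in matrix.columns}
    preferential: dict[str, set[str]] = {t: set() for t in matrix.columns}
    row_max = matrix.max(axis=1)
    for tissue in matrix.columns:
        col = matrix[tissue]
        high[tissue] = set(matrix.index[col >= threshold])
        preferential[tissue] = set(
            matrix.index[(col >= threshold) & (col == row_max)]
        )
    return high, preferential


def row_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Row-wise z-scoring ((x - mean) / sd, sd with n-1 denominator).

    Constant rows map to all-zeros.
    """
    if matrix.shape[1] < 2:
        raise ValueError("row scaling requires at least 2 samples")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    scaled = matrix.sub(mean, axis=0).div(sd.replace(0.0, np.nan), axis=0)
    return scaled.fillna(0.0)


def differential_call(
    control: pd.Series,
    treated: pd.Series,
    min_fc: float = DEFAULT_MIN_FC,
    min_fpkm: float = DEFAULT_MIN_FPKM,
    pseudo: float = PSEUDO_FPKM,
) -> pd.Series:
    """Per-gene up/down/unchanged call from paired condition values."""
    control = control.astype(float)
    treated = treated.astype(float)
    up = (treated / (control + pseudo) >= min_fc) & (treated >= min_fpkm)
    down = (control / (treated + pseudo) >= min_fc) & (control >= min_fpkm)
    calls = pd.Series("unchanged", index=control.index, name="call")
    calls[up] = "up"
    calls[down & ~up] = "down"
    return calls


def percentage(k: int, n: int) -> float:
    """Percent k of n, rounded half away from zero to one decimal."""
    if n == 0:
        raise ValueError("percentage undefined for n = 0")
    if not 0 <= k <= n:
        raise ValueError(f"count k={k} outside [0, n={n}]")
    value = Decimal(100 * k) / Decimal(n)
    return float(value.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
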