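"""Pearson coexpression and top-partner selection over a TPM matrix."""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


def pearson_with_p(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson r with the two-sided p-value from the t transform
    t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def top_partners(
    target: str,
    matrix: pd.DataFrame,
    k: int = 30,
    alpha: float = 1e-5,
) -> pd.DataFrame:
    """Top-k coexpressed partners of ``target`` with raw p < alpha.

    ``matrix`` is genes × samples (TPM, untransformed by default — the
    published pipeline correlates TPM directly). Genes with zero variance are
    excluded; ties in r break by gene id for determinism. Columns:
    target, partner, r, p, rank.
    """
    if target not in matrix.index:
        raise KeyError(f"target {target!r} not in expression matrix")
    x = matrix.loc[target].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"target {target!r} has zero variance")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 samples")

    others = matrix.drop(index=target)
    Y = others.to_numpy(dtype=float)
    keep = Y.std(axis=1) > 0
    others = others[keep]
    Y = Y[keep]

    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    r = (Yc @ xc) / (np.linalg.norm(Yc, axis=1) * np.linalg.norm(xc))
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)

    df = pd.DataFrame({"partner": others.index, "r": r, "p": p})
    df = df[df["p"] < alpha]
    df = df.sort_values(["r", "partner"], ascending=[False, True], kind="mergesort")
    df = df.head(k).reset_index(drop=True)
    df.insert(0, "target", target)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
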