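"""Distribution screening and rank correlation for element concentrations.

Environmental concentration data are typically right-skewed; the pipeline
therefore screens each element with the Shapiro-Wilk test and, when any
element departs from normality, describes inter-element association with
Spearman's rank correlation (tie-corrected) rather than Pearson's r.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core import ELEMENTS, SoilDataset


def spearman_matrix(ds: SoilDataset, alpha: tuple[float, float] = (0.05, 0.01)):
    """9 x 9 Spearman rank-correlation matrix with significance flags.

    Returns ``(rho, pvalues, flags)`` DataFrames; ``flags`` holds "", "*" or
    "**" for significance at the two configured levels.
    """
    X = ds.concentrations()
    if X.shape[0] < 3:
        raise ValueError("need at least three samples")
    for j, el in enumerate(ELEMENTS):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"constant concentration column {el}")
    rho, p = stats.spearmanr(X)
    rho = pd.DataFrame(rho, index=ELEMENTS, columns=ELEMENTS)
    p = pd.DataFrame(p, index=ELEMENTS, columns=ELEMENTS)
    a1, a2 = alpha
    flags = p.map(lambda v: "**" if v < a2 else ("*" if v < a1 else ""))
    for el in ELEMENTS:
        flags.loc[el, el] = ""
    return rho, p, flags


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a flat p-value vector."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def normality_screen(ds: SoilDataset) -> pd.DataFrame:
    """Shapiro-Wilk W and p per element."""
    X = ds.concentrations()
    n = X.shape[0]
    if n < 3:
        raise ValueError("Shapiro-Wilk requires at least three samples")
    rows = []
    for j, el in enumerate(ELEMENTS):
        if np.all(X[:, j] == X[0, j]):
            raise ValueError(f"constant concentration column {el}")
        w, p = stats.shapiro(X[:, j])
        rows.append({"element": el, "W": float(w), "p": float(p),
                     "normal_at_0.05": p >= 0.05})
    return pd.DataFrame(rows).set_index("element")


def recommend_correlation_method(ds: SoilDataset) -> str:
    """"spearman" when any element rejects normality at 0.05, else
    "pearson"."""
    screen = normality_screen(ds)
    return "spearman" if (screen["p"] < 0.05).any() else "pearson"
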