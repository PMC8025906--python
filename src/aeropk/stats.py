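"""Correlation screening and two-way ANOVA without replication.

The screening relates powder/particle descriptors (rows = materials) to
aerodynamic-performance and pharmacokinetic outcomes via plain Pearson
product-moment correlations — a ranking heatmap, deliberately without any
multiple-testing correction (raw r values are reported, not inferences).
The ANOVA decomposes a materials-by-descriptors matrix into row, column and
residual sums of squares with the residual as the error term (no replicates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidInputError


def pearson_matrix(props: pd.DataFrame, outcomes: pd.DataFrame) -> pd.DataFrame:
    """Pearson r for every (property, outcome) column pair.

    Rows of the two tables must be the same materials (matched index).
    Cells with fewer than 3 paired observations or a constant column are
    undefined and reported as NaN, never as 0.
    """
    if not props.index.equals(outcomes.index):
        raise InvalidInputError("props and outcomes must have matched rows")
    out = pd.DataFrame(index=props.columns, columns=outcomes.columns, dtype=float)
    for pcol in props.columns:
        x = props[pcol].to_numpy(dtype=float)
        for ocol in outcomes.columns:
            y = outcomes[ocol].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                out.loc[pcol, ocol] = np.nan
            else:
                out.loc[pcol, ocol] = float(sps.pearsonr(x[ok], y[ok])[0])
    return out


@dataclass(frozen=True)
class TwoWayAnovaResult:
    F_rows: float
    p_rows: float
    F_cols: float
    p_cols: float
    ss_rows: float
    ss_cols: float
    ss_resid: float
    ss_total: float
    df_rows: int
    df_cols: int
    df_resid: int
    degenerate: bool  # zero residual SS: F is unbounded


def anova_two_way_noreplication(matrix) -> TwoWayAnovaResult:
    """Two-way ANOVA without replication on a rows x columns value matrix.

    SS_total = SS_rows + SS_cols + SS_residual; F statistics test row and
    column effects against the residual mean square, p-values from the F
    distribution.  A zero residual SS is flagged degenerate (F unbounded).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise InvalidInputError("need a 2-D matrix with >= 2 rows and >= 2 columns")
    if not np.all(np.isfinite(m)):
        raise InvalidInputError("missing cells are not allowed")
    r, c = m.shape
    grand = m.mean()
    ss_rows = c * float(((m.mean(axis=1) - grand) ** 2).sum())
    ss_cols = r * float(((m.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_resid = ss_total - ss_rows - ss_cols
    df_rows, df_cols = r - 1, c - 1
    df_resid = df_rows * df_cols
    degenerate = ss_resid <= 1e-300
    if degenerate:
        F_rows = math.inf if ss_rows > 0 else 0.0
        F_cols = math.inf if ss_cols > 0 else 0.0
        p_rows = 0.0 if ss_rows > 0 else 1.0
        p_cols = 0.0 if ss_cols > 0 else 1.0
    else:
        ms_resid = ss_resid / df_resid
        F_rows = (ss_rows / df_rows) / ms_resid
        F_cols = (ss_cols / df_cols) / ms_resid
        p_rows = float(sps.f.sf(F_rows, df_rows, df_resid))
        p_cols = float(sps.f.sf(F_cols, df_cols, df_resid))
    return TwoWayAnovaResult(
        F_rows=float(F_rows), p_rows=float(p_rows), F_cols=float(F_cols), p_cols=float(p_cols),
        ss_rows=ss_rows, ss_cols=ss_cols, ss_resid=max(ss_resid, 0.0), ss_total=ss_total,
        df_rows=df_rows, df_cols=df_cols, df_resid=df_resid, degenerate=degenerate,
    )


def correlation_heatmap(rmatrix: pd.DataFrame, path, title: str = "Pearson r"):
    """Save a heatmap of a correlation matrix (display only; values unchanged)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * rmatrix.shape[1], 1.0 + 0.5 * rmatrix.shape[0]))
    im = ax.imshow(rmatrix.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(rmatrix.shape[1]), rmatrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(rmatrix.shape[0]), rmatrix.index, fontsize=7)
    fig.colorbar(im, ax=ax, label=title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
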