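"""PCA of centrality Z-scores across plastid-nuclear combinations.

The analysis matrix has one row per plastid-nuclear combination (16 for
four lineages) and one column per residue of the interface gene pair; cells
are per-network centrality Z-scores.  A principal component analysis of
this matrix asks whether reciprocal crosses separate along the leading axes
of centrality variation.  Columns are centred and, by default, scaled to
unit variance (a correlation PCA): the Z-scores are standardised within
each network, not within each residue column, and column variances differ
by orders of magnitude, so an unscaled PCA would be dominated by the two or
three most variable residues.

:class:`PCAResult` carries variance percentages, individual scores
(combination coordinates), loadings, and per-residue contribution
percentages (squared loadings, normalised to 100 per component).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CentralityTable",
    "PCAResult",
    "DegenerateInputError",
    "assemble_centrality_matrix",
    "run_pca",
    "variable_contributions",
    "reciprocal_cross_separation",
]


class DegenerateInputError(ValueError):
    """Raised for matrices with no usable variance."""


@dataclass
class CentralityTable:
    """Combinations x residues matrix of centrality Z-scores."""

    measure: str
    data: pd.DataFrame

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def assemble_centrality_matrix(
    tables: Mapping[str, Mapping[str, float]],
    measure: str,
    residue_subset: Sequence[str] | None = None,
    row_order: Sequence[str] | None = None,
) -> CentralityTable:
    """Assemble per-combination Z-score maps into a complete matrix.

    ``tables`` maps combination labels to ``{residue_label: zscore}``.
    Columns default to the residue labels shared by every combination, in
    the first combination's order; rows follow ``row_order`` (default: the
    given mapping order).  Missing cells are an assembly error naming the
    offending combination.
    """
    if not tables:
        raise ValueError("no combinations to assemble")
    rows = list(row_order) if row_order is not None else list(tables)
    for label in rows:
        if label not in tables:
            raise KeyError(f"combination {label!r} missing from assembly input")
    if residue_subset is None:
        first = rows[0]
        shared = set(tables[first])
        for label in rows[1:]:
            shared &= set(tables[label])
        columns = [c for c in tables[first] if c in shared]
    else:
        columns = list(residue_subset)
    cells = np.empty((len(rows), len(columns)))
    for i, label in enumerate(rows):
        for j, col in enumerate(columns):
            if col not in tables[label]:
                raise KeyError(f"combination {label!r} lacks residue {col!r} ({measure})")
            cells[i, j] = tables[label][col]
    return CentralityTable(
        measure=measure, data=pd.DataFrame(cells, index=rows, columns=columns)
    )


@dataclass
class PCAResult:
    """Eigen-decomposition outputs of a centred (optionally scaled) matrix."""

    measure: str
    eigenvalues: np.ndarray
    variance_pct: pd.Series
    scores: pd.DataFrame  # combinations x components
    loadings: pd.DataFrame  # residues x components
    contributions_pct: pd.DataFrame  # residues x components
    center: bool = True
    scale: bool = True
    column_means: pd.Series | None = None
    column_sds: pd.Series | None = None

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def summary(self, n: int = 5) -> str:
        n = min(n, self.n_components)
        lines = [
            f"PCA of {self.measure} centrality Z-scores "
            f"({self.scores.shape[0]} combinations x {self.loadings.shape[0]} residues, "
            f"center={self.center}, scale={self.scale})",
            "",
            "component  eigenvalue  variance%  cumulative%",
        ]
        cum = 0.0
        for k in range(n):
            cum += self.variance_pct.iloc[k]
            lines.append(
                f"{self.variance_pct.index[k]:>9}  {self.eigenvalues[k]:>10.4f}"
                f"  {self.variance_pct.iloc[k]:>9.1f}  {cum:>11.1f}"
            )
        for k in range(min(2, self.n_components)):
            pc = self.contributions_pct.iloc[:, k]
            top = pc.sort_values(ascending=False).head(3)
            lines.append("")
            lines.append(
                f"top contributors to {pc.name}: "
                + ", ".join(f"{r} ({v:.1f}%)" for r, v in top.items())
            )
        return "\n".join(lines)

    def plot_scores(self, ax=None):
        """Scatter of the combinations in the PC1-PC2 plane."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.scores.iloc[:, 0], self.scores.iloc[:, 1]
        ax.scatter(x, y)
        for label, xi, yi in zip(self.scores.index, x, y):
            ax.annotate(label, (xi, yi), fontsize=8)
        ax.axhline(0, lw=0.5, color="grey")
        ax.axvline(0, lw=0.5, color="grey")
        ax.set_xlabel(f"PC1 ({self.variance_pct.iloc[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({self.variance_pct.iloc[1]:.1f}%)")
        ax.set_title(self.measure)
        return ax

    def plot_contributions(self, component: int = 1, ax=None):
        """Bar chart of residue contributions with the uniform reference."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        contrib, uniform = variable_contributions(self, component)
        contrib = contrib.sort_values(ascending=False)
        ax.bar(range(len(contrib)), contrib.values)
        ax.set_xticks(range(len(contrib)))
        ax.set_xticklabels(contrib.index, rotation=90, fontsize=7)
        ax.axhline(uniform, color="red", ls="--", lw=1)
        ax.set_ylabel(f"contribution to PC{component} (%)")
        ax.set_title(self.measure)
        return ax


def run_pca(m: CentralityTable, center: bool = True, scale: bool = True) -> PCAResult:
    """Singular-value PCA of a combinations x residues matrix.

    Columns are centred and (by default) scaled to unit sample variance.
    Eigenvalues follow the usual sample-covariance convention
    (singular value² / (n-1)).  The component sign is fixed so that each
    loading column's largest-magnitude entry is positive, making outputs
    stable across linear-algebra backends.
    """
    X = m.data.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise DegenerateInputError("need at least two combinations (rows)")
    sds = X.std(axis=0, ddof=1)
    if not (sds > 0).any():
        raise DegenerateInputError("all columns are constant; PCA undefined")
    means = X.mean(axis=0)
    if center:
        X = X - means
    if scale:
        if (sds == 0).any():
            bad = [c for c, s in zip(m.data.columns, sds) if s == 0]
            raise DegenerateInputError(f"cannot scale constant column(s): {bad}")
        X = X / sds
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    k = min(n - 1 if center else n, p)
    U, s, Vt = U[:, :k], s[:k], Vt[:k]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(k):
        if Vt[j, np.argmax(np.abs(Vt[j]))] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    eigenvalues = s**2 / (n - 1)
    pcs = [f"PC{j + 1}" for j in range(k)]
    variance = pd.Series(eigenvalues / eigenvalues.sum() * 100, index=pcs, name="variance_pct")
    scores = pd.DataFrame(U * s, index=m.data.index, columns=pcs)
    loadings = pd.DataFrame(Vt.T, index=m.data.columns, columns=pcs)
    sq = loadings**2
    contributions = sq * 100 / sq.sum(axis=0)
    return PCAResult(
        measure=m.measure,
        eigenvalues=eigenvalues,
        variance_pct=variance,
        scores=scores,
        loadings=loadings,
        contributions_pct=contributions,
        center=center,
        scale=scale,
        column_means=pd.Series(means, index=m.data.columns),
        column_sds=pd.Series(sds, index=m.data.columns),
    )


def variable_contributions(r: PCAResult, component: int) -> tuple[pd.Series, float]:
    """Per-residue contribution percentages to one component (1-based).

    Also returns the uniform reference 100 / n_residues — the expected
    value if every residue contributed equally.
    """
    if not 1 <= component <= r.n_components:
        raise IndexError(f"component {component} outside 1..{r.n_components}")
    contrib = r.contributions_pct.iloc[:, component - 1]
    return contrib, 100.0 / len(contrib)


def reciprocal_cross_separation(r: PCAResult) -> pd.DataFrame:
    """Distance between reciprocal crosses in the PC1-PC2 score plane.

    One row per unordered lineage pair (self-crosses excluded); a missing
    reciprocal is reported with a NaN distance rather than an error.
    """
    plane = r.scores.iloc[:, : min(2, r.scores.shape[1])]
    labels = list(plane.index)
    pairs = {}
    for label in labels:
        if "_" not in label:
            continue
        p, n = label.split("_", 1)
        if p == n:
            continue
        pairs.setdefault(frozenset((p, n)), []).append(label)
    rows = []
    for key in sorted(pairs, key=sorted):
        a, b = sorted(key)
        fwd, rev = f"{a}_{b}", f"{b}_{a}"
        if fwd in labels and rev in labels:
            dist = float(np.linalg.norm(plane.loc[fwd] - plane.loc[rev]))
        else:
            dist = float("nan")
        rows.append({"pair": f"{a}-{b}", "forward": fwd, "reverse": rev, "distance": dist})
    return pd.DataFrame(rows)
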