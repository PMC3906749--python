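"""Per-gene differential-expression ranking for a two-group expression study.

This stage turns a log2 expression matrix with a binary phenotype
(virgin vs postpartum) into a ranked table of per-gene statistics — a
two-sided Welch t-test p-value, a Benjamini-Hochberg q-value, and a
linear-scale fold change (postpartum over virgin; values above 1 mean
higher expression in postpartum samples).  Thresholding that table at a
nominal alpha and collapsing duplicate probes yields the significant
gene set consumed by the enrichment stage.

The Welch t-test deliberately stands in for array-specific
empirical-Bayes model fits: everything downstream only needs
``(symbol, p, fold change)`` per row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

VIRGIN = "virgin"
POSTPARTUM = "postpartum"

#: smallest reportable p-value; keeps p in (0, 1] for degenerate zero-variance rows
_P_FLOOR = np.nextafter(0.0, 1.0)

__all__ = [
    "VIRGIN",
    "POSTPARTUM",
    "ExpressionStudy",
    "SignificantSet",
    "rank_genes",
    "bh_fdr",
    "select_significant",
    "read_expression_study",
    "write_expression_study",
]


@dataclass
class ExpressionStudy:
    """A gene-by-sample log2 expression matrix with a binary phenotype.

    Parameters
    ----------
    values
        DataFrame of log2 expression, rows indexed by gene symbol
        (duplicates allowed — multiple probes per gene; the empty string
        marks an unannotated row), columns indexed by sample id.
    groups
        Per-sample label, either ``"virgin"`` or ``"postpartum"``,
        indexed like the columns of ``values``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = pd.Series(self.groups)
        if list(self.values.columns) != list(self.groups.index):
            self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            raise ValueError("every sample column needs a group label")
        bad = set(self.groups.unique()) - {VIRGIN, POSTPARTUM}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (VIRGIN, POSTPARTUM):
            if int((self.groups == g).sum()) < 2:
                raise ValueError(f"need at least 2 samples in group {g!r}")
        if self.values.isna().to_numpy().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def symbols(self) -> np.ndarray:
        return self.values.index.to_numpy(dtype=object)

    @property
    def annotated(self) -> np.ndarray:
        """Boolean mask of rows that carry a gene symbol."""
        return np.asarray([bool(str(s).strip()) for s in self.symbols])

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def group_mask(self, group: str) -> np.ndarray:
        return (self.groups == group).to_numpy()


@dataclass(frozen=True)
class SignificantSet:
    """Unique gene symbols passing a nominal-p threshold."""

    symbols: tuple[str, ...]
    alpha: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "symbols", tuple(sorted(set(self.symbols))))

    @property
    def n(self) -> int:
        return len(self.symbols)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.symbols)

    def without(self, remove) -> "SignificantSet":
        """A copy with the given symbols removed (symbols not present are ignored)."""
        drop = set(remove)
        return SignificantSet(tuple(s for s in self.symbols if s not in drop), self.alpha)


def _welch(post: np.ndarray, virg: np.ndarray) -> np.ndarray:
    """Vectorized two-sided Welch t-test p-values, rows = genes.

    Degenerate rows (zero variance in both groups) get p=1 when the
    group means are equal, else the p floor.
    """
    n1, n0 = post.shape[1], virg.shape[1]
    m1, m0 = post.mean(axis=1), virg.mean(axis=1)
    v1 = post.var(axis=1, ddof=1)
    v0 = virg.var(axis=1, ddof=1)
    se2 = v1 / n1 + v0 / n0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v0**2 / (n0**2 * (n0 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = se2 == 0.0
    p = np.where(degenerate, np.where(m1 == m0, 1.0, _P_FLOOR), p)
    return np.clip(p, _P_FLOOR, 1.0)


def rank_genes(study: ExpressionStudy) -> pd.DataFrame:
    """Rank every row of a study by differential-expression evidence.

    Returns a DataFrame sorted by ``p_nominal`` ascending with columns
    ``symbol, row, mean_postpartum, mean_virgin, fold_change, p_nominal,
    p_fdr``.  Means are back-transformed to the linear scale before the
    fold-change ratio is taken, so ``fold_change =
    mean_postpartum / mean_virgin`` holds on the linear scale.  ``row``
    is the position in the input matrix (used to map table rows back to
    expression rows downstream).
    """
    X = study.values.to_numpy(dtype=float)
    post = X[:, study.group_mask(POSTPARTUM)]
    virg = X[:, study.group_mask(VIRGIN)]
    p = _welch(post, virg)
    mean_post = 2.0 ** post.mean(axis=1)
    mean_virg = 2.0 ** virg.mean(axis=1)
    table = pd.DataFrame(
        {
            "symbol": study.symbols,
            "row": np.arange(X.shape[0]),
            "mean_postpartum": mean_post,
            "mean_virgin": mean_virg,
            "fold_change": mean_post / mean_virg,
            "p_nominal": p,
        }
    )
    table["p_fdr"] = bh_fdr(table["p_nominal"].to_numpy())
    table = table.sort_values("p_nominal", kind="mergesort").reset_index(drop=True)
    return table


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q(i) = min_{j >= i} p_(j) * m / j`` after an ascending sort,
    mapped back to input order; the empty input yields an empty output.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_significant(
    table: pd.DataFrame, alpha: float = 0.01, annotated_only: bool = True
) -> SignificantSet:
    """Threshold a ranked table at a strict nominal alpha.

    Rows with ``p_nominal < alpha`` are kept (ties at exactly alpha are
    excluded); unannotated rows are dropped when ``annotated_only``;
    duplicate symbols collapse to the smallest p.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    hits = table[table["p_nominal"] < alpha]
    if annotated_only:
        hits = hits[hits["symbol"].astype(str).str.strip() != ""]
    # table is sorted by p ascending, so first occurrence has the best p
    symbols = pd.unique(hits.sort_values("p_nominal", kind="mergesort")["symbol"])
    return SignificantSet(tuple(symbols), alpha)


def read_expression_study(expression_tsv, samples_tsv) -> ExpressionStudy:
    """Read the expression TSV (first column ``symbol``) and sample metadata TSV."""
    expr = pd.read_csv(expression_tsv, sep="\t")
    expr = expr.set_index(expr.columns[0])
    expr.index = expr.index.fillna("").astype(str)
    meta = pd.read_csv(samples_tsv, sep="\t")
    groups = pd.Series(meta["group"].to_numpy(), index=meta["sample_id"].astype(str))
    expr.columns = expr.columns.astype(str)
    return ExpressionStudy(expr, groups)


def write_expression_study(study: ExpressionStudy, expression_tsv, samples_tsv) -> None:
    out = study.values.copy()
    out.insert(0, "symbol", study.symbols)
    out.to_csv(expression_tsv, sep="\t", index=False)
    pd.DataFrame(
        {"sample_id": study.groups.index, "group": study.groups.to_numpy()}
    ).to_csv(samples_tsv, sep="\t", index=False)
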