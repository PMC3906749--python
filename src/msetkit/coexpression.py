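"""Weighted gene co-expression network and module-trait analysis.

Implements the weighted-network workflow on the genes that survive the
ranking filter: soft-threshold adjacency ``a_ij = |cor(x_i, x_j)|^beta``
(unsigned), scale-free topology fit across a grid of candidate powers,
topological overlap (TOM) similarity, average-linkage clustering with a
static tree cut, eigengene computation, module merging by eigengene
similarity, Pearson module-trait correlation with Student-t
significance, and export of within-module edges touching a regulator
catalog (transcription factors and friends) in a Cytoscape-importable
form.

Modules are labeled by size rank using the conventional color order
("turquoise" largest, then "blue", ...), so synthetic runs read like
classical weighted-network reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .gene_lists import RegulatorCatalog
from .ranking import VIRGIN, POSTPARTUM, ExpressionStudy

UNASSIGNED = "unassigned"

#: WGCNA-style size-rank color order for module labels
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
)

__all__ = [
    "NetworkConfig",
    "CoexpressionNetwork",
    "CoexpressionResult",
    "adjacency_matrix",
    "pick_soft_threshold",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "merge_modules",
    "module_trait_correlation",
    "student_p_from_r",
    "export_tf_edges",
    "UNASSIGNED",
    "MODULE_COLORS",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Tunable parameters of the network stage.

    beta_grid : candidate integer soft-threshold powers.
    scale_free_target : R^2 the log-log connectivity fit must exceed for
        a power to be accepted (0.8 by convention).
    min_module_size : clusters below this size become unassigned.
    merge_threshold : modules whose eigengene dissimilarity ``1 - cor``
        falls below this are merged (0.25 by convention).
    cut_height_fraction : static tree cut at this fraction of the
        maximum merge height.
    input_alpha : nominal-p filter for genes entering the network.
    """

    beta_grid: tuple[int, ...] = tuple(range(1, 31))
    scale_free_target: float = 0.8
    min_module_size: int = 30
    merge_threshold: float = 0.25
    cut_height_fraction: float = 0.99
    input_alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.scale_free_target < 1:
            raise ValueError("scale_free_target must lie in (0, 1)")
        if not 0 < self.merge_threshold < 1:
            raise ValueError("merge_threshold must lie in (0, 1)")
        if not 0 < self.cut_height_fraction < 1:
            raise ValueError("cut_height_fraction must lie in (0, 1)")
        if not 0 < self.input_alpha <= 1:
            raise ValueError("input_alpha must lie in (0, 1]")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if any(b < 1 for b in self.beta_grid):
            raise ValueError("soft-threshold powers must be >= 1")


def _check_variance(expr: np.ndarray, genes) -> None:
    sd = expr.std(axis=1)
    if np.any(sd == 0):
        bad = np.asarray(genes)[sd == 0]
        raise ValueError(f"zero-variance gene(s): {', '.join(map(str, bad[:5]))}")


def adjacency_matrix(expr: np.ndarray, beta: float, genes=None) -> np.ndarray:
    """Unsigned weighted adjacency ``|pearson cor|^beta`` with unit diagonal."""
    expr = np.asarray(expr, dtype=float)
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if beta < 1:
        raise ValueError("beta must be >= 1")
    _check_variance(expr, genes if genes is not None else np.arange(expr.shape[0]))
    a = np.abs(np.corrcoef(expr)) ** beta
    np.fill_diagonal(a, 1.0)
    return np.clip(a, 0.0, 1.0)


def _scale_free_fit(k: np.ndarray, n_bins: int = 10) -> float:
    """R^2 of the log-log connectivity-distribution fit, 0 if slope >= 0.

    Connectivities are binned into ``n_bins`` equal-width bins;
    log10(bin frequency) is regressed on log10(mean bin connectivity)
    over non-empty bins.  NaN when fewer than 3 bins are usable.
    """
    k = np.asarray(k, dtype=float)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    freq, mean_k = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        mk = k[sel].mean()
        if mk <= 0:
            continue
        freq.append(sel.sum() / k.size)
        mean_k.append(mk)
    if len(freq) < 3:
        return float("nan")
    slope, _, r, _, _ = stats.linregress(np.log10(mean_k), np.log10(freq))
    if slope >= 0:
        return 0.0
    return float(r**2)


def pick_soft_threshold(
    expr: np.ndarray, cfg: NetworkConfig = NetworkConfig(), genes=None
) -> tuple[int, pd.DataFrame]:
    """Choose the soft-threshold power by the scale-free topology criterion.

    Returns the smallest candidate power whose fit R^2 exceeds
    ``cfg.scale_free_target``; if none qualifies, falls back to the
    argmax R^2 with a warning.  The fit table (beta, R2, mean_k) is
    returned alongside for inspection.
    """
    rows = []
    for beta in cfg.beta_grid:
        a = adjacency_matrix(expr, beta, genes=genes)
        k = a.sum(axis=1) - 1.0
        rows.append({"beta": beta, "R2": _scale_free_fit(k), "mean_k": float(k.mean())})
    fit_table = pd.DataFrame(rows)
    ok = fit_table[fit_table["R2"] > cfg.scale_free_target]
    if len(ok):
        beta = int(ok.iloc[0]["beta"])
    else:
        usable = fit_table.dropna(subset=["R2"])
        if usable.empty:
            raise ValueError("scale-free fit undefined for every candidate power")
        beta = int(usable.loc[usable["R2"].idxmax(), "beta"])
        warnings.warn(
            f"no candidate power reached scale-free R^2 > {cfg.scale_free_target}; "
            f"falling back to argmax R^2 (beta = {beta})",
            stacklevel=2,
        )
    return beta, fit_table


def tom_similarity(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of an unsigned adjacency.

    ``w_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``l_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{j != i} a_ij``;
    unit diagonal.  High overlap means two genes share neighbors as
    well as a direct edge.
    """
    a = np.asarray(adjacency, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be a symmetric square matrix")
    # (A @ A)_ij counts u = i and u = j, each contributing a_ij once (unit diagonal)
    l = a @ a - 2.0 * a
    k = a.sum(axis=1) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(divide="ignore", invalid="ignore"):
        w = (l + a) / denom
    np.fill_diagonal(w, 1.0)
    return np.clip(w, 0.0, 1.0)


def detect_modules(
    tom: np.ndarray, cfg: NetworkConfig = NetworkConfig()
) -> np.ndarray:
    """Average-linkage clustering of ``1 - TOM`` with a static tree cut.

    The dendrogram is cut at ``cut_height_fraction`` of its maximum
    merge height; flat clusters smaller than ``min_module_size`` are
    folded into the unassigned pool (label 0).  Returns integer labels,
    0 = unassigned, clusters numbered 1.. in decreasing size order.
    """
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    z = linkage(squareform(d, checks=False), method="average")
    cut = cfg.cut_height_fraction * z[:, 2].max()
    raw = fcluster(z, t=cut, criterion="distance")
    labels = np.zeros(raw.size, dtype=int)
    sizes = pd.Series(raw).value_counts()
    keep = [c for c in sizes.index if sizes[c] >= cfg.min_module_size]
    # number surviving clusters by decreasing size (ties: first gene index)
    keep.sort(key=lambda c: (-sizes[c], int(np.argmax(raw == c))))
    for new, c in enumerate(keep, start=1):
        labels[raw == c] = new
    if not keep:
        warnings.warn("no cluster reached min_module_size; all genes unassigned",
                      stacklevel=2)
    return labels


def module_eigengene(expr: np.ndarray, members: np.ndarray) -> tuple[np.ndarray, float]:
    """First principal component of a module across samples.

    The module submatrix is standardized per gene (zero mean, unit
    variance across samples) and decomposed by SVD; the eigengene is the
    first right singular vector (one value per sample), sign-oriented so
    its mean correlation with member genes is non-negative.
    variance_explained is the share of squared singular values.
    """
    sub = np.asarray(expr, dtype=float)[np.asarray(members)]
    if sub.shape[0] < 2:
        raise ValueError("module must contain at least 2 genes")
    sd = sub.std(axis=1, ddof=1)
    if np.any(sd == 0):
        raise ValueError("zero-variance gene inside module")
    z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]
    # orientation: member genes should, on average, follow the eigengene
    cors = np.array([np.corrcoef(e, row)[0, 1] for row in z])
    if cors.mean() < 0:
        e = -e
    return e, float(s[0] ** 2 / (s**2).sum())


def merge_modules(
    expr: np.ndarray, modules: dict[int, np.ndarray], merge_threshold: float = 0.25
) -> dict[int, np.ndarray]:
    """Iteratively merge the closest module pair while below the threshold.

    Closeness is eigengene dissimilarity ``1 - cor(E_a, E_b)``;
    eigengenes are recomputed after each merge.  Ties break to the
    smallest label pair, and merged modules keep the smaller label, so
    the result is independent of input order.
    """
    modules = {k: np.asarray(v) for k, v in sorted(modules.items())}
    while len(modules) > 1:
        eig = {k: module_eigengene(expr, v)[0] for k, v in modules.items()}
        best, best_d = None, np.inf
        for a in sorted(modules):
            for b in sorted(modules):
                if b <= a:
                    continue
                d = 1.0 - float(np.corrcoef(eig[a], eig[b])[0, 1])
                if d < best_d - 1e-12:
                    best, best_d = (a, b), d
        if best is None or best_d >= merge_threshold:
            break
        a, b = best
        modules[a] = np.sort(np.concatenate([modules[a], modules.pop(b)]))
    return modules


def student_p_from_r(r: float, n: int) -> float:
    """Two-sided Student p of a Pearson correlation: t = r sqrt(n-2)/sqrt(1-r^2)."""
    if n < 4:
        raise ValueError("need at least 4 samples")
    if abs(r) >= 1.0:
        return float(np.nextafter(0.0, 1.0))
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def module_trait_correlation(eigengene: np.ndarray, trait: np.ndarray) -> tuple[float, float]:
    """Pearson correlation of an eigengene with a 0/1 trait and its Student p.

    Trait coding is 0 = virgin, 1 = postpartum, so positive r means the
    module tracks the postpartum state.
    """
    eigengene = np.asarray(eigengene, dtype=float)
    trait = np.asarray(trait, dtype=float)
    if eigengene.size != trait.size or eigengene.size < 4:
        raise ValueError("need >= 4 paired samples")
    if len(np.unique(trait)) < 2:
        raise ValueError("trait must have both levels")
    if np.std(eigengene) == 0:
        raise ValueError("constant eigengene")
    r = float(np.corrcoef(eigengene, trait)[0, 1])
    return r, student_p_from_r(r, eigengene.size)


@dataclass
class CoexpressionResult:
    """Fitted co-expression network: modules, eigengenes, trait statistics."""

    genes: tuple[str, ...]
    beta: int
    fit_table: pd.DataFrame | None
    modules: dict[str, tuple[str, ...]]
    unassigned: tuple[str, ...]
    eigengenes: pd.DataFrame  # modules x samples
    variance_explained: dict[str, float]
    trait_stats: pd.DataFrame  # module, r, student_p, n
    tom: np.ndarray
    adjacency: np.ndarray
    samples: tuple[str, ...]
    trait: np.ndarray

    @property
    def n_modules(self) -> int:
        return len(self.modules)

    def module_of(self) -> dict[str, str]:
        """gene -> module label map (unassigned genes included)."""
        out = {g: UNASSIGNED for g in self.unassigned}
        for label, members in self.modules.items():
            out.update({g: label for g in members})
        return out

    def assignment_table(self) -> pd.DataFrame:
        m = self.module_of()
        return pd.DataFrame({"gene": self.genes, "module": [m[g] for g in self.genes]})

    def tf_edges(
        self,
        catalog: RegulatorCatalog,
        module: str,
        top_k_per_tf: int | None = None,
        weight: str = "tom",
    ) -> pd.DataFrame:
        return export_tf_edges(self, module, catalog, top_k_per_tf=top_k_per_tf,
                               weight=weight)

    def summary(self) -> str:
        lines = [
            "Weighted co-expression network",
            f"  genes: {len(self.genes)}  samples: {len(self.samples)}  beta: {self.beta}",
            f"  modules: {self.n_modules} "
            + "".join(f"\n    {m}: {len(v)} genes (VE {self.variance_explained[m]:.2f})"
                      for m, v in self.modules.items()),
            f"  unassigned: {len(self.unassigned)} genes",
            "  module-trait correlations (trait 1 = postpartum):",
        ]
        for _, row in self.trait_stats.iterrows():
            lines.append(
                f"    {row['module']}: r = {row['r']:+.3f}, "
                f"student p = {row['student_p']:.3g} (n = {int(row['n'])})"
            )
        return "\n".join(lines)


def export_tf_edges(
    result: CoexpressionResult,
    module: str,
    catalog: RegulatorCatalog,
    top_k_per_tf: int | None = None,
    weight: str = "tom",
) -> pd.DataFrame:
    """Within-module edges touching at least one catalog regulator.

    Edge weight is the TOM similarity by default (``weight="adjacency"``
    selects the raw soft-threshold adjacency).  Per regulator only the
    ``top_k_per_tf`` strongest edges are kept (all by default); output
    is sorted by weight descending with a stable symbol-pair tie-break
    and is directly importable by Cytoscape (columns source, target,
    weight; regulator endpoint as source).
    """
    if module not in result.modules:
        raise KeyError(f"unknown module {module!r}")
    if weight not in ("tom", "adjacency"):
        raise ValueError("weight must be 'tom' or 'adjacency'")
    mat = result.tom if weight == "tom" else result.adjacency
    gene_pos = {g: i for i, g in enumerate(result.genes)}
    members = list(result.modules[module])
    regulators = [g for g in members if g in catalog]
    edges: dict[tuple[str, str], float] = {}
    for tf in regulators:
        partners = [
            (g, float(mat[gene_pos[tf], gene_pos[g]])) for g in members if g != tf
        ]
        partners.sort(key=lambda t: (-t[1], t[0]))
        if top_k_per_tf is not None:
            partners = partners[:top_k_per_tf]
        for g, w in partners:
            key = (tf, g) if g not in catalog or tf <= g else (g, tf)
            edges.setdefault(key, w)
    rows = [{"source": a, "target": b, "weight": w} for (a, b), w in edges.items()]
    df = pd.DataFrame(rows, columns=["source", "target", "weight"])
    return df.sort_values(
        ["weight", "source", "target"], ascending=[False, True, True]
    ).reset_index(drop=True)


class CoexpressionNetwork:
    """Model object for the co-expression stage.

    Built from an expression study (optionally pre-filtered through a
    ranked table), ``fit()`` runs power selection (unless ``beta`` is
    given), adjacency, TOM, clustering, merging, eigengenes, and
    module-trait statistics, returning a :class:`CoexpressionResult`.
    """

    def __init__(
        self,
        expr: pd.DataFrame,
        trait: np.ndarray,
        config: NetworkConfig = NetworkConfig(),
        beta: int | None = None,
    ):
        if expr.index.has_duplicates:
            raise ValueError("gene index must be unique (collapse probes first)")
        self.expr = expr
        self.trait = np.asarray(trait, dtype=float)
        if self.trait.size != expr.shape[1]:
            raise ValueError("trait length must match the number of samples")
        self.config = config
        self.beta = beta

    @classmethod
    def from_study(
        cls,
        study: ExpressionStudy,
        ranked: pd.DataFrame,
        config: NetworkConfig = NetworkConfig(),
        beta: int | None = None,
    ) -> "CoexpressionNetwork":
        """Select network genes from a ranked table: annotated rows with
        ``p_nominal < config.input_alpha``, duplicate symbols collapsed
        to the best-p probe."""
        hits = ranked[
            (ranked["p_nominal"] < config.input_alpha)
            & (ranked["symbol"].astype(str).str.strip() != "")
        ]
        hits = hits.drop_duplicates(subset="symbol", keep="first")
        rows = hits["row"].to_numpy()
        sub = study.values.iloc[rows]
        sub.index = hits["symbol"].to_numpy()
        trait = (study.groups == POSTPARTUM).to_numpy().astype(float)
        return cls(sub, trait, config=config, beta=beta)

    def fit(self) -> CoexpressionResult:
        cfg = self.config
        X = self.expr.to_numpy(dtype=float)
        genes = tuple(map(str, self.expr.index))
        fit_table = None
        beta = self.beta
        if beta is None:
            beta, fit_table = pick_soft_threshold(X, cfg, genes=genes)
        adj = adjacency_matrix(X, beta, genes=genes)
        tom = tom_similarity(adj)
        labels = detect_modules(tom, cfg)
        raw_modules = {
            int(c): np.flatnonzero(labels == c) for c in np.unique(labels) if c != 0
        }
        merged = merge_modules(X, raw_modules, cfg.merge_threshold) if raw_modules else {}

        # final labels: size-rank color convention
        ordered = sorted(merged.items(), key=lambda kv: (-len(kv[1]), kv[1][0]))
        modules: dict[str, tuple[str, ...]] = {}
        eig_rows, ve, stats_rows = {}, {}, []
        for rank, (_, members) in enumerate(ordered):
            label = (
                MODULE_COLORS[rank] if rank < len(MODULE_COLORS) else f"module{rank + 1}"
            )
            modules[label] = tuple(genes[i] for i in members)
            e, v = module_eigengene(X, members)
            eig_rows[label] = e
            ve[label] = v
            r, p = module_trait_correlation(e, self.trait)
            stats_rows.append(
                {"module": label, "r": r, "student_p": p, "n": self.trait.size}
            )
        assigned = {g for mem in modules.values() for g in mem}
        samples = tuple(map(str, self.expr.columns))
        return CoexpressionResult(
            genes=genes,
            beta=int(beta),
            fit_table=fit_table,
            modules=modules,
            unassigned=tuple(g for g in genes if g not in assigned),
            eigengenes=pd.DataFrame(eig_rows, index=samples).T,
            variance_explained=ve,
            trait_stats=pd.DataFrame(
                stats_rows, columns=["module", "r", "student_p", "n"]
            ),
            tom=tom,
            adjacency=adj,
            samples=samples,
            trait=self.trait,
        )
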