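"""Modular Single-Set Enrichment Test (MSET).

MSET asks whether a curated gene list is over-represented among the
significant genes of a two-group expression study.  The observed match
count ``k = |sig n list|`` is compared with a null built by repeatedly
drawing ``n = |sig|`` genes uniformly without replacement from the
unique annotated array background and counting matches to the list.
The one-sided empirical p-value uses the add-one permutation convention

    p_emp = (1 + #{null >= k}) / (B + 1),

which can never be zero and attains its floor ``1/(B+1)`` when the
observed count exceeds every null count.  Because sampling is without
replacement, the null match count is exactly hypergeometric; the exact
tail (:func:`hypergeom_tail`) therefore serves as an independent oracle
for the randomization machinery.

Beyond the single test, this module runs whole panels of disorder and
control lists with independent per-list random substreams, reports
genes matched by two or more lists of the same disorder category, and
re-runs a panel after removing named genes from the significant set (a
robustness check mirroring post-hoc removal of unverified genes).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gene_lists import GeneSet, GeneSetPanel, canonicalize_symbol
from .ranking import SignificantSet

#: a null is flagged as unreliable when |skewness| exceeds this ...
SKEW_LIMIT = 1.0
#: ... or when its mean match count falls below this
MIN_NULL_MEAN = 5.0

__all__ = [
    "MsetResult",
    "MsetTest",
    "PanelResult",
    "RobustnessResult",
    "mset_test",
    "hypergeom_tail",
    "flag_skew",
    "run_panel",
    "robustness_rerun",
    "randomized_null_rank",
]


@dataclass
class MsetResult:
    """Outcome of one MSET randomization test."""

    list_name: str
    observed: int
    null_counts: np.ndarray
    p_emp: float
    null_mean: float
    fold_enrichment: float
    skewness: float
    flagged_skew: bool
    matched_symbols: tuple[str, ...]
    n: int  # significant-set size
    K: int  # list size on background
    N: int  # background size
    B: int
    seed: int | None = None
    note: str = ""

    @property
    def degenerate_null(self) -> bool:
        return bool(np.all(self.null_counts == self.null_counts[0]))

    def null_histogram(self) -> pd.DataFrame:
        """Match-count frequencies of the null, for density-plot style export."""
        counts = np.bincount(self.null_counts, minlength=self.observed + 1)
        return pd.DataFrame(
            {"matches": np.arange(counts.size), "count": counts, "frequency": counts / self.B}
        )

    def plot_null(self, ax=None):
        """Bar plot of the null match-count density with the observed count marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        h = self.null_histogram()
        ax.bar(h["matches"], h["frequency"], color="steelblue", width=0.9)
        ax.axvline(self.observed, color="crimson", lw=2, label=f"observed = {self.observed}")
        ax.set_xlabel("matches to list per randomization")
        ax.set_ylabel("probability")
        ax.set_title(f"{self.list_name}: p = {self.p_emp:.4g}")
        ax.legend()
        return ax

    def summary(self) -> str:
        lines = [
            f"MSET randomization test: {self.list_name}",
            f"  background N = {self.N}, list K = {self.K}, significant n = {self.n}",
            f"  observed matches  : {self.observed}",
            f"  null mean matches : {self.null_mean:.3f} ({self.B} randomizations)",
            f"  fold enrichment   : {self.fold_enrichment:.3f}"
            if np.isfinite(self.fold_enrichment)
            else "  fold enrichment   : undefined (null mean 0)",
            f"  empirical p       : {self.p_emp:.6g}",
            f"  null skewness     : {self.skewness:.3f}"
            + ("  [FLAGGED: unreliable null]" if self.flagged_skew else ""),
        ]
        if self.note:
            lines.append(f"  note: {self.note}")
        return "\n".join(lines)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    This is the infinite-randomization limit of the MSET p-value and is
    used as the analytic oracle for the sampling implementation.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N or min(N, K, n) < 0:
        raise ValueError(f"inconsistent hypergeometric arguments N={N} K={K} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def flag_skew(null_counts: np.ndarray) -> tuple[float, bool]:
    """Sample skewness of the null and the reliability flag.

    A null is flagged when ``|g1| > 1`` or its mean is below 5 — an
    explicit, reproducible stand-in for discarding visibly skewed
    density plots.  A zero-variance (degenerate) null reports skewness 0
    and is always flagged.
    """
    null_counts = np.asarray(null_counts)
    if null_counts.size < 100:
        raise ValueError("need at least 100 randomizations to judge the null shape")
    mean = float(null_counts.mean())
    if np.all(null_counts == null_counts[0]):
        return 0.0, True
    g1 = float(stats.skew(null_counts, bias=False))
    return g1, abs(g1) > SKEW_LIMIT or mean < MIN_NULL_MEAN


def _null_match_counts(
    rng: np.random.Generator,
    N: int,
    n: int,
    member_mask: np.ndarray,
    B: int,
    chunk: int = 512,
) -> np.ndarray:
    """Match counts of B uniform without-replacement draws of size n from N.

    Each draw is realized as the n smallest of N iid uniform keys
    (a uniformly random size-n subset), vectorized in chunks.
    """
    counts = np.empty(B, dtype=np.int64)
    for start in range(0, B, chunk):
        b = min(chunk, B - start)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        counts[start : start + b] = member_mask[idx].sum(axis=1)
    return counts


def mset_test(
    sig: SignificantSet | Iterable[str],
    gene_set: GeneSet,
    background: Iterable[str],
    B: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> MsetResult:
    """Run the MSET randomization test for one gene list.

    ``sig`` and ``gene_set`` must already be subsets of ``background``
    (restrict lists with
    :func:`msetkit.gene_lists.restrict_to_background` first); a list
    that is empty on the background is refused with an
    "excluded (too small)" error.
    """
    bg = sorted({canonicalize_symbol(s) for s in background})
    N = len(bg)
    sig_symbols = frozenset(sig.symbols if isinstance(sig, SignificantSet) else
                            (canonicalize_symbol(s) for s in sig))
    if not sig_symbols:
        raise ValueError("significant set is empty")
    if not sig_symbols <= set(bg):
        raise ValueError("significant set is not a subset of the background")
    if len(gene_set) == 0 or gene_set.too_small:
        raise ValueError(f"gene set {gene_set.name!r}: excluded (too small)")
    if not gene_set.symbol_set <= set(bg):
        raise ValueError(f"gene set {gene_set.name!r} is not a subset of the background")
    n, K = len(sig_symbols), len(gene_set)
    if n > N:
        raise ValueError("significant set larger than background")
    if B < 1:
        raise ValueError("B must be positive")

    member_mask = np.array([s in gene_set.symbol_set for s in bg])
    matched = tuple(sorted(sig_symbols & gene_set.symbol_set))
    observed = len(matched)

    if rng is None:
        rng = np.random.default_rng(seed)
    null_counts = _null_match_counts(rng, N, n, member_mask, B)
    p_emp = (1 + int((null_counts >= observed).sum())) / (B + 1)
    null_mean = float(null_counts.mean())
    fold = observed / null_mean if null_mean > 0 else float("nan")
    skewness, flagged = flag_skew(null_counts) if B >= 100 else (float("nan"), False)
    return MsetResult(
        list_name=gene_set.name,
        observed=observed,
        null_counts=null_counts,
        p_emp=p_emp,
        null_mean=null_mean,
        fold_enrichment=fold,
        skewness=skewness,
        flagged_skew=flagged,
        matched_symbols=matched,
        n=n,
        K=K,
        N=N,
        B=B,
        seed=seed,
    )


def randomized_null_rank(result: MsetResult, rng: np.random.Generator) -> float:
    """Tie-randomized rank p of the observed count within its null.

    ``(#{null > k} + U * (1 + #{null = k})) / (B + 1)`` with
    ``U ~ Uniform(0,1)`` rounded up to the null-rank grid.  Under the
    null hypothesis (the significant set is exchangeable with the
    randomized draws) this statistic is exactly uniform on
    ``{(1+j)/(B+1) : j = 0..B}``, unlike the raw conservative ``p_emp``
    whose ties with the observed count all resolve upward.  Used for
    calibration diagnostics.
    """
    greater = int((result.null_counts > result.observed).sum())
    ties = int((result.null_counts == result.observed).sum())
    r = greater + int(rng.integers(0, ties + 1))  # rank among null + observed itself
    return (1 + r) / (result.B + 1)


class MsetTest:
    """Model-style wrapper: configure an MSET test, then ``fit(seed)``.

    Parameters mirror :func:`mset_test`; ``fit`` returns a
    :class:`MsetResult`.
    """

    def __init__(
        self,
        sig: SignificantSet | Iterable[str],
        gene_set: GeneSet,
        background: Iterable[str],
        n_randomizations: int = 10_000,
    ):
        self.sig = sig
        self.gene_set = gene_set
        self.background = tuple(background)
        self.n_randomizations = n_randomizations

    def fit(self, seed: int | None = None) -> MsetResult:
        return mset_test(self.sig, self.gene_set, self.background,
                         B=self.n_randomizations, seed=seed)


def _list_seed(master_seed: int | None, name: str) -> np.random.Generator:
    """Independent, composition-invariant substream for one list.

    The child seed depends only on the master seed and the list name, so
    adding or removing other lists never perturbs a list's result.
    """
    entropy = [zlib.crc32(name.encode("utf-8"))]
    if master_seed is not None:
        entropy.insert(0, int(master_seed))
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass
class PanelResult:
    """Per-list MSET results plus the multi-list gene report."""

    table: pd.DataFrame
    results: dict[str, MsetResult]
    excluded: list[str]
    multi_list_genes: dict[str, tuple[str, ...]]

    def summary(self) -> str:
        lines = ["MSET panel"]
        with pd.option_context("display.width", 120):
            lines.append(self.table.to_string(index=False))
        if self.excluded:
            lines.append("excluded (too small): " + ", ".join(self.excluded))
        for cat, genes in self.multi_list_genes.items():
            lines.append(f"genes on >=2 {cat} lists: " + (", ".join(genes) or "(none)"))
        return "\n".join(lines)


def run_panel(
    sig: SignificantSet,
    panel: GeneSetPanel,
    background: Iterable[str],
    B: int = 10_000,
    seed: int | None = None,
    control_sets: Sequence[GeneSet] = (),
) -> PanelResult:
    """Run MSET for every list of a panel plus optional control lists.

    Each list gets an independent seeded substream derived from the
    master seed and its own name.  Lists that are empty after background
    restriction are reported as excluded, not fatal.  The multi-list
    report collects, per disorder category, the matched genes appearing
    on at least two lists of that category (control lists do not
    contribute).
    """
    background = tuple(background)
    rows, results, excluded = [], {}, []
    all_sets = [(g, False) for g in panel] + [(g, True) for g in control_sets]
    for gene_set, is_control in all_sets:
        if len(gene_set) == 0 or gene_set.too_small:
            excluded.append(gene_set.name)
            rows.append(
                {
                    "list": gene_set.name,
                    "source": gene_set.source,
                    "category": gene_set.category or gene_set.name,
                    "control": is_control,
                    "N": len(set(background)),
                    "K": 0,
                    "n": sig.n,
                    "observed": np.nan,
                    "null_mean": np.nan,
                    "fold_enrichment": np.nan,
                    "skewness": np.nan,
                    "flagged": True,
                    "p_emp": np.nan,
                    "note": "excluded (too small)",
                }
            )
            continue
        res = mset_test(sig, gene_set, background, B=B,
                        rng=_list_seed(seed, gene_set.name))
        res.seed = seed
        results[gene_set.name] = res
        rows.append(
            {
                "list": gene_set.name,
                "source": gene_set.source,
                "category": gene_set.category or gene_set.name,
                "control": is_control,
                "N": res.N,
                "K": res.K,
                "n": res.n,
                "observed": res.observed,
                "null_mean": res.null_mean,
                "fold_enrichment": res.fold_enrichment,
                "skewness": res.skewness,
                "flagged": res.flagged_skew,
                "p_emp": res.p_emp,
                "note": "",
            }
        )
    table = pd.DataFrame(rows)

    multi: dict[str, tuple[str, ...]] = {}
    disorder_sets = [g for g in panel if g.name in results]
    for cat in sorted({g.category or g.name for g in disorder_sets}):
        members = [g.name for g in disorder_sets if (g.category or g.name) == cat]
        if len(members) < 2:
            continue
        hits: dict[str, int] = {}
        for name in members:
            for s in results[name].matched_symbols:
                hits[s] = hits.get(s, 0) + 1
        multi[cat] = tuple(sorted(s for s, c in hits.items() if c >= 2))
    return PanelResult(table=table, results=results, excluded=excluded,
                       multi_list_genes=multi)


@dataclass
class RobustnessResult:
    """Before/after panels for a gene-removal robustness re-run."""

    before: PanelResult
    after: PanelResult
    removed: tuple[str, ...]
    ignored: tuple[str, ...]

    @property
    def deltas(self) -> pd.DataFrame:
        b = self.before.table.set_index("list")
        a = self.after.table.set_index("list")
        out = pd.DataFrame(
            {
                "p_before": b["p_emp"],
                "p_after": a["p_emp"],
                "observed_before": b["observed"],
                "observed_after": a["observed"],
            }
        )
        out["p_delta"] = out["p_after"] - out["p_before"]
        return out.reset_index()


def robustness_rerun(
    sig: SignificantSet,
    panel: GeneSetPanel,
    background: Iterable[str],
    remove: Iterable[str],
    B: int = 10_000,
    seed: int | None = None,
    control_sets: Sequence[GeneSet] = (),
) -> RobustnessResult:
    """Re-run a panel after deleting genes from the significant set.

    The background is left unchanged (the genes were measured; only
    their claim to significance is withdrawn), so ``n`` shrinks by the
    number of removed genes actually present in ``sig``.  Removal
    symbols absent from the significant set are noted and ignored.
    """
    remove_canon = {canonicalize_symbol(s) for s in remove}
    present = tuple(sorted(remove_canon & sig.as_set()))
    ignored = tuple(sorted(remove_canon - sig.as_set()))
    reduced = sig.without(present)
    if reduced.n == 0:
        raise ValueError("removal would empty the significant set")
    before = run_panel(sig, panel, background, B=B, seed=seed, control_sets=control_sets)
    after = run_panel(reduced, panel, background, B=B, seed=seed, control_sets=control_sets)
    return RobustnessResult(before=before, after=after, removed=present, ignored=ignored)
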