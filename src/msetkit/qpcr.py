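"""REST-style relative expression from qPCR threshold cycles.

For each target gene the efficiency-corrected expression ratio
(postpartum over virgin) is

    ratio = E_t^(dCt_t) / geomean_r( E_r^(dCt_r) ),

where ``dCt_g = mean Ct in the control (virgin) group minus mean Ct in
the treated (postpartum) group``, ``E`` is the per-gene amplification
efficiency in (1, 2] (2 = perfect doubling per cycle), and the
geometric mean runs over the stable reference genes (e.g. Hmbs and
Hprt).  Significance comes from a two-sided randomization test that
permutes the sample group labels jointly for the target and the
references and recomputes the log-ratio; when the number of distinct
label allocations is small enough, the full allocation set is
enumerated exactly instead of sampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ranking import VIRGIN, POSTPARTUM

__all__ = ["QpcrAssay", "RestResult", "RestModel", "expression_ratio",
           "rest_randomization_test", "read_qpcr_tsv"]


@dataclass
class QpcrAssay:
    """Ct table plus the metadata needed for REST-style ratios.

    ct : long DataFrame with columns ``sample, group, gene, ct``
        (missing Ct values drop that sample for that gene only).
    efficiencies : per-gene amplification efficiency; must cover every
        target and reference — there is no silent default (set
        ``global_efficiency=2.0`` explicitly to assume perfect
        efficiency everywhere; the choice is recorded on the assay).
    """

    ct: pd.DataFrame
    efficiencies: Mapping[str, float] | None
    reference_genes: tuple[str, ...]
    target_genes: tuple[str, ...]
    global_efficiency: float | None = None

    def __post_init__(self) -> None:
        need = {"sample", "group", "gene", "ct"}
        if not need <= set(self.ct.columns):
            raise ValueError(f"ct table must have columns {sorted(need)}")
        self.ct = self.ct.dropna(subset=["ct"]).copy()
        bad = set(self.ct["group"].unique()) - {VIRGIN, POSTPARTUM}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.reference_genes = tuple(self.reference_genes)
        self.target_genes = tuple(self.target_genes)
        if not self.reference_genes:
            raise ValueError("need at least one reference gene")
        if set(self.reference_genes) & set(self.target_genes):
            raise ValueError("reference genes must not also be targets")
        if self.global_efficiency is not None:
            if not 1.0 < self.global_efficiency <= 2.0:
                raise ValueError("efficiency must lie in (1, 2]")
            self.efficiencies = {
                g: self.global_efficiency
                for g in (*self.target_genes, *self.reference_genes)
            }
        if self.efficiencies is None:
            raise ValueError(
                "efficiencies are required; pass per-gene values or set "
                "global_efficiency explicitly"
            )
        for g in (*self.target_genes, *self.reference_genes):
            e = self.efficiencies.get(g)
            if e is None:
                raise ValueError(f"missing amplification efficiency for {g!r}")
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {g!r} must lie in (1, 2], got {e}")
            per_group = self.ct[self.ct["gene"] == g].groupby("group")["ct"].size()
            for grp in (VIRGIN, POSTPARTUM):
                if per_group.get(grp, 0) < 2:
                    raise ValueError(f"gene {g!r}: fewer than 2 Ct values in {grp!r}")

    def efficiency(self, gene: str) -> float:
        return float(self.efficiencies[gene])

    def samples(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.ct["sample"].astype(str)))

    def sample_groups(self) -> pd.Series:
        g = self.ct.drop_duplicates("sample").set_index("sample")["group"]
        return g.reindex(self.samples())


@dataclass(frozen=True)
class RestResult:
    gene: str
    ratio: float
    p_rand: float
    direction: str  # up / down / none
    exact: bool
    n_permutations: int

    def summary(self) -> str:
        method = "exact enumeration" if self.exact else "Monte Carlo"
        return (
            f"{self.gene}: ratio = {self.ratio:.4f} (postpartum/virgin), "
            f"p = {self.p_rand:.4g} [{method}, {self.n_permutations} allocations], "
            f"direction: {self.direction}"
        )


def _gene_arrays(assay: QpcrAssay, gene: str, sample_index: Mapping[str, int]):
    """(sample positions, ct values) for one gene."""
    sub = assay.ct[assay.ct["gene"] == gene]
    pos = np.array([sample_index[s] for s in sub["sample"].astype(str)])
    return pos, sub["ct"].to_numpy(dtype=float)


def _log2_ratios_for_masks(
    assay: QpcrAssay, gene: str, masks: np.ndarray, sample_index: Mapping[str, int]
) -> np.ndarray:
    """Vectorized log2 efficiency-corrected ratios, one per treated mask.

    ``masks`` is a boolean (allocations x samples) array; per gene the
    group means use only that gene's available samples.
    """
    masks = np.atleast_2d(masks)

    def dct(g: str) -> np.ndarray:
        pos, ct = _gene_arrays(assay, g, sample_index)
        sel = masks[:, pos]
        n_t = sel.sum(axis=1)
        n_c = pos.size - n_t
        sum_t = sel @ ct
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(
                (n_t > 0) & (n_c > 0),
                (ct.sum() - sum_t) / n_c - sum_t / np.maximum(n_t, 1),
                np.nan,
            )

    stat = np.log2(assay.efficiency(gene)) * dct(gene)
    ref = np.mean(
        [np.log2(assay.efficiency(r)) * dct(r) for r in assay.reference_genes], axis=0
    )
    return stat - ref


def _log2_ratio(
    assay: QpcrAssay, gene: str, treated: np.ndarray, sample_index: Mapping[str, int]
) -> float:
    return float(_log2_ratios_for_masks(assay, gene, treated, sample_index)[0])


def expression_ratio(assay: QpcrAssay, gene: str) -> float:
    """Efficiency-corrected expression ratio, postpartum over virgin."""
    if gene not in assay.target_genes:
        raise ValueError(f"{gene!r} is not a target gene of this assay")
    samples = assay.samples()
    index = {s: i for i, s in enumerate(samples)}
    treated = (assay.sample_groups() == POSTPARTUM).to_numpy()
    return float(2.0 ** _log2_ratio(assay, gene, treated, index))


def rest_randomization_test(
    assay: QpcrAssay,
    gene: str,
    B: int = 2000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> RestResult:
    """Two-sided randomization test on the log expression ratio.

    Group labels are permuted at the sample level, jointly for the
    target and the reference genes, and the efficiency-corrected
    log-ratio is recomputed per permutation:

    * if the number of distinct treated-set allocations ``C(m, m_t)``
      is at most ``B``, all allocations are enumerated and
      ``p = #{|stat| >= |observed|} / total`` (the observed allocation
      is one of them, so p is never zero);
    * otherwise ``B`` random label permutations give the add-one
      Monte-Carlo p ``(1 + #{|stat| >= |obs|}) / (B + 1)``.

    ``direction`` is "up"/"down" by ratio vs 1 when ``p < alpha``,
    else "none".
    """
    if gene not in assay.target_genes:
        raise ValueError(f"{gene!r} is not a target gene of this assay")
    samples = assay.samples()
    index = {s: i for i, s in enumerate(samples)}
    groups = assay.sample_groups()
    observed_treated = (groups == POSTPARTUM).to_numpy()
    m, mt = len(samples), int(observed_treated.sum())
    obs = _log2_ratio(assay, gene, observed_treated, index)

    n_alloc = comb(m, mt)
    exact = n_alloc <= max(B, 20)
    if exact:
        masks = np.zeros((n_alloc, m), dtype=bool)
        for a, chosen in enumerate(combinations(range(m), mt)):
            masks[a, list(chosen)] = True
        stats = _log2_ratios_for_masks(assay, gene, masks, index)
        hits = int(np.sum(np.abs(stats) >= abs(obs) - 1e-12))
        p = hits / n_alloc
        n_perm = n_alloc
    else:
        rng = np.random.default_rng(seed)
        keys = rng.random((B, m))
        idx = np.argpartition(keys, mt - 1, axis=1)[:, :mt]
        masks = np.zeros((B, m), dtype=bool)
        np.put_along_axis(masks, idx, True, axis=1)
        stats = _log2_ratios_for_masks(assay, gene, masks, index)
        hits = int(np.sum(np.abs(stats) >= abs(obs) - 1e-12))
        p = (1 + hits) / (B + 1)
        n_perm = B
    ratio = float(2.0**obs)
    if p < alpha:
        direction = "up" if ratio > 1 else ("down" if ratio < 1 else "none")
    else:
        direction = "none"
    return RestResult(gene=gene, ratio=ratio, p_rand=p, direction=direction,
                      exact=exact, n_permutations=n_perm)


class RestModel:
    """Model-style wrapper running the REST analysis for every target gene."""

    def __init__(self, assay: QpcrAssay, B: int = 2000):
        self.assay = assay
        self.B = B

    def fit(self, seed: int | None = None) -> "RestResults":
        rng = np.random.default_rng(seed)
        results = [
            rest_randomization_test(
                self.assay, g, B=self.B, seed=int(rng.integers(0, 2**31 - 1))
            )
            for g in self.assay.target_genes
        ]
        return RestResults(results)


@dataclass
class RestResults:
    results: list[RestResult]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "gene": r.gene,
                    "ratio": r.ratio,
                    "p_rand": r.p_rand,
                    "direction": r.direction,
                    "exact": r.exact,
                }
                for r in self.results
            ]
        )

    def summary(self) -> str:
        return "REST relative expression (postpartum / virgin)\n" + "\n".join(
            "  " + r.summary() for r in self.results
        )


def read_qpcr_tsv(ct_tsv, efficiency_tsv, reference_genes: Sequence[str]) -> QpcrAssay:
    """Assemble an assay from a Ct TSV (sample, group, gene, ct) and an
    efficiency TSV (gene, efficiency)."""
    ct = pd.read_csv(ct_tsv, sep="\t")
    ct.columns = [c.lower() for c in ct.columns]
    eff_df = pd.read_csv(efficiency_tsv, sep="\t")
    eff_df.columns = [c.lower() for c in eff_df.columns]
    eff = dict(zip(eff_df["gene"].astype(str), eff_df["efficiency"].astype(float)))
    refs = tuple(reference_genes)
    targets = tuple(g for g in pd.unique(ct["gene"].astype(str)) if g not in refs)
    return QpcrAssay(ct=ct, efficiencies=eff, reference_genes=refs, target_genes=targets)
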