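"""Synthetic two-group expression studies with known ground truth.

The generator emulates a virgin-vs-postpartum microarray design at desk
scale: a gene universe (default 5,000 symbols standing in for a
35,557-target array), 6 samples per group, a planted fraction of
differentially expressed genes with fold changes straddling 1, planted
co-expression modules whose latent eigen-signal is correlated with the
phenotype at a chosen level (opposite signs allowed), disorder-style
gene-list panels with a tunable fraction of members drawn from the true
DE genes, a regulator catalog, and qPCR Ct tables with known
amplification efficiencies and stable reference genes.

Everything is generated on the log2 scale as

    x_gi = baseline_g + group_effect_g(sample) + loading_g * eigen_m(sample)
           + Normal(0, noise_sd),

deterministic given the seed, so every downstream stage can be tested
against the planted truth without external data.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gene_lists import (
    CHROMATIN_REMODELING_FACTOR,
    CO_FACTOR,
    TRANSCRIPTION_FACTOR,
    GeneSet,
    GeneSetPanel,
    RegulatorCatalog,
    write_gmt,
)
from .qpcr import QpcrAssay
from .ranking import POSTPARTUM, VIRGIN, ExpressionStudy, write_expression_study

__all__ = ["ListSpec", "QpcrSpec", "SimConfig", "SyntheticStudy",
           "simulate_study", "simulate_gene_set_panel", "simulate_qpcr",
           "write_study"]


@dataclass(frozen=True)
class ListSpec:
    """One synthetic gene list: size and the fraction drawn from true-DE genes."""

    name: str
    size: int
    enrichment_rho: float
    category: str | None = None
    control: bool = False

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("list size must be positive")
        if not 0.0 <= self.enrichment_rho <= 1.0:
            raise ValueError("enrichment_rho must lie in [0, 1]")


@dataclass(frozen=True)
class QpcrSpec:
    """Design of the synthetic qPCR assay.

    ``group_shifts`` are log2 expression differences (postpartum minus
    virgin), so a shift of +1 with perfect efficiency plants a true
    expression ratio of 2.0.  Reference genes always get shift 0; giving
    a reference a nonzero shift is a configuration error.
    """

    targets: tuple[str, ...] = ("Oxtr", "Socs2", "Gabre", "Ace")
    group_shifts: tuple[float, ...] = (0.19, 0.7, -0.45, -0.14)
    efficiencies: Mapping[str, float] | None = None  # None = 2.0 for every gene
    reference_genes: tuple[str, ...] = ("Hmbs", "Hprt")
    baseline_ct: float = 24.0
    noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.group_shifts):
            raise ValueError("need one group shift per target")
        if set(self.targets) & set(self.reference_genes):
            raise ValueError("reference genes must not also be targets")
        for g, e in (self.efficiencies or {}).items():
            if not 1.0 < e <= 2.0:
                raise ValueError(f"efficiency for {g!r} must lie in (1, 2]")

    def efficiency(self, gene: str) -> float:
        return float((self.efficiencies or {}).get(gene, 2.0))


@dataclass(frozen=True)
class SimConfig:
    """Full specification of one synthetic study.

    Defaults mirror the emulated design: 6 + 6 arrays, a 5,000-gene
    desk-scale universe, 5% of genes truly DE with fold-change
    magnitudes in [1.4, 2] (half inverted below 1), per-gene log2 noise
    SD 0.2, and two planted modules of 60 and 40 genes whose
    eigen-signals correlate with the phenotype at +0.85 and -0.85.
    """

    n_genes: int = 5000
    n_per_group: int = 6
    de_fraction: float = 0.05
    fc_range: tuple[float, float] = (1.4, 2.0)
    down_fraction: float = 0.5
    noise_sd: float = 0.2
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    module_sizes: tuple[int, ...] = (60, 40)
    module_trait_r: tuple[float, ...] = (0.85, -0.85)
    module_signal_sd: float = 1.0
    modules_overlap_de: bool = False
    list_specs: tuple[ListSpec, ...] = (
        ListSpec("asd_db", 50, 0.5, category="asd"),
        ListSpec("asd_gwas", 60, 0.4, category="asd"),
        ListSpec("depression_db", 50, 0.4, category="depression"),
        ListSpec("schizophrenia_db", 55, 0.4, category="schizophrenia"),
        ListSpec("parkinsons_ctrl", 50, 0.0, category="parkinsons", control=True),
        ListSpec("arthritis_ctrl", 50, 0.0, category="arthritis", control=True),
        ListSpec("liver_ctrl", 50, 0.0, category="liver", control=True),
    )
    qpcr_spec: QpcrSpec = field(default_factory=QpcrSpec)
    n_regulators: tuple[int, int, int] = (37, 17, 7)  # TF, co-factor, chromatin
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_per_group) < 2:
            raise ValueError("n_genes and n_per_group must be >= 2")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if not 0.0 <= self.down_fraction <= 1.0:
            raise ValueError("down_fraction must lie in [0, 1]")
        if self.noise_sd < 0 or self.module_signal_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if min(self.fc_range) <= 0:
            raise ValueError("fold-change range must be positive")
        if len(self.module_sizes) != len(self.module_trait_r):
            raise ValueError("need one trait correlation per module")
        if any(s < 2 for s in self.module_sizes):
            raise ValueError("module sizes must be >= 2")
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError("module sizes exceed the gene universe")
        if any(abs(r) >= 1.0 for r in self.module_trait_r):
            raise ValueError("|module_trait_r| must be < 1")


@dataclass
class SyntheticStudy:
    """A generated study with its full ground truth."""

    expression: ExpressionStudy
    truth_de: dict[str, float]  # symbol -> planted linear fold change
    truth_modules: dict[str, str]  # symbol -> planted module label (M1, M2, ...)
    truth_trait_r: dict[str, float]
    panel: GeneSetPanel
    truth_rho: dict[str, float]
    regulator_catalog: RegulatorCatalog
    qpcr: QpcrAssay
    config: SimConfig

    @property
    def universe(self) -> tuple[str, ...]:
        return tuple(self.expression.values.index)

    def control_sets(self) -> list[GeneSet]:
        names = {s.name for s in self.config.list_specs if s.control}
        return [g for g in self.panel if g.name in names]

    def disorder_panel(self) -> GeneSetPanel:
        names = {s.name for s in self.config.list_specs if not s.control}
        return GeneSetPanel([g for g in self.panel if g.name in names])


def _trait_vector(n_per_group: int) -> np.ndarray:
    """0/1 phenotype coding: first block virgin, second postpartum."""
    return np.r_[np.zeros(n_per_group), np.ones(n_per_group)]


def _eigen_signal(
    rng: np.random.Generator,
    trait: np.ndarray,
    r: float,
    orthogonal_to: Sequence[np.ndarray] = (),
) -> tuple[np.ndarray, np.ndarray]:
    """A standardized per-sample signal whose sample correlation with the
    trait is exactly ``r``.

    The residual component is orthogonalized against the trait and
    against the residuals of previously planted modules (so distinct
    modules stay distinguishable in-sample — with a dozen samples two
    unconstrained random residuals can be nearly collinear by chance,
    which would silently collapse the planted truth), then renormalized.
    Returns ``(signal, residual)``.
    """
    t = (trait - trait.mean()) / trait.std()
    g = rng.normal(size=trait.size)
    g = g - g.mean()
    for v in (t, *orthogonal_to):
        g = g - (g @ v) / (v @ v) * v
    g = g / np.sqrt((g**2).mean())
    return r * t + np.sqrt(1.0 - r * r) * g, g


def simulate_study(cfg: SimConfig) -> SyntheticStudy:
    """Generate a complete synthetic study from a configuration.

    Deterministic given ``cfg.seed``; calling twice with the same config
    yields bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_per_group
    genes = np.array([f"G{i:05d}" for i in range(1, cfg.n_genes + 1)], dtype=object)
    trait = _trait_vector(n)
    samples = [f"V{i+1}" for i in range(n)] + [f"P{i+1}" for i in range(n)]

    # planted modules first (disjoint), then DE genes outside them by default
    order = rng.permutation(cfg.n_genes)
    cursor = 0
    truth_modules: dict[str, str] = {}
    module_members: list[np.ndarray] = []
    for m, size in enumerate(cfg.module_sizes):
        members = order[cursor : cursor + size]
        cursor += size
        module_members.append(members)
        for g in genes[members]:
            truth_modules[g] = f"M{m + 1}"
    truth_trait_r = {f"M{m + 1}": r for m, r in enumerate(cfg.module_trait_r)}

    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    de_pool = order[cursor:] if not cfg.modules_overlap_de else order
    if n_de > de_pool.size:
        raise ValueError("de_fraction leaves no room outside the planted modules")
    de_idx = rng.choice(de_pool, size=n_de, replace=False)

    lo, hi = sorted(1.0 / f if f < 1 else f for f in cfg.fc_range)
    log2fc = rng.uniform(np.log2(lo), np.log2(hi), size=n_de)
    down = rng.random(n_de) < cfg.down_fraction
    log2fc = np.where(down, -log2fc, log2fc)
    truth_de = {genes[i]: float(2.0**f) for i, f in zip(de_idx, log2fc)}

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    X = np.tile(baseline[:, None], (1, 2 * n))
    X[de_idx] += np.outer(log2fc, trait)
    residuals: list[np.ndarray] = []
    for members, r in zip(module_members, cfg.module_trait_r):
        e, g = _eigen_signal(rng, trait, r, orthogonal_to=residuals)
        residuals.append(g)
        loadings = rng.uniform(0.8, 1.2, size=members.size)
        X[members] += np.outer(loadings, e * cfg.module_signal_sd)
    X += rng.normal(0.0, cfg.noise_sd, size=X.shape)

    expression = ExpressionStudy(
        pd.DataFrame(X, index=pd.Index(genes, name="symbol"), columns=samples),
        pd.Series([VIRGIN] * n + [POSTPARTUM] * n, index=samples),
    )

    panel, truth_rho = simulate_gene_set_panel(
        set(truth_de), set(genes), cfg.list_specs, rng=rng
    )
    catalog = _simulate_regulators(rng, genes, truth_de, truth_modules, cfg.n_regulators)
    qpcr = simulate_qpcr(
        targets=cfg.qpcr_spec.targets,
        efficiencies={
            g: cfg.qpcr_spec.efficiency(g)
            for g in (*cfg.qpcr_spec.targets, *cfg.qpcr_spec.reference_genes)
        },
        refs=cfg.qpcr_spec.reference_genes,
        group_shifts=dict(zip(cfg.qpcr_spec.targets, cfg.qpcr_spec.group_shifts)),
        n_per_group=cfg.n_per_group,
        noise_sd=cfg.qpcr_spec.noise_sd,
        baseline_ct=cfg.qpcr_spec.baseline_ct,
        rng=rng,
    )
    return SyntheticStudy(
        expression=expression,
        truth_de=truth_de,
        truth_modules=truth_modules,
        truth_trait_r=truth_trait_r,
        panel=panel,
        truth_rho=truth_rho,
        regulator_catalog=catalog,
        qpcr=qpcr,
        config=cfg,
    )


def simulate_gene_set_panel(
    truth_de: set[str],
    universe: set[str],
    list_specs: Sequence[ListSpec],
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> tuple[GeneSetPanel, dict[str, float]]:
    """Draw gene lists with a controlled fraction of true-DE members.

    Each list takes ``round(rho * size)`` symbols uniformly from the
    true-DE genes and the rest uniformly from the remainder of the
    universe, without replacement; the planted rho is returned as ground
    truth per list.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    truth = np.array(sorted(truth_de), dtype=object)
    rest = np.array(sorted(universe - truth_de), dtype=object)
    sets, rhos = [], {}
    for spec in list_specs:
        if spec.size > len(universe):
            raise ValueError(f"list {spec.name!r} larger than the universe")
        n_de = int(round(spec.enrichment_rho * spec.size))
        if n_de > truth.size:
            raise ValueError(
                f"list {spec.name!r}: rho x size = {n_de} exceeds |truth_de| = {truth.size}"
            )
        members = list(rng.choice(truth, size=n_de, replace=False)) + list(
            rng.choice(rest, size=spec.size - n_de, replace=False)
        )
        sets.append(
            GeneSet(
                name=spec.name,
                symbols=tuple(members),
                source="synthetic",
                category=spec.category,
            )
        )
        rhos[spec.name] = spec.enrichment_rho
    return GeneSetPanel(sets), rhos


def _simulate_regulators(
    rng: np.random.Generator,
    genes: np.ndarray,
    truth_de: Mapping[str, float],
    truth_modules: Mapping[str, str],
    counts: tuple[int, int, int],
) -> RegulatorCatalog:
    """Assign regulator categories, preferring module and DE genes so the
    catalog intersects the interesting parts of the study."""
    total = sum(counts)
    preferred = sorted(set(truth_modules) | set(truth_de))
    pool = list(rng.permutation(np.array(preferred, dtype=object))) + list(
        rng.permutation(np.array(sorted(set(genes) - set(preferred)), dtype=object))
    )
    chosen = pool[:total]
    mapping: dict[str, str] = {}
    i = 0
    for cat, cnt in zip(
        (TRANSCRIPTION_FACTOR, CO_FACTOR, CHROMATIN_REMODELING_FACTOR), counts
    ):
        for sym in chosen[i : i + cnt]:
            mapping[sym] = cat
        i += cnt
    return RegulatorCatalog(mapping)


def simulate_qpcr(
    targets: Sequence[str],
    efficiencies: Mapping[str, float],
    refs: Sequence[str],
    group_shifts: Mapping[str, float],
    n_per_group: int = 6,
    noise_sd: float = 0.15,
    baseline_ct: float = 24.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> QpcrAssay:
    """Generate a Ct table with known true expression ratios.

    Per sample, ``Ct = baseline - shift(group) / log2(E) + noise`` with
    ``shift`` applied in the postpartum group only; reference genes are
    generated with shift 0 (listing a reference in ``group_shifts`` with
    a nonzero value is a configuration error).  The true expression
    ratio of a target is ``2**shift`` regardless of its efficiency.
    """
    for r in refs:
        if group_shifts.get(r, 0.0) != 0.0:
            raise ValueError(f"reference gene {r!r} must have group shift 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    baselines = {
        g: baseline_ct + float(rng.uniform(-2.0, 2.0))
        for g in (*targets, *refs)
    }
    samples = [(f"V{i+1}", VIRGIN) for i in range(n_per_group)] + [
        (f"P{i+1}", POSTPARTUM) for i in range(n_per_group)
    ]
    rows = []
    for gene in (*targets, *refs):
        e = efficiencies[gene]
        if not 1.0 < e <= 2.0:
            raise ValueError(f"efficiency for {gene!r} must lie in (1, 2]")
        shift = float(group_shifts.get(gene, 0.0)) if gene in targets else 0.0
        for sample, group in samples:
            ct = baselines[gene]
            if group == POSTPARTUM:
                ct -= shift / np.log2(e)
            if noise_sd > 0:
                ct += float(rng.normal(0.0, noise_sd))
            rows.append({"sample": sample, "group": group, "gene": gene, "ct": ct})
    return QpcrAssay(
        ct=pd.DataFrame(rows),
        efficiencies=dict(efficiencies),
        reference_genes=tuple(refs),
        target_genes=tuple(targets),
    )


def write_study(study: SyntheticStudy, outdir) -> None:
    """Write a synthetic study as plain-text files.

    expression.tsv / samples.tsv / panel.gmt / regulators.tsv /
    qpcr_ct.tsv / qpcr_efficiencies.tsv / truth.json
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_expression_study(
        study.expression, outdir / "expression.tsv", outdir / "samples.tsv"
    )
    write_gmt(list(study.panel), outdir / "panel.gmt")
    study.regulator_catalog.to_tsv(outdir / "regulators.tsv")
    study.qpcr.ct.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(study.qpcr.efficiencies.items()), columns=["gene", "efficiency"]
    ).to_csv(outdir / "qpcr_efficiencies.tsv", sep="\t", index=False)
    truth = {
        "truth_de": study.truth_de,
        "truth_modules": study.truth_modules,
        "truth_trait_r": study.truth_trait_r,
        "truth_rho": study.truth_rho,
        "seed": study.config.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
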