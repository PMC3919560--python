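"""Hypergeometric annotation of modules and evaluation baselines.

Modules are annotated by over-representation of flat annotation terms (GO
biological-process categories for the mRNA side, miRNA families/genomic
clusters for the miRNA side).  For a term with ``N`` members in a universe
of ``U``, a module sample of ``S`` ids containing ``n`` term members has

    p = P(X >= n),  X ~ Hypergeometric(U, N, S)

The universe defaults to the identifiers of the association matrix, not
the genome.  Raw p-values are reported; optional Benjamini–Hochberg
correction is available.

Two evaluation procedures accompany annotation: a permuted-label baseline
(rerun discovery after shuffling matrix row/column labels and compare the
top-term p-value distributions) and a validated-pair density report
(experimentally confirmed miRNA–mRNA pairs falling inside modules versus
the cell area the modules cover).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .association import InvalidInputError
from .bicluster import Module, SearchConfig, discover_modules

__all__ = [
    "AnnotationSet",
    "EnrichmentResult",
    "ModuleAnnotation",
    "PermutedBaseline",
    "DensityReport",
    "hypergeom_pvalue",
    "hypergeom_enrich",
    "label_modules",
    "permute_labels",
    "permuted_baseline",
    "validated_pair_density",
]

logger = logging.getLogger(__name__)

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class AnnotationSet:
    """Flat term → member mapping over a fixed universe.

    Term memberships are intersected with the universe at construction, so
    downstream counts are always consistent.
    """

    terms: dict[str, frozenset[str]]
    universe: frozenset[str]
    kind: str = "gene_category"

    def __post_init__(self) -> None:
        if not self.universe:
            raise InvalidInputError("annotation universe is empty")
        object.__setattr__(
            self,
            "terms",
            {t: frozenset(m) & self.universe for t, m in self.terms.items()},
        )

    @classmethod
    def from_pairs(
        cls, pairs: list[tuple[str, str]], universe: set[str], kind: str = "gene_category"
    ) -> "AnnotationSet":
        terms: dict[str, set[str]] = {}
        for term, member in pairs:
            terms.setdefault(term, set()).add(member)
        return cls(
            {t: frozenset(m) for t, m in terms.items()}, frozenset(universe), kind
        )


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's over-representation in a module sample."""

    term: str
    n: int  # overlap
    N: int  # term size in universe
    S: int  # sample size
    U: int  # universe size
    p_value: float
    q_value: float | None = None

    @property
    def fraction(self) -> float:
        """Enriched fraction n/S of the sample (bubble-size statistic)."""
        return self.n / self.S if self.S else 0.0


@dataclass
class ModuleAnnotation:
    """Top-term labels attached to a module by :func:`label_modules`."""

    top_term: str
    top_result: EnrichmentResult | None
    gene_results: list[EnrichmentResult]  # top-10 retained
    mirna_term: str
    mirna_result: EnrichmentResult | None

    @property
    def fraction(self) -> float:
        return self.top_result.fraction if self.top_result else 0.0


def hypergeom_pvalue(U: int, N: int, S: int, n: int) -> float:
    """Upper-tail P(X ≥ n) for X ~ Hypergeometric(U, N, S)."""
    if not (0 <= N <= U and 0 <= S <= U and 0 <= n <= min(N, S)):
        raise InvalidInputError(f"inconsistent counts U={U} N={N} S={S} n={n}")
    if n == 0:
        return 1.0
    return float(stats.hypergeom.sf(n - 1, U, N, S))


def hypergeom_enrich(
    sample: set[str],
    annot: AnnotationSet,
    bh_correct: bool = False,
) -> list[EnrichmentResult]:
    """Score every annotation term against a module sample.

    Sample ids outside the universe are dropped (count logged).  Results
    are sorted by ascending p, ties broken by term id.  With
    ``bh_correct=True`` Benjamini–Hochberg q-values are attached.
    """
    inside = set(sample) & annot.universe
    dropped = len(sample) - len(inside)
    if dropped:
        logger.info("dropped %d sample ids outside the universe", dropped)
    if not inside:
        return []
    U, S = len(annot.universe), len(inside)
    results = []
    for term, members in annot.terms.items():
        N = len(members)
        if N == 0:
            continue
        n = len(inside & members)
        results.append(
            EnrichmentResult(term, n, N, S, U, hypergeom_pvalue(U, N, S, n))
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    if bh_correct and results:
        m = len(results)
        q_raw = [r.p_value * m / (i + 1) for i, r in enumerate(results)]
        # enforce monotonicity from the largest p down
        q = list(q_raw)
        for i in range(m - 2, -1, -1):
            q[i] = min(q[i], q[i + 1])
        results = [
            EnrichmentResult(r.term, r.n, r.N, r.S, r.U, r.p_value, min(1.0, qi))
            for r, qi in zip(results, q)
        ]
    return results


def label_modules(
    modules: list[Module],
    gene_annot: AnnotationSet | None,
    mirna_annot: AnnotationSet | None = None,
    top_k: int = 10,
) -> list[Module]:
    """Attach top GO term and top miRNA class to each module (in place).

    The gene sample is the combined direct + indirect mRNA set.  Modules
    with no annotated members are labelled ``"unannotated"``.  Returns the
    same module list for chaining.
    """
    for mod in modules:
        gene_results: list[EnrichmentResult] = []
        if gene_annot is not None and gene_annot.terms:
            gene_results = hypergeom_enrich(set(mod.mrnas), gene_annot)
        mirna_results: list[EnrichmentResult] = []
        if mirna_annot is not None and mirna_annot.terms:
            mirna_results = hypergeom_enrich(set(mod.mirnas), mirna_annot)
        top = gene_results[0] if gene_results and gene_results[0].n > 0 else None
        mtop = mirna_results[0] if mirna_results and mirna_results[0].n > 0 else None
        mod.annotation = ModuleAnnotation(
            top_term=top.term if top else UNANNOTATED,
            top_result=top,
            gene_results=gene_results[:top_k],
            mirna_term=mtop.term if mtop else UNANNOTATED,
            mirna_result=mtop,
        )
    return modules


def permute_labels(
    assoc: pd.DataFrame, rng: np.random.Generator | int | None = None
) -> pd.DataFrame:
    """Shuffle row and column labels, keeping the value grid in place.

    The value multiset (and hence the bicluster score landscape) is
    preserved; only the mapping from cells to identifiers is destroyed.
    """
    rng = np.random.default_rng(rng)
    rows = assoc.index.to_numpy().copy()
    cols = assoc.columns.to_numpy().copy()
    rng.shuffle(rows)
    rng.shuffle(cols)
    return pd.DataFrame(assoc.to_numpy().copy(), index=rows, columns=cols)


@dataclass
class PermutedBaseline:
    """Top-term p-values of a permuted-label rerun versus the real run."""

    permuted_pvalues: list[float]
    real_pvalues: list[float] = field(default_factory=list)
    mannwhitney_p: float = float("nan")
    permuted_modules: list[Module] = field(default_factory=list, repr=False)


def _top_pvalues(modules: list[Module]) -> list[float]:
    out = []
    for m in modules:
        ann = m.annotation
        out.append(ann.top_result.p_value if ann and ann.top_result else 1.0)
    return out


def permuted_baseline(
    assoc: pd.DataFrame,
    cfg: SearchConfig,
    gene_annot: AnnotationSet,
    rng: np.random.Generator | int | None = None,
    real_modules: list[Module] | None = None,
) -> PermutedBaseline:
    """Discovery rerun on label-permuted data as a significance baseline.

    Permutes the association matrix labels, reruns :func:`discover_modules`
    with the identical configuration, annotates the permuted modules, and
    (when ``real_modules`` is given) tests whether the real top-term
    p-values are stochastically smaller via a one-sided Mann–Whitney U on
    −log10 p.
    """
    permuted = permute_labels(assoc, rng)
    perm_modules = discover_modules(permuted, cfg)
    label_modules(perm_modules, gene_annot)
    perm_p = _top_pvalues(perm_modules)

    result = PermutedBaseline(permuted_pvalues=perm_p, permuted_modules=perm_modules)
    if real_modules is not None:
        real_p = _top_pvalues(real_modules)
        result.real_pvalues = real_p
        if real_p and perm_p:
            real_s = -np.log10(np.maximum(real_p, 1e-300))
            perm_s = -np.log10(np.maximum(perm_p, 1e-300))
            result.mannwhitney_p = float(
                stats.mannwhitneyu(real_s, perm_s, alternative="greater").pvalue
            )
    return result


@dataclass
class DensityReport:
    """Validated-pair coverage of a module set (optionally vs a baseline)."""

    n_pairs_inside: int
    covered_cells: int
    density: float
    modules_with_pair: int
    mean_mirnas: float
    mean_mrnas: float
    baseline_density: float = float("nan")
    fold: float = float("nan")


def _density(modules: list[Module], pairs: set[tuple[str, str]]) -> tuple[int, int, int]:
    hits = 0
    cells = 0
    with_pair = 0
    for mod in modules:
        mirnas = set(mod.mirnas)
        mrnas = set(mod.mrnas)
        cells += len(mirnas) * len(mrnas)
        inside = sum(1 for m, g in pairs if m in mirnas and g in mrnas)
        hits += inside
        with_pair += inside > 0
    return hits, cells, with_pair


def validated_pair_density(
    modules: list[Module],
    pairs: set[tuple[str, str]],
    baseline: list[Module] | None = None,
) -> DensityReport:
    """Density of experimentally validated pairs inside the modules.

    ``density`` = validated (miRNA, mRNA) pairs falling inside modules /
    total cells covered (sum of per-module |miRNAs| × |mRNAs| areas).
    With a baseline module set (e.g. from a permuted-label run), the fold
    change of densities is reported; an empty pair set yields zero density
    and an undefined fold.
    """
    if not modules:
        raise InvalidInputError("empty module list")
    pairs = set(pairs)
    hits, cells, with_pair = _density(modules, pairs)
    density = hits / cells if cells else 0.0
    report = DensityReport(
        n_pairs_inside=hits,
        covered_cells=cells,
        density=density,
        modules_with_pair=with_pair,
        mean_mirnas=float(np.mean([len(m.mirnas) for m in modules])),
        mean_mrnas=float(np.mean([len(m.mrnas) for m in modules])),
    )
    if baseline:
        bhits, bcells, _ = _density(baseline, pairs)
        report.baseline_density = bhits / bcells if bcells else 0.0
        if report.baseline_density > 0 and not math.isnan(density):
            report.fold = density / report.baseline_density
    return report
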