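"""Synthetic matched miRNA/mRNA data with planted module structure.

Every pipeline stage can be exercised without downloads: the generator
emits matched expression matrices, target predictions, gene annotations,
miRNA groupings, validated pairs and a ground-truth record.

The expression model is latent-activity linear-Gaussian.  Each planted
module has a per-sample activity ``a ~ N(0, 1)``; member miRNAs follow
``+a + σε``, direct-arm mRNAs ``−e·a + σε`` (inverse), indirect-arm mRNAs
``+e·a + σε`` (downstream upregulation), with effect size ``e`` and noise
standard deviation ``σ``.  Background features are independent ``N(0, 1)``
noise.  The Spearman correlation implied by a linear-Gaussian signal is
analytically predictable from its Pearson counterpart, which keeps oracle
checks simple.

Cooperativity groups plant an additive dose response: group members share
a latent activity, and a target mRNA with ``k`` targeting members is
generated with correlation ``c_k = min(0.95, |effect|·k)`` to that
activity, so the per-level median trend is linear with slope ≈ the
per-miRNA effect.

Target predictions are TRUE for planted direct pairs minus a false-negative
rate, plus background pairs at a false-positive rate — echoing the fact
that real target predictions contain both error types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .association import InvalidInputError
from .cooperativity import MiRNAGrouping
from .enrichment import AnnotationSet

__all__ = [
    "PlantedModuleSpec",
    "CoopGroupSpec",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_dataset",
    "default_benchmark",
]


@dataclass(frozen=True)
class PlantedModuleSpec:
    """Shape and strength of one planted module."""

    n_mirnas: int = 6
    n_direct: int = 30
    n_indirect: int = 10
    effect: float = 1.0
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if min(self.n_mirnas, self.n_direct) < 1 or self.n_indirect < 0:
            raise InvalidInputError("module spec counts must be positive")
        if self.noise_sd < 0:
            raise InvalidInputError("noise sd must be ≥ 0")


@dataclass(frozen=True)
class CoopGroupSpec:
    """One planted cooperative miRNA group (family-like)."""

    n_members: int = 8
    n_targets: int = 500
    effect: float = 0.1  # per-miRNA increment of inverse correlation
    noise_sd: float = 0.05
    member_noise_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.n_members < 2 or self.n_targets < 1:
            raise InvalidInputError("cooperative group needs ≥2 members, ≥1 target")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset (JSON-serializable)."""

    rng_seed: int
    modules: list[dict] = field(default_factory=list)
    coop_groups: list[dict] = field(default_factory=list)
    categories: dict[str, list[str]] = field(default_factory=dict)
    validated_pairs: list[list[str]] = field(default_factory=list)

    def planted_pairs(self) -> set[tuple[str, str]]:
        """All planted (miRNA, direct mRNA) pairs across modules."""
        out: set[tuple[str, str]] = set()
        for mod in self.modules:
            for m in mod["mirnas"]:
                for g in mod["direct_mrnas"]:
                    out.add((m, g))
        return out

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class SyntheticDataset:
    mirna_expr: pd.DataFrame
    mrna_expr: pd.DataFrame
    targets: pd.DataFrame
    gene_annotation: AnnotationSet
    mirna_groupings: list[MiRNAGrouping]
    validated_pairs: set[tuple[str, str]]
    truth: SyntheticTruth


def _ids(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def generate_dataset(
    n_mirnas: int = 200,
    n_mrnas: int = 2000,
    n_samples: int = 40,
    module_specs: tuple[PlantedModuleSpec, ...] = (),
    coop_specs: tuple[CoopGroupSpec, ...] = (),
    background_target_rate: float = 0.02,
    target_fn_rate: float = 0.1,
    category_purity: float = 0.8,
    n_random_categories: int = 30,
    validated_in_rate: float = 0.05,
    validated_bg_rate: float = 0.005,
    rng_seed: int = 0,
) -> SyntheticDataset:
    """Generate one fully specified synthetic study.

    Planted modules occupy leading miRNA/mRNA slots, cooperative groups the
    next ones, and everything else is background noise.  Per planted
    module, a gene category covering its mRNA arms at ``category_purity``
    is added to the annotation, its miRNA set becomes a family grouping,
    and validated pairs are sampled inside modules at
    ``validated_in_rate`` versus ``validated_bg_rate`` elsewhere.
    Reproducible: the same ``rng_seed`` yields an identical dataset.
    """
    need_mirnas = sum(s.n_mirnas for s in module_specs) + sum(
        s.n_members for s in coop_specs
    )
    need_mrnas = sum(s.n_direct + s.n_indirect for s in module_specs) + sum(
        s.n_targets for s in coop_specs
    )
    if need_mirnas > n_mirnas or need_mrnas > n_mrnas:
        raise InvalidInputError(
            f"planted structure needs {need_mirnas} miRNAs × {need_mrnas} mRNAs, "
            f"matrix is {n_mirnas} × {n_mrnas}"
        )
    rng = np.random.default_rng(rng_seed)
    mirna_ids = _ids("mir-", n_mirnas)
    mrna_ids = _ids("gene-", n_mrnas)
    samples = _ids("sample-", n_samples)

    x = rng.normal(size=(n_mirnas, n_samples))
    y = rng.normal(size=(n_mrnas, n_samples))
    t = rng.random(size=(n_mirnas, n_mrnas)) < background_target_rate

    truth = SyntheticTruth(rng_seed=rng_seed)
    mi = 0  # next free miRNA slot
    gi = 0  # next free mRNA slot

    # --- planted modules ---
    for spec in module_specs:
        activity = rng.normal(size=n_samples)
        mod_mirs = mirna_ids[mi : mi + spec.n_mirnas]
        mir_rows = slice(mi, mi + spec.n_mirnas)
        mi += spec.n_mirnas
        direct = mrna_ids[gi : gi + spec.n_direct]
        dir_rows = slice(gi, gi + spec.n_direct)
        gi += spec.n_direct
        indirect = mrna_ids[gi : gi + spec.n_indirect]
        ind_rows = slice(gi, gi + spec.n_indirect)
        gi += spec.n_indirect

        x[mir_rows] = activity + spec.noise_sd * rng.normal(
            size=(spec.n_mirnas, n_samples)
        )
        y[dir_rows] = -spec.effect * activity + spec.noise_sd * rng.normal(
            size=(spec.n_direct, n_samples)
        )
        if spec.n_indirect:
            y[ind_rows] = spec.effect * activity + spec.noise_sd * rng.normal(
                size=(spec.n_indirect, n_samples)
            )

        # direct pairs get sites minus the false-negative rate;
        # indirect pairs must NOT carry sites (they model downstream effects)
        keep = rng.random(size=(spec.n_mirnas, spec.n_direct)) >= target_fn_rate
        t[mir_rows, dir_rows.start : dir_rows.stop] = keep
        if spec.n_indirect:
            t[mir_rows, ind_rows.start : ind_rows.stop] = False

        truth.modules.append(
            {
                "mirnas": list(mod_mirs),
                "direct_mrnas": list(direct),
                "indirect_mrnas": list(indirect),
                "effect": spec.effect,
                "noise_sd": spec.noise_sd,
            }
        )

    # --- cooperative groups (additive dose response) ---
    coop_groupings: list[MiRNAGrouping] = []
    for ci, spec in enumerate(coop_specs, start=1):
        activity = rng.normal(size=n_samples)
        members = mirna_ids[mi : mi + spec.n_members]
        mem_rows = slice(mi, mi + spec.n_members)
        mi += spec.n_members
        targets_g = mrna_ids[gi : gi + spec.n_targets]
        tgt_rows = slice(gi, gi + spec.n_targets)
        gi += spec.n_targets

        x[mem_rows] = activity + spec.member_noise_sd * rng.normal(
            size=(spec.n_members, n_samples)
        )
        ks = rng.integers(1, spec.n_members + 1, size=spec.n_targets)
        for off, k in enumerate(ks):
            which = rng.choice(spec.n_members, size=k, replace=False)
            t[mem_rows.start + which, tgt_rows.start + off] = True
            c_k = min(0.95, abs(spec.effect) * k)
            eps = rng.normal(size=n_samples)
            y[tgt_rows.start + off] = -c_k * activity + np.sqrt(1 - c_k**2) * eps

        name = f"coop-family-{ci}"
        coop_groupings.append(
            MiRNAGrouping(name=name, kind="family", members=frozenset(members))
        )
        truth.coop_groups.append(
            {
                "name": name,
                "members": list(members),
                "effect": spec.effect,
                "target_counts": [int(k) for k in ks],
            }
        )

    # --- gene annotation: one category per planted module + random terms ---
    cat_pairs: list[tuple[str, str]] = []
    for idx, mod in enumerate(truth.modules, start=1):
        term = f"GO:planted{idx:02d}"
        members = list(mod["direct_mrnas"]) + list(mod["indirect_mrnas"])
        if category_purity < 1.0 and members:
            n_extra = int(round(len(members) * (1 - category_purity) / category_purity))
            pool = [g for g in mrna_ids if g not in set(members)]
            extra = rng.choice(len(pool), size=min(n_extra, len(pool)), replace=False)
            members += [pool[e] for e in sorted(extra)]
        truth.categories[term] = sorted(members)
        cat_pairs += [(term, g) for g in members]
    for r in range(1, n_random_categories + 1):
        term = f"GO:random{r:02d}"
        size = int(rng.integers(20, 80))
        pick = rng.choice(n_mrnas, size=min(size, n_mrnas), replace=False)
        members = sorted(mrna_ids[p] for p in pick)
        truth.categories[term] = members
        cat_pairs += [(term, g) for g in members]
    gene_annot = AnnotationSet.from_pairs(cat_pairs, set(mrna_ids), "gene_category")

    # --- miRNA groupings: planted-module families + cooperative groups ---
    groupings = list(coop_groupings)
    for idx, mod in enumerate(truth.modules, start=1):
        groupings.append(
            MiRNAGrouping(
                name=f"module-family-{idx}",
                kind="family",
                members=frozenset(mod["mirnas"]),
            )
        )

    # --- validated pairs: enriched inside planted modules ---
    validated: set[tuple[str, str]] = set()
    for mod in truth.modules:
        for m in mod["mirnas"]:
            for g in mod["direct_mrnas"]:
                if rng.random() < validated_in_rate:
                    validated.add((m, g))
    n_bg = rng.binomial(n_mirnas * n_mrnas, validated_bg_rate)
    for _ in range(n_bg):
        m = mirna_ids[rng.integers(n_mirnas)]
        g = mrna_ids[rng.integers(n_mrnas)]
        validated.add((m, g))
    truth.validated_pairs = sorted([m, g] for m, g in validated)

    return SyntheticDataset(
        mirna_expr=pd.DataFrame(x, index=mirna_ids, columns=samples),
        mrna_expr=pd.DataFrame(y, index=mrna_ids, columns=samples),
        targets=pd.DataFrame(t, index=mirna_ids, columns=mrna_ids),
        gene_annotation=gene_annot,
        mirna_groupings=groupings,
        validated_pairs=validated,
        truth=truth,
    )


def default_benchmark(
    rng_seed: int = 0,
    n_mirnas: int = 200,
    n_mrnas: int = 2000,
    n_samples: int = 40,
    n_modules: int = 5,
    noise_sd: float = 0.1,
    with_coop: bool = False,
) -> SyntheticDataset:
    """The default planted benchmark: 200 miRNAs × 2000 mRNAs × 40 samples,
    5 planted modules (6 miRNAs, 30 direct + 10 indirect mRNAs each)."""
    specs = tuple(PlantedModuleSpec(noise_sd=noise_sd) for _ in range(n_modules))
    coop = (CoopGroupSpec(),) if with_coop else ()
    return generate_dataset(
        n_mirnas=n_mirnas,
        n_mrnas=n_mrnas,
        n_samples=n_samples,
        module_specs=specs,
        coop_specs=coop,
        rng_seed=rng_seed,
    )
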