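"""Readers and writers for the pipeline's file dialects.

All tables are TSV (gzip accepted on read where noted) with ``#`` treated
as a comment prefix; nested structures (modules, run manifests, ground
truth) are JSON.  Formats:

* expression: first column = feature id, header row = sample ids;
* targets: either a two-column (miRNA, mRNA) pair list or a dense 0/1
  matrix in the expression layout;
* annotation: two-column (term, member id) or GAF 2.x (columns 2 and 5);
* families: two-column (family name, miRNA id), miFam-like;
* loci: BED6, 0-based half-open, name = miRNA id, optional 7th column =
  host gene;
* validated pairs: two-column (miRNA, mRNA).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .association import InvalidInputError, validate_expression
from .bicluster import Module, Submatrix
from .cooperativity import GenomicLocus, MiRNAGrouping
from .enrichment import AnnotationSet
from .modulemap import ModuleLayout

__all__ = [
    "read_expression",
    "write_expression",
    "read_targets",
    "write_targets",
    "read_annotation",
    "read_families",
    "read_bed_loci",
    "read_validated_pairs",
    "write_matrix",
    "write_sparse_triplets",
    "modules_to_json",
    "write_modules_json",
    "read_modules_json",
    "write_modules_tsv",
    "write_layout_tsv",
    "write_cooperativity_tsv",
]

_TSV = dict(sep="\t", comment="#")


def read_expression(path: str | Path) -> pd.DataFrame:
    """Expression matrix TSV (features × samples); gzip accepted."""
    df = pd.read_csv(path, index_col=0, **_TSV)
    if df.empty:
        raise InvalidInputError(f"empty expression matrix: {path}")
    df.index.name = None
    df.columns.name = None
    return validate_expression(df)


def write_expression(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="feature_id", float_format="%.6g")


def read_targets(
    path: str | Path,
    dialect: str = "pairs",
    mirna_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Target predictions as a boolean miRNA × mRNA DataFrame.

    ``dialect="pairs"``: two-column pair list; the label universe is taken
    from ``mirna_ids``/``mrna_ids`` when given, else from the pairs.
    ``dialect="matrix"``: dense 0/1 matrix in the expression layout.
    """
    if dialect == "matrix":
        df = pd.read_csv(path, index_col=0, **_TSV)
        return df.astype(float).astype(bool)
    if dialect != "pairs":
        raise InvalidInputError(f"unknown target dialect {dialect!r}")
    pairs = pd.read_csv(path, header=None, usecols=[0, 1],
                        names=["mirna", "mrna"], dtype=str, **_TSV)
    pairs = pairs.dropna()
    rows = mirna_ids if mirna_ids is not None else sorted(pairs["mirna"].unique())
    cols = mrna_ids if mrna_ids is not None else sorted(pairs["mrna"].unique())
    t = pd.DataFrame(False, index=pd.Index(rows), columns=pd.Index(cols))
    known = pairs[pairs["mirna"].isin(t.index) & pairs["mrna"].isin(t.columns)]
    t.values[
        t.index.get_indexer(known["mirna"]), t.columns.get_indexer(known["mrna"])
    ] = True
    return t


def write_targets(targets: pd.DataFrame, path: str | Path, dialect: str = "pairs") -> None:
    if dialect == "matrix":
        targets.astype(int).to_csv(path, sep="\t", index_label="mirna_id")
        return
    m, g = np.nonzero(targets.to_numpy(bool))
    pd.DataFrame(
        {"mirna": targets.index[m], "mrna": targets.columns[g]}
    ).to_csv(path, sep="\t", index=False, header=False)


def read_annotation(
    path: str | Path, universe: set[str], kind: str = "gene_category",
    dialect: str = "pairs",
) -> AnnotationSet:
    """Annotation table → :class:`AnnotationSet` over the given universe."""
    if dialect == "gaf":
        df = pd.read_csv(path, sep="\t", comment="!", header=None, dtype=str)
        pairs = list(zip(df[4], df[2]))  # GO id, DB object symbol
    elif dialect == "pairs":
        df = pd.read_csv(path, header=None, usecols=[0, 1],
                         names=["term", "member"], dtype=str, **_TSV)
        pairs = list(zip(df["term"], df["member"]))
    else:
        raise InvalidInputError(f"unknown annotation dialect {dialect!r}")
    return AnnotationSet.from_pairs(pairs, universe, kind)


def write_annotation(annot: AnnotationSet, path: str | Path) -> None:
    rows = [
        (term, member)
        for term in sorted(annot.terms)
        for member in sorted(annot.terms[term])
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_families(path: str | Path) -> list[MiRNAGrouping]:
    """miFam-like two-column TSV (family name, miRNA id)."""
    df = pd.read_csv(path, header=None, usecols=[0, 1],
                     names=["family", "mirna"], dtype=str, **_TSV)
    return [
        MiRNAGrouping(name=name, kind="family", members=frozenset(sub["mirna"]))
        for name, sub in df.groupby("family", sort=True)
    ]


def write_families(groups: list[MiRNAGrouping], path: str | Path) -> None:
    rows = [(g.name, m) for g in groups for m in sorted(g.members)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, header=False)


def read_bed_loci(path: str | Path) -> list[GenomicLocus]:
    """BED6(+1) miRNA loci; optional column 7 is the host gene."""
    df = pd.read_csv(path, header=None, dtype=str, **_TSV)
    if df.shape[1] < 4:
        raise InvalidInputError("BED file needs at least 4 columns (chrom start end name)")
    loci = []
    for row in df.itertuples(index=False):
        host = row[6] if len(row) > 6 and pd.notna(row[6]) else None
        strand = row[5] if len(row) > 5 and pd.notna(row[5]) else "."
        loci.append(
            GenomicLocus(
                mirna_id=str(row[3]),
                chromosome=str(row[0]),
                start=int(row[1]),
                end=int(row[2]),
                strand=str(strand),
                host_gene=host,
            )
        )
    return loci


def write_bed_loci(loci: list[GenomicLocus], path: str | Path) -> None:
    with open(path, "w") as fh:
        for l in loci:
            host = l.host_gene if l.host_gene is not None else ""
            fh.write(
                f"{l.chromosome}\t{l.start}\t{l.end}\t{l.mirna_id}\t0\t{l.strand}"
                + (f"\t{host}" if host else "")
                + "\n"
            )


def read_validated_pairs(path: str | Path) -> set[tuple[str, str]]:
    df = pd.read_csv(path, header=None, usecols=[0, 1],
                     names=["mirna", "mrna"], dtype=str, **_TSV)
    return set(zip(df["mirna"], df["mrna"]))


def write_validated_pairs(pairs: set[tuple[str, str]], path: str | Path) -> None:
    pd.DataFrame(sorted(pairs)).to_csv(path, sep="\t", index=False, header=False)


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Dense miRNA × mRNA matrix TSV (expression layout)."""
    matrix.to_csv(path, sep="\t", index_label="mirna_id", float_format="%.6g")


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0, **_TSV).astype(float)


def write_sparse_triplets(matrix: pd.DataFrame, path: str | Path) -> None:
    """Compact (miRNA, mRNA, value) triplets of the non-zero cells."""
    m, g = np.nonzero(matrix.to_numpy(float))
    pd.DataFrame(
        {
            "mirna": matrix.index[m],
            "mrna": matrix.columns[g],
            "value": matrix.to_numpy(float)[m, g],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _module_record(mod: Module) -> dict:
    rec = {
        "module_id": mod.module_id,
        "mirnas": list(mod.mirnas),
        "direct_mrnas": list(mod.direct_mrnas),
        "indirect_mrnas": list(mod.indirect_mrnas),
        "score": mod.score,
        "seed": {"mirnas": list(mod.seed.mirnas), "mrnas": list(mod.seed.mrnas)},
        "edges": [[m, g, v] for (m, g), v in sorted(mod.edges.items())],
    }
    ann = mod.annotation
    if ann is not None:
        rec["annotation"] = {
            "top_term": ann.top_term,
            "fraction": ann.fraction,
            "mirna_term": ann.mirna_term,
            "gene_results": [
                {"term": r.term, "n": r.n, "N": r.N, "S": r.S, "U": r.U,
                 "p_value": r.p_value}
                for r in ann.gene_results
            ],
        }
    return rec


def modules_to_json(modules: list[Module]) -> str:
    """Canonical JSON of a module list (sorted keys, repr floats)."""
    return json.dumps([_module_record(m) for m in modules], indent=1, sort_keys=True)


def write_modules_json(modules: list[Module], path: str | Path) -> None:
    Path(path).write_text(modules_to_json(modules) + "\n")


def read_modules_json(path: str | Path) -> list[Module]:
    records = json.loads(Path(path).read_text())
    modules = []
    for rec in records:
        mod = Module(
            mirnas=tuple(rec["mirnas"]),
            direct_mrnas=tuple(rec["direct_mrnas"]),
            indirect_mrnas=tuple(rec["indirect_mrnas"]),
            score=float(rec["score"]),
            seed=Submatrix(
                mirnas=tuple(rec["seed"]["mirnas"]),
                mrnas=tuple(rec["seed"]["mrnas"]),
            ),
            edges={(m, g): float(v) for m, g, v in rec.get("edges", [])},
            module_id=rec.get("module_id", ""),
        )
        modules.append(mod)
    return modules


def write_modules_tsv(modules: list[Module], path: str | Path) -> None:
    """Flat per-member table (module_id, side, feature_id, mean_association)."""
    rows = []
    for mod in modules:
        arr = np.array(
            [[mod.edges.get((m, g), 0.0) for g in mod.direct_mrnas] for m in mod.mirnas]
        ) if mod.direct_mrnas else np.zeros((len(mod.mirnas), 0))
        for i, m in enumerate(mod.mirnas):
            mean_a = float(arr[i].mean()) if arr.size else 0.0
            rows.append((mod.module_id, "mirna", m, mean_a))
        for side, ids in (("direct_mrna", mod.direct_mrnas),
                          ("indirect_mrna", mod.indirect_mrnas)):
            for g in ids:
                vals = [mod.edges.get((m, g), 0.0) for m in mod.mirnas]
                rows.append((mod.module_id, side, g, float(np.mean(vals))))
    pd.DataFrame(
        rows, columns=["module_id", "side", "feature_id", "mean_association"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_layout_tsv(layouts: list[ModuleLayout], path: str | Path) -> None:
    pd.DataFrame(
        [
            (l.module_id, l.x, l.y, l.radius, l.term, l.fraction,
             l.perimeter_color, l.area_color, l.z_rank)
            for l in layouts
        ],
        columns=["module_id", "x", "y", "radius", "term", "fraction",
                 "perimeter_color", "area_color", "z_rank"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_cooperativity_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.4g")
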