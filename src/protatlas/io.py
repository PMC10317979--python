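"""Reading and writing the plain-text formats of the pipeline.

All tabular files are tab-separated with a header row; lines starting with
``#`` are comments (output files carry a provenance comment naming the
producing operation and the units).  Gene sets use the GMT convention: one
set per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import os
from typing import Iterable

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, AnnotationTable, GeneSetCollection, macro_region_of, validate_meta


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype={0: str})


def read_abundance(matrix_path, meta_path) -> AbundanceMatrix:
    """Load an LFQ matrix (proteins x samples TSV) and its sample metadata.

    The matrix columns are reordered to the metadata row order; a sample in
    one file but not the other is a hard error naming the sample, as is any
    negative intensity.
    """
    mat = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    meta = pd.read_csv(meta_path, sep="\t", comment="#", index_col=0, dtype={"day": int})
    meta.index = meta.index.astype(str)
    mat.columns = mat.columns.astype(str)
    unmatched_cols = set(mat.columns) - set(meta.index)
    if unmatched_cols:
        raise ValueError(f"matrix samples without metadata: {sorted(unmatched_cols)}")
    unmatched_meta = set(meta.index) - set(mat.columns)
    if unmatched_meta:
        raise ValueError(f"metadata samples missing from matrix: {sorted(unmatched_meta)}")
    if "macro_region" not in meta.columns:
        meta["macro_region"] = meta["region"].map(macro_region_of)
    mat = mat.loc[:, meta.index]
    return AbundanceMatrix(mat, meta)


def write_abundance(m: AbundanceMatrix, matrix_path, meta_path) -> None:
    """Write matrix and metadata TSVs; round-trips through read_abundance."""
    with open(matrix_path, "w") as fh:
        fh.write("# produced_by=write_abundance units=LFQ_intensity (0 = undetected)\n")
        m.lfq.to_csv(fh, sep="\t", index_label="protein_id")
    with open(meta_path, "w") as fh:
        fh.write("# produced_by=write_abundance units=sample_metadata day=days_post_fertilization\n")
        m.meta.to_csv(fh, sep="\t", index_label="sample_id")


def read_annotation(path) -> AnnotationTable:
    """Load a protein annotation TSV.

    Expected columns: ``protein_id``, optional ``gene_symbol``,
    ``localization`` and ``family`` (semicolon-separated multi-labels).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "protein_id" not in df.columns:
        raise ValueError("annotation table needs a protein_id column")
    gene, loc, fam = {}, {}, {}
    for row in df.itertuples(index=False):
        pid = row.protein_id
        g = getattr(row, "gene_symbol", "")
        if g:
            gene[pid] = g
        for attr, store in (("localization", loc), ("family", fam)):
            raw = getattr(row, attr, "")
            if raw:
                store[pid] = frozenset(x for x in raw.split(";") if x)
    return AnnotationTable(gene_symbol=gene, localization=loc, family=fam)


def write_annotation(ann: AnnotationTable, path) -> None:
    pids = sorted(set(ann.gene_symbol) | set(ann.localization) | set(ann.family))
    rows = [
        {
            "protein_id": p,
            "gene_symbol": ann.gene_symbol.get(p, ""),
            "localization": ";".join(sorted(ann.localizations(p))),
            "family": ";".join(sorted(ann.families(p))),
        }
        for p in pids
    ]
    with open(path, "w") as fh:
        fh.write("# produced_by=write_annotation units=labels multi-label=semicolon\n")
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Parse a GMT file into a GeneSetCollection."""
    sets: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line (need name, desc, >=1 gene): {line[:80]!r}")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
    return GeneSetCollection(sets, frozenset(universe) if universe is not None else None)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection.sets):
            genes = sorted(collection.sets[name])
            fh.write("\t".join([name, "na", *genes]) + "\n")


def write_table(df: pd.DataFrame, path, produced_by: str, units: str, index: bool = False) -> None:
    """Write a result TSV with a provenance comment header."""
    os.makedirs(os.path.dirname(str(path)) or ".", exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# produced_by={produced_by} units={units}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_ortholog_panel(path):
    """Load a long-format ortholog panel TSV: ortholog_id, species, region, abundance."""
    from .cross_species import OrthologPanel

    df = pd.read_csv(path, sep="\t", comment="#", dtype={"ortholog_id": str})
    need = {"ortholog_id", "species", "region", "abundance"}
    if not need.issubset(df.columns):
        raise ValueError(f"ortholog panel needs columns {sorted(need)}")
    regions = list(dict.fromkeys(df["region"]))
    tables = {
        sp: sub.pivot(index="ortholog_id", columns="region", values="abundance")[regions]
        for sp, sub in df.groupby("species", sort=True)
    }
    return OrthologPanel(abundance=tables, regions=tuple(regions))


def write_ortholog_panel(panel, path) -> None:
    frames = []
    for sp, tab in panel.abundance.items():
        long = tab.reset_index().melt(id_vars="ortholog_id", var_name="region", value_name="abundance")
        long.insert(1, "species", sp)
        frames.append(long)
    out = pd.concat(frames, ignore_index=True)
    write_table(out, path, "write_ortholog_panel", "mean_abundance_per_region")
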