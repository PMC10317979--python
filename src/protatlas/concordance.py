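"""RNA versus protein fold-change concordance typing.

For each gene, the prenatal-to-postnatal fold change is computed at the RNA
level and at the protein level; genes are then placed into six mutually
exclusive types by the magnitude (twofold threshold) and direction agreement
of the two changes.  Writing a = log2 FC_RNA, b = log2 FC_protein and
"large" for |log2 FC| >= 1 (i.e. |FC| >= 2 with |FC| = max(ratio, 1/ratio)):

- Type1: neither large — small change at both levels;
- Type2: protein large, RNA small;
- Type3: RNA large, protein small, directions not consistently nonzero;
- Type4: RNA large, protein small, consistent nonzero direction;
- Type5: both large, opposite direction;
- Type6: both large, consistent direction.

The printed definitions of these types overlap when read literally; the
partition above is the unique disambiguation that (i) tiles FC-space, (ii)
keeps Type2/Type3 the dominant magnitude-discrepancy cells, and (iii)
assigns every unambiguous case to its stated type.  See docs/methods.md.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .core import AbundanceMatrix, AnnotationTable, GeneSetCollection
from .enrichment import ora

TYPES = ("Type1", "Type2", "Type3", "Type4", "Type5", "Type6")


def compute_fc_pairs(m: AbundanceMatrix, rna: pd.DataFrame, ann: AnnotationTable,
                     region: str, stages: tuple[str, str] = ("F120", "P3")) -> pd.DataFrame:
    """Per-gene (RNA FC, protein FC) pairs for one region.

    ``rna`` is a table with columns gene, region, prenatal_mean,
    postnatal_mean.  Protein fold change is the ratio of stage means of
    detected LFQ intensities in the region's samples, mapped to genes via
    the annotation (multi-protein genes average their stage means).  Genes
    with an undefined FC on either layer are excluded with a warning count.
    """
    pre_s, post_s = stages
    pre = m.samples(stage=pre_s, region=region)
    post = m.samples(stage=post_s, region=region)
    if not pre or not post:
        raise ValueError(f"region {region!r} missing samples at {pre_s} or {post_s}")
    lfq_pre = m.lfq.loc[:, pre].to_numpy()
    lfq_post = m.lfq.loc[:, post].to_numpy()

    def _mean_detected(x):
        det = x > 0
        n = det.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            mu = np.where(det, x, 0.0).sum(axis=1) / n
        mu[n == 0] = np.nan
        return mu

    mu_pre = pd.Series(_mean_detected(lfq_pre), index=m.proteins)
    mu_post = pd.Series(_mean_detected(lfq_post), index=m.proteins)
    by_gene = ann.proteins_for_gene()
    rna_r = rna[rna["region"] == region].set_index("gene")
    rows, n_dropped = [], 0
    for gene, sub in rna_r.iterrows():
        pids = [p for p in by_gene.get(gene, []) if p in m.proteins]
        if not pids:
            continue
        pre_mu = float(np.nanmean(mu_pre[pids]))
        post_mu = float(np.nanmean(mu_post[pids]))
        rna_pre, rna_post = float(sub["prenatal_mean"]), float(sub["postnatal_mean"])
        if not (pre_mu > 0 and post_mu > 0 and rna_pre > 0 and rna_post > 0):
            n_dropped += 1
            continue
        rows.append((gene, region, rna_post / rna_pre, post_mu / pre_mu))
    if n_dropped:
        warnings.warn(f"{n_dropped} genes dropped for undefined fold change in {region}")
    return pd.DataFrame(rows, columns=["gene", "region", "fc_rna", "fc_protein"])


def classify_type(fc_rna: float, fc_protein: float, threshold: float = 2.0) -> str:
    """Assign one of the six concordance types to a fold-change pair."""
    if not (fc_rna > 0 and fc_protein > 0 and np.isfinite(fc_rna) and np.isfinite(fc_protein)):
        raise ValueError("fold changes must be positive finite ratios")
    a = np.log2(fc_rna)
    b = np.log2(fc_protein)
    cut = np.log2(threshold)
    big_r, big_p = abs(a) >= cut, abs(b) >= cut
    same_dir = a * b > 0
    if big_r and big_p:
        return "Type6" if same_dir else "Type5"
    if big_p:
        return "Type2"
    if big_r:
        return "Type4" if same_dir else "Type3"
    return "Type1"


def classify_six_types(pairs: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Vectorized typing of an fc_rna/fc_protein table; adds ``type``."""
    out = pairs.copy()
    out["type"] = [classify_type(r, p, threshold)
                   for r, p in zip(out["fc_rna"], out["fc_protein"])]
    return out


def type_percentages(typed: pd.DataFrame, by: str | None = "region") -> pd.DataFrame:
    """Percent of genes per type (per region when ``by`` is set)."""
    keys = [by] if by and by in typed.columns else []
    rows = []
    for key, sub in (typed.groupby(by, sort=True) if keys else [("all", typed)]):
        n = len(sub)
        counts = sub["type"].value_counts()
        for t in TYPES:
            rows.append((key, t, int(counts.get(t, 0)), 100.0 * counts.get(t, 0) / n))
    return pd.DataFrame(rows, columns=[by or "group", "type", "n", "percent"])


def type_enrichment(typed: pd.DataFrame, sets: GeneSetCollection,
                    q_threshold: float = 0.05) -> dict[str, pd.DataFrame]:
    """ORA per concordance type against the universe of all typed genes."""
    universe = set(typed["gene"])
    out = {}
    for t in TYPES:
        genes = set(typed.loc[typed["type"] == t, "gene"])
        if not genes:
            continue
        out[t] = ora(genes, sets, universe, q_threshold)
    return out
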