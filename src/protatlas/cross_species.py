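"""Cross-species 1:1 ortholog correlation analysis and conservation classes.

Each ortholog carries one mean-abundance vector per species over five shared
brain regions.  The three pairwise Pearson correlations of those vectors
(monkey-human, mouse-human, monkey-mouse) drive the classification:

- human-specific: r(monkey,human) and r(mouse,human) both in [-1, -0.5];
- conserved: r(monkey,human) and r(monkey,mouse) both in [0.75, 1];
- primate-specific: r(monkey,human) in [0.75, 1] but neither r(mouse,human)
  nor r(monkey,mouse) in [0.75, 1];
- unclassified otherwise.

With only five regions per vector these correlations are high-variance;
that is a property of the design, not of the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import AnnotationTable

DEFAULT_REGIONS = ("PFC", "STr", "MD", "Hipp", "CB")
SPECIES = ("human", "monkey", "mouse")
PAIRS = (("monkey", "human"), ("mouse", "human"), ("monkey", "mouse"))
PAIR_COLUMNS = {p: f"r_{p[0]}_{p[1]}" for p in PAIRS}

CLASSES = ("human_specific", "primate_specific", "conserved", "unclassified")


@dataclass
class OrthologPanel:
    """Per-species ortholog x region abundance tables with a fixed region order."""

    abundance: dict[str, pd.DataFrame]
    regions: tuple[str, ...] = DEFAULT_REGIONS

    def __post_init__(self) -> None:
        missing = set(SPECIES) - set(self.abundance)
        if missing:
            raise ValueError(f"panel missing species: {sorted(missing)}")
        ids = None
        for sp, tab in self.abundance.items():
            if list(tab.columns) != list(self.regions):
                raise ValueError(f"{sp} regions {list(tab.columns)} != {list(self.regions)}")
            if ids is None:
                ids = tab.index
            elif not tab.index.equals(ids):
                raise ValueError("species tables index different orthologs")

    @property
    def ortholog_ids(self) -> pd.Index:
        return self.abundance[SPECIES[0]].index


def _rowwise_pearson(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per row; NaN for constant rows."""
    a = a - a.mean(axis=1, keepdims=True)
    b = b - b.mean(axis=1, keepdims=True)
    na = np.sqrt((a**2).sum(axis=1))
    nb = np.sqrt((b**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (a * b).sum(axis=1) / (na * nb)
    r[(na == 0) | (nb == 0)] = np.nan
    return np.clip(r, -1.0, 1.0)


def ortholog_correlations(panel: OrthologPanel) -> pd.DataFrame:
    """Three pairwise Pearson correlations per ortholog over the shared regions."""
    arrs = {sp: panel.abundance[sp].to_numpy(dtype=float) for sp in SPECIES}
    out = {"ortholog_id": panel.ortholog_ids}
    for pair, col in PAIR_COLUMNS.items():
        out[col] = _rowwise_pearson(arrs[pair[0]], arrs[pair[1]])
    return pd.DataFrame(out)


def classify_conservation(corrs: pd.DataFrame) -> pd.DataFrame:
    """Assign each ortholog exactly one conservation class.

    Interval endpoints are closed.  Human-specific is evaluated first, then
    conserved, then primate-specific (whose own subtraction clause makes it
    residual); the human-specific intervals are disjoint from the positive
    ones, so precedence only orders the two positive rules.
    """
    r_mh = corrs[PAIR_COLUMNS[("monkey", "human")]].to_numpy()
    r_oh = corrs[PAIR_COLUMNS[("mouse", "human")]].to_numpy()
    r_mm = corrs[PAIR_COLUMNS[("monkey", "mouse")]].to_numpy()

    def in_hi(x):
        return (x >= 0.75) & (x <= 1.0)

    def in_lo(x):
        return (x >= -1.0) & (x <= -0.5)

    human = in_lo(r_mh) & in_lo(r_oh)
    conserved = in_hi(r_mh) & in_hi(r_mm) & ~human
    primate = in_hi(r_mh) & ~in_hi(r_oh) & ~in_hi(r_mm) & ~human & ~conserved
    label = np.select([human, conserved, primate],
                      ["human_specific", "conserved", "primate_specific"],
                      default="unclassified")
    label = np.where(np.isnan(r_mh) | np.isnan(r_oh) | np.isnan(r_mm),
                     "unclassified", label)
    out = corrs.copy()
    out["conservation_class"] = label
    return out


def correlation_distribution(corrs: pd.DataFrame, n_bins: int = 8) -> dict:
    """Histogram, cumulative curve, medians and pairwise KS over [-1, 1].

    Bins are fixed-width over [-1, 1] (default 8 bins of 0.25).  The KS
    entries compare the correlation distributions of the three species
    pairs with the two-sample Kolmogorov-Smirnov test.
    """
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    hist_rows, med = [], {}
    series = {}
    for pair, col in PAIR_COLUMNS.items():
        vals = corrs[col].dropna().to_numpy()
        if vals.size < 2:
            raise ValueError(f"<2 defined correlations for {col}")
        series[col] = vals
        counts, _ = np.histogram(vals, bins=edges)
        pct = counts / vals.size * 100.0
        cum = np.cumsum(pct)
        med[col] = float(np.median(vals))
        for i in range(n_bins):
            hist_rows.append((col, float(edges[i]), float(edges[i + 1]),
                              int(counts[i]), float(pct[i]), float(cum[i])))
    hist = pd.DataFrame(hist_rows, columns=["comparison", "bin_lo", "bin_hi",
                                            "count", "percent", "cumulative_percent"])
    ks_rows = []
    cols = list(PAIR_COLUMNS.values())
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            res = stats.ks_2samp(series[cols[i]], series[cols[j]])
            ks_rows.append((cols[i], cols[j], float(res.statistic), float(res.pvalue)))
    ks = pd.DataFrame(ks_rows, columns=["comparison_a", "comparison_b", "D", "p"])
    return {"histogram": hist, "medians": med, "ks": ks}


def family_correlations(panel: OrthologPanel, ann: AnnotationTable,
                        top_k: int = 5) -> pd.DataFrame:
    """Pairwise correlations of every member of the top-k most abundant
    protein families (ranked by summed abundance across species and regions).

    Heatmap-ready long table: one row per (family, ortholog) with the three
    pairwise correlations.  ``top_k`` beyond the number of annotated
    families returns all of them.
    """
    total = sum(panel.abundance[sp].sum(axis=1) for sp in SPECIES)
    fam_members: dict[str, list[str]] = {}
    for oid in panel.ortholog_ids:
        for fam in ann.families(oid):
            fam_members.setdefault(fam, []).append(oid)
    fam_abund = {f: float(total.loc[m].sum()) for f, m in fam_members.items()}
    top = sorted(fam_abund, key=lambda f: (-fam_abund[f], f))[:top_k]
    corrs = ortholog_correlations(panel).set_index("ortholog_id")
    rows = []
    for rank, fam in enumerate(top, start=1):
        for oid in fam_members[fam]:
            r = corrs.loc[oid]
            rows.append((fam, rank, fam_abund[fam], oid,
                         *[float(r[c]) for c in PAIR_COLUMNS.values()]))
    return pd.DataFrame(rows, columns=["family", "family_rank", "family_abundance",
                                       "ortholog_id", *PAIR_COLUMNS.values()])
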