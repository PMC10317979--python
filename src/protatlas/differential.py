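"""Differentially expressed protein (DEP) identification.

DEPs are called by a two-sided Student's t-test on log2 LFQ intensities,
one group versus the rest, with Bonferroni correction over the proteins
tested in that contrast; a protein is a DEP when the adjusted p-value is
below alpha (default 0.05).  Undetected entries are excluded (never entered
as zeros), and a protein is tested only when each side retains at least
``min_detected`` values.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import bonferroni, ttest_rows
from .core import STAGES, AbundanceMatrix, group_fold_changes

RESULT_COLUMNS = [
    "protein_id", "contrast", "group", "stage", "n_in", "n_out",
    "t", "p", "p_adj", "fold_change", "direction", "tested", "dep",
]


def _contrast(m: AbundanceMatrix, in_samples: Sequence[str], out_samples: Sequence[str],
              label: str, group: str, stage: str, alpha: float, min_detected: int,
              equal_var: bool) -> pd.DataFrame:
    log2 = m.log2
    a = log2.loc[:, list(in_samples)].to_numpy()
    b = log2.loc[:, list(out_samples)].to_numpy()
    na = (~np.isnan(a)).sum(axis=1)
    nb = (~np.isnan(b)).sum(axis=1)
    tested = (na >= min_detected) & (nb >= min_detected)
    t, p, _ = ttest_rows(a, b, equal_var=equal_var)
    t = np.where(tested, t, np.nan)
    p = np.where(tested, p, np.nan)
    family = int(tested.sum())
    p_adj = np.where(tested, bonferroni(p, family), np.nan)
    fc = group_fold_changes(m.lfq.loc[:, list(in_samples)].to_numpy(),
                            m.lfq.loc[:, list(out_samples)].to_numpy())
    direction = np.where(np.isnan(t), "na", np.where(t >= 0, "up", "down"))
    return pd.DataFrame({
        "protein_id": m.proteins,
        "contrast": label,
        "group": group,
        "stage": stage,
        "n_in": na,
        "n_out": nb,
        "t": t,
        "p": p,
        "p_adj": p_adj,
        "fold_change": fc,
        "direction": direction,
        "tested": tested,
        "dep": tested & (p_adj < alpha),
    })


def dep_region_vs_rest(m: AbundanceMatrix, stage: str, alpha: float = 0.05,
                       min_detected: int = 2, equal_var: bool = True) -> pd.DataFrame:
    """DEPs per region at one stage: each region versus all other same-stage
    samples.  Returns one long table over regions (untested proteins kept,
    flagged ``tested=False``)."""
    stage_samples = m.samples(stage=stage)
    if not stage_samples:
        raise ValueError(f"stage {stage!r} absent from matrix")
    sub = m.subset(stage_samples)
    frames = []
    for region in dict.fromkeys(sub.meta["region"]):
        in_s = sub.samples(region=region)
        out_s = [s for s in stage_samples if s not in set(in_s)]
        if not out_s:
            raise ValueError(f"region {region!r} is the only region at stage {stage}")
        frames.append(_contrast(sub, in_s, out_s, f"{region}-vs-rest@{stage}",
                                region, stage, alpha, min_detected, equal_var))
    return pd.concat(frames, ignore_index=True)


def dep_stage_vs_rest(m: AbundanceMatrix, macro_region: str | Sequence[str] | None = None,
                      exclude_region: str | Sequence[str] | None = "CB",
                      alpha: float = 0.05, min_detected: int = 2,
                      equal_var: bool = True) -> pd.DataFrame:
    """DEPs per stage, one stage versus all others, over a sample pool
    optionally restricted to a macro-region group and excluding regions
    (cerebellum by default, whose divergence would dominate)."""
    pool = m.samples(macro_region=macro_region, exclude_region=exclude_region)
    sub = m.subset(pool)
    stages = [s for s in STAGES if s in set(sub.meta["stage"])]
    if len(stages) < 2:
        raise ValueError("stage one-vs-rest needs at least two stages after filtering")
    full = {s for s in STAGES if s in set(m.meta["stage"])}
    if set(stages) != full:
        raise ValueError(f"grouping removed whole stage(s): {sorted(full - set(stages))}")
    frames = []
    for stage in stages:
        in_s = sub.samples(stage=stage)
        out_s = [s for s in pool if s not in set(in_s)]
        frames.append(_contrast(sub, in_s, out_s, f"{stage}-vs-rest",
                                stage, stage, alpha, min_detected, equal_var))
    return pd.concat(frames, ignore_index=True)


def dep_summary(stage_deps: pd.DataFrame, region_deps: pd.DataFrame) -> dict:
    """Venn-style union counts: proteins that are a DEP in any stage contrast
    versus any region contrast, and their intersection."""
    s = set(stage_deps.loc[stage_deps["dep"], "protein_id"])
    r = set(region_deps.loc[region_deps["dep"], "protein_id"])
    return {
        "n_stage_deps": len(s),
        "n_region_deps": len(r),
        "n_intersection": len(s & r),
        "n_stage_only": len(s - r),
        "n_region_only": len(r - s),
    }


def dep_counts_by_group(deps: pd.DataFrame) -> pd.DataFrame:
    """DEP counts per contrast group (region x stage or stage)."""
    out = (deps[deps["dep"]]
           .groupby(["stage", "group"], sort=False)["protein_id"]
           .nunique().rename("n_dep").reset_index())
    return out
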