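"""Intensity-weighted composition profiles.

For each sample, the share of a subcellular localization (or protein family)
is the summed LFQ intensity of the proteins carrying that label divided by
the total LFQ intensity of the sample, times 100.  Multi-label proteins
contribute fully to each of their labels, so profile sums can exceed 100%;
unannotated proteins stay in the denominator.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from ._stats import ttest_rows
from .core import STAGES, AbundanceMatrix, AnnotationTable


def composition_percent(m: AbundanceMatrix, ann: AnnotationTable,
                        scheme: str = "localization") -> pd.DataFrame:
    """Long table sample_id x category -> percent of total LFQ intensity."""
    totals = m.lfq.sum(axis=0)
    zero = totals.index[totals <= 0].tolist()
    if zero:
        raise ValueError(f"samples with zero total intensity: {zero}")
    store = ann.localization if scheme == "localization" else ann.family
    all_labels = sorted({lab for labels in store.values() for lab in labels})
    categories: dict[str, list[str]] = {lab: [] for lab in all_labels}
    for pid in m.proteins:
        for label in ann.labels(pid, scheme):
            categories[label].append(pid)
    rows = []
    for label in all_labels:
        members = categories[label]
        if members:
            share = m.lfq.loc[members].sum(axis=0) / totals * 100.0
        else:
            share = pd.Series(0.0, index=m.sample_ids)
        for sid, pct in share.items():
            rows.append((sid, label, float(pct)))
    df = pd.DataFrame(rows, columns=["sample_id", "category", "percent"])
    return df


def adjacent_stage_trend_test(profiles: pd.DataFrame, meta: pd.DataFrame,
                              group_by: str = "region", alpha: float = 0.05,
                              bonferroni_segments: bool = False) -> pd.DataFrame:
    """t-test of category percentages between adjacent stages within groups.

    Mirrors the solid/dashed line convention of trend plots: a category in a
    group is "significant" when at least one adjacent-stage segment differs
    at level alpha (raw two-sided t-test per segment by default; an optional
    Bonferroni over the segments of one category x group).

    Returns per-segment rows with t, p, significant, plus the segment count;
    aggregate with :func:`trend_flags` for the per-category flag.
    """
    merged = profiles.merge(meta[["stage", group_by]], left_on="sample_id", right_index=True)
    stages_present = [s for s in STAGES if s in set(merged["stage"])]
    segments = list(zip(stages_present, stages_present[1:]))
    rows = []
    for (cat, grp), sub in merged.groupby(["category", group_by], sort=True):
        by_stage = {s: sub.loc[sub["stage"] == s, "percent"].to_numpy() for s in stages_present}
        n_seg = 0
        seg_results = []
        for s0, s1 in segments:
            a, b = by_stage.get(s0, np.array([])), by_stage.get(s1, np.array([]))
            if len(a) < 2 or len(b) < 2:
                warnings.warn(f"segment {s0}->{s1} skipped for {cat}/{grp}: too few samples")
                continue
            n_seg += 1
            t, p, _ = ttest_rows(a[None, :], b[None, :])
            seg_results.append((s0, s1, float(t[0]), float(p[0])))
        m_corr = n_seg if bonferroni_segments else 1
        for s0, s1, t, p in seg_results:
            p_eff = min(1.0, p * m_corr)
            rows.append((cat, grp, f"{s0}->{s1}", t, p, p_eff, bool(p_eff < alpha)))
    return pd.DataFrame(rows, columns=["category", "group", "segment", "t", "p",
                                       "p_segment", "significant"])


def trend_flags(segment_tests: pd.DataFrame) -> pd.DataFrame:
    """Per category x group: True when any adjacent segment is significant
    (the 'solid line' flag)."""
    return (segment_tests.groupby(["category", "group"], sort=True)["significant"]
            .any().rename("any_significant_segment").reset_index())
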