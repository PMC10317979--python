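"""Temporal events: protein emergence, per-day rates of change, gene-set
trajectories and fuzzy c-means trend clustering.

A "new" protein at a stage transition is one with LFQ intensity 0 in every
sample of the earlier stage (within the region class) and detection at the
later stage, that additionally passes p < 0.05 and fold change > 1 in the
later-vs-earlier comparison.  Because the earlier group is all zeros, the
test and fold change are computed against the dataset's detection floor
(the smallest positive LFQ intensity observed); the floor used is reported
in the output.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from ._stats import ttest_rows
from .core import STAGES, AbundanceMatrix, AnnotationTable, GeneSetCollection, stage_index


def _adjacent(transition: tuple[str, str]) -> tuple[str, str]:
    s0, s1 = transition
    if stage_index(s1) != stage_index(s0) + 1:
        raise ValueError(f"transition {s0}->{s1} is not adjacent in stage order {STAGES}")
    return s0, s1


def call_new_proteins(m: AbundanceMatrix, transition: tuple[str, str],
                      region: str | Sequence[str] | None = None,
                      macro_region: str | Sequence[str] | None = None,
                      alpha: float = 0.05, fc_threshold: float = 1.0) -> pd.DataFrame:
    """Classify each protein as new / absent / continuing over a transition.

    Status per protein within the selected region class:

    - ``absent``: undetected at both stages;
    - ``new``: all earlier-stage intensities exactly 0, detected later, and
      the later-vs-earlier comparison passes p < alpha and FC > fc_threshold
      (earlier group placed at the detection floor);
    - ``lost``: detected earlier, all zero later;
    - ``continuing``: detected at both stages.
    """
    s0, s1 = _adjacent(transition)
    early = m.samples(stage=s0, region=region, macro_region=macro_region)
    late = m.samples(stage=s1, region=region, macro_region=macro_region)
    if not early or not late:
        raise ValueError(f"both stages of {s0}->{s1} must be present in the region class")
    floor = m.detection_floor
    lfq_e = m.lfq.loc[:, early].to_numpy()
    lfq_l = m.lfq.loc[:, late].to_numpy()
    det_e = (lfq_e > 0).any(axis=1)
    det_l = (lfq_l > 0).any(axis=1)
    # floored log2 for the emergence test: zeros at the detection floor
    a = np.log2(np.maximum(lfq_l, floor))
    b = np.log2(np.maximum(lfq_e, floor))
    t, p, _ = ttest_rows(a, b)
    fc = np.maximum(lfq_l, floor).mean(axis=1) / np.maximum(lfq_e, floor).mean(axis=1)
    candidate = ~det_e & det_l
    is_new = candidate & (p < alpha) & (fc > fc_threshold)
    status = np.where(~det_e & ~det_l, "absent",
                      np.where(candidate & is_new, "new",
                               np.where(candidate, "candidate_failed",
                                        np.where(det_e & ~det_l, "lost", "continuing"))))
    return pd.DataFrame({
        "protein_id": m.proteins,
        "transition": f"{s0}->{s1}",
        "status": status,
        "p": p,
        "fold_change": fc,
        "detection_floor": floor,
    })


def rate_of_change(m: AbundanceMatrix, transition: tuple[str, str],
                   proteins: Sequence[str] | None = None,
                   region: str | Sequence[str] | None = None,
                   macro_region: str | Sequence[str] | None = None) -> pd.DataFrame:
    """Per-day rate of log2 abundance change over a stage transition.

    (mean log2 at later stage - mean log2 at earlier stage) / days elapsed,
    per protein over detected entries; NaN when a stage has no detection.
    """
    s0, s1 = _adjacent(transition)
    days = m.stage_days()
    gap = days[s1] - days[s0]
    if gap == 0:
        raise ValueError(f"zero-day gap between {s0} and {s1}")
    early = m.samples(stage=s0, region=region, macro_region=macro_region)
    late = m.samples(stage=s1, region=region, macro_region=macro_region)
    sel = m.proteins if proteins is None else pd.Index(proteins)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        me = np.nanmean(m.log2.loc[sel, early].to_numpy(), axis=1)
        ml = np.nanmean(m.log2.loc[sel, late].to_numpy(), axis=1)
    return pd.DataFrame({
        "protein_id": sel,
        "transition": f"{s0}->{s1}",
        "delta_log2": ml - me,
        "days": gap,
        "rate_per_day": (ml - me) / gap,
    })


def set_trajectory(m: AbundanceMatrix, sets: GeneSetCollection, ann: AnnotationTable,
                   region: str | Sequence[str] | None = None,
                   macro_region: str | Sequence[str] | None = None,
                   alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summed member abundance per sample, averaged per stage, per gene set.

    Gene symbols are mapped to proteins through the annotation.  Returns
    (trajectory table with mean/sd per stage, adjacent-segment t-test table
    carrying the solid/dashed significance flag).  Empty mapped sets are
    skipped with a warning.
    """
    pool = m.samples(region=region, macro_region=macro_region)
    sub = m.subset(pool)
    by_gene = ann.proteins_for_gene()
    stages = [s for s in STAGES if s in set(sub.meta["stage"])]
    traj_rows, seg_rows = [], []
    for name, genes in sets.items():
        members = sorted({p for g in genes for p in by_gene.get(g, []) if p in set(sub.proteins)})
        if not members:
            warnings.warn(f"gene set {name!r} maps to no protein; skipped")
            continue
        per_sample = sub.lfq.loc[members].sum(axis=0)
        by_stage = {s: per_sample[sub.samples(stage=s)].to_numpy() for s in stages}
        for s in stages:
            v = by_stage[s]
            traj_rows.append((name, s, len(members), float(v.mean()),
                              float(v.std(ddof=1)) if len(v) > 1 else float("nan"), len(v)))
        for s0, s1 in zip(stages, stages[1:]):
            a, b = by_stage[s0], by_stage[s1]
            if len(a) < 2 or len(b) < 2:
                continue
            t, p, _ = ttest_rows(a[None, :], b[None, :])
            seg_rows.append((name, f"{s0}->{s1}", float(t[0]), float(p[0]),
                             bool(p[0] < alpha)))
    traj = pd.DataFrame(traj_rows, columns=["set_name", "stage", "n_proteins",
                                            "mean_abundance", "sd", "n_samples"])
    seg = pd.DataFrame(seg_rows, columns=["set_name", "segment", "t", "p", "significant"])
    return traj, seg


# ---------------------------------------------------------------------------
# Fuzzy c-means trend clustering
# ---------------------------------------------------------------------------

def stage_mean_trajectories(m: AbundanceMatrix, standardize: bool = True,
                            region: str | Sequence[str] | None = None,
                            macro_region: str | Sequence[str] | None = None) -> pd.DataFrame:
    """Proteins x stages table of mean log2 abundance (z-scored per protein).

    Proteins undetected at any stage (no stage mean) are dropped; constant
    trajectories are dropped when standardizing (no trend to cluster)."""
    pool = m.samples(region=region, macro_region=macro_region)
    sub = m.subset(pool)
    stages = [s for s in STAGES if s in set(sub.meta["stage"])]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cols = {s: np.nanmean(sub.log2.loc[:, sub.samples(stage=s)].to_numpy(), axis=1)
                for s in stages}
    traj = pd.DataFrame(cols, index=sub.proteins)
    traj = traj.dropna()
    if standardize:
        sd = traj.std(axis=1, ddof=0)
        traj = traj[sd > 0]
        traj = traj.sub(traj.mean(axis=1), axis=0).div(traj.std(axis=1, ddof=0), axis=0)
    return traj


def fuzzy_cmeans(x: np.ndarray, c: int, fuzzifier: float = 2.0, tol: float = 1e-6,
                 max_iter: int = 500, seed: int = 0, init: np.ndarray | None = None):
    """Fuzzy c-means on rows of ``x``.

    Standard alternating optimization of the objective
    J = sum_ik u_ik^m ||x_i - v_k||^2 with membership exponent m > 1.
    Centroids are initialized from c distinct data rows drawn with a seeded
    generator unless ``init`` supplies explicit starting centroids.
    Returns (centroids, memberships, objective_history).
    """
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if n < c:
        raise ValueError(f"need at least c={c} profiles, got {n}")
    if init is not None:
        v = np.array(init, dtype=float)
        if v.shape != (c, x.shape[1]):
            raise ValueError(f"init must have shape ({c}, {x.shape[1]})")
    else:
        rng = np.random.default_rng(seed)
        # prefer distinct rows as initial centroids
        idx = rng.permutation(n)
        chosen: list[int] = []
        seen = set()
        for i in idx:
            key = tuple(np.round(x[i], 12))
            if key not in seen:
                seen.add(key)
                chosen.append(i)
            if len(chosen) == c:
                break
        if len(chosen) < c:
            raise ValueError(f"fewer than c={c} distinct profiles")
        v = x[chosen].copy()
    expo = 2.0 / (fuzzifier - 1.0)
    history = []
    u = None
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - v[None, :, :]) ** 2).sum(axis=2)
        d2 = np.maximum(d2, 1e-300)
        # normalize by the row minimum so large exponents cannot overflow
        ratio = d2 / d2.min(axis=1, keepdims=True)
        inv = ratio ** (-expo / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
        # exact-hit rows: put full membership on the matching centroid
        hits = d2 < 1e-24
        if hits.any():
            rows = hits.any(axis=1)
            u[rows] = hits[rows] / hits[rows].sum(axis=1, keepdims=True)
        um = u**fuzzifier
        v_new = (um.T @ x) / um.sum(axis=0)[:, None]
        j = float((um * d2).sum())
        history.append(j)
        shift = np.abs(v_new - v).max()
        v = v_new
        if shift < tol:
            break
    return v, u, history


def fuzzy_cmeans_trends(m: AbundanceMatrix, c: int = 4, fuzzifier: float = 2.0,
                        tol: float = 1e-6, max_iter: int = 500, seed: int = 0,
                        **traj_kwargs):
    """Cluster standardized stage-mean trajectories into ``c`` fuzzy trends.

    Returns (membership DataFrame with hard ``cluster`` labels, centroid
    DataFrame over stages, objective history).
    """
    traj = stage_mean_trajectories(m, **traj_kwargs)
    if traj.shape[1] < 2:
        raise ValueError("need at least two stages to cluster trends")
    v, u, history = fuzzy_cmeans(traj.to_numpy(), c, fuzzifier, tol, max_iter, seed)
    memb = pd.DataFrame(u, index=traj.index,
                        columns=[f"cluster_{k}" for k in range(c)])
    memb["cluster"] = u.argmax(axis=1)
    centroids = pd.DataFrame(v, columns=traj.columns,
                             index=[f"cluster_{k}" for k in range(c)])
    return memb, centroids, history
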