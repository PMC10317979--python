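"""One-vs-rest ROC-AUC marker protein detection.

A protein is a marker of a class (a stage, the cerebellum, cortical vs
subcortical, ...) when its one-vs-rest area under the ROC curve exceeds 0.7
and its linear fold change (class over rest, detected entries only) exceeds
1.  The AUC uses the Mann-Whitney construction: the fraction of (in, out)
value pairs where the in-class value wins, ties counting half.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .core import AbundanceMatrix, group_fold_changes

AUC_THRESHOLD = 0.7
FC_THRESHOLD = 1.0


def auc_one_vs_rest(values_in, values_out) -> float:
    """Mann-Whitney AUC of ``values_in`` against ``values_out``.

    NaNs are excluded.  Returns NaN when either group is empty after
    exclusion.  Equivalent to (#{a>b} + 0.5#{a=b}) / (n_in * n_out) over all
    cross pairs, computed via average ranks.
    """
    a = np.asarray(values_in, dtype=float)
    b = np.asarray(values_out, dtype=float)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        return float("nan")
    ranks = rankdata(np.concatenate([a, b]))
    u = ranks[: a.size].sum() - a.size * (a.size + 1) / 2.0
    return float(u / (a.size * b.size))


def _auc_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise AUC with per-row NaN exclusion."""
    out = np.empty(a.shape[0])
    for i in range(a.shape[0]):
        out[i] = auc_one_vs_rest(a[i], b[i])
    return out


def find_markers(
    m: AbundanceMatrix,
    classes: Mapping[str, Sequence[str]] | str,
    auc_threshold: float = AUC_THRESHOLD,
    fc_threshold: float = FC_THRESHOLD,
    min_detected: int = 2,
    log2_fc: bool = False,
) -> pd.DataFrame:
    """Score every protein for every class, one versus rest.

    Parameters
    ----------
    classes
        Either a metadata column name (``"stage"``, ``"region"``,
        ``"macro_region"``) whose values partition the samples, or an
        explicit mapping of class label to sample ids.
    log2_fc
        When True the fold-change threshold is applied on the log2 scale
        (ratio > 2**fc_threshold) instead of the linear ratio.

    Returns a long DataFrame with auc, fold_change, the marker flag and the
    per-class rank (AUC desc, fold change desc, protein id asc).  Classes
    with fewer than 2 samples are skipped with a warning.  A protein must be
    detected in at least ``min_detected`` class samples to be a candidate.
    """
    if isinstance(classes, str):
        col = m.meta[classes]
        class_map = {lab: m.meta.index[col == lab].tolist() for lab in dict.fromkeys(col)}
    else:
        class_map = {k: list(v) for k, v in classes.items()}
    log2 = m.log2
    frames = []
    for label, in_samples in class_map.items():
        if len(in_samples) < 2:
            warnings.warn(f"class {label!r} has <2 samples; skipped")
            continue
        in_set = set(in_samples)
        out_samples = [s for s in m.sample_ids if s not in in_set]
        if not out_samples:
            warnings.warn(f"class {label!r} covers all samples; skipped")
            continue
        a = log2.loc[:, in_samples].to_numpy()
        b = log2.loc[:, out_samples].to_numpy()
        auc = _auc_rows(a, b)
        fc = group_fold_changes(m.lfq.loc[:, in_samples].to_numpy(),
                                m.lfq.loc[:, out_samples].to_numpy())
        n_det_in = (~np.isnan(a)).sum(axis=1)
        eligible = n_det_in >= min_detected
        cut = 2.0**fc_threshold if log2_fc else fc_threshold
        with np.errstate(invalid="ignore"):
            is_marker = eligible & (auc > auc_threshold) & (fc > cut)
        df = pd.DataFrame({
            "protein_id": m.proteins,
            "class": label,
            "n_in": len(in_samples),
            "n_detected_in": n_det_in,
            "auc": auc,
            "fold_change": fc,
            "marker": np.where(np.isnan(auc) | np.isnan(fc), False, is_marker),
        })
        df = df.sort_values(["auc", "fold_change", "protein_id"],
                            ascending=[False, False, True], na_position="last",
                            kind="mergesort").reset_index(drop=True)
        df["rank"] = np.arange(1, len(df) + 1)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["protein_id", "class", "n_in", "n_detected_in",
                                     "auc", "fold_change", "marker", "rank"])
    return pd.concat(frames, ignore_index=True)


def top_marker_matrix(m: AbundanceMatrix, markers: pd.DataFrame, top_n: int = 10,
                      by: str = "stage") -> pd.DataFrame:
    """Class x protein table of mean z-scored log2 intensity for the top-n
    markers of each class (heatmap-ready)."""
    chosen: list[str] = []
    for label, sub in markers[markers["marker"]].groupby("class", sort=False):
        chosen.extend(sub.nsmallest(top_n, "rank")["protein_id"].tolist())
    chosen = list(dict.fromkeys(chosen))
    log2 = m.log2.loc[chosen]
    z = log2.sub(log2.mean(axis=1), axis=0).div(log2.std(axis=1, ddof=0).replace(0, np.nan), axis=0)
    groups = m.meta[by]
    out = {lab: z.loc[:, groups.index[groups == lab]].mean(axis=1)
           for lab in dict.fromkeys(groups)}
    return pd.DataFrame(out).T
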