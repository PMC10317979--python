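"""Inter-regional dynamics: dissimilarity statistics, cerebellum distances,
stage correlations and PCA of the sample space.

The inter-regional difference of a macro-region group at one stage is the
mean absolute difference of log2 LFQ intensities over proteins detected in
both members of a sample pair, averaged over all cross-region pairs in the
group.  Cerebellum divergence is summarized as the Euclidean distance
between mean log2 profiles over shared detected proteins.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import STAGES, AbundanceMatrix


@dataclass
class InterRegionalDifference:
    stage: str
    group: str
    value: float
    n_pairs: int


def inter_regional_difference(m: AbundanceMatrix, stage: str, group: str,
                              include_same_region: bool = False) -> InterRegionalDifference:
    """Mean absolute log2 difference over cross-region sample pairs.

    Pairs within the same region (biological/technical replicates) are
    excluded by default — the statistic is inter-regional.  When the group
    holds a single region (cerebellum), it falls back to all pairs with a
    warning, reproducing replicate-based values.
    """
    samples = m.samples(stage=stage, macro_region=group)
    if len(samples) < 2:
        raise ValueError(f"group {group!r} at stage {stage!r} has <2 samples")
    sub = m.subset(samples)
    regions = sub.meta["region"]
    log2 = sub.log2.to_numpy()
    cols = {s: i for i, s in enumerate(sub.sample_ids)}
    pairs = [
        (a, b) for a, b in itertools.combinations(samples, 2)
        if include_same_region or regions[a] != regions[b]
    ]
    if not pairs:
        warnings.warn(
            f"group {group!r} at {stage!r} has one region; falling back to all sample pairs")
        pairs = list(itertools.combinations(samples, 2))
    vals = []
    for a, b in pairs:
        xa, xb = log2[:, cols[a]], log2[:, cols[b]]
        shared = ~np.isnan(xa) & ~np.isnan(xb)
        if not shared.any():
            continue
        vals.append(np.abs(xa[shared] - xb[shared]).mean())
    if not vals:
        raise ValueError(f"no shared detected proteins in any pair for {group}@{stage}")
    return InterRegionalDifference(stage=stage, group=group,
                                   value=float(np.mean(vals)), n_pairs=len(vals))


def inter_regional_curve(m: AbundanceMatrix, groups=("CB", "CTX", "sCTX"),
                         include_same_region: bool = False) -> pd.DataFrame:
    """Inter-regional difference for every stage x macro-region group present."""
    rows = []
    for stage in [s for s in STAGES if s in set(m.meta["stage"])]:
        for group in groups:
            if not m.samples(stage=stage, macro_region=group):
                continue
            try:
                r = inter_regional_difference(m, stage, group, include_same_region)
            except ValueError:
                continue
            rows.append((r.stage, r.group, r.value, r.n_pairs))
    return pd.DataFrame(rows, columns=["stage", "group", "value", "n_pairs"])


def _mean_log2_profile(m: AbundanceMatrix, samples) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(m.log2.loc[:, list(samples)].to_numpy(), axis=1)


def cb_distance(m: AbundanceMatrix, stage: str, reference_region: str = "CB") -> pd.DataFrame:
    """Euclidean distance of the reference region's mean log2 profile to each
    other region at the stage, over proteins detected in both profiles."""
    ref_samples = m.samples(stage=stage, region=reference_region)
    if not ref_samples:
        raise ValueError(f"region {reference_region!r} absent at stage {stage!r}")
    ref = _mean_log2_profile(m, ref_samples)
    rows = []
    stage_meta = m.meta[m.meta["stage"] == stage]
    for region in dict.fromkeys(stage_meta["region"]):
        if region == reference_region:
            continue
        prof = _mean_log2_profile(m, m.samples(stage=stage, region=region))
        shared = ~np.isnan(ref) & ~np.isnan(prof)
        if not shared.any():
            raise ValueError(f"no shared detected proteins between {reference_region} and {region}")
        d = float(np.sqrt(np.sum((ref[shared] - prof[shared]) ** 2)))
        rows.append((stage, region, d, int(shared.sum())))
    return pd.DataFrame(rows, columns=["stage", "region", "distance", "n_shared"])


def stage_correlation(m: AbundanceMatrix) -> pd.DataFrame:
    """Pearson correlation between mean stage profiles, pairwise-complete.

    Replicates are averaged into one mean log2 profile per stage first; the
    correlation of a stage pair is computed over proteins detected in both
    stage profiles, with the two-sided p-value of the correlation test.
    """
    stages = [s for s in STAGES if s in set(m.meta["stage"])]
    profiles = {s: _mean_log2_profile(m, m.samples(stage=s)) for s in stages}
    rows = []
    for s0 in stages:
        for s1 in stages:
            a, b = profiles[s0], profiles[s1]
            shared = ~np.isnan(a) & ~np.isnan(b)
            if shared.sum() < 3:
                raise ValueError(f"<3 shared proteins between stages {s0} and {s1}")
            aa, bb = a[shared], b[shared]
            if np.ptp(aa) == 0 or np.ptp(bb) == 0:
                r, p = float("nan"), float("nan")
            elif s0 == s1:
                r, p = 1.0, 0.0
            else:
                res = stats.pearsonr(aa, bb)
                r, p = float(res.statistic), float(res.pvalue)
            rows.append((s0, s1, r, p, int(shared.sum())))
    return pd.DataFrame(rows, columns=["stage_a", "stage_b", "r", "p", "n_shared"])


def pca_scores(m: AbundanceMatrix, n_components: int = 2,
               scale: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA (SVD) of samples on complete-case log2 proteins.

    Only proteins detected in every sample enter (no imputation).  Returns
    (scores DataFrame indexed by sample, explained-variance fractions).
    """
    log2 = m.log2.to_numpy()
    complete = ~np.isnan(log2).any(axis=1)
    x = log2[complete].T  # samples x proteins
    if x.shape[1] < n_components:
        raise ValueError(
            f"only {x.shape[1]} complete-case proteins; need >= {n_components}")
    x = x - x.mean(axis=0, keepdims=True)
    if scale:
        sd = x.std(axis=0, ddof=1)
        x = x / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :n_components] * s[:n_components]
    var = s**2 / (x.shape[0] - 1)
    frac = var / var.sum()
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return (pd.DataFrame(scores, index=m.sample_ids, columns=cols), frac[:n_components])
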