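"""Core data model and shared transforms for LFQ proteomic atlases.

The central container is :class:`AbundanceMatrix`: a proteins x samples table
of label-free quantification (LFQ) intensities together with per-sample
metadata (developmental stage, brain region, macro-region, animal, day
post-fertilization).  An LFQ intensity of exactly 0 means the protein was not
detected in that sample; every derived statistic treats such entries as
missing, never as a measured zero abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Developmental stages in chronological order: three fetal time points
#: (days post-fertilization) and one postnatal (3 days after birth).
STAGES: tuple[str, ...] = ("F50", "F90", "F120", "P3")

#: Default day-post-fertilization per stage.  Gestation is ~150 days, so the
#: postnatal P3 stage sits at 153 days on the same clock.
DEFAULT_STAGE_DAYS: dict[str, int] = {"F50": 50, "F90": 90, "F120": 120, "P3": 153}

#: Macro-region groups: cerebellum, cortex, subcortical tissue.
MACRO_REGIONS: tuple[str, ...] = ("CTX", "sCTX", "CB")

_SUBCORTICAL = frozenset({"STr", "Hipp", "MD", "Amy"})

#: Region layout per stage mirroring the sampling design of a fetal macaque
#: brain atlas: 5 regions at F50, 11 at F90, 18 at F120 and P3.
DEFAULT_STAGE_REGIONS: dict[str, tuple[str, ...]] = {
    "F50": ("PFC", "TL", "PL", "V1", "CB"),
    "F90": ("aPFC", "pPFC", "IC", "M1", "TL", "PL", "V1", "CB", "STr", "Hipp", "Amy"),
    "F120": (
        "sPFG", "mPFG", "iPFG", "OFC", "IC", "M1", "aCG", "sTG", "mTG", "iTG",
        "S1", "sPL", "V1", "CB", "STr", "Hipp", "MD", "Amy",
    ),
    "P3": (
        "sPFG", "mPFG", "iPFG", "OFC", "IC", "M1", "aCG", "sTG", "mTG", "iTG",
        "S1", "sPL", "V1", "CB", "STr", "Hipp", "MD", "Amy",
    ),
}

META_COLUMNS = ("stage", "day", "region", "macro_region", "animal_id", "replicate_kind")


def stage_index(stage: str) -> int:
    """Position of ``stage`` in chronological order; raises on unknown stage."""
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


def macro_region_of(region: str) -> str:
    """Map a region code to its macro-region (CB, sCTX, or CTX)."""
    if region == "CB":
        return "CB"
    if region in _SUBCORTICAL:
        return "sCTX"
    return "CTX"


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample-metadata table indexed by sample_id."""
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata missing required columns: {missing}")
    if meta.index.has_duplicates:
        dupes = meta.index[meta.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids in metadata: {dupes}")
    bad_stage = set(meta["stage"]) - set(STAGES)
    if bad_stage:
        raise ValueError(f"unknown stages in metadata: {sorted(bad_stage)}")
    bad_macro = set(meta["macro_region"]) - set(MACRO_REGIONS)
    if bad_macro:
        raise ValueError(f"unknown macro regions: {sorted(bad_macro)}")
    # day must respect chronological stage order
    day_by_stage = meta.groupby("stage")["day"].first()
    present = [s for s in STAGES if s in day_by_stage.index]
    days = [day_by_stage[s] for s in present]
    if any(b <= a for a, b in zip(days, days[1:])):
        raise ValueError(f"stage days not strictly increasing over {present}: {days}")
    return meta


@dataclass
class AbundanceMatrix:
    """Proteins x samples LFQ intensity matrix plus sample metadata.

    Parameters
    ----------
    lfq
        DataFrame of non-negative intensities, rows indexed by protein id,
        columns by sample id.  0 encodes non-detection.
    meta
        DataFrame indexed by sample id with columns ``stage``, ``day``,
        ``region``, ``macro_region``, ``animal_id``, ``replicate_kind``,
        ordered identically to the matrix columns.
    """

    lfq: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.lfq.columns) != list(self.meta.index):
            extra = set(self.lfq.columns) - set(self.meta.index)
            if extra:
                raise ValueError(f"matrix samples missing from metadata: {sorted(extra)}")
            # same set, different order: align matrix to metadata order
            self.lfq = self.lfq.loc[:, self.meta.index]
        validate_meta(self.meta)
        vals = self.lfq.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("LFQ matrix contains NaN; undetected entries must be 0")
        if (vals < 0).any():
            bad = self.lfq.columns[(vals < 0).any(axis=0)].tolist()
            raise ValueError(f"negative LFQ intensities in samples {bad}")

    # -- basic views ------------------------------------------------------

    @property
    def proteins(self) -> pd.Index:
        return self.lfq.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.lfq.columns

    @property
    def n_proteins(self) -> int:
        return self.lfq.shape[0]

    @property
    def n_samples(self) -> int:
        return self.lfq.shape[1]

    @property
    def detected(self) -> pd.DataFrame:
        """Boolean detection mask: LFQ intensity > 0."""
        return self.lfq > 0

    @property
    def log2(self) -> pd.DataFrame:
        """log2 LFQ with undetected entries as NaN."""
        with np.errstate(divide="ignore"):
            arr = np.log2(self.lfq.to_numpy(dtype=float))
        arr[~(self.lfq.to_numpy() > 0)] = np.nan
        return pd.DataFrame(arr, index=self.lfq.index, columns=self.lfq.columns)

    @property
    def detection_floor(self) -> float:
        """Smallest positive LFQ intensity in the dataset."""
        vals = self.lfq.to_numpy()
        pos = vals[vals > 0]
        if pos.size == 0:
            raise ValueError("matrix contains no detected entry")
        return float(pos.min())

    # -- sample selection -------------------------------------------------

    def samples(
        self,
        stage: str | Sequence[str] | None = None,
        region: str | Sequence[str] | None = None,
        macro_region: str | Sequence[str] | None = None,
        exclude_region: str | Sequence[str] | None = None,
    ) -> list[str]:
        """Sample ids matching the given metadata filters (AND-combined)."""

        def _as_set(x):
            return {x} if isinstance(x, str) else set(x)

        mask = pd.Series(True, index=self.meta.index)
        if stage is not None:
            mask &= self.meta["stage"].isin(_as_set(stage))
        if region is not None:
            mask &= self.meta["region"].isin(_as_set(region))
        if macro_region is not None:
            mask &= self.meta["macro_region"].isin(_as_set(macro_region))
        if exclude_region is not None:
            mask &= ~self.meta["region"].isin(_as_set(exclude_region))
        return self.meta.index[mask].tolist()

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceMatrix":
        """New matrix restricted to the given samples, order preserved."""
        ids = list(sample_ids)
        missing = set(ids) - set(self.sample_ids)
        if missing:
            raise KeyError(f"unknown samples: {sorted(missing)}")
        return AbundanceMatrix(self.lfq.loc[:, ids].copy(), self.meta.loc[ids].copy())

    def stage_days(self) -> dict[str, int]:
        return {s: int(self.meta.loc[self.meta["stage"] == s, "day"].iloc[0])
                for s in STAGES if (self.meta["stage"] == s).any()}


def fold_change(values_a: np.ndarray, values_b: np.ndarray) -> float:
    """Linear-scale fold change: mean detected LFQ of A over mean detected of B.

    Undetected entries (LFQ == 0) are excluded from both means.  Returns NaN
    (the "undefined" flag) when either side has no detected value.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a = a[a > 0]
    b = b[b > 0]
    if a.size == 0 or b.size == 0:
        return float("nan")
    return float(a.mean() / b.mean())


def group_fold_changes(lfq_a: np.ndarray, lfq_b: np.ndarray) -> np.ndarray:
    """Row-wise fold change (A over B) on detected entries; NaN where undefined."""
    lfq_a = np.asarray(lfq_a, dtype=float)
    lfq_b = np.asarray(lfq_b, dtype=float)
    det_a = lfq_a > 0
    det_b = lfq_b > 0
    na = det_a.sum(axis=1)
    nb = det_b.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_a = np.where(det_a, lfq_a, 0.0).sum(axis=1) / na
        mean_b = np.where(det_b, lfq_b, 0.0).sum(axis=1) / nb
        fc = mean_a / mean_b
    fc[(na == 0) | (nb == 0)] = np.nan
    return fc


@dataclass
class AnnotationTable:
    """Protein annotations: gene symbol, subcellular localization, family.

    Lookups on unknown proteins return empty values rather than raising, so
    sparsely annotated datasets flow through every analysis.
    """

    gene_symbol: dict[str, str] = field(default_factory=dict)
    localization: dict[str, frozenset[str]] = field(default_factory=dict)
    family: dict[str, frozenset[str]] = field(default_factory=dict)

    def gene(self, protein_id: str) -> str | None:
        return self.gene_symbol.get(protein_id)

    def localizations(self, protein_id: str) -> frozenset[str]:
        return self.localization.get(protein_id, frozenset())

    def families(self, protein_id: str) -> frozenset[str]:
        return self.family.get(protein_id, frozenset())

    def labels(self, protein_id: str, scheme: str) -> frozenset[str]:
        if scheme == "localization":
            return self.localizations(protein_id)
        if scheme == "family":
            return self.families(protein_id)
        raise ValueError(f"unknown annotation scheme {scheme!r}")

    def proteins_for_gene(self) -> dict[str, list[str]]:
        """Inverse map gene symbol -> protein ids."""
        out: dict[str, list[str]] = {}
        for pid, g in self.gene_symbol.items():
            out.setdefault(g, []).append(pid)
        return out


@dataclass
class GeneSetCollection:
    """Named gene sets (GO-style processes, disease lists) keyed by symbol."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        empty = [k for k, v in self.sets.items() if not v]
        if empty:
            raise ValueError(f"empty gene sets: {empty}")
        self.sets = {k: frozenset(v) for k, v in self.sets.items()}
        if self.universe is not None:
            self.universe = frozenset(self.universe)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def items(self):
        return self.sets.items()
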