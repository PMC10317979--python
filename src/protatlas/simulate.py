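"""Synthetic LFQ atlas, ortholog panel and RNA/protein pair generators.

Every generator plants known structure and returns a truth ledger alongside
the data, so each downstream analysis can be validated by recovery of the
planted memberships.  Defaults emulate the sampling design of a fetal
macaque brain atlas: four stages (F50, F90, F120, P3) with 5/11/18/18
regions and three biological replicates per region and stage; log-normal
LFQ intensities (Gaussian on the log2 scale); zero-inflated detection where
an intensity of 0 means "not detected".
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_STAGE_DAYS,
    DEFAULT_STAGE_REGIONS,
    STAGES,
    AbundanceMatrix,
    AnnotationTable,
    GeneSetCollection,
    macro_region_of,
    stage_index,
)
from .cross_species import DEFAULT_REGIONS as ORTHOLOG_REGIONS
from .cross_species import OrthologPanel

LOCALIZATIONS = ("Nucleus", "Cytosol", "Mitochondria", "ER", "Golgi",
                 "PlasmaMembrane", "Vesicles", "Cytoskeleton")
FAMILIES = ("Kinase", "Tubulin", "Ribosomal", "Proteasome", "HSP", "Myelin")


@dataclass
class SimConfig:
    """Parameters of the synthetic atlas.

    The log2 intensity of protein p in sample s is
    ``baseline_p + stage_effect_{p,stage(s)} + scale_stage * region_effect_{p,region(s)} + noise``,
    with every effect drawn Gaussian.  Planted markers receive an additive
    log2 shift in their target class; planted emergent proteins are forced
    to 0 before their onset stage.  ``dropout`` zeroes entries at random
    (intensity-independent unless ``dropout_logistic_scale`` is set).
    """

    n_proteins: int = 1000
    stage_regions: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_REGIONS))
    replicates: int = 3
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    stage_effect_sd: float = 0.6
    region_effect_sd: float = 0.3
    region_scale_by_stage: Mapping[str, float] | None = None
    noise_sd: float = 0.5
    dropout: float = 0.1
    dropout_logistic_scale: float | None = 0.5
    n_stage_markers: int = 20
    n_macro_markers: int = 10
    marker_shift: float = 2.0
    n_emergent_per_transition: int = 15
    stage_days: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_STAGE_DAYS))
    cb_f90_technical: bool = False
    n_background_sets: int = 10
    background_set_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.replicates <= 0:
            raise ValueError("counts must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        stages = [s for s in STAGES if s in self.stage_regions]
        n_transitions = max(len(stages) - 1, 0)
        planted = (self.n_stage_markers * len(stages)
                   + self.n_macro_markers * 3
                   + self.n_emergent_per_transition * n_transitions)
        if planted > self.n_proteins:
            raise ValueError(
                f"{planted} planted proteins exceed n_proteins={self.n_proteins}")

    @property
    def stages(self) -> list[str]:
        return [s for s in STAGES if s in self.stage_regions]


def null_config(**overrides) -> SimConfig:
    """A no-signal configuration: no effects, no plants, no dropout."""
    base = dict(stage_effect_sd=0.0, region_effect_sd=0.0, dropout=0.0,
                n_stage_markers=0, n_macro_markers=0, n_emergent_per_transition=0)
    base.update(overrides)
    return SimConfig(**base)


@dataclass
class AtlasSim:
    """Bundle returned by :func:`simulate_atlas`."""

    matrix: AbundanceMatrix
    ledger: pd.DataFrame
    annotation: AnnotationTable
    gene_sets: GeneSetCollection


def _build_meta(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for stage in cfg.stages:
        day = cfg.stage_days[stage]
        for region in cfg.stage_regions[stage]:
            if cfg.cb_f90_technical and stage == "F90" and region == "CB":
                for animal in (1, 2):
                    for tech in (1, 2, 3):
                        rows.append((f"{stage}_{region}_A{animal}T{tech}", stage, day,
                                     region, macro_region_of(region),
                                     f"{stage}_A{animal}", "technical"))
                continue
            for rep in range(1, cfg.replicates + 1):
                rows.append((f"{stage}_{region}_R{rep}", stage, day, region,
                             macro_region_of(region), f"{stage}_A{rep}", "biological"))
    meta = pd.DataFrame(rows, columns=["sample_id", "stage", "day", "region",
                                       "macro_region", "animal_id", "replicate_kind"])
    return meta.set_index("sample_id")


def simulate_annotation(proteins, seed: int, multi_label_rate: float = 0.0) -> AnnotationTable:
    """Gene symbols (1:1), a localization and a family label per protein.

    ``multi_label_rate`` is the fraction of proteins given a second
    localization, exercising the multi-label composition convention.
    """
    rng = np.random.default_rng(seed)
    gene, loc, fam = {}, {}, {}
    for i, pid in enumerate(proteins):
        gene[pid] = f"GENE{i:05d}"
        labels = {LOCALIZATIONS[rng.integers(len(LOCALIZATIONS))]}
        if rng.random() < multi_label_rate:
            labels.add(LOCALIZATIONS[rng.integers(len(LOCALIZATIONS))])
        loc[pid] = frozenset(labels)
        fam[pid] = frozenset({FAMILIES[rng.integers(len(FAMILIES))]})
    return AnnotationTable(gene_symbol=gene, localization=loc, family=fam)


def simulate_atlas(cfg: SimConfig) -> AtlasSim:
    """Generate the synthetic atlas, its truth ledger, annotation and GMT.

    The ledger has one row per planted protein: role (``marker`` or
    ``emergent``), the class kind and label (stage / macro-region /
    transition) and the planted shift or onset.  Planted roles are disjoint.
    """
    rng = np.random.default_rng(cfg.seed)
    meta = _build_meta(cfg)
    n_s = len(meta)
    proteins = pd.Index([f"P{i:05d}" for i in range(cfg.n_proteins)], name="protein_id")

    stages = cfg.stages
    all_regions = list(dict.fromkeys(r for s in stages for r in cfg.stage_regions[s]))
    stage_of = meta["stage"].to_numpy()
    stage_idx = np.array([stages.index(s) for s in stage_of])
    region_idx = np.array([all_regions.index(r) for r in meta["region"]])
    scale = np.array([(cfg.region_scale_by_stage or {}).get(s, 1.0) for s in stage_of])

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)
    stage_eff = rng.normal(0.0, cfg.stage_effect_sd, size=(cfg.n_proteins, len(stages)))
    region_eff = rng.normal(0.0, cfg.region_effect_sd, size=(cfg.n_proteins, len(all_regions)))
    noise = rng.normal(0.0, cfg.noise_sd, size=(cfg.n_proteins, n_s))

    log2 = (baseline[:, None] + stage_eff[:, stage_idx]
            + region_eff[:, region_idx] * scale[None, :] + noise)

    # --- plant structure on disjoint protein blocks -----------------------
    pool = rng.permutation(cfg.n_proteins)
    cursor = 0
    ledger_rows = []

    def _take(n):
        nonlocal cursor
        block = pool[cursor:cursor + n]
        cursor += n
        return block

    macro_of = meta["macro_region"].to_numpy()
    for stage in stages:
        idx = _take(cfg.n_stage_markers)
        cols = stage_of == stage
        log2[np.ix_(idx, cols)] += cfg.marker_shift
        for i in idx:
            ledger_rows.append((proteins[i], "marker", "stage", stage, cfg.marker_shift, ""))
    for macro in ("CTX", "sCTX", "CB"):
        idx = _take(cfg.n_macro_markers)
        cols = macro_of == macro
        if cols.any():
            log2[np.ix_(idx, cols)] += cfg.marker_shift
        for i in idx:
            ledger_rows.append((proteins[i], "marker", "macro_region", macro,
                                cfg.marker_shift, ""))

    emergent_zero = np.zeros((cfg.n_proteins, n_s), dtype=bool)
    for s_prev, s_next in zip(stages, stages[1:]):
        idx = _take(cfg.n_emergent_per_transition)
        before = stage_idx < stages.index(s_next)
        emergent_zero[np.ix_(idx, before)] = True
        for i in idx:
            ledger_rows.append((proteins[i], "emergent", "transition",
                                f"{s_prev}->{s_next}", np.nan, s_next))

    lfq = np.exp2(log2)
    if cfg.dropout > 0:
        if cfg.dropout_logistic_scale is not None:
            # intensity-dependent missingness: low-abundance proteins drop more
            centred = (baseline - cfg.baseline_mean) / cfg.dropout_logistic_scale
            p_drop = cfg.dropout * 2.0 / (1.0 + np.exp(centred))
            lfq[rng.random(lfq.shape) < p_drop[:, None]] = 0.0
        else:
            lfq[rng.random(lfq.shape) < cfg.dropout] = 0.0
    lfq[emergent_zero] = 0.0

    matrix = AbundanceMatrix(pd.DataFrame(lfq, index=proteins, columns=meta.index), meta)
    ledger = pd.DataFrame(ledger_rows, columns=["protein_id", "role", "class_kind",
                                                "class_label", "shift", "onset_stage"])
    ann = simulate_annotation(proteins, seed=int(rng.integers(2**31)))

    # planted process sets (one per stage-marker class) + random background
    sets: dict[str, frozenset[str]] = {}
    for stage in stages:
        members = ledger.query("role == 'marker' and class_label == @stage")["protein_id"]
        genes = frozenset(ann.gene_symbol[p] for p in members)
        if genes:
            sets[f"PROC_{stage}_MARKERS"] = genes
    all_genes = [ann.gene_symbol[p] for p in proteins]
    for j in range(cfg.n_background_sets):
        pick = rng.choice(cfg.n_proteins, size=min(cfg.background_set_size, cfg.n_proteins),
                          replace=False)
        sets[f"BG_SET_{j:02d}"] = frozenset(all_genes[i] for i in pick)
    gene_sets = GeneSetCollection(sets, universe=frozenset(all_genes)) if sets else \
        GeneSetCollection({"ALL": frozenset(all_genes)}, universe=frozenset(all_genes))
    return AtlasSim(matrix=matrix, ledger=ledger, annotation=ann, gene_sets=gene_sets)


# ---------------------------------------------------------------------------
# Ortholog panel
# ---------------------------------------------------------------------------

DEFAULT_CLASS_FRACTIONS = {"conserved": 0.2, "primate_specific": 0.2, "human_specific": 0.2}


def _orthonormal_centered_basis(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k orthonormal vectors of length n, each summing to zero."""
    basis = []
    while len(basis) < k:
        v = rng.normal(size=n)
        v = v - v.mean()
        for e in basis:
            v = v - (v @ e) * e
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            basis.append(v / norm)
    return np.array(basis)


def simulate_ortholog_panel(n_orthologs: int = 300,
                            class_fractions: Mapping[str, float] | None = None,
                            noise_sd: float = 0.0, seed: int = 0,
                            regions: tuple[str, ...] = ORTHOLOG_REGIONS,
                            families: tuple[str, ...] | None = None
                            ) -> tuple[OrthologPanel, pd.DataFrame, AnnotationTable]:
    """Three-species regional abundance vectors with planted correlation classes.

    Vectors are constructed (base direction plus scaled orthogonal residual)
    so pairwise Pearson correlations land exactly in each class's defining
    interval; ``noise_sd`` (in units of the profile's spread) perturbs them
    for noisy-recovery experiments.  Returns (panel, ledger, family
    annotation for the family-correlation analysis).
    """
    fracs = dict(DEFAULT_CLASS_FRACTIONS if class_fractions is None else class_fractions)
    if any(f < 0 for f in fracs.values()):
        raise ValueError("class fractions must be non-negative")
    if sum(fracs.values()) > 1 + 1e-12:
        raise ValueError("class fractions sum above 1")
    n_reg = len(regions)
    if n_reg < 4:
        raise ValueError("need >=4 regions for independent pairwise correlation targets")
    rng = np.random.default_rng(seed)
    counts = {k: int(round(f * n_orthologs)) for k, f in fracs.items()}
    labels = ([c for c, n in counts.items() for _ in range(n)])
    labels += ["unclassified"] * (n_orthologs - len(labels))

    data = {sp: np.empty((n_orthologs, n_reg)) for sp in ("human", "monkey", "mouse")}
    ledger_rows = []
    fam_pool = families or FAMILIES
    fam_map = {}
    for i, label in enumerate(labels):
        e = _orthonormal_centered_basis(rng, n_reg, 3)
        if label == "conserved":
            r1 = rng.uniform(0.80, 0.97)   # monkey-human
            r2 = rng.uniform(0.80, 0.97)   # monkey-mouse
            monkey, human = e[0], r1 * e[0] + np.sqrt(1 - r1**2) * e[1]
            mouse = r2 * e[0] + np.sqrt(1 - r2**2) * e[2]
        elif label == "primate_specific":
            r1 = rng.uniform(0.80, 0.97)   # monkey-human
            r2 = rng.uniform(-0.30, 0.30)  # monkey-mouse
            monkey, human = e[0], r1 * e[0] + np.sqrt(1 - r1**2) * e[1]
            mouse = r2 * e[0] + np.sqrt(1 - r2**2) * e[2]
        elif label == "human_specific":
            r1 = rng.uniform(-0.90, -0.55)  # monkey-human
            r2 = rng.uniform(-0.90, -0.55)  # mouse-human
            human = e[0]
            monkey = r1 * e[0] + np.sqrt(1 - r1**2) * e[1]
            mouse = r2 * e[0] + np.sqrt(1 - r2**2) * e[2]
        elif label == "unclassified":
            r1 = rng.uniform(-0.30, 0.50)
            r2 = rng.uniform(-0.30, 0.50)
            monkey, human = e[0], r1 * e[0] + np.sqrt(1 - r1**2) * e[1]
            mouse = r2 * e[0] + np.sqrt(1 - r2**2) * e[2]
        else:
            raise ValueError(f"unknown ortholog class {label!r}")
        mu = float(np.exp(rng.normal(4.5, 1.0)))
        sigma = 0.2 * mu
        for sp, vec in (("human", human), ("monkey", monkey), ("mouse", mouse)):
            v = mu + sigma * vec
            if noise_sd > 0:
                v = v + rng.normal(0.0, noise_sd * sigma, size=n_reg)
            data[sp][i] = v
        oid = f"ORTH{i:05d}"
        fam_map[oid] = frozenset({fam_pool[i % len(fam_pool)]})
        ledger_rows.append((oid, label, r1, r2))
    ids = pd.Index([f"ORTH{i:05d}" for i in range(n_orthologs)], name="ortholog_id")
    panel = OrthologPanel(
        abundance={sp: pd.DataFrame(arr, index=ids, columns=list(regions))
                   for sp, arr in data.items()},
        regions=tuple(regions))
    ledger = pd.DataFrame(ledger_rows, columns=["ortholog_id", "class", "r_target_1", "r_target_2"])
    ann = AnnotationTable(gene_symbol={o: o for o in ids}, family=fam_map)
    return panel, ledger, ann


# ---------------------------------------------------------------------------
# RNA/protein fold-change pairs
# ---------------------------------------------------------------------------

DEFAULT_TYPE_FRACTIONS = {"Type1": 0.70, "Type2": 0.15, "Type3": 0.03,
                          "Type4": 0.04, "Type5": 0.03, "Type6": 0.05}


def simulate_rna_protein_pairs(n_genes: int = 600,
                               type_fractions: Mapping[str, float] | None = None,
                               seed: int = 0, margin: float = 0.05
                               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired (RNA FC, protein FC) draws from each concordance type's region
    of fold-change space.  ``margin`` (log2 units) keeps draws away from the
    twofold decision boundary so typing is exact.  Returns (pairs table with
    fc_rna / fc_protein, ledger with the intended type)."""
    fracs = dict(DEFAULT_TYPE_FRACTIONS if type_fractions is None else type_fractions)
    if any(f < 0 for f in fracs.values()):
        raise ValueError("type fractions must be non-negative")
    if abs(sum(fracs.values()) - 1.0) > 1e-9:
        raise ValueError("type fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = {t: int(round(f * n_genes)) for t, f in fracs.items()}
    counts["Type1"] += n_genes - sum(counts.values())

    def small():
        return rng.uniform(-(1 - margin), 1 - margin)

    def small_signed(sign):
        return sign * rng.uniform(margin, 1 - margin)

    def large(sign=None):
        s = sign if sign is not None else rng.choice([-1.0, 1.0])
        return s * rng.uniform(1 + margin, 3.0)

    rows = []
    i = 0
    for t in sorted(counts):
        for _ in range(counts[t]):
            if t == "Type1":
                a, b = small(), small()
            elif t == "Type2":
                a, b = small(), large()
            elif t == "Type3":
                a = large()
                b = small_signed(-np.sign(a))
            elif t == "Type4":
                a = large()
                b = small_signed(np.sign(a))
            elif t == "Type5":
                a = large()
                b = large(-np.sign(a))
            elif t == "Type6":
                a = large()
                b = large(np.sign(a))
            else:
                raise ValueError(f"unknown type {t!r}")
            rows.append((f"GENE{i:05d}", float(2.0**a), float(2.0**b), t))
            i += 1
    df = pd.DataFrame(rows, columns=["gene", "fc_rna", "fc_protein", "true_type"])
    df = df.sample(frac=1.0, random_state=np.random.RandomState(seed)).reset_index(drop=True)
    pairs = df[["gene", "fc_rna", "fc_protein"]].copy()
    ledger = df[["gene", "true_type"]].copy()
    return pairs, ledger
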