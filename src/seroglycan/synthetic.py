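"""Synthetic study generator for every input the pipeline consumes.

Generates, from explicit parameters and a seed: spot-level glycan-array
tables (scanner-export shape), sorted/unsorted OTU count tables with
taxonomy and a sample sheet, and qPCR Ct tables — together with a
machine-readable ground-truth record so that every pipeline stage can be
verified by parameter recovery.

The array generator emulates a three-group serology design (20 healthy
controls, 17 ulcerative-colitis and 23 Crohn's-disease sera) probed
against a ~220-feature milk-oligosaccharide library, with a planted
CD-specific log2 elevation on a decoration subgroup (by default the di- to
tetra-fucosylated band) and an IgM channel coupled to IgG at a
configurable per-sample correlation.  The sorting generator emulates
lectin- (AAL) and serum-IgG-capture experiments on a fermenter community:
a multi-species Bacteroides genus is planted as lectin-bound and
CD-IgG-bound, and counts are drawn multinomially at a configurable read
depth from capture-probability-tilted community proportions.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .glycans import LibraryPartition, partition_library

GROUPS = ("ctrl", "UC", "CD")

__all__ = [
    "ArraySimConfig",
    "TaxonSpec",
    "SortSimConfig",
    "SimTruth",
    "simulate_array_study",
    "simulate_sort_study",
    "simulate_qpcr",
    "write_fixtures",
]


# ---------------------------------------------------------------------------
# Configurations


class ArraySimConfig(BaseModel):
    """Parameters of a simulated glycan-array serology study.

    The class mix is a stand-in for the (unpublished) composition of the
    real array library; it is configurable and documented as such.  All
    level parameters are on the log2(RFU) scale; spot parameters are in
    raw RFU.
    """

    n_glycans: int = 220
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "undecorated": 0.20,
            "fucosylated_f1": 0.25,
            "fucosylated_f2to4": 0.25,
            "sialylated": 0.20,
            "fucosylated_sialylated": 0.10,
        }
    )
    group_sizes: dict[str, int] = Field(
        default_factory=lambda: {"ctrl": 20, "UC": 17, "CD": 23}
    )
    target_subgroup: str = "F2to4"
    delta: float = 1.5
    baseline_mean: float = 9.0
    baseline_sd: float = 1.2
    sample_offset_sd: float = 0.25
    noise_sd: float = 1.0
    replicates: int = 4
    spot_noise_sd: float = 10.0
    background_level: float = 100.0
    background_cv: float = 0.2
    isotype_coupling: float = 0.8
    isotypes: tuple[str, ...] = ("IgG", "IgM")
    seed: int = 0

    @field_validator("n_glycans", "replicates")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("delta", "baseline_sd", "sample_offset_sd", "noise_sd",
                     "spot_noise_sd", "background_level", "background_cv")
    @classmethod
    def _non_negative(cls, v: float) -> float:
        if v < 0:
            raise ValueError("must be >= 0")
        return v

    @field_validator("isotype_coupling")
    @classmethod
    def _unit_interval(cls, v: float) -> float:
        if not 0.0 <= v <= 1.0:
            raise ValueError("isotype coupling must be in [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_structure(self) -> "ArraySimConfig":
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mix must sum to 1 (got {total})")
        if any(p < 0 for p in self.class_mix.values()):
            raise ValueError("class mix proportions must be >= 0")
        for group, size in self.group_sizes.items():
            if size < 2:
                raise ValueError(f"group {group!r} needs >= 2 samples")
        if not self.isotypes or any(i not in ("IgG", "IgM") for i in self.isotypes):
            raise ValueError("isotypes must be a non-empty subset of (IgG, IgM)")
        return self


class TaxonSpec(BaseModel):
    """One OTU of the simulated community."""

    otu_id: str
    lineage: str
    base_proportion: float

    @field_validator("base_proportion")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("base proportion must be > 0")
        return v


def _default_community() -> list[TaxonSpec]:
    """A fermenter-like gut community with a planted 3-species genus.

    This is a synthetic stand-in for a real fecal-fermenter community:
    genus names follow taxa commonly recovered in lectin-sorting
    experiments, proportions are invented.
    """
    planted = [
        ("otu_bst", "d:Bacteria;p:Bacteroidetes;f:Bacteroidaceae;g:Bacteroides;s:stercoris", 0.020),
        ("otu_bvu", "d:Bacteria;p:Bacteroidetes;f:Bacteroidaceae;g:Bacteroides;s:vulgatus", 0.020),
        ("otu_bin", "d:Bacteria;p:Bacteroidetes;f:Bacteroidaceae;g:Bacteroides;s:intestinalis", 0.020),
    ]
    background = [
        ("otu_fpr", "d:Bacteria;p:Firmicutes;f:Ruminococcaceae;g:Faecalibacterium;s:prausnitzii", 0.120),
        ("otu_bl1", "d:Bacteria;p:Firmicutes;f:Lachnospiraceae;g:Blautia;s:obeum", 0.090),
        ("otu_ro1", "d:Bacteria;p:Firmicutes;f:Lachnospiraceae;g:Roseburia;s:intestinalis", 0.080),
        ("otu_pre", "d:Bacteria;p:Bacteroidetes;f:Prevotellaceae;g:Prevotella;s:copri", 0.090),
        ("otu_par", "d:Bacteria;p:Bacteroidetes;f:Tannerellaceae;g:Parabacteroides;s:distasonis", 0.060),
        ("otu_aga", "d:Bacteria;p:Firmicutes;f:Lachnospiraceae;g:Agathobacter;s:rectalis", 0.060),
        ("otu_ana", "d:Bacteria;p:Firmicutes;f:Lachnospiraceae;g:Anaerostipes;s:hadrus", 0.050),
        ("otu_rum", "d:Bacteria;p:Firmicutes;f:Ruminococcaceae;g:Ruminococcus;s:bromii", 0.060),
        ("otu_eub", "d:Bacteria;p:Firmicutes;f:Eubacteriaceae;g:Eubacterium;s:rectale", 0.050),
        ("otu_esc", "d:Bacteria;p:Proteobacteria;f:Enterobacteriaceae;g:Escherichia;s:coli", 0.030),
        ("otu_ent", "d:Bacteria;p:Firmicutes;f:Enterococcaceae;g:Enterococcus;s:faecalis", 0.020),
        ("otu_bif", "d:Bacteria;p:Actinobacteria;f:Bifidobacteriaceae;g:Bifidobacterium;s:longum", 0.060),
        ("otu_akk", "d:Bacteria;p:Verrucomicrobia;f:Akkermansiaceae;g:Akkermansia;s:muciniphila", 0.040),
        ("otu_lac", "d:Bacteria;p:Firmicutes;f:Lachnospiraceae;g:Lachnospira;s:pectinoschiza", 0.030),
        ("otu_hol", "d:Bacteria;p:Firmicutes;f:Erysipelotrichaceae;g:Holdemania;s:filiformis", 0.020),
        ("otu_sla", "d:Bacteria;p:Actinobacteria;f:Eggerthellaceae;g:Slackia;s:isoflavoniconvertens", 0.020),
        ("otu_pep", "d:Bacteria;p:Firmicutes;f:Peptoniphilaceae;g:Peptoniphilus;s:harei", 0.020),
        ("otu_rut", "d:Bacteria;p:Firmicutes;f:Ruminococcaceae;g:Ruthenibacterium;s:lactatiformans", 0.020),
        ("otu_fri", "d:Bacteria;p:Firmicutes;f:Lachnospiraceae;g:Frisingicoccus;s:caecimuris", 0.020),
        ("otu_ulx", "d:Bacteria;p:Firmicutes;f:Lachnospiraceae", 0.040),
        ("otu_urx", "d:Bacteria;p:Firmicutes;f:Ruminococcaceae", 0.030),
    ]
    return [
        TaxonSpec(otu_id=o, lineage=l, base_proportion=p)
        for o, l, p in planted + background
    ]


class SortSimConfig(BaseModel):
    """Parameters of a simulated lectin/IgG sorting study.

    Sorted-fraction proportions are the community proportions tilted by
    per-taxon capture probabilities; the planted genus gets the high
    probability for the lectin stain and for CD-serum IgG, the low one
    elsewhere.
    """

    taxa: list[TaxonSpec] = Field(default_factory=_default_community)
    planted_genus: str = "g:Bacteroides"
    dirichlet_concentration: float = 300.0
    capture_hi: float = 0.6
    capture_lo: float = 0.2
    igg_capture_planted: dict[str, float] = Field(
        default_factory=lambda: {"ctrl": 0.2, "UC": 0.2, "CD": 0.6}
    )
    depth: int = 20_000
    n_sorted_per_group: int = 6
    n_lectin_replicates: int = 3
    seed: int = 0

    @field_validator("depth", "n_sorted_per_group", "n_lectin_replicates")
    @classmethod
    def _positive(cls, v: int) -> int:
        if v <= 0:
            raise ValueError("must be positive")
        return v

    @field_validator("capture_hi", "capture_lo")
    @classmethod
    def _probability(cls, v: float) -> float:
        if not 0.0 < v <= 1.0:
            raise ValueError("capture probabilities must be in (0, 1]")
        return v

    @model_validator(mode="after")
    def _check_structure(self) -> "SortSimConfig":
        if self.capture_hi < self.capture_lo:
            raise ValueError("capture_hi must be >= capture_lo")
        if not self.taxa:
            raise ValueError("community must contain at least one taxon")
        for group in GROUPS:
            if group not in self.igg_capture_planted:
                raise ValueError(f"igg_capture_planted missing group {group!r}")
        for p in self.igg_capture_planted.values():
            if not 0.0 < p <= 1.0:
                raise ValueError("IgG capture probabilities must be in (0, 1]")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        return self


class SimTruth(BaseModel):
    """Machine-readable ground truth of a simulated study."""

    seed: int
    config: dict
    affected_glycan_ids: list[str] | None = None
    delta: float | None = None
    target_subgroup: str | None = None
    glycan_labels: dict[str, str] | None = None
    planted_taxa: list[str] | None = None
    planted_genus: str | None = None
    true_proportions: dict[str, dict[str, float]] | None = None
    expected_fold_lectin: dict[str, float] | None = None
    qpcr_true_proportions: dict[str, dict[str, float]] | None = None


# ---------------------------------------------------------------------------
# Array study


def _make_library(config: ArraySimConfig, rng: np.random.Generator) -> list[str]:
    """Composition labels for the synthetic library, honouring the class mix."""
    quotas = {k: config.n_glycans * p for k, p in config.class_mix.items()}
    counts = {k: int(math.floor(q)) for k, q in quotas.items()}
    remainder = config.n_glycans - sum(counts.values())
    by_frac = sorted(quotas, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in by_frac[:remainder]:
        counts[k] += 1

    labels: list[str] = []
    for cls, n in counts.items():
        for _ in range(n):
            h = int(rng.integers(2, 11))
            nn = max(h - 2, 0)
            f, s = 0, 0
            if cls == "fucosylated_f1":
                f = 1
            elif cls == "fucosylated_f2to4":
                f = int(rng.integers(2, 5))
            elif cls == "sialylated":
                s = int(rng.integers(1, 3))
            elif cls == "fucosylated_sialylated":
                f = int(rng.integers(1, 4))
                s = int(rng.integers(1, 3))
            parts = []
            if h:
                parts.append(f"H{h}")
            if nn:
                parts.append(f"N{nn}")
            if f:
                parts.append(f"F{f}")
            if s:
                parts.append(f"S{s}")
            labels.append("".join(parts))
    return labels


def _target_ids(partition: LibraryPartition, subgroup: str) -> list[str]:
    from .glycans import DecorationClass, FucoseBand, SialicBand

    if subgroup in ("none", ""):
        return []
    if subgroup == "all":
        return list(partition.classes)
    for band in FucoseBand:
        if subgroup == band.value and band.value not in ("ambiguous",):
            return partition.ids_in_fucose_band(band)
    for band in SialicBand:
        if subgroup == band.value and band.value not in ("ambiguous",):
            return partition.ids_in_sialic_band(band)
    for cls in DecorationClass:
        if subgroup == cls.value:
            return partition.ids_in_class(cls)
    raise ValueError(f"unknown target subgroup {subgroup!r}")


def simulate_array_study(
    config: ArraySimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate a spot-level array table, sample metadata and ground truth.

    Model: glycan baseline b_g ~ N(mu, sigma_b); sample offset a_i ~
    N(0, sigma_a); IgG log2-level = b_g + a_i + delta * 1[i in CD, g in
    target] + N(0, sigma_e).  The IgM level shares the glycan-varying
    signal at correlation rho and adds independent matched-variance noise.
    Spot foreground = 2^level + local background + Gaussian spot noise,
    replicated; the local background is lognormal.  Deterministic under
    (config, seed).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    labels = _make_library(config, rng)
    glycan_ids = [f"g{i + 1:04d}" for i in range(config.n_glycans)]
    library = dict(zip(glycan_ids, labels))
    partition = partition_library(library)
    target = sorted(_target_ids(partition, config.target_subgroup))
    target_mask = np.array([g in set(target) for g in glycan_ids])

    sample_ids, groups = [], []
    for group in GROUPS:
        for i in range(config.group_sizes.get(group, 0)):
            sample_ids.append(f"{group}_{i + 1:02d}")
            groups.append(group)
    n_samples, n_glycans = len(sample_ids), config.n_glycans
    group_arr = np.array(groups)

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, n_glycans)
    offsets = rng.normal(0.0, config.sample_offset_sd, n_samples)
    effect = (
        config.delta
        * np.outer((group_arr == "CD").astype(float), target_mask.astype(float))
    )
    eps = rng.normal(0.0, config.noise_sd, (n_samples, n_glycans))
    signal = baselines[None, :] + effect + eps  # glycan-varying part
    levels = {"IgG": offsets[:, None] + signal}
    if "IgM" in config.isotypes:
        rho = config.isotype_coupling
        sd_signal = math.sqrt(config.baseline_sd**2 + config.noise_sd**2)
        eta = rng.normal(0.0, 1.0, (n_samples, n_glycans))
        levels["IgM"] = (
            offsets[:, None]
            + config.baseline_mean
            + rho * (signal - config.baseline_mean)
            + math.sqrt(max(1.0 - rho**2, 0.0)) * sd_signal * eta
        )
    levels = {iso: levels[iso] for iso in config.isotypes if iso in levels}

    frames = []
    r = config.replicates
    lognormal_bg = config.background_cv > 0 and config.background_level > 0
    if lognormal_bg:
        sigma_log = math.sqrt(math.log(1.0 + config.background_cv**2))
        mu_log = math.log(config.background_level) - sigma_log**2 / 2.0
    for isotype, lvl in levels.items():
        true_sig = np.power(2.0, lvl)[:, :, None]  # (samples, glycans, 1)
        shape = (n_samples, n_glycans, r)
        if lognormal_bg:
            bg_true = rng.lognormal(mu_log, sigma_log, shape)
        else:
            bg_true = np.full(shape, config.background_level)
        fg = true_sig + bg_true + rng.normal(0.0, config.spot_noise_sd, shape)
        bg = bg_true + rng.normal(0.0, config.spot_noise_sd, shape)
        np.clip(fg, 0.0, None, out=fg)
        np.clip(bg, 0.0, None, out=bg)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": np.repeat(sample_ids, n_glycans * r),
                    "isotype": isotype,
                    "glycan_id": np.tile(np.repeat(glycan_ids, r), n_samples),
                    "composition_label": np.tile(np.repeat(labels, r), n_samples),
                    "replicate_index": np.tile(np.arange(1, r + 1), n_samples * n_glycans),
                    "foreground_mean": fg.ravel(),
                    "background_mean": bg.ravel(),
                }
            )
        )
    spots = pd.concat(frames, ignore_index=True)

    igg_conc = rng.lognormal(math.log(10.0), 0.3, n_samples)
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "group": groups,
            "igg_concentration": igg_conc,
        }
    )

    truth = SimTruth(
        seed=seed,
        config=config.model_dump(),
        affected_glycan_ids=target,
        delta=config.delta,
        target_subgroup=config.target_subgroup,
        glycan_labels=library,
    )
    return spots, metadata, truth


# ---------------------------------------------------------------------------
# Sorting study


def _planted_mask(config: SortSimConfig) -> np.ndarray:
    from .enrichment import taxon_key

    return np.array(
        [
            taxon_key(t.lineage, config.planted_genus.split(":", 1)[0])
            == config.planted_genus
            for t in config.taxa
        ]
    )


def simulate_sort_study(
    config: SortSimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SimTruth]:
    """Generate OTU counts, taxonomy, a sample sheet and ground truth.

    For each sorted sample: community proportions pi ~ Dirichlet
    (concentration x base); the matched unsorted counts are
    Multinomial(depth, pi); sorted-fraction counts are
    Multinomial(depth, pi * capture / sum(pi * capture)) where capture is
    the per-taxon probability of being stained and sorted (lectin or
    group-specific serum IgG).
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    otu_ids = [t.otu_id for t in config.taxa]
    base = np.array([t.base_proportion for t in config.taxa], dtype=float)
    base = base / base.sum()
    alpha = config.dirichlet_concentration * base
    planted = _planted_mask(config)
    if not planted.any():
        raise ValueError(
            f"no taxon matches planted genus {config.planted_genus!r}"
        )

    lectin_capture = np.where(planted, config.capture_hi, config.capture_lo)

    counts: dict[str, np.ndarray] = {}
    sheet_rows = []
    truth_props: dict[str, dict[str, float]] = {}

    def _one_pair(tag: str, fraction: str, group: str, capture: np.ndarray):
        pi = rng.dirichlet(alpha)
        unsorted_id = f"uns_{tag}"
        sorted_id = f"{fraction.lower()}_{tag}"
        counts[unsorted_id] = rng.multinomial(config.depth, pi)
        tilted = pi * capture
        counts[sorted_id] = rng.multinomial(config.depth, tilted / tilted.sum())
        sheet_rows.append(
            {
                "sample_id": unsorted_id,
                "fraction": "unsorted",
                "serum_group": "none",
                "matched_unsorted_id": "",
            }
        )
        sheet_rows.append(
            {
                "sample_id": sorted_id,
                "fraction": fraction,
                "serum_group": group,
                "matched_unsorted_id": unsorted_id,
            }
        )
        truth_props[unsorted_id] = dict(zip(otu_ids, pi.astype(float)))

    for rep in range(config.n_lectin_replicates):
        _one_pair(f"aal_{rep + 1}", "AAL_pos", "none", lectin_capture)
    for group in GROUPS:
        igg_capture = np.where(
            planted, config.igg_capture_planted[group], config.capture_lo
        )
        for rep in range(config.n_sorted_per_group):
            _one_pair(f"{group}_{rep + 1}", "IgG_pos", group, igg_capture)

    counts_df = pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"))
    taxonomy_df = pd.DataFrame(
        {"otu_id": otu_ids, "lineage": [t.lineage for t in config.taxa]}
    )
    samples_df = pd.DataFrame(sheet_rows)

    mean_capture = float(np.sum(base * lectin_capture))
    expected_fold = {
        otu: float(c / mean_capture) for otu, c in zip(otu_ids, lectin_capture)
    }
    truth = SimTruth(
        seed=seed,
        config=config.model_dump(),
        planted_taxa=[t.otu_id for t, m in zip(config.taxa, planted) if m],
        planted_genus=config.planted_genus,
        true_proportions=truth_props,
        expected_fold_lectin=expected_fold,
    )
    return counts_df, taxonomy_df, samples_df, truth


# ---------------------------------------------------------------------------
# qPCR


def simulate_qpcr(
    true_proportions: Mapping[str, Mapping[str, float]],
    noise_sd: float = 0.1,
    seed: int = 0,
    baseline_ct: float = 12.0,
    total_template: float = 1.0,
) -> tuple[pd.DataFrame, SimTruth]:
    """Generate a Ct table whose expected 2^-dCt equals the true proportion.

    Per sample: Ct_total = c0 - log2(T); per target with template
    proportion p: Ct_target = c0 - log2(T * p) + N(0, sd), so the expected
    recovered relative quantity is p.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for sample_id, targets in true_proportions.items():
        ct_total = baseline_ct - math.log2(total_template)
        rows.append(
            {
                "sample_id": sample_id,
                "target": "total_bacteria",
                "ct": ct_total,
                "plate_id": "plate1",
            }
        )
        for target, p in targets.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(
                    f"true proportion for {sample_id}/{target} must be in (0, 1]"
                )
            ct = (
                baseline_ct
                - math.log2(total_template * p)
                + rng.normal(0.0, noise_sd)
            )
            rows.append(
                {
                    "sample_id": sample_id,
                    "target": target,
                    "ct": ct,
                    "plate_id": "plate1",
                }
            )
    ct_df = pd.DataFrame(rows)
    truth = SimTruth(
        seed=seed,
        config={
            "noise_sd": noise_sd,
            "baseline_ct": baseline_ct,
            "total_template": total_template,
        },
        qpcr_true_proportions={
            s: dict(t) for s, t in true_proportions.items()
        },
    )
    return ct_df, truth


# ---------------------------------------------------------------------------
# Fixture writer


def write_fixtures(
    out_dir,
    array_config: ArraySimConfig | None = None,
    sort_config: SortSimConfig | None = None,
    qpcr_noise_sd: float = 0.1,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write the full synthetic study to ``out_dir`` (7 deterministic files).

    Emits the spot table, sample metadata, OTU counts, taxonomy, sample
    sheet, qPCR Ct table and a combined ground-truth JSON.  Identical
    configs and seed produce byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    array_config = array_config or ArraySimConfig()
    sort_config = sort_config or SortSimConfig()
    array_seed = array_config.seed if seed is None else seed
    sort_seed = sort_config.seed if seed is None else seed + 1
    qpcr_seed = (array_seed + 2) % (2**31)

    spots, metadata, array_truth = simulate_array_study(array_config, array_seed)
    counts, taxonomy, sheet, sort_truth = simulate_sort_study(sort_config, sort_seed)

    from .enrichment import taxon_key

    genus_rank = sort_config.planted_genus.split(":", 1)[0]
    planted_otus = set(sort_truth.planted_taxa or [])
    first_species = sorted(planted_otus)[0] if planted_otus else None
    qpcr_props: dict[str, dict[str, float]] = {}
    for sample_id, props in (sort_truth.true_proportions or {}).items():
        genus_p = sum(p for o, p in props.items() if o in planted_otus)
        entry = {"genus_target": genus_p}
        if first_species is not None:
            entry["species_target"] = props[first_species]
        qpcr_props[sample_id] = entry
    ct_table, qpcr_truth = simulate_qpcr(
        qpcr_props, noise_sd=qpcr_noise_sd, seed=qpcr_seed
    )

    paths = {
        "spot_table": out / "array_spots.tsv",
        "sample_metadata": out / "array_samples.tsv",
        "otu_counts": out / "otu_counts.tsv",
        "taxonomy": out / "taxonomy.tsv",
        "sample_sheet": out / "sample_sheet.tsv",
        "ct_table": out / "qpcr_ct.tsv",
        "truth": out / "truth.json",
    }
    fmt = "%.6g"
    spots.to_csv(paths["spot_table"], sep="\t", index=False, float_format=fmt)
    metadata.to_csv(
        paths["sample_metadata"], sep="\t", index=False, float_format=fmt
    )
    counts.to_csv(paths["otu_counts"], sep="\t")
    taxonomy.to_csv(paths["taxonomy"], sep="\t", index=False)
    sheet.to_csv(paths["sample_sheet"], sep="\t", index=False)
    ct_table.to_csv(paths["ct_table"], sep="\t", index=False, float_format=fmt)

    truth = {
        "array": array_truth.model_dump(),
        "sort": sort_truth.model_dump(),
        "qpcr": qpcr_truth.model_dump(),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths


def file_checksum(path) -> str:
    """SHA-256 of a file, for determinism checks."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
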