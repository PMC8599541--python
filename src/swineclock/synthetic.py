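"""Synthetic methylation datasets with the statistical structure of a
dual-species aging study.

The generator emulates a porcine methylation-array cohort (three pig lines,
six tissues) with an optional human companion cohort, planting:

* age-associated CpGs whose beta values drift linearly with a scaled age
  signal, hypermethylating with age preferentially inside CpG islands;
* a subset of age CpGs *shared* across species, whose trajectory is a
  function of relative age (age / species max lifespan) in both species, so
  a joint relative-age clock is learnable from the output;
* species-restricted age CpGs — pig-only CpGs linear in chronological age,
  and (when a human cohort is requested) human-only CpGs that follow the
  species' log-linear age curve, mimicking the rapid early-life methylation
  drift that saturates after maturity;
* breed-baseline CpGs with constant methylation offsets between domestic
  pigs and minipigs, plus a small positive island-methylation shift in
  minipigs;
* breed x age interaction CpGs whose aging slopes differ between breeds,
  including opposite-sign (divergent) patterns;
* tissue- and sex-signature CpGs with constant class-specific offsets, the
  structure that makes real methylation cohorts almost perfectly separable
  by tissue, sex, and breed.

Every random draw flows from a single ``numpy`` Generator seeded by
``SimulationConfig.seed``, so outputs are bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MethylationDataset
from .transforms import DEFAULT_MATURITY, DEFAULT_MAX_LIFESPAN, AgeTransform

__all__ = [
    "CohortCell",
    "SimulationConfig",
    "simulate_dataset",
    "default_paper_design",
]


@dataclass(frozen=True)
class CohortCell:
    """One (species, line, tissue) cell of the study design."""

    species: str
    line: str  # pig line label or "human"
    breed: str  # contrast label: domestic | minipig | human
    tissue: str
    n: int
    age_min: float
    age_max: float
    age_mean: float | None = None  # None -> uniform ages on [age_min, age_max]
    frac_female: float = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic methylation study.

    ``slope_scale`` is in beta units per unit of the scaled age signal
    (relative age for shared/pig CpGs), ``noise_sd`` in beta units.
    """

    n_probes: int = 2000
    cells: tuple[CohortCell, ...] = ()
    frac_age_cpgs: float = 0.10
    frac_island: float = 0.30
    island_hyper_bias: float = 0.8
    slope_scale: float = 0.5
    noise_sd: float = 0.02
    n_breed_baseline_cpgs: int = 20
    breed_offset: float = 0.08
    n_interaction_cpgs: int = 10
    frac_shared_across_species: float = 0.5
    frac_mappable: float = 0.9
    minipig_island_offset: float = 0.02
    n_tissue_signature_cpgs: int = 0
    tissue_signature_offset: float = 0.2
    n_sex_cpgs: int = 0
    sex_offset: float = 0.1
    trajectory: str = "linear"  # or "logistic"
    max_lifespans: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MAX_LIFESPAN)
    )
    maturities: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MATURITY)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "frac_age_cpgs",
            "frac_island",
            "island_hyper_bias",
            "frac_shared_across_species",
            "frac_mappable",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.trajectory not in ("linear", "logistic"):
            raise ValueError(f"unknown trajectory {self.trajectory!r}")
        n_special = (
            round(self.frac_age_cpgs * self.n_probes)
            + self.n_breed_baseline_cpgs
            + self.n_interaction_cpgs
            + self.n_tissue_signature_cpgs
            + self.n_sex_cpgs
        )
        if n_special > self.n_probes:
            raise ValueError(
                f"infeasible config: {n_special} special CpGs exceed {self.n_probes} probes"
            )

    @property
    def n_age_cpgs(self) -> int:
        return round(self.frac_age_cpgs * self.n_probes)


# Table-1-style study design: three pig lines, blood for all, five extra
# tissues from the domestic x minipig cross (16 samples per cross tissue).
_PIG_CELLS = (
    CohortCell("pig", "domestic", "domestic", "blood", 82, 0.030, 6.26, 2.34, 1.0),
    CohortCell("pig", "minipig", "minipig", "blood", 60, 0.0219, 5.15, 0.997, 1.0),
    CohortCell("pig", "cross", "domestic", "blood", 16, 0.0795, 3.96, 1.44, 0.56),
    CohortCell("pig", "cross", "domestic", "bladder", 16, 0.0795, 3.96, 1.54, 0.56),
    CohortCell("pig", "cross", "domestic", "frontal cortex", 16, 0.0795, 3.96, 1.44, 0.56),
    CohortCell("pig", "cross", "domestic", "kidney", 16, 0.0795, 3.96, 1.44, 0.56),
    CohortCell("pig", "cross", "domestic", "liver", 16, 0.0795, 3.96, 1.61, 0.62),
    CohortCell("pig", "cross", "domestic", "lung", 16, 0.0795, 3.96, 1.54, 0.56),
)

_HUMAN_TISSUES = ("blood", "skin", "liver", "muscle")


def default_paper_design(n_probes: int = 2000, human_n: int = 0, seed: int = 0) -> SimulationConfig:
    """Study design mirroring the porcine cohort table: 238 pig samples
    (82 domestic blood, 60 minipig blood, 16 per cross tissue across six
    tissues), ages 0.02-6.26 years, with an optional human companion cohort
    (ages 0-93, four tissues).

    ``human_n`` samples stand in for the full human reference cohort; pass
    e.g. 200 for a desk-scale dual-species run.
    """
    cells = list(_PIG_CELLS)
    if human_n > 0:
        per = [human_n // len(_HUMAN_TISSUES)] * len(_HUMAN_TISSUES)
        per[0] += human_n - sum(per)
        for tissue, n in zip(_HUMAN_TISSUES, per):
            cells.append(
                CohortCell("human", "human", "human", tissue, n, 0.0, 93.0, None, 0.5)
            )
    return SimulationConfig(
        n_probes=n_probes,
        cells=tuple(cells),
        # tissue/sex signature CpGs make the cohort separable by tissue,
        # sex, and breed, as real methylation cohorts are; counts scale
        # down with small desk-size probe sets
        n_tissue_signature_cpgs=min(30, n_probes // 10),
        n_sex_cpgs=min(10, n_probes // 25),
        seed=seed,
    )


def _draw_ages(rng: np.random.Generator, cell: CohortCell) -> np.ndarray:
    lo, hi = cell.age_min, cell.age_max
    if cell.age_mean is None:
        return rng.uniform(lo, hi, cell.n)
    # Beta-shaped ages matching the cell's mean (right-skewed cohorts)
    f = np.clip((cell.age_mean - lo) / (hi - lo), 0.05, 0.95)
    a, b = max(4 * f, 0.5), max(4 * (1 - f), 0.5)
    return lo + (hi - lo) * rng.beta(a, b, cell.n)


def _shape(g: np.ndarray, trajectory: str) -> np.ndarray:
    if trajectory == "linear":
        return g
    # logistic option: sigmoidal drift saturating at both ends of the scaled
    # age axis (maps [0,1] to roughly [0.05, 0.95])
    return 1.0 / (1.0 + np.exp(-6.0 * (g - 0.5)))


def simulate_dataset(cfg: SimulationConfig) -> tuple[MethylationDataset, pd.DataFrame]:
    """Generate a methylation dataset and its per-probe ground truth.

    Returns ``(dataset, truth)`` where ``truth`` is a DataFrame aligned
    1:1 with the generated probes, carrying the planted roles (age CpG,
    breed-baseline CpG, interaction CpG), slopes, directions, and
    cross-species sharing flags.
    """
    if not cfg.cells:
        raise ValueError("config has no cohort cells")
    rng = np.random.default_rng(cfg.seed)

    # ---- samples ---------------------------------------------------------------
    rows = []
    for ci, cell in enumerate(cfg.cells):
        ages = _draw_ages(rng, cell)
        sexes = np.where(rng.random(cell.n) < cell.frac_female, "F", "M")
        for j in range(cell.n):
            rows.append(
                {
                    "sample_id": f"{cell.line}_{cell.tissue}_{ci}_{j:03d}".replace(" ", ""),
                    "species": cell.species,
                    "line": cell.line,
                    "breed": cell.breed,
                    "tissue": cell.tissue,
                    "sex": sexes[j],
                    "age_years": float(ages[j]),
                }
            )
    samples = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(samples)
    age = samples["age_years"].to_numpy()
    species = samples["species"].to_numpy(object)
    breed = samples["breed"].to_numpy(object)
    lifespan = np.array([cfg.max_lifespans[s] for s in species])
    rel_age = age / lifespan
    is_pig = species == "pig"
    is_minipig = breed == "minipig"
    have_humans = bool(np.any(~is_pig))

    # ---- probes and roles --------------------------------------------------------
    p = cfg.n_probes
    probe_ids = np.array([f"cg{i:06d}" for i in range(p)])
    island = rng.random(p) < cfg.frac_island
    mappable = rng.random(p) < cfg.frac_mappable
    chrom = rng.choice([f"chr{c}" for c in range(1, 19)], p)
    pos = rng.integers(1, 150_000_000, p)
    nearest_gene = np.array([f"GENE{i % max(p // 4, 1):05d}" for i in range(p)])
    dist_to_tss = rng.integers(-50_000, 50_000, p)

    perm = rng.permutation(p)
    n_age = cfg.n_age_cpgs
    age_idx = perm[:n_age]
    inter_idx = perm[n_age : n_age + cfg.n_interaction_cpgs]
    base_idx = perm[
        n_age + cfg.n_interaction_cpgs : n_age
        + cfg.n_interaction_cpgs
        + cfg.n_breed_baseline_cpgs
    ]

    used = n_age + cfg.n_interaction_cpgs + cfg.n_breed_baseline_cpgs
    tissue_idx = perm[used : used + cfg.n_tissue_signature_cpgs]
    used += cfg.n_tissue_signature_cpgs
    sex_idx = perm[used : used + cfg.n_sex_cpgs]

    is_age = np.zeros(p, bool)
    is_age[age_idx] = True
    is_inter = np.zeros(p, bool)
    is_inter[inter_idx] = True
    is_base = np.zeros(p, bool)
    is_base[base_idx] = True
    is_tissue_sig = np.zeros(p, bool)
    is_tissue_sig[tissue_idx] = True
    is_sex = np.zeros(p, bool)
    is_sex[sex_idx] = True

    # direction: island age CpGs hypermethylate with probability island_hyper_bias
    direction = np.zeros(p)
    hyper_prob = np.where(island, cfg.island_hyper_bias, 0.5)
    direction[age_idx] = np.where(
        rng.random(n_age) < hyper_prob[age_idx], 1.0, -1.0
    )

    slope = np.zeros(p)
    slope[age_idx] = direction[age_idx] * cfg.slope_scale * rng.uniform(0.5, 1.5, n_age)

    # cross-species scope of each age CpG
    scope = np.array([""] * p, dtype=object)
    shared_draw = rng.random(n_age) < cfg.frac_shared_across_species
    scope[age_idx[shared_draw]] = "shared"
    nonshared = age_idx[~shared_draw]
    if have_humans and len(nonshared):
        half = len(nonshared) // 2
        scope[nonshared[:half]] = "human"
        scope[nonshared[half:]] = "pig"
    else:
        scope[nonshared] = "pig"
    is_shared = scope == "shared"

    # interaction CpGs: per-breed slopes with guaranteed rate differences;
    # the first two are forced to diverge in sign (the extreme pattern)
    slope_dom = np.zeros(p)
    slope_mini = np.zeros(p)
    if cfg.n_interaction_cpgs:
        k = cfg.n_interaction_cpgs
        sd = rng.choice([-1.0, 1.0], k) * cfg.slope_scale * rng.uniform(0.5, 1.5, k)
        delta = rng.choice([-1.0, 1.0], k) * cfg.slope_scale * rng.uniform(1.0, 2.0, k)
        sm = sd + delta
        if k >= 2:
            sd[0], sm[0] = -abs(sd[0]), abs(sd[0]) + abs(delta[0])
            sd[1], sm[1] = abs(sd[1]), -abs(sd[1]) - abs(delta[1])
        slope_dom[inter_idx] = sd
        slope_mini[inter_idx] = sm

    base_offset = np.zeros(p)
    if cfg.n_breed_baseline_cpgs:
        base_offset[base_idx] = (
            rng.choice([-1.0, 1.0], cfg.n_breed_baseline_cpgs)
            * cfg.breed_offset
            * rng.uniform(0.75, 1.25, cfg.n_breed_baseline_cpgs)
        )

    # ---- baselines ---------------------------------------------------------------
    baseline = np.empty(p)
    plain = ~(is_age | is_inter | is_base)
    n_plain = int(plain.sum())
    isl_plain = plain & island
    non_plain = plain & ~island
    baseline[isl_plain] = rng.beta(1.5, 15.0, int(isl_plain.sum()))
    mix = rng.random(int(non_plain.sum()))
    b_non = np.empty(int(non_plain.sum()))
    hi = mix < 0.6
    lo = (mix >= 0.6) & (mix < 0.85)
    mid = mix >= 0.85
    b_non[hi] = rng.beta(15, 2, int(hi.sum()))
    b_non[lo] = rng.beta(2, 15, int(lo.sum()))
    b_non[mid] = rng.beta(8, 8, int(mid.sum()))
    baseline[non_plain] = b_non
    # age CpGs start low if gaining methylation, high if losing, leaving
    # headroom for the trajectory before clipping
    up = is_age & (direction > 0)
    dn = is_age & (direction < 0)
    baseline[up] = rng.uniform(0.15, 0.45, int(up.sum()))
    baseline[dn] = rng.uniform(0.55, 0.85, int(dn.sum()))
    baseline[is_inter] = rng.uniform(0.30, 0.60, int(is_inter.sum()))
    baseline[is_base] = rng.uniform(0.20, 0.70, int(is_base.sum()))
    baseline[is_tissue_sig] = rng.uniform(0.15, 0.55, int(is_tissue_sig.sum()))
    baseline[is_sex] = rng.uniform(0.15, 0.6, int(is_sex.sum()))

    # ---- scaled age signals per sample -------------------------------------------
    # shared CpGs: relative age in every species; pig-restricted CpGs: linear
    # chronological age in pigs (scaled by pig lifespan so slope units match);
    # human-restricted CpGs: log-linear age curve in humans, rescaled to [0,1]
    g_shared = rel_age
    g_pig = np.where(is_pig, rel_age, 0.0)
    if have_humans:
        tf = AgeTransform(
            kind="loglinear",
            max_lifespan_by_species=cfg.max_lifespans,
            maturity_by_species=cfg.maturities,
        )
        f = np.asarray(tf.forward(age, species), float)
        f0 = float(tf.forward(0.0, "human"))
        f1 = float(tf.forward(93.0, "human"))
        g_hum = np.where(~is_pig, (f - f0) / (f1 - f0), 0.0)
    else:
        g_hum = np.zeros(n_samples)

    # ---- assemble beta matrix ----------------------------------------------------
    betas = np.tile(baseline[:, None], (1, n_samples))
    shp = lambda g: _shape(g, cfg.trajectory)
    m_sh = is_shared
    m_pg = scope == "pig"
    m_hu = scope == "human"
    betas[m_sh] += slope[m_sh, None] * shp(g_shared)[None, :]
    betas[m_pg] += slope[m_pg, None] * shp(g_pig)[None, :]
    betas[m_hu] += slope[m_hu, None] * shp(g_hum)[None, :]
    # interaction CpGs: breed-specific aging slopes (pigs only)
    g_dom = np.where(is_pig & ~is_minipig, rel_age, 0.0)
    g_min = np.where(is_minipig, rel_age, 0.0)
    betas[is_inter] += (
        slope_dom[is_inter, None] * shp(g_dom)[None, :]
        + slope_mini[is_inter, None] * shp(g_min)[None, :]
    )
    # tissue and sex signatures: constant class-specific offsets
    sig_tissue = np.array([""] * p, dtype=object)
    if cfg.n_tissue_signature_cpgs:
        tissues = sorted(samples["tissue"].unique())
        tissue_arr = samples["tissue"].to_numpy(object)
        for j, pi in enumerate(tissue_idx):
            t = tissues[j % len(tissues)]
            sig_tissue[pi] = t
            betas[pi] += cfg.tissue_signature_offset * (tissue_arr == t).astype(float)
    if cfg.n_sex_cpgs:
        is_male = (samples["sex"].to_numpy(object) == "M").astype(float)
        betas[is_sex] += cfg.sex_offset * is_male[None, :]
    # breed-baseline offsets and the minipig island methylation shift
    betas[is_base] += base_offset[is_base, None] * is_minipig[None, :].astype(float)
    betas[island] += cfg.minipig_island_offset * is_minipig[None, :].astype(float)
    if cfg.noise_sd > 0:
        betas += rng.normal(0.0, cfg.noise_sd, betas.shape)
    np.clip(betas, 0.0, 1.0, out=betas)

    probes = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": pos,
            "nearest_gene": nearest_gene,
            "dist_to_tss": dist_to_tss,
            "island": island,
            "mappable": mappable,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    truth = pd.DataFrame(
        {
            "is_age_cpg": is_age,
            "is_interaction_cpg": is_inter,
            "is_breed_baseline_cpg": is_base,
            "is_shared_species_cpg": is_shared,
            "age_associated": is_age | is_inter,
            "scope": scope,
            "direction": direction,
            "slope": slope,
            "slope_domestic": np.where(is_inter, slope_dom, np.where(m_pg | m_sh, slope, 0.0)),
            "slope_minipig": np.where(is_inter, slope_mini, np.where(m_pg | m_sh, slope, 0.0)),
            "baseline_offset": base_offset,
            "is_tissue_signature_cpg": is_tissue_sig,
            "signature_tissue": sig_tissue,
            "is_sex_cpg": is_sex,
        },
        index=probes.index,
    )
    ds = MethylationDataset(
        pd.DataFrame(betas, index=probes.index, columns=samples.index),
        samples,
        probes,
    )
    return ds, truth


def null_config(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of ``cfg`` with no planted effects (pure-noise null)."""
    return replace(
        cfg,
        frac_age_cpgs=0.0,
        n_breed_baseline_cpgs=0,
        n_interaction_cpgs=0,
        minipig_island_offset=0.0,
        n_tissue_signature_cpgs=0,
        n_sex_cpgs=0,
    )
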