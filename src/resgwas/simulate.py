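"""Synthetic layer-hen batch generator.

Emulates a single production batch of a purebred layer line: a two-generation
pedigree of maternal families hatched in three consecutive fortnights, a SNP
panel (macro-, micro- and Z-chromosomes) transmitted by Mendelian gene
dropping, polygenic natural-antibody (NAb) titers with plate and age-class
fixed effects, and daily egg laying driven by an individual potential curve
with stochastic disturbance episodes, culling, and interval registration.

All randomness flows through a single :class:`numpy.random.Generator`, so a
config plus a seed reproduces the batch byte-for-byte.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "Pedigree",
    "GenotypePanel",
    "EggLogSet",
    "SimulatedBatch",
    "default_snp_map",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_breeding_values",
    "simulate_nab_phenotypes",
    "simulate_egg_production",
    "simulate_batch",
]

MISSING_CALL = -1  # sentinel in int8 genotype matrices

LN2 = math.log(2.0)


class ConfigError(ValueError):
    """Raised for invalid simulation or pipeline configuration."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Parameters of the synthetic batch.

    Defaults reproduce the published batch: 2,494 hens in ~500 maternal
    families over 3 hatch weeks, a genotyped subset of 1,221 hens, a lay
    curve peaking at 6.8 eggs/wk at wk 29 and declining to 4.9 at wk 92,
    IgM/IgG titers with heritabilities 0.39/0.20, 146 ELISA plates, age
    classes 112/123/124/138 d and 12 barn rows.
    """

    # pedigree
    n_hens: int = 2494
    n_families: int = 500
    n_sires: int = 50
    hatch_week_props: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    n_rows: int = 12

    # genotyping
    n_genotyped: int = 1221
    genotyped_per_family: int = 5
    n_snps: int = 5000
    z_fraction: float = 0.05
    maf_low: float = 0.05
    maf_high: float = 0.95
    missing_rate: float = 0.0

    # lay curve (eggs/week anchors of the batch mean)
    onset_week: int = 18
    peak_week: int = 29
    peak_mean: float = 6.8
    end_week: int = 92
    end_mean: float = 4.9

    # genetics of production
    var_level: float = 0.15**2          # eggs/wk additive SD 0.15
    var_persistency: float = 0.01**2    # eggs/wk^2 slope SD
    corr_level_persistency: float = 0.0

    # disturbance episodes
    disturbance_rate: float = 0.015     # Poisson onsets per hen-week
    depth_low: float = 0.1
    depth_high: float = 0.8
    recovery_half_life: float = 1.5     # weeks

    # culling
    weekly_hazard: float = 0.0025
    hazard_start_week: int = 25

    # registration
    first_collection_week: int = 16
    boundary_overlap_quirk: bool = False  # allow intervals to straddle week ends

    # natural antibodies
    igm_mean: float = 6.85
    igm_var: float = 1.35               # sigma_a^2 + sigma_e^2
    igm_h2: float = 0.39
    igg_mean: float = 6.03
    igg_var: float = 1.65
    igg_h2: float = 0.20
    n_plates: int = 146
    plate_var: float = 0.10
    age_effects: dict[int, float] = field(
        default_factory=lambda: {112: 0.05, 123: 0.0, 124: 0.0, 138: -0.05}
    )

    def validate(self) -> None:
        if self.n_hens < 1 or self.n_families < 1 or self.n_sires < 1:
            raise ConfigError("n_hens, n_families and n_sires must be >= 1")
        if self.n_hens < self.n_families:
            raise ConfigError("need at least one hen per family")
        if not math.isclose(sum(self.hatch_week_props), 1.0, abs_tol=1e-9):
            raise ConfigError("hatch_week_props must sum to 1")
        for name in ("var_level", "var_persistency", "igm_var", "igg_var", "plate_var"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for name in ("missing_rate", "weekly_hazard", "igm_h2", "igg_h2"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        if not (0 < self.depth_low <= self.depth_high <= 1.0):
            raise ConfigError("disturbance depths must satisfy 0 < low <= high <= 1")
        if self.peak_mean > 7.0:
            raise ConfigError("peak_mean cannot exceed 7 eggs/week")
        if not (self.onset_week < self.peak_week < self.end_week):
            raise ConfigError("lay-curve weeks must be ordered onset < peak < end")
        if abs(self.corr_level_persistency) > 1:
            raise ConfigError("corr_level_persistency must be in [-1, 1]")


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class Pedigree:
    """Two-generation pedigree in parents-first order.

    ``table`` columns: animal, sire, dam, sex ('F'/'M'), hatch_week (0 for
    founders), plus generator metadata for hens (family, row). Unknown
    parents are empty strings.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.table.itertuples(index=False):
            if rec.animal in seen:
                raise ValueError(f"duplicate animal id {rec.animal!r}")
            for parent in (rec.sire, rec.dam):
                if parent and parent == rec.animal:
                    raise ValueError(f"animal {rec.animal!r} is its own parent")
                if parent and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {rec.animal!r} does not precede it"
                    )
            seen.add(rec.animal)

    @property
    def animals(self) -> list[str]:
        return self.table["animal"].tolist()

    @property
    def hens(self) -> pd.DataFrame:
        """Phenotyped generation: females with both parents known."""
        t = self.table
        return t[(t["sex"] == "F") & (t["sire"] != "") & (t["dam"] != "")]

    def parent_indices(self) -> np.ndarray:
        """(n, 2) row indices of sire/dam per animal, -1 for unknown."""
        pos = {a: i for i, a in enumerate(self.table["animal"])}
        out = np.full((len(self.table), 2), -1, dtype=np.int64)
        for i, rec in enumerate(self.table.itertuples(index=False)):
            if rec.sire:
                out[i, 0] = pos[rec.sire]
            if rec.dam:
                out[i, 1] = pos[rec.dam]
        return out


@dataclass
class GenotypePanel:
    """Call matrix (individuals x SNPs, int8, 0/1/2, -1 missing) plus map."""

    ids: list[str]
    snp_map: pd.DataFrame  # snp_id, chromosome, position_bp [, founder_freq]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.ids), len(self.snp_map)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.snp_map)} SNPs"
            )

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_map)

    @property
    def is_z(self) -> np.ndarray:
        return (self.snp_map["chromosome"].astype(str) == "Z").to_numpy()

    def subset_individuals(self, keep: list[str]) -> "GenotypePanel":
        pos = {a: i for i, a in enumerate(self.ids)}
        idx = [pos[a] for a in keep]
        return GenotypePanel(list(keep), self.snp_map.copy(), self.calls[idx])

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(
            list(self.ids),
            self.snp_map.loc[mask].reset_index(drop=True),
            self.calls[:, np.asarray(mask)],
        )


@dataclass
class EggLogSet:
    """Interval egg-collection records for a batch.

    ``records``: long table (hen, day, eggs) with day = day of age of the
    collection; ``last_day``: per-hen last day alive (records never exceed
    it).
    """

    records: pd.DataFrame
    last_day: pd.Series

    def for_hen(self, hen: str) -> pd.DataFrame:
        return self.records[self.records["hen"] == hen]


@dataclass
class SimulatedBatch:
    config: SimulationConfig
    pedigree: Pedigree
    panel: GenotypePanel            # all pedigree animals
    genotyped_hens: list[str]
    breeding_values: dict[str, pd.Series]  # trait -> values per animal
    nab: pd.DataFrame               # hen, isotype, titer, plate, age_class
    egg_logs: EggLogSet


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator) -> Pedigree:
    """Founder sires/dams plus one generation of hens in maternal families.

    Each family is one dam mated to one of ``n_sires`` sires (paternal
    half-sib structure across families); family sizes are as even as
    possible; hatch week is assigned per family in the configured
    proportions; hens get a barn row round-robin within hatch week.
    """
    config.validate()
    nf, nh = config.n_families, config.n_hens
    sires = [f"S{i + 1:04d}" for i in range(config.n_sires)]
    dams = [f"D{i + 1:04d}" for i in range(nf)]

    rows: list[tuple] = []
    for s in sires:
        rows.append((s, "", "", "M", 0, -1, -1))
    for d in dams:
        rows.append((d, "", "", "F", 0, -1, -1))

    # family sizes: as even as possible
    base, extra = divmod(nh, nf)
    sizes = np.full(nf, base, dtype=int)
    sizes[: extra] += 1
    fam_sire = rng.integers(0, config.n_sires, size=nf)

    # hatch weeks per family in configured proportions
    props = np.asarray(config.hatch_week_props, dtype=float)
    counts = np.floor(props * nf).astype(int)
    while counts.sum() < nf:
        counts[int(np.argmax(props * nf - counts))] += 1
    hatch_of_family = np.repeat(np.arange(1, 4), counts)
    rng.shuffle(hatch_of_family)

    hen_no = 0
    row_counter = {1: 0, 2: 0, 3: 0}
    for f in range(nf):
        hw = int(hatch_of_family[f])
        for _ in range(sizes[f]):
            hen_no += 1
            barn_row = row_counter[hw] % config.n_rows + 1
            row_counter[hw] += 1
            rows.append(
                (f"H{hen_no:05d}", sires[fam_sire[f]], dams[f], "F", hw, f + 1, barn_row)
            )

    table = pd.DataFrame(
        rows, columns=["animal", "sire", "dam", "sex", "hatch_week", "family", "row"]
    )
    return Pedigree(table)


# ---------------------------------------------------------------------------
# SNP map and genotypes
# ---------------------------------------------------------------------------

# rough relative SNP-density weights for a layer chip: five macro-chromosomes,
# a block of micro-chromosomes, and Z
_CHROM_WEIGHTS = {
    "1": 0.20, "2": 0.15, "3": 0.11, "4": 0.09, "5": 0.06,
    "6": 0.04, "7": 0.04, "8": 0.03, "9": 0.03, "10": 0.03,
    "11": 0.025, "12": 0.025, "13": 0.02, "14": 0.02, "15": 0.02,
    "17": 0.015, "18": 0.015, "19": 0.015, "20": 0.015,
    "21": 0.01, "22": 0.01, "23": 0.01, "24": 0.01, "26": 0.01, "27": 0.01, "28": 0.01,
}


def default_snp_map(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """SNP map across macro-, micro- and Z-chromosomes with founder freqs."""
    weights = dict(_CHROM_WEIGHTS)
    total_auto = sum(weights.values())
    weights = {c: w / total_auto * (1 - config.z_fraction) for c, w in weights.items()}
    weights["Z"] = config.z_fraction
    chroms, props = zip(*weights.items())
    counts = np.floor(np.asarray(props) * config.n_snps).astype(int)
    while counts.sum() < config.n_snps:
        counts[int(np.argmax(np.asarray(props) * config.n_snps - counts))] += 1

    frames = []
    for chrom, cnt in zip(chroms, counts):
        if cnt == 0:
            continue
        span = int(2e8 * weights[chrom] / max(weights.values())) + 10 * cnt
        pos = np.sort(rng.choice(np.arange(1, span), size=cnt, replace=False))
        frames.append(pd.DataFrame({"chromosome": chrom, "position_bp": pos}))
    snp_map = pd.concat(frames, ignore_index=True)
    snp_map.insert(0, "snp_id", [f"snp{i + 1:06d}" for i in range(len(snp_map))])
    snp_map["founder_freq"] = rng.uniform(config.maf_low, config.maf_high, len(snp_map))
    return snp_map


def _generation_levels(parents: np.ndarray) -> list[np.ndarray]:
    """Partition animals into levels so parents are always in earlier levels."""
    n = parents.shape[0]
    level = np.zeros(n, dtype=int)
    for i in range(n):
        ps = parents[i]
        lv = 0
        for p in ps:
            if p >= 0:
                lv = max(lv, level[p] + 1)
        level[i] = lv
    return [np.flatnonzero(level == lv) for lv in range(level.max() + 1)]


def simulate_genotypes(
    pedigree: Pedigree,
    snp_map: pd.DataFrame,
    rng: np.random.Generator,
    missing_rate: float = 0.0,
) -> GenotypePanel:
    """Gene-drop genotypes through the pedigree.

    Founders draw Hardy-Weinberg genotypes at ``founder_freq``; offspring
    receive one allele per parent, independently per SNP (unlinked loci).
    On Z, females are hemizygous: dams and hens carry a single Z allele
    coded 0/2 (never 1); a hen's Z call is a single paternal allele.
    """
    if "founder_freq" not in snp_map.columns:
        raise ValueError("snp_map must carry founder_freq for gene dropping")
    freqs = snp_map["founder_freq"].to_numpy(dtype=float)
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("founder_freq must be strictly inside (0, 1)")

    n = len(pedigree.table)
    m = len(snp_map)
    is_z = (snp_map["chromosome"].astype(str) == "Z").to_numpy()
    sexes = pedigree.table["sex"].to_numpy()
    parents = pedigree.parent_indices()

    calls = np.empty((n, m), dtype=np.int8)
    for idx in _generation_levels(parents):
        founders = idx[parents[idx, 0] < 0]
        offspring = idx[parents[idx, 0] >= 0]
        if founders.size:
            g = rng.binomial(2, freqs, size=(founders.size, m)).astype(np.int8)
            # hemizygous Z for females: one allele, coded 0/2
            fem = sexes[founders] == "F"
            if fem.any() and is_z.any():
                hemi = rng.binomial(1, freqs[is_z], size=(int(fem.sum()), int(is_z.sum())))
                gz = g[fem]
                gz[:, is_z] = (2 * hemi).astype(np.int8)
                g[fem] = gz
            calls[founders] = g
        if offspring.size:
            gs = calls[parents[offspring, 0]].astype(np.float64)
            gd = calls[parents[offspring, 1]].astype(np.float64)
            pat = rng.binomial(1, gs / 2.0)
            mat = rng.binomial(1, gd / 2.0)
            g = (pat + mat).astype(np.int8)
            fem = sexes[offspring] == "F"
            if fem.any() and is_z.any():
                # females: single paternal Z allele, coded 0/2
                gz = g[fem]
                gz[:, is_z] = (2 * pat[fem][:, is_z]).astype(np.int8)
                g[fem] = gz
            calls[offspring] = g

    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls[mask] = MISSING_CALL

    return GenotypePanel(pedigree.animals, snp_map.reset_index(drop=True), calls)


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------


def simulate_breeding_values(
    pedigree: Pedigree, sigma_a2: float, rng: np.random.Generator
) -> pd.Series:
    """Additive genetic values: founders ~ N(0, sigma_a2), offspring = parent
    average + Mendelian-sampling deviate with variance sigma_a2 / 2.

    Inbreeding of parents is ignored (pedigree depth is 2 and founders are
    unrelated, so the non-inbred approximation is exact here). The implied
    covariance of values is A * sigma_a2.
    """
    if sigma_a2 < 0:
        raise ValueError("sigma_a2 must be >= 0")
    n = len(pedigree.table)
    parents = pedigree.parent_indices()
    values = np.zeros(n)
    if sigma_a2 > 0:
        sd = math.sqrt(sigma_a2)
        for idx in _generation_levels(parents):
            founders = idx[parents[idx, 0] < 0]
            offspring = idx[parents[idx, 0] >= 0]
            if founders.size:
                values[founders] = rng.normal(0.0, sd, founders.size)
            if offspring.size:
                mid = 0.5 * (values[parents[offspring, 0]] + values[parents[offspring, 1]])
                values[offspring] = mid + rng.normal(0.0, sd / math.sqrt(2.0), offspring.size)
    return pd.Series(values, index=pedigree.animals, name="breeding_value")


# ---------------------------------------------------------------------------
# natural antibodies
# ---------------------------------------------------------------------------


def _age_class_for_hatch_week(hw: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Age at sampling is confounded with hatch week: wk1 -> 112 d,
    wk2 -> 123 or 124 d, wk3 -> 138 d."""
    age = np.where(hw == 1, 112, np.where(hw == 3, 138, 0))
    second = hw == 2
    age = age + second * np.where(rng.random(hw.size) < 0.5, 123, 124)
    return age.astype(int)


def select_genotyped_hens(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator
) -> list[str]:
    """Random maternal families, up to ``genotyped_per_family`` random hens
    each, until ``n_genotyped`` hens are drawn."""
    hens = pedigree.hens
    fam_ids = hens["family"].unique()
    order = rng.permutation(fam_ids)
    chosen: list[str] = []
    for fam in order:
        if len(chosen) >= config.n_genotyped:
            break
        members = hens.loc[hens["family"] == fam, "animal"].to_numpy()
        k = min(config.genotyped_per_family, members.size, config.n_genotyped - len(chosen))
        chosen.extend(rng.choice(members, size=k, replace=False).tolist())
    chosen.sort()
    return chosen


def simulate_nab_phenotypes(
    pedigree: Pedigree,
    breeding_values: dict[str, pd.Series],
    config: SimulationConfig,
    rng: np.random.Generator,
    hens: list[str] | None = None,
) -> pd.DataFrame:
    """KLH-binding NAb titers per isotype: titer = mu + plate + age + a + e.

    Hens are assigned to plates in id order (~n/146 per plate); plate
    effects are Normal(0, plate_var); age-class effects follow hatch week.
    Returns a long table (hen, isotype, titer, plate, age_class).
    """
    tab = pedigree.hens.set_index("animal")
    if hens is None:
        hens = select_genotyped_hens(pedigree, config, rng)
    n = len(hens)
    hw = tab.loc[hens, "hatch_week"].to_numpy()
    age = _age_class_for_hatch_week(hw, rng)
    per_plate = max(1, math.ceil(n / config.n_plates))
    plate = np.arange(n) // per_plate + 1
    plate_eff = rng.normal(0.0, math.sqrt(config.plate_var), int(plate.max()))

    frames = []
    for isotype, mu, var, h2 in (
        ("IgM", config.igm_mean, config.igm_var, config.igm_h2),
        ("IgG", config.igg_mean, config.igg_var, config.igg_h2),
    ):
        a = breeding_values[isotype].reindex(hens).to_numpy()
        e = rng.normal(0.0, math.sqrt(var * (1 - h2)), n)
        age_eff = np.array([config.age_effects.get(int(x), 0.0) for x in age])
        titer = mu + plate_eff[plate - 1] + age_eff + a + e
        frames.append(
            pd.DataFrame(
                {"hen": hens, "isotype": isotype, "titer": titer,
                 "plate": plate, "age_class": age}
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# egg production
# ---------------------------------------------------------------------------


def batch_anchor_curve(config: SimulationConfig, weeks: np.ndarray) -> np.ndarray:
    """Target batch-mean curve: 0 before onset, linear rise onset->peak,
    linear decline peak->end (the two printed anchors)."""
    w = np.asarray(weeks, dtype=float)
    rise = (w - config.onset_week) / (config.peak_week - config.onset_week)
    fall = (w - config.peak_week) / (config.end_week - config.peak_week)
    curve = np.where(
        w <= config.peak_week,
        config.peak_mean * np.clip(rise, 0.0, 1.0),
        config.peak_mean + (config.end_mean - config.peak_mean) * fall,
    )
    return np.clip(curve, 0.0, None)


def expected_disturbance_multiplier(config: SimulationConfig) -> float:
    """Steady-state expected multiplicative loss from disturbance episodes.

    Episodes arrive at ``rate`` per hen-week and scale production by
    ``1 - depth * 2^(-k / half_life)`` in the k-th week after onset, so the
    expected total loss is ``rate * E[depth] * sum_k 2^(-k/half_life)``
    (the discrete geometric sum, since laying is sampled weekly).
    """
    mean_depth = 0.5 * (config.depth_low + config.depth_high)
    geom = 1.0 / (1.0 - 2.0 ** (-1.0 / config.recovery_half_life))
    loss = config.disturbance_rate * mean_depth * geom
    return max(1e-6, 1.0 - loss)


def simulate_egg_production(
    pedigree: Pedigree,
    bv_level: pd.Series,
    bv_persistency: pd.Series,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> EggLogSet:
    """Daily Bernoulli laying aggregated into interval collection records.

    Per hen and week, laying probability is
    ``clip((potential + level + persistency * max(0, w - peak)) * f, 0, 7) / 7``
    where the potential curve is the batch anchor curve divided by the
    expected disturbance multiplier (so the realized batch mean tracks the
    anchors) and ``f`` is the product of active disturbance factors
    ``1 - depth * 2^-(w - onset)/half_life``. Hens face a weekly culling
    hazard; records stop at death.
    """
    hens = pedigree.hens["animal"].tolist()
    n = len(hens)
    weeks = np.arange(config.onset_week, config.end_week + 1)
    nw = weeks.size
    potential = batch_anchor_curve(config, weeks) / expected_disturbance_multiplier(config)

    level = bv_level.reindex(hens).to_numpy()[:, None]
    pers = bv_persistency.reindex(hens).to_numpy()[:, None]
    post_peak = np.clip(weeks - config.peak_week, 0, None)[None, :]
    pot = potential[None, :] + level + pers * post_peak

    # disturbance factors
    factor = np.ones((n, nw))
    n_events = rng.poisson(config.disturbance_rate, size=(n, nw))
    hen_idx, week_idx = np.nonzero(n_events)
    reps = n_events[hen_idx, week_idx]
    hen_idx = np.repeat(hen_idx, reps)
    week_idx = np.repeat(week_idx, reps)
    depths = rng.uniform(config.depth_low, config.depth_high, hen_idx.size)
    for h, w0, d in zip(hen_idx, week_idx, depths):
        decay = d * np.power(2.0, -(np.arange(nw - w0)) / config.recovery_half_life)
        factor[h, w0:] *= 1.0 - decay

    p_week = np.clip(pot * factor, 0.0, 7.0) / 7.0

    # death days
    last_day = np.full(n, 7 * config.end_week - 1)
    hz = config.weekly_hazard
    if hz > 0:
        u = rng.random(n)
        n_risk_weeks = config.end_week - config.hazard_start_week + 1
        # geometric week of death counted from hazard_start_week
        death_wk = np.where(
            u < 1 - (1 - hz) ** n_risk_weeks,
            config.hazard_start_week + np.floor(np.log1p(-u) / math.log(1 - hz)).astype(int),
            np.iinfo(np.int64).max,
        )
        died = death_wk <= config.end_week
        if died.any():
            day_in_week = rng.integers(0, 7, n)
            last_day[died] = 7 * (death_wk[died] - 1) + day_in_week[died]

    # daily laying
    days = np.arange(7 * (config.onset_week - 1), 7 * config.end_week)
    week_of_day = days // 7 + 1
    p_day = p_week[:, week_of_day - config.onset_week]
    alive = days[None, :] <= last_day[:, None]
    eggs_day = (rng.random(p_day.shape) < p_day) & alive

    # farm-wide collection schedule with 1-4 day gaps; by default a
    # collection is forced on each age-week's last day so no interval
    # straddles a week boundary (weekly registered counts stay <= 7)
    start = 7 * (config.first_collection_week - 1)
    end = 7 * config.end_week - 1
    gaps = rng.integers(1, 5, size=end - start + 1)
    sched = start + np.cumsum(gaps)
    sched = sched[sched <= end]
    if not config.boundary_overlap_quirk:
        week_ends = np.arange(start + 6, end + 1, 7)
        sched = np.union1d(sched, week_ends)
    sched = np.union1d(sched, [end])

    # cumulative eggs over simulated days, indexed by absolute day
    cum = np.zeros((n, days.size + 1), dtype=np.int64)
    np.cumsum(eggs_day, axis=1, out=cum[:, 1:])

    def cum_at(day: np.ndarray) -> np.ndarray:
        # eggs laid on days < day + 1 within the simulated window
        pos = np.clip(day + 1 - days[0], 0, days.size)
        return cum[:, pos]

    prev = np.concatenate([[start - 1], sched[:-1]])
    per_record = cum_at(sched) - cum_at(prev)  # n x n_records

    # build long records, truncated at each hen's last day alive
    keep = sched[None, :] <= last_day[:, None]
    hen_rep = np.repeat(np.arange(n), keep.sum(axis=1))
    day_rep = np.concatenate([sched[k] for k in keep])
    egg_rep = per_record[keep]
    records = pd.DataFrame(
        {"hen": np.asarray(hens, dtype=object)[hen_rep], "day": day_rep, "eggs": egg_rep}
    )
    return EggLogSet(records, pd.Series(last_day, index=hens, name="last_day"))


# ---------------------------------------------------------------------------
# batch orchestration
# ---------------------------------------------------------------------------


def simulate_batch(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedBatch:
    """Generate a complete batch (pedigree, genotypes, NAbs, egg logs)."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    ped = simulate_pedigree(config, rng)
    snp_map = default_snp_map(config, rng)
    panel = simulate_genotypes(ped, snp_map, rng, config.missing_rate)
    bvs = {
        "IgM": simulate_breeding_values(ped, config.igm_var * config.igm_h2, rng),
        "IgG": simulate_breeding_values(ped, config.igg_var * config.igg_h2, rng),
        "level": simulate_breeding_values(ped, config.var_level, rng),
        "persistency": simulate_breeding_values(ped, config.var_persistency, rng),
    }
    genotyped = select_genotyped_hens(ped, config, rng)
    nab = simulate_nab_phenotypes(ped, bvs, config, rng, hens=genotyped)
    logs = simulate_egg_production(ped, bvs["level"], bvs["persistency"], config, rng)
    return SimulatedBatch(config, ped, panel, genotyped, bvs, nab, logs)


def small_config(**overrides) -> SimulationConfig:
    """A fast, reduced-scale configuration for examples and smoke tests."""
    base = SimulationConfig(
        n_hens=300, n_families=60, n_sires=12, n_genotyped=150, n_snps=400
    )
    return replace(base, **overrides)
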