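"""Synthetic two-transect community datasets with known ground truth.

The generator emulates the sampling design of a grassland aridity-gradient
isotope survey: two transects of roughly ten sites each, species richness
declining toward the dry end, site-mean intrinsic water-use efficiency
(iWUE) rising and its community coefficient of variation falling with
aridity, most iWUE variance residing within sites, a small C4 subpopulation
with enriched delta13C, leaf traits (Delta18O, SLA, N per area) coupled to
iWUE with configurable correlations, and a Yule phylogeny carrying no trait
signal by construction.

Every latent quantity the downstream statistics are meant to recover (site
mean targets, variance fractions, trait correlations, regression slopes) is
echoed back in a truth dictionary, so parameter-recovery tests can compare
estimate against truth without re-deriving it.

Construction of a record's iWUE is additive Gaussian:

    iwue = mu(site) + e_species + e_species_x_site + e_residual(site)

with mu(site) linear in aridity plus site-level noise.  Variance fractions
``var_frac_*`` are shares of the total record variance T; the within-site
residual standard deviation varies linearly with aridity (through the CV
targets), which is what produces community convergence at the dry end.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, asdict
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .errors import ConfigurationError, DomainError
from .isotopes import (
    DEFAULT_CONSTANTS,
    DiscriminationConstants,
    leaf_delta13C_for_target_iwue,
)
from .phylo import vcv_matrix

__all__ = [
    "EnvironmentModel",
    "TraitCorrelations",
    "TransectConfig",
    "SyntheticDataset",
    "aridity_index",
    "saturation_vapor_pressure",
    "vpd_from_vapor_pressure",
    "generate_transect",
    "generate_phylogeny",
    "generate_trait_on_tree",
    "two_transect_study",
    "fixed_count_dataset",
]

# Magnus coefficients for saturation vapour pressure over water, kPa / degC.
_MAGNUS_A = 0.6108
_MAGNUS_B = 17.27
_MAGNUS_C = 237.3


def aridity_index(mean_annual_precipitation, potential_evapotranspiration):
    """Aridity = 1 - MAP/PET; higher is drier."""
    map_ = np.asarray(mean_annual_precipitation, dtype=float)
    pet = np.asarray(potential_evapotranspiration, dtype=float)
    if np.any(pet <= 0):
        raise DomainError("potential evapotranspiration must be positive")
    if np.any(map_ < 0):
        raise DomainError("precipitation cannot be negative")
    out = 1.0 - map_ / pet
    return out if out.ndim else float(out)


def saturation_vapor_pressure(temperature_c):
    """Magnus-form saturation vapour pressure, kPa."""
    t = np.asarray(temperature_c, dtype=float)
    out = _MAGNUS_A * np.exp(_MAGNUS_B * t / (t + _MAGNUS_C))
    return out if out.ndim else float(out)


def vpd_from_vapor_pressure(temperature_c, actual_vapor_pressure_kpa):
    """Vapour pressure deficit es(T) - ea, kPa, clipped at zero.

    Supersaturated inputs (ea > es) are clipped to zero; callers that need
    to know can compare the returned value against es - ea themselves.
    """
    ea = np.asarray(actual_vapor_pressure_kpa, dtype=float)
    if np.any(ea < 0):
        raise DomainError("actual vapour pressure cannot be negative")
    out = np.clip(saturation_vapor_pressure(temperature_c) - ea, 0.0, None)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class EnvironmentModel:
    """Linear maps from aridity to site covariates, plus noise scales.

    Soil moisture and the soil organic-carbon to total-nitrogen ratio
    decline with aridity; temperature rises and relative humidity falls, so
    vapour pressure deficit (derived through the Magnus formula) rises.
    Source-water delta18O becomes more depleted toward the continental dry
    end.  Atmospheric CO2 and its delta13C are held constant across sites
    by default (growing-season values; both remain per-site columns and may
    be overridden).
    """

    sm_intercept: float = 0.38
    sm_slope: float = -0.32
    sm_sd: float = 0.012
    temp_intercept: float = 15.0
    temp_slope: float = 10.0
    rh_intercept: float = 0.78
    rh_slope: float = -0.58
    soctn_intercept: float = 15.0
    soctn_slope: float = -6.0
    soctn_sd: float = 0.35
    source_water_intercept: float = -5.0
    source_water_slope: float = -6.0
    Ca: float = 400.0
    delta13C_air: float = -8.5


@dataclass(frozen=True)
class TraitCorrelations:
    """Target Pearson correlations of leaf traits with iWUE."""

    d18o: float = 0.55
    n_area: float = 0.45
    sla: float = -0.55

    def as_vector(self) -> np.ndarray:
        return np.array([self.d18o, self.n_area, self.sla])


@dataclass(frozen=True)
class TransectConfig:
    """Generating parameters for one transect.

    ``var_frac_*`` are shares of total record variance attributed to
    species identity, site (aridity trend plus site noise) and the
    species-by-site interaction; the remainder is within-record residual.
    ``iwue_cv_*`` set the per-site community CV (%) of iWUE as a linear
    function of aridity and thereby control how the residual scale varies
    along the gradient.  ``species_block_sites`` gives the (min, max)
    number of contiguous sites a species occupies; ``None`` puts every
    species at every site (a balanced design, used by calibration tests).
    """

    n_sites: int = 10
    aridity_range: tuple[float, float] = (0.42, 0.83)
    richness_at_low_aridity: int = 45
    richness_slope: float = -35.0
    iwue_mean_intercept: float = 30.0
    iwue_mean_slope: float = 90.0
    iwue_cv_intercept: float = 40.0
    iwue_cv_slope: float = -25.0
    var_frac_species: float = 0.50
    var_frac_site: float = 0.25
    var_frac_interaction: float = 0.15
    c4_fraction: float = 0.09
    trait_correlations: TraitCorrelations = field(default_factory=TraitCorrelations)
    env_model: EnvironmentModel = field(default_factory=EnvironmentModel)
    replicates_per_species: int = 1
    species_block_sites: Optional[tuple[int, int]] = (3, 6)
    seed: int = 0

    def validate(self) -> None:
        fr = (self.var_frac_species, self.var_frac_site, self.var_frac_interaction)
        if any(f < 0 for f in fr) or sum(fr) >= 1:
            raise ConfigurationError(
                "variance fractions must be non-negative and sum to < 1"
            )
        if self.n_sites < 2:
            raise ConfigurationError("need at least 2 sites")
        if not 0 <= self.c4_fraction < 1:
            raise ConfigurationError("c4_fraction must lie in [0, 1)")
        lo, hi = self.aridity_range
        if not (0 < lo < hi < 1):
            raise ConfigurationError("aridity_range must satisfy 0 < low < high < 1")
        if self.richness_at_low_aridity < 3:
            raise ConfigurationError("richness_at_low_aridity must be >= 3")
        # One-factor Gaussian copula: full correlation matrix must be PD.
        rho = self.trait_correlations.as_vector()
        if np.any(np.abs(rho) >= 1):
            raise ConfigurationError("trait correlations must lie strictly in (-1, 1)")
        full = np.eye(4)
        full[0, 1:] = full[1:, 0] = rho
        full[1:, 1:] += np.outer(rho, rho) - np.diag(rho**2)
        try:
            np.linalg.cholesky(full)
        except np.linalg.LinAlgError as exc:
            raise ConfigurationError(
                "trait correlation targets imply a non-positive-definite matrix"
            ) from exc


@dataclass
class SyntheticDataset:
    """Generated tables, phylogeny, and the generating truth."""

    leaf_samples: pd.DataFrame
    sites: pd.DataFrame
    phylogeny: Optional[dendropy.Tree]
    truth: dict


def generate_phylogeny(
    n_tips: int, seed: int, tip_labels: Optional[list[str]] = None
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree with unit birth rate.

    The simulator stops at the n-th speciation, which leaves the last
    terminal branches at length zero; the correct completion is to let all
    extant lineages grow for one further exponential waiting time, which is
    added here so terminal branches are strictly positive and tips stay
    contemporaneous.
    """
    if n_tips < 2:
        raise DomainError("a phylogeny needs at least 2 tips")
    rng = random.Random(seed)
    tree = birthdeath.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips, rng=rng
    )
    extra = rng.expovariate(n_tips * 1.0)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    labels = tip_labels or [f"sp{i:04d}" for i in range(1, n_tips + 1)]
    if len(labels) != n_tips:
        raise DomainError("tip_labels length must equal n_tips")
    for leaf, lab in zip(tree.leaf_node_iter(), labels):
        leaf.taxon.label = lab
    return tree


def generate_trait_on_tree(
    tree: dendropy.Tree, model: str, sigma2: float, seed: int
) -> dict[str, float]:
    """Simulate a tip trait: Brownian motion, or Brownian with shuffled tips.

    ``brownian`` draws from the multivariate normal with covariance
    sigma2 * C (C = shared path lengths); ``shuffled`` takes the same draw
    and randomly permutes the tip labels, destroying the signal while
    keeping the trait distribution.
    """
    if sigma2 <= 0:
        raise DomainError("sigma2 must be positive")
    if model not in {"brownian", "shuffled"}:
        raise DomainError(f"unknown trait model: {model!r}")
    labels, C = vcv_matrix(tree)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(sigma2 * C)
    x = L @ rng.standard_normal(len(labels))
    if model == "shuffled":
        labels = list(rng.permutation(labels))
    return dict(zip(labels, x.tolist()))


def _site_table(cfg: TransectConfig, rng: np.random.Generator) -> pd.DataFrame:
    em = cfg.env_model
    aridity = np.linspace(*cfg.aridity_range, cfg.n_sites)
    temp = em.temp_intercept + em.temp_slope * aridity
    ea = saturation_vapor_pressure(temp) * (em.rh_intercept + em.rh_slope * aridity)
    sm = np.clip(
        em.sm_intercept + em.sm_slope * aridity + rng.normal(0, em.sm_sd, cfg.n_sites),
        0.01,
        0.99,
    )
    soctn = np.clip(
        em.soctn_intercept
        + em.soctn_slope * aridity
        + rng.normal(0, em.soctn_sd, cfg.n_sites),
        1.0,
        None,
    )
    return pd.DataFrame(
        {
            "site_id": [f"S{i + 1:02d}" for i in range(cfg.n_sites)],
            "aridity": aridity,
            "SM": sm,
            "VPD": vpd_from_vapor_pressure(temp, ea),
            "SOC_TN": soctn,
            "delta18O_source": em.source_water_intercept
            + em.source_water_slope * aridity,
            "delta13C_air": em.delta13C_air,
            "Ca": em.Ca,
        }
    )


def _species_blocks(cfg: TransectConfig, aridity: np.ndarray, rng: np.random.Generator):
    """Assign species to contiguous site blocks so richness tracks aridity."""
    n = cfg.n_sites
    blocks: list[tuple[str, int, int]] = []  # (species_id, first, last)
    if cfg.species_block_sites is None:
        r0 = cfg.richness_at_low_aridity
        return [(f"sp{k:04d}", 0, n - 1) for k in range(1, r0 + 1)]
    lo, hi = cfg.species_block_sites
    counter = 0
    active_until = []  # exclusive end site of each created species
    for i in range(n):
        target = max(3, round(cfg.richness_at_low_aridity
                              + cfg.richness_slope * (aridity[i] - aridity[0])))
        n_active = sum(1 for end in active_until if end > i)
        for _ in range(target - n_active):
            counter += 1
            length = int(rng.integers(lo, hi + 1))
            end = min(i + length, n)
            blocks.append((f"sp{counter:04d}", i, end - 1))
            active_until.append(end)
    return blocks


def generate_transect(config: TransectConfig) -> SyntheticDataset:
    """Generate one transect: leaf samples, site table, phylogeny, truth.

    See the module docstring for the generative model.  Fully reproducible:
    the same config (including its seed) yields identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sites = _site_table(config, rng)
    aridity = sites["aridity"].to_numpy()
    constants = DEFAULT_CONSTANTS

    # Variance budget (see module docstring).
    mu_site = config.iwue_mean_intercept + config.iwue_mean_slope * aridity
    cv_site = config.iwue_cv_intercept + config.iwue_cv_slope * aridity
    if np.any(mu_site <= 0) or np.any(cv_site <= 0):
        raise ConfigurationError("iWUE mean/CV targets must be positive at all sites")
    s2_within = (cv_site / 100.0 * mu_site) ** 2  # within-site variance targets
    f_within = 1.0 - config.var_frac_site
    T = float(np.mean(s2_within)) / f_within  # total variance scale
    sd_species = math.sqrt(config.var_frac_species * T)
    sd_interaction = math.sqrt(config.var_frac_interaction * T)
    trend_var = float(np.var(config.iwue_mean_slope * aridity))
    site_noise_var = max(config.var_frac_site * T - trend_var, 0.0)
    sd_site_noise = math.sqrt(site_noise_var)
    res_var = np.maximum(s2_within - sd_species**2 - sd_interaction**2, 1e-12)

    mu_realized = mu_site + rng.normal(0, sd_site_noise, config.n_sites)

    blocks = _species_blocks(config, aridity, rng)
    species_ids = [b[0] for b in blocks]
    species_effect = {sp: rng.normal(0, sd_species) for sp in species_ids}
    is_c4 = {sp: bool(rng.random() < config.c4_fraction) for sp in species_ids}

    rows = []
    for sp, first, last in blocks:
        for i in range(first, last + 1):
            e_cell = rng.normal(0, sd_interaction)
            for _ in range(config.replicates_per_species):
                if is_c4[sp]:
                    rows.append((sp, i, np.nan, True))
                else:
                    w = (
                        mu_realized[i]
                        + species_effect[sp]
                        + e_cell
                        + rng.normal(0, math.sqrt(res_var[i]))
                    )
                    rows.append((sp, i, w, False))
    leaf = pd.DataFrame(rows, columns=["species_id", "site_idx", "iwue_true", "is_c4"])
    leaf["site_id"] = sites["site_id"].to_numpy()[leaf["site_idx"]]

    # Leaf delta13C: inversion of the discrimination chain for C3 records,
    # a uniform enriched draw for C4 records.
    c3 = ~leaf["is_c4"].to_numpy()
    upper = constants.diffusion_ratio  # Ca cancels below; clip in iWUE space
    ca = sites["Ca"].to_numpy()[leaf["site_idx"]]
    iwue = leaf["iwue_true"].to_numpy().copy()
    iwue[c3] = np.clip(iwue[c3], 1.0, ca[c3] / upper - 1.0)
    leaf["iwue_true"] = np.where(c3, iwue, np.nan)
    d13_air = sites["delta13C_air"].to_numpy()[leaf["site_idx"]]
    delta13 = np.empty(len(leaf))
    delta13[c3] = leaf_delta13C_for_target_iwue(
        iwue[c3], ca[c3], d13_air[c3], constants
    )
    delta13[~c3] = rng.uniform(-16.0, -11.0, int((~c3).sum()))
    leaf["delta13C_leaf"] = delta13

    # Traits from a one-factor Gaussian copula on the standardized iWUE
    # deviation; C4 records get uncoupled draws (their iWUE scale differs).
    z = np.empty(len(leaf))
    z[c3] = (iwue[c3] - iwue[c3].mean()) / iwue[c3].std(ddof=1)
    z[~c3] = rng.standard_normal(int((~c3).sum()))
    rho = config.trait_correlations
    eps = rng.standard_normal((len(leaf), 3))

    def factor(r, col):
        return r * z + math.sqrt(1 - r * r) * eps[:, col]

    d18o_enrich = 30.0 + 4.0 * factor(rho.d18o, 0)
    n_area = np.clip(2.0 + 0.45 * factor(rho.n_area, 1), 0.05, None)
    sla = np.clip(16.0 + 3.2 * factor(rho.sla, 2), 0.5, None)
    d18o_src = sites["delta18O_source"].to_numpy()[leaf["site_idx"]]
    leaf["delta18O_leaf"] = d18o_enrich * (1.0 + d18o_src / 1000.0) + d18o_src
    leaf["SLA"] = sla
    leaf["N_area"] = n_area

    c3_species = sorted(sp for sp in species_ids if not is_c4[sp])
    phylogeny = None
    if len(c3_species) >= 2:
        # Random tip assignment: species ids are ordered by site block, and
        # traversal-order labelling would alias spatial structure into
        # phylogenetic signal.
        shuffled = list(rng.permutation(c3_species))
        phylogeny = generate_phylogeny(
            len(c3_species), seed=int(rng.integers(0, 2**31 - 1)),
            tip_labels=shuffled,
        )

    leaf_out = leaf[
        ["species_id", "site_id", "delta13C_leaf", "delta18O_leaf", "SLA", "N_area"]
    ].reset_index(drop=True)

    truth = {
        "config": asdict(config),
        "site_mean_target": mu_site.tolist(),
        "site_mean_realized": mu_realized.tolist(),
        "site_cv_target_pct": cv_site.tolist(),
        "total_variance_scale": T,
        "sd_species": sd_species,
        "sd_interaction": sd_interaction,
        "sd_site_noise": sd_site_noise,
        "residual_variance_by_site": res_var.tolist(),
        "record_iwue_true": leaf["iwue_true"].tolist(),
        "n_species": len(species_ids),
        "n_c4_species": sum(is_c4.values()),
        "within_site_share_pct": 100.0 * (1.0 - config.var_frac_site),
    }
    return SyntheticDataset(
        leaf_samples=leaf_out, sites=sites, phylogeny=phylogeny, truth=truth
    )


def two_transect_study(seed: int = 0) -> dict[str, SyntheticDataset]:
    """The default two-transect study design.

    One short, moderately arid transect (aridity 0.51-0.63, the loess-type
    gradient) and one long, strongly contrasting transect (0.42-0.83, the
    steppe-type gradient), ten sites each, richness declining with aridity.
    """
    lp = TransectConfig(
        aridity_range=(0.51, 0.63),
        richness_at_low_aridity=58,
        richness_slope=-40.0,
        c4_fraction=0.096,
        seed=seed,
    )
    mp = TransectConfig(
        aridity_range=(0.42, 0.83),
        richness_at_low_aridity=48,
        richness_slope=-35.0,
        c4_fraction=0.072,
        seed=seed + 1,
    )
    return {"LP": generate_transect(lp), "MP": generate_transect(mp)}


def fixed_count_dataset(
    n_records: int = 574, n_c4: int = 55, seed: int = 0
) -> SyntheticDataset:
    """A dataset with an exact record count and C4 count.

    Used for filter-bookkeeping checks: downstream the C3 filter must
    retain exactly ``n_records - n_c4`` records.  Built by generating a
    transect and then topping up / trimming record counts per pathway.
    """
    if n_c4 >= n_records:
        raise ConfigurationError("n_c4 must be smaller than n_records")
    cfg = TransectConfig(
        richness_at_low_aridity=70, richness_slope=-30.0, c4_fraction=0.12, seed=seed
    )
    ds = generate_transect(cfg)
    leaf = ds.leaf_samples
    c4_mask = leaf["delta13C_leaf"].to_numpy() >= -20.0
    c3_rows = leaf[~c4_mask]
    c4_rows = leaf[c4_mask]
    n_c3 = n_records - n_c4
    if len(c3_rows) < n_c3 or len(c4_rows) < n_c4:
        raise ConfigurationError("base transect too small for requested counts")
    leaf_out = pd.concat(
        [c3_rows.iloc[:n_c3], c4_rows.iloc[:n_c4]], ignore_index=True
    )
    truth = dict(ds.truth, n_records=n_records, n_c4_records=n_c4)
    return SyntheticDataset(
        leaf_samples=leaf_out, sites=ds.sites, phylogeny=ds.phylogeny, truth=truth
    )
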