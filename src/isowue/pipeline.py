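"""End-to-end pipeline: derive -> filter -> statistics -> partitions ->
gradient -> ordination -> phylogenetic signal, with a reproducible report
bundle.

A run is driven by a :class:`PipelineConfig` holding, per transect, either
paths to input tables (and an optional Newick tree) or a simulation block.
Outputs are plain delimited text plus a JSON manifest that echoes the
configuration, the seed, and the row counts at every filter step, so
``rows_in == rows_retained + rows_dropped`` is auditable.  Identical
config and seed produce byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import community, gradient, phylo, simulate, traits, varcomp
from .errors import ConfigurationError, DomainError, ValidationError
from .isotopes import DiscriminationConstants, derive_traits

__all__ = ["PipelineConfig", "TransectInput", "run_pipeline", "validate_inputs"]

log = logging.getLogger("isowue")

LEAF_COLUMNS = ["species_id", "site_id", "delta13C_leaf", "delta18O_leaf", "SLA", "N_area"]
SITE_COLUMNS = [
    "site_id", "aridity", "SM", "VPD", "SOC_TN",
    "delta18O_source", "delta13C_air", "Ca",
]
_CSV_KW = dict(index=False, float_format="%.10g", lineterminator="\n")


@dataclass
class TransectInput:
    """One transect's data source: file paths or a simulation block."""

    name: str
    leaf_samples: Optional[str] = None
    sites: Optional[str] = None
    tree: Optional[str] = None
    simulate: Optional[simulate.TransectConfig] = None

    def __post_init__(self) -> None:
        has_paths = self.leaf_samples is not None and self.sites is not None
        if has_paths == (self.simulate is not None):
            raise ConfigurationError(
                f"transect {self.name!r}: provide either input paths or a "
                "simulate block, not both"
            )


@dataclass
class PipelineConfig:
    transects: list[TransectInput] = field(default_factory=list)
    constants: DiscriminationConstants = field(default_factory=DiscriminationConstants)
    drop_c4: bool = True
    drop_out_of_range: bool = False
    r2_kind: str = "adjusted"
    pooled: bool = False
    n_permutations: int = 999
    seed: int = 0
    out_dir: str = "isowue_report"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        transects = []
        for name, block in raw.get("transects", {}).items():
            sim = block.get("simulate")
            if sim is not None:
                for key in ("trait_correlations", "env_model"):
                    if key in sim:
                        klass = (
                            simulate.TraitCorrelations
                            if key == "trait_correlations"
                            else simulate.EnvironmentModel
                        )
                        sim[key] = klass(**sim[key])
                if "aridity_range" in sim:
                    sim["aridity_range"] = tuple(sim["aridity_range"])
                if sim.get("species_block_sites") is not None:
                    sim["species_block_sites"] = tuple(sim["species_block_sites"])
                sim = simulate.TransectConfig(**sim)
            transects.append(
                TransectInput(
                    name=name,
                    leaf_samples=block.get("leaf_samples"),
                    sites=block.get("sites"),
                    tree=block.get("tree"),
                    simulate=sim,
                )
            )
        kwargs = {
            k: raw[k]
            for k in (
                "drop_c4", "drop_out_of_range", "r2_kind", "pooled",
                "n_permutations", "seed", "out_dir",
            )
            if k in raw
        }
        if "constants" in raw:
            kwargs["constants"] = DiscriminationConstants(**raw["constants"])
        kwargs.update(overrides)
        return cls(transects=transects, **kwargs)


def validate_inputs(
    leaf: pd.DataFrame, sites: pd.DataFrame, tree: Optional[dendropy.Tree] = None
) -> list[str]:
    """Schema and sanity checks; returns a list of issue strings (empty = ok)."""
    issues: list[str] = []
    for col in LEAF_COLUMNS:
        if col not in leaf.columns:
            issues.append(f"leaf table missing column {col!r}")
    for col in SITE_COLUMNS:
        if col not in sites.columns:
            issues.append(f"site table missing column {col!r}")
    if issues:
        return issues
    known = set(sites["site_id"])
    for i, sid in enumerate(leaf["site_id"]):
        if sid not in known:
            issues.append(f"leaf row {i}: unknown site_id {sid!r}")
    dup = leaf.duplicated(subset=["species_id", "site_id"])
    for i in leaf.index[dup]:
        issues.append(f"leaf row {i}: duplicate (species_id, site_id)")
    bad13 = (leaf["delta13C_leaf"] < -40) | (leaf["delta13C_leaf"] > 0)
    for i in leaf.index[bad13 | ~np.isfinite(leaf["delta13C_leaf"])]:
        issues.append(
            f"leaf row {i}: delta13C_leaf={leaf.loc[i, 'delta13C_leaf']} "
            "outside [-40, 0]"
        )
    for col in ("SLA", "N_area"):
        for i in leaf.index[leaf[col] <= 0]:
            issues.append(f"leaf row {i}: {col} must be positive")
    if (sites["Ca"] <= 0).any():
        issues.append("site table: Ca must be positive")
    if ((sites["aridity"] <= 0) | (sites["aridity"] >= 1)).any():
        issues.append("site table: aridity must lie in (0, 1)")
    if ((sites["SM"] <= 0) | (sites["SM"] >= 1)).any():
        issues.append("site table: SM must lie in (0, 1)")
    if (sites["VPD"] < 0).any():
        issues.append("site table: VPD must be non-negative")
    if tree is not None:
        tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
        absent = set(leaf["species_id"]) - tips
        if absent:
            issues.append(f"{len(absent)} species absent from the tree")
    return issues


def _load_transect(tr: TransectInput, seed: int):
    if tr.simulate is not None:
        cfg = dataclasses.replace(tr.simulate, seed=tr.simulate.seed + seed)
        ds = simulate.generate_transect(cfg)
        return ds.leaf_samples, ds.sites, ds.phylogeny, ds.truth
    leaf = pd.read_csv(tr.leaf_samples)
    sites = pd.read_csv(tr.sites)
    tree = None
    if tr.tree:
        tree = dendropy.Tree.get(path=tr.tree, schema="newick")
    return leaf, sites, tree, None


def _analyse_transect(
    name: str,
    leaf: pd.DataFrame,
    sites: pd.DataFrame,
    tree: Optional[dendropy.Tree],
    cfg: PipelineConfig,
    out: Path,
    manifest: dict,
) -> None:
    tdir = out / name
    tdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {"rows_in": len(leaf)}

    derived = derive_traits(leaf, sites, cfg.constants)
    derived.to_csv(tdir / "derived_traits.csv", **_CSV_KW)

    kept = derived
    dropped_c4 = 0
    if cfg.drop_c4:
        mask = kept["pathway"] == "C3"
        dropped_c4 = int((~mask).sum())
        kept = kept[mask]
    dropped_oor = 0
    if cfg.drop_out_of_range:
        mask = ~kept["flags"].str.contains("ci_ca_out_of_range")
        dropped_oor = int((~mask).sum())
        kept = kept[mask]
    counts.update(
        rows_dropped_c4=dropped_c4,
        rows_dropped_out_of_range=dropped_oor,
        rows_retained=len(kept),
    )
    assert counts["rows_in"] == counts["rows_retained"] + dropped_c4 + dropped_oor
    if len(kept) == 0:
        raise DomainError(f"transect {name}: no records left after filtering")
    log.info("%s: %d records retained of %d", name, len(kept), len(leaf))

    # Per-site distribution characteristics.
    site_stats = community.site_distribution_table(kept)
    site_stats = site_stats.merge(
        sites[["site_id", "aridity", "SM", "VPD", "SOC_TN"]], on="site_id"
    )
    site_stats.rename(columns={"mean": "iWUE_mean", "cv": "iWUE_cv"}, inplace=True)
    site_stats.to_csv(tdir / "site_distributions.csv", **_CSV_KW)

    # Variance partitions.
    vc = varcomp.partition_species_site(kept)
    vc.ss_table.to_csv(tdir / "variance_components_ss.csv", **_CSV_KW)
    pct_within, pct_among = community.within_among_partition(
        kept[["site_id", "iWUE"]]
    )
    pd.DataFrame(
        {
            "pct_species": [vc.pct_species],
            "pct_site": [vc.pct_site],
            "pct_interaction": [vc.pct_interaction],
            "model_r2": [vc.model_r2],
            "pct_within_site": [pct_within],
            "pct_among_site": [pct_among],
        }
    ).to_csv(tdir / "variance_partition.csv", **_CSV_KW)

    # Gradient regressions of every distribution characteristic on aridity.
    fits = []
    for stat in ("iWUE_mean", "variance", "sd", "iWUE_cv", "range", "skewness", "kurtosis"):
        sub = site_stats.dropna(subset=[stat])
        if len(sub) >= 3 and np.ptp(sub["aridity"]) > 0:
            fit = gradient.linear_regression(sub["aridity"], sub[stat])
            fits.append({"statistic": stat, **dataclasses.asdict(fit)})
    pd.DataFrame(fits).to_csv(tdir / "aridity_regressions.csv", **_CSV_KW)

    # Correlation table and variation partitioning, mean and CV.
    corr = gradient.pearson_table(
        site_stats[["site_id", "iWUE_mean", "iWUE_cv"]], sites
    )
    corr.columns = [f"{a}_{b}" for a, b in corr.columns]
    corr.to_csv(tdir / "correlations.csv", index=True, lineterminator="\n",
                float_format="%.10g")
    parts = []
    for stat in ("iWUE_mean", "iWUE_cv"):
        for kind in ("raw", "adjusted"):
            pf = gradient.variation_partition(
                site_stats[stat],
                site_stats[["SM", "VPD"]].to_numpy(),
                site_stats[["SOC_TN"]].to_numpy(),
                r2_kind=kind,
            )
            parts.append({"statistic": stat, **dataclasses.asdict(pf)})
    pd.DataFrame(parts).to_csv(tdir / "variation_partition.csv", **_CSV_KW)

    # Trait-spectrum ordinations.
    table4 = kept.set_index(kept.index)[list(traits.TRAIT_COLUMNS)]
    full = traits.pca(table4)
    reduced = traits.pca_excluding(table4, "iWUE")
    full.loadings.to_csv(tdir / "pca_full_loadings.csv", lineterminator="\n",
                         float_format="%.10g")
    reduced.loadings.to_csv(tdir / "pca_traits_loadings.csv", lineterminator="\n",
                            float_format="%.10g")
    pd.DataFrame(
        {
            "axis": [f"Axis{i + 1}" for i in range(len(full.eigenvalues))],
            "eigenvalue_full": full.eigenvalues,
            "variance_explained_full_pct": full.variance_explained,
        }
    ).to_csv(tdir / "pca_full_eigenvalues.csv", **_CSV_KW)
    axis_fits = traits.iwue_vs_axis_scores(
        reduced.scores, table4.loc[reduced.scores.index, "iWUE"]
    )
    pd.DataFrame(
        [{"axis": ax, **dataclasses.asdict(f)} for ax, f in axis_fits.items()]
    ).to_csv(tdir / "iwue_axis_regressions.csv", **_CSV_KW)

    # Phylogenetic signal of species-mean iWUE.
    if tree is not None:
        trait = kept.groupby("species_id")["iWUE"].mean().to_dict()
        try:
            res = phylo.phylo_signal_test(
                tree, trait, n_permutations=cfg.n_permutations, seed=cfg.seed
            )
            pd.DataFrame([dataclasses.asdict(res)]).to_csv(
                tdir / "phylo_signal.csv", **_CSV_KW
            )
        except DomainError as exc:
            log.warning("%s: phylogenetic signal skipped (%s)", name, exc)

    manifest["transects"][name] = counts


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every analysis stage for every configured transect.

    Returns the output directory.  The manifest (``manifest.json``) echoes
    the configuration, seed and filter bookkeeping; all tables are
    comma-separated text.
    """
    if not cfg.transects:
        raise ConfigurationError("no transects configured")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "config": json.loads(json.dumps(_config_echo(cfg))),
        "transects": {},
    }
    pooled_frames = []
    for tr in cfg.transects:
        leaf, sites, tree, truth = _load_transect(tr, cfg.seed)
        issues = validate_inputs(leaf, sites, tree=None)
        if issues:
            raise ValidationError(
                f"transect {tr.name}: input validation failed: " + "; ".join(issues[:5])
            )
        if truth is not None:
            (out / tr.name).mkdir(parents=True, exist_ok=True)
            (out / tr.name / "truth.txt").write_text(
                "\n".join(f"{k} = {v}" for k, v in truth.items()) + "\n"
            )
            leaf.to_csv(out / tr.name / "leaf_samples.csv", **_CSV_KW)
            sites.to_csv(out / tr.name / "sites.csv", **_CSV_KW)
            if tree is not None:
                (out / tr.name / "phylogeny.nwk").write_text(
                    tree.as_string(schema="newick")
                )
        _analyse_transect(tr.name, leaf, sites, tree, cfg, out, manifest)
        sites_tagged = sites.copy()
        leaf_tagged = leaf.copy()
        pooled_frames.append((leaf_tagged, sites_tagged, tr.name))

    if cfg.pooled and len(pooled_frames) > 1:
        leaf = pd.concat(
            [lf.assign(site_id=f"{nm}:" + lf["site_id"]) for lf, _, nm in pooled_frames],
            ignore_index=True,
        )
        sites = pd.concat(
            [st.assign(site_id=f"{nm}:" + st["site_id"]) for _, st, nm in pooled_frames],
            ignore_index=True,
        )
        _analyse_transect("pooled", leaf, sites, None, cfg, out, manifest)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def _config_echo(cfg: PipelineConfig) -> dict:
    echo = dataclasses.asdict(cfg)
    return echo


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
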