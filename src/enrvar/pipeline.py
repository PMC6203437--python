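"""End-to-end orchestration: simulate -> derive -> test -> correlate -> report.

A single :class:`RunConfig` (constructed in code or parsed from a YAML
file) drives the full analysis: obtain a cohort (simulated or from CSV),
derive the trajectory- and behavior-based phenotypes, run the per-trait
mean/variance comparison, build the group-wise Spearman matrices with the
enriched group's clustering order, and write every result table plus a
machine-readable run manifest.  Identical config and seed produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import pandas as pd
import yaml

from . import behavior, correlation, stats, synthetic, trajectory

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full analysis run needs.

    When ``phenotype_csv``/``tracking_csv`` are unset, the synthetic
    cohort generator supplies the data (two groups of ``n_per_group``
    animals with the default trait panel).
    """

    out_dir: str = "enrvar_out"
    seed: int = 0
    alpha: float = 0.05
    n_per_group: int = 40
    grid_rows: int = 10
    grid_cols: int = 10
    arena_side: float = 60.0
    log_traits: tuple[str, ...] = tuple(sorted(synthetic.DEFAULT_LOG_TRAITS))
    di_threshold: float = 0.0
    #: trajectory trial-2 records lost in the CTRL group (technical loss)
    n_lost_trial2_ctrl: int = 8
    phenotype_csv: str | None = None
    tracking_csv: str | None = None
    nor_csv: str | None = None
    rotarod_csv: str | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be at least 1x1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        """Load a run configuration from a declarative YAML key-value file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "log_traits" in raw:
            raw["log_traits"] = tuple(raw["log_traits"])
        return cls(**raw)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output path excluded)."""
        d = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _derive_seed(seed: int, salt: str) -> int:
    """Stable per-stage sub-seed below 2**31."""
    h = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_analysis(config: RunConfig) -> dict:
    """Execute the full pipeline and write the report bundle to disk.

    Returns the manifest dict.  Output files (all plain text) land in
    ``config.out_dir``: the merged phenotype table, the per-animal roaming
    entropy and discrimination-index tables, the per-trait comparison
    results (TSV and JSON), both groups' Spearman rho/p matrices in the
    ENR clustering order, the correlation restructuring report, and
    ``manifest.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    manifest: dict = {
        "package": "enrvar",
        "seed": config.seed,
        "alpha": config.alpha,
        "config_hash": config.config_hash(),
        "config": asdict(config),
    }

    # --- stage 1: cohort phenotypes -------------------------------------
    if config.phenotype_csv:
        table = pd.read_csv(config.phenotype_csv)
        logger.info("loaded phenotype table %s: %d animals", config.phenotype_csv, len(table))
    else:
        cohort_cfg = synthetic.default_cohort_config(
            seed=_derive_seed(config.seed, "cohort"), n_per_group=config.n_per_group
        )
        # rotarod summary is derived from raw trial records below
        cohort_cfg = replace(
            cohort_cfg,
            traits=tuple(t for t in cohort_cfg.traits if t.name != "rotarod_mean_s"),
        )
        table = synthetic.simulate_cohort(cohort_cfg)

    # --- stage 2: trajectories -> roaming entropy -----------------------
    if config.tracking_csv:
        trajs = trajectory.read_trajectories(config.tracking_csv, config.arena_side)
    else:
        walk = synthetic.WalkConfig(arena_side=config.arena_side)
        trajs = synthetic.simulate_cohort_trajectories(
            walk,
            n_per_group=config.n_per_group,
            seed=_derive_seed(config.seed, "walk"),
            n_lost_trial2_ctrl=config.n_lost_trial2_ctrl,
        )
    re_tab = trajectory.re_table(trajs, rows=config.grid_rows, cols=config.grid_cols)
    re_tab.to_csv(out / "re_table.csv", index=False)
    table = table.merge(
        re_tab[["animal_id", "re_trial1", "re_trial2", "habituation"]],
        on="animal_id", how="left",
    )

    # --- stage 3: behavioral phenotypes ---------------------------------
    if config.nor_csv:
        nor = pd.read_csv(config.nor_csv)
    else:
        nor = synthetic.simulate_nor_records(
            n_per_group=config.n_per_group, seed=_derive_seed(config.seed, "nor")
        )
    partition = behavior.apply_nor_exclusions(nor, threshold=config.di_threshold)
    di_tab = behavior.discrimination_table(nor, threshold=config.di_threshold)
    di_tab.to_csv(out / "di_table.csv", index=False)
    table = table.merge(di_tab, on="animal_id", how="left")
    manifest["nor_excluded"] = list(partition.excluded)
    manifest["nor_flagged"] = list(partition.flagged)

    if config.rotarod_csv:
        rot = pd.read_csv(config.rotarod_csv)
    else:
        rot = synthetic.simulate_rotarod_records(
            n_per_group=config.n_per_group, seed=_derive_seed(config.seed, "rotarod")
        )
    rot_mean = (
        rot.groupby("animal_id")["latency_s"]
        .apply(lambda v: behavior.summarize_rotarod(v.to_numpy()))
        .rename("rotarod_mean_s")
        .reset_index()
    )
    table = table.merge(rot_mean, on="animal_id", how="left")

    table.to_csv(out / "phenotypes.csv", index=False)
    traits = [c for c in table.columns if c not in ("animal_id", "group")]
    manifest["n_animals"] = int(len(table))
    manifest["n_traits"] = len(traits)

    # --- stage 4: per-trait mean/variance comparison --------------------
    results = stats.compare_all_traits(
        table, traits, alpha=config.alpha, log_traits=frozenset(config.log_traits)
    )
    results = stats.multiplicity_policy(results)
    results.to_csv(out / "comparison_results.tsv", sep="\t", index=False)
    results.to_json(out / "comparison_results.json", orient="records", indent=2)
    manifest["n_significant_mean"] = int(results["significant_mean"].fillna(False).sum())
    manifest["n_significant_variance"] = int(results["significant_variance"].fillna(False).sum())
    manifest["n_untestable"] = int(results["mean_p"].isna().sum()) if "mean_p" in results else 0

    # --- stage 5: correlation structure ---------------------------------
    m_ctrl = correlation.spearman_matrix(table, "CTRL", traits)
    m_enr = correlation.spearman_matrix(table, "ENR", traits)
    order = correlation.cluster_order(m_enr)
    m_ctrl, m_enr = m_ctrl.reordered(order), m_enr.reordered(order)
    for m in (m_ctrl, m_enr):
        m.rho.to_csv(out / f"rho_{m.group}.tsv", sep="\t")
        m.p.to_csv(out / f"p_{m.group}.tsv", sep="\t")
    report, summary = correlation.compare_structures(m_ctrl, m_enr, alpha=config.alpha)
    report.to_csv(out / "restructuring.tsv", sep="\t", index=False)
    manifest["restructuring_summary"] = summary
    manifest["trait_order"] = order

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline finished in %.1f s -> %s", time.perf_counter() - t0, out)
    return manifest
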