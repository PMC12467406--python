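"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: read + hard filter + MAF filter ->
diversity tables -> SGS per stratification level -> per-patch spatial
autocorrelation -> per-patch parentage and dispersal events -> direct and
indirect dispersal tables.  One global seed deterministically derives all
stage seeds, so a rerun with the same configuration is byte-identical.
Failure of one stratum is logged and does not abort the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autocorr import SpatialAutocorrelation
from .datatypes import InputError
from .dispersal import DispersalCurve, direct_summary, indirect_summary
from .distance import DistanceClassSpec
from .io import FilterThresholds, diversity, hard_filter, ho_he_ttest, maf_filter, read_vcf
from .kinship import sgs_by_stratum
from .parentage import TrioParentage, assignments_frame, dispersal_events

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    vcf: str = ""
    metadata: str = ""
    out_dir: str = "finesgs_out"
    seed: int = 42
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    n_distance_classes: int = 10
    distance_class_edges: tuple[float, ...] | None = None
    n_permutations: int = 999
    n_bootstraps: int = 999
    levels: tuple[str, ...] = ("population", "age_class", "patch")
    min_stratum_size: int = 10
    prop_candidates_sampled: float = 0.9
    parentage_error: float = 0.01
    mismatch_tolerance: float = 0.01
    confidence_level: float = 0.80
    n_sim_offspring: int = 10_000
    cross_patch_candidates: bool = False

    # -- (de)serialization ------------------------------------------------
    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        thr = FilterThresholds(**raw.pop("thresholds", {}))
        edges = raw.pop("distance_class_edges", None)
        cfg = cls(thresholds=thr, **raw)
        if edges is not None:
            cfg.distance_class_edges = tuple(float(v) for v in edges)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)  # analysis identity only, not where it lands
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def class_spec(self) -> DistanceClassSpec:
        if self.distance_class_edges is not None:
            return DistanceClassSpec(mode="fixed_edges", edges=self.distance_class_edges)
        return DistanceClassSpec(mode="equal_count", n_classes=self.n_distance_classes)


def validate_config(config: PipelineConfig) -> list[str]:
    """Return a list of problems; empty iff the configuration is usable."""
    problems: list[str] = []
    if not config.vcf:
        problems.append("vcf: no path given")
    elif not Path(config.vcf).exists():
        problems.append(f"vcf: path does not exist: {config.vcf}")
    if not config.metadata:
        problems.append("metadata: no path given")
    elif not Path(config.metadata).exists():
        problems.append(f"metadata: path does not exist: {config.metadata}")
    if config.n_permutations < 0:
        problems.append("n_permutations: must be >= 0")
    if config.n_bootstraps < 0:
        problems.append("n_bootstraps: must be >= 0")
    if config.n_distance_classes < 1:
        problems.append("n_distance_classes: must be >= 1")
    if config.min_stratum_size < 2:
        problems.append("min_stratum_size: must be >= 2")
    for name in (
        "prop_candidates_sampled",
        "parentage_error",
        "mismatch_tolerance",
        "confidence_level",
    ):
        v = getattr(config, name)
        if not 0.0 <= v <= 1.0:
            problems.append(f"{name}: must be in [0, 1]")
    if config.n_sim_offspring < 1:
        problems.append("n_sim_offspring: must be >= 1")
    for level in config.levels:
        if level not in ("population", "age_class", "patch"):
            problems.append(f"levels: unknown stratification level {level!r}")
    return problems


def _stage_seed(global_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def _write_table(df: pd.DataFrame, path: Path, config: PipelineConfig, precision: int | None = None) -> None:
    header = (
        f"# finesgs {__version__} seed={config.seed} config={config.config_hash()}\n"
    )
    out = df.copy()
    if precision is not None:
        for col in out.select_dtypes(include=[float]).columns:
            out[col] = out[col].round(precision)
    with open(path, "w") as fh:
        fh.write(header)
        out.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute every stage and write the table bundle; returns the paths."""
    problems = validate_config(config)
    if problems:
        raise InputError("invalid configuration: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    spec = config.class_spec()

    gm, meta, coord_mode = read_vcf(config.vcf, config.metadata)
    gm = hard_filter(gm, config.thresholds)
    gm = maf_filter(gm, config.thresholds.maf_min)
    logger.info("pipeline: %d samples x %d loci after filtering", gm.n_samples, gm.n_loci)
    if coord_mode == "geographic":
        from .distance import project_lonlat

        xy = project_lonlat(meta["x"].to_numpy(), meta["y"].to_numpy())
        meta = meta.assign(x=xy[:, 0], y=xy[:, 1])

    # --- diversity + t-test ---------------------------------------------
    div = diversity(gm, meta, group="patch")
    written["diversity"] = out / "diversity_patch.tsv"
    _write_table(div, written["diversity"], config)
    trows = []
    for pop, sub in div.groupby("population", sort=True):
        if len(sub) < 2:
            continue
        try:
            t = ho_he_ttest(sub["ho"].to_numpy(), sub["he"].to_numpy())
        except InputError as exc:
            logger.warning("t-test skipped for %s: %s", pop, exc)
            continue
        trows.append(
            {
                "population": pop,
                "mean_difference": t.mean_difference,
                "t_value": t.t_value,
                "df": t.df,
                "p_value": t.p_value,
                "significance": t.significance,
            }
        )
    written["ttest"] = out / "diversity_ttest.tsv"
    _write_table(pd.DataFrame(trows), written["ttest"], config)

    # --- SGS per level ---------------------------------------------------
    for level in config.levels:
        seed = _stage_seed(config.seed, f"sgs:{level}")
        try:
            results = sgs_by_stratum(
                gm,
                meta,
                level,
                classes=spec,
                n_permutations=config.n_permutations,
                random_state=seed,
                min_individuals=config.min_stratum_size,
            )
        except InputError as exc:
            logger.warning("SGS level %s failed: %s", level, exc)
            continue
        rows = []
        for name, res in sorted(results.items()):
            rows.append(
                {
                    "stratum": name,
                    "bF": res.b_f,
                    "F1": res.f1,
                    "Sp": res.sp,
                    "se_bF": res.se_bf,
                    "bf_significant": res.bf_significant,
                    "n_pairs": res.n_pairs_used,
                }
            )
            cpath = out / f"sgs_correlogram_{level}_{name}.tsv"
            _write_table(res.per_class, cpath, config)
            written[f"sgs_correlogram_{level}_{name}"] = cpath
        path = out / f"sgs_{level}.tsv"
        _write_table(pd.DataFrame(rows), path, config)
        written[f"sgs_{level}"] = path

    # --- per-patch autocorrelation --------------------------------------
    auto_rows = []
    per_patch_autocorr: dict[str, object] = {}
    for patch, sub in meta.groupby("patch", sort=True):
        if len(sub) < config.min_stratum_size:
            logger.warning("autocorr: patch %s too small; skipped", patch)
            continue
        seed = _stage_seed(config.seed, f"autocorr:{patch}")
        try:
            est = SpatialAutocorrelation(
                classes=spec,
                n_permutations=config.n_permutations,
                n_bootstraps=config.n_bootstraps,
                random_state=seed,
            ).fit(
                gm.select_samples(sub["id"].tolist()),
                coords=sub[["x", "y"]].to_numpy(),
            )
        except InputError as exc:
            logger.warning("autocorr: patch %s failed: %s", patch, exc)
            continue
        per_patch_autocorr[patch] = est
        cpath = out / f"autocorr_{patch}.tsv"
        _write_table(est.result_().per_class, cpath, config)
        written[f"autocorr_{patch}"] = cpath
        auto_rows.append(
            {
                "patch": patch,
                "x_intercept_m": est.x_intercept_ if est.x_intercept_ is not None else np.nan,
                "immediate": est.x_intercept_immediate_,
            }
        )
    written["autocorr_intercepts"] = out / "autocorr_intercepts.tsv"
    _write_table(pd.DataFrame(auto_rows), written["autocorr_intercepts"], config)

    # --- parentage + direct dispersal -----------------------------------
    all_assignments = []
    for patch, sub in meta.groupby("patch", sort=True):
        offspring = sub[sub["age_class"] == "sapling"]
        cand_pool = meta if config.cross_patch_candidates else sub
        candidates = cand_pool[cand_pool["age_class"].isin(("adult", "mature"))]
        if offspring.empty or len(candidates) < 1:
            logger.info("parentage: patch %s has no offspring or candidates", patch)
            continue
        seed = _stage_seed(config.seed, f"parentage:{patch}")
        try:
            est = TrioParentage(
                prop_candidates_sampled=config.prop_candidates_sampled,
                genotyping_error=config.parentage_error,
                mismatch_tolerance=config.mismatch_tolerance,
                confidence_level=config.confidence_level,
                n_sim_offspring=config.n_sim_offspring,
                random_state=seed,
            ).fit(gm.select_samples(candidates["id"].tolist()))
            assigns = est.predict(gm.select_samples(offspring["id"].tolist()))
        except InputError as exc:
            logger.warning("parentage: patch %s failed: %s", patch, exc)
            continue
        all_assignments.extend(assigns)
    adf = assignments_frame(all_assignments)
    written["assignments"] = out / "parentage_assignments.tsv"
    _write_table(adf, written["assignments"], config)
    events = dispersal_events(all_assignments, meta) if all_assignments else pd.DataFrame(
        columns=["kind", "distance", "patch", "offspring"]
    )
    written["events"] = out / "dispersal_events.tsv"
    _write_table(events, written["events"], config)
    patch_to_pop = dict(zip(meta["patch"], meta["population"]))
    direct = direct_summary(events, patch_to_pop)
    written["direct"] = out / "dispersal_direct.tsv"
    _write_table(direct, written["direct"], config)
    rounded = out / "dispersal_direct_rounded.tsv"
    _write_table(direct, rounded, config, precision=2)
    written["direct_rounded"] = rounded

    # --- indirect dispersal ----------------------------------------------
    ind_rows = []
    for patch, est in sorted(per_patch_autocorr.items()):
        roots: tuple[float, ...] | None = None
        try:
            curve = DispersalCurve().fit(est.class_midpoints_, est.r_)
            roots = curve.roots_
        except InputError as exc:
            logger.info("indirect: cubic fit unavailable for %s: %s", patch, exc)
        rng = indirect_summary(est.x_intercept_, roots)
        ind_rows.append(
            {
                "patch": patch,
                "min_m": rng.min_m if rng.min_m is not None else np.nan,
                "max_m": rng.max_m if rng.max_m is not None else np.nan,
                "collapsed": rng.collapsed,
                "random_variation": rng.random_variation,
            }
        )
    written["indirect"] = out / "dispersal_indirect.tsv"
    _write_table(pd.DataFrame(ind_rows), written["indirect"], config)

    logger.info("pipeline: wrote %d tables to %s", len(written), out)
    return written
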