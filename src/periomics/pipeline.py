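"""End-to-end orchestration: generate/read -> abundance -> screen -> cluster
-> networks -> responders -> calibration -> stats, with one config, one seed
and a manifest.

Each stage is an importable function taking and returning plain tables, so
the thin CLI and the tests drive exactly the same code paths.  Artifacts are
written as CSV/TSV/GraphML/JSON under the configured output directory; the
manifest records per-stage outputs, row counts, package versions and a hash
of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    AbundanceMatrix,
    prevalence_filter,
    read_metaphlan_table,
    write_metaphlan_table,
)
from .calibration import (
    calibration_report,
    curves_from_long,
    estimate_lps,
    fit_onset_model,
)
from .networks import (
    build_commensal_network,
    build_network,
    cluster_taxa,
    expand_constellations,
    select_commensal,
    select_pathogenic,
)
from .responders import responder_analysis, train_state_model
from .rmcorr import NINE_FACTORS, CorrelationScreen, screen
from .stats import (
    hurdle_gamma_fit,
    independent_t,
    kruskal_dunn,
    paired_t,
    wilcoxon_signed_rank,
)
from .synthetic import CONDITIONS, CohortConfig, SyntheticCohort, generate_cohort

logger = logging.getLogger("periomics")

__all__ = ["PipelineConfig", "run_pipeline", "condition_level_factors"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    outdir: str = "periomics_out"
    prevalence: float = 0.10
    pathogenic_p: float = 0.001
    pathogenic_target_n: int = 20
    edge_r: float = 0.6
    expansion_r: float = 0.5
    expansion_p: float = 0.05
    commensal_edge: float = 0.1
    commensal_min_factors: int = 6
    commensal_criterion: str = "p_gt_0.05"
    importance_min: float = 2.0
    n_trees: int = 400
    rf_seed: int = 12345
    onset_fraction: float = 0.30
    root_k: int = 10
    use_absolute: bool = True  # screen absolute biomass rather than percentages
    responder_unit: str = "condition"  # condition-pooled or per-site features

    def validate(self) -> None:
        checks = [
            (0.0 <= self.prevalence <= 1.0, "prevalence outside [0, 1]"),
            (0.0 < self.pathogenic_p <= 1.0, "pathogenic p threshold outside (0, 1]"),
            (-1.0 <= self.edge_r <= 1.0, "edge threshold outside [-1, 1]"),
            (-1.0 <= self.expansion_r <= 1.0, "expansion threshold outside [-1, 1]"),
            (0.0 <= self.commensal_edge <= 1.0, "commensal edge outside [0, 1]"),
            (0.0 < self.onset_fraction < 1.0, "onset fraction outside (0, 1)"),
            (self.n_trees >= 1, "n_trees must be positive"),
            (self.root_k >= 1, "root_k must be >= 1"),
            (self.responder_unit in ("condition", "site"), "bad responder unit"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"invalid pipeline configuration: {msg}")
        self.cohort.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"] = self.cohort.to_dict()
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls()
        cohort = d.pop("cohort", None)
        for key, val in d.items():
            if hasattr(cfg, key):
                setattr(cfg, key, val)
        if cohort:
            tmp = Path(path).with_suffix(".cohort.tmp.yaml")
            with open(tmp, "w") as fh:
                yaml.safe_dump(cohort, fh)
            cfg.cohort = CohortConfig.from_yaml(tmp)
            tmp.unlink()
        return cfg


# ---------------------------------------------------------------------------
# alignment helpers


def condition_level_factors(
    biomarkers: pd.DataFrame,
    factors=NINE_FACTORS,
    index: pd.MultiIndex | None = None,
) -> pd.DataFrame:
    """Average site-level factor values per (subject, condition, visit) cell.

    Sequencing samples are pooled per condition while the biomarker panel is
    measured per site, so screening a taxon against a factor pairs the
    pooled abundance with the mean of that condition's sites.
    """
    cols = [f for f in factors if f in biomarkers.columns]
    grouped = (
        biomarkers.groupby(["subject_id", "condition", "visit_month"])[cols]
        .mean()
    )
    if index is not None:
        grouped = grouped.reindex(index)
    return grouped


def condition_features(
    biomarkers: pd.DataFrame, visit: int, analytes: list[str]
) -> pd.DataFrame:
    """Condition-pooled feature rows for the site-state model at one visit."""
    sub = biomarkers[biomarkers["visit_month"] == visit]
    feats = (
        sub.groupby(["subject_id", "condition"])[analytes].mean().dropna(axis=1, how="all")
    )
    arms = sub.groupby(["subject_id", "condition"])["arm"].first()
    return feats.join(arms)


# ---------------------------------------------------------------------------
# pipeline


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray, pd.Index)):
        return list(o)
    return str(o)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the outdir)."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if not logger.handlers:
        logging.basicConfig(level=logging.INFO, format="%(name)s %(message)s")
    fh = logging.FileHandler(out / "pipeline.log")
    logger.addHandler(fh)
    manifest: dict = {
        "version": __version__,
        "seed": config.cohort.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }
    t_start = time.time()
    stage = "generate"
    try:
        # 1 -- generate -----------------------------------------------------
        cohort = generate_cohort(config.cohort)
        cohort.metadata.to_csv(out / "metadata.csv")
        cohort.biomarkers.to_csv(out / "biomarkers.csv")
        write_metaphlan_table(cohort.abundance, out / "abundance.tsv")
        cohort.standards.to_csv(out / "standards.csv", index=False)
        config.cohort.to_yaml(out / "cohort_config.yaml")
        manifest["stages"]["generate"] = {
            "outputs": ["metadata.csv", "biomarkers.csv", "abundance.tsv", "standards.csv"],
            "n_samples": int(len(cohort.metadata)),
            "n_sites": int(len(cohort.biomarkers)),
        }
        logger.info("generate: %d pooled samples, %d site rows",
                    len(cohort.metadata), len(cohort.biomarkers))

        # 2 -- abundance ----------------------------------------------------
        stage = "abundance"
        filtered = prevalence_filter(cohort.abundance, config.prevalence)
        biomass = filtered.to_biomass()
        summary = pd.DataFrame(
            {
                "microbial_dna_ng": cohort.abundance.microbial_dna(),
                "shannon": cohort.abundance.shannon(),
                "observed_species": cohort.abundance.observed(),
            }
        )
        summary.to_csv(out / "abundance_summary.csv")
        manifest["stages"]["abundance"] = {
            "outputs": ["abundance_summary.csv"],
            "n_species_total": int(len(cohort.abundance.species)),
            "n_species_prevalent": int(len(filtered.species)),
        }
        logger.info("abundance: %d/%d species pass the %.0f%% prevalence filter",
                    len(filtered.species), len(cohort.abundance.species),
                    100 * config.prevalence)

        # 3 -- screen -------------------------------------------------------
        stage = "screen"
        meta = cohort.metadata
        taxa_table = (biomass.absolute if config.use_absolute
                      else filtered.relative).T
        cell_index = pd.MultiIndex.from_frame(
            meta[["subject_id", "condition", "visit_month"]]
        )
        factor_table = condition_level_factors(
            cohort.biomarkers, NINE_FACTORS, index=cell_index
        )
        factor_table.index = taxa_table.index
        corr = screen(
            taxa_table, factor_table, meta["subject_id"].to_numpy(), root_k=config.root_k
        )
        corr.to_csv(out / "screen_r.csv", out / "screen_p.csv")
        manifest["stages"]["screen"] = {
            "outputs": ["screen_r.csv", "screen_p.csv"],
            "n_taxa": int(len(corr.taxa)),
            "n_factors": int(len(corr.factors)),
        }
        logger.info("screen: %d taxa x %d factors", len(corr.taxa), len(corr.factors))

        # 4 -- cluster ------------------------------------------------------
        stage = "cluster"
        clusters = cluster_taxa(corr)
        clusters.to_csv(out / "clusters.csv")
        sizes = clusters.value_counts().to_dict()
        manifest["stages"]["cluster"] = {
            "outputs": ["clusters.csv"],
            "sizes": {str(k): int(v) for k, v in sizes.items()},
        }
        logger.info("cluster sizes: %s", sizes)

        # 5 -- networks -----------------------------------------------------
        stage = "network"
        pathogenic, thr = select_pathogenic(
            corr, config.pathogenic_p, config.pathogenic_target_n
        )
        from .rmcorr import rmcorr_matrix

        tt_r, tt_p = rmcorr_matrix(
            taxa_table[pathogenic], meta["subject_id"].to_numpy(), root_k=config.root_k
        ) if pathogenic else (pd.DataFrame(), pd.DataFrame())
        net = (
            build_network(tt_r, config.edge_r, screen=corr, include_factors=True,
                          clusters=clusters)
            if pathogenic
            else None
        )
        expansion = {}
        if net is not None and net.constellations:
            core = sorted({t for c in net.constellations for t in c})
            core_screen = screen(
                taxa_table, taxa_table[core], meta["subject_id"].to_numpy(),
                root_k=config.root_k, skip_root=(),
            )
            expansion = expand_constellations(
                core, core_screen.r, core_screen.p,
                config.expansion_r, config.expansion_p,
            )
            net.to_graphml(out / "pathogenic_network.graphml")
            net.to_edgelist_tsv(out / "pathogenic_edges.tsv")
        commensal = select_commensal(
            corr, config.commensal_criterion, config.commensal_min_factors
        )
        comm_net = None
        if len(commensal) >= 2:
            cc_r, cc_p = rmcorr_matrix(
                taxa_table[commensal], meta["subject_id"].to_numpy(), root_k=config.root_k
            )
            comm_net = build_commensal_network(cc_r, cc_p, config.commensal_edge)
            comm_net.to_graphml(out / "commensal_network.graphml")
            comm_net.to_edgelist_tsv(out / "commensal_edges.tsv")
        _write_json(
            {
                "pathogenic_taxa": pathogenic,
                "r_threshold": thr,
                "constellations": [list(c) for c in (net.constellations if net else [])],
                "expansion": expansion,
                "commensal_taxa": commensal,
            },
            out / "networks.json",
        )
        manifest["stages"]["network"] = {
            "outputs": ["networks.json", "pathogenic_network.graphml",
                        "pathogenic_edges.tsv", "commensal_network.graphml",
                        "commensal_edges.tsv"],
            "n_pathogenic": len(pathogenic),
            "n_constellations": len(net.constellations) if net else 0,
            "n_commensal": len(commensal),
        }
        logger.info("network: %d pathogenic taxa (r threshold %.2f), %d constellations",
                    len(pathogenic), thr if thr == thr else float("nan"),
                    len(net.constellations) if net else 0)

        # 6 -- responders ---------------------------------------------------
        stage = "responders"
        analyte_names = list(config.cohort.analytes)
        if config.responder_unit == "condition":
            base = condition_features(cohort.biomarkers, 0, analyte_names)
            month24 = condition_features(cohort.biomarkers, 24, analyte_names)
        else:
            cols = ["subject_id", "condition", "site"]
            base = (cohort.biomarkers[cohort.biomarkers.visit_month == 0]
                    .set_index(cols)[analyte_names + ["arm"]])
            month24 = (cohort.biomarkers[cohort.biomarkers.visit_month == 24]
                       .set_index(cols)[analyte_names + ["arm"]])
        shared = base.index.intersection(month24.index)
        dropped = len(base.index.union(month24.index)) - len(shared)
        if dropped:
            logger.info("responders: %d sites missing a visit, excluded", dropped)
        base, month24 = base.loc[shared], month24.loc[shared]
        labels = [ix[1] for ix in base.index]
        feature_cols = [c for c in base.columns if c != "arm"]
        model = train_state_model(
            base[feature_cols], labels, n_trees=config.n_trees,
            seed=config.rf_seed, importance_min=config.importance_min,
        )
        table = responder_analysis(
            model, labels, month24[feature_cols], month24["arm"]
        )
        table.to_csv(out / "responders.csv")
        _write_json(
            {"model": model.metadata(), **table.summary()}, out / "responder_summary.json"
        )
        manifest["stages"]["responders"] = {
            "outputs": ["responders.csv", "responder_summary.json"],
            "n_sites": int(len(table.sites)),
            "proportions": table.proportions,
            "p": table.p_value,
        }
        logger.info("responders: %s (chi-square p=%.3g)", table.proportions, table.p_value)

        # 7 -- calibrate ----------------------------------------------------
        stage = "calibrate"
        standards = curves_from_long(cohort.standards)
        model_fit = fit_onset_model(standards, config.onset_fraction)
        estimates = {}
        if cohort.site_curves is not None:
            sample = cohort.site_curves[
                ~cohort.site_curves.get("clamped", False)
            ]
            for well, grp in list(sample.groupby("well_id"))[:200]:
                from .calibration import FluorescenceCurve

                curve = FluorescenceCurve(
                    grp["time"].to_numpy(float), grp["value"].to_numpy(float)
                )
                estimates[str(well)] = estimate_lps(model_fit, curve, config.onset_fraction)
        _write_json(calibration_report(model_fit, estimates), out / "calibration.json")
        manifest["stages"]["calibrate"] = {
            "outputs": ["calibration.json"],
            "r_squared": model_fit.r_squared,
        }
        logger.info("calibrate: R^2 = %.4f", model_fit.r_squared)

        # 8 -- stats --------------------------------------------------------
        stage = "stats"
        rows = _stats_stage(cohort, summary)
        stats_df = pd.DataFrame(rows)
        stats_df.to_csv(out / "stats.csv", index=False)
        manifest["stages"]["stats"] = {
            "outputs": ["stats.csv"],
            "n_tests": int(len(stats_df)),
        }
        logger.info("stats: %d tests", len(stats_df))
    except Exception as exc:  # pragma: no cover - error path
        logger.error("stage %r failed: %s", stage, exc)
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        _write_json(manifest, out / "manifest.json")
        raise RuntimeError(f"pipeline aborted in stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(fh)
        fh.close()

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    _write_json(manifest, out / "manifest.json")
    return manifest


def _stats_stage(cohort: SyntheticCohort, summary: pd.DataFrame) -> list[dict]:
    """Baseline condition contrasts and month-24 arm contrasts."""
    rows: list[dict] = []
    meta = cohort.metadata.join(summary)
    base = meta[meta.visit_month == 0]
    # paired t-tests across conditions for DNA / diversity / richness
    for var in ("microbial_dna_ng", "shannon", "observed_species"):
        wide = base.pivot_table(index="subject_id", columns="condition", values=var)
        for a, b in (("healthy", "gingivitis"), ("gingivitis", "periodontitis")):
            res = paired_t(wide[a].to_numpy(), wide[b].to_numpy())
            rows.append(res.as_row(f"{var}: {a} vs {b} (baseline)"))
    m24 = meta[meta.visit_month == 24]
    for var in ("microbial_dna_ng", "shannon"):
        res = independent_t(
            m24.loc[m24.arm == "regimen", var].to_numpy(),
            m24.loc[m24.arm == "control", var].to_numpy(),
        )
        rows.append(res.as_row(f"{var}: regimen vs control (month 24)"))
    # biomarker contrasts: Wilcoxon across conditions at baseline,
    # Kruskal-Wallis + Dunn between arms at month 24
    bio = cohort.biomarkers
    b0 = bio[bio.visit_month == 0]
    b24 = bio[bio.visit_month == 24]
    for analyte in ("IL-1b", "MMP-1", "MMP-9", "endotoxin", "PAD"):
        wide = b0.pivot_table(index=["subject_id", "site"], columns="condition",
                              values=analyte)
        for a, b in (("healthy", "gingivitis"), ("gingivitis", "periodontitis")):
            res = wilcoxon_signed_rank(wide[a].to_numpy(), wide[b].to_numpy())
            rows.append(res.as_row(f"{analyte}: {a} vs {b} (baseline)"))
        kw, dunn = kruskal_dunn(
            {
                "regimen": b24.loc[b24.arm == "regimen", analyte].dropna().to_numpy(),
                "control": b24.loc[b24.arm == "control", analyte].dropna().to_numpy(),
            }
        )
        rows.append(kw.as_row(f"{analyte}: regimen vs control (month 24)"))
        for d in dunn:
            rows.append(
                {
                    "comparison": f"{analyte}: Dunn {d.pair[0]} vs {d.pair[1]} (month 24)",
                    "method": "dunn",
                    "statistic": d.z,
                    "df": None,
                    "p": d.p,
                    "p_formatted": ("<0.001" if d.p < 0.001 else f"{d.p:.4g}"),
                }
            )
    return rows
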