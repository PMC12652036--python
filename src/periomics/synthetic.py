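"""Synthetic longitudinal cohort generator.

Emulates a two-arm, 24-month early-periodontitis study in which every
subject contributes three healthy, three gingivitis and three periodontitis
gingival sites per visit.  Site-level biomarker panels are generated per
site; sequencing samples are pooled per (subject, condition, visit), as the
lab pooled the sequencing half of each sample set.

Model sketch (all on the log scale):

* Every (subject, condition, visit) cell carries a latent standard-normal
  severity fluctuation ``eta`` shared by all variables of that cell, plus
  independent "constellation" factors (red, pink, commensal).
* A variable (biomarker or taxon) with condition targets ``T_c``, log-scale
  dispersion ``sigma`` and severity loading ``a`` is generated as

      log x = log T_c - V/2 + sigma * (a*eta + c*f_group + e*eps)
              + s_u * u_subject + 1[month 24] * rho_subject * L_arm

  where ``V`` is the total log variance (so large-n condition means equal
  the targets exactly for mean-matched analytes; median-matched analytes
  drop the -V/2 term), ``u_subject`` is a subject intercept (removed by the
  repeated-measures correlation), ``rho_subject`` a Gamma-distributed
  responder propensity with mean 1, and ``L_arm`` the per-arm month-24
  treatment log-shift (corrected so the *mean* shift equals the configured
  multiplicative effect).
* Named pair correlations (P. gingivalis with PAD, IL-1beta with MMP-9) are
  calibrated in closed form: the within-subject covariance decomposes into
  the condition-jump pattern of the targets, the shared severity factor and
  the treatment-shift term, so the severity loadings of the pair are solved
  to make the repeated-measures correlation hit the configured value.

Standard fluorescence curves for the LPS calibration are monotone power
ramps whose interpolated 30%-of-saturation onset time is solved to match
``onset = a / (log(conc) - b)`` exactly (plus optional onset noise).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .abundance import AbundanceMatrix
from .calibration import FluorescenceCurve, onset_time

__all__ = [
    "AnalyteSpec",
    "TaxonSpec",
    "CohortConfig",
    "LatentSiteState",
    "SyntheticCohort",
    "ConfigurationError",
    "generate_cohort",
    "generate_standard_curves",
    "onset_from_model",
    "default_analytes",
    "default_taxa",
    "default_treatment_effects",
]

CONDITIONS = ("healthy", "gingivitis", "periodontitis")
ARMS = ("regimen", "control")


class ConfigurationError(ValueError):
    pass


@dataclass
class AnalyteSpec:
    """One biomarker/clinical analyte of the site panel."""

    name: str
    targets: tuple[float, float, float]  # healthy, gingivitis, periodontitis
    unit: str = ""
    stat: str = "mean"  # which location statistic the targets pin: mean|median
    sigma: float = 0.5  # within-cell log-scale SD
    loading: float = 0.4  # severity loading in [0, 1]

    def validate(self) -> None:
        if any(t <= 0 for t in self.targets):
            raise ConfigurationError(f"{self.name}: targets must be positive")
        if self.stat not in ("mean", "median"):
            raise ConfigurationError(f"{self.name}: stat must be mean or median")
        if not 0.0 <= self.loading <= 1.0:
            raise ConfigurationError(f"{self.name}: loading outside [0, 1]")


@dataclass
class TaxonSpec:
    """One species of the simulated subgingival community.

    ``presence`` is the probability the taxon is detected in a pooled sample;
    a scalar applies to every site condition, a 3-tuple gives
    (healthy, gingivitis, periodontitis) probabilities — absence of a
    pathogen is itself condition-linked in subgingival plaque.
    """

    name: str
    weights: tuple[float, float, float]  # mean ng per pooled sample when present
    presence: float | tuple[float, float, float] = 0.9
    sigma: float = 0.55
    loading: float = 0.3
    group: str | None = None  # red | pink | commensal | None
    group_loading: float = 0.0
    tier: str = "filler"  # core | pathogen | commensal | filler | rare

    def presence_by_condition(self) -> tuple[float, float, float]:
        if isinstance(self.presence, (int, float)):
            return (float(self.presence),) * 3
        return tuple(float(p) for p in self.presence)

    def validate(self) -> None:
        if any(w <= 0 for w in self.weights):
            raise ConfigurationError(f"{self.name}: weights must be positive")
        if any(not 0.0 <= p <= 1.0 for p in self.presence_by_condition()):
            raise ConfigurationError(f"{self.name}: presence outside [0, 1]")
        if self.loading**2 + self.group_loading**2 > 1.0 + 1e-12:
            raise ConfigurationError(
                f"{self.name}: loadings give a non-PSD latent covariance"
            )


@dataclass(frozen=True)
class LatentSiteState:
    """Latent construct behind one generated cell (not observed in real data)."""

    severity: float
    subject_effect: float
    responder_propensity: float


def default_analytes() -> dict[str, AnalyteSpec]:
    """Default analyte panel; site-type targets follow the study's printed
    baseline summaries where available, plausible values elsewhere."""
    specs = [
        AnalyteSpec("IL-1b", (116.55, 153.06, 215.69), "pg/mL", "mean", 0.28, 0.40),
        AnalyteSpec("TNF-a", (3.75, 3.43, 4.47), "pg/mL", "mean", 0.30, 0.15),
        AnalyteSpec("IL-2", (0.80, 0.92, 1.30), "pg/mL", "mean", 0.30, 0.25),
        AnalyteSpec("IL-6", (2.00, 2.05, 2.15), "pg/mL", "mean", 0.30, 0.05),
        AnalyteSpec("IL-8", (180.0, 205.0, 290.0), "pg/mL", "mean", 0.30, 0.30),
        AnalyteSpec("MMP-1", (223.26, 401.77, 457.02), "pg/mL", "mean", 0.32, 0.45),
        AnalyteSpec("MMP-3", (10.0, 14.0, 20.0), "ng/mL", "mean", 0.30, 0.35),
        AnalyteSpec("MMP-9", (165.79, 222.01, 331.56), "ng/mL", "mean", 0.28, 0.40),
        AnalyteSpec("endotoxin", (20.77, 26.75, 88.46), "EU", "mean", 0.50, 0.62),
        AnalyteSpec("gingipain", (0.65, 0.74, 1.38), "RFU", "mean", 0.30, 0.45),
        AnalyteSpec("PAD", (0.90, 1.40, 2.60), "RFU", "mean", 0.32, 0.50),
        AnalyteSpec("TLR-ATP", (0.02, 0.04, 0.20), "ug/mL", "median", 1.10, 0.55),
        AnalyteSpec("TLR-SEAP", (0.08, 0.20, 1.30), "AU", "median", 1.10, 0.60),
        AnalyteSpec("GBI", (0.06, 0.95, 1.15), "", "mean", 0.40, 0.55),
        AnalyteSpec("MGI", (0.45, 1.70, 2.40), "", "mean", 0.30, 0.50),
    ]
    return {s.name: s for s in specs}


def default_treatment_effects() -> dict[str, dict[str, float]]:
    """Month-24 multiplicative shifts of the arm-pooled mean, per analyte.

    Where the study prints month-24 arm means the shift is that mean divided
    by the pooled baseline target mean; elsewhere a plausible modest
    reduction under the regimen is assumed.
    """

    def from_arm_means(targets, control, regimen):
        base = sum(targets) / 3.0
        return {"control": control / base, "regimen": regimen / base}

    return {
        "IL-1b": from_arm_means((116.55, 153.06, 215.69), 166.34, 115.90),
        "MMP-1": from_arm_means((223.26, 401.77, 457.02), 519.71, 395.35),
        "MMP-9": from_arm_means((165.79, 222.01, 331.56), 211.0, 193.8),
        "endotoxin": {"control": 0.95, "regimen": 0.70},
        "gingipain": {"control": 0.97, "regimen": 0.80},
        "PAD": {"control": 0.95, "regimen": 0.70},
        "TLR-ATP": {"control": 1.10, "regimen": 0.60},
        "TLR-SEAP": {"control": 1.00, "regimen": 0.70},
        "GBI": {"control": 0.95, "regimen": 0.50},
        "MGI": {"control": 0.97, "regimen": 0.75},
    }


def default_transitions() -> dict[str, dict[str, dict[str, float]]]:
    """Month-24 site-state transition probabilities per arm.

    Sites genuinely change state over two years — also under usual care —
    and the treatment regimen raises the improvement rates.  These defaults
    are calibrated so that, after the site-state classifier re-states month
    24, roughly 70% of regimen and 47% of control condition-units are called
    responders (a calibration of the generator, not a finding).
    """
    return {
        "regimen": {
            "periodontitis": {"healthy": 0.32, "gingivitis": 0.50},
            "gingivitis": {"healthy": 0.66},
            "healthy": {"gingivitis": 0.03},
        },
        "control": {
            "periodontitis": {"healthy": 0.08, "gingivitis": 0.17},
            "gingivitis": {"healthy": 0.25},
            "healthy": {"gingivitis": 0.12},
        },
    }


def default_month6_effects() -> dict[str, dict[str, float]]:
    # month-6 medians for the TLR-ATP assay: 0.07 (control) vs 0.03 (regimen)
    # against a pooled baseline median near 0.04
    return {
        "TLR-ATP": {"control": 1.75, "regimen": 0.75},
        "TLR-SEAP": {"control": 1.00, "regimen": 0.85},
    }


_RED_CORE = (
    "Porphyromonas_endodontalis",
    "Tannerella_forsythia",
    "Treponema_denticola",
    "Filifactor_alocis",
)
_PINK_CORE = (
    "Fusobacterium_nucleatum",
    "Candidatus_Nanosynsacchari_sp_TM7_ANC_38_39_G1_1",
    "Dialister_invisus",
    "Treponema_socranskii",
)
_RED_ASSOC = ("Campylobacter_rectus", "Fastidiosipila_fastidiosum")
_PINK_ASSOC = ("Prevotella_maculosa", "Actinomyces_dentalis")
_COMMENSALS = (
    "Rothia_mucilaginosa",
    "Haemophilus_haemolyticus",
    "Haemophilus_paraphrohaemolyticus",
    "Streptococcus_mutans",
    "Streptococcus_sobrinus",
    "Enterobacter_hormaechei",
    "Neisseria_cinerea",
    "Klebsiella_bonacorsii",
    "Propionibacterium_acidifaciens",
)
_PATHOGEN_NAMED = (
    "Prevotella_intermedia",
    "Prevotella_nigrescens",
    "Parvimonas_micra",
    "Porphyromonas_oris",
    "Treponema_putidum",
    "Prevotella_multiformis",
    "Campylobacter_showae",
    "Campylobacter_gracilis",
    "Eubacterium_nodatum",
    "Streptococcus_constellatus",
    "Lancefieldella_rimae",
    "Peptostreptococcus_stomatis",
    "Eubacterium_saphenum",
    "Treponema_medium",
    "Treponema_maltophilum",
    "Desulfobulbus_oralis",
    "Mogibacterium_timidum",
    "Eubacterium_brachy",
    "Filifactor_villosus",
    "Treponema_vincentii",
    "Prevotella_dentalis",
    "Porphyromonas_catoniae",
)
_PATHOGEN_NUMERIC = (
    "GGB9342_SGB14341",
    "Prevotella_sp_GGB1287_SGB1266",
    "Saccharibacteria_sp_OTU512",
)
_FILLER_GENERA = (
    "Streptococcus", "Prevotella", "Actinomyces", "Veillonella",
    "Capnocytophaga", "Leptotrichia", "Selenomonas", "Corynebacterium",
    "Neisseria", "Rothia", "Gemella", "Granulicatella", "Kingella",
    "Lautropia", "Oribacterium", "Peptoniphilus", "Solobacterium",
    "Stomatobaculum", "Catonella", "Johnsonella",
)
_FILLER_EPITHETS = (
    "oris", "buccae", "dentium", "salivae", "mucosae", "parvula", "elongata",
    "gracilior", "compacta", "minuta", "flava", "aurea", "lenta", "rapida",
    "serena",
)


def default_taxa(
    n_species: int = 513, n_common_filler: int = 271, n_rare: int = 195
) -> list[TaxonSpec]:
    """Default 513-species community.

    Tiers: the two four-member pathogenic constellations plus P. gingivalis
    and four constellation-associated species; a 25-species pathogenic
    fringe (including three placeholder-named bins); nine commensals on a
    health factor uncorrelated with severity; 271 moderately loaded common
    fillers (the heatmap's middle cluster) of which essentially all pass the
    10% prevalence filter; and 195 rare species that do not.
    """
    taxa: list[TaxonSpec] = []
    # the two constellations use distinct condition profiles (red rises late,
    # pink rises already in gingivitis) so their cross-correlations fall
    # below the 0.6 edge threshold while within-clique pairs stay above it
    for name in _RED_CORE:
        taxa.append(TaxonSpec(name, (0.10, 0.13, 0.40), 1.0, 0.55, 0.32, "red", 0.74, "core"))
    for name in _PINK_CORE:
        taxa.append(TaxonSpec(name, (0.10, 0.31, 0.40), 1.0, 0.55, 0.32, "pink", 0.74, "core"))
    taxa.append(
        TaxonSpec("Porphyromonas_gingivalis", (0.06, 0.12, 0.18), 1.0, 0.55, 0.50, None, 0.0, "core")
    )
    for name in _RED_ASSOC:
        taxa.append(TaxonSpec(name, (0.06, 0.08, 0.24), 1.0, 0.55, 0.32, "red", 0.50, "core"))
    for name in _PINK_ASSOC:
        taxa.append(TaxonSpec(name, (0.06, 0.186, 0.24), 1.0, 0.55, 0.32, "pink", 0.50, "core"))
    for i, name in enumerate(_COMMENSALS):
        c = -0.45 if name == "Streptococcus_mutans" else 0.40
        taxa.append(TaxonSpec(name, (0.08, 0.08, 0.08), 0.95, 0.55, 0.0, "commensal", c, "commensal"))
    fringe = _PATHOGEN_NAMED + _PATHOGEN_NUMERIC
    for i, name in enumerate(fringe):
        f = i / max(len(fringe) - 1, 1)
        taxa.append(
            TaxonSpec(
                name,
                (0.05, 0.09, 0.18),
                (0.30 + 0.3 * f, 0.50 + 0.3 * f, 0.70 + 0.3 * f),
                0.60,
                0.30 + 0.25 * f,
                None,
                0.0,
                "pathogen",
            )
        )
    combos = [f"{g}_{e}" for g in _FILLER_GENERA for e in _FILLER_EPITHETS]
    for i in range(n_common_filler):
        f = (i * 37 % n_common_filler) / n_common_filler
        g = (i * 53 % n_common_filler) / n_common_filler
        base = 0.03 + 0.09 * g
        p = 0.16 + 0.74 * f
        taxa.append(
            TaxonSpec(
                combos[i],
                (base, base * (1.1 + 0.4 * f), base * (1.3 + 1.2 * g)),
                (max(p - 0.08, 0.12), p, min(p + 0.08, 1.0)),
                0.60,
                0.15 + 0.30 * f,
                None,
                0.0,
                "filler",
            )
        )
    for i in range(n_rare):
        f = (i * 29 % n_rare) / n_rare
        taxa.append(
            TaxonSpec(
                f"GGB{6000 + i}_SGB{9000 + i}",
                (0.01, 0.011, 0.015),
                0.01 + 0.06 * f,
                0.60,
                0.20,
                None,
                0.0,
                "rare",
            )
        )
    if len(taxa) != n_species:
        raise ConfigurationError(
            f"taxa construction produced {len(taxa)} species, expected {n_species}"
        )
    return taxa


_TAXA_TREATMENT = {
    # residual month-24 multiplicative shift of taxon biomass by tier, on
    # top of what the site-state transitions already do
    "core": {"control": 1.00, "regimen": 0.85},
    "pathogen": {"control": 1.00, "regimen": 0.90},
    "commensal": {"control": 1.00, "regimen": 1.00},
    "filler": {"control": 1.00, "regimen": 0.95},
    "rare": {"control": 1.00, "regimen": 1.00},
}


@dataclass
class CohortConfig:
    """Everything the generator needs; defaults mirror the study conditions."""

    n_subjects_per_arm: tuple[int, int] = (38, 45)  # regimen, control
    sites_per_condition: int = 3
    visits: tuple[int, ...] = (0, 6, 24)
    sequenced_visits: tuple[int, ...] = (0, 24)
    analytes: dict[str, AnalyteSpec] = field(default_factory=default_analytes)
    taxa: list[TaxonSpec] = field(default_factory=default_taxa)
    treatment_effects: dict[str, dict[str, float]] = field(
        default_factory=default_treatment_effects
    )
    transitions: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=default_transitions
    )
    month6_effects: dict[str, dict[str, float]] = field(
        default_factory=default_month6_effects
    )
    taxa_treatment: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in _TAXA_TREATMENT.items()}
    )
    #: (variable, variable, repeated-measures r) pairs whose severity
    #: loadings are solved by moment matching
    target_pairs: tuple[tuple[str, str, float], ...] = (
        ("Porphyromonas_gingivalis", "PAD", 0.68),
        ("IL-1b", "MMP-9", 0.77),
    )
    month6_panel: tuple[str, ...] = ("TLR-SEAP", "TLR-ATP")
    site_jitter_sd: float = 0.10  # log-scale site-to-site spread within a cell
    subject_sd_frac: float = 0.30  # subject intercept SD as fraction of sigma
    responder_shape: float = 4.0  # Gamma shape of the responder propensity
    # TLR-ATP biosensor onset model and standard series
    lps_a: float = -10.0
    lps_b: float = 6.0
    standard_concs: tuple[float, ...] = tuple(
        float(x) for x in np.geomspace(0.01, 3.0, 8).round(4)
    )
    standard_noise_sd: float = 0.01
    curve_points: int = 121
    emit_site_curves: bool = True
    seed: int = 0

    def validate(self) -> None:
        n_reg, n_ctrl = self.n_subjects_per_arm
        if n_reg < 1 or n_ctrl < 1:
            raise ConfigurationError("need at least one subject per arm")
        if not self.visits:
            raise ConfigurationError("visits must be non-empty")
        if not set(self.sequenced_visits) <= set(self.visits):
            raise ConfigurationError("sequenced_visits must be a subset of visits")
        for spec in self.analytes.values():
            spec.validate()
        for spec in self.taxa:
            spec.validate()
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate taxon names")
        for eff in list(self.treatment_effects.values()) + list(
            self.month6_effects.values()
        ):
            for arm, k in eff.items():
                if k <= 0:
                    raise ConfigurationError("treatment effects must be positive")

    # -- serialisation -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "n_subjects_per_arm": list(self.n_subjects_per_arm),
            "sites_per_condition": self.sites_per_condition,
            "visits": list(self.visits),
            "sequenced_visits": list(self.sequenced_visits),
            "analytes": {
                k: {
                    "targets": list(v.targets),
                    "unit": v.unit,
                    "stat": v.stat,
                    "sigma": v.sigma,
                    "loading": v.loading,
                }
                for k, v in self.analytes.items()
            },
            "treatment_effects": self.treatment_effects,
            "month6_effects": self.month6_effects,
            "taxa_treatment": self.taxa_treatment,
            "target_pairs": [list(p) for p in self.target_pairs],
            "month6_panel": list(self.month6_panel),
            "site_jitter_sd": self.site_jitter_sd,
            "subject_sd_frac": self.subject_sd_frac,
            "responder_shape": self.responder_shape,
            "lps_a": self.lps_a,
            "lps_b": self.lps_b,
            "standard_concs": list(self.standard_concs),
            "standard_noise_sd": self.standard_noise_sd,
            "curve_points": self.curve_points,
            "emit_site_curves": self.emit_site_curves,
            "seed": self.seed,
            "n_taxa": len(self.taxa),
        }
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        cfg = cls()
        if "n_subjects_per_arm" in d:
            cfg.n_subjects_per_arm = tuple(d["n_subjects_per_arm"])
        for key in (
            "sites_per_condition", "site_jitter_sd", "subject_sd_frac",
            "responder_shape", "lps_a", "lps_b", "standard_noise_sd",
            "curve_points", "emit_site_curves", "seed",
        ):
            if key in d:
                setattr(cfg, key, d[key])
        for key in ("visits", "sequenced_visits", "month6_panel", "standard_concs"):
            if key in d:
                setattr(cfg, key, tuple(d[key]))
        if "analytes" in d:
            for name, a in d["analytes"].items():
                cfg.analytes[name] = AnalyteSpec(
                    name, tuple(a["targets"]), a.get("unit", ""), a.get("stat", "mean"),
                    a.get("sigma", 0.5), a.get("loading", 0.4),
                )
        for key in ("treatment_effects", "month6_effects", "taxa_treatment"):
            if key in d:
                setattr(cfg, key, d[key])
        if "target_pairs" in d:
            cfg.target_pairs = tuple((p[0], p[1], float(p[2])) for p in d["target_pairs"])
        return cfg


@dataclass
class SyntheticCohort:
    """Bundle of generated tables plus the latent truth behind them."""

    metadata: pd.DataFrame  # one row per pooled sequencing sample
    biomarkers: pd.DataFrame  # one row per site per visit
    abundance: AbundanceMatrix
    standards: pd.DataFrame  # long (well_id, known_conc, time, value)
    site_curves: pd.DataFrame | None
    latent: pd.DataFrame  # per cell: severity, subject effect, responder propensity
    config: CohortConfig
    calibration: dict


# ---------------------------------------------------------------------------
# calibration arithmetic


def _log_shift(kappa: float, shape: float) -> float:
    """Per-unit-propensity log shift whose Gamma-mixture mean shift is kappa.

    With rho ~ Gamma(shape, 1/shape), E[exp(rho * L)] = (1 - L/shape)^-shape,
    inverted so the realized mean multiplicative effect equals kappa.
    """
    if kappa == 1.0:
        return 0.0
    return shape * (1.0 - kappa ** (-1.0 / shape))


def _centered_log_targets(targets) -> np.ndarray:
    lt = np.log(np.asarray(targets, dtype=float))
    return lt - lt.mean()


def _transition_matrix(config: CohortConfig, arm: str) -> np.ndarray:
    """3x3 month-24 state transition matrix (rows: baseline condition)."""
    P = np.eye(3)
    spec = config.transitions.get(arm, {})
    for i, base in enumerate(CONDITIONS):
        moves = spec.get(base, {})
        for new, p in moves.items():
            j = CONDITIONS.index(new)
            P[i, j] = p
        P[i, i] = 1.0 - sum(moves.values())
        if P[i, i] < -1e-9:
            raise ConfigurationError(f"transition probabilities for {base} exceed 1")
    return P


def _mixture_factor(targets, P: np.ndarray) -> float:
    """Expected month-24 pooled mean relative to baseline, from transitions alone."""
    T = np.asarray(targets, dtype=float)
    return float((P @ T).mean() / T.mean())


def _applied_kappa(config: CohortConfig, name: str, arm: str) -> float:
    """Residual multiplicative month-24 shift actually applied to one variable.

    For mean-matched analytes the configured effect is the *net* shift of the
    arm-pooled mean (calibrated to printed arm means), so the state
    transitions' own contribution is divided out; median-matched analytes and
    taxa apply their configured shift directly.
    """
    if name in config.analytes:
        spec = config.analytes[name]
        kappa = config.treatment_effects.get(name, {}).get(arm, 1.0)
        if spec.stat == "mean":
            M = _mixture_factor(spec.targets, _transition_matrix(config, arm))
            return kappa / M
        return kappa
    spec = next((t for t in config.taxa if t.name == name), None)
    if spec is None:
        raise ConfigurationError(f"variable {name!r} not found")
    return config.taxa_treatment.get(spec.tier, {}).get(arm, 1.0)


def _modulated_transition(P: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Per-subject transition matrices: responder propensity amplifies
    improvement probabilities (1-(1-p)^rho) and damps deterioration
    (1-(1-p)^(1/rho))."""
    n = len(rho)
    out = np.repeat(P[None, :, :], n, axis=0)
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            p = P[i, j]
            if p <= 0:
                continue
            expo = rho if j < i else 1.0 / rho
            out[:, i, j] = 1.0 - (1.0 - p) ** expo
    out[:, np.arange(3), np.arange(3)] = 0.0
    resid = 1.0 - out.sum(axis=2)
    out[:, np.arange(3), np.arange(3)] = np.clip(resid, 0.0, 1.0)
    return out


def _variable_terms(config: CohortConfig, name: str) -> dict:
    """Ingredients of one variable for the pair calibration."""
    if name in config.analytes:
        spec = config.analytes[name]
        jumps = np.log(np.asarray(spec.targets, dtype=float))
        kind = "analyte"
    else:
        spec = next((t for t in config.taxa if t.name == name), None)
        if spec is None:
            raise ConfigurationError(f"target-pair variable {name!r} not found")
        jumps = np.log(np.asarray(spec.weights, dtype=float))
        kind = "taxon"
    L = {
        arm: _log_shift(_applied_kappa(config, name, arm), config.responder_shape)
        for arm in ARMS
    }
    return {"kind": kind, "spec": spec, "sigma": spec.sigma, "jumps": jumps, "L": L}


_CALIBRATION_MC = 60_000
_CALIBRATION_SEED = 202_400


def _pattern_moments(config: CohortConfig, tv: dict, tw: dict) -> tuple[float, float, float]:
    """Within-subject variance/covariance of the deterministic log patterns.

    Simulates the non-Gaussian part of the model (condition layout, month-24
    state transitions, responder propensity, treatment log-shifts) for many
    synthetic subjects with a fixed internal seed and returns the
    subject-centered second moments of the two variables' patterns over a
    subject's six cells (3 conditions x baseline/month-24).
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    n = _CALIBRATION_MC
    n_reg, n_ctrl = config.n_subjects_per_arm
    w_reg = n_reg / (n_reg + n_ctrl)
    shape = config.responder_shape
    rho = rng.gamma(shape, 1.0 / shape, size=n)
    is_reg = rng.random(n) < w_reg

    trans = {arm: _transition_matrix(config, arm) for arm in ARMS}
    new_cond = np.empty((n, 3), dtype=int)
    for arm, mask in (("regimen", is_reg), ("control", ~is_reg)):
        if not mask.any():
            continue
        Pmod = _modulated_transition(trans[arm], rho[mask])
        u = rng.random((mask.sum(), 3))
        for base in range(3):
            cdf = np.cumsum(Pmod[:, base, :], axis=1)
            new_cond[mask, base] = (u[:, base : base + 1] > cdf).sum(axis=1)

    def patterns(t: dict) -> np.ndarray:
        g = t["jumps"]
        L = np.where(is_reg, t["L"]["regimen"], t["L"]["control"])
        base = np.tile(g, (n, 1))  # 3 baseline cells
        m24 = g[new_cond] + (rho * L)[:, None]  # 3 month-24 cells
        return np.concatenate([base, m24], axis=1)

    hv, hw = patterns(tv), patterns(tw)
    hv = hv - hv.mean(axis=1, keepdims=True)
    hw = hw - hw.mean(axis=1, keepdims=True)
    var_v = float((hv**2).sum(axis=1).mean() / hv.shape[1])
    var_w = float((hw**2).sum(axis=1).mean() / hw.shape[1])
    cov = float((hv * hw).sum(axis=1).mean() / hv.shape[1])
    return var_v, var_w, cov


def _solve_pair_loadings(config: CohortConfig) -> dict:
    """Solve the severity loadings of each configured target pair.

    The within-subject covariance on the log scale decomposes as
    condition-jump covariance + sigma_v*sigma_w*a_v*a_w + treatment term;
    both loadings of a pair are set equal to the square root of the product
    that makes the ratio equal the requested correlation.
    """
    out = {}
    for v, w, r_target in config.target_pairs:
        tv, tw = _variable_terms(config, v), _variable_terms(config, w)
        pat_v, pat_w, pat_cov = _pattern_moments(config, tv, tw)
        # Gaussian components: cell-level (severity/idiosyncratic) terms are
        # shrunk by subject-mean centering over the 6 cells; site jitter is
        # full for an analyte-analyte pair measured on the same sites,
        # averaged over sites when the partner is a pooled taxon
        n_sites = config.sites_per_condition
        shrink_cell = 1.0 - 1.0 / 6.0
        jit = config.site_jitter_sd**2
        both_analyte = tv["kind"] == "analyte" and tw["kind"] == "analyte"
        if both_analyte:
            jit_v = jit_w = jit * (1.0 - 1.0 / (6.0 * n_sites))
        else:
            jit_v = 0.0 if tv["kind"] == "taxon" else jit / n_sites * shrink_cell
            jit_w = 0.0 if tw["kind"] == "taxon" else jit / n_sites * shrink_cell
        var_v = pat_v + tv["sigma"] ** 2 * shrink_cell + jit_v
        var_w = pat_w + tw["sigma"] ** 2 * shrink_cell + jit_w
        prod = (r_target * math.sqrt(var_v * var_w) - pat_cov) / (
            tv["sigma"] * tw["sigma"] * shrink_cell
        )
        if prod <= 0:
            raise ConfigurationError(
                f"pair ({v}, {w}): target r={r_target} unreachable (condition "
                "jumps already exceed it)"
            )
        a = math.sqrt(prod)
        for t in (tv, tw):
            cap = math.sqrt(max(1.0 - getattr(t["spec"], "group_loading", 0.0) ** 2, 0.0))
            if a > cap + 1e-9:
                raise ConfigurationError(
                    f"pair ({v}, {w}): required loading {a:.3f} exceeds the "
                    "PSD bound; reduce sigma or the target correlation"
                )
        out[v] = a
        out[w] = a
        out[(v, w)] = {"r_target": r_target, "loading": a}
    return out


# ---------------------------------------------------------------------------
# fluorescence curve synthesis


def onset_from_model(a: float, b: float, conc: float) -> float:
    """Onset time implied by log(conc) = a/onset + b (natural log)."""
    if a == 0:
        raise ValueError("a = 0 leaves the onset undefined")
    return a / (math.log(conc) - b)


def _ramp_curve(tau: float, horizon: float, n_points: int) -> np.ndarray:
    """Monotone power-ramp fluorescence whose discrete 30% onset equals tau.

    Any onset in (0.3*horizon, horizon) is representable: cumulative area of
    (t/T)^p crosses 30% of its total at T * 0.3^(1/(p+1)); p is refined so
    the trapezoid+interpolation onset matches tau exactly.
    """
    times = np.linspace(0.0, horizon, n_points)
    frac = tau / horizon
    if not 0.3 < frac < 1.0:
        raise ValueError(
            f"onset {tau:.4g} outside the representable range "
            f"({0.3 * horizon:.4g}, {horizon:.4g}) for a monotone curve"
        )

    def discrete_onset(p: float) -> float:
        curve = FluorescenceCurve(times, (times / horizon) ** p)
        return onset_time(curve, 0.30)

    p0 = math.log(0.3) / math.log(frac) - 1.0
    lo, hi = max(p0 / 8.0, 1e-9), p0 * 8.0 + 1.0
    p = brentq(lambda q: discrete_onset(q) - tau, lo, hi, xtol=1e-13)
    return (times / horizon) ** p


def generate_standard_curves(
    a: float,
    b: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_points: int = 121,
    horizon: float | None = None,
) -> pd.DataFrame:
    """Standard fluorescence series for the onset-time calibration.

    Each concentration yields a monotone saturating curve whose 30%-of-
    saturation onset equals ``a / (ln(conc) - b)``, optionally perturbed by a
    multiplicative Gaussian of SD ``noise_sd``.  Returns a long table
    (well_id, known_conc, time, value).
    """
    concs = [float(c) for c in concentrations]
    if len(concs) < 2:
        raise ValueError(
            "need >= 2 concentrations: a single standard leaves the "
            "calibration regression underdetermined"
        )
    if any(c <= 0 for c in concs):
        raise ValueError("concentrations must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    onsets = np.array([onset_from_model(a, b, c) for c in concs])
    if (onsets <= 0).any():
        raise ValueError(
            "onset model gives non-positive onsets over this concentration "
            "range; adjust a/b"
        )
    if horizon is None:
        horizon = float(onsets.max() / 0.85)
    if onsets.min() <= 0.3 * horizon:
        raise ValueError(
            "onset spread too wide for one plate horizon: the earliest onset "
            "falls below 30% of the horizon, unreachable for a monotone curve"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times = np.linspace(0.0, horizon, n_points)
    records = []
    for i, (conc, tau) in enumerate(zip(concs, onsets)):
        if noise_sd > 0:
            tau = tau * (1.0 + noise_sd * rng.standard_normal())
            tau = float(np.clip(tau, 0.301 * horizon, 0.999 * horizon))
        values = _ramp_curve(tau, horizon, n_points)
        records.append(
            pd.DataFrame(
                {
                    "well_id": f"std_{i:02d}",
                    "known_conc": conc,
                    "time": times,
                    "value": values,
                }
            )
        )
    return pd.concat(records, ignore_index=True)


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Generate one cohort; same config (and seed) gives identical output."""
    config = config if config is not None else CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_reg, n_ctrl = config.n_subjects_per_arm
    n_subj = n_reg + n_ctrl
    shape = config.responder_shape

    loadings = _solve_pair_loadings(config)
    analytes = {
        name: replace(spec, loading=loadings.get(name, spec.loading))
        for name, spec in config.analytes.items()
    }
    taxa = [replace(t, loading=loadings.get(t.name, t.loading)) for t in config.taxa]

    subjects = np.array([f"S{i:04d}" for i in range(1, n_subj + 1)])
    arms = np.array(["regimen"] * n_reg + ["control"] * n_ctrl)
    u = rng.standard_normal(n_subj)
    rho = rng.gamma(shape, 1.0 / shape, size=n_subj)

    visits = list(config.visits)
    cells = pd.DataFrame(
        [
            (subjects[s], arms[s], cond, v, s, ci)
            for s in range(n_subj)
            for ci, cond in enumerate(CONDITIONS)
            for v in visits
        ],
        columns=["subject_id", "arm", "condition", "visit_month", "subj_idx", "cond_idx"],
    )
    n_cells = len(cells)
    eta = rng.standard_normal(n_cells)
    factors = {
        g: rng.standard_normal(n_cells) for g in ("red", "pink", "commensal")
    }
    subj_idx = cells["subj_idx"].to_numpy()
    cond_idx = cells["cond_idx"].to_numpy()
    visit = cells["visit_month"].to_numpy()
    is_seq = np.isin(visit, config.sequenced_visits)
    arm_is_reg = (cells["arm"] == "regimen").to_numpy()

    # month-24 effective site states: sites genuinely improve (or worsen)
    # over two years; the recorded condition label stays the baseline one
    eff_cond = cond_idx.copy()
    m24 = visit == 24
    trans = {arm: _transition_matrix(config, arm) for arm in ARMS}
    u_trans = rng.random(n_cells)
    for arm, mask_arm in (("regimen", arm_is_reg), ("control", ~arm_is_reg)):
        mask = m24 & mask_arm
        if not mask.any():
            continue
        Pmod = _modulated_transition(trans[arm], rho[subj_idx[mask]])
        rows = Pmod[np.arange(mask.sum()), cond_idx[mask], :]
        cdf = np.cumsum(rows, axis=1)
        eff_cond[mask] = (u_trans[mask, None] > cdf).sum(axis=1)

    def treatment_term(name: str, at_visit: np.ndarray) -> np.ndarray:
        L = np.where(
            arm_is_reg,
            _log_shift(_applied_kappa(config, name, "regimen"), shape),
            _log_shift(_applied_kappa(config, name, "control"), shape),
        )
        return np.where(at_visit, rho[subj_idx] * L, 0.0)

    def month6_term(name: str) -> np.ndarray:
        eff = config.month6_effects.get(name, {})
        L = np.where(
            arm_is_reg,
            _log_shift(eff.get("regimen", 1.0), shape),
            _log_shift(eff.get("control", 1.0), shape),
        )
        return np.where(visit == 6, rho[subj_idx] * L, 0.0)

    # --- biomarker panel ---------------------------------------------------
    n_sites = config.sites_per_condition
    jit = config.site_jitter_sd
    site_frames = {}
    for name, spec in analytes.items():
        a = spec.loading
        c = 0.0
        e = math.sqrt(max(1.0 - a * a - c * c, 0.0))
        s_u = config.subject_sd_frac * spec.sigma
        eps = rng.standard_normal(n_cells)
        total_var = spec.sigma**2 + s_u**2 + jit**2
        mu = np.log([spec.targets[i] for i in range(3)])
        if spec.stat == "mean":
            mu = mu - total_var / 2.0
        logval = (
            mu[eff_cond]
            + spec.sigma * (a * eta + e * eps)
            + s_u * u[subj_idx]
            + treatment_term(name, at_visit=m24)
            + month6_term(name)
        )
        site_jitter = rng.standard_normal((n_cells, n_sites)) * jit
        site_frames[name] = np.exp(logval[:, None] + site_jitter)

    bio_rows = []
    for k in range(n_sites):
        df = cells[["subject_id", "arm", "condition", "visit_month"]].copy()
        df["site"] = k + 1
        for name in analytes:
            df[name] = site_frames[name][:, k]
        bio_rows.append(df)
    biomarkers = pd.concat(bio_rows, ignore_index=True)
    biomarkers["sample_id"] = (
        biomarkers["subject_id"]
        + "_" + biomarkers["condition"].str[0].str.upper()
        + "_m" + biomarkers["visit_month"].astype(str)
        + "_s" + biomarkers["site"].astype(str)
    )
    # month-6 visits carry only the TLR panel by default
    off_panel = [n for n in analytes if n not in config.month6_panel]
    biomarkers.loc[biomarkers["visit_month"] == 6, off_panel] = np.nan
    biomarkers = biomarkers.set_index("sample_id").sort_values(
        ["subject_id", "condition", "visit_month", "site"]
    )

    # --- pooled abundance samples -------------------------------------------
    seq = np.flatnonzero(is_seq)
    n_seq = len(seq)
    names = [t.name for t in taxa]
    abs_matrix = np.zeros((len(taxa), n_seq))
    group_arr = {g: factors[g][seq] for g in factors}
    eta_seq = eta[seq]
    for i, t in enumerate(taxa):
        a, c = t.loading, t.group_loading
        e = math.sqrt(max(1.0 - a * a - c * c, 0.0))
        s_u = config.subject_sd_frac * t.sigma
        eps = rng.standard_normal(n_seq)
        fterm = group_arr[t.group] if t.group in group_arr else 0.0
        mu = np.log(t.weights) - (t.sigma**2 + s_u**2) / 2.0
        logval = (
            mu[eff_cond[seq]]
            + t.sigma * (a * eta_seq + c * fterm + e * eps)
            + s_u * u[subj_idx[seq]]
            + treatment_term(t.name, at_visit=m24)[seq]
        )
        p_present = np.asarray(t.presence_by_condition())[eff_cond[seq]]
        present = rng.random(n_seq) < p_present
        abs_matrix[i] = np.where(present, np.exp(logval), 0.0)

    dna = abs_matrix.sum(axis=0)
    frac = np.clip(
        0.25 + 0.10 * cond_idx[seq] + 0.05 * rng.standard_normal(n_seq), 0.05, 0.9
    )
    total_dna = np.where(frac > 0, dna / frac, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(dna > 0, abs_matrix / dna * 100.0, 0.0)

    sample_ids = (
        cells.loc[seq, "subject_id"]
        + "_" + cells.loc[seq, "condition"].str[0].str.upper()
        + "_m" + cells.loc[seq, "visit_month"].astype(str)
    ).to_numpy()
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": cells.loc[seq, "subject_id"].to_numpy(),
            "arm": cells.loc[seq, "arm"].to_numpy(),
            "visit_month": cells.loc[seq, "visit_month"].to_numpy(),
            "condition": cells.loc[seq, "condition"].to_numpy(),
            "total_dna_ng": total_dna,
            "microbial_read_fraction": frac,
        }
    ).set_index("sample_id")
    abundance = AbundanceMatrix(
        pd.DataFrame(rel, index=names, columns=sample_ids),
        metadata[["total_dna_ng", "microbial_read_fraction"]],
    )

    # --- fluorescence curves -------------------------------------------------
    standards = generate_standard_curves(
        config.lps_a,
        config.lps_b,
        config.standard_concs,
        noise_sd=config.standard_noise_sd,
        seed=rng,
        n_points=config.curve_points,
    )
    site_curves = None
    if config.emit_site_curves:
        site_curves = _site_curves(config, biomarkers, standards)

    latent = cells[["subject_id", "arm", "condition", "visit_month"]].copy()
    latent["effective_condition"] = [CONDITIONS[i] for i in eff_cond]
    latent["severity"] = eff_cond.astype(float) + 0.5 * eta
    latent["subject_effect"] = u[subj_idx]
    latent["responder_propensity"] = rho[subj_idx]

    calibration = {
        "pairs": {
            f"{v}|{w}": info
            for (v, w), info in (
                ((p[0], p[1]), loadings[(p[0], p[1])]) for p in config.target_pairs
            )
        },
        "loadings": {k: v for k, v in loadings.items() if isinstance(k, str)},
    }
    return SyntheticCohort(
        metadata=metadata,
        biomarkers=biomarkers,
        abundance=abundance,
        standards=standards,
        site_curves=site_curves,
        latent=latent,
        config=config,
        calibration=calibration,
    )


def _site_curves(
    config: CohortConfig, biomarkers: pd.DataFrame, standards: pd.DataFrame
) -> pd.DataFrame:
    """Raw TLR-ATP kinetics per site, consistent with the biomarker values."""
    horizon = float(standards["time"].max())
    n_points = config.curve_points
    times = np.linspace(0.0, horizon, n_points)
    rows = biomarkers.dropna(subset=["TLR-ATP"])
    vals = rows["TLR-ATP"].to_numpy(float)
    with np.errstate(divide="ignore"):
        tau = config.lps_a / (np.log(vals) - config.lps_b)
    clamped = (tau <= 0.302 * horizon) | (tau >= 0.995 * horizon) | ~np.isfinite(tau)
    tau = np.clip(np.nan_to_num(tau, nan=0.302 * horizon), 0.302 * horizon, 0.995 * horizon)
    # closed-form ramp exponent; the small interpolation bias is irrelevant here
    p = np.log(0.3) / np.log(tau / horizon) - 1.0
    values = (times[None, :] / horizon) ** p[:, None]
    out = pd.DataFrame(
        {
            "well_id": np.repeat(rows.index.to_numpy(), n_points),
            "known_conc": np.nan,
            "time": np.tile(times, len(rows)),
            "value": values.ravel(),
        }
    )
    out["clamped"] = np.repeat(clamped, n_points)
    return out
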