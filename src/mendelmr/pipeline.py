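"""End-to-end orchestration: select -> proxy -> harmonise -> estimate -> power.

A single :class:`RunConfig` (usually loaded from YAML) drives the whole
analysis across one exposure and any number of outcomes, at a
genome-wide instrument-selection tier and optionally a more liberal one.
Failures are contained per outcome: a malformed or unusable outcome
yields a structured error entry while the remaining outcomes complete.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .errors import ConfigError, MrError
from .estimators import (
    Z_975,
    MrResult,
    ivw,
    kept_only,
    mr_egger,
    mr_raps,
    to_odds_scale,
    wald_ratio,
    weighted_median,
)
from .harmonise import HarmonisedVariant, harmonise_pair, harmonise_panels, harmonisation_log
from .io import read_panel, write_report
from .records import Method, ReportRow, TraitPanel, TraitType
from .select import SelectionParams, clump
from .simulate import LdTable, SimulationConfig, generate_two_sample
from .power import PowerQuery, detectable_or

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureSpec",
    "OutcomeSpec",
    "EstimatorSettings",
    "PowerSettings",
    "RunConfig",
    "RunReport",
    "run",
    "simulate_and_recover",
    "harmonise_matched_panels",
]

GENOME_WIDE_TIER = "genome_wide"
LIBERAL_TIER = "liberal"


@dataclass
class ExposureSpec:
    path: str
    trait_type: str = "continuous"
    trait_id: Optional[str] = None
    column_map: Optional[dict] = None
    sep: str = "\t"


@dataclass
class OutcomeSpec:
    outcome_id: str
    path: str
    trait_type: str = "binary"
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    column_map: Optional[dict] = None
    sep: str = "\t"


@dataclass
class EstimatorSettings:
    effects_mode: str = "auto"
    bootstrap_reps: int = 1000
    seed: int = 0


@dataclass
class PowerSettings:
    alpha: float = 0.05
    target_power: float = 0.80
    #: Fixed instrument r2 to use instead of the set's own summed
    #: variance explained (e.g. an externally estimated value).
    r2_override: Optional[float] = None


@dataclass
class RunConfig:
    exposure: ExposureSpec
    outcomes: list[OutcomeSpec]
    selection: SelectionParams = field(default_factory=SelectionParams)
    liberal_p_threshold: Optional[float] = None
    ld_path: Optional[str] = None
    proxy_path: Optional[str] = None
    estimators: EstimatorSettings = field(default_factory=EstimatorSettings)
    power: PowerSettings = field(default_factory=PowerSettings)
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.outcomes:
            raise ConfigError("at least one outcome is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        try:
            return cls(
                exposure=ExposureSpec(**raw["exposure"]),
                outcomes=[OutcomeSpec(**o) for o in raw["outcomes"]],
                selection=SelectionParams(**raw.get("selection", {})),
                liberal_p_threshold=raw.get("liberal_p_threshold"),
                ld_path=raw.get("ld_path"),
                proxy_path=raw.get("proxy_path"),
                estimators=EstimatorSettings(**raw.get("estimators", {})),
                power=PowerSettings(**raw.get("power", {})),
                output_dir=raw.get("output_dir"),
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid run configuration: {exc}") from exc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Full result of one pipeline run."""

    rows: list[ReportRow]
    harmonisation_log: pd.DataFrame
    qc: dict
    power: list[dict]
    failures: dict[str, str]
    provenance: dict

    def to_json_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "qc": self.qc,
            "power": self.power,
            "failures": self.failures,
            "results": [
                {
                    "outcome_id": r.outcome_id,
                    "method": r.method.value,
                    "selection_tier": r.selection_tier,
                    "n_snp": r.n_snp,
                    "beta": r.beta,
                    "se": r.se,
                    "or": r.or_,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "pval": r.pval,
                    "egger_intercept": r.egger_intercept,
                    "intercept_se": r.intercept_se,
                    "intercept_p": r.intercept_p,
                }
                for r in self.rows
            ],
            "harmonisation_log": self.harmonisation_log.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True, indent=2)

    @property
    def all_failed(self) -> bool:
        return len(self.rows) == 0


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _derived_seed(base: int, *key: int) -> int:
    ss = np.random.SeedSequence(entropy=base, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _estimate_battery(
    kept: list[HarmonisedVariant],
    outcome_id: str,
    tier: str,
    trait_type: TraitType,
    settings: EstimatorSettings,
    wm_seed: int,
) -> list[ReportRow]:
    """IVW / weighted-median / Egger / RAPS battery, degraded gracefully.

    Single-instrument outcomes fall back to the Wald ratio; the median
    and Egger require at least three instruments, RAPS at least two.
    """
    rows: list[ReportRow] = []
    n = len(kept)
    if n == 1:
        theta, se = wald_ratio(kept[0])
        res = MrResult(
            method=Method.Wald,
            n_snp=1,
            beta=theta,
            se=se,
            ci_low=theta - Z_975 * se,
            ci_high=theta + Z_975 * se,
            pval=float(min(1.0, 2.0 * stats.norm.sf(abs(theta) / se))),
        )
        rows.append(to_odds_scale(res, outcome_id, trait_type, tier))
        return rows

    rows.append(to_odds_scale(ivw(kept, settings.effects_mode), outcome_id, trait_type, tier))
    if n >= 3:
        rows.append(
            to_odds_scale(
                weighted_median(kept, settings.bootstrap_reps, wm_seed),
                outcome_id,
                trait_type,
                tier,
            )
        )
        rows.append(to_odds_scale(mr_egger(kept), outcome_id, trait_type, tier))
    rows.append(to_odds_scale(mr_raps(kept), outcome_id, trait_type, tier))
    return rows


def run(config: RunConfig) -> RunReport:
    """Execute the full analysis described by ``config``.

    Deterministic given the config (including its seed): re-running
    yields a byte-identical JSON report.  Writes ``report.tsv``,
    ``report.json`` and ``harmonisation_log.tsv`` to ``output_dir``
    when one is configured.
    """
    exposure_panel = read_panel(
        config.exposure.path,
        trait_type=config.exposure.trait_type,
        column_map=config.exposure.column_map,
        trait_id=config.exposure.trait_id,
        sep=config.exposure.sep,
    )
    ld = (
        LdTable.from_frame(pd.read_csv(config.ld_path, sep="\t"))
        if config.ld_path
        else LdTable()
    )
    proxies = pd.read_csv(config.proxy_path, sep="\t") if config.proxy_path else None

    tiers: dict[str, SelectionParams] = {GENOME_WIDE_TIER: config.selection}
    if config.liberal_p_threshold is not None:
        tiers[LIBERAL_TIER] = dataclasses.replace(
            config.selection, p_threshold=config.liberal_p_threshold
        )

    rows: list[ReportRow] = []
    logs: list[pd.DataFrame] = []
    failures: dict[str, str] = {}
    qc: dict = {"exposure_candidates": len(exposure_panel), "tiers": {}}
    power_rows: list[dict] = []

    for tier_idx, (tier, params) in enumerate(tiers.items()):
        try:
            instruments = clump(exposure_panel, ld, params)
        except MrError as exc:
            failures[f"{tier}:selection"] = str(exc)
            continue
        qc["tiers"][tier] = {
            "n_instruments": len(instruments),
            "per_variant_f": {k: float(v) for k, v in instruments.per_variant_f.items()},
            "mean_f": float(instruments.mean_f),
            "r2_total": None if instruments.r2_total is None else float(instruments.r2_total),
        }
        logger.info(
            "tier %s: %d candidates -> %d instruments (mean F %.1f)",
            tier, len(exposure_panel), len(instruments), instruments.mean_f,
        )

        for out_idx, outcome_spec in enumerate(config.outcomes):
            key = f"{tier}:{outcome_spec.outcome_id}"
            try:
                outcome_panel = read_panel(
                    outcome_spec.path,
                    trait_type=outcome_spec.trait_type,
                    column_map=outcome_spec.column_map,
                    trait_id=outcome_spec.outcome_id,
                    sep=outcome_spec.sep,
                    n_cases=outcome_spec.n_cases,
                    n_controls=outcome_spec.n_controls,
                )
                harmonised = harmonise_panels(instruments, outcome_panel, proxies, params)
                logs.append(
                    harmonisation_log(harmonised, outcome_spec.outcome_id).assign(selection_tier=tier)
                )
                kept = kept_only(harmonised)
                logger.info(
                    "%s: %d instruments -> %d harmonised -> %d analysed",
                    key, len(instruments), len(harmonised), len(kept),
                )
                wm_seed = _derived_seed(config.estimators.seed, tier_idx, out_idx)
                rows.extend(
                    _estimate_battery(
                        kept,
                        outcome_spec.outcome_id,
                        tier,
                        TraitType(outcome_spec.trait_type),
                        config.estimators,
                        wm_seed,
                    )
                )
            except MrError as exc:
                failures[key] = str(exc)
                continue

            if tier == GENOME_WIDE_TIER and TraitType(outcome_spec.trait_type) is TraitType.binary:
                n_cases = outcome_spec.n_cases or outcome_panel.n_cases
                n_controls = outcome_spec.n_controls or outcome_panel.n_controls
                r2 = config.power.r2_override or instruments.r2_total
                if n_cases and n_controls and r2:
                    pr = detectable_or(
                        PowerQuery(
                            n_cases=n_cases,
                            n_controls=n_controls,
                            r2_instruments=r2,
                            alpha=config.power.alpha,
                            target_power=config.power.target_power,
                        )
                    )
                    power_rows.append(
                        {
                            "outcome_id": outcome_spec.outcome_id,
                            "n_cases": n_cases,
                            "n_controls": n_controls,
                            "r2_instruments": r2,
                            "alpha": config.power.alpha,
                            "target_power": config.power.target_power,
                            "detectable_or_protective": pr.or_protective,
                            "detectable_or_harmful": pr.or_harmful,
                        }
                    )

    log_df = (
        pd.concat(logs, ignore_index=True)
        if logs
        else pd.DataFrame()
    )
    report = RunReport(
        rows=rows,
        harmonisation_log=log_df,
        qc=qc,
        power=power_rows,
        failures=failures,
        provenance={
            "config_hash": _config_hash(config),
            "seed": config.estimators.seed,
            "version": __version__,
        },
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        if rows:
            write_report(rows, out / "report.tsv")
        (out / "report.json").write_text(report.to_json())
        log_df.to_csv(out / "harmonisation_log.tsv", sep="\t", index=False)
    return report


def harmonise_matched_panels(
    exposure: TraitPanel, outcome: TraitPanel
) -> list[HarmonisedVariant]:
    """Harmonise every variant the two panels share, in exposure order."""
    return [
        harmonise_pair(rec, outcome.records[vid])
        for vid, rec in exposure.records.items()
        if vid in outcome.records
    ]


def simulate_and_recover(
    sim: SimulationConfig,
    replicates: int,
    config: Optional[RunConfig] = None,
    estimators: Sequence[str] = ("IVW", "weighted_median", "MR_Egger", "MR_RAPS"),
    bootstrap_reps: int = 200,
) -> pd.DataFrame:
    """Repeated-simulation validation of the estimator battery.

    For each of ``replicates`` independent datasets drawn under ``sim``
    (per-replicate seeds derived from ``sim.seed``), all generated
    variants are harmonised and fed to each requested estimator.
    Returns one row per estimator with mean bias against the true causal
    effect, empirical SE of the estimates, mean estimated SE, empirical
    95% CI coverage, and the rejection rate at alpha = 0.05 (the type-I
    error when ``sim.true_beta`` is zero).  For MR-Egger an extra row
    summarises the pleiotropy intercept against ``sim.pleiotropy_mean``.

    The weighted-median bootstrap inside each replicate uses
    ``bootstrap_reps`` resamples (or the run config's setting when a
    config is supplied).
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    if config is not None:
        bootstrap_reps = config.estimators.bootstrap_reps

    seeds = np.random.SeedSequence(sim.seed).generate_state(2 * replicates) % (2**31)
    est_rows: dict[str, list[tuple[float, float]]] = {e: [] for e in estimators}
    intercepts: list[tuple[float, float]] = []

    for r in range(replicates):
        sim_r = dataclasses.replace(sim, seed=int(seeds[r]))
        exposure, outcome, _truth = generate_two_sample(sim_r)
        hs = harmonise_matched_panels(exposure, outcome)
        for name in estimators:
            if name == "IVW":
                res = ivw(hs)
            elif name == "weighted_median":
                res = weighted_median(hs, bootstrap_reps, int(seeds[replicates + r]))
            elif name == "MR_Egger":
                res = mr_egger(hs)
                intercepts.append((res.intercept, res.intercept_se))
            elif name == "MR_RAPS":
                res = mr_raps(hs)
            else:
                raise ConfigError(f"unknown estimator {name!r}")
            est_rows[name].append((res.beta, res.se))

    out = []
    for name in estimators:
        betas = np.array([b for b, _ in est_rows[name]])
        ses = np.array([s for _, s in est_rows[name]])
        covered = np.abs(betas - sim.true_beta) <= Z_975 * ses
        rejected = np.abs(betas) / ses > Z_975
        out.append(
            {
                "estimator": name,
                "n_replicates": replicates,
                "true_beta": sim.true_beta,
                "mean_bias": float(np.mean(betas) - sim.true_beta),
                "empirical_se": float(np.std(betas, ddof=1)) if replicates > 1 else float("nan"),
                "mean_se": float(np.mean(ses)),
                "coverage": float(np.mean(covered)),
                "rejection_rate": float(np.mean(rejected)),
            }
        )
    if intercepts:
        ints = np.array([b for b, _ in intercepts])
        int_ses = np.array([s for _, s in intercepts])
        covered = np.abs(ints - sim.pleiotropy_mean) <= Z_975 * int_ses
        rejected = np.abs(ints) / int_ses > Z_975
        out.append(
            {
                "estimator": "MR_Egger_intercept",
                "n_replicates": replicates,
                "true_beta": sim.pleiotropy_mean,
                "mean_bias": float(np.mean(ints) - sim.pleiotropy_mean),
                "empirical_se": float(np.std(ints, ddof=1)) if replicates > 1 else float("nan"),
                "mean_se": float(np.mean(int_ses)),
                "coverage": float(np.mean(covered)),
                "rejection_rate": float(np.mean(rejected)),
            }
        )
    return pd.DataFrame(out)
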