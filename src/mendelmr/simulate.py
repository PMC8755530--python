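"""Synthetic two-sample GWAS summary statistics for MR validation.

The generator draws per-variant true exposure effects gamma_j, direct
(pleiotropic) outcome effects alpha_j, and observed estimates with
GWAS-realistic standard errors, so that every estimator in
:mod:`mendelmr.estimators` can be checked against known truth.  It also
produces deliberately corrupted panels (allele swaps, strand
complements, palindromic conversions, masked frequencies) to exercise
harmonisation, and block-structured LD/proxy tables to exercise clumping
and proxy lookup.

Model
-----
For variant j with effect-allele frequency p_j ~ Uniform(0.05, 0.95):

* gamma_j ~ Normal(0, gamma_sd); observed gamma_hat_j = gamma_j + e_j
  with e_j ~ Normal(0, se_xj), se_xj = 1/sqrt(2 p_j (1-p_j) n_exposure)
  (standardised-trait GWAS precision).
* alpha_j ~ Normal(pleiotropy_mean, pleiotropy_sd) in the
  exposure-increasing allele orientation (sign(gamma_j) maps it to the
  effect-allele frame), optionally correlated with |gamma_j| at
  ``inside_violation`` through a Gaussian construction (violating the
  InSIDE condition that instrument strength be independent of direct
  effects).  A positive ``pleiotropy_mean`` therefore models direct
  effects systematically aligned with the exposure-raising allele, the
  situation the Egger intercept is designed to flag.
* Outcome (log-odds scale when ``case_fraction`` K is set):
  Gamma_j = true_beta * gamma_j + alpha_j, observed with
  se_yj = 1/sqrt(2 p_j (1-p_j) n_outcome K (1-K)); for a continuous
  outcome the K(1-K) factor is omitted.

Defaults mirror a cytokine-on-infection study design: a small exposure
GWAS (n = 3636, instrument strength giving mean F around 30), a very
large binary outcome GWAS (n = 1e6, ~4% cases), and a modest protective
causal effect (log-OR -0.04 per SD of exposure).

The RNG stream is derived from ``config.seed`` alone: generation,
corruption and LD construction each consume an independent child stream
of the same seed sequence, so any subset of the three operations is
reproducible without re-running the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError
from .records import AssociationRecord, TraitPanel, TraitType

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "LdTable",
    "CorruptionResult",
    "generate_two_sample",
    "corrupt_for_harmonisation",
    "generate_ld_and_proxies",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}
#: Non-palindromic allele pairs cycled over generated variants.
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"), ("A", "C"), ("G", "T"))

_PVAL_FLOOR = 1e-300


@dataclass
class SimulationConfig:
    """Full generative specification for a synthetic two-sample dataset.

    All corruption fractions default to zero (clean panels); ``seed``
    fixes every random draw, including corruption and LD construction.
    """

    j_variants: int = 100
    n_exposure: int = 3636
    n_outcome: int = 1_000_000
    true_beta: float = -0.04
    gamma_sd: float = 0.15
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    inside_violation: float = 0.0
    case_fraction: Optional[float] = 0.04
    palindromic_fraction: float = 0.0
    allele_swap_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    missing_eaf_fraction: float = 0.0
    ld_block_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.j_variants < 1:
            raise ConfigError("j_variants must be >= 1")
        if self.n_exposure < 2 or self.n_outcome < 2:
            raise ConfigError("sample sizes must be >= 2")
        if not (self.gamma_sd > 0):
            raise ConfigError("gamma_sd must be positive")
        if not (-1.0 <= self.inside_violation <= 1.0):
            raise ConfigError("inside_violation must lie in [-1, 1]")
        if self.case_fraction is not None and not (0.0 < self.case_fraction < 1.0):
            raise ConfigError("case_fraction must lie in (0, 1)")
        for name in (
            "palindromic_fraction",
            "allele_swap_fraction",
            "strand_flip_fraction",
            "missing_eaf_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.ld_block_size < 1:
            raise ConfigError("ld_block_size must be >= 1")


@dataclass
class SimulationTruth:
    """Per-variant ground truth recorded for recovery tests."""

    variant_ids: list[str]
    gamma: np.ndarray
    alpha: np.ndarray
    eaf: np.ndarray
    true_beta: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "gamma": self.gamma,
                "alpha": self.alpha,
                "eaf": self.eaf,
                "true_beta": self.true_beta,
            }
        )


@dataclass
class LdTable:
    """Sparse symmetric pairwise r-squared; absent pairs are r2 = 0."""

    pairs: dict[tuple[str, str], float] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ConfigError(f"r2 must lie in [0, 1], got {r2}")
        if a != b:
            self.pairs[self._key(a, b)] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.pairs.get(self._key(a, b), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"variant_a": a, "variant_b": b, "r2": v} for (a, b), v in sorted(self.pairs.items())
        ]
        return pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LdTable":
        table = cls()
        for _, row in df.iterrows():
            table.set(str(row["variant_a"]), str(row["variant_b"]), float(row["r2"]))
        return table


@dataclass
class CorruptionResult:
    """Corrupted panels plus the manifest of applied corruptions."""

    outcome: TraitPanel
    exposure: Optional[TraitPanel]
    #: variant_id -> tuple of applied corruption labels, in application order.
    manifest: dict[str, tuple[str, ...]]


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(stream,)))


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, _PVAL_FLOOR, 1.0)


def generate_two_sample(
    config: SimulationConfig,
) -> tuple[TraitPanel, TraitPanel, SimulationTruth]:
    """Generate exposure and outcome panels plus the truth manifest.

    Draw order within the generation stream is fixed (gamma, EAF,
    pleiotropy, exposure noise, outcome noise) so that identical seeds
    give byte-identical panels.
    """
    rng = _rng(config, 0)
    j = config.j_variants

    gamma = rng.normal(0.0, config.gamma_sd, size=j)
    eaf = rng.uniform(0.05, 0.95, size=j)

    # Pleiotropy, defined in the exposure-increasing allele orientation
    # (the frame in which a directional mean is estimable by the Egger
    # intercept); correlated with standardised |gamma| at the requested
    # level via a Gaussian construction (InSIDE holds at 0).  The
    # effect-allele-frame direct effect is sign(gamma) times this.
    z = rng.normal(size=j)
    rho = config.inside_violation
    if config.pleiotropy_sd > 0:
        half_mean = config.gamma_sd * np.sqrt(2.0 / np.pi)
        half_sd = config.gamma_sd * np.sqrt(1.0 - 2.0 / np.pi)
        g_std = (np.abs(gamma) - half_mean) / half_sd
        alpha_oriented = config.pleiotropy_mean + config.pleiotropy_sd * (
            rho * g_std + np.sqrt(1.0 - rho**2) * z
        )
    else:
        alpha_oriented = np.full(j, config.pleiotropy_mean)
    alpha = np.where(gamma >= 0, 1.0, -1.0) * alpha_oriented

    se_x = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_exposure)
    gamma_hat = gamma + rng.normal(size=j) * se_x

    big_gamma = config.true_beta * gamma + alpha
    if config.case_fraction is not None:
        k = config.case_fraction
        se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome * k * (1.0 - k))
    else:
        se_y = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * config.n_outcome)
    big_gamma_hat = big_gamma + rng.normal(size=j) * se_y

    p_x = _two_sided_p(gamma_hat, se_x)
    p_y = _two_sided_p(big_gamma_hat, se_y)

    ids = [f"rs{i + 1:06d}" for i in range(j)]
    chroms = [str(i % 22 + 1) for i in range(j)]
    positions = [1_000_000 * (i // 22 + 1) for i in range(j)]
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(j)]

    exp_records = []
    out_records = []
    if config.case_fraction is not None:
        n_cases = int(round(config.n_outcome * config.case_fraction))
        n_controls = config.n_outcome - n_cases
        out_type = TraitType.binary
    else:
        n_cases = n_controls = None
        out_type = TraitType.continuous

    for i in range(j):
        ea, oa = pairs[i]
        exp_records.append(
            AssociationRecord(
                variant_id=ids[i],
                chromosome=chroms[i],
                position=positions[i],
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[i]),
                beta=float(gamma_hat[i]),
                se=float(se_x[i]),
                pval=float(p_x[i]),
                n=config.n_exposure,
            )
        )
        out_records.append(
            AssociationRecord(
                variant_id=ids[i],
                chromosome=chroms[i],
                position=positions[i],
                effect_allele=ea,
                other_allele=oa,
                eaf=float(eaf[i]),
                beta=float(big_gamma_hat[i]),
                se=float(se_y[i]),
                pval=float(p_y[i]),
                n=config.n_outcome,
            )
        )

    exposure = TraitPanel.from_records("sim_exposure", TraitType.continuous, exp_records)
    outcome = TraitPanel.from_records(
        "sim_outcome", out_type, out_records, n_cases=n_cases, n_controls=n_controls
    )
    truth = SimulationTruth(ids, gamma, alpha, eaf, config.true_beta)
    return exposure, outcome, truth


def corrupt_for_harmonisation(
    outcome: TraitPanel,
    config: SimulationConfig,
    exposure: Optional[TraitPanel] = None,
) -> CorruptionResult:
    """Apply information-preserving corruptions to exercise harmonisation.

    Per variant, independently:

    * ``palindromic``: both panels' allele pair replaced by A/T (same
      orientation, effects and frequencies untouched) — requires
      ``exposure`` so the pair stays consistent across panels;
    * ``allele_swap``: outcome effect/other alleles swapped, beta
      negated, EAF complemented (information-preserving);
    * ``strand_flip``: outcome alleles strand-complemented (skipped for
      variants made palindromic, where a complement is indistinguishable
      from a swap);
    * ``missing_eaf``: exposure EAF masked (requires ``exposure``).

    Returns the corrupted panels and a manifest listing, per touched
    variant, the corruption labels in application order.
    """
    rng = _rng(config, 1)
    ids = list(outcome.records)
    u = rng.random((len(ids), 4))

    out_records: dict[str, AssociationRecord] = {}
    exp_records: dict[str, AssociationRecord] = dict(exposure.records) if exposure else {}
    manifest: dict[str, tuple[str, ...]] = {}

    for i, vid in enumerate(ids):
        rec = outcome.records[vid]
        actions: list[str] = []

        palin = u[i, 0] < config.palindromic_fraction
        if palin:
            rec = rec.copy(effect_allele="A", other_allele="T")
            if exposure and vid in exp_records:
                exp_records[vid] = exp_records[vid].copy(effect_allele="A", other_allele="T")
            actions.append("palindromic")

        if u[i, 1] < config.allele_swap_fraction:
            eaf = None if rec.eaf is None else 1.0 - rec.eaf
            rec = rec.copy(
                effect_allele=rec.other_allele,
                other_allele=rec.effect_allele,
                beta=-rec.beta,
                eaf=eaf,
            )
            actions.append("allele_swap")

        if not palin and u[i, 2] < config.strand_flip_fraction:
            rec = rec.copy(
                effect_allele=_COMP[rec.effect_allele],
                other_allele=_COMP[rec.other_allele],
            )
            actions.append("strand_flip")

        if exposure and vid in exp_records and u[i, 3] < config.missing_eaf_fraction:
            exp_records[vid] = exp_records[vid].copy(eaf=None)
            actions.append("missing_eaf")

        out_records[vid] = rec
        if actions:
            manifest[vid] = tuple(actions)

    corrupted_outcome = TraitPanel(
        outcome.trait_id,
        outcome.trait_type,
        out_records,
        n_cases=outcome.n_cases,
        n_controls=outcome.n_controls,
    )
    corrupted_exposure = None
    if exposure:
        corrupted_exposure = TraitPanel(
            exposure.trait_id, exposure.trait_type, exp_records,
            n_cases=exposure.n_cases, n_controls=exposure.n_controls,
        )
    return CorruptionResult(corrupted_outcome, corrupted_exposure, manifest)


def generate_ld_and_proxies(
    panel: TraitPanel, config: SimulationConfig
) -> tuple[LdTable, pd.DataFrame]:
    """Build a block-structured LD table and proxy table for a panel.

    Variants are grouped into consecutive blocks of ``ld_block_size``;
    within-block r2 is drawn Uniform(0.5, 1), between-block r2 is 0.
    The proxy table lists, for every variant, its block-mates with their
    r2 (both directions), mirroring a local replay of an online proxy
    lookup service.
    """
    if len(panel) == 0:
        raise ConfigError("cannot build an LD table for an empty panel")
    rng = _rng(config, 2)
    ids = list(panel.records)
    table = LdTable()
    proxy_rows = []
    size = config.ld_block_size
    for start in range(0, len(ids), size):
        block = ids[start : start + size]
        for a_idx in range(len(block)):
            for b_idx in range(a_idx + 1, len(block)):
                r2 = float(rng.uniform(0.5, 1.0))
                table.set(block[a_idx], block[b_idx], r2)
                proxy_rows.append({"variant_a": block[a_idx], "variant_b": block[b_idx], "r2": r2})
                proxy_rows.append({"variant_a": block[b_idx], "variant_b": block[a_idx], "r2": r2})
    proxies = pd.DataFrame(proxy_rows, columns=["variant_a", "variant_b", "r2"])
    return table, proxies
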