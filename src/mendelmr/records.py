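"""Domain types for GWAS summary statistics and MR report rows.

The package works entirely at the summary level: one
:class:`AssociationRecord` per variant per trait, grouped into a
:class:`TraitPanel` keyed by variant identifier.  Effect sizes for binary
traits are log odds ratios per effect-allele copy; effect sizes for
standardised continuous traits are in SD units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional

from .errors import DuplicateVariantError, FormatError

__all__ = [
    "AssociationRecord",
    "TraitPanel",
    "TraitType",
    "Method",
    "ReportRow",
]

VALID_ALLELES = frozenset("ACGT")


class TraitType(str, Enum):
    binary = "binary"
    continuous = "continuous"


class Method(str, Enum):
    IVW = "IVW"
    weighted_median = "weighted_median"
    MR_Egger = "MR_Egger"
    MR_RAPS = "MR_RAPS"
    Wald = "Wald"


@dataclass
class AssociationRecord:
    """One variant's summary association with one trait.

    Parameters
    ----------
    variant_id
        rsID-style identifier; the join key between traits.
    chromosome, position
        Genomic coordinates (1-based).  Carried for tie-breaking only;
        never used in effect arithmetic.
    effect_allele, other_allele
        Single-nucleotide alleles over {A, C, G, T}; ``beta`` is per copy
        of ``effect_allele``.
    eaf
        Effect-allele frequency in (0, 1), or ``None`` when the source
        did not report it.  Missingness is meaningful downstream
        (palindromic variants without an exposure EAF are dropped).
    beta, se
        Effect estimate and its standard error (se > 0).
    pval
        Two-sided p-value in (0, 1].
    n, n_cases, n_controls
        Sample sizes; case/control counts optional, for binary traits.
    """

    variant_id: str
    chromosome: str
    position: int
    effect_allele: str
    other_allele: str
    eaf: Optional[float]
    beta: float
    se: float
    pval: float
    n: int
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        self.effect_allele = str(self.effect_allele).upper()
        self.other_allele = str(self.other_allele).upper()
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise FormatError(
                f"{self.variant_id}: alleles must be single nucleotides over ACGT, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise FormatError(f"{self.variant_id}: effect and other allele are identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise FormatError(f"{self.variant_id}: standard error must be positive, got {self.se}")
        if self.eaf is not None:
            if isinstance(self.eaf, float) and math.isnan(self.eaf):
                self.eaf = None
            elif not (0.0 < self.eaf < 1.0):
                raise FormatError(f"{self.variant_id}: eaf must lie in (0, 1), got {self.eaf}")
        if not (0.0 < self.pval <= 1.0):
            raise FormatError(f"{self.variant_id}: p-value must lie in (0, 1], got {self.pval}")
        if self.n_cases is not None and self.n_controls is not None:
            if self.n != self.n_cases + self.n_controls:
                raise FormatError(
                    f"{self.variant_id}: n ({self.n}) != n_cases + n_controls "
                    f"({self.n_cases} + {self.n_controls})"
                )

    @property
    def is_palindromic(self) -> bool:
        """True for A/T and C/G pairs (self-complementary, strand-ambiguous)."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        return self.other_allele == comp[self.effect_allele]

    def copy(self, **changes) -> "AssociationRecord":
        return replace(self, **changes)


@dataclass
class TraitPanel:
    """All summary associations for one trait, keyed by variant id."""

    trait_id: str
    trait_type: TraitType
    records: dict[str, AssociationRecord] = field(default_factory=dict)
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    @classmethod
    def from_records(
        cls,
        trait_id: str,
        trait_type: TraitType | str,
        records: Iterable[AssociationRecord],
        n_cases: Optional[int] = None,
        n_controls: Optional[int] = None,
    ) -> "TraitPanel":
        trait_type = TraitType(trait_type)
        keyed: dict[str, AssociationRecord] = {}
        dups = []
        for rec in records:
            if rec.variant_id in keyed:
                dups.append(rec.variant_id)
            keyed[rec.variant_id] = rec
        if dups:
            raise DuplicateVariantError(set(dups))
        return cls(trait_id, trait_type, keyed, n_cases=n_cases, n_controls=n_controls)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.records

    def get(self, variant_id: str) -> Optional[AssociationRecord]:
        return self.records.get(variant_id)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitPanel):
            return NotImplemented
        return (
            self.trait_id == other.trait_id
            and self.trait_type == other.trait_type
            and self.records == other.records
        )


@dataclass
class ReportRow:
    """One estimator's result for one outcome, on the reporting scale.

    ``or_`` and the CI bounds are odds ratios for binary outcomes
    (``or_ = exp(beta)``); for continuous outcomes the odds-ratio fields
    are ``None`` and the CI bounds are on the beta scale.
    """

    outcome_id: str
    method: Method
    n_snp: int
    beta: float
    se: float
    or_: Optional[float]
    ci_low: float
    ci_high: float
    pval: float
    egger_intercept: Optional[float] = None
    intercept_se: Optional[float] = None
    intercept_p: Optional[float] = None
    selection_tier: str = "genome_wide"

    def __post_init__(self) -> None:
        self.method = Method(self.method)
        if self.or_ is not None:
            if not (self.ci_low <= self.or_ <= self.ci_high):
                raise FormatError(
                    f"{self.outcome_id}/{self.method.value}: OR {self.or_} outside "
                    f"CI [{self.ci_low}, {self.ci_high}]"
                )
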