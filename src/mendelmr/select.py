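"""Instrument selection: significance screening, LD clumping, F-statistics.

Selection follows the conventional summary-statistic recipe: keep
variants below a genome-wide p-value threshold (5e-8; a liberal tier at
5e-6 is supported), greedily clump to pairwise independence (r2 below
0.001 by default), and screen out weak instruments with the per-variant
approximation F = (beta/se)^2, requiring F > 10.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import ConfigError, MissingDataError, NoInstrumentsError
from .records import AssociationRecord, TraitPanel
from .simulate import LdTable

__all__ = [
    "SelectionParams",
    "InstrumentSet",
    "f_statistic",
    "variance_explained",
    "clump",
    "find_proxy",
]

GENOME_WIDE_P = 5e-8
LIBERAL_P = 5e-6


@dataclass(frozen=True)
class SelectionParams:
    """Thresholds governing instrument selection and proxy lookup."""

    p_threshold: float = GENOME_WIDE_P
    clump_r2: float = 0.001
    f_min: float = 10.0
    proxy_r2_min: float = 0.8

    def __post_init__(self) -> None:
        if not (0.0 < self.p_threshold < 1.0):
            raise ConfigError(f"p_threshold must lie in (0, 1), got {self.p_threshold}")
        if not (0.0 <= self.clump_r2 <= 1.0):
            raise ConfigError(f"clump_r2 must lie in [0, 1], got {self.clump_r2}")
        if self.f_min < 0:
            raise ConfigError(f"f_min must be >= 0, got {self.f_min}")
        if not (0.0 < self.proxy_r2_min <= 1.0):
            raise ConfigError(f"proxy_r2_min must lie in (0, 1], got {self.proxy_r2_min}")


@dataclass
class InstrumentSet:
    """A clumped, screened set of exposure instruments with QC summaries.

    ``r2_total`` is the summed per-variant variance explained
    (2 p (1-p) beta^2); it is ``None`` when any retained variant lacks
    an EAF, since a partial sum would understate instrument strength.
    """

    variants: list[AssociationRecord] = field(default_factory=list)
    per_variant_f: dict[str, float] = field(default_factory=dict)
    mean_f: float = float("nan")
    r2_total: Optional[float] = None

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


def f_statistic(record: AssociationRecord) -> float:
    """Per-variant instrument-strength approximation F = (beta/se)^2."""
    return (record.beta / record.se) ** 2


def variance_explained(record: AssociationRecord) -> float:
    """Variance in a standardised exposure explained by one variant.

    Uses 2 p (1-p) beta^2 with p the effect-allele frequency; requires
    beta in SD units and a reported EAF.
    """
    if record.eaf is None:
        raise MissingDataError(
            f"{record.variant_id}: effect-allele frequency required for variance explained"
        )
    return record.beta**2 * 2.0 * record.eaf * (1.0 - record.eaf)


def _clump_sort_key(rec: AssociationRecord):
    # Ties in p broken by (chromosome, position) then variant_id for determinism.
    return (rec.pval, rec.chromosome, rec.position, rec.variant_id)


def clump(panel: TraitPanel, ld: LdTable, params: SelectionParams) -> InstrumentSet:
    """Greedy p-value clumping with significance and F screening.

    Repeatedly retain the smallest-p remaining candidate with
    p < ``p_threshold`` (strict) and F >= ``f_min``, then discard every
    remaining candidate in LD with it at r2 >= ``clump_r2``.
    Deterministic given inputs; invariant to input row order.

    Raises
    ------
    NoInstrumentsError
        If no variant survives, naming the thresholds applied.
    """
    candidates = [
        rec
        for rec in panel.records.values()
        if rec.pval < params.p_threshold and f_statistic(rec) >= params.f_min
    ]
    candidates.sort(key=_clump_sort_key)

    retained: list[AssociationRecord] = []
    while candidates:
        index = candidates.pop(0)
        retained.append(index)
        candidates = [
            rec for rec in candidates if ld.r2(index.variant_id, rec.variant_id) < params.clump_r2
        ]

    if not retained:
        raise NoInstrumentsError(
            f"no instruments in panel '{panel.trait_id}' at p < {params.p_threshold:g}, "
            f"F >= {params.f_min:g}"
        )

    per_f = {rec.variant_id: f_statistic(rec) for rec in retained}
    mean_f = sum(per_f.values()) / len(per_f)
    if all(rec.eaf is not None for rec in retained):
        r2_total: Optional[float] = sum(variance_explained(rec) for rec in retained)
    else:
        r2_total = None
    return InstrumentSet(variants=retained, per_variant_f=per_f, mean_f=mean_f, r2_total=r2_total)


def find_proxy(
    variant_id: str,
    outcome: TraitPanel,
    proxies: Optional[pd.DataFrame],
    params: SelectionParams,
) -> Optional[AssociationRecord]:
    """Look up a variant in the outcome panel, falling back to the best proxy.

    Returns the outcome record itself when present; otherwise the
    highest-r2 proxy with r2 > ``proxy_r2_min`` that is present in the
    outcome; otherwise ``None`` (the variant is dropped from that
    outcome's analysis — absence is a valid result, not an error).

    The proxy table has columns ``variant_a`` (index variant),
    ``variant_b`` (proxy) and ``r2``; proxy records are assumed already
    oriented to the index variant's alleles.
    """
    rec = outcome.get(variant_id)
    if rec is not None:
        return rec
    if proxies is None or proxies.empty:
        return None
    hits = proxies[(proxies["variant_a"] == variant_id) & (proxies["r2"] > params.proxy_r2_min)]
    if hits.empty:
        return None
    # Stable argmax: highest r2 first, variant id as deterministic tie-break.
    hits = hits.sort_values(["r2", "variant_b"], ascending=[False, True])
    for _, row in hits.iterrows():
        proxy_rec = outcome.get(str(row["variant_b"]))
        if proxy_rec is not None:
            return proxy_rec
    return None
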