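"""Harmonisation of exposure and outcome associations to a common effect allele.

Two-sample MR requires the variant-exposure and variant-outcome effects
to refer to the same allele.  Published summary statistics disagree in
three ways: the effect/other labels may be swapped, the alleles may be
reported on opposite strands, or the pair may be palindromic (A/T, C/G)
so that strand orientation is undecidable from allele labels alone.
This module resolves the first two mechanically and the third by
allele-frequency agreement, dropping palindromic variants whose
orientation cannot be established — in particular whenever the exposure
effect-allele frequency is not given.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import pandas as pd

from .errors import HarmonisationError, MrError
from .records import AssociationRecord, TraitPanel
from .select import InstrumentSet, SelectionParams, find_proxy

__all__ = [
    "HarmonisationAction",
    "HarmonisedVariant",
    "harmonise_pair",
    "harmonise_panels",
    "harmonisation_log",
    "PALINDROMIC_MAF_WINDOW",
]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Palindromic variants are frequency-aligned only when both minor-allele
#: frequencies fall below this bound; nearer 0.5 the orientation signal
#: vanishes and the variant is dropped instead.
PALINDROMIC_MAF_WINDOW = 0.42


class HarmonisationAction(str, Enum):
    kept = "kept"
    flipped = "flipped"
    strand_flipped = "strand_flipped"
    dropped_palindromic = "dropped_palindromic"
    dropped_allele_mismatch = "dropped_allele_mismatch"
    dropped_missing = "dropped_missing"

    @property
    def is_drop(self) -> bool:
        return self.value.startswith("dropped")


@dataclass
class HarmonisedVariant:
    """An exposure/outcome effect pair aligned to a common effect allele.

    Records whose ``action`` is a drop carry NaN outcome effects and must
    never reach an estimator; :func:`mendelmr.estimators.kept_only`
    enforces this.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf_exposure: Optional[float]
    action: HarmonisationAction

    @property
    def kept(self) -> bool:
        return not self.action.is_drop


def _dropped(
    exposure: AssociationRecord, action: HarmonisationAction
) -> HarmonisedVariant:
    return HarmonisedVariant(
        variant_id=exposure.variant_id,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=float("nan"),
        se_outcome=float("nan"),
        eaf_exposure=exposure.eaf,
        action=action,
    )


def harmonise_pair(
    exposure: AssociationRecord,
    outcome: AssociationRecord,
    maf_window: float = PALINDROMIC_MAF_WINDOW,
) -> HarmonisedVariant:
    """Align one outcome record to the exposure's effect allele.

    Resolution order:

    1. identical allele pair — kept as-is, or outcome beta negated and
       EAF complemented when the labels are swapped (``flipped``);
    2. pair matches after strand complement (A<->T, C<->G) — complement,
       then rule 1 (``strand_flipped``);
    3. palindromic pair — dropped when the exposure EAF is missing;
       otherwise aligned by frequency agreement provided both
       minor-allele frequencies are below ``maf_window``, else dropped;
    4. anything else — ``dropped_allele_mismatch``.

    Raises
    ------
    MrError
        If the two records do not share a variant identifier.
    """
    if exposure.variant_id != outcome.variant_id:
        raise MrError(
            f"variant_id mismatch: {exposure.variant_id} vs {outcome.variant_id}"
        )

    e1, o1 = exposure.effect_allele, exposure.other_allele
    e2, o2 = outcome.effect_allele, outcome.other_allele
    beta_out, se_out, eaf_out = outcome.beta, outcome.se, outcome.eaf
    action = HarmonisationAction.kept

    if exposure.is_palindromic:
        # Allele labels cannot settle strand for palindromes; outcome pair
        # must at least be the same pair (any orientation) to proceed.
        if {e2, o2} != {e1, o1}:
            return _dropped(exposure, HarmonisationAction.dropped_allele_mismatch)
        if exposure.eaf is None or eaf_out is None:
            return _dropped(exposure, HarmonisationAction.dropped_palindromic)
        # Textual alignment first, then orientation check by frequency.
        if e2 != e1:
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
        maf_exp = min(exposure.eaf, 1.0 - exposure.eaf)
        maf_out = min(eaf_out, 1.0 - eaf_out)
        if maf_exp >= maf_window or maf_out >= maf_window:
            return _dropped(exposure, HarmonisationAction.dropped_palindromic)
        if (exposure.eaf < 0.5) != (eaf_out < 0.5):
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out
            action = HarmonisationAction.flipped
    else:
        if {e2, o2} == {_COMP[e1], _COMP[o1]} and {e2, o2} != {e1, o1}:
            e2, o2 = _COMP[e2], _COMP[o2]
            action = HarmonisationAction.strand_flipped
        if {e2, o2} == {e1, o1}:
            if e2 != e1:
                beta_out = -beta_out
                if eaf_out is not None:
                    eaf_out = 1.0 - eaf_out
                if action is HarmonisationAction.kept:
                    action = HarmonisationAction.flipped
        else:
            return _dropped(exposure, HarmonisationAction.dropped_allele_mismatch)

    return HarmonisedVariant(
        variant_id=exposure.variant_id,
        effect_allele=e1,
        other_allele=o1,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=se_out,
        eaf_exposure=exposure.eaf,
        action=action,
    )


def harmonise_panels(
    instruments: InstrumentSet,
    outcome: TraitPanel,
    proxies: Optional[pd.DataFrame],
    params: SelectionParams,
) -> list[HarmonisedVariant]:
    """Harmonise every instrument against an outcome panel.

    Each instrument is looked up in the outcome (via
    :func:`mendelmr.select.find_proxy`, so a sufficiently correlated
    proxy stands in for a missing variant) and aligned with
    :func:`harmonise_pair`.  Instruments absent with no valid proxy are
    recorded as ``dropped_missing``.  A proxy record is relabelled to the
    index variant id; its alleles are taken as already oriented to the
    index variant.

    Raises
    ------
    HarmonisationError
        If zero records survive as kept.
    """
    if len(instruments) == 0:
        raise HarmonisationError("instrument set is empty")

    results: list[HarmonisedVariant] = []
    for exp_rec in instruments.variants:
        out_rec = find_proxy(exp_rec.variant_id, outcome, proxies, params)
        if out_rec is None:
            results.append(_dropped(exp_rec, HarmonisationAction.dropped_missing))
            continue
        if out_rec.variant_id != exp_rec.variant_id:
            out_rec = out_rec.copy(
                variant_id=exp_rec.variant_id,
                effect_allele=exp_rec.effect_allele,
                other_allele=exp_rec.other_allele,
            )
        results.append(harmonise_pair(exp_rec, out_rec))

    if not any(h.kept for h in results):
        raise HarmonisationError(
            f"no instruments could be harmonised against outcome '{outcome.trait_id}'"
        )
    return results


def harmonisation_log(harmonised: list[HarmonisedVariant], outcome_id: str) -> pd.DataFrame:
    """Audit table: one row per instrument with the action taken."""
    return pd.DataFrame(
        [
            {
                "outcome_id": outcome_id,
                "variant_id": h.variant_id,
                "effect_allele": h.effect_allele,
                "other_allele": h.other_allele,
                "beta_exposure": h.beta_exposure,
                "se_exposure": h.se_exposure,
                "beta_outcome": h.beta_outcome,
                "se_outcome": h.se_outcome,
                "eaf_exposure": h.eaf_exposure,
                "action": h.action.value,
            }
            for h in harmonised
        ]
    )
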