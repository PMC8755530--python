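"""Readers and writers for summary-statistic panels and MR reports.

One canonical column schema is used internally; files in foreign dialects
(e.g. COVID-19 HGI round-6 headers) are mapped at the boundary via a
``column_map`` of canonical name -> file column name.  All files are
delimited text with a header row.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .errors import DuplicateVariantError, EmptyReportError, FormatError
from .records import AssociationRecord, Method, ReportRow, TraitPanel, TraitType

__all__ = [
    "CANONICAL_COLUMNS",
    "read_panel",
    "write_panel",
    "write_report",
    "read_report",
]

CANONICAL_COLUMNS: tuple[str, ...] = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
    "n_cases",
    "n_controls",
)

#: Columns that must be present (directly or via column_map) in every panel.
REQUIRED_COLUMNS: tuple[str, ...] = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
    "n",
)

REPORT_COLUMNS: tuple[str, ...] = (
    "outcome_id",
    "method",
    "selection_tier",
    "n_snp",
    "beta",
    "se",
    "or_",
    "ci_low",
    "ci_high",
    "pval",
    "egger_intercept",
    "intercept_se",
    "intercept_p",
)


def _opt_int(value) -> Optional[int]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return int(value)


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def read_panel(
    path: str | Path,
    trait_type: TraitType | str,
    column_map: Optional[Mapping[str, str]] = None,
    trait_id: Optional[str] = None,
    sep: str = "\t",
    n_cases: Optional[int] = None,
    n_controls: Optional[int] = None,
) -> TraitPanel:
    """Read a delimited summary-statistics file into a :class:`TraitPanel`.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    trait_type
        ``"binary"`` or ``"continuous"``; binary betas are taken to be
        log odds ratios as published.
    column_map
        Mapping of canonical column name -> column name in the file.
        Unmapped canonical names are looked up verbatim.
    n_cases, n_controls
        Panel-level case/control counts for binary traits whose files do
        not carry per-variant counts.

    Raises
    ------
    FormatError
        If a mapped column is missing or any row violates a record
        invariant (e.g. non-positive standard error).
    DuplicateVariantError
        If a variant identifier occurs more than once.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    column_map = dict(column_map or {})

    rename = {}
    for canonical in CANONICAL_COLUMNS:
        source = column_map.get(canonical, canonical)
        if source in df.columns:
            rename[source] = canonical
        elif canonical in REQUIRED_COLUMNS:
            raise FormatError(f"{path.name}: missing required column '{source}' (for '{canonical}')")
    df = df.rename(columns=rename)

    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                AssociationRecord(
                    variant_id=str(row["variant_id"]),
                    chromosome=str(row["chromosome"]),
                    position=int(row["position"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    eaf=_opt_float(row["eaf"]) if "eaf" in df.columns else None,
                    beta=float(row["beta"]),
                    se=float(row["se"]),
                    pval=float(row["pval"]),
                    n=int(row["n"]),
                    n_cases=_opt_int(row["n_cases"]) if "n_cases" in df.columns else None,
                    n_controls=_opt_int(row["n_controls"]) if "n_controls" in df.columns else None,
                )
            )
        except FormatError as exc:
            raise FormatError(f"{path.name}, row {idx + 2}: {exc}") from exc

    return TraitPanel.from_records(
        trait_id=trait_id or path.stem,
        trait_type=trait_type,
        records=records,
        n_cases=n_cases,
        n_controls=n_controls,
    )


def panel_to_frame(panel: TraitPanel) -> pd.DataFrame:
    """Panel as a DataFrame in canonical column order."""
    rows = [
        {col: getattr(rec, col) for col in CANONICAL_COLUMNS}
        for rec in panel.records.values()
    ]
    return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def write_panel(panel: TraitPanel, path: str | Path, sep: str = "\t") -> None:
    """Write a panel as delimited text with canonical headers."""
    panel_to_frame(panel).to_csv(path, sep=sep, index=False, na_rep="NA")


def write_report(rows: Sequence[ReportRow], path: str | Path, sep: str = "\t") -> None:
    """Write report rows as delimited text, floats at 6 significant digits.

    Column order is fixed (see ``REPORT_COLUMNS``); optional fields
    (odds ratio for continuous outcomes, intercept columns for
    non-Egger methods) are left blank.
    """
    if not rows:
        raise EmptyReportError("cannot write a report with no rows")
    data = []
    for r in rows:
        data.append(
            {
                "outcome_id": r.outcome_id,
                "method": r.method.value,
                "selection_tier": r.selection_tier,
                "n_snp": r.n_snp,
                "beta": r.beta,
                "se": r.se,
                "or_": r.or_,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "pval": r.pval,
                "egger_intercept": r.egger_intercept,
                "intercept_se": r.intercept_se,
                "intercept_p": r.intercept_p,
            }
        )
    df = pd.DataFrame(data, columns=list(REPORT_COLUMNS))
    df.to_csv(path, sep=sep, index=False, na_rep="", float_format="%.6g")


def read_report(path: str | Path, sep: str = "\t") -> list[ReportRow]:
    """Read a report written by :func:`write_report` back into rows."""
    df = pd.read_csv(path, sep=sep)
    rows = []
    for _, r in df.iterrows():
        rows.append(
            ReportRow(
                outcome_id=str(r["outcome_id"]),
                method=Method(r["method"]),
                n_snp=int(r["n_snp"]),
                beta=float(r["beta"]),
                se=float(r["se"]),
                or_=_opt_float(r["or_"]),
                ci_low=float(r["ci_low"]),
                ci_high=float(r["ci_high"]),
                pval=float(r["pval"]),
                egger_intercept=_opt_float(r["egger_intercept"]),
                intercept_se=_opt_float(r["intercept_se"]),
                intercept_p=_opt_float(r["intercept_p"]),
                selection_tier=str(r["selection_tier"]),
            )
        )
    return rows
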