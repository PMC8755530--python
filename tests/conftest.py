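"""Shared fixtures: record builders and a small synthetic two-sample study."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from mendelmr import AssociationRecord, HarmonisedVariant, TraitPanel
from mendelmr.harmonise import HarmonisationAction


def pval_for(beta: float, se: float) -> float:
    return float(max(2.0 * stats.norm.sf(abs(beta) / se), 1e-300))


def rec(
    vid="rs1",
    chrom="1",
    pos=1000,
    ea="A",
    oa="G",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    pval=None,
    n=3636,
    **kw,
) -> AssociationRecord:
    return AssociationRecord(
        variant_id=vid,
        chromosome=chrom,
        position=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pval=pval if pval is not None else pval_for(beta, se),
        n=n,
        **kw,
    )


def hv(
    vid="rs1",
    be=0.2,
    se_e=0.03,
    bo=-0.01,
    se_o=0.005,
    eaf=0.3,
    action=HarmonisationAction.kept,
) -> HarmonisedVariant:
    return HarmonisedVariant(
        variant_id=vid,
        effect_allele="A",
        other_allele="G",
        beta_exposure=be,
        se_exposure=se_e,
        beta_outcome=bo,
        se_outcome=se_o,
        eaf_exposure=eaf,
        action=action,
    )


def random_harmonised(rng: np.random.Generator, n: int) -> list[HarmonisedVariant]:
    """A generic kept-variant set with heterogeneous effects and SEs."""
    be = rng.normal(0.2, 0.05, n)
    be[np.abs(be) < 0.02] = 0.05
    se_e = rng.uniform(0.01, 0.05, n)
    bo = -0.04 * be + rng.normal(0, 0.01, n)
    se_o = rng.uniform(0.004, 0.02, n)
    return [
        hv(vid=f"rs{i}", be=float(be[i]), se_e=float(se_e[i]), bo=float(bo[i]), se_o=float(se_o[i]))
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# A hand-built four-instrument study mirroring a cytokine-on-infection
# design: one exposure panel, three binary outcome panels (one of which
# lacks an instrument whose best proxy is too weakly correlated), LD and
# proxy tables.  All files are written programmatically into tmp_path.
# ---------------------------------------------------------------------------

TRUE_BETA = -0.04

EXPOSURE_ROWS = [
    # vid, chrom, pos, ea, oa, eaf, beta, se
    ("ins1", "2", 100_000, "A", "G", 0.35, 0.25, 0.030),
    ("ins2", "5", 200_000, "C", "T", 0.45, 0.18, 0.030),
    ("ins3", "1", 300_000, "A", "C", 0.25, 0.20, 0.035),
    ("ins4", "5", 900_000, "G", "T", 0.10, 0.22, 0.040),
    # correlated with ins1 (r2 = 0.95); slightly larger p so clumping drops it
    ("cor1", "2", 101_000, "T", "C", 0.34, 0.24, 0.030),
    # liberal-tier only: p ~ 1e-7
    ("lib1", "9", 400_000, "A", "G", 0.30, 0.16, 0.030),
    # weak and non-significant
    ("weak1", "11", 500_000, "C", "A", 0.40, 0.05, 0.020),
]


def _exposure_panel() -> TraitPanel:
    records = [
        rec(vid=v, chrom=c, pos=p, ea=ea, oa=oa, eaf=f, beta=b, se=s)
        for v, c, p, ea, oa, f, b, s in EXPOSURE_ROWS
    ]
    return TraitPanel.from_records("il18_like", "continuous", records)


def _outcome_rows(
    drop: set[str],
    extra: list[tuple] = (),
    rng_seed: int = 5,
    swap_ins3: bool = False,
):
    """Outcome records proportional to exposure effects plus small noise."""
    rng_local = np.random.default_rng(rng_seed)
    rows = []
    for v, c, p, ea, oa, f, b, s in EXPOSURE_ROWS:
        if v in drop:
            continue
        se_o = float(rng_local.uniform(0.005, 0.012))
        bo = TRUE_BETA * b + float(rng_local.normal(0, se_o))
        if swap_ins3 and v == "ins3":
            # swapped allele labels: beta sign and EAF must be flipped back
            rows.append((v, c, p, oa, ea, 1 - f, -bo, se_o))
        else:
            rows.append((v, c, p, ea, oa, f, bo, se_o))
    rows.extend(extra)
    return rows


def write_panel_tsv(path, rows, n, n_cases=None, n_controls=None):
    header = [
        "variant_id", "chromosome", "position", "effect_allele", "other_allele",
        "eaf", "beta", "se", "pval", "n",
    ]
    lines = ["\t".join(header)]
    for v, c, p, ea, oa, f, b, s in rows:
        lines.append(
            "\t".join(
                [v, c, str(p), ea, oa, f"{f:.6g}", f"{b:.10g}", f"{s:.10g}",
                 f"{pval_for(b, s):.6g}", str(n)]
            )
        )
    path.write_text("\n".join(lines) + "\n")


@pytest.fixture
def study_files(tmp_path):
    """Write the full synthetic study to disk; return paths and config dict."""
    exp_path = tmp_path / "exposure.tsv"
    write_panel_tsv(exp_path, EXPOSURE_ROWS, n=3636)

    # prox2 stands in for ins2 (r2 = 0.9); prox4 for ins4 at only 0.65.
    prox2 = ("prox2", "5", 201_000, "C", "T", 0.44, TRUE_BETA * 0.18 + 0.001, 0.008)
    prox4 = ("prox4", "5", 901_000, "G", "T", 0.11, TRUE_BETA * 0.22 - 0.002, 0.009)

    any_path = tmp_path / "outcome_any.tsv"
    write_panel_tsv(
        any_path, _outcome_rows(drop=set(), rng_seed=5, swap_ins3=True),
        n=2_500_000,
    )
    hosp_path = tmp_path / "outcome_hosp.tsv"
    write_panel_tsv(
        hosp_path, _outcome_rows(drop={"ins2"}, extra=[prox2], rng_seed=6),
        n=2_000_000,
    )
    severe_path = tmp_path / "outcome_severe.tsv"
    write_panel_tsv(
        severe_path, _outcome_rows(drop={"ins4"}, extra=[prox4], rng_seed=7),
        n=1_000_000,
    )

    ld_path = tmp_path / "ld.tsv"
    ld_path.write_text("variant_a\tvariant_b\tr2\nins1\tcor1\t0.95\n")
    proxy_path = tmp_path / "proxies.tsv"
    proxy_path.write_text(
        "variant_a\tvariant_b\tr2\n"
        "ins2\tprox2\t0.9\n"
        "ins4\tprox4\t0.65\n"
    )

    config = {
        "exposure": {"path": str(exp_path), "trait_type": "continuous"},
        "outcomes": [
            {"outcome_id": "any", "path": str(any_path), "trait_type": "binary",
             "n_cases": 100_000, "n_controls": 2_400_000},
            {"outcome_id": "hospitalised", "path": str(hosp_path), "trait_type": "binary",
             "n_cases": 25_000, "n_controls": 1_975_000},
            {"outcome_id": "very_severe", "path": str(severe_path), "trait_type": "binary",
             "n_cases": 9_000, "n_controls": 991_000},
        ],
        "selection": {"p_threshold": 5e-8, "clump_r2": 0.001, "f_min": 10.0,
                      "proxy_r2_min": 0.8},
        "liberal_p_threshold": 5e-6,
        "ld_path": str(ld_path),
        "proxy_path": str(proxy_path),
        "estimators": {"effects_mode": "auto", "bootstrap_reps": 200, "seed": 13},
        "power": {"alpha": 0.05, "target_power": 0.8, "r2_override": 0.07},
    }
    return config


@pytest.fixture
def exposure_panel():
    return _exposure_panel()
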