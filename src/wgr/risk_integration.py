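"""Carrier-stratified integration of monogenic and polygenic risk.

A pathogenic variant in a high-impact gene (e.g. BRCA1 for breast cancer)
both shifts risk on its own and attenuates the slope of the polygenic score:
the combined model is a logistic fit with separate PRS effect sizes for
carriers and noncarriers,

    OR = exp(alpha_carrier * 1{carrier} + beta_stratum * PRS),

with beta_stratum = beta_carrier for carriers and beta_noncarrier otherwise.
The published per-SD ORs for the breast-cancer model are 1.3 among carriers
and 1.6 among noncarriers; the carrier main effect alpha_carrier must be
supplied by the panel file (the source fits it on biobank data but does not
print it — example configurations ship a clearly synthetic placeholder).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import normalize_chrom
from .embryo_reconstruction import ReconstructedGenome
from .errors import FormatError, WgrError

CARRIER = "carrier"
NONCARRIER = "noncarrier"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class PanelVariant:
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    condition: str


@dataclass(frozen=True)
class ConditionBetas:
    """Carrier-stratified logistic coefficients for one condition (log-odds)."""

    alpha_carrier: float  # carrier main effect at PRS = 0
    beta_carrier: float  # log OR per SD of PRS among carriers
    beta_noncarrier: float  # log OR per SD of PRS among noncarriers


@dataclass
class MonogenicPanel:
    """Pathogenic variants to screen, plus per-condition stratified betas."""

    variants: list[PanelVariant] = field(default_factory=list)
    betas: dict[str, ConditionBetas] = field(default_factory=dict)

    def conditions(self) -> list[str]:
        return list(dict.fromkeys(v.condition for v in self.variants))


def read_panel(path: str | Path) -> MonogenicPanel:
    """Tab-separated panel: gene chrom pos ref alt condition alpha_carrier
    beta_carrier beta_noncarrier."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = [
        "gene", "chrom", "pos", "ref", "alt", "condition",
        "alpha_carrier", "beta_carrier", "beta_noncarrier",
    ]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: panel lacks column {col!r}")
    panel = MonogenicPanel()
    for _, row in df.iterrows():
        if not np.isfinite([row.alpha_carrier, row.beta_carrier, row.beta_noncarrier]).all():
            raise FormatError(f"{path}: non-finite beta for {row.gene}")
        panel.variants.append(
            PanelVariant(
                gene=row.gene, chrom=normalize_chrom(row.chrom), pos=int(row.pos),
                ref=row.ref, alt=row.alt, condition=row.condition,
            )
        )
        panel.betas[row.condition] = ConditionBetas(
            float(row.alpha_carrier), float(row.beta_carrier), float(row.beta_noncarrier)
        )
    return panel


def write_panel(path: str | Path, panel: MonogenicPanel) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\tchrom\tpos\tref\talt\tcondition\t"
            "alpha_carrier\tbeta_carrier\tbeta_noncarrier\n"
        )
        for v in panel.variants:
            b = panel.betas[v.condition]
            fh.write(
                f"{v.gene}\t{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{v.condition}\t"
                f"{b.alpha_carrier}\t{b.beta_carrier}\t{b.beta_noncarrier}\n"
            )


def call_carriers(
    genome: ReconstructedGenome, panel: MonogenicPanel
) -> dict[str, tuple[str, list[str]]]:
    """Per condition: carrier status and the genes driving it.

    Carrier iff the reconstructed genome carries >= 1 pathogenic (alternate)
    allele at any panel site of the condition. A panel site without a
    prediction (aneuploid chromosome, uncovered site) makes the status
    ``unknown`` rather than silently noncarrier — unless another predicted
    site already establishes carrier status.
    """
    key = {
        (c, int(p)): i
        for i, (c, p) in enumerate(zip(genome.sites.chrom, genome.sites.pos))
    }
    out: dict[str, tuple[str, list[str]]] = {}
    for condition in panel.conditions():
        status = NONCARRIER
        genes: list[str] = []
        any_unknown = False
        for v in panel.variants:
            if v.condition != condition:
                continue
            row = key.get((v.chrom, v.pos))
            if row is None or not genome.predicted[row]:
                any_unknown = True
                continue
            if genome.genotypes[row] >= 1:  # >= 1 alternate (pathogenic) allele
                status = CARRIER
                genes.append(v.gene)
        if status != CARRIER and any_unknown:
            status = UNKNOWN
        out[condition] = (status, genes)
    return out


def combined_or(
    standardized_prs: float, carrier_status: str, betas: ConditionBetas
) -> float | tuple[float, float]:
    """Single combined odds ratio; for ``unknown`` carrier status, the pair
    (OR if carrier, OR if noncarrier)."""
    if betas is None:
        raise WgrError("no carrier-stratified betas for this condition")

    def _or(carrier: bool) -> float:
        beta = betas.beta_carrier if carrier else betas.beta_noncarrier
        alpha = betas.alpha_carrier if carrier else 0.0
        return float(np.exp(alpha + beta * standardized_prs))

    if carrier_status == CARRIER:
        return _or(True)
    if carrier_status == NONCARRIER:
        return _or(False)
    return (_or(True), _or(False))


@dataclass
class EmbryoRisk:
    """Per embryo x condition risk components."""

    embryo: str
    condition: str
    standardized_prs: float
    carrier_status: str
    carrier_genes: list[str]
    prs_only_or: float
    combined_odds_ratio: float | tuple[float, float]


def assess_embryo(
    name: str,
    standardized_prs: float,
    carrier_calls: dict[str, tuple[str, list[str]]],
    panel: MonogenicPanel,
    condition: str,
) -> EmbryoRisk:
    status, genes = carrier_calls.get(condition, (NONCARRIER, []))
    betas = panel.betas.get(condition)
    if betas is None:
        raise WgrError(f"no betas for condition {condition!r}")
    return EmbryoRisk(
        embryo=name,
        condition=condition,
        standardized_prs=standardized_prs,
        carrier_status=status,
        carrier_genes=genes,
        prs_only_or=float(np.exp(betas.beta_noncarrier * standardized_prs)),
        combined_odds_ratio=combined_or(standardized_prs, status, betas),
    )


@dataclass
class FamilyReport:
    """Ranked per-condition risk table for one family's embryos."""

    table: pd.DataFrame  # one row per embryo x condition, sorted by OR
    fold_difference: dict[str, float]  # condition -> max OR / min OR
    low_prs_carriers: list[str]  # embryos below the population median PRS yet carrier


def _scalar_or(value) -> float:
    # unknown status contributes its noncarrier branch to the ranking
    return float(value[1]) if isinstance(value, tuple) else float(value)


def family_report(risks: list[EmbryoRisk]) -> FamilyReport:
    """Summarize a family: embryos ranked by combined OR, the fold difference
    (max/min OR) per condition, and the inadvertent-transfer flags — embryos
    whose PRS is below the population 50th percentile (standardized score
    < 0) yet which carry a pathogenic variant."""
    if not risks:
        raise WgrError("family report needs >= 1 embryo")
    rows = []
    for r in risks:
        rows.append(
            {
                "embryo": r.embryo,
                "condition": r.condition,
                "standardized_prs": r.standardized_prs,
                "carrier_status": r.carrier_status,
                "carrier_genes": ",".join(r.carrier_genes),
                "prs_only_or": r.prs_only_or,
                "combined_or": _scalar_or(r.combined_odds_ratio),
            }
        )
    table = (
        pd.DataFrame(rows)
        .sort_values(["condition", "combined_or"])
        .reset_index(drop=True)
    )
    fold = {
        cond: float(sub["combined_or"].max() / sub["combined_or"].min())
        for cond, sub in table.groupby("condition")
    }
    low_carriers = sorted(
        set(
            table.loc[
                (table.standardized_prs < 0) & (table.carrier_status == CARRIER),
                "embryo",
            ]
        )
    )
    return FamilyReport(table=table, fold_difference=fold, low_prs_carriers=low_carriers)
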