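"""Scoring reconstructions against a truth genome (the born-child design).

Accuracy is the fraction of compared sites whose *unordered* diploid
genotype matches the truth — a phase error is not a genotype error.
Half-called or unpredicted sites inside the comparison mask count as
discordant (conservative). Accuracy is stratified by truth genotype class
(heterozygous vs homozygous, the display used for the clinical validation)
and by population rarity (rare = AF < 0.1% or absent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import TrueMeiosis
from .embryo_reconstruction import (
    RARE_AF_THRESHOLD,
    ReconstructedGenome,
    TransmissionPath,
)
from .errors import DegenerateInputError
from .io_formats import AlleleFrequencyTable


@dataclass
class AccuracyReport:
    n_sites_compared: int
    n_predicted_sites: int
    genome_wide_accuracy: float  # percent
    by_genotype: dict[str, float] = field(default_factory=dict)  # het / hom, percent
    by_rarity: dict[str, float] = field(default_factory=dict)  # rare / common, percent
    prs_site_accuracy: float = float("nan")  # percent, over loaded model sites
    stratum_sizes: dict[str, int] = field(default_factory=dict)


def _pct(concordant: np.ndarray, mask: np.ndarray) -> float:
    n = int(mask.sum())
    return float(100.0 * concordant[mask].sum() / n) if n else float("nan")


def genotype_accuracy(
    recon: ReconstructedGenome,
    truth_genotypes: np.ndarray,
    mask: np.ndarray | None = None,
    af_table: AlleleFrequencyTable | None = None,
    prs_site_rows: np.ndarray | None = None,
) -> AccuracyReport:
    """Compare predicted to truth genotypes over ``mask`` (default: all sites
    predicted and called in truth). ``prs_site_rows`` restricts an extra
    accuracy figure to polygenic-model sites."""
    truth = np.asarray(truth_genotypes)
    pred = recon.genotypes
    if mask is None:
        mask = recon.predicted & (truth >= 0)
    else:
        mask = np.asarray(mask, dtype=bool) & (truth >= 0)
    if not mask.any():
        raise DegenerateInputError("empty comparison mask")
    concordant = (pred == truth) & recon.predicted  # unpredicted = discordant

    report = AccuracyReport(
        n_sites_compared=int(mask.sum()),
        n_predicted_sites=int(recon.predicted.sum()),
        genome_wide_accuracy=_pct(concordant, mask),
    )
    het = truth == 1
    report.by_genotype = {
        "het": _pct(concordant, mask & het),
        "hom": _pct(concordant, mask & ~het),
    }
    report.stratum_sizes = {
        "het": int((mask & het).sum()),
        "hom": int((mask & ~het).sum()),
    }
    if af_table is not None:
        afs = af_table.lookup(recon.sites.chrom, recon.sites.pos)
        rare = np.isnan(afs) | (afs < RARE_AF_THRESHOLD)
        report.by_rarity = {
            "rare": _pct(concordant, mask & rare),
            "common": _pct(concordant, mask & ~rare),
        }
        report.stratum_sizes.update(
            rare=int((mask & rare).sum()), common=int((mask & ~rare).sum())
        )
    if prs_site_rows is not None:
        prs_mask = np.zeros(len(truth), dtype=bool)
        prs_mask[prs_site_rows[prs_site_rows >= 0]] = True
        report.prs_site_accuracy = _pct(concordant, mask & prs_mask)
    return report


def prs_concordance(embryo_scores: np.ndarray, truth_scores: np.ndarray) -> float:
    """Squared Pearson correlation between paired embryo and truth-genome
    scores (centered scores, pooled over conditions). Sign-invariant by
    construction. Zero variance in either vector is a typed error."""
    x = np.asarray(embryo_scores, dtype=float)
    y = np.asarray(truth_scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DegenerateInputError("concordance needs >= 3 paired scores")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateInputError("zero variance in one score vector")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


@dataclass
class CrossoverAssessment:
    parent: str
    chrom: str
    true_position: int
    observable: bool  # inside the informative span, odd crossover count in its gap
    detected: bool
    contained: bool  # true position inside the matched reported interval
    interval_width: int | None


def breakpoint_accuracy(
    path: TransmissionPath,
    maternal_meiosis: TrueMeiosis,
    paternal_meiosis: TrueMeiosis,
) -> tuple[list[CrossoverAssessment], int]:
    """Match reported breakpoint intervals against the true crossovers of one
    embryo (synthetic data only, where the meioses are known).

    A crossover can only manifest between two consecutive sites heterozygous
    in the transmitting parent (its "gap"); crossovers outside the outermost
    such sites, or falling in a gap in even number (they cancel), are
    *unobservable in principle* and are flagged rather than blamed on the
    decoder. An observable crossover is detected iff its gap is reported as a
    breakpoint interval; reported intervals whose gap holds an even (possibly
    zero) number of true crossovers count as false positives.
    """
    out: list[CrossoverAssessment] = []
    n_false = 0
    for parent, col, meiosis in (
        ("mother", 0, maternal_meiosis),
        ("father", 1, paternal_meiosis),
    ):
        for chrom in path.chromosomes():
            dec = path.decodings.get(chrom)
            inf_pos = (
                dec.positions[dec.informative_for[parent]]
                if dec is not None
                else np.empty(0, dtype=np.int64)
            )
            truths = np.asarray(meiosis.crossovers.get(chrom, np.empty(0)))
            reported = path.breakpoints(chrom, parent)
            reported_gaps = {
                int(np.searchsorted(inf_pos, (lo + hi) / 2.0)) for lo, hi in reported
            }
            gap_of = np.searchsorted(inf_pos, truths)
            in_span = (gap_of > 0) & (gap_of < len(inf_pos))
            counts = {int(g): int(np.sum(gap_of[in_span] == g)) for g in gap_of[in_span]}
            for xo, g, ok in zip(truths, gap_of, in_span):
                observable = bool(ok) and counts[int(g)] % 2 == 1
                detected = bool(ok) and int(g) in reported_gaps
                lo, hi = (int(inf_pos[g - 1]), int(inf_pos[g])) if ok else (0, 0)
                out.append(
                    CrossoverAssessment(
                        parent=parent,
                        chrom=chrom,
                        true_position=int(xo),
                        observable=observable,
                        detected=detected,
                        contained=detected and lo <= xo <= hi,
                        interval_width=(hi - lo) if detected else None,
                    )
                )
            odd_gaps = {g for g, c in counts.items() if c % 2 == 1}
            n_false += len(reported_gaps - odd_gaps)
    return out, n_false
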