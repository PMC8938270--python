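"""Distribution of polygenic scores among a couple's potential embryos.

Two sampling schemes generate virtual embryos from the parents:

* **linkage** — one simulated meiosis per parent on the phased genomes, with
  crossovers drawn from the genetic map (Poisson on the centimorgan scale,
  no interference), then the two virtual gametes are combined. Neighbouring
  variants co-segregate according to their genetic distance.
* **unlinked** — one allele drawn independently per site per parent, i.e. no
  linkage at all; a useful upper bound on between-sibling score variance for
  models whose linked weights share sign.

The default cohort size is 500 replicates. The expected embryo score under
either scheme is the midparent mean (the average of the two parents' scores).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import GeneticMap, PhasedParentalGenome
from .io_formats import AlleleFrequencyTable, PrsModel
from .prs_engine import PcModel, center_and_standardize, raw_prs
from .risk_integration import MonogenicPanel

DEFAULT_N_REPLICATES = 500

from .synthetic_cohort import draw_meiosis, make_embryo  # noqa: E402


def simulate_embryo_linkage(
    mother: PhasedParentalGenome,
    father: PhasedParentalGenome,
    genetic_map: GeneticMap,
    rng,
) -> np.ndarray:
    """One virtual embryo genome (genotype codes): a map-driven meiosis per
    parent, gametes combined."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    _, m_gam = draw_meiosis(mother, genetic_map, rng)
    _, p_gam = draw_meiosis(father, genetic_map, rng)
    return make_embryo(m_gam, p_gam)


def simulate_embryo_unlinked(
    mother_genotypes: np.ndarray, father_genotypes: np.ndarray, rng
) -> np.ndarray:
    """One virtual embryo genome with every site transmitted independently:
    a homozygous parent transmits deterministically, a heterozygous parent
    transmits either allele with probability 1/2."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng

    def gamete(gt: np.ndarray) -> np.ndarray:
        gt = np.asarray(gt)
        allele = (gt == 2).astype(np.int8)
        het = gt == 1
        allele[het] = rng.integers(0, 2, size=int(het.sum()), dtype=np.int8)
        return allele

    return (gamete(mother_genotypes) + gamete(father_genotypes)).astype(np.int8)


@dataclass
class SimulatedCohort:
    """Scores (and optional carrier flags) of n simulated embryos."""

    mode: str  # "linkage" | "unlinked"
    seed: int
    raw_scores: np.ndarray
    standardized_scores: np.ndarray | None = None
    carrier_flags: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_replicates(self) -> int:
        return len(self.raw_scores)

    @property
    def scores(self) -> np.ndarray:
        return (
            self.standardized_scores
            if self.standardized_scores is not None
            else self.raw_scores
        )


def simulate_prs_cohort(
    mother: PhasedParentalGenome,
    father: PhasedParentalGenome,
    model: PrsModel,
    seed: int,
    mode: str = "linkage",
    n_replicates: int = DEFAULT_N_REPLICATES,
    genetic_map: GeneticMap | None = None,
    af_table: AlleleFrequencyTable | None = None,
    pc_model: PcModel | None = None,
    pc_scores: np.ndarray | None = None,
    population: str | None = None,
    panel: MonogenicPanel | None = None,
) -> SimulatedCohort:
    """Simulate ``n_replicates`` virtual embryos of a couple and score each.

    Standardization (when a fitted ``pc_model`` is given) reuses the scoring
    engine's centering so simulated distributions are on the same scale as
    reconstructed embryos; ``pc_scores`` fixes the couple's ancestry PCs for
    every replicate (virtual embryos share the parents' ancestry). A
    ``panel`` adds per-replicate carrier flags.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if mode not in ("linkage", "unlinked"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "linkage" and genetic_map is None:
        raise ValueError("linkage mode requires a genetic map")
    rng = np.random.default_rng(seed)

    panel_rows: dict[str, np.ndarray] = {}
    if panel is not None:
        key = {
            (c, int(p)): i
            for i, (c, p) in enumerate(zip(mother.sites.chrom, mother.sites.pos))
        }
        for cond in panel.conditions():
            rows = [
                key[(v.chrom, v.pos)]
                for v in panel.variants
                if v.condition == cond and (v.chrom, v.pos) in key
            ]
            panel_rows[cond] = np.array(rows, dtype=np.int64)

    raw = np.empty(n_replicates)
    flags = {cond: np.zeros(n_replicates, dtype=bool) for cond in panel_rows}
    for k in range(n_replicates):
        if mode == "linkage":
            g = simulate_embryo_linkage(mother, father, genetic_map, rng)
        else:
            g = simulate_embryo_unlinked(mother.genotypes, father.genotypes, rng)
        raw[k] = raw_prs(g, model, af_table).raw_score
        for cond, rows in panel_rows.items():
            flags[cond][k] = bool(np.any(g[rows] >= 1))

    standardized = None
    if pc_model is not None and pc_model.centering_coefficients is not None:
        if pc_scores is None:
            raise ValueError("standardization requires the couple's PC scores")
        standardized = np.array(
            [
                center_and_standardize(s, pc_scores, pc_model, population)[1]
                for s in raw
            ]
        )
    return SimulatedCohort(
        mode=mode, seed=seed, raw_scores=raw,
        standardized_scores=standardized, carrier_flags=flags,
    )


@dataclass
class CohortSummary:
    mode: str
    n_replicates: int
    mean: float
    sd: float
    quantiles: dict[str, float]
    midparent_mean: float
    carrier_fraction: dict[str, float]


def cohort_summary(
    cohort: SimulatedCohort,
    mother_score: float,
    father_score: float,
) -> CohortSummary:
    """Distribution statistics of a simulated cohort alongside the midparent
    mean — the Mendelian expectation of the offspring score. Parent scores
    must be on the same scale as the cohort's (raw with raw, standardized
    with standardized)."""
    if cohort.n_replicates < 2:
        raise ValueError("summary needs >= 2 replicates")
    s = cohort.scores
    qs = np.quantile(s, [0.025, 0.25, 0.5, 0.75, 0.975])
    return CohortSummary(
        mode=cohort.mode,
        n_replicates=cohort.n_replicates,
        mean=float(s.mean()),
        sd=float(s.std(ddof=1)),
        quantiles=dict(zip(["q2.5", "q25", "q50", "q75", "q97.5"], map(float, qs))),
        midparent_mean=float((mother_score + father_score) / 2.0),
        carrier_fraction={
            cond: float(f.mean()) for cond, f in cohort.carrier_flags.items()
        },
    )
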