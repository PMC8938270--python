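"""Step 1 of parental support: phase each parent from sibling embryos.

A heterozygous parental site transmits one of its two alleles to each
embryo; two nearby heterozygous sites tend to transmit alleles that sit on
the same physical chromosome (their co-inheritance is broken only by a
meiotic crossover, with probability given by the genetic map). Observing
several sibling embryos therefore identifies the *relative* phase of
adjacent heterozygous sites: the package maximizes, over the two possible
relative phases, the likelihood of all embryos' (noisy) array calls under
the same transmission model used downstream — a per-parent two-state hidden
chain with Haldane switch probabilities and the biopsy noise emission model.
The other parent is marginalized too: its transmitted haplotype per embryo
(uniform start, Haldane switch), and — because all sibling embryos share it —
its own unknown pair-phase jointly across embryos.

Decisions are made pairwise over adjacent heterozygous sites and chained
along the chromosome; the global hap-1/hap-2 labeling is arbitrary and fixed
at the first heterozygous site. With a single embryo inter-site phase is
unidentifiable and the operation refuses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .core import (
    EmbryoArrayObservation,
    GeneticMap,
    NoiseProfile,
    PhasedParentalGenome,
    SiteTable,
    haldane_switch_probability,
)
from .errors import PhaseConflictWarning, UnidentifiableError, WgrError


@dataclass
class PhaseScaffold:
    """Relative-phase assignment at a parent's heterozygous array sites.

    ``hap1_allele[i]`` is the allele (0=ref, 1=alt) placed on haplotype 1 at
    site ``i`` (-1 at sites not heterozygous in this parent).
    ``confidence[i]`` is the posterior probability of the chosen relative
    phase with respect to the previous heterozygous site (1.0 at the first
    heterozygous site of a chromosome, whose labeling is arbitrary).
    """

    sites: SiteTable
    hap1_allele: np.ndarray
    confidence: np.ndarray
    parent_name: str = "parent"

    def __post_init__(self) -> None:
        self.hap1_allele = np.asarray(self.hap1_allele, dtype=np.int8)
        self.confidence = np.asarray(self.confidence, dtype=float)

    def het_rows(self) -> np.ndarray:
        return np.flatnonzero(self.hap1_allele >= 0)

    def __len__(self) -> int:
        return len(self.het_rows())

    def to_genome(self, parent_genotypes: np.ndarray) -> PhasedParentalGenome:
        """Materialize a phased genome over the scaffold's (array) sites."""
        n = len(self.sites)
        haps = np.zeros((2, n), dtype=np.int8)
        gt = np.asarray(parent_genotypes)
        haps[:, gt == 2] = 1
        het = self.hap1_allele >= 0
        haps[0, het] = self.hap1_allele[het]
        haps[1, het] = 1 - self.hap1_allele[het]
        conf = np.where(het, self.confidence, 1.0)
        return PhasedParentalGenome(
            sites=self.sites, haplotypes=haps, phase_confidence=conf,
            sample_name=self.parent_name,
        )


_PAIR_PHASES = (((1, 1), (0, 0)), ((1, 0), (0, 1)))  # coupling, repulsion


def _other_allele_options(gt: int, psi: int, hap: int, site: int) -> tuple[int, ...] | int:
    """Allele(s) the other parent's haplotype ``hap`` carries at ``site``
    under its pair-phase ``psi``; a tuple means uniform uncertainty."""
    if gt == 0:
        return 0
    if gt == 2:
        return 1
    if gt == 1:
        return _PAIR_PHASES[psi][hap][site]
    return (0, 1)  # missing parental genotype: uninformative


def _pair_log_likelihoods(
    o_i: np.ndarray,
    o_j: np.ndarray,
    other_gt_i: int,
    other_gt_j: int,
    r: float,
    emat: np.ndarray,
) -> tuple[float, float]:
    """Log-likelihood of all embryos' calls at two adjacent heterozygous
    sites of the target parent, under coupling and repulsion phase.

    Marginalized per embryo: the transmitted haplotype of each parent
    (uniform start, Haldane switch probability ``r`` between the sites).
    Marginalized *across* embryos: the other parent's own pair-phase, which
    all sibling embryos share — ignoring that coupling between siblings
    misreads the other parent's linkage as the target parent's.
    """
    chan = (np.where(o_i < 0, 3, o_i), np.where(o_j < 0, 3, o_j))
    gts = (int(other_gt_i), int(other_gt_j))
    n_psi = 2 if gts[0] == 1 and gts[1] == 1 else 1
    path_prior = {True: (1 - r) / 2.0, False: r / 2.0}  # stay vs switch

    out = []
    for target_haps in _PAIR_PHASES:
        ll_by_psi = []
        for psi in range(n_psi):
            lik = np.zeros(len(o_i))
            for h_i in (0, 1):  # target parent's transmitted haplotype path
                for h_j in (0, 1):
                    p_h = path_prior[h_i == h_j]
                    for k_i in (0, 1):  # other parent's transmitted haplotype path
                        for k_j in (0, 1):
                            p_k = path_prior[k_i == k_j]
                            term = np.ones(len(o_i)) * (p_h * p_k)
                            for site, h, k in ((0, h_i, k_i), (1, h_j, k_j)):
                                m = target_haps[h][site]
                                f = _other_allele_options(gts[site], psi, k, site)
                                if isinstance(f, tuple):
                                    e = 0.5 * (
                                        emat[m + f[0], chan[site]]
                                        + emat[m + f[1], chan[site]]
                                    )
                                else:
                                    e = emat[m + f, chan[site]]
                                term = term * e
                            lik += term
            with np.errstate(divide="ignore"):
                ll_by_psi.append(np.log(lik).sum() - np.log(n_psi))
        out.append(float(logsumexp(ll_by_psi)))
    return out[0], out[1]


def phase_parent(
    parent_genotypes: np.ndarray,
    other_parent_genotypes: np.ndarray,
    observations: list[EmbryoArrayObservation],
    genetic_map: GeneticMap,
    profile: NoiseProfile,
    parent_name: str = "parent",
) -> PhaseScaffold:
    """Maximum-likelihood relative phasing of one parent's heterozygous array
    sites from >= 2 sibling embryo observations.

    ``parent_genotypes``/``other_parent_genotypes`` are genotype codes over
    the array site table shared by all ``observations``. Chromosomes flagged
    aneuploid in an embryo are skipped for that embryo. Likelihood ties break
    toward coupling (alt alleles on the same haplotype as at the previous
    site), deterministically.
    """
    if len(observations) < 2:
        raise UnidentifiableError(
            "parental phasing needs >= 2 sibling embryos; inter-site phase is "
            "unidentifiable from a single embryo"
        )
    sites = observations[0].sites
    for obs in observations[1:]:
        if len(obs.sites) != len(sites):
            raise WgrError("all embryo observations must share one array manifest")
    parent_genotypes = np.asarray(parent_genotypes)
    other_parent_genotypes = np.asarray(other_parent_genotypes)

    hap1 = np.full(len(sites), -1, dtype=np.int8)
    conf = np.full(len(sites), 0.5)
    emat = profile.emission_matrix()

    for chrom in sites.chromosomes():
        rows = sites.chrom_indices(chrom)
        het = rows[parent_genotypes[rows] == 1]
        if len(het) == 0:
            continue
        usable = [o for o in observations if chrom not in o.aneuploid_chromosomes]
        if len(usable) < 2:
            raise UnidentifiableError(
                f"fewer than 2 embryos observe chromosome {chrom}"
            )
        calls = np.stack([o.calls for o in usable])
        cm = genetic_map.cm_at(chrom, sites.pos[het])

        hap1[het[0]] = 0  # arbitrary labeling anchor: ref allele on haplotype 1
        conf[het[0]] = 1.0
        # chain along het sites, but keep the anchor at the last *informative*
        # decision: an uninformative pair (exact likelihood tie, e.g. every
        # embryo ambiguous at one of the two sites) must not corrupt the
        # phase of everything downstream of it
        anchor = het[0]
        anchor_cm = cm[0]
        for j, cm_j in zip(het[1:], cm[1:]):
            r = float(haldane_switch_probability(cm_j - anchor_cm))
            ll_c, ll_r = _pair_log_likelihoods(
                calls[:, anchor],
                calls[:, j],
                int(other_parent_genotypes[anchor]),
                int(other_parent_genotypes[j]),
                r,
                emat,
            )
            # tie-break toward coupling, with a tolerance so that embryo
            # ordering (float summation order) cannot flip exact ties
            tie = abs(ll_c - ll_r) <= 1e-9
            coupling = ll_c >= ll_r - 1e-9
            # posterior of the chosen relative phase under a uniform prior
            m = max(ll_c, ll_r)
            post = 1.0 / (np.exp(ll_c - m) + np.exp(ll_r - m))
            hap1[j] = hap1[anchor] if coupling else 1 - hap1[anchor]
            conf[j] = post
            if not tie:
                anchor, anchor_cm = j, cm_j
    return PhaseScaffold(sites=sites, hap1_allele=hap1, confidence=conf, parent_name=parent_name)


def merge_with_truth_phase(
    scaffold: PhaseScaffold, external: PhasedParentalGenome
) -> PhasedParentalGenome:
    """Anchor an externally phased genome (reference-panel phasing, or truth
    phase in simulation) to the embryo-derived scaffold.

    Per chromosome the external haplotype labels are flipped, by majority vote
    over shared scaffold sites, to agree with the scaffold orientation.
    Post-flip disagreement above 40% raises a sample-swap warning. Scaffold
    sites absent from the external genome keep their scaffold phase (the
    merged site table is the union).
    """
    scaf_rows = scaffold.het_rows()
    scaf_sites = scaffold.sites.subset(scaf_rows)
    ext_rows = scaf_sites.index_in(external.sites)

    haps = external.haplotypes.copy()
    conf = external.phase_confidence.copy()
    for chrom in external.sites.chromosomes():
        shared = np.flatnonzero((scaf_sites.chrom == chrom) & (ext_rows >= 0))
        if len(shared) == 0:
            continue
        e_rows = ext_rows[shared]
        ext_het = external.het_mask()[e_rows]
        shared = shared[ext_het]
        e_rows = e_rows[ext_het]
        if len(shared) == 0:
            continue
        scaf_h1 = scaffold.hap1_allele[scaf_rows[shared]]
        ext_h0 = haps[0, e_rows]
        idx = external.sites.chrom_indices(chrom)
        if float(np.mean(scaf_h1 == ext_h0)) < 0.5:  # orientation by majority vote
            haps[:, idx] = haps[::-1][:, idx]
        if len(shared) >= 2:
            # systematic disagreement is judged on *relative* phase of adjacent
            # shared sites (orientation- and switch-error-robust): a true sample
            # swap randomizes it to ~50%, a good scaffold disagrees only at its
            # sparse switch errors
            scaf_rel = scaf_h1[1:] == scaf_h1[:-1]
            ext_rel = ext_h0[1:] == ext_h0[:-1]
            discord = float(np.mean(scaf_rel != ext_rel))
            if discord > 0.4:
                warnings.warn(
                    f"scaffold and external phase disagree on {100 * discord:.0f}% of "
                    f"adjacent-site phase relations on chromosome {chrom}: "
                    "suspected sample swap",
                    PhaseConflictWarning,
                )

    missing = np.flatnonzero(ext_rows < 0)
    if len(missing) == 0:
        return PhasedParentalGenome(
            sites=external.sites, haplotypes=haps, phase_confidence=conf,
            sample_name=external.sample_name,
        )
    # union: append scaffold-only heterozygous sites with scaffold phase
    extra_sites = scaf_sites.subset(missing)
    extra_rows = scaf_rows[missing]
    frames = [external.sites.frame, extra_sites.frame]
    merged = (
        np.concatenate([haps[0], scaffold.hap1_allele[extra_rows]]),
        np.concatenate([haps[1], 1 - scaffold.hap1_allele[extra_rows]]),
    )
    conf_all = np.concatenate([conf, scaffold.confidence[extra_rows]])
    frame = pd.concat(frames, ignore_index=True)
    order = np.lexsort((frame["pos"].to_numpy(), frame["chrom"].to_numpy()))
    frame = frame.iloc[order].reset_index(drop=True)
    return PhasedParentalGenome(
        sites=SiteTable(frame),
        haplotypes=np.stack([merged[0][order], merged[1][order]]),
        phase_confidence=conf_all[order],
        sample_name=external.sample_name,
    )


@dataclass(frozen=True)
class RareVariant:
    """A rare heterozygous parental variant with direct phase evidence
    (e.g. from linked reads): either an explicit haplotype index, or a linked
    anchor site whose ``anchor_allele`` shares the molecule with this
    variant's alternate allele."""

    chrom: str
    pos: int
    haplotype: int | None = None
    anchor_pos: int | None = None
    anchor_allele: int = 1


def attach_rare_variants(
    genome: PhasedParentalGenome, variants: list[RareVariant]
) -> tuple[PhasedParentalGenome, list[RareVariant]]:
    """Place rare heterozygous variants onto a stated (or anchor-inherited)
    haplotype. Returns the updated genome and the variants left unphased
    (absent site, non-heterozygous site, or unphased/absent anchor)."""
    haps = genome.haplotypes.copy()
    conf = genome.phase_confidence.copy()
    key = {(c, int(p)): i for i, (c, p) in
           enumerate(zip(genome.sites.chrom, genome.sites.pos))}
    flagged: list[RareVariant] = []
    for v in variants:
        row = key.get((v.chrom, v.pos))
        if row is None or haps[0, row] == haps[1, row]:
            flagged.append(v)
            continue
        if v.haplotype is not None:
            hap = v.haplotype
        else:
            anchor = key.get((v.chrom, v.anchor_pos))
            if (
                anchor is None
                or haps[0, anchor] == haps[1, anchor]
                or conf[anchor] <= 0.5
            ):
                flagged.append(v)
                continue
            hap = 0 if haps[0, anchor] == v.anchor_allele else 1
        haps[hap, row] = 1
        haps[1 - hap, row] = 0
        conf[row] = 1.0
    return (
        PhasedParentalGenome(
            sites=genome.sites, haplotypes=haps, phase_confidence=conf,
            sample_name=genome.sample_name,
        ),
        flagged,
    )
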