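"""Transmitted-haplotype inference and dense genome reconstruction.

Step 2 of parental support: given phased parental genomes and one embryo's
sparse, noisy array calls, a four-state hidden Markov model infers which
maternal and which paternal haplotype the embryo inherited along each
chromosome. The hidden state at a site is the pair (m, p) with
m, p in {0, 1} indexing the transmitted haplotype of mother and father.
Per-parent switch probability between adjacent informative sites at genetic
distance d cM is the Haldane recombination fraction r(d) = (1 - e^(-2d/100))/2,
and the two parents' meioses are independent, so the joint transition
factorizes. Emissions come from the biopsy noise model (allele dropout,
random miscall, no-call).

The Viterbi path defines segment structure and recombination breakpoints
(reported as the full interval between flanking informative sites);
forward-backward marginals provide per-site confidence. Reconstructed
genotypes at all parental variant sites are read off the transmitted
haplotypes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .core import (
    MISSING,
    EmbryoArrayObservation,
    GeneticMap,
    NoiseProfile,
    PhasedParentalGenome,
    SiteTable,
    haldane_switch_probability,
)
from .errors import UninformativeChromosomeError

PARENTS = ("mother", "father")


@dataclass(frozen=True)
class Segment:
    """Half-inferred constant-haplotype interval. ``start``/``end`` are 1-based
    inclusive and tile the chromosome; ``bp_lo``/``bp_hi`` bound the breakpoint
    interval at the segment's *left* edge (equal to start for the first segment)."""

    chrom: str
    start: int
    end: int
    parent: str
    haplotype: int  # 0 or 1
    mean_posterior: float
    bp_lo: int
    bp_hi: int


@dataclass
class ChromosomeDecoding:
    """Per-chromosome HMM decode for one embryo."""

    chrom: str
    site_indices: np.ndarray  # rows of the array SiteTable used (informative sites)
    positions: np.ndarray
    viterbi_states: np.ndarray  # (n, 2) per-parent haplotype indices along Viterbi path
    posteriors: np.ndarray  # (n, 2) P(transmitted hap = viterbi hap) per parent
    state_posteriors: np.ndarray  # (n, 4) joint state marginals
    log_likelihood: float
    viterbi_log_likelihood: float = float("nan")
    informative_for: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class TransmissionPath:
    """Per embryo: which parental haplotype is inherited in each interval.

    Segments tile each chromosome without gaps or overlaps; adjacent segments
    of the same parent differ in haplotype index.
    """

    segments: list[Segment]
    decodings: dict[str, ChromosomeDecoding] = field(default_factory=dict)

    def chromosome_segments(self, chrom: str, parent: str) -> list[Segment]:
        return [s for s in self.segments if s.chrom == chrom and s.parent == parent]

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(s.chrom for s in self.segments))

    def breakpoints(self, chrom: str, parent: str) -> list[tuple[int, int]]:
        """Breakpoint uncertainty intervals (bp_lo, bp_hi), excluding the
        chromosome start."""
        segs = self.chromosome_segments(chrom, parent)
        return [(s.bp_lo, s.bp_hi) for s in segs[1:]]


@dataclass
class ReconstructedGenome:
    """Dense predicted diploid genome of one embryo over the full site table.

    ``maternal_allele``/``paternal_allele`` are the alleles read off the
    transmitted haplotypes (-1 where no prediction, e.g. aneuploid
    chromosomes); ``maternal_hap``/``paternal_hap`` record which parental
    haplotype was transmitted (-1 where unpredicted).
    """

    sites: SiteTable
    maternal_allele: np.ndarray
    paternal_allele: np.ndarray
    confidence: np.ndarray
    maternal_hap: np.ndarray
    paternal_hap: np.ndarray
    name: str = "embryo"

    def __post_init__(self) -> None:
        self.maternal_allele = np.asarray(self.maternal_allele, dtype=np.int8)
        self.paternal_allele = np.asarray(self.paternal_allele, dtype=np.int8)
        # single precision: ample for a probability, and exact across the
        # VCF round trip (FORMAT Float fields are 32-bit)
        self.confidence = np.asarray(self.confidence, dtype=np.float32)
        self.maternal_hap = np.asarray(self.maternal_hap, dtype=np.int8)
        self.paternal_hap = np.asarray(self.paternal_hap, dtype=np.int8)

    @property
    def genotypes(self) -> np.ndarray:
        """Diploid genotype codes; MISSING where either allele is unpredicted."""
        gt = (self.maternal_allele + self.paternal_allele).astype(np.int8)
        gt[(self.maternal_allele < 0) | (self.paternal_allele < 0)] = MISSING
        return gt

    @property
    def predicted(self) -> np.ndarray:
        return (self.maternal_allele >= 0) & (self.paternal_allele >= 0)


def _emission_loglik(
    calls: np.ndarray,
    mat_alleles: np.ndarray,
    pat_alleles: np.ndarray,
    profile: NoiseProfile,
) -> np.ndarray:
    """log P(obs | state) for each site and each of the four (m, p) states.

    ``mat_alleles``/``pat_alleles``: (2, n) haplotype alleles at the sites.
    Returns (n, 4) with state order (m, p) = (0,0), (0,1), (1,0), (1,1).
    """
    emat = profile.emission_matrix()  # (3 true genotypes, 4 channels)
    obs_channel = np.where(calls == MISSING, 3, calls)
    n = len(calls)
    out = np.empty((n, 4))
    with np.errstate(divide="ignore"):
        log_emat = np.log(emat)
    for s, (m, p) in enumerate([(0, 0), (0, 1), (1, 0), (1, 1)]):
        g = mat_alleles[m] + pat_alleles[p]
        out[:, s] = log_emat[g, obs_channel]
    return out


def _log_transition(d_cm: float) -> np.ndarray:
    """4x4 joint log-transition for one inter-site gap (per-parent Haldane
    switches, independent across parents)."""
    r = float(haldane_switch_probability(d_cm))
    t = np.array([[1 - r, r], [r, 1 - r]])
    with np.errstate(divide="ignore"):
        return np.log(np.kron(t, t))


def decode_chromosome(
    chrom: str,
    observation: EmbryoArrayObservation,
    mother: PhasedParentalGenome,
    father: PhasedParentalGenome,
    genetic_map: GeneticMap,
    profile: NoiseProfile,
) -> ChromosomeDecoding:
    """Run forward-backward and Viterbi over the informative sites of one
    chromosome. Informative = heterozygous in at least one parent."""
    if chrom in observation.aneuploid_chromosomes:
        raise ValueError(f"chromosome {chrom} is flagged aneuploid; refusing to decode")

    arr_idx = observation.sites.chrom_indices(chrom)
    par_rows = observation.sites.subset(arr_idx).index_in(mother.sites)
    if np.any(par_rows < 0):
        raise ValueError("array sites must be a subset of parental sites")

    mat_h = mother.haplotypes[:, par_rows]
    pat_h = father.haplotypes[:, par_rows]
    informative = (mat_h[0] != mat_h[1]) | (pat_h[0] != pat_h[1])
    if not informative.any():
        raise UninformativeChromosomeError(
            f"no site on chromosome {chrom} is heterozygous in either parent"
        )

    keep = np.flatnonzero(informative)
    site_indices = arr_idx[keep]
    positions = observation.sites.pos[site_indices]
    calls = observation.calls[site_indices]
    mat_h, pat_h = mat_h[:, keep], pat_h[:, keep]

    log_e = _emission_loglik(calls, mat_h, pat_h, profile)
    cm = genetic_map.cm_at(chrom, positions)
    gaps = np.diff(cm)

    n = len(calls)
    log_pi = np.full(4, np.log(0.25))
    trans = [_log_transition(d) for d in gaps]

    # forward-backward in log space
    fwd = np.empty((n, 4))
    fwd[0] = log_pi + log_e[0]
    for i in range(1, n):
        fwd[i] = log_e[i] + logsumexp(fwd[i - 1][:, None] + trans[i - 1], axis=0)
    bwd = np.zeros((n, 4))
    for i in range(n - 2, -1, -1):
        bwd[i] = logsumexp(trans[i] + (log_e[i + 1] + bwd[i + 1])[None, :], axis=1)
    log_lik = float(logsumexp(fwd[-1]))
    post = np.exp(fwd + bwd - log_lik)
    post /= post.sum(axis=1, keepdims=True)

    # Viterbi
    delta = np.empty((n, 4))
    psi = np.zeros((n, 4), dtype=np.int64)
    delta[0] = log_pi + log_e[0]
    for i in range(1, n):
        cand = delta[i - 1][:, None] + trans[i - 1]
        psi[i] = np.argmax(cand, axis=0)
        delta[i] = log_e[i] + np.max(cand, axis=0)
    states = np.empty(n, dtype=np.int64)
    states[-1] = int(np.argmax(delta[-1]))
    for i in range(n - 2, -1, -1):
        states[i] = psi[i + 1][states[i + 1]]

    vit = np.column_stack([states // 2, states % 2])  # (m, p) per site
    # per-parent marginal posterior of the Viterbi-assigned haplotype
    mat_post = post[:, 2] + post[:, 3]  # P(m = 1)
    pat_post = post[:, 1] + post[:, 3]  # P(p = 1)
    per_parent = np.column_stack(
        [
            np.where(vit[:, 0] == 1, mat_post, 1 - mat_post),
            np.where(vit[:, 1] == 1, pat_post, 1 - pat_post),
        ]
    )
    return ChromosomeDecoding(
        chrom=chrom,
        site_indices=site_indices,
        positions=positions,
        viterbi_states=vit,
        posteriors=per_parent,
        state_posteriors=post,
        log_likelihood=log_lik,
        viterbi_log_likelihood=float(np.max(delta[-1])),
        informative_for={
            "mother": mat_h[0] != mat_h[1],
            "father": pat_h[0] != pat_h[1],
        },
    )


def _segments_from_decoding(
    dec: ChromosomeDecoding, parent: str, parent_col: int, chrom_end: int
) -> list[Segment]:
    """Project the Viterbi path onto sites heterozygous in one parent and
    collapse runs into tiling segments.

    A switch of the *other* parent is invisible at these sites, so segment
    boundaries are only ever placed between consecutive sites heterozygous in
    this parent; the breakpoint interval spans those two flanking sites and
    segments are cut at the interval midpoint so they tile the chromosome.
    """
    het = dec.informative_for[parent]
    if not het.any():
        # parent homozygous along the chromosome: transmission unidentifiable
        # (and irrelevant for genotypes) — single haplotype-0 segment.
        return [Segment(dec.chrom, 1, chrom_end, parent, 0, 0.5, 1, 1)]
    idx = np.flatnonzero(het)
    haps = dec.viterbi_states[idx, parent_col]
    pos = dec.positions[idx]
    post = dec.posteriors[idx, parent_col]

    change = np.flatnonzero(np.diff(haps)) + 1  # run starts (into idx-space)
    run_starts = np.concatenate([[0], change])
    run_ends = np.concatenate([change, [len(idx)]])

    segments: list[Segment] = []
    prev_cut = 1
    for k, (a, b) in enumerate(zip(run_starts, run_ends)):
        if k + 1 < len(run_starts):
            lo, hi = int(pos[b - 1]), int(pos[b])
            cut = (lo + hi) // 2
        else:
            lo = hi = cut = chrom_end
        bp_lo, bp_hi = (1, 1) if k == 0 else (int(pos[a - 1]), int(pos[a]))
        segments.append(
            Segment(
                chrom=dec.chrom,
                start=prev_cut,
                end=cut,
                parent=parent,
                haplotype=int(haps[a]),
                mean_posterior=float(np.mean(post[a:b])),
                bp_lo=bp_lo,
                bp_hi=bp_hi,
            )
        )
        prev_cut = cut + 1
    return segments


def decode_transmission(
    observation: EmbryoArrayObservation,
    mother: PhasedParentalGenome,
    father: PhasedParentalGenome,
    genetic_map: GeneticMap,
    profile: NoiseProfile,
    chrom_ends: dict[str, int] | None = None,
) -> TransmissionPath:
    """Infer the transmitted parental haplotypes for every non-aneuploid
    chromosome of one embryo.

    ``chrom_ends`` optionally fixes the 1-based end coordinate of each
    chromosome (default: the last parental site position).
    """
    path = TransmissionPath(segments=[])
    for chrom in observation.sites.chromosomes():
        if chrom in observation.aneuploid_chromosomes:
            continue
        dec = decode_chromosome(chrom, observation, mother, father, genetic_map, profile)
        end = (
            chrom_ends[chrom]
            if chrom_ends is not None
            else int(mother.sites.pos[mother.sites.chrom_indices(chrom)].max())
        )
        path.decodings[chrom] = dec
        for parent, col in zip(PARENTS, (0, 1)):
            path.segments.extend(_segments_from_decoding(dec, parent, col, end))
    return path


def fill_genome(
    path: TransmissionPath,
    mother: PhasedParentalGenome,
    father: PhasedParentalGenome,
    sites: SiteTable | None = None,
    name: str = "embryo",
) -> ReconstructedGenome:
    """Read the embryo's dense diploid genotypes off the transmitted haplotypes.

    Every parental variant site on a decoded chromosome receives the allele
    pair carried by the transmitted maternal and paternal haplotypes. Per-site
    confidence combines the transmission posterior at the nearest informative
    site of each parent with the parental phase confidence; sites inside a
    breakpoint interval inherit the (lower) posterior of the flanking sites
    rather than being dropped.
    """
    if sites is None:
        sites = mother.sites
    n = len(sites)
    mat_al = np.full(n, -1, dtype=np.int8)
    pat_al = np.full(n, -1, dtype=np.int8)
    confidence = np.zeros(n)
    mat_hap = np.full(n, -1, dtype=np.int8)
    pat_hap = np.full(n, -1, dtype=np.int8)

    rows_in_mother = sites.index_in(mother.sites)
    rows_in_father = sites.index_in(father.sites)

    for chrom in path.chromosomes():
        site_rows = sites.chrom_indices(chrom)
        if len(site_rows) == 0:
            continue
        pos = sites.pos[site_rows]
        dec = path.decodings.get(chrom)
        hap_choice = {}
        conf_choice = {}
        for parent, col in zip(PARENTS, (0, 1)):
            segs = path.chromosome_segments(chrom, parent)
            starts = np.array([s.start for s in segs])
            seg_of = np.clip(np.searchsorted(starts, pos, side="right") - 1, 0, len(segs) - 1)
            hap_choice[parent] = np.array([segs[k].haplotype for k in seg_of], dtype=np.int8)
            if dec is not None and dec.informative_for[parent].any():
                inf_pos = dec.positions[dec.informative_for[parent]]
                inf_post = dec.posteriors[dec.informative_for[parent], col]
                # nearest informative site on each side; confidence = min of the two
                right = np.clip(np.searchsorted(inf_pos, pos), 0, len(inf_pos) - 1)
                left = np.clip(right - 1, 0, len(inf_pos) - 1)
                conf_choice[parent] = np.minimum(inf_post[left], inf_post[right])
            else:
                conf_choice[parent] = np.full(len(pos), 0.5)

        m_rows = rows_in_mother[site_rows]
        p_rows = rows_in_father[site_rows]
        ok = (m_rows >= 0) & (p_rows >= 0)
        mh, ph = hap_choice["mother"], hap_choice["father"]
        rows = site_rows[ok]
        mat_al[rows] = mother.haplotypes[mh[ok], m_rows[ok]]
        pat_al[rows] = father.haplotypes[ph[ok], p_rows[ok]]
        mat_hap[rows] = mh[ok]
        pat_hap[rows] = ph[ok]
        phase_conf = np.minimum(
            np.where(
                mother.het_mask()[m_rows[ok]], mother.phase_confidence[m_rows[ok]], 1.0
            ),
            np.where(
                father.het_mask()[p_rows[ok]], father.phase_confidence[p_rows[ok]], 1.0
            ),
        )
        confidence[rows] = (
            conf_choice["mother"][ok] * conf_choice["father"][ok] * np.maximum(phase_conf, 0.5)
        )
    return ReconstructedGenome(
        sites=sites,
        maternal_allele=mat_al,
        paternal_allele=pat_al,
        confidence=confidence,
        maternal_hap=mat_hap,
        paternal_hap=pat_hap,
        name=name,
    )


def high_confidence_filter(
    mother_gt: np.ndarray,
    father_gt: np.ndarray,
    child_gt: np.ndarray,
    low_quality: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of trio-consistent sites.

    Excludes sites where the child genotype is Mendelian-impossible given the
    parents, sites with any missing trio genotype, and (optionally) sites
    flagged low-quality upstream. Multiallelic sites never reach this point —
    they are rejected at load.
    """
    mother_gt = np.asarray(mother_gt)
    father_gt = np.asarray(father_gt)
    child_gt = np.asarray(child_gt)
    present = (mother_gt >= 0) & (father_gt >= 0) & (child_gt >= 0)

    def contributions(g):
        # possible transmitted allele counts {0,1} for genotype codes 0/1/2
        lo = (g == 2).astype(np.int8)
        hi = (g >= 1).astype(np.int8)
        return lo, hi

    mlo, mhi = contributions(mother_gt)
    flo, fhi = contributions(father_gt)
    consistent = (child_gt >= mlo + flo) & (child_gt <= mhi + fhi)
    mask = present & consistent
    if low_quality is not None:
        mask &= ~np.asarray(low_quality, dtype=bool)
    return mask


RARE_AF_THRESHOLD = 1e-3  # "rare" = population allele frequency < 0.1%


def classify_rare(af: float | None) -> str:
    """Classify a variant as rare or common: rare iff AF < 0.1% or the site
    is absent from the population frequency table (af=None)."""
    if af is None:
        return "rare"
    return "rare" if af < RARE_AF_THRESHOLD else "common"


def reconstruct_embryo(
    observation: EmbryoArrayObservation,
    mother: PhasedParentalGenome,
    father: PhasedParentalGenome,
    genetic_map: GeneticMap,
    profile: NoiseProfile,
    sites: SiteTable | None = None,
) -> tuple[ReconstructedGenome, TransmissionPath]:
    """Convenience driver: decode transmission then fill the dense genome."""
    full_sites = sites if sites is not None else mother.sites
    chrom_ends = {
        c: int(full_sites.pos[full_sites.chrom_indices(c)].max())
        for c in full_sites.chromosomes()
    }
    path = decode_transmission(
        observation, mother, father, genetic_map, profile, chrom_ends=chrom_ends
    )
    genome = fill_genome(path, mother, father, sites=full_sites, name=observation.name)
    return genome, path
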