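"""Ground-truthed synthetic IVF families.

Generates everything a reconstruction study needs without any external data:
phased parental genomes drawn from a population allele-frequency spectrum,
gametes produced by map-driven meiosis (crossovers as a Poisson process on
the centimorgan scale, i.e. no interference), diploid embryos, a designated
"born child" whose genome is known exactly (mirroring the study design of
validating against WGS of the child born from one transferred embryo), and
noisy biopsy observations at day-3 or day-5 severity.

The noise presets are package calibration constants, not published values:
true biopsy error rates for the assay are not public. Day-3 (single-cell
blastomere) is strictly noisier than day-5 (multi-cell trophectoderm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    EmbryoArrayObservation,
    GeneticMap,
    NoiseProfile,
    PhasedParentalGenome,
    SiteTable,
    TrueMeiosis,
)
from .io_formats import AlleleFrequencyTable

DEFAULT_CHROM_LENGTH_BP = 100_000_000
DEFAULT_CM_PER_MB = 1.0


def uniform_genetic_map(
    n_chromosomes: int,
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP,
    cm_per_mb: float = DEFAULT_CM_PER_MB,
) -> GeneticMap:
    """A constant-rate map: ``cm_per_mb`` centimorgans per megabase on each
    chromosome (two anchors per chromosome suffice for a linear map)."""
    anchors = {}
    for c in range(1, n_chromosomes + 1):
        pos = np.array([1, chrom_length_bp], dtype=np.int64)
        cm = np.array([0.0, chrom_length_bp / 1e6 * cm_per_mb])
        anchors[str(c)] = (pos, cm)
    return GeneticMap(anchors)


def simulate_parents(
    n_sites: int,
    n_chromosomes: int,
    seed: int,
    allele_freq_spectrum=None,
    chrom_length_bp: int = DEFAULT_CHROM_LENGTH_BP,
) -> tuple[PhasedParentalGenome, PhasedParentalGenome, SiteTable, AlleleFrequencyTable]:
    """Draw a couple's phased genomes.

    Each haplotype allele is an independent Bernoulli draw from the site's
    population alternate-allele frequency (Hardy-Weinberg parents).
    ``allele_freq_spectrum`` is a callable ``(rng, n) -> AF array``; the
    default draws uniformly on (0.05, 0.95), a common-SNP array spectrum.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    if allele_freq_spectrum is None:
        allele_freq_spectrum = lambda r, n: r.uniform(0.05, 0.95, size=n)  # noqa: E731

    per_chrom = np.full(n_chromosomes, n_sites // n_chromosomes)
    per_chrom[: n_sites % n_chromosomes] += 1
    chroms, poss = [], []
    for c, k in enumerate(per_chrom, start=1):
        pos = np.unique(rng.integers(2, chrom_length_bp, size=k, dtype=np.int64))
        while len(pos) < k:  # collisions are rare at realistic densities
            extra = rng.integers(2, chrom_length_bp, size=k - len(pos), dtype=np.int64)
            pos = np.unique(np.concatenate([pos, extra]))
        chroms.extend([str(c)] * k)
        poss.extend(pos.tolist())
    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    sites = SiteTable.from_arrays(chroms, poss, bases[ref_idx], bases[alt_idx])

    afs = np.asarray(allele_freq_spectrum(rng, n_sites), dtype=float)
    if np.any((afs <= 0) | (afs >= 1)):
        raise ValueError("allele frequencies must lie in (0, 1)")
    mother_h = (rng.random((2, n_sites)) < afs).astype(np.int8)
    father_h = (rng.random((2, n_sites)) < afs).astype(np.int8)
    af_table = AlleleFrequencyTable(
        {(c, int(p)): float(a) for c, p, a in zip(sites.chrom, sites.pos, afs)}
    )
    mother = PhasedParentalGenome(sites=sites, haplotypes=mother_h, sample_name="mother")
    father = PhasedParentalGenome(sites=sites, haplotypes=father_h, sample_name="father")
    return mother, father, sites, af_table


def draw_meiosis(
    parent: PhasedParentalGenome, genetic_map: GeneticMap, rng
) -> tuple[TrueMeiosis, np.ndarray]:
    """One meiosis: per chromosome, Poisson(L_cM/100) crossovers placed
    uniformly on the centimorgan scale (mapped back to bp), starting from a
    random haplotype. Returns the meiosis record and the gamete alleles."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    start = {}
    crossovers = {}
    gamete = np.empty(len(parent.sites), dtype=np.int8)
    for chrom in parent.sites.chromosomes():
        l_cm = genetic_map.span_cm(chrom)
        n_xo = rng.poisson(l_cm / 100.0)
        cm0 = genetic_map.anchors[chrom][1][0]
        xo_cm = np.sort(rng.uniform(0.0, l_cm, size=n_xo)) + cm0
        xo_bp = np.unique(np.round(genetic_map.pos_at_cm(chrom, xo_cm)).astype(np.int64))
        start[chrom] = int(rng.integers(0, 2))
        crossovers[chrom] = xo_bp
        idx = parent.sites.chrom_indices(chrom)
        meiosis_tmp = TrueMeiosis(start_haplotype={chrom: start[chrom]}, crossovers={chrom: xo_bp})
        hap_at = meiosis_tmp.haplotype_at(chrom, parent.sites.pos[idx])
        gamete[idx] = parent.haplotypes[hap_at, idx]
    return TrueMeiosis(start_haplotype=start, crossovers=crossovers), gamete


def make_embryo(maternal_gamete: np.ndarray, paternal_gamete: np.ndarray) -> np.ndarray:
    """True diploid genotype codes of the embryo (dosage of the alt allele)."""
    return (maternal_gamete + paternal_gamete).astype(np.int8)


def make_observation(
    embryo_genotypes: np.ndarray,
    sites: SiteTable,
    array_rows: np.ndarray,
    profile: NoiseProfile,
    rng,
    aneuploid_chromosomes=frozenset(),
    name: str = "embryo",
) -> EmbryoArrayObservation:
    """Apply the biopsy noise model to the truth restricted to array sites.

    The generative process matches :meth:`NoiseProfile.emission_matrix`
    exactly: sample the observed channel (call 0/1/2 or no-call) from
    P(obs | true genotype) independently per site.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    truth = embryo_genotypes[array_rows]
    emat = profile.emission_matrix()
    u = rng.random(len(truth))
    cdf = np.cumsum(emat, axis=1)
    channel = np.minimum((u[:, None] > cdf[truth]).sum(axis=1), 3)
    calls = np.where(channel == 3, -1, channel).astype(np.int8)
    return EmbryoArrayObservation(
        sites=sites.subset(array_rows),
        calls=calls,
        aneuploid_chromosomes=frozenset(aneuploid_chromosomes),
        name=name,
    )


@dataclass
class SyntheticEmbryo:
    """One simulated embryo: ground truth plus its noisy biopsy observation."""

    name: str
    maternal_meiosis: TrueMeiosis
    paternal_meiosis: TrueMeiosis
    true_genotypes: np.ndarray
    observation: EmbryoArrayObservation
    aneuploid_chromosomes: frozenset[str] = frozenset()


@dataclass
class SyntheticFamily:
    """A complete ground-truthed fixture: phased parents, sibling embryos with
    observations, and a designated born child whose truth genome is exact."""

    mother: PhasedParentalGenome
    father: PhasedParentalGenome
    sites: SiteTable
    allele_frequencies: AlleleFrequencyTable
    genetic_map: GeneticMap
    array_rows: np.ndarray
    embryos: list[SyntheticEmbryo] = field(default_factory=list)
    born_child_index: int = 0
    noise: NoiseProfile = None  # type: ignore[assignment]

    @property
    def born_child(self) -> SyntheticEmbryo:
        return self.embryos[self.born_child_index]

    @property
    def observations(self) -> list[EmbryoArrayObservation]:
        return [e.observation for e in self.embryos]


def simulate_family(
    n_embryos: int,
    noise: NoiseProfile,
    seed: int,
    n_sites: int = 2000,
    n_chromosomes: int = 2,
    n_array_sites: int | None = None,
    aneuploid_spec: dict[int, list[str]] | None = None,
    genetic_map: GeneticMap | None = None,
    born_child_index: int = 0,
) -> SyntheticFamily:
    """Simulate a full family.

    ``n_array_sites`` array-manifest sites are a random subset of the
    ``n_sites`` analysis sites (default: half). ``aneuploid_spec`` maps embryo
    index -> chromosomes to flag aneuploid (consumed as flags downstream, as a
    clinical copy-number caller would supply them). The born child's truth
    genome is exact; its index defaults to embryo 0.
    """
    if n_embryos < 1:
        raise ValueError("n_embryos must be >= 1")
    rng = np.random.default_rng(seed)
    mother, father, sites, af_table = simulate_parents(
        n_sites, n_chromosomes, seed=int(rng.integers(2**31))
    )
    if genetic_map is None:
        genetic_map = uniform_genetic_map(n_chromosomes)
    if n_array_sites is None:
        n_array_sites = n_sites // 2
    array_rows = np.sort(rng.choice(n_sites, size=n_array_sites, replace=False))
    aneuploid_spec = aneuploid_spec or {}

    family = SyntheticFamily(
        mother=mother,
        father=father,
        sites=sites,
        allele_frequencies=af_table,
        genetic_map=genetic_map,
        array_rows=array_rows,
        born_child_index=born_child_index,
        noise=noise,
    )
    for k in range(n_embryos):
        m_meio, m_gam = draw_meiosis(mother, genetic_map, rng)
        p_meio, p_gam = draw_meiosis(father, genetic_map, rng)
        truth = make_embryo(m_gam, p_gam)
        aneu = frozenset(aneuploid_spec.get(k, ()))
        obs = make_observation(
            truth, sites, array_rows, noise, rng, aneuploid_chromosomes=aneu,
            name=f"embryo_{k}",
        )
        family.embryos.append(
            SyntheticEmbryo(
                name=f"embryo_{k}",
                maternal_meiosis=m_meio,
                paternal_meiosis=p_meio,
                true_genotypes=truth,
                observation=obs,
                aneuploid_chromosomes=aneu,
            )
        )
    return family
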