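"""Core in-memory containers shared across the pipeline.

Genotypes are encoded as small integers throughout:

====  =========================
code  meaning
====  =========================
0     homozygous reference
1     heterozygous
2     homozygous alternate
-1    missing / no-call
====  =========================

Coordinates are 1-based inclusive (VCF convention) everywhere in memory;
only BED output is 0-based half-open. Chromosome labels are normalized by
stripping a leading ``chr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import MapError

HOM_REF = np.int8(0)
HET = np.int8(1)
HOM_ALT = np.int8(2)
MISSING = np.int8(-1)

#: observation-channel index for each call code (missing mapped to column 3)
N_OBS_CHANNELS = 4


def normalize_chrom(label: str) -> str:
    label = str(label)
    return label[3:] if label.lower().startswith("chr") else label


@dataclass(frozen=True)
class SiteTable:
    """Ordered table of biallelic SNV sites.

    Positions are strictly increasing within a chromosome; multiallelic
    rows are rejected upstream at load time.
    """

    frame: pd.DataFrame  # columns: chrom, pos, ref, alt, site_id

    def __post_init__(self) -> None:
        df = self.frame
        required = ["chrom", "pos", "ref", "alt", "site_id"]
        if list(df.columns[:5]) != required:
            raise ValueError(f"SiteTable requires columns {required}")
        for chrom, sub in df.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if not np.all(np.diff(pos) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {chrom}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chrom(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.frame["chrom"]))

    def chrom_indices(self, chrom: str) -> np.ndarray:
        """Row indices of a chromosome (contiguous because the table is sorted)."""
        return np.flatnonzero(self.frame["chrom"].to_numpy() == chrom)

    def subset(self, rows: np.ndarray) -> "SiteTable":
        return SiteTable(self.frame.iloc[rows].reset_index(drop=True))

    def index_in(self, other: "SiteTable") -> np.ndarray:
        """For each of our sites, the row index in ``other`` (-1 if absent)."""
        key = pd.MultiIndex.from_frame(other.frame[["chrom", "pos"]])
        ours = pd.MultiIndex.from_frame(self.frame[["chrom", "pos"]])
        return key.get_indexer(ours)

    @staticmethod
    def from_arrays(chrom, pos, ref, alt, site_id=None) -> "SiteTable":
        n = len(pos)
        if site_id is None:
            site_id = [f"site_{c}_{p}" for c, p in zip(chrom, pos)]
        return SiteTable(
            pd.DataFrame(
                {
                    "chrom": [normalize_chrom(c) for c in chrom],
                    "pos": np.asarray(pos, dtype=np.int64),
                    "ref": list(ref),
                    "alt": list(alt),
                    "site_id": list(site_id),
                }
            )
        )


@dataclass(frozen=True)
class GeneticMap:
    """Cumulative genetic map: per chromosome, anchor positions (bp) with
    non-decreasing centimorgan values. Queries interpolate linearly and
    clamp outside the anchored span."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]]  # chrom -> (pos, cM)

    def __post_init__(self) -> None:
        for chrom, (pos, cm) in self.anchors.items():
            if np.any(np.diff(pos) <= 0):
                raise MapError(f"map positions not increasing on chromosome {chrom}")
            if np.any(np.diff(cm) < 0):
                raise MapError(f"decreasing cM on chromosome {chrom}")
            if np.any(cm < 0):
                raise MapError(f"negative cM on chromosome {chrom}")

    def cm_at(self, chrom: str, positions) -> np.ndarray:
        chrom = normalize_chrom(chrom)
        if chrom not in self.anchors:
            raise MapError(f"chromosome {chrom} absent from genetic map")
        pos, cm = self.anchors[chrom]
        return np.interp(np.asarray(positions, dtype=float), pos, cm)

    def pos_at_cm(self, chrom: str, cms) -> np.ndarray:
        """Inverse lookup (cM -> bp); flat map segments resolve to their left edge."""
        pos, cm = self.anchors[normalize_chrom(chrom)]
        return np.interp(np.asarray(cms, dtype=float), cm, pos)

    def span_cm(self, chrom: str) -> float:
        pos, cm = self.anchors[normalize_chrom(chrom)]
        return float(cm[-1] - cm[0])


def haldane_switch_probability(d_cm) -> np.ndarray:
    """Recombination fraction between two loci d centimorgans apart under the
    Haldane (no-interference) map function: r = (1 - exp(-2d/100)) / 2."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0)) / 2.0


@dataclass(frozen=True)
class NoiseProfile:
    """Biopsy genotyping noise model.

    allele_dropout_rate
        Probability that a heterozygous site is observed as one of the two
        homozygotes (uniform over the two) — the dominant artifact of
        few-cell whole-genome amplification.
    genotype_error_rate
        Probability of a random miscall, uniform over the two wrong calls.
        Homozygous dropout is observationally silent and folded in here.
    missing_rate
        Probability of a no-call, independent of the true genotype.
    """

    allele_dropout_rate: float
    genotype_error_rate: float
    missing_rate: float
    label: str = "custom"

    def __post_init__(self) -> None:
        for r in (self.allele_dropout_rate, self.genotype_error_rate, self.missing_rate):
            if not (0.0 <= r < 1.0):
                raise ValueError("noise rates must lie in [0, 1)")

    def emission_matrix(self) -> np.ndarray:
        """P(observed channel | true genotype): rows = true genotype 0/1/2,
        columns = observed call 0/1/2 and no-call (column 3). Rows sum to 1."""
        a, e, m = self.allele_dropout_rate, self.genotype_error_rate, self.missing_rate
        called = 1.0 - m
        hom_as_het = called * e / 2.0
        het_as_hom = called * (a / 2.0 + (1.0 - a) * e / 2.0)
        return np.array(
            [
                [called * (1 - e), hom_as_het, hom_as_het, m],
                [het_as_hom, called * (1 - a) * (1 - e), het_as_hom, m],
                [hom_as_het, hom_as_het, called * (1 - e), m],
            ]
        )


#: day-5 trophectoderm (multi-cell) biopsy preset — package calibration constants
DAY5 = NoiseProfile(0.02, 0.005, 0.02, label="day5")
#: day-3 blastomere (single-cell) biopsy preset — strictly noisier than day-5
DAY3 = NoiseProfile(0.10, 0.01, 0.05, label="day3")
NOISELESS = NoiseProfile(0.0, 0.0, 0.0, label="noiseless")

NOISE_PRESETS = {"day3": DAY3, "day5": DAY5, "noiseless": NOISELESS}


@dataclass
class PhasedParentalGenome:
    """One parent's diploid genome with haplotype-resolved alleles.

    ``haplotypes`` has shape (2, n_sites) with allele codes 0 (ref) / 1 (alt)
    aligned to ``sites``. ``phase_confidence`` is the per-site probability that
    the hap-1/hap-2 assignment is correct relative to its neighbours; it is
    meaningful only at heterozygous sites (0.5 = unphased).
    """

    sites: SiteTable
    haplotypes: np.ndarray
    phase_confidence: np.ndarray = None  # type: ignore[assignment]
    sample_name: str = "parent"

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.shape != (2, len(self.sites)):
            raise ValueError("haplotypes must have shape (2, n_sites)")
        if self.phase_confidence is None:
            self.phase_confidence = np.ones(len(self.sites))
        self.phase_confidence = np.asarray(self.phase_confidence, dtype=float)

    @property
    def genotypes(self) -> np.ndarray:
        return (self.haplotypes[0] + self.haplotypes[1]).astype(np.int8)

    def het_mask(self) -> np.ndarray:
        return self.haplotypes[0] != self.haplotypes[1]

    def flipped(self, chrom: str | None = None) -> "PhasedParentalGenome":
        """Swap haplotype labels (on one chromosome, or everywhere)."""
        haps = self.haplotypes.copy()
        if chrom is None:
            haps = haps[::-1]
        else:
            idx = self.sites.chrom_indices(chrom)
            haps[:, idx] = haps[::-1][:, idx]
        return replace(self, haplotypes=haps)


@dataclass
class EmbryoArrayObservation:
    """Sparse, noisy genotype calls from one embryo biopsy.

    ``sites`` is the array manifest (a subset of the analysis sites);
    ``calls`` are genotype codes (-1 = no-call). ``aneuploid_chromosomes``
    lists chromosomes flagged aneuploid by an upstream copy-number caller;
    they are excluded from reconstruction.
    """

    sites: SiteTable
    calls: np.ndarray
    aneuploid_chromosomes: frozenset[str] = frozenset()
    name: str = "embryo"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sites),):
            raise ValueError("calls must align with sites")
        self.aneuploid_chromosomes = frozenset(
            normalize_chrom(c) for c in self.aneuploid_chromosomes
        )


@dataclass
class TrueMeiosis:
    """Ground-truth meiosis for one gamete: per chromosome, the starting
    haplotype index (0/1) and strictly increasing crossover positions (bp)."""

    start_haplotype: dict[str, int]
    crossovers: dict[str, np.ndarray] = field(default_factory=dict)

    def haplotype_at(self, chrom: str, positions) -> np.ndarray:
        """Transmitted haplotype index at each query position."""
        xo = self.crossovers.get(chrom, np.empty(0))
        n_below = np.searchsorted(xo, np.asarray(positions), side="left")
        return (self.start_haplotype[chrom] + n_below) % 2
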