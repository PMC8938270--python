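"""Readers and writers for every external format the pipeline touches.

Dialects (all plain text):

* **VCF 4.2** — parents, optional born child, reconstructed embryos. Only
  biallelic SNVs are loaded; multiallelic and non-SNV records are dropped
  with a counted warning. Phase (``|``) is preserved when present. No-call
  is ``./.`` and maps to the MISSING code, never to hom-ref.
* **Genetic map** — 3-column whitespace table ``chrom pos cM`` (the layout of
  public sex-specific map distributions), optional header line.
* **PRS scoring file** — tab-separated with a header naming at least
  ``chr_name``/``chrom``, ``chr_position``/``pos``, ``effect_allele`` and
  ``effect_weight`` (the PGS-Catalog convention); ``#`` lines are comments.
* **Allele-frequency table** — 2 columns: ``chrom:pos`` key and AF in [0,1].
* **Array-call table** — tab-separated ``chrom pos call`` with calls
  ``0/0 0/1 1/1 ./.``; aneuploid chromosomes listed in a ``#aneuploid=``
  header comment.
* **Segments BED** — 0-based half-open intervals
  ``chrom start end parent haplotype mean_posterior bp_lo bp_hi``.

In-memory coordinates are 1-based inclusive; only the BED output is 0-based.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    MISSING,
    GeneticMap,
    PhasedParentalGenome,
    SiteTable,
    normalize_chrom,
)
from .embryo_reconstruction import ReconstructedGenome, Segment, TransmissionPath
from .errors import FormatError, MapError, MissingSampleError

logger = logging.getLogger(__name__)

_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
_STR_GT = {v: k for k, v in _GT_STR.items()}
_STR_GT["1/0"] = 1


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


@dataclass
class VcfData:
    """Biallelic-SNV genotype matrix parsed from a VCF."""

    sites: SiteTable
    genotypes: dict[str, np.ndarray]  # sample -> codes
    haplotypes: dict[str, np.ndarray]  # sample -> (2, n) alleles, -1 where unphased
    phased: dict[str, np.ndarray]  # sample -> bool mask
    n_dropped_multiallelic: int = 0
    n_dropped_non_snv: int = 0

    def phased_genome(self, sample: str) -> PhasedParentalGenome:
        """Interpret one fully phased sample as a parental genome."""
        haps = self.haplotypes[sample].copy()
        unphased = ~self.phased[sample]
        gt = self.genotypes[sample]
        # unphased hom sites are trivially phased; unphased hets get 0.5 confidence
        haps[:, unphased & (gt == 0)] = 0
        haps[:, unphased & (gt == 2)] = 1
        haps[0, unphased & (gt == 1)] = 0
        haps[1, unphased & (gt == 1)] = 1
        conf = np.where(unphased & (gt == 1), 0.5, 1.0)
        return PhasedParentalGenome(
            sites=self.sites, haplotypes=haps, phase_confidence=conf, sample_name=sample
        )


def read_vcf(path: str | Path, sample_names: list[str] | None = None) -> VcfData:
    """Load biallelic SNV genotypes for the requested samples.

    Multiallelic and non-SNV records are excluded (with counts logged);
    a requested sample missing from the header is fatal.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if sample_names is None:
        sample_names = samples
    for s in sample_names:
        if s not in samples:
            raise MissingSampleError(f"sample {s!r} not in VCF {path}")
    cols = [samples.index(s) for s in sample_names]

    chroms, poss, refs, alts, ids = [], [], [], [], []
    gts = {s: [] for s in sample_names}
    haps = {s: [] for s in sample_names}
    phased = {s: [] for s in sample_names}
    n_multi = n_non_snv = 0
    last: dict[str, int] = {}
    for rec_no, v in enumerate(vcf, start=1):
        try:
            if len(v.ALT) != 1:
                n_multi += 1
                continue
            if len(v.REF) != 1 or len(v.ALT[0]) != 1:
                n_non_snv += 1
                continue
            chrom = normalize_chrom(v.CHROM)
            if last.get(chrom, 0) >= v.POS:
                raise FormatError(
                    f"{path}: record {rec_no}: positions not strictly increasing on {chrom}"
                )
            last[chrom] = v.POS
            g = v.genotypes  # [a0, a1, phased] per sample
            for s, c in zip(sample_names, cols):
                a0, a1, ph = g[c][0], g[c][1], bool(g[c][2])
                if a0 < 0 or a1 < 0:
                    gts[s].append(MISSING)
                    haps[s].append((-1, -1))
                    phased[s].append(False)
                else:
                    gts[s].append(a0 + a1)
                    haps[s].append((a0, a1) if ph else (-1, -1))
                    phased[s].append(ph)
            chroms.append(chrom)
            poss.append(v.POS)
            refs.append(v.REF)
            alts.append(v.ALT[0])
            ids.append(v.ID or f"site_{chrom}_{v.POS}")
        except FormatError:
            raise
        except Exception as exc:  # malformed record
            raise FormatError(f"{path}: malformed record {rec_no}: {exc}") from exc
    if n_multi:
        logger.warning("%s: dropped %d multiallelic records", path, n_multi)
    if n_non_snv:
        logger.warning("%s: dropped %d non-SNV records", path, n_non_snv)
    sites = SiteTable.from_arrays(chroms, poss, refs, alts, ids)
    return VcfData(
        sites=sites,
        genotypes={s: np.array(gts[s], dtype=np.int8) for s in sample_names},
        haplotypes={s: np.array(haps[s], dtype=np.int8).reshape(-1, 2).T for s in sample_names},
        phased={s: np.array(phased[s], dtype=bool) for s in sample_names},
        n_dropped_multiallelic=n_multi,
        n_dropped_non_snv=n_non_snv,
    )


_VCF_HEADER = """##fileformat=VCFv4.2
##source=wgr
{extra}{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}
"""


def _contig_lines(sites: SiteTable) -> str:
    return "".join(f"##contig=<ID={c}>\n" for c in sites.chromosomes())


def write_genotype_vcf(
    path: str | Path,
    sites: SiteTable,
    genotypes: dict[str, np.ndarray],
    haplotypes: dict[str, np.ndarray] | None = None,
    phase_confidence: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a genotype (optionally phased) VCF. Samples with an entry in
    ``haplotypes`` are written phased (``a|b``); a ``PC`` FORMAT field carries
    per-site phase confidence when given."""
    haplotypes = haplotypes or {}
    phase_confidence = phase_confidence or {}
    names = list(genotypes)
    fmt = "GT" + (":PC" if phase_confidence else "")
    extra = (
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        + (
            '##FORMAT=<ID=PC,Number=1,Type=Float,Description="Phase confidence">\n'
            if phase_confidence
            else ""
        )
    )
    with open(path, "w") as fh:
        fh.write(
            _VCF_HEADER.format(
                extra=extra, contigs=_contig_lines(sites), samples="\t".join(names)
            )
        )
        df = sites.frame
        for i in range(len(sites)):
            fields = []
            for s in names:
                if s in haplotypes and haplotypes[s][0, i] >= 0:
                    gt = f"{haplotypes[s][0, i]}|{haplotypes[s][1, i]}"
                else:
                    gt = _GT_STR[int(genotypes[s][i])]
                if phase_confidence:
                    pc = phase_confidence.get(s)
                    gt += ":" + (str(float(pc[i])) if pc is not None else ".")
                fields.append(gt)
            fh.write(
                f"{df.chrom.iat[i]}\t{df.pos.iat[i]}\t{df.site_id.iat[i]}\t"
                f"{df.ref.iat[i]}\t{df.alt.iat[i]}\t.\t.\t.\t{fmt}\t" + "\t".join(fields) + "\n"
            )


def write_phased_vcf(path: str | Path, genome: PhasedParentalGenome) -> None:
    write_genotype_vcf(
        path,
        genome.sites,
        genotypes={genome.sample_name: genome.genotypes},
        haplotypes={genome.sample_name: genome.haplotypes},
        phase_confidence={genome.sample_name: genome.phase_confidence},
    )


def write_reconstruction(path: str | Path, recon: ReconstructedGenome) -> None:
    """Write a reconstructed embryo genome as VCF: phased GT (maternal|paternal
    transmitted allele), CF = confidence, MH/PH = transmitted haplotype index."""
    extra = (
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype (maternal|paternal)">\n'
        '##FORMAT=<ID=CF,Number=1,Type=Float,Description="Reconstruction confidence">\n'
        '##FORMAT=<ID=MH,Number=1,Type=Integer,Description="Transmitted maternal haplotype">\n'
        '##FORMAT=<ID=PH,Number=1,Type=Integer,Description="Transmitted paternal haplotype">\n'
    )
    df = recon.sites.frame
    with open(path, "w") as fh:
        fh.write(
            _VCF_HEADER.format(
                extra=extra, contigs=_contig_lines(recon.sites), samples=recon.name
            )
        )
        for i in range(len(recon.sites)):
            if recon.maternal_allele[i] < 0 or recon.paternal_allele[i] < 0:
                sample = "./.:.:.:."
            else:
                sample = (
                    f"{recon.maternal_allele[i]}|{recon.paternal_allele[i]}:"
                    f"{float(recon.confidence[i])}:"
                    f"{int(recon.maternal_hap[i])}:{int(recon.paternal_hap[i])}"
                )
            fh.write(
                f"{df.chrom.iat[i]}\t{df.pos.iat[i]}\t{df.site_id.iat[i]}\t"
                f"{df.ref.iat[i]}\t{df.alt.iat[i]}\t.\t.\t.\tGT:CF:MH:PH\t{sample}\n"
            )


def read_reconstruction(path: str | Path, sample: str | None = None) -> ReconstructedGenome:
    vcf = VCF(str(path))
    name = sample or vcf.samples[0]
    col = vcf.samples.index(name)
    chroms, poss, refs, alts, ids = [], [], [], [], []
    mals, pals, confs, mhs, phs = [], [], [], [], []
    for v in vcf:
        chroms.append(normalize_chrom(v.CHROM))
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        ids.append(v.ID or f"site_{v.CHROM}_{v.POS}")
        g = v.genotypes[col]
        if g[0] < 0:
            mals.append(-1)
            pals.append(-1)
            confs.append(0.0)
            mhs.append(-1)
            phs.append(-1)
        else:
            mals.append(g[0])  # maternal|paternal orientation by convention
            pals.append(g[1])
            confs.append(float(v.format("CF")[col][0]))
            mhs.append(int(v.format("MH")[col][0]))
            phs.append(int(v.format("PH")[col][0]))
    return ReconstructedGenome(
        sites=SiteTable.from_arrays(chroms, poss, refs, alts, ids),
        maternal_allele=np.array(mals, dtype=np.int8),
        paternal_allele=np.array(pals, dtype=np.int8),
        confidence=np.array(confs),
        maternal_hap=np.array(mhs, dtype=np.int8),
        paternal_hap=np.array(phs, dtype=np.int8),
        name=name,
    )


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Parse a 3-column ``chrom pos cM`` whitespace table (optional header)."""
    anchors: dict[str, tuple[list, list]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                pos, cm = int(float(parts[1])), float(parts[2])
            except (ValueError, IndexError):
                if line_no == 1:  # header
                    continue
                raise FormatError(f"{path}:{line_no}: malformed map row {line!r}")
            chrom = normalize_chrom(parts[0])
            anchors.setdefault(chrom, ([], []))
            anchors[chrom][0].append(pos)
            anchors[chrom][1].append(cm)
    try:
        return GeneticMap(
            {c: (np.array(p, dtype=np.int64), np.array(m)) for c, (p, m) in anchors.items()}
        )
    except MapError as exc:
        raise MapError(f"{path}: {exc}") from exc


def write_genetic_map(path: str | Path, gmap: GeneticMap) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcM\n")
        for chrom, (pos, cm) in gmap.anchors.items():
            for p, c in zip(pos, cm):
                fh.write(f"{chrom}\t{p}\t{float(c)}\n")


# ---------------------------------------------------------------------------
# PRS scoring files (PGS-Catalog convention)
# ---------------------------------------------------------------------------


@dataclass
class PrsModel:
    """A published polygenic score: weighted sum of effect-allele dosages.

    ``variants`` aligns four arrays: chrom, pos, effect_allele and weight
    (log-odds units). ``site_rows`` maps each variant to its row in the
    analysis SiteTable (-1 = unpredictable: the variant has no genotype data
    and is scored via its population allele frequency instead).
    ``beta_per_sd`` is the log OR per SD of the standardized score.
    """

    condition_name: str
    chrom: np.ndarray
    pos: np.ndarray
    effect_allele: np.ndarray
    weight: np.ndarray
    site_rows: np.ndarray = None  # type: ignore[assignment]
    effect_is_alt: np.ndarray = None  # type: ignore[assignment]
    beta_per_sd: float = float("nan")
    population_sd: float = 1.0

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        if not np.all(np.isfinite(self.weight)):
            raise FormatError("non-finite PRS weight")
        if self.site_rows is None:
            self.site_rows = np.full(len(self.weight), -1, dtype=np.int64)
        if self.effect_is_alt is None:
            self.effect_is_alt = np.ones(len(self.weight), dtype=bool)

    def __len__(self) -> int:
        return len(self.weight)

    @property
    def n_unpredictable(self) -> int:
        return int(np.sum(self.site_rows < 0))

    def attach_sites(self, sites: SiteTable) -> "PrsModel":
        """Map variants onto the analysis site table and normalize effect-allele
        orientation (effect_allele may be either ref or alt in published files)."""
        own = SiteTable.from_arrays(
            self.chrom, self.pos, ["N"] * len(self), ["N"] * len(self)
        )
        rows = own.index_in(sites)
        is_alt = np.ones(len(self), dtype=bool)
        for i, r in enumerate(rows):
            if r < 0:
                continue
            ref = sites.frame.ref.iat[r]
            alt = sites.frame.alt.iat[r]
            ea = self.effect_allele[i]
            if ea == alt:
                is_alt[i] = True
            elif ea == ref:
                is_alt[i] = False
            else:
                rows[i] = -1  # allele mismatch: treat as unpredictable
        self.site_rows = rows
        self.effect_is_alt = is_alt
        return self


_PGS_COLMAP = {
    "chr_name": "chrom",
    "chr": "chrom",
    "chrom": "chrom",
    "chr_position": "pos",
    "pos": "pos",
    "position": "pos",
    "effect_allele": "effect_allele",
    "effect_weight": "effect_weight",
}


def read_prs_model(
    path: str | Path,
    condition_name: str | None = None,
    sites: SiteTable | None = None,
    beta_per_sd: float = float("nan"),
) -> PrsModel:
    """Load a PGS-Catalog-style scoring file. Duplicate (chrom, pos) rows are
    fatal; variants absent from ``sites`` are flagged unpredictable, not dropped."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df = df.rename(columns={c: _PGS_COLMAP[c] for c in df.columns if c in _PGS_COLMAP})
    for col in ("chrom", "pos", "effect_allele", "effect_weight"):
        if col not in df.columns:
            raise FormatError(f"{path}: scoring file lacks column {col!r}")
    if not pd.api.types.is_numeric_dtype(df["effect_weight"]):
        raise FormatError(f"{path}: non-numeric effect_weight")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise FormatError(f"{path}: duplicate (chrom, pos) rows in scoring file")
    model = PrsModel(
        condition_name=condition_name or Path(path).stem,
        chrom=np.array([normalize_chrom(c) for c in df["chrom"]]),
        pos=df["pos"].to_numpy(dtype=np.int64),
        effect_allele=df["effect_allele"].astype(str).to_numpy(),
        weight=df["effect_weight"].to_numpy(dtype=float),
        beta_per_sd=beta_per_sd,
    )
    if sites is not None:
        model.attach_sites(sites)
    return model


def write_prs_model(path: str | Path, model: PrsModel) -> None:
    with open(path, "w") as fh:
        fh.write("chr_name\tchr_position\teffect_allele\teffect_weight\n")
        for c, p, a, w in zip(model.chrom, model.pos, model.effect_allele, model.weight):
            fh.write(f"{c}\t{p}\t{a}\t{float(w)}\n")


# ---------------------------------------------------------------------------
# Allele-frequency table
# ---------------------------------------------------------------------------


@dataclass
class AlleleFrequencyTable:
    """Population alternate-allele frequencies keyed by (chrom, pos).
    Absent sites are queryable and return None ("absent" = rare by rule)."""

    frequencies: dict[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, af in self.frequencies.items():
            if not (0.0 <= af <= 1.0):
                raise FormatError(f"allele frequency out of [0,1] at {key}: {af}")

    def get(self, chrom: str, pos: int) -> float | None:
        return self.frequencies.get((normalize_chrom(chrom), int(pos)))

    def lookup(self, chroms, poss) -> np.ndarray:
        """Vectorized lookup; absent sites yield NaN."""
        return np.array(
            [
                self.frequencies.get((normalize_chrom(c), int(p)), math.nan)
                for c, p in zip(chroms, poss)
            ]
        )


def read_af_table(path: str | Path) -> AlleleFrequencyTable:
    """2-column table: ``chrom:pos`` and AF."""
    freqs = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0] == "site":
                continue
            try:
                key, af = parts[0], float(parts[1])
                chrom, pos = key.rsplit(":", 1)
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{line_no}: malformed AF row {line!r}")
            if not (0.0 <= af <= 1.0):
                raise FormatError(f"{path}:{line_no}: AF out of [0,1]: {af}")
            freqs[(normalize_chrom(chrom), int(pos))] = af
    return AlleleFrequencyTable(freqs)


def write_af_table(path: str | Path, table: AlleleFrequencyTable) -> None:
    with open(path, "w") as fh:
        fh.write("site\taf\n")
        for (chrom, pos), af in table.frequencies.items():
            fh.write(f"{chrom}:{pos}\t{float(af)}\n")


# ---------------------------------------------------------------------------
# Array-call tables
# ---------------------------------------------------------------------------


def write_array_calls(path: str | Path, obs) -> None:
    from .core import EmbryoArrayObservation  # noqa: F401 (type only)

    with open(path, "w") as fh:
        if obs.aneuploid_chromosomes:
            fh.write("#aneuploid=" + ",".join(sorted(obs.aneuploid_chromosomes)) + "\n")
        fh.write("chrom\tpos\tcall\n")
        df = obs.sites.frame
        for i in range(len(obs.sites)):
            fh.write(f"{df.chrom.iat[i]}\t{df.pos.iat[i]}\t{_GT_STR[int(obs.calls[i])]}\n")


def read_array_calls(path: str | Path, sites: SiteTable | None = None, name: str = "embryo"):
    """Read an array-call table. If ``sites`` is given (the array manifest with
    ref/alt alleles), rows are matched against it; otherwise placeholder
    alleles are used."""
    from .core import EmbryoArrayObservation

    aneuploid: set[str] = set()
    chroms, poss, calls = [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if line.startswith("#aneuploid="):
                aneuploid = {c for c in line.strip().split("=", 1)[1].split(",") if c}
                continue
            parts = line.split()
            if not parts or parts[0].startswith("#") or parts[0] == "chrom":
                continue
            try:
                chroms.append(normalize_chrom(parts[0]))
                poss.append(int(parts[1]))
                calls.append(_STR_GT[parts[2]])
            except (KeyError, ValueError, IndexError):
                raise FormatError(f"{path}:{line_no}: malformed array-call row {line!r}")
    table = SiteTable.from_arrays(chroms, poss, ["N"] * len(poss), ["N"] * len(poss))
    if sites is not None:
        rows = table.index_in(sites)
        if np.any(rows < 0):
            raise FormatError(f"{path}: array site absent from manifest")
        table = sites.subset(rows)
    return EmbryoArrayObservation(
        sites=table,
        calls=np.array(calls, dtype=np.int8),
        aneuploid_chromosomes=frozenset(aneuploid),
        name=name,
    )


# ---------------------------------------------------------------------------
# Segments BED
# ---------------------------------------------------------------------------


def write_segments(path: str | Path, tpath: TransmissionPath) -> None:
    """Write transmission segments as BED (0-based half-open). Columns:
    chrom start end parent haplotype mean_posterior bp_lo bp_hi."""
    for chrom in tpath.chromosomes():
        for parent in ("mother", "father"):
            segs = tpath.chromosome_segments(chrom, parent)
            for a, b in zip(segs, segs[1:]):
                if b.start <= a.end:
                    raise FormatError(
                        f"overlapping segments on {chrom} ({parent}): "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )
    with open(path, "w") as fh:
        for s in tpath.segments:
            fh.write(
                f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.parent}\t{s.haplotype + 1}\t"
                f"{float(s.mean_posterior)}\t{s.bp_lo}\t{s.bp_hi}\n"
            )


def read_segments(path: str | Path) -> TransmissionPath:
    segments = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                segments.append(
                    Segment(
                        chrom=normalize_chrom(parts[0]),
                        start=int(parts[1]) + 1,
                        end=int(parts[2]),
                        parent=parts[3],
                        haplotype=int(parts[4]) - 1,
                        mean_posterior=float(parts[5]),
                        bp_lo=int(parts[6]),
                        bp_hi=int(parts[7]),
                    )
                )
            except (ValueError, IndexError):
                raise FormatError(f"{path}:{line_no}: malformed segment row {line!r}")
    return TransmissionPath(segments=segments)
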