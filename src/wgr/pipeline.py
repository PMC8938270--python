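"""End-to-end orchestration: simulate -> phase -> reconstruct -> score ->
report -> simulate-embryos -> evaluate, as composable file-based stages.

Each stage reads and writes the package's text dialects, so running the
stages separately over a run directory produces the same outputs as
:func:`run_end_to_end`, which simply calls them in order. A manifest records
the configuration, its hash and per-stage counts; two runs with the same
configuration and seed produce byte-identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import NOISE_PRESETS, PhasedParentalGenome
from .embryo_reconstruction import reconstruct_embryo
from .errors import WgrError
from .evaluation import genotype_accuracy, prs_concordance
from .io_formats import (
    read_af_table,
    read_array_calls,
    read_genetic_map,
    read_prs_model,
    read_reconstruction,
    read_vcf,
    write_af_table,
    write_array_calls,
    write_genetic_map,
    write_genotype_vcf,
    write_phased_vcf,
    write_prs_model,
    write_reconstruction,
    write_segments,
)
from .parental_phasing import merge_with_truth_phase, phase_parent
from .prs_engine import (
    PcModel,
    center_and_standardize,
    fit_centering,
    fit_pc_model,
    load_pc_model,
    project_pcs,
    raw_prs,
    save_pc_model,
)
from .risk_integration import (
    ConditionBetas,
    MonogenicPanel,
    PanelVariant,
    assess_embryo,
    call_carriers,
    family_report,
    read_panel,
    write_panel,
)
from .embryo_simulation import cohort_summary, simulate_prs_cohort
from .synthetic_cohort import simulate_family, uniform_genetic_map

logger = logging.getLogger(__name__)

# demo-scale carrier-stratified betas: per-SD ORs 1.3 (carriers) / 1.6
# (noncarriers) as published for the breast-cancer model; the carrier main
# effect is NOT published and this value is a synthetic placeholder.
DEMO_BETAS = ConditionBetas(
    alpha_carrier=float(np.log(2.0)),  # synthetic placeholder
    beta_carrier=float(np.log(1.3)),
    beta_noncarrier=float(np.log(1.6)),
)


@dataclass
class RunConfig:
    """Everything a reproducible run needs. ``seed`` drives all randomness."""

    seed: int
    noise_preset: str = "day5"
    n_embryos: int = 6
    n_sites: int = 2000
    n_chromosomes: int = 2
    n_array_sites: int | None = None
    n_prs_variants: int = 40
    n_pc_panel_sites: int = 200
    n_reference_individuals: int = 300
    n_pcs: int = 4
    n_simulation_replicates: int = 500
    population: str | None = None
    aneuploid: dict[int, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        if self.noise_preset not in NOISE_PRESETS:
            raise WgrError(f"unknown noise preset {self.noise_preset!r}")
        if self.n_embryos < 1 or self.n_sites < 10:
            raise WgrError("n_embryos >= 1 and n_sites >= 10 required")
        if self.n_pcs < 4:
            raise WgrError("at least 4 PCs are required for centering")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["aneuploid"] = {int(k): list(v) for k, v in (raw.get("aneuploid") or {}).items()}
        return RunConfig(**raw)

    def digest(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Stages (file-based)
# ---------------------------------------------------------------------------


def stage_simulate(config: RunConfig, outdir: Path) -> dict:
    """Generate the synthetic family plus scoring assets and write every
    input file downstream stages consume."""
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    family = simulate_family(
        n_embryos=config.n_embryos,
        noise=NOISE_PRESETS[config.noise_preset],
        seed=int(rng.integers(2**31)),
        n_sites=config.n_sites,
        n_chromosomes=config.n_chromosomes,
        n_array_sites=config.n_array_sites,
        aneuploid_spec=config.aneuploid,
    )
    write_genotype_vcf(
        outdir / "parents.vcf",
        family.sites,
        genotypes={"mother": family.mother.genotypes, "father": family.father.genotypes},
        haplotypes={"mother": family.mother.haplotypes, "father": family.father.haplotypes},
    )
    write_genotype_vcf(
        outdir / "truth.vcf",
        family.sites,
        genotypes={e.name: e.true_genotypes for e in family.embryos},
    )
    for e in family.embryos:
        write_array_calls(outdir / f"{e.name}.array.tsv", e.observation)
    write_genetic_map(outdir / "map.tsv", family.genetic_map)
    write_af_table(outdir / "af.tsv", family.allele_frequencies)

    # synthetic PRS model over a random subset of family sites
    model_rows = np.sort(rng.choice(config.n_sites, size=config.n_prs_variants, replace=False))
    model_df = family.sites.frame.iloc[model_rows]
    from .io_formats import PrsModel

    model = PrsModel(
        condition_name="demo_condition",
        chrom=model_df["chrom"].to_numpy(),
        pos=model_df["pos"].to_numpy(),
        effect_allele=model_df["alt"].to_numpy(),
        weight=rng.normal(0.0, 0.15, size=config.n_prs_variants),
        beta_per_sd=DEMO_BETAS.beta_noncarrier,
    )
    write_prs_model(outdir / "prs_model.tsv", model)

    # reference panel for PCs: two synthetic populations split on allele
    # frequency, the family drawn from the first
    panel_rows = np.sort(rng.choice(config.n_sites, size=config.n_pc_panel_sites, replace=False))
    panel_sites = family.sites.subset(panel_rows)
    afs = family.allele_frequencies.lookup(panel_sites.chrom, panel_sites.pos)
    n_ref = config.n_reference_individuals
    pops = ["POP1"] * (n_ref // 2) + ["POP2"] * (n_ref - n_ref // 2)
    af_by_pop = {"POP1": afs, "POP2": np.clip(afs + rng.normal(0, 0.15, len(afs)), 0.02, 0.98)}
    panel_g = np.stack(
        [
            (rng.random(len(afs)) < af_by_pop[p]).astype(np.int8)
            + (rng.random(len(afs)) < af_by_pop[p]).astype(np.int8)
            for p in pops
        ]
    )
    pc_model = fit_pc_model(panel_g, panel_sites, populations=pops, n_components=config.n_pcs)
    # centering on the panel (all controls) + per-population SDs of centered score
    model.attach_sites(panel_sites)
    raw_panel = np.array(
        [raw_prs(panel_g[i], model, family.allele_frequencies).raw_score for i in range(n_ref)]
    )
    pcs_panel = np.stack([project_pcs(panel_g[i], pc_model) for i in range(n_ref)])
    pc_model.centering_coefficients = fit_centering(raw_panel, pcs_panel)
    from .prs_engine import center_score

    centered = center_score(raw_panel, pcs_panel, pc_model.centering_coefficients)
    pop_arr = np.asarray(pops)
    pc_model.population_sds = {
        p: float(np.std(centered[pop_arr == p], ddof=1)) for p in ("POP1", "POP2")
    }
    save_pc_model(outdir / "pc_model.json", pc_model)

    # synthetic pathogenic panel: the rarest maternal heterozygous site
    het_rows = np.flatnonzero(family.mother.het_mask())
    het_afs = family.allele_frequencies.lookup(
        family.sites.chrom[het_rows], family.sites.pos[het_rows]
    )
    v_row = int(het_rows[np.argmin(het_afs)])
    panel = MonogenicPanel(
        variants=[
            PanelVariant(
                gene="GENE_SYN",
                chrom=str(family.sites.chrom[v_row]),
                pos=int(family.sites.pos[v_row]),
                ref=str(family.sites.frame.ref.iat[v_row]),
                alt=str(family.sites.frame.alt.iat[v_row]),
                condition="demo_condition",
            )
        ],
        betas={"demo_condition": DEMO_BETAS},
    )
    write_panel(outdir / "panel.tsv", panel)
    return {
        "n_sites": config.n_sites,
        "n_array_sites": len(family.array_rows),
        "n_embryos": config.n_embryos,
        "n_prs_variants": config.n_prs_variants,
        "panel_variant_row": v_row,
    }


def _load_parents(outdir: Path) -> tuple[PhasedParentalGenome, PhasedParentalGenome]:
    data = read_vcf(outdir / "parents.vcf", ["mother", "father"])
    return data.phased_genome("mother"), data.phased_genome("father")


def _load_observations(outdir: Path, n_embryos: int, sites):
    return [
        read_array_calls(outdir / f"embryo_{k}.array.tsv", sites=sites, name=f"embryo_{k}")
        for k in range(n_embryos)
    ]


def stage_phase(config: RunConfig, outdir: Path) -> dict:
    """Parental-support phasing of both parents from the embryo observations,
    anchored to the external (truth) phase of the parents' VCF."""
    mother, father = _load_parents(outdir)
    gmap = read_genetic_map(outdir / "map.tsv")
    observations = _load_observations(outdir, config.n_embryos, mother.sites)
    profile = NOISE_PRESETS[config.noise_preset]
    array_rows = observations[0].sites.index_in(mother.sites)

    counts = {}
    for name, parent, other in (("mother", mother, father), ("father", father, mother)):
        scaffold = phase_parent(
            parent.genotypes[array_rows],
            other.genotypes[array_rows],
            observations,
            gmap,
            profile,
            parent_name=name,
        )
        merged = merge_with_truth_phase(scaffold, parent)
        write_phased_vcf(outdir / f"{name}.phased.vcf", merged)
        counts[f"{name}_scaffold_sites"] = int(len(scaffold))
    return counts


def stage_reconstruct(config: RunConfig, outdir: Path) -> dict:
    profile = NOISE_PRESETS[config.noise_preset]
    gmap = read_genetic_map(outdir / "map.tsv")
    mother = read_vcf(outdir / "mother.phased.vcf").phased_genome("mother")
    father = read_vcf(outdir / "father.phased.vcf").phased_genome("father")
    observations = _load_observations(outdir, config.n_embryos, mother.sites)
    n_segments = 0
    for obs in observations:
        recon, path = reconstruct_embryo(obs, mother, father, gmap, profile)
        write_reconstruction(outdir / f"{obs.name}.recon.vcf", recon)
        write_segments(outdir / f"{obs.name}.segments.bed", path)
        n_segments += len(path.segments)
    return {"n_segments": n_segments, "n_reconstructed": len(observations)}


def stage_score(config: RunConfig, outdir: Path) -> dict:
    """Raw -> centered -> standardized PRS and OR for every embryo, the born
    child truth genome and both parents."""
    af = read_af_table(outdir / "af.tsv")
    pc_model = load_pc_model(outdir / "pc_model.json")
    mother, father = _load_parents(outdir)
    model = read_prs_model(
        outdir / "prs_model.tsv",
        condition_name="demo_condition",
        sites=mother.sites,
        beta_per_sd=DEMO_BETAS.beta_noncarrier,
    )
    panel_rows = pc_model.panel_sites.index_in(mother.sites)
    truth = read_vcf(outdir / "truth.vcf")

    def score(genotypes: np.ndarray, label: str) -> dict:
        res = raw_prs(genotypes, model, af)
        pcs = project_pcs(genotypes[panel_rows], pc_model)
        centered, standardized, pop = center_and_standardize(
            res.raw_score, pcs, pc_model, config.population
        )
        return {
            "label": label,
            "raw": res.raw_score,
            "centered": centered,
            "standardized": standardized,
            "population": pop,
            "odds_ratio": float(np.exp(model.beta_per_sd * standardized)),
            "n_sites_used": res.n_sites_used,
            "n_sites_af_adjusted": res.n_sites_af_adjusted,
        }

    scores = {}
    for k in range(config.n_embryos):
        recon = read_reconstruction(outdir / f"embryo_{k}.recon.vcf")
        scores[f"embryo_{k}"] = score(recon.genotypes, f"embryo_{k}")
        scores[f"embryo_{k}_truth"] = score(truth.genotypes[f"embryo_{k}"], f"embryo_{k}_truth")
    scores["mother"] = score(mother.genotypes, "mother")
    scores["father"] = score(father.genotypes, "father")
    with open(outdir / "scores.json", "w") as fh:
        json.dump(scores, fh, sort_keys=True)
    return {"n_scored": len(scores)}


def stage_report(config: RunConfig, outdir: Path) -> dict:
    panel = read_panel(outdir / "panel.tsv")
    with open(outdir / "scores.json") as fh:
        scores = json.load(fh)
    risks = []
    for k in range(config.n_embryos):
        recon = read_reconstruction(outdir / f"embryo_{k}.recon.vcf")
        calls = call_carriers(recon, panel)
        risks.append(
            assess_embryo(
                f"embryo_{k}",
                scores[f"embryo_{k}"]["standardized"],
                calls,
                panel,
                "demo_condition",
            )
        )
    report = family_report(risks)
    report.table.to_csv(outdir / "report.tsv", sep="\t", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump(
            {
                "fold_difference": report.fold_difference,
                "low_prs_carriers": report.low_prs_carriers,
            },
            fh,
            sort_keys=True,
        )
    fold = report.fold_difference["demo_condition"]
    logger.info("combined-OR fold difference across embryos: %.2f", fold)
    n_carriers = int((report.table.carrier_status == "carrier").sum())
    return {"fold_difference": fold, "n_carriers": n_carriers}


def stage_simulate_embryos(config: RunConfig, outdir: Path) -> dict:
    mother = read_vcf(outdir / "mother.phased.vcf").phased_genome("mother")
    father = read_vcf(outdir / "father.phased.vcf").phased_genome("father")
    gmap = read_genetic_map(outdir / "map.tsv")
    af = read_af_table(outdir / "af.tsv")
    model = read_prs_model(
        outdir / "prs_model.tsv", condition_name="demo_condition", sites=mother.sites,
        beta_per_sd=DEMO_BETAS.beta_noncarrier,
    )
    panel = read_panel(outdir / "panel.tsv")
    cohort = simulate_prs_cohort(
        mother, father, model,
        seed=config.seed + 1,
        mode="linkage",
        n_replicates=config.n_simulation_replicates,
        genetic_map=gmap,
        af_table=af,
        panel=panel,
    )
    with open(outdir / "scores.json") as fh:
        scores = json.load(fh)
    summary = cohort_summary(cohort, scores["mother"]["raw"], scores["father"]["raw"])
    np.savetxt(outdir / "simulated_prs.tsv", cohort.raw_scores, header="raw_prs", comments="")
    with open(outdir / "simulation_summary.json", "w") as fh:
        json.dump(
            {
                "mode": summary.mode,
                "n_replicates": summary.n_replicates,
                "mean": summary.mean,
                "sd": summary.sd,
                "quantiles": summary.quantiles,
                "midparent_mean": summary.midparent_mean,
                "carrier_fraction": summary.carrier_fraction,
            },
            fh,
            sort_keys=True,
        )
    return {"n_replicates": summary.n_replicates}


def stage_evaluate(config: RunConfig, outdir: Path) -> dict:
    truth = read_vcf(outdir / "truth.vcf")
    with open(outdir / "scores.json") as fh:
        scores = json.load(fh)
    per_embryo = {}
    embryo_scores, truth_scores = [], []
    for k in range(config.n_embryos):
        recon = read_reconstruction(outdir / f"embryo_{k}.recon.vcf")
        report = genotype_accuracy(recon, truth.genotypes[f"embryo_{k}"])
        per_embryo[f"embryo_{k}"] = {
            "genome_wide_accuracy": report.genome_wide_accuracy,
            "het_accuracy": report.by_genotype["het"],
            "hom_accuracy": report.by_genotype["hom"],
            "n_sites_compared": report.n_sites_compared,
        }
        embryo_scores.append(scores[f"embryo_{k}"]["centered"])
        truth_scores.append(scores[f"embryo_{k}_truth"]["centered"])
        logger.info(
            "%s: genome-wide accuracy %.2f%% (het %.2f%%, hom %.2f%%)",
            f"embryo_{k}", report.genome_wide_accuracy,
            report.by_genotype["het"], report.by_genotype["hom"],
        )
    result = {"per_embryo": per_embryo}
    if config.n_embryos >= 3:
        result["prs_r2"] = prs_concordance(np.array(embryo_scores), np.array(truth_scores))
    with open(outdir / "evaluation.json", "w") as fh:
        json.dump(result, fh, sort_keys=True)
    mean_acc = float(
        np.mean([v["genome_wide_accuracy"] for v in per_embryo.values()])
    )
    return {"mean_genome_wide_accuracy": mean_acc, "prs_r2": result.get("prs_r2")}


STAGES = (
    ("simulate", stage_simulate),
    ("phase", stage_phase),
    ("reconstruct", stage_reconstruct),
    ("score", stage_score),
    ("report", stage_report),
    ("simulate_embryos", stage_simulate_embryos),
    ("evaluate", stage_evaluate),
)


def run_end_to_end(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages into ``outdir`` and write a manifest. Any stage error
    aborts with the stage name attached."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_sha256": config.digest(),
        "stages": {},
    }
    for name, fn in STAGES:
        logger.info("stage: %s", name)
        try:
            manifest["stages"][name] = fn(config, outdir)
        except Exception as exc:
            raise WgrError(f"stage {name!r} failed: {exc}") from exc
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, sort_keys=True, indent=1)
    return manifest
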