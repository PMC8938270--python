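"""Polygenic risk scoring: raw weighted sums, ancestry-PC centering,
per-population standardization, odds-ratio conversion and model QC.

The score is a weighted sum of effect-allele dosages, PRS = sum_i w_i d_i.
Sites where the embryo genome provides no prediction contribute their
population expectation w_i * 2 * AF_i instead of being dropped. The raw
score is centered by subtracting the value predicted from an ordinary
least-squares regression of PRS on the first four ancestry principal
components (fit in control individuals), then divided by the standard
deviation of the centered score in the reference population most closely
related to the individual, and finally converted to an odds ratio as
OR = exp(beta * PRS) with beta the log OR per standard deviation.

Model QC follows the published gates: area under the ROC curve >= 0.6,
odds ratios increasing across score deciles, and a top-versus-bottom decile
odds ratio >= 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.metrics import roc_auc_score

from .core import MISSING, SiteTable
from .errors import CoverageError, DegenerateInputError, WgrError
from .io_formats import AlleleFrequencyTable, PrsModel

N_CENTERING_PCS = 4  # centering regresses PRS on the first four PC scores


# ---------------------------------------------------------------------------
# Raw score
# ---------------------------------------------------------------------------


@dataclass
class PrsResult:
    """One genome's score for one condition, at each stage of the transform."""

    condition_name: str
    raw_score: float
    n_sites_used: int
    n_sites_af_adjusted: int
    n_sites_skipped: int = 0
    centered_score: float = float("nan")
    standardized_score: float = float("nan")
    odds_ratio: float = float("nan")
    population: str | None = None


def effect_allele_dosage(
    genotypes: np.ndarray, model: PrsModel
) -> tuple[np.ndarray, np.ndarray]:
    """Dosage of the effect allele for each model variant (NaN where the
    genome provides no genotype). ``genotypes`` are codes over the analysis
    site table the model was attached to."""
    if model.site_rows is None:
        raise WgrError("model not attached to a site table (call attach_sites)")
    d = np.full(len(model), np.nan)
    predictable = model.site_rows >= 0
    rows = model.site_rows[predictable]
    g = np.asarray(genotypes, dtype=float)[rows]
    g[g == MISSING] = np.nan
    # orientation normalization: if the effect allele is the reference allele,
    # count reference copies (published scoring files mix orientations)
    alt_dose = g
    eff = np.where(model.effect_is_alt[predictable], alt_dose, 2.0 - alt_dose)
    d[predictable] = eff
    return d, predictable


def raw_prs(
    genotypes: np.ndarray,
    model: PrsModel,
    af_table: AlleleFrequencyTable | None = None,
) -> PrsResult:
    """Weighted sum of effect-allele dosages; unpredicted sites contribute
    their expected dosage 2*AF (effect-allele frequency); sites with neither
    genotype nor frequency contribute 0 and are counted as skipped."""
    dosage, _ = effect_allele_dosage(genotypes, model)
    have_gt = np.isfinite(dosage)
    score = float(np.sum(model.weight[have_gt] * dosage[have_gt]))

    n_adj = n_skip = 0
    for i in np.flatnonzero(~have_gt):
        af = af_table.get(model.chrom[i], model.pos[i]) if af_table is not None else None
        if af is None:
            n_skip += 1
            continue
        eff_af = af if model.effect_is_alt[i] else 1.0 - af
        score += model.weight[i] * 2.0 * eff_af
        n_adj += 1
    return PrsResult(
        condition_name=model.condition_name,
        raw_score=score,
        n_sites_used=int(have_gt.sum()),
        n_sites_af_adjusted=n_adj,
        n_sites_skipped=n_skip,
    )


# ---------------------------------------------------------------------------
# Principal components
# ---------------------------------------------------------------------------


@dataclass
class PcModel:
    """Ancestry PC projection fitted on a reference genotype panel.

    ``loadings`` (n_panel_sites x K, orthonormal columns) project
    frequency-standardized genotypes onto PC space. ``population_centroids``
    (first four PCs) assign a nearest reference population when no label is
    given; ``population_sds`` hold the per-population standard deviation of
    the *centered* PRS; ``centering_coefficients`` are the OLS intercept plus
    four PC slopes fitted on controls.
    """

    panel_sites: SiteTable
    allele_freqs: np.ndarray
    loadings: np.ndarray
    population_centroids: dict[str, np.ndarray] = field(default_factory=dict)
    population_sds: dict[str, float] = field(default_factory=dict)
    centering_coefficients: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_pc_model(
    panel_genotypes: np.ndarray,
    panel_sites: SiteTable,
    populations: list[str] | None = None,
    n_components: int = 4,
) -> PcModel:
    """PCA of a reference panel (individuals x sites genotype dosage matrix).

    Genotypes are standardized by panel allele frequency,
    (g - 2p) / sqrt(2p(1-p)), and decomposed by SVD; loadings are the
    right-singular vectors, so projecting a panel individual reproduces its
    own PC score exactly.
    """
    if n_components < N_CENTERING_PCS:
        raise ValueError(f"need at least {N_CENTERING_PCS} components for centering")
    g = np.asarray(panel_genotypes, dtype=float)
    p = g.mean(axis=0) / 2.0
    p = np.clip(p, 1e-6, 1 - 1e-6)
    xs = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    loadings = vt[:n_components].T
    model = PcModel(panel_sites=panel_sites, allele_freqs=p, loadings=loadings)
    if populations is not None:
        scores = xs @ loadings
        pops = np.asarray(populations)
        for pop in dict.fromkeys(populations):
            model.population_centroids[pop] = scores[pops == pop, :N_CENTERING_PCS].mean(axis=0)
    return model


def project_pcs(genotypes: np.ndarray, pc_model: PcModel, min_coverage: float = 0.8) -> np.ndarray:
    """Project one genome (codes over the PC panel sites, -1 = missing) onto
    the reference PCs. Missing panel sites are mean-imputed at the panel
    frequency; below ``min_coverage`` genotyped the projection refuses."""
    g = np.asarray(genotypes, dtype=float)
    if g.shape != (len(pc_model.panel_sites),):
        raise WgrError("genotypes must align with the PC panel site table")
    have = g != MISSING
    if have.mean() < min_coverage:
        raise CoverageError(
            f"only {100 * have.mean():.1f}% of PC panel sites genotyped "
            f"(need >= {100 * min_coverage:.0f}%)"
        )
    p = pc_model.allele_freqs
    g = np.where(have, g, 2 * p)
    xs = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
    return xs @ pc_model.loadings


def assign_population(pc_scores: np.ndarray, pc_model: PcModel) -> str:
    """Nearest reference-population centroid in PC1-4 Euclidean distance."""
    if not pc_model.population_centroids:
        raise WgrError("PC model carries no population centroids")
    pops = list(pc_model.population_centroids)
    cents = np.stack([pc_model.population_centroids[p] for p in pops])
    d = cdist(pc_scores[None, :N_CENTERING_PCS], cents)[0]
    return pops[int(np.argmin(d))]


def save_pc_model(path, pc_model: PcModel) -> None:
    """Serialize a PC model to JSON (text-only artifact)."""
    import json

    df = pc_model.panel_sites.frame
    payload = {
        "sites": {
            "chrom": df["chrom"].tolist(),
            "pos": df["pos"].tolist(),
            "ref": df["ref"].tolist(),
            "alt": df["alt"].tolist(),
        },
        "allele_freqs": pc_model.allele_freqs.tolist(),
        "loadings": pc_model.loadings.tolist(),
        "population_centroids": {
            k: v.tolist() for k, v in pc_model.population_centroids.items()
        },
        "population_sds": pc_model.population_sds,
        "centering_coefficients": (
            pc_model.centering_coefficients.tolist()
            if pc_model.centering_coefficients is not None
            else None
        ),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_pc_model(path) -> PcModel:
    import json

    with open(path) as fh:
        payload = json.load(fh)
    s = payload["sites"]
    sites = SiteTable.from_arrays(s["chrom"], s["pos"], s["ref"], s["alt"])
    coef = payload["centering_coefficients"]
    return PcModel(
        panel_sites=sites,
        allele_freqs=np.array(payload["allele_freqs"]),
        loadings=np.array(payload["loadings"]),
        population_centroids={
            k: np.array(v) for k, v in payload["population_centroids"].items()
        },
        population_sds={k: float(v) for k, v in payload["population_sds"].items()},
        centering_coefficients=np.array(coef) if coef is not None else None,
    )


# ---------------------------------------------------------------------------
# Centering, standardization, odds ratio
# ---------------------------------------------------------------------------


def fit_centering(raw_scores: np.ndarray, pc_scores: np.ndarray) -> np.ndarray:
    """OLS fit of raw PRS on the first four PC scores in controls.
    Returns (intercept, beta_1..beta_4)."""
    x = np.column_stack(
        [np.ones(len(raw_scores)), np.asarray(pc_scores)[:, :N_CENTERING_PCS]]
    )
    coef, *_ = np.linalg.lstsq(x, np.asarray(raw_scores, dtype=float), rcond=None)
    return coef


def center_score(raw_score, pc_scores, coefficients) -> np.ndarray:
    """Subtract the ancestry-predicted PRS."""
    pcs = np.atleast_2d(np.asarray(pc_scores))[:, :N_CENTERING_PCS]
    pred = coefficients[0] + pcs @ coefficients[1:]
    return np.asarray(raw_score, dtype=float) - pred


def center_and_standardize(
    raw_score: float,
    pc_scores: np.ndarray,
    pc_model: PcModel,
    population: str | None = None,
) -> tuple[float, float, str]:
    """Centered score, standardized score (SD units) and the population whose
    SD was used (nearest PC centroid when no label is given)."""
    if pc_model.centering_coefficients is None:
        raise WgrError("centering regression not fitted (call fit_centering first)")
    centered = float(center_score(raw_score, pc_scores, pc_model.centering_coefficients)[0])
    if population is None:
        population = assign_population(np.asarray(pc_scores), pc_model)
    if population not in pc_model.population_sds:
        raise WgrError(f"no reference SD for population {population!r}")
    return centered, centered / pc_model.population_sds[population], population


def or_from_prs(standardized_score: float, beta_per_sd: float) -> float:
    """Odds ratio of disease given the PRS: OR = exp(beta * PRS), beta in
    log-odds per standard deviation."""
    if not np.isfinite(beta_per_sd):
        raise ValueError("beta_per_sd must be finite")
    return float(np.exp(beta_per_sd * np.asarray(standardized_score, dtype=float)))


# ---------------------------------------------------------------------------
# Model QC
# ---------------------------------------------------------------------------


@dataclass
class QcVerdict:
    """Validation summary of one PRS model on a case/control cohort."""

    auc: float
    or_per_sd: float
    decile_ors: np.ndarray  # OR of each decile vs pooled deciles 5-6
    top_bottom_or: float
    monotone_deciles: bool
    passed: bool
    status: str = "ok"  # "ok" | "indeterminate"


def _decile_odds_ratios(scores: np.ndarray, status: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-decile odds ratios against the pooled middle deciles (5-6), with
    approximate standard errors of the log OR (Woolf, 0.5 continuity)."""
    ranks = np.argsort(np.argsort(scores))
    decile = np.minimum((10 * (ranks + 0.5) / len(scores)).astype(int), 9)
    ref = np.isin(decile, (4, 5))
    ref_case = status[ref].sum() + 0.5
    ref_ctrl = (~status[ref].astype(bool)).sum() + 0.5
    ors, ses = [], []
    for d in range(10):
        sel = decile == d
        case = status[sel].sum() + 0.5
        ctrl = (~status[sel].astype(bool)).sum() + 0.5
        if sel.sum() == 0:
            raise DegenerateInputError("empty decile")
        ors.append((case / ctrl) / (ref_case / ref_ctrl))
        ses.append(np.sqrt(1 / case + 1 / ctrl + 1 / ref_case + 1 / ref_ctrl))
    return np.array(ors), np.array(ses)


def validate_model(
    standardized_scores: np.ndarray,
    case_status: np.ndarray,
    min_group: int = 10,
) -> QcVerdict:
    """Apply the internal QC gates to a scored case/control cohort.

    Gates: AUC >= 0.6; decile odds ratios weakly increasing (each decile may
    fall below its predecessor by at most two standard errors of the log OR —
    strict weak increase over ten sampled deciles would reject genuinely
    strong scores at realistic cohort sizes); top-vs-bottom decile OR >= 2.
    The per-SD OR is estimated by logistic regression of status on the score.
    """
    import statsmodels.api as sm

    scores = np.asarray(standardized_scores, dtype=float)
    status = np.asarray(case_status).astype(int)
    if status.sum() < min_group or (1 - status).sum() < min_group:
        raise DegenerateInputError(
            f"QC needs >= {min_group} cases and >= {min_group} controls"
        )
    auc = float(roc_auc_score(status, scores))
    try:
        fit = sm.Logit(status, sm.add_constant(scores)).fit(disp=False)
        or_per_sd = float(np.exp(fit.params[1]))
    except Exception:  # perfect separation: the per-SD OR is unbounded
        or_per_sd = float("inf")
    try:
        decile_ors, ses = _decile_odds_ratios(scores, status)
    except DegenerateInputError:
        return QcVerdict(
            auc=auc, or_per_sd=or_per_sd, decile_ors=np.full(10, np.nan),
            top_bottom_or=float("nan"), monotone_deciles=False, passed=False,
            status="indeterminate",
        )
    log_or = np.log(decile_ors)
    slack = 2.0 * np.sqrt(ses[1:] ** 2 + ses[:-1] ** 2)
    monotone = bool(np.all(np.diff(log_or) >= -slack))
    top_bottom = float(decile_ors[9] / decile_ors[0])
    passed = auc >= 0.6 and monotone and top_bottom >= 2.0
    return QcVerdict(
        auc=auc, or_per_sd=or_per_sd, decile_ors=decile_ors,
        top_bottom_or=top_bottom, monotone_deciles=monotone, passed=passed,
    )


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def score_genome(
    genotypes: np.ndarray,
    model: PrsModel,
    af_table: AlleleFrequencyTable | None,
    pc_model: PcModel | None = None,
    pc_panel_genotypes: np.ndarray | None = None,
    population: str | None = None,
) -> PrsResult:
    """Full transform for one genome: raw score, then (when a PC model with a
    fitted centering regression is supplied) centering, standardization and
    the odds ratio at ``model.beta_per_sd``."""
    res = raw_prs(genotypes, model, af_table)
    if pc_model is not None:
        pcs = project_pcs(
            pc_panel_genotypes if pc_panel_genotypes is not None else genotypes, pc_model
        )
        centered, standardized, pop = center_and_standardize(
            res.raw_score, pcs, pc_model, population
        )
        res.centered_score = centered
        res.standardized_score = standardized
        res.population = pop
        if np.isfinite(model.beta_per_sd):
            res.odds_ratio = or_from_prs(standardized, model.beta_per_sd)
    return res
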