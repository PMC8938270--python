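import numpy as np
import pytest

from wgr.core import SiteTable
from wgr.errors import CoverageError, DegenerateInputError
from wgr.io_formats import AlleleFrequencyTable, PrsModel
from wgr.prs_engine import (
    assign_population,
    center_and_standardize,
    center_score,
    fit_centering,
    fit_pc_model,
    load_pc_model,
    or_from_prs,
    project_pcs,
    raw_prs,
    save_pc_model,
    validate_model,
)


def _model(weights, sites, effect_alleles=None):
    n = len(weights)
    effect_alleles = effect_alleles or [sites.frame.alt.iat[i] for i in range(n)]
    m = PrsModel(
        condition_name="test",
        chrom=sites.chrom[:n],
        pos=sites.pos[:n],
        effect_allele=np.array(effect_alleles),
        weight=np.array(weights, dtype=float),
    )
    return m.attach_sites(sites)


@pytest.fixture()
def two_sites():
    return SiteTable.from_arrays(["1", "1"], [100, 200], "AC", "GT")


class TestRawPrs:
    def test_weighted_sum(self, two_sites):
        model = _model([0.1, 0.2], two_sites)
        res = raw_prs(np.array([2, 1], dtype=np.int8), model)
        assert res.raw_score == pytest.approx(0.4)
        assert res.n_sites_used == 2 and res.n_sites_af_adjusted == 0

    def test_unpredicted_site_uses_expected_dosage(self, two_sites):
        model = _model([0.1, 0.2], two_sites)
        af = AlleleFrequencyTable({("1", 200): 0.25})
        res = raw_prs(np.array([2, -1], dtype=np.int8), model, af)
        # 0.1*2 + 0.2*(2*0.25)
        assert res.raw_score == pytest.approx(0.3)
        assert res.n_sites_af_adjusted == 1

    def test_all_sites_unpredicted(self, two_sites):
        model = _model([0.1, 0.2], two_sites)
        af = AlleleFrequencyTable({("1", 100): 0.5, ("1", 200): 0.25})
        res = raw_prs(np.array([-1, -1], dtype=np.int8), model, af)
        assert res.raw_score == pytest.approx(0.1 * 1.0 + 0.2 * 0.5)
        assert res.n_sites_used == 0

    def test_no_genotype_no_af_contributes_zero(self, two_sites):
        model = _model([0.1, 0.2], two_sites)
        res = raw_prs(np.array([2, -1], dtype=np.int8), model, AlleleFrequencyTable({}))
        assert res.raw_score == pytest.approx(0.2)
        assert res.n_sites_skipped == 1

    def test_linear_in_weights(self, two_sites, rng):
        g = rng.integers(0, 3, 2).astype(np.int8)
        w1, w2 = [0.3, -0.1], [0.05, 0.7]
        s1 = raw_prs(g, _model(w1, two_sites)).raw_score
        s2 = raw_prs(g, _model(w2, two_sites)).raw_score
        s12 = raw_prs(g, _model(list(np.add(w1, w2)), two_sites)).raw_score
        assert s12 == pytest.approx(s1 + s2)

    def test_effect_allele_orientation_invariance(self, two_sites):
        """Flipping a row to the other allele with negated weight changes the
        score only by a constant (2w), i.e. differences between genomes are
        invariant."""
        ref_model = _model([0.4, 0.2], two_sites)
        flip_model = _model(
            [-0.4, 0.2], two_sites,
            effect_alleles=[two_sites.frame.ref.iat[0], two_sites.frame.alt.iat[1]],
        )
        g1 = np.array([2, 1], dtype=np.int8)
        g2 = np.array([0, 1], dtype=np.int8)
        d_ref = raw_prs(g1, ref_model).raw_score - raw_prs(g2, ref_model).raw_score
        d_flip = raw_prs(g1, flip_model).raw_score - raw_prs(g2, flip_model).raw_score
        assert d_ref == pytest.approx(d_flip)


@pytest.fixture(scope="module")
def panel():
    rng = np.random.default_rng(55)
    n_sites, n_ind = 120, 240
    sites = SiteTable.from_arrays(
        ["1"] * n_sites, np.arange(1, n_sites + 1) * 1000,
        ["A"] * n_sites, ["G"] * n_sites,
    )
    pops = np.array(["POP1"] * (n_ind // 2) + ["POP2"] * (n_ind // 2))
    af1 = rng.uniform(0.1, 0.9, n_sites)
    af2 = np.clip(af1 + rng.normal(0, 0.25, n_sites), 0.05, 0.95)
    g = np.stack(
        [
            (rng.random(n_sites) < (af1 if p == "POP1" else af2)).astype(np.int8)
            + (rng.random(n_sites) < (af1 if p == "POP1" else af2)).astype(np.int8)
            for p in pops
        ]
    )
    model = fit_pc_model(g, sites, populations=list(pops), n_components=4)
    return g, pops, model


class TestPcProjection:
    def test_panel_individual_projects_to_own_score(self, panel):
        g, _, model = panel
        p = np.clip(g.mean(axis=0) / 2.0, 1e-6, 1 - 1e-6)
        xs = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        expected = xs[0] @ model.loadings
        assert np.allclose(project_pcs(g[0], model), expected, atol=1e-6)

    def test_two_populations_separate_and_assign(self, panel):
        g, pops, model = panel
        scores = np.stack([project_pcs(row, model) for row in g])
        assigned = [assign_population(s, model) for s in scores]
        acc = np.mean(np.array(assigned) == pops)
        assert acc > 0.95

    def test_low_coverage_refuses(self, panel):
        g, _, model = panel
        masked = g[0].copy()
        masked[: int(0.3 * len(masked))] = -1
        with pytest.raises(CoverageError):
            project_pcs(masked, model)

    def test_json_roundtrip(self, panel, tmp_path):
        _, _, model = panel
        model.population_sds = {"POP1": 1.2, "POP2": 0.8}
        model.centering_coefficients = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        save_pc_model(tmp_path / "pc.json", model)
        back = load_pc_model(tmp_path / "pc.json")
        assert np.allclose(back.loadings, model.loadings)
        assert back.population_sds == model.population_sds
        assert np.allclose(back.centering_coefficients, model.centering_coefficients)


class TestCentering:
    def test_pc_linear_cohort_annihilated(self, rng):
        """A control cohort whose raw PRS is an exact linear function of PC1
        centers to zero."""
        pcs = rng.normal(size=(500, 4))
        raw = 3.0 + 2.5 * pcs[:, 0]
        coef = fit_centering(raw, pcs)
        centered = center_score(raw, pcs, coef)
        assert np.max(np.abs(centered)) < 1e-9

    def test_centering_idempotent(self, rng):
        pcs = rng.normal(size=(400, 4))
        raw = rng.normal(size=400) + pcs @ [1.0, -0.5, 0.2, 0.0]
        centered = center_score(raw, pcs, fit_centering(raw, pcs))
        again = center_score(centered, pcs, fit_centering(centered, pcs))
        assert np.max(np.abs(again - centered)) < 1e-9

    def test_identity_when_coefficients_zero(self, panel):
        _, _, model = panel
        model.centering_coefficients = np.zeros(5)
        model.population_sds = {"POP1": 1.0, "POP2": 1.0}
        centered, standardized, _ = center_and_standardize(
            1.7, np.zeros(4), model, population="POP1"
        )
        assert centered == standardized == pytest.approx(1.7)

    def test_control_scores_standardized(self, rng):
        """Standardized control scores have mean ~ 0 (3 SE) and SD in
        [0.9, 1.1] at n = 2,000 by construction."""
        n = 2000
        pcs = rng.normal(size=(n, 4))
        raw = 0.4 * rng.normal(size=n) + pcs @ [0.8, 0.3, 0.0, -0.2]
        coef = fit_centering(raw, pcs)
        centered = center_score(raw, pcs, coef)
        sd = np.std(centered, ddof=1)
        standardized = centered / sd
        assert abs(standardized.mean()) < 3 / np.sqrt(n)
        assert 0.9 <= np.std(standardized, ddof=1) <= 1.1


class TestOrFromPrs:
    def test_published_noncarrier_effect(self):
        # one SD above the mean at a per-SD OR of 1.6
        assert or_from_prs(1.0, np.log(1.6)) == pytest.approx(1.6)

    def test_null_score(self):
        assert or_from_prs(0.0, np.log(1.6)) == 1.0

    def test_symmetry(self):
        assert or_from_prs(-1.0, np.log(1.3)) == pytest.approx(1 / 1.3)
        x = 0.73
        assert or_from_prs(x, 0.5) * or_from_prs(-x, 0.5) == pytest.approx(1.0)

    def test_strictly_monotone(self):
        xs = np.linspace(-3, 3, 25)
        ors = [or_from_prs(x, np.log(1.6)) for x in xs]
        assert np.all(np.diff(ors) > 0)


class TestValidateModel:
    def _liability_cohort(self, rng, n, beta, base_logit=-1.0):
        score = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(base_logit + beta * score)))
        status = (rng.random(n) < p).astype(int)
        return score, status

    def test_strong_score_passes(self, rng):
        score, status = self._liability_cohort(rng, 5000, np.log(2.2))
        v = validate_model(score, status)
        assert v.auc >= 0.6
        assert v.monotone_deciles
        assert v.top_bottom_or >= 2.0
        assert v.passed

    def test_null_score_fails(self, rng):
        score, status = self._liability_cohort(rng, 5000, 0.0)
        v = validate_model(score, status)
        assert abs(v.auc - 0.5) < 0.05
        assert not v.passed

    def test_per_sd_or_recovered(self, rng):
        true_or = 1.8
        score, status = self._liability_cohort(rng, 5000, np.log(true_or))
        v = validate_model(score, status)
        assert abs(v.or_per_sd - true_or) / true_or < 0.15

    def test_perfect_separation_auc_one(self):
        score = np.concatenate([np.zeros(50), np.ones(50)])
        status = np.concatenate([np.zeros(50, int), np.ones(50, int)])
        v = validate_model(score, status)
        assert v.auc == 1.0

    def test_too_few_cases_is_degenerate(self, rng):
        with pytest.raises(DegenerateInputError):
            validate_model(rng.normal(size=100), np.zeros(100, int))
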