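import numpy as np
import pytest

from wgr.core import (
    DAY3,
    DAY5,
    NOISELESS,
    EmbryoArrayObservation,
    GeneticMap,
    PhasedParentalGenome,
    SiteTable,
    haldane_switch_probability,
)
from wgr.errors import PhaseConflictWarning, UnidentifiableError
from wgr.parental_phasing import (
    RareVariant,
    attach_rare_variants,
    merge_with_truth_phase,
    phase_parent,
)
from wgr.synthetic_cohort import simulate_family

from .oracles import global_ml_phase


def _toy_two_site_setup():
    """Mother het at two sites 0.1 cM apart (alt alleles in coupling), father
    hom-ref; four noiseless embryos all transmit an intact maternal haplotype."""
    sites = SiteTable.from_arrays(["1", "1"], [1_000_000, 1_100_000], "AC", "GT")
    gmap = GeneticMap({"1": (np.array([1, 2_000_000]), np.array([0.0, 2.0]))})
    mother_gt = np.array([1, 1], dtype=np.int8)
    father_gt = np.array([0, 0], dtype=np.int8)
    observations = [
        EmbryoArrayObservation(sites=sites, calls=np.array(c, dtype=np.int8), name=f"e{i}")
        for i, c in enumerate([[1, 1], [0, 0], [1, 1], [0, 0]])
    ]
    return sites, gmap, mother_gt, father_gt, observations


class TestPhaseParent:
    def test_coupling_recovered_with_high_confidence(self):
        _, gmap, mother_gt, father_gt, obs = _toy_two_site_setup()
        scaffold = phase_parent(mother_gt, father_gt, obs, gmap, NOISELESS)
        # both alt alleles on the same haplotype, i.e. coupling
        assert scaffold.hap1_allele[0] == scaffold.hap1_allele[1]
        assert scaffold.confidence[1] > 0.99

    def test_single_embryo_is_unidentifiable(self):
        _, gmap, mother_gt, father_gt, obs = _toy_two_site_setup()
        with pytest.raises(UnidentifiableError):
            phase_parent(mother_gt, father_gt, obs[:1], gmap, NOISELESS)

    def test_no_het_sites_gives_empty_scaffold(self):
        sites, gmap, _, _, obs = _toy_two_site_setup()
        scaffold = phase_parent(
            np.array([0, 2], dtype=np.int8), np.array([1, 1], dtype=np.int8),
            obs, gmap, NOISELESS,
        )
        assert len(scaffold) == 0

    def test_embryo_order_invariance(self, day5_family):
        fam = day5_family
        rows = fam.array_rows
        args = (
            fam.mother.genotypes[rows],
            fam.father.genotypes[rows],
        )
        a = phase_parent(*args, fam.observations, fam.genetic_map, DAY5)
        b = phase_parent(*args, fam.observations[::-1], fam.genetic_map, DAY5)
        assert np.array_equal(a.hap1_allele, b.hap1_allele)
        assert np.allclose(a.confidence, b.confidence)

    @staticmethod
    def _switch_error(scaffold, truth_genome, rows):
        # evaluated over confidently phased sites: confidence 0.5 means the
        # scaffold makes no phase claim there (intrinsically unphasable from
        # the embryo data, e.g. every sibling ambiguous at the site)
        het = scaffold.het_rows()
        het = het[scaffold.confidence[het] > 0.5]
        truth_h0 = truth_genome.haplotypes[0][rows][het]
        scaf = scaffold.hap1_allele[het]
        by_chrom_err, by_chrom_n = 0, 0
        chroms = scaffold.sites.chrom[het]
        for c in np.unique(chroms):
            sel = chroms == c
            t, s = truth_h0[sel], scaf[sel]
            truth_rel = t[1:] == t[:-1]
            scaf_rel = s[1:] == s[:-1]
            by_chrom_err += int(np.sum(truth_rel != scaf_rel))
            by_chrom_n += len(t) - 1
        return by_chrom_err / by_chrom_n

    def test_switch_error_below_regression_bound(self):
        """Six day-5 embryos, ~1,000 maternal het array sites: the scaffold's
        switch-error rate against the generating phase stays under 2%
        (a package regression bound at the package noise presets)."""
        fam = simulate_family(
            n_embryos=6, noise=DAY5, seed=23, n_sites=3000, n_chromosomes=2,
            n_array_sites=3000,
        )
        rows = fam.array_rows
        scaffold = phase_parent(
            fam.mother.genotypes[rows], fam.father.genotypes[rows],
            fam.observations, fam.genetic_map, DAY5, parent_name="mother",
        )
        assert len(scaffold) > 800
        assert self._switch_error(scaffold, fam.mother, rows) < 0.02

    @pytest.mark.parametrize("seed", [31, 32, 33, 34])
    def test_chained_result_matches_global_ml_on_small_noiseless_instance(self, seed):
        """On instances small enough for exhaustive phase enumeration the
        chained pairwise phase equals the global maximum-likelihood
        configuration. The father is homozygous reference throughout so the
        exhaustive oracle's per-site marginalization is exact."""
        rng = np.random.default_rng(seed)
        n = 8
        pos = np.sort(rng.choice(np.arange(100, 60_000_000), n, replace=False))
        sites = SiteTable.from_arrays(["1"] * n, pos, ["A"] * n, ["G"] * n)
        gmap = GeneticMap({"1": (np.array([1, 60_000_000]), np.array([0.0, 60.0]))})
        mother = PhasedParentalGenome(
            sites=sites, haplotypes=rng.integers(0, 2, (2, n)).astype(np.int8)
        )
        mother.haplotypes[1] = 1 - mother.haplotypes[0]  # het everywhere
        from wgr.synthetic_cohort import draw_meiosis

        observations = []
        for k in range(3):
            _, gamete = draw_meiosis(mother, gmap, rng)
            observations.append(
                EmbryoArrayObservation(sites=sites, calls=gamete.copy(), name=f"e{k}")
            )
        mother_gt = np.ones(n, dtype=np.int8)
        father_gt = np.zeros(n, dtype=np.int8)
        scaffold = phase_parent(
            mother_gt, father_gt, observations, gmap, NOISELESS
        )
        calls = np.stack([o.calls for o in observations])
        dists = np.tile([1.0, 0.0], (n, 1))
        r = haldane_switch_probability(np.diff(gmap.cm_at("1", pos)))
        oracle = global_ml_phase(calls, dists, r, NOISELESS.emission_matrix())
        # oracle convention: hap-1 allele 0 at the first site, matching ours
        assert np.array_equal(scaffold.hap1_allele, oracle)

    def test_confidence_is_calibrated(self):
        """Among phase decisions reported with confidence in [0.9, 0.95],
        empirical correctness lies in [0.85, 1.0]."""
        correct, total = 0, 0
        for seed in (101, 102, 103):
            fam = simulate_family(
                n_embryos=3, noise=DAY3, seed=seed, n_sites=3000, n_chromosomes=2,
                n_array_sites=3000,
            )
            rows = fam.array_rows
            scaffold = phase_parent(
                fam.mother.genotypes[rows], fam.father.genotypes[rows],
                fam.observations, fam.genetic_map, DAY3,
            )
            het = scaffold.het_rows()
            truth_h0 = fam.mother.haplotypes[0][rows][het]
            scaf = scaffold.hap1_allele[het]
            conf = scaffold.confidence[het]
            chroms = scaffold.sites.chrom[het]
            for c in np.unique(chroms):
                sel = chroms == c
                t, s, cf = truth_h0[sel], scaf[sel], conf[sel]
                ok = (t[1:] == t[:-1]) == (s[1:] == s[:-1])
                in_bin = (cf[1:] >= 0.9) & (cf[1:] <= 0.95)
                correct += int(ok[in_bin].sum())
                total += int(in_bin.sum())
        assert total >= 50, "calibration bin under-populated"
        assert 0.85 <= correct / total <= 1.0


class TestMergeWithTruthPhase:
    def _scaffold_from(self, genome, rows):
        from wgr.parental_phasing import PhaseScaffold

        hap1 = np.full(len(genome.sites), -1, dtype=np.int8)
        het = genome.het_mask()
        hap1[het] = genome.haplotypes[0][het]
        conf = np.where(het, 0.99, 0.5)
        return PhaseScaffold(
            sites=genome.sites, hap1_allele=hap1, confidence=conf,
            parent_name=genome.sample_name,
        )

    def test_identical_phase_passes_through(self, day5_family):
        genome = day5_family.mother
        scaffold = self._scaffold_from(genome, None)
        merged = merge_with_truth_phase(scaffold, genome)
        assert np.array_equal(merged.haplotypes, genome.haplotypes)

    def test_global_flip_reoriented(self, day5_family):
        genome = day5_family.mother
        scaffold = self._scaffold_from(genome, None)
        merged = merge_with_truth_phase(scaffold, genome.flipped("1"))
        assert np.array_equal(merged.haplotypes, genome.haplotypes)

    def test_empty_scaffold_keeps_external_unchanged(self, day5_family):
        genome = day5_family.mother
        from wgr.parental_phasing import PhaseScaffold

        empty = PhaseScaffold(
            sites=genome.sites,
            hap1_allele=np.full(len(genome.sites), -1, dtype=np.int8),
            confidence=np.full(len(genome.sites), 0.5),
        )
        merged = merge_with_truth_phase(empty, genome)
        assert np.array_equal(merged.haplotypes, genome.haplotypes)

    def test_systematic_disagreement_warns(self, day5_family, rng):
        genome = day5_family.mother
        scaffold = self._scaffold_from(genome, None)
        het = scaffold.het_rows()
        # randomize the scaffold's phase: relative phase becomes ~50% discordant
        scaffold.hap1_allele[het] = rng.integers(0, 2, len(het)).astype(np.int8)
        with pytest.warns(PhaseConflictWarning):
            merge_with_truth_phase(scaffold, genome)


class TestAttachRareVariants:
    def _genome(self):
        sites = SiteTable.from_arrays(["1"] * 3, [100, 200, 300], "ACA", "GTG")
        return PhasedParentalGenome(
            sites=sites,
            haplotypes=np.array([[0, 0, 1], [0, 1, 0]], dtype=np.int8),
            phase_confidence=np.array([1.0, 1.0, 1.0]),
        )

    def test_explicit_haplotype_assignment(self):
        genome = self._genome()
        # site 200 is het; force the alt allele onto haplotype 1 (index 0)
        updated, flagged = attach_rare_variants(
            genome, [RareVariant("1", 200, haplotype=0)]
        )
        assert not flagged
        assert updated.haplotypes[0, 1] == 1 and updated.haplotypes[1, 1] == 0

    def test_anchor_inherits_haplotype(self):
        genome = self._genome()
        # anchor at 300 carries its alt allele on haplotype 1 (index 0)
        updated, flagged = attach_rare_variants(
            genome, [RareVariant("1", 200, anchor_pos=300, anchor_allele=1)]
        )
        assert not flagged
        assert updated.haplotypes[0, 1] == 1

    def test_missing_anchor_flagged_unphased(self):
        genome = self._genome()
        updated, flagged = attach_rare_variants(
            genome, [RareVariant("1", 200, anchor_pos=999)]
        )
        assert len(flagged) == 1
        assert np.array_equal(updated.haplotypes, genome.haplotypes)
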