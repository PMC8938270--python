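"""Distribution of polygenic scores among a couple's potential embryos.

Simulates 500 virtual embryos (the default) under the linkage scheme —
map-driven crossovers on the phased parental genomes — and under the
unlinked scheme, and compares both distributions with the midparent mean,
the Mendelian expectation of the offspring score.
"""

import numpy as np

from wgr import (
    PrsModel,
    cohort_summary,
    raw_prs,
    simulate_parents,
    simulate_prs_cohort,
    uniform_genetic_map,
)

mother, father, sites, af = simulate_parents(800, 2, seed=33)
rng = np.random.default_rng(34)
rows = np.sort(rng.choice(len(sites), 80, replace=False))
model = PrsModel(
    condition_name="demo", chrom=sites.chrom[rows], pos=sites.pos[rows],
    effect_allele=sites.frame.alt.to_numpy()[rows],
    weight=rng.normal(0, 0.2, len(rows)),
).attach_sites(sites)
gmap = uniform_genetic_map(2)

mother_prs = raw_prs(mother.genotypes, model, af).raw_score
father_prs = raw_prs(father.genotypes, model, af).raw_score

for mode in ("linkage", "unlinked"):
    cohort = simulate_prs_cohort(
        mother, father, model, seed=35, mode=mode, genetic_map=gmap, af_table=af
    )
    s = cohort_summary(cohort, mother_prs, father_prs)
    print(
        f"{mode:>9}: n={s.n_replicates}  mean={s.mean:+.3f}  sd={s.sd:.3f}  "
        f"95% range=[{s.quantiles['q2.5']:+.3f}, {s.quantiles['q97.5']:+.3f}]"
    )
print(f"midparent: mean={(mother_prs + father_prs) / 2:+.3f}  (expected embryo mean)")
print("\nBoth schemes center on the midparent mean; linkage widens or narrows")
print("the spread according to how the model's weights sit on shared haplotypes.")
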