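"""Reconstruct the genomes of a family of sibling embryos from noisy array data.

Simulates a couple and six day-5 embryo biopsies, phases each parent from the
sibling embryos (parental support), anchors the scaffold to the external
phase, decodes each embryo's transmitted haplotypes with the HMM, and scores
every reconstruction against the embryo's true genome.
"""

import numpy as np

from wgr import (
    DAY5,
    genotype_accuracy,
    merge_with_truth_phase,
    phase_parent,
    reconstruct_embryo,
    simulate_family,
)

family = simulate_family(
    n_embryos=6, noise=DAY5, seed=7, n_sites=3000, n_chromosomes=2,
    n_array_sites=1500,
)
rows = family.array_rows

parents = {}
for name, parent, other in (
    ("mother", family.mother, family.father),
    ("father", family.father, family.mother),
):
    scaffold = phase_parent(
        parent.genotypes[rows], other.genotypes[rows], family.observations,
        family.genetic_map, DAY5, parent_name=name,
    )
    # in production the external phase comes from reference-panel phasing of
    # the parents' WGS; in simulation the generating phase plays that role
    parents[name] = merge_with_truth_phase(scaffold, parent)
    print(f"{name}: phased {len(scaffold)} heterozygous array sites")

print()
print(f"{'embryo':<10} {'genome-wide':>12} {'het sites':>10} {'hom sites':>10} {'segments':>9}")
for e in family.embryos:
    recon, path = reconstruct_embryo(
        e.observation, parents["mother"], parents["father"], family.genetic_map, DAY5
    )
    r = genotype_accuracy(recon, e.true_genotypes)
    print(
        f"{e.name:<10} {r.genome_wide_accuracy:>11.2f}% "
        f"{r.by_genotype['het']:>9.2f}% {r.by_genotype['hom']:>9.2f}% "
        f"{len(path.segments):>9}"
    )

print()
print("Accuracy is the percent of sites whose unordered diploid genotype")
print("matches the truth; 'segments' counts constant-haplotype intervals")
print("(each extra segment beyond 4 reflects a detected meiotic crossover).")
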