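"""Independent brute-force oracles used by the test suite."""

from itertools import combinations

import numpy as np

from steppedemo.simulate import MISSING, GenotypeMatrix


def bruteforce_sfs(gm: GenotypeMatrix, pop_assignment, n_proj: dict[str, int]):
    """Expected marginal/joint SFS by explicit enumeration of every subsample.

    For each site and population, every size-n_proj subset of the called
    alleles is enumerated and the derived-count histogram averaged; the joint
    spectrum averages the product over independent subsets per population.
    Only feasible for tiny matrices.
    """
    if pop_assignment is None:
        pops_per_ind = list(gm.lineages)
    else:
        pops_per_ind = [pop_assignment[i] for i in gm.individual_ids]
    pops = list(dict.fromkeys(pops_per_ind))
    row_pops = np.repeat(pops_per_ind, 2)
    marginal = {p: np.zeros(n_proj[p] + 1) for p in pops}
    joint = np.zeros((n_proj[pops[0]] + 1, n_proj[pops[1]] + 1)) if len(pops) == 2 else None
    used = dropped = 0
    for s in range(gm.n_sites):
        per_pop = {}
        ok = True
        for p in pops:
            rows = np.flatnonzero(row_pops == p)
            alleles = [int(gm.values[r, s]) for r in rows if gm.values[r, s] != MISSING]
            if len(alleles) < n_proj[p]:
                ok = False
                break
            vec = np.zeros(n_proj[p] + 1)
            subsets = list(combinations(alleles, n_proj[p]))
            for sub in subsets:
                vec[sum(sub)] += 1.0
            per_pop[p] = vec / len(subsets)
        if not ok:
            dropped += 1
            continue
        used += 1
        for p in pops:
            marginal[p] += per_pop[p]
        if joint is not None:
            joint += np.outer(per_pop[pops[0]], per_pop[pops[1]])
    return marginal, joint, used, dropped


def random_genotype_matrix(rng: np.random.Generator, n_ind_ez=2, n_ind_z=2, n_sites=5,
                           missing_p=0.3) -> GenotypeMatrix:
    """Random small matrix obeying the haplotype-pair missingness rule."""
    n_ind = n_ind_ez + n_ind_z
    while True:
        values = rng.integers(0, 2, size=(2 * n_ind, n_sites)).astype(np.int8)
        miss = rng.random((n_ind, n_sites)) < missing_p
        if miss.all(axis=0).any():
            continue
        values[np.repeat(miss, 2, axis=0)] = MISSING
        break
    return GenotypeMatrix(
        values=values,
        individual_ids=[f"i{k}" for k in range(n_ind)],
        lineages=np.array(["EZ"] * n_ind_ez + ["Z"] * n_ind_z),
        locus_ids=np.array([f"l{j}" for j in range(n_sites)]),
    )


def hudson_fst(gm: GenotypeMatrix) -> float:
    """Ratio-of-sums Hudson FST between the EZ and Z blocks."""
    row_lin = gm.row_lineages
    num = den = 0.0
    for s in range(gm.n_sites):
        col = gm.values[:, s]
        parts = []
        for lin in ("EZ", "Z"):
            x = col[(row_lin == lin) & (col != MISSING)]
            if x.size < 2:
                parts = None
                break
            parts.append((x.mean(), x.size))
        if parts is None:
            continue
        (p1, n1), (p2, n2) = parts
        hw = (2 * p1 * (1 - p1) * n1 / (n1 - 1) + 2 * p2 * (1 - p2) * n2 / (n2 - 1)) / 2
        hb = p1 * (1 - p2) + p2 * (1 - p1)
        num += hb - hw
        den += hb
    return num / den
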