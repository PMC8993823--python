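"""Site frequency spectra from genotype matrices with missing data.

Missing genotypes are handled by hypergeometric down-projection: each site is
projected to a reduced haploid sample size, averaging over all possible
subsamples of the called alleles, so that sites with different call rates
contribute comparably.  Sites with fewer called alleles than the projection
size are dropped (and counted).  Marginal spectra can be written in the
single-line whitespace format consumed by stairway-style tools.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from .simulate import MISSING, GenotypeMatrix

__all__ = [
    "ProjectionSpec",
    "SpectrumResult",
    "project_site",
    "compute_sfs",
    "choose_projection",
    "write_marginal_sfs",
]


@dataclass(frozen=True)
class ProjectionSpec:
    """Projected haploid sample size per population."""

    n_proj: dict[str, int]

    def __post_init__(self) -> None:
        for pop, n in self.n_proj.items():
            if n < 2:
                raise ValueError(f"projection for {pop} must be >= 2")


@dataclass
class SpectrumResult:
    """Marginal (per population) and joint expected spectra.

    Every used site contributes total expected weight 1 to each marginal and
    to the joint array, so each array's mass equals ``sites_used``.
    """

    marginal: dict[str, np.ndarray]
    joint: np.ndarray | None
    pops: list[str]
    sites_used: int
    sites_dropped: int
    folded: bool


def project_site(d: int, n_called: int, n_proj: int) -> np.ndarray:
    """Expected distribution of the derived count in a hypergeometric
    subsample of size ``n_proj`` from ``n_called`` alleles with ``d`` derived.

    Entry j equals C(d, j) * C(n_called - d, n_proj - j) / C(n_called, n_proj).
    Raises when the site cannot support the projection (n_called < n_proj).
    """
    if not 0 <= d <= n_called:
        raise ValueError("need 0 <= d <= n_called")
    if n_called < n_proj:
        raise ValueError("site has fewer called alleles than the projection size")
    j = np.arange(n_proj + 1)
    return hypergeom.pmf(j, n_called, d, n_proj)


def _site_counts(gm: GenotypeMatrix, pop_rows: dict[str, np.ndarray]):
    """Per-population called and derived allele counts for every site."""
    called, derived = {}, {}
    for pop, rows in pop_rows.items():
        block = gm.values[rows]
        is_called = block != MISSING
        called[pop] = is_called.sum(axis=0)
        derived[pop] = np.where(is_called, block, 0).sum(axis=0)
    return called, derived


def _pop_rows(gm: GenotypeMatrix, pop_assignment: dict[str, str] | None) -> dict[str, np.ndarray]:
    if pop_assignment is None:
        pops_per_ind = np.asarray(gm.lineages)
    else:
        missing = [i for i in gm.individual_ids if i not in pop_assignment]
        if missing:
            raise ValueError(f"individuals without population assignment: {missing}")
        pops_per_ind = np.asarray([pop_assignment[i] for i in gm.individual_ids])
    pops = list(dict.fromkeys(pops_per_ind.tolist()))
    row_pops = np.repeat(pops_per_ind, 2)
    out = {p: np.flatnonzero(row_pops == p) for p in pops}
    for p, rows in out.items():
        if rows.size == 0:
            raise ValueError(f"population {p!r} has zero individuals")
    return out


def _fold_marginal(v: np.ndarray) -> np.ndarray:
    n = v.size - 1
    out = np.zeros_like(v)
    for j in range(n + 1):
        out[min(j, n - j)] += v[j]
    return out


def _fold_joint(a: np.ndarray) -> np.ndarray:
    """Fold a joint spectrum on total allele count (dadi-style: cell (i, j)
    merges with (nA-i, nB-j); the central diagonal is split evenly)."""
    na, nb = a.shape[0] - 1, a.shape[1] - 1
    rev = a[::-1, ::-1]
    i = np.arange(na + 1)[:, None]
    j = np.arange(nb + 1)[None, :]
    total = i + j
    half = (na + nb) / 2
    out = np.where(total < half, a + rev, np.where(total == half, (a + rev) / 2, 0.0))
    return out


def compute_sfs(
    gm: GenotypeMatrix,
    pop_assignment: dict[str, str] | None,
    proj: ProjectionSpec,
    folded: bool = False,
) -> SpectrumResult:
    """Accumulate marginal and joint expected spectra over all usable sites.

    A site is used only if every population has at least ``n_proj`` called
    alleles at it; the joint spectrum is the accumulated outer product of the
    per-population projection vectors.  Folding is applied after projection.
    """
    pop_rows = _pop_rows(gm, pop_assignment)
    pops = list(pop_rows)
    for p in pops:
        if p not in proj.n_proj:
            raise ValueError(f"no projection size for population {p!r}")
        if proj.n_proj[p] > pop_rows[p].size:
            raise ValueError(f"projection for {p!r} exceeds its haploid sample size")
    called, derived = _site_counts(gm, pop_rows)
    usable = np.ones(gm.n_sites, dtype=bool)
    for p in pops:
        usable &= called[p] >= proj.n_proj[p]
    marginal = {p: np.zeros(proj.n_proj[p] + 1) for p in pops}
    joint = (
        np.zeros((proj.n_proj[pops[0]] + 1, proj.n_proj[pops[1]] + 1)) if len(pops) == 2 else None
    )
    for s in np.flatnonzero(usable):
        vecs = {p: project_site(int(derived[p][s]), int(called[p][s]), proj.n_proj[p]) for p in pops}
        for p in pops:
            marginal[p] += vecs[p]
        if joint is not None:
            joint += np.outer(vecs[pops[0]], vecs[pops[1]])
    if folded:
        marginal = {p: _fold_marginal(v) for p, v in marginal.items()}
        if joint is not None:
            joint = _fold_joint(joint)
    return SpectrumResult(
        marginal=marginal,
        joint=joint,
        pops=pops,
        sites_used=int(usable.sum()),
        sites_dropped=int((~usable).sum()),
        folded=folded,
    )


def choose_projection(
    gm: GenotypeMatrix,
    pop_assignment: dict[str, str] | None = None,
    strategy: str = "MAX_SEG_SITES",
) -> ProjectionSpec:
    """Pick, per population, the projection size maximizing the expected
    number of segregating sites (projected mass outside the monomorphic
    bins); ties go to the larger projection."""
    if strategy != "MAX_SEG_SITES":
        raise ValueError(f"unknown projection strategy {strategy!r}")
    if gm.n_sites == 0:
        raise ValueError("empty genotype matrix")
    pop_rows = _pop_rows(gm, pop_assignment)
    called, derived = _site_counts(gm, pop_rows)
    choice = {}
    for p, rows in pop_rows.items():
        best_n, best_score = None, -1.0
        for n_proj in range(2, rows.size + 1):
            score = 0.0
            ok = called[p] >= n_proj
            for s in np.flatnonzero(ok):
                v = project_site(int(derived[p][s]), int(called[p][s]), n_proj)
                score += 1.0 - v[0] - v[-1]
            if score >= best_score:  # >= : ties resolved toward larger n_proj
                best_n, best_score = n_proj, score
        choice[p] = best_n
    return ProjectionSpec(n_proj=choice)


def write_marginal_sfs(result: SpectrumResult, pop: str, path) -> None:
    """Write one marginal spectrum as a single whitespace-separated line."""
    v = result.marginal[pop]
    with open(path, "w") as fh:
        fh.write(" ".join(f"{x:.6f}" for x in v) + "\n")
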