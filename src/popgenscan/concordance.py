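"""Agreement between two SNP call sets on shared samples.

Quantifies how well a sparse low-coverage call set (the "query", e.g.
GBS) reproduces a benchmark call set (the "reference", e.g. WGS):
a site partition (shared-concordant / shared-ALT-discordant / novel),
per-genotype-class match rates conditioned on the reference call, the
allele-sharing distance matrix, and the Pearson correlation between two
distance matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from ._util import percent
from .vcfio import GenotypeMatrix, intersect_sites

__all__ = [
    "ConcordanceReport",
    "classify_sites",
    "genotype_match_rates",
    "allele_sharing_distance",
    "matrix_correlation",
]

_CLASS_NAMES = {0: "RR", 1: "RA", 2: "AA"}


@dataclass(frozen=True)
class ConcordanceReport:
    """Site-partition counts for a query call set against a reference.

    Every query site belongs to exactly one of: allele-concordant shared
    (same position, same ALT), ALT-discordant shared (same position,
    different ALT), or novel (position absent from the reference set).
    Percentages are reported to two decimals, rounded half-up, so that
    printed percentages are exactly recomputable from the counts.
    """

    query_loci: int
    shared: int
    concordant: int
    discordant: int
    novel: int

    def __post_init__(self) -> None:
        if self.shared + self.novel != self.query_loci:
            raise ValueError("shared + novel must equal query loci")
        if self.concordant + self.discordant != self.shared:
            raise ValueError("concordant + discordant must equal shared")
        if min(self.query_loci, self.shared, self.concordant, self.discordant, self.novel) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def shared_pct(self) -> float:
        return percent(self.shared, self.query_loci)

    @property
    def concordance_pct(self) -> float:
        return percent(self.concordant, self.shared)

    @property
    def novel_pct(self) -> float:
        return percent(self.novel, self.query_loci)

    def to_json(self) -> str:
        d = asdict(self)
        d.update(
            shared_pct=self.shared_pct,
            concordance_pct=self.concordance_pct,
            novel_pct=self.novel_pct,
        )
        return json.dumps(d, indent=2)

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        for k, v in json.loads(self.to_json()).items():
            lines.append(f"{k}\t{v}")
        return "\n".join(lines) + "\n"


def classify_sites(query: GenotypeMatrix, reference: GenotypeMatrix) -> ConcordanceReport:
    """Partition every query site against the reference call set."""
    if not set(query.samples) & set(reference.samples):
        raise ValueError("query and reference share no sample identifiers")
    ref_alt = {k: a for k, a in zip(reference.site_keys(), reference.alt)}
    shared = concordant = 0
    for key, alt in zip(query.site_keys(), query.alt):
        if key in ref_alt:
            shared += 1
            if ref_alt[key] == alt:
                concordant += 1
    return ConcordanceReport(
        query_loci=query.n_sites,
        shared=shared,
        concordant=concordant,
        discordant=shared - concordant,
        novel=query.n_sites - shared,
    )


def genotype_match_rates(
    query: GenotypeMatrix, reference: GenotypeMatrix
) -> dict[str, float | None]:
    """Per-genotype-class match rates over shared samples at
    allele-concordant shared sites.

    The class (RR / RA / AA) is taken from the reference call — the
    benchmark framing — and a comparison enters the denominator only
    when both calls are non-missing.  A class with no comparable
    genotype is reported as None.
    """
    shared_samples = [s for s in query.samples if s in set(reference.samples)]
    if not shared_samples:
        raise ValueError("query and reference share no sample identifiers")
    q, r = intersect_sites(query, reference)
    conc = np.array([a == b for a, b in zip(q.alt, r.alt)], dtype=bool)
    q = q.subset_sites(conc)
    r = r.subset_sites(conc)
    qg = q.subset_samples(shared_samples).geno
    rg = r.subset_samples(shared_samples).geno

    comparable = (qg >= 0) & (rg >= 0)
    rates: dict[str, float | None] = {}
    for cls, name in _CLASS_NAMES.items():
        mask = comparable & (rg == cls)
        denom = int(mask.sum())
        rates[name] = float((qg[mask] == cls).mean()) if denom else None
    return rates


def allele_sharing_distance(gm: GenotypeMatrix) -> np.ndarray:
    """Pairwise allele-sharing distance: mean over co-called sites of
    |g_i - g_j| / 2.  Symmetric, zero diagonal, values in [0, 1]."""
    if gm.n_samples < 2:
        raise ValueError("need at least two samples")
    g = gm.geno.astype(np.float64)
    called = g >= 0
    gz = np.where(called, g, 0.0)
    c = called.astype(np.float64)
    # co-called counts and summed |gi - gj| via the polarization identity
    n_pair = c @ c.T
    zero = np.argwhere(n_pair == 0)
    if zero.size:
        i, j = zero[0]
        raise ValueError(
            f"samples {gm.samples[int(i)]!r} and {gm.samples[int(j)]!r} share no called sites"
        )
    # |gi-gj| for codes in {0,1,2}: sum via direct pair loop is O(n^2 m);
    # use (gi-gj)^2 decomposition plus the fact |d| = d^2 - correction only
    # for |d|<=2 with d integer: |d| = (d^2 + |d|) - d^2 ... not linear, so
    # compute per-pair with masked matrix algebra on indicator channels.
    ind = np.stack([(g == k) & called for k in (0, 1, 2)]).astype(np.float64)
    # counts of (k, l) genotype pairings: N_kl = ind_k @ ind_l.T
    dist_sum = np.zeros((gm.n_samples, gm.n_samples))
    for k in range(3):
        for l in range(3):
            if k == l:
                continue
            dist_sum += abs(k - l) / 2.0 * (ind[k] @ ind[l].T)
    d = dist_sum / n_pair
    np.fill_diagonal(d, 0.0)
    return d


def matrix_correlation(d1: np.ndarray, d2: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (with t-test p-value) between the strictly
    lower triangles of two same-shape distance matrices."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape or d1.ndim != 2 or d1.shape[0] != d1.shape[1]:
        raise ValueError("matrices must be square and of identical shape")
    i, j = np.tril_indices(d1.shape[0], k=-1)
    x, y = d1[i, j], d2[i, j]
    if x.size < 3:
        raise ValueError("need at least three off-diagonal pairs")
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("zero variance in a distance vector")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def write_distance_matrix(d: np.ndarray, labels: list[str], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for lab, row in zip(labels, d):
            fh.write(lab + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
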