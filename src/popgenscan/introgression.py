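"""Patterson's D statistic ("ABBA-BABA") on population allele
frequencies, with block-jackknife standard errors.

For an ordered quadruple ((P1, P2), P3, Outgroup) and per-population
derived-allele frequencies p1..p4 at a site (derived = the allele that
is rare/absent in the outgroup), the discordant site-pattern weights
are

    ABBA = (1 - p1) * p2 * p3 * (1 - p4)
    BABA = p1 * (1 - p2) * p3 * (1 - p4)

and D = sum(ABBA - BABA) / sum(ABBA + BABA).  Under tree-like ancestry
(no gene flow between P3 and either of P1/P2) E[D] = 0; an excess of
ABBA (D > 0) indicates gene flow between P3 and P2, of BABA (D < 0)
between P3 and P1.  The standard error comes from a delete-one
jackknife over contiguous genomic blocks, which is robust to linkage;
|Z| >= 3 is the conventional significance line.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .vcfio import GenotypeMatrix

__all__ = ["DstatResult", "d_statistic", "all_quadruples", "write_dstat_table"]


@dataclass(frozen=True)
class DstatResult:
    p1: str
    p2: str
    p3: str
    outgroup: str
    abba: float
    baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int

    @property
    def significant(self) -> bool:
        """|Z| >= 3 convention; no multiple-testing correction."""
        return abs(self.z) >= 3.0


def _site_patterns(
    gm: GenotypeMatrix,
    p1, p2, p3, outgroup,
    polarize_max: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site (ABBA, BABA, usable) with outgroup-based polarization.

    The derived allele is the outgroup minor allele; sites where the
    outgroup ALT frequency falls strictly inside
    (polarize_max, 1 - polarize_max) are dropped as unpolarizable, as
    are sites with no called allele in any population.
    """
    freqs = [gm.allele_frequencies(p) for p in (p1, p2, p3, outgroup)]
    usable = np.all(np.isfinite(freqs), axis=0)
    f4 = freqs[3]
    with np.errstate(invalid="ignore"):
        polarizable = (f4 <= polarize_max) | (f4 >= 1.0 - polarize_max)
    usable &= polarizable
    flip = f4 >= 0.5  # ALT is the outgroup major allele -> derived is REF
    der = [np.where(flip, 1.0 - f, f) for f in freqs]
    q1, q2, q3, q4 = der
    abba = (1.0 - q1) * q2 * q3 * (1.0 - q4)
    baba = q1 * (1.0 - q2) * q3 * (1.0 - q4)
    abba = np.where(usable, abba, 0.0)
    baba = np.where(usable, baba, 0.0)
    return abba, baba, usable


def d_statistic(
    gm: GenotypeMatrix,
    p1: str | list[str],
    p2: str | list[str],
    p3: str | list[str],
    outgroup: str | list[str],
    block_bp: int = 5_000_000,
    min_blocks: int = 20,
    polarize_max: float = 0.1,
) -> DstatResult:
    """Patterson's D for one population quadruple.

    Blocks are contiguous genomic spans of ``block_bp``; when the data
    span fewer than ``min_blocks`` such blocks, the block size shrinks
    so that at least ``min_blocks`` are formed (block count takes
    precedence over block size on short synthetic chromosomes).
    """
    groups = [_l(p1), _l(p2), _l(p3), _l(outgroup)]
    flat = [x for g in groups for x in g]
    if len(set(flat)) != len(flat):
        raise ValueError("the four population groups must be disjoint")
    abba, baba, usable = _site_patterns(gm, *groups, polarize_max)
    total = float((abba + baba).sum())
    if total == 0:
        raise ValueError("D undefined: no informative (ABBA+BABA > 0) site")

    # contiguous blocks along the genome
    span = sum(
        int(gm.pos[gm.chrom == c].max() - gm.pos[gm.chrom == c].min()) + 1
        for c in dict.fromkeys(gm.chrom.tolist())
    )
    if span / block_bp < min_blocks:
        block_bp = max(1, span // min_blocks)
    block_id = np.empty(gm.n_sites, dtype=np.int64)
    next_block = 0
    for c in dict.fromkeys(gm.chrom.tolist()):
        on = gm.chrom == c
        rel = (gm.pos[on] - gm.pos[on].min()) // block_bp
        block_id[on] = next_block + rel
        next_block = int(block_id[on].max()) + 1

    informative = usable & ((abba + baba) > 0)
    blocks = np.unique(block_id[informative])
    if blocks.size < 2:
        raise ValueError("need at least two non-empty blocks for the jackknife")

    num_b = np.array([float((abba - baba)[informative & (block_id == b)].sum()) for b in blocks])
    den_b = np.array([float((abba + baba)[informative & (block_id == b)].sum()) for b in blocks])
    d = num_b.sum() / den_b.sum()
    d_loo = (num_b.sum() - num_b) / (den_b.sum() - den_b)
    m = blocks.size
    se = float(np.sqrt((m - 1) / m * ((d_loo - d_loo.mean()) ** 2).sum()))
    z = d / se if se > 0 else (0.0 if d == 0 else np.inf * np.sign(d))
    return DstatResult(
        p1="+".join(groups[0]),
        p2="+".join(groups[1]),
        p3="+".join(groups[2]),
        outgroup="+".join(groups[3]),
        abba=float(abba[informative].sum()),
        baba=float(baba[informative].sum()),
        d=float(d),
        se=se,
        z=float(z),
        n_blocks=int(m),
        n_sites=int(informative.sum()),
    )


def _l(x) -> list[str]:
    return [x] if isinstance(x, str) else list(x)


def all_quadruples(
    gm: GenotypeMatrix,
    populations: list[str],
    outgroup: str | list[str],
    **kwargs,
) -> list[DstatResult]:
    """Every distinct test ((P1, P2), P3, outgroup) over the listed
    populations: unordered {P1, P2} pairs (the swap only flips the sign
    of D) crossed with each remaining population as P3."""
    if len(populations) < 3:
        raise ValueError("need at least three non-outgroup populations")
    out = []
    for pair in itertools.combinations(sorted(populations), 2):
        for p3 in sorted(set(populations) - set(pair)):
            out.append(d_statistic(gm, pair[0], pair[1], p3, outgroup, **kwargs))
    return out


def write_dstat_table(results: list[DstatResult], path, header: str | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#P1\tP2\tP3\tP4\tD\tSE\tZ\tnBlocks\tnSites\tsignificant\n")
        for r in results:
            fh.write(
                f"{r.p1}\t{r.p2}\t{r.p3}\t{r.outgroup}\t{r.d:.6g}\t{r.se:.6g}\t"
                f"{r.z:.6g}\t{r.n_blocks}\t{r.n_sites}\t{'|Z|>=3' if r.significant else 'ns'}\n"
            )
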