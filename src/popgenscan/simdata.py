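"""Synthetic multi-population SNP genotype data with known divergence,
known selective sweeps, and a low-coverage reduced-representation
("GBS-like") re-call of selected samples.

The demographic model is a fixed five-population tree

    (((target, sister), distant), outgroup1), outgroup2

mimicking a West-African zebu study design: a target population
(Nigerian-zebu-like), a closely related zebu control, a distantly
related taurine control, and two outgroup species (banteng- and water
buffalo-like) for polarization and rooting.

Allele frequencies evolve by Balding-Nichols beta drift: along a branch
of t generations in a population of effective size Ne, the child
frequency is drawn from Beta with mean p and variance F*p*(1-p) where
F = 1 - exp(-t / (2*Ne)).  Two populations whose connecting branches
each span t generations therefore show expected FST of 1 - exp(-t/(2Ne))
under ratio-of-averages Hudson/Weir-Cockerham estimation, which gives
the downstream estimators an analytic recovery target.

Sweeps are deterministic frequency distortions confined to the target
branch: within a radius of the sweep center the derived (ALT) frequency
is pushed toward fixation, at near-full intensity across the sweep core
and decaying quadratically to zero at the affected radius.  The
distortion is a ground-truth device for validating the PBS and CLR
scans, not a hitchhiking simulation.

Optional directed gene flow mixes a fraction of a source population's
allele frequencies into a destination population after divergence,
giving the introgression tests a known alternative hypothesis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._util import MISSING, rng_for
from .vcfio import GenotypeMatrix

__all__ = [
    "DemographyConfig",
    "SweepSpec",
    "PlatformConfig",
    "simulate_truth",
    "emulate_platform",
    "write_sweep_truth",
    "read_sweep_truth",
]

_ROLES = ("target", "sister", "distant", "outgroup1", "outgroup2")


@dataclass(frozen=True)
class DemographyConfig:
    """Study design for the five-population divergence simulation.

    ``sample_sizes`` are haploid counts (must be even; individuals are
    diploid).  ``split_times`` are generations before present for, in
    order: the target/sister split, the distant-control split, the
    first-outgroup split, and the second-outgroup split; they must be
    increasing.  ``mutation_density`` is the expected number of
    segregating sites per bp.
    """

    labels: tuple[str, str, str, str, str] = ("NGZ", "EAZ", "EUT", "BAN", "BUF")
    sample_sizes: tuple[int, int, int, int, int] = (60, 24, 24, 12, 8)
    ne: tuple[float, float, float, float, float] = (1000.0, 1000.0, 1000.0, 1000.0, 1000.0)
    ancestral_ne: float = 1000.0
    split_times: tuple[float, float, float, float] = (200.0, 500.0, 2000.0, 2600.0)
    mutation_density: float = 0.002
    chrom_lengths: dict[str, int] = field(default_factory=lambda: {"1": 2_000_000})
    seed: int = 0
    freq_floor: float = 0.05
    gene_flow: tuple[tuple[str, str, float], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.labels)) != 5:
            raise ValueError("population labels must be five unique names")
        if any(n <= 0 or n % 2 for n in self.sample_sizes):
            raise ValueError("haploid sample sizes must be positive and even")
        if any(x <= 0 for x in self.ne) or self.ancestral_ne <= 0:
            raise ValueError("effective sizes must be positive")
        if any(t <= 0 for t in self.split_times) or list(self.split_times) != sorted(
            self.split_times
        ):
            raise ValueError("split times must be positive and increasing")
        if self.mutation_density <= 0:
            raise ValueError("mutation density must be positive")
        if not self.chrom_lengths or any(v <= 0 for v in self.chrom_lengths.values()):
            raise ValueError("chromosome lengths must be positive")
        for src, dst, w in self.gene_flow:
            if src not in self.labels or dst not in self.labels or src == dst:
                raise ValueError(f"gene-flow edge {src}->{dst} must join two populations")
            if not 0.0 <= w <= 1.0:
                raise ValueError("gene-flow weight must lie in [0, 1]")

    def role(self, name: str) -> str:
        return self.labels[_ROLES.index(name)]


@dataclass(frozen=True)
class SweepSpec:
    """A localized selective sweep in the target population.

    ``intensity`` in [0, 1] controls how strongly the derived (ALT)
    frequency is pushed toward 1 within ``radius`` bp of ``center``;
    the push tapers linearly with distance from the center.
    """

    chrom: str
    center: int
    radius: int
    intensity: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sweep radius must be positive")
        if not 0.0 <= self.intensity <= 1.0:
            raise ValueError("sweep intensity must lie in [0, 1]")


@dataclass(frozen=True)
class PlatformConfig:
    """Low-coverage re-sequencing emulation.

    ``retention`` models restriction-site subsetting (each site kept
    independently); ``mean_depth`` is the Poisson read-depth mean per
    retained genotype; ``base_error`` is the per-read error rate; calls
    whose phred genotype quality falls below ``gq_floor`` are set
    missing (0 disables the floor).
    """

    retention: float = 0.5
    mean_depth: float = 4.87
    base_error: float = 0.005
    gq_floor: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.retention <= 1.0:
            raise ValueError("retention must lie in (0, 1]")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")
        if not 0.0 <= self.base_error < 0.5:
            raise ValueError("base error rate must lie in [0, 0.5)")


# ---------------------------------------------------------------------------
# truth simulation
# ---------------------------------------------------------------------------

def _drift(rng: np.random.Generator, p: np.ndarray, fst: float) -> np.ndarray:
    """Balding-Nichols beta perturbation with variance F*p*(1-p)."""
    if fst <= 0:
        return p.copy()
    scale = (1.0 - fst) / fst
    out = p.copy()
    inner = (p > 0) & (p < 1)
    out[inner] = rng.beta(p[inner] * scale, (1.0 - p[inner]) * scale)
    return out


def _branch_fst(t: float, ne: float) -> float:
    return 1.0 - float(np.exp(-t / (2.0 * ne)))


def _neutral_frequencies(rng: np.random.Generator, size: int, floor: float) -> np.ndarray:
    # density ~ 1/p truncated to [floor, 1-floor]; inverse-CDF sampling
    u = rng.random(size)
    return floor * ((1.0 - floor) / floor) ** u


def simulate_truth(
    config: DemographyConfig, sweeps: list[SweepSpec] | None = None
) -> tuple[GenotypeMatrix, list[SweepSpec]]:
    """Simulate diploid genotypes for the five populations.

    Returns the genotype matrix and the sweep truth record (the sweeps
    actually applied).  Output is byte-deterministic under the config
    seed.
    """
    sweeps = list(sweeps or [])
    for sw in sweeps:
        if sw.chrom not in config.chrom_lengths:
            raise ValueError(f"sweep chromosome {sw.chrom!r} not in config")
        if not 1 <= sw.center <= config.chrom_lengths[sw.chrom]:
            raise ValueError(f"sweep center {sw.center} outside chromosome {sw.chrom}")
    by_chrom: dict[str, list[SweepSpec]] = {}
    for sw in sweeps:
        by_chrom.setdefault(sw.chrom, []).append(sw)
    for chrom, group in by_chrom.items():
        ivals = sorted((s.center - s.radius, s.center + s.radius) for s in group)
        for (a0, a1), (b0, _b1) in zip(ivals, ivals[1:]):
            if b0 <= a1:
                raise ValueError(f"overlapping sweeps on chromosome {chrom}")

    t1, t2, t3, t4 = config.split_times
    ne_t, ne_s, ne_d, ne_o1, ne_o2 = config.ne
    ne_a = config.ancestral_ne

    all_chrom: list[str] = []
    all_pos: list[np.ndarray] = []
    freqs = {name: [] for name in _ROLES}
    for ci, (chrom, length) in enumerate(sorted(config.chrom_lengths.items())):
        rng = rng_for(config.seed, 1, ci)
        n_sites = int(round(config.mutation_density * length))
        if n_sites <= 0:
            raise ValueError(f"zero sites requested on chromosome {chrom}")
        pos = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1

        p_root = _neutral_frequencies(rng, n_sites, config.freq_floor)
        p_og2 = _drift(rng, p_root, _branch_fst(t4, ne_o2))
        p_n3 = _drift(rng, p_root, _branch_fst(t4 - t3, ne_a))
        p_og1 = _drift(rng, p_n3, _branch_fst(t3, ne_o1))
        p_n2 = _drift(rng, p_n3, _branch_fst(t3 - t2, ne_a))
        p_dist = _drift(rng, p_n2, _branch_fst(t2, ne_d))
        p_n1 = _drift(rng, p_n2, _branch_fst(t2 - t1, ne_a))
        p_target = _drift(rng, p_n1, _branch_fst(t1, ne_t))
        p_sister = _drift(rng, p_n1, _branch_fst(t1, ne_s))

        by_role = dict(
            zip(_ROLES, (p_target, p_sister, p_dist, p_og1, p_og2))
        )
        label_to_role = dict(zip(config.labels, _ROLES))
        for src, dst, weight in config.gene_flow:
            s, d_role = label_to_role[src], label_to_role[dst]
            by_role[d_role] = (1.0 - weight) * by_role[d_role] + weight * by_role[s]

        for sw in by_chrom.get(chrom, []):
            d = np.abs(pos - sw.center)
            # quadratic taper: near-full push across the sweep core,
            # decaying to zero at the affected radius
            w = np.clip(1.0 - (d / sw.radius) ** 2, 0.0, 1.0)
            push = sw.intensity * w
            by_role["target"] = by_role["target"] + push * (1.0 - by_role["target"])

        all_chrom.extend([chrom] * n_sites)
        all_pos.append(pos)
        for name in _ROLES:
            freqs[name].append(by_role[name])

    samples: list[str] = []
    pops: list[str] = []
    blocks: list[np.ndarray] = []
    total_sites = int(sum(p.size for p in all_pos))
    for ri, role in enumerate(_ROLES):
        label = config.labels[ri]
        n_dip = config.sample_sizes[ri] // 2
        rng = rng_for(config.seed, 2, ri)
        p = np.concatenate(freqs[role])
        g = rng.binomial(2, p[None, :].repeat(n_dip, axis=0)).astype(np.int8)
        blocks.append(g)
        samples.extend(f"{label}_{i:03d}" for i in range(n_dip))
        pops.extend([label] * n_dip)
        assert g.shape == (n_dip, total_sites)

    geno = np.concatenate(blocks, axis=0)
    n_total = geno.shape[1]
    rng = rng_for(config.seed, 3)
    bases = np.array(list("ACGT"), dtype=object)
    ref_i = rng.integers(0, 4, size=n_total)
    alt_i = (ref_i + rng.integers(1, 4, size=n_total)) % 4

    gm = GenotypeMatrix(
        samples=samples,
        populations=np.array(pops, dtype=object),
        chrom=np.array(all_chrom, dtype=object),
        pos=np.concatenate(all_pos),
        ref=bases[ref_i],
        alt=bases[alt_i],
        geno=geno,
        chrom_lengths=dict(config.chrom_lengths),
    )
    return gm, sweeps


# ---------------------------------------------------------------------------
# platform emulation
# ---------------------------------------------------------------------------

def _alt_read_prob(base_error: float) -> np.ndarray:
    return np.array([base_error, 0.5, 1.0 - base_error])


def emulate_platform(
    truth: GenotypeMatrix, platform: PlatformConfig, samples: list[str]
) -> GenotypeMatrix:
    """Re-call a sample subset through a low-coverage platform model.

    Each site is retained independently with the retention probability;
    at retained sites each genotype receives a Poisson read depth, reads
    are drawn binomially from the true alleles with the base-error rate,
    and the genotype is re-called by flat-prior maximum likelihood over
    {RR, RA, AA} (ties resolved toward RR).  Depth 0 gives a missing
    call.  Positions, alleles and sample order are never altered.
    """
    if not samples:
        raise ValueError("sample subset must be non-empty")
    sub = truth.subset_samples(samples)
    rng = rng_for(platform.seed, 7)

    keep = rng.random(sub.n_sites) < platform.retention
    sub = sub.subset_sites(keep)

    g = sub.geno
    depth = rng.poisson(platform.mean_depth, size=g.shape)
    p_alt = _alt_read_prob(platform.base_error)
    true_p = np.where(g >= 0, p_alt[np.clip(g, 0, 2)], 0.0)
    alt_reads = rng.binomial(depth, true_p)

    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.log(p_alt)
        log1m = np.log(1.0 - p_alt)
        # log-likelihood per candidate genotype, shape (3, n_samples, n_sites);
        # 0 * log(0) is a zero contribution, not NaN
        a = alt_reads[None, :, :]
        ra = (depth - alt_reads)[None, :, :]
        term_alt = np.where(a > 0, a * logp[:, None, None], 0.0)
        term_ref = np.where(ra > 0, ra * log1m[:, None, None], 0.0)
        ll = term_alt + term_ref
    ll = np.nan_to_num(ll, nan=-np.inf)
    call = np.argmax(ll, axis=0).astype(np.int8)  # first max -> ties toward RR

    if platform.gq_floor > 0:
        order = np.sort(ll, axis=0)
        gq = 10.0 / np.log(10.0) * (order[-1] - order[-2])
        call = np.where(gq < platform.gq_floor, MISSING, call).astype(np.int8)

    call = np.where((depth == 0) | (g < 0), MISSING, call).astype(np.int8)

    out = sub
    out.geno[:, :] = call
    return out


def genotype_miscall_probability(
    true_genotype: int, mean_depth: float, base_error: float, max_depth: int = 64
) -> float:
    """Exact P(re-call != g | true g, depth >= 1) by enumeration.

    Enumerates read depth (Poisson, truncated at ``max_depth`` which must
    cover essentially all mass) and alt-read counts, applying the same
    flat-prior ML call rule (ties toward RR) as :func:`emulate_platform`.
    """
    if true_genotype not in (0, 1, 2):
        raise ValueError("true genotype must be 0, 1 or 2")
    p_alt = _alt_read_prob(base_error)
    total = 0.0
    norm = 0.0
    for d in range(1, max_depth + 1):
        pd = stats.poisson.pmf(d, mean_depth)
        norm += pd
        a = np.arange(d + 1)
        pa = stats.binom.pmf(a, d, p_alt[true_genotype])
        with np.errstate(divide="ignore", invalid="ignore"):
            t_alt = np.where(a[None, :] > 0, a[None, :] * np.log(p_alt)[:, None], 0.0)
            t_ref = np.where(
                (d - a)[None, :] > 0,
                (d - a)[None, :] * np.log(1.0 - p_alt)[:, None],
                0.0,
            )
        ll = np.nan_to_num(t_alt + t_ref, nan=-np.inf)
        miscalled = np.argmax(ll, axis=0) != true_genotype
        total += pd * float(pa[miscalled].sum())
    return total / norm


def het_miscall_probability(mean_depth: float, base_error: float, max_depth: int = 64) -> float:
    """Exact P(re-call != RA | true RA, depth >= 1); see
    :func:`genotype_miscall_probability`."""
    return genotype_miscall_probability(1, mean_depth, base_error, max_depth)


# ---------------------------------------------------------------------------
# truth record I/O
# ---------------------------------------------------------------------------

def write_sweep_truth(sweeps: list[SweepSpec], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("#chrom\tcenter\tradius\tintensity\n")
        for sw in sweeps:
            fh.write(f"{sw.chrom}\t{sw.center}\t{sw.radius}\t{sw.intensity}\n")


def read_sweep_truth(path) -> list[SweepSpec]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            c, ce, r, i = line.rstrip("\n").split("\t")
            out.append(SweepSpec(c, int(ce), int(r), float(i)))
    return out
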