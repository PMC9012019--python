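"""VCF input/output, the genotype matrix container, site filters, and
region intersection of two call sets.

The :class:`GenotypeMatrix` is the carrier between every pipeline stage:
an ordered samples x sites array of diploid genotype codes
(0 = homozygous reference RR, 1 = heterozygous RA, 2 = homozygous
alternate AA, -1 = missing) plus site records (chromosome, 1-based
position, REF, ALT) and a population label per sample.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace

import numpy as np

from ._util import MISSING, percent  # noqa: F401  (percent re-exported for reports)


class VcfParseError(ValueError):
    """Raised when a VCF cannot be parsed into a genotype matrix."""


@dataclass
class GenotypeMatrix:
    """Diploid genotypes for an ordered sample set at an ordered site set.

    Parameters
    ----------
    samples : list of str
        Sample identifiers, in column order of the source VCF.
    populations : ndarray of str
        Population label per sample (empty string when unassigned).
    chrom, pos, ref, alt : ndarray
        Per-site records; ``pos`` is 1-based and strictly increasing
        within each chromosome.
    geno : ndarray of int8, shape (n_samples, n_sites)
        Genotype codes; -1 marks a missing call.
    """

    samples: list[str]
    populations: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    geno: np.ndarray
    chrom_lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.populations = np.asarray(self.populations, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.samples), self.pos.size):
            raise ValueError(
                f"genotype array shape {self.geno.shape} does not match "
                f"{len(self.samples)} samples x {self.pos.size} sites"
            )
        if self.populations.size != len(self.samples):
            raise ValueError("one population label required per sample")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample identifiers must be unique")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {c}")

    # -- basic properties -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_sites(self) -> int:
        return int(self.pos.size)

    def population_labels(self) -> list[str]:
        seen: list[str] = []
        for p in self.populations:
            if p and p not in seen:
                seen.append(p)
        return seen

    # -- subsetting -------------------------------------------------------
    def sample_indices(self, population: str | list[str]) -> np.ndarray:
        pops = [population] if isinstance(population, str) else list(population)
        idx = np.flatnonzero(np.isin(self.populations, pops))
        if idx.size == 0:
            raise KeyError(f"no samples with population label(s) {pops}")
        return idx

    def subset_samples(self, samples: list[str]) -> "GenotypeMatrix":
        index = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not present: {missing}")
        idx = np.array([index[s] for s in samples], dtype=int)
        return replace(
            self,
            samples=list(samples),
            populations=self.populations[idx].copy(),
            geno=self.geno[idx].copy(),
        )

    def subset_sites(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return replace(
            self,
            chrom=self.chrom[idx].copy(),
            pos=self.pos[idx].copy(),
            ref=self.ref[idx].copy(),
            alt=self.alt[idx].copy(),
            geno=self.geno[:, idx].copy(),
        )

    def with_populations(self, mapping: dict[str, str]) -> "GenotypeMatrix":
        labels = np.array([mapping.get(s, "") for s in self.samples], dtype=object)
        return replace(self, populations=labels)

    # -- per-site summaries -----------------------------------------------
    def allele_counts(self, population: str | list[str] | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Alt-allele count j and called-allele count n per site.

        Missing genotypes contribute to neither count.
        """
        if population is None:
            g = self.geno
        else:
            g = self.geno[self.sample_indices(population)]
        called = g >= 0
        n = 2 * called.sum(axis=0)
        j = np.where(called, g, 0).sum(axis=0)
        return j.astype(np.int64), n.astype(np.int64)

    def allele_frequencies(self, population: str | list[str] | None = None) -> np.ndarray:
        """Alt-allele frequency per site; NaN where no allele is called."""
        j, n = self.allele_counts(population)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, j / np.maximum(n, 1), np.nan)

    def call_rate(self) -> np.ndarray:
        return (self.geno >= 0).mean(axis=0)

    def site_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.chrom.tolist(), self.pos.tolist()))

    def equal_genotypes(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.site_keys() == other.site_keys()
            and bool(np.array_equal(self.geno, other.geno))
        )


@dataclass(frozen=True)
class FilterSpec:
    """Site filter: minimum genotype call rate, biallelic/segregating
    requirement, and an optional minimum minor-allele count."""

    min_call_rate: float = 0.9
    biallelic_only: bool = True
    min_mac: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_call_rate <= 1.0:
            raise ValueError("min_call_rate must lie in [0, 1]")
        if self.min_mac is not None and self.min_mac < 0:
            raise ValueError("min_mac must be non-negative")


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------

# gts012 convention: 0=RR, 1=RA, 2=AA, 3=missing
_GT_FROM_CYVCF2 = {0: 0, 1: 1, 2: 2, 3: MISSING}


def read_population_map(path) -> dict[str, str]:
    """Two-column tab-separated sample -> population table."""
    mapping: dict[str, str] = {}
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
            mapping[parts[0]] = parts[1]
    return mapping


def read_vcf(
    path,
    biallelic_only: bool = True,
    populations: dict[str, str] | None = None,
    min_gq: float | None = None,
) -> GenotypeMatrix:
    """Read a (possibly gzip-compressed) VCF 4.2 into a genotype matrix.

    Multiallelic records are skipped when ``biallelic_only`` is set and
    rejected otherwise.  Phased separators are accepted; phase is not
    retained.  When ``min_gq`` is given and the GQ FORMAT field is
    present, calls below the floor are set missing; files without GQ are
    accepted unchanged.
    """
    import cyvcf2

    try:
        vcf = cyvcf2.VCF(str(path), gts012=True)
    except Exception as exc:  # htslib reports its own diagnostics
        raise VcfParseError(f"cannot open {path}: {exc}") from exc

    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"{path}: no samples / no GT field in header")

    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    chrom_lengths: dict[str, int] = {}
    for name, length in zip(vcf.seqnames, vcf.seqlens or []):
        if length:
            chrom_lengths[name] = int(length)

    for recno, var in enumerate(vcf, 1):
        if len(var.ALT) != 1:
            if biallelic_only:
                continue
            raise VcfParseError(
                f"{path}: record {recno} ({var.CHROM}:{var.POS}) is not biallelic"
            )
        gt = np.array([_GT_FROM_CYVCF2[g] for g in var.gt_types], dtype=np.int8)
        if min_gq is not None:
            gq = var.format("GQ")
            if gq is not None:
                gq = np.asarray(gq, dtype=float).reshape(-1)
                gt = np.where(gq < min_gq, MISSING, gt).astype(np.int8)
        chroms.append(var.CHROM)
        positions.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        rows.append(gt)
    vcf.close()

    geno = (
        np.stack(rows, axis=1) if rows else np.zeros((len(samples), 0), dtype=np.int8)
    )
    gm = GenotypeMatrix(
        samples=samples,
        populations=np.array([""] * len(samples), dtype=object),
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        geno=geno,
        chrom_lengths=chrom_lengths,
    )
    if populations is not None:
        gm = gm.with_populations(populations)
    return gm


_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with a GT FORMAT field.

    The writer is plain text and fully deterministic: the same matrix
    always produces the same bytes.
    """
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=popgenscan\n")
        for name in sorted(gm.chrom_lengths):
            fh.write(f"##contig=<ID={name},length={gm.chrom_lengths[name]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for s in range(gm.n_sites):
            gts = "\t".join(_GT_STRING[int(g)] for g in gm.geno[:, s])
            fh.write(
                f"{gm.chrom[s]}\t{gm.pos[s]}\t.\t{gm.ref[s]}\t{gm.alt[s]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# filtering and intersection
# ---------------------------------------------------------------------------

def filter_sites(gm: GenotypeMatrix, spec: FilterSpec) -> GenotypeMatrix:
    """Retain sites passing the call-rate / biallelic / MAC filter.

    Site order is preserved; the operation is idempotent. ``biallelic_only``
    additionally requires a segregating minor allele (every retained site
    has both alleles observed), matching the 'biallelic SNP' usage for
    call sets that may contain monomorphic records.
    """
    keep = gm.call_rate() >= spec.min_call_rate
    if spec.biallelic_only or spec.min_mac is not None:
        j, n = gm.allele_counts()
        mac = np.minimum(j, n - j)
        floor = max(1 if spec.biallelic_only else 0, spec.min_mac or 0)
        keep &= (n > 0) & (mac >= floor)
    return gm.subset_sites(keep)


def intersect_sites(a: GenotypeMatrix, b: GenotypeMatrix) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Restrict both call sets to (chromosome, position) pairs present in
    both, in matching site order.

    Sites whose ALT alleles differ between the two sets are retained (the
    concordance report classifies them); only positional co-occurrence is
    required here.
    """
    keys_a = a.site_keys()
    keys_b = b.site_keys()
    common = set(keys_a) & set(keys_b)
    idx_a = np.array([i for i, k in enumerate(keys_a) if k in common], dtype=int)
    pos_b = {k: i for i, k in enumerate(keys_b)}
    idx_b = np.array([pos_b[keys_a[i]] for i in idx_a], dtype=int)
    return a.subset_sites(idx_a), b.subset_sites(idx_b)
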