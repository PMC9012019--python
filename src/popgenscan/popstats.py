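"""Windowed nucleotide diversity, FST, the population branch statistic
(PBS), and empirical top-quantile outlier calling.

Per-site nucleotide diversity uses the unbiased pairwise-heterozygosity
form pi = 2 j (n - j) / (n (n - 1)) for j ALT alleles among n called
alleles; window values are the site sum divided by the window span in
bp.  FST offers the Weir-Cockerham (1984) estimator (default) and the
Hudson estimator, both aggregated over windows as a ratio of summed
components (ratio of averages), never as an average of per-site ratios.

PBS re-expresses three pairwise windowed FST values as branch lengths
t = -ln(1 - FST) and isolates the target branch:

    PBS = (t_N,OT + t_N,D - t_OT,D) / 2

for target N, control OT and distantly related D.  Four preset
target-vs-control scenarios (European, Asian, pooled Euro-Asian, other
African zebu) mirror the common study design.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._util import to_zero_based_half_open
from .vcfio import GenotypeMatrix

__all__ = [
    "WindowStat",
    "PbsComponents",
    "make_windows",
    "window_pi",
    "site_fst",
    "window_fst",
    "pbs_scan",
    "pbs_four_scenarios",
    "empirical_outliers",
    "write_window_stats",
]

_FST_CLAMP = 1.0 - 1e-9


@dataclass(frozen=True)
class WindowStat:
    """One genomic window with a named statistic.

    ``start``/``end`` are 1-based inclusive.  A window with no usable
    site carries ``value = None`` (never a spurious 0).
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    value: float | None
    name: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("window end before start")
        if self.n_sites < 0:
            raise ValueError("negative site count")


@dataclass(frozen=True)
class PbsComponents:
    """Windowed three-branch PBS with its ingredients.

    The three FST values are clamped to [0, 1-1e-9] before the log
    transform so no NaN or infinity is ever produced; ``pbs`` is
    (t_no + t_nd - t_od) / 2 exactly.
    """

    chrom: str
    start: int
    end: int
    n_sites: int
    fst_no: float
    fst_nd: float
    fst_od: float

    @staticmethod
    def _t(fst: float) -> float:
        return -math.log(1.0 - min(max(fst, 0.0), _FST_CLAMP))

    @property
    def t_no(self) -> float:
        return self._t(self.fst_no)

    @property
    def t_nd(self) -> float:
        return self._t(self.fst_nd)

    @property
    def t_od(self) -> float:
        return self._t(self.fst_od)

    @property
    def pbs(self) -> float:
        return (self.t_no + self.t_nd - self.t_od) / 2.0


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def make_windows(
    gm: GenotypeMatrix,
    window_bp: int,
    step_bp: int | None = None,
    anchor: str = "first_variant",
) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome window grid, 1-based inclusive.

    ``anchor='first_variant'`` starts the grid at the first variant of
    each chromosome and extends it until the last variant;
    ``anchor='coordinate'`` starts at position 1 and covers the
    chromosome length when known (else the last variant).  ``step_bp``
    of None gives non-overlapping windows (step = size).
    """
    if window_bp <= 0:
        raise ValueError("window size must be positive")
    step = step_bp if step_bp is not None else window_bp
    if step <= 0:
        raise ValueError("window step must be positive")
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom in dict.fromkeys(gm.chrom.tolist()):
        pos = gm.pos[gm.chrom == chrom]
        if anchor == "first_variant":
            lo, hi = int(pos.min()), int(pos.max())
        elif anchor == "coordinate":
            lo = 1
            hi = int(gm.chrom_lengths.get(chrom, int(pos.max())))
        else:
            raise ValueError(f"unknown anchor mode {anchor!r}")
        wins = []
        start = lo
        while start <= hi:
            wins.append((start, start + window_bp - 1))
            start += step
        out[chrom] = wins
    return out


def _window_slices(
    chrom_arr: np.ndarray, pos_arr: np.ndarray, windows: dict[str, list[tuple[int, int]]]
):
    """Yield (chrom, start, end, site-index array) for every window."""
    for chrom, wins in windows.items():
        on = np.flatnonzero(chrom_arr == chrom)
        pos = pos_arr[on]
        for start, end in wins:
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="right")
            yield chrom, start, end, on[lo:hi]


# ---------------------------------------------------------------------------
# nucleotide diversity
# ---------------------------------------------------------------------------

def site_pi(gm: GenotypeMatrix, population: str | list[str] | None = None) -> np.ndarray:
    """Per-site pi = 2 j (n - j) / (n (n - 1)); NaN where n < 2."""
    j, n = gm.allele_counts(population)
    with np.errstate(divide="ignore", invalid="ignore"):
        pi = 2.0 * j * (n - j) / (n * (n - 1.0))
    return np.where(n >= 2, pi, np.nan)


def window_pi(
    gm: GenotypeMatrix,
    population: str | list[str] | None = None,
    window_bp: int = 100_000,
    step_bp: int | None = None,
    anchor: str = "coordinate",
) -> list[WindowStat]:
    """Nucleotide diversity per window: summed site pi / window bp."""
    pi = site_pi(gm, population)
    if not np.any(np.isfinite(pi)):
        raise ValueError("population has no site with two called alleles")
    windows = make_windows(gm, window_bp, step_bp, anchor)
    out = []
    for chrom, start, end, idx in _window_slices(gm.chrom, gm.pos, windows):
        vals = pi[idx]
        vals = vals[np.isfinite(vals)]
        span = end - start + 1
        out.append(
            WindowStat(chrom, start, end, int(vals.size), float(vals.sum()) / span, "pi")
        )
    return out


# ---------------------------------------------------------------------------
# FST
# ---------------------------------------------------------------------------

def _pop_site_stats(gm: GenotypeMatrix, pops) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(called individuals, ALT frequency, het fraction) per site."""
    g = gm.geno[gm.sample_indices(pops)]
    called = g >= 0
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(called, g, 0).sum(axis=0) / (2.0 * n)
        h = ((g == 1).sum(axis=0)) / n
    return n, p, h


def site_fst(
    gm: GenotypeMatrix,
    pop1: str | list[str],
    pop2: str | list[str],
    estimator: str = "wc",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-site FST variance components for two populations.

    Returns ``(num, den, usable)``: the per-site numerator and
    denominator components (Weir-Cockerham a and a+b+c, or the Hudson
    numerator/denominator) and a usability mask.  A site is usable when
    every population has at least two called alleles (Hudson's
    finite-sample correction additionally needs more than one allele,
    and Weir-Cockerham needs a positive mean sample size minus one).
    The per-site ratio is num/den; windows should aggregate sums of the
    components, not per-site ratios.
    """
    n1, p1, h1 = _pop_site_stats(gm, pop1)
    n2, p2, h2 = _pop_site_stats(gm, pop2)
    usable = (n1 >= 1) & (n2 >= 1)

    if estimator == "wc":
        usable &= n1 + n2 >= 3  # nbar must exceed 1
        with np.errstate(invalid="ignore", divide="ignore"):
            r = 2.0
            nbar = (n1 + n2) / r
            nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
            pbar = (n1 * p1 + n2 * p2) / (r * nbar)
            s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
            hbar = (n1 * h1 + n2 * h2) / (r * nbar)
            inner = pbar * (1.0 - pbar) - (r - 1.0) / r * s2
            a = nbar / nc * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
            b = nbar / (nbar - 1.0) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
            c = hbar / 2.0
            num, den = a, a + b + c
    elif estimator == "hudson":
        m1, m2 = 2.0 * n1, 2.0 * n2  # haploid counts
        usable &= (m1 >= 2) & (m2 >= 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            num = (
                (p1 - p2) ** 2
                - p1 * (1.0 - p1) / (m1 - 1.0)
                - p2 * (1.0 - p2) / (m2 - 1.0)
            )
            den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")

    num = np.where(usable, num, np.nan)
    den = np.where(usable, den, np.nan)
    return num, den, usable


def window_fst(
    gm: GenotypeMatrix,
    pop1: str | list[str],
    pop2: str | list[str],
    window_bp: int = 50_000,
    step_bp: int | None = 2_000,
    estimator: str = "wc",
    anchor: str = "first_variant",
) -> list[WindowStat]:
    """Windowed FST as a ratio of summed per-site components."""
    num, den, usable = site_fst(gm, pop1, pop2, estimator)
    windows = make_windows(gm, window_bp, step_bp, anchor)
    out = []
    for chrom, start, end, idx in _window_slices(gm.chrom, gm.pos, windows):
        u = usable[idx]
        k = int(u.sum())
        if k == 0:
            value = None
        else:
            dsum = float(den[idx][u].sum())
            value = float(num[idx][u].sum()) / dsum if dsum != 0 else None
        out.append(WindowStat(chrom, start, end, k, value, f"fst_{estimator}"))
    return out


def mean_fst(stats: list[WindowStat]) -> float:
    vals = [w.value for w in stats if w.value is not None]
    if not vals:
        raise ValueError("no window with a defined FST")
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# PBS
# ---------------------------------------------------------------------------

def _as_list(x) -> list[str]:
    return [x] if isinstance(x, str) else list(x)


def pbs_scan(
    gm: GenotypeMatrix,
    target: str | list[str],
    control: str | list[str],
    distant: str | list[str],
    window_bp: int = 50_000,
    step_bp: int | None = 2_000,
    estimator: str = "wc",
    anchor: str = "first_variant",
) -> list[PbsComponents]:
    """Windowed PBS of the target against a control group and a
    distantly related group.

    The three pairwise windowed FST series share one window grid; a
    window where any pair has no usable site is dropped.
    """
    groups = [_as_list(target), _as_list(control), _as_list(distant)]
    flat = [p for g in groups for p in g]
    if len(set(flat)) != len(flat):
        raise ValueError("target, control and distant groups must be disjoint")

    pairs = [(groups[0], groups[1]), (groups[0], groups[2]), (groups[1], groups[2])]
    series = [
        window_fst(gm, a, b, window_bp, step_bp, estimator, anchor) for a, b in pairs
    ]
    out = []
    for w_no, w_nd, w_od in zip(*series):
        if None in (w_no.value, w_nd.value, w_od.value):
            continue
        out.append(
            PbsComponents(
                w_no.chrom,
                w_no.start,
                w_no.end,
                min(w_no.n_sites, w_nd.n_sites, w_od.n_sites),
                w_no.value,
                w_nd.value,
                w_od.value,
            )
        )
    return out


def pbs_four_scenarios(
    gm: GenotypeMatrix,
    target: str | list[str],
    european: str | list[str],
    asian: str | list[str],
    african_zebu: str | list[str],
    distant: str | list[str],
    **kwargs,
) -> dict[str, list[PbsComponents]]:
    """The four standard control configurations for one target:
    European control, Asian control, pooled Euro-Asian control, and
    other-African-zebu control; outgroups are the distant group in all."""
    return {
        "PBS1": pbs_scan(gm, target, european, distant, **kwargs),
        "PBS2": pbs_scan(gm, target, asian, distant, **kwargs),
        "PBS3": pbs_scan(gm, target, _as_list(european) + _as_list(asian), distant, **kwargs),
        "PBS4": pbs_scan(gm, target, african_zebu, distant, **kwargs),
    }


def pbs_to_window_stats(components: list[PbsComponents]) -> list[WindowStat]:
    return [
        WindowStat(c.chrom, c.start, c.end, c.n_sites, c.pbs, "pbs") for c in components
    ]


# ---------------------------------------------------------------------------
# empirical outliers
# ---------------------------------------------------------------------------

def empirical_outliers(stats: list[WindowStat], quantile: float = 0.01) -> list[WindowStat]:
    """Windows whose value reaches the empirical top ``quantile``.

    The threshold is the ceil((1-q)*n)-th smallest non-missing value, so
    n windows with distinct values yield exactly round(q*n) outliers;
    ties at the threshold are all included; missing-value windows never
    rank.
    """
    if not 0.0 < quantile < 1.0:
        raise ValueError("quantile must lie in (0, 1)")
    scored = [w for w in stats if w.value is not None]
    if not scored:
        raise ValueError("no window with a defined statistic")
    vals = np.sort([w.value for w in scored])
    k = min(int(math.ceil((1.0 - quantile) * vals.size)), vals.size - 1)
    threshold = vals[k]
    return [w for w in scored if w.value >= threshold]


# ---------------------------------------------------------------------------
# output
# ---------------------------------------------------------------------------

def write_window_stats(stats: list[WindowStat], path, bed: bool = False, header: str | None = None) -> None:
    """Tab-separated window table; ``bed`` switches to 0-based half-open."""
    with open(path, "w", newline="\n") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#chrom\tstart\tend\tn_sites\tvalue\tstat\n")
        for w in stats:
            s, e = (to_zero_based_half_open(w.start, w.end) if bed else (w.start, w.end))
            v = "NA" if w.value is None else f"{w.value:.8g}"
            fh.write(f"{w.chrom}\t{s}\t{e}\t{w.n_sites}\t{v}\t{w.name}\n")
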