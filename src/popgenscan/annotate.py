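"""Window-to-gene mapping and gene-set (Venn) overlap accounting.

Outlier windows from a selection scan are mapped to annotated gene
intervals (any overlap of at least 1 bp, optionally with a flank), and
gene sets from different methods or species are intersected into the
exclusive-region counts of a Venn diagram.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from .popstats import WindowStat

logger = logging.getLogger(__name__)

__all__ = [
    "GeneInterval",
    "GeneSet",
    "read_bed",
    "read_gtf",
    "read_gene_list",
    "map_windows_to_genes",
    "overlap_counts",
]


@dataclass(frozen=True)
class GeneInterval:
    """A gene span; ``start``/``end`` are 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene identifier must be non-empty")
        if self.end < self.start:
            raise ValueError(f"gene {self.gene_id}: end before start")


@dataclass(frozen=True)
class GeneSet:
    """A named set of unique gene identifiers."""

    name: str
    genes: frozenset[str]

    @classmethod
    def from_iterable(cls, name: str, genes) -> "GeneSet":
        return cls(name, frozenset(genes))

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GeneInterval]:
    """BED (0-based half-open) gene intervals; name column required."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: BED needs chrom,start,end,name")
            strand = f[5] if len(f) > 5 else "."
            out.append(GeneInterval(f[3], f[0], int(f[1]) + 1, int(f[2]), strand))
    return out


def read_gtf(path) -> list[GeneInterval]:
    """Gene intervals from GTF/GFF3 (1-based inclusive).

    'gene' features are used when present; otherwise the envelope of
    each gene_id's transcripts/exons is taken.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, GeneInterval] = {}
    featuretypes = set(db.featuretypes())
    if "gene" in featuretypes:
        for feat in db.features_of_type("gene"):
            gid = _feature_gene_id(feat)
            genes[gid] = GeneInterval(gid, feat.seqid, feat.start, feat.end, feat.strand or ".")
    else:
        for feat in db.all_features():
            gid = _feature_gene_id(feat)
            if gid is None:
                continue
            prev = genes.get(gid)
            if prev is None:
                genes[gid] = GeneInterval(gid, feat.seqid, feat.start, feat.end, feat.strand or ".")
            else:
                genes[gid] = GeneInterval(
                    gid, prev.chrom, min(prev.start, feat.start), max(prev.end, feat.end), prev.strand
                )
    return sorted(genes.values(), key=lambda g: (g.chrom, g.start, g.gene_id))


def _feature_gene_id(feat):
    for key in ("gene_id", "gene_name", "ID", "Name"):
        if key in feat.attributes:
            return feat.attributes[key][0]
    return feat.id or None


def read_gene_list(path, name: str | None = None) -> GeneSet:
    """One gene symbol per line (case preserved; matching is
    case-insensitive in overlap operations)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            g = line.strip()
            if g and not g.startswith("#"):
                genes.append(g)
    return GeneSet.from_iterable(name or str(path), genes)


# ---------------------------------------------------------------------------
# mapping and overlap
# ---------------------------------------------------------------------------

def map_windows_to_genes(
    windows: list[WindowStat] | list[tuple[str, int, int]],
    annotation: list[GeneInterval],
    set_name: str = "outliers",
    flank_bp: int = 0,
) -> GeneSet:
    """Genes whose interval overlaps any outlier window by >= 1 bp.

    ``flank_bp`` extends every window symmetrically before testing.
    Chromosome names present in the windows but absent from the
    annotation produce a logged warning, not an error.
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    spans = [
        (w.chrom, w.start, w.end) if isinstance(w, WindowStat) else tuple(w)
        for w in windows
    ]
    ann_chroms = {g.chrom for g in annotation}
    missing = {c for c, _, _ in spans if c not in ann_chroms}
    if missing:
        logger.warning(
            "%d window(s) on %d chromosome(s) absent from the annotation: %s",
            sum(1 for c, _, _ in spans if c in missing),
            len(missing),
            ", ".join(sorted(missing)),
        )

    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in spans:
        by_chrom.setdefault(c, []).append((s - flank_bp, e + flank_bp))
    hits = set()
    for g in annotation:
        for s, e in by_chrom.get(g.chrom, ()):
            if g.start <= e and s <= g.end:  # 1-based inclusive overlap
                hits.add(g.gene_id)
                break
    return GeneSet.from_iterable(set_name, sorted(hits))


def overlap_counts(sets: list[GeneSet]) -> dict:
    """Venn-style accounting over >= 2 gene sets.

    Gene matching is case-insensitive.  Returns exclusive-region counts
    for every non-empty subset of set names, per-set totals, pairwise
    intersection sizes, and 'shared by >= k sets' counts; the region
    counts sum to the size of the union exactly.
    """
    if len(sets) < 2:
        raise ValueError("need at least two gene sets")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise ValueError("set names must be unique")
    norm = [frozenset(g.upper() for g in s.genes) for s in sets]
    universe = frozenset().union(*norm)

    regions: dict[frozenset, int] = {}
    for gene in universe:
        member = frozenset(n for n, s in zip(names, norm) if gene in s)
        regions[member] = regions.get(member, 0) + 1

    exclusive = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            exclusive[combo] = regions.get(frozenset(combo), 0)

    pairwise = {
        (a, b): len(sa & sb)
        for (a, sa), (b, sb) in itertools.combinations(zip(names, norm), 2)
    }
    shared_by = {
        k: sum(c for member, c in regions.items() if len(member) >= k)
        for k in range(1, len(names) + 1)
    }
    return {
        "totals": {n: len(s) for n, s in zip(names, norm)},
        "exclusive": exclusive,
        "pairwise": pairwise,
        "shared_by_at_least": shared_by,
        "union": len(universe),
    }


def write_overlap_table(counts: dict, path, header: str | None = None) -> None:
    with open(path, "w", newline="\n") as fh:
        if header:
            fh.write(f"# {header}\n")
        fh.write("#region\tcount\n")
        for combo, c in counts["exclusive"].items():
            fh.write("&".join(combo) + f"\t{c}\n")
        fh.write(f"union\t{counts['union']}\n")
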