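"""Hox cluster domain types, file I/O and distance algebra.

A Hox cluster is modeled as an ordered list of genes — anterior (3') end
first — joined by strictly positive intergenic distances d(i,i+1) in Kbp.
Three reference clusters ship with the package: the mouse HoxD cluster
(compact, vertebrate-type), the amphioxus cluster (loose, invertebrate-type)
and a "modified amphioxus" cluster in which only the paralog numbers present
in mouse HoxD are retained, with spanned intergenic stretches summed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "HoxValidationError",
    "HoxGene",
    "HoxCluster",
    "ClusterStats",
    "read_cluster_table",
    "write_cluster_table",
    "cluster_stats",
    "restrict_to_genes",
    "cluster_span",
    "load_mouse_hoxd",
    "load_amphioxus",
    "load_amphioxus_modified",
    "load_fixture_clusters",
]


class HoxValidationError(ValueError):
    """Raised when a cluster description violates the model's invariants."""


@dataclass(frozen=True)
class HoxGene:
    """A single Hox gene: paralog index, display label, and fiber length.

    ``length_kbp`` is usually 0 — the model works with intergenic distances
    only — but a nonzero gene length contributes to the cluster span.
    """

    number: int
    label: str = ""
    length_kbp: float = 0.0

    def __post_init__(self) -> None:
        if self.number < 1:
            raise HoxValidationError(f"gene number must be >= 1, got {self.number}")
        if self.length_kbp < 0:
            raise HoxValidationError(
                f"gene length must be nonnegative, got {self.length_kbp}"
            )
        if not self.label:
            object.__setattr__(self, "label", f"Hox{self.number}")


@dataclass(frozen=True)
class HoxCluster:
    """An ordered Hox cluster with intergenic distances in Kbp.

    ``fixed_posterior_end`` records whether the 5' extremity is anchored
    (the fixed end of the elastic-spring analogue).  ``relaxed`` marks
    clusters produced by genetic manipulations, for which strict gene-number
    monotonicity and distance positivity may not hold (e.g. a tandem
    duplication carries a zero-length junction); it never compares.
    """

    organism: str
    genes: tuple[HoxGene, ...]
    distances_kbp: tuple[float, ...]
    fixed_posterior_end: bool = True
    relaxed: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        distances = tuple(float(d) for d in self.distances_kbp)
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "distances_kbp", distances)
        if len(genes) < 1:
            raise HoxValidationError("a cluster needs at least one gene")
        if len(distances) != len(genes) - 1:
            raise HoxValidationError(
                f"{len(genes)} genes require {len(genes) - 1} distances, "
                f"got {len(distances)}"
            )
        if not self.relaxed:
            numbers = [g.number for g in genes]
            if any(b <= a for a, b in zip(numbers, numbers[1:])):
                raise HoxValidationError(
                    f"gene numbers must be strictly increasing, got {numbers}"
                )
            if any(d <= 0 for d in distances):
                raise HoxValidationError(
                    f"all intergenic distances must be > 0, got {distances}"
                )
        else:
            if any(d < 0 for d in distances):
                raise HoxValidationError("distances cannot be negative")

    @property
    def gene_numbers(self) -> tuple[int, ...]:
        return tuple(g.number for g in self.genes)

    def gene_position_kbp(self, number: int) -> float:
        """Fiber distance from the anterior (3') end to gene ``number``.

        Gene lengths of earlier genes are included; the position refers to
        the anterior edge of the gene.
        """
        pos = 0.0
        for gene, dist in zip(self.genes, self.distances_kbp + (0.0,)):
            if gene.number == number:
                return pos
            pos += gene.length_kbp + dist
        raise HoxValidationError(f"gene {number} not in cluster {self.organism!r}")

    def with_fixed_end(self, fixed: bool) -> "HoxCluster":
        return replace(self, fixed_posterior_end=fixed)


@dataclass(frozen=True)
class ClusterStats:
    """Descriptive statistics of the intergenic distances (Kbp)."""

    total_kbp: float
    mean_kbp: float
    variance_kbp2: float  # population variance, divisor n


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _organism_from_comments(text: str) -> str | None:
    for line in text.splitlines():
        if line.startswith("#") and "organism:" in line:
            return line.split("organism:", 1)[1].strip()
        if not line.startswith("#"):
            break
    return None


def _cluster_from_distance_rows(
    rows: pd.DataFrame, organism: str
) -> HoxCluster:
    numbers: list[int] = []
    distances: list[float] = []
    for i, row in enumerate(rows.itertuples(index=False)):
        a, b, d = int(row.gene_from), int(row.gene_to), float(row.distance_kbp)
        if i == 0:
            numbers.append(a)
        elif a != numbers[-1]:
            raise HoxValidationError(
                f"row {i}: gene_from {a} does not chain from previous gene_to "
                f"{numbers[-1]}"
            )
        if b <= a:
            raise HoxValidationError(f"row {i}: gene_to {b} must exceed gene_from {a}")
        if d <= 0:
            raise HoxValidationError(f"row {i}: non-positive distance {d}")
        numbers.append(b)
        distances.append(d)
    genes = tuple(HoxGene(number=n) for n in numbers)
    return HoxCluster(organism=organism, genes=genes, distances_kbp=tuple(distances))


def read_cluster_table(
    path: str | Path,
    dialect: str = "distance-list",
    organism: str | None = None,
) -> HoxCluster:
    """Read a cluster from a distance-list TSV or a BED interval file.

    distance-list: tab-separated columns ``gene_from, gene_to, distance_kbp``
    with a header line; ``#`` lines are comments (an ``# organism:`` comment
    names the cluster).  BED: standard 0-based half-open intervals on one
    strand; genes are ordered by start coordinate and distances are taken
    between successive start positions (converted from bp to Kbp); the gene
    number is parsed from trailing digits of the name column when present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if organism is None:
        organism = _organism_from_comments(text) or path.stem

    if dialect == "distance-list":
        try:
            rows = pd.read_csv(io.StringIO(text), sep="\t", comment="#", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise HoxValidationError(f"{path}: empty cluster file") from exc
        expected = {"gene_from", "gene_to", "distance_kbp"}
        if rows.empty or not expected.issubset(rows.columns):
            raise HoxValidationError(
                f"{path}: distance-list file needs columns {sorted(expected)} "
                "and at least one row"
            )
        return _cluster_from_distance_rows(rows, organism)

    if dialect == "bed-intervals":
        try:
            bed = pd.read_csv(
                io.StringIO(text),
                sep="\t",
                comment="#",
                header=None,
                usecols=[0, 1, 2, 3],
                names=["chrom", "start", "end", "name"],
            )
        except (pd.errors.EmptyDataError, ValueError) as exc:
            raise HoxValidationError(f"{path}: unreadable BED file: {exc}") from exc
        if bed.empty:
            raise HoxValidationError(f"{path}: empty BED file")
        if bed["chrom"].nunique() > 1:
            raise HoxValidationError(f"{path}: BED intervals span several sequences")
        bed = bed.sort_values("start", kind="stable").reset_index(drop=True)
        numbers = []
        for i, name in enumerate(bed["name"].astype(str)):
            digits = "".join(ch for ch in name if ch.isdigit())
            numbers.append(int(digits) if digits else i + 1)
        genes = tuple(
            HoxGene(number=n, label=str(nm))
            for n, nm in zip(numbers, bed["name"].astype(str))
        )
        starts = bed["start"].astype(float).to_numpy()
        distances = tuple(np.diff(starts) / 1000.0)  # bp -> Kbp, start-to-start
        return HoxCluster(organism=organism, genes=genes, distances_kbp=distances)

    raise HoxValidationError(f"unknown dialect {dialect!r}")


def write_cluster_table(
    cluster: HoxCluster, path: str | Path, dialect: str = "distance-list"
) -> Path:
    """Write ``cluster`` so that :func:`read_cluster_table` round-trips it."""
    path = Path(path)
    if dialect == "distance-list":
        lines = [f"# organism: {cluster.organism}", "gene_from\tgene_to\tdistance_kbp"]
        for a, b, d in zip(cluster.genes, cluster.genes[1:], cluster.distances_kbp):
            lines.append(f"{a.number}\t{b.number}\t{d:g}")
        path.write_text("\n".join(lines) + "\n")
    elif dialect == "bed-intervals":
        lines = [f"# organism: {cluster.organism}"]
        pos = 0.0
        for gene, dist in zip(cluster.genes, cluster.distances_kbp + (0.0,)):
            start = int(round(pos * 1000))
            end = start + max(int(round(gene.length_kbp * 1000)), 1)
            lines.append(f"cluster\t{start}\t{end}\t{gene.label}\t0\t+")
            pos += gene.length_kbp + dist
        path.write_text("\n".join(lines) + "\n")
    else:
        raise HoxValidationError(f"unknown dialect {dialect!r}")
    return path


# ---------------------------------------------------------------------------
# Distance algebra
# ---------------------------------------------------------------------------

def cluster_stats(cluster: HoxCluster) -> ClusterStats:
    """Total, mean and population variance of the intergenic distances.

    The variance uses divisor n (population variance): that is the convention
    that reproduces the printed reference statistics for all three fixture
    clusters.
    """
    if len(cluster.genes) < 2:
        raise HoxValidationError("statistics need at least 2 genes (1 distance)")
    d = np.asarray(cluster.distances_kbp, dtype=float)
    return ClusterStats(
        total_kbp=float(d.sum()),
        mean_kbp=float(d.mean()),
        variance_kbp2=float(d.var(ddof=0)),
    )


def restrict_to_genes(cluster: HoxCluster, keep: Iterable[int]) -> HoxCluster:
    """Drop genes not in ``keep``, summing the intergenic stretches they spanned.

    The fiber span between the outermost retained genes is conserved: each new
    distance is the sum of the original distances (plus dropped-gene lengths)
    it spans.
    """
    keep_set = set(keep)
    present = set(cluster.gene_numbers)
    missing = keep_set - present
    if missing:
        raise HoxValidationError(
            f"genes {sorted(missing)} not present in cluster {cluster.organism!r}"
        )
    if len(keep_set) < 2:
        raise HoxValidationError("need at least 2 genes to retain")

    genes: list[HoxGene] = []
    distances: list[float] = []
    acc = 0.0
    for gene, dist in zip(cluster.genes, cluster.distances_kbp + (0.0,)):
        if gene.number in keep_set:
            if genes:
                distances.append(acc)
            genes.append(gene)
            acc = dist
        else:
            if genes:  # spanned stretch absorbs the dropped gene's extent
                acc += gene.length_kbp + dist
    return HoxCluster(
        organism=cluster.organism,
        genes=tuple(genes),
        distances_kbp=tuple(distances),
        fixed_posterior_end=cluster.fixed_posterior_end,
    )


def cluster_span(cluster: HoxCluster) -> float:
    """Total fiber extent of the cluster: Σ distances + Σ gene lengths (Kbp).

    This is the carrier of the cluster 'charge' N in the force model.
    """
    return float(
        sum(cluster.distances_kbp) + sum(g.length_kbp for g in cluster.genes)
    )


# ---------------------------------------------------------------------------
# Packaged reference clusters
# ---------------------------------------------------------------------------

def _load_packaged(name: str) -> HoxCluster:
    ref = resources.files("hoxphys.data").joinpath(name)
    with resources.as_file(ref) as path:
        return read_cluster_table(path, dialect="distance-list")


def load_mouse_hoxd() -> HoxCluster:
    """Mouse HoxD cluster: 9 genes, 8 distances, total 94 Kbp."""
    return _load_packaged("mouse_hoxd.tsv")


def load_amphioxus() -> HoxCluster:
    """Amphioxus Hox cluster: 14 genes, 13 distances, total 446 Kbp."""
    return _load_packaged("amphioxus.tsv")


def load_amphioxus_modified() -> HoxCluster:
    """Amphioxus restricted to the mouse-HoxD paralog numbers (gene 14 kept)."""
    return _load_packaged("amphioxus_modified.tsv")


def load_fixture_clusters() -> tuple[HoxCluster, HoxCluster, HoxCluster]:
    """The three packaged reference clusters (mouse, amphioxus, modified)."""
    return load_mouse_hoxd(), load_amphioxus(), load_amphioxus_modified()
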