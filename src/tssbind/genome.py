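"""Genomic coordinate types and interval computations.

All coordinates are 0-based, half-open (BED convention). A peak's "middle"
is ``floor((start + end) / 2)`` and anchors every distance computation.
Signed TSS distances are strand-aware: negative means the peak midpoint lies
upstream of the TSS (5' of the gene), positive downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GenomeLayout",
    "Peak",
    "PeakSet",
    "GeneAnnotation",
    "ElementAnnotation",
    "intersect_replicates",
    "distance_to_nearest_tss",
    "distances_to_nearest_tss",
    "bound_genes",
    "annotate_elements",
    "random_control_peaks",
    "tss_distance_histogram",
]


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths; the coordinate universe.

    ``n_basepairs`` (total size) plays the role the full assembly size plays
    when similarity scores are computed on real genomes.
    """

    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")
        object.__setattr__(self, "_lengths", dict(self.chromosomes))

    @property
    def names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    @property
    def n_basepairs(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths  # type: ignore[attr-defined]

    @classmethod
    def from_chrom_sizes(cls, path) -> "GenomeLayout":
        """Read a UCSC-style two-column ``chrom.sizes`` file."""
        rows = []
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                name, length = line.split()[:2]
                rows.append((name, int(length)))
        return cls(tuple(rows))

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self.chromosomes:
                fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class Peak:
    """A half-open genomic interval with an optional score."""

    chrom: str
    start: int
    end: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid peak interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.score is not None and self.score < 0:
            raise ValueError("peak score must be nonnegative")

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def __len__(self) -> int:
        return self.end - self.start


class PeakSet:
    """A collection of peaks sorted by (chrom, start, end)."""

    def __init__(self, peaks: Iterable[Peak], layout: GenomeLayout | None = None):
        self.peaks: list[Peak] = sorted(
            peaks, key=lambda p: (p.chrom, p.start, p.end)
        )
        self.layout = layout
        if layout is not None:
            for p in self.peaks:
                if p.chrom not in layout:
                    raise ValueError(f"peak on unknown chromosome {p.chrom!r}")
                if p.end > layout.length(p.chrom):
                    raise ValueError(
                        f"peak {p.chrom}:{p.start}-{p.end} exceeds chromosome "
                        f"length {layout.length(p.chrom)}"
                    )

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __getitem__(self, i) -> Peak:
        return self.peaks[i]

    def by_chrom(self) -> dict[str, list[Peak]]:
        out: dict[str, list[Peak]] = {}
        for p in self.peaks:
            out.setdefault(p.chrom, []).append(p)
        return out

    def chroms(self) -> set[str]:
        return {p.chrom for p in self.peaks}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [p.chrom for p in self.peaks],
                "start": [p.start for p in self.peaks],
                "end": [p.end for p in self.peaks],
                "score": [p.score for p in self.peaks],
            }
        )


@dataclass
class GeneAnnotation:
    """A gene reduced to its TSS, strand and expression level.

    ``expression`` holds CAGE-style tag counts (absolute promoter-level
    expression). ``bound`` and ``methylation_grade`` are populated by the
    downstream analyses, not at load time.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    expression: float = 0.0
    bound: bool | None = None
    methylation_grade: float | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be nonnegative")
        if self.expression < 0:
            raise ValueError("expression must be nonnegative")


ELEMENT_CATEGORIES = ("promoter", "enhancer", "gene_body", "intergenic")


@dataclass
class ElementAnnotation:
    """Per-peak genomic element assignment plus category frequencies."""

    table: pd.DataFrame  # columns: chrom,start,end,gene_id,distance,category
    frequencies: dict[str, float] = field(default_factory=dict)


def _check_same_namespace(a: PeakSet, b: PeakSet) -> None:
    only_a = a.chroms() - b.chroms()
    only_b = b.chroms() - a.chroms()
    if a.layout is not None and b.layout is not None:
        if a.layout.names != b.layout.names:
            missing = set(a.layout.names) ^ set(b.layout.names)
            raise ValueError(
                f"peak sets use different chromosome namespaces: {sorted(missing)}"
            )
        return
    # Without explicit layouts we only require that shared chromosomes exist;
    # a replicate may simply lack peaks on some chromosome.
    _ = only_a, only_b


def intersect_replicates(peaks_a: PeakSet, peaks_b: PeakSet) -> PeakSet:
    """Reproducible peaks: the intersection spans of overlapping pairs.

    One output peak per overlapping pair (a, b), with coordinates equal to
    the shared span. Scores are the minimum of the two inputs' scores when
    both are present. Output sorted by (chrom, start).
    """
    _check_same_namespace(peaks_a, peaks_b)
    out: list[Peak] = []
    b_by_chrom = peaks_b.by_chrom()
    for chrom, a_list in peaks_a.by_chrom().items():
        b_list = b_by_chrom.get(chrom, [])
        if not b_list:
            continue
        b_starts = np.array([p.start for p in b_list])
        b_ends = np.array([p.end for p in b_list])
        # sorted by start; ends need not be sorted, scan a window
        for pa in a_list:
            # candidates: b.start < a.end and b.end > a.start
            hi = int(np.searchsorted(b_starts, pa.end, side="left"))
            for j in range(hi):
                if b_ends[j] > pa.start:
                    pb = b_list[j]
                    score = None
                    if pa.score is not None and pb.score is not None:
                        score = min(pa.score, pb.score)
                    out.append(
                        Peak(chrom, max(pa.start, pb.start), min(pa.end, pb.end), score)
                    )
    layout = peaks_a.layout or peaks_b.layout
    return PeakSet(out, layout=layout)


def _genes_by_chrom(genes: Sequence[GeneAnnotation]) -> dict[str, list[GeneAnnotation]]:
    out: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        out.setdefault(g.chrom, []).append(g)
    # sort by (tss, gene_id) so nearest-ties resolve to the smaller gene_id
    for chrom in out:
        out[chrom].sort(key=lambda g: (g.tss, g.gene_id))
    return out


def distance_to_nearest_tss(
    peak: Peak, genes: Sequence[GeneAnnotation]
) -> tuple[str, int]:
    """Nearest gene (by |TSS - midpoint|) and the signed, strand-aware distance.

    Negative distances place the peak upstream of the TSS. Ties in distance
    are broken by the smaller ``gene_id``.
    """
    same = [g for g in genes if g.chrom == peak.chrom]
    if not same:
        raise ValueError(f"no gene on chromosome {peak.chrom!r}")
    mid = peak.midpoint
    best = min(same, key=lambda g: (abs(g.tss - mid), g.gene_id))
    return best.gene_id, signed_tss_distance(best, mid)


def signed_tss_distance(gene: GeneAnnotation, position: int) -> int:
    """Signed distance of ``position`` from the gene's TSS (upstream < 0)."""
    d = position - gene.tss
    return d if gene.strand == "+" else -d


def distances_to_nearest_tss(
    peaks: PeakSet, genes: Sequence[GeneAnnotation]
) -> pd.DataFrame:
    """Vectorised nearest-TSS search for a whole peak set.

    Returns one row per peak with the nearest gene and the signed distance;
    peaks on chromosomes without genes get gene_id NaN and are excluded from
    histograms downstream.
    """
    by_chrom = _genes_by_chrom(genes)
    rows = []
    for p in peaks:
        chrom_genes = by_chrom.get(p.chrom)
        if not chrom_genes:
            rows.append((p.chrom, p.start, p.end, None, np.nan))
            continue
        mid = p.midpoint
        tss = np.array([g.tss for g in chrom_genes])
        i = int(np.searchsorted(tss, mid))
        cand = {j for j in (i - 1, i, i + 1) if 0 <= j < len(chrom_genes)}
        # expand across equal-TSS runs so gene_id tie-break is exact
        best_j = min(
            cand, key=lambda j: (abs(int(tss[j]) - mid), chrom_genes[j].gene_id)
        )
        best_d = abs(int(tss[best_j]) - mid)
        lo, hi = min(cand), max(cand)
        while lo - 1 >= 0 and abs(int(tss[lo - 1]) - mid) <= best_d:
            lo -= 1
        while hi + 1 < len(chrom_genes) and abs(int(tss[hi + 1]) - mid) <= best_d:
            hi += 1
        g = min(
            chrom_genes[lo : hi + 1],
            key=lambda g: (abs(g.tss - mid), g.gene_id),
        )
        rows.append((p.chrom, p.start, p.end, g.gene_id, signed_tss_distance(g, mid)))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "gene_id", "distance"]
    )


def bound_genes(
    peaks: PeakSet, genes: Sequence[GeneAnnotation], window: int = 1000
) -> set[str]:
    """Genes with a peak midpoint within ``window`` bp of the TSS (inclusive).

    The default window of 1000 bp is the one used to call a gene "bound"
    throughout the expression, methylation and knockdown analyses.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mids_by_chrom: dict[str, np.ndarray] = {}
    for chrom, plist in peaks.by_chrom().items():
        mids_by_chrom[chrom] = np.array(sorted(p.midpoint for p in plist))
    out: set[str] = set()
    for g in genes:
        mids = mids_by_chrom.get(g.chrom)
        if mids is None or len(mids) == 0:
            continue
        lo = np.searchsorted(mids, g.tss - window, side="left")
        hi = np.searchsorted(mids, g.tss + window, side="right")
        if hi > lo:
            out.add(g.gene_id)
    return out


def annotate_elements(
    peaks: PeakSet,
    genes: Sequence[GeneAnnotation],
    promoter_bp: int = 2000,
    enhancer_bp: int = 30000,
) -> ElementAnnotation:
    """Assign each peak to promoter / enhancer / gene body / intergenic.

    Windows are strand-aware and upstream of the nearest gene's TSS:
    promoter = the ``promoter_bp`` (default 2000) bp upstream, enhancer = the
    ``enhancer_bp`` (default 30000) bp upstream. Precedence is
    promoter > enhancer > gene_body > intergenic; "gene_body" here means the
    peak midpoint lies downstream of the TSS within ``enhancer_bp`` bp (a
    proxy for the transcribed unit, since only TSSs are annotated).
    """
    if promoter_bp <= 0 or enhancer_bp <= 0 or promoter_bp > enhancer_bp:
        raise ValueError("require 0 < promoter_bp <= enhancer_bp")
    dist = distances_to_nearest_tss(peaks, genes)
    cats = []
    for d in dist["distance"]:
        if np.isnan(d):
            cats.append("intergenic")
        elif -promoter_bp <= d < 0 or d == 0:
            cats.append("promoter")
        elif -enhancer_bp <= d < 0:
            cats.append("enhancer")
        elif 0 < d <= enhancer_bp:
            cats.append("gene_body")
        else:
            cats.append("intergenic")
    dist["category"] = cats
    n = max(len(dist), 1)
    freqs = {c: float((dist["category"] == c).sum()) / n for c in ELEMENT_CATEGORIES}
    return ElementAnnotation(table=dist, frequencies=freqs)


def random_control_peaks(
    n: int,
    template: PeakSet,
    genome: GenomeLayout,
    seed: int | np.random.Generator,
) -> PeakSet:
    """Random control peaks: uniform positions, template-resampled lengths.

    Start positions are drawn uniformly over the genome (chromosome chosen
    proportional to length); lengths are resampled with replacement from the
    template's length distribution. A draw whose length does not fit its
    chromosome is redrawn.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if len(template) == 0:
        raise ValueError("template peak set is empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lengths = np.array([len(p) for p in template])
    chrom_names = genome.names
    chrom_lens = np.array([genome.length(c) for c in chrom_names], dtype=float)
    probs = chrom_lens / chrom_lens.sum()
    out: list[Peak] = []
    while len(out) < n:
        k = n - len(out)
        ci = rng.choice(len(chrom_names), size=k, p=probs)
        L = rng.choice(lengths, size=k, replace=True)
        starts = np.floor(rng.random(k) * chrom_lens[ci]).astype(int)
        for c, s, l in zip(ci, starts, L):
            if s + l <= chrom_lens[c]:
                out.append(Peak(chrom_names[int(c)], int(s), int(s + l)))
    return PeakSet(out, layout=genome)


def tss_distance_histogram(
    distances: Iterable[float],
    half_range: int,
    bin_width: int,
) -> pd.DataFrame:
    """Histogram of signed TSS distances over [-half_range, +half_range).

    Bins are half-open ``[lo, lo + bin_width)``; distances outside the range
    (and NaNs from peaks without a same-chromosome gene) are excluded, so the
    total count never exceeds the number of peaks.
    """
    if half_range % bin_width != 0:
        raise ValueError("half_range must be a multiple of bin_width")
    d = np.asarray([x for x in distances if not np.isnan(x)], dtype=float)
    edges = np.arange(-half_range, half_range + bin_width, bin_width)
    counts, _ = np.histogram(d, bins=edges)
    # np.histogram closes the last bin on the right; drop exact +half_range hits
    counts[-1] -= int(np.sum(d == half_range))
    return pd.DataFrame(
        {"bin_start": edges[:-1], "bin_end": edges[1:], "count": counts}
    )
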