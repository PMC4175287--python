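"""Genome-wide weight tracks and the per-basepair similarity analysis.

A weight track assigns a nonnegative weight to every base of the genome
(implicitly zero outside its intervals) — a ChIP-seq tag pileup, a peak-score
track, or any bedGraph-style signal. Two tracks are compared by the sum over
all bases of the products of their weights, normalised for track size. Two
normalisations are offered:

``cosine`` (default)
    S = sum_i w1_i w2_i / sqrt(sum_i w1_i^2 * sum_i w2_i^2), the cosine of
    the angle between the two per-base weight vectors. Bounded in [0, 1] for
    nonnegative tracks, scale-invariant, and maximal (1) for self-comparison.

``literal``
    S = n_basepairs * sum_i w1_i w2_i / (W1^2 * W2^2) where W is a track's
    total weight — the size correction read as the inverse square of each
    track's total weight. Not scale-invariant; kept selectable because the
    published description admits this reading.

Scores are computed by a sweep over interval overlaps; per-base arrays are
never materialised, so whole-genome tracks stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeLayout, PeakSet

__all__ = [
    "TrackLabel",
    "WeightTrack",
    "SimilarityRanking",
    "track_from_peaks",
    "similarity",
    "similarity_matrix",
    "rank_compendium",
    "rank_label_enrichment",
    "median_label_rank_profile",
    "load_compendium",
]


@dataclass(frozen=True)
class TrackLabel:
    factor: str
    cell_type: str = ""
    experiment_id: str = ""


class WeightTrack:
    """Sparse nonnegative per-base weights stored as run-length intervals."""

    def __init__(
        self,
        layout: GenomeLayout,
        intervals: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]],
        label: TrackLabel | None = None,
    ):
        self.layout = layout
        self.label = label or TrackLabel("unknown")
        self._data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, weights) in intervals.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            weights = np.asarray(weights, dtype=float)
            if chrom not in layout:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if len(starts) == 0:
                continue
            order = np.argsort(starts, kind="stable")
            starts, ends, weights = starts[order], ends[order], weights[order]
            if np.any(starts >= ends) or starts[0] < 0 or ends[-1] > layout.length(chrom):
                raise ValueError(f"interval out of bounds on {chrom}")
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            if not np.all(np.isfinite(weights)) or np.any(weights < 0):
                raise ValueError("weights must be finite and nonnegative")
            keep = weights > 0
            if keep.any():
                self._data[chrom] = (starts[keep], ends[keep], weights[keep])

    @classmethod
    def from_intervals(
        cls,
        layout: GenomeLayout,
        intervals: list[tuple[str, int, int, float]],
        label: TrackLabel | None = None,
    ) -> "WeightTrack":
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, w in intervals:
            by_chrom.setdefault(chrom, []).append((start, end, w))
        data = {}
        for chrom, rows in by_chrom.items():
            s, e, w = zip(*rows)
            data[chrom] = (np.array(s), np.array(e), np.array(w, dtype=float))
        return cls(layout, data, label=label)

    def intervals(self) -> list[tuple[str, int, int, float]]:
        out = []
        for chrom in self.layout.names:
            if chrom in self._data:
                s, e, w = self._data[chrom]
                out.extend(
                    (chrom, int(a), int(b), float(v)) for a, b, v in zip(s, e, w)
                )
        return out

    @property
    def total_weight(self) -> float:
        return float(
            sum(((e - s) * w).sum() for s, e, w in self._data.values())
        )

    @property
    def sq_norm(self) -> float:
        """Sum over bases of squared weight."""
        return float(
            sum(((e - s) * w**2).sum() for s, e, w in self._data.values())
        )

    @property
    def is_empty(self) -> bool:
        return not self._data

    def dense(self, chrom: str) -> np.ndarray:
        """Materialise per-base weights for one chromosome (tests/toys only)."""
        arr = np.zeros(self.layout.length(chrom))
        if chrom in self._data:
            s, e, w = self._data[chrom]
            for a, b, v in zip(s, e, w):
                arr[a:b] += v
        return arr

    def binned(self, width: int) -> "WeightTrack":
        """Re-express the track on a fixed grid of ``width``-bp bins.

        Each bin carries the track's total weight mass inside it, spread
        evenly over the bin (mass-preserving). ``width == 1`` is the
        identity up to interval fragmentation and leaves scores unchanged.
        """
        if width < 1:
            raise ValueError("width must be >= 1")
        if width == 1:
            return self
        data = {}
        for chrom, (s, e, w) in self._data.items():
            L = self.layout.length(chrom)
            nbins = -(-L // width)
            mass = np.zeros(nbins)
            lo_bin = s // width
            hi_bin = (e - 1) // width
            for a, b, v, bl, bh in zip(s, e, w, lo_bin, hi_bin):
                for bi in range(bl, bh + 1):
                    ov = min(b, (bi + 1) * width) - max(a, bi * width)
                    mass[bi] += v * ov
            nz = np.nonzero(mass)[0]
            starts = nz * width
            ends = np.minimum((nz + 1) * width, L)
            data[chrom] = (starts, ends, mass[nz] / (ends - starts))
        return WeightTrack(self.layout, data, label=self.label)


def track_from_peaks(
    peaks: PeakSet, layout: GenomeLayout, label: TrackLabel | None = None
) -> WeightTrack:
    """Turn a peak set into a weight track (weight = score, or 1 if absent).

    Overlapping peaks contribute additively, so the result is the score
    pileup of the peak set.
    """
    data = {}
    for chrom, plist in peaks.by_chrom().items():
        events: dict[int, float] = {}
        for p in plist:
            w = 1.0 if p.score is None else float(p.score)
            events[p.start] = events.get(p.start, 0.0) + w
            events[p.end] = events.get(p.end, 0.0) - w
        pos = np.array(sorted(events))
        delta = np.array([events[x] for x in pos])
        level = np.cumsum(delta)
        starts, ends, weights = pos[:-1], pos[1:], level[:-1]
        nz = weights > 1e-12
        data[chrom] = (starts[nz], ends[nz], weights[nz])
    return WeightTrack(layout, data, label=label)


def _chrom_dot(t1, t2) -> float:
    s1, e1, w1 = t1
    s2, e2, w2 = t2
    bounds = np.union1d(
        np.concatenate([s1, e1]), np.concatenate([s2, e2])
    )
    seg_start = bounds[:-1]
    seg_len = np.diff(bounds)

    def values(s, e, w):
        idx = np.searchsorted(s, seg_start, side="right") - 1
        v = np.zeros(len(seg_start))
        ok = idx >= 0
        j = idx[ok]
        v[ok] = np.where(seg_start[ok] < e[j], w[j], 0.0)
        return v

    return float(np.sum(values(s1, e1, w1) * values(s2, e2, w2) * seg_len))


def weighted_dot(a: WeightTrack, b: WeightTrack) -> float:
    """Sum over all bases of the product of the two tracks' weights."""
    total = 0.0
    for chrom in a._data:
        if chrom in b._data:
            total += _chrom_dot(a._data[chrom], b._data[chrom])
    return total


def similarity(
    a: WeightTrack,
    b: WeightTrack,
    mode: str = "cosine",
    bin_width: int | None = None,
) -> float:
    """Similarity between two weight tracks (see module docstring for modes)."""
    if a.layout.chromosomes != b.layout.chromosomes:
        raise ValueError("tracks are defined on different genome layouts")
    if bin_width is not None and bin_width > 1:
        a, b = a.binned(bin_width), b.binned(bin_width)
    if a.is_empty or b.is_empty:
        return 0.0
    dot = weighted_dot(a, b)
    if mode == "cosine":
        return dot / np.sqrt(a.sq_norm * b.sq_norm)
    if mode == "literal":
        return a.layout.n_basepairs * dot / (a.total_weight**2 * b.total_weight**2)
    raise ValueError(f"unknown similarity mode {mode!r}")


def similarity_matrix(
    tracks: list[WeightTrack], mode: str = "cosine"
) -> np.ndarray:
    """Symmetric all-versus-all similarity matrix (diagonal included)."""
    n = len(tracks)
    S = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            s = similarity(tracks[i], tracks[j], mode=mode)
            S[i, j] = S[j, i] = s
    return S


@dataclass
class SimilarityRanking:
    """A query track's compendium ranking, most similar first."""

    query: TrackLabel
    entries: list[tuple[TrackLabel, float]]  # descending score

    def __post_init__(self) -> None:
        scores = [s for _, s in self.entries]
        if any(scores[i] < scores[i + 1] for i in range(len(scores) - 1)):
            raise ValueError("scores must be non-increasing")

    def rank_of(self, experiment_id: str) -> int:
        for i, (lab, _) in enumerate(self.entries, start=1):
            if lab.experiment_id == experiment_id:
                return i
        raise KeyError(experiment_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.entries) + 1),
                "experiment_id": [l.experiment_id for l, _ in self.entries],
                "factor": [l.factor for l, _ in self.entries],
                "cell_type": [l.cell_type for l, _ in self.entries],
                "score": [s for _, s in self.entries],
            }
        )


def rank_compendium(
    query: WeightTrack,
    compendium: list[WeightTrack],
    mode: str = "cosine",
    scores: np.ndarray | None = None,
) -> SimilarityRanking:
    """Score the query against every compendium track and rank descending.

    Ties are broken lexicographically by experiment_id so rankings are
    deterministic. Precomputed ``scores`` (aligned with ``compendium``) may
    be supplied to avoid recomputation in all-versus-all analyses.
    """
    if not compendium:
        raise ValueError("compendium is empty")
    if scores is None:
        scores = np.array([similarity(query, t, mode=mode) for t in compendium])
    order = sorted(
        range(len(compendium)),
        key=lambda i: (-scores[i], compendium[i].label.experiment_id),
    )
    return SimilarityRanking(
        query=query.label,
        entries=[(compendium[i].label, float(scores[i])) for i in order],
    )


def rank_label_enrichment(
    ranking: SimilarityRanking,
    labels: set[str],
    n_perm: int = 100_000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Do the labelled experiments concentrate at the top of the ranking?

    The statistic is the mean rank of the labelled tracks; small values mean
    the labelled binding patterns cluster among the most similar. The
    permutation p-value re-labels uniformly at random ``n_perm`` times and
    uses add-one smoothing: p = (1 + #{perm mean <= observed}) / (1 + n_perm).
    The normal-approximation Mann-Whitney p (labelled ranks vs the rest,
    one-sided) is reported alongside.
    """
    ids = [lab.experiment_id for lab, _ in ranking.entries]
    unknown = sorted(labels - set(ids))
    if unknown:
        raise ValueError(f"labels not in compendium: {unknown}")
    N = len(ids)
    K = len(labels)
    if not 0 < K < N:
        raise ValueError("need 0 < |labels| < compendium size")
    ranks = np.arange(1, N + 1)
    is_lab = np.array([i in labels for i in ids])
    observed = float(ranks[is_lab].mean())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    keys = rng.random((n_perm, N))
    pick = np.argpartition(keys, K - 1, axis=1)[:, :K]
    perm_means = (pick + 1).mean(axis=1)
    p_perm = (1 + int(np.sum(perm_means <= observed + 1e-12))) / (1 + n_perm)

    mw = stats.mannwhitneyu(
        ranks[is_lab], ranks[~is_lab], alternative="less", method="asymptotic"
    )
    return {
        "statistic": observed,
        "p_permutation": float(p_perm),
        "p_mannwhitney": float(mw.pvalue),
        "n_labelled": K,
        "n_total": N,
    }


def _lower_median(values: np.ndarray) -> float:
    v = np.sort(values)
    return float(v[(len(v) - 1) // 2])


def median_label_rank_profile(
    compendium: list[WeightTrack],
    label_factor: str,
    mode: str = "cosine",
    S: np.ndarray | None = None,
) -> pd.DataFrame:
    """For every query track: the median rank of ``label_factor`` tracks.

    Each compendium track in turn ranks all *other* tracks by similarity;
    the ranks of the tracks whose factor equals ``label_factor`` (the query
    itself excluded) are extracted and their lower median taken. Low median
    rank means the query's binding pattern co-locates with the labelled
    factor across the whole compendium. Queries with no labelled tracks
    among the others get NaN and sort last.
    """
    factors = [t.label.factor for t in compendium]
    if label_factor not in factors:
        raise ValueError(f"no track carries factor {label_factor!r}")
    if S is None:
        S = similarity_matrix(compendium, mode=mode)
    rows = []
    n = len(compendium)
    for qi in range(n):
        others = [i for i in range(n) if i != qi]
        order = sorted(
            others,
            key=lambda i: (-S[qi, i], compendium[i].label.experiment_id),
        )
        lab_ranks = np.array(
            [r for r, i in enumerate(order, start=1) if factors[i] == label_factor]
        )
        med = _lower_median(lab_ranks) if len(lab_ranks) else np.nan
        rows.append(
            {
                "experiment_id": compendium[qi].label.experiment_id,
                "factor": factors[qi],
                "median_label_rank": med,
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["median_label_rank", "experiment_id"], na_position="last"
    ).reset_index(drop=True)


def load_compendium(manifest_path) -> list[WeightTrack]:
    """Load tracks from a manifest TSV (experiment_id, factor, cell_type, path).

    Paths are resolved relative to the manifest's directory. All tracks must
    share one genome layout, inferred from a ``genome`` column pointing at a
    chrom.sizes file (same for every row).
    """
    from .io import read_bedgraph

    base = Path(manifest_path).parent
    df = pd.read_csv(manifest_path, sep="\t")
    need = {"experiment_id", "factor", "cell_type", "path", "genome"}
    if not need.issubset(df.columns):
        raise ValueError(f"manifest requires columns {sorted(need)}")
    layouts = set(df["genome"])
    if len(layouts) != 1:
        raise ValueError("all manifest rows must share one genome file")
    layout = GenomeLayout.from_chrom_sizes(base / layouts.pop())
    tracks = []
    for r in df.itertuples():
        intervals = read_bedgraph(base / r.path)
        tracks.append(
            WeightTrack.from_intervals(
                layout,
                intervals,
                label=TrackLabel(str(r.factor), str(r.cell_type), str(r.experiment_id)),
            )
        )
    return tracks
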