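"""Long shared-haplotype (IBD) segment detection and sharing profiles.

Detection follows the GERMLINE idea: slide fixed-size marker windows, hash
exact allele words to find candidate pairs cheaply, then extend matches
along the chromosome and report maximal shared runs at least ``min_cm``
centimorgans long (lengths from piecewise-linear interpolation of a genetic
map).  A genotype mode breaks matches only at opposite homozygotes, since
unphased data cannot resolve which haplotype is shared.  Sharing profiles
count, at grid sites every 2.5 cM, how many pairs share a spanning segment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import ValidationError

__all__ = [
    "GeneticMap",
    "SharedSegment",
    "detect_segments",
    "sharing_profile",
    "group_excess_sharing",
]


@dataclass
class GeneticMap:
    """Per-chromosome (bp, cM) anchors, strictly increasing in both."""

    anchors: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "GeneticMap":
        out = cls()
        for chrom, sub in df.groupby("chrom"):
            sub = sub.sort_values("bp")
            bp = sub["bp"].to_numpy(dtype=float)
            cm = sub["cm"].to_numpy(dtype=float)
            if np.any(np.diff(bp) <= 0) or np.any(np.diff(cm) <= 0):
                raise ValidationError(f"map for chromosome {chrom} is not strictly increasing")
            out.anchors[str(chrom)] = (bp, cm)
        return out

    @classmethod
    def read(cls, path) -> "GeneticMap":
        df = pd.read_csv(
            path, sep=None, engine="python", header=None, names=["chrom", "bp", "cm"], comment="#"
        )
        return cls.from_table(df)

    def cm_at(self, chrom: str, bp: np.ndarray) -> np.ndarray:
        """Interpolated cM positions; outside the anchors, clamped with a warning."""
        chrom = str(chrom)
        if chrom not in self.anchors:
            raise ValidationError(f"no genetic map for chromosome {chrom}")
        xb, xc = self.anchors[chrom]
        bp = np.asarray(bp, dtype=float)
        if np.any(bp < xb[0]) or np.any(bp > xb[-1]):
            warnings.warn(
                f"positions outside map anchors on chromosome {chrom}; clamped", stacklevel=2
            )
        return np.interp(bp, xb, xc)

    def span(self, chrom: str) -> tuple[float, float]:
        _, xc = self.anchors[str(chrom)]
        return float(xc[0]), float(xc[-1])


@dataclass(frozen=True)
class SharedSegment:
    id1: str
    id2: str
    chrom: str
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.id1, self.id2)))


def _candidate_pairs(seqs: np.ndarray, window: int) -> set[tuple[int, int]]:
    """Pairs of rows sharing at least one exact allele word of ``window`` markers.

    Windows slide by half a window so a shared run need only cover 1.5
    windows to guarantee one fully contained word.
    """
    n, m = seqs.shape
    pairs: set[tuple[int, int]] = set()
    for lo in range(0, m, max(1, window // 2)):
        words = [hash(seqs[i, lo : lo + window].tobytes()) for i in range(n)]
        buckets: dict[int, list[int]] = {}
        for i, w in enumerate(words):
            buckets.setdefault(w, []).append(i)
        for members in buckets.values():
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    pairs.add((members[a], members[b]))
    return pairs


def _segments_from_breaks(
    breaks: np.ndarray, m: int, mismatch_per_100: float
) -> list[tuple[int, int]]:
    """Maximal runs [i, j] (marker indices) merging across isolated mismatches.

    Adjacent mismatch-free runs are merged greedily left to right while the
    total mismatch count inside the merged span stays within the budget of
    ``mismatch_per_100`` per 100 markers.
    """
    cuts = np.concatenate([[-1], breaks, [m]])
    runs = [(int(cuts[k] + 1), int(cuts[k + 1] - 1)) for k in range(cuts.size - 1)]
    runs = [r for r in runs if r[1] >= r[0]]
    if not runs:
        return []
    merged = [runs[0]]
    n_mis = 0
    for r in runs[1:]:
        start, _ = merged[-1]
        span = r[1] - start + 1
        if (n_mis + 1) <= mismatch_per_100 * span / 100.0:
            n_mis += 1
            merged[-1] = (start, r[1])
        else:
            merged.append(r)
            n_mis = 0
    return merged


def detect_segments(
    data: np.ndarray,
    ids: Sequence[str],
    snps: pd.DataFrame,
    gmap: GeneticMap,
    min_cm: float = 5.0,
    mode: str = "haplotype",
    window: int = 64,
    mismatch_per_100: float | None = None,
) -> list[SharedSegment]:
    """Windowed-hashing IBD segment detection.

    ``data`` is (n_sequences, n_markers): haplotype alleles (0/1) in
    haplotype mode, or dosages (0/1/2) in genotype mode, where only opposite
    homozygotes break a match.  ``snps`` needs chrom and pos columns sorted
    by position within chromosome.  Segments shorter than ``min_cm`` are not
    reported.  ``mismatch_per_100`` is the extension mismatch budget per 100
    markers; it defaults to 1 for haplotypes (genotyping error) and to 0 in
    genotype mode, where an opposite-homozygote pair is a hard exclusion of
    any shared haplotype.
    """
    if mismatch_per_100 is None:
        mismatch_per_100 = 1.0 if mode == "haplotype" else 0.0
    data = np.ascontiguousarray(np.asarray(data, dtype=np.int8))
    if data.shape[0] != len(ids):
        raise ValidationError("one id per sequence required")
    segments: list[SharedSegment] = []
    snps = snps.reset_index(drop=True)
    for chrom, sub in snps.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValidationError(f"markers unsorted on chromosome {chrom}")
        cols = sub.index.to_numpy()
        block = data[:, cols]
        cm = gmap.cm_at(str(chrom), pos)
        m = pos.size
        if mode == "haplotype":
            pairs = _candidate_pairs(block, window)
        elif mode == "genotype":
            # hashing exact dosage words still finds long identical stretches;
            # opposite-homozygote breaking happens at extension time
            pairs = _candidate_pairs(block, window)
        else:
            raise ValidationError(f"unknown mode: {mode}")
        for i, j in sorted(pairs):
            if mode == "haplotype":
                breaks = np.flatnonzero(block[i] != block[j])
            else:
                breaks = np.flatnonzero(np.abs(block[i].astype(int) - block[j]) == 2)
            for lo, hi in _segments_from_breaks(breaks, m, mismatch_per_100):
                length = cm[hi] - cm[lo]
                if length >= min_cm:
                    segments.append(
                        SharedSegment(
                            id1=str(ids[i]),
                            id2=str(ids[j]),
                            chrom=str(chrom),
                            start_bp=int(pos[lo]),
                            end_bp=int(pos[hi]),
                            start_cm=float(cm[lo]),
                            end_cm=float(cm[hi]),
                        )
                    )
    return segments


def sharing_profile(
    segments: Sequence[SharedSegment],
    gmap: GeneticMap,
    n_pairs: int,
    grid_cm: float = 2.5,
    mask: Sequence[tuple[str, float, float]] = (),
) -> pd.DataFrame:
    """Pair-sharing counts at grid sites every ``grid_cm`` centimorgans.

    ``mask`` lists (chrom, start_cm, end_cm) intervals (telomeres,
    centromeres) whose grid sites are excluded.  ``n_pairs`` is the number
    of possible pairs, the denominator of the sharing proportion.
    """
    if grid_cm <= 0:
        raise ValidationError("grid step must be positive")
    rows = []
    for chrom in gmap.anchors:
        lo, hi = gmap.span(chrom)
        sites = np.arange(lo, hi + 1e-9, grid_cm)
        for chrom_m, a, b in mask:
            if str(chrom_m) == chrom:
                sites = sites[(sites < a) | (sites > b)]
        segs = [s for s in segments if s.chrom == chrom]
        starts = np.array([s.start_cm for s in segs]) if segs else np.empty(0)
        ends = np.array([s.end_cm for s in segs]) if segs else np.empty(0)
        for site in sites:
            count = int(np.sum((starts <= site) & (ends >= site))) if segs else 0
            rows.append(
                {
                    "chrom": chrom,
                    "cm": float(site),
                    "count": count,
                    "proportion": count / n_pairs if n_pairs else 0.0,
                }
            )
    return pd.DataFrame(rows)


def group_excess_sharing(
    segments: Sequence[SharedSegment],
    pairs_a: Sequence[tuple[str, str]],
    pairs_b: Sequence[tuple[str, str]],
    gmap: GeneticMap,
    grid_cm: float = 2.5,
    target: tuple[str, float] | None = None,
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
    mask: Sequence[tuple[str, float, float]] = (),
) -> dict:
    """Per-site sharing difference between two pair groups with permutation p-values.

    Builds a pair x grid-site span indicator, contrasts the mean sharing
    proportion of groups A and B at every site (label-permutation p-values),
    and, if ``target`` = (chrom, cM) is given, reports the empirical
    percentile of the target site's group-A sharing within group A's
    genome-wide profile.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pa = [tuple(sorted(p)) for p in pairs_a]
    pb = [tuple(sorted(p)) for p in pairs_b]
    all_pairs = pa + pb
    labels = np.array([0] * len(pa) + [1] * len(pb))
    pair_index: dict[tuple[str, str], list[int]] = {}
    for k, p in enumerate(all_pairs):  # the same pair may appear in both groups
        pair_index.setdefault(p, []).append(k)

    sites = []
    for chrom in gmap.anchors:
        lo, hi = gmap.span(chrom)
        s = np.arange(lo, hi + 1e-9, grid_cm)
        for chrom_m, a, b in mask:
            if str(chrom_m) == chrom:
                s = s[(s < a) | (s > b)]
        sites.extend((chrom, float(x)) for x in s)
    span = np.zeros((len(all_pairs), len(sites)), dtype=bool)
    site_arr: dict[str, list[tuple[int, float]]] = {}
    for k, (chrom, x) in enumerate(sites):
        site_arr.setdefault(chrom, []).append((k, x))
    for seg in segments:
        for idx in pair_index.get(seg.pair, ()):
            for k, x in site_arr.get(seg.chrom, ()):
                if seg.start_cm <= x <= seg.end_cm:
                    span[idx, k] = True

    in_a = labels == 0
    prop_a = span[in_a].mean(axis=0) if in_a.any() else np.zeros(len(sites))
    prop_b = span[~in_a].mean(axis=0) if (~in_a).any() else np.zeros(len(sites))
    diff = prop_a - prop_b
    exceed = np.zeros(len(sites))
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        pa_m = perm == 0
        d = span[pa_m].mean(axis=0) - span[~pa_m].mean(axis=0)
        exceed += np.abs(d) >= np.abs(diff) - 1e-15
    pvals = (1 + exceed) / (1 + n_perm)

    table = pd.DataFrame(
        {
            "chrom": [c for c, _ in sites],
            "cm": [x for _, x in sites],
            "prop_a": prop_a,
            "prop_b": prop_b,
            "diff": diff,
            "perm_p": pvals,
        }
    )
    out = {"table": table}
    if target is not None:
        chrom_t, cm_t = target
        sub = table[table["chrom"] == str(chrom_t)]
        if sub.empty:
            raise ValidationError(f"target chromosome {chrom_t} not on the grid")
        k = (sub["cm"] - cm_t).abs().idxmin()
        target_prop = table.loc[k, "prop_a"]
        others = table["prop_a"].drop(index=k).to_numpy()
        if others.size:
            pct = 100.0 * ((others < target_prop).sum() + 0.5 * (others == target_prop).sum()) / others.size
        else:
            pct = 100.0
        out["target_site"] = {
            "chrom": str(chrom_t),
            "cm": float(table.loc[k, "cm"]),
            "prop_a": float(target_prop),
            "genome_percentile": float(pct),
        }
    return out
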