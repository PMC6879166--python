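"""Recombination landscapes: per-site posterior means, binned maps, and
map-to-map comparison/clustering.

The per-site map is the posterior expectation of the local rho over the
discretised Gamma categories (a convex combination of rho0 * r_l, hence
bounded by the extreme category rates).  Time-restricted maps condition the
category posterior on the MAP TMRCA interval and, downstream, only average
sites whose MAP interval is recent enough — de-weighting ancient shared
recombination events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.stats import pearsonr, rankdata

from .errors import InvalidArgumentError
from .hmm import MISSING, PosteriorField
from .model import RhoPrior

__all__ = [
    "RecombinationMap",
    "BinnedMap",
    "R2Result",
    "ClusterResult",
    "posterior_mean_rho",
    "time_restricted_rho",
    "bin_map",
    "bin_values",
    "compare_r2",
    "map_distance_cluster",
]

DEFAULT_WINDOW_WIDTHS = (50_000, 200_000, 500_000, 1_000_000)


@dataclass
class RecombinationMap:
    """Per-site posterior-mean rho with optional TMRCA annotation."""

    rho: np.ndarray
    missing: np.ndarray
    contigs: list
    map_interval: np.ndarray | None = None
    restrict_below: int | None = None
    fallback: np.ndarray | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.rho)

    @classmethod
    def from_values(cls, values: np.ndarray, contigs: list | None = None,
                    provenance: str = "truth") -> "RecombinationMap":
        values = np.asarray(values, dtype=float)
        return cls(rho=values, missing=np.zeros(len(values), dtype=bool),
                   contigs=contigs or [("seq", 0, len(values))],
                   provenance=provenance)


@dataclass
class BinnedMap:
    """Fixed-width windowed averages of a per-site map.

    Windows exceeding the missing-data threshold (or containing no
    includable site) are masked.
    """

    chroms: np.ndarray
    starts: np.ndarray
    ends: np.ndarray
    values: np.ndarray
    missing_frac: np.ndarray
    mask: np.ndarray
    width: int

    def __len__(self) -> int:
        return len(self.values)

    def same_grid(self, other: "BinnedMap") -> bool:
        return (len(self) == len(other) and self.width == other.width
                and np.array_equal(self.starts, other.starts)
                and np.array_equal(self.chroms, other.chroms))

    def to_frame(self) -> pd.DataFrame:
        vals = np.where(self.mask, np.nan, self.values)
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts,
                             "end": self.ends, "value": vals})


@dataclass(frozen=True)
class R2Result:
    r2: float
    ci_low: float
    ci_high: float
    n_windows: int
    n_bootstrap: int
    seed: int


@dataclass
class ClusterResult:
    labels: list
    distance: pd.DataFrame
    linkage: np.ndarray
    newick: str
    supports: dict = field(default_factory=dict)
    n_windows: int = 0


# ---------------------------------------------------------------------------
# posterior -> per-site maps
# ---------------------------------------------------------------------------

def posterior_mean_rho(posterior: PosteriorField, prior: RhoPrior
                       ) -> RecombinationMap:
    """Posterior-mean rho per site: rho0 * sum_l r_l * P_i(category l)."""
    if posterior.k != prior.k:
        raise InvalidArgumentError("posterior/prior category mismatch")
    rho = prior.rho0 * (posterior.cat_marginal.astype(np.float64)
                        @ prior.category_means)
    return RecombinationMap(rho=rho, missing=posterior.codes == MISSING,
                            contigs=list(posterior.contigs),
                            map_interval=posterior.map_interval,
                            provenance="posterior_mean")


def time_restricted_rho(posterior: PosteriorField, prior: RhoPrior,
                        max_interval: int) -> RecombinationMap:
    """Per-site rho conditioned on the MAP TMRCA interval.

    Sites whose MAP interval index is >= ``max_interval`` are excluded from
    downstream window averages; sites where the MAP interval carried no
    numerical mass fall back to the unrestricted posterior mean and are
    flagged.
    """
    if not 1 <= max_interval <= posterior.t:
        raise InvalidArgumentError("max_interval out of range")
    if posterior.k != prior.k:
        raise InvalidArgumentError("posterior/prior category mismatch")
    rho = prior.rho0 * (posterior.cat_given_map.astype(np.float64)
                        @ prior.category_means)
    return RecombinationMap(rho=rho, missing=posterior.codes == MISSING,
                            contigs=list(posterior.contigs),
                            map_interval=posterior.map_interval,
                            restrict_below=int(max_interval),
                            fallback=posterior.fallback,
                            provenance="time_restricted")


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def _window_grid(length: int, width: int):
    """Non-overlapping windows; a trailing partial window is kept only if it
    covers at least half the width."""
    n_full = length // width
    rem = length - n_full * width
    n = n_full + (1 if rem >= width / 2 else 0)
    n = max(n, 1) if length else 0
    starts = np.arange(n) * width
    ends = np.minimum(starts + width, length)
    return starts, ends


def bin_map(rmap: RecombinationMap, width: int,
            missing_threshold: float = 0.5) -> BinnedMap:
    """Average a per-site map into fixed-width windows.

    The mean is taken over includable sites (all sites, or — for
    time-restricted maps — sites with a recent-enough MAP TMRCA); windows
    with a missing-data fraction above the threshold, or with no includable
    site, are masked.
    """
    if width < 1:
        raise InvalidArgumentError("window width must be >= 1")
    chroms, starts, ends, vals, miss, mask = [], [], [], [], [], []
    for name, cstart, cend in rmap.contigs:
        length = cend - cstart
        ws, we = _window_grid(length, width)
        rho = rmap.rho[cstart:cend]
        missing = rmap.missing[cstart:cend]
        include = np.ones(length, dtype=bool)
        if rmap.restrict_below is not None and rmap.map_interval is not None:
            include = rmap.map_interval[cstart:cend] < rmap.restrict_below
        for s, e in zip(ws, we):
            inc = include[s:e]
            n_inc = int(inc.sum())
            mfrac = float(missing[s:e].mean())
            masked = mfrac > missing_threshold or n_inc == 0
            vals.append(float(rho[s:e][inc].mean()) if n_inc else np.nan)
            chroms.append(name)
            starts.append(int(s))
            ends.append(int(e))
            miss.append(mfrac)
            mask.append(masked)
    return BinnedMap(chroms=np.asarray(chroms), starts=np.asarray(starts),
                     ends=np.asarray(ends), values=np.asarray(vals),
                     missing_frac=np.asarray(miss),
                     mask=np.asarray(mask, dtype=bool), width=int(width))


def bin_values(values: np.ndarray, width: int, chrom: str = "seq"
               ) -> BinnedMap:
    """Bin a raw per-site array (e.g. a simulated truth landscape)."""
    return bin_map(RecombinationMap.from_values(values,
                                                [(chrom, 0, len(values))]),
                   width)


# ---------------------------------------------------------------------------
# comparison and clustering
# ---------------------------------------------------------------------------

def compare_r2(inferred: BinnedMap, truth: BinnedMap,
               n_bootstrap: int = 100, seed: int = 0) -> R2Result:
    """Squared Pearson correlation over jointly unmasked windows with a
    percentile bootstrap CI from window resampling."""
    if not inferred.same_grid(truth):
        raise InvalidArgumentError("maps are binned on different grids")
    ok = ~inferred.mask & ~truth.mask
    x = inferred.values[ok]
    y = truth.values[ok]
    if len(x) < 3:
        raise InvalidArgumentError("fewer than 3 shared unmasked windows")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        # a flat map explains no variance; correlation is otherwise undefined
        return R2Result(r2=0.0, ci_low=0.0, ci_high=0.0,
                        n_windows=int(ok.sum()), n_bootstrap=n_bootstrap,
                        seed=seed)
    r2 = float(pearsonr(x, y)[0] ** 2)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_bootstrap)
    for i in range(n_bootstrap):
        idx = rng.integers(0, len(x), len(x))
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            boots[i] = np.nan
            continue
        boots[i] = pearsonr(xb, yb)[0] ** 2
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    return R2Result(r2=r2, ci_low=float(lo), ci_high=float(hi),
                    n_windows=int(ok.sum()), n_bootstrap=n_bootstrap,
                    seed=seed)


def _spearman_distance_matrix(data: np.ndarray) -> np.ndarray:
    """1 - Spearman rank correlation between the rows of ``data``."""
    ranks = np.apply_along_axis(rankdata, 1, data)  # average ranks for ties
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks ** 2).sum(axis=1))
    corr = (ranks @ ranks.T) / np.outer(norm, norm)
    np.fill_diagonal(corr, 1.0)
    return 1.0 - corr


def _clades(linkage: np.ndarray, n: int):
    """Leaf sets of every internal node of a linkage tree."""
    members = {i: frozenset([i]) for i in range(n)}
    out = []
    for row_idx, (a, b, _, _) in enumerate(linkage):
        merged = members[int(a)] | members[int(b)]
        members[n + row_idx] = merged
        out.append(merged)
    return out


def _to_newick(linkage: np.ndarray, labels, supports, threshold):
    """Newick string with bootstrap supports; internal nodes below the
    support threshold are collapsed into polytomies (depths preserved)."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height):
        length = parent_height - (node.dist if not node.is_leaf() else 0.0)
        if node.is_leaf():
            return [f"{labels[node.id]}:{length:.6g}"]
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        leaves = frozenset(_leaf_ids(node))
        sup = supports.get(leaves, 1.0)
        if sup < threshold and parent_height < np.inf:
            # collapse: splice children into the parent level
            return [_re_root(part, node.dist, parent_height)
                    for part in left + right]
        inner = ",".join(left + right)
        return [f"({inner}){sup:.2f}:{length:.6g}"]

    parts = render(tree, np.inf)
    if len(parts) == 1 and parts[0].endswith(":inf"):
        parts[0] = parts[0][: -len(":inf")]
    body = parts[0] if len(parts) == 1 else "(" + ",".join(parts) + ")"
    return body + ";"


def _leaf_ids(node):
    return node.pre_order(lambda x: x.id)


def _re_root(part: str, old_parent_height: float, new_parent_height: float):
    """Extend the branch length of a spliced subtree to its new parent."""
    head, _, length = part.rpartition(":")
    extra = new_parent_height - old_parent_height
    if not np.isfinite(extra):
        return part
    return f"{head}:{float(length) + extra:.6g}"


def map_distance_cluster(maps, n_bootstrap: int = 1000,
                         support_threshold: float = 0.6, seed: int = 0,
                         labels=None) -> ClusterResult:
    """UPGMA clustering of binned maps by 1 - Spearman correlation.

    Windows masked in *any* map are excluded for all; clade support is the
    fraction of window-resampling bootstrap replicates containing the clade,
    and clades below the threshold are collapsed in the Newick output.
    """
    maps = list(maps)
    if len(maps) < 3:
        raise InvalidArgumentError("need at least 3 maps to cluster")
    grid = maps[0]
    for m in maps[1:]:
        if not grid.same_grid(m):
            raise InvalidArgumentError("maps are binned on different grids")
    ok = ~np.any([m.mask for m in maps], axis=0)
    if ok.sum() < 10:
        raise InvalidArgumentError("fewer than 10 jointly unmasked windows")
    data = np.vstack([m.values[ok] for m in maps])
    n, w = data.shape
    labels = list(labels) if labels is not None else \
        [f"map{i}" for i in range(n)]

    dist = _spearman_distance_matrix(data)
    link = hierarchy.linkage(dist[np.triu_indices(n, 1)], method="average")
    observed = _clades(link, n)

    rng = np.random.default_rng(seed)
    counts = {c: 0 for c in observed}
    for _ in range(n_bootstrap):
        idx = rng.integers(0, w, w)
        db = _spearman_distance_matrix(data[:, idx])
        lb = hierarchy.linkage(db[np.triu_indices(n, 1)], method="average")
        for clade in _clades(lb, n):
            if clade in counts:
                counts[clade] += 1
    supports = {c: counts[c] / n_bootstrap for c in observed}

    newick = _to_newick(link, labels, supports, support_threshold)
    dist_df = pd.DataFrame(dist, index=labels, columns=labels)
    named_supports = {
        tuple(sorted(labels[i] for i in clade)): supports[clade]
        for clade in observed}
    return ClusterResult(labels=labels, distance=dist_df, linkage=link,
                         newick=newick, supports=named_supports,
                         n_windows=int(ok.sum()))
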