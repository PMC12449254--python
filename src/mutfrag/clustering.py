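"""Group mutations into fragment regions.

The search couples a partitioning-around-medoids (PAM) heuristic over bp
positions — with distances between paired (combined) mutations shrunk to
promote co-clustering — to an exact dynamic program over position-sorted
mutation atoms. The PAM loop follows the iterate-k scheme (start at one
cluster, split until every cluster is already below the minimum fragment
core size); the DP guarantees that, whenever any size-valid partition
exists, one with the minimum number of regions (and the minimum total
fragment length among contiguous partitions) is among the candidates.

A cluster is size-valid when a wild-type region length W exists such that
every member mutation's fragment (W + member net indel + 2 minimal flanks)
fits the provider's [min_fragment_bp, max_fragment_bp] range.
"""
from __future__ import annotations

import logging
import random
from dataclasses import dataclass

import numpy as np

from .model import (
    Clustering,
    ClusteringError,
    DesignSettings,
    GeneContext,
    MutationPoint,
    MutationSpec,
    spec_hull,
)

logger = logging.getLogger(__name__)

#: multiplier applied to distances within a combined group
CO_CLUSTER_FACTOR = 0.01

_INF = float("inf")


# ---------------------------------------------------------------------------
# Mutation points and distances
# ---------------------------------------------------------------------------


def mutation_points(muts: list[MutationSpec], gene: GeneContext) -> list[MutationPoint]:
    """One clusterable point per point-mutation member; one per indel.

    Points carry the codon midpoint (3(r-1)+1) for substitutions, the floor
    midpoint of the affected interval for deletions, and the insertion
    boundary 3*anchor for insertions.
    """
    pts: list[MutationPoint] = []
    for spec in muts:
        if spec.kind in ("point", "combined"):
            for i, sub in enumerate(spec.subs):
                start = 3 * (sub.residue - 1)
                pts.append(MutationPoint(spec.label, i, start + 1, (start, start + 3)))
        elif spec.kind == "deletion":
            (s, e), = spec.extents()
            pts.append(MutationPoint(spec.label, 0, (s + e) // 2, (s, e)))
        else:  # insertion
            (s, e), = spec.extents()
            pts.append(MutationPoint(spec.label, 0, s, (s, e)))
    return pts


def combined_groups(muts: list[MutationSpec]) -> list[set[str]]:
    """Label sets whose points must co-cluster (one per combined spec)."""
    return [{m.label} for m in muts if m.kind == "combined"]


def constrained_distance_matrix(
    points: list[MutationPoint],
    groups: list[set[str]] | None = None,
    factor: float = CO_CLUSTER_FACTOR,
) -> np.ndarray:
    """Pairwise |position difference|, shrunk by ``factor`` for point pairs
    belonging to one combined group."""
    groups = groups or []
    pos = np.array([p.position_bp for p in points], dtype=float)
    d = np.abs(pos[:, None] - pos[None, :])
    for g in groups:
        idx = [i for i, p in enumerate(points) if p.mutation_ref in g]
        for a in idx:
            for b in idx:
                if a != b:
                    d[a, b] *= factor
    return d


# ---------------------------------------------------------------------------
# PAM (partitioning around medoids)
# ---------------------------------------------------------------------------


def cluster_k(matrix: np.ndarray, k: int, seed: int = 42) -> list[int]:
    """Deterministic PAM: greedy BUILD then best-improvement SWAP.

    The seed only shuffles exact ties. Returns a cluster index per point,
    with clusters numbered by ascending medoid index.
    """
    d = np.asarray(matrix, dtype=float)
    n = d.shape[0]
    if not 1 <= k <= n:
        raise ClusteringError(f"k={k} outside [1, {n}]")
    rng = random.Random(seed)

    def pick(candidates: list[int], scores: np.ndarray, minimize: bool) -> int:
        best = min(scores[c] for c in candidates) if minimize else max(
            scores[c] for c in candidates)
        tied = sorted(c for c in candidates if scores[c] == best)
        return tied[0] if len(tied) == 1 else rng.choice(tied)

    # BUILD
    totals = d.sum(axis=1)
    medoids = [pick(list(range(n)), totals, minimize=True)]
    nearest = d[medoids[0]].copy()
    while len(medoids) < k:
        gains = np.full(n, -_INF)
        for c in range(n):
            if c in medoids:
                continue
            gains[c] = np.maximum(nearest - d[c], 0.0).sum()
        c = pick([i for i in range(n) if i not in medoids], gains, minimize=False)
        medoids.append(c)
        nearest = np.minimum(nearest, d[c])

    def cost_of(meds: list[int]) -> float:
        return d[meds].min(axis=0).sum()

    # SWAP
    current = cost_of(medoids)
    while True:
        best_delta = -1e-12
        best_swaps: list[tuple[int, int]] = []
        med_set = set(medoids)
        for m in medoids:
            rest = [x for x in medoids if x != m]
            for o in range(n):
                if o in med_set:
                    continue
                delta = current - cost_of(rest + [o])
                if delta > best_delta + 1e-12:
                    best_delta = delta
                    best_swaps = [(m, o)]
                elif abs(delta - best_delta) <= 1e-12 and delta > 0:
                    best_swaps.append((m, o))
        if not best_swaps or best_delta <= 0:
            break
        m, o = best_swaps[0] if len(best_swaps) == 1 else rng.choice(sorted(best_swaps))
        medoids[medoids.index(m)] = o
        current = cost_of(medoids)

    medoids = sorted(medoids)
    assign = []
    for j in range(n):
        dists = [d[m, j] for m in medoids]
        assign.append(int(np.argmin(dists)))
    # renumber so cluster ids appear in order of first point
    remap: dict[int, int] = {}
    out = []
    for a in assign:
        if a not in remap:
            remap[a] = len(remap)
        out.append(remap[a])
    return out


# ---------------------------------------------------------------------------
# Cluster size validity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterStats:
    span_bp: int          # codon-aligned wild-type hull of member extents
    w_low: int            # smallest admissible wild-type region length
    w_high: int           # largest admissible wild-type region length
    prototype_len: int    # implied fragment length of the region prototype
    valid: bool


def _align_down(x: int) -> int:
    return x - x % 3


def _align_up(x: int) -> int:
    return x + (-x) % 3


def cluster_stats(specs: list[MutationSpec], settings: DesignSettings) -> ClusterStats:
    """Size feasibility of one cluster.

    W ranges over wild-type region lengths; every member m implies a mutant
    fragment of W + net_indel(m) + 2*min_flank bp, all of which must fall in
    [min_fragment_bp, max_fragment_bp].
    """
    hulls = [spec_hull(s) for s in specs]
    s0 = _align_down(min(h[0] for h in hulls))
    e0 = _align_up(max(h[1] for h in hulls))
    span = e0 - s0
    nets = [s.net_indel_bp for s in specs]
    w_low = _align_up(max(span, settings.min_region_core_bp - min(nets), 0))
    w_high = (settings.max_fragment_bp - 2 * settings.min_flank_bp) - max(nets)
    prototype = w_low + 2 * settings.min_flank_bp + sum(nets)
    return ClusterStats(span, w_low, w_high, prototype, w_low <= w_high)


def fragment_span_bp(specs: list[MutationSpec], settings: DesignSettings) -> int:
    """Implied fragment length of a cluster: wild-type hull padded to the
    minimum core, plus two minimal flanks, adjusted for member indels."""
    return cluster_stats(specs, settings).prototype_len


# ---------------------------------------------------------------------------
# Candidate enumeration and selection
# ---------------------------------------------------------------------------


def _partition_key(blocks: list[list[MutationSpec]]) -> frozenset:
    return frozenset(frozenset(s.label for s in b) for b in blocks)


def _make_clustering(blocks: list[list[MutationSpec]], settings: DesignSettings,
                     source: str) -> Clustering | None:
    stats = [cluster_stats(b, settings) for b in blocks]
    if not all(st.valid for st in stats):
        return None
    # deterministic cluster order: by leftmost member hull
    order = sorted(range(len(blocks)),
                   key=lambda i: (min(spec_hull(s)[0] for s in blocks[i]),
                                  sorted(s.label for s in blocks[i])))
    assignment = {}
    for new_idx, i in enumerate(order):
        for s in blocks[i]:
            assignment[s.label] = new_idx
    total = sum(st.prototype_len for st in stats)
    k = len(blocks)
    return Clustering(k=k, assignment=assignment, valid=True,
                      total_fragment_bp=total, n_fragments=k, source=source)


def _contiguous_dp(atoms: list[MutationSpec], settings: DesignSettings
                   ) -> dict[int, tuple[int, list[list[MutationSpec]]]]:
    """For each block count k, the minimum total implied fragment length over
    partitions of ``atoms`` (given in position-sorted order) into k
    contiguous runs of size-valid blocks. Empty input -> {0: (0, [])}."""
    n = len(atoms)
    cost = [[_INF] * (n + 1) for _ in range(n + 1)]
    for i in range(n):
        for j in range(i + 1, n + 1):
            st = cluster_stats(atoms[i:j], settings)
            if st.valid:
                cost[i][j] = st.prototype_len
    best: list[dict[int, tuple[float, int]]] = [dict() for _ in range(n + 1)]
    best[0][0] = (0.0, -1)
    for j in range(1, n + 1):
        for i in range(j):
            if cost[i][j] == _INF:
                continue
            for k, (c, _) in best[i].items():
                cand = c + cost[i][j]
                if k + 1 not in best[j] or cand < best[j][k + 1][0]:
                    best[j][k + 1] = (cand, i)
    out: dict[int, tuple[int, list[list[MutationSpec]]]] = {}
    for k, (c, _) in best[n].items():
        blocks: list[list[MutationSpec]] = []
        j, kk = n, k
        while j > 0:
            _, i = best[j][kk]
            blocks.append(atoms[i:j])
            j, kk = i, kk - 1
        out[k] = (int(c), list(reversed(blocks)))
    if n == 0:
        out[0] = (0, [])
    return out


#: exact subset optimization is used up to this many mutation atoms
EXACT_SEARCH_MAX_ATOMS = 12


def _subset_dp_candidates(atoms: list[MutationSpec], settings: DesignSettings
                          ) -> dict[int, tuple[int, list[list[MutationSpec]]]]:
    """Exact optimization over ALL set partitions: for every block count k,
    the minimum total implied fragment length (O(3^n), n <= 12)."""
    n = len(atoms)
    hulls = [spec_hull(a) for a in atoms]
    nets = [a.net_indel_bp for a in atoms]
    core = settings.min_region_core_bp
    flanks = 2 * settings.min_flank_bp
    cap = settings.max_fragment_bp - flanks
    n_masks = 1 << n
    cost = [0.0] * n_masks
    lo = [0] * n_masks
    hi = [0] * n_masks
    net_min = [0] * n_masks
    net_max = [0] * n_masks
    net_sum = [0] * n_masks
    for mask in range(1, n_masks):
        lb = mask & -mask
        i = lb.bit_length() - 1
        rest = mask ^ lb
        if rest:
            lo[mask] = min(lo[rest], hulls[i][0])
            hi[mask] = max(hi[rest], hulls[i][1])
            net_min[mask] = min(net_min[rest], nets[i])
            net_max[mask] = max(net_max[rest], nets[i])
            net_sum[mask] = net_sum[rest] + nets[i]
        else:
            lo[mask], hi[mask] = hulls[i]
            net_min[mask] = net_max[mask] = net_sum[mask] = nets[i]
        span = _align_up(hi[mask]) - _align_down(lo[mask])
        w_low = _align_up(max(span, core - net_min[mask], 0))
        if w_low <= cap - net_max[mask]:
            cost[mask] = w_low + flanks + net_sum[mask]
        else:
            cost[mask] = _INF
    # dp[mask] : {k: (total, block_mask)}
    dp: list[dict[int, tuple[float, int]]] = [dict() for _ in range(n_masks)]
    dp[0][0] = (0.0, 0)
    for mask in range(1, n_masks):
        j = (mask & -mask).bit_length() - 1
        others = mask ^ (1 << j)
        sub = others
        while True:
            block = sub | (1 << j)
            if cost[block] != _INF:
                rem = mask ^ block
                for k, (c, _) in dp[rem].items():
                    cand = c + cost[block]
                    if k + 1 not in dp[mask] or cand < dp[mask][k + 1][0]:
                        dp[mask][k + 1] = (cand, block)
            if sub == 0:
                break
            sub = (sub - 1) & others
    full = n_masks - 1
    out: dict[int, tuple[int, list[list[MutationSpec]]]] = {}
    for k, (total, _) in dp[full].items():
        blocks, mask, kk = [], full, k
        while mask:
            _, block = dp[mask][kk]
            blocks.append([atoms[i] for i in range(n) if block >> i & 1])
            mask, kk = mask ^ block, kk - 1
        out[k] = (int(total), blocks)
    return out


def _exact_candidates(specs: list[MutationSpec], settings: DesignSettings
                      ) -> list[Clustering]:
    """Per block count k, the best partition from an exact search: a full
    subset dynamic program for panels up to EXACT_SEARCH_MAX_ATOMS atoms,
    otherwise the optimal position-contiguous partition (with an interval
    enumeration around a single indel atom so it can be kept out of blocks
    it would oversize)."""
    atoms = sorted(specs, key=lambda s: (spec_hull(s)[0], spec_hull(s)[1], s.label))
    best_per_k: dict[int, tuple[int, list[list[MutationSpec]]]] = {}

    def consider(total: int, blocks: list[list[MutationSpec]]) -> None:
        k = len(blocks)
        if k not in best_per_k or total < best_per_k[k][0]:
            best_per_k[k] = (total, blocks)

    if len(atoms) <= EXACT_SEARCH_MAX_ATOMS:
        for k, (total, blocks) in _subset_dp_candidates(atoms, settings).items():
            consider(total, blocks)
    else:
        indel_idx = [i for i, a in enumerate(atoms) if a.net_indel_bp != 0]
        if len(indel_idx) == 1:
            idx = indel_idx[0]
            n = len(atoms)
            for i in range(idx + 1):
                for j in range(idx + 1, n + 1):
                    st = cluster_stats(atoms[i:j], settings)
                    if not st.valid:
                        continue
                    rest = atoms[:i] + atoms[j:]
                    for _, (c, blocks) in _contiguous_dp(rest, settings).items():
                        consider(st.prototype_len + c, blocks + [atoms[i:j]])
        else:
            for k, (c, blocks) in _contiguous_dp(atoms, settings).items():
                consider(c, blocks)

    out = []
    for k in sorted(best_per_k):
        if k == 0:
            continue
        total, blocks = best_per_k[k]
        cl = _make_clustering(blocks, settings, source="dp")
        if cl is not None:
            out.append(cl)
    return out


def find_valid_clusterings(muts: list[MutationSpec], gene: GeneContext,
                           settings: DesignSettings,
                           seed: int | None = None) -> list[Clustering]:
    """Evaluate k = 1, 2, ... and collect every clustering in which all
    clusters are size-valid and every combined group is co-clustered.

    The PAM loop stops after the first k at which every cluster's wild-type
    span is already below the minimum fragment core (further splitting
    cannot help), or at k = n. Exact contiguous candidates are merged in for
    every k.
    """
    if not muts:
        raise ClusteringError("no mutations to cluster")
    seed = settings.random_seed if seed is None else seed
    pts = mutation_points(muts, gene)
    by_label = {m.label: m for m in muts}
    d = constrained_distance_matrix(pts, combined_groups(muts))
    results: list[Clustering] = []
    seen: set[frozenset] = set()

    for k in range(1, len(pts) + 1):
        assign = cluster_k(d, k, seed=seed)
        spec_cluster: dict[str, int] = {}
        consistent = True
        for p, c in zip(pts, assign):
            if spec_cluster.setdefault(p.mutation_ref, c) != c:
                consistent = False  # combined group split by PAM
        clusters: dict[int, list[MutationSpec]] = {}
        if consistent:
            for label, c in spec_cluster.items():
                clusters.setdefault(c, []).append(by_label[label])
            blocks = list(clusters.values())
            cl = _make_clustering(blocks, settings, source="pam")
            if cl is not None:
                key = _partition_key(blocks)
                if key not in seen:
                    seen.add(key)
                    results.append(cl)
        # stop rule: every point-cluster hull already below the minimum core
        hulls: dict[int, tuple[int, int]] = {}
        for p, c in zip(pts, assign):
            s, e = p.extent_bp
            if c in hulls:
                hulls[c] = (min(hulls[c][0], s), max(hulls[c][1], e))
            else:
                hulls[c] = (s, e)
        if all(_align_up(e) - _align_down(s) < settings.min_region_core_bp
               for s, e in hulls.values()):
            break

    for cl in _exact_candidates(list(muts), settings):
        labels_by_cluster: dict[int, set[str]] = {}
        for label, c in cl.assignment.items():
            labels_by_cluster.setdefault(c, set()).add(label)
        key = frozenset(frozenset(v) for v in labels_by_cluster.values())
        if key not in seen:
            seen.add(key)
            results.append(cl)

    if not results:
        blockers = [m.label for m in muts
                    if not cluster_stats([m], settings).valid]
        detail = (f"mutations unplaceable even alone: {', '.join(blockers)}"
                  if blockers else "no partition satisfies the size limits")
        raise ClusteringError(f"no valid clustering: {detail}")
    logger.info("collected %d valid clusterings (k in %s)",
                len(results), sorted({c.k for c in results}))
    return results


def select_clustering(candidates: list[Clustering], mode: str) -> Clustering:
    """quantity: fewest regions (tie: smallest total bp); length: smallest
    total bp (tie: fewest regions). Remaining ties: smaller k, then a
    canonical partition ordering."""
    valid = [c for c in candidates if c.valid]
    if not valid:
        raise ClusteringError("no valid clustering to select from")
    if mode == "quantity":
        key = lambda c: (c.n_fragments, c.total_fragment_bp, c.k,
                         sorted(c.assignment.items()))
    elif mode == "length":
        key = lambda c: (c.total_fragment_bp, c.n_fragments, c.k,
                         sorted(c.assignment.items()))
    else:
        raise ValueError(f"unknown optimization mode {mode!r}")
    return min(valid, key=key)
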