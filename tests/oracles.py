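"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results from first principles (literal filter
comprehensions, hand-rolled UPGMA, explicit quantile fences, exhaustive
permutation) and share no code with the package implementation.
"""

from __future__ import annotations

import itertools

import numpy as np

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
BASES = "ACGT"


def oracle_call_events(induced, controls, site_gene, params, chemistry):
    """Literal four-filter caller: returns a set of
    (gene, contig, position, alt_count, depth) tuples.

    ``site_gene`` maps (contig, position) -> (gene_id, strand).
    """
    ref_t, alt_t = chemistry.split(">")
    control_maps = [{(s.contig, s.position): s for s in c} for c in controls]
    candidates = []
    for s in induced:
        if s.depth == 0 or (s.contig, s.position) not in site_gene:
            continue
        gene, strand = site_gene[(s.contig, s.position)]
        ref = ref_t if strand == "+" else COMP[ref_t]
        alt = alt_t if strand == "+" else COMP[alt_t]
        if s.ref_base != ref or s.depth < max(params.min_depth, 1):
            continue
        a = s.counts.get(alt, 0)
        # (3) support
        if a < params.min_alt:
            continue
        # (1) absent from every covering control; no covering control -> policy
        covering = [cm[(s.contig, s.position)] for cm in control_maps
                    if (s.contig, s.position) in cm]
        if not covering:
            if params.missing_control_policy != "accept":
                continue
        elif any(c.counts.get(alt, 0) > params.control_max_alt for c in covering):
            continue
        # (2) single SNV type
        nonref = {b: s.counts.get(b, 0) for b in BASES
                  if b != s.ref_base and s.counts.get(b, 0) > 0}
        total = sum(nonref.values())
        if total == 0 or a / total < params.purity_min_fraction:
            continue
        if any(n > params.max_secondary_alt for b, n in nonref.items() if b != alt):
            continue
        candidates.append((gene, s.contig, s.position, a, s.depth))
    # (4) per-transcript floor over events with ratio > min_event_ratio
    kept = set()
    genes = {c[0] for c in candidates}
    for g in genes:
        qual = [c for c in candidates
                if c[0] == g and c[3] / c[4] > params.min_event_ratio]
        if len(qual) >= params.min_events_per_transcript:
            kept.update(qual)
    return kept


def oracle_upgma(matrix: np.ndarray):
    """Hand-rolled UPGMA on correlation distance.

    Returns the sorted list of merge heights and the final two-cluster
    partition (frozenset of frozensets of row indices).
    """
    n = matrix.shape[0]

    def corr_dist(i, j):
        r = np.corrcoef(matrix[i], matrix[j])[0, 1]
        return 1.0 - r

    dist = {frozenset((i, j)): corr_dist(i, j)
            for i, j in itertools.combinations(range(n), 2)}
    clusters = {i: {i} for i in range(n)}
    heights = []
    partitions = []
    while len(clusters) > 1:
        pair = min(dist, key=lambda k: (dist[k], sorted(k)))
        a, b = sorted(pair)
        heights.append(dist[pair])
        merged = clusters[a] | clusters[b]
        del dist[pair]
        for c in clusters:
            if c in (a, b):
                continue
            ka, kb = frozenset((c, a)), frozenset((c, b))
            na, nb = len(clusters[a]), len(clusters[b])
            d = (dist.pop(ka) * na + dist.pop(kb) * nb) / (na + nb)
            dist[frozenset((c, a))] = d
        del clusters[b]
        clusters[a] = merged
        partitions.append(frozenset(frozenset(c) for c in clusters.values()))
    return heights, partitions


def oracle_qc(detected, edited, mode, min_genes, editing_ratio=None,
              nes_factor=1.5, erm_floor=200, erm_factor=3.0):
    """Literal QC fences: returns the boolean keep mask."""
    detected = np.asarray(detected)
    edited = np.asarray(edited, dtype=float)
    alive = detected >= min_genes
    if alive.sum() < 4:
        raise ValueError("quartiles unstable")

    def fences(v, f):
        q1 = np.quantile(v[alive], 0.25)
        q3 = np.quantile(v[alive], 0.75)
        return q1 - f * (q3 - q1), q3 + f * (q3 - q1)

    keep = alive.copy()
    if mode == "NES":
        lo, hi = fences(edited, nes_factor)
        keep &= (edited >= lo) & (edited <= hi)
        if editing_ratio is not None:
            er = np.asarray(editing_ratio, dtype=float)
            lo, hi = fences(er, nes_factor)
            keep &= (er >= lo) & (er <= hi)
    else:
        _, hi = fences(edited, erm_factor)
        keep &= (edited >= erm_floor) & (edited <= hi)
    return keep


def oracle_exact_mannwhitney_p(a, b):
    """Exact two-sided Mann-Whitney p by full enumeration of group
    assignments (small n only, no ties)."""
    pooled = list(a) + list(b)
    n_a = len(a)

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y) \
            + 0.5 * sum(1 for x in group_a for y in group_b if x == y)

    observed = u_stat(a, b)
    n_total = 0
    n_extreme = 0
    m = n_a * len(b)
    for combo in itertools.combinations(range(len(pooled)), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(len(pooled)) if i not in combo]
        u = u_stat(ga, gb)
        n_total += 1
        # two-sided: as or more extreme in either tail (distance from m/2)
        if abs(u - m / 2) >= abs(observed - m / 2) - 1e-12:
            n_extreme += 1
    return n_extreme / n_total
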