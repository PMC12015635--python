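"""Genotype-dosage linkage (r2) and greedy pruning of candidate markers.

Linkage between two candidate SNPs is summarized by the squared Pearson
correlation of their reference-allele dosages (0/1/2) over samples typed
at both sites.  Pairs closer than a genomic window with r2 above a
threshold are resolved greedily in coordinate order, dropping the site
with more missing data (then by an optional enzyme-accessibility rank,
then the larger coordinate), so a multilocus assay contains no pair of
markers in apparent linkage disequilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .variant_io import MISSING, GenotypeMatrix, snp_id

__all__ = ["LinkagePair", "dosage_r2", "prune", "PruneResult"]


@dataclass(frozen=True)
class LinkagePair:
    site_a: str
    site_b: str
    distance: int
    r_squared: float
    n_shared: int


def dosage_r2(x, y) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Missing calls (``MISSING``) are removed pairwise.  Raises when fewer
    than two shared samples remain or either vector is constant after
    pairwise deletion (r2 undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("dosage vectors differ in length")
    keep = (x != MISSING) & (y != MISSING)
    x, y = x[keep], y[keep]
    if x.size < 2:
        raise ValueError("fewer than 2 pairwise-complete samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance after pairwise deletion: r2 undefined")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class PruneResult:
    kept: list[int]  # indices into the input site list
    dropped: list[tuple[str, str, str]]  # (dropped snp_id, kept snp_id, rule)
    pairs: list[LinkagePair]  # all evaluated pairs above the threshold


def prune(
    matrix: GenotypeMatrix,
    r2_max: float = 0.2,
    window: int = 1_000_000,
    enzyme_rank: dict[str, float] | None = None,
) -> PruneResult:
    """Greedy linkage pruning of candidate sites.

    Every same-contig pair within *window* bp is evaluated; for each pair
    with ``r2 > r2_max`` one site is dropped: (1) the one with more
    missing data; (2) on a tie, the lower enzyme-accessibility rank
    (user-supplied mapping snp_id -> rank, higher = keep; absent = neutral);
    (3) on a tie, the larger coordinate.  Resolution is pair-at-a-time in
    coordinate order and deterministic; the surviving set contains no pair
    above the threshold.
    """
    enzyme_rank = enzyme_rank or {}
    ids = [snp_id(s.contig, s.pos, s.ref, s.alts[0]) for s in matrix.sites]
    n_missing = [
        int((matrix.dosage[i] == MISSING).sum()) for i in range(matrix.n_sites)
    ]
    order = sorted(range(matrix.n_sites), key=lambda i: (matrix.sites[i].contig, matrix.sites[i].pos))
    alive = set(order)
    dropped: list[tuple[str, str, str]] = []
    pairs: list[LinkagePair] = []
    for ai, i in enumerate(order):
        if i not in alive:
            continue
        si = matrix.sites[i]
        for j in order[ai + 1 :]:
            if i not in alive:
                break
            if j not in alive:
                continue
            sj = matrix.sites[j]
            if sj.contig != si.contig:
                break  # sorted order: no more same-contig sites
            dist = abs(sj.pos - si.pos)
            if dist > window:
                break
            try:
                r2 = dosage_r2(matrix.dosage[i], matrix.dosage[j])
            except ValueError:
                continue  # undefined pair: skipped, not counted as linked
            keep = (matrix.dosage[i] != MISSING) & (matrix.dosage[j] != MISSING)
            if r2 > r2_max:
                pairs.append(
                    LinkagePair(ids[i], ids[j], dist, r2, int(keep.sum()))
                )
                loser, rule = _resolve(i, j, ids, n_missing, enzyme_rank, matrix)
                winner = j if loser == i else i
                alive.discard(loser)
                dropped.append((ids[loser], ids[winner], rule))
    return PruneResult(sorted(alive), dropped, pairs)


def _resolve(i, j, ids, n_missing, enzyme_rank, matrix):
    """Which of a linked pair to drop, and by which rule."""
    if n_missing[i] != n_missing[j]:
        loser = i if n_missing[i] > n_missing[j] else j
        return loser, "more_missing_data"
    ri = enzyme_rank.get(ids[i], 0.0)
    rj = enzyme_rank.get(ids[j], 0.0)
    if not math.isclose(ri, rj):
        return (i if ri < rj else j), "enzyme_accessibility"
    pi = (matrix.sites[i].contig, matrix.sites[i].pos)
    pj = (matrix.sites[j].contig, matrix.sites[j].pos)
    return (i if pi > pj else j), "larger_coordinate"
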