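"""LD-threshold haplotype block construction.

Pairwise r² is computed on phased haplotypes within a marker scan
window.  Candidate blocks are contiguous marker intervals whose
bounding pair reaches the LD threshold and in which a quorum
(``min_pair_fraction``) of within-window pairs also reaches it; a
non-overlapping subset maximizing the number of covered markers is then
chosen by weighted-interval dynamic programming.  Markers covered by no
block are labelled non-clustered SNPs (NCSNP).  Blocks contain at least
two loci and never span chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .simdata import MISSING, MarkerMap, PhasedGenotypes


class LdPair(NamedTuple):
    i: int  # marker index on the chromosome (map order)
    j: int
    r2: float


@dataclass
class HaploBlock:
    block_id: str
    chrom: int
    first: int  # marker index within the chromosome
    last: int
    marker_ids: list[str]
    span_bp: int
    ld_threshold: float

    @property
    def n_snps(self) -> int:
        return len(self.marker_ids)


@dataclass
class BlockingConfig:
    ld_threshold: float = 0.50
    scan_window_markers: int = 50
    min_pair_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.ld_threshold <= 1:
            raise ValueError("ld_threshold must be in (0, 1]")
        if self.scan_window_markers < 2:
            raise ValueError("scan window must cover at least 2 markers")


def haplotype_r2(hap_i: np.ndarray, hap_j: np.ndarray) -> float:
    """r² between two loci from phased haplotype allele vectors.

    r² = (pAB - pA pB)² / (pA(1-pA) pB(1-pB)); missing haplotypes
    (coded -1) are excluded pairwise; a monomorphic locus yields 0.
    """
    ok = (hap_i != MISSING) & (hap_j != MISSING)
    a = hap_i[ok].astype(float)
    b = hap_j[ok].astype(float)
    if a.size == 0:
        return 0.0
    pa, pb = a.mean(), b.mean()
    va, vb = pa * (1 - pa), pb * (1 - pb)
    if va <= 0 or vb <= 0:
        return 0.0
    pab = (a * b).mean()
    return float((pab - pa * pb) ** 2 / (va * vb))


def pairwise_r2(phased: PhasedGenotypes, chromosome: int,
                scan_window_markers: int = 50) -> list[LdPair]:
    """All within-window marker pairs and their r² on one chromosome."""
    if scan_window_markers < 2:
        raise ValueError("scan window must cover at least 2 markers")
    sel = np.where(phased.markers.chroms == chromosome)[0]
    H = np.vstack([phased.hapA[:, sel], phased.hapB[:, sel]]).astype(float)
    H[H == MISSING] = np.nan
    mc = len(sel)
    pairs: list[LdPair] = []
    for d in range(1, min(scan_window_markers, mc)):
        A = H[:, : mc - d]
        B = H[:, d:]
        ok = ~np.isnan(A) & ~np.isnan(B)
        n = ok.sum(axis=0).astype(float)
        n = np.where(n == 0, np.nan, n)
        Az = np.where(ok, A, 0.0)
        Bz = np.where(ok, B, 0.0)
        pa = Az.sum(axis=0) / n
        pb = Bz.sum(axis=0) / n
        pab = (Az * Bz).sum(axis=0) / n
        va = pa * (1 - pa)
        vb = pb * (1 - pb)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = (pab - pa * pb) ** 2 / (va * vb)
        r2 = np.where(np.isfinite(r2), r2, 0.0)
        for i in range(mc - d):
            pairs.append(LdPair(i, i + d, float(r2[i])))
    return pairs


def _candidate_intervals(q: dict, mc: int, window: int,
                         min_pair_fraction: float) -> list[tuple[int, int]]:
    """Intervals [i, j] whose bounding pair qualifies and whose
    within-window qualifying-pair quorum is met."""
    cands = []
    for i in range(mc):
        n_pairs = 0
        n_hit = 0
        for j in range(i + 1, min(i + window, mc)):
            # add pairs (a, j) for a in [i, j-1] within window
            for a in range(max(i, j - window + 1), j):
                n_pairs += 1
                n_hit += q.get((a, j), 0)
            if q.get((i, j), 0) and n_pairs > 0 and n_hit / n_pairs >= min_pair_fraction:
                cands.append((i, j))
    return cands


def _select_intervals(cands: list[tuple[int, int]], mc: int) -> list[tuple[int, int]]:
    """Max-coverage non-overlapping subset by DP over marker positions.

    Ties are broken toward the selection that is lexicographically
    smallest by (start, span): earliest-starting, then shortest,
    intervals are preferred.
    """
    by_start: dict[int, list[tuple[int, int]]] = {}
    for (i, j) in cands:
        by_start.setdefault(i, []).append((i, j))
    for v in by_start.values():
        v.sort(key=lambda ij: ij[1] - ij[0])  # shortest span first
    # best[k] = max markers coverable in suffix starting at k
    best = np.zeros(mc + 1, dtype=int)
    for k in range(mc - 1, -1, -1):
        b = best[k + 1]
        for (i, j) in by_start.get(k, []):
            b = max(b, (j - i + 1) + best[j + 1])
        best[k] = b
    # greedy left-to-right reconstruction honouring the tie-break
    chosen = []
    k = 0
    while k < mc:
        picked = None
        for (i, j) in by_start.get(k, []):
            if (j - i + 1) + best[j + 1] == best[k]:
                picked = (i, j)
                break  # shortest qualifying span at this start
        if picked is None:
            k += 1
        else:
            chosen.append(picked)
            k = picked[1] + 1
    return chosen


def build_blocks(pairs: list[LdPair], marker_map_chrom: pd.DataFrame,
                 config: BlockingConfig, chrom: int,
                 block_start_index: int = 1,
                 ) -> tuple[list[HaploBlock], list[str]]:
    """Partition one chromosome into haploblocks and NCSNPs.

    ``marker_map_chrom`` holds the chromosome's markers in map order;
    pair indices refer to positions in that frame.
    """
    mc = len(marker_map_chrom)
    q = {(p.i, p.j): 1 for p in pairs if p.r2 >= config.ld_threshold}
    cands = _candidate_intervals(q, mc, config.scan_window_markers,
                                 config.min_pair_fraction)
    chosen = _select_intervals(cands, mc)
    pos = marker_map_chrom["pos"].to_numpy()
    ids = list(marker_map_chrom["marker_id"])
    blocks = []
    covered = np.zeros(mc, dtype=bool)
    for k, (i, j) in enumerate(chosen):
        covered[i:j + 1] = True
        blocks.append(HaploBlock(
            block_id=f"block_{block_start_index + k}_chr_{chrom}",
            chrom=chrom, first=i, last=j,
            marker_ids=ids[i:j + 1],
            span_bp=int(pos[j] - pos[i]),
            ld_threshold=config.ld_threshold,
        ))
    ncsnp = [ids[k] for k in range(mc) if not covered[k]]
    return blocks, ncsnp


def build_blocks_genome(phased: PhasedGenotypes, config: BlockingConfig,
                        ) -> tuple[list[HaploBlock], list[str]]:
    """Run r² scan + blocking on every chromosome of a phased set."""
    blocks: list[HaploBlock] = []
    ncsnp: list[str] = []
    mm = phased.markers.frame
    for c in pd.unique(mm["chrom"]):
        sub = mm[mm["chrom"] == c].reset_index(drop=True)
        pairs = pairwise_r2(phased, c, config.scan_window_markers)
        b, n = build_blocks(pairs, sub, config, int(c),
                            block_start_index=1)
        blocks.extend(b)
        ncsnp.extend(n)
    return blocks, ncsnp


def block_stats(blocks: list[HaploBlock], ncsnp: list[str],
                marker_map: MarkerMap) -> dict:
    """Descriptive statistics of a blocking run (counts, sizes, spans)."""
    n_clustered = sum(b.n_snps for b in blocks)
    sizes = [b.n_snps for b in blocks]
    spans = [b.span_bp for b in blocks]
    return {
        "n_non_clustered": len(ncsnp),
        "n_clustered": n_clustered,
        "n_blocks": len(blocks),
        "min_snps_per_block": int(min(sizes)) if sizes else 0,
        "max_snps_per_block": int(max(sizes)) if sizes else 0,
        "min_span_bp": int(min(spans)) if spans else None,
        "max_span_bp": int(max(spans)) if spans else None,
        "mean_span_bp": float(np.mean(spans)) if spans else None,
        "sd_span_bp": float(np.std(spans, ddof=1)) if len(spans) > 1 else None,
    }


def write_blocks_bed(path, blocks: list[HaploBlock], marker_map: MarkerMap) -> None:
    mm = marker_map.frame.set_index("marker_id")
    with open(path, "w") as fh:
        for b in blocks:
            start = int(mm.loc[b.marker_ids[0], "pos"])
            end = int(mm.loc[b.marker_ids[-1], "pos"])
            fh.write(f"{b.chrom}\t{start}\t{end}\t{b.block_id}\t{b.n_snps}\t{b.ld_threshold}\n")
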