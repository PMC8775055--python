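"""Pedigree and genomic relationship matrices and the single-step H⁻¹.

The pedigree numerator relationship matrix A is built by the tabular
(recursive) method, the genomic matrix G by VanRaden's first method
from centred marker dosages, and the single-step inverse combines them
as

    H⁻¹ = A⁻¹ + [0 0; 0  τ(αG + βA22)⁻¹ − ωA22⁻¹]

on the genotyped block, with default τ = ω = 1 and blending weights
α = 0.90, β = 0.10.  Dense linear algebra throughout: the intended
scale is a few thousand pedigree animals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pseudosnp import MarkerMatrix
from .simdata import Pedigree


@dataclass
class HInverseConfig:
    tau: float = 1.0
    omega: float = 1.0
    alpha: float = 0.90
    beta: float = 0.10


@dataclass
class RelationshipSet:
    """All matrices of one single-step evaluation, in pedigree order."""

    A: np.ndarray
    A22: np.ndarray
    G: np.ndarray
    G_blend: np.ndarray
    Hinv: np.ndarray
    geno_index: np.ndarray  # rows of A that are genotyped, in G row order
    config: HInverseConfig


def prune_pedigree(pedigree: Pedigree, anchor_ids: list[str],
                   max_generations: int = 4) -> Pedigree:
    """Keep anchors plus their ancestors within ``max_generations``.

    Parents falling outside the cut become unknown.  Record order (and
    hence parent-precedes-offspring) is preserved.
    """
    idx = pedigree.index
    depth = {}
    for a in anchor_ids:
        if a in idx:
            depth[idx[a]] = 0
    frontier = list(depth)
    while frontier:
        nxt = []
        for i in frontier:
            d = depth[i]
            if d >= max_generations:
                continue
            for p in (pedigree.sire[i], pedigree.dam[i]):
                if p >= 0 and depth.get(p, np.inf) > d + 1:
                    depth[p] = d + 1
                    nxt.append(p)
        frontier = nxt
    keep = sorted(depth)
    old_to_new = {o: n for n, o in enumerate(keep)}
    sire = []
    dam = []
    for o in keep:
        s, d = pedigree.sire[o], pedigree.dam[o]
        in_cut = depth[o] < max_generations
        sire.append(old_to_new.get(s, -1) if (s >= 0 and in_cut and s in old_to_new) else -1)
        dam.append(old_to_new.get(d, -1) if (d >= 0 and in_cut and d in old_to_new) else -1)
    return Pedigree([pedigree.ids[o] for o in keep], np.array(sire), np.array(dam))


def build_A(pedigree: Pedigree) -> np.ndarray:
    """Numerator relationship matrix by the tabular method.

    a(i,i) = 1 + 0.5 a(s,d); a(i,j) = 0.5 (a(j,s) + a(j,d)) for j < i;
    unknown parents contribute zero.  Inbreeding is handled implicitly.
    """
    n = len(pedigree)
    A = np.zeros((n, n))
    s_arr, d_arr = pedigree.sire, pedigree.dam
    for i in range(n):
        s, d = s_arr[i], d_arr[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


def build_G(marker_matrix: MarkerMatrix, weights: np.ndarray | None = None,
            ) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G = (M - 2p) D (M - 2p)' / (2 Σ p(1-p)) with D the diagonal marker
    weights (identity for the unweighted analysis).  Missing dosages
    are mean-imputed to 2p beforehand.
    """
    M = marker_matrix.dosages
    p = marker_matrix.p
    d = marker_matrix.weights if weights is None else np.asarray(weights, float)
    Z = M - 2.0 * p
    Z = np.where(np.isnan(Z), 0.0, Z)  # mean imputation after centring
    k = marker_matrix.k
    if k <= 0:
        raise ValueError("non-positive VanRaden denominator: all markers monomorphic?")
    return (Z * d) @ Z.T / k


def blend_G(G: np.ndarray, A22: np.ndarray, config: HInverseConfig) -> np.ndarray:
    return config.alpha * G + config.beta * A22


def build_Hinv(A: np.ndarray, geno_index: np.ndarray, G: np.ndarray,
               config: HInverseConfig | None = None) -> np.ndarray:
    """Single-step H⁻¹ for the full pedigree with a genotyped block.

    Adds τ(αG + βA22)⁻¹ − ωA22⁻¹ on the genotyped rows/columns of A⁻¹.
    Raises if the blended matrix is numerically singular, reporting its
    smallest eigenvalue.
    """
    config = config or HInverseConfig()
    geno_index = np.asarray(geno_index, dtype=int)
    Ainv = np.linalg.inv(A)
    Hinv = Ainv.copy()
    if geno_index.size == 0:
        return Hinv
    A22 = A[np.ix_(geno_index, geno_index)]
    Gb = blend_G(G, A22, config)
    w = np.linalg.eigvalsh(Gb)
    if w[0] < 1e-10:
        raise np.linalg.LinAlgError(
            f"blended genomic matrix is singular (smallest eigenvalue {w[0]:.3e})")
    corr = config.tau * np.linalg.inv(Gb) - config.omega * np.linalg.inv(A22)
    Hinv[np.ix_(geno_index, geno_index)] += corr
    return 0.5 * (Hinv + Hinv.T)


def build_relationships(pedigree: Pedigree, marker_matrix: MarkerMatrix,
                        genotyped_ids: list[str],
                        config: HInverseConfig | None = None) -> RelationshipSet:
    """A, A22, G, blended G and H⁻¹ for one evaluation."""
    config = config or HInverseConfig()
    A = build_A(pedigree)
    idx = pedigree.index
    # G row order must follow the marker matrix's individual order
    geno_index = np.array([idx[a] for a in marker_matrix.ids], dtype=int)
    G = build_G(marker_matrix)
    A22 = A[np.ix_(geno_index, geno_index)]
    Gb = blend_G(G, A22, config)
    Hinv = build_Hinv(A, geno_index, G, config)
    return RelationshipSet(A=A, A22=A22, G=G, G_blend=Gb, Hinv=Hinv,
                           geno_index=geno_index, config=config)
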