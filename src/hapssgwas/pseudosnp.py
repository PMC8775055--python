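"""Pseudo-SNP encoding of haploblock alleles and marker-matrix assembly.

Every distinct phased haplotype allele observed within a block becomes
a pseudo-SNP, coded 0/1/2 as the number of copies an individual
carries.  Scenario matrices stack pseudo-SNP columns (always) and
non-clustered SNP columns (optionally), run the standard marker QC on
all columns, and carry the per-column allele frequency p, weight d and
the VanRaden scale constant k = 2 * sum p_i (1 - p_i).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haploblock import HaploBlock
from .qc import QcThresholds, apply_marker_qc
from .simdata import MISSING, MarkerMap, PhasedGenotypes


@dataclass
class PseudoSnp:
    pseudo_id: str
    block_id: str
    allele_string: str
    frequency: float
    chrom: int
    position_bp: int  # representative: position of the block's first SNP


@dataclass
class MarkerMatrix:
    """Dosage matrix over pseudo-SNP and/or NCSNP columns.

    ``dosages`` is individuals x columns with entries {0,1,2} and NaN
    for missing.  ``meta`` has one row per column: col_id, source
    ("pseudo" or "ncsnp"), block_id (NCSNPs: ""), chrom, pos, p, weight.
    """

    ids: list[str]
    dosages: np.ndarray
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosages.shape != (len(self.ids), len(self.meta)):
            raise ValueError("dosage matrix shape must match ids x meta")

    @property
    def p(self) -> np.ndarray:
        return self.meta["p"].to_numpy()

    @property
    def weights(self) -> np.ndarray:
        return self.meta["weight"].to_numpy()

    @property
    def k(self) -> float:
        """VanRaden denominator 2 * sum p(1-p)."""
        p = self.p
        return float(2.0 * np.sum(p * (1.0 - p)))

    def with_weights(self, d: np.ndarray) -> "MarkerMatrix":
        meta = self.meta.copy()
        meta["weight"] = np.asarray(d, dtype=float)
        return MarkerMatrix(self.ids, self.dosages, meta)


def write_matrix(prefix, matrix: "MarkerMatrix") -> None:
    """Persist a marker matrix as a plain dosage table + column-meta TSV."""
    pd.DataFrame(matrix.dosages, index=matrix.ids,
                 columns=matrix.meta["col_id"]).to_csv(
        f"{prefix}.dosages.tsv", sep="\t")
    matrix.meta.to_csv(f"{prefix}.meta.tsv", sep="\t", index=False)


def block_haplotype_strings(phased: PhasedGenotypes, block: HaploBlock,
                            ) -> tuple[list[str | None], list[str | None]]:
    """Per-individual allele strings for a block's two haplotypes.

    Any missing SNP call inside the block makes the whole allele string
    undefined (None) for that individual.
    """
    mm = phased.markers.frame
    idx = mm.index[mm["marker_id"].isin(block.marker_ids)].to_numpy()
    order = np.argsort(mm.loc[idx, "pos"].to_numpy())
    idx = idx[order]
    a = phased.hapA[:, idx]
    b = phased.hapB[:, idx]
    out_a, out_b = [], []
    for i in range(len(phased.ids)):
        if np.any(a[i] == MISSING):
            out_a.append(None)
            out_b.append(None)
        else:
            out_a.append("".join(map(str, a[i])))
            out_b.append("".join(map(str, b[i])))
    return out_a, out_b


def enumerate_alleles(phased: PhasedGenotypes, block: HaploBlock) -> list[PseudoSnp]:
    """One PseudoSnp per distinct allele string among non-missing haplotypes.

    Frequencies are shares of non-missing haplotypes, so they sum to 1
    within the block.  Alleles are ordered by decreasing frequency, then
    lexicographically, for a stable id assignment.
    """
    sa, sb = block_haplotype_strings(phased, block)
    counts: dict[str, int] = {}
    total = 0
    for s in sa + sb:
        if s is not None:
            counts[s] = counts.get(s, 0) + 1
            total += 1
    if total == 0:
        return []
    mm = phased.markers.frame.set_index("marker_id")
    pos = int(mm.loc[block.marker_ids[0], "pos"])
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        PseudoSnp(
            pseudo_id=f"{block.block_id}_a{k}",
            block_id=block.block_id,
            allele_string=s,
            frequency=c / total,
            chrom=block.chrom,
            position_bp=pos,
        )
        for k, (s, c) in enumerate(ordered)
    ]


def encode_dosages(phased: PhasedGenotypes, pseudo_snps: list[PseudoSnp],
                   block: HaploBlock) -> np.ndarray:
    """0/1/2 copy-number dosage of each pseudo-SNP allele per individual."""
    sa, sb = block_haplotype_strings(phased, block)
    n = len(phased.ids)
    out = np.full((n, len(pseudo_snps)), np.nan)
    for j, ps in enumerate(pseudo_snps):
        for i in range(n):
            if sa[i] is not None:
                out[i, j] = (sa[i] == ps.allele_string) + (sb[i] == ps.allele_string)
    return out


def assemble_matrix(phased: PhasedGenotypes, blocks: list[HaploBlock],
                    ncsnp_ids: list[str], include_ncsnp: bool,
                    qc: QcThresholds | None = None) -> MarkerMatrix:
    """Build the scenario marker matrix (haplotypes only, or + NCSNP).

    Pseudo-SNP columns for every block are always included; NCSNP
    dosage columns are appended when ``include_ncsnp``.  Marker QC from
    the standard pipeline runs on all columns; per-column p and the
    scale constant k are computed on the survivors.  Columns are ordered
    by chromosome, then position, pseudo-SNPs before NCSNPs at equal
    position.
    """
    qc = qc or QcThresholds()
    cols = []
    meta_rows = []
    for b in blocks:
        ps = enumerate_alleles(phased, b)
        if not ps:
            continue
        dos = encode_dosages(phased, ps, b)
        for j, p in enumerate(ps):
            cols.append(dos[:, j])
            meta_rows.append((p.pseudo_id, "pseudo", p.block_id, p.chrom, p.position_bp))
    if include_ncsnp:
        mm = phased.markers.frame
        lookup = {mid: k for k, mid in enumerate(mm["marker_id"])}
        full = phased.dosages()
        for mid in ncsnp_ids:
            k = lookup[mid]
            cols.append(full[:, k])
            meta_rows.append((mid, "ncsnp", "", int(mm["chrom"].iat[k]), int(mm["pos"].iat[k])))
    if not cols:
        raise ValueError("no marker columns to assemble")
    dosages = np.column_stack(cols)
    meta = pd.DataFrame(meta_rows, columns=["col_id", "source", "block_id", "chrom", "pos"])
    # sort: chromosome, position, pseudo before ncsnp at equal position
    src_rank = (meta["source"] == "ncsnp").astype(int)
    order = np.lexsort((src_rank.to_numpy(), meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
    dosages = dosages[:, order]
    meta = meta.iloc[order].reset_index(drop=True)

    # pseudo-SNP columns are not physical loci: the PAR rule was already
    # applied to the underlying SNPs, so only the statistical rules act here
    qc_eff = QcThresholds(**{**qc.__dict__, "apply_par_rule": False})
    filtered, keep, report = apply_marker_qc(dosages, None, qc_eff,
                                             marker_ids=list(meta["col_id"]))
    if filtered.shape[1] == 0:
        raise ValueError("no marker columns survive QC")
    meta = meta.iloc[keep].reset_index(drop=True)
    obs = ~np.isnan(filtered)
    p = np.nansum(filtered, axis=0) / (2.0 * obs.sum(axis=0))
    meta["p"] = p
    meta["weight"] = 1.0
    out = MarkerMatrix(list(phased.ids), filtered, meta)
    out.qc_report = report
    return out
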