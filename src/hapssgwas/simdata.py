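"""Synthetic pedigrees, phased genotypes and ordered-categorical phenotypes.

The generator emulates the design of a beef-cattle temperament study:
a multi-generation pedigree in which only part of the population is
genotyped, SNP haplotypes with linkage disequilibrium that decays with
physical distance (so haplotype blocks are detectable at r² thresholds
from 0.15 to 0.80), and a polygenic liability trait observed as four
ordered categories with very unbalanced frequencies.

LD is produced by a distance-decaying first-order copying model rather
than a coalescent: each haplotype carries a latent uniform "ancestral
state" along the chromosome which is retained between adjacent markers
with probability exp(-ld_decay_rate * distance_bp) and refreshed
otherwise.  Markers sharing the state are comonotone, so a pair of
adjacent markers with equal allele frequency has population
r² = exp(-2 * ld_decay_rate * d).  Allele frequencies are constant
within short "frequency runs" so that runs of markers in near-complete
LD (block cores) arise naturally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

MISSING = -1


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Pedigree:
    """Ordered pedigree: parents always precede offspring.

    ``sire``/``dam`` hold positional indices into ``ids`` or -1 for an
    unknown parent.  ``birth_order`` is the record position.
    """

    ids: list[str]
    sire: np.ndarray
    dam: np.ndarray
    sex: np.ndarray | None = None  # 0 = male, 1 = female, optional

    def __post_init__(self) -> None:
        self.sire = np.asarray(self.sire, dtype=np.int64)
        self.dam = np.asarray(self.dam, dtype=np.int64)
        n = len(self.ids)
        if self.sire.shape != (n,) or self.dam.shape != (n,):
            raise ValueError("sire/dam index arrays must match ids length")
        for i in range(n):
            if self.sire[i] >= i or self.dam[i] >= i:
                raise ValueError(
                    f"pedigree order violation at record {i}: parents must precede offspring"
                )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def index(self) -> dict[str, int]:
        return {a: i for i, a in enumerate(self.ids)}

    def to_frame(self) -> pd.DataFrame:
        unk = "0"
        return pd.DataFrame(
            {
                "animal_id": self.ids,
                "sire_id": [self.ids[s] if s >= 0 else unk for s in self.sire],
                "dam_id": [self.ids[d] if d >= 0 else unk for d in self.dam],
                "birth_order": np.arange(len(self.ids)),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        ids = list(frame["animal_id"].astype(str))
        idx = {a: i for i, a in enumerate(ids)}
        def look(col):
            return np.array(
                [idx.get(str(v), -1) if str(v) not in ("0", "nan", "") else -1
                 for v in frame[col]],
                dtype=np.int64,
            )
        return cls(ids=ids, sire=look("sire_id"), dam=look("dam_id"))


@dataclass
class MarkerMap:
    """Marker id / chromosome / bp-position table.

    Positions are strictly increasing within a chromosome.  Chromosome
    30 labels the X pseudo-autosomal region by convention.
    """

    frame: pd.DataFrame  # columns marker_id, chrom, pos

    def __post_init__(self) -> None:
        req = {"marker_id", "chrom", "pos"}
        if not req <= set(self.frame.columns):
            raise ValueError(f"marker map needs columns {req}")
        for c, sub in self.frame.groupby("chrom"):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise ValueError(f"positions not strictly increasing on chromosome {c}")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> np.ndarray:
        return self.frame["chrom"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.frame["pos"].to_numpy()

    @property
    def marker_ids(self) -> list[str]:
        return list(self.frame["marker_id"])


@dataclass
class PhasedGenotypes:
    """Pair of haplotype allele matrices (individuals x markers).

    Alleles are coded 0/1; ``MISSING`` (-1) marks a missing genotype
    call, which always affects both haplotypes of an individual at a
    marker simultaneously.
    """

    ids: list[str]
    markers: MarkerMap
    hapA: np.ndarray  # int8, n x m
    hapB: np.ndarray

    def __post_init__(self) -> None:
        n, m = len(self.ids), len(self.markers)
        if self.hapA.shape != (n, m) or self.hapB.shape != (n, m):
            raise ValueError("haplotype matrices must be n_individuals x n_markers")
        if not np.array_equal(self.hapA == MISSING, self.hapB == MISSING):
            raise ValueError("missingness must hit both haplotypes of a call")

    def dosages(self) -> np.ndarray:
        """0/1/2 dosage matrix with NaN for missing calls."""
        d = (self.hapA + self.hapB).astype(float)
        d[self.hapA == MISSING] = np.nan
        return d

    def subset_individuals(self, keep_ids: list[str]) -> "PhasedGenotypes":
        pos = {a: i for i, a in enumerate(self.ids)}
        rows = [pos[a] for a in keep_ids]
        return PhasedGenotypes(list(keep_ids), self.markers,
                               self.hapA[rows].copy(), self.hapB[rows].copy())

    def subset_markers(self, cols: np.ndarray) -> "PhasedGenotypes":
        sub = self.markers.frame.iloc[cols].reset_index(drop=True)
        return PhasedGenotypes(self.ids, MarkerMap(sub),
                               self.hapA[:, cols].copy(), self.hapB[:, cols].copy())


@dataclass
class TraitSimSpec:
    """Generative settings for the ordered-categorical liability trait.

    The liability is covariates + contemporary-group effect + breeding
    value + residual; h2 = sigma_g^2 / (sigma_g^2 + sigma_w^2 + sigma_e^2)
    with the non-covariate variance normalised to 1.
    """

    n_qtl: int = 300
    qtl_effect_sd: float = 1.0
    h2: float = 0.38
    category_probs: tuple = (0.719, 0.222, 0.051, 0.008)
    cg_count: int = 25
    cg_var_fraction: float = 0.10
    age_of_dam_classes: int = 4
    conception_types: int = 2
    covariate_effect_sd: float = 0.10
    age_dev_sd_days: float = 30.0
    age_dev_slope: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.category_probs, dtype=float)
        if np.any(p <= 0):
            raise ValueError("category_probs must be strictly positive (threshold degeneracy)")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("category_probs must sum to 1")
        if not 0 <= self.h2 < 1:
            raise ValueError("h2 must be in [0, 1)")
        if self.h2 + self.cg_var_fraction >= 1:
            raise ValueError("h2 + cg_var_fraction must leave residual variance > 0")


# ---------------------------------------------------------------------------
# Pedigree simulation
# ---------------------------------------------------------------------------

def simulate_pedigree(n_founders: int, n_generations: int,
                      offspring_per_mating: int = 2, seed: int = 0) -> Pedigree:
    """Simulate a discrete-generation pedigree.

    Founders get alternating sexes (so at least one male and one female
    when ``n_founders >= 2``).  Each generation, males and females of the
    previous generation are paired at random; every pair produces
    ``offspring_per_mating`` offspring with random sexes.
    """
    if n_founders < 2 and n_generations > 0:
        raise ValueError("infeasible mating: need at least one male and one female founder")
    rng = np.random.default_rng(seed)
    ids = [f"G0_{i}" for i in range(n_founders)]
    sire = [-1] * n_founders
    dam = [-1] * n_founders
    sex = [i % 2 for i in range(n_founders)]  # alternating M/F
    prev = list(range(n_founders))
    for g in range(1, n_generations + 1):
        males = [i for i in prev if sex[i] == 0]
        females = [i for i in prev if sex[i] == 1]
        if not males or not females:
            raise ValueError("infeasible mating: a generation lacks one sex")
        rng.shuffle(males)
        rng.shuffle(females)
        n_matings = min(len(males), len(females))
        cohort = []
        for k in range(n_matings):
            s, d = males[k], females[k]
            for _ in range(offspring_per_mating):
                ids.append(f"G{g}_{len(cohort)}")
                sire.append(s)
                dam.append(d)
                sex.append(int(rng.integers(0, 2)))
                cohort.append(len(ids) - 1)
        prev = cohort
    return Pedigree(ids, np.array(sire), np.array(dam), np.array(sex))


# ---------------------------------------------------------------------------
# Founder haplotypes
# ---------------------------------------------------------------------------

def decay_rate_for_adjacent_r2(target_r2: float, spacing_bp: float) -> float:
    """Decay rate giving population r² = target for equal-frequency adjacent pairs.

    Under the copying model r²(d) = exp(-2 * rate * d) when the two
    markers share an allele frequency.
    """
    if not 0 < target_r2 <= 1:
        raise ValueError("target_r2 must be in (0, 1]")
    return -np.log(target_r2) / (2.0 * spacing_bp)


def simulate_founder_haplotypes(n_markers_per_chr: int, n_chr: int,
                                ld_decay_rate: float, maf_floor: float,
                                seed: int = 0, *, n_individuals: int = 100,
                                spacing_bp: int = 50_000,
                                freq_run_len: float = 5.0,
                                chrom_labels: list[int] | None = None,
                                ) -> tuple[MarkerMap, PhasedGenotypes]:
    """Generate founder haplotypes with distance-decaying LD.

    Parameters
    ----------
    ld_decay_rate : per-bp rate of the exponential state-retention decay;
        0 gives complete LD along each chromosome, ``np.inf`` independence.
    maf_floor : allele frequencies are drawn uniformly on
        [maf_floor, 1 - maf_floor], so expected MAF >= maf_floor.
    freq_run_len : mean length (markers, geometric) of runs sharing one
        allele frequency; runs in shared ancestral state are in complete LD.
    """
    if n_markers_per_chr < 2:
        raise ValueError("need at least 2 markers per chromosome to form blocks")
    if not 0 <= maf_floor < 0.5:
        raise ValueError("maf_floor must be in [0, 0.5)")
    if ld_decay_rate < 0:
        raise ValueError("ld_decay_rate must be >= 0")
    rng = np.random.default_rng(seed)
    if chrom_labels is None:
        chrom_labels = list(range(1, n_chr + 1))

    rows = []
    freqs = []
    for c in chrom_labels:
        pos = spacing_bp * (1 + np.arange(n_markers_per_chr))
        pos = pos + rng.integers(0, spacing_bp // 4, size=n_markers_per_chr)
        pos = np.sort(pos)
        # enforce strict increase despite jitter ties
        pos = pos + np.arange(n_markers_per_chr)
        for j in range(n_markers_per_chr):
            rows.append((f"snp_{c}_{j}", c, int(pos[j])))
        # frequency runs: geometric lengths with mean freq_run_len
        p_chr = np.empty(n_markers_per_chr)
        j = 0
        while j < n_markers_per_chr:
            run = 1 + rng.geometric(min(1.0, 1.0 / freq_run_len)) - 1 if freq_run_len > 1 else 1
            p = rng.uniform(maf_floor, 1 - maf_floor)
            p_chr[j:j + run] = p
            j += run
        freqs.append(p_chr)

    mmap = MarkerMap(pd.DataFrame(rows, columns=["marker_id", "chrom", "pos"]))
    m = len(mmap)
    n_hap = 2 * n_individuals
    hap = np.empty((n_hap, m), dtype=np.int8)

    col = 0
    for ci, c in enumerate(chrom_labels):
        p_chr = freqs[ci]
        mc = n_markers_per_chr
        pos = mmap.positions[col:col + mc]
        d = np.diff(pos).astype(float)
        keep_prob = np.exp(-ld_decay_rate * d) if np.isfinite(ld_decay_rate) else np.zeros_like(d)
        u = rng.uniform(size=(n_hap, mc))
        keep = rng.uniform(size=(n_hap, mc - 1)) < keep_prob
        for j in range(1, mc):
            u[keep[:, j - 1], j] = u[keep[:, j - 1], j - 1]
        hap[:, col:col + mc] = (u < p_chr).astype(np.int8)
        col += mc

    ids = [f"G0_{i}" for i in range(n_individuals)]
    geno = PhasedGenotypes(ids, mmap, hap[0::2].copy(), hap[1::2].copy())
    return mmap, geno


# ---------------------------------------------------------------------------
# Gene dropping
# ---------------------------------------------------------------------------

def _gamete(hapA: np.ndarray, hapB: np.ndarray, mmap: MarkerMap,
            recomb_rate_per_bp: float, rng: np.random.Generator) -> np.ndarray:
    """Sample one recombined gamete from a parent's two haplotypes."""
    m = len(mmap)
    out = np.empty(m, dtype=np.int8)
    chroms = mmap.chroms
    pos = mmap.positions
    for c in np.unique(chroms):
        sel = np.where(chroms == c)[0]
        p = pos[sel]
        span = float(p[-1] - p[0])
        cur = int(rng.integers(0, 2))
        if recomb_rate_per_bp > 0 and span > 0:
            n_x = rng.poisson(recomb_rate_per_bp * span)
            xpos = np.sort(rng.uniform(p[0], p[-1], size=n_x))
        else:
            xpos = np.empty(0)
        # phase switches at each crossover position
        switches = np.searchsorted(xpos, p, side="right") % 2
        phase = (cur + switches) % 2
        src = np.where(phase == 0, hapA[sel], hapB[sel])
        out[sel] = src
    return out


def gene_drop(pedigree: Pedigree, founder_haplotypes: PhasedGenotypes,
              recomb_rate_per_bp: float = 1e-8, seed: int = 0) -> PhasedGenotypes:
    """Drop founder haplotypes through the pedigree with recombination.

    Crossovers follow a Poisson process along bp positions at
    ``recomb_rate_per_bp`` per meiosis.  Every animal must have either
    both parents known or none (founder); founders must have haplotypes.
    """
    rng = np.random.default_rng(seed)
    mmap = founder_haplotypes.markers
    m = len(mmap)
    n = len(pedigree)
    hapA = np.empty((n, m), dtype=np.int8)
    hapB = np.empty((n, m), dtype=np.int8)
    fpos = {a: i for i, a in enumerate(founder_haplotypes.ids)}
    for i, aid in enumerate(pedigree.ids):
        s, d = pedigree.sire[i], pedigree.dam[i]
        if (s < 0) != (d < 0):
            raise ValueError(f"animal {aid} has exactly one known parent; gene drop needs both or none")
        if s < 0:
            if aid not in fpos:
                raise ValueError(f"founder {aid} has no haplotypes")
            j = fpos[aid]
            hapA[i] = founder_haplotypes.hapA[j]
            hapB[i] = founder_haplotypes.hapB[j]
        else:
            hapA[i] = _gamete(hapA[s], hapB[s], mmap, recomb_rate_per_bp, rng)
            hapB[i] = _gamete(hapA[d], hapB[d], mmap, recomb_rate_per_bp, rng)
    return PhasedGenotypes(list(pedigree.ids), mmap, hapA, hapB)


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------

def _solve_thresholds(offsets: np.ndarray, sigma_e: float,
                      category_probs: np.ndarray) -> np.ndarray:
    """Thresholds giving the target marginal category frequencies.

    Solves mean_i Phi((t - offset_i)/sigma_e) = cumulative prob for each
    interior threshold; exact in expectation over the residual.
    """
    cum = np.cumsum(category_probs)[:-1]
    lo = offsets.min() - 8 * sigma_e - 1
    hi = offsets.max() + 8 * sigma_e + 1
    ts = []
    for q in cum:
        f = lambda t: np.mean(ndtr((t - offsets) / sigma_e)) - q
        ts.append(brentq(f, lo, hi, xtol=1e-10))
    return np.asarray(ts)


def simulate_phenotypes(genotypes: PhasedGenotypes, pedigree: Pedigree,
                        spec: TraitSimSpec,
                        true_bv: np.ndarray | None = None) -> pd.DataFrame:
    """Simulate the ordered-categorical trait for every pedigree animal.

    Returns a phenotype table with the observed score (1..C), covariates
    and contemporary group, plus ``true_``-prefixed columns carrying the
    latent breeding value and liability for validation.  ``true_bv``
    overrides the internal random-QTL architecture with a caller-built
    genetic value (rescaled to the h²-implied variance).
    """
    rng = np.random.default_rng(spec.seed)
    n = len(pedigree)
    order = {a: i for i, a in enumerate(genotypes.ids)}
    rows = np.array([order[a] for a in pedigree.ids])
    dos = genotypes.hapA[rows].astype(float) + genotypes.hapB[rows].astype(float)

    sigma_g2 = spec.h2
    sigma_w2 = spec.cg_var_fraction
    sigma_e2 = 1.0 - sigma_g2 - sigma_w2

    m = dos.shape[1]
    tbv = np.zeros(n)
    if true_bv is not None:
        raw = np.asarray(true_bv, dtype=float) - np.mean(true_bv)
        sd = raw.std()
        if sigma_g2 > 0 and sd > 0:
            tbv = raw * (np.sqrt(sigma_g2) / sd)
    elif sigma_g2 > 0 and spec.n_qtl > 0:
        qtl_idx = rng.choice(m, size=min(spec.n_qtl, m), replace=False)
        qtl_eff = rng.normal(0, spec.qtl_effect_sd, size=len(qtl_idx))
        raw = dos[:, qtl_idx] @ qtl_eff
        raw = raw - raw.mean()
        sd = raw.std()
        if sd > 0:
            tbv = raw * (np.sqrt(sigma_g2) / sd)

    cg = rng.integers(0, spec.cg_count, size=n)
    cg_eff = rng.normal(0, np.sqrt(sigma_w2), size=spec.cg_count) if sigma_w2 > 0 else np.zeros(spec.cg_count)

    aod = rng.integers(0, spec.age_of_dam_classes, size=n)
    aod_eff = rng.normal(0, spec.covariate_effect_sd, size=spec.age_of_dam_classes)
    ct = rng.integers(0, spec.conception_types, size=n)
    ct_eff = rng.normal(0, spec.covariate_effect_sd, size=spec.conception_types)
    age_dev = rng.normal(0, spec.age_dev_sd_days, size=n)
    cov = aod_eff[aod] + ct_eff[ct] + spec.age_dev_slope * age_dev

    offsets = cov + cg_eff[cg] + tbv
    sigma_e = np.sqrt(sigma_e2)
    resid = rng.normal(0, sigma_e, size=n)
    liab = offsets + resid

    thr = _solve_thresholds(offsets, sigma_e, np.asarray(spec.category_probs))
    score = 1 + np.searchsorted(thr, liab, side="left")

    return pd.DataFrame(
        {
            "animal_id": pedigree.ids,
            "score": score.astype(int),
            "cg": [f"cg{g}" for g in cg],
            "age_of_dam": [f"aod{a}" for a in aod],
            "conception_type": [f"ct{t}" for t in ct],
            "age_dev": age_dev,
            "true_bv": tbv,
            "true_liability": liab,
        }
    )


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_data(genotypes: PhasedGenotypes, genotyped_fraction: float = 1.0,
              call_rate: float = 1.0, seed: int = 0) -> tuple[PhasedGenotypes, list[str]]:
    """Flag a random subset of animals as genotyped and thin their calls.

    Each call of a genotyped animal is set missing independently with
    probability ``1 - call_rate`` (both haplotypes at once).  Returns the
    full phased object (ungenotyped animals keep their true haplotypes —
    downstream code must honour the genotyped-id list) and that list.
    """
    rng = np.random.default_rng(seed)
    n, m = genotypes.hapA.shape
    n_geno = int(round(genotyped_fraction * n))
    geno_rows = np.sort(rng.choice(n, size=n_geno, replace=False))
    hapA = genotypes.hapA.copy()
    hapB = genotypes.hapB.copy()
    if call_rate < 1.0:
        miss = rng.uniform(size=(n_geno, m)) > call_rate
        sub = hapA[geno_rows]
        sub[miss] = MISSING
        hapA[geno_rows] = sub
        sub = hapB[geno_rows]
        sub[miss] = MISSING
        hapB[geno_rows] = sub
    out = PhasedGenotypes(list(genotypes.ids), genotypes.markers, hapA, hapB)
    return out, [genotypes.ids[i] for i in geno_rows]


# ---------------------------------------------------------------------------
# File output (VCF / CSV / YAML scenario)
# ---------------------------------------------------------------------------

def write_vcf(path, genotypes: PhasedGenotypes, genotyped_ids: list[str] | None = None) -> None:
    """Write phased genotypes as a minimal VCF with phased GT (0|1) calls."""
    ids = genotyped_ids if genotyped_ids is not None else genotypes.ids
    sub = genotypes.subset_individuals(ids)
    mm = sub.markers.frame
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(ids) + "\n")
        for j in range(len(mm)):
            a = sub.hapA[:, j]
            b = sub.hapB[:, j]
            calls = [
                "./." if a[i] == MISSING else f"{a[i]}|{b[i]}"
                for i in range(len(ids))
            ]
            fh.write(
                f"{mm['chrom'].iat[j]}\t{mm['pos'].iat[j]}\t{mm['marker_id'].iat[j]}"
                "\tA\tC\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def write_marker_map(path, mmap: MarkerMap) -> None:
    mmap.frame.to_csv(path, sep="\t", index=False)


def read_vcf(path) -> PhasedGenotypes:
    """Read a phased VCF written by :func:`write_vcf` (GT-only, biallelic)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                ids = line.rstrip("\n").split("\t")[9:]
                continue
            rows.append(line.rstrip("\n").split("\t"))
    mm = MarkerMap(pd.DataFrame(
        {"marker_id": [r[2] for r in rows],
         "chrom": [int(r[0]) for r in rows],
         "pos": [int(r[1]) for r in rows]}))
    n, m = len(ids), len(rows)
    hapA = np.empty((n, m), dtype=np.int8)
    hapB = np.empty((n, m), dtype=np.int8)
    for j, r in enumerate(rows):
        for i, call in enumerate(r[9:]):
            if call.startswith("."):
                hapA[i, j] = hapB[i, j] = MISSING
            else:
                a, b = call.split("|")
                hapA[i, j] = int(a)
                hapB[i, j] = int(b)
    return PhasedGenotypes(ids, mm, hapA, hapB)
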