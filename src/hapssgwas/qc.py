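"""Marker- and animal-level genotype quality control.

Filters mirror a standard SNP-chip pipeline for dosage data: animals
with low call rate are removed first, then markers failing (in order)
the X-chromosome pseudo-autosomal-region rule, call rate, minor allele
frequency, or heterozygosity departure from Hardy-Weinberg expectation.
The same operations apply unchanged to pseudo-SNP dosage columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .simdata import MarkerMap


@dataclass
class QcThresholds:
    maf_min: float = 0.01
    marker_call_rate_min: float = 0.90
    animal_call_rate_min: float = 0.90
    het_departure_max: float = 0.15
    het_rule: str = "two_sided"  # or "excess"
    par_start_bp: int = 133_300_518
    x_chromosome_label: int = 30
    apply_par_rule: bool = True

    def __post_init__(self) -> None:
        for v in (self.maf_min, self.marker_call_rate_min,
                  self.animal_call_rate_min, self.het_departure_max):
            if not 0 <= v <= 1:
                raise ValueError("QC fractions must lie in [0, 1]")


@dataclass
class QcReport:
    """Bookkeeping of removals; removed + surviving = input per dimension."""

    n_markers_in: int = 0
    n_animals_in: int = 0
    removed_markers: dict = field(default_factory=dict)  # rule -> count
    removed_animals: dict = field(default_factory=dict)
    surviving_markers: list = field(default_factory=list)
    surviving_animals: list = field(default_factory=list)

    @property
    def n_markers_removed(self) -> int:
        return sum(self.removed_markers.values())

    @property
    def n_animals_removed(self) -> int:
        return sum(self.removed_animals.values())

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)


def marker_stats(dosages: np.ndarray) -> pd.DataFrame:
    """Per-marker allele frequency, call rate and heterozygosity.

    ``dosages`` is animals x markers in {0,1,2} with NaN for missing.
    p is the mean non-missing dosage / 2; exp_het = 2p(1-p); obs_het is
    the share of non-missing calls equal to 1.  An all-missing marker
    gets call_rate 0 and NaN frequency (removed by the call-rate rule).
    """
    dosages = np.asarray(dosages, dtype=float)
    obs = ~np.isnan(dosages)
    n_obs = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nansum(dosages, axis=0) / (2.0 * n_obs)
        obs_het = np.nansum(dosages == 1, axis=0) / n_obs
    p[n_obs == 0] = np.nan
    obs_het = np.where(n_obs == 0, np.nan, obs_het)
    return pd.DataFrame(
        {
            "p": p,
            "call_rate": n_obs / dosages.shape[0],
            "obs_het": obs_het,
            "exp_het": 2.0 * p * (1.0 - p),
        }
    )


def apply_animal_qc(dosages: np.ndarray, animal_ids: list[str],
                    thresholds: QcThresholds) -> tuple[np.ndarray, list[str], QcReport]:
    """Drop animals whose genotype call rate falls below the minimum."""
    dosages = np.asarray(dosages, dtype=float)
    cr = (~np.isnan(dosages)).mean(axis=1)
    keep = cr >= thresholds.animal_call_rate_min
    rep = QcReport(
        n_markers_in=dosages.shape[1],
        n_animals_in=dosages.shape[0],
        removed_animals={"call_rate": int((~keep).sum())},
        surviving_animals=[a for a, k in zip(animal_ids, keep) if k],
        surviving_markers=[],
    )
    return dosages[keep], rep.surviving_animals, rep


def apply_marker_qc(dosages: np.ndarray, marker_map: MarkerMap | None,
                    thresholds: QcThresholds,
                    marker_ids: list[str] | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, QcReport]:
    """Remove markers failing the PAR / call-rate / MAF / heterozygosity rules.

    Each removal is attributed to the first failing rule in that fixed
    order.  Returns filtered dosages, the kept column indices, and the
    report.  ``marker_map`` may be None for pseudo-SNP columns, in which
    case the PAR rule is skipped.
    """
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    if marker_ids is None:
        marker_ids = (list(marker_map.marker_ids) if marker_map is not None
                      else [f"col{j}" for j in range(m)])
    stats = marker_stats(dosages)
    removed = {"par": 0, "call_rate": 0, "maf": 0, "het_departure": 0}
    keep = np.ones(m, dtype=bool)

    if marker_map is not None and thresholds.apply_par_rule:
        on_x = marker_map.chroms == thresholds.x_chromosome_label
        # "above" the PAR boundary is read strictly: position must exceed it
        bad = on_x & (marker_map.positions <= thresholds.par_start_bp)
        removed["par"] = int(bad.sum())
        keep &= ~bad

    bad = keep & (stats["call_rate"].to_numpy() < thresholds.marker_call_rate_min)
    removed["call_rate"] = int(bad.sum())
    keep &= ~bad

    p = stats["p"].to_numpy()
    with np.errstate(invalid="ignore"):
        maf = np.minimum(p, 1 - p)
    bad = keep & (maf < thresholds.maf_min)
    removed["maf"] = int(bad.sum())
    keep &= ~bad

    dep = stats["obs_het"].to_numpy() - stats["exp_het"].to_numpy()
    if thresholds.het_rule == "two_sided":
        dep = np.abs(dep)
    bad = keep & (dep > thresholds.het_departure_max)
    removed["het_departure"] = int(bad.sum())
    keep &= ~bad

    rep = QcReport(
        n_markers_in=m,
        n_animals_in=dosages.shape[0],
        removed_markers=removed,
        surviving_markers=[marker_ids[j] for j in np.where(keep)[0]],
    )
    return dosages[:, keep], np.where(keep)[0], rep


def run_qc(dosages: np.ndarray, animal_ids: list[str], marker_map: MarkerMap,
           thresholds: QcThresholds | None = None,
           ) -> tuple[np.ndarray, list[str], np.ndarray, QcReport]:
    """Animal QC first, then marker QC with statistics recomputed after."""
    thresholds = thresholds or QcThresholds()
    d1, surv_animals, rep_a = apply_animal_qc(dosages, animal_ids, thresholds)
    d2, keep_cols, rep_m = apply_marker_qc(d1, marker_map, thresholds)
    rep = QcReport(
        n_markers_in=rep_m.n_markers_in,
        n_animals_in=rep_a.n_animals_in,
        removed_markers=rep_m.removed_markers,
        removed_animals=rep_a.removed_animals,
        surviving_markers=rep_m.surviving_markers,
        surviving_animals=surv_animals,
    )
    return d2, surv_animals, keep_cols, rep
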