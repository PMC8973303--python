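"""Plate-level screening statistics for motility screens.

A well's particle-level integrated-distance distribution is compared against
the pooled vehicle (DMSO) distribution with a two-sample Kolmogorov–Smirnov
test, and each per-well statistic is standardised against the vehicle wells
with the plate formula Z = (x − μ)/σ (sample SD over the vehicle wells).
Hits are compounds whose Z exceeds the threshold (default 2) in *both*
replicates.

Because the KS D statistic is non-negative and therefore directionless, the
reported KS Z-score is signed by the direction of the mean-distance shift
relative to the pooled vehicle, so motility enhancers score positive and
suppressors negative.  An alternative ``ks_z_mode='pvalue'`` converts the
KS p-value directly through the normal quantile function.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WellSummary", "HitCall", "ks_two_sample", "well_zscore",
           "call_hits", "plate_summary"]


@dataclass
class WellSummary:
    """Screening statistics for one well, with its particle distances."""

    well: str
    compound: str
    replicate: int
    distances_um: np.ndarray
    concentration_um: float = float("nan")
    is_vehicle: bool = False
    percent_motile: float = float("nan")
    mean_integrated_distance_um: float = float("nan")

    def __post_init__(self):
        self.distances_um = np.asarray(self.distances_um, dtype=float)
        if self.distances_um.size < 1:
            raise ValueError("a well needs at least one particle")
        if np.isnan(self.mean_integrated_distance_um):
            self.mean_integrated_distance_um = float(self.distances_um.mean())
        if not np.isnan(self.percent_motile) and not (
                0.0 <= self.percent_motile <= 100.0):
            raise ValueError("percent_motile must be in [0, 100]")

    @property
    def n(self) -> int:
        return self.distances_um.size


@dataclass(frozen=True)
class HitCall:
    compound: str
    z_rep1: float
    z_rep2: float
    hit: bool


def ks_two_sample(sample_a, sample_b) -> tuple[float, float]:
    """Two-sample KS statistic D = sup|ECDF_a − ECDF_b| and asymptotic p."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("KS comparison needs at least 2 values per sample")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def well_zscore(x: float, control_values) -> float:
    """Plate Z-score of ``x`` against vehicle-well values: (x − μ)/σ.

    μ and σ are the mean and sample SD (n−1) of the vehicle wells'
    statistic; enhancement of the statistic scores positive.
    """
    c = np.asarray(control_values, dtype=float)
    if c.size < 2:
        raise ValueError("need at least 2 control values")
    sd = float(c.std(ddof=1))
    if sd == 0:
        raise ValueError("control values are degenerate (zero SD)")
    return (float(x) - float(c.mean())) / sd


def call_hits(per_compound: dict, threshold: float = 2.0) -> list[HitCall]:
    """Replicate-concordant hit calling: hit iff Z > threshold in both.

    ``per_compound`` maps compound name → sequence of two replicate
    Z-scores.  Compounds with a missing replicate are excluded with a
    warning.  Threshold 2 is the primary-screen criterion; 3 is the stricter
    confirmation criterion — both are just values of ``threshold``.
    """
    calls = []
    for compound, zs in per_compound.items():
        zs = [z for z in np.atleast_1d(np.asarray(zs, dtype=float))
              if np.isfinite(z)]
        if len(zs) != 2:
            warnings.warn(f"compound {compound!r} lacks two replicate "
                          f"Z-scores ({len(zs)} found); excluded")
            continue
        z1, z2 = float(zs[0]), float(zs[1])
        calls.append(HitCall(compound, z1, z2,
                             hit=bool(z1 > threshold and z2 > threshold)))
    return calls


def plate_summary(wells: list[WellSummary], ks_z_mode: str = "plate"
                  ) -> pd.DataFrame:
    """Per-well screening statistics against the plate's vehicle wells.

    All same-plate vehicle wells are pooled to form the reference distance
    distribution.  For every well three standardised statistics are emitted:

    * ``ks_d`` — KS D of the well's distances vs the pooled vehicle;
    * ``ks_z`` — plate Z of that D across wells (signed by the direction of
      the mean-distance shift), or the normal quantile of the KS p-value in
      ``ks_z_mode='pvalue'``;
    * ``percent_motile_z`` and ``mean_distance_z`` — plate Z of the well's
      percent motile / mean integrated distance.

    Vehicle wells are included in the output and score ~0 on the location
    statistics by construction.
    """
    if ks_z_mode not in ("plate", "pvalue"):
        raise ValueError("ks_z_mode must be 'plate' or 'pvalue'")
    vehicle = [w for w in wells if w.is_vehicle]
    if len(vehicle) < 2:
        raise ValueError("plate needs at least 2 vehicle wells")
    pooled = np.concatenate([w.distances_um for w in vehicle])
    pooled_mean = float(pooled.mean())

    rows = []
    for w in wells:
        d, p = ks_two_sample(w.distances_um, pooled)
        sign = 1.0 if float(w.distances_um.mean()) >= pooled_mean else -1.0
        rows.append({
            "well": w.well, "compound": w.compound,
            "replicate": w.replicate,
            "concentration_uM": w.concentration_um,
            "is_vehicle": w.is_vehicle,
            "n_particles": w.n,
            "mean_integrated_distance_um": w.mean_integrated_distance_um,
            "percent_motile": w.percent_motile,
            "ks_d": d, "ks_p": p, "ks_sign": sign,
        })
    df = pd.DataFrame(rows)

    veh = df[df["is_vehicle"]]
    def plate_z(col):
        return df[col].map(lambda x: well_zscore(x, veh[col].to_numpy()))

    if ks_z_mode == "plate":
        df["ks_z"] = df["ks_sign"] * plate_z("ks_d")
    else:
        # directly invert the KS p-value through the standard normal
        p = df["ks_p"].clip(1e-300, 1.0)
        df["ks_z"] = df["ks_sign"] * stats.norm.isf(p)
    df["mean_distance_z"] = plate_z("mean_integrated_distance_um")
    if df["percent_motile"].notna().all():
        df["percent_motile_z"] = plate_z("percent_motile")
    else:
        df["percent_motile_z"] = np.nan
    return df.drop(columns=["ks_sign"])
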