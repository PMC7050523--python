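"""Fitness scoring from plate-reader growth curves.

The screen's predictions are validated by growing candidate mutants with
and without drug and summarizing each curve by its *incremental area under
the curve* (iAUC): the trapezoidal integral of optical density above the
well's own first reading (self-baselining removes inoculum differences;
dips below baseline contribute zero, not negative, area).

A strain's fitness under treatment is the ratio of its iAUC at the
treatment concentration to the mean iAUC of its drug-free references,
clamped to [0, 1].  A data-set-wide zero-avoidance shift (adding the
smallest nonzero ratio to every value) prepares the ratios for
beta-family downstream modelling, which is itself out of scope here —
this module emits descriptive per-strain summaries against the parent
strain instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class GrowthCurve:
    """One well's growth curve: OD readings (AU) over time (hours)."""

    strain: str
    plate: str
    concentration: float  # mg/L
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "od", np.asarray(self.od, dtype=float))
        if self.times.size != self.od.size:
            raise ValueError("times and od must have equal length")
        if self.times.size < 2:
            raise ValueError("need at least 2 time points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if (self.od < 0).any():
            raise ValueError("optical densities must be >= 0")


@dataclass(frozen=True)
class FitnessRatio:
    """Treated-over-reference iAUC ratio for one strain on one plate, clamped to [0, 1]."""

    strain: str
    plate: str
    ratio: float
    iauc_treated: float
    iauc_ref: float
    undefined: bool = False  # both reference iAUCs were zero


def iauc(curve: GrowthCurve) -> float:
    """Incremental AUC: trapezoidal integral of max(0, OD(t) - OD(t0)), in AU*h."""
    incremental = np.maximum(0.0, curve.od - curve.od[0])
    return float(np.trapezoid(incremental, curve.times))


def fitness_ratio(
    curves: Sequence[GrowthCurve],
    treated_conc: float = 0.125,
    reference_concs: Sequence[float] = (0.0, 0.015),
) -> FitnessRatio:
    """iAUC ratio of the treated curve to the mean of the reference curves.

    ``curves`` are one strain/plate's wells at the treated concentration
    and each reference concentration.  The ratio is clamped to [0, 1];
    when every reference iAUC is zero the ratio is undefined and flagged.
    """
    by_conc = {c.concentration: c for c in curves}
    missing = [c for c in (treated_conc, *reference_concs) if c not in by_conc]
    if missing:
        raise ValueError(f"missing curves at concentrations {missing}")
    strains = {c.strain for c in curves}
    plates = {c.plate for c in curves}
    if len(strains) != 1 or len(plates) != 1:
        raise ValueError("curves must come from a single strain and plate")

    treated = iauc(by_conc[treated_conc])
    refs = [iauc(by_conc[c]) for c in reference_concs]
    ref_mean = float(np.mean(refs))
    if ref_mean == 0.0:
        return FitnessRatio(curves[0].strain, curves[0].plate, float("nan"), treated, 0.0, undefined=True)
    ratio = float(np.clip(treated / ref_mean, 0.0, 1.0))
    return FitnessRatio(curves[0].strain, curves[0].plate, ratio, treated, ref_mean)


def shift_ratios(ratios: Sequence[float]) -> np.ndarray:
    """Zero-avoidance shift: add the smallest nonzero ratio to every value."""
    r = np.asarray(ratios, dtype=float)
    nonzero = r[r > 0]
    if nonzero.size == 0:
        raise ValueError("no nonzero ratios to define the shift")
    return r + float(nonzero.min())


def compare_to_parent(
    ratios_by_strain: Mapping[str, Sequence[float]],
    parent: str,
    change_threshold: float = 0.2,
) -> pd.DataFrame:
    """Descriptive per-strain fitness summary against the parent strain.

    Returns one row per strain: mean ratio, replicate count, difference of
    means versus the parent, and a flag marking |difference| greater than
    ``change_threshold`` times the parent mean.
    """
    if parent not in ratios_by_strain:
        raise ValueError(f"parent strain {parent!r} absent from data")
    parent_mean = float(np.mean(ratios_by_strain[parent]))
    rows = []
    for strain in sorted(ratios_by_strain):
        vals = np.asarray(ratios_by_strain[strain], dtype=float)
        diff = float(vals.mean() - parent_mean)
        rows.append(
            {
                "strain": strain,
                "mean_ratio": float(vals.mean()),
                "n_replicates": int(vals.size),
                "diff_vs_parent": diff,
                "changed": bool(abs(diff) > change_threshold * parent_mean),
            }
        )
    return pd.DataFrame(rows, columns=["strain", "mean_ratio", "n_replicates", "diff_vs_parent", "changed"])


def read_curves(path) -> list[GrowthCurve]:
    """Load curves from a tidy TSV with columns strain, plate, concentration, time_h, od."""
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "plate", "concentration", "time_h", "od"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve table missing columns: {sorted(missing)}")
    curves = []
    for (strain, plate, conc), grp in df.groupby(["strain", "plate", "concentration"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                strain=str(strain),
                plate=str(plate),
                concentration=float(conc),
                times=grp["time_h"].to_numpy(),
                od=grp["od"].to_numpy(),
            )
        )
    return curves
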