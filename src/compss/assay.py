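"""Analysis of spectrophotometric enzyme-assay readouts.

Two assay families are supported.  The dehydrogenase (MDH) assay follows
NADH oxidation as falling absorbance at 340 nm; absorbance converts to
concentration through the Beer-Lambert law c = A / (d * eps) with
eps = 6.22 mM^-1 cm^-1 and path length d = 0.29 cm (100 ul in a 96-well
plate).  A sample is called active when its endpoint absorbance is
significantly *lower* than the negative control's (one-sided Welch t-test,
p <= 0.05).  The superoxide-dismutase (SOD) assay measures percent
inhibition of WST-1 formazan formation at 450 nm:

    inhibition % = ((A - B) - (C - D)) / (A - B) * 100

with A = no-SOD control, B = blank, C = sample, D = no-xanthine-oxidase
control, evaluated at the 20-minute read.

Semiquantitative specific activity normalizes each enzyme's signal to
wild-type controls: for MDH, the mean concentration drop between the 0 s
and 90 s reads (after flooring low t0 values to the negative-control mean),
averaged over replicates and divided by the wild-type mean; for SOD, the
mean inhibition rate divided by the wild-type mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .stats_eval import welch_t_test

#: NADH extinction coefficient at 340 nm, mM^-1 cm^-1.
NADH_EPSILON = 6.22
#: Optical path length of 100 ul in a 96-well plate, cm.
PLATE_PATH_CM = 0.29
#: MDH semiquantitative floor on the t=0 NADH concentration, mM (275 uM).
T0_FLOOR_MM = 0.275

ROLES = {"sample", "negative_control", "no_xo", "no_sod", "blank", "wildtype"}


@dataclass
class PlateSeries:
    """One well's kinetic trace."""

    well: str
    role: str
    replicate: int
    times_s: tuple[float, ...]
    absorbance: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        t = np.asarray(self.times_s)
        if len(t) != len(self.absorbance):
            raise ValueError("times and absorbances differ in length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")

    def at(self, t: float) -> float:
        idx = np.where(np.isclose(self.times_s, t))[0]
        if idx.size == 0:
            raise ValueError(f"no reading at t={t} s in well {self.well}")
        return float(self.absorbance[int(idx[0])])

    @property
    def endpoint(self) -> float:
        return float(self.absorbance[-1])


def read_plate_table(path: str | Path) -> list[PlateSeries]:
    """Read a long-format plate table (well, role, replicate, time_s, absorbance)."""
    df = pd.read_csv(path, sep="\t")
    required = {"well", "role", "replicate", "time_s", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    series = []
    for (well, role, rep), grp in df.groupby(["well", "role", "replicate"],
                                             sort=False):
        grp = grp.sort_values("time_s")
        series.append(PlateSeries(
            well=str(well), role=str(role), replicate=int(rep),
            times_s=tuple(grp["time_s"]), absorbance=tuple(grp["absorbance"])))
    return series


def nadh_concentration(absorbance: float | np.ndarray) -> float | np.ndarray:
    """Beer-Lambert conversion A -> mM NADH (path 0.29 cm, eps 6.22)."""
    a = np.asarray(absorbance, dtype=float)
    if np.any(a < 0):
        raise ValueError("negative absorbance")
    c = a / (PLATE_PATH_CM * NADH_EPSILON)
    return float(c) if np.isscalar(absorbance) else c


def subtract_unspecific(series: PlateSeries,
                        no_substrate_mean: Sequence[float]) -> PlateSeries:
    """Per-timepoint subtraction of the no-substrate control mean."""
    corrected = tuple(a - m for a, m in zip(series.absorbance, no_substrate_mean))
    return PlateSeries(well=series.well, role=series.role,
                       replicate=series.replicate, times_s=series.times_s,
                       absorbance=corrected)


def mdh_activity_call(sample_endpoints: Sequence[float],
                      negative_endpoints: Sequence[float],
                      alpha: float = 0.05) -> tuple[bool, float]:
    """Active iff endpoint absorbance is significantly below the control.

    One-sided Welch t-test (sample < control); needs >= 2 replicates per
    group.  Returns (active, p).
    """
    if len(sample_endpoints) < 2 or len(negative_endpoints) < 2:
        raise ValueError("need >= 2 replicates per group")
    if (np.std(sample_endpoints) == 0 and np.std(negative_endpoints) == 0
            and np.mean(sample_endpoints) == np.mean(negative_endpoints)):
        return False, 1.0
    _, p = welch_t_test(sample_endpoints, negative_endpoints, alternative="less")
    return bool(p <= alpha), float(p)


def sod_inhibition(a_no_sod: float, b_blank: float, c_sample: float,
                   d_no_xo: float) -> float:
    """Percent inhibition of formazan formation.

    May legitimately fall below 0 or above 100 (reported as-is); an
    uninhibited signal A <= B means the assay is degenerate and raises.
    """
    if a_no_sod <= b_blank:
        raise ValueError("degenerate assay: no-SOD signal <= blank")
    return ((a_no_sod - b_blank) - (c_sample - d_no_xo)) \
        / (a_no_sod - b_blank) * 100.0


def sod_activity_call(sample_rates: Sequence[float],
                      negative_rates: Sequence[float],
                      alpha: float = 0.05) -> tuple[bool, float]:
    """Active iff inhibition rate significantly above the negative control."""
    if len(sample_rates) < 2 or len(negative_rates) < 2:
        raise ValueError("need >= 2 replicates per group")
    if (np.std(sample_rates) == 0 and np.std(negative_rates) == 0
            and np.mean(sample_rates) == np.mean(negative_rates)):
        return False, 1.0
    _, p = welch_t_test(sample_rates, negative_rates, alternative="greater")
    return bool(p <= alpha), float(p)


def _mdh_delta(series: Sequence[PlateSeries],
               negative_t0_mean_mM: float | None) -> list[float]:
    """Per-replicate concentration drop 0 -> 90 s with the t0 floor rule."""
    deltas = []
    for s in series:
        c0 = nadh_concentration(s.at(0.0))
        c90 = nadh_concentration(s.at(90.0))
        if negative_t0_mean_mM is not None and c0 < T0_FLOOR_MM:
            c0 = negative_t0_mean_mM
        deltas.append(c0 - c90)
    return deltas


def specific_activity(series: Sequence[PlateSeries],
                      wildtype_series: Sequence[PlateSeries],
                      mode: str,
                      negative_series: Sequence[PlateSeries] = (),
                      sod_controls: dict | None = None) -> float:
    """Wild-type-normalized semiquantitative activity.

    mode="mdh": mean concentration drop between the 0 and 90 s reads,
    replicate t0 values below 275 uM replaced by the negative-control t0
    mean, averaged and divided by the wild-type mean of the same quantity.
    mode="sod": mean inhibition rate over replicates divided by the
    wild-type controls' mean; ``sod_controls`` supplies A (no_sod), B
    (blank) and D (no_xo) absorbances at the 20-min read, and the series'
    20-min (1200 s) reads are C.
    """
    if mode == "mdh":
        neg_t0 = (float(np.mean([nadh_concentration(s.at(0.0))
                                 for s in negative_series]))
                  if negative_series else None)
        sample = float(np.mean(_mdh_delta(series, neg_t0)))
        wt = float(np.mean(_mdh_delta(wildtype_series, neg_t0)))
    elif mode == "sod":
        if not sod_controls:
            raise ValueError("sod mode requires sod_controls with a/b/d reads")
        a, b, d = (sod_controls[k] for k in ("a_no_sod", "b_blank", "d_no_xo"))
        sample = float(np.mean([sod_inhibition(a, b, s.at(1200.0), d)
                                for s in series]))
        wt = float(np.mean([sod_inhibition(a, b, s.at(1200.0), d)
                            for s in wildtype_series]))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if wt == 0:
        raise ValueError("wild-type activity is zero; cannot normalize")
    return sample / wt
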