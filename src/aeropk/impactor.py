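"""Cascade-impactor (NGI) data reduction.

Reduces per-run stage-mass tables from a Next Generation Impactor to the
aerodynamic descriptors used to characterise dry powder inhaler output:

* ED  — emitted dose, the drug mass leaving the device (everything recovered
  outside the device/capsule residue);
* MMAD / GSD — median and geometric standard deviation of the mass-weighted
  aerodynamic size distribution, from a probit(ln d) regression under the
  log-normal assumption;
* FPM — fine particle mass, the sized mass with aerodynamic diameter between
  1 and 5 um, evaluated on the fitted log-normal;
* FPF — FPM as a percentage of ED.

Stage cut-off diameters are flow-scaled from the bundled archival calibration
at 60 L/min.  Induction-port and pre-separator mass counts toward ED but not
toward the sized distribution (no cut-off is defined for those surfaces at
arbitrary flows); this convention is recorded in the output metadata.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDistributionError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedDistributionError,
    UndefinedRatioError,
)

#: Impactor collection surfaces, in airflow order.
LOCATIONS = (
    "device_residue",
    "induction_port",
    "pre_separator",
    "stage1",
    "stage2",
    "stage3",
    "stage4",
    "stage5",
    "stage6",
    "stage7",
    "MOC",
)

#: Surfaces whose mass is apportioned by aerodynamic size (stages + MOC).
SIZED_LOCATIONS = ("stage1", "stage2", "stage3", "stage4", "stage5", "stage6", "stage7", "MOC")

_FLOW_WINDOW = (15.0, 100.0)  # calibration validity window, L/min


@dataclass(frozen=True)
class StageMassTable:
    """Drug mass (mg) recovered on each impactor location for one run."""

    run_id: str
    device: str  # "capsule" or "reservoir"
    flow: float  # volumetric flow, L/min
    masses: dict

    def __post_init__(self):
        if self.device not in ("capsule", "reservoir"):
            raise InvalidInputError(f"unknown device type {self.device!r}")
        if self.flow <= 0:
            raise InvalidInputError("flow must be positive")
        missing = [loc for loc in LOCATIONS if loc not in self.masses]
        if missing:
            raise InvalidInputError(f"missing locations: {missing}")
        for loc, m in self.masses.items():
            if m < 0:
                raise InvalidInputError(f"negative mass at {loc}")

    @property
    def total_recovered(self) -> float:
        return float(sum(self.masses[loc] for loc in LOCATIONS))

    @property
    def sized_mass(self) -> float:
        return float(sum(self.masses[loc] for loc in SIZED_LOCATIONS))


@dataclass(frozen=True)
class CutoffSet:
    """Stage cut-off aerodynamic diameters (um) at one flow (L/min).

    ``d50[i]`` is the cut-off of stage ``i+1``; the MOC collects everything
    below the stage-7 cut-off.
    """

    flow: float
    d50: tuple

    def __post_init__(self):
        if self.flow <= 0:
            raise InvalidInputError("flow must be positive")
        d = np.asarray(self.d50, dtype=float)
        if len(d) != 7 or np.any(d <= 0) or np.any(np.diff(d) >= 0):
            raise InvalidInputError("d50 must be 7 strictly decreasing positive diameters")


@dataclass(frozen=True)
class AerodynamicSummary:
    """Per-run aerodynamic descriptors."""

    run_id: str
    ED: float  # mg
    FPM: float  # mg
    FPF: float  # percent of ED
    MMAD: float  # um
    GSD: float  # dimensionless, >= 1
    fit_r2: float
    metadata: dict = field(default_factory=dict)


def _reference_table() -> pd.DataFrame:
    with resources.files("aeropk.data").joinpath("ngi_cutoffs.csv").open() as fh:
        return pd.read_csv(fh, comment="#")


def ngi_cutoffs(flow: float) -> CutoffSet:
    """Flow-scaled NGI stage cut-offs: d50(Q) = d50(60) * (60/Q)^x per stage.

    Outside the 15-100 L/min calibration window a warning is issued (the
    scaling law is extrapolated); nonpositive flow is an error.
    """
    if flow <= 0:
        raise InvalidInputError("flow must be positive")
    if not (_FLOW_WINDOW[0] <= flow <= _FLOW_WINDOW[1]):
        warnings.warn(
            f"flow {flow:g} L/min outside the {_FLOW_WINDOW} calibration window; "
            "cut-offs are extrapolated",
            stacklevel=2,
        )
    ref = _reference_table()
    d50 = ref["d50_60lpm_um"].to_numpy() * (60.0 / flow) ** ref["flow_exponent"].to_numpy()
    return CutoffSet(flow=flow, d50=tuple(float(x) for x in d50))


def emitted_dose(table: StageMassTable) -> float:
    """ED (mg): total recovered mass excluding the device/capsule residue."""
    return float(sum(table.masses[loc] for loc in LOCATIONS if loc != "device_residue"))


def cumulative_undersize(table: StageMassTable, cutoffs: CutoffSet):
    """Cumulative mass fraction of the sized mass below each stage cut-off.

    Returns ``[(d50_i, fraction finer than d50_i), ...]`` for stages 1..7.
    Mass below the cut-off of stage i is the mass collected on stages i+1..7
    and the MOC.  Induction port and pre-separator are excluded.
    """
    sized = table.sized_mass
    if sized <= 0:
        raise UndefinedDistributionError(f"run {table.run_id}: no mass on sized surfaces")
    out = []
    for i, d in enumerate(cutoffs.d50):
        below = sum(table.masses[loc] for loc in SIZED_LOCATIONS[i + 1 :])
        out.append((float(d), float(below / sized)))
    return out


def fit_lognormal(cumulative) -> tuple:
    """Probit fit of the cumulative-undersize curve.

    Least-squares line of probit(fraction) against ln(diameter); points with
    fraction outside the open interval (0, 1) carry no probit information and
    are excluded.  Returns ``(MMAD um, GSD, r^2)`` with MMAD the diameter at
    probit zero and GSD = exp(1/slope).
    """
    pts = [(d, f) for d, f in cumulative if 0.0 < f < 1.0]
    if len(pts) < 3:
        raise InsufficientDataError(f"only {len(pts)} usable points for the probit fit")
    x = np.log([d for d, _ in pts])
    z = stats.norm.ppf([f for _, f in pts])
    slope, intercept, r, _, _ = stats.linregress(x, z)
    if slope <= 0:
        raise DegenerateDistributionError("nonpositive probit slope")
    mmad = float(np.exp(-intercept / slope))
    gsd = float(np.exp(1.0 / slope))
    return mmad, gsd, float(r**2)


def fine_particle_mass(table: StageMassTable, cutoffs: CutoffSet) -> float:
    """FPM (mg): sized mass between 1 and 5 um on the fitted log-normal."""
    mmad, gsd, _ = fit_lognormal(cumulative_undersize(table, cutoffs))
    return table.sized_mass * _band_fraction(mmad, gsd, 1.0, 5.0)


def _band_fraction(mmad: float, gsd: float, lo: float, hi: float) -> float:
    sig = np.log(gsd)
    if sig == 0.0:
        return float(lo <= mmad <= hi)
    mu = np.log(mmad)
    return float(stats.norm.cdf((np.log(hi) - mu) / sig) - stats.norm.cdf((np.log(lo) - mu) / sig))


def fine_particle_fraction(FPM: float, ED: float) -> float:
    """FPF (%) = 100 * FPM / ED."""
    if ED <= 0:
        raise UndefinedRatioError("emitted dose is zero; FPF undefined")
    return 100.0 * FPM / ED


def summarize_run(table: StageMassTable, cutoffs: CutoffSet | None = None) -> AerodynamicSummary:
    """Full reduction of one run to its aerodynamic descriptors."""
    if cutoffs is None:
        cutoffs = ngi_cutoffs(table.flow)
    ed = emitted_dose(table)
    mmad, gsd, r2 = fit_lognormal(cumulative_undersize(table, cutoffs))
    fpm = table.sized_mass * _band_fraction(mmad, gsd, 1.0, 5.0)
    fpf = fine_particle_fraction(fpm, ed) if ed > 0 else 0.0
    return AerodynamicSummary(
        run_id=table.run_id,
        ED=ed,
        FPM=fpm,
        FPF=fpf,
        MMAD=mmad,
        GSD=gsd,
        fit_r2=r2,
        metadata={
            "sized_mass_mg": table.sized_mass,
            "convention": "IP/pre-separator in ED only; FPM from probit fit of stage1..MOC",
        },
    )


# ---------------------------------------------------------------------------
# Delimited-text interface

_CSV_COLUMNS = [
    "run_id",
    "device",
    "flow_lpm",
    "device_residue_mg",
    "induction_port_mg",
    "pre_separator_mg",
    "stage1_mg",
    "stage2_mg",
    "stage3_mg",
    "stage4_mg",
    "stage5_mg",
    "stage6_mg",
    "stage7_mg",
    "moc_mg",
]


def read_runs_csv(path) -> list:
    """Read one StageMassTable per row from the documented CSV dialect."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"runs CSV missing columns: {missing}")
    tables = []
    for _, row in df.iterrows():
        masses = {
            "device_residue": row["device_residue_mg"],
            "induction_port": row["induction_port_mg"],
            "pre_separator": row["pre_separator_mg"],
            "MOC": row["moc_mg"],
        }
        for s in range(1, 8):
            masses[f"stage{s}"] = row[f"stage{s}_mg"]
        tables.append(
            StageMassTable(
                run_id=str(row["run_id"]),
                device=str(row["device"]),
                flow=float(row["flow_lpm"]),
                masses={k: float(v) for k, v in masses.items()},
            )
        )
    return tables


def reduce_runs(tables, per_replicate: bool = True) -> pd.DataFrame:
    """Reduce runs to a summary DataFrame (one row per run)."""
    rows = []
    for t in tables:
        s = summarize_run(t)
        rows.append(
            {
                "run_id": s.run_id,
                "ED_mg": s.ED,
                "FPM_mg": s.FPM,
                "FPF_pct": s.FPF,
                "MMAD_um": s.MMAD,
                "GSD": s.GSD,
                "fit_r2": s.fit_r2,
            }
        )
    df = pd.DataFrame(rows)
    if per_replicate:
        return df
    # Replicates: per-run summaries averaged; mean +/- SD with n.
    df["formulation"] = df["run_id"].str.replace(r"[_-]?rep\d+$", "", regex=True)
    agg = df.groupby("formulation", sort=False).agg(["mean", "std", "count"])
    agg.columns = ["_".join(c) for c in agg.columns]
    return agg.reset_index()
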