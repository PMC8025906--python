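"""Synthetic measurement generators.

Produce every input the pipeline consumes — NGI stage-mass tables drawn from
a log-normal aerodynamic size distribution with multiplicative replicate
noise, and material descriptor/outcome tables with a controllable
correlation structure — so the whole toolchain is testable without any
instrument data.

All generators are pure functions of (spec, seed): one global integer seed
drives named RNG substreams (one per run/material), so adding replicates
never perturbs earlier draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .descriptors import DESCRIPTOR_COLUMNS
from .errors import InvalidInputError
from .impactor import SIZED_LOCATIONS, CutoffSet, StageMassTable, ngi_cutoffs

#: outcome columns of a descriptor/outcome table pair
OUTCOME_COLUMNS = ("ED", "FPM", "FPF", "MMAD", "Lung", "Ext", "Cmax", "tmax", "AUC_0_12", "ConcU")


@dataclass(frozen=True)
class SynthSpec:
    """Study-condition parameters of the synthetic generators.

    Defaults emulate one capsule-device formulation run at 60 L/min with the
    replicate noise of a careful impactor experiment (a few percent per
    collection surface).
    """

    seed: int = 0
    n_replicates: int = 3
    mmad: float = 2.6  # um
    gsd: float = 1.9
    ed_mg: float = 3.10
    device_residue_mg: float = 0.80
    sized_frac_of_ed: float = 0.40  # sized (stage1..MOC) share of ED
    stage_cv: float = 0.02  # multiplicative log-normal noise CV per surface
    flow: float = 60.0  # L/min
    device: str = "capsule"
    rho: float = 0.8  # designed property-outcome correlation
    n_materials: int = 4
    descriptor_mean: float = 10.0
    descriptor_sd: float = 2.0

    def __post_init__(self):
        if self.stage_cv < 0:
            raise InvalidInputError("stage CV must be nonnegative")
        if abs(self.rho) > 1:
            raise InvalidInputError("|rho| must be <= 1")
        if not (0 < self.sized_frac_of_ed <= 1):
            raise InvalidInputError("sized_frac_of_ed must lie in (0, 1]")


def stream(seed: int, *keys) -> np.random.Generator:
    """Named RNG substream: a stable function of the seed and the key path."""
    digest = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *digest]))


def _stage_fractions(mmad: float, gsd: float, cutoffs: CutoffSet) -> np.ndarray:
    """Log-normal CDF differences over the stage bands (stage1 .. MOC)."""
    sig = np.log(gsd)
    mu = np.log(mmad)
    cdf = sps.norm.cdf((np.log(cutoffs.d50) - mu) / sig)  # undersize at each cut-off
    frac = np.empty(8)
    frac[0] = 1.0 - cdf[0]  # stage1 collects everything above its cut-off
    frac[1:7] = cdf[:6] - cdf[1:7]
    frac[7] = cdf[6]  # MOC: everything below the stage-7 cut-off
    return frac


def gen_ngi_run(spec: SynthSpec) -> list:
    """Generate ``spec.n_replicates`` StageMassTables for one formulation.

    The sized mass is apportioned to stage1..MOC by log-normal CDF
    differences at the flow-correct cut-offs; the non-sized part of the ED is
    split evenly between induction port and pre-separator; every collection
    surface then receives independent multiplicative log-normal noise with
    the requested CV (mean-one convention, so expectations are unbiased).
    """
    cutoffs = ngi_cutoffs(spec.flow)
    frac = _stage_fractions(spec.mmad, spec.gsd, cutoffs)
    sized = spec.ed_mg * spec.sized_frac_of_ed
    unsized = spec.ed_mg - sized
    sigma = np.sqrt(np.log1p(spec.stage_cv**2))
    tables = []
    for rep in range(spec.n_replicates):
        rng = stream(spec.seed, "ngi", rep)
        noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=11)) if sigma > 0 else np.ones(11)
        masses = {
            "device_residue": spec.device_residue_mg * noise[0],
            "induction_port": 0.5 * unsized * noise[1],
            "pre_separator": 0.5 * unsized * noise[2],
        }
        for i, loc in enumerate(SIZED_LOCATIONS):
            masses[loc] = sized * frac[i] * noise[3 + i]
        tables.append(
            StageMassTable(
                run_id=f"synth_rep{rep + 1}",
                device=spec.device,
                flow=spec.flow,
                masses=masses,
            )
        )
    return tables


def gen_descriptor_tables(spec: SynthSpec):
    """(props, outcomes) tables with a designed correlation structure.

    Jointly Gaussian columns: a latent standard normal per material drives
    the first property column and the first outcome column with correlation
    ``spec.rho``; the remaining columns are independent draws around the
    descriptor mean/SD.  ``n_materials=4`` mimics a four-carrier design.
    """
    import pandas as pd

    n = spec.n_materials
    rng = stream(spec.seed, "descriptors")
    latent = rng.normal(size=n)
    props = {}
    for j, col in enumerate(DESCRIPTOR_COLUMNS):
        if j == 0:
            z = latent
        else:
            z = rng.normal(size=n)
        props[col] = spec.descriptor_mean + spec.descriptor_sd * z
    outcomes = {}
    for j, col in enumerate(OUTCOME_COLUMNS):
        eps = rng.normal(size=n)
        if j == 0:
            z = spec.rho * latent + np.sqrt(max(1.0 - spec.rho**2, 0.0)) * eps
        else:
            z = eps
        outcomes[col] = spec.descriptor_mean + spec.descriptor_sd * z
    index = [f"material_{i + 1}" for i in range(n)]
    return (
        pd.DataFrame(props, index=index),
        pd.DataFrame(outcomes, index=index),
    )
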