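"""Seeded generators of synthetic inputs for every pipeline stage.

Each generator produces data with the statistical structure the matching
analysis stage assumes: noisy reporter time courses from the circuit
model, FP titration curves, qPCR CT triplicates against the hrdB
reference, and observed peptide mass lists with MS1 intensities.  At zero
noise each generator composed with its analysis stage is the identity on
the ground truth.

Noise models are assumptions (the experiments report only mean +/- SD of
three repeats): Gaussian on anisotropy and CT, lognormal on MS
intensities.  Identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binding import BindingSystem, TitrationCurve, anisotropy, fraction_bound
from .circuit import CircuitParams, CircuitState, SulfurSchedule, default_init, simulate
from .massspec import (
    CARBAMIDOMETHYL,
    PERSULFIDE_CARBAMIDOMETHYL,
    ProteinRecord,
    monoisotopic_mass,
    tryptic_digest,
)

__all__ = [
    "NoiseModel",
    "gen_reporter_timecourse",
    "gen_fp_titration",
    "gen_qpcr",
    "gen_peptide_dataset",
    "synthetic_adpa_standin",
    "DEFAULT_FP_GRID",
]

# 12 log-spaced TF concentrations over the FP working range 10 nM - 22.5 uM
DEFAULT_FP_GRID = np.logspace(1.0, math.log10(22500.0), 12)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise description: kind, scale, and the seed that fixes it."""

    kind: str = "gaussian-additive"  # or "lognormal-multiplicative"
    scale: float = 0.0               # sd (additive) or log-sd (multiplicative)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian-additive", "lognormal-multiplicative"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.scale < 0:
            raise ValueError("scale must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.scale == 0:
            return values.copy()
        if self.kind == "gaussian-additive":
            return values + rng.normal(0.0, self.scale, size=values.shape)
        return values * rng.lognormal(0.0, self.scale, size=values.shape)


def gen_reporter_timecourse(params: CircuitParams, schedule: SulfurSchedule,
                            sample_times, noise: NoiseModel, n_rep: int = 3,
                            init: CircuitState | None = None,
                            dt: float = 1.0):
    """Noisy replicate readings of the target reporter G.

    Simulates the circuit once, samples G at ``sample_times`` and applies
    the noise model independently per replicate.  Returns (table, traj):
    a tidy DataFrame (time, replicate, G) and the ground-truth trajectory.
    """
    sample_times = np.asarray(sample_times, dtype=float)
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    horizon = float(sample_times.max())
    if init is None:
        init = default_init(params)
    traj = simulate(params, init, schedule, horizon, dt)
    g_true = np.interp(sample_times, traj.times, traj.G)
    rng = noise.rng()
    rows = []
    for rep in range(1, n_rep + 1):
        g_obs = noise.apply(g_true, rng)
        for t, g in zip(sample_times, g_obs):
            rows.append({"time": t, "replicate": rep, "G": g})
    return pd.DataFrame(rows), traj


def gen_fp_titration(Kd_true: float, r_free: float, r_bound: float,
                     conc_grid=None, noise: NoiseModel = NoiseModel(),
                     probe_conc: float = 1.0) -> TitrationCurve:
    """FP titration curve from the exact binding model plus anisotropy noise."""
    if conc_grid is None:
        conc_grid = DEFAULT_FP_GRID
    conc_grid = np.asarray(conc_grid, dtype=float)
    if conc_grid.size == 0:
        raise ValueError("empty concentration grid")
    rs = []
    for c in conc_grid:
        f = fraction_bound(BindingSystem(T_total=float(c), D_total=probe_conc,
                                         Kd=Kd_true))
        rs.append(r_free + (r_bound - r_free) * f)
    rs = noise.apply(np.array(rs), noise.rng())
    return TitrationCurve(points=tuple(zip(conc_grid, rs)),
                          r_free=r_free, r_bound=r_bound,
                          probe_conc=probe_conc)


def gen_qpcr(true_fold: float, ct_ref_mean: float = 20.0,
             ct_noise_sd: float = 0.2, n_rep: int = 3, seed: int = 0,
             ct_offset: float = 3.0) -> pd.DataFrame:
    """CT table (condition, replicate, gene, ct) encoding a known fold change.

    The control condition's target amplifies ``ct_offset`` cycles after the
    reference; the test condition's target CT is shifted down by
    log2(true_fold).  Gaussian CT noise is added per replicate and gene.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be > 0")
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    specs = {
        "control": ct_ref_mean + ct_offset,
        "test": ct_ref_mean + ct_offset - math.log2(true_fold),
    }
    for cond, ct_target_mean in specs.items():
        for rep in range(1, n_rep + 1):
            noise_t = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
            noise_r = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
            rows.append({"condition": cond, "replicate": rep, "gene": "target",
                         "ct": ct_target_mean + noise_t})
            rows.append({"condition": cond, "replicate": rep, "gene": "hrdB",
                         "ct": ct_ref_mean + noise_r})
    return pd.DataFrame(rows)


# Synthetic stand-in for the AdpA protein (no database download in the
# build environment).  The sequence is invented; like the real protein it
# carries a solvent-exposed cysteine at position 62 inside an ~1.3 kDa
# tryptic peptide, plus three further cysteines, so the digestion,
# modification and matching machinery is exercised on a realistic shape.
_STANDIN_SEQ = (
    "MTDQHALRVEGAPSWTVLHNGELYR"      # 1-25
    "AGDPTAVLPWQSEHLTDAVGNKLER"      # 26-50
    "TVDFLNSAGHDCAQETPLGVYKDAR"      # 51-75,  Cys62 in peptide TVDFLNSAGHDCAQETPLGVYK
    "SGELVWNPQHTMDCLAKEPVNR"         # 76-97,  Cys89
    "AQTDLSGHEVYPWMKCSDNTELR"        # 98-120, Cys113
    "GVHAPDWQESTLYKNACDMPGSR"        # 121-143, Cys137
)


def synthetic_adpa_standin() -> ProteinRecord:
    """Synthetic AdpA-like protein with Cys62 in a mid-size tryptic peptide."""
    return ProteinRecord(id="synthetic-adpa-standin", sequence=_STANDIN_SEQ)


def gen_peptide_dataset(protein: ProteinRecord, persulfidated_positions,
                        ratio_percent: float = 17.0,
                        mass_jitter_ppm: float = 0.0, seed: int = 0,
                        max_missed: int = 0,
                        base_intensity: float = 1e6) -> pd.DataFrame:
    """Observed-mass/intensity rows emulating an IAM-blocked digest in MS1.

    Every cysteine-containing tryptic peptide appears in its
    carbamidomethyl (AM) state.  Peptides covering a position listed in
    ``persulfidated_positions`` additionally appear in the
    persulfide-carbamidomethyl (S-AM) state, with the AM/S-AM MS1
    intensity ratio equal to ``ratio_percent`` (the persulfidated state
    dominates).  Masses are jittered uniformly within +/- mass_jitter_ppm.
    """
    positions = sorted(int(p) for p in persulfidated_positions)
    for pos in positions:
        if not 1 <= pos <= len(protein.sequence):
            raise ValueError(f"position {pos} outside protein")
        if protein.sequence[pos - 1] != "C":
            raise ValueError(f"position {pos} is {protein.sequence[pos - 1]!r},"
                             " not a cysteine")
    rng = np.random.default_rng(seed)
    rows = []

    def jitter(mass: float) -> float:
        if mass_jitter_ppm == 0:
            return mass
        return mass * (1.0 + rng.uniform(-mass_jitter_ppm, mass_jitter_ppm) * 1e-6)

    for pep in tryptic_digest(protein, max_missed=max_missed):
        n_cys = pep.sequence.count("C")
        if n_cys == 0:
            continue
        flagged = [pos for pos in positions if pep.start <= pos <= pep.end]
        base = base_intensity * rng.lognormal(0.0, 0.3)
        m_am = monoisotopic_mass(pep, [CARBAMIDOMETHYL] * n_cys)
        if flagged:
            mods = ([PERSULFIDE_CARBAMIDOMETHYL] * len(flagged)
                    + [CARBAMIDOMETHYL] * (n_cys - len(flagged)))
            m_sam = monoisotopic_mass(pep, mods)
            rows.append({"observed_mass_da": jitter(m_sam), "intensity": base})
            rows.append({"observed_mass_da": jitter(m_am),
                         "intensity": base * ratio_percent / 100.0})
        else:
            rows.append({"observed_mass_da": jitter(m_am), "intensity": base})
    return pd.DataFrame(rows)
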