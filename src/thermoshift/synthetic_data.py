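"""Ground-truthed reporter-intensity simulator for thermal-shift layouts.

Generates MaxQuant-proteinGroups-style tables for three experiment layouts —
a temperature-ladder TPP run (multiplexed per temperature), a single-tube
ramp experiment (test ramp plus 37 C control in one 16-plex), and an
isothermal hold — from a per-protein two-state Arrhenius denaturation model.

Each simulated protein gets a melting midpoint (T_m-50, normal around the
mammalian average of 51 C), an activation energy, and a base abundance;
treatment effects plant T_m shifts (the treated condition's kinetics are
recalibrated so its 50% point moves by exactly delta T_m at fixed Ea) and/or
condition-wide base-abundance fold changes, which exercise the
abundance-correction step downstream.  Noise is multiplicative log-normal per
measurement, optionally with an additive background and MaxQuant-style zeros
for missing values.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .io_filters import ChannelMeta, DesignError, IntensityMatrix
from .thermal_model import (
    CELSIUS_OFFSET,
    GAS_CONSTANT,
    DEFAULT_ACTIVATION_ENERGY,
    DEFAULT_TMAX,
    STPP_EQUILIBRATION_SECONDS,
    STPP_RAMP_RATE,
    STPP_RAMP_START,
    TPP_HOLD_SECONDS,
    TPP_LADDER,
)

TPP_PLEX_SIZE = 10
STPP_PLEX_SIZE = 16

LAYOUTS = ("TPP", "STPP_UP", "ISOTHERMAL")


@dataclass(frozen=True)
class ProteomeSpec:
    """Distributional description of the simulated proteome.

    T_m-50 values are drawn from Normal(51, 4) C by default (clipped to the
    calibratable range), base abundances from a log-normal on the reporter
    intensity scale (log2-mean 20, log2-sd 2), activation energies from a
    truncated normal around the package default, and unique-peptide counts
    from 2 + Poisson(4) so that an unfiltered proteome passes the two-peptide
    rule.  Each protein also gets a non-melting residual fraction (plateau,
    uniform on [plateau_min, plateau_max]) that survives any heating — the
    high-temperature plateau real melting curves show; without it soluble
    signal at the top of the ladder would vanish into the noise floor for the
    entire proteome.
    """

    n_proteins: int
    tm50_mean: float = 51.0
    tm50_sd: float = 4.0
    abundance_log2_mean: float = 20.0
    abundance_log2_sd: float = 2.0
    activation_energy_mean: float = DEFAULT_ACTIVATION_ENERGY
    activation_energy_sd: float = 25e3
    peptides_extra_mean: float = 4.0
    plateau_min: float = 0.02
    plateau_max: float = 0.12

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise DesignError("n_proteins must be >= 1")
        for name in ("tm50_sd", "abundance_log2_sd", "activation_energy_sd"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        if not (0.0 <= self.plateau_min <= self.plateau_max < 1.0):
            raise DesignError("need 0 <= plateau_min <= plateau_max < 1")


@dataclass(frozen=True)
class TreatmentEffect:
    """Planted effects, all applied to the treated condition only.

    ``stabilized_targets`` / ``destabilized_targets`` map protein index to a
    T_m shift in C (positive / negative respectively); ``abundance_effects``
    maps protein index to a heating-independent log2 fold change of base
    abundance.  A protein may appear in more than one mapping.
    """

    stabilized_targets: Mapping[int, float] = field(default_factory=dict)
    destabilized_targets: Mapping[int, float] = field(default_factory=dict)
    abundance_effects: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for idx, shift in self.stabilized_targets.items():
            if shift <= 0:
                raise DesignError(f"stabilized target {idx}: delta T_m must be > 0")
        for idx, shift in self.destabilized_targets.items():
            if shift >= 0:
                raise DesignError(f"destabilized target {idx}: delta T_m must be < 0")

    def delta_tm(self, n_proteins: int) -> np.ndarray:
        out = np.zeros(n_proteins)
        for mapping in (self.stabilized_targets, self.destabilized_targets):
            for idx, shift in mapping.items():
                if not (0 <= int(idx) < n_proteins):
                    raise DesignError(f"target index {idx} out of range")
                out[int(idx)] += shift
        return out

    def abundance_log2fc(self, n_proteins: int) -> np.ndarray:
        out = np.zeros(n_proteins)
        for idx, fc in self.abundance_effects.items():
            if not (0 <= int(idx) < n_proteins):
                raise DesignError(f"abundance-effect index {idx} out of range")
            out[int(idx)] += fc
        return out


@dataclass(frozen=True)
class NoiseModel:
    """Two-component measurement error, the model the glog transform targets.

    Each measurement is ``signal * lognormal(cv)`` (mean-one multiplicative
    noise) plus an additive floor drawn from Normal(``background``,
    ``background_sd``) clipped at zero — the detector/co-isolation noise
    floor, which also stands in for the non-melting residual fraction real
    melting curves show.  ``background_sd`` defaults to half the background.
    Values drop to 0 (the MaxQuant missing-value convention) with probability
    ``missing_rate``.  Identical seeds give identical output.
    """

    cv: float = 0.1
    background: float = 1024.0
    background_sd: Optional[float] = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise DesignError("cv must be >= 0")
        if self.background < 0:
            raise DesignError("background must be >= 0")
        if self.background_sd is None:
            object.__setattr__(self, "background_sd", 0.5 * self.background)
        if self.background_sd < 0:
            raise DesignError("background_sd must be >= 0")
        if not (0.0 <= self.missing_rate < 1.0):
            raise DesignError("missing_rate must be in [0, 1)")


@dataclass(frozen=True)
class ExperimentDesign:
    """Channel layout of one multiplexed thermal-shift experiment.

    * ``TPP``: one plex per ladder temperature, each holding every
      condition x replicate (plex capacity 10);
    * ``STPP_UP``: one 16-plex holding, per condition x replicate, a ramped
      "test" channel and a 37 C "control" channel;
    * ``ISOTHERMAL``: like STPP_UP but the test channel is a constant hold
      at ``t_max``.
    """

    layout: str
    n_replicates: int = 3
    temperature_ladder: tuple[float, ...] = TPP_LADDER
    t_max: float = DEFAULT_TMAX
    ramp_rate: float = STPP_RAMP_RATE

    def __post_init__(self) -> None:
        if self.layout not in LAYOUTS:
            raise DesignError(f"layout must be one of {LAYOUTS}, got {self.layout!r}")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        object.__setattr__(self, "temperature_ladder", tuple(float(t) for t in self.temperature_ladder))
        if self.layout == "TPP":
            if len(self.temperature_ladder) < 2:
                raise DesignError("TPP ladder needs at least 2 temperatures")
            per_plex = 2 * self.n_replicates
            if per_plex > TPP_PLEX_SIZE:
                raise DesignError(
                    f"TPP plex overfull: {per_plex} channels per temperature "
                    f"exceed a {TPP_PLEX_SIZE}-plex"
                )
        else:
            total = 2 * 2 * self.n_replicates
            if total > STPP_PLEX_SIZE:
                raise DesignError(
                    f"plex overfull: {total} channels exceed a {STPP_PLEX_SIZE}-plex"
                )

    @classmethod
    def tpp(cls, n_replicates: int = 2, temperature_ladder=TPP_LADDER) -> "ExperimentDesign":
        return cls("TPP", n_replicates=n_replicates, temperature_ladder=tuple(temperature_ladder))

    @classmethod
    def stpp_up(cls, n_replicates: int = 3, t_max: float = DEFAULT_TMAX,
                ramp_rate: float = STPP_RAMP_RATE) -> "ExperimentDesign":
        return cls("STPP_UP", n_replicates=n_replicates, t_max=t_max, ramp_rate=ramp_rate)

    @classmethod
    def isothermal(cls, n_replicates: int = 3, t_max: float = DEFAULT_TMAX) -> "ExperimentDesign":
        return cls("ISOTHERMAL", n_replicates=n_replicates, t_max=t_max)

    def channels(self) -> tuple[ChannelMeta, ...]:
        """Channel metadata, one entry per reporter column, in plex order."""
        metas: list[ChannelMeta] = []
        k = 0
        if self.layout == "TPP":
            for temp in self.temperature_ladder:
                for cond in ("treated", "untreated"):
                    for rep in range(1, self.n_replicates + 1):
                        metas.append(ChannelMeta(
                            name=f"Reporter intensity corrected {k}",
                            condition=cond, replicate=rep,
                            role="temperature", temperature=temp,
                        ))
                        k += 1
        else:
            for cond in ("treated", "untreated"):
                for rep in range(1, self.n_replicates + 1):
                    for role in ("test", "control"):
                        metas.append(ChannelMeta(
                            name=f"Reporter intensity corrected {k}",
                            condition=cond, replicate=rep, role=role,
                        ))
                        k += 1
        return tuple(metas)


@dataclass(frozen=True)
class GroundTruth:
    """Everything the simulator planted, for downstream benchmarking."""

    tm50: np.ndarray
    delta_tm: np.ndarray
    abundance_log2fc: np.ndarray
    activation_energy: np.ndarray
    base_abundance: np.ndarray
    plateau: np.ndarray
    protein_ids: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "protein_id": self.protein_ids,
            "tm50_c": self.tm50,
            "delta_tm_c": self.delta_tm,
            "abundance_log2fc": self.abundance_log2fc,
            "activation_energy_j_mol": self.activation_energy,
            "base_abundance": self.base_abundance,
            "plateau": self.plateau,
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Survival evaluation (vectorized over proteins)
# ---------------------------------------------------------------------------

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(64)


def _hold_exponent(log_a: np.ndarray, ea: np.ndarray, temp_c: float, duration: float) -> np.ndarray:
    t_k = temp_c + CELSIUS_OFFSET
    return duration * np.exp(log_a - ea / (GAS_CONSTANT * t_k))


def _ramp_exponent_vec(log_a: np.ndarray, ea: np.ndarray, start: float, end: float,
                       rate: float) -> np.ndarray:
    """Integral of k over a linear ramp for vectors of kinetics, by fixed
    64-node Gauss-Legendre quadrature (the integrand is smooth; agreement
    with adaptive quadrature is far below 1e-9)."""
    duration = (end - start) / rate
    t_mid = 0.5 * duration * (_GL_NODES + 1.0)
    temps_k = start + rate * t_mid + CELSIUS_OFFSET
    # proteins x nodes
    rates = np.exp(log_a[:, None] - ea[:, None] / (GAS_CONSTANT * temps_k[None, :]))
    return 0.5 * duration * rates @ _GL_WEIGHTS


def _calibrated_log_a(tm50: np.ndarray, ea: np.ndarray, exposure: float = TPP_HOLD_SECONDS) -> np.ndarray:
    """Vectorized closed-form calibration: survival(Hold(tm50, exposure)) = 1/2."""
    t_k = tm50 + CELSIUS_OFFSET
    return math.log(math.log(2.0) / exposure) + ea / (GAS_CONSTANT * t_k)


def _channel_survival(design: ExperimentDesign, channel: ChannelMeta,
                      log_a: np.ndarray, ea: np.ndarray) -> np.ndarray:
    if design.layout == "TPP":
        expo = _hold_exponent(log_a, ea, channel.temperature, TPP_HOLD_SECONDS)
    elif channel.role == "control":
        expo = _hold_exponent(log_a, ea, STPP_RAMP_START, TPP_HOLD_SECONDS)
    elif design.layout == "STPP_UP":
        expo = _hold_exponent(log_a, ea, STPP_RAMP_START, STPP_EQUILIBRATION_SECONDS)
        expo = expo + _ramp_exponent_vec(log_a, ea, STPP_RAMP_START, design.t_max, design.ramp_rate)
    else:  # ISOTHERMAL test channel
        expo = _hold_exponent(log_a, ea, design.t_max, TPP_HOLD_SECONDS)
    return np.exp(-expo)


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

_TM_MIN, _TM_MAX = 38.0, 69.0  # keep every (shifted) T_m calibratable


def simulate_experiment(
    proteome: ProteomeSpec,
    effect: TreatmentEffect,
    design: ExperimentDesign,
    noise: NoiseModel,
    pinned_tm50: Optional[Mapping[int, float]] = None,
) -> tuple[IntensityMatrix, GroundTruth]:
    """Simulate one multiplexed experiment.

    Per protein and channel the expected intensity is

        base * 2^(abundance_log2fc if treated) * survival(kinetics, program)

    where the treated condition's kinetics are recalibrated to T_m + delta
    T_m at fixed activation energy; measurement error follows
    :class:`NoiseModel`.  Deterministic given ``noise.seed``.

    ``pinned_tm50`` optionally fixes the T_m-50 of chosen proteins instead of
    drawing it — benchmark scenarios pin the planted target at a known point
    of the melting range (typically the proteome average) so that recovery
    rates measure statistical power rather than the heating program's
    dynamic-range limits.
    """
    rng = np.random.default_rng(noise.seed)
    n = proteome.n_proteins

    tm50 = rng.normal(proteome.tm50_mean, proteome.tm50_sd, size=n)
    tm50 = np.clip(tm50, _TM_MIN, _TM_MAX)
    if pinned_tm50:
        for idx, value in pinned_tm50.items():
            if not (0 <= int(idx) < n):
                raise DesignError(f"pinned_tm50 index {idx} out of range")
            tm50[int(idx)] = float(value)
    ea = rng.normal(proteome.activation_energy_mean, proteome.activation_energy_sd, size=n)
    ea = np.clip(ea, 1e4, None)
    base = np.exp2(rng.normal(proteome.abundance_log2_mean, proteome.abundance_log2_sd, size=n))
    peptides = 2 + rng.poisson(proteome.peptides_extra_mean, size=n)
    plateau = rng.uniform(proteome.plateau_min, proteome.plateau_max, size=n)

    delta_tm = effect.delta_tm(n)
    tm50_treated = np.clip(tm50 + delta_tm, _TM_MIN - 0.5, _TM_MAX + 0.5)
    ab_fc = effect.abundance_log2fc(n)

    log_a = {"untreated": _calibrated_log_a(tm50, ea),
             "treated": _calibrated_log_a(tm50_treated, ea)}

    channels = design.channels()
    expected = np.empty((n, len(channels)))
    for j, ch in enumerate(channels):
        surv = _channel_survival(design, ch, log_a[ch.condition], ea)
        soluble = plateau + (1.0 - plateau) * surv  # non-melting residual
        col = base * soluble
        if ch.condition == "treated":
            col = col * np.exp2(ab_fc)
        expected[:, j] = col

    if noise.cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise.cv ** 2))
        factors = np.exp(rng.normal(0.0, sigma, size=expected.shape) - 0.5 * sigma * sigma)
        values = expected * factors
    else:
        values = expected.copy()
    if noise.background > 0:
        floor = rng.normal(noise.background, noise.background_sd, size=values.shape)
        values += np.clip(floor, 0.0, None)
    if noise.missing_rate > 0:
        values[rng.random(size=values.shape) < noise.missing_rate] = 0.0

    ids = np.array([f"P{i:05d}" for i in range(n)], dtype=object)
    genes = np.array([f"GENE{i:05d}" for i in range(n)], dtype=object)
    matrix = IntensityMatrix(
        protein_ids=ids, gene_names=genes,
        reverse=np.zeros(n, dtype=bool), contaminant=np.zeros(n, dtype=bool),
        site_only=np.zeros(n, dtype=bool), unique_peptides=peptides,
        intensities=values, channels=channels,
    )
    truth = GroundTruth(tm50, delta_tm, ab_fc, ea, base, plateau, ids)
    return matrix, truth


def write_protein_groups(
    matrix: IntensityMatrix,
    path,
    n_decoys: int = 0,
    n_contaminants: int = 0,
    n_site_only: int = 0,
    extra_seed: int = 0,
) -> None:
    """Write a proteinGroups-dialect TSV, optionally appending flagged rows.

    The appended decoy ('+' in Reverse), contaminant, and site-only rows have
    plausible random intensities (seeded by ``extra_seed``) and exist purely
    to exercise the QC filters.  The file round-trips losslessly through
    :func:`thermoshift.io_filters.read_protein_groups`.
    """
    frame = matrix.to_frame()
    rng = np.random.default_rng(extra_seed)
    extras = []
    specs = [("REV__DECOY", "Reverse", n_decoys),
             ("CON__CONTAM", "Potential contaminant", n_contaminants),
             ("SITE__ONLY", "Only identified by site", n_site_only)]
    for prefix, flag_col, count in specs:
        for i in range(count):
            row = {col: "" for col in frame.columns}
            row["Protein IDs"] = f"{prefix}{i:03d}"
            row["Gene names"] = f"{prefix}{i:03d}"
            row[flag_col] = "+"
            row["Unique peptides"] = int(rng.integers(2, 10))
            for ch in matrix.channels:
                row[ch.name] = float(np.exp2(rng.normal(18.0, 2.0)))
            extras.append(row)
    if extras:
        frame = pd.concat([frame, pd.DataFrame(extras)], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False)
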