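"""Synthetic field-test generator with known ground truth.

The plant is modelled as a tip-loaded elastic cantilever with a rigid
base: during a test the device rotates the stalk through a triangle-wave
angle protocol (three cycles to ~15 degrees) and the load cell reads

    force = k_true * h * sin(theta) + noise        (loading legs)
    force = eta * k_true * h * sin(theta) + noise  (unloading legs)

where ``k_true`` is the true force-deflection slope (N/m) and
``eta <= 1`` a hysteresis multiplier capturing the loading/unloading
asymmetry of real traces. Gaussian sensor noise acts on force; optional
wind bursts add serially correlated (AR(1)/Ornstein-Uhlenbeck-like)
disturbances to the recorded rotation over contiguous windows, which is
the mechanism that breaks the monotone-run cycle parser and exercises
the full-trace fallback.

Brace-root anchorage enters through multiplicative whorl factors
``f1..fK`` in (0, 1], ``f1`` for the soil-closest whorl: excising the
top soil-entering whorl multiplies the true slope by ``fK``, the next by
``f(K-1)``, and so on, so the adjacent-label whorl ratios of the
analysis are exactly the generator parameters and the overall
contribution ratio is their product.

Everything is deterministic given (configuration, seed).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError
from .trace_io import (
    ForceRotationTrace,
    PlantRecord,
    RemovalSeries,
    write_metadata_csv,
    write_trace_csv,
)

__all__ = [
    "PlantTruth",
    "ProtocolConfig",
    "ExperimentDesign",
    "SimulatedSeries",
    "simulate_trace",
    "simulate_removal_series",
    "simulate_pure_beam_lengthening",
    "simulate_repeat_slopes",
    "simulate_line_means",
    "simulate_experiment",
    "write_dataset",
]


@dataclass(frozen=True)
class PlantTruth:
    """Ground-truth mechanical state of one simulated plant."""

    base_slope_N_per_m: float
    whorl_factors: tuple[float, ...] = (0.65, 0.85, 0.95)
    attachment_height_m: float | None = None
    load_height_m: float = 0.64
    plant_id: str = "plant"

    def __post_init__(self):
        if not self.base_slope_N_per_m > 0:
            raise ParameterError("base slope must be > 0")
        if any(not 0 < f <= 1 for f in self.whorl_factors):
            raise ParameterError("whorl factors must lie in (0, 1]")

    @property
    def true_ratio(self) -> float:
        """True contribution ratio = product of whorl factors."""
        return float(np.prod(self.whorl_factors))

    def true_slopes(self) -> dict[str, float]:
        """True slope per test label A.. (top whorl excised first)."""
        k = len(self.whorl_factors)
        slopes = {"A": self.base_slope_N_per_m}
        s = self.base_slope_N_per_m
        for m in range(1, k + 1):
            s *= self.whorl_factors[k - m]
            slopes[string.ascii_uppercase[m]] = s
        return slopes


@dataclass(frozen=True)
class ProtocolConfig:
    """Device protocol and noise settings for one simulated test.

    Defaults follow the field protocol: three cycles to ~15 degrees with
    the load cell at 0.64 m. Noise magnitudes are assumptions (real
    traces do not come with published noise floors): 0.5 N force noise
    and hysteresis 0.8 give visibly hysteretic but well-behaved traces.
    """

    n_cycles: int = 3
    points_per_leg: int = 50
    max_angle_deg: float = 15.0
    load_height_m: float = 0.64
    noise_sd_N: float = 0.5
    hysteresis_factor: float = 0.8
    wind_burst_prob: float = 0.0
    wind_magnitude_deg: float = 2.0
    wind_duration: int = 25
    wind_ar: float = 0.9

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ParameterError("n_cycles must be >= 1")
        if not 0 < self.max_angle_deg < 90:
            raise ParameterError("max_angle_deg must lie in (0, 90)")
        if self.noise_sd_N < 0:
            raise ParameterError("noise_sd_N must be >= 0")
        if not 0 < self.hysteresis_factor <= 1:
            raise ParameterError("hysteresis_factor must lie in (0, 1]")
        if self.points_per_leg < 2:
            raise ParameterError("points_per_leg must be >= 2")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _triangle_protocol(protocol: ProtocolConfig) -> tuple[np.ndarray, np.ndarray]:
    """Rotation sequence (deg) and loading-leg mask for the triangle wave."""
    p = protocol.points_per_leg
    up = np.linspace(0.0, protocol.max_angle_deg, p)
    down = np.linspace(protocol.max_angle_deg, 0.0, p)[1:-1]
    angles, loading = [], []
    for _ in range(protocol.n_cycles):
        angles.append(up)
        loading.append(np.ones(up.size, dtype=bool))
        angles.append(down)
        loading.append(np.zeros(down.size, dtype=bool))
    return np.concatenate(angles), np.concatenate(loading)


def simulate_trace(
    k_true: float,
    protocol: ProtocolConfig = ProtocolConfig(),
    seed=None,
    plant_id: str = "sim",
    test_label: str = "A",
) -> ForceRotationTrace:
    """Simulate one device test for a plant of true slope ``k_true``."""
    rng = _rng(seed)
    angles, loading = _triangle_protocol(protocol)
    n = angles.size
    h = protocol.load_height_m

    recorded = angles.copy()
    if protocol.wind_burst_prob > 0 and rng.random() < protocol.wind_burst_prob:
        start = int(rng.integers(0, max(1, n - protocol.wind_duration)))
        length = min(protocol.wind_duration, n - start)
        burst = np.empty(length)
        sd_innov = protocol.wind_magnitude_deg * math.sqrt(1 - protocol.wind_ar**2)
        burst[0] = rng.normal(0.0, protocol.wind_magnitude_deg)
        for t in range(1, length):
            burst[t] = protocol.wind_ar * burst[t - 1] + rng.normal(0.0, sd_innov)
        recorded[start : start + length] += burst

    deflection = h * np.sin(np.deg2rad(angles))  # true kinematics drive the force
    gain = np.where(loading, 1.0, protocol.hysteresis_factor)
    force = gain * k_true * deflection + rng.normal(0.0, protocol.noise_sd_N, size=n)
    return ForceRotationTrace(
        index=np.arange(n),
        rotation_deg=recorded,
        force_N=force,
        load_height_m=h,
        plant_id=plant_id,
        test_label=test_label,
    )


@dataclass
class SimulatedSeries:
    """A removal series plus the ground truth it was generated from."""

    series: RemovalSeries
    truth: PlantTruth
    true_slopes: dict[str, float] = field(default_factory=dict)


def simulate_removal_series(
    truth: PlantTruth,
    protocol: ProtocolConfig = ProtocolConfig(),
    seed=None,
) -> SimulatedSeries:
    """Simulate the full excision sequence A..(K+1 tests) for one plant."""
    rng = _rng(seed)
    true_slopes = truth.true_slopes()
    k_whorls = len(truth.whorl_factors)
    protocol = replace(protocol, load_height_m=truth.load_height_m)
    traces = {
        lab: simulate_trace(k, protocol, rng, truth.plant_id, lab)
        for lab, k in true_slopes.items()
    }
    plant = PlantRecord(
        plant_id=truth.plant_id,
        whorls_in_soil=k_whorls,
        whorls_total=k_whorls,
        attachment_height_m=truth.attachment_height_m,
    )
    return SimulatedSeries(RemovalSeries(plant, traces), truth, true_slopes)


def simulate_pure_beam_lengthening(
    EI_like: float,
    load_height_m: float = 0.64,
    attachment_height_m: float = 0.032,
    protocol: ProtocolConfig = ProtocolConfig(),
    seed=None,
) -> SimulatedSeries:
    """Null-model series where removal only lengthens the cantilever.

    Both tests share the flexural constant: intact the beam length is
    ``h - a`` (anchored at the attachment height), after removal it is
    ``h`` (anchored at the soil), so the slopes are ``3 EI/(h - a)^3``
    and ``3 EI/h^3`` and the true ratio is ``((h - a)/h)^3`` — the
    geometric null the beam-length correction must map to 1.
    """
    h, a = load_height_m, attachment_height_m
    if not 0 <= a < h:
        raise GeometryError(f"need 0 <= a < h, got a={a}, h={h}")
    rng = _rng(seed)
    k_with = 3.0 * EI_like / (h - a) ** 3
    k_without = 3.0 * EI_like / h**3
    protocol = replace(protocol, load_height_m=h)
    traces = {
        "A": simulate_trace(k_with, protocol, rng, "beam-null", "A"),
        "B": simulate_trace(k_without, protocol, rng, "beam-null", "B"),
    }
    plant = PlantRecord("beam-null", whorls_in_soil=1, whorls_total=1, attachment_height_m=a)
    truth = PlantTruth(k_with, (k_without / k_with,), a, h, "beam-null")
    return SimulatedSeries(RemovalSeries(plant, traces), truth, {"A": k_with, "B": k_without})


def simulate_repeat_slopes(
    n_plants: int = 23,
    n_repeats: int = 3,
    variance_share: float = 0.876,
    mean_slope: float = 40.0,
    total_sd: float = 8.0,
    seed=None,
) -> pd.DataFrame:
    """True slopes for a repeat-test design with a known repeatability.

    Plant effects and test residuals are Gaussian with variances split by
    ``variance_share`` (the true intraclass correlation). Returns a tidy
    frame with columns ``plant_id, repeat, k_true``.
    """
    if not 0 <= variance_share <= 1:
        raise ParameterError("variance_share must lie in [0, 1]")
    rng = _rng(seed)
    sd_plant = total_sd * math.sqrt(variance_share)
    sd_resid = total_sd * math.sqrt(1.0 - variance_share)
    rows = []
    for i in range(n_plants):
        effect = rng.normal(0.0, sd_plant)
        for r in range(n_repeats):
            k = mean_slope + effect + rng.normal(0.0, sd_resid)
            rows.append({"plant_id": f"p{i:03d}", "repeat": r, "k_true": max(k, 1e-3)})
    return pd.DataFrame(rows)


def simulate_line_means(
    n_lines: int = 26,
    b0: float = 30.0,
    b_dts: float = 0.44,
    b_ph: float = -0.07,
    predictor_corr: float = 0.8,
    noise_sd: float = 2.0,
    seed=None,
) -> pd.DataFrame:
    """Line-mean table for the stiffness ~ flowering-time + height regression.

    Days-to-silking (DTS) and plant height (PH) are drawn correlated
    (default r = 0.8, mimicking the strong DTS-PH coupling of selection
    populations) and the line-mean slope responds with a positive DTS
    and negative PH effect. Default spreads (sd 5.6 d, 21.6 cm) and
    noise are calibrated so that at n = 26 the fitted model lands near
    R^2 ~ 0.4 with a strongly significant DTS and marginally significant
    PH coefficient — the regime this analysis is designed for.
    """
    rng = _rng(seed)
    cov = np.array([[1.0, predictor_corr], [predictor_corr, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_lines)
    dts = 65.0 + 5.6 * z[:, 0]
    ph = 245.0 + 21.6 * z[:, 1]
    slope = b0 + b_dts * dts + b_ph * ph + rng.normal(0.0, noise_sd, size=n_lines)
    return pd.DataFrame({"line": [f"L{i:02d}" for i in range(n_lines)],
                         "dts": dts, "ph": ph, "fd_slope": slope})


@dataclass(frozen=True)
class ExperimentDesign:
    """Population-level design for a simulated field experiment.

    ``whorl_probs`` gives the distribution of soil-entering whorl counts
    (the field population mixes two- and three-whorl plants);
    ``time_multipliers``, when set, measures every plant once per
    time-of-day group with the given multiplicative stiffness effect
    applied to the plant's base slope.
    """

    n_plants: int = 23
    repeats_per_plant: int = 1
    whorl_probs: Mapping[int, float] = field(default_factory=lambda: {2: 0.5, 3: 0.5})
    whorl_factors: tuple[float, ...] = (0.65, 0.85, 0.95)
    log_mean_slope: float = math.log(40.0)
    log_sd_slope: float = 0.25
    time_multipliers: tuple[float, ...] | None = None
    attachment_height_range: tuple[float, float] = (0.015, 0.032)
    plot_ids: tuple[str, ...] = ("A", "B")

    def __post_init__(self):
        if self.n_plants < 1:
            raise ParameterError("n_plants must be >= 1")
        if self.repeats_per_plant < 1:
            raise ParameterError("repeats_per_plant must be >= 1")
        total = sum(self.whorl_probs.values())
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ParameterError(f"whorl_probs must sum to 1, got {total}")


def simulate_experiment(
    design: ExperimentDesign,
    protocol: ProtocolConfig = ProtocolConfig(),
    seed=None,
) -> tuple[list[SimulatedSeries], pd.DataFrame]:
    """Simulate a whole removal experiment with ground truth.

    Returns one removal series per plant (each ``repeats_per_plant``
    draws a fresh series under the same truth, suffixing the plant id)
    and a tidy ground-truth frame (plant, plot, whorl count, base slope,
    factors, attachment height).
    """
    rng = _rng(seed)
    counts = sorted(design.whorl_probs)
    probs = [design.whorl_probs[c] for c in counts]
    out: list[SimulatedSeries] = []
    truth_rows = []
    for i in range(design.n_plants):
        k_whorls = int(rng.choice(counts, p=probs))
        base = float(rng.lognormal(design.log_mean_slope, design.log_sd_slope))
        factors = tuple(design.whorl_factors[:k_whorls])
        a = float(rng.uniform(*design.attachment_height_range))
        plot = design.plot_ids[i % len(design.plot_ids)]
        for rep in range(design.repeats_per_plant):
            pid = f"p{i:03d}" if design.repeats_per_plant == 1 else f"p{i:03d}r{rep}"
            truth = PlantTruth(base, factors, a, protocol.load_height_m, pid)
            sim = simulate_removal_series(truth, protocol, rng)
            sim.series.plant.plot_id = plot
            out.append(sim)
            truth_rows.append({
                "plant_id": pid, "plot_id": plot, "whorls_in_soil": k_whorls,
                "base_slope_N_per_m": base, "attachment_height_m": a,
                **{f"f{j + 1}": factors[j] for j in range(k_whorls)},
                "true_ratio": truth.true_ratio,
            })
    return out, pd.DataFrame(truth_rows)


def write_dataset(
    simulated: list[SimulatedSeries],
    truth_table: pd.DataFrame,
    directory: str | Path,
    seed: int | None = None,
) -> Path:
    """Write a simulated experiment as a trace-CSV dataset directory.

    Produces one trace file per test, ``metadata.csv`` and
    ``ground_truth.csv`` (plus a small manifest with the seed), in the
    exact dialect the loaders read back.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records, files = [], {}
    for sim in simulated:
        plant = sim.series.plant
        records.append(plant)
        files[plant.plant_id] = {}
        for lab, tr in sorted(sim.series.traces.items()):
            fname = f"trace_{plant.plant_id}_{lab}.csv"
            write_trace_csv(tr, directory / fname)
            files[plant.plant_id][lab] = fname
    write_metadata_csv(records, files, directory / "metadata.csv")
    truth_table.to_csv(directory / "ground_truth.csv", index=False)
    h = simulated[0].series.traces["A"].load_height_m if simulated else float("nan")
    (directory / "manifest.txt").write_text(
        f"seed={seed}\nn_plants={len(simulated)}\nload_height_m={h}\n"
    )
    return directory
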