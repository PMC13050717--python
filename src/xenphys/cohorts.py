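"""End-to-end simulated-cohort analysis: generation through group metrics.

This module wires the generator to the full measurement pipeline the way
the study design prescribes: simulate a control cohort and derive the
pooled 3xSD threshold from it alone; apply that fixed threshold to every
cohort; report per-animal event counts, event amplitudes, integrated
0.01-1 Hz power, homotopic synchrony from the mixing model, and swim
velocity.  Per-animal seeds expand deterministically from one master
seed with fixed per-cohort offsets, so whole cohorts are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from xenphys import events as ev
from xenphys import locomotion as loco
from xenphys import spectral as sp
from xenphys.imaging import Trace
from xenphys.simulate import (
    COHORT_PRESETS,
    TRAJECTORY_PRESETS,
    CohortPreset,
    animal_seed,
    cohort_trace,
    mix_correlated_pair,
    simulate_trajectory,
)
from xenphys.synchrony import pearson_r

__all__ = [
    "SEED_OFFSETS",
    "CohortResult",
    "generate_cohort",
    "analyze_cohorts",
    "mixing_synchrony_cohort",
    "velocity_cohort",
    "recover_study_metrics",
]

#: Fixed per-cohort seed offsets (animal i of a block uses
#: master*10000 + offset + i + 1).
SEED_OFFSETS = {
    "control_traces": 0,
    "crispant_traces": 100,
    "mb_crispant": 200,
    "mb_control": 300,
    "fb_crispant": 400,
    "fb_control": 500,
    "trajectories": 600,
    "losartan_traces": 700,
}


@dataclass
class CohortResult:
    """Per-animal pipeline outputs for one simulated cohort."""

    name: str
    counts: np.ndarray
    mean_amplitudes: np.ndarray  # per-animal mean detected amplitude (NaN if no events)
    integrated_power: np.ndarray

    @property
    def n(self) -> int:
        return len(self.counts)


def generate_cohort(
    preset: CohortPreset, master_seed: int, offset: int, n: int | None = None
) -> list[Trace]:
    """Whole-brain traces for one cohort (trace-space mode)."""
    n = n or preset.n_animals
    return [
        cohort_trace(preset, animal_seed(master_seed, offset + i + 1))[0] for i in range(n)
    ]


def _analyze(
    name: str,
    traces: list[Trace],
    detector: ev.CalciumEventDetector,
) -> CohortResult:
    counts, amps, power = [], [], []
    for trace in traces:
        eventset = detector.predict(trace)
        count, mean_amp = ev.summarize_events(eventset)
        counts.append(count)
        amps.append(mean_amp)
        spec = sp.roi_power_spectrum(trace)
        power.append(sp.integrated_low_freq_power(sp.animal_mean_spectrum([spec])))
    return CohortResult(name, np.asarray(counts), np.asarray(amps), np.asarray(power))


def analyze_cohorts(master_seed: int = 0) -> dict[str, CohortResult]:
    """Simulate and analyze the three imaging cohorts under one threshold.

    The detector is fitted on the simulated control cohort only; the same
    fixed threshold is applied to the CRISPant and treated cohorts.
    """
    control = generate_cohort(
        COHORT_PRESETS["control"], master_seed, SEED_OFFSETS["control_traces"]
    )
    crispant = generate_cohort(
        COHORT_PRESETS["crispant"], master_seed, SEED_OFFSETS["crispant_traces"]
    )
    losartan = generate_cohort(
        COHORT_PRESETS["crispant_losartan"], master_seed, SEED_OFFSETS["losartan_traces"]
    )
    detector = ev.CalciumEventDetector().fit(control)
    return {
        "control": _analyze("control", control, detector),
        "crispant": _analyze("crispant", crispant, detector),
        "crispant_losartan": _analyze("crispant_losartan", losartan, detector),
    }


def mixing_synchrony_cohort(
    preset: CohortPreset, rho: float, master_seed: int, offset: int, n: int
) -> np.ndarray:
    """Per-animal Pearson r of left/right pairs from the mixing model."""
    out = np.empty(n)
    for i in range(n):
        seed = animal_seed(master_seed, offset + i + 1)
        shared, _ = cohort_trace(preset, seed)
        left, right = mix_correlated_pair(shared, rho, seed + 5_000)
        out[i] = pearson_r(left.values, right.values)
    return out


def velocity_cohort(master_seed: int, offset: int, n: int, preset_name: str) -> np.ndarray:
    """Per-animal mean swim velocity from simulated trajectories."""
    cfg = TRAJECTORY_PRESETS[preset_name]
    out = np.empty(n)
    for i in range(n):
        traj = simulate_trajectory(cfg, animal_seed(master_seed, offset + i + 1))
        out[i] = loco.locomotion_metrics(traj).mean_velocity_mm_s
    return out


def recover_study_metrics(master_seed: int = 0) -> dict[str, dict]:
    """All cohort-level recovery metrics as {name: {value, n}}.

    Values are on the scale the study reports: event counts per 30-min
    recording, amplitudes in ΔF/F₀%, integrated 0.01-1 Hz power in
    (ΔF/F₀)², Pearson r, and mm/s.
    """
    cohorts = analyze_cohorts(master_seed)
    control, crispant, losartan = (
        cohorts["control"], cohorts["crispant"], cohorts["crispant_losartan"]
    )

    mb_x = mixing_synchrony_cohort(
        COHORT_PRESETS["crispant"], COHORT_PRESETS["crispant"].synchrony.rho_homotopic_mb,
        master_seed, SEED_OFFSETS["mb_crispant"], 13,
    )
    mb_c = mixing_synchrony_cohort(
        COHORT_PRESETS["control"], COHORT_PRESETS["control"].synchrony.rho_homotopic_mb,
        master_seed, SEED_OFFSETS["mb_control"], 12,
    )
    fb_x = mixing_synchrony_cohort(
        COHORT_PRESETS["crispant"], COHORT_PRESETS["crispant"].synchrony.rho_homotopic_fb,
        master_seed, SEED_OFFSETS["fb_crispant"], 13,
    )
    fb_c = mixing_synchrony_cohort(
        COHORT_PRESETS["control"], COHORT_PRESETS["control"].synchrony.rho_homotopic_fb,
        master_seed, SEED_OFFSETS["fb_control"], 12,
    )
    vel = velocity_cohort(master_seed, SEED_OFFSETS["trajectories"], 11, "crispant_losartan")

    def entry(values: np.ndarray) -> dict:
        values = np.asarray(values, dtype=float)
        return {"value": float(np.nanmean(values)), "n": int(values.size)}

    return {
        "control_event_count": entry(control.counts),
        "crispant_event_count": entry(crispant.counts),
        "crispant_event_amplitude": entry(crispant.mean_amplitudes),
        "control_event_amplitude": entry(control.mean_amplitudes),
        "crispant_integrated_power": entry(crispant.integrated_power),
        "control_integrated_power": entry(control.integrated_power),
        "crispant_mb_synchrony": entry(mb_x),
        "control_mb_synchrony": entry(mb_c),
        "crispant_fb_synchrony": entry(fb_x),
        "control_fb_synchrony": entry(fb_c),
        "losartan_mean_velocity": entry(vel),
        "losartan_integrated_power": entry(losartan.integrated_power),
    }
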