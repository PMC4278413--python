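"""In-silico experiments on fitted CBF3 models.

Three discriminating analyses, all run on the fitted kinetic parameters:

* **peak phase** — the clock time of maximal CBF3 mRNA over the final
  simulated cycle, used to compare waveform phase across architectures and
  light regimes;
* **mutant fold change** — ratio of mutant to wild-type cycle-peak CBF3
  mRNA in constant light for clock-mutant genotypes (knockouts with
  configured knock-on amplitude effects), classified qualitatively;
* **cold gating profile** — the predicted time-of-day dependence of cold
  induction, simulated either as a transient rise of LHY/CCA1 protein
  (cold signalling through the clock, e.g. temperature-controlled CCA1
  splicing) or as a direct multiplication of the CBF3 transcript (a
  clock-independent cold pathway), applied at 4-h intervals across the
  subjective day.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .cbf_model import (
    ArchitectureSpec,
    CBFParameters,
    CBFTrajectory,
    integrate_production_decay,
    production_rate,
    simulate_cbf3,
    _substeps,
)
from .clock_driver import (
    GENOTYPES,
    REGIMES,
    WILD_TYPE,
    ClockTrajectory,
    Genotype,
    LightRegime,
    Waveform,
    simulate_clock,
)

__all__ = [
    "ArrhythmicTrajectoryError",
    "ClassThresholds",
    "MutantPrediction",
    "GatingProfile",
    "peak_phase",
    "simulate_fitted",
    "mutant_fold_change",
    "cold_gating_profile",
]


class ArrhythmicTrajectoryError(ValueError):
    """Raised when a phase is requested of an (effectively) flat trajectory."""


def peak_phase(traj: CBFTrajectory, regime: LightRegime | None = None) -> float:
    """Clock time (hours after dawn, in [0, 24)) of the mRNA maximum.

    Evaluated over the final full 24-h cycle of the trajectory, which must
    span at least two cycles beyond the discarded transient so that the
    final cycle is on the entrained orbit.  The grid argmax is refined by a
    parabolic fit through the three points around the maximum.  A flat
    trajectory (relative amplitude below 1e-9) raises
    :class:`ArrhythmicTrajectoryError` rather than returning a number.
    """
    times, mrna = np.asarray(traj.times), np.asarray(traj.mrna)
    if times[-1] - times[0] < 48.0:
        raise ValueError("trajectory must span at least two cycles")
    window = times > times[-1] - 24.0 + 1e-9
    t_win, c_win = times[window], mrna[window]
    cmax, cmin = float(np.max(c_win)), float(np.min(c_win))
    if cmax <= 0 or (cmax - cmin) < 1e-9 * cmax:
        raise ArrhythmicTrajectoryError("trajectory is arrhythmic (flat over the final cycle)")
    i = int(np.argmax(c_win))
    t_peak = t_win[i]
    if 0 < i < len(c_win) - 1:
        y0, y1, y2 = c_win[i - 1], c_win[i], c_win[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            t_peak = t_peak + 0.5 * (y0 - y2) / denom * (t_win[1] - t_win[0])
    return float(t_peak % 24.0)


def simulate_fitted(
    arch: ArchitectureSpec,
    params: CBFParameters,
    genotype: Genotype = WILD_TYPE,
    regime: LightRegime = REGIMES["24L/0D"],
    duration: float = 96.0,
    step: float = 0.25,
    waveforms: Mapping[str, Waveform] | None = None,
) -> CBFTrajectory:
    """Convenience wrapper: clock simulation followed by the CBF3 submodel."""
    clock = simulate_clock(regime, genotype, duration=duration, step=step, waveforms=waveforms)
    return simulate_cbf3(clock, arch, params)


@dataclass(frozen=True)
class ClassThresholds:
    """Fold-change boundaries for the qualitative mutant classes."""

    abolished_below: float = 0.05
    reduced_below: float = 0.5
    elevated_above: float = 2.0

    def classify(self, fold: float) -> str:
        if fold < self.abolished_below:
            return "abolished"
        if fold < self.reduced_below:
            return "reduced"
        if fold <= self.elevated_above:
            return "wild-type-like"
        return "elevated"


@dataclass(frozen=True)
class MutantPrediction:
    """Predicted CBF3 expression change in one clock-mutant background."""

    genotype: str
    fold_change: float
    qualitative_class: str
    mutant_arrhythmic: bool = False


def _final_cycle(traj: CBFTrajectory) -> np.ndarray:
    times = np.asarray(traj.times)
    return np.asarray(traj.mrna)[times > times[-1] - 24.0 + 1e-9]


def mutant_fold_change(
    arch: ArchitectureSpec,
    params: CBFParameters,
    genotype: Genotype,
    regime: LightRegime = REGIMES["24L/0D"],
    thresholds: ClassThresholds = ClassThresholds(),
    duration: float = 96.0,
    step: float = 0.25,
    waveforms: Mapping[str, Waveform] | None = None,
) -> MutantPrediction:
    """Mutant/wild-type ratio of cycle-peak CBF3 mRNA, constant light.

    Both genotypes are simulated with the same (wild-type-fitted) kinetic
    parameters.  An arrhythmic wild type is an error; an arrhythmic mutant
    is allowed, in which case its mean level over the final cycle stands in
    for the peak and the prediction is flagged.
    """
    wt = simulate_fitted(arch, params, WILD_TYPE, regime, duration, step, waveforms)
    wt_cycle = _final_cycle(wt)
    wt_peak = float(np.max(wt_cycle))
    if wt_peak <= 0 or (wt_peak - float(np.min(wt_cycle))) < 1e-9 * wt_peak:
        raise ArrhythmicTrajectoryError("wild-type trajectory is arrhythmic")
    mut = simulate_fitted(arch, params, genotype, regime, duration, step, waveforms)
    mut_cycle = _final_cycle(mut)
    mut_peak = float(np.max(mut_cycle))
    arrhythmic = mut_peak <= 0 or (mut_peak - float(np.min(mut_cycle))) < 1e-9 * mut_peak
    stat = float(np.mean(mut_cycle)) if arrhythmic else mut_peak
    fold = stat / wt_peak
    return MutantPrediction(
        genotype=genotype.label,
        fold_change=fold,
        qualitative_class=thresholds.classify(fold),
        mutant_arrhythmic=arrhythmic,
    )


def predict_mutants(
    arch: ArchitectureSpec,
    params: CBFParameters,
    genotypes: Sequence[Genotype] | None = None,
    **kwargs,
) -> list[MutantPrediction]:
    """Mutant predictions for a panel of genotypes (default: the built-ins)."""
    if genotypes is None:
        genotypes = [g for g in GENOTYPES.values() if g.label != "wild type"]
    return [mutant_fold_change(arch, params, g, **kwargs) for g in genotypes]


@dataclass(frozen=True)
class GatingProfile:
    """Cold-induction magnitude as a function of pulse time of day."""

    pulse_times: tuple[float, ...]
    induction: tuple[float, ...]
    mode: str
    fold: float
    normalised: bool
    statistic: str = "response"

    @property
    def peak_pulse_time(self) -> float:
        return float(self.pulse_times[int(np.argmax(self.induction))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pulse_zt_h": self.pulse_times,
                "induction": self.induction,
                "mode": self.mode,
                "fold": self.fold,
            }
        )


def cold_gating_profile(
    arch: ArchitectureSpec,
    params: CBFParameters,
    mode: str,
    fold: float = 5.0,
    pulse_times: Sequence[float] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0),
    pulse_duration_h: float = 4.0,
    observe_window_h: float = 4.0,
    normalise: bool = True,
    statistic: str = "response",
    step: float = 0.25,
    waveforms: Mapping[str, Waveform] | None = None,
) -> GatingProfile:
    """Simulated circadian gating of cold induction of CBF3.

    Runs in constant light (pulse times are hours after subjective dawn),
    after two settling cycles.  Modes:

    * ``"via_LHY"`` — the LHY/CCA1 protein abundance is multiplied by
      ``fold`` for ``pulse_duration_h`` hours from the pulse time (cold
      signalling through the clock);
    * ``"direct"`` — the CBF3 mRNA state is multiplied by ``fold`` at the
      pulse instant (clock-independent cold induction).

    The induction at each pulse time is taken over ``observe_window_h``
    hours from pulse onset, as either the ``"response"`` (default: maximum
    excess of the pulsed over the unperturbed trajectory, i.e. the part of
    the transcript attributable to the stimulus) or the ``"absolute"``
    maximum of the pulsed trajectory itself.  The absolute reading is
    bounded below by the ambient waveform's maximum in the window, so only
    the response reading discriminates the two cold-signalling modes at
    pulse times near the ambient peak.  With ``fold = 1`` the pulsed
    trajectory reproduces the unperturbed one bit-for-bit (zero response).
    """
    if mode not in ("via_LHY", "direct"):
        raise ValueError(f"mode must be 'via_LHY' or 'direct', got {mode!r}")
    if statistic not in ("response", "absolute"):
        raise ValueError(f"statistic must be 'response' or 'absolute', got {statistic!r}")
    if fold < 1:
        raise ValueError(f"fold must be at least 1, got {fold}")
    if pulse_duration_h > 24 or observe_window_h > 24:
        raise ValueError("pulse/observation windows must not exceed 24 h")
    settle = 48.0
    duration = settle + max(pulse_times) + max(pulse_duration_h, observe_window_h) + 1.0
    duration = 24.0 * np.ceil(duration / 24.0)
    clock = simulate_clock(
        REGIMES["24L/0D"], WILD_TYPE, duration=duration, step=step, waveforms=waveforms
    )
    m = _substeps(step)
    fine_t = np.linspace(clock.times[0], clock.times[-1], m * (len(clock.times) - 1) + 1)
    fine_dt = float(fine_t[1] - fine_t[0])
    species = {}
    for sp in arch.regulators:
        spline = CubicSpline(clock.times, clock.abundances[sp])
        species[sp] = np.clip(spline(fine_t), 0.0, None)
    p_ref = np.broadcast_to(
        np.asarray(production_rate(arch, params, species), dtype=float), fine_t.shape
    )
    c0 = float(p_ref[0] / params.d)
    c_ref = integrate_production_decay(p_ref, fine_dt, params.d, c0)

    inductions = []
    for zt in pulse_times:
        t_on = settle + float(zt)
        i_on = int(round((t_on - fine_t[0]) / fine_dt))
        i_obs = int(round((t_on + observe_window_h - fine_t[0]) / fine_dt))
        if mode == "via_LHY":
            i_off = int(round((t_on + pulse_duration_h - fine_t[0]) / fine_dt))
            pulsed = {sp: arr for sp, arr in species.items()}
            if "LHY_CCA1" in pulsed:
                boosted = pulsed["LHY_CCA1"].copy()
                boosted[i_on:i_off] *= fold
                pulsed["LHY_CCA1"] = boosted
            p = np.broadcast_to(
                np.asarray(production_rate(arch, params, pulsed), dtype=float), fine_t.shape
            )
            c = integrate_production_decay(p, fine_dt, params.d, c0)
        else:
            tail = integrate_production_decay(
                p_ref[i_on:], fine_dt, params.d, float(c_ref[i_on]) * fold
            )
            c = np.concatenate([c_ref[:i_on], tail])
        window = slice(i_on, i_obs + 1)
        if statistic == "response":
            inductions.append(float(np.max(c[window] - c_ref[window])))
        else:
            inductions.append(float(np.max(c[window])))
    induction = np.asarray(inductions)
    if normalise and induction.max() > 0:
        induction = induction / induction.max()
    return GatingProfile(
        pulse_times=tuple(float(z) for z in pulse_times),
        induction=tuple(float(v) for v in induction),
        mode=mode,
        fold=float(fold),
        normalised=bool(normalise),
        statistic=statistic,
    )
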