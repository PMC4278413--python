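"""Deterministic time courses of the circadian clock regulators that drive CBF3.

The CBF3 transcription submodel consumes protein-level waveforms of six clock
species: the merged morning factor LHY/CCA1, the day-phased pseudo-response
regulators PRR9, PRR7 and NI (the model proxy for PRR5), evening-expressed
TOC1, and the Evening Complex (EC, the LUX-ELF3-ELF4 complex).

Two driver modes are supported:

* **surrogate** (default, self-contained): each species is a smooth,
  strictly positive, 24-h periodic bump with configurable peak phase, width
  and amplitude.  Default phases encode the canonical ordering — LHY peaks
  in the early morning, PRR9/PRR7/NI peak in sequence through the day, TOC1
  peaks near dusk, and EC activity is high from late night across dawn and
  low in the afternoon.
* **SBML** (optional): an externally supplied clock ODE model can be
  integrated instead; see :mod:`cbf3select.sbml_driver`.

Genotypes (knockouts and amplitude modifiers) act on the surrogate waveforms
as configuration, not mechanism: a knocked-out species is identically zero,
and knock-on effects of a mutation on other species are expressed as
amplitude multipliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "SPECIES",
    "LightRegime",
    "REGIMES",
    "Genotype",
    "WILD_TYPE",
    "GENOTYPES",
    "Waveform",
    "DEFAULT_WAVEFORMS",
    "ClockTrajectory",
    "simulate_clock",
]

#: Identifiers of the six regulator species, in canonical order.
SPECIES: tuple[str, ...] = ("LHY_CCA1", "PRR9", "PRR7", "NI", "TOC1", "EC")


@dataclass(frozen=True)
class LightRegime:
    """A 24-h light/dark regime; dawn (lights-on) is time 0 of each cycle."""

    hours_light: float
    label: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.hours_light <= 24.0:
            raise ValueError(f"hours_light must lie in [0, 24], got {self.hours_light}")

    @property
    def constant_light(self) -> bool:
        return self.hours_light >= 24.0

    def lights_on(self, t: np.ndarray) -> np.ndarray:
        """Boolean light indicator at time(s) ``t`` (hours after dawn)."""
        return np.asarray(t) % 24.0 < self.hours_light


#: The four photoperiodic regimes used throughout: short days, equinox,
#: long days and constant light.
REGIMES: dict[str, LightRegime] = {
    "8L/16D": LightRegime(8.0, "8L/16D"),
    "12L/12D": LightRegime(12.0, "12L/12D"),
    "16L/8D": LightRegime(16.0, "16L/8D"),
    "24L/0D": LightRegime(24.0, "24L/0D"),
}


@dataclass(frozen=True)
class Genotype:
    """Clock genotype: knocked-out species and amplitude modifiers.

    ``knocked_out`` species have abundance identically zero.  ``modifiers``
    multiply the wild-type amplitude of a species (default 1 for unlisted
    species); they encode knock-on effects of a mutation on the rest of the
    clock without re-simulating the clock mechanism.
    """

    label: str = "wild type"
    knocked_out: frozenset[str] = frozenset()
    modifiers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp in self.knocked_out:
            if sp not in SPECIES:
                raise ValueError(f"unknown species in knockout set: {sp!r}")
        for sp, m in self.modifiers.items():
            if sp not in SPECIES:
                raise ValueError(f"unknown species in modifiers: {sp!r}")
            if m < 0:
                raise ValueError(f"modifier for {sp} must be non-negative, got {m}")

    def multiplier(self, species: str) -> float:
        """Net amplitude multiplier for one species (0 if knocked out)."""
        if species in self.knocked_out:
            return 0.0
        return float(self.modifiers.get(species, 1.0))


WILD_TYPE = Genotype()

#: Built-in mutant genotypes.  Knock-on effects mirror the clock circuitry:
#: the day-phased PRRs repress LHY/CCA1, so removing all three doubles the
#: LHY/CCA1 amplitude; lux (and elf3) mutants lack the EC and have low LHY
#: levels because the EC is required for normal LHY/CCA1 expression.
GENOTYPES: dict[str, Genotype] = {
    "wild type": WILD_TYPE,
    "lhy cca1": Genotype("lhy cca1", frozenset({"LHY_CCA1"})),
    "ni prr7 prr9": Genotype(
        "ni prr7 prr9",
        frozenset({"NI", "PRR7", "PRR9"}),
        {"LHY_CCA1": 2.0},
    ),
    "toc1": Genotype("toc1", frozenset({"TOC1"})),
    "lux": Genotype("lux", frozenset({"EC"}), {"LHY_CCA1": 0.3}),
}


@dataclass(frozen=True)
class Waveform:
    """One species' surrogate waveform: a circular (von-Mises-shaped) bump.

    ``x(t) = amplitude * exp(kappa * (cos(2*pi*(t - peak_zt)/24) - 1))``

    with ``kappa`` set from the full width at half maximum.  The waveform is
    exactly 24-h periodic, smooth, and strictly positive.
    """

    peak_zt: float
    fwhm_h: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fwhm_h < 24:
            raise ValueError(f"fwhm_h must lie in (0, 24), got {self.fwhm_h}")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")

    @property
    def kappa(self) -> float:
        return np.log(2.0) / (1.0 - np.cos(np.pi * self.fwhm_h / 24.0))

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.amplitude * np.exp(
            self.kappa * (np.cos(2.0 * np.pi * (t - self.peak_zt) / 24.0) - 1.0)
        )


#: Default surrogate waveforms.  Peak phases (h after dawn) encode the
#: narrated ordering: LHY early morning; PRR9, PRR7, NI in sequence through
#: the day; TOC1 near dusk; EC centred late at night with a width that keeps
#: its activity high across dawn and low through the afternoon.  The four
#: PRR-family waves (PRR9, PRR7, NI, TOC1) share a common 6-h width, the
#: broader LHY/CCA1 and EC waves an 8-h width; unequal widths for LHY/CCA1
#: and TOC1 also avoid a degeneracy of the circular bump form, under which
#: two antiphase waves of equal width satisfy ``x1(t) * x2(t) = const`` and
#: activation by one becomes exactly interchangeable with repression by the
#: other.
DEFAULT_WAVEFORMS: dict[str, Waveform] = {
    "LHY_CCA1": Waveform(peak_zt=1.0, fwhm_h=8.0),
    "PRR9": Waveform(peak_zt=3.0, fwhm_h=6.0),
    "PRR7": Waveform(peak_zt=6.0, fwhm_h=6.0),
    "NI": Waveform(peak_zt=9.0, fwhm_h=6.0),
    "TOC1": Waveform(peak_zt=13.0, fwhm_h=6.0),
    "EC": Waveform(peak_zt=23.0, fwhm_h=8.0),
}


@dataclass(frozen=True)
class ClockTrajectory:
    """Regulator abundances on a uniform time grid.

    ``abundances`` maps each species identifier to a non-negative array on
    ``times`` (hours after dawn of the first simulated cycle).  The
    pre-genotype baseline is retained so that genotype application is
    idempotent: applying the same genotype to an already-mutant trajectory
    re-derives it from the wild-type baseline.
    """

    times: np.ndarray
    abundances: Mapping[str, np.ndarray]
    regime: LightRegime
    genotype: Genotype = WILD_TYPE
    baseline: Mapping[str, np.ndarray] | None = None

    @property
    def step(self) -> float:
        return float(self.times[1] - self.times[0])

    def with_genotype(self, genotype: Genotype) -> "ClockTrajectory":
        """Trajectory with ``genotype`` applied to the wild-type baseline."""
        base = self.baseline if self.baseline is not None else self.abundances
        mutated = {sp: genotype.multiplier(sp) * base[sp] for sp in base}
        return replace(self, abundances=mutated, genotype=genotype, baseline=base)

    def to_frame(self):
        import pandas as pd

        data = {"time_h": self.times}
        data.update({sp: self.abundances[sp] for sp in SPECIES if sp in self.abundances})
        return pd.DataFrame(data)


def simulate_clock(
    regime: LightRegime,
    genotype: Genotype = WILD_TYPE,
    duration: float = 96.0,
    step: float = 0.25,
    waveforms: Mapping[str, Waveform] | None = None,
) -> ClockTrajectory:
    """Simulate the six clock regulators under a light regime and genotype.

    In surrogate mode the waveforms are prescribed functions of zeitgeber
    time, so every regime (including constant light, where the free-running
    period drift is out of scope) yields 24-h periodic trajectories with
    identical phases.  Genotypes zero out knocked-out species and scale the
    others multiplicatively.

    Parameters
    ----------
    regime : light/dark regime (period exactly 24 h; dawn at t = 0).
    genotype : knockouts and amplitude modifiers (default wild type).
    duration : simulated span in hours; at least 48 so that analyses can
        discard the first cycle as an entrainment transient.
    step : output grid spacing in hours; must divide 24 evenly.
    waveforms : per-species overrides of :data:`DEFAULT_WAVEFORMS`.
    """
    if duration < 48.0:
        raise ValueError(f"duration must be at least 48 h, got {duration}")
    n_per_day = 24.0 / step
    if abs(n_per_day - round(n_per_day)) > 1e-9:
        raise ValueError(f"step must evenly divide 24 h, got {step}")
    wf = dict(DEFAULT_WAVEFORMS)
    if waveforms:
        for sp in waveforms:
            if sp not in SPECIES:
                raise ValueError(f"unknown species in waveform overrides: {sp!r}")
        wf.update(waveforms)
    times = np.arange(0.0, duration + 0.5 * step, step)
    baseline = {sp: wf[sp](times) for sp in SPECIES}
    traj = ClockTrajectory(times=times, abundances=baseline, regime=regime, baseline=baseline)
    if genotype is not WILD_TYPE:
        traj = traj.with_genotype(genotype)
    return traj
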