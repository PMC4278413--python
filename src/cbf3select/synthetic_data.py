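"""Synthetic CBF3 expression time series.

Emulates the statistical structure of diurnal microarray measurements of
CBF3 mRNA: a sharp unimodal daily waveform peaking 8 h after dawn, a phase
that is robust across photoperiods and persists in constant light, plus
additive measurement noise.  The waveform is a raised-cosine bump of
configurable width on a low baseline; the noise is Gaussian, truncated at
zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .clock_driver import REGIMES, LightRegime

__all__ = [
    "TemplateShape",
    "DEFAULT_SHAPE",
    "ExpressionDataset",
    "cbf3_template",
    "generate_dataset",
    "default_sampling_times",
]


@dataclass(frozen=True)
class TemplateShape:
    """Shape of the noiseless daily CBF3 waveform.

    peak_zt : hours after dawn of the expression maximum.
    fwhm_h : full width at half maximum of the raised-cosine bump.
    baseline : expression floor as a fraction of the peak.
    peak : peak expression level (a.u.).
    """

    peak_zt: float = 8.0
    fwhm_h: float = 4.0
    baseline: float = 0.05
    peak: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.fwhm_h <= 24:
            raise ValueError("fwhm_h must lie in (0, 24]")
        if not 0 <= self.baseline < 1:
            raise ValueError("baseline must lie in [0, 1)")
        if self.peak <= 0:
            raise ValueError("peak must be positive")


DEFAULT_SHAPE = TemplateShape()


def cbf3_template(
    regime: LightRegime,
    t: np.ndarray | float,
    shape: TemplateShape = DEFAULT_SHAPE,
) -> np.ndarray:
    """Noiseless 24-h periodic CBF3 expression template.

    The peak phase is identical in every regime, including constant light —
    the defining experimental feature of the CBF3 waveform.  ``regime`` is
    accepted for interface symmetry and future photoperiod-dependent
    extensions.
    """
    del regime  # phase is photoperiod-robust by construction
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("sampling times must be non-negative")
    # circular distance to the peak, in (-12, 12]
    dt = (t - shape.peak_zt + 12.0) % 24.0 - 12.0
    half_support = shape.fwhm_h  # raised cosine: support = 2*FWHM
    bump = np.where(
        np.abs(dt) <= half_support,
        0.5 * (1.0 + np.cos(np.pi * dt / half_support)),
        0.0,
    )
    return shape.peak * (shape.baseline + (1.0 - shape.baseline) * bump)


@dataclass(frozen=True)
class ExpressionDataset:
    """Expression measurements for one light regime."""

    times: np.ndarray
    values: np.ndarray
    regime: LightRegime
    noise_sd: float
    seed: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")

    @property
    def n_points(self) -> int:
        return len(self.times)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"time_h": self.times, "expression": self.values})

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(
        cls, path: str | Path, regime: LightRegime, noise_sd: float = float("nan"), seed: int = -1
    ) -> "ExpressionDataset":
        import pandas as pd

        frame = pd.read_csv(path)
        return cls(
            times=frame["time_h"].to_numpy(float),
            values=frame["expression"].to_numpy(float),
            regime=regime,
            noise_sd=noise_sd,
            seed=seed,
        )


def default_sampling_times() -> np.ndarray:
    """Standard diurnal sampling design: every 4 h over two days."""
    return np.arange(0.0, 48.0 + 1e-9, 4.0)


def generate_dataset(
    regimes: Sequence[LightRegime] | None = None,
    times: np.ndarray | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
    shape: TemplateShape = DEFAULT_SHAPE,
) -> dict[str, ExpressionDataset]:
    """Generate one seeded expression dataset per regime.

    Values are the template plus independent Gaussian noise of standard
    deviation ``noise_sd`` (a.u., default 10% of the unit peak), truncated
    at zero.  Identical seed and settings reproduce the dataset exactly;
    each regime consumes an independent child stream of the seed.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if regimes is None:
        regimes = list(REGIMES.values())
    if times is None:
        times = default_sampling_times()
    times = np.asarray(times, dtype=float)
    datasets: dict[str, ExpressionDataset] = {}
    for i, regime in enumerate(regimes):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        clean = cbf3_template(regime, times, shape)
        noisy = clean + rng.normal(0.0, noise_sd, size=times.shape) if noise_sd > 0 else clean
        datasets[regime.label] = ExpressionDataset(
            times=times,
            values=np.clip(noisy, 0.0, None),
            regime=regime,
            noise_sd=noise_sd,
            seed=seed,
        )
    return datasets


def write_dataset_csvs(
    datasets: Mapping[str, ExpressionDataset], outdir: str | Path
) -> list[Path]:
    """Write one CSV per regime; slashes in regime labels become dashes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for label, ds in datasets.items():
        path = outdir / f"expression_{label.replace('/', '-')}.csv"
        ds.to_csv(path)
        paths.append(path)
    return paths
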