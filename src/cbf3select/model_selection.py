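"""Corrected-AIC scoring, Akaike weights, and ensemble ranking.

Residuals are treated as i.i.d. Gaussian with the variance profiled out of
the likelihood, giving the standard RSS form of the corrected Akaike
Information Criterion.  The profiled variance counts as one parameter, so a
model with ``k_free`` kinetic parameters carries ``k = k_free + 1`` in the
penalty.  Akaike weights convert score differences into relative model
probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fitting import FitResult

__all__ = ["aicc", "aicc_weights", "rank_ensemble", "SelectionRow", "SelectionTable"]


def aicc(rss: float, n_points: int, k_free: int) -> float:
    """Corrected AIC from a residual sum of squares.

    ``aicc = n ln(rss/n) + 2k + 2k(k+1)/(n - k - 1)`` with
    ``k = k_free + 1`` for the profiled residual variance.  Requires
    ``rss > 0`` and ``n_points > k + 1`` (otherwise the small-sample
    correction is undefined).
    """
    if rss <= 0:
        raise ValueError("rss must be positive for the Gaussian AICc")
    k = k_free + 1
    if n_points <= k + 1:
        raise ValueError(
            f"AICc undefined: need n_points > k_total + 1 (n={n_points}, k_total={k})"
        )
    score = n_points * np.log(rss / n_points) + 2 * k + 2 * k * (k + 1) / (n_points - k - 1)
    return float(score)


def aicc_weights(scores: Sequence[float]) -> np.ndarray:
    """Akaike weights: ``w_i = exp(-d_i/2) / sum_j exp(-d_j/2)``.

    ``d_i`` is the score difference to the best (lowest) model, so the
    computation is overflow-safe and invariant to adding a constant to all
    scores.  Infinite scores receive weight zero.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("at least one score is required")
    finite = np.isfinite(scores)
    if not np.any(finite):
        raise ValueError("at least one finite score is required")
    delta = scores - np.min(scores[finite])
    with np.errstate(over="ignore"):
        raw = np.where(finite, np.exp(-0.5 * delta), 0.0)
    return raw / raw.sum()


@dataclass(frozen=True)
class SelectionRow:
    rank: int
    label: str
    score: float
    weight: float
    fit: FitResult
    features: str = ""


@dataclass(frozen=True)
class SelectionTable:
    """Ensemble ranked by ascending AICc (low scores = favoured models)."""

    rows: tuple[SelectionRow, ...]

    def __iter__(self):
        return iter(self.rows)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def best(self) -> SelectionRow:
        return self.rows[0]

    def row_for(self, label: str) -> SelectionRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "rank": [r.rank for r in self.rows],
                "model": [r.label for r in self.rows],
                "aicc_score": [r.score for r in self.rows],
                "aicc_weight": [r.weight for r in self.rows],
                "rss": [r.fit.rss for r in self.rows],
                "k_free": [r.fit.k_free for r in self.rows],
                "features": [r.features for r in self.rows],
            }
        )

    def to_text(self) -> str:
        """Human-readable table (scores and weights to two decimals)."""
        lines = [f"{'Rank':<5}{'Model':<32}{'AICc score':>12}{'AICc weight':>13}  Features"]
        for r in self.rows:
            lines.append(
                f"{r.rank:<5}{r.label:<32}{r.score:>12.2f}{r.weight:>13.2f}  {r.features}"
            )
        return "\n".join(lines)


def rank_ensemble(fits: Sequence[FitResult], features: dict[str, str] | None = None) -> SelectionTable:
    """Score fitted architectures by AICc and rank them ascending.

    All fits must share the same pooled data-point count.  Ties in score
    are broken deterministically by architecture label; input order never
    affects the result.  ``features`` optionally annotates rows by label.
    """
    if not fits:
        raise ValueError("no fits to rank")
    n_points = {f.n_points for f in fits}
    if len(n_points) != 1:
        raise ValueError(f"fits mix different data sizes: {sorted(n_points)}")
    scored = [(aicc(f.rss, f.n_points, f.k_free), f.arch.label, f) for f in fits]
    scored.sort(key=lambda item: (item[0], item[1]))
    weights = aicc_weights([s for s, _, _ in scored])
    features = features or {}
    rows = tuple(
        SelectionRow(
            rank=i + 1,
            label=label,
            score=score,
            weight=float(w),
            fit=fit,
            features=features.get(label, ""),
        )
        for i, ((score, label, fit), w) in enumerate(zip(scored, weights))
    )
    return SelectionTable(rows=rows)
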