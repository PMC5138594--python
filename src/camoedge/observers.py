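"""Synthetic observers: behavioural data with the structure the analysis assumes.

Human participants searched a wall-sized display for the camouflaged snake;
here a simple generative stand-in produces reaction times and errors (for
the search experiments) and ordinal depth judgements (for the
depth-judgement experiment) so the statistical pipeline can be exercised
and validated by parameter recovery.

Search model: log reaction time is participant intercept + condition effect
+ Gaussian noise, i.e. RTs are log-normal with additive effects on the log
scale — exactly the regime the analysis's log transform and per-participant
z-scoring assume, so the null case is literally true under the null model.
Errors become more likely on slow trials (positive RT–error coupling, the
pattern reported for human observers), and error trials are later discarded
by the analysis.

Depth model: an ordinal-probit response — a unit-variance Gaussian latent
judgement around a per-condition shift, cut at two thresholds into
"flatter" (−1), "same" (0), "more relief" (+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .designs import TrialSpec

__all__ = ["ObserverModel", "ConfigurationError", "simulate_rt_dataset",
           "simulate_depth_dataset", "depth_response_mean"]


class ConfigurationError(ValueError):
    """Raised when the observer model does not cover the design."""


@dataclass
class ObserverModel:
    """Generative parameters of the synthetic search observer.

    ``condition_effects`` maps edge-condition labels (``EdgeProfile.label``)
    to additive log-RT shifts; every condition present in the design must
    have an entry (0.0 allowed).  Intercepts are per-participant mean log
    RTs in log-seconds: the defaults centre on ≈5 s searches
    (``intercept_mean = log 5``) with 35% between-participant spread and
    20% trial-to-trial RT variability, the order of magnitude expected for
    an effortful search over a very large display.  ``error_base`` is the
    error probability on a typical-speed trial and ``error_slope`` its
    increase per log-RT unit above the participant's mean, coupling errors
    to slow searches.
    """

    n_participants: int = 10
    intercept_mean: float = float(np.log(5.0))
    intercept_sd: float = 0.35
    participant_sd: float = 0.20
    condition_effects: dict[str, float] = field(default_factory=dict)
    error_base: float = 0.05
    error_slope: float = 0.10

    def __post_init__(self) -> None:
        if self.participant_sd <= 0 or self.intercept_sd < 0:
            raise ValueError("spreads must be positive")
        if not 0.0 <= self.error_base <= 1.0:
            raise ValueError("error_base must be a probability")


def simulate_rt_dataset(
    design: list[TrialSpec],
    model: ObserverModel,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate all participants through a search design.

    Returns one row per participant × trial with columns participant,
    trial, variant, offset, width, edge (condition label), shadows, rt
    (seconds), correct.  Deterministic under ``rng``.
    """
    labels = {t.condition.edge.label for t in design}
    missing = labels - set(model.condition_effects)
    if missing:
        raise ConfigurationError(
            f"no condition effect for {sorted(missing)}; use 0.0 explicitly"
        )
    intercepts = rng.normal(
        model.intercept_mean, model.intercept_sd, model.n_participants
    )
    rows = []
    for p in range(model.n_participants):
        for t in design:
            edge = t.condition.edge
            log_rt = (
                intercepts[p]
                + model.condition_effects[edge.label]
                + rng.normal(0.0, model.participant_sd)
            )
            p_err = float(
                np.clip(
                    model.error_base
                    + model.error_slope * (log_rt - intercepts[p]),
                    0.0,
                    1.0,
                )
            )
            rows.append(
                {
                    "participant": p,
                    "trial": t.index,
                    "variant": edge.variant,
                    "offset": edge.offset,
                    "width": edge.width,
                    "edge": edge.label,
                    "shadows": t.condition.shadows,
                    "rt": float(np.exp(log_rt)),
                    "correct": bool(rng.random() >= p_err),
                }
            )
    return pd.DataFrame(rows)


def simulate_depth_dataset(
    design: list[TrialSpec],
    shift: dict[str, float],
    thresholds: tuple[float, float],
    rng: np.random.Generator,
    n_participants: int = 10,
) -> pd.DataFrame:
    """Simulate ordinal depth judgements for a depth-judgement design.

    ``shift`` maps edge-condition labels to the latent mean judged-relief
    advantage; the unit-variance latent is cut at ``thresholds = (low,
    high)`` into coded responses −1 / 0 / +1.
    """
    low, high = thresholds
    if not low < high:
        raise ValueError("thresholds must satisfy low < high")
    labels = {t.condition.edge.label for t in design}
    missing = labels - set(shift)
    if missing:
        raise ConfigurationError(f"no latent shift for {sorted(missing)}")
    rows = []
    for p in range(n_participants):
        for t in design:
            edge = t.condition.edge
            latent = rng.normal(shift[edge.label], 1.0)
            response = -1 if latent < low else (0 if latent <= high else 1)
            rows.append(
                {
                    "participant": p,
                    "trial": t.index,
                    "variant": edge.variant,
                    "offset": edge.offset,
                    "width": edge.width,
                    "edge": edge.label,
                    "shadows": t.condition.shadows,
                    "depth_response": response,
                }
            )
    return pd.DataFrame(rows)


def depth_response_mean(
    shift: float, thresholds: tuple[float, float]
) -> float:
    """Closed-form expected coded response of the ordinal-probit model.

    E[resp] = P(latent > high) − P(latent < low) for latent ~ N(shift, 1);
    the independent check for :func:`simulate_depth_dataset`.
    """
    from scipy.stats import norm

    low, high = thresholds
    return float(norm.sf(high - shift) - norm.cdf(low - shift))
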