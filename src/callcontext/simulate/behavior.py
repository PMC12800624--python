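"""Behavioral trial-table generator for the playback experiment.

Given a playback design, emits one row per session with gaze counts and
self-directed-behavior (SDB) counts before/after the stimulus and a
binary yawn response within the 3-minute post-stimulus window, under the
generating model the downstream mixed models assume:

* gaze: zero-inflated Poisson on the log scale with subject random
  intercept; by default the after-count is before + a ZIP draw, so the
  after-minus-before difference is exactly the ZIP variate (a switch
  emits raw differences that can go negative instead);
* yawn: Bernoulli on the logit scale with subject random intercept,
  mixed with a spontaneous-yawning floor 1 - exp(-rate * 3 min) so the
  evoked probability never drops below what idle animals produce anyway.

Coefficient defaults are the fitted fixed effects a field study of this
design reported, so simulations run at realistic effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .stimuli import PlaybackDesign

__all__ = ["BehavioralGenConfig", "TRIAL_COLUMNS", "generate_behavioral_dataset"]

#: dummy coding: sex male=1; receiver_context social=1; trigger baseline is
#: high_social with low/non/grunt dummies; trial_order enters linearly.
GAZE_TERMS = ("intercept", "sex_male", "receiver_social", "trigger_low", "trigger_non", "trigger_grunt", "trial_order")
YAWN_TERMS = GAZE_TERMS

TRIAL_COLUMNS = (
    "subject_id",
    "sex",
    "trial_order",
    "receiver_context",
    "trigger_context",
    "gazes_before",
    "gazes_after",
    "sdb_before",
    "sdb_after",
    "yawn_before",
    "yawn_after",
)


@dataclass(frozen=True)
class BehavioralGenConfig:
    """Effect sizes for the trial generator (log / logit scales)."""

    beta_gaze: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": 1.192,
            "sex_male": 0.331,
            "receiver_social": -0.095,
            "trigger_low": 0.162,
            "trigger_non": -0.938,
            "trigger_grunt": -0.938,
            "trial_order": -0.184,
        }
    )
    beta_yawn: Mapping[str, float] = field(
        default_factory=lambda: {
            "intercept": -1.786,
            "sex_male": -1.799,
            "receiver_social": 3.162,
            "trigger_low": -1.861,
            "trigger_non": -2.042,
            "trigger_grunt": -3.5,
            "trial_order": -0.184,
        }
    )
    zi_prob: float = 0.15
    sigma_subject: float = 0.19
    spontaneous_yawn_rate_per_min: float = 0.25
    gaze_before_mean: float = 1.0
    sdb_mean: float = 0.8

    def __post_init__(self) -> None:
        if not (0 <= self.zi_prob < 1):
            raise ValueError("zi_prob must lie in [0, 1)")
        if self.sigma_subject < 0:
            raise ValueError("sigma_subject must be nonnegative")
        if self.spontaneous_yawn_rate_per_min < 0:
            raise ValueError("spontaneous yawn rate must be nonnegative")
        for terms, betas in ((GAZE_TERMS, self.beta_gaze), (YAWN_TERMS, self.beta_yawn)):
            missing = set(terms) - set(betas)
            if missing:
                raise ValueError(f"missing coefficients: {sorted(missing)}")


def _design_row(sex: str, receiver: str, trigger: str, order: int) -> dict[str, float]:
    return {
        "intercept": 1.0,
        "sex_male": 1.0 if sex == "male" else 0.0,
        "receiver_social": 1.0 if receiver == "social" else 0.0,
        "trigger_low": 1.0 if trigger == "low_social" else 0.0,
        "trigger_non": 1.0 if trigger == "non_social" else 0.0,
        "trigger_grunt": 1.0 if trigger == "grunt" else 0.0,
        "trial_order": float(order),
    }


def _linpred(x: Mapping[str, float], beta: Mapping[str, float]) -> float:
    return float(sum(beta[k] * x[k] for k in beta))


def generate_behavioral_dataset(
    design: PlaybackDesign,
    config: BehavioralGenConfig | None = None,
    seed: int = 0,
    gaze_mode: Literal["floor0", "raw"] = "floor0",
) -> pd.DataFrame:
    """Simulate coded video responses for every session in ``design``.

    ``gaze_mode="floor0"`` (default): gazes_after = gazes_before + Z with
    Z ~ ZIP, so the difference is the nonnegative ZIP variate itself.
    ``gaze_mode="raw"``: gazes_after ~ ZIP around its own mean and the
    difference can be negative.
    """
    config = config or BehavioralGenConfig()
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    sex_map = dict(zip(design.subjects["subject_id"], design.subjects["sex"]))

    # one random intercept per subject per response process
    subject_ids = list(design.subjects["subject_id"])
    b_gaze = {s: rng.normal(0.0, config.sigma_subject) for s in subject_ids}
    b_yawn = {s: rng.normal(0.0, config.sigma_subject) for s in subject_ids}

    floor = 1.0 - np.exp(-config.spontaneous_yawn_rate_per_min * 3.0)
    rows = []
    for r in design.sessions.itertuples(index=False):
        sex = sex_map[r.subject_id]
        x = _design_row(sex, r.receiver_context, r.condition, r.trial_order)

        lam = np.exp(_linpred(x, config.beta_gaze) + b_gaze[r.subject_id])
        zip_draw = 0 if rng.random() < config.zi_prob else int(rng.poisson(lam))
        before = int(rng.poisson(config.gaze_before_mean))
        if gaze_mode == "floor0":
            after = before + zip_draw
        elif gaze_mode == "raw":
            after = zip_draw
        else:
            raise ValueError(f"unknown gaze_mode {gaze_mode!r}")

        sdb_before = int(rng.poisson(config.sdb_mean))
        sdb_after = int(rng.poisson(config.sdb_mean))

        eta = _linpred(x, config.beta_yawn) + b_yawn[r.subject_id]
        p_evoked = 1.0 / (1.0 + np.exp(-eta))
        p_yawn = 1.0 - (1.0 - p_evoked) * (1.0 - floor)
        rows.append(
            {
                "subject_id": r.subject_id,
                "sex": sex,
                "trial_order": int(r.trial_order),
                "receiver_context": r.receiver_context,
                "trigger_context": r.condition,
                "gazes_before": before,
                "gazes_after": int(after),
                "sdb_before": sdb_before,
                "sdb_after": sdb_after,
                "yawn_before": int(rng.random() < floor),
                "yawn_after": int(rng.random() < p_yawn),
            }
        )
    return pd.DataFrame(rows, columns=list(TRIAL_COLUMNS))
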