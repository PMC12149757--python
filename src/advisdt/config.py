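"""Configuration objects for the two-session advised-classification experiment.

The default configuration mirrors a two-session Wizard-of-Oz study design:
an unadvised baseline session of 216 binary classification trials, followed
by an advised session of 9 blocks x 24 trials in which the mock "AI" advice
is correct with a blocked Bernoulli probability -- 0.9 in the three pre-error
and three post-error blocks, degrading block-wise through 0.75, 0.6, 0.45
during the error phase.  Trust/distrust/use self-reports are queried five
times, after blocks 2, 4, 6, 8 and 9.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, Field, model_validator

Phase = Literal["pre-error", "error", "post-error"]
Condition = Literal["distrust", "information-only"]

CONDITIONS: tuple[Condition, Condition] = ("distrust", "information-only")

DEFAULT_BLOCKS: tuple[tuple[int, float], ...] = (
    (24, 0.9),
    (24, 0.9),
    (24, 0.9),
    (24, 0.75),
    (24, 0.6),
    (24, 0.45),
    (24, 0.9),
    (24, 0.9),
    (24, 0.9),
)

DEFAULT_PHASES: tuple[Phase, ...] = (
    "pre-error", "pre-error", "pre-error",
    "error", "error", "error",
    "post-error", "post-error", "post-error",
)

# self-reports are taken after every second block plus after the final block
DEFAULT_SELFREPORT_BLOCKS: tuple[int, ...] = (2, 4, 6, 8, 9)


class BlockSpec(BaseModel):
    """One advised block: its length and the advice-correctness probability."""

    n_trials: int = Field(gt=0)
    p_correct_advice: float = Field(ge=0.0, le=1.0)


class ExperimentConfig(BaseModel):
    """Full description of one simulated two-session experiment."""

    n_participants_per_condition: int = Field(default=66, gt=0)
    # odd cohort sizes (e.g. the 131-participant study scale) cannot be
    # expressed per condition; when set, this overrides the total and the
    # split is as balanced as possible (distrust gets the extra participant)
    n_participants_total: int | None = Field(default=None, gt=1)
    n_trials_session1: int = Field(default=216, gt=0)
    blocks_session2: tuple[BlockSpec, ...] = tuple(
        BlockSpec(n_trials=n, p_correct_advice=p) for n, p in DEFAULT_BLOCKS
    )
    phase_labels: tuple[Phase, ...] = DEFAULT_PHASES
    signal_proportion: float = Field(default=0.5, ge=0.0, le=1.0)
    selfreport_timepoints: tuple[int, ...] = DEFAULT_SELFREPORT_BLOCKS
    rng_seed: int = 0

    @model_validator(mode="after")
    def _check_structure(self) -> "ExperimentConfig":
        if len(self.phase_labels) != len(self.blocks_session2):
            raise ValueError(
                f"{len(self.phase_labels)} phase labels for "
                f"{len(self.blocks_session2)} blocks"
            )
        # phases must partition the blocks into three contiguous runs
        order = [p for i, p in enumerate(self.phase_labels)
                 if i == 0 or p != self.phase_labels[i - 1]]
        if order != ["pre-error", "error", "post-error"]:
            raise ValueError(
                "phase labels must form contiguous pre-error, error, "
                f"post-error runs, got {self.phase_labels}"
            )
        if len(self.selfreport_timepoints) != 5:
            raise ValueError("exactly 5 self-report time points are required")
        n_blocks = len(self.blocks_session2)
        for b in self.selfreport_timepoints:
            if not 1 <= b <= n_blocks:
                raise ValueError(f"self-report block index {b} out of range")
        if list(self.selfreport_timepoints) != sorted(set(self.selfreport_timepoints)):
            raise ValueError("self-report block indices must be strictly increasing")
        return self

    @property
    def n_trials_session2(self) -> int:
        return sum(b.n_trials for b in self.blocks_session2)

    @property
    def n_participants(self) -> int:
        if self.n_participants_total is not None:
            return self.n_participants_total
        return 2 * self.n_participants_per_condition

    @property
    def condition_sizes(self) -> dict[str, int]:
        n = self.n_participants
        return {"distrust": n - n // 2, "information-only": n // 2}


class ProfileDistribution(BaseModel):
    """Population distribution the simulator draws participant profiles from.

    Sensitivity and bias are on the usual equal-variance SDT scale (d' in
    standard-deviation units of the latent evidence axis, c the distance of
    the decision criterion from the unbiased point).  The adoption weight is
    the probability of deferring to the advice when it conflicts with the
    participant's own judgment; it is drawn from a Beta distribution
    parameterised by its mean and concentration.  Self-report baselines live
    on the latent 1-7 Likert scale.
    """

    dprime_mean: float = 0.95
    dprime_sd: float = Field(default=0.8, ge=0.0)
    practice_gain_mean: float = 0.0
    practice_gain_sd: float = Field(default=0.0, ge=0.0)
    criterion_mean: float = 0.0
    criterion_sd: float = Field(default=0.3, ge=0.0)
    adoption_mean: float = Field(default=0.5, gt=0.0, lt=1.0)
    adoption_concentration: float = Field(default=10.0, gt=0.0)
    trust_baseline_mean: float = Field(default=4.5, ge=1.0, le=7.0)
    distrust_baseline_mean: float = Field(default=3.0, ge=1.0, le=7.0)
    baseline_sd: float = Field(default=0.8, ge=0.0)
    error_shift_mean: float = 0.8
    error_shift_sd: float = Field(default=0.3, ge=0.0)
    selfreport_noise_sd: float = Field(default=0.6, ge=0.0)
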