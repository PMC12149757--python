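"""Synthetic two-session advised-classification experiment.

Generates trial tables, repeated self-reports and the ground-truth
participant parameters that produced them, so that every downstream stage
(SDT inference, reliance metrics, mixed regression) can be exercised and
validated by parameter recovery without any external data.

Generative model
----------------
Each participant is an equal-variance Gaussian SDT observer: on a trial with
true category ``signal`` the latent evidence is Normal(+d'/2, 1), on a
``noise`` trial Normal(-d'/2, 1), and the observer responds "signal" whenever
the evidence exceeds the criterion c.  This is exactly the inverse of the
reparametrisation h = Phi(d'/2 - c), f = Phi(-d'/2 - c) used by the
inference module.  When advice is shown and conflicts with the observer's
own judgment, the advice is adopted with probability ``adoption_weight``;
agreeing advice never changes the response.

Self-reports follow a latent step trajectory: baseline at time points 1-2,
then a persistent shift from time point 3 on (downward for trust, upward
for distrust), mirroring the asymmetry by which trust, once lost during a
phase of bad advice, does not recover.  The "use" control item dips at time
point 3 only and recovers.  Latent values receive Gaussian noise and are
rounded and clamped to the 1..7 Likert scale.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .config import CONDITIONS, Condition, ExperimentConfig, ProfileDistribution

TRIAL_COLUMNS = [
    "participant_id", "condition", "session", "block_index", "trial_index",
    "phase", "stimulus_id", "true_category", "advice_shown", "advice_correct",
    "response", "response_correct",
]

REPORT_COLUMNS = ["participant_id", "condition", "timepoint", "item", "rating"]

SELFREPORT_ITEMS = ("trust", "distrust", "use")


@dataclass(frozen=True)
class ParticipantProfile:
    """Ground-truth latent parameters of one simulated participant."""

    participant_id: str
    condition: Condition
    true_dprime_s1: float
    true_dprime_s2_own: float
    true_criterion: float
    adoption_weight: float
    trust_baseline: float
    distrust_baseline: float
    use_baseline: float
    selfreport_error_shift: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.adoption_weight <= 1.0:
            raise ValueError(f"adoption_weight {self.adoption_weight} not in [0, 1]")
        for name in ("trust_baseline", "distrust_baseline", "use_baseline"):
            v = getattr(self, name)
            if not 1.0 <= v <= 7.0:
                raise ValueError(f"{name} {v} outside the latent 1..7 range")

    def to_dict(self) -> dict:
        return asdict(self)


def sample_advice_schedule(config: ExperimentConfig, rng_seed: int) -> np.ndarray:
    """Draw per-trial advice-correctness flags for the advised session.

    Within each block the flags are independent Bernoulli draws with that
    block's correctness probability.  Returns one boolean per Session-2
    trial, in trial order.
    """
    rng = np.random.default_rng(rng_seed)
    flags = [
        rng.random(block.n_trials) < block.p_correct_advice
        for block in config.blocks_session2
    ]
    return np.concatenate(flags)


def simulate_response(
    dprime: float,
    criterion: float,
    true_category: np.ndarray,
    advice_shown: np.ndarray,
    adoption_weight: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorised two-stage response: SDT judgment, then advice adoption.

    ``true_category`` and ``advice_shown`` are arrays of "signal"/"noise"
    labels; ``advice_shown`` may contain "none" for unadvised trials.
    """
    true_category = np.asarray(true_category)
    advice_shown = np.asarray(advice_shown)
    n = true_category.shape[0]
    mean = np.where(true_category == "signal", dprime / 2.0, -dprime / 2.0)
    evidence = rng.normal(mean, 1.0)
    own = np.where(evidence > criterion, "signal", "noise")

    advised = advice_shown != "none"
    conflict = advised & (advice_shown != own)
    adopt = conflict & (rng.random(n) < adoption_weight)
    return np.where(adopt, advice_shown, own)


def simulate_self_reports(
    profile: ParticipantProfile,
    config: ExperimentConfig,
    rng: np.random.Generator,
    noise_sd: float,
) -> list[dict]:
    """Five trust/distrust/use ratings following the latent step trajectory."""
    records = []
    shift = profile.selfreport_error_shift
    for t in range(1, 6):
        after_error = t >= 3
        latent = {
            "trust": profile.trust_baseline - (shift if after_error else 0.0),
            "distrust": profile.distrust_baseline + (shift if after_error else 0.0),
            # "use" dips during the bad-advice phase only and recovers
            "use": profile.use_baseline - (shift if t == 3 else 0.0),
        }
        for item in SELFREPORT_ITEMS:
            value = latent[item] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            rating = int(np.clip(np.rint(value), 1, 7))
            records.append({
                "participant_id": profile.participant_id,
                "condition": profile.condition,
                "timepoint": t,
                "item": item,
                "rating": rating,
            })
    return records


def sample_profiles(
    config: ExperimentConfig,
    dist: ProfileDistribution,
    rng: np.random.Generator,
) -> list[ParticipantProfile]:
    """Draw participant profiles, balanced across the two conditions."""
    profiles = []
    sizes = config.condition_sizes
    width = len(str(config.n_participants))
    assignment = np.concatenate([np.repeat(c, sizes[c]) for c in CONDITIONS])
    rng.shuffle(assignment)
    a = dist.adoption_mean * dist.adoption_concentration
    b = (1.0 - dist.adoption_mean) * dist.adoption_concentration
    for i, cond in enumerate(assignment):
        d1 = rng.normal(dist.dprime_mean, dist.dprime_sd)
        gain = (
            rng.normal(dist.practice_gain_mean, dist.practice_gain_sd)
            if (dist.practice_gain_sd > 0 or dist.practice_gain_mean != 0.0)
            else 0.0
        )
        profiles.append(ParticipantProfile(
            participant_id=f"p{i + 1:0{width}d}",
            condition=cond,
            true_dprime_s1=d1,
            true_dprime_s2_own=d1 + gain,
            true_criterion=rng.normal(dist.criterion_mean, dist.criterion_sd),
            adoption_weight=float(rng.beta(a, b)),
            trust_baseline=float(np.clip(
                rng.normal(dist.trust_baseline_mean, dist.baseline_sd), 1, 7)),
            distrust_baseline=float(np.clip(
                rng.normal(dist.distrust_baseline_mean, dist.baseline_sd), 1, 7)),
            use_baseline=float(np.clip(
                rng.normal(dist.trust_baseline_mean, dist.baseline_sd), 1, 7)),
            selfreport_error_shift=float(rng.normal(
                dist.error_shift_mean, dist.error_shift_sd)),
        ))
    return profiles


def _stimulus_truth(config: ExperimentConfig, rng: np.random.Generator) -> np.ndarray:
    """Fixed truth labels for the shared stimulus pool (exact 50/50 split)."""
    n = config.n_trials_session1
    n_signal = round(n * config.signal_proportion)
    truth = np.array(["signal"] * n_signal + ["noise"] * (n - n_signal))
    rng.shuffle(truth)
    return truth


def _session2_order(
    truth: np.ndarray, config: ExperimentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Stimulus presentation order for Session 2, truth-balanced per block.

    Signal and noise stimuli are shuffled separately and dealt into blocks in
    proportion to the block length, then shuffled within block, so each block
    sees (near-)exact category balance; small-cell counts in the per-block
    analyses stay stable.
    """
    sig = rng.permutation(np.flatnonzero(truth == "signal"))
    noi = rng.permutation(np.flatnonzero(truth == "noise"))
    order = []
    si = ni = 0
    for block in config.blocks_session2:
        k_sig = min(block.n_trials // 2, len(sig) - si)
        k_noi = block.n_trials - k_sig
        chunk = np.concatenate([sig[si:si + k_sig], noi[ni:ni + k_noi]])
        si += k_sig
        ni += k_noi
        rng.shuffle(chunk)
        order.append(chunk)
    return np.concatenate(order)


def simulate_experiment(
    config: ExperimentConfig,
    dist: ProfileDistribution | None = None,
    rng_seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[ParticipantProfile]]:
    """Generate one complete synthetic dataset.

    Returns ``(trials, self_reports, profiles)``.  Both sessions present the
    same 216 stimulus identities per participant (the pairing the switch
    percentage requires), in independently shuffled orders.  Fully
    reproducible for a fixed config and seed.
    """
    if dist is None:
        dist = ProfileDistribution()
    if config.n_trials_session2 != config.n_trials_session1:
        raise ValueError(
            f"Session 2 blocks sum to {config.n_trials_session2} trials but "
            f"Session 1 has {config.n_trials_session1}; the two sessions must "
            "present the same stimulus set"
        )
    seed = config.rng_seed if rng_seed is None else rng_seed
    root = np.random.SeedSequence(seed)
    profile_rng = np.random.default_rng(root.spawn(1)[0])
    profiles = sample_profiles(config, dist, profile_rng)

    block_of_trial = np.concatenate([
        np.full(b.n_trials, i) for i, b in enumerate(config.blocks_session2)
    ])
    phase_of_trial = np.array([config.phase_labels[b] for b in block_of_trial])

    trial_frames = []
    report_records: list[dict] = []
    for profile, child in zip(profiles, root.spawn(len(profiles) + 1)[1:]):
        rng = np.random.default_rng(child)
        truth = _stimulus_truth(config, rng)
        stim_ids = np.array([f"s{j + 1:03d}" for j in range(len(truth))])

        # --- Session 1: unadvised ---
        order1 = rng.permutation(len(truth))
        truth1 = truth[order1]
        none1 = np.full(len(truth1), "none")
        resp1 = simulate_response(
            profile.true_dprime_s1, profile.true_criterion,
            truth1, none1, profile.adoption_weight, rng,
        )
        n1 = len(truth1)
        block_len1 = 27 if n1 % 27 == 0 else n1
        trial_frames.append(pd.DataFrame({
            "participant_id": profile.participant_id,
            "condition": profile.condition,
            "session": 1,
            "block_index": np.arange(n1) // block_len1 + 1,
            "trial_index": np.arange(1, n1 + 1),
            "phase": "none",
            "stimulus_id": stim_ids[order1],
            "true_category": truth1,
            "advice_shown": "none",
            "advice_correct": "n/a",
            "response": resp1,
            "response_correct": resp1 == truth1,
        }))

        # --- Session 2: advised ---
        order2 = _session2_order(truth, config, rng)
        truth2 = truth[order2]
        correct_flags = sample_advice_schedule(
            config, int(rng.integers(0, 2**31 - 1)))
        other = np.where(truth2 == "signal", "noise", "signal")
        advice = np.where(correct_flags, truth2, other)
        resp2 = simulate_response(
            profile.true_dprime_s2_own, profile.true_criterion,
            truth2, advice, profile.adoption_weight, rng,
        )
        trial_frames.append(pd.DataFrame({
            "participant_id": profile.participant_id,
            "condition": profile.condition,
            "session": 2,
            "block_index": block_of_trial + 1,
            "trial_index": np.arange(1, len(truth2) + 1),
            "phase": phase_of_trial,
            "stimulus_id": stim_ids[order2],
            "true_category": truth2,
            "advice_shown": advice,
            "advice_correct": np.where(correct_flags, "true", "false"),
            "response": resp2,
            "response_correct": resp2 == truth2,
        }))

        report_records.extend(
            simulate_self_reports(profile, config, rng, dist.selfreport_noise_sd)
        )

    trials = pd.concat(trial_frames, ignore_index=True)[TRIAL_COLUMNS]
    reports = pd.DataFrame(report_records)[REPORT_COLUMNS]
    return trials, reports, profiles
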