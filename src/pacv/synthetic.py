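"""Synthetic repeated-measures data with participant random effects.

The generator emulates the structure of a hop-test cohort: 72 participants,
a participant-constant binary label split 36/36, 5–10 trials each, and —
in signal mode — 48 smooth per-trial waveforms. Features follow the
additive random-effects model

    x_pt = y_p * beta + u_p + eps_pt,

with a participant signature ``u_p ~ N(0, sigma_p^2 I)`` drawn once per
participant, trial noise ``eps_pt ~ N(0, sigma_e^2 I)``, and a class shift
``delta`` on the first ``n_informative`` coordinates. The intraclass
correlation ICC = sigma_p^2 / (sigma_p^2 + sigma_e^2) governs how much a
trial betrays the participant's identity — and hence how severely trial-wise
cross-validation inflates accuracy. This is the minimal model in which the
effective sample size is the participant count rather than the trial count,
which is exactly the phenomenon the toolkit quantifies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .data import TrialTable


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-shaped generator settings.

    Defaults mirror the emulated cohort: 72 participants, 36 labeled 1
    ("high fear"), 5–10 trials per participant, and in signal mode 48
    waveforms per trial with raw lengths 80–160 before time normalization.

    ``class_effect`` (delta) is the mean shift per informative feature;
    ``participant_sd`` (sigma_p) and ``noise_sd`` (sigma_e) set the
    between-participant and within-participant standard deviations. With the
    defaults sigma_p = sigma_e = 1 the ICC is 0.5.
    """

    n_participants: int = 72
    n_high_fear: int = 36
    trials_min: int = 5
    trials_max: int = 10
    n_features: int = 10
    n_signals: int = 48
    n_informative: int | None = None
    class_effect: float = 0.6
    participant_sd: float = 1.0
    noise_sd: float = 1.0
    raw_length_range: tuple[int, int] = (80, 160)
    trials_per_class: tuple[int, int] | None = None
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 <= self.n_high_fear <= self.n_participants):
            raise ConfigError("require 0 <= n_high_fear <= n_participants")
        if not (1 <= self.trials_min <= self.trials_max):
            raise ConfigError("require 1 <= trials_min <= trials_max")
        if self.n_features < 1 or self.n_signals < 1:
            raise ConfigError("n_features and n_signals must be >= 1")
        if self.class_effect < 0 or self.participant_sd < 0 or self.noise_sd <= 0:
            raise ConfigError("require class_effect, participant_sd >= 0 and noise_sd > 0")
        if self.raw_length_range[0] < 4:
            raise ConfigError("raw_length_range lower bound must be >= 4 (cubic interpolation)")
        if self.raw_length_range[0] > self.raw_length_range[1]:
            raise ConfigError("raw_length_range must be (lo, hi) with lo <= hi")

    @property
    def icc(self) -> float:
        """Intraclass correlation sigma_p^2 / (sigma_p^2 + sigma_e^2)."""
        return self.participant_sd**2 / (self.participant_sd**2 + self.noise_sd**2)

    def effective_n_informative(self, total: int) -> int:
        k = total if self.n_informative is None else self.n_informative
        return int(min(max(k, 0), total))


@dataclass
class RawTrialSignals:
    """One trial's multi-channel waveforms plus its metadata."""

    participant_id: str
    trial_index: int
    label: int
    signals: np.ndarray  # shape (n_signals, length)
    signal_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be a (n_signals, length) matrix")
        if not self.signal_names:
            self.signal_names = [f"signal_{j:02d}" for j in range(self.signals.shape[0])]


def _streams(config: GeneratorConfig):
    """Disjoint substreams so e.g. changing n_features never perturbs trial counts."""
    ss = np.random.SeedSequence(config.seed)
    kids = ss.spawn(4)
    return tuple(np.random.default_rng(k) for k in kids)  # cohort, effects, noise, signals


def _cohort(config: GeneratorConfig, rng: np.random.Generator):
    """Participant IDs, labels (exactly n_high_fear ones), trial counts."""
    width = len(str(config.n_participants))
    pids = np.array([f"P{i + 1:0{width}d}" for i in range(config.n_participants)], dtype=object)
    labels = np.zeros(config.n_participants, dtype=int)
    ones = rng.choice(config.n_participants, size=config.n_high_fear, replace=False)
    labels[ones] = 1
    counts = rng.integers(config.trials_min, config.trials_max + 1, size=config.n_participants)
    if config.trials_per_class is not None:
        counts = _adjust_class_totals(labels, counts, config)
    return pids, labels, counts


def _adjust_class_totals(labels, counts, config: GeneratorConfig):
    """Nudge per-participant counts so class trial totals hit fixed targets.

    Used for study-shaped fixtures (e.g. 301 high-fear / 322 low-fear
    trials); adjustments stay within [trials_min, trials_max].
    """
    counts = counts.copy()
    targets = {1: config.trials_per_class[0], 0: config.trials_per_class[1]}
    for cls, target in targets.items():
        members = np.flatnonzero(labels == cls)
        lo, hi = config.trials_min * len(members), config.trials_max * len(members)
        if not (lo <= target <= hi):
            raise ConfigError(
                f"class {cls} trial total {target} unreachable with "
                f"{len(members)} participants and trials in "
                f"[{config.trials_min}, {config.trials_max}]"
            )
        i = 0
        while counts[members].sum() != target:
            diff = target - counts[members].sum()
            m = members[i % len(members)]
            if diff > 0 and counts[m] < config.trials_max:
                counts[m] += 1
            elif diff < 0 and counts[m] > config.trials_min:
                counts[m] -= 1
            i += 1
    return counts


def generate_feature_table(config: GeneratorConfig) -> TrialTable:
    """Draw a trial-level feature table from the random-effects model.

    Labels are constant within each participant; exactly ``n_high_fear``
    participants carry label 1. Identical configs (including seed) produce
    identical tables.
    """
    rng_cohort, rng_eff, rng_noise, _ = _streams(config)
    pids, labels, counts = _cohort(config, rng_cohort)
    d = config.n_features
    k_inf = config.effective_n_informative(d)
    beta = np.zeros(d)
    beta[:k_inf] = config.class_effect
    u = rng_eff.normal(0.0, config.participant_sd, size=(config.n_participants, d))

    rows_f, rows_y, rows_p, rows_t = [], [], [], []
    for i in range(config.n_participants):
        eps = rng_noise.normal(0.0, config.noise_sd, size=(counts[i], d))
        x = labels[i] * beta + u[i] + eps
        rows_f.append(x)
        rows_y.extend([labels[i]] * counts[i])
        rows_p.extend([pids[i]] * counts[i])
        rows_t.extend(range(1, counts[i] + 1))
    return TrialTable(
        features=np.vstack(rows_f),
        labels=np.array(rows_y, dtype=int),
        participant_ids=np.array(rows_p, dtype=object),
        trial_indices=np.array(rows_t, dtype=int),
        feature_names=[f"f{j}" for j in range(d)],
    )


def generate_raw_signals(config: GeneratorConfig) -> list[RawTrialSignals]:
    """Draw smooth multi-channel per-trial waveforms.

    Each signal is a sum of three sinusoids over the unit interval whose
    coefficients are participant-level draws, shifted by ``class_effect`` on
    the first ``n_informative`` signals for label-1 participants, with
    per-trial coefficient noise. Raw lengths are drawn uniformly from
    ``raw_length_range`` — downstream code is expected to time-normalize.
    """
    rng_cohort, rng_eff, rng_noise, rng_sig = _streams(config)
    pids, labels, counts = _cohort(config, rng_cohort)
    s = config.n_signals
    k_inf = config.effective_n_informative(s)
    n_harmonics = 3
    # Signal-level phases shared by the whole cohort; participant coefficients
    # around them carry the identity signature.
    phases = rng_sig.uniform(0.0, 2 * np.pi, size=(s, n_harmonics))
    coef_p = rng_eff.normal(0.0, config.participant_sd, size=(config.n_participants, s, n_harmonics))

    out: list[RawTrialSignals] = []
    lo, hi = config.raw_length_range
    names = [f"signal_{j:02d}" for j in range(s)]
    for i in range(config.n_participants):
        offset = np.zeros((s, n_harmonics))
        offset[:k_inf, 0] = labels[i] * config.class_effect
        for t in range(1, counts[i] + 1):
            length = int(rng_noise.integers(lo, hi + 1))
            coef = coef_p[i] + offset + rng_noise.normal(0.0, config.noise_sd, size=(s, n_harmonics))
            tt = np.linspace(0.0, 1.0, length)
            # waves: (s, n_harmonics, length)
            harmonics = np.sin(
                2 * np.pi * np.arange(1, n_harmonics + 1)[None, :, None] * tt[None, None, :]
                + phases[:, :, None]
            )
            sig = np.einsum("sk,skl->sl", coef, harmonics)
            out.append(
                RawTrialSignals(
                    participant_id=str(pids[i]),
                    trial_index=t,
                    label=int(labels[i]),
                    signals=sig,
                    signal_names=list(names),
                )
            )
    return out


def time_normalize(series, n_points: int = 101) -> np.ndarray:
    """Resample a series onto ``n_points`` equally spaced normalized-time points.

    Piecewise-cubic (natural-spline) interpolation over the unit interval;
    the first and last samples are preserved exactly. This is the standard
    101-point stance-phase normalization for gait/hop waveforms.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 4:
        raise ValueError(f"series length {x.size} < 4: cubic interpolation needs >= 4 points")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    t_in = np.linspace(0.0, 1.0, x.size)
    t_out = np.linspace(0.0, 1.0, n_points)
    y = CubicSpline(t_in, x, bc_type="natural")(t_out)
    y[0], y[-1] = x[0], x[-1]
    return y


def icc_oneway(values: np.ndarray, groups: np.ndarray) -> float:
    """One-way ANOVA intraclass correlation estimate ICC(1).

    Used to check that generated features carry the configured participant
    signature: ICC(1) = (MSB - MSW) / (MSB + (k0 - 1) MSW) with k0 the
    average-adjusted group size.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq, inv = np.unique(groups, return_inverse=True)
    g = len(uniq)
    n = len(values)
    if g < 2 or n <= g:
        raise ValueError("need >= 2 groups with replication")
    grand = values.mean()
    counts = np.bincount(inv)
    means = np.bincount(inv, weights=values) / counts
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((values - means[inv]) ** 2))
    msb = ssb / (g - 1)
    msw = ssw / (n - g)
    k0 = (n - np.sum(counts**2) / n) / (g - 1)
    return float((msb - msw) / (msb + (k0 - 1) * msw))
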