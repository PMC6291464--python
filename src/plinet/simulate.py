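"""Synthetic EEG cohorts with planted, analytically known phase coupling.

The signal model plants pairwise phase coupling whose expected phase lag
index (PLI) has a closed form.  Time is divided into *realization blocks*;
within each block the phase difference between a coupled channel pair is
held at ``+lag_angle`` with probability ``q = (1 + target_pli) / 2`` and at
``-lag_angle`` otherwise, so the sign of ``sin(phase difference)`` is an
i.i.d. +/-1 draw per block and

    E[ mean sign ] = 2q - 1 = target_pli   (noise-free limit).

The |.| in the PLI estimator makes short-window estimates upward-biased
(folded-normal bias); estimates converge to the target as the number of
realization blocks grows.

The module also generates n-back trial schedules with exact match counts and
behavioral outcomes (truncated-normal accuracy, log-normal reaction times),
so every downstream stage of the pipeline has ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import CONDITIONS, DEFAULT_MONTAGE_59, BandDefinition, EEGRecording, band_from_name

__all__ = [
    "CouplingPair",
    "CouplingSpec",
    "Trial",
    "TrialSchedule",
    "GroupSpec",
    "CohortSpec",
    "SyntheticCohort",
    "generate_trial_schedule",
    "derive_match_flags",
    "generate_coupled_pair",
    "generate_recording",
    "generate_cohort",
    "default_cohort_spec",
    "demo_cohort_spec",
]

#: Stimulus alphabet: 25 distinct character identities (the task uses 25
#: candidate characters) plus the asterisk used by the 0-back control.
STIMULUS_ALPHABET: tuple[str, ...] = tuple(f"C{i:02d}" for i in range(1, 26))
ASTERISK = "*"

#: Trial timing (s): 0.5 fixation + 0.5 stimulus + 4.0 blank.
TRIAL_PERIOD = 5.0
FIXATION_LEN = 0.5

#: Default realization-block length (s) for the mixture-of-lags model.
DEFAULT_REALIZATION_LEN = 0.25


# ---------------------------------------------------------------------------
# coupling specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CouplingPair:
    """One planted coupling: channels ``i``–``j`` at ``target_pli`` with ``lag_angle``."""

    i: int
    j: int
    target_pli: float
    lag_angle: float = math.pi / 4

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("coupling pair indices must be distinct")
        if not 0.0 <= self.target_pli <= 1.0:
            raise ValueError(f"target_pli must be in [0, 1], got {self.target_pli}")
        if not 0.0 < self.lag_angle < math.pi:
            raise ValueError(f"lag_angle must be strictly inside (0, pi), got {self.lag_angle}")


@dataclass(frozen=True)
class CouplingSpec:
    """Band-specific coupling plan for a recording."""

    band: BandDefinition
    pairs: tuple[CouplingPair, ...]
    carrier_freq: float | None = None
    background_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.carrier_freq is None:
            object.__setattr__(self, "carrier_freq", self.band.center)
        if not self.band.contains(self.carrier_freq):
            raise ValueError(
                f"carrier_freq {self.carrier_freq} Hz outside band "
                f"{self.band.name} ({self.band.low}-{self.band.high} Hz)"
            )
        if self.background_noise_sd < 0:
            raise ValueError("background_noise_sd must be >= 0")
        seen: set[int] = set()
        for p in self.pairs:
            if p.i in seen or p.j in seen:
                raise ValueError(
                    f"channel {p.i if p.i in seen else p.j} appears in more than one "
                    f"coupling pair of band {self.band.name}"
                )
            seen.update((p.i, p.j))

    def validate_channels(self, n_channels: int) -> None:
        for p in self.pairs:
            for idx in (p.i, p.j):
                if not 0 <= idx < n_channels:
                    raise ValueError(
                        f"coupling pair references channel {idx}, recording has "
                        f"{n_channels} channels"
                    )


# ---------------------------------------------------------------------------
# trial schedules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trial:
    stimulus_id: str
    is_match: bool
    onset: float  # stimulus onset, seconds from recording start


@dataclass
class TrialSchedule:
    """Ordered trials for one n-back run (all sequences concatenated)."""

    task: str
    trials: list[Trial]
    n_sequences: int
    trials_per_sequence: int

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_matches(self) -> int:
        return sum(t.is_match for t in self.trials)

    @property
    def stimuli(self) -> list[str]:
        return [t.stimulus_id for t in self.trials]

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.trials])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(self.n_trials),
                "sequence": np.repeat(np.arange(self.n_sequences), self.trials_per_sequence),
                "stimulus_id": self.stimuli,
                "is_match": [t.is_match for t in self.trials],
                "onset_s": self.onsets,
            }
        )


def derive_match_flags(stimuli: list[str], task: str) -> list[bool]:
    """Recompute match flags from stimulus identities alone.

    For 2-back a trial is a match iff its stimulus equals the one two
    positions earlier *within its sequence context* (here: the flat list;
    callers working per-sequence should pass one sequence at a time).  For
    0-back a "match" trial is a character (non-asterisk) trial.
    """
    if task == "0-back":
        return [s != ASTERISK for s in stimuli]
    if task == "2-back":
        return [i >= 2 and stimuli[i] == stimuli[i - 2] for i in range(len(stimuli))]
    raise ValueError(f"unknown task {task!r}")


def _split_matches(n_match_total: int, n_sequences: int, per_seq_cap: int) -> list[int]:
    """Distribute matches across sequences as evenly as feasibility allows."""
    base, rem = divmod(n_match_total, n_sequences)
    counts = [base + (1 if k < rem else 0) for k in range(n_sequences)]
    # rebalance any overflow beyond the per-sequence cap
    for k in range(n_sequences):
        if counts[k] > per_seq_cap:
            spill = counts[k] - per_seq_cap
            counts[k] = per_seq_cap
            for m in range(n_sequences):
                if m == k:
                    continue
                room = per_seq_cap - counts[m]
                take = min(room, spill)
                counts[m] += take
                spill -= take
            if spill:
                raise ValueError("internal error: match rebalancing failed")
    return counts


def generate_trial_schedule(
    task: str,
    n_sequences: int = 3,
    trials_per_sequence: int = 40,
    n_match_total: int = 39,
    seed: int | np.random.Generator = 0,
) -> TrialSchedule:
    """Build an n-back schedule with exactly ``n_match_total`` matches.

    Defaults reproduce the three-sequence, 120-trial, 39-match design.
    Stimulus onsets are spaced ``TRIAL_PERIOD`` (5.0 s) apart, offset by the
    0.5-s fixation.

    For 2-back, match positions are sampled among positions >= 2 of each
    sequence and the stimulus stream is constructed so that lag-2 equality
    holds exactly at the flagged positions and nowhere else.  For 0-back,
    ``n_match_total`` counts character (non-asterisk) trials.
    """
    rng = np.random.default_rng(seed)
    if task not in ("0-back", "2-back"):
        raise ValueError(f"unknown task {task!r}")
    if n_sequences < 1 or trials_per_sequence < 1:
        raise ValueError("n_sequences and trials_per_sequence must be >= 1")
    if n_match_total < 0:
        raise ValueError("n_match_total must be >= 0")

    if task == "0-back":
        per_seq_cap = trials_per_sequence
    else:
        per_seq_cap = max(0, trials_per_sequence - 2)
    if n_match_total > n_sequences * per_seq_cap:
        raise ValueError(
            f"{n_match_total} matches infeasible for {n_sequences} sequences of "
            f"{trials_per_sequence} trials ({task}: max {n_sequences * per_seq_cap})"
        )

    per_seq = _split_matches(n_match_total, n_sequences, per_seq_cap)
    alphabet = list(STIMULUS_ALPHABET)

    stimuli: list[str] = []
    flags: list[bool] = []
    for n_match in per_seq:
        if task == "0-back":
            is_char = np.zeros(trials_per_sequence, dtype=bool)
            pos = rng.choice(trials_per_sequence, size=n_match, replace=False)
            is_char[pos] = True
            seq = [str(rng.choice(alphabet)) if c else ASTERISK for c in is_char]
            stimuli.extend(seq)
            flags.extend(bool(c) for c in is_char)
        else:
            match_pos = set(
                rng.choice(np.arange(2, trials_per_sequence), size=n_match, replace=False)
                .tolist()
            ) if n_match else set()
            seq: list[str] = []
            for i in range(trials_per_sequence):
                if i in match_pos:
                    seq.append(seq[i - 2])
                else:
                    choices = alphabet if i < 2 else [s for s in alphabet if s != seq[i - 2]]
                    seq.append(str(rng.choice(choices)))
            stimuli.extend(seq)
            flags.extend(i in match_pos for i in range(trials_per_sequence))

    # independent consistency check against the stated rule, per sequence
    rederived: list[bool] = []
    for k in range(n_sequences):
        sl = slice(k * trials_per_sequence, (k + 1) * trials_per_sequence)
        rederived.extend(derive_match_flags(stimuli[sl], task))
    if rederived != flags:
        raise RuntimeError("internal consistency error: n-back rule violated in schedule")

    onsets = FIXATION_LEN + TRIAL_PERIOD * np.arange(n_sequences * trials_per_sequence)
    trials = [Trial(s, f, float(o)) for s, f, o in zip(stimuli, flags, onsets)]
    return TrialSchedule(task=task, trials=trials, n_sequences=n_sequences,
                         trials_per_sequence=trials_per_sequence)


# ---------------------------------------------------------------------------
# coupled signals
# ---------------------------------------------------------------------------

def _realization_signs(rng: np.random.Generator, n_realizations: int, target_pli: float
                       ) -> np.ndarray:
    q = 0.5 * (1.0 + target_pli)
    return np.where(rng.random(n_realizations) < q, 1.0, -1.0)


def generate_coupled_pair(
    duration: float,
    fs: float,
    *,
    target_pli: float,
    lag_angle: float = math.pi / 4,
    carrier_freq: float = 6.0,
    noise_sd: float = 0.0,
    n_realizations: int | None = None,
    seed: int | np.random.Generator = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two narrowband signals with planted expected PLI = ``target_pli``.

    The first signal is a unit cosine carrier; the second tracks it with a
    phase difference of ``+lag_angle`` (probability ``q=(1+target_pli)/2``)
    or ``-lag_angle`` per realization block.  Independent Gaussian noise of
    SD ``noise_sd`` is added to each channel.  ``n_realizations`` defaults to
    ``duration / 0.25 s`` blocks.
    """
    pair = CouplingPair(0, 1, target_pli, lag_angle)  # validates pli/lag
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError(f"duration x fs must be >= 2 samples, got {n}")
    rng = np.random.default_rng(seed)
    if n_realizations is None:
        n_realizations = max(1, int(round(duration / DEFAULT_REALIZATION_LEN)))
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")

    signs = _realization_signs(rng, n_realizations, pair.target_pli)
    per_block = -(-n // n_realizations)
    block = np.repeat(signs, per_block)[:n]  # per-sample lag sign
    # fresh random carrier phase per realization block, so carriers of
    # *different* pairs (same frequency) decorrelate instead of holding a
    # constant offset; within a pair the offset stays +/-lag_angle exactly
    phase0 = np.repeat(rng.uniform(0.0, 2.0 * np.pi, n_realizations), per_block)[:n]

    t = np.arange(n) / fs
    theta = 2.0 * np.pi * carrier_freq * t + phase0
    x = np.cos(theta)
    y = np.cos(theta - block * pair.lag_angle)
    if noise_sd > 0:
        x = x + noise_sd * rng.standard_normal(n)
        y = y + noise_sd * rng.standard_normal(n)
    return x, y


def generate_recording(
    n_channels: int,
    duration: float,
    fs: float,
    specs: tuple[CouplingSpec, ...] = (),
    seed: int | np.random.Generator = 0,
    *,
    labels: list[str] | None = None,
    condition: str | None = None,
    noise_sd: float = 1.0,
    carrier_amplitude: float = 5.0,
    realization_len: float = DEFAULT_REALIZATION_LEN,
) -> EEGRecording:
    """Multichannel recording with independent noise plus planted couplings.

    Every channel receives i.i.d. Gaussian background noise (``noise_sd``,
    microvolts).  For each :class:`CouplingSpec`, each coupled pair gets a
    shared mixture-of-lags carrier at ``carrier_amplitude`` microvolts (plus
    optional extra in-spec noise).  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    if labels is None:
        if n_channels == 59:
            labels = list(DEFAULT_MONTAGE_59)
        else:
            labels = [f"ch{i:02d}" for i in range(n_channels)]
    if len(labels) != n_channels:
        raise ValueError(f"{len(labels)} labels for {n_channels} channels")
    n = int(round(duration * fs))
    if n < 2:
        raise ValueError("duration x fs must be >= 2 samples")

    data = noise_sd * rng.standard_normal((n_channels, n)) if noise_sd > 0 else np.zeros(
        (n_channels, n))

    n_real = max(1, int(round(duration / realization_len)))
    for spec in specs:
        spec.validate_channels(n_channels)
        for pair in spec.pairs:
            x, y = generate_coupled_pair(
                duration, fs,
                target_pli=pair.target_pli, lag_angle=pair.lag_angle,
                carrier_freq=spec.carrier_freq, noise_sd=0.0,
                n_realizations=n_real, seed=rng,
            )
            data[pair.i] += carrier_amplitude * x
            data[pair.j] += carrier_amplitude * y
        if spec.background_noise_sd > 0:
            touched = sorted({c for p in spec.pairs for c in (p.i, p.j)})
            data[touched] += spec.background_noise_sd * rng.standard_normal(
                (len(touched), n))

    return EEGRecording(data=data, fs=fs, labels=labels, condition=condition)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Per-group generative parameters."""

    n: int
    age_mean: float
    age_sd: float
    education_mean: float
    education_sd: float
    #: band -> condition -> (mean target PLI, between-subject SD)
    pli_targets: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    #: task -> (accuracy mean, accuracy SD, RT mean ms, RT SD ms)
    behavior: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.age_sd < 0 or self.education_sd < 0:
            raise ValueError("SDs must be >= 0")
        for band in self.pli_targets.values():
            for mean, sd in band.values():
                if not 0.0 <= mean <= 1.0 or sd < 0:
                    raise ValueError("PLI target mean must be in [0,1] with SD >= 0")
        for acc_mean, acc_sd, rt_mean, rt_sd in self.behavior.values():
            if not 0.0 <= acc_mean <= 1.0:
                raise ValueError("accuracy mean must be in [0, 1]")
            if acc_sd < 0 or rt_sd < 0 or rt_mean <= 0:
                raise ValueError("behavior SDs must be >= 0 and RT mean > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Full cohort recipe: groups, recording geometry, coupling layout."""

    groups: dict[str, GroupSpec]
    n_channels: int = 59
    fs: float = 500.0
    n_epochs: int = 40               # 3.5-s epochs per condition
    conditions: tuple[str, ...] = CONDITIONS
    bands: tuple[str, ...] = ("theta",)
    n_coupled_pairs: int = 2         # disjoint pairs (0,1), (2,3), ...
    lag_angle: float = math.pi / 4
    noise_sd: float = 0.25
    carrier_amplitude: float = 5.0
    realization_len: float = DEFAULT_REALIZATION_LEN
    epoch_len: float = 3.5

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        if 2 * self.n_coupled_pairs > self.n_channels:
            raise ValueError("too many coupled pairs for channel count")
        for g in self.groups.values():
            for band in self.bands:
                if band not in g.pli_targets:
                    raise ValueError(f"group missing PLI targets for band {band!r}")
                missing = [c for c in self.conditions if c not in g.pli_targets[band]]
                if missing:
                    raise ValueError(f"group missing PLI targets for conditions {missing}")

    @property
    def n_subjects(self) -> int:
        return sum(g.n for g in self.groups.values())

    @property
    def duration(self) -> float:
        return self.n_epochs * self.epoch_len


@dataclass
class SyntheticCohort:
    """Generated cohort: subject table plus per (subject, condition) recordings."""

    spec: CohortSpec
    table: pd.DataFrame
    recordings: dict[tuple[str, str], EEGRecording]
    onsets: dict[tuple[str, str], np.ndarray]
    targets: pd.DataFrame  # planted per-subject target PLIs (ground truth)


#: Paper-calibrated defaults: group sizes, demographics, theta-band 2-back
#: average PLI (senior > young) and Table-2 behavior.  SEs printed for the
#: theta PLI (0.005, 0.012) are converted to between-subject SDs.
def default_cohort_spec(**overrides) -> CohortSpec:
    theta_young = {"rest": (0.205, 0.019), "0-back": (0.205, 0.019), "2-back": (0.205, 0.019)}
    theta_senior = {"rest": (0.205, 0.038), "0-back": (0.205, 0.038), "2-back": (0.223, 0.038)}
    groups = {
        "young": GroupSpec(
            n=15, age_mean=23.1, age_sd=2.0, education_mean=16.1, education_sd=1.9,
            pli_targets={"theta": theta_young},
            behavior={"0-back": (0.95, 0.03, 497.0, 109.0),
                      "2-back": (0.96, 0.03, 743.0, 244.0)},
        ),
        "senior": GroupSpec(
            n=10, age_mean=64.0, age_sd=3.3, education_mean=9.3, education_sd=3.0,
            pli_targets={"theta": theta_senior},
            behavior={"0-back": (0.88, 0.10, 660.0, 127.0),
                      "2-back": (0.73, 0.20, 1092.0, 527.0)},
        ),
    }
    return replace(CohortSpec(groups=groups), **overrides) if overrides else CohortSpec(
        groups=groups)


def demo_cohort_spec(
    n_young: int = 15,
    n_senior: int = 10,
    *,
    effect_d: float = 1.5,
    base_pli: float = 0.45,
    between_sd: float = 0.12,
    n_channels: int = 6,
    fs: float = 250.0,
    n_epochs: int = 40,
    bands: tuple[str, ...] = ("theta",),
    noise_sd: float = 0.1,
    education_young: tuple[float, float] = (16.1, 1.9),
    education_senior: tuple[float, float] = (9.3, 3.0),
    **overrides,
) -> CohortSpec:
    """Small, fast cohort with a planted 2-back theta group effect of size ``effect_d``.

    The senior 2-back target mean is ``base_pli + effect_d * between_sd``; all
    other condition targets sit at ``base_pli`` for both groups, so only the
    2-back condition carries a group difference.  Unless overridden, every
    disjoint channel pair (0,1), (2,3), ... carries the planted coupling.
    """
    overrides.setdefault("n_coupled_pairs", max(1, n_channels // 2))
    young_t = {c: (base_pli, between_sd) for c in CONDITIONS}
    senior_t = {c: (base_pli, between_sd) for c in CONDITIONS}
    senior_t["2-back"] = (min(1.0, base_pli + effect_d * between_sd), between_sd)
    per_band_young = {b: dict(young_t) for b in bands}
    per_band_senior = {b: dict(senior_t) for b in bands}
    groups = {
        "young": GroupSpec(
            n=n_young, age_mean=23.1, age_sd=2.0,
            education_mean=education_young[0], education_sd=education_young[1],
            pli_targets=per_band_young,
            behavior={"0-back": (0.95, 0.03, 497.0, 109.0),
                      "2-back": (0.96, 0.03, 743.0, 244.0)},
        ),
        "senior": GroupSpec(
            n=n_senior, age_mean=64.0, age_sd=3.3,
            education_mean=education_senior[0], education_sd=education_senior[1],
            pli_targets=per_band_senior,
            behavior={"0-back": (0.88, 0.10, 660.0, 127.0),
                      "2-back": (0.73, 0.20, 1092.0, 527.0)},
        ),
    }
    return CohortSpec(groups=groups, n_channels=n_channels, fs=fs, n_epochs=n_epochs,
                      bands=bands, noise_sd=noise_sd, **overrides)


def _truncnorm01(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal draw on [0, 1] by rejection (falls back to clipping)."""
    if sd == 0:
        return float(mean)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if 0.0 <= v <= 1.0:
            return float(v)
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Log-normal draw with the requested arithmetic mean and SD."""
    if sd == 0:
        return float(mean)
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def generate_cohort(spec: CohortSpec, seed: int | np.random.Generator = 0
                    ) -> SyntheticCohort:
    """Generate the subject table and one recording per subject x condition.

    Per-subject target PLIs are drawn from the group distributions (clipped
    to [0, 1]); coupling is planted on disjoint channel pairs (0,1), (2,3),
    ...; behavioral accuracy is truncated-normal in [0, 1] and reaction time
    log-normal.  All draws flow from ``seed``.
    """
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    target_rows: list[dict] = []
    recordings: dict[tuple[str, str], EEGRecording] = {}
    onsets: dict[tuple[str, str], np.ndarray] = {}

    pair_layout = [(2 * k, 2 * k + 1) for k in range(spec.n_coupled_pairs)]
    epoch_starts = spec.epoch_len * np.arange(spec.n_epochs)

    sid = 0
    for group_name, g in spec.groups.items():
        for _ in range(g.n):
            subject = f"S{sid:03d}"
            sid += 1
            row = {
                "subject": subject,
                "group": group_name,
                "group_code": 0 if group_name == "young" else 1,
                "age": float(rng.normal(g.age_mean, g.age_sd)),
                "education": float(np.clip(rng.normal(g.education_mean, g.education_sd),
                                           0.0, None)),
            }
            for task in ("0-back", "2-back"):
                if task in g.behavior:
                    acc_m, acc_sd, rt_m, rt_sd = g.behavior[task]
                    row[f"accuracy_{task}"] = _truncnorm01(rng, acc_m, acc_sd)
                    row[f"rt_{task}"] = _lognormal(rng, rt_m, rt_sd)
            rows.append(row)

            # subject-level coupling targets, then recordings per condition
            for cond in spec.conditions:
                specs = []
                for band_name in spec.bands:
                    mean, sd = g.pli_targets[band_name][cond]
                    target = float(np.clip(rng.normal(mean, sd), 0.0, 1.0))
                    target_rows.append({"subject": subject, "group": group_name,
                                        "band": band_name, "condition": cond,
                                        "target_pli": target})
                    band = band_from_name(band_name)
                    pairs = tuple(CouplingPair(i, j, target, spec.lag_angle)
                                  for i, j in pair_layout)
                    specs.append(CouplingSpec(band=band, pairs=pairs))
                rec = generate_recording(
                    spec.n_channels, spec.duration, spec.fs, tuple(specs), rng,
                    condition=cond, noise_sd=spec.noise_sd,
                    carrier_amplitude=spec.carrier_amplitude,
                    realization_len=spec.realization_len,
                )
                recordings[(subject, cond)] = rec
                onsets[(subject, cond)] = epoch_starts.copy()

    table = pd.DataFrame(rows)
    targets = pd.DataFrame(target_rows)
    return SyntheticCohort(spec=spec, table=table, recordings=recordings,
                           onsets=onsets, targets=targets)
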