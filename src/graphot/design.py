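"""Pseudorandom trial schedules for the alphabetic decision task.

A session presents 30 lower-case German letters 25 times each (750 go
trials) and 28 false-font characters 6 times each (168 no-go trials), in
14 blocks of 66 trials except a final block of 60.  Constraints:

* each block contains 10-14 false-font trials;
* no stimulus identity repeats within 3 trials of its last presentation
  (true- and false-font counterparts count as distinct identities);
* for every letter, the probability of appearing immediately before or
  after a false-font trial, out of its 25 presentations, stays below
  0.33.

The last constraint is only satisfiable if false-font trials are allowed
to occur in short consecutive runs: fully dispersed false fonts would
leave ~336 letter-adjacent positions for 750 letter trials, forcing an
average adjacency fraction of ~0.36.  The generator therefore places
false fonts in runs of 1-3 trials and assigns letters to run-adjacent
positions constructively, capping each letter at 8 adjacencies
(8/25 = 0.32).  Adjacency is counted within blocks only, since blocks
are separated by self-paced breaks.

Generation is rejection sampling with restarts: identities are filled
greedily (weighted by remaining repetitions) and the attempt restarts on
a dead end.  Identical seeds give identical schedules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glyphs import GERMAN_LETTERS

__all__ = [
    "DesignConfig",
    "Trial",
    "TrialSchedule",
    "ValidationReport",
    "generate_trial_schedule",
    "generate_practice_block",
    "validate_schedule",
    "max_transition_probability",
    "schedule_to_tsv",
    "schedule_from_tsv",
]

#: false-font identities: letters minus the two without usable counterparts
FALSE_FONT_IDS: tuple[str, ...] = tuple(
    f"ff_{c}" for c in GERMAN_LETTERS if c not in ("ö", "ß")
)


@dataclass(frozen=True)
class DesignConfig:
    letters: tuple[str, ...] = GERMAN_LETTERS
    letter_reps: int = 25
    false_fonts: tuple[str, ...] = FALSE_FONT_IDS
    ff_reps: int = 6
    block_sizes: tuple[int, ...] = (66,) * 13 + (60,)
    ff_per_block: tuple[int, int] = (10, 14)
    min_gap: int = 4  # same identity at least this many trials apart
    max_transition_prob: float = 0.33
    max_attempts: int = 10_000

    @property
    def n_trials(self) -> int:
        return len(self.letters) * self.letter_reps + len(self.false_fonts) * self.ff_reps

    @property
    def adjacency_cap(self) -> int:
        """Largest adjacency count keeping the fraction strictly below bound."""
        cap = int(np.floor(self.max_transition_prob * self.letter_reps))
        if cap / self.letter_reps >= self.max_transition_prob:
            cap -= 1
        return cap

    def validate(self) -> None:
        if sum(self.block_sizes) != self.n_trials:
            raise ValueError("block sizes do not sum to the total trial count")
        total_ff = len(self.false_fonts) * self.ff_reps
        lo, hi = self.ff_per_block
        nb = len(self.block_sizes)
        if not (lo * nb <= total_ff <= hi * nb):
            raise ValueError("false-font count incompatible with per-block range")


@dataclass(frozen=True)
class Trial:
    stimulus_id: str
    stimulus_class: str  # "letter" | "false_font"
    block: int


@dataclass(frozen=True)
class TrialSchedule:
    trials: tuple[Trial, ...]
    block_sizes: tuple[int, ...]
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def block(self, b: int) -> list[Trial]:
        return [t for t in self.trials if t.block == b]


class ScheduleError(RuntimeError):
    """Raised when constraint satisfaction fails after all restarts."""


def _ff_counts_per_block(cfg: DesignConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.ff_per_block
    nb = len(cfg.block_sizes)
    total = len(cfg.false_fonts) * cfg.ff_reps
    counts = np.full(nb, total // nb)
    counts[: total - counts.sum()] += 1
    for _ in range(4 * nb):  # random sum-preserving perturbations
        i, j = rng.integers(0, nb, size=2)
        if i != j and counts[i] < hi and counts[j] > lo:
            counts[i] += 1
            counts[j] -= 1
    return counts


def _run_lengths(f: int, rng: np.random.Generator) -> list[int]:
    """Partition f false fonts into runs of 1-3 consecutive trials."""
    runs: list[int] = []
    left = f
    while left > 0:
        r = min(left, int(rng.choice([1, 2, 3], p=[0.45, 0.40, 0.15])))
        runs.append(r)
        left -= r
    rng.shuffle(runs)
    return runs


def _block_layout(
    n_block: int, f: int, rng: np.random.Generator
) -> list[str] | None:
    """Class layout for one block: 'L' letter slots with false-font runs
    inserted at distinct letter gaps."""
    n_letters = n_block - f
    runs = _run_lengths(f, rng)
    if len(runs) > n_letters + 1:
        return None
    gaps = rng.choice(n_letters + 1, size=len(runs), replace=False)
    layout: list[str] = []
    by_gap = dict(zip(gaps.tolist(), runs))
    for g in range(n_letters + 1):
        if g in by_gap:
            layout.extend(["F"] * by_gap[g])
        if g < n_letters:
            layout.append("L")
    return layout


def _fill_identities(
    layout_blocks: list[list[str]], cfg: DesignConfig, rng: np.random.Generator
) -> list[Trial] | None:
    remaining = {c: cfg.letter_reps for c in cfg.letters}
    remaining.update({c: cfg.ff_reps for c in cfg.false_fonts})
    last_seen: dict[str, int] = {}
    adj_count = {c: 0 for c in cfg.letters}
    cap = cfg.adjacency_cap
    trials: list[Trial] = []
    t = 0
    for b, layout in enumerate(layout_blocks):
        for pos, cls in enumerate(layout):
            adjacent_ff = cls == "L" and (
                (pos > 0 and layout[pos - 1] == "F")
                or (pos + 1 < len(layout) and layout[pos + 1] == "F")
            )
            pool = cfg.letters if cls == "L" else cfg.false_fonts
            elig = [
                c
                for c in pool
                if remaining[c] > 0
                and t - last_seen.get(c, -cfg.min_gap) >= cfg.min_gap
                and (not adjacent_ff or adj_count[c] < cap)
            ]
            if not elig:
                return None
            weights = np.array([remaining[c] for c in elig], dtype=float)
            chosen = elig[rng.choice(len(elig), p=weights / weights.sum())]
            remaining[chosen] -= 1
            last_seen[chosen] = t
            if adjacent_ff:
                adj_count[chosen] += 1
            trials.append(
                Trial(chosen, "letter" if cls == "L" else "false_font", b)
            )
            t += 1
    return trials


def generate_trial_schedule(
    config: DesignConfig | None = None, seed: int = 0
) -> TrialSchedule:
    """Generate a constraint-satisfying schedule, deterministically per seed.

    Raises
    ------
    ScheduleError
        If no valid schedule is found within ``max_attempts`` restarts;
        the message names the first violated constraint of the last
        attempt.
    """
    cfg = config or DesignConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)
    last_failure = "no attempt completed"
    for _ in range(cfg.max_attempts):
        counts = _ff_counts_per_block(cfg, rng)
        layouts = [
            _block_layout(nb, int(f), rng)
            for nb, f in zip(cfg.block_sizes, counts)
        ]
        if any(l is None for l in layouts):
            last_failure = "false-font run placement"
            continue
        trials = _fill_identities(layouts, cfg, rng)  # type: ignore[arg-type]
        if trials is None:
            last_failure = "identity assignment (lag or adjacency dead end)"
            continue
        schedule = TrialSchedule(tuple(trials), cfg.block_sizes, seed)
        report = validate_schedule(schedule, cfg)
        if report.passed:
            return schedule
        last_failure = ", ".join(report.failures)  # pragma: no cover
    raise ScheduleError(
        f"no valid schedule after {cfg.max_attempts} attempts; "
        f"last violation: {last_failure}"
    )


def generate_practice_block(seed: int = 0, n_letters: int = 17, n_ff: int = 3) -> TrialSchedule:
    """Short practice block (17 letters + 3 false fonts by default).

    Excluded from analysis outputs; uses the same lag constraint.
    """
    cfg = DesignConfig(
        letter_reps=1,
        ff_reps=1,
        block_sizes=(n_letters + n_ff,),
        ff_per_block=(n_ff, n_ff),
    )
    rng = np.random.default_rng(seed)
    letters = tuple(rng.choice(cfg.letters, size=n_letters, replace=False))
    ffs = tuple(rng.choice(cfg.false_fonts, size=n_ff, replace=False))
    order = list(letters) + list(ffs)
    rng.shuffle(order)
    trials = tuple(
        Trial(c, "letter" if c in letters else "false_font", 0) for c in order
    )
    return TrialSchedule(trials, cfg.block_sizes, seed)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ValidationReport:
    checks: dict[str, tuple[bool, str]]
    max_transition_probability: float

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    @property
    def failures(self) -> list[str]:
        return [k for k, (ok, _) in self.checks.items() if not ok]


def _adjacency_fractions(schedule: TrialSchedule, cfg: DesignConfig) -> dict[str, float]:
    """Per letter: fraction of its presentations immediately before or
    after a false-font trial (within-block adjacency)."""
    counts = {c: 0 for c in cfg.letters}
    totals = {c: 0 for c in cfg.letters}
    trials = schedule.trials
    for i, tr in enumerate(trials):
        if tr.stimulus_class != "letter":
            continue
        totals[tr.stimulus_id] = totals.get(tr.stimulus_id, 0) + 1
        prev_ff = (
            i > 0
            and trials[i - 1].block == tr.block
            and trials[i - 1].stimulus_class == "false_font"
        )
        next_ff = (
            i + 1 < len(trials)
            and trials[i + 1].block == tr.block
            and trials[i + 1].stimulus_class == "false_font"
        )
        if prev_ff or next_ff:
            counts[tr.stimulus_id] = counts.get(tr.stimulus_id, 0) + 1
    return {c: counts[c] / totals[c] if totals[c] else 0.0 for c in counts}


def max_transition_probability(
    schedule: TrialSchedule, config: DesignConfig | None = None
) -> float:
    """Maximum over letters of the false-font adjacency fraction."""
    cfg = config or DesignConfig()
    return max(_adjacency_fractions(schedule, cfg).values())


def validate_schedule(
    schedule: TrialSchedule, config: DesignConfig | None = None
) -> ValidationReport:
    """Independently check every schedule invariant; each entry reports
    pass/fail with offending indices or values."""
    cfg = config or DesignConfig()
    checks: dict[str, tuple[bool, str]] = {}
    trials = schedule.trials

    n_letter = sum(t.stimulus_class == "letter" for t in trials)
    n_ff = len(trials) - n_letter
    exp_l = len(cfg.letters) * cfg.letter_reps
    exp_f = len(cfg.false_fonts) * cfg.ff_reps
    checks["total_counts"] = (
        (n_letter, n_ff) == (exp_l, exp_f),
        f"{n_letter} letter + {n_ff} false-font trials "
        f"(expected {exp_l} + {exp_f})",
    )

    ident_counts: dict[str, int] = {}
    for t in trials:
        ident_counts[t.stimulus_id] = ident_counts.get(t.stimulus_id, 0) + 1
    bad_ident = sorted(
        c
        for c in list(cfg.letters) + list(cfg.false_fonts)
        if ident_counts.get(c, 0)
        != (cfg.letter_reps if c in cfg.letters else cfg.ff_reps)
    )
    checks["per_identity_counts"] = (not bad_ident, f"off-count ids: {bad_ident}")

    sizes = tuple(sum(t.block == b for t in trials) for b in range(len(cfg.block_sizes)))
    checks["block_sizes"] = (
        sizes == tuple(cfg.block_sizes),
        f"block sizes {sizes}",
    )

    lo, hi = cfg.ff_per_block
    ff_counts = [
        sum(t.block == b and t.stimulus_class == "false_font" for t in trials)
        for b in range(len(cfg.block_sizes))
    ]
    bad_blocks = [b for b, f in enumerate(ff_counts) if not lo <= f <= hi]
    checks["false_fonts_per_block"] = (
        not bad_blocks,
        f"per-block false-font counts {ff_counts}; out of range: {bad_blocks}",
    )

    last: dict[str, int] = {}
    repeats = []
    for i, t in enumerate(trials):
        if t.stimulus_id in last and i - last[t.stimulus_id] < cfg.min_gap:
            repeats.append(i)
        last[t.stimulus_id] = i
    checks["identity_lag"] = (
        not repeats,
        f"identities repeated within {cfg.min_gap - 1} trials at indices {repeats}",
    )

    max_p = max_transition_probability(schedule, cfg)
    checks["transition_probability"] = (
        max_p < cfg.max_transition_prob,
        f"max adjacency fraction {max_p:.4f} (bound {cfg.max_transition_prob})",
    )
    return ValidationReport(checks=checks, max_transition_probability=max_p)


# --------------------------------------------------------------------------
# serialisation
# --------------------------------------------------------------------------

def schedule_to_tsv(schedule: TrialSchedule, path: str) -> None:
    df = pd.DataFrame(
        {
            "trial": range(len(schedule.trials)),
            "block": [t.block for t in schedule.trials],
            "stimulus_id": [t.stimulus_id for t in schedule.trials],
            "class": [t.stimulus_class for t in schedule.trials],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def schedule_from_tsv(path: str, seed: int = -1) -> TrialSchedule:
    df = pd.read_csv(path, sep="\t")
    trials = tuple(
        Trial(str(sid), str(cls), int(b))
        for sid, cls, b in zip(df["stimulus_id"], df["class"], df["block"])
    )
    sizes = tuple(
        int((df["block"] == b).sum()) for b in sorted(df["block"].unique())
    )
    return TrialSchedule(trials, sizes, seed)
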