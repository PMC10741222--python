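"""Task generators and scorers: go/nogo sustained attention, the adaptive
calculation task, and the transfer-paradigm block structure."""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field

import numpy as np

from .io import EventTable

__all__ = [
    "GoNogoConfig",
    "GoNogoTrial",
    "GoNogoScore",
    "CalcTrial",
    "TransferConfig",
    "generate_gonogo_block",
    "score_gonogo",
    "clean_rt",
    "next_calc_trial",
    "transfer_paradigm",
]

GO_LETTERS = [c for c in string.ascii_uppercase if c != "X"]


@dataclass(frozen=True)
class GoNogoConfig:
    n_trials: int = 20
    nogo_fraction: float = 0.25
    t_fix_ms: float = 750.0
    t_stim_ms: float = 250.0
    t_resp_ms: float = 1000.0
    trial_len_ms: float = 2000.0
    jitter: float = 0.10          # uniform fractional jitter per sub-duration
    rt_limit_ms: float = 1000.0   # response later than this is an omission


@dataclass(frozen=True)
class GoNogoTrial:
    letter: str
    t_fix: float                  # ms
    t_stim: float
    t_resp: float
    block_id: int
    distraction_condition: str    # "with" | "without"
    onset: float = 0.0            # s, within the task

    @property
    def is_nogo(self) -> bool:
        return self.letter == "X"

    @property
    def distracted(self) -> bool:
        return self.distraction_condition == "with"


@dataclass(frozen=True)
class GoNogoScore:
    n_trials: int
    hits: int
    omissions: int
    commissions: int
    correct_rejections: int
    accuracy: float
    rt_mean: float      # ms over cleaned go hits; nan if none
    rt_sd: float
    n_rt_used: int
    by_condition: dict = field(default_factory=dict)


def generate_gonogo_block(config: GoNogoConfig = GoNogoConfig(), block_id: int = 0,
                          condition: str = "without", seed: int = 0,
                          t0: float = 0.0) -> list[GoNogoTrial]:
    """One block of trials with an exact 25% nogo composition.

    Sub-durations get uniform +/-``jitter`` around their nominal values and
    are then renormalized so every trial lasts exactly ``trial_len_ms``.
    """
    if condition not in ("with", "without"):
        raise ValueError("condition must be 'with' or 'without'")
    rng = np.random.default_rng(seed)
    n = config.n_trials
    n_nogo = int(round(config.nogo_fraction * n))
    nogo_pos = set(rng.choice(n, size=n_nogo, replace=False).tolist())
    trials = []
    t = t0
    for i in range(n):
        letter = "X" if i in nogo_pos else GO_LETTERS[rng.integers(len(GO_LETTERS))]
        durs = np.array([config.t_fix_ms, config.t_stim_ms, config.t_resp_ms])
        durs = durs * (1.0 + rng.uniform(-config.jitter, config.jitter, 3))
        durs *= config.trial_len_ms / durs.sum()
        trials.append(GoNogoTrial(letter=letter, t_fix=float(durs[0]),
                                  t_stim=float(durs[1]), t_resp=float(durs[2]),
                                  block_id=block_id, distraction_condition=condition,
                                  onset=t))
        t += config.trial_len_ms / 1000.0
    return trials


def score_gonogo(trials, responses, rt_limit_ms: float = 1000.0,
                 clean: bool = True) -> GoNogoScore:
    """Score aligned (trial, response) pairs.

    A go trial with no press, or a press later than ``rt_limit_ms``, is an
    omission; any press on a nogo trial is a commission. RT statistics are
    computed over go hits, optionally after +/-3 SD cleaning.
    """
    if len(trials) != len(responses):
        raise ValueError(f"{len(trials)} trials but {len(responses)} responses")
    hits = omissions = commissions = crs = 0
    cells = {}
    hit_rts = []
    for trial, (pressed, rt) in zip(trials, responses):
        cond = trial.distraction_condition
        c = cells.setdefault(cond, {"hits": 0, "omissions": 0, "commissions": 0,
                                    "correct_rejections": 0, "rts": []})
        if trial.is_nogo:
            if pressed:
                commissions += 1
                c["commissions"] += 1
            else:
                crs += 1
                c["correct_rejections"] += 1
        else:
            if pressed and rt is not None and rt <= rt_limit_ms:
                hits += 1
                c["hits"] += 1
                hit_rts.append(float(rt))
                c["rts"].append(float(rt))
            else:
                omissions += 1
                c["omissions"] += 1

    def _rt_stats(rts):
        if not rts:
            return float("nan"), float("nan"), 0
        arr = np.asarray(rts)
        if clean and len(arr) >= 2:
            mask = clean_rt(arr, np.zeros(len(arr), dtype=bool))
            arr = arr[mask]
        return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0, len(arr)

    rt_mean, rt_sd, n_used = _rt_stats(hit_rts)
    by_cond = {}
    for cond, c in cells.items():
        m, s, k = _rt_stats(c["rts"])
        n_c = c["hits"] + c["omissions"] + c["commissions"] + c["correct_rejections"]
        by_cond[cond] = {
            **{k2: v for k2, v in c.items() if k2 != "rts"},
            "n_trials": n_c,
            "accuracy": (c["hits"] + c["correct_rejections"]) / n_c if n_c else float("nan"),
            "rt_mean": m, "rt_sd": s, "n_rt_used": k,
        }
    n = len(trials)
    return GoNogoScore(
        n_trials=n, hits=hits, omissions=omissions, commissions=commissions,
        correct_rejections=crs,
        accuracy=(hits + crs) / n if n else float("nan"),
        rt_mean=rt_mean, rt_sd=rt_sd, n_rt_used=n_used, by_condition=by_cond,
    )


def clean_rt(rts, error_flags) -> np.ndarray:
    """Retained-trial mask: drop errors, then RTs beyond mean +/- 3 SD.

    Mean and SD are computed over the correct trials only, and the outlier
    pass runs exactly once (no re-iteration).
    """
    rts = np.asarray(rts, dtype=float)
    errors = np.asarray(error_flags, dtype=bool)
    if rts.shape != errors.shape:
        raise ValueError("rts and error_flags must align")
    correct = ~errors
    if correct.sum() == 0:
        raise ValueError("all trials are errors")
    mean = rts[correct].mean()
    sd = rts[correct].std(ddof=0)
    keep = correct & (np.abs(rts - mean) <= 3.0 * sd)
    return keep


# ---------------------------------------------------------------------------
# adaptive calculation task

@dataclass(frozen=True)
class CalcTrial:
    level: int
    operands: tuple[int, int]
    operator: str                 # "+", "-", "x"
    options: tuple[int, int, int]
    correct_index: int

    @property
    def answer(self) -> int:
        a, b = self.operands
        return {"+": a + b, "-": a - b, "x": a * b}[self.operator]

    @property
    def expression(self) -> str:
        return f"{self.operands[0]} {self.operator} {self.operands[1]}"


def _level_for(history) -> int:
    if not history:
        return 1
    acc = sum(1 for h in history if h) / len(history)
    return 2 if acc > 0.70 else 1


def next_calc_trial(history, seed: int = 0, distractor_distance: int = 10) -> CalcTrial:
    """Generate the next trial; difficulty follows running accuracy.

    Accuracy strictly above 70% over ``history`` (booleans: correct?)
    unlocks the level-2 pool (two-digit addition/subtraction and one-digit
    multiplication alongside the level-1 forms); otherwise only single-digit
    addition/subtraction is drawn. The rule is symmetric: dropping back
    below the threshold returns the task to level 1.
    """
    rng = np.random.default_rng((seed, len(history)))
    level = _level_for(list(history))
    if level == 1:
        op = "+" if rng.random() < 0.5 else "-"
        a, b = int(rng.integers(1, 10)), int(rng.integers(1, 10))
        if op == "-" and b > a:
            a, b = b, a
    else:
        form = rng.integers(3)  # 0: two-digit add, 1: two-digit sub, 2: 1-digit mult
        if form == 0:
            a = int(rng.integers(10, 90))
            b = int(rng.integers(1, 100 - a))
            op = "+"
        elif form == 1:
            a = int(rng.integers(10, 100))
            b = int(rng.integers(1, a + 1))
            op = "-"
        else:
            a, b = int(rng.integers(2, 10)), int(rng.integers(2, 10))
            op = "x"
    answer = {"+": a + b, "-": a - b, "x": a * b}[op]
    options = {answer}
    while len(options) < 3:
        d = int(rng.integers(1, distractor_distance + 1)) * (1 if rng.random() < 0.5 else -1)
        cand = answer + d
        if cand >= 0:
            options.add(cand)
    opts = list(options)
    rng.shuffle(opts)
    return CalcTrial(level=level, operands=(a, b), operator=op,
                     options=tuple(int(o) for o in opts),
                     correct_index=opts.index(answer))


# ---------------------------------------------------------------------------
# transfer paradigm

@dataclass(frozen=True)
class TransferConfig:
    block_len_s: float = 30.0
    n_blocks_per_condition: int = 6
    first_label: str = "Rest"
    second_label: str = "Regulation"


def transfer_paradigm(config: TransferConfig = TransferConfig()) -> EventTable:
    """Strictly alternating Rest/Regulation blocks, 6 of each by default."""
    rows = []
    labels = (config.first_label, config.second_label)
    for i in range(2 * config.n_blocks_per_condition):
        rows.append((i * config.block_len_s, config.block_len_s, labels[i % 2], {}))
    return EventTable(rows)
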