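"""Stimulus design, trial sequences, and subject cohorts.

The experimental design factorially crosses speakers, pseudowords, emotion
categories, and voice-morphing conditions.  With the default parameters this
yields 8 speakers x 3 pseudowords x 4 emotions x 3 morph conditions = 288
emotional stimuli, plus one emotionally uninformative "average" stimulus per
(speaker, pseudoword) pair, i.e. 312 stimuli in total.  Each stimulus is
presented twice (two independent random orderings of the full set), giving a
624-trial session split into 8 blocks of 78 trials; 10% of the trials carry a
response prompt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EMOTIONS = ("happiness", "pleasure", "fear", "sadness")
MORPH_CONDITIONS = ("full", "f0", "timbre")
PSEUDOWORDS = ("molen", "loman", "belam")
AVERAGE = "average"

#: columns of a stimulus-design table
DESIGN_COLUMNS = ["stimulus_id", "speaker", "pseudoword", "emotion", "morph"]
#: columns of a trial table
TRIAL_COLUMNS = ["trial_index", "stimulus_ref", "block", "repetition", "prompt"]


def _word_names(n_words: int) -> list[str]:
    if n_words <= len(PSEUDOWORDS):
        return list(PSEUDOWORDS[:n_words])
    extra = [f"word{i}" for i in range(len(PSEUDOWORDS) + 1, n_words + 1)]
    return list(PSEUDOWORDS) + extra


def build_stimulus_design(
    n_speakers: int = 8,
    n_words: int = 3,
    emotions: tuple[str, ...] = EMOTIONS,
    morph_conditions: tuple[str, ...] = MORPH_CONDITIONS,
    include_averages: bool = True,
) -> pd.DataFrame:
    """Build the factorial stimulus set.

    Returns a DataFrame with one row per stimulus and columns
    ``stimulus_id, speaker, pseudoword, emotion, morph``.  When
    ``include_averages`` is set, one emotionally averaged stimulus per
    (speaker, pseudoword) pair is appended with ``emotion == morph ==
    'average'``.
    """
    if n_speakers < 1 or n_words < 1:
        raise ValueError("n_speakers and n_words must be >= 1")
    if len(emotions) == 0 or len(morph_conditions) == 0:
        raise ValueError("emotions and morph_conditions must be non-empty")
    if AVERAGE in emotions or AVERAGE in morph_conditions:
        raise ValueError(f"{AVERAGE!r} is reserved for averaged stimuli")

    words = _word_names(n_words)
    rows = []
    for speaker in range(1, n_speakers + 1):
        for word in words:
            for emotion in emotions:
                for morph in morph_conditions:
                    rows.append((speaker, word, emotion, morph))
    if include_averages:
        for speaker in range(1, n_speakers + 1):
            for word in words:
                rows.append((speaker, word, AVERAGE, AVERAGE))
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS[1:])
    design.insert(0, "stimulus_id", np.arange(len(design)))
    return design


def build_trial_table(
    design: pd.DataFrame,
    n_reps: int = 2,
    n_blocks: int = 8,
    prompt_rate: float = 0.10,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Build a randomized trial sequence from a stimulus design.

    The full design is presented ``n_reps`` times, each repetition in an
    independent random order; the concatenated sequence is cut sequentially
    into ``n_blocks`` equal blocks.  Exactly ``round(prompt_rate * N)`` trials
    are flagged as response-prompt trials, sampled without replacement.
    Deterministic for a fixed seed.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_stimuli = len(design)
    n_trials = n_reps * n_stimuli
    if n_trials % n_blocks != 0:
        raise ValueError(
            f"{n_trials} trials ({n_reps} reps x {n_stimuli} stimuli) cannot be "
            f"split into {n_blocks} equal blocks"
        )
    if not 0.0 <= prompt_rate <= 1.0:
        raise ValueError("prompt_rate must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    stim_ids = design["stimulus_id"].to_numpy()
    order = np.concatenate([rng.permutation(stim_ids) for _ in range(n_reps)])
    repetition = np.repeat(np.arange(1, n_reps + 1), n_stimuli)

    block_size = n_trials // n_blocks
    block = 1 + np.arange(n_trials) // block_size

    n_prompts = round(prompt_rate * n_trials)
    prompt = np.zeros(n_trials, dtype=bool)
    prompt[rng.choice(n_trials, size=n_prompts, replace=False)] = True

    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n_trials + 1),
            "stimulus_ref": order,
            "block": block,
            "repetition": repetition,
            "prompt": prompt,
        }
    )


@dataclass(frozen=True)
class Subject:
    """A simulated participant: id, group membership, and private RNG seed."""

    subject_id: str
    group: str
    seed: int


def build_cohort(
    n_musicians: int = 38,
    n_non_musicians: int = 39,
    master_seed: int = 0,
) -> list[Subject]:
    """Build the two-group cohort with per-subject seeds derived from the
    master seed.

    Seeds are drawn from a child stream of ``master_seed`` so that every
    subject's data are reproducible independently; changing the cohort size
    never perturbs the seeds of earlier subjects.
    """
    if n_musicians < 0 or n_non_musicians < 0:
        raise ValueError("group sizes must be non-negative")

    def seed_for(group_code: int, index: int) -> int:
        ss = np.random.SeedSequence([int(master_seed), group_code, index])
        return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))

    subjects = []
    for i in range(n_musicians):
        subjects.append(Subject(f"mus{i + 1:02d}", "musician", seed_for(0, i)))
    for j in range(n_non_musicians):
        subjects.append(
            Subject(f"non{j + 1:02d}", "non_musician", seed_for(1, j)))
    return subjects
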