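"""Simulated 3AFC phoneme-discrimination experiment.

Drives the full pipeline: pick a token of each pair member, duration-match
the audio (unless the pair is exempt), vocode both members under the
condition's filterbank/carriers, assemble a roved three-interval trial and
let the simulated listener respond.  Vocoded stimuli and their listener
features are cached per (talker, pair, token indices, condition) since the
rove is re-applied per interval and the features are rove-invariant.

The full design is 53 pairs x 2 talkers x 2 repeats x 5 conditions = 1060
trials per simulated participant; scaled-down subsets (fewer pairs,
conditions or participants) use the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import (
    Corpus,
    DEFAULT_INTERNAL_NOISE_SD,
    PairSpec,
    _respond_from_features,
    stimulus_features,
)
from .levels import LevelSpec
from .stimulus import TrialRecord, assemble_trial, match_durations
from .synthesis import CONDITIONS, vocode

__all__ = ["ExperimentConfig", "run_experiment", "run_rove_only_trials"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of a (possibly scaled-down) simulated experiment."""

    conditions: tuple = tuple(CONDITIONS)
    n_participants: int = 26
    n_repeats: int = 2
    internal_noise_sd: float = DEFAULT_INTERNAL_NOISE_SD
    level_spec: LevelSpec = field(default_factory=LevelSpec)
    contrast_types: tuple | None = None  # restrict pairs; None = all
    seed: int = 0


def _pairs_for(config: ExperimentConfig, corpus: Corpus) -> list[PairSpec]:
    pairs = corpus.pairs
    if config.contrast_types is not None:
        pairs = [p for p in pairs if p.contrast_type in config.contrast_types]
    if not pairs:
        raise ValueError("no pairs match the requested contrast types")
    return pairs


def _cached_pair_stimuli(
    cache: dict,
    corpus: Corpus,
    talker: str,
    pair: PairSpec,
    ia: int,
    ib: int,
    condition: str,
    level_spec: LevelSpec,
):
    key = (talker, pair.pair_id, ia, ib, condition)
    if key not in cache:
        tok_a = corpus.tokens[(talker, pair.token_a)][ia]
        tok_b = corpus.tokens[(talker, pair.token_b)][ib]
        tok_a, tok_b = match_durations(tok_a, tok_b, exempt=pair.exempt)
        stim_a = vocode(tok_a, condition, level_spec, apply_rove=False)
        stim_b = vocode(tok_b, condition, level_spec, apply_rove=False)
        cache[key] = (stim_a, stim_b)
    return cache[key]


def run_experiment(corpus: Corpus, config: ExperimentConfig) -> pd.DataFrame:
    """Simulate all participants; returns one row per trial.

    Columns: participant, condition, pair_id, contrast_type, phoneme_class,
    talker, repeat, odd_interval, response, correct, rove offsets.
    """
    pairs = _pairs_for(config, corpus)
    unknown = [c for c in config.conditions if c not in CONDITIONS]
    if unknown:
        raise ValueError(f"unknown conditions: {unknown}")
    cache: dict = {}
    rows = []
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_participants)
    for p_idx, seq in enumerate(seeds):
        rng = np.random.default_rng(seq)
        for condition in config.conditions:
            for pair in pairs:
                consonant = PairSpec(pair.token_a, pair.token_b, pair.contrast_type)
                for talker in corpus.talkers:
                    n_avail = len(corpus.tokens[(talker, pair.token_a)])
                    for repeat in range(config.n_repeats):
                        ia = int(rng.integers(n_avail))
                        ib = int(rng.integers(n_avail))
                        stim_a, stim_b = _cached_pair_stimuli(
                            cache, corpus, talker, pair, ia, ib, condition,
                            config.level_spec,
                        )
                        trial = assemble_trial(
                            stim_a,
                            stim_b,
                            rng,
                            level_spec=config.level_spec,
                            pair_id=pair.pair_id,
                            talker_id=talker,
                        )
                        feats = [
                            stimulus_features(s) for s in trial.interval_stimuli
                        ]
                        response = _respond_from_features(
                            feats, config.internal_noise_sd, rng
                        )
                        trial.respond(response)
                        rows.append(
                            dict(
                                participant=p_idx,
                                condition=condition,
                                pair_id=pair.pair_id,
                                contrast_type=pair.contrast_type,
                                phoneme_class=(
                                    "vowel"
                                    if pair.contrast_type.startswith(
                                        ("monophthong", "diphthong")
                                    )
                                    else "consonant"
                                ),
                                talker=talker,
                                repeat=repeat,
                                token_a=ia,
                                token_b=ib,
                                odd_interval=trial.odd_interval,
                                response=trial.response,
                                correct=trial.correct,
                                rove_db_0=trial.rove_offsets_db[0],
                                rove_db_1=trial.rove_offsets_db[1],
                                rove_db_2=trial.rove_offsets_db[2],
                            )
                        )
    return pd.DataFrame(rows)


def run_rove_only_trials(
    corpus: Corpus,
    condition: str = "8FB8T",
    n_trials: int = 200,
    internal_noise_sd: float = DEFAULT_INTERNAL_NOISE_SD,
    level_spec: LevelSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Control trials where every interval holds the same token.

    Only the level rove differs between intervals; a listener with no
    access to absolute intensity must perform at chance (1/3).
    """
    level_spec = level_spec or LevelSpec()
    rng = np.random.default_rng(seed)
    keys = sorted(corpus.tokens)
    stim_cache: dict = {}
    rows = []
    for i in range(n_trials):
        talker, phoneme = keys[int(rng.integers(len(keys)))]
        tok_idx = int(rng.integers(len(corpus.tokens[(talker, phoneme)])))
        ckey = (talker, phoneme, tok_idx, condition)
        if ckey not in stim_cache:
            stim_cache[ckey] = vocode(
                corpus.tokens[(talker, phoneme)][tok_idx],
                condition,
                level_spec,
                apply_rove=False,
            )
        stim = stim_cache[ckey]
        trial = assemble_trial(
            stim, stim, rng, level_spec=level_spec,
            pair_id=f"{phoneme}-{phoneme}", talker_id=talker,
        )
        feats = [stimulus_features(s) for s in trial.interval_stimuli]
        trial.respond(_respond_from_features(feats, internal_noise_sd, rng))
        rows.append(
            dict(
                trial=i,
                talker=talker,
                phoneme=phoneme,
                condition=condition,
                odd_interval=trial.odd_interval,
                response=trial.response,
                correct=trial.correct,
            )
        )
    return pd.DataFrame(rows)
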