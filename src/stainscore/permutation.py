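"""Empirical null distributions of the staining score from random gene lists.

Repeatedly samples gene lists of fixed sizes uniformly (without
replacement) from the atlas gene universe, scores each list, and records
both the top-k staining scores and the full score vector per run.  On a
heterogeneous atlas the all-results distribution shifts downward as the
list grows: seldom-scored, weakly-staining cell types enter the result
table (t >= 1) more often with larger lists.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .enriched import Stringency, filter_by_stringency
from .errors import ConfigurationError, EmptyInputError
from .scoring import ScoreOptions, score_query


@dataclasses.dataclass(frozen=True)
class PermutationConfig:
    """Null-study parameters.

    The full profile is 1000 runs over list sizes 10/25/50/100 keeping the
    top 10 scores per run; tests use a reduced run count.
    """

    n_runs: int = 1000
    list_sizes: tuple[int, ...] = (10, 25, 50, 100)
    top_k: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 1 or self.top_k < 1 or min(self.list_sizes) < 1:
            raise ConfigurationError("runs, sizes and top_k must be positive")


@dataclasses.dataclass
class PermutationResult:
    """Null scores for one list size.

    ``top_scores`` is (n_runs, top_k), NaN-padded when a run produced
    fewer cell types; ``all_scores`` concatenates every run's full score
    vector.
    """

    size: int
    top_scores: np.ndarray
    all_scores: np.ndarray
    run_lengths: np.ndarray


def run_permutations(
    records: pd.DataFrame,
    config: PermutationConfig,
    stringency: Optional[Stringency] = None,
) -> dict[int, PermutationResult]:
    """Run the null study; fully reproducible from ``config.seed``.

    The sampling frame is the sorted set of distinct gene symbols in the
    atlas (optionally restricted to stringency-admitted records).  Seeds
    are split per (size, run) so results for early sizes are unchanged by
    adding later ones.
    """
    frame_records = (
        filter_by_stringency(records, stringency) if stringency is not None else records
    )
    universe = np.sort(frame_records["gene_name"].str.upper().unique())
    if universe.size == 0:
        raise EmptyInputError("atlas contains no genes")
    if max(config.list_sizes) > universe.size:
        raise ConfigurationError(
            f"list size {max(config.list_sizes)} exceeds gene universe {universe.size}"
        )

    opts = ScoreOptions(show_proteins=False, compute_pvalues=False)
    root = np.random.SeedSequence(config.seed)
    size_seqs = root.spawn(len(config.list_sizes))
    out: dict[int, PermutationResult] = {}
    for size, size_seq in zip(config.list_sizes, size_seqs):
        run_seqs = size_seq.spawn(config.n_runs)
        tops = np.full((config.n_runs, config.top_k), np.nan)
        all_parts = []
        lengths = np.empty(config.n_runs, dtype=int)
        for j, run_seq in enumerate(run_seqs):
            rng = np.random.default_rng(run_seq)
            genes = rng.choice(universe, size=size, replace=False)
            scores = score_query(records, list(genes), opts)["staining_score"].to_numpy()
            k = min(config.top_k, scores.size)
            tops[j, :k] = scores[:k]  # score_query returns scores sorted descending
            all_parts.append(scores)
            lengths[j] = scores.size
        out[size] = PermutationResult(
            size=size,
            top_scores=tops,
            all_scores=np.concatenate(all_parts),
            run_lengths=lengths,
        )
    return out


def summarize_null(scores) -> Mapping[str, float]:
    """Moment and quantile summary of a null score sample.

    Skewness is the Fisher-Pearson moment coefficient, reported as 0 for
    a constant sample (where it is otherwise undefined).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise EmptyInputError("no scores to summarize")
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
    skew = float(stats.skew(arr)) if sd > 0 else 0.0
    q = np.percentile(arr, [0, 25, 50, 75, 100])
    return {
        "n": int(arr.size),
        "mean": float(np.mean(arr)),
        "sd": sd,
        "min": float(q[0]),
        "q25": float(q[1]),
        "median": float(q[2]),
        "q75": float(q[3]),
        "max": float(q[4]),
        "skewness": skew,
    }
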