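"""Coding of raw recall transcripts into model-ready category counts.

Implements the scoring pipeline for the two recall paradigms: fuzzy
matching of typed responses to the study vocabulary (verbatim recall
with at most one typo), pair-clustering category coding (E1-E4 pair
events, F1/F2 singleton events), free-then-cued coding (C1-C6), the
Adjusted Ratio of Clustering (ARC), and the working-memory-capacity
composite from complex-span scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "StudyList",
    "Transcript",
    "ScoredRecall",
    "ArcResult",
    "SpanRecord",
    "match_response",
    "score_transcript",
    "code_pair_clustering",
    "code_free_then_cued",
    "arc_score",
    "wmc_composite",
    "cronbach_alpha",
]


@dataclass(frozen=True)
class StudyList:
    """Stimulus definition: word pairs with category labels, singletons, order.

    For pair-clustering lists the two members of each pair must be
    separated in the presentation order by one to four intervening words.
    """

    pairs: tuple[tuple[str, str, str], ...]  # (word_a, word_b, category_label)
    singletons: tuple[tuple[str, str], ...]  # (word, category_label)
    presentation_order: tuple[str, ...] = ()
    enforce_lag: bool = True

    def __post_init__(self) -> None:
        words = list(self.all_words())
        if len(set(words)) != len(words):
            raise ValueError("study-list words must be unique")
        if self.presentation_order:
            if sorted(self.presentation_order) != sorted(words):
                raise ValueError("presentation order must be a permutation of all words")
            if self.enforce_lag:
                pos = {w: i for i, w in enumerate(self.presentation_order)}
                for a, b, cat in self.pairs:
                    lag = abs(pos[a] - pos[b]) - 1
                    if not (1 <= lag <= 4):
                        raise ValueError(
                            f"pair {cat!r}: members separated by {lag} intervening "
                            "words; the design requires 1-4"
                        )

    def all_words(self) -> Iterable[str]:
        for a, b, _ in self.pairs:
            yield a
            yield b
        for w, _ in self.singletons:
            yield w

    def category_of(self, word: str) -> str:
        for a, b, cat in self.pairs:
            if word in (a, b):
                return cat
        for w, cat in self.singletons:
            if word == w:
                return cat
        raise KeyError(word)


@dataclass(frozen=True)
class Transcript:
    """Raw typed recall of one participant, in output order."""

    person_id: str
    responses: tuple[str, ...]
    cued_responses: Mapping[str, str] | None = None  # cue word -> typed response

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "responses", tuple(r for r in self.responses if r.strip())
        )


@dataclass(frozen=True)
class ScoredRecall:
    """Coded transcript: matched study words in output order, plus leftovers.

    ``raw_positions`` optionally records each matched word's index in the
    raw transcript (including intrusions/duplicates), for the
    ``adjacency='raw_output'`` coding variant.
    """

    matched: tuple[str, ...]
    intrusions: tuple[str, ...] = ()
    duplicates: tuple[str, ...] = ()
    raw_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.matched)) != len(self.matched):
            raise ValueError("matched sequence may not repeat a word")
        if self.raw_positions and len(self.raw_positions) != len(self.matched):
            raise ValueError("raw_positions must align with matched")


@dataclass(frozen=True)
class ArcResult:
    """Adjusted Ratio of Clustering: chance-corrected category repetitions.

    ``arc = (R - expected_R) / (max_R - expected_R)`` where R counts
    adjacent same-category transitions in the recall output, expected_R
    is its chance value under random output order, and max_R = N - k.
    ``arc`` is None (undefined) when max_R equals expected_R.
    """

    R: int
    expected_R: float
    max_R: int
    arc: float | None

    @property
    def defined(self) -> bool:
        return self.arc is not None


@dataclass(frozen=True)
class SpanRecord:
    person_id: str
    operation_score: float | None = None
    symmetry_score: float | None = None

    @property
    def n_valid(self) -> int:
        return (self.operation_score is not None) + (self.symmetry_score is not None)


def _distance(a: str, b: str, k: int = 1) -> int:
    """Levenshtein distance, capped at k+1 (edlib returns -1 beyond k)."""
    d = edlib.align(a, b, k=k)["editDistance"]
    return d if d >= 0 else k + 1


def match_response(
    response: str,
    vocabulary: Iterable[str],
    already_matched: Iterable[str] = (),
) -> str | None:
    """Match a typed response to the study vocabulary, allowing one typo.

    Case-folding and whitespace trimming precede the comparison; the
    distance is full Levenshtein (insertion, deletion, substitution each
    cost 1).  Returns the unique vocabulary word at distance <= 1, or
    None.  A tie between two candidates at equal minimal distance is
    resolved in favor of a word not yet recalled (``already_matched``);
    an unresolvable tie yields None and is logged.
    """
    vocab = list(vocabulary)
    if not vocab:
        raise ValueError("vocabulary must be non-empty")
    resp = response.strip().casefold()
    dists = [_distance(resp, w.strip().casefold()) for w in vocab]
    best = min(dists)
    if best > 1:
        return None
    candidates = [w for w, d in zip(vocab, dists) if d == best]
    if len(candidates) == 1:
        return candidates[0]
    seen = set(already_matched)
    fresh = [w for w in candidates if w not in seen]
    if len(fresh) == 1:
        return fresh[0]
    logger.info(
        "ambiguous response %r matches %s at distance %d; not credited",
        response, candidates, best,
    )
    return None


def score_transcript(t: Transcript, study_list: StudyList) -> ScoredRecall:
    """Apply fuzzy matching token-wise in output order.

    Keeps the first occurrence of each matched study word; later
    re-matches are recorded as duplicates, unmatched strings as
    intrusions.  An empty transcript codes as zero recall.
    """
    vocab = list(study_list.all_words())
    matched: list[str] = []
    positions: list[int] = []
    intrusions: list[str] = []
    duplicates: list[str] = []
    for i, resp in enumerate(t.responses):
        w = match_response(resp, vocab, already_matched=matched)
        if w is None:
            intrusions.append(resp)
        elif w in matched:
            duplicates.append(w)
        else:
            matched.append(w)
            positions.append(i)
    return ScoredRecall(
        tuple(matched), tuple(intrusions), tuple(duplicates), tuple(positions)
    )


def code_pair_clustering(
    s: ScoredRecall,
    study_list: StudyList,
    adjacency: str = "matched_only",
) -> dict[str, np.ndarray]:
    """Code a scored free-recall transcript into pair-clustering counts.

    Per pair: E1 if both members were recalled immediately adjacently
    (either order), E2 if both recalled but separated, E3 if exactly one,
    E4 if neither.  Singletons: F1 recalled, F2 not.  With the default
    ``adjacency='matched_only'`` adjacency is judged on the matched-word
    sequence after intrusions and duplicate repeats are removed, so an
    intrusion between pair members does not break adjacency but an
    intervening different study word does.  ``adjacency='raw_output'``
    instead judges adjacency on raw transcript positions (requires
    ScoredRecall.raw_positions, i.e. output of :func:`score_transcript`),
    so intrusions and duplicates do break adjacency.
    """
    if adjacency == "matched_only":
        pos = {w: i for i, w in enumerate(s.matched)}
    elif adjacency == "raw_output":
        if len(s.raw_positions) != len(s.matched):
            raise ValueError("raw_output adjacency requires raw_positions")
        pos = {w: p for w, p in zip(s.matched, s.raw_positions)}
    else:
        raise ValueError(f"unknown adjacency mode {adjacency!r}")
    e = np.zeros(4, dtype=int)
    for a, b, _ in study_list.pairs:
        ia, ib = pos.get(a), pos.get(b)
        if ia is not None and ib is not None:
            e[0 if abs(ia - ib) == 1 else 1] += 1
        elif ia is not None or ib is not None:
            e[2] += 1
        else:
            e[3] += 1
    f = np.zeros(2, dtype=int)
    for w, _ in study_list.singletons:
        f[0 if w in pos else 1] += 1
    return {"pairs": e, "singletons": f}


def code_free_then_cued(
    free: ScoredRecall,
    cued: Mapping[str, str],
    study_list: StudyList,
) -> dict[str, np.ndarray]:
    """Code free-then-cued recall into the six C categories.

    Pairs are (cue, target); free-recall status (both / one / none) comes
    from the matched free-recall set, cued status is success iff the
    response typed under that pair's cue matches the target within one
    typo.  Categories: C1 both+success, C2 both+fail, C3 one+success,
    C4 one+fail, C5 none+success, C6 none+fail.
    """
    cues = {a for a, _, _ in study_list.pairs}
    for cue in cued:
        if cue not in cues:
            raise ValueError(f"cued response for unknown cue {cue!r}")
    recalled = set(free.matched)
    c = np.zeros(6, dtype=int)
    for cue, target, _ in study_list.pairs:
        n_free = (cue in recalled) + (target in recalled)
        resp = (cued.get(cue) or "").strip()
        ok = bool(resp) and _distance(resp.casefold(), target.strip().casefold()) <= 1
        row = {2: 0, 1: 2, 0: 4}[n_free] + (0 if ok else 1)
        c[row] += 1
    return {"pairs": c}


def arc_score(s: ScoredRecall, study_list: StudyList) -> ArcResult:
    """Adjusted Ratio of Clustering of the matched recall sequence.

    Each word pair forms one category; singletons are each their own
    category, so only pair repetitions can contribute.  R is the number
    of adjacent same-category transitions; expected_R = sum(n_i^2)/N - 1;
    max_R = N - k.  The score is undefined (arc=None) when the
    denominator max_R - expected_R is zero, e.g. when at most one word
    per category was recalled.
    """
    cats = [study_list.category_of(w) for w in s.matched]
    N = len(cats)
    if N == 0:
        return ArcResult(R=0, expected_R=0.0, max_R=0, arc=None)
    R = sum(1 for x, y in zip(cats, cats[1:]) if x == y)
    counts = pd.Series(cats).value_counts()
    expected = float((counts**2).sum()) / N - 1.0
    max_R = N - len(counts)
    denom = max_R - expected
    arc = (R - expected) / denom if abs(denom) > 1e-12 else None
    return ArcResult(R=R, expected_R=expected, max_R=max_R, arc=arc)


def wmc_composite(records: Sequence[SpanRecord]) -> pd.DataFrame:
    """Working-memory-capacity composite: per-task z-scores, averaged.

    Scores are z-standardized within task over all valid scores in the
    analyzed sample; the composite is the mean of the available z-scores,
    so a participant with a single valid span score contributes that
    score's z-transform as a proxy.  Participants with no valid score are
    excluded (logged).  Standardizing a task whose valid scores have zero
    variance is an error.
    """
    rows = []
    for r in records:
        if r.n_valid == 0:
            logger.info("excluding %s: no valid span score", r.person_id)
            continue
        rows.append(r)
    if not rows:
        return pd.DataFrame(columns=["person_id", "wmc_z"]).set_index("person_id")

    def zscores(values: list[float | None], task: str) -> list[float | None]:
        valid = np.array([v for v in values if v is not None], dtype=float)
        if valid.size == 0:
            return [None] * len(values)
        if valid.size < 2 or valid.std(ddof=1) == 0:
            raise ValueError(f"cannot standardize {task}: zero variance or <2 valid scores")
        mu, sd = valid.mean(), valid.std(ddof=1)
        return [None if v is None else (v - mu) / sd for v in values]

    z_op = zscores([r.operation_score for r in rows], "operation span")
    z_sym = zscores([r.symmetry_score for r in rows], "symmetry span")
    out = []
    for r, zo, zs in zip(rows, z_op, z_sym):
        zvals = [z for z in (zo, zs) if z is not None]
        out.append({"person_id": r.person_id, "wmc_z": float(np.mean(zvals))})
    return pd.DataFrame(out).set_index("person_id")


def cronbach_alpha(item_scores: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha internal-consistency estimate.

    ``item_scores`` is persons x items.  alpha = k/(k-1) * (1 - sum of
    item variances / variance of person totals); variances use the
    unbiased (n-1) denominator.  Raises on zero total variance.
    """
    x = np.asarray(item_scores, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 persons and 2 items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1).sum()
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero variance of person totals; alpha undefined")
    return float(k / (k - 1) * (1.0 - item_var / total_var))
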