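"""File formats: counts/covariate CSV, study-list and transcript JSON, EQN."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .coding import StudyList, Transcript
from .models import MPTModel, PersonCounts

__all__ = [
    "write_counts_csv", "read_counts_csv",
    "write_covariates_csv", "read_covariates_csv",
    "write_study_list_json", "read_study_list_json",
    "write_transcripts_json", "read_transcripts_json",
    "write_transcripts_csv", "read_transcripts_csv",
]


def write_counts_csv(path, counts: PersonCounts, model: MPTModel) -> None:
    counts.to_dataframe(model).to_csv(path, index=False)


def read_counts_csv(path, model: MPTModel) -> PersonCounts:
    return PersonCounts.from_dataframe(pd.read_csv(path), model)


def write_covariates_csv(path, covariates: pd.DataFrame) -> None:
    covariates.reset_index().to_csv(path, index=False)


def read_covariates_csv(path) -> pd.DataFrame:
    return pd.read_csv(path).set_index("person_id")


def write_study_list_json(path, sl: StudyList) -> None:
    Path(path).write_text(json.dumps(dict(
        pairs=[list(p) for p in sl.pairs],
        singletons=[list(s) for s in sl.singletons],
        presentation_order=list(sl.presentation_order),
        enforce_lag=sl.enforce_lag,
    ), indent=1))


def read_study_list_json(path) -> StudyList:
    d = json.loads(Path(path).read_text())
    return StudyList(
        pairs=tuple(tuple(p) for p in d["pairs"]),
        singletons=tuple(tuple(s) for s in d["singletons"]),
        presentation_order=tuple(d.get("presentation_order", ())),
        enforce_lag=bool(d.get("enforce_lag", True)),
    )


def write_transcripts_json(path, transcripts: list[Transcript]) -> None:
    Path(path).write_text(json.dumps([
        dict(person_id=t.person_id, responses=list(t.responses),
             cued_responses=dict(t.cued_responses) if t.cued_responses else None)
        for t in transcripts
    ], indent=1))


def read_transcripts_json(path) -> list[Transcript]:
    data = json.loads(Path(path).read_text())
    return [
        Transcript(d["person_id"], tuple(d["responses"]),
                   d.get("cued_responses") or None)
        for d in data
    ]


def write_transcripts_csv(path, transcripts: list[Transcript]) -> None:
    """Free-recall-only CSV: person_id, position, response."""
    rows = [
        dict(person_id=t.person_id, position=i, response=r)
        for t in transcripts for i, r in enumerate(t.responses)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transcripts_csv(path) -> list[Transcript]:
    df = pd.read_csv(path).sort_values(["person_id", "position"])
    return [
        Transcript(str(pid), tuple(g["response"].astype(str)))
        for pid, g in df.groupby("person_id", sort=True)
    ]
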