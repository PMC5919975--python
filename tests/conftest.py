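import numpy as np
import pandas as pd
import pytest

from sempe import behavior
from sempe import pe as pe_mod
from sempe.config import ParadigmConfig, substream
from sempe.paradigm import simulate_cohort


@pytest.fixture(scope="session")
def recall_cohort() -> pd.DataFrame:
    """Fixed-seed recall cohort at the study's size (20 subjects x 100)."""
    cfg = ParadigmConfig.recall(n_subjects=20)
    return simulate_cohort(cfg, substream(11, "recall-fixture"))


@pytest.fixture(scope="session")
def recognition_cohort() -> pd.DataFrame:
    """Fixed-seed recognition cohort (27 subjects x 100, confidence grid 10)."""
    cfg = ParadigmConfig.recognition(n_subjects=27)
    return simulate_cohort(cfg, substream(12, "recognition-fixture"))


@pytest.fixture(scope="session")
def recall_kept(recall_cohort) -> pd.DataFrame:
    return behavior.prepare(recall_cohort)


@pytest.fixture(scope="session")
def recognition_kept(recognition_cohort) -> pd.DataFrame:
    return behavior.prepare(recognition_cohort)


def toy_trials(rows: list[dict]) -> pd.DataFrame:
    """Minimal trial table with defaults filled in."""
    defaults = dict(
        subject_id=0,
        test1_correct=False,
        test1_confidence=40,
        skipped=False,
        feedback_kind="veridical",
        test2_outcome="incorrect",
        test2_confidence=0,
    )
    out = []
    for i, r in enumerate(rows):
        d = dict(defaults, question_id=i)
        d.update(r)
        out.append(d)
    return pd.DataFrame(out)
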