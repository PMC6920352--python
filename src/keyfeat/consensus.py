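"""Step 3: cross-magnification consensus and per-patient feature vectors.

A patch's "character" is positive when its impact score exceeds 0.5 and
negative when below; scores of exactly 0.5, or missing scores, are ties.
Only patches whose Step-1 and Step-2 characters are both defined and agree
are retained.  Retained patches are tallied per feature into slide count
vectors; a patient's vector is the mean over their slides, elementwise
multiplied by the predictive weight w_k = 1 + |I_k - 0.5|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .step1_features import Assignment, ImpactProfile

POSITIVE, NEGATIVE, TIE = "positive", "negative", "tie"


def classify_character(score: float) -> str:
    """Impact-score character: >0.5 positive, <0.5 negative, else tie."""
    if score is None or np.isnan(score):
        return TIE
    if score > 0.5:
        return POSITIVE
    if score < 0.5:
        return NEGATIVE
    return TIE


@dataclass
class ConsensusResult:
    """Per-patch characters at both steps and the retained mask."""

    character1: np.ndarray  # (N,) str
    character2: np.ndarray  # (N,) str
    retained: np.ndarray    # (N,) bool

    def __len__(self) -> int:
        return len(self.retained)


def consensus_filter(scores1: np.ndarray, scores2: np.ndarray
                     ) -> ConsensusResult:
    """Retain patches whose Step-1/Step-2 characters are equal and not ties."""
    s1 = np.asarray(scores1, dtype=np.float64)
    s2 = np.asarray(scores2, dtype=np.float64)
    if s1.shape != s2.shape:
        raise ValueError(
            f"score sets cover different patch refs: {s1.shape} vs {s2.shape}"
        )
    c1 = np.array([classify_character(s) for s in s1])
    c2 = np.array([classify_character(s) for s in s2])
    retained = (c1 == c2) & (c1 != TIE)
    return ConsensusResult(c1, c2, retained)


@dataclass
class SlideFeatureVector:
    slide_id: str
    counts: np.ndarray  # (K,) retained-patch counts per feature


def feature_counts(assignment: Assignment, retained: np.ndarray,
                   background: Optional[set[int]] = None,
                   slide_id: str = "") -> SlideFeatureVector:
    """Count retained patches per non-background feature for one slide."""
    retained = np.asarray(retained, dtype=bool)
    if len(retained) != len(assignment):
        raise ValueError("retained mask and assignment must align")
    counts = np.bincount(assignment.labels[retained],
                         minlength=assignment.n_clusters).astype(np.float64)
    for k in (background or ()):
        counts[k] = 0.0
    return SlideFeatureVector(slide_id, counts)


@dataclass
class PatientFeatureVector:
    patient_id: str
    values: np.ndarray  # (K,) weighted mean feature counts


def aggregate_patient(slide_vectors: Sequence[SlideFeatureVector],
                      profile: ImpactProfile,
                      patient_id: str = "") -> PatientFeatureVector:
    """Average a patient's slide vectors and apply w_k = 1 + |I_k - 0.5|.

    Undefined impact scores contribute a neutral weight of 1.
    """
    if not slide_vectors:
        raise ValueError(f"patient {patient_id!r} has no slide vectors")
    stack = np.stack([sv.counts for sv in slide_vectors])
    if stack.shape[1] != profile.n_clusters:
        raise ValueError("slide vectors and impact profile have different K")
    return PatientFeatureVector(patient_id,
                                stack.mean(axis=0) * profile.weights())


def feature_matrix(patient_vectors: Iterable[PatientFeatureVector]
                   ) -> pd.DataFrame:
    """Patients-by-features table with feature ids as columns."""
    vecs = list(patient_vectors)
    return pd.DataFrame(
        np.stack([v.values for v in vecs]),
        index=[v.patient_id for v in vecs],
        columns=[f"f{k}" for k in range(len(vecs[0].values))],
    )
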