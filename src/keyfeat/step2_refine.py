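"""Step 2: high-magnification refinement at bottleneck-unit granularity.

Each 28-px sub-patch is scored by the argmax of its bottleneck activation
vector v',

    u'_{i,j,j',k'} = 1  if k' = argmax_{k'} v'_{i,j,j',k'},  else 0,

units receive group-normalised hit degrees r'_pos,k' and r'_neg,k'
(mirroring Step 1's Eqs. at unit granularity), and the refinement score of
a low-magnification patch is the mean unit impact over its m sub-patches:

    I'_{i,j} = sum_{j'} sum_{k'} [r'_pos,k' / (r'_pos,k' + r'_neg,k')]
               * u'_{i,j,j',k'} / m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .step1_features import ImpactProfile


def standardize_units(codes: np.ndarray,
                      mean: np.ndarray | None = None,
                      std: np.ndarray | None = None,
                      eps: float = 1e-6) -> np.ndarray:
    """Z-score each bottleneck unit across sub-patches.

    Raw bottleneck activations carry per-unit scale differences (some units
    sit at a high baseline for every input), which would let a single unit
    win the argmax everywhere.  Standardising each unit to its typical
    response level makes winner-take-all reflect which unit responds most
    strongly *for this particular sub-patch*.  ``mean``/``std`` may be
    supplied (e.g. from a training subset) for out-of-sample scoring.
    """
    codes = np.asarray(codes, dtype=np.float64)
    if mean is None:
        mean = codes.mean(axis=0)
    if std is None:
        std = codes.std(axis=0)
    return (codes - mean) / (std + eps)


@dataclass
class UnitActivationAssignment:
    """Argmax bottleneck unit per sub-patch (one-hot u')."""

    units: np.ndarray       # (N,) int, winning unit k'*
    activations: np.ndarray  # (N,) float, winning activation value
    n_units: int

    def __len__(self) -> int:
        return len(self.units)

    def one_hot(self) -> np.ndarray:
        u = np.zeros((len(self.units), self.n_units), dtype=np.int8)
        u[np.arange(len(self.units)), self.units] = 1
        return u


def unit_activations(codes: np.ndarray) -> UnitActivationAssignment:
    """Winner-take-all over bottleneck units; ties go to the smallest index."""
    codes = np.asarray(codes)
    if codes.ndim != 2:
        raise ValueError("expected a (sub-patches x units) activation matrix")
    if not np.isfinite(codes).all():
        raise ValueError("non-finite activations in the code matrix")
    units = np.argmax(codes, axis=1)
    return UnitActivationAssignment(
        units, codes[np.arange(len(codes)), units].astype(np.float64),
        codes.shape[1],
    )


def compute_unit_profile(assignment: UnitActivationAssignment,
                         is_positive: np.ndarray) -> ImpactProfile:
    """Per-unit positive/negative degrees from grouped sub-patch hits."""
    is_positive = np.asarray(is_positive, dtype=bool)
    if len(is_positive) != len(assignment):
        raise ValueError("group labels and assignment must align")
    n_pos = int(is_positive.sum())
    n_neg = int((~is_positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome groups need at least one sub-patch")
    k = assignment.n_units
    pos = np.bincount(assignment.units[is_positive], minlength=k)
    neg = np.bincount(assignment.units[~is_positive], minlength=k)
    r_pos = pos / n_pos
    r_neg = neg / n_neg
    with np.errstate(invalid="ignore", divide="ignore"):
        impact = np.where(r_pos + r_neg > 0, r_pos / (r_pos + r_neg), np.nan)
    return ImpactProfile(r_pos, r_neg, impact, n_pos, n_neg)


def region_impact(assignment: UnitActivationAssignment,
                  profile: ImpactProfile,
                  region_index: np.ndarray,
                  n_regions: int) -> np.ndarray:
    """Mean unit impact per low-magnification patch, I'_{i,j}.

    ``region_index`` maps each sub-patch to the low-magnification patch it
    came from (0..n_regions-1).  Patches with no scored sub-patch (m = 0)
    are returned as NaN.  Units hit by at least one sub-patch always have a
    positive degree sum, so every hit unit has a defined impact.
    """
    if profile.n_clusters != assignment.n_units:
        raise ValueError("profile and assignment have different unit counts")
    region_index = np.asarray(region_index)
    if len(region_index) != len(assignment):
        raise ValueError("region index and assignment must align")
    unit_impact = profile.impact[assignment.units]
    scored = ~np.isnan(unit_impact)
    sums = np.bincount(region_index[scored], weights=unit_impact[scored],
                       minlength=n_regions)
    m = np.bincount(region_index[scored], minlength=n_regions)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(m > 0, sums / m, np.nan)
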