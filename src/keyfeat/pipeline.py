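"""End-to-end orchestration on synthetic cohorts.

Runs the full chain — cohort generation, streaming slide tiling at both
magnifications, autoencoder training and encoding, Step 1 clustering and
impact scoring, Step 2 unit refinement, Step 3 consensus and per-patient
aggregation — and returns every intermediate artifact so that validation
checks (ground-truth recovery, label permutation) can reuse the expensive
stages.

The default problem sizes here are desk-scale study conditions: slides of
4x4 1024-px regions, 20 clusters, 64/48-unit bottlenecks and 16 sampled
sub-patches per region, trainable in a couple of minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import consensus as cons
from . import prediction, step1_features, step2_refine
from .autoencoder import Autoencoder, EncoderConfig
from .synthdata import (BACKGROUND, POSITIVE, SyntheticCohortSpec,
                        class_enrichment, generate_cohort)
from .tiling import SUB_PATCH_SIZE, block_mean_downsample, tile


def _small_low_config(seed: int = 0) -> EncoderConfig:
    return EncoderConfig(input_size_px=128, code_dim=128,
                         conv_blocks=((16, 16),), epochs=5, seed=seed,
                         learning_rate=3e-3)


def _small_high_config(seed: int = 0) -> EncoderConfig:
    return EncoderConfig(input_size_px=28, code_dim=48,
                         conv_blocks=((7, 12),), epochs=5, seed=seed)


@dataclass
class PipelineConfig:
    """Problem sizes and model settings for one end-to-end run."""

    k_clusters: int = 20
    low_config: Optional[EncoderConfig] = None
    high_config: Optional[EncoderConfig] = None
    subpatches_per_region: int = 16
    max_train_patches: int = 4000
    horizon_months: float = 12.0
    kmeans_restarts: int = 10


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    cohort: pd.DataFrame
    analysis: pd.DataFrame            # after the exclusion cascade
    patch_refs: pd.DataFrame          # one row per low-magnification patch
    cluster_model: step1_features.ClusterModel
    assignment: step1_features.Assignment
    profile1: step1_features.ImpactProfile
    scores1: np.ndarray               # I_{i,j}
    unit_assignment: step2_refine.UnitActivationAssignment
    sub_region_index: np.ndarray      # sub-patch -> patch row index
    profile2: step1_features.ImpactProfile
    scores2: np.ndarray               # I'_{i,j}
    retained: np.ndarray
    key_patch: np.ndarray             # bool: patch in the key-feature subset
    features: pd.DataFrame            # patients x K weighted feature matrix
    labels: pd.Series                 # outcome at the horizon, per patient
    enrichment: np.ndarray            # ground-truth e_k per texture class
    low_encoder: Autoencoder
    high_encoder: Autoencoder

    @property
    def patch_is_positive(self) -> np.ndarray:
        return self.patch_refs["is_positive"].to_numpy()


def run_pipeline(spec: SyntheticCohortSpec, seed: int,
                 config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full key-feature pipeline on one synthetic cohort."""
    config = config or PipelineConfig()
    low_cfg = config.low_config or _small_low_config(seed)
    high_cfg = config.high_config or _small_high_config(seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9199]))

    cohort, slides = generate_cohort(spec, seed)
    analysis, _ = prediction.apply_cohort_filter(cohort)
    groups = dict(zip(analysis["patient_id"], analysis["group"]))

    # --- streaming patch collection at both magnifications ----------------
    low_patches, refs = [], []
    sub_patches, sub_region = [], []
    for pid in analysis["patient_id"]:
        for s_idx in range(spec.slides_per_patient):
            for r, c, cls, region in slides.iter_regions(pid, s_idx):
                patch_idx = len(low_patches)
                low_patches.append(block_mean_downsample(region))
                refs.append((pid, s_idx, r, c, cls,
                             groups[pid] == POSITIVE))
                grid = tile(region, SUB_PATCH_SIZE)
                take = min(config.subpatches_per_region, len(grid))
                chosen = rng.choice(len(grid), size=take, replace=False)
                sub_patches.append(grid.patches[np.sort(chosen)])
                sub_region.append(np.full(take, patch_idx))
    low_patches = np.stack(low_patches)
    patch_refs = pd.DataFrame(
        refs, columns=["patient_id", "slide_index", "row", "col",
                       "true_class", "is_positive"])
    sub_patches = np.concatenate(sub_patches)
    sub_region = np.concatenate(sub_region)
    is_pos_patch = patch_refs["is_positive"].to_numpy()

    # --- key-feature set: balanced patient subset -------------------------
    # Feature generation uses a group-balanced slide set (all positive
    # patients plus an equal-size random draw of negatives), so cluster
    # allocation is not driven by the cohort's class imbalance; every slide
    # is then scored against the fitted features.
    pos_pids = analysis.loc[analysis["group"].eq(POSITIVE), "patient_id"]
    neg_pids = analysis.loc[~analysis["group"].eq(POSITIVE), "patient_id"]
    n_key = min(len(pos_pids), len(neg_pids))
    key_pids = set(pos_pids.sample(n=n_key, random_state=int(rng.integers(2**31)))
                   ) | set(neg_pids.sample(n=n_key,
                                           random_state=int(rng.integers(2**31))))
    key_patch = patch_refs["patient_id"].isin(key_pids).to_numpy()
    key_sub = key_patch[sub_region]

    # --- Step 1: low-magnification features -------------------------------
    key_idx = np.flatnonzero(key_patch)
    train_idx = rng.permutation(key_idx)[:config.max_train_patches]
    low_ae = Autoencoder(low_cfg).fit(low_patches[train_idx])
    codes_low = low_ae.encode(low_patches)
    model = step1_features.fit_clusters(codes_low[key_idx], config.k_clusters,
                                        seed, n_init=config.kmeans_restarts)
    assignment = step1_features.assign(codes_low, model)
    key_assignment = step1_features.Assignment(
        assignment.labels[key_idx], assignment.distances[key_idx],
        assignment.n_clusters)
    step1_features.flag_background_clusters(
        model, low_patches[key_idx], key_assignment)
    profile1 = step1_features.compute_impact_profile(
        key_assignment, is_pos_patch[key_idx], model.background)
    scores1 = step1_features.patch_impact(assignment, profile1)

    # --- Step 2: high-magnification refinement ----------------------------
    key_sub_idx = np.flatnonzero(key_sub)
    sub_train = rng.permutation(key_sub_idx)[:config.max_train_patches]
    high_ae = Autoencoder(high_cfg).fit(sub_patches[sub_train])
    raw_high = high_ae.encode(sub_patches)
    codes_high = step2_refine.standardize_units(
        raw_high, mean=raw_high[key_sub_idx].mean(axis=0),
        std=raw_high[key_sub_idx].std(axis=0))
    unit_assignment = step2_refine.unit_activations(codes_high)
    profile2 = step2_refine.compute_unit_profile(
        step2_refine.UnitActivationAssignment(
            unit_assignment.units[key_sub_idx],
            unit_assignment.activations[key_sub_idx],
            unit_assignment.n_units),
        is_pos_patch[sub_region][key_sub_idx])
    scores2 = step2_refine.region_impact(
        unit_assignment, profile2, sub_region, len(low_patches))

    # --- Step 3: consensus and per-patient aggregation --------------------
    features, labels, retained = _aggregate(
        analysis, patch_refs, assignment, profile1, scores1, scores2,
        model.background, config.horizon_months)

    return PipelineResult(
        cohort=cohort, analysis=analysis, patch_refs=patch_refs,
        cluster_model=model, assignment=assignment, profile1=profile1,
        scores1=scores1, unit_assignment=unit_assignment,
        sub_region_index=sub_region, profile2=profile2, scores2=scores2,
        retained=retained, key_patch=key_patch, features=features,
        labels=labels, enrichment=class_enrichment(spec), low_encoder=low_ae,
        high_encoder=high_ae,
    )


def _aggregate(analysis: pd.DataFrame, patch_refs: pd.DataFrame,
               assignment: step1_features.Assignment,
               profile1: step1_features.ImpactProfile,
               scores1: np.ndarray, scores2: np.ndarray,
               background: set[int], horizon: float
               ) -> tuple[pd.DataFrame, pd.Series, np.ndarray]:
    result = cons.consensus_filter(scores1, scores2)
    patient_vectors = []
    for pid, sub in patch_refs.groupby("patient_id", sort=False):
        slide_vecs = []
        for s_idx, srows in sub.groupby("slide_index", sort=False):
            idx = srows.index.to_numpy()
            part = step1_features.Assignment(
                assignment.labels[idx], assignment.distances[idx],
                assignment.n_clusters)
            slide_vecs.append(cons.feature_counts(
                part, result.retained[idx], background, f"{pid}_s{s_idx}"))
        patient_vectors.append(cons.aggregate_patient(slide_vecs, profile1, pid))
    features = cons.feature_matrix(patient_vectors)
    labels = prediction.cohort_labels(
        analysis.set_index("patient_id"), horizon)
    labels = labels.loc[features.index]
    return features, labels, result.retained


def rescore_with_groups(result: PipelineResult, patient_groups: dict[str, str],
                        horizon: float = 12.0
                        ) -> tuple[pd.DataFrame, pd.Series,
                                   step1_features.ImpactProfile]:
    """Recompute impact profiles, consensus and features under new labels.

    Encodings and cluster/unit assignments are label-free, so relabelling
    (e.g. a permutation null) only requires recomputing the statistics.
    """
    refs = result.patch_refs
    is_pos = refs["patient_id"].map(patient_groups).eq(POSITIVE).to_numpy()
    key_idx = np.flatnonzero(result.key_patch)
    key_assignment = step1_features.Assignment(
        result.assignment.labels[key_idx],
        result.assignment.distances[key_idx], result.assignment.n_clusters)
    profile1 = step1_features.compute_impact_profile(
        key_assignment, is_pos[key_idx], result.cluster_model.background)
    scores1 = step1_features.patch_impact(result.assignment, profile1)
    key_sub_idx = np.flatnonzero(result.key_patch[result.sub_region_index])
    profile2 = step2_refine.compute_unit_profile(
        step2_refine.UnitActivationAssignment(
            result.unit_assignment.units[key_sub_idx],
            result.unit_assignment.activations[key_sub_idx],
            result.unit_assignment.n_units),
        is_pos[result.sub_region_index][key_sub_idx])
    scores2 = step2_refine.region_impact(
        result.unit_assignment, profile2, result.sub_region_index, len(refs))
    analysis = result.analysis.copy()
    analysis["group"] = analysis["patient_id"].map(patient_groups)
    features, _, _ = _aggregate(
        analysis, refs, result.assignment, profile1, scores1, scores2,
        result.cluster_model.background, horizon)
    labels = pd.Series(
        analysis.set_index("patient_id")["group"].eq(POSITIVE).astype(float),
        name="label").loc[features.index]
    return features, labels, profile1


def permute_groups(result: PipelineResult, seed: int) -> dict[str, str]:
    """A seeded permutation of the patients' outcome groups."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x9E47]))
    pids = result.analysis["patient_id"].to_numpy()
    groups = result.analysis["group"].to_numpy()
    return dict(zip(pids, groups[rng.permutation(len(groups))]))


def cluster_truth(result: PipelineResult) -> pd.DataFrame:
    """Majority ground-truth texture class and enrichment per cluster."""
    rows = []
    classes = result.patch_refs["true_class"].to_numpy()
    for k in range(result.cluster_model.n_clusters):
        members = result.assignment.labels == k
        if not members.any() or k in result.cluster_model.background:
            continue
        vals, counts = np.unique(classes[members], return_counts=True)
        majority = int(vals[np.argmax(counts)])
        e = (np.nan if majority == BACKGROUND
             else float(result.enrichment[majority]))
        rows.append((k, majority, e, float(result.profile1.impact[k]),
                     int(members.sum())))
    return pd.DataFrame(rows, columns=["k", "majority_class", "enrichment",
                                       "impact", "n_members"])


def impact_recovery_spearman(result: PipelineResult) -> float:
    """Spearman correlation of cluster impact vs ground-truth enrichment."""
    truth = cluster_truth(result)
    truth = truth.dropna(subset=["enrichment", "impact"])
    rho, _ = stats.spearmanr(truth["impact"], truth["enrichment"])
    return float(rho)
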