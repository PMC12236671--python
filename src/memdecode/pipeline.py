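"""End-to-end orchestration: events -> tensors -> decoder -> recall
activations -> MCS -> pooled statistics.

These helpers glue the stage modules together for synthetic studies,
the acceptance script, the circular-shift control and the CLI.
"""

from __future__ import annotations

import numpy as np

from . import mcs as mcs_mod
from . import preprocessing as pp
from .annotation import VocalizationLog, dedup_concept_onsets
from .model.network import (LogisticBaseline, ModelConfig,
                            MultiRegionTransformer, TrainingConfig)
from .model.training import partition_channels, train
from .synthetic import SimulationSpec, simulate_recall, simulate_viewing


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC (equivalent to the Mann-Whitney statistic),
    with midrank tie handling."""
    from scipy.stats import rankdata
    labels = np.asarray(labels).astype(bool)
    n1, n0 = labels.sum(), (~labels).sum()
    if n1 == 0 or n0 == 0:
        return float("nan")
    r = rankdata(scores)
    return float((r[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def tensors_from_events(trains, duration_s: float, fs: float) -> np.ndarray:
    """Discretize + bin one epoch of event trains into window tensors."""
    disc = [pp.discretize(t) for t in trains]
    return pp.bin_segments(disc, int(round(duration_s * fs)), fs=fs)


class SyntheticStudy:
    """A simulated participant: viewing and recall epochs preprocessed
    into normalized region streams, with ground truth attached."""

    def __init__(self, spec: SimulationSpec, vocab: list,
                 n_concept_vocalizations: dict, recall_kwargs: dict = None):
        self.spec = spec
        v_trains, self.labels, self.viewing_manifest = simulate_viewing(spec)
        r_trains, log, self.recall_manifest = simulate_recall(
            spec, vocab, n_concept_vocalizations, **(recall_kwargs or {}))
        self.log: VocalizationLog = dedup_concept_onsets(log)
        fs = spec.sample_rate_hz
        viewing = tensors_from_events(v_trains, spec.episode_duration_s, fs)
        recall = tensors_from_events(
            r_trains, self.recall_manifest.recall_duration_s, fs)
        bundles = spec.bundle_of_channel()
        normed = pp.zscore_bundle({"viewing": viewing, "recall": recall}, bundles)
        cmap = {b: list(np.flatnonzero(bundles == b)) for b in np.unique(bundles)}
        self.viewing_regions = partition_channels(normed["viewing"], cmap)
        self.recall_regions = partition_channels(normed["recall"], cmap)

    def region_shapes(self) -> list:
        return [x.shape[1:] for x in self.viewing_regions]


def fit_decoder(viewing_regions: list, labels: np.ndarray,
                model_config: ModelConfig, training_config: TrainingConfig,
                baseline: bool = False):
    """Train a transformer (or the logistic control) on viewing data."""
    shapes = [x.shape[1:] for x in viewing_regions]
    cls = LogisticBaseline if baseline else MultiRegionTransformer
    model = cls(shapes, model_config)
    history = train(model, viewing_regions, labels, training_config)
    return model, history


def recall_timeline(model, recall_regions: list) -> mcs_mod.ActivationTimeline:
    """Inference over a recall epoch: one activation per concept per
    250-ms window."""
    act = model.predict(recall_regions)
    return mcs_mod.ActivationTimeline(act)


def score_study(model, study: SyntheticStudy, n_surrogates: int = 1500,
                seed: int = 0) -> dict:
    """MCS per eligible concept plus the pooled Wilcoxon/Cohen test."""
    tl = recall_timeline(model, study.recall_regions)
    results = mcs_mod.score_recall(tl, study.log, n_surrogates=n_surrogates,
                                   seed=seed)
    values = np.array([r.mcs for r in results.values()])
    pooled = mcs_mod.pooled_test(values) if len(values) else None
    return {"timeline": tl, "mcs": results, "pooled": pooled}


def heldout_auc(model, spec: SimulationSpec, heldout_seed: int) -> dict:
    """Per-concept ROC AUC on a freshly simulated viewing segment with
    the same ground-truth channel assignment but new event noise."""
    import dataclasses
    spec2 = dataclasses.replace(spec, seed=heldout_seed)
    trains, labels, _ = simulate_viewing(spec2)
    tensor = tensors_from_events(trains, spec2.episode_duration_s,
                                 spec2.sample_rate_hz)
    bundles = spec2.bundle_of_channel()
    stats = pp.bundle_zscore_stats(tensor, bundles)
    tensor = pp.apply_bundle_zscore(tensor, bundles, stats)
    cmap = {b: list(np.flatnonzero(bundles == b)) for b in np.unique(bundles)}
    regions = partition_channels(tensor, cmap)
    act = model.predict(regions)
    aucs = {}
    for c in range(labels.shape[1]):
        if labels[:, c].any() and not labels[:, c].all():
            aucs[c] = roc_auc(act[:, c], labels[:, c])
    return aucs


def make_train_and_score(studies: dict, model_config: ModelConfig,
                         training_config: TrainingConfig,
                         n_surrogates: int = 300, mcs_seed: int = 0):
    """Build the pipeline callable consumed by
    :func:`memdecode.controls.shift_test`: viewing data (possibly
    circularly shifted) -> pooled Z over all participants' concepts."""

    def train_and_score(viewing: dict) -> float:
        all_mcs = []
        for pid, (regions, labels) in viewing.items():
            study = studies[pid]
            model, _ = fit_decoder(regions, labels, model_config, training_config)
            res = score_study(model, study, n_surrogates=n_surrogates,
                              seed=mcs_seed)
            all_mcs += [r.mcs for r in res["mcs"].values()]
        return mcs_mod.pooled_test(np.array(all_mcs))["z"]

    return train_and_score
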