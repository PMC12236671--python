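"""Training loop: label-combination stratification, screen-time
exclusion, Adam with step-decayed learning rate, BCE objective.

The full viewing period is used for training (no held-out split):
training and recall data come from different distributions with only a
limited shared component, so the aim is to fit the viewing signal as
faithfully as possible and let the surrogate statistics downstream
judge generalization.
"""

from __future__ import annotations

import numpy as np

from .network import Adam, ModelConfig, TrainingConfig, bce_with_logits


def partition_channels(tensor: np.ndarray, channel_map) -> list[np.ndarray]:
    """Split a windowed tensor ``(n, 2, Ne, B)`` into per-bundle region
    streams ``(n, 2, 8, B)``.

    ``channel_map`` is a :class:`~memdecode.controls.ChannelMap` or any
    object with ``bundles() -> dict bundle -> list of channel indices``.
    Each bundle must hold exactly 8 distinct channels on the clusterless
    path.
    """
    bundles = channel_map.bundles() if hasattr(channel_map, "bundles") else dict(channel_map)
    if not bundles:
        raise ValueError("empty channel map")
    seen: set[int] = set()
    streams = []
    order = []
    for bundle in sorted(bundles):
        chans = list(bundles[bundle])
        if len(chans) != 8 or len(set(chans)) != 8:
            raise ValueError(f"bundle {bundle!r} must hold exactly 8 distinct channels")
        dup = seen.intersection(chans)
        if dup:
            raise ValueError(f"channel(s) {sorted(dup)} assigned to more than one bundle")
        seen.update(chans)
        streams.append(np.ascontiguousarray(tensor[:, :, chans, :]))
        order.append((bundle, chans))
    return streams


def exclude_rare_combinations(labels: np.ndarray, min_screentime_s: float,
                              window_s: float = 0.25) -> np.ndarray:
    """Boolean keep-mask over windows: label combinations whose total
    screen time is below the cutoff are dropped together with their
    neural segments. A combination with exactly the cutoff is retained
    (the rule is 'less than')."""
    labels = np.asarray(labels)
    combos, inverse, counts = np.unique(
        labels, axis=0, return_inverse=True, return_counts=True)
    screentime = counts * window_s
    keep_combo = screentime >= min_screentime_s
    return keep_combo[inverse]


def stratified_epoch_order(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Window order for one epoch such that every contiguous batch
    approximately preserves each label combination's proportion.

    Windows of each combination are shuffled, then all windows are
    interleaved by their within-group quantile position.
    """
    labels = np.asarray(labels)
    _, inverse = np.unique(labels, axis=0, return_inverse=True)
    n = len(labels)
    pos = np.empty(n)
    for g in np.unique(inverse):
        idx = np.flatnonzero(inverse == g)
        idx = rng.permutation(idx)
        # quantile positions with jitter to break ties between groups
        pos[idx] = (np.arange(len(idx)) + rng.uniform(0, 1, len(idx))) / len(idx)
    return np.argsort(pos, kind="stable")


def train(model, region_inputs: list[np.ndarray], labels: np.ndarray,
          config: TrainingConfig) -> dict:
    """Train a decoder (transformer or logistic baseline) in place.

    Returns a history dict with per-epoch mean loss and learning rate.
    """
    labels = np.asarray(labels, dtype=np.float32)
    n = labels.shape[0]
    if any(x.shape[0] != n for x in region_inputs):
        raise ValueError("labels must align 1:1 with windows")

    keep = exclude_rare_combinations(labels, config.min_combination_screentime_s,
                                     config.window_s)
    if not keep.any():
        raise ValueError("all label combinations excluded by the screen-time rule")
    region_inputs = [x[keep] for x in region_inputs]
    labels = labels[keep]

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.lr)
    history = {"epoch": [], "loss": [], "lr": []}
    for epoch in range(config.epochs):
        lr = config.lr * config.lr_decay ** (epoch // config.lr_step_epochs)
        opt.lr = lr
        order = stratified_epoch_order(labels, rng)
        losses = []
        for a in range(0, len(order), config.batch_size):
            idx = order[a:a + config.batch_size]
            opt.zero_grad()
            z = model.logits([x[idx] for x in region_inputs])
            loss = bce_with_logits(z, labels[idx])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history["epoch"].append(epoch)
        history["loss"].append(float(np.mean(losses)))
        history["lr"].append(lr)
    return history
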