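"""Weighted-average ensembling of base-learner probability maps.

The ensemble prediction is the per-pixel, per-class convex combination
``sum_m w_m P_m`` of member probability maps, with non-negative weights
summing to one.  Weights come from a grid search: raw weights are drawn
from {0, step, 2*step, ..., 1} per member, the all-zero vector is dropped,
each vector is normalized to sum one and duplicates are removed.  Because
the grid contains every one-hot vector and the uniform vector, the
selected ensemble can never score below the best single member or the
equal-weights ensemble on the search data.  The search metric is the mean
Jaccard (macro over classes) on validation images; searching happens on
training/validation data only, never the hold-out test set.  Argmax-based
scores tie easily (any sufficiently dominant blend of an accurate member
decodes identically), so ties are resolved by a cascade: higher mean fused
probability of the true class (confidence), then maximal weight entropy
(preferring the most even blend — identical members thus get equal
weights), then lexicographic order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data_io import ClassScheme
from .metrics import evaluate_dataset

__all__ = ["EnsembleWeights", "EnsembleModel", "enumerate_weight_grid",
           "weighted_average_predict", "grid_search_weights",
           "ensemble_predict_labels", "evaluate_weights"]


@dataclass(frozen=True)
class EnsembleWeights:
    """Non-negative member weights summing to one."""

    weights: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=np.float64)
        if w.size == 0:
            raise ValueError("weights must be non-empty")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=np.float64)

    def entropy(self) -> float:
        w = self.as_array()
        nz = w[w > 0]
        return float(-(nz * np.log(nz)).sum())

    def rounded(self, decimals: int = 2) -> tuple[float, ...]:
        """Round for reporting with largest-remainder correction so the
        rounded values still sum to one (e.g. 1/3-triples print as
        0.34/0.33/0.33)."""
        w = self.as_array()
        scale = 10 ** decimals
        floors = np.floor(w * scale).astype(int)
        short = int(round(scale - floors.sum()))
        remainders = w * scale - floors
        for i in np.argsort(-remainders)[:short]:
            floors[i] += 1
        return tuple(float(f) / scale for f in floors)


@dataclass
class EnsembleModel:
    """Selected members (weight > 0) with their weights and class scheme."""

    members: list
    weights: EnsembleWeights
    scheme: ClassScheme

    def __post_init__(self):
        if len(self.members) != len(self.weights.weights):
            raise ValueError("one weight per member required")
        keep = [i for i, w in enumerate(self.weights.weights) if w > 0]
        if not keep:
            raise ValueError("at least one member must have positive weight")
        if len(keep) != len(self.members):
            self.members = [self.members[i] for i in keep]
            w = np.asarray([self.weights.weights[i] for i in keep])
            self.weights = EnsembleWeights(tuple(w / w.sum()))

    def predict_proba(self, image: np.ndarray) -> np.ndarray:
        maps = [m.predict_proba(image) for m in self.members]
        return weighted_average_predict_maps(maps, self.weights)

    def predict_labels(self, image: np.ndarray) -> np.ndarray:
        return self.predict_proba(image).argmax(axis=2).astype(np.int32)

    def to_json(self, path: str | Path, checkpoints: list[str] | None = None,
                extra: dict | None = None) -> None:
        doc = {"members": [m.encoder.name if hasattr(m, "encoder")
                           else getattr(m, "name", str(i))
                           for i, m in enumerate(self.members)],
               "weights": list(self.weights.weights),
               "weights_rounded": list(self.weights.rounded()),
               "classes": list(self.scheme.names)}
        if checkpoints:
            doc["checkpoints"] = checkpoints
        if extra:
            doc.update(extra)
        Path(path).write_text(json.dumps(doc, indent=2))


def enumerate_weight_grid(n_members: int, step: float = 0.1) -> list[EnsembleWeights]:
    """All normalized, deduplicated weight vectors with raw entries in
    {0, step, ..., 1}; includes every one-hot vector and the uniform one."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    n_steps = round(1.0 / step)
    if n_steps < 1 or abs(n_steps * step - 1.0) > 1e-9:
        raise ValueError("step must divide 1")
    levels = np.arange(n_steps + 1)
    grids = np.meshgrid(*[levels] * n_members, indexing="ij")
    raw = np.stack([g.ravel() for g in grids], axis=1).astype(np.float64)
    raw = raw[raw.sum(axis=1) > 0]
    norm = raw / raw.sum(axis=1, keepdims=True)
    seen: dict[tuple, EnsembleWeights] = {}
    for row in norm:
        key = tuple(np.round(row, 12))
        if key not in seen:
            seen[key] = EnsembleWeights(tuple(row))
    return list(seen.values())


def weighted_average_predict_maps(maps: list[np.ndarray],
                                  weights: EnsembleWeights) -> np.ndarray:
    if len(maps) != len(weights.weights):
        raise ValueError("number of maps and weights must agree")
    out = np.zeros_like(np.asarray(maps[0], dtype=np.float64))
    for w, m in zip(weights.weights, maps):
        out += w * np.asarray(m, dtype=np.float64)
    return out


def weighted_average_predict(members: list, weights: EnsembleWeights,
                             image: np.ndarray) -> np.ndarray:
    """Fuse member probability maps for one image; result is itself a valid
    probability map (convexity)."""
    maps = [m.predict_proba(image) for m in members]
    return weighted_average_predict_maps(maps, weights)


def evaluate_weights(member_maps: list[list[np.ndarray]],
                     truths: list[np.ndarray], weights: EnsembleWeights,
                     scheme: ClassScheme) -> float:
    """Mean Jaccard of the fused argmax over a validation set.

    ``member_maps[m][i]`` is member m's probability map for image i.
    """
    return _score_weights(member_maps, truths, weights, scheme)[0]


def _score_weights(member_maps, truths, weights, scheme):
    """(mean Jaccard, mean fused true-class probability) of a candidate."""
    preds = []
    conf = 0.0
    npx = 0
    for i, truth in enumerate(truths):
        fused = weighted_average_predict_maps([mm[i] for mm in member_maps],
                                              weights)
        preds.append(fused.argmax(axis=2))
        conf += float(np.take_along_axis(fused, np.asarray(truth)[..., None],
                                         axis=2).sum())
        npx += truth.size
    jac = evaluate_dataset(preds, truths, scheme).mean_jaccard
    return jac, conf / npx


def grid_search_weights(members: list, val_data, step: float = 0.1,
                        scheme: ClassScheme | None = None,
                        member_maps: list[list[np.ndarray]] | None = None
                        ) -> tuple[EnsembleWeights, float]:
    """Exhaustively score every grid candidate on the validation images and
    return the argmax (confidence, entropy, then lexicographic tie-break).

    ``val_data`` is a list of LabeledSample (or (image, mask) pairs);
    precomputed ``member_maps`` may be passed to skip the forward passes.
    """
    if not members:
        raise ValueError("need at least one member")
    samples = list(val_data)
    if not samples and member_maps is None:
        raise ValueError("validation data must be non-empty")
    truths = []
    images = []
    for s in samples:
        if hasattr(s, "mask"):
            images.append(s.image)
            truths.append(s.mask)
        else:
            images.append(s[0])
            truths.append(s[1])
    if member_maps is None:
        member_maps = [[m.predict_proba(img) for img in images]
                       for m in members]
    if scheme is None:
        n_classes = member_maps[0][0].shape[2]
        from .synthetic import scheme_for
        scheme = scheme_for(min(n_classes, 4))
    grid = enumerate_weight_grid(len(members), step)
    if not grid:
        raise ValueError("empty weight grid")
    best: tuple | None = None
    best_w: EnsembleWeights | None = None
    for cand in grid:
        score, conf = _score_weights(member_maps, truths, cand, scheme)
        key = (score, round(conf, 9), cand.entropy(),
               tuple(-x for x in cand.weights))
        if best is None or key > best:
            best = key
            best_w = cand
    assert best_w is not None and best is not None
    return best_w, float(best[0])


def ensemble_predict_labels(ensemble: EnsembleModel,
                            image: np.ndarray) -> np.ndarray:
    """Argmax decode of the fused probability map (ties to lower index)."""
    return ensemble.predict_labels(image)
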