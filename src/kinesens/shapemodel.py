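"""Principal-component shape model of spinal alignment.

The model is fitted to the measurement-node coordinates (vertebral
centre-of-gravity x, z in mm) of a population of aligned spines.  The
sacrum node is excluded: it is the fixed origin of the alignment and
carries no variance by construction.

Fitting is covariance PCA on the raw mm coordinates (all features share
units).  Scores are expressed in population-SD units, so a score of +1
means one standard deviation along that component.  The first component
is sign-fixed so that a positive score moves the C7 measurement node
posteriorly (a more reclined overall posture); remaining components are
sign-fixed by their largest-magnitude loading entry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import numpy as np

from .spine import SpineModel, VertebraLandmarks

__all__ = ["SpineShapeModel", "fit_shape_model", "generate_spine", "explained_variance"]


@dataclass(frozen=True)
class SpineShapeModel:
    """Fitted PCA shape model over spine measurement nodes.

    Attributes
    ----------
    levels : vertebra labels covered by the model (sacrum excluded).
    mean : (2p,) mean vector, interleaved (x, z) per level, mm.
    loadings : (k, 2p) unit-norm principal directions.
    sds : (k,) per-component score standard deviations, mm.
    explained : (k,) per-component fraction of total variance.
    template : the template spine used to rebuild full landmark sets.
    """

    levels: tuple[str, ...]
    mean: np.ndarray
    loadings: np.ndarray
    sds: np.ndarray
    explained: np.ndarray
    template: SpineModel | None = None

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])

    # -- statsmodels-style constructor ------------------------------------
    @classmethod
    def fit(
        cls,
        spines: list[SpineModel],
        n_components: int = 2,
        template: SpineModel | None = None,
    ) -> "SpineShapeModel":
        return fit_shape_model(spines, n_components=n_components, template=template)

    def generate(self, scores) -> SpineModel:
        return generate_spine(self, scores)

    def scores_of(self, spine: SpineModel) -> np.ndarray:
        """Score vector (SD units) of a spine under this model."""
        x = _flatten_nodes(spine, self.levels)
        raw = self.loadings @ (x - self.mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(self.sds > 0, raw / np.where(self.sds > 0, self.sds, 1.0), 0.0)
        return s

    def cumulative_explained(self, k: int) -> float:
        return explained_variance(self, k)

    # -- persistence -------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "levels": list(self.levels),
            "mean": self.mean.tolist(),
            "loadings": self.loadings.tolist(),
            "sds": self.sds.tolist(),
            "explained": self.explained.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path, template: SpineModel | None = None) -> "SpineShapeModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            levels=tuple(payload["levels"]),
            mean=np.asarray(payload["mean"], dtype=float),
            loadings=np.asarray(payload["loadings"], dtype=float),
            sds=np.asarray(payload["sds"], dtype=float),
            explained=np.asarray(payload["explained"], dtype=float),
            template=template,
        )


def _flatten_nodes(spine: SpineModel, levels: tuple[str, ...]) -> np.ndarray:
    pts = []
    for lv in levels:
        x, z = spine[lv].measurement_point
        pts.extend((x, z))
    return np.asarray(pts, dtype=float)


def fit_shape_model(
    spines: list[SpineModel],
    n_components: int = 2,
    template: SpineModel | None = None,
) -> SpineShapeModel:
    """Covariance PCA over stacked measurement-node coordinates."""
    if len(spines) < 3:
        raise ValueError("need at least 3 spines to fit a shape model")
    levels = tuple(lv for lv in spines[0].levels if lv != "S1")
    for s in spines[1:]:
        if tuple(lv for lv in s.levels if lv != "S1") != levels:
            raise ValueError("all spines must share the same vertebra levels")
    X = np.stack([_flatten_nodes(s, levels) for s in spines])
    mean = X.mean(axis=0)
    Xc = X - mean
    # SVD of the centred data matrix: rows are subjects.
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    n = X.shape[0]
    var = svals**2 / (n - 1)
    total = float(var.sum())
    k = min(n_components, vt.shape[0])
    loadings = vt[:k].copy()
    sds = np.sqrt(var[:k])
    explained = var[:k] / total if total > 0 else np.zeros(k)
    # Sign conventions (see module docstring).
    c7x = 2 * levels.index("C7") if "C7" in levels else 0
    for j in range(k):
        if j == 0 and "C7" in levels:
            if loadings[0, c7x] > 0:  # positive PC1 must move C7 posteriorly
                loadings[0] = -loadings[0]
        else:
            lead = int(np.argmax(np.abs(loadings[j])))
            if loadings[j, lead] < 0:
                loadings[j] = -loadings[j]
    if template is None and spines:
        template = spines[0]
    return SpineShapeModel(
        levels=levels,
        mean=mean,
        loadings=loadings,
        sds=sds,
        explained=np.asarray(explained, dtype=float),
        template=template,
    )


def explained_variance(model: SpineShapeModel, k: int) -> float:
    """Cumulative fraction of variance captured by the first k components."""
    if not (1 <= k <= model.n_components):
        raise ValueError(f"k={k} out of range 1..{model.n_components}")
    return float(np.sum(model.explained[:k]))


def _rigid_fit_vertebra(
    v: VertebraLandmarks,
    old_node: np.ndarray,
    new_node: np.ndarray,
    rot: np.ndarray,
) -> VertebraLandmarks:
    def _t(p):
        q = rot @ (np.asarray(p, dtype=float) - old_node) + new_node
        return (float(q[0]), float(q[1]))

    return replace(
        v,
        corners={k: _t(c) for k, c in v.corners.items()},
        measurement_point=_t(v.measurement_point),
        pivot=None if v.pivot is None else _t(v.pivot),
    )


def generate_spine(model: SpineShapeModel, scores) -> SpineModel:
    """Generate a spine at the given PC scores (SD units).

    Measurement nodes are mean + sum_k score_k * sd_k * loading_k.  The
    full landmark set is rebuilt by rigidly placing each template
    vertebra at its generated node, with an orientation change inferred
    from the direction between neighbouring nodes (the sacrum keeps its
    template pose).
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (model.n_components,):
        raise ValueError(
            f"expected {model.n_components} scores, got shape {scores.shape}"
        )
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if model.template is None:
        raise ValueError("model carries no template spine for reconstruction")
    nodes = model.mean + (scores * model.sds) @ model.loadings
    nodes = nodes.reshape(-1, 2)
    template = model.template
    old_nodes = template.measurement_nodes(exclude=("S1",))

    def _chain_dirs(pts: np.ndarray) -> np.ndarray:
        """Per-node tangent from neighbouring nodes along the chain."""
        d = np.empty_like(pts)
        d[0] = pts[1] - pts[0]
        d[-1] = pts[-1] - pts[-2]
        d[1:-1] = pts[2:] - pts[:-2]
        return d

    old_dir = _chain_dirs(old_nodes)
    new_dir = _chain_dirs(nodes)
    vertebrae = [template["S1"]]
    for i, lv in enumerate(model.levels):
        a = np.arctan2(old_dir[i, 1], old_dir[i, 0])
        b = np.arctan2(new_dir[i, 1], new_dir[i, 0])
        da = b - a
        c, s = np.cos(da), np.sin(da)
        rot = np.array([[c, -s], [s, c]])
        vertebrae.append(
            _rigid_fit_vertebra(template[lv], old_nodes[i], nodes[i], rot)
        )
    return replace(template, vertebrae=tuple(vertebrae))
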