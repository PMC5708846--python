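"""PCA over binding-pocket C-alpha coordinates of superimposed models.

Each pocket is flattened to a 3n-coordinate feature vector (n pocket
residues, already superimposed by :func:`core_model.superimpose_pockets`)
and decomposed by covariance PCA — no per-feature scaling, since all
features are like-for-like Angstrom coordinates.  Components are ordered
by explained variance fraction and sign-fixed so the largest-magnitude
loading of each component is positive (PCA signs are otherwise
arbitrary).  An optional annotation colours each model by its
fingerprint Jaccard distance to a reference complex.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .core_model import BindingPocket
from .errors import CorrespondenceError, DimensionError
from .ifp import InteractionFingerprint, jaccard_distance

__all__ = ["PCAResult", "pocket_pca", "annotate_by_reference"]


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance fractions of a pocket PCA."""

    scores: np.ndarray               # (n_models, n_components)
    explained_fraction: np.ndarray   # per component, non-increasing
    components: np.ndarray           # (n_components, 3 * n_residues)
    mean: np.ndarray                 # feature mean (3 * n_residues,)
    model_ids: tuple[str, ...] = ()
    zero_variance: bool = False
    annotation: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pocket_pca(
    pockets: list[BindingPocket],
    n_components: int = 2,
    model_ids=None,
) -> PCAResult:
    """Covariance PCA of flattened pocket C-alpha coordinates.

    Requires >= 2 pockets sharing the identical ordered residue list and
    already superimposed.  ``n_components`` is clipped (with a warning)
    to ``n_models - 1``, the rank bound of the centered data.  When all
    pockets are identical the total variance is zero; explained fractions
    are then reported as 0 with ``zero_variance=True``.
    """
    if len(pockets) < 2:
        raise DimensionError("need at least two pockets for PCA")
    first = pockets[0]
    for p in pockets[1:]:
        if p.residues != first.residues:
            diff = set(p.residues) ^ set(first.residues)
            raise CorrespondenceError(
                f"pocket residue lists differ: {sorted(diff)}"
            )
    x = np.stack([p.ca_coords.reshape(-1) for p in pockets])
    n_models, n_feat = x.shape
    max_comp = min(n_models - 1, n_feat)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds the rank bound "
            f"{max_comp}; clipping"
        )
        n_components = max_comp

    mean = x.mean(axis=0)
    centered = x - mean
    total_var = float(np.sum(centered ** 2) / (n_models - 1))
    ids = tuple(model_ids) if model_ids is not None \
        else tuple(f"model_{i}" for i in range(n_models))
    if len(ids) != n_models:
        raise DimensionError("model_ids length does not match pockets")

    if total_var == 0.0:
        return PCAResult(
            scores=np.zeros((n_models, n_components)),
            explained_fraction=np.zeros(n_components),
            components=np.zeros((n_components, n_feat)),
            mean=mean,
            model_ids=ids,
            zero_variance=True,
        )

    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(x)
    components = pca.components_.copy()
    # deterministic sign: largest-magnitude loading positive
    for i in range(components.shape[0]):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] *= -1
            scores[:, i] *= -1
    return PCAResult(
        scores=scores,
        explained_fraction=pca.explained_variance_ratio_.copy(),
        components=components,
        mean=mean,
        model_ids=ids,
    )


def annotate_by_reference(
    pca: PCAResult,
    ifps: list[InteractionFingerprint],
    reference: InteractionFingerprint,
) -> PCAResult:
    """Attach per-model Jaccard distances to a reference fingerprint.

    ``ifps`` must supply one fingerprint per PCA model, in the same
    order.  The annotation is the colour channel of the conventional
    score plot (distance 0 = same interaction pattern as the reference).
    """
    if len(ifps) != pca.scores.shape[0]:
        raise DimensionError(
            f"{len(ifps)} fingerprints for {pca.scores.shape[0]} models"
        )
    ann = np.array(
        [jaccard_distance(f.flatten(), reference.flatten()).d_J for f in ifps]
    )
    pca.annotation = ann
    return pca
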