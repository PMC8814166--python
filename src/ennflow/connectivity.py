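"""Principal-components-regression functional connectivity.

A source layer's vertex time series are reduced to K principal components
(covariance PCA on per-vertex de-meaned data); each target vertex's time
series is then regressed on the K component time series:

    Y = beta_0 + sum_i X_i beta_i + eps        (K = 500 by default)

The orthonormal loading matrix U (V_src x K) and the component coefficients
W_pc (K x V_tgt) compose back to a vertex-to-vertex weight map

    W_x = U W_pc

which is what activity-flow mapping applies to activation patterns.  Source
vertices that overlap the target layer can be excluded from the predictors;
their rows of W_x are zero.  Intercepts are estimated but never applied to
activation patterns, which are baseline-relative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FcMapping",
    "VertexWeightMap",
    "estimate_pcr_fc",
    "compose_vertex_weights",
    "group_average_fc",
    "apply_fc",
]

logger = logging.getLogger(__name__)


@dataclass
class FcMapping:
    source: str
    target: str
    U: np.ndarray  # V_src x K, orthonormal columns (excluded rows zero)
    W_pc: np.ndarray  # K x V_tgt
    beta0: np.ndarray  # V_tgt intercepts
    K: int
    residual_variance: np.ndarray  # per target vertex
    excluded_source_vertices: np.ndarray  # indices into the source axis


@dataclass
class VertexWeightMap:
    W: np.ndarray  # V_src x V_tgt
    source: str = ""
    target: str = ""
    provenance: str = "subject"


def estimate_pcr_fc(
    source_ts: np.ndarray,
    target_ts: np.ndarray,
    n_components: int = 500,
    excluded: np.ndarray | None = None,
    source: str = "",
    target: str = "",
) -> FcMapping:
    """Fit the PCR FC mapping from ``source_ts`` (T x V_src) to ``target_ts``
    (T x V_tgt).

    Both series are de-meaned per vertex internally.  The requested component
    count is silently capped at min(K, T-1, effective V_src) and the cap is
    logged.  ``excluded`` names source vertices (e.g., overlapping the target
    layer) dropped from the predictors.
    """
    source_ts = np.asarray(source_ts, dtype=np.float64)
    target_ts = np.asarray(target_ts, dtype=np.float64)
    T = source_ts.shape[0]
    if target_ts.shape[0] != T:
        raise ValueError("source and target must share the time axis")
    if T < 3:
        raise ValueError("need at least 3 time points")
    v_src = source_ts.shape[1]
    excluded = (
        np.asarray([], dtype=np.int64)
        if excluded is None
        else np.unique(np.asarray(excluded, dtype=np.int64))
    )
    keep = np.setdiff1d(np.arange(v_src), excluded)
    if keep.size == 0:
        raise ValueError("no source vertices left after exclusion")

    Xs = source_ts[:, keep] - source_ts[:, keep].mean(axis=0)
    Yc = target_ts - target_ts.mean(axis=0)

    K = min(n_components, T - 1, keep.size)
    if K < n_components:
        logger.info(
            "PCR components capped at %d (requested %d, T=%d, V_src_eff=%d)",
            K, n_components, T, keep.size,
        )
    # covariance PCA via thin SVD; loadings are right singular vectors
    _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
    U_eff = Vt[:K].T  # keep.size x K
    scores = Xs @ U_eff  # T x K
    design = np.column_stack([np.ones(T), scores])
    coef, _, _, _ = np.linalg.lstsq(design, Yc, rcond=None)
    beta0, W_pc = coef[0], coef[1:]
    resid = Yc - design @ coef
    residual_variance = resid.var(axis=0)

    U = np.zeros((v_src, K))
    U[keep] = U_eff
    return FcMapping(
        source=source,
        target=target,
        U=U,
        W_pc=W_pc,
        beta0=beta0,
        K=K,
        residual_variance=residual_variance,
        excluded_source_vertices=excluded,
    )


def compose_vertex_weights(mapping: FcMapping) -> VertexWeightMap:
    """W_x = U W_pc; excluded source rows are zero."""
    return VertexWeightMap(
        W=mapping.U @ mapping.W_pc,
        source=mapping.source,
        target=mapping.target,
        provenance="subject",
    )


def group_average_fc(maps: list[VertexWeightMap]) -> VertexWeightMap:
    """Element-wise mean of composed vertex-space maps across subjects."""
    if not maps:
        raise ValueError("no maps to average")
    shapes = {m.W.shape for m in maps}
    if len(shapes) > 1:
        raise ValueError(f"inconsistent shapes: {shapes}")
    return VertexWeightMap(
        W=np.mean([m.W for m in maps], axis=0),
        source=maps[0].source,
        target=maps[0].target,
        provenance=f"group_mean(n={len(maps)})",
    )


def apply_fc(weight_map: VertexWeightMap, pattern: np.ndarray) -> np.ndarray:
    """Activity-flow application: pattern @ W_x, no intercept."""
    pattern = np.asarray(pattern, dtype=np.float64)
    if pattern.shape[-1] != weight_map.W.shape[0]:
        raise ValueError(
            f"pattern length {pattern.shape[-1]} != V_src {weight_map.W.shape[0]}"
        )
    return pattern @ weight_map.W
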