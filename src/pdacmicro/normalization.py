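"""Frozen log.clr normalization for compositional abundance profiles.

The transform used throughout the modelling pipeline is, per sample:

1. ``L = log10(x + pseudocount)`` — the pseudocount (default 1e-05) keeps the
   logarithm finite for structural zeros;
2. centred log-ratio: ``clr = L - mean(L)``, centring within the sample over
   the model's feature universe, which removes the compositional scale;
3. per-feature z-standardization with the *training* mean and standard
   deviation of the clr values.

Step 3's centre and scale, together with the feature universe and the
pseudocount, form :class:`NormalizationParams` — a frozen record that is
applied verbatim to any later cohort (missing features imputed as zero
abundance, extra features ignored), so that external samples are placed on
exactly the training scale and the transform never refits.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["NormalizationParams", "fit_normalization", "apply_frozen"]


@dataclass(frozen=True)
class NormalizationParams:
    """Frozen record sufficient to reproduce the training normalization."""

    feature_ids: tuple[str, ...]
    pseudocount: float
    centre: np.ndarray  # per-feature training mean of clr values
    scale: np.ndarray   # per-feature training sd (ddof=1); degenerate sd -> 1

    def __post_init__(self) -> None:
        if not (len(self.feature_ids) == len(self.centre) == len(self.scale)):
            raise ValueError("feature_ids, centre and scale lengths differ")
        if np.any(self.scale <= 0):
            raise ValueError("feature scales must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "feature_ids": list(self.feature_ids),
            "pseudocount": self.pseudocount,
            "centre": self.centre.tolist(),
            "scale": self.scale.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            feature_ids=tuple(d["feature_ids"]),
            pseudocount=float(d["pseudocount"]),
            centre=np.asarray(d["centre"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "NormalizationParams":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _clr_matrix(table: pd.DataFrame, feature_ids: tuple[str, ...], pseudocount: float) -> np.ndarray:
    """log10(x+pc) centred within each sample over ``feature_ids``.

    Features absent from ``table`` are imputed as zero abundance *before* the
    pseudocount — the only choice that keeps the frozen transform total.
    """
    # contiguous copy: summation order in the per-sample mean must not depend
    # on the source frame's memory layout, or bit-identical transfer breaks
    x = np.ascontiguousarray(
        table.reindex(index=list(feature_ids), fill_value=0.0).to_numpy(dtype=float)
    )
    L = np.log10(x + pseudocount)
    return L - L.mean(axis=0, keepdims=True)


def fit_normalization(
    table: pd.DataFrame, pseudocount: float = 1e-5
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Fit the log.clr normalization on a (model-feature-filtered) training table.

    Returns the normalized training matrix and the frozen parameters.  The
    matrix is produced by :func:`apply_frozen` on the freshly fitted
    parameters, so refitting and re-applying are bit-identical by
    construction.  A feature constant across training samples gets scale 1
    (with a warning): it then contributes a constant and cannot break transfer.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    feature_ids = tuple(str(f) for f in table.index)
    clr = _clr_matrix(table, feature_ids, pseudocount)
    centre = clr.mean(axis=1)
    if clr.shape[1] < 2:
        scale = np.ones(clr.shape[0])
    else:
        scale = clr.std(axis=1, ddof=1)
    degenerate = ~(scale > 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant feature(s); scale set to 1", stacklevel=2
        )
        scale = np.where(degenerate, 1.0, scale)
    params = NormalizationParams(feature_ids, float(pseudocount), centre, scale)
    return apply_frozen(params, table), params


def apply_frozen(params: NormalizationParams, table: pd.DataFrame) -> pd.DataFrame:
    """Apply a previously fitted normalization to any profile table.

    Selects exactly ``params.feature_ids`` (missing features treated as zero
    abundance and logged), ignores extras, and uses the frozen centre/scale —
    never refits.  Output shape is ``len(params.feature_ids) x n_samples``.
    """
    missing = [f for f in params.feature_ids if f not in table.index]
    if missing:
        warnings.warn(
            f"apply_frozen: {len(missing)} model feature(s) absent from table; "
            "imputed as zero abundance",
            stacklevel=2,
        )
    clr = _clr_matrix(table, params.feature_ids, params.pseudocount)
    z = (clr - params.centre[:, None]) / params.scale[:, None]
    return pd.DataFrame(z, index=pd.Index(params.feature_ids, name="feature_id"),
                        columns=table.columns)
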