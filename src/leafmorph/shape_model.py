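"""PCA-weighted leaf shape models and the typical-leaf acceptance test.

Two scores summarize a candidate leaf against the population of clusters
the model was fitted on:

* size score  F(X) = sum_i a_i (X_0i - mean_0i) / mean_0i  over the four
  scale traits (area, perimeter, length, width);
* architecture score  G(X) = sum_i b_i X_1i  over the six ratio traits.

The weights a and b are the variance contribution rates (the normalized
eigenvalue spectrum) of a PCA over the fitting clusters' traits, computed
on correlation-scaled data so that mm^2-valued area cannot dominate the
spectrum; each spectrum sums to 1.  A cluster is a *typical leaf* when
both scores fall in the (0.25, 1.25) acceptance band: since the fitting-set
mean of the shifted size score 1 + F is exactly 1 (the weights sum to 1),
the size test is 0.25 < 1 + F < 1.25, and the architecture test is
0.25 Gbar < G < 1.25 Gbar with Gbar the fitting-set mean of G.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import InputError
from .traits import TraitVector

__all__ = ["ShapeModel", "DetectionResult", "fit_shape_model", "score_F", "score_G",
           "detect_typical"]

#: acceptance band applied to the shifted size score and to G relative to Gbar
BAND_LOW = 0.25
BAND_HIGH = 1.25

#: minimum number of fitting clusters for a stable PCA spectrum
MIN_ROWS_FOR_PCA = 5


@dataclass(frozen=True)
class ShapeModel:
    """Fitted leaf shape model: PCA weight spectra, trait means and band."""

    a: np.ndarray  # 4 weights for the scale traits
    b: np.ndarray  # 6 weights for the ratio traits
    mean_scale: np.ndarray  # means of (s, c, l, w)
    mean_g: float  # mean of G over the fitting clusters
    band: tuple[float, float] = (BAND_LOW, BAND_HIGH)
    n_fit: int = 0
    degenerate: bool = False

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "a": self.a.tolist(),
            "b": self.b.tolist(),
            "mean_scale": self.mean_scale.tolist(),
            "mean_g": self.mean_g,
            "band": list(self.band),
            "n_fit": int(self.n_fit),
            "degenerate": bool(self.degenerate),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "ShapeModel":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        return cls(
            a=np.array(d["a"]),
            b=np.array(d["b"]),
            mean_scale=np.array(d["mean_scale"]),
            mean_g=float(d["mean_g"]),
            band=tuple(d["band"]),
            n_fit=int(d["n_fit"]),
            degenerate=bool(d["degenerate"]),
        )


@dataclass(frozen=True)
class DetectionResult:
    """Outcome of the typical-leaf test for one cluster."""

    f_score: float
    g_score: float
    is_typical: bool
    reason: str  # pass | size_out_of_band | shape_out_of_band | degenerate_model


def variance_contribution_rates(matrix: np.ndarray) -> np.ndarray:
    """Normalized eigenvalue spectrum of the correlation matrix of ``matrix``
    (rows = observations), sorted descending; sums to 1.

    Constant columns contribute zero variance and receive weight 0.
    """
    x = np.asarray(matrix, dtype=float)
    std = x.std(axis=0, ddof=1)
    active = std > 1e-12
    p = x.shape[1]
    if active.sum() == 0:
        raise InputError("all trait columns are constant; spectrum undefined")
    corr = np.corrcoef(x[:, active], rowvar=False)
    corr = np.atleast_2d(corr)
    evals = np.linalg.eigvalsh(corr)[::-1]
    evals = np.clip(evals, 0.0, None)
    spectrum = np.zeros(p)
    spectrum[: active.sum()] = evals / evals.sum()
    return spectrum


def fit_shape_model(trait_rows: Sequence[TraitVector] | Iterable[TraitVector]) -> ShapeModel:
    """Fit both shape models from the trait vectors of a set of clusters.

    With at least :data:`MIN_ROWS_FOR_PCA` clusters and non-degenerate
    variance, the weights are PCA variance contribution rates of the
    correlation-scaled trait matrices, paired with the traits in their
    fixed order (descending spectrum).  Below that, or with zero variance,
    the model falls back to equal weights and is flagged degenerate.
    """
    rows = list(trait_rows)
    if len(rows) == 0:
        raise InputError("cannot fit a shape model on zero clusters")
    scale = np.array([r.scale_array() for r in rows])
    ratio = np.array([r.ratio_array() for r in rows])
    if (scale <= 0).any() or (ratio <= 0).any():
        raise InputError("shape model fitting requires strictly positive traits")
    n = len(rows)
    mean_scale = scale.mean(axis=0)
    degenerate = n < MIN_ROWS_FOR_PCA or (
        scale.std(axis=0).max() < 1e-12 and ratio.std(axis=0).max() < 1e-12
    )
    if degenerate:
        a = np.full(4, 0.25)
        b = np.full(6, 1.0 / 6.0)
    else:
        a = variance_contribution_rates(scale)
        b = variance_contribution_rates(ratio)
    model = ShapeModel(
        a=a, b=b, mean_scale=mean_scale, mean_g=0.0, n_fit=n, degenerate=degenerate
    )
    mean_g = float(np.mean([score_G(r, model) for r in rows]))
    return ShapeModel(
        a=a, b=b, mean_scale=mean_scale, mean_g=mean_g, n_fit=n, degenerate=degenerate
    )


def score_F(traits: TraitVector, model: ShapeModel) -> float:
    """Size score: weighted mean relative deviation of the scale traits
    from the model means; 0 for a leaf at the mean size."""
    if (model.mean_scale <= 0).any():
        raise InputError("shape model has a non-positive mean scale trait")
    dev = (traits.scale_array() - model.mean_scale) / model.mean_scale
    return float(model.a @ dev)


def score_G(traits: TraitVector, model: ShapeModel) -> float:
    """Architecture score: weighted sum of the six raw ratio traits."""
    return float(model.b @ traits.ratio_array())


def detect_typical(traits: TraitVector, model: ShapeModel) -> DetectionResult:
    """Apply the acceptance band to both scores.

    A model fitted on fewer than two clusters carries no population
    information; every candidate is then accepted with reason
    ``degenerate_model``.
    """
    f = score_F(traits, model)
    g = score_G(traits, model)
    if model.n_fit < 2:
        return DetectionResult(f, g, True, "degenerate_model")
    lo, hi = model.band
    if not (lo < 1.0 + f < hi):
        return DetectionResult(f, g, False, "size_out_of_band")
    if not (lo * model.mean_g < g < hi * model.mean_g):
        return DetectionResult(f, g, False, "shape_out_of_band")
    return DetectionResult(f, g, True, "pass")
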