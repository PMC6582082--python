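"""Thresholding and model evaluation: ROC/AUC and the binomial omission test.

The minimum-training-presence rule binarizes a suitability surface at
the least suitable training record, guaranteeing zero training
omission; model discrimination is summarized by the presence-vs-
background AUC; and the exact one-sided binomial test asks whether test
presences land in the predicted-suitable area more often than a random
point would, given the map's fractional predicted area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import binom, rankdata

from .geodata import RasterStack, extract_covariates
from .maxent import MaxentModel, SuitabilityMap, predict


@dataclass
class BinaryMap:
    """Suitable/unsuitable classification of a suitability surface."""

    suitable: np.ndarray       # boolean grid; False on missing cells too
    threshold: float
    scale: str
    fractional_area: float     # suitable cells / non-missing cells
    valid: np.ndarray | None = None  # non-missing mask, if known


@dataclass
class EvalReport:
    auc: float
    omission_pvalue: float
    threshold: float
    fractional_area: float
    n_presence: int
    n_background: int
    threshold_rule: str = "minimum_training_presence"

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "omission_pvalue": self.omission_pvalue,
            "threshold": self.threshold,
            "fractional_area": self.fractional_area,
            "n_presence": self.n_presence,
            "n_background": self.n_background,
            "threshold_rule": self.threshold_rule,
        }


def minimum_training_presence(training_scores) -> float:
    """The least suitable training presence: the zero-omission threshold."""
    scores = np.asarray(training_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("no training scores supplied")
    if not np.all(np.isfinite(scores)):
        raise ValueError("training scores must be finite")
    return float(scores.min())


def apply_threshold(suitability: SuitabilityMap, threshold: float) -> BinaryMap:
    """Mark cells with value ≥ threshold as suitable (non-missing only).

    The ≥ comparison makes the minimum training presence itself
    suitable, so training omission is exactly zero by construction.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    valid = np.isfinite(suitability.values)
    suitable = valid & (suitability.values >= threshold)
    n_valid = int(valid.sum())
    frac = float(suitable.sum()) / n_valid if n_valid else 0.0
    return BinaryMap(suitable=suitable, threshold=float(threshold),
                     scale=suitability.scale, fractional_area=frac,
                     valid=valid)


def roc_auc(presence_scores, background_scores) -> float:
    """Presence-vs-background AUC via the Mann–Whitney rank statistic.

    Equals (#{presence > background pairs} + ½·ties) / (n_p·n_b), and is
    invariant under strictly monotone transforms of the scores.
    """
    p = np.asarray(presence_scores, dtype=float).ravel()
    b = np.asarray(background_scores, dtype=float).ravel()
    if p.size == 0 or b.size == 0:
        raise ValueError("both score vectors must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    r_p = ranks[:p.size].sum()
    u = r_p - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def binomial_omission_test(binary: BinaryMap, n_test: int,
                           n_suitable: int) -> float:
    """Exact one-sided binomial tail P(X ≥ k), X ~ Bin(n, fractional area).

    Small p means test presences fall in predicted-suitable area more
    often than expected if they were thrown down at random.
    """
    if n_test < 1:
        raise ValueError("need at least one test point")
    if not 0 <= n_suitable <= n_test:
        raise ValueError("suitable count must lie in [0, n_test]")
    a = binary.fractional_area
    if not 0.0 <= a <= 1.0:
        raise ValueError(f"fractional area {a} outside [0, 1]")
    return float(binom.sf(n_suitable - 1, n_test, a))


def evaluate_model(model: MaxentModel, stack: RasterStack,
                   occurrences, scale: str = "logistic") -> EvalReport:
    """Training-data evaluation: AUC, MTP threshold and omission test.

    AUC is computed on the training presences against the full
    background (the stack's non-missing cells) and labelled as such —
    with no held-out data it measures fit, not transferability.
    """
    surface = predict(model, stack, scale=scale)
    pres_cov, kept = extract_covariates(stack, occurrences)
    if kept.size == 0:
        raise ValueError("no occurrence points fall on usable stack cells")
    pres_scores = model.predict_values(pres_cov, scale=scale,
                                       all_names=stack.layer_names)
    bg_scores = surface.valid_values()
    auc = roc_auc(pres_scores, bg_scores)
    thr = minimum_training_presence(pres_scores)
    binary = apply_threshold(surface, thr)
    k = int((pres_scores >= thr).sum())  # = n by construction of MTP
    p = binomial_omission_test(binary, len(pres_scores), k)
    return EvalReport(auc=auc, omission_pvalue=p, threshold=thr,
                      fractional_area=binary.fractional_area,
                      n_presence=int(len(pres_scores)),
                      n_background=int(bg_scores.size))
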