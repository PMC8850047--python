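"""Tanimoto fingerprint similarity and average-similarity prioritization.

For bit sets A, B the Tanimoto index is c / (a + b - c) with a = |A|,
b = |B|, c = |A ∩ B|.  Unknown compounds are prioritized by their mean
similarity to the panel of known actives; candidates whose mean exceeds a
strict threshold (default 0.7) pass.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .compounds import Fingerprint


def tanimoto(fa: Fingerprint, fb: Fingerprint) -> float:
    """Tanimoto similarity c/(a+b-c) between two fingerprints.

    Both fingerprints must share scheme and length.  Two empty bit sets are
    defined as identical (similarity 1.0, with a warning) — degenerate but
    consistent with "identical objects are maximally similar".
    """
    if fa.scheme != fb.scheme or fa.nbits != fb.nbits:
        raise ValueError(
            f"fingerprint scheme mismatch: {fa.scheme}/{fa.nbits} vs "
            f"{fb.scheme}/{fb.nbits}"
        )
    a, b = len(fa.bits), len(fb.bits)
    if a == 0 and b == 0:
        warnings.warn("Tanimoto of two empty fingerprints defined as 1.0")
        return 1.0
    c = len(fa.bits & fb.bits)
    return c / (a + b - c)


def similarity_matrix(
    unknowns: Sequence[Fingerprint], knowns: Sequence[Fingerprint]
) -> pd.DataFrame:
    """Dense unknown × known Tanimoto matrix, in input order."""
    if not unknowns or not knowns:
        raise ValueError("both fingerprint sets must be non-empty")
    data = [[tanimoto(u, k) for k in knowns] for u in unknowns]
    return pd.DataFrame(
        data,
        index=[u.compound_id for u in unknowns],
        columns=[k.compound_id for k in knowns],
    )


def prioritize(
    sm: pd.DataFrame, threshold: float = 0.7, stat: str = "mean"
) -> pd.DataFrame:
    """Rank unknowns by average similarity to the known actives.

    Returns a table (id, mean_similarity, passes) sorted descending by the
    summary statistic; ``passes`` is strict (> threshold).  ``stat`` may be
    "mean" (default) or "median".
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if stat == "mean":
        agg = sm.mean(axis=1)
    elif stat == "median":
        agg = sm.median(axis=1)
    else:
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    out = pd.DataFrame(
        {"id": sm.index, "mean_similarity": agg.to_numpy()}
    )
    out["passes"] = out["mean_similarity"] > threshold
    return out.sort_values("mean_similarity", ascending=False,
                           kind="mergesort").reset_index(drop=True)


class TanimotoPrioritizer(BaseEstimator):
    """Similarity screen against a fitted panel of known-active fingerprints.

    fit(fps) stores the known actives; transform(fps) returns each unknown's
    mean Tanimoto similarity to the panel, predict(fps) the strict-threshold
    pass flag.
    """

    def __init__(self, threshold: float = 0.7, stat: str = "mean"):
        self.threshold = threshold
        self.stat = stat

    def fit(self, fps: Sequence[Fingerprint], y=None):
        if not fps:
            raise ValueError("need at least one known-active fingerprint")
        self.known_fps_ = list(fps)
        return self

    def transform(self, fps: Sequence[Fingerprint]) -> np.ndarray:
        sm = similarity_matrix(fps, self.known_fps_)
        agg = sm.mean(axis=1) if self.stat == "mean" else sm.median(axis=1)
        return agg.to_numpy()

    def predict(self, fps: Sequence[Fingerprint]) -> np.ndarray:
        return self.transform(fps) > self.threshold

    def rank(self, fps: Sequence[Fingerprint]) -> pd.DataFrame:
        return prioritize(similarity_matrix(fps, self.known_fps_),
                          self.threshold, self.stat)
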