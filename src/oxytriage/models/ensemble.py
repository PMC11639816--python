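"""Soft and hard voting over fitted baseline tree models."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = ["EnsembleConfig", "VotingEnsemble", "vote"]


@dataclass(frozen=True)
class EnsembleConfig:
    """Members are baseline (default-parameter) configurations."""

    member_keys: tuple[str, ...]
    voting: str  # "soft" | "hard"

    def __post_init__(self) -> None:
        if len(self.member_keys) < 2:
            raise ValueError("an ensemble needs at least 2 members")
        if self.voting not in ("soft", "hard"):
            raise ValueError(f"voting must be 'soft' or 'hard', got {self.voting!r}")


@dataclass
class VotingEnsemble:
    """Vote over pre-fitted members exposing predict/predict_proba."""

    members: Sequence
    voting: str = "soft"

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Unweighted mean of member probabilities."""
        probas = [np.asarray(m.predict_proba(X), dtype=float) for m in self.members]
        shapes = {p.shape for p in probas}
        if len(shapes) != 1:
            raise ValueError(f"members disagree on probability shape: {shapes}")
        return np.mean(probas, axis=0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        mean_proba = self.predict_proba(X)
        if self.voting == "soft":
            return np.argmax(mean_proba, axis=1)
        votes = np.stack([np.asarray(m.predict(X)) for m in self.members])  # (M, n)
        n_classes = mean_proba.shape[1]
        counts = np.stack([(votes == c).sum(axis=0) for c in range(n_classes)], axis=1)
        top = counts.max(axis=1, keepdims=True)
        tied = counts == top
        # Plurality; ties broken by mean probability, then lowest class index
        # (argmax returns the first maximum, which is the lowest tied index).
        tiebreak = np.where(tied, mean_proba, -np.inf)
        return np.argmax(tiebreak, axis=1)


def vote(members: Sequence, mode: str, X: np.ndarray):
    """Functional form: predicted classes (+ probabilities when soft)."""
    ens = VotingEnsemble(members=list(members), voting=mode)
    if mode == "soft":
        proba = ens.predict_proba(X)
        return np.argmax(proba, axis=1), proba
    return ens.predict(X)
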