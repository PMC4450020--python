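"""Slack-variable discriminant machinery for the class coupling.

The class block enters the multiblock correlation model through an
augmented matrix ``chi_5 = X_5 + b (*) m`` (``(*)`` is the Hadamard
product): ``b`` is the +/-1 class direction and ``m >= 0`` a per-sample
slack that can only push a sample's working label further from the
decision boundary, never across it.  This is the discriminative
least-squares (DLSR) device: the regression of the expression block onto
its working response is free to enlarge between-class margins.

The loading update of the expression block is a univariate
soft-threshold of the regression of the working response
``gamma = upsilon + b (*) m`` on the centered expression block; the slack
update is the positive part of the class-directed residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlackState",
    "update_discriminant_loading",
    "update_slack",
    "augmented_class_block",
]


@dataclass
class SlackState:
    """Class direction ``b`` (+/-1) and nonnegative slack ``m``."""

    b: np.ndarray
    m: np.ndarray

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float)
        self.m = np.asarray(self.m, dtype=float)
        if self.b.shape != self.m.shape:
            raise ValueError("b and m must have the same length")
        if not np.all(np.isin(self.b, (-1.0, 1.0))):
            raise ValueError("b entries must be -1 or +1")
        if np.any(self.m < 0):
            raise ValueError("slack entries must be nonnegative")

    @classmethod
    def zeros(cls, labels: np.ndarray) -> "SlackState":
        """Initial state: direction from the labels, zero slack."""
        b = np.where(np.asarray(labels, dtype=float) < 0, -1.0, 1.0)
        return cls(b=b, m=np.zeros_like(b))

    def margin_shift(self) -> np.ndarray:
        """``b (*) m``, the signed shift applied to the class block."""
        return self.b * self.m


def update_discriminant_loading(
    chi4: np.ndarray, gamma: np.ndarray, lambda4: float
) -> np.ndarray:
    """Soft-thresholded regression of the working response on the block.

    ``alpha(i) = sign(chi4(i)' gamma) (|chi4(i)' gamma| - lambda4)_+``.
    The result is unnormalized; the caller rescales it to the model's
    latent-norm convention.
    """
    if lambda4 < 0:
        raise ValueError("lambda4 must be nonnegative")
    g = chi4.T @ np.asarray(gamma, dtype=float)
    return np.sign(g) * np.maximum(np.abs(g) - lambda4, 0.0)


def update_slack(
    chi4: np.ndarray,
    alpha4: np.ndarray,
    upsilon: np.ndarray,
    b: np.ndarray,
) -> np.ndarray:
    """Optimal slack given the current loading: ``m = max(b (*) (chi4 alpha4 - upsilon), 0)``.

    ``alpha4`` must be on the regression scale (so that ``chi4 @ alpha4``
    approximates the working response); the slack is then the positive
    part of the class-directed residual.
    """
    residual = chi4 @ np.asarray(alpha4, dtype=float) - np.asarray(upsilon, dtype=float)
    return np.maximum(np.asarray(b, dtype=float) * residual, 0.0)


def augmented_class_block(X5: np.ndarray, b: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Working class block ``chi_5 = X_5 + b (*) m``.

    With +1 labels shifted up and -1 labels shifted down, the slack only
    ever widens the separation between the classes.
    """
    X5 = np.asarray(X5, dtype=float)
    shift = np.asarray(b, dtype=float) * np.asarray(m, dtype=float)
    if X5.ndim == 2:
        return X5 + shift[:, None]
    return X5 + shift
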