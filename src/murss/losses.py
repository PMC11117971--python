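"""Selective segmentation objective (SSM).

The model emits three per-pixel outputs: class scores ``O`` from the
prediction head ``f``, a selection score ``S`` in [0, 1] from the selection
head ``g``, and auxiliary class scores ``A`` from ``h``. Training minimizes

    L_total = alpha * (r + lambda * max(0, T - mean g)^2) + (1 - alpha) * L_aux

where the empirical coverage risk

    r = sum_ij l(f_ij, y_ij) g_ij / sum_ij g_ij

is the selection-weighted average pixel cross-entropy over the covered
region, the quadratic penalty forces the mean selection (the coverage) up
to the target ratio ``T``, and ``L_aux`` is the plain mean cross-entropy of
the auxiliary head over all pixels, which keeps the shared trunk from
overfitting to the covered subset. Pixels labeled with the ignore value are
excluded from every sum.

All functions accept either autograd tensors (differentiable path used in
training) or plain numpy arrays, and return an autograd ``Tensor`` —
call ``.item()`` for the float value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn.autograd import Tensor, as_tensor, cross_entropy_map

IGNORE = 255


@dataclass
class LossConfig:
    """Selective-loss hyperparameters.

    T: target coverage ratio in (0, 1] — fraction of pixels the model must
       keep. lambda_: weight of the quadratic coverage penalty. alpha:
       mixing weight between the selective and the auxiliary risk.
    """

    T: float = 0.95
    lambda_: float = 32.0
    alpha: float = 0.5
    ignore_label: int = IGNORE
    class_weights: tuple | None = None

    def __post_init__(self):
        if not 0.0 < self.T <= 1.0:
            raise ValueError("T must be in (0, 1]")
        if self.lambda_ < 0:
            raise ValueError("lambda_ must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def _selection_map(S) -> Tensor:
    S = as_tensor(S)
    if S.ndim == 4:  # (B, 1, H, W) -> (B, H, W)
        S = S.reshape(S.shape[0], S.shape[2], S.shape[3])
    return S


def _pixel_loss(scores, y, ignore_label, from_logits, class_weights) -> Tensor:
    scores = as_tensor(scores)
    y = np.asarray(y)
    if from_logits:
        return cross_entropy_map(scores, y, ignore_label, class_weights)
    # scores already normalized per pixel: l = -log p_y
    k = scores.shape[1]
    valid = y != ignore_label
    if not np.isin(y[valid], np.arange(k)).all():
        raise ValueError(f"labels must be in 0..{k - 1} or {ignore_label}")
    safe = np.where(valid, y, 0)
    onehot = np.zeros(scores.shape)
    np.put_along_axis(onehot, safe[:, None], 1.0, axis=1)
    if class_weights is not None:
        onehot *= np.asarray(class_weights, dtype=np.float64)[safe][:, None]
    clipped = scores * (1.0 - 1e-12) + 1e-12
    return -(clipped.log() * onehot).sum(axis=1) * valid


def coverage_risk(
    O,
    S,
    y,
    ignore_label: int = IGNORE,
    from_logits: bool = True,
    class_weights=None,
    eps: float = 1e-8,
) -> Tensor:
    """Empirical coverage risk: selection-weighted mean pixel loss.

    With ``S`` identically 1 this reduces to the plain mean cross-entropy.
    When the selection mass over valid pixels falls below ``eps`` the risk
    is defined as 0 (the penalty term is what pushes coverage back up, so
    the degenerate ratio never destabilizes training).
    """
    y = np.asarray(y)
    loss_map = _pixel_loss(O, y, ignore_label, from_logits, class_weights)
    g = _selection_map(S)
    valid = (y != ignore_label).astype(np.float64)
    denom = (g * valid).sum()
    if float(denom.data) < eps:
        return Tensor(0.0)
    num = (loss_map * g * valid).sum()
    return num / denom


def coverage_penalty(S, T: float, y=None, ignore_label: int = IGNORE) -> Tensor:
    """Quadratic coverage shortfall, ``max(0, T - mean g)^2``.

    Zero as soon as the mean selection over valid pixels reaches the target
    coverage ``T``; grows quadratically with the shortfall below it.
    """
    g = _selection_map(S)
    if y is not None:
        valid = (np.asarray(y) != ignore_label).astype(np.float64)
        mean_g = (g * valid).sum() / max(valid.sum(), 1.0)
    else:
        mean_g = g.mean()
    return (as_tensor(T) - mean_g).relu() ** 2


def selective_loss(O, S, y, cfg: LossConfig, from_logits: bool = True) -> Tensor:
    """Coverage risk plus the weighted coverage penalty."""
    r = coverage_risk(
        O, S, y, cfg.ignore_label, from_logits=from_logits,
        class_weights=cfg.class_weights,
    )
    pen = coverage_penalty(S, cfg.T, y=y, ignore_label=cfg.ignore_label)
    return r + cfg.lambda_ * pen


def auxiliary_risk(A, y, cfg: LossConfig, from_logits: bool = True) -> Tensor:
    """Mean cross-entropy of the auxiliary head over all valid pixels."""
    y = np.asarray(y)
    loss_map = _pixel_loss(A, y, cfg.ignore_label, from_logits, cfg.class_weights)
    valid = (y != cfg.ignore_label).astype(np.float64)
    n = max(valid.sum(), 1.0)
    return (loss_map * valid).sum() / n


def total_loss(O, S, A, y, cfg: LossConfig, from_logits: bool = True):
    """Full training objective; returns ``(L_total, components)``.

    ``components`` is a plain-float dict (risk, penalty, l_select, l_aux,
    l_total, coverage) suitable for structured step logging.
    """
    r = coverage_risk(
        O, S, y, cfg.ignore_label, from_logits=from_logits,
        class_weights=cfg.class_weights,
    )
    pen = coverage_penalty(S, cfg.T, y=y, ignore_label=cfg.ignore_label)
    l_select = r + cfg.lambda_ * pen
    l_aux = auxiliary_risk(A, y, cfg, from_logits=from_logits)
    l_tot = cfg.alpha * l_select + (1.0 - cfg.alpha) * l_aux
    g = _selection_map(S)
    valid = np.asarray(y) != cfg.ignore_label
    coverage = float((g.data * valid).sum() / max(valid.sum(), 1))
    components = {
        "risk": r.item(),
        "penalty": pen.item(),
        "l_select": l_select.item(),
        "l_aux": l_aux.item(),
        "l_total": l_tot.item(),
        "coverage": coverage,
    }
    return l_tot, components


def select_pixels(S, threshold: float = 0.5) -> np.ndarray:
    """Binarize selection scores: accept where ``S >= threshold``."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    S = S.data if isinstance(S, Tensor) else np.asarray(S)
    if S.ndim == 4:
        S = S[:, 0]
    return S >= threshold
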