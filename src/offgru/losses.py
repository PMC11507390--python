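"""Class-balanced loss functions and the knowledge-distillation composite.

Off-target datasets are severely imbalanced (imbalance ratios up to several
thousand negatives per positive), so plain cross-entropy drives the model
toward the majority class.  The losses here weight the minority class
implicitly: the default, soft dice, measures batch-level overlap between
the predicted off-target probabilities and the positive labels, which is
insensitive to the number of true negatives.

Each loss exposes ``value(y_true, y_pred)`` and ``grad(y_true, y_pred)``
on the off-target probability column (``bce`` uses both output columns via
the training adapter), so the numpy training loop can backpropagate
analytically.

The distillation objective combines the student's hard-label loss SL with
a distillation term DL against the teacher's soft predictions:

    L_KD = alpha * SL + (1 - alpha) * DL,    alpha in [0, 1]

with alpha = 0.2 by default.
"""

from __future__ import annotations

import numpy as np

EPS = 1e-6  # smoothing for overlap losses
LOG_EPS = 1e-7  # guard for logarithms

LOSS_NAMES = ("dice", "focal", "tversky", "asymmetric", "hinge", "bce")


def _check_inputs(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ValueError(
            f"length mismatch: {y_true.shape[0]} labels vs {y_pred.shape[0]} predictions"
        )
    if np.any((y_pred < 0) | (y_pred > 1)):
        raise ValueError("predictions must lie in [0, 1]")
    return y_true, y_pred


def dice_loss(y_true, y_pred, eps: float = EPS) -> float:
    """Soft dice loss: 1 - (2*sum(t*p) + eps) / (sum(t) + sum(p) + eps).

    Batch-wise overlap between predicted probabilities and binary labels;
    0 at perfect overlap, approaching 1 with none.
    """
    t, p = _check_inputs(y_true, y_pred)
    return float(1.0 - (2.0 * (t * p).sum() + eps) / (t.sum() + p.sum() + eps))


def _dice_grad(t, p, eps=EPS):
    denom = t.sum() + p.sum() + eps
    numer = 2.0 * (t * p).sum() + eps
    return (numer / denom ** 2) - (2.0 * t / denom)


def kd_loss(sl: float, dl: float, alpha: float) -> float:
    """Combined distillation loss ``alpha*SL + (1-alpha)*DL`` (alpha in [0,1])."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * sl + (1.0 - alpha) * dl


class _Loss:
    """Value + gradient on the off-target probability column."""

    name: str = ""

    def value(self, y_true, y_pred) -> float:
        raise NotImplementedError

    def grad(self, y_true, y_pred) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, y_true, y_pred) -> float:
        return self.value(y_true, y_pred)


class DiceLoss(_Loss):
    name = "dice"

    def __init__(self, eps: float = EPS):
        self.eps = eps

    def value(self, y_true, y_pred):
        return dice_loss(y_true, y_pred, self.eps)

    def grad(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        return _dice_grad(t, p, self.eps)


class FocalLoss(_Loss):
    """Focal loss; gamma=0 with balance weights off reduces to cross-entropy."""

    name = "focal"

    def __init__(self, gamma: float = 2.0, alpha: float = 0.25):
        self.gamma, self.alpha = gamma, alpha

    def value(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        p = np.clip(p, LOG_EPS, 1.0 - LOG_EPS)
        g, a = self.gamma, self.alpha
        pos = -a * (1.0 - p) ** g * np.log(p)
        neg = -(1.0 - a) * p ** g * np.log(1.0 - p)
        return float(np.mean(t * pos + (1.0 - t) * neg))

    def grad(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        p = np.clip(p, LOG_EPS, 1.0 - LOG_EPS)
        g, a = self.gamma, self.alpha
        q = 1.0 - p
        dpos = a * (g * q ** (g - 1.0) * np.log(p) - q ** g / p)
        dneg = (1.0 - a) * (-g * p ** (g - 1.0) * np.log(1.0 - p) + p ** g / q)
        return (t * dpos + (1.0 - t) * dneg) / t.size


class TverskyLoss(_Loss):
    """Tversky index loss; alpha/beta weight false positives/negatives."""

    name = "tversky"

    def __init__(self, alpha: float = 0.3, beta: float = 0.7, eps: float = EPS):
        self.alpha, self.beta, self.eps = alpha, beta, eps

    def _terms(self, t, p):
        tp = (t * p).sum()
        fp = ((1.0 - t) * p).sum()
        fn = (t * (1.0 - p)).sum()
        denom = tp + self.alpha * fp + self.beta * fn + self.eps
        return tp, denom

    def value(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        tp, denom = self._terms(t, p)
        return float(1.0 - (tp + self.eps) / denom)

    def grad(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        tp, denom = self._terms(t, p)
        dtp = t
        ddenom = t + self.alpha * (1.0 - t) - self.beta * t
        return -(dtp * denom - (tp + self.eps) * ddenom) / denom ** 2


class AsymmetricLoss(_Loss):
    """Asymmetric focal loss: separate focusing exponents per class and a
    probability margin that discards easy negatives."""

    name = "asymmetric"

    def __init__(self, gamma_pos: float = 1.0, gamma_neg: float = 4.0,
                 margin: float = 0.05):
        self.gamma_pos, self.gamma_neg, self.margin = gamma_pos, gamma_neg, margin

    def value(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        p = np.clip(p, LOG_EPS, 1.0 - LOG_EPS)
        pm = np.clip(p - self.margin, LOG_EPS, 1.0 - LOG_EPS)
        pos = (1.0 - p) ** self.gamma_pos * (-np.log(p))
        neg = pm ** self.gamma_neg * (-np.log(1.0 - pm))
        return float(np.mean(t * pos + (1.0 - t) * neg))

    def grad(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        p = np.clip(p, LOG_EPS, 1.0 - LOG_EPS)
        gp, gn = self.gamma_pos, self.gamma_neg
        q = 1.0 - p
        dpos = gp * q ** (gp - 1.0) * np.log(p) - q ** gp / p
        pm = p - self.margin
        active = pm > LOG_EPS
        pm = np.clip(pm, LOG_EPS, 1.0 - LOG_EPS)
        dneg = (-gn * pm ** (gn - 1.0) * np.log(1.0 - pm) + pm ** gn / (1.0 - pm))
        dneg = np.where(active, dneg, 0.0)
        return (t * dpos + (1.0 - t) * dneg) / t.size


class HingeLoss(_Loss):
    """Hinge loss on labels mapped to +/-1 and scores 2p-1."""

    name = "hinge"

    def value(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        y = 2.0 * t - 1.0
        s = 2.0 * p - 1.0
        return float(np.mean(np.maximum(0.0, 1.0 - y * s)))

    def grad(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        y = 2.0 * t - 1.0
        active = (1.0 - y * (2.0 * p - 1.0)) > 0.0
        return np.where(active, -2.0 * y, 0.0) / t.size


class BCELoss(_Loss):
    name = "bce"

    def value(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        p = np.clip(p, LOG_EPS, 1.0 - LOG_EPS)
        return float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))

    def grad(self, y_true, y_pred):
        t, p = _check_inputs(y_true, y_pred)
        p = np.clip(p, LOG_EPS, 1.0 - LOG_EPS)
        return ((1.0 - t) / (1.0 - p) - t / p) / t.size


_REGISTRY = {cls.name: cls for cls in
             (DiceLoss, FocalLoss, TverskyLoss, AsymmetricLoss, HingeLoss, BCELoss)}


def make_loss(name: str, **kwargs) -> _Loss:
    """Instantiate a loss by name (one of dice, focal, tversky, asymmetric,
    hinge, bce), with documented default hyperparameters."""
    try:
        cls = _REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown loss {name!r}; valid losses: {', '.join(LOSS_NAMES)}"
        ) from None
    return cls(**kwargs)


class TrainingLoss:
    """Adapter mapping a column loss onto the two-neuron network output.

    The network emits ``(n, 2)`` sigmoid probabilities (on-target,
    off-target).  Losses are computed on the off-target column against the
    binary label, which is where the class-imbalance correction acts;
    ``bce`` is additionally applied to the on-target column against the
    complement label so both neurons stay calibrated.

    Overlap losses (dice, tversky) are symmetrised over the two classes:
    the loss is averaged with its value on ``(1-t, 1-p)``.  A one-sided
    overlap loss admits a degenerate minimum at all-ones predictions
    (overlap is complete, the denominator merely doubles), and gradient
    descent from a sigmoid initialisation reliably falls into it before
    the features can separate the classes; the complement term removes
    that attractor while keeping the batch-overlap character of the loss.
    """

    def __init__(self, loss: _Loss | str, **kwargs):
        self.loss = make_loss(loss, **kwargs) if isinstance(loss, str) else loss
        self.symmetric = self.loss.name in ("dice", "tversky")

    def __call__(self, y_true: np.ndarray, probs: np.ndarray):
        t = np.asarray(y_true, dtype=float)
        p = probs[:, 1]
        dP = np.zeros_like(probs)
        value = self.loss.value(t, p)
        dP[:, 1] = self.loss.grad(t, p)
        if self.symmetric:
            value = 0.5 * (value + self.loss.value(1.0 - t, 1.0 - p))
            dP[:, 1] = 0.5 * (dP[:, 1] - self.loss.grad(1.0 - t, 1.0 - p))
        elif self.loss.name == "bce":
            value = 0.5 * (value + self.loss.value(1.0 - t, probs[:, 0]))
            dP[:, 0] = 0.5 * self.loss.grad(1.0 - t, probs[:, 0])
            dP[:, 1] *= 0.5
        return value, dP


class DistillationLoss:
    """L_KD = alpha*SL(hard labels) + (1-alpha)*DL(teacher soft labels).

    DL is the cross-entropy between the teacher's off-target probability
    (optionally sharpened/softened by a temperature on the logit scale) and
    the student's off-target probability.
    """

    def __init__(self, student_loss: _Loss | str = "dice", alpha: float = 0.2,
                 temperature: float = 1.0):
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        self.hard = TrainingLoss(student_loss)
        self.alpha = alpha
        self.temperature = temperature

    def _soften(self, q: np.ndarray) -> np.ndarray:
        if self.temperature == 1.0:
            return q
        q = np.clip(q, LOG_EPS, 1.0 - LOG_EPS)
        logits = np.log(q / (1.0 - q)) / self.temperature
        return 1.0 / (1.0 + np.exp(-logits))

    def __call__(self, y_true: np.ndarray, probs: np.ndarray,
                 teacher_probs: np.ndarray):
        sl, dP_sl = self.hard(y_true, probs)
        q = self._soften(np.asarray(teacher_probs, dtype=float).ravel())
        p = np.clip(probs[:, 1], LOG_EPS, 1.0 - LOG_EPS)
        dl = float(-np.mean(q * np.log(p) + (1.0 - q) * np.log(1.0 - p)))
        dP_dl = np.zeros_like(probs)
        dP_dl[:, 1] = ((1.0 - q) / (1.0 - p) - q / p) / p.size
        value = kd_loss(sl, dl, self.alpha)
        dP = self.alpha * dP_sl + (1.0 - self.alpha) * dP_dl
        return value, dP
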