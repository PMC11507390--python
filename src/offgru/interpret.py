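"""Knowledge distillation and position/base-pair attribution.

The full classifier reads the 7-channel OR-composite encoding, which
destroys mismatch identity (an A-G and a G-A mismatch share base
channels, disambiguated only by the direction bits).  To attribute
predictions to specific base pairs, a small *student* model is trained on
the lossless 24x16 base-pair encoding against a mixture of the hard
labels and the teacher's soft off-target probabilities
(``L_KD = alpha*SL + (1-alpha)*DL``, alpha = 0.2 by default).

Attribution uses expected gradients, an additive feature-attribution
method in the Deep SHAP family: contributions are the input-minus-baseline
times the path-integrated gradient of the off-target output, averaged over
a background sample of training records.  Per-sample attributions
approximately satisfy the completeness identity

    sum_features phi(x) ~= f(x) - E_background[f(b)],

and the reported map is the per-cell mean over an explained subset (all
positives plus an equal-count random draw of negatives), standardized to
zero mean / unit variance over active cells so maps are comparable
across datasets.  Base-pair maps additionally restrict each record's
contribution to the one-hot cells it actually sets; otherwise present
and absent contributions of the same cell cancel across the subset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .encoding import GuidePair, PAIR_ORDER, encode_batch
from .network import ModelConfig, ModelHandle, TrainConfig, train


@dataclass
class AttributionMap:
    """Mean per-cell attribution, positions x channels."""

    values: np.ndarray
    channel_names: tuple[str, ...]
    standardized: bool
    sample_spec: str = ""

    def position_importance(self) -> np.ndarray:
        """Per-position attribution magnitude (sum of |cell| over channels)."""
        return np.abs(self.values).sum(axis=1)

    def standardize(self, mask: np.ndarray | None = None) -> "AttributionMap":
        """Z-score the map over (optionally masked) cells; idempotent up to
        the affine rescaling, so ordering of cells is preserved."""
        v = self.values.copy()
        cells = v[mask] if mask is not None else v.ravel()
        sd = cells.std()
        if sd == 0:
            sd = 1.0
        v = (v - cells.mean()) / sd
        return replace(self, values=v, standardized=True)


def expected_gradients(predict_grad, x: np.ndarray, background: np.ndarray,
                       n_steps: int = 24,
                       rng: np.random.Generator | int = 0) -> np.ndarray:
    """Expected-gradients attributions for a batch of inputs.

    Parameters
    ----------
    predict_grad
        Callable ``f(batch) -> gradient batch`` returning the gradient of
        the explained scalar output with respect to each input row.
    x
        Inputs to explain, shape ``(n, ...)``.
    background
        Baseline sample, shape ``(m, ...)``; every explained input is
        integrated against every background row.
    n_steps
        Midpoint-rule resolution of the path integral; higher is closer
        to exact completeness.

    Returns per-input attributions of the same shape as ``x``.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    x = np.asarray(x, dtype=float)
    background = np.asarray(background, dtype=float)
    m = background.shape[0]
    alphas = (np.arange(n_steps) + 0.5) / n_steps
    attr = np.zeros_like(x)
    tail = [1] * (x.ndim - 1)
    for i in range(x.shape[0]):
        diff = x[i][None] - background  # (m, ...)
        # all (background, alpha) interpolants in one batched pass,
        # background-major so the reshape below recovers the pairing
        interp = (background[:, None] + alphas.reshape(1, -1, *tail)
                  * diff[:, None]).reshape(m * n_steps, *x.shape[1:])
        grads = predict_grad(interp).reshape(m, n_steps, *x.shape[1:])
        attr[i] = (diff * grads.mean(axis=1)).mean(axis=0)
    return attr


def _model_grad(model: ModelHandle, output_index: int = 1):
    def predict_grad(batch):
        return model.net.input_gradient(batch, output_index)
    return predict_grad


def _explained_subset(pairs: list[GuidePair], rng: np.random.Generator):
    """All positives plus an equal-count seeded random draw of negatives."""
    labels = np.array([p.label for p in pairs])
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0:
        raise ValueError("attribution needs at least one positive record")
    take = min(pos.size, neg.size)
    chosen = np.concatenate([pos, rng.choice(neg, size=take, replace=False)])
    return chosen, labels


def _explain(model: ModelHandle, pairs: list[GuidePair], scheme: str,
             channel_names: tuple[str, ...], n_background: int,
             n_steps: int, seed: int,
             mask_to_active: bool = False) -> AttributionMap:
    rng = np.random.default_rng(seed)
    chosen, _ = _explained_subset(pairs, rng)
    X = encode_batch(pairs, scheme)
    bg_idx = rng.choice(X.shape[0], size=min(n_background, X.shape[0]),
                        replace=False)
    attr = expected_gradients(_model_grad(model), X[chosen], X[bg_idx],
                              n_steps=n_steps, rng=rng)
    if mask_to_active:
        # one-hot channels: each record credits only the cell it sets.
        # Averaging present and absent contributions together cancels
        # them (a base pair that raises the score when present lowers
        # it, relative to background, in every record lacking it).
        attr = attr * X[chosen]
    amap = AttributionMap(values=attr.mean(axis=0),
                          channel_names=channel_names, standardized=False,
                          sample_spec=f"{chosen.size} records "
                                      f"({chosen.size // 2}+ / rest matched -), "
                                      f"{bg_idx.size} background, "
                                      f"{n_steps} path steps, seed {seed}")
    # standardize over cells that are ever active in the explained subset
    active = X[chosen].max(axis=0) > 0
    return amap.standardize(mask=active)


def explain_positions(model: ModelHandle, pairs: list[GuidePair],
                      n_background: int = 100, n_steps: int = 24,
                      seed: int = 0) -> AttributionMap:
    """Position x channel attribution map on the 7-channel teacher input."""
    names = ("A", "T", "G", "C", "indel", "dir<", "dir>")
    return _explain(model, pairs, "7ch", names, n_background, n_steps, seed)


def explain_base_pairs(model: ModelHandle, pairs: list[GuidePair],
                       n_background: int = 100, n_steps: int = 24,
                       seed: int = 0) -> AttributionMap:
    """Position x base-pair (24x16) attribution map for the student model."""
    if any(p.has_indel for p in pairs):
        raise ValueError("base-pair attribution is defined for mismatch-only "
                         "datasets (the 16-channel scheme has no bulge code)")
    return _explain(model, pairs, "16ch", PAIR_ORDER, n_background, n_steps,
                    seed, mask_to_active=True)


def base_pair_table(amap: AttributionMap) -> pd.DataFrame:
    """Long-format export of a 24x16 map with labels like ``C-A:18``.

    ``X-Y:p`` means guide base X against DNA base Y at protospacer
    position p (1 = PAM-distal).  Pad and PAM rows are omitted; only the
    20 protospacer positions carry base-pair attributions of interest.
    """
    if amap.values.shape != (24, 16):
        raise ValueError("expected a 24x16 base-pair map")
    rows = []
    for pos in range(20):
        for ci, pair in enumerate(amap.channel_names):
            rows.append({"label": f"{pair[0]}-{pair[1]}:{pos + 1}",
                         "position": pos + 1, "guide_base": pair[0],
                         "dna_base": pair[1],
                         "value": float(amap.values[pos, ci])})
    return pd.DataFrame(rows)


def distill(teacher: ModelHandle, pairs: list[GuidePair],
            student_cfg: ModelConfig | None = None, alpha: float = 0.2,
            seed: int = 0, train_cfg: TrainConfig | None = None,
            with_control: bool = False):
    """Train a 16-channel student against hard labels + teacher soft labels.

    The teacher must have been trained on the 7-channel encoding; its
    off-target probabilities on the same records become the soft labels.
    With ``with_control=True`` also returns a no-distillation control
    student (``alpha = 1``) trained from the identical seed.

    Raises on datasets containing bulges: the 16-channel scheme encodes
    base pairs only.
    """
    if any(p.has_indel for p in pairs):
        raise ValueError("distillation requires a mismatch-only dataset: "
                         "the 16-channel student encoding has no bulge code")
    if teacher.config.input_shape[1] != 7:
        raise ValueError("teacher must be a 7-channel model")
    student_cfg = student_cfg or ModelConfig.student()
    labels = np.array([p.label for p in pairs])
    X7 = encode_batch(pairs, "7ch")
    X16 = encode_batch(pairs, "16ch")
    soft = teacher.predict_scores(X7)

    student = ModelHandle(student_cfg, seed=seed)
    train(student, X16, labels, train_cfg, teacher_scores=soft,
          kd_alpha=alpha)
    if not with_control:
        return student
    control = ModelHandle(student_cfg, seed=seed)
    train(control, X16, labels, train_cfg, teacher_scores=soft, kd_alpha=1.0)
    return student, control
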