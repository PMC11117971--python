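"""Scikit-learn style estimator for the selective segmentation model.

:class:`MurSSSegmenter` exposes the network + selective objective as a
``fit``/``predict`` estimator so it composes with sklearn tooling
(``clone``, ``get_params``/``set_params``, pipelines). Input samples are
dual-resolution patch pairs:

    X : float array (n, 2, 3, H, W) in [-1, 1] — X[:, 0] the
        high-magnification patch, X[:, 1] the co-centered
        low-magnification patch, both channels-first RGB
    y : int array (n, H, W) with labels {0, 1, 2} and 255 = ignore

Use :func:`triplets_to_arrays` to convert :class:`~murss.patching.PatchTriplet`
lists into this layout (the mid patch is not used by this model).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from ._nn.optim import Adam
from .losses import LossConfig, select_pixels, total_loss
from .metrics import evaluate_with_rejection
from .model import ModelConfig, MurSSNet


def triplets_to_arrays(triplets):
    """Stack patch triplets into the (X, y) layout the estimator expects.

    Images are centered to [-1, 1]: with strictly positive inputs, randomly
    initialized conv units whose weights sum negative would start (and often
    stay) silent.
    """
    xs, ys = [], []
    for t in triplets:
        hi = t.high.astype(np.float64).transpose(2, 0, 1) / 127.5 - 1.0
        lo = t.low.astype(np.float64).transpose(2, 0, 1) / 127.5 - 1.0
        xs.append(np.stack([hi, lo]))
        ys.append(t.mask.astype(np.int64))
    return np.stack(xs), np.stack(ys)


class MurSSSegmenter(BaseEstimator):
    """Dual-resolution selective pixel classifier.

    Parameters
    ----------
    coverage : target coverage ratio T in (0, 1]; the selective loss is
        penalized whenever the mean selection score drops below it.
    lambda_, alpha : penalty weight and selective/auxiliary mixing weight.
    c_stem, c_mid : backbone widths (mid-level feature width; the published
        configuration corresponds to ``c_mid=32``).
    adain_mode : "split" (parameter-free context statistics) or "projected".
    selective : with False, trains the prediction head only with plain
        cross-entropy (the non-selective MurAN variant); the selection
        scores returned are then identically 1.
    threshold : inference-time binarization threshold on the selection
        score (fixed, not recalibrated on validation data).
    epochs, batch_size, lr : optimization settings (adaptive-moment
        updates).
    class_weights : optional per-class cross-entropy weights.
    random_state : seed controlling init, shuffling and everything else.

    Attributes (after ``fit``)
    --------------------------
    model_ : the fitted :class:`~murss.model.MurSSNet`
    history_ : list of per-step dicts (step, risk, penalty, l_select,
        l_aux, l_total, coverage)
    val_history_ : per-epoch validation records when validation data was
        supplied
    best_epoch_ : epoch whose checkpoint was retained (validation mIoU on
        covered pixels; last epoch when no validation data)
    """

    def __init__(
        self,
        coverage: float = 0.95,
        lambda_: float = 32.0,
        alpha: float = 0.5,
        c_stem: int = 16,
        c_mid: int = 32,
        adain_mode: str = "split",
        selective: bool = True,
        threshold: float = 0.5,
        epochs: int = 10,
        batch_size: int = 8,
        lr: float = 1e-4,
        select_lr_mult: float = 20.0,
        class_weights=None,
        ignore_label: int = 255,
        random_state: int = 0,
    ):
        self.coverage = coverage
        self.lambda_ = lambda_
        self.alpha = alpha
        self.c_stem = c_stem
        self.c_mid = c_mid
        self.adain_mode = adain_mode
        self.selective = selective
        self.threshold = threshold
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.select_lr_mult = select_lr_mult
        self.class_weights = class_weights
        self.ignore_label = ignore_label
        self.random_state = random_state

    # -- helpers ----------------------------------------------------------
    def _check_X(self, X):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 5 or X.shape[1] != 2 or X.shape[2] != 3:
            raise ValueError("X must be (n, 2, 3, H, W) dual-resolution pairs")
        return X

    def _loss_config(self):
        return LossConfig(
            T=self.coverage,
            lambda_=self.lambda_,
            alpha=self.alpha,
            ignore_label=self.ignore_label,
            class_weights=self.class_weights,
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y, validation_data=None, log_callback=None):
        """Optimize the selective objective on patch pairs.

        ``validation_data=(Xv, yv)`` enables per-epoch model selection:
        the parameters from the epoch with the best validation mIoU over
        covered pixels are restored at the end. A non-finite loss aborts
        with a diagnostic snapshot of the offending step's components.
        """
        X = self._check_X(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0],) + X.shape[3:]:
            raise ValueError("y must be (n, H, W) aligned with X")
        rng = np.random.default_rng(self.random_state)
        cfg = ModelConfig(
            c_stem=self.c_stem,
            c_mid=self.c_mid,
            adain_mode=self.adain_mode,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        self.model_ = MurSSNet(cfg)
        self.config_ = cfg
        if self.selective and self.coverage < 1.0:
            # Start the normalized selection logits shifted to the target
            # coverage: the penalty begins near-inactive and the
            # risk/selection covariance shapes scores from the first step.
            self.model_.head_g.mods[-1].beta.data[:] = np.log(
                self.coverage / (1.0 - self.coverage)
            )
        loss_cfg = self._loss_config()
        n_samples = X.shape[0]
        sel_params = self.model_.head_g.parameters() if self.selective else []
        sel_ids = {id(p) for p in sel_params}
        trunk_params = [p for p in self.model_.parameters() if id(p) not in sel_ids]
        # The selection head chases a slowly-emerging covariance signal
        # through a sigmoid; it gets its own, larger step size. Both
        # groups decay on a cosine schedule so the coverage/risk balance
        # settles late in training.
        steps_per_epoch = int(np.ceil(n_samples / self.batch_size))
        total = max(self.epochs * steps_per_epoch, 1)
        opts = [Adam(trunk_params, lr=self.lr, total_steps=total)]
        if sel_params:
            # no decay here: the selection signal (which pixels stay hard)
            # only emerges as the classifier converges, so the head must
            # keep learning at full rate to the end
            opts.append(Adam(sel_params, lr=self.lr * self.select_lr_mult))
        self.history_ = []
        self.val_history_ = []
        n = X.shape[0]
        best = (-np.inf, None, -1)
        step = 0
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                xb, yb = X[idx], y[idx]
                self.model_.train_mode(True)
                if self.selective:
                    o, s, a = self.model_.murss_forward(xb[:, 0], xb[:, 1])
                    loss, comps = total_loss(o, s, a, yb, loss_cfg)
                else:
                    o = self.model_.muran_forward(xb[:, 0], xb[:, 1], return_probs=False)
                    from ._nn.autograd import cross_entropy_map

                    lmap = cross_entropy_map(o, yb, self.ignore_label, self.class_weights)
                    valid = (yb != self.ignore_label).astype(np.float64)
                    loss = (lmap * valid).sum() / max(valid.sum(), 1.0)
                    comps = {"l_total": loss.item(), "coverage": 1.0}
                if not np.isfinite(loss.item()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch} step {step}: {comps}"
                    )
                self.model_.zero_grad()
                loss.backward()
                for opt in opts:
                    opt.step()
                record = {"epoch": epoch, "step": step, **comps}
                self.history_.append(record)
                if log_callback is not None:
                    log_callback(record)
                step += 1
            if validation_data is not None:
                xv, yv = validation_data
                report = self.evaluate(xv, yv)
                miou = report.miou if np.isfinite(report.miou) else -np.inf
                self.val_history_.append(
                    {"epoch": epoch, "val_miou": report.miou,
                     "val_accuracy": report.accuracy,
                     "val_rejection": report.rejection_fraction}
                )
                if miou > best[0]:
                    best = (miou, self.model_.state_dict(), epoch)
        if validation_data is not None and best[1] is not None:
            self.model_.load_state_dict(best[1])
            self.best_epoch_ = best[2]
        else:
            self.best_epoch_ = self.epochs - 1
        return self

    # -- inference --------------------------------------------------------
    def _forward_batches(self, X, chunk=8):
        X = self._check_X(X)
        self.model_.train_mode(False)
        outs, sels = [], []
        for start in range(0, X.shape[0], chunk):
            xb = X[start : start + chunk]
            if self.selective:
                o, s, _ = self.model_.murss_forward(xb[:, 0], xb[:, 1])
                from ._nn.autograd import softmax

                probs = softmax(o, axis=1).data
                sel = s.data[:, 0]
            else:
                probs = self.model_.muran_forward(xb[:, 0], xb[:, 1]).data
                sel = np.ones(probs.shape[:1] + probs.shape[2:])
            outs.append(probs)
            sels.append(sel)
        return np.concatenate(outs), np.concatenate(sels)

    def predict_proba(self, X):
        """Per-pixel class probabilities, (n, 3, H, W)."""
        return self._forward_batches(X)[0]

    def predict(self, X):
        """Per-pixel argmax labels, (n, H, W)."""
        return self.predict_proba(X).argmax(axis=1)

    def selection_scores(self, X):
        """Per-pixel selection scores in [0, 1], (n, H, W)."""
        return self._forward_batches(X)[1]

    def predict_with_rejection(self, X, threshold: float | None = None):
        """Labels plus accept mask at the binarization threshold."""
        probs, sel = self._forward_batches(X)
        thr = self.threshold if threshold is None else threshold
        return probs.argmax(axis=1), select_pixels(sel, thr)

    def evaluate(self, X, y, threshold: float | None = None, mode="paper_table1",
                 per_unit=False, seed: int = 0):
        """Rejection-aware evaluation report against integer masks."""
        probs, sel = self._forward_batches(X)
        thr = self.threshold if threshold is None else threshold
        return evaluate_with_rejection(
            probs, sel, np.asarray(y), thr, mode=mode, per_unit=per_unit, seed=seed
        )

    def score(self, X, y):
        """Mean IoU over covered pixels (sklearn scorer convention)."""
        report = self.evaluate(X, y)
        return report.miou

    # -- persistence ------------------------------------------------------
    def save(self, path):
        """Write weights + full configuration to an .npz checkpoint."""
        import json

        state = self.model_.state_dict()
        meta = json.dumps(
            {"params": {k: v for k, v in self.get_params().items()
                        if not callable(v)},
             "model_config": self.config_.to_dict(),
             "best_epoch": getattr(self, "best_epoch_", None)}
        )
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **state)

    @classmethod
    def load(cls, path):
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        params = meta["params"]
        est = cls(**params)
        est.config_ = ModelConfig(**meta["model_config"])
        est.model_ = MurSSNet(est.config_)
        est.model_.load_state_dict(state)
        est.history_ = []
        est.best_epoch_ = meta.get("best_epoch")
        return est
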