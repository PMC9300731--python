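"""Training strategies: aggregated-loss MTL, alternating updates, MTL-IO.

Three step rules are implemented over the same gradient interface:

* ``vanilla_step``   - one update on the aggregated loss: all task
  gradients are evaluated at the same weights, summed with weights
  c^(k) (uniform by default), and applied through one shared optimizer.
* ``alternate_step`` - N sequential plain gradient-descent updates, task
  k differentiating at the intermediate weights left by task k-1.
* ``mtl_io_step``    - the alternating rule where each task's gradient
  is additionally transformed by that task's OWN moving-average
  optimizer (Adam by default).  The per-task accumulators see only that
  task's gradients, so no momentum or second-moment state ever mixes
  across tasks; with plain SGD as the per-task optimizer the rule
  degenerates bitwise to ``alternate_step``.

A "task" here is any callable ``fn(params, batch) -> (loss, grads)``
with ``params`` a dict of named arrays updated in place and ``grads`` a
dict over the parameters the task touches.  The scalar toy problems in
the test-suite and the full fundus network use the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import losses as L
from .model import MultiTaskNet
from .postprocess import (MAP_THRESHOLD, LogisticClassifier, compute_vcdr,
                          fit_logistic, largest_connected_component,
                          predict_images)

STRATEGIES = ("mtl_io", "mtl_alternate", "mtl_vanilla")


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite; training aborts loudly."""


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``strategy`` is one of ``mtl_io``, ``mtl_alternate``, ``mtl_vanilla``
    or ``stl:<task>``.  ``task_order`` defaults to (od, oc, fovea,
    glaucoma) restricted to the active tasks; one mini-batch is shared
    by all sub-steps of an iteration.  ``optimizer_kind`` ("adam" or
    "sgd") applies to the shared optimizer of the vanilla rule and to
    every per-task optimizer of MTL-IO; the alternating rule is plain
    gradient descent by definition.
    """

    strategy: str = "mtl_io"
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 8
    task_order: tuple | None = None
    seed: int = 0
    optimizer_kind: str = "adam"
    adam_betas: tuple = (0.9, 0.999)
    adam_eps: float = 1e-8
    loss_weights: dict = field(default_factory=dict)  # c^(k), default 1
    fovea_sigma: float | None = None  # default: losses.default_sigma(input_size)
    focal_gamma: float = 2.0
    l2_lambda: float = 1e-3  # vCDR logistic classifier regularization
    fit_vcdr_classifier: bool = True  # skip on intermediate phases of staged training

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        ok = self.strategy in STRATEGIES or (
            self.strategy.startswith("stl:") and self.strategy[4:] in ("od", "oc", "fovea", "glaucoma")
        )
        if not ok:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.optimizer_kind not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer_kind {self.optimizer_kind!r}")

    def weight(self, task: str) -> float:
        return float(self.loss_weights.get(task, 1.0))


# ---------------------------------------------------------------------------
# per-task optimizers


class SgdTransform:
    """Identity moving-average: the update direction is the raw gradient."""

    def transform(self, grads: dict) -> dict:
        return grads


@njit(cache=True)
def _adam_kernel(m, v, g, b1, b2, c1, c2, eps):
    # fused moment update + bias-corrected direction, written back into g
    for i in range(m.size):
        gi = g[i]
        m[i] = b1 * m[i] + (1.0 - b1) * gi
        v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
        g[i] = (m[i] / c1) / (math.sqrt(v[i] / c2) + eps)


class AdamTransform:
    """Adam's bias-corrected moving-average mechanism m-hat.

    Holds first/second moment accumulators and a step counter; the
    caller applies ``w -= eta * direction``.  The gradient arrays passed
    in are per-step temporaries and are overwritten with the direction.
    """

    def __init__(self, betas=(0.9, 0.999), eps=1e-8):
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def transform(self, grads: dict) -> dict:
        self.t += 1
        out = {}
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            m, v = self.m[name], self.v[name]
            if isinstance(g, np.ndarray) and g.ndim and g.flags.c_contiguous and g.dtype == m.dtype:
                _adam_kernel(m.ravel(), v.ravel(), g.ravel(), b1, b2, c1, c2, self.eps)
                out[name] = g
            else:  # 0-d toy problems and odd dtypes
                mm = b1 * m + (1 - b1) * g
                vv = b2 * v + (1 - b2) * g * g
                self.m[name], self.v[name] = mm, vv
                out[name] = (mm / c1) / (np.sqrt(vv / c2) + self.eps)
        return out


def make_optimizer(config: TrainConfig):
    if config.optimizer_kind == "sgd":
        return SgdTransform()
    return AdamTransform(betas=config.adam_betas, eps=config.adam_eps)


class OptimizerState:
    """One independent optimizer per task; accumulators never mix."""

    def __init__(self, tasks, config: TrainConfig):
        self.per_task = {t: make_optimizer(config) for t in tasks}

    def __getitem__(self, task: str):
        try:
            return self.per_task[task]
        except KeyError:
            raise KeyError(f"no optimizer state for task {task!r}") from None


def _check_finite(task: str, loss: float):
    if not math.isfinite(loss):
        raise TrainingDiverged(f"non-finite loss {loss!r} on task {task!r}")


def _apply(params: dict, direction: dict, eta: float):
    for name, d in direction.items():
        p = params[name]
        if isinstance(d, np.ndarray) and d.dtype == p.dtype and d.shape == p.shape:
            d *= eta  # directions are per-step temporaries; scale in place
            p -= d
        else:
            p -= np.asarray(eta * d, dtype=p.dtype)


def _order(config: TrainConfig, grad_fns: dict) -> tuple:
    order = config.task_order if config.task_order is not None else tuple(grad_fns)
    if set(order) != set(grad_fns) or len(order) != len(grad_fns):
        raise ValueError(f"task_order {order!r} must cover exactly the active tasks {tuple(grad_fns)!r}")
    return tuple(order)


# ---------------------------------------------------------------------------
# step rules


def vanilla_step(params: dict, batch, grad_fns: dict, config: TrainConfig, state) -> dict:
    """Single update on the aggregated loss sum_k c^(k) L^(k).

    Every task gradient is evaluated at the SAME weights; ``state`` is
    the one shared optimizer transform.
    """
    order = _order(config, grad_fns)
    total: dict = {}
    out = {}
    for task in order:
        loss, grads = grad_fns[task](params, batch)
        _check_finite(task, loss)
        out[task] = loss
        c = config.weight(task)
        for name, g in grads.items():
            total[name] = total.get(name, 0) + c * g
    _apply(params, state.transform(total), config.learning_rate)
    return out


def alternate_step(params: dict, batch, grad_fns: dict, config: TrainConfig) -> dict:
    """N sequential plain gradient-descent updates, one per task.

    Task k differentiates at the weights left by task k-1; the first
    task of an iteration sees the previous iteration's final weights.
    """
    order = _order(config, grad_fns)
    out = {}
    for task in order:
        loss, grads = grad_fns[task](params, batch)
        _check_finite(task, loss)
        out[task] = loss
        _apply(params, {n: config.weight(task) * g for n, g in grads.items()}, config.learning_rate)
    return out


def mtl_io_step(params: dict, batch, grad_fns: dict, config: TrainConfig, state: OptimizerState) -> dict:
    """Alternating updates with one independent optimizer per task.

    Identical to ``alternate_step`` except that task k's gradient passes
    through its own moving-average transform, whose memory involves only
    previous updates of task k.
    """
    order = _order(config, grad_fns)
    out = {}
    for task in order:
        loss, grads = grad_fns[task](params, batch)
        _check_finite(task, loss)
        out[task] = loss
        direction = state[task].transform({n: config.weight(task) * g for n, g in grads.items()})
        _apply(params, direction, config.learning_rate)
    return out


# ---------------------------------------------------------------------------
# analytic loss gradients with respect to head pre-activations


def _bce_logit_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    # d/dz of pixel-mean BCE through the sigmoid, averaged over the batch
    return (p - y) / p[0].size / p.shape[0]


def _l1_grad(p: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.sign(p - y) / p.shape[0]


def _focal_logit_grad(p: np.ndarray, y: np.ndarray, gamma: float) -> np.ndarray:
    # d/dz of -(1-p_t)^g log p_t through the sigmoid, per sample, batch-averaged
    pc = np.clip(p, L.EPS, 1 - L.EPS)
    pos = gamma * pc * (1 - pc) ** gamma * np.log(pc) - (1 - pc) ** (gamma + 1)
    neg = -gamma * (1 - pc) * pc**gamma * np.log(1 - pc) + pc ** (gamma + 1)
    return np.where(y == 1, pos, neg) / p.shape[0]


def make_task_grad_fns(model: MultiTaskNet, config: TrainConfig, stl: bool = False) -> dict:
    """Gradient callables for the model's active tasks.

    A batch is a dict with ``images`` plus the targets of the active
    tasks (``od``/``oc`` binary masks, ``fovea_target`` saliency maps,
    ``labels``).  The glaucoma gradient stays inside the dense branch
    under multi-task training and flows back into the encoder only for
    the glaucoma-only single-task model (otherwise nothing upstream of
    its head would ever train).
    """

    def map_fn(task):
        key = "fovea_target" if task == "fovea" else task

        def fn(params, batch):
            if key not in batch:
                raise KeyError(f"batch is missing target for active task {task!r}")
            out = model.forward(batch["images"])
            y = batch[key]
            if task == "fovea":
                p = out.fovea_map
                loss = L.l1_loss(p, y) / p.shape[0]
                dz = _l1_grad(p, y)
            else:
                p = getattr(out, f"{task}_map")
                loss = L.bce_loss(p, y)
                dz = _bce_logit_grad(p, y)
            model.zero_grad()
            model.backward_map_task(task, dz)
            return loss, model.grads()

        return fn

    def glaucoma_fn(params, batch):
        if "labels" not in batch:
            raise KeyError("batch is missing target for active task 'glaucoma'")
        out = model.forward(batch["images"], need_maps=False)
        p, y = out.glaucoma_prob, batch["labels"]
        loss = L.focal_loss(p, y, gamma=config.focal_gamma)
        dz = _focal_logit_grad(p, y, config.focal_gamma)
        model.zero_grad()
        model.backward_classifier(dz, into_encoder=stl)
        return loss, model.grads()

    fns = {}
    for t in model.config.tasks:
        target_key = {"od": "od", "oc": "oc", "fovea": "fovea_target", "glaucoma": "labels"}[t]
        fns[t] = glaucoma_fn if t == "glaucoma" else map_fn(t)
        fns[t].__name__ = f"grad_{t}"
        fns[t].target_key = target_key
    return fns


def _fused_vanilla_fn(model: MultiTaskNet, config: TrainConfig):
    """All task gradients from ONE forward pass (aggregated-loss rule)."""

    def fn(params, batch):
        out = model.forward(batch["images"])
        model.zero_grad()
        losses = {}
        for task in model.config.tasks:
            c = config.weight(task)
            if task == "od" or task == "oc":
                p = getattr(out, f"{task}_map")
                losses[task] = L.bce_loss(p, batch[task])
                model.backward_map_task(task, c * _bce_logit_grad(p, batch[task]))
            elif task == "fovea":
                p = out.fovea_map
                losses[task] = L.l1_loss(p, batch["fovea_target"]) / p.shape[0]
                model.backward_map_task(task, c * _l1_grad(p, batch["fovea_target"]))
            else:
                p = out.glaucoma_prob
                losses[task] = L.focal_loss(p, batch["labels"], gamma=config.focal_gamma)
                model.backward_classifier(c * _focal_logit_grad(p, batch["labels"], config.focal_gamma))
        return losses, model.grads()

    return fn


# ---------------------------------------------------------------------------
# the epoch loop


@dataclass
class TrainResult:
    model: MultiTaskNet
    history: list            # per-epoch dict: task -> mean loss
    logistic: LogisticClassifier | None
    config: TrainConfig


def _batch_targets(dataset, fovea_target_maps):
    def make(idx):
        b = {"images": dataset.images[idx]}
        if dataset.od_masks is not None:
            b["od"] = dataset.od_masks[idx].astype(np.float32)
            b["oc"] = dataset.oc_masks[idx].astype(np.float32)
        if fovea_target_maps is not None:
            b["fovea_target"] = fovea_target_maps[idx]
        if dataset.labels is not None:
            b["labels"] = dataset.labels[idx].astype(np.float32)
        return b

    return make


def train(model: MultiTaskNet, dataset, config: TrainConfig) -> TrainResult:
    """Run seeded epochs of shuffled mini-batches under the chosen rule.

    After the epochs finish, the vCDR logistic classifier is fitted on
    the training-set segmentation predictions (it is a second, separate
    classifier, not trained jointly).  Returns the per-epoch loss
    history alongside the trained model.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    stl = config.strategy.startswith("stl:")
    active = (config.strategy[4:],) if stl else model.config.tasks
    if stl and active[0] not in model.config.tasks:
        raise ValueError(f"model has no head for {active[0]!r}")

    sigma = config.fovea_sigma or L.default_sigma(model.config.input_size)
    fovea_maps = None
    if "fovea" in active and dataset.fovea is not None:
        size = model.config.input_size
        fovea_maps = np.stack([
            L.make_fovea_map(L.SaliencyMapSpec(x, y, sigma, size, size)).astype(np.float32)
            for x, y in dataset.fovea
        ])
    make_batch = _batch_targets(dataset, fovea_maps)

    all_fns = make_task_grad_fns(model, config, stl=stl)
    grad_fns = {t: all_fns[t] for t in active}
    params = {name: p.data for name, p in model.params.items()}
    cfg = config if config.task_order is not None else replace(config, task_order=tuple(active))

    state = None
    fused = None
    if config.strategy == "mtl_vanilla" or stl:
        state = make_optimizer(config)
        fused = _fused_vanilla_fn(model, cfg) if not stl else None
    elif config.strategy == "mtl_io":
        state = OptimizerState(active, config)

    rng = np.random.default_rng(config.seed)
    history = []
    n = len(dataset)
    for _ in range(config.epochs):
        order = rng.permutation(n)
        sums = {t: 0.0 for t in active}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            batch = make_batch(idx)
            if config.strategy == "mtl_io":
                losses = mtl_io_step(params, batch, grad_fns, cfg, state)
            elif config.strategy == "mtl_alternate":
                losses = alternate_step(params, batch, grad_fns, cfg)
            elif config.strategy == "mtl_vanilla":
                losses, grads = fused(params, batch)
                for t, v in losses.items():
                    _check_finite(t, v)
                _apply(params, state.transform(grads), config.learning_rate)
            else:  # stl:<task>
                losses = vanilla_step(params, batch, grad_fns, cfg, state)
            for t, v in losses.items():
                sums[t] += v
            n_batches += 1
        history.append({t: sums[t] / n_batches for t in active})

    logistic = None
    if (
        config.fit_vcdr_classifier
        and "glaucoma" in active
        and dataset.od_masks is not None
        and dataset.labels is not None
        and len(np.unique(dataset.labels)) == 2
        and "od" in model.config.tasks
    ):
        preds = predict_images(model, dataset.images, batch_size=config.batch_size)
        vcdrs = []
        import warnings as _w
        for i in range(n):
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                od = largest_connected_component(preds["od_map"][i] >= MAP_THRESHOLD)
                oc = largest_connected_component(preds["oc_map"][i] >= MAP_THRESHOLD)
            rec = compute_vcdr(od, oc)
            vcdrs.append(0.0 if rec.od_empty else rec.vcdr)
        logistic = fit_logistic(vcdrs, dataset.labels, l2_lambda=config.l2_lambda)

    return TrainResult(model=model, history=history, logistic=logistic, config=config)


def kfold_splits(item_ids, k: int, seed: int) -> list:
    """Deterministic shuffled partition into k near-equal validation folds."""
    ids = list(item_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(ids):
        raise ValueError(f"k={k} exceeds the {len(ids)} available items")
    perm = np.random.default_rng(seed).permutation(len(ids))
    folds = np.array_split(perm, k)
    out = []
    for f in folds:
        val = set(f.tolist())
        out.append((
            [ids[i] for i in perm if i not in val],
            [ids[i] for i in f],
        ))
    return out
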